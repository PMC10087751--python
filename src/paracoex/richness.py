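"""Accumulation-curve power-law estimation of total parasite richness.

Parasite richness P is assumed to scale with host richness H as a power
law, P = b * H**z. For each parasite group the observed network yields a
host-accumulation curve: hosts with records are taken in random order and
the cumulative count of distinct parasite species is recorded at every
prefix length. Bootstrapping over orderings gives a cloud of curves; a
bounded nonlinear least-squares fit per curve gives replicate (b, z)
draws; medians summarise the fit and percentiles carry the uncertainty
into the extrapolated richness at the full host pool.

z near 1 marks a specialist-dominated fauna (each new host brings new
parasites), z near 0 a generalist-dominated one.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammaln

from ._util import round_half_away
from .data_model import AssociationDataset, ParasiteGroup
from .errors import ComputationError, UsageError

__all__ = [
    "AccumulationReplicate",
    "PowerLawFit",
    "RichnessPrediction",
    "build_accumulation_replicates",
    "expected_accumulation",
    "fit_power_law",
    "fit_group",
    "extrapolate_richness",
    "undescribed_percent",
]

Z_BOUNDS = (0.0, 2.0)  # keeps runaway exponents off tiny noisy curves
FIT_TOL = 1e-8
MAX_NFEV = 500


def _percentile_band(values: np.ndarray, axis=None) -> tuple:
    """2.5/97.5 percentile band using nearest-outside order statistics.

    With few replicates this returns the extreme draws themselves rather
    than interpolating inside them, so the band never understates the
    replicate spread.
    """
    lo = np.percentile(values, 2.5, method="lower", axis=axis)
    hi = np.percentile(values, 97.5, method="higher", axis=axis)
    if axis is None:
        return float(lo), float(hi)
    return lo, hi


@dataclass(frozen=True)
class AccumulationReplicate:
    """One random host ordering: cumulative distinct parasites at each prefix."""

    replicate_id: int
    cumulative_richness: np.ndarray  # P at h = 1..H_obs

    @property
    def points(self) -> list[tuple[int, int]]:
        return [(h + 1, int(p)) for h, p in enumerate(self.cumulative_richness)]

    @property
    def n_hosts(self) -> int:
        return len(self.cumulative_richness)


@dataclass(frozen=True)
class PowerLawFit:
    """Replicate-wise power-law coefficients for one parasite group.

    ``b_hat``/``z_hat`` are coordinate-wise medians of the replicate
    parameters. A plug-in fit built from bare coefficients carries a single
    degenerate replicate so downstream percentile machinery still applies.
    """

    b_hat: float
    z_hat: float
    replicate_params: np.ndarray  # shape (n_boot, 2), columns (b, z)
    group: Optional[ParasiteGroup] = None
    seed: Optional[int] = None
    n_hosts_fit: Optional[int] = None

    @property
    def n_boot(self) -> int:
        return len(self.replicate_params)

    @property
    def replicate_b(self) -> np.ndarray:
        return self.replicate_params[:, 0]

    @property
    def replicate_z(self) -> np.ndarray:
        return self.replicate_params[:, 1]

    @classmethod
    def from_coefficients(
        cls, b: float, z: float, group: Optional[ParasiteGroup] = None
    ) -> "PowerLawFit":
        if b <= 0:
            raise UsageError("power-law coefficient b must be positive")
        return cls(
            b_hat=float(b),
            z_hat=float(z),
            replicate_params=np.array([[b, z]], dtype=float),
            group=group,
        )


@dataclass(frozen=True)
class RichnessPrediction:
    """Extrapolated total richness for one group (one summary-table row)."""

    group: Optional[ParasiteGroup]
    h_total: int
    observed_richness: int
    point_estimate: float
    ci_low: float
    ci_high: float
    rounded_estimate: int
    undescribed_percent: int


def _group_incidence(ds: AssociationDataset, group: ParasiteGroup):
    """Boolean hosts-with-records x parasites incidence matrix for one group."""
    recs = ds.group_records(group)
    if not recs:
        raise ComputationError(f"no records for group {group.value!r}")
    hosts = sorted({r.host for r in recs})
    parasites = sorted({r.parasite for r in recs})
    hi = {h: i for i, h in enumerate(hosts)}
    pi = {p: j for j, p in enumerate(parasites)}
    M = np.zeros((len(hosts), len(parasites)), dtype=bool)
    for r in recs:
        M[hi[r.host], pi[r.parasite]] = True
    return M, hosts, parasites


def build_accumulation_replicates(
    ds: AssociationDataset,
    group: Union[ParasiteGroup, str],
    n_boot: int,
    seed: int,
) -> list[AccumulationReplicate]:
    """Bootstrap host-accumulation curves for one parasite group.

    Each replicate draws an independent uniform permutation of the group's
    hosts-with-records and records the cumulative number of distinct
    parasite species at every prefix length 1..H_obs. Deterministic under a
    fixed seed.
    """
    group = ParasiteGroup(group)
    if n_boot < 1:
        raise UsageError("n_boot must be >= 1")
    M, hosts, _ = _group_incidence(ds, group)
    if len(hosts) < 2:
        raise ComputationError(
            f"group {group.value!r} has {len(hosts)} host(s) with records; need >= 2"
        )
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_boot):
        perm = rng.permutation(len(hosts))
        cum = np.maximum.accumulate(M[perm], axis=0).sum(axis=1)
        out.append(AccumulationReplicate(i, cum.astype(np.int64)))
    return out


def expected_accumulation(ds: AssociationDataset, group: Union[ParasiteGroup, str]) -> np.ndarray:
    """Exact expected accumulation curve under uniform host orderings.

    E[P(h)] = sum over parasites of 1 - C(H - r, h)/C(H, h) with r the
    parasite's host range among the H hosts-with-records: the chance the
    parasite is hit by a uniform h-subset of hosts, summed over parasites.
    """
    group = ParasiteGroup(group)
    M, hosts, _ = _group_incidence(ds, group)
    H = len(hosts)
    ranges = M.sum(axis=0)
    h = np.arange(1, H + 1)
    expect = np.zeros(H)
    for r in ranges:
        miss = np.zeros(H)
        valid = h <= H - r
        if valid.any():
            hv = h[valid]
            miss[valid] = np.exp(
                (gammaln(H - r + 1) - gammaln(hv + 1) - gammaln(H - r - hv + 1))
                - (gammaln(H + 1) - gammaln(hv + 1) - gammaln(H - hv + 1))
            )
        expect += 1.0 - miss
    return expect


def _fit_single_curve(h: np.ndarray, P: np.ndarray) -> tuple[float, float, bool]:
    """Fit P = b * h**z to one curve; returns (b, z, converged)."""
    if np.ptp(P) == 0:
        # degenerate constant curve: exactly representable with z = 0
        return float(P[0]), 0.0, True
    pos = P > 0
    slope, intercept = np.polyfit(np.log(h[pos]), np.log(P[pos]), 1)
    z0 = float(np.clip(slope, *Z_BOUNDS))
    b0 = float(np.clip(np.exp(intercept), 1e-9, 1e9))
    res = least_squares(
        lambda th: th[0] * np.power(h, th[1]) - P,
        x0=[b0, z0],
        bounds=([1e-12, Z_BOUNDS[0]], [np.inf, Z_BOUNDS[1]]),
        xtol=FIT_TOL,
        ftol=FIT_TOL,
        gtol=FIT_TOL,
        max_nfev=MAX_NFEV,
    )
    return float(res.x[0]), float(res.x[1]), bool(res.success)


def fit_power_law(
    replicates: Sequence[AccumulationReplicate],
    group: Optional[ParasiteGroup] = None,
    seed: Optional[int] = None,
    max_failure_fraction: float = 0.10,
) -> PowerLawFit:
    """Fit P = b * h**z to every accumulation replicate; summarise by medians.

    Each replicate is fitted by bounded nonlinear least squares (b > 0,
    z in [0, 2]) initialised from the log-log least-squares line. More than
    ``max_failure_fraction`` non-convergent replicates is an error.
    """
    if not replicates:
        raise UsageError("fit_power_law needs at least one replicate")
    params = np.empty((len(replicates), 2))
    failures = 0
    for i, rep in enumerate(replicates):
        P = np.asarray(rep.cumulative_richness, dtype=float)
        if P.size < 2:
            raise UsageError("each replicate needs at least 2 points")
        h = np.arange(1, P.size + 1, dtype=float)
        b, z, ok = _fit_single_curve(h, P)
        params[i] = (b, z)
        failures += not ok
    frac = failures / len(replicates)
    if frac > max_failure_fraction:
        raise ComputationError(
            f"power-law fit failed to converge in {frac:.0%} of replicates"
        )
    return PowerLawFit(
        b_hat=float(np.median(params[:, 0])),
        z_hat=float(np.median(params[:, 1])),
        replicate_params=params,
        group=group,
        seed=seed,
        n_hosts_fit=int(replicates[0].n_hosts),
    )


def fit_group(
    ds: AssociationDataset,
    group: Union[ParasiteGroup, str],
    n_boot: int = 1000,
    seed: int = 0,
) -> PowerLawFit:
    """Convenience: bootstrap accumulation curves for a group and fit them."""
    group = ParasiteGroup(group)
    reps = build_accumulation_replicates(ds, group, n_boot=n_boot, seed=seed)
    return fit_power_law(reps, group=group, seed=seed)


def extrapolate_richness(
    fit_or_coeffs: Union[PowerLawFit, tuple[float, float]],
    h_total: int,
    observed_richness: int,
) -> RichnessPrediction:
    """Evaluate the fitted power law at the full host-pool size.

    With a bootstrap fit, the point estimate is the median of the replicate
    predictions b_i * h_total**z_i and the CI their 2.5/97.5 percentiles;
    with bare (b, z) coefficients the plug-in value is returned with a
    degenerate CI. Counts are rounded half away from zero.
    """
    if h_total < 1:
        raise UsageError("h_total must be >= 1")
    if isinstance(fit_or_coeffs, PowerLawFit):
        fit = fit_or_coeffs
    else:
        b, z = fit_or_coeffs
        fit = PowerLawFit.from_coefficients(b, z)
    if fit.n_hosts_fit is not None and h_total < fit.n_hosts_fit:
        warnings.warn(
            f"h_total={h_total} below the {fit.n_hosts_fit} hosts used for "
            "fitting; interpolating rather than extrapolating",
            stacklevel=2,
        )
    preds = fit.replicate_b * np.power(float(h_total), fit.replicate_z)
    point = float(np.median(preds))
    lo, hi = (float(q) for q in np.percentile(preds, [2.5, 97.5]))
    rounded = round_half_away(point)
    return RichnessPrediction(
        group=fit.group,
        h_total=int(h_total),
        observed_richness=int(observed_richness),
        point_estimate=point,
        ci_low=lo,
        ci_high=hi,
        rounded_estimate=rounded,
        undescribed_percent=undescribed_percent(observed_richness, point),
    )


def undescribed_percent(observed: int, predicted: float) -> int:
    """Percentage of the predicted fauna not yet described, as a whole number.

    100 * (predicted - observed) / predicted, rounded half away from zero;
    an observed count exceeding the prediction clamps to 0 with a warning
    (it signals curve misfit, not negative undescribed diversity).
    """
    if predicted <= 0:
        raise ComputationError("predicted richness must be positive")
    if observed < 0:
        raise UsageError("observed richness cannot be negative")
    if observed > predicted:
        if observed - predicted < 1e-6 * max(1.0, observed):
            return 0  # exact-fit boundary up to float noise
        warnings.warn(
            f"observed richness {observed} exceeds predicted {predicted:.2f}; "
            "clamping undescribed percentage to 0",
            stacklevel=2,
        )
        return 0
    return round_half_away(100.0 * (predicted - observed) / predicted)
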