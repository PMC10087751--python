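"""Coextinction projection: parasite loss under random host extinction.

If richness scales as P = b * H**z and a proportion p of hosts is lost in
random order, the surviving richness is b * ((1-p) H)**z, so the expected
proportion of parasite species lost is

    1 - (1 - p)**z

independent of b. Scenario evaluation plugs in the host-loss proportion
implied by the threat registry (all EN hosts, or all EN + TH hosts);
uncertainty comes from the bootstrap replicate draws of z. A Monte-Carlo
host-removal simulation on the observed network serves as an independent
check of the closed form.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from ._util import round_half_away
from .data_model import AssociationDataset, ParasiteGroup, Scenario
from .errors import ComputationError, UsageError
from .richness import PowerLawFit, RichnessPrediction, _percentile_band

__all__ = [
    "ExtinctionScenario",
    "CoextinctionEstimate",
    "CoextinctionCurve",
    "MonteCarloResult",
    "proportion_extinct",
    "coextinction_curve",
    "evaluate_scenario",
    "aggregate_total",
    "monte_carlo_host_removal",
]


@dataclass(frozen=True)
class ExtinctionScenario:
    """A host-extinction scenario: its name and the proportion of hosts lost."""

    name: str
    p_host: float

    def __post_init__(self):
        if not 0.0 <= self.p_host <= 1.0:
            raise UsageError(f"p_host must lie in [0, 1], got {self.p_host}")


@dataclass(frozen=True)
class CoextinctionEstimate:
    """Projected parasite loss for one group under one scenario."""

    group: Optional[ParasiteGroup]
    scenario: ExtinctionScenario
    proportion_extinct: float
    ci_low: float
    ci_high: float
    species_extinct: float
    rounded_species: int

    @property
    def percent(self) -> float:
        """Percentage lost, reported to 1 decimal place."""
        return round(100.0 * self.proportion_extinct, 1)


@dataclass(frozen=True)
class CoextinctionCurve:
    """Parasite loss as a function of host loss, with a 95% replicate band."""

    group: Optional[ParasiteGroup]
    grid: np.ndarray
    mean_line: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


@dataclass(frozen=True)
class MonteCarloResult:
    proportion: float
    se: float
    n_reps: int


def proportion_extinct(p_host: float, z: float) -> float:
    """Expected proportion of parasites lost when a fraction p_host of hosts goes.

    1 - (1 - p_host)**z; b cancels between surviving and total richness.
    Convex in p_host for 0 < z < 1: loss starts slow (generalists persist
    on remaining hosts) and accelerates as the pool empties.
    """
    if not 0.0 <= p_host <= 1.0:
        raise UsageError(f"p_host must lie in [0, 1], got {p_host}")
    if z < 0:
        raise UsageError(f"z must be nonnegative, got {z}")
    return float(1.0 - (1.0 - p_host) ** z)


def coextinction_curve(fit: PowerLawFit, grid_size: int = 101) -> CoextinctionCurve:
    """Evaluate the loss curve on an even p-grid including the endpoints.

    The mean line uses the median exponent z_hat; the band is the 2.5/97.5
    percentile of 1 - (1-p)**z over the replicate z draws at each grid
    point.
    """
    if grid_size < 2:
        raise UsageError("grid_size must be >= 2")
    p = np.linspace(0.0, 1.0, grid_size)
    zs = fit.replicate_z
    surv = np.power.outer(1.0 - p, zs)  # (grid, n_boot)
    losses = 1.0 - surv
    lo, hi = _percentile_band(losses, axis=1)
    return CoextinctionCurve(
        group=fit.group,
        grid=p,
        mean_line=1.0 - (1.0 - p) ** fit.z_hat,
        ci_low=lo,
        ci_high=hi,
    )


def evaluate_scenario(
    fit: PowerLawFit,
    prediction: RichnessPrediction,
    scenario: ExtinctionScenario,
) -> CoextinctionEstimate:
    """Project one group's loss under one scenario.

    The proportion uses z_hat; the CI the replicate z draws; absolute
    species losses multiply the proportion by the unrounded predicted
    richness and round half away from zero only for display.
    """
    if prediction is None:
        raise UsageError("evaluate_scenario needs a RichnessPrediction for the group")
    p = scenario.p_host
    prop = proportion_extinct(p, fit.z_hat)
    losses = 1.0 - (1.0 - p) ** fit.replicate_z
    lo, hi = _percentile_band(losses)
    species = prop * prediction.point_estimate
    return CoextinctionEstimate(
        group=fit.group,
        scenario=scenario,
        proportion_extinct=prop,
        ci_low=lo,
        ci_high=hi,
        species_extinct=species,
        rounded_species=round_half_away(species),
    )


def aggregate_total(
    estimates: Sequence[CoextinctionEstimate],
    predictions: Sequence[RichnessPrediction],
) -> CoextinctionEstimate:
    """Pool per-group estimates into a total, weighting by predicted richness.

    total proportion = sum_g proportion_g * predicted_g / sum_g predicted_g
    on unrounded predictions; total species lost is the sum of unrounded
    per-group losses. CIs pool the per-group bounds with the same weights.
    """
    if len(estimates) != len(predictions):
        raise UsageError("estimates and predictions must cover the same groups")
    for est, pred in zip(estimates, predictions):
        if est.group != pred.group:
            raise UsageError(
                f"group mismatch: estimate {est.group} vs prediction {pred.group}"
            )
    if not estimates:
        raise UsageError("nothing to aggregate")
    scenarios = {e.scenario.name for e in estimates}
    if len(scenarios) > 1:
        raise UsageError(f"cannot aggregate across scenarios: {sorted(scenarios)}")
    w = np.array([p.point_estimate for p in predictions])
    props = np.array([e.proportion_extinct for e in estimates])
    los = np.array([e.ci_low for e in estimates])
    his = np.array([e.ci_high for e in estimates])
    total_prop = float(np.average(props, weights=w))
    species = float(np.sum(props * w))
    return CoextinctionEstimate(
        group=None,
        scenario=estimates[0].scenario,
        proportion_extinct=total_prop,
        ci_low=float(np.average(los, weights=w)),
        ci_high=float(np.average(his, weights=w)),
        species_extinct=species,
        rounded_species=round_half_away(species),
    )


def monte_carlo_host_removal(
    ds: AssociationDataset,
    group: Union[ParasiteGroup, str],
    p_host: float,
    n_reps: int,
    seed: int,
    pool: str = "all",
) -> MonteCarloResult:
    """Simulate random host removal on the observed network.

    Per replicate, round(p_host * H) hosts are removed uniformly at random
    from the host pool (``pool="all"``: every registered host, matching the
    extrapolated interpretation; ``pool="recorded"``: only the group's
    hosts with records). A parasite goes extinct when every host it was
    recorded in is removed. Returns the mean extinct fraction and its
    Monte-Carlo standard error.
    """
    group = ParasiteGroup(group)
    if n_reps < 1:
        raise UsageError("n_reps must be >= 1")
    if not 0.0 <= p_host <= 1.0:
        raise UsageError(f"p_host must lie in [0, 1], got {p_host}")
    recs = ds.group_records(group)
    if not recs:
        raise ComputationError(f"no records for group {group.value!r}")
    if pool == "all":
        hosts = sorted(ds.hosts)
    elif pool == "recorded":
        hosts = sorted({r.host for r in recs})
    else:
        raise UsageError(f"pool must be 'all' or 'recorded', got {pool!r}")
    parasites = sorted({r.parasite for r in recs})
    hi = {h: i for i, h in enumerate(hosts)}
    M = np.zeros((len(parasites), len(hosts)), dtype=bool)
    for r in recs:
        M[parasites.index(r.parasite), hi[r.host]] = True
    H = len(hosts)
    k = round_half_away(p_host * H)
    rng = np.random.default_rng(seed)
    fractions = np.empty(n_reps)
    for i in range(n_reps):
        keep = np.ones(H, dtype=bool)
        keep[rng.choice(H, size=k, replace=False)] = False
        survives = M[:, keep].any(axis=1)
        fractions[i] = 1.0 - survives.mean()
    mean = float(fractions.mean())
    se = float(fractions.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else float("nan")
    return MonteCarloResult(proportion=mean, se=se, n_reps=n_reps)
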