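"""Descriptive comparisons on the association network.

Covers the host-centric view (parasite richness per host species), the
parasite-centric view (host range per parasite species), rank tests
between regions and between parasite groups, the log-log regression of
host range on total observation effort with its isometry diagnostic, and
the specialist-richness comparison between threatened and non-threatened
hosts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Union

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data_model import (
    AssociationDataset,
    ParasiteGroup,
    Region,
    ThreatClass,
)
from .errors import ComputationError, UsageError

__all__ = [
    "MarginalAxis",
    "MarginalCounts",
    "RankTestResult",
    "LogLogFit",
    "marginal_counts",
    "kruskal_wallis",
    "range_vs_observations_fit",
    "specialist_richness_by_threat",
]


class MarginalAxis(str, Enum):
    PER_HOST_RICHNESS = "per_host_richness"
    PER_PARASITE_HOST_RANGE = "per_parasite_host_range"


@dataclass(frozen=True)
class MarginalCounts:
    """Marginal totals of the bipartite network along one axis."""

    axis: MarginalAxis
    entries: dict[str, int]
    grouping: Optional[str] = None

    @property
    def values(self) -> np.ndarray:
        return np.asarray(list(self.entries.values()), dtype=float)

    def mean(self) -> float:
        return float(self.values.mean())

    def se(self) -> float:
        """Standard error of the mean (SD with n-1 denominator over sqrt n)."""
        v = self.values
        if v.size < 2:
            return float("nan")
        return float(v.std(ddof=1) / math.sqrt(v.size))


@dataclass(frozen=True)
class RankTestResult:
    """Kruskal-Wallis omnibus result: H is chi-square distributed under H0."""

    statistic: float
    df: int
    p_value: float
    group_sizes: tuple[int, ...]


@dataclass(frozen=True)
class LogLogFit:
    """OLS of log10(host range) on log10(total observations), one point per parasite.

    ``ci_low``/``ci_high`` bound the 95% pointwise confidence band of the
    mean line at each observed x. Because every association carries at
    least one observation, a parasite's total observations can never fall
    below its host range; ``above_isometry`` is True when the whole 95%
    band is strictly separated from the 1:1 line on the repeat-observation
    side (observations exceeding host range at every observed x) — the
    signature of parasites being observed repeatedly within the same
    hosts. Plotted with observations on the y axis this is the band lying
    above the isometry line.
    """

    slope: float
    intercept: float
    x: np.ndarray
    fitted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_points: int
    above_isometry: bool


def marginal_counts(
    ds: AssociationDataset,
    axis: Union[MarginalAxis, str],
    region: Optional[Region] = None,
    group: Optional[ParasiteGroup] = None,
) -> MarginalCounts:
    """Count distinct partners per taxon along one side of the network.

    PER_HOST_RICHNESS: distinct parasite species per host *with records*
    (hosts without records are excluded, so means are over recorded hosts).
    PER_PARASITE_HOST_RANGE: distinct host species per recorded parasite.
    """
    axis = MarginalAxis(axis)
    recs = ds.restrict(region).records
    if group is not None:
        group = ParasiteGroup(group)
        recs = tuple(r for r in recs if ds.parasites[r.parasite].group == group)
    if not recs:
        raise ComputationError(
            "no records after restriction (region="
            f"{region.value if region else None}, "
            f"group={group.value if group else None})"
        )
    entries: dict[str, set] = {}
    for r in recs:
        if axis is MarginalAxis.PER_HOST_RICHNESS:
            entries.setdefault(r.host, set()).add(r.parasite)
        else:
            entries.setdefault(r.parasite, set()).add(r.host)
    label = "/".join(str(x.value) for x in (region, group) if x is not None) or None
    return MarginalCounts(
        axis=axis,
        entries={k: len(v) for k, v in sorted(entries.items())},
        grouping=label,
    )


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> RankTestResult:
    """Kruskal-Wallis rank test on two or more groups.

    H uses midranks with the standard tie correction; the p-value comes
    from the chi-square upper tail with k-1 degrees of freedom. A pooled
    sample in which every value is identical gives H = 0, p = 1 by
    convention rather than an error.
    """
    if len(samples) < 2:
        raise UsageError("kruskal_wallis needs at least 2 groups")
    groups = [np.asarray(s, dtype=float) for s in samples]
    if any(g.size == 0 for g in groups):
        raise UsageError("kruskal_wallis groups must be nonempty")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise UsageError("kruskal_wallis needs a total sample size of at least 3")
    df = len(groups) - 1
    if np.ptp(pooled) == 0:
        return RankTestResult(0.0, df, 1.0, tuple(g.size for g in groups))
    h, p = stats.kruskal(*groups)
    return RankTestResult(float(h), df, float(p), tuple(g.size for g in groups))


def range_vs_observations_fit(
    ds: AssociationDataset, region: Optional[Region] = None
) -> LogLogFit:
    """Fit log10(host range) against log10(total observations) across parasites.

    Each parasite contributes one point: its distinct-host count against the
    sum of its per-association observation counts. Under one-observation-
    per-association the points sit exactly on the isometry line; repeated
    within-host observation pushes them below it on the y axis (equivalently,
    the observation axis runs ahead of the range axis).
    """
    recs = ds.restrict(region).records
    totals: dict[str, int] = {}
    hosts: dict[str, set] = {}
    for r in recs:
        totals[r.parasite] = totals.get(r.parasite, 0) + r.n_observations
        hosts.setdefault(r.parasite, set()).add(r.host)
    if len(totals) < 3:
        raise ComputationError(
            f"range_vs_observations_fit needs >= 3 parasites, got {len(totals)}"
        )
    names = sorted(totals)
    x = np.log10([totals[n] for n in names])
    y = np.log10([len(hosts[n]) for n in names])
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X).summary_frame(alpha=0.05)
    ci_low = pred["mean_ci_lower"].to_numpy()
    ci_high = pred["mean_ci_upper"].to_numpy()
    return LogLogFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        x=x,
        fitted=pred["mean"].to_numpy(),
        ci_low=ci_low,
        ci_high=ci_high,
        n_points=len(names),
        above_isometry=bool(np.all(ci_high < x)),
    )


def specialist_richness_by_threat(
    ds: AssociationDataset, max_range_for_specialist: int = 1
) -> RankTestResult:
    """Compare specialist-parasite richness between threatened and other hosts.

    A parasite is a specialist when its global host range (over the whole
    dataset) is at most ``max_range_for_specialist``. Each host with records
    contributes its count of specialist parasites; threatened hosts (threat
    class EN or TH) are compared against non-threatened assessed hosts with
    :func:`kruskal_wallis`. If host threat is assigned independently of
    parasite load the test should be null-distributed.
    """
    ranges = marginal_counts(ds, MarginalAxis.PER_PARASITE_HOST_RANGE).entries
    specialists = {p for p, r in ranges.items() if r <= max_range_for_specialist}
    per_host: dict[str, int] = {h: 0 for h in ds.hosts_with_records}
    for r in ds.records:
        if r.parasite in specialists:
            per_host[r.host] += 1
    threatened, other = [], []
    for h, count in sorted(per_host.items()):
        cls = ds.hosts[h].threat_class
        if cls in (ThreatClass.EN, ThreatClass.TH):
            threatened.append(count)
        elif cls is ThreatClass.NOT_THREATENED:
            other.append(count)
    if not threatened or not other:
        raise ComputationError(
            "need at least one threatened and one non-threatened host with records"
        )
    return kruskal_wallis([threatened, other])
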