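"""Synthetic host-parasite network generator.

Emulates the statistical structure the analysis assumes: a host pool of
which only a fraction has been sampled, four parasite groups with
group-specific host-range distributions (generalist aspidogastreans,
specialist digeneans and ciliates, mildly generalist mites), repeat
within-host observation effort, detection thinning (missing links), and
host threat labels assigned independently of parasite load.

The default configuration mirrors the study system: 295 hosts of which
128 are sampled, 96 parasites split 5/25/58/8 across the four groups,
mean observation effort 3 per association, and roughly a quarter of
assessed hosts endangered.

Beyond fixed, geometric and truncated-zeta host-range distributions, the
``POWER_LAW`` distribution designs a host-range *multiset* whose exact
expected accumulation curve equals b * h**z for a requested exponent z
(solved by nonnegative least squares against the hypergeometric presence
probabilities), which makes parameter-recovery experiments possible with
a known ground truth.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from functools import lru_cache
from typing import Optional, Union

import numpy as np
from scipy.optimize import nnls
from scipy.special import gammaln

from .data_model import (
    AssociationDataset,
    AssociationRecord,
    HostTaxon,
    ParasiteGroup,
    ParasiteTaxon,
    Region,
    ThreatScheme,
    ThreatStatus,
)
from .errors import ConfigurationError

__all__ = [
    "RangeDistribution",
    "GroupSpec",
    "SyntheticConfig",
    "power_law_ranges",
    "generate_network",
    "generate_observation_effort",
    "simulate_dataset",
    "default_study_config",
]


class RangeDistribution(str, Enum):
    FIXED = "fixed"
    GEOMETRIC = "geometric"
    TRUNCATED_ZETA = "truncated_zeta"
    POWER_LAW = "power_law"


@dataclass(frozen=True)
class GroupSpec:
    """Host-range model for one parasite group.

    range_params by distribution: FIXED {"r": int}; GEOMETRIC
    {"mean": float >= 1}; TRUNCATED_ZETA {"alpha": float > 1}; POWER_LAW
    {"z": float in (0, 1]} (accumulation-curve exponent).
    """

    n_parasites: int
    range_distribution: RangeDistribution
    range_params: dict

    def __post_init__(self):
        if self.n_parasites < 1:
            raise ConfigurationError("each group needs n_parasites >= 1")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one synthetic dataset."""

    seed: int
    n_hosts: int = 295
    fraction_hosts_sampled: float = 128 / 295
    groups: dict[str, GroupSpec] = field(default_factory=lambda: _default_groups())
    effort_mean: float = 3.0
    detection_prob: float = 1.0
    threat_proportions: dict[str, float] = field(
        default_factory=lambda: {"EN": 0.26, "TH": 0.07, "excluded": 0.0}
    )
    prop_us: float = 279 / 295

    def __post_init__(self):
        if not 0.0 < self.fraction_hosts_sampled <= 1.0:
            raise ConfigurationError("fraction_hosts_sampled must lie in (0, 1]")
        if self.effort_mean < 1.0:
            raise ConfigurationError("effort_mean must be >= 1")
        if not 0.0 < self.detection_prob <= 1.0:
            raise ConfigurationError("detection_prob must lie in (0, 1]")
        tp = self.threat_proportions
        if any(v < 0 for v in tp.values()) or sum(tp.values()) > 1.0 + 1e-12:
            raise ConfigurationError("threat proportions must be >= 0 and sum to <= 1")
        if not self.groups:
            raise ConfigurationError("at least one parasite group is required")

    @property
    def n_sampled(self) -> int:
        return max(1, round(self.fraction_hosts_sampled * self.n_hosts))

    def to_dict(self) -> dict:
        d = asdict(self)
        for name, g in d["groups"].items():
            g["range_distribution"] = self.groups[name].range_distribution.value
        return d


def _default_groups() -> dict[str, GroupSpec]:
    """Study-shaped group mix: 96 parasites, 5/25/58/8 across the four groups.

    Aspidogastreans are broad generalists (geometric, mean 30 hosts);
    digeneans and ciliates are specialists (zeta alpha 2, median range 1);
    mites sit between (zeta alpha 1.5, median range 2).
    """
    return {
        ParasiteGroup.ASPIDOGASTREAN.value: GroupSpec(
            5, RangeDistribution.GEOMETRIC, {"mean": 30.0}
        ),
        ParasiteGroup.DIGENEAN.value: GroupSpec(
            25, RangeDistribution.TRUNCATED_ZETA, {"alpha": 2.0}
        ),
        ParasiteGroup.MITE.value: GroupSpec(
            58, RangeDistribution.TRUNCATED_ZETA, {"alpha": 1.5}
        ),
        ParasiteGroup.CILIATE.value: GroupSpec(
            8, RangeDistribution.TRUNCATED_ZETA, {"alpha": 2.0}
        ),
    }


def default_study_config(seed: int) -> SyntheticConfig:
    """The study-shaped default configuration under a caller-chosen seed."""
    return SyntheticConfig(seed=seed)


def power_law_ranges(z: float, n_parasites: int, n_hosts: int) -> np.ndarray:
    """Design integer host ranges whose expected accumulation is b * h**z.

    Solves, by nonnegative least squares, for counts m_r of parasites with
    range r such that sum_r m_r * (1 - C(H-r, h)/C(H, h)) = b * h**z at
    every prefix length h, with b = n_parasites / H**z so the curve passes
    through the observed richness at h = H. The real-valued solution is
    rounded to integers by largest remainder, preserving the parasite
    count. Returns one range per parasite, sorted descending.
    """
    if not 0.0 < z <= 1.0:
        raise ConfigurationError(f"POWER_LAW needs z in (0, 1], got {z}")
    return np.array(_power_law_counts(float(z), int(n_parasites), int(n_hosts)))


@lru_cache(maxsize=32)
def _power_law_counts(z: float, n_parasites: int, n_hosts: int) -> tuple[int, ...]:
    H = int(n_hosts)
    h = np.arange(1, H + 1, dtype=float)
    lchoose_H = gammaln(H + 1) - gammaln(h + 1) - gammaln(H - h + 1)
    A = np.zeros((H, H))
    for j, r in enumerate(range(1, H + 1)):
        valid = h <= H - r
        miss = np.zeros(H)
        if valid.any():
            hv = h[valid]
            miss[valid] = np.exp(
                gammaln(H - r + 1) - gammaln(hv + 1) - gammaln(H - r - hv + 1)
                - lchoose_H[valid]
            )
        A[:, j] = 1.0 - miss
    b = n_parasites / H**z
    target = b * h**z
    m, _ = nnls(A, target)
    counts = np.floor(m).astype(int)
    deficit = int(n_parasites - counts.sum())
    if deficit > 0:
        frac = m - counts
        counts[np.argsort(-frac)[:deficit]] += 1
    elif deficit < 0:
        order = np.argsort(m - counts)
        i = 0
        while deficit < 0 and i < H:
            j = order[i]
            if counts[j] > 0:
                counts[j] -= 1
                deficit += 1
            i += 1
    return tuple(int(r) for r in np.repeat(np.arange(1, H + 1), counts)[::-1])


def _draw_ranges(spec: GroupSpec, n_avail: int, rng: np.random.Generator) -> np.ndarray:
    dist = RangeDistribution(spec.range_distribution)
    n = spec.n_parasites
    if dist is RangeDistribution.FIXED:
        r = int(spec.range_params["r"])
        if not 1 <= r <= n_avail:
            raise ConfigurationError(
                f"FIXED range r={r} outside [1, {n_avail}] available hosts"
            )
        return np.full(n, r)
    if dist is RangeDistribution.GEOMETRIC:
        mean = float(spec.range_params["mean"])
        if mean < 1.0:
            raise ConfigurationError("GEOMETRIC mean must be >= 1")
        draws = rng.geometric(1.0 / mean, size=n)
        return np.clip(draws, 1, n_avail)
    if dist is RangeDistribution.TRUNCATED_ZETA:
        alpha = float(spec.range_params["alpha"])
        if alpha <= 1.0:
            raise ConfigurationError("TRUNCATED_ZETA alpha must exceed 1")
        support = np.arange(1, n_avail + 1, dtype=float)
        w = support**-alpha
        return rng.choice(np.arange(1, n_avail + 1), size=n, p=w / w.sum())
    # POWER_LAW: i.i.d. draws from the designed range distribution, so each
    # realization is a fresh fauna whose *expected* accumulation is b * h**z
    design = power_law_ranges(float(spec.range_params["z"]), n, n_avail)
    weights = np.bincount(design, minlength=n_avail + 1)[1:].astype(float)
    return rng.choice(np.arange(1, n_avail + 1), size=n, p=weights / weights.sum())


_THREAT_RAW = {
    "EN": ("EN", ThreatStatus.EN),
    "TH": ("VU", ThreatStatus.TH),
    "excluded": ("DD", ThreatStatus.DATA_DEFICIENT),
    "not_threatened": ("LC", ThreatStatus.NOT_THREATENED),
}


def generate_network(config: SyntheticConfig) -> AssociationDataset:
    """Generate the association network (one observation per link).

    Randomness is split into three independent streams (host labels,
    sampled-host subset, range draws + host assignment) spawned from the
    config seed, so each stage is reproducible on its own. Threat labels
    are drawn independently of parasite assignment; all synthetic hosts
    carry IUCN-style raw tokens (EN/VU/LC/DD).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_hosts, rng_sample, rng_links = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )

    tp = config.threat_proportions
    labels = ["EN", "TH", "excluded", "not_threatened"]
    probs = np.array(
        [tp.get("EN", 0.0), tp.get("TH", 0.0), tp.get("excluded", 0.0), 0.0]
    )
    probs[3] = max(0.0, 1.0 - probs[:3].sum())
    width = len(str(config.n_hosts))
    hosts: dict[str, HostTaxon] = {}
    for i in range(config.n_hosts):
        name = f"host_{i:0{width}d}"
        label = labels[rng_hosts.choice(4, p=probs)]
        raw, status = _THREAT_RAW[label]
        region = Region.US if rng_hosts.random() < config.prop_us else Region.EUROPE
        hosts[name] = HostTaxon(
            name=name,
            region=region,
            threat=status,
            source_scheme=ThreatScheme.IUCN,
            raw_status=raw,
        )
    host_names = list(hosts)

    sampled = sorted(
        rng_sample.choice(config.n_hosts, size=config.n_sampled, replace=False)
    )
    sampled_names = [host_names[i] for i in sampled]

    parasites: dict[str, ParasiteTaxon] = {}
    records: list[AssociationRecord] = []
    for group_name, spec in config.groups.items():
        group = ParasiteGroup(group_name)
        ranges = _draw_ranges(spec, len(sampled_names), rng_links)
        for j, r in enumerate(ranges):
            pname = f"{group.value}_{j:03d}"
            parasites[pname] = ParasiteTaxon(name=pname, group=group)
            chosen = rng_links.choice(len(sampled_names), size=int(r), replace=False)
            for c in sorted(chosen):
                records.append(AssociationRecord(sampled_names[c], pname, 1))

    return AssociationDataset(hosts=hosts, parasites=parasites, records=tuple(records))


def generate_observation_effort(
    ds: AssociationDataset,
    effort_mean: float,
    detection_prob: float,
    seed: int,
) -> AssociationDataset:
    """Overlay observation effort and detection thinning on a network.

    Per-association observation counts are 1 + Poisson(effort_mean - 1),
    so the mean is effort_mean and every retained link has at least one
    observation. With detection_prob < 1 each association is then
    independently dropped (a "missing link"), except that every parasite
    always keeps at least one association — observed richness stays equal
    to true richness, only host ranges shrink.
    """
    if effort_mean < 1.0:
        raise ConfigurationError("effort_mean must be >= 1")
    if detection_prob <= 0.0 or detection_prob > 1.0:
        raise ConfigurationError("detection_prob must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(ds.records)
    counts = 1 + rng.poisson(effort_mean - 1.0, size=n)
    if detection_prob < 1.0:
        keep = rng.random(n) < detection_prob
        by_parasite: dict[str, list[int]] = {}
        for i, rec in enumerate(ds.records):
            by_parasite.setdefault(rec.parasite, []).append(i)
        for parasite, idx in by_parasite.items():
            if not keep[idx].any():
                keep[idx[rng.integers(len(idx))]] = True
    else:
        keep = np.ones(n, dtype=bool)
    records = tuple(
        AssociationRecord(rec.host, rec.parasite, int(c))
        for rec, c, k in zip(ds.records, counts, keep)
        if k
    )
    return AssociationDataset(hosts=ds.hosts, parasites=ds.parasites, records=records)


def simulate_dataset(config: SyntheticConfig) -> tuple[AssociationDataset, dict]:
    """Generate a full dataset (network + effort + thinning) and its truth sidecar.

    The sidecar records the generating parameters and per-parasite true
    host ranges so downstream estimates can be scored against the truth.
    """
    network = generate_network(config)
    effort_seed = int(
        np.random.SeedSequence(config.seed).spawn(4)[3].generate_state(1)[0] % (2**31)
    )
    ds = generate_observation_effort(
        network, config.effort_mean, config.detection_prob, seed=effort_seed
    )
    true_ranges: dict[str, int] = {}
    for rec in network.records:
        true_ranges[rec.parasite] = true_ranges.get(rec.parasite, 0) + 1
    truth = {
        "config": config.to_dict(),
        "effort_seed": effort_seed,
        "n_sampled_hosts": config.n_sampled,
        "true_richness": len(true_ranges),
        "true_host_ranges": true_ranges,
    }
    return ds, truth
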