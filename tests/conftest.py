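import numpy as np
import pytest
from hypothesis import settings

from paracoex import (
    AssociationDataset,
    AssociationRecord,
    HostTaxon,
    ParasiteGroup,
    ParasiteTaxon,
    Region,
    ThreatScheme,
    ThreatStatus,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def mk_host(name, region=Region.US, threat=ThreatStatus.NOT_THREATENED,
            scheme=ThreatScheme.USFWS, raw="NotListed"):
    return HostTaxon(name=name, region=region, threat=threat,
                     source_scheme=scheme, raw_status=raw)


def mk_parasite(name, group=ParasiteGroup.MITE, species_level=True, obligate=True):
    return ParasiteTaxon(name=name, group=group,
                         species_level=species_level, obligate=obligate)


def make_dataset(n_hosts, links, group=ParasiteGroup.MITE, n_obs=1, hosts=None):
    """Build a small dataset from {parasite: [host indices]} link spec."""
    if hosts is None:
        hosts = {f"h{i}": mk_host(f"h{i}") for i in range(n_hosts)}
    parasites = {p: mk_parasite(p, group=group) for p in links}
    records = tuple(
        AssociationRecord(f"h{i}", p, n_obs) for p, idx in links.items() for i in idx
    )
    return AssociationDataset(hosts=hosts, parasites=parasites, records=records)


@pytest.fixture
def mixed_fixture():
    """4 hosts, 3 parasites with host ranges 1, 2, 3 — the brute-force oracle fixture."""
    return make_dataset(4, {"p_a": [0], "p_b": [0, 1], "p_c": [1, 2, 3]})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_expected_accumulation(ds, group):
    """Independent oracle: enumerate every h-subset of hosts-with-records."""
    import itertools

    recs = [r for r in ds.records if ds.parasites[r.parasite].group == group]
    hosts = sorted({r.host for r in recs})
    by_host = {h: {r.parasite for r in recs if r.host == h} for h in hosts}
    out = []
    for h in range(1, len(hosts) + 1):
        vals = [
            len(set().union(*(by_host[x] for x in combo)))
            for combo in itertools.combinations(hosts, h)
        ]
        out.append(np.mean(vals))
    return np.asarray(out)
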