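"""Host-parasite association data structures and delimited-text input handling.

The empirical substrate of the whole pipeline is a bipartite association
network: a registry of host species (freshwater mussels, with region and
threat status), a registry of parasite species (four obligate groups), and
a set of (host, parasite) association records each carrying the number of
times the pair has been reported.

Hosts with no recorded parasites stay in the registry: richness is fitted
on hosts *with* records but extrapolated to the full host pool, so the
registry size and the record count play different roles downstream.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .errors import ComputationError, UsageError, ValidationError

__all__ = [
    "Region",
    "ThreatScheme",
    "ThreatStatus",
    "ThreatClass",
    "ParasiteGroup",
    "Scenario",
    "HostTaxon",
    "ParasiteTaxon",
    "AssociationRecord",
    "AssociationDataset",
    "map_threat_category",
    "read_association_data",
    "write_association_data",
    "filter_records",
    "scenario_host_proportion",
]


class Region(str, Enum):
    US = "US"
    EUROPE = "Europe"


class ThreatScheme(str, Enum):
    """Origin of a host's raw threat token (US federal list or IUCN Red List)."""

    USFWS = "USFWS"
    IUCN = "IUCN"


class ThreatStatus(str, Enum):
    """Host threat status after scheme translation (detailed form)."""

    EN = "EN"
    TH = "TH"
    NOT_THREATENED = "NOT_THREATENED"
    DATA_DEFICIENT = "DATA_DEFICIENT"
    NOT_EVALUATED = "NOT_EVALUATED"


class ThreatClass(str, Enum):
    """Collapsed threat class used by extinction scenarios.

    DATA_DEFICIENT and NOT_EVALUATED hosts collapse to EXCLUDED: they
    cannot be placed in or out of a scenario and drop out of the assessed
    denominator.
    """

    EN = "EN"
    TH = "TH"
    NOT_THREATENED = "NOT_THREATENED"
    EXCLUDED = "EXCLUDED"


class ParasiteGroup(str, Enum):
    ASPIDOGASTREAN = "aspidogastrean"
    DIGENEAN = "digenean"
    MITE = "mite"
    CILIATE = "ciliate"


class Scenario(str, Enum):
    """Named host-extinction scenarios: all EN hosts lost, or all EN and TH hosts."""

    EN = "EN"
    EN_TH = "EN+TH"


_USFWS_MAP = {
    "Endangered": (ThreatStatus.EN, ThreatClass.EN),
    "Threatened": (ThreatStatus.TH, ThreatClass.TH),
    "NotListed": (ThreatStatus.NOT_THREATENED, ThreatClass.NOT_THREATENED),
}

_IUCN_MAP = {
    "CR": (ThreatStatus.EN, ThreatClass.EN),
    "EN": (ThreatStatus.EN, ThreatClass.EN),
    "VU": (ThreatStatus.TH, ThreatClass.TH),
    "NT": (ThreatStatus.NOT_THREATENED, ThreatClass.NOT_THREATENED),
    "LC": (ThreatStatus.NOT_THREATENED, ThreatClass.NOT_THREATENED),
    "DD": (ThreatStatus.DATA_DEFICIENT, ThreatClass.EXCLUDED),
    "NE": (ThreatStatus.NOT_EVALUATED, ThreatClass.EXCLUDED),
}


def map_threat_category(scheme: Union[ThreatScheme, str], raw_category: str) -> ThreatClass:
    """Translate a raw scheme token into a scenario threat class.

    USFWS: Endangered -> EN, Threatened -> TH, NotListed -> NOT_THREATENED.
    IUCN: CR and EN -> EN, VU -> TH, NT and LC -> NOT_THREATENED,
    DD and NE -> EXCLUDED (unassessed hosts cannot enter a scenario).
    """
    return _map_threat(scheme, raw_category)[1]


def _map_threat(scheme, raw_category) -> tuple[ThreatStatus, ThreatClass]:
    scheme = ThreatScheme(scheme)
    table = _USFWS_MAP if scheme is ThreatScheme.USFWS else _IUCN_MAP
    token = str(raw_category).strip()
    if token not in table:
        raise ValidationError(
            f"unknown threat token {token!r} for scheme {scheme.value}; "
            f"expected one of {sorted(table)}"
        )
    return table[token]


@dataclass(frozen=True)
class HostTaxon:
    """A host species: binomial name, region, translated threat status."""

    name: str
    region: Region
    threat: ThreatStatus
    source_scheme: ThreatScheme
    raw_status: str = ""

    def __post_init__(self):
        if not self.name or not self.name.strip():
            raise ValidationError("host name must be nonempty")

    @property
    def threat_class(self) -> ThreatClass:
        if self.threat in (ThreatStatus.DATA_DEFICIENT, ThreatStatus.NOT_EVALUATED):
            return ThreatClass.EXCLUDED
        return ThreatClass(self.threat.value)


@dataclass(frozen=True)
class ParasiteTaxon:
    """A parasite species with its group and record-quality flags.

    ``species_level`` is False for records only determined to genus or
    higher; ``obligate`` is False for endosymbionts that may be incidental.
    Both flags feed :func:`filter_records`.
    """

    name: str
    group: ParasiteGroup
    species_level: bool = True
    obligate: bool = True

    def __post_init__(self):
        if not self.name or not self.name.strip():
            raise ValidationError("parasite name must be nonempty")


@dataclass(frozen=True)
class AssociationRecord:
    host: str
    parasite: str
    n_observations: int = 1

    def __post_init__(self):
        if int(self.n_observations) < 1:
            raise ValidationError(
                f"n_observations must be >= 1 for ({self.host}, {self.parasite})"
            )


@dataclass(frozen=True)
class AssociationDataset:
    """A validated bipartite host-parasite network with observation counts."""

    hosts: Mapping[str, HostTaxon]
    parasites: Mapping[str, ParasiteTaxon]
    records: tuple[AssociationRecord, ...]

    def __post_init__(self):
        seen = set()
        bad_rows, dup_rows = [], []
        for rec in self.records:
            if rec.host not in self.hosts or rec.parasite not in self.parasites:
                bad_rows.append((rec.host, rec.parasite))
            key = (rec.host, rec.parasite)
            if key in seen:
                dup_rows.append(key)
            seen.add(key)
        if bad_rows:
            raise ValidationError(
                f"associations reference unregistered taxa: {bad_rows[:10]}"
                + (" ..." if len(bad_rows) > 10 else "")
            )
        if dup_rows:
            raise ValidationError(f"duplicate (host, parasite) rows: {dup_rows[:10]}")

    # -- derived counts ---------------------------------------------------
    @property
    def n_hosts(self) -> int:
        """Size of the full host pool, including hosts without records."""
        return len(self.hosts)

    @property
    def hosts_with_records(self) -> frozenset[str]:
        return frozenset(rec.host for rec in self.records)

    @property
    def n_hosts_with_records(self) -> int:
        return len(self.hosts_with_records)

    @property
    def recorded_parasites(self) -> frozenset[str]:
        return frozenset(rec.parasite for rec in self.records)

    @property
    def n_pairs(self) -> int:
        return len(self.records)

    def group_records(self, group: ParasiteGroup) -> tuple[AssociationRecord, ...]:
        return tuple(
            rec for rec in self.records if self.parasites[rec.parasite].group == group
        )

    def groups_present(self) -> list[ParasiteGroup]:
        present = {self.parasites[rec.parasite].group for rec in self.records}
        return [g for g in ParasiteGroup if g in present]

    def restrict(self, region: Optional[Region] = None) -> "AssociationDataset":
        """Keep only records whose host is in ``region`` (registries unchanged)."""
        if region is None:
            return self
        region = Region(region)
        recs = tuple(r for r in self.records if self.hosts[r.host].region == region)
        return replace(self, records=recs)

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "host": [r.host for r in self.records],
                "parasite": [r.parasite for r in self.records],
                "n_observations": [r.n_observations for r in self.records],
            }
        )


_HOST_COLUMNS = ["host", "region", "scheme", "status"]
_PARASITE_COLUMNS = ["parasite", "group", "species_level", "obligate"]
_ASSOC_COLUMNS = ["host", "parasite", "n_observations"]

_REGION_TOKENS = {"US": Region.US, "Europe": Region.EUROPE}
_BOOL_TOKENS = {"true": True, "false": False}


def _read_csv(path, columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    for c in df.columns:
        df[c] = df[c].str.strip()
    return df


def _parse_bool(token: str, where: str) -> bool:
    if token.lower() not in _BOOL_TOKENS:
        raise ValidationError(f"{where}: expected true/false, got {token!r}")
    return _BOOL_TOKENS[token.lower()]


def read_association_data(host_path, parasite_path, association_path) -> AssociationDataset:
    """Read and validate the three comma-delimited inputs.

    ``hosts.csv`` columns: host,region,scheme,status; ``parasites.csv``:
    parasite,group,species_level,obligate; ``associations.csv``:
    host,parasite,n_observations. Unknown enum tokens, dangling references
    and duplicate association rows raise :class:`ValidationError`.
    """
    hosts_df = _read_csv(host_path, _HOST_COLUMNS)
    par_df = _read_csv(parasite_path, _PARASITE_COLUMNS)
    assoc_df = _read_csv(association_path, _ASSOC_COLUMNS)

    hosts: dict[str, HostTaxon] = {}
    for i, row in hosts_df.iterrows():
        if row["region"] not in _REGION_TOKENS:
            raise ValidationError(
                f"{host_path} row {i}: unknown region {row['region']!r}"
            )
        scheme = row["scheme"]
        try:
            scheme = ThreatScheme(scheme)
        except ValueError:
            raise ValidationError(
                f"{host_path} row {i}: unknown scheme {row['scheme']!r}"
            ) from None
        status, _ = _map_threat(scheme, row["status"])
        if row["host"] in hosts:
            raise ValidationError(f"{host_path}: duplicate host {row['host']!r}")
        hosts[row["host"]] = HostTaxon(
            name=row["host"],
            region=_REGION_TOKENS[row["region"]],
            threat=status,
            source_scheme=scheme,
            raw_status=row["status"],
        )

    parasites: dict[str, ParasiteTaxon] = {}
    for i, row in par_df.iterrows():
        try:
            group = ParasiteGroup(row["group"])
        except ValueError:
            raise ValidationError(
                f"{parasite_path} row {i}: unknown group {row['group']!r}"
            ) from None
        if row["parasite"] in parasites:
            raise ValidationError(
                f"{parasite_path}: duplicate parasite {row['parasite']!r}"
            )
        parasites[row["parasite"]] = ParasiteTaxon(
            name=row["parasite"],
            group=group,
            species_level=_parse_bool(row["species_level"], f"{parasite_path} row {i}"),
            obligate=_parse_bool(row["obligate"], f"{parasite_path} row {i}"),
        )

    records = []
    for i, row in assoc_df.iterrows():
        try:
            n_obs = int(row["n_observations"])
        except ValueError:
            raise ValidationError(
                f"{association_path} row {i}: bad n_observations {row['n_observations']!r}"
            ) from None
        records.append(AssociationRecord(row["host"], row["parasite"], n_obs))

    return AssociationDataset(hosts=hosts, parasites=parasites, records=tuple(records))


def write_association_data(ds: AssociationDataset, out_dir) -> dict[str, Path]:
    """Write the dataset back to the three-file dialect; inverse of reading."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hosts": out_dir / "hosts.csv",
        "parasites": out_dir / "parasites.csv",
        "associations": out_dir / "associations.csv",
    }
    pd.DataFrame(
        {
            "host": [h.name for h in ds.hosts.values()],
            "region": [h.region.value for h in ds.hosts.values()],
            "scheme": [h.source_scheme.value for h in ds.hosts.values()],
            "status": [h.raw_status for h in ds.hosts.values()],
        }
    ).to_csv(paths["hosts"], index=False)
    pd.DataFrame(
        {
            "parasite": [p.name for p in ds.parasites.values()],
            "group": [p.group.value for p in ds.parasites.values()],
            "species_level": [str(p.species_level).lower() for p in ds.parasites.values()],
            "obligate": [str(p.obligate).lower() for p in ds.parasites.values()],
        }
    ).to_csv(paths["parasites"], index=False)
    ds.records_frame().to_csv(paths["associations"], index=False)
    return paths


def filter_records(
    ds: AssociationDataset,
    require_species_level: bool = True,
    require_obligate: bool = True,
) -> AssociationDataset:
    """Drop association records whose parasite fails the enabled quality flags.

    Registries are left untouched: a host may lose all its records yet stays
    in the pool (it still counts toward the extrapolation target), and a
    filtered-out parasite remains registered. Idempotent by construction.
    """
    def keep(p: ParasiteTaxon) -> bool:
        if require_species_level and not p.species_level:
            return False
        if require_obligate and not p.obligate:
            return False
        return True

    recs = tuple(r for r in ds.records if keep(ds.parasites[r.parasite]))
    return replace(ds, records=recs)


def scenario_host_proportion(
    hosts: Union[AssociationDataset, Iterable[HostTaxon]],
    scenario: Union[Scenario, str],
    include_unassessed: bool = False,
) -> float:
    """Proportion of hosts lost under a named scenario.

    The numerator counts EN hosts (EN scenario) or EN plus TH hosts (EN+TH).
    By default the denominator counts only assessed hosts (threat class not
    EXCLUDED); pass ``include_unassessed=True`` to divide by the full pool,
    which makes the proportion — and every downstream extinction estimate —
    strictly smaller.
    """
    scenario = Scenario(scenario)
    if isinstance(hosts, AssociationDataset):
        hosts = hosts.hosts.values()
    classes = [h.threat_class for h in hosts]
    assessed = [c for c in classes if c is not ThreatClass.EXCLUDED]
    denom = len(classes) if include_unassessed else len(assessed)
    if denom == 0:
        raise ComputationError("no assessed hosts: cannot form a scenario proportion")
    lost = {ThreatClass.EN} if scenario is Scenario.EN else {ThreatClass.EN, ThreatClass.TH}
    num = sum(1 for c in assessed if c in lost)
    return num / denom
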