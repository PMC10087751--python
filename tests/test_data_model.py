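"""Data structures, file dialect, record filters and threat mapping."""
import textwrap

import pytest
from hypothesis import given
from hypothesis import strategies as st

import paracoex as pc
from paracoex.errors import ComputationError, ValidationError

from conftest import make_dataset, mk_host, mk_parasite


def _write_inputs(tmp_path, hosts, parasites, assocs):
    paths = {}
    for name, text in (("hosts", hosts), ("parasites", parasites), ("associations", assocs)):
        p = tmp_path / f"{name}.csv"
        p.write_text(textwrap.dedent(text))
        paths[name] = p
    return paths


TINY_HOSTS = """\
    host,region,scheme,status
    Anodonta anatina,Europe,IUCN,LC
    Margaritifera margaritifera,Europe,IUCN,EN
"""
TINY_PARASITES = """\
    parasite,group,species_level,obligate
    Unionicola ypsilophora,mite,true,true
    Rhipidocotyle campanula,digenean,true,true
"""
TINY_ASSOCS = """\
    host,parasite,n_observations
    Anodonta anatina,Unionicola ypsilophora,3
    Anodonta anatina,Rhipidocotyle campanula,1
    Margaritifera margaritifera,Unionicola ypsilophora,2
"""


class TestReading:
    def test_direct_readback_counts(self, tmp_path):
        paths = _write_inputs(tmp_path, TINY_HOSTS, TINY_PARASITES, TINY_ASSOCS)
        ds = pc.read_association_data(paths["hosts"], paths["parasites"], paths["associations"])
        assert ds.n_hosts == 2
        assert ds.n_hosts_with_records == 2
        assert len(ds.recorded_parasites) == 2
        assert ds.n_pairs == 3

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(ValidationError, match="nowhere"):
            pc.read_association_data(tmp_path / "nowhere.csv", tmp_path / "x", tmp_path / "y")

    def test_unregistered_host_rejected(self, tmp_path):
        assocs = TINY_ASSOCS + "    Unio pictorum,Unionicola ypsilophora,1\n"
        paths = _write_inputs(tmp_path, TINY_HOSTS, TINY_PARASITES, assocs)
        with pytest.raises(ValidationError, match="Unio pictorum"):
            pc.read_association_data(paths["hosts"], paths["parasites"], paths["associations"])

    def test_duplicate_pair_rejected(self, tmp_path):
        assocs = TINY_ASSOCS + "    Anodonta anatina,Unionicola ypsilophora,1\n"
        paths = _write_inputs(tmp_path, TINY_HOSTS, TINY_PARASITES, assocs)
        with pytest.raises(ValidationError, match="duplicate"):
            pc.read_association_data(paths["hosts"], paths["parasites"], paths["associations"])

    @pytest.mark.parametrize(
        "column,bad_row",
        [
            ("hosts", "Unio crassus,Atlantis,IUCN,LC"),
            ("hosts", "Unio crassus,Europe,IUCN,Mystery"),
            ("parasites", "Conchophthirus sp,protist,true,true"),
            ("parasites", "Conchophthirus sp,ciliate,maybe,true"),
        ],
    )
    def test_unknown_tokens_rejected(self, tmp_path, column, bad_row):
        blocks = {"hosts": TINY_HOSTS, "parasites": TINY_PARASITES, "associations": TINY_ASSOCS}
        blocks[column] = blocks[column] + f"    {bad_row}\n"
        paths = _write_inputs(tmp_path, blocks["hosts"], blocks["parasites"], blocks["associations"])
        with pytest.raises(ValidationError):
            pc.read_association_data(paths["hosts"], paths["parasites"], paths["associations"])

    def test_round_trip(self, tmp_path):
        paths = _write_inputs(tmp_path, TINY_HOSTS, TINY_PARASITES, TINY_ASSOCS)
        ds = pc.read_association_data(paths["hosts"], paths["parasites"], paths["associations"])
        out = tmp_path / "out"
        written = pc.write_association_data(ds, out)
        again = pc.read_association_data(written["hosts"], written["parasites"], written["associations"])
        assert again == ds


class TestThreatMapping:
    @pytest.mark.parametrize(
        "scheme,raw,expected",
        [
            ("USFWS", "Endangered", pc.ThreatClass.EN),
            ("USFWS", "Threatened", pc.ThreatClass.TH),
            ("USFWS", "NotListed", pc.ThreatClass.NOT_THREATENED),
            ("IUCN", "CR", pc.ThreatClass.EN),
            ("IUCN", "EN", pc.ThreatClass.EN),
            ("IUCN", "VU", pc.ThreatClass.TH),
            ("IUCN", "NT", pc.ThreatClass.NOT_THREATENED),
            ("IUCN", "LC", pc.ThreatClass.NOT_THREATENED),
            ("IUCN", "DD", pc.ThreatClass.EXCLUDED),
            ("IUCN", "NE", pc.ThreatClass.EXCLUDED),
        ],
    )
    def test_mapping_table(self, scheme, raw, expected):
        assert pc.map_threat_category(scheme, raw) is expected

    def test_unknown_token_names_scheme(self):
        with pytest.raises(ValidationError, match="USFWS"):
            pc.map_threat_category("USFWS", "CR")


class TestFilters:
    def _quality_mix(self):
        hosts = {f"h{i}": mk_host(f"h{i}") for i in range(2)}
        parasites = {
            "good": mk_parasite("good"),
            "genus_only": mk_parasite("genus_only", species_level=False),
            "commensal": mk_parasite("commensal", obligate=False),
        }
        records = tuple(pc.AssociationRecord("h0", p) for p in parasites)
        return pc.AssociationDataset(hosts, parasites, records)

    def test_flags_drop_matching_records(self):
        ds = self._quality_mix()
        out = pc.filter_records(ds, require_species_level=True, require_obligate=True)
        assert {r.parasite for r in out.records} == {"good"}
        assert out.n_hosts == 2  # host registry untouched

    def test_flags_off_is_identity(self):
        ds = self._quality_mix()
        out = pc.filter_records(ds, require_species_level=False, require_obligate=False)
        assert out == ds

    def test_idempotent(self):
        ds = self._quality_mix()
        once = pc.filter_records(ds, True, True)
        twice = pc.filter_records(once, True, True)
        assert once == twice

    def test_marked_fraction_removed_exactly(self):
        # 30 records, every 10th parasite flagged non-obligate -> 10% removed
        hosts = {f"h{i}": mk_host(f"h{i}") for i in range(30)}
        parasites = {
            f"p{i}": mk_parasite(f"p{i}", obligate=(i % 10 != 0)) for i in range(30)
        }
        records = tuple(pc.AssociationRecord(f"h{i}", f"p{i}") for i in range(30))
        ds = pc.AssociationDataset(hosts, parasites, records)
        expected = sum(1 for p in parasites.values() if p.obligate)
        out = pc.filter_records(ds, require_species_level=False, require_obligate=True)
        assert out.n_pairs == expected == 27


class TestScenarioProportion:
    def _registry(self, en=0, th=0, nt=0, dd=0):
        hosts = []
        statuses = (
            [pc.ThreatStatus.EN] * en
            + [pc.ThreatStatus.TH] * th
            + [pc.ThreatStatus.NOT_THREATENED] * nt
            + [pc.ThreatStatus.DATA_DEFICIENT] * dd
        )
        for i, s in enumerate(statuses):
            hosts.append(mk_host(f"h{i}", threat=s, scheme=pc.ThreatScheme.IUCN, raw=""))
        return hosts

    def test_basic_arithmetic(self):
        reg = self._registry(en=3, th=2, nt=5)
        assert pc.scenario_host_proportion(reg, "EN") == pytest.approx(0.3)
        assert pc.scenario_host_proportion(reg, "EN+TH") == pytest.approx(0.5)

    def test_unassessed_excluded_from_denominator(self):
        reg = self._registry(en=1, nt=3, dd=6)
        assert pc.scenario_host_proportion(reg, "EN") == pytest.approx(0.25)
        assert pc.scenario_host_proportion(reg, "EN", include_unassessed=True) == pytest.approx(0.1)

    def test_zero_assessed_is_error(self):
        reg = self._registry(dd=4)
        with pytest.raises(ComputationError):
            pc.scenario_host_proportion(reg, "EN")

    @given(st.lists(st.sampled_from(["EN", "TH", "NOT_THREATENED", "DATA_DEFICIENT"]),
                    min_size=1, max_size=40))
    def test_en_never_exceeds_en_th(self, statuses):
        hosts = [mk_host(f"h{i}", threat=pc.ThreatStatus(s), scheme=pc.ThreatScheme.IUCN)
                 for i, s in enumerate(statuses)]
        if all(s == "DATA_DEFICIENT" for s in statuses):
            return
        en = pc.scenario_host_proportion(hosts, "EN")
        enth = pc.scenario_host_proportion(hosts, "EN+TH")
        assert en <= enth

    def test_generated_registry_recovers_proportion(self):
        cfg = pc.SyntheticConfig(seed=5, n_hosts=295)
        ds = pc.generate_network(cfg)
        p_en = pc.scenario_host_proportion(ds, "EN")
        # binomial sampling error around the generating EN proportion 0.26
        assert abs(p_en - 0.26) < 4 * (0.26 * 0.74 / 295) ** 0.5
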