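"""Marginal counts, rank tests, and the observation-effort regression."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import paracoex as pc
from paracoex.errors import ComputationError, UsageError

from conftest import make_dataset, mk_host, mk_parasite


class TestMarginalCounts:
    def test_shared_parasite(self):
        ds = make_dataset(2, {"p": [0, 1]})
        rich = pc.marginal_counts(ds, "per_host_richness")
        rng = pc.marginal_counts(ds, "per_parasite_host_range")
        assert rich.entries == {"h0": 1, "h1": 1}
        assert rng.entries == {"p": 2}

    def test_fully_specialist_fixture(self):
        ds = make_dataset(5, {f"p{i}": [i] for i in range(5)})
        rng = pc.marginal_counts(ds, "per_parasite_host_range")
        assert all(v == 1 for v in rng.entries.values())

    def test_totals_conserved(self, rng):
        # random bipartite network: both marginals must sum to the pair count
        links = {}
        for j in range(12):
            hosts = rng.choice(15, size=rng.integers(1, 6), replace=False)
            links[f"p{j}"] = list(hosts)
        ds = make_dataset(15, links)
        rich = pc.marginal_counts(ds, "per_host_richness")
        ranges = pc.marginal_counts(ds, "per_parasite_host_range")
        assert sum(rich.entries.values()) == sum(ranges.entries.values()) == ds.n_pairs

    def test_empty_restriction_is_error(self):
        ds = make_dataset(2, {"p": [0, 1]}, group=pc.ParasiteGroup.MITE)
        with pytest.raises(ComputationError, match="ciliate"):
            pc.marginal_counts(ds, "per_host_richness", group=pc.ParasiteGroup.CILIATE)

    def test_mean_and_se(self):
        ds = make_dataset(3, {"p0": [0, 1, 2], "p1": [0], "p2": [0]})
        rich = pc.marginal_counts(ds, "per_host_richness")
        assert rich.mean() == pytest.approx(np.mean([3, 1, 1]))
        assert rich.se() == pytest.approx(np.std([3, 1, 1], ddof=1) / np.sqrt(3))


class TestKruskalWallis:
    def test_hand_computed_two_groups(self):
        # rank sums 6 and 15: H = (12/42)(36/3 + 225/3) - 21 = 3.857
        res = pc.kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(3.857, abs=5e-4)
        assert res.df == 1

    def test_identical_groups_give_zero(self):
        res = pc.kruskal_wallis([[1, 2], [1, 2]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_tied_convention(self):
        res = pc.kruskal_wallis([[2, 2, 2], [2, 2]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_fewer_than_two_groups_is_error(self):
        with pytest.raises(UsageError):
            pc.kruskal_wallis([[1, 2, 3]])

    @given(
        st.lists(
            st.lists(st.integers(-20, 20), min_size=1, max_size=8),
            min_size=2,
            max_size=4,
        )
    )
    def test_invariant_under_monotone_transform(self, groups):
        if sum(len(g) for g in groups) < 3:
            return
        base = pc.kruskal_wallis(groups)
        cubed = pc.kruskal_wallis([[x**3 for x in g] for g in groups])
        assert cubed.statistic == pytest.approx(base.statistic, abs=1e-9)


class TestRangeVsObservations:
    def test_single_observation_per_association_is_isometric(self):
        ds = make_dataset(6, {"p0": [0], "p1": [0, 1], "p2": [0, 1, 2, 3]}, n_obs=1)
        fit = pc.range_vs_observations_fit(ds)
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert not fit.above_isometry

    def test_constant_repeat_observation_shifts_intercept(self):
        ds = make_dataset(6, {"p0": [0], "p1": [0, 1], "p2": [0, 1, 2, 3]}, n_obs=3)
        fit = pc.range_vs_observations_fit(ds)
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(-np.log10(3), abs=1e-9)
        assert fit.above_isometry  # separated on the repeat-observation side

    def test_synthetic_effort_separates_band(self):
        cfg = pc.SyntheticConfig(seed=3, effort_mean=4.0)
        ds, _ = pc.simulate_dataset(cfg)
        fit = pc.range_vs_observations_fit(ds)
        assert fit.above_isometry

    def test_too_few_points_is_error(self):
        ds = make_dataset(2, {"p0": [0], "p1": [1]})
        with pytest.raises(ComputationError):
            pc.range_vs_observations_fit(ds)

    def test_band_contains_fitted_line(self):
        ds = make_dataset(8, {f"p{i}": list(range(i + 1)) for i in range(5)}, n_obs=2)
        fit = pc.range_vs_observations_fit(ds)
        assert np.all(fit.ci_low <= fit.fitted + 1e-12)
        assert np.all(fit.fitted <= fit.ci_high + 1e-12)


class TestSpecialistRichnessByThreat:
    def _threat_hosts(self, n_threatened, n_other):
        hosts = {}
        for i in range(n_threatened + n_other):
            threat = pc.ThreatStatus.EN if i < n_threatened else pc.ThreatStatus.NOT_THREATENED
            hosts[f"h{i}"] = mk_host(f"h{i}", threat=threat, scheme=pc.ThreatScheme.IUCN)
        return hosts

    def test_identical_specialist_loads_give_zero(self):
        hosts = self._threat_hosts(2, 2)
        links = {f"p{i}": [i] for i in range(4)}  # one specialist each
        ds = make_dataset(4, links, hosts=hosts)
        res = pc.specialist_richness_by_threat(ds)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_specialists_concentrated_on_one_side(self):
        hosts = self._threat_hosts(3, 3)
        links = {"gen": [0, 1, 2, 3, 4, 5]}
        links.update({f"s{i}": [3 + i] for i in range(3)})  # specialists only on non-threatened
        ds = make_dataset(6, links, hosts=hosts)
        res = pc.specialist_richness_by_threat(ds)
        assert res.statistic > 0
        assert res.p_value < 0.05

    def test_one_side_empty_is_error(self):
        hosts = self._threat_hosts(0, 4)
        ds = make_dataset(4, {"p": [0, 1]}, hosts=hosts)
        with pytest.raises(ComputationError):
            pc.specialist_richness_by_threat(ds)

    def test_null_when_threat_independent_of_load(self):
        # threat assigned independently of parasites: p-values roughly uniform
        pvals = []
        for seed in range(40):
            cfg = pc.SyntheticConfig(seed=seed, n_hosts=60, fraction_hosts_sampled=1.0,
                                     effort_mean=1.0)
            ds = pc.generate_network(cfg)
            try:
                pvals.append(pc.specialist_richness_by_threat(ds).p_value)
            except ComputationError:
                continue
        pvals = np.asarray(pvals)
        assert pvals.size >= 30
        # a uniform sample of this size should not concentrate below 0.05
        assert (pvals < 0.05).mean() < 0.2
        assert pvals.mean() == pytest.approx(0.5, abs=0.2)
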