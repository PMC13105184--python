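import numpy as np
import pytest
from scipy.spatial.distance import pdist

from stomanet.network import mst_total_length
from stomanet.patterns import ObservationWindow
from stomanet.simulate import (
    HEX_PACKING_FRACTION,
    ClassificationResult,
    PackingInfeasibleError,
    ScenarioEnvelope,
    ScenarioSpec,
    classify_sample,
    simulate_clustered,
    simulate_csr,
    simulate_envelope,
    simulate_inhibited,
    summarize_classifications,
)

from conftest import UNIT


def make_envelope(kind, lo, med, hi, **kw):
    spec_kw = {}
    if kind == "clustered":
        spec_kw["cluster_sd"] = 0.05
    if kind == "over_dispersed":
        spec_kw["inhibition_distance"] = 0.04
    spec = ScenarioSpec(kind, reps=3, **spec_kw)
    return ScenarioEnvelope(spec, np.array([lo, med, hi]), med, lo, hi, **kw)


THREE = {
    "clustered": make_envelope("clustered", 3.0, 4.0, 5.0),
    "random": make_envelope("random", 8.0, 9.0, 10.0),
    "over_dispersed": make_envelope("over_dispersed", 11.0, 11.5, 12.0),
}


class TestScenarioSpec:
    def test_clustered_requires_sd(self):
        with pytest.raises(ValueError, match="cluster_sd"):
            ScenarioSpec("clustered")

    def test_over_dispersed_requires_distance(self):
        with pytest.raises(ValueError, match="inhibition_distance"):
            ScenarioSpec("over_dispersed")

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            ScenarioSpec("lattice")


class TestCSR:
    def test_empty(self, rng):
        assert simulate_csr(0, UNIT, rng).n == 0

    def test_quadrant_counts_near_uniform(self, rng):
        """Each quadrant of the window holds ~n/4 points (binomial spread)."""
        hits = 0
        reps = 20
        for r in rng.spawn(reps):
            p = simulate_csr(10_000, UNIT, r)
            q = (p.points[:, 0] < 0.5) & (p.points[:, 1] < 0.5)
            hits += abs(q.sum() - 2500) <= 0.05 * 2500
        assert hits / reps >= 0.95

    def test_respects_window_bounds(self, rng):
        win = ObservationWindow(2.0, -1.0, 5.0, 3.0)
        p = simulate_csr(500, win, rng)
        assert win.contains(p.points).all()


class TestClustered:
    def test_zero_dispersion_limit_collapses_onto_parents(self, rng):
        p = simulate_clustered(4, UNIT, cluster_sd=1e-12, rng=rng, n_clusters=4)
        # 4 points in 4 clusters, sd ~ 0: one point per parent, all distinct
        assert p.n == 4
        assert pdist(p.points).min() > 1e-6

    def test_clustering_shortens_mst_vs_csr(self, rng):
        n = 100
        reps = 60
        clustered = np.mean(
            [
                mst_total_length(simulate_clustered(n, UNIT, 0.02, r).points)
                for r in rng.spawn(reps)
            ]
        )
        csr = np.mean(
            [mst_total_length(simulate_csr(n, UNIT, r).points) for r in rng.spawn(reps)]
        )
        assert clustered < csr

    def test_wide_clusters_approach_csr(self, rng):
        """With parent spread ~ window size the cluster process loses its
        aggregation: its envelope median lands inside the CSR band."""
        n = 200
        spec = ScenarioSpec("clustered", cluster_sd=0.5, reps=100)
        env = simulate_envelope(spec, n, UNIT, rng)
        csr_env = simulate_envelope(ScenarioSpec("random", reps=200), n, UNIT, rng)
        assert csr_env.ci_low <= env.median <= csr_env.ci_high

    def test_points_stay_inside_window(self, rng):
        p = simulate_clustered(300, UNIT, 0.3, rng)
        assert UNIT.contains(p.points).all()


class TestInhibited:
    def test_min_pairwise_distance_enforced(self, rng):
        p = simulate_inhibited(50, UNIT, 0.05, rng)
        assert pdist(p.points).min() >= 0.05

    def test_geometrically_impossible_request(self, rng):
        with pytest.raises(PackingInfeasibleError):
            simulate_inhibited(2, UNIT, 10.0, rng)

    def test_packing_bound_precheck(self, rng):
        # n*pi*(d/2)^2/A just above the hexagonal bound
        d = 0.1
        n = int(HEX_PACKING_FRACTION / (np.pi * (d / 2) ** 2)) + 2
        with pytest.raises(PackingInfeasibleError, match="hexagonal"):
            simulate_inhibited(n, UNIT, d, rng)

    def test_stalled_placement_reports_partial_count(self, rng):
        # feasible by the hexagonal bound but far beyond the RSA jamming
        # density, so placement exhausts its attempt budget
        with pytest.raises(PackingInfeasibleError) as err:
            simulate_inhibited(80, UNIT, 0.1, rng, max_attempts=2000)
        assert 0 < err.value.placed < 80

    def test_inhibition_lengthens_mst_vs_csr(self, rng):
        n = 200
        reps = 50
        inhibited = np.mean(
            [
                mst_total_length(simulate_inhibited(n, UNIT, 0.04, r).points)
                for r in rng.spawn(reps)
            ]
        )
        csr = np.mean(
            [mst_total_length(simulate_csr(n, UNIT, r).points) for r in rng.spawn(reps)]
        )
        assert inhibited > csr


class TestEnvelope:
    def test_single_replicate_degenerate_band(self, rng):
        env = simulate_envelope(ScenarioSpec("random", reps=1), 50, UNIT, rng)
        assert env.ci_low == env.median == env.ci_high == env.lengths[0]

    def test_band_orders_and_brackets_median(self, rng):
        env = simulate_envelope(ScenarioSpec("random", reps=200), 100, UNIT, rng)
        assert env.ci_low <= env.median <= env.ci_high
        assert len(env.lengths) == 200

    def test_reproducible_from_equal_streams(self):
        a = simulate_envelope(ScenarioSpec("random", reps=50), 60, UNIT, np.random.default_rng(5))
        b = simulate_envelope(ScenarioSpec("random", reps=50), 60, UNIT, np.random.default_rng(5))
        np.testing.assert_array_equal(a.lengths, b.lengths)

    def test_infeasible_envelope_aborts_with_diagnostics(self, rng):
        spec = ScenarioSpec("over_dispersed", inhibition_distance=0.1, reps=20)
        with pytest.raises(PackingInfeasibleError, match="infeasible"):
            simulate_envelope(spec, 80, UNIT, rng)


class TestClassification:
    def test_exclusive_random(self):
        res, warnings = classify_sample(9.0, THREE, "s")
        assert res.membership == frozenset({"random"})
        assert res.exclusive and res.position == "within_or_overlapping"
        assert warnings == []

    def test_overlapping_bands_give_multiple_membership(self):
        overlapping = dict(THREE)
        overlapping["over_dispersed"] = make_envelope("over_dispersed", 9.5, 11.0, 12.0)
        res, _ = classify_sample(9.8, overlapping, "s")
        assert res.membership == frozenset({"random", "over_dispersed"})
        assert not res.exclusive

    def test_above_overdispersed(self):
        res, _ = classify_sample(13.0, THREE, "s")
        assert res.membership == frozenset()
        assert res.position == "above_overdispersed"

    def test_below_clustered(self):
        res, _ = classify_sample(1.0, THREE, "s")
        assert res.position == "below_clustered"

    @pytest.mark.parametrize(
        "value,expected",
        [(6.0, "between_clustered_random"), (10.5, "between_random_overdispersed")],
    )
    def test_gap_positions(self, value, expected):
        res, _ = classify_sample(value, THREE, "s")
        assert res.membership == frozenset() and res.position == expected

    def test_unordered_medians_warn_but_classify(self):
        swapped = dict(THREE)
        swapped["clustered"] = make_envelope("clustered", 10.5, 11.0, 11.2)
        res, warnings = classify_sample(9.0, swapped, "s")
        assert any("not ordered" in w for w in warnings)
        assert "random" in res.membership

    def test_missing_envelope_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            classify_sample(9.0, {"random": THREE["random"]}, "s")


class TestSummary:
    def _result(self, membership, position, sid="s"):
        ms = frozenset(membership)
        return ClassificationResult(sid, ms, position, len(ms) == 1, observed_length=1.0)

    def test_all_exclusive_random(self):
        results = [self._result({"random"}, "within_or_overlapping") for _ in range(10)]
        s = summarize_classifications(results)
        assert s["pct_exclusive_random"] == 100.0
        assert s["pct_exclusive_clustered"] == 0.0 and s["pct_non_exclusive"] == 0.0

    def test_non_exclusive_share(self):
        results = [
            self._result({"random"}, "within_or_overlapping"),
            self._result({"clustered"}, "within_or_overlapping"),
            self._result({"random", "over_dispersed"}, "within_or_overlapping"),
            self._result(set(), "above_overdispersed"),
        ]
        s = summarize_classifications(results)
        assert s["pct_non_exclusive"] == 50.0
        assert s["above_overdispersed"] == 1
        assert s["within_or_above_overdispersed"] == 2
        # only the sample above every band sits above random: the
        # double-membership sample still touches the random band
        assert s["above_random"] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_classifications([])
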