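import numpy as np
import pytest

from caimnet.behavior import BoutSegmentation, segment_bouts
from caimnet.connectivity import (
    CORRELATED,
    INELIGIBLE,
    _null_r,
    _pearson_binary,
    centroid_distance_um,
    classify_session,
    correlation_test,
    pair_eligible,
    rate_correlation_control,
    state_concatenate,
    subgroup_means,
)
from caimnet.modulation import BinarizedTrain, ModulationResult, binarize
from caimnet.events import detect_events
from caimnet.synthetic import SimConfig, simulate_speed, simulate_traces

from conftest import alternating_segmentation, sparse_train


class TestPairEligibility:
    def test_distance_boundary_is_inclusive(self):
        assert not pair_eligible((0, 0), (19.9, 0))
        assert pair_eligible((0, 0), (20.0, 0))

    def test_twenty_pixels_is_26_microns(self):
        assert centroid_distance_um((0, 0), (20, 0)) == pytest.approx(26.2, abs=0.05)


class TestStateConcatenate:
    def test_session_scope_is_identity(self, rng):
        seg = alternating_segmentation(1200)
        x = sparse_train(rng, 1200)
        assert np.array_equal(state_concatenate(x, seg, "session"), x)

    def test_concatenated_length_is_total_state_time(self):
        seg = BoutSegmentation(
            [(0, 100, "run"), (100, 500, "rest"), (500, 600, "run")],
            n_samples=600, fs=20.0)
        x = np.arange(600)
        out = state_concatenate(x, seg, "run")
        assert out.size == 200
        assert np.array_equal(out, np.r_[np.arange(100), np.arange(500, 600)])

    def test_event_count_preserved_inside_bouts(self, rng):
        seg = alternating_segmentation(6000)
        x = sparse_train(rng, 6000)
        out = state_concatenate(x, seg, "rest")
        assert out.sum() == x[seg.mask("rest")].sum()

    def test_empty_scope_rejected(self, rng):
        seg = BoutSegmentation([(0, 100, "rest")], n_samples=100, fs=20.0)
        with pytest.raises(ValueError):
            state_concatenate(np.zeros(100, np.uint8), seg, "run")


class TestCorrelationTest:
    def test_identical_trains_perfectly_correlated(self, rng):
        x = sparse_train(rng, 4000)
        res = correlation_test(x, x.copy(), n_shuffles=500, rng=1)
        assert res.r == pytest.approx(1.0)
        assert res.klass == CORRELATED

    def test_constant_train_is_ineligible(self):
        res = correlation_test(np.zeros(100, np.uint8),
                               np.ones(100, np.uint8), rng=0)
        assert res.klass == INELIGIBLE
        assert np.isnan(res.r)

    def test_symmetric_in_pair_order(self, rng):
        xi, xj = sparse_train(rng, 4000), sparse_train(rng, 4000)
        a = correlation_test(xi, xj, i=3, j=7, rng=11)
        b = correlation_test(xj, xi, i=7, j=3, rng=11)
        assert (a.i, a.j, a.r, a.null_p95, a.klass) == (b.i, b.j, b.r, b.null_p95, b.klass)

    def test_null_r_matches_rolled_pearson(self, rng):
        xi, xj = sparse_train(rng, 2000), sparse_train(rng, 2000)
        lags = np.array([5, 123, 1999])
        fast = _null_r(xi, xj, lags)
        slow = [np.corrcoef(xi, np.roll(xj, lag))[0, 1] for lag in lags]
        assert np.allclose(fast, slow)

    def test_mean_r_grows_with_shared_fraction(self):
        """Pairs copying from a common source correlate more strongly."""
        means = {}
        for sf in (0.0, 0.5):
            cfg = SimConfig(n_cells=12, shared_fraction=sf,
                            correlated_pair_fraction=1.0 if sf else 0.0,
                            source_rate=3.0, seed=51)
            _, bouts = simulate_speed(cfg)
            _, truth = simulate_traces(cfg, bouts)
            cfg2 = cfg
            traces, truth = simulate_traces(cfg2, bouts)
            n = traces[0].values.size
            rs = []
            for i, j in [(2 * k, 2 * k + 1) for k in range(6)]:
                xi = binarize(n, detect_events(traces[i].values)).x
                xj = binarize(n, detect_events(traces[j].values)).x
                rs.append(_pearson_binary(xi, xj))
            means[sf] = np.nanmean(rs)
        assert means[0.5] > means[0.0]


class TestClassifySession:
    def _setup(self, rng, n_cells=6, n=4000):
        trains = [BinarizedTrain(cell_id=i, x=sparse_train(rng, n))
                  for i in range(n_cells)]
        centroids = np.array([(40.0 * i, 0.0) for i in range(n_cells)])
        seg = alternating_segmentation(n)
        return trains, centroids, seg

    def test_identical_trains_all_correlated(self, rng):
        x = sparse_train(rng, 4000)
        trains = [BinarizedTrain(cell_id=i, x=x.copy()) for i in range(4)]
        centroids = np.array([(40.0 * i, 0.0) for i in range(4)])
        seg = alternating_segmentation(4000)
        _, frac = classify_session(trains, centroids, seg, scope="session",
                                   n_shuffles=200, rng=3)
        assert frac == 1.0

    def test_close_pairs_are_ineligible(self, rng):
        trains, centroids, seg = self._setup(rng)
        centroids[1] = centroids[0] + (5.0, 0.0)  # under 20 px
        pairs, _ = classify_session(trains, centroids, seg, scope="session",
                                    n_shuffles=100, rng=4)
        p01 = next(p for p in pairs if (p.i, p.j) == (0, 1))
        assert p01.klass == INELIGIBLE

    def test_deterministic_under_fixed_seed(self, rng):
        trains, centroids, seg = self._setup(rng)
        a = classify_session(trains, centroids, seg, "rest", 200, rng=9)
        b = classify_session(trains, centroids, seg, "rest", 200, rng=9)
        assert [(p.r, p.klass) for p in a[0]] == [(p.r, p.klass) for p in b[0]]
        assert a[1] == b[1]


class TestSubgroupMeans:
    def _mods(self, flags):
        return [ModulationResult(cell_id=i, A_obs=0, threshold=0, is_modulated=f)
                for i, f in enumerate(flags)]

    def test_all_modulated_leaves_only_modmod(self, rng):
        n = 4000
        seg = alternating_segmentation(n)
        trains = [BinarizedTrain(i, sparse_train(rng, n)) for i in range(4)]
        pairs = [correlation_test(trains[i].x, trains[j].x, 100, rng, i=i, j=j)
                 for i in range(4) for j in range(i + 1, 4)]
        # force all pairs session-relevant for the decomposition
        for p in pairs:
            p.klass = CORRELATED
        out = subgroup_means(pairs, self._mods([True] * 4), trains, seg)
        assert set(out["subgroup"]) == {"Mod-Mod"}

    def test_subgroup_rows_partition_pairs(self, rng):
        n = 4000
        seg = alternating_segmentation(n)
        trains = [BinarizedTrain(i, sparse_train(rng, n)) for i in range(6)]
        pairs = [correlation_test(trains[i].x, trains[j].x, 100, rng, i=i, j=j)
                 for i in range(6) for j in range(i + 1, 6)]
        for p in pairs:
            p.klass = CORRELATED
        mods = self._mods([True, True, False, False, True, False])
        # per-pair detail: each correlated pair contributes one subgroup x 2 states
        detail_rows = 0
        out = subgroup_means(pairs, mods, trains, seg)
        assert set(out["state"]) == {"rest", "run"}
        assert set(out["subgroup"]) <= {"Mod-Mod", "Mod-Non", "Non-Non"}

    def test_run_active_shared_source_shows_in_modmod_run_mean(self):
        """Mod-Mod pairs driven by a running-only source correlate during run."""
        rng = np.random.default_rng(61)
        n = 12000
        seg = alternating_segmentation(n)
        run_mask = seg.mask("run")
        source = np.flatnonzero((rng.random(n) < 0.004) & run_mask)
        trains = []
        for i in range(4):
            x = sparse_train(rng, n, rate_per_min=1.0)
            if i < 2:  # modulated cells share the run-active source
                for o in source[rng.random(source.size) < 0.9]:
                    x[o : o + 10] = 1
            trains.append(BinarizedTrain(i, x))
        pairs = [correlation_test(trains[i].x, trains[j].x, 100, rng, i=i, j=j)
                 for i in range(4) for j in range(i + 1, 4)]
        for p in pairs:
            p.klass = CORRELATED
        out = subgroup_means(pairs, self._mods([True, True, False, False]),
                             trains, seg)
        mm = out[out["subgroup"] == "Mod-Mod"].set_index("state")["mean_r"]
        assert mm["run"] > mm["rest"]


class TestRateCorrelationControl:
    def test_shuffled_r_centered_on_zero_and_rate_dependence(self):
        rng = np.random.default_rng(71)
        n = 12000  # full 600-s session, where the sparse-regime effect lives
        seg = alternating_segmentation(n)
        trains = [BinarizedTrain(i, sparse_train(rng, n, rate_per_min=1.0))
                  for i in range(6)]
        trains += [BinarizedTrain(6 + i, sparse_train(rng, n, rate_per_min=4.0))
                   for i in range(6)]
        out = rate_correlation_control(trains, seg, scope="session",
                                       n_shuffles=100, rng=rng)
        all_r = np.concatenate(out["r_shuffled"].to_list())
        assert abs(all_r.mean()) < 0.01
        # chance-level r shrinks as event rate rises in the sparse regime
        lo = out[out["mean_rate"] < 2.0]
        hi = out[out["mean_rate"] > 3.0]
        p95_lo = np.mean([np.percentile(r, 95) for r in lo["r_shuffled"]])
        p95_hi = np.mean([np.percentile(r, 95) for r in hi["r_shuffled"]])
        assert p95_hi < p95_lo

    def test_identical_trains_still_shuffle_to_zero(self, rng):
        n = 8000
        seg = alternating_segmentation(n)
        x = sparse_train(rng, n)
        trains = [BinarizedTrain(0, x), BinarizedTrain(1, x.copy())]
        out = rate_correlation_control(trains, seg, scope="rest",
                                       n_shuffles=200, rng=rng)
        assert abs(np.mean(out["r_shuffled"].iloc[0])) < 0.02
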