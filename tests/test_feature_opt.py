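import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evobci.bmflc import AmplitudeMap, BMFLCConfig
from evobci.evolution import EvolutionTrace
from evobci.feature_opt import (
    MAX_BW_HZ,
    SpatialFilterBank,
    _fast_lda_predict,
    build_feature_matrix,
    decode_solution,
    error_improvement,
    fitness,
    optimize,
    project_features,
    solution_bounds,
    solution_length,
)

CFG = BMFLCConfig()  # 6-14 Hz, 0.5 Hz grid, 17 bins


def random_map(rng, channels=4, samples=50):
    return AmplitudeMap(
        amplitudes=rng.uniform(0, 2, size=(channels, CFG.n_bins, samples)),
        bin_freqs_hz=CFG.bin_freqs_hz,
    )


def make_sol(bank, fs, bw):
    return np.concatenate([np.ravel(bank), [fs, bw]])


class TestDecode:
    def test_layout_forces_length_46_for_22ch(self):
        assert solution_length(22, 2) == 46
        sol = np.zeros(46)
        sol[-2:] = [8.0, 2.0]
        bank, _ = decode_solution(sol, CFG, 22, 2)
        assert bank.matrix.shape == (2, 22)

    def test_snapping_rule_by_hand(self):
        # FS=8.3 snaps to 8.5 Hz (bin 5); BW=2.0 spans 4 grid steps -> fe
        # at 10.5 Hz (bin 9), 5 bins selected
        sol = make_sol(np.zeros((2, 4)), 8.3, 2.0)
        _, (fs, fe) = decode_solution(sol, CFG, 4, 2)
        assert (fs, fe) == (5, 9)
        assert CFG.bin_freqs_hz[fs] == 8.5
        assert CFG.bin_freqs_hz[fe] == 10.5

    def test_max_bandwidth_selects_seven_bins(self):
        sol = make_sol(np.zeros((2, 4)), 9.0, 3.0)
        _, (fs, fe) = decode_solution(sol, CFG, 4, 2)
        assert fe - fs + 1 == 7

    def test_infeasible_values_repaired(self):
        sol = make_sol(np.zeros((2, 4)), 20.0, 9.0)
        _, (fs, fe) = decode_solution(sol, CFG, 4, 2)
        n = CFG.n_bins
        assert 0 <= fs <= fe <= n - 1
        assert (fe - fs) * CFG.delta_f_hz <= MAX_BW_HZ

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            decode_solution(np.zeros(9), CFG, 4, 2)

    @settings(max_examples=200, deadline=None)
    @given(
        fs=st.floats(-50, 50, allow_nan=False),
        bw=st.floats(-10, 10, allow_nan=False),
    )
    def test_every_decoded_band_feasible(self, fs, bw):
        sol = make_sol(np.zeros((2, 4)), fs, bw)
        _, (lo, hi) = decode_solution(sol, CFG, 4, 2)
        assert 0 <= lo <= hi <= CFG.n_bins - 1
        assert (hi - lo) * CFG.delta_f_hz <= MAX_BW_HZ + 1e-12


class TestFeatureMatrix:
    def test_full_band_shape(self, rng):
        m = random_map(rng, channels=22)
        F = build_feature_matrix(m, (0, 16), k=3)
        assert F.shape == (22, 17)
        assert F.size == 374

    def test_single_bin_column(self, rng):
        F = build_feature_matrix(random_map(rng), (4, 4), k=0)
        assert F.shape == (4, 1)

    def test_entries_are_indexed_lookup(self, rng):
        m = random_map(rng)
        F = build_feature_matrix(m, (2, 6), k=7)
        np.testing.assert_array_equal(F, m.amplitudes[:, 2:7, 7])

    def test_invalid_band_rejected(self, rng):
        with pytest.raises(ValueError):
            build_feature_matrix(random_map(rng), (5, 99), k=0)


class TestProjection:
    def test_selector_rows_give_channel_means(self, rng):
        m = random_map(rng)
        bank = SpatialFilterBank(np.eye(4)[:2])
        out = project_features(m, (3, 5), bank)
        expect = m.amplitudes[:2, 3:6, :].mean(axis=2).ravel()
        np.testing.assert_allclose(out, expect)

    def test_zero_bank_gives_zero_features(self, rng):
        out = project_features(random_map(rng), (0, 2),
                               SpatialFilterBank(np.zeros((2, 4))))
        assert np.all(out == 0)

    def test_matches_triple_loop_oracle(self, rng):
        m = random_map(rng, channels=3, samples=10)
        W = rng.standard_normal((2, 3))
        fs, fe = 2, 5
        out = project_features(m, (fs, fe), SpatialFilterBank(W))
        n_sel = fe - fs + 1
        expect = np.zeros((2, n_sel))
        for p in range(2):
            for j in range(n_sel):
                acc = 0.0
                for k in range(10):
                    for c in range(3):
                        acc += W[p, c] * m.amplitudes[c, fs + j, k]
                expect[p, j] = acc / 10
        np.testing.assert_allclose(out, expect.ravel())

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            project_features(random_map(rng, channels=3), (0, 1),
                             SpatialFilterBank(np.zeros((2, 5))))


def planted_maps(rng, n_trials=24, channels=4, bins_hot=(6, 8)):
    """Amplitude maps where class 1 has extra power in given bins/ch 0."""
    maps, labels = [], []
    for t in range(n_trials):
        lab = t % 2
        amp = rng.uniform(0.5, 1.0, size=(channels, CFG.n_bins, 30))
        if lab:
            amp[0, bins_hot[0]: bins_hot[1] + 1, :] += 3.0
        maps.append(AmplitudeMap(amplitudes=amp, bin_freqs_hz=CFG.bin_freqs_hz))
        labels.append(lab)
    return maps, np.array(labels)


class TestFitness:
    def test_separable_data_reaches_zero_error(self, rng):
        maps, labels = planted_maps(rng)
        sol = make_sol(np.eye(4)[:2], 9.0, 1.0)
        err = fitness(sol, maps, labels, CFG, 4, 2, cv_folds=4, seed=0)
        assert err == 0.0

    def test_permuted_labels_near_chance(self, rng):
        maps, labels = planted_maps(rng, n_trials=40)
        sol = make_sol(rng.standard_normal((2, 4)), 9.0, 1.0)
        errs = [
            fitness(sol, maps, np.random.default_rng(s).permutation(labels),
                    CFG, 4, 2, cv_folds=4, seed=0)
            for s in range(20)
        ]
        assert abs(np.mean(errs) - 0.5) < 0.1

    def test_bit_identical_for_same_seed(self, rng):
        maps, labels = planted_maps(rng)
        sol = make_sol(rng.standard_normal((2, 4)), 8.0, 2.0)
        a = fitness(sol, maps, labels, CFG, 4, 2, seed=5)
        b = fitness(sol, maps, labels, CFG, 4, 2, seed=5)
        assert a == b

    def test_bounded_in_unit_interval(self, rng):
        maps, labels = planted_maps(rng)
        for _ in range(10):
            sol = make_sol(rng.standard_normal((2, 4)),
                           rng.uniform(0, 20), rng.uniform(-1, 5))
            err = fitness(sol, maps, labels, CFG, 4, 2, seed=1)
            assert 0.0 <= err <= 1.0

    def test_row_scale_equivariance(self, rng):
        # positive rescaling of one filter row cannot change the error:
        # features are z-scored with fold-train statistics
        maps, labels = planted_maps(rng)
        bank = rng.standard_normal((2, 4))
        e1 = fitness(make_sol(bank, 9.0, 2.0), maps, labels, CFG, 4, 2, seed=2)
        bank2 = bank.copy()
        bank2[0] *= 37.5
        e2 = fitness(make_sol(bank2, 9.0, 2.0), maps, labels, CFG, 4, 2, seed=2)
        assert e1 == pytest.approx(e2, abs=1e-12)


class TestFastLDAOracle:
    def test_matches_sklearn_estimator_route(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        for _ in range(25):
            Xtr = rng.standard_normal((30, 6))
            ytr = rng.integers(0, 2, 30)
            if len(np.unique(ytr)) < 2 or np.bincount(ytr).min() < 2:
                continue
            Xtr[ytr == 1] += 0.8
            Xte = rng.standard_normal((15, 6)) + 0.4
            sk = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.1)
            sk.fit(Xtr, ytr)
            np.testing.assert_array_equal(
                _fast_lda_predict(Xtr, ytr, Xte, gamma=0.1), sk.predict(Xte)
            )


class TestOptimize:
    def test_recovers_planted_band(self, small_subject):
        ep, truth = small_subject
        res = optimize(ep, engine="cmaes", seed=0, max_generations=25)
        lo, hi = res.band_hz
        assert lo <= truth.band_hz[1] and hi >= truth.band_hz[0]  # overlap
        assert res.best_error <= 0.2

    def test_filter_count_defaults_to_class_count(self, small_subject):
        ep, _ = small_subject
        res = optimize(ep, engine="cmaes", seed=1, max_generations=2)
        assert res.bank.matrix.shape == (2, ep.n_channels)
        assert len(res.solution) == solution_length(ep.n_channels, 2)

    def test_unknown_engine_rejected(self, small_subject):
        ep, _ = small_subject
        with pytest.raises(ValueError):
            optimize(ep, engine="annealing")

    def test_decoded_bandwidth_never_exceeds_cap(self, small_subject):
        ep, _ = small_subject
        for seed in range(3):
            res = optimize(ep, engine="cmaes", seed=seed, max_generations=3)
            lo, hi = res.band_hz
            assert hi - lo <= MAX_BW_HZ + 1e-12

    def test_bounds_layout(self):
        b = solution_bounds(4, 2, CFG)
        assert b.shape == (10, 2)
        assert np.all(np.isinf(b[:-2]))
        assert tuple(b[-2]) == (6.0, 14.0)
        assert tuple(b[-1]) == (0.5, 3.0)


class TestErrorImprovement:
    def test_constant_trace_zero(self):
        tr = EvolutionTrace(best_fitness=[0.4, 0.4, 0.4])
        assert error_improvement(tr) == 0.0

    def test_direct_arithmetic(self):
        tr = EvolutionTrace(best_fitness=[0.5, 0.4, 0.3])
        assert error_improvement(tr) == pytest.approx(0.2)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_monotone_trace_is_first_minus_last(self, values):
        series = np.minimum.accumulate(values)  # any non-increasing trace
        tr = EvolutionTrace(best_fitness=list(series))
        assert error_improvement(tr) == pytest.approx(series[0] - series[-1])

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            error_improvement(EvolutionTrace())
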