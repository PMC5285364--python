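import numpy as np
import pytest
from scipy import linalg

from evobci.preprocess import DataError, EpochSet
from evobci.spatial import (
    PairSelectionTable,
    apply_filters,
    class_covariances,
    generalization_index,
    optimal_pair_count,
    select_alpha,
    trcsp_fit,
)
from evobci.synth import SynthConfig, generate_subject


def mixture_epochs(rng, mixing, n_trials=20, n_samples=500):
    sources = rng.standard_normal((n_trials, mixing.shape[1], n_samples))
    data = np.einsum("cm,tms->tcs", mixing, sources)
    labels = np.arange(n_trials) % 2
    return EpochSet(data=data, labels=labels, rate_hz=250.0)


class TestClassCovariances:
    def test_isotropic_noise_gives_scaled_identity(self, rng):
        data = rng.standard_normal((40, 4, 2000))
        ep = EpochSet(data=data, labels=np.arange(40) % 2, rate_hz=250.0)
        c1, c2 = class_covariances(ep)
        np.testing.assert_allclose(c1, np.eye(4) / 4, atol=0.02)
        np.testing.assert_allclose(c2, np.eye(4) / 4, atol=0.02)

    def test_known_mixture_recovered(self, rng):
        A = rng.standard_normal((4, 4))
        ep = mixture_epochs(rng, A, n_trials=40, n_samples=4000)
        c1, _ = class_covariances(ep)
        target = A @ A.T
        np.testing.assert_allclose(c1, target / np.trace(target), atol=0.02)

    def test_unit_trace_contract(self, noise_epochs):
        c1, c2 = class_covariances(noise_epochs)
        assert np.trace(c1) == pytest.approx(1.0, abs=1e-10)
        assert np.trace(c2) == pytest.approx(1.0, abs=1e-10)

    def test_zero_trial_rejected(self):
        ep = EpochSet(data=np.zeros((2, 2, 50)), labels=np.array([0, 1]),
                      rate_hz=100.0)
        with pytest.raises(DataError):
            class_covariances(ep)


class TestTRCSP:
    def test_two_by_two_hand_solution(self):
        c1 = np.diag([4.0, 1.0])
        c2 = np.diag([1.0, 4.0])
        model = trcsp_fit(c1, c2, n_pairs=1, alpha=0.0)
        # best class-1 filter picks channel 1 with objective 4/(4+1) = 0.8
        assert abs(model.filters[0, 0]) == pytest.approx(1.0)
        assert model.objective_values[0] == pytest.approx(0.8)
        assert model.objective_values[1] == pytest.approx(0.8)

    def test_identical_covariances_tie(self, rng):
        c = np.cov(rng.standard_normal((3, 200)))
        model = trcsp_fit(c, c, n_pairs=1, alpha=0.0)
        np.testing.assert_allclose(model.objective_values, 0.5, atol=1e-10)

    def test_matches_generalized_eig_oracle(self, rng):
        # alpha=0 must agree with a direct generalized eigendecomposition
        # up to sign/scale
        X = rng.standard_normal((5, 200))
        Y = rng.standard_normal((5, 200))
        c1, c2 = np.cov(X), np.cov(Y)
        model = trcsp_fit(c1, c2, n_pairs=2, alpha=0.0)
        vals, vecs = linalg.eigh(c1, c1 + c2)
        order = np.argsort(vals)[::-1]
        for j, row in enumerate([0, 2]):  # class-1 rows
            w = model.filters[row]
            v = vecs[:, order[j]] / np.linalg.norm(vecs[:, order[j]])
            assert min(np.linalg.norm(w - v), np.linalg.norm(w + v)) < 1e-8

    def test_objectives_pair_sum_to_one(self, rng):
        A = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        B = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        c1, c2 = A @ A.T, B @ B.T
        c1, c2 = c1 / np.trace(c1), c2 / np.trace(c2)
        model = trcsp_fit(c1, c2, n_pairs=2)
        v = model.objective_values
        assert np.all((v >= 0) & (v <= 1 + 1e-12))
        # every filter's two Rayleigh quotients are complementary:
        # w'C1w/w'(C1+C2)w + w'C2w/w'(C1+C2)w = 1, and the stored value is
        # the quotient for the filter's own class
        for row, val in zip(model.filters, v, strict=True):
            q1 = row @ c1 @ row / (row @ (c1 + c2) @ row)
            q2 = row @ c2 @ row / (row @ (c1 + c2) @ row)
            assert q1 + q2 == pytest.approx(1.0)
            assert val == pytest.approx(max(q1, q2) if val > 0.5 else min(q1, q2),
                                        abs=1e-8)

    def test_simultaneous_diagonalization(self, rng):
        A = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        B = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        c1, c2 = A @ A.T, B @ B.T
        model = trcsp_fit(c1, c2, n_pairs=2, alpha=0.0)
        W = model.filters
        # class-1 rows (0, 2) are eigenvectors of (C1, C1+C2): off-diagonal
        # cross terms vanish among them
        for rows in ([0, 2], [1, 3]):
            G1 = W[rows] @ c1 @ W[rows].T
            G2 = W[rows] @ c2 @ W[rows].T
            np.testing.assert_allclose(G1 - np.diag(np.diag(G1)), 0, atol=1e-8)
            np.testing.assert_allclose(G2 - np.diag(np.diag(G2)), 0, atol=1e-8)

    def test_regularization_shrinks_objectives(self, rng):
        A = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        c1, c2 = A @ A.T, np.eye(4)
        prev = np.inf
        for alpha in (0.0, 1.0, 100.0, 1e4):
            v = trcsp_fit(c1, c2, 1, alpha).objective_values.max()
            assert v <= prev + 1e-12
            prev = v
        assert prev < 0.05

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            trcsp_fit(np.eye(2), np.eye(2), 1, alpha=-0.1)

    def test_pair_capacity_bound(self):
        c = np.eye(22)
        trcsp_fit(c, c, n_pairs=11)  # 11 pairs fit a 22-channel montage
        with pytest.raises(ValueError):
            trcsp_fit(c, c, n_pairs=12)

    def test_apply_filters_projects(self, rng):
        ep = mixture_epochs(rng, rng.standard_normal((4, 4)))
        model = trcsp_fit(*class_covariances(ep), n_pairs=1)
        out = apply_filters(ep, model)
        assert out.data.shape == (ep.n_trials, 2, ep.n_samples)
        np.testing.assert_allclose(
            out.data[0], model.filters @ ep.data[0], atol=1e-12
        )


class TestSelectAlpha:
    def test_single_candidate_returned(self, small_subject):
        ep, _ = small_subject
        assert select_alpha(ep, candidates=[0.01], folds=3) == 0.01

    def test_clean_data_prefers_smallest_tie(self):
        cfg = SynthConfig(channels=4, trials_per_class=10, rate_hz=160,
                          duration_s=1.5, erd_depth=0.95, noise_level=0.3,
                          seed=11)
        ep, _ = generate_subject(cfg)
        # perfectly separable at alpha=0, so the parsimony tie-break wins
        assert select_alpha(ep, candidates=[0.0, 0.1], folds=3) == 0.0

    def test_matches_exhaustive_sweep(self, small_subject):
        from evobci.classify import cross_validate
        from evobci.pipelines import csp_bmflc_pipeline

        ep, _ = small_subject
        cands = [0.0, 0.5]
        got = select_alpha(ep, candidates=cands, folds=3, seed=1)
        scores = {
            a: cross_validate(ep, csp_bmflc_pipeline(1, a), folds=3, seed=1).mean
            for a in cands
        }
        best = max(sorted(cands), key=lambda a: (scores[a], -a))
        assert got == best


class TestGeneralizationIndex:
    def test_hand_computed_example(self):
        table = PairSelectionTable(
            accuracy=[[0.6, 0.8, 0.7], [0.9, 0.7, 0.8]],
            pair_counts=[1, 2, 3],
        )
        np.testing.assert_allclose(generalization_index(table), [0.5, 0.5, 0.5])
        assert optimal_pair_count(table) == 1  # tie resolves to fewer pairs

    def test_single_subject_is_own_curve(self):
        table = PairSelectionTable(accuracy=[[0.55, 0.75, 0.65]],
                                   pair_counts=[1, 2, 3])
        idx = generalization_index(table)
        np.testing.assert_allclose(idx, [0.0, 1.0, 0.5])
        assert idx.max() == 1.0

    def test_constant_row_treated_as_indifferent(self):
        table = PairSelectionTable(accuracy=[[0.7, 0.7], [0.6, 0.9]],
                                   pair_counts=[1, 2])
        np.testing.assert_allclose(generalization_index(table), [0.5, 1.0])

    def test_affine_invariance(self, rng):
        acc = rng.uniform(0.5, 1.0, size=(5, 4))
        t1 = PairSelectionTable(accuracy=acc, pair_counts=np.arange(1, 5))
        scaled = 0.3 * acc + 0.1 * rng.uniform(size=(5, 1))
        t2 = PairSelectionTable(accuracy=scaled, pair_counts=np.arange(1, 5))
        np.testing.assert_allclose(
            generalization_index(t1), generalization_index(t2), atol=1e-12
        )
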