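"""EKI arm tests: SMOTE geometry, constrained fit vs grid oracle, scoring."""

import numpy as np
import pytest

from sozloc import eki


def _pair(vec, y, synthetic=False):
    v = np.asarray(vec, float)
    if not synthetic:
        v = v / np.linalg.norm(v)
    return eki.TrainingPair(v, y, synthetic)


def grid_fit_objective(pairs, omega):
    A = np.stack([p.y * p.f_hat for p in pairs])
    r = 1.0 - A @ omega
    return float(r @ r)


def grid_search_omega(pairs, d, lo=-3.0, hi=4.0, steps=281):
    """Dense search over the sum-to-one constraint set (d <= 3)."""
    best, best_obj = None, np.inf
    grid = np.linspace(lo, hi, steps)
    if d == 2:
        cands = ([a, 1 - a] for a in grid)
    elif d == 3:
        cands = ([a, b, 1 - a - b] for a in grid for b in grid)
    else:
        raise ValueError
    for w in cands:
        obj = grid_fit_objective(pairs, np.asarray(w))
        if obj < best_obj:
            best_obj, best = obj, np.asarray(w)
    return best, best_obj


class TestSmote:
    def test_balances_and_interpolates_between_minority_neighbors(self):
        rng = np.random.default_rng(0)
        soz = [_pair([1, 0.1 * k], 1) for k in range(2)]
        rsn = [_pair([0.1 * k + 0.05, 1], -1) for k in range(10)]
        out = eki.balance_with_smote(soz + rsn, k_neighbors=1, rng=rng)
        pos = [p for p in out if p.y == 1]
        neg = [p for p in out if p.y == -1]
        assert len(pos) == len(neg) == 10
        a, b = soz[0].f_hat, soz[1].f_hat
        for p in pos:
            if not p.synthetic:
                continue
            # on the segment between the only two real SOZ points
            t = np.linalg.norm(p.f_hat - a) / np.linalg.norm(b - a)
            np.testing.assert_allclose(p.f_hat, a + t * (b - a), atol=1e-9)
            assert -1e-9 <= t <= 1 + 1e-9

    def test_already_balanced_unchanged(self):
        pairs = [_pair([1, 0], 1), _pair([0, 1], -1)]
        assert eki.balance_with_smote(pairs, rng=0) == pairs

    def test_synthetic_values_within_minority_envelope(self):
        rng = np.random.default_rng(1)
        soz = [_pair(v, 1) for v in np.random.default_rng(2).random((5, 3)) + 0.1]
        rsn = [_pair(v, -1) for v in np.random.default_rng(3).random((20, 3)) + 0.1]
        out = eki.balance_with_smote(soz + rsn, k_neighbors=3, rng=rng)
        X = np.stack([p.f_hat for p in soz])
        lo, hi = X.min(axis=0), X.max(axis=0)
        for p in out:
            if p.synthetic:
                assert np.all(p.f_hat >= lo - 1e-12)
                assert np.all(p.f_hat <= hi + 1e-12)

    def test_single_minority_sample_rejected(self):
        pairs = [_pair([1, 0], 1)] + [_pair([0, 1], -1)] * 5
        with pytest.raises(ValueError):
            eki.balance_with_smote(pairs, rng=0)


class TestFitWeights:
    def test_one_dimension_forced_by_constraint(self):
        pairs = [
            eki.TrainingPair(np.array([1.0]), 1),
            eki.TrainingPair(np.array([1.0]), -1),
        ]
        model = eki.fit_weights(pairs)
        np.testing.assert_allclose(model.omega, [1.0])

    def test_perfectly_separating_feature_takes_all_weight(self):
        pairs = [
            eki.TrainingPair(np.array([1.0, 0.0]), 1),
            eki.TrainingPair(np.array([-1.0, 0.0]), -1),
        ] * 3
        model = eki.fit_weights(pairs)
        np.testing.assert_allclose(model.omega, [1.0, 0.0], atol=1e-9)
        assert model.objective == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_features_split_evenly(self):
        v = 1 / np.sqrt(2)
        with pytest.warns(UserWarning):
            model = eki.fit_weights(
                [
                    eki.TrainingPair(np.array([v, v]), 1),
                    eki.TrainingPair(np.array([-v, -v]), -1),
                ]
            )
        np.testing.assert_allclose(model.omega, [0.5, 0.5], atol=1e-9)

    def test_sum_constraint_holds_after_every_fit(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            d = int(rng.integers(1, 5))
            n = int(rng.integers(2, 20))
            pairs = []
            for k in range(n):
                v = rng.normal(size=d)
                pairs.append(eki.TrainingPair(v / np.linalg.norm(v), 1 if k % 2 else -1))
            model = eki.fit_weights(pairs)
            assert abs(model.omega.sum() - 1.0) < 1e-9

    @pytest.mark.parametrize("d", [2, 3])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_grid_search_oracle(self, d, seed):
        rng = np.random.default_rng(seed)
        pairs = []
        for k in range(12):
            v = rng.normal(size=d)
            pairs.append(eki.TrainingPair(v / np.linalg.norm(v), 1 if k % 2 else -1))
        model = eki.fit_weights(pairs)
        _, grid_obj = grid_search_omega(pairs, d)
        assert model.objective <= grid_obj + 1e-3

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            eki.fit_weights([eki.TrainingPair(np.array([1.0]), 1)])


class TestConfidence:
    MODEL4 = eki.EKIModel(np.array([1.0, 0, 0, 0]))

    def test_aligned_unit_weight_scores_one(self):
        assert eki.confidence_score(self.MODEL4, np.array([2.0, 0, 0, 0])) == pytest.approx(1.0)

    def test_scale_invariance(self):
        m = eki.EKIModel(np.array([0.3, 0.2, 0.1, 0.4]))
        f = np.array([0.5, 1.2, 0.1, 0.9])
        assert eki.confidence_score(m, f) == pytest.approx(
            eki.confidence_score(m, 10.0 * f), abs=1e-12
        )

    def test_hand_computed_value(self):
        m = eki.EKIModel(np.array([0.5, 0.5]), feature_names=("a", "b"))
        assert eki.confidence_score(m, np.array([3.0, 4.0])) == pytest.approx(0.7)

    def test_zero_vector_scores_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert eki.confidence_score(self.MODEL4, np.zeros(4)) == 0.0


class TestClassify:
    def test_sign_rule(self):
        m = eki.EKIModel(np.array([1.0, 0.0]), feature_names=("a", "b"))
        lab_pos, rho_pos, _ = eki.classify_eki(m, np.array([0.95, 0.1]))
        lab_neg, rho_neg, _ = eki.classify_eki(m, np.array([-0.3, 0.1]))
        assert lab_pos == "SOZ" and rho_pos > 0
        assert lab_neg == "RSN" and rho_neg < 0

    def test_explanation_is_largest_contribution(self):
        m = eki.EKIModel(np.array([0.7, 0.3]), feature_names=("a", "b"))
        _, _, expl = eki.classify_eki(m, np.array([0.2, 0.9]))
        assert expl == "b"  # contributions (0.14, 0.27)
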