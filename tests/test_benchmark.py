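import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mhc2lig.benchmark import (
    PairData,
    auc,
    auc01,
    auc01_from_scores,
    auc_from_scores,
    cross_validate,
    evaluate_dataset,
    evaluate_pair,
    grid_search,
    model_scores,
    paired_model_test,
    roc_points,
)
from mhc2lig.data_io import ValidationError
from mhc2lig.scaling_model import ModelWeights, build_scalers
from mhc2lig.window_features import build_pair_windows


from _oracles import (
    brute_force_pauc,
    mann_whitney_auc,
    random_roc_instance as random_instance,
)


# ---------------------------------------------------------------------------
# ROC primitives
# ---------------------------------------------------------------------------

class TestRocPoints:
    def test_perfect_separation_passes_through_0_1(self):
        curve = roc_points([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert any(np.allclose(p, [0.0, 1.0]) for p in curve)
        assert np.allclose(curve[0], [0.0, 0.0])
        assert np.allclose(curve[-1], [1.0, 1.0])

    def test_all_equal_scores_is_diagonal(self):
        curve = roc_points([0.5] * 6, [True, False, True, False, False, False])
        assert np.allclose(curve, [[0, 0], [1, 1]])
        assert auc(curve) == pytest.approx(0.5)

    def test_spec_instance_auc_0875(self):
        scores = [0.9, 0.5, 0.5, 0.1]
        labels = [True, True, False, False]
        assert mann_whitney_auc(scores, labels) == pytest.approx(0.875)
        assert auc_from_scores(scores, labels) == pytest.approx(0.875)

    def test_single_class_error(self):
        with pytest.raises(ValidationError):
            roc_points([0.1, 0.2], [True, True])


class TestAuc:
    def test_perfect(self):
        assert auc_from_scores([0.9, 0.1], [True, False]) == pytest.approx(1.0)

    def test_reversed(self):
        assert auc_from_scores([0.1, 0.9], [True, False]) == pytest.approx(0.0)

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            scores, labels = random_instance(rng)
            assert auc_from_scores(scores, labels) == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12)


class TestAuc01:
    def test_perfect(self):
        assert auc01_from_scores([0.9, 0.8, 0.1, 0.2],
                                 [True, True, False, False]) == pytest.approx(1.0)

    def test_random_scores_large_sample(self):
        rng = np.random.default_rng(77)
        n = 40_000
        scores = rng.uniform(0, 1, n)
        labels = np.arange(n) < n // 2
        assert auc01_from_scores(scores, labels) == pytest.approx(0.05, abs=0.01)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(321)
        for _ in range(300):
            scores, labels = random_instance(rng)
            assert auc01_from_scores(scores, labels) == pytest.approx(
                brute_force_pauc(scores, labels), abs=1e-12)

    def test_bounds_and_perfect_iff(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            scores, labels = random_instance(rng)
            v = auc01_from_scores(scores, labels)
            assert 0.0 <= v <= 1.0
            if min(scores[labels]) > max(scores[~labels]):
                assert v == pytest.approx(1.0)

    @given(st.integers(0, 2**31))
    @settings(max_examples=60, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = random_instance(rng)
        transformed = np.exp(3.0 * scores) + 1.0  # strictly increasing
        assert auc_from_scores(transformed, labels) == pytest.approx(
            auc_from_scores(scores, labels), abs=1e-12)
        assert auc01_from_scores(transformed, labels) == pytest.approx(
            auc01_from_scores(scores, labels), abs=1e-12)


# ---------------------------------------------------------------------------
# Pair/dataset evaluation
# ---------------------------------------------------------------------------

def _toy_pair(scores, ligand_idx, features=None):
    n = len(scores)
    labels = np.zeros(n, dtype=bool)
    labels[ligand_idx] = True
    feats = {f: (features[f] if features and f in features else np.zeros(n))
             for f in ("rsa", "helix", "strand", "coil")}
    return PairData("P", "L", "DRB1*0401", np.asarray(scores, float),
                    np.asarray(scores, float), feats, labels)


class TestEvaluatePair:
    def test_ligand_highest_is_perfect(self):
        pair = _toy_pair([0.1, 0.2, 0.9, 0.3], 2)
        a, a01 = evaluate_pair(pair, ModelWeights("rsa", 0.0))
        assert a == pytest.approx(1.0)
        assert a01 == pytest.approx(1.0)

    def test_ligand_lowest_is_zero(self):
        pair = _toy_pair([0.5, 0.2, 0.05, 0.3], 2)
        a, _ = evaluate_pair(pair, ModelWeights("rsa", 0.0))
        assert a == pytest.approx(0.0)

    def test_six_window_toy_matches_oracle(self):
        scores = [0.41, 0.55, 0.38, 0.55, 0.12, 0.70]
        pair = _toy_pair(scores, 1)
        labels = np.array([False, True, False, False, False, False])
        a, a01 = evaluate_pair(pair, ModelWeights("rsa", 0.0))
        assert a == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)
        assert a01 == pytest.approx(brute_force_pauc(scores, labels), abs=1e-12)

    def test_missing_ligand_error(self):
        pair = _toy_pair([0.1, 0.2], 0)
        pair.labels[:] = False
        with pytest.raises(ValidationError):
            evaluate_pair(pair, ModelWeights("rsa", 0.0))


class TestEvaluateDataset:
    def test_single_pair_mean(self):
        pair = _toy_pair([0.1, 0.9, 0.2], 1)
        res = evaluate_dataset([pair], ModelWeights("rsa", 0.0))
        assert res.mean_auc == pytest.approx(1.0)
        assert res.n_pairs == 1

    def test_mean_of_two_pairs(self):
        p1 = _toy_pair([0.9, 0.1, 0.2], 0)   # auc01 = 1.0
        p2 = _toy_pair([0.1, 0.9, 0.8], 0)   # auc01 = 0.0
        res = evaluate_dataset([p1, p2], ModelWeights("rsa", 0.0))
        assert res.mean_auc01 == pytest.approx(0.5)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        pairs = [_toy_pair(rng.uniform(0, 1, 20), int(rng.integers(20)))
                 for _ in range(10)]
        a = evaluate_dataset(pairs, ModelWeights("rsa", 0.0))
        b = evaluate_dataset(pairs[::-1], ModelWeights("rsa", 0.0))
        assert a.mean_auc == pytest.approx(b.mean_auc)
        assert a.mean_auc01 == pytest.approx(b.mean_auc01)


class TestGridSearch:
    def test_single_point_grid(self):
        pair = _toy_pair([0.1, 0.9, 0.2], 1)
        res = grid_search([pair], "rsa", alphas=[0.25])
        assert res.best_weights.alpha == 0.25

    def test_objective_at_zero_matches_baseline(self, small_dataset):
        ds = small_dataset
        pairs = build_pair_windows(ds.proteins, ds.ligands, ds.tracks, ds.binding)
        scalers = build_scalers(ds.backgrounds)
        pdata = [PairData.from_windows(p, scalers) for p in pairs]
        res = grid_search(pdata, "rsa", alphas=[0.0, 0.5])
        baseline = evaluate_dataset(pdata, ModelWeights("rsa", 0.0))
        assert res.objective[0] == pytest.approx(baseline.mean_auc01, abs=1e-12)

    def test_planted_exposure_bias_gives_positive_alpha(self, small_dataset):
        ds = small_dataset
        pairs = build_pair_windows(ds.proteins, ds.ligands, ds.tracks, ds.binding)
        scalers = build_scalers(ds.backgrounds)
        pdata = [PairData.from_windows(p, scalers) for p in pairs]
        res = grid_search(pdata, "rsa")
        assert res.best_weights.alpha > 0
        assert res.best_objective >= max(res.objective[0], 0)

    def test_tie_broken_toward_smallest(self):
        # constant feature: every alpha yields identical rankings
        pair = _toy_pair([0.1, 0.9, 0.2], 1,
                         features={"rsa": np.full(3, 0.5)})
        res = grid_search([pair], "rsa")
        assert res.best_weights.alpha == 0.0

    def test_two_dim_grid_coil_rsa(self):
        pair = _toy_pair([0.1, 0.9, 0.2], 1)
        res = grid_search([pair], "coil+rsa", alphas=[0.0, 0.1],
                          betas=[0.0, 0.2])
        assert len(res.grid) == 4
        assert res.best_weights.feature == "coil+rsa"
        assert (res.best_weights.alpha, res.best_weights.beta) == (0.0, 0.0)


class TestCrossValidate:
    def _pairs(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        return [_toy_pair(rng.uniform(0, 1, 25), int(rng.integers(25)),
                          features={"rsa": rng.uniform(0, 1, 25)})
                for _ in range(n)]

    def test_partition_contract(self):
        pairs = self._pairs()
        res = cross_validate(pairs, "rsa", k=4, seed=1, alphas=[0.0, 0.5])
        assert sorted(set(res.fold_assignment)) == [0, 1, 2, 3]
        counts = np.bincount(res.fold_assignment)
        assert counts.sum() == len(pairs)
        assert counts.max() - counts.min() <= 1

    def test_leave_one_out(self):
        pairs = self._pairs(n=6)
        res = cross_validate(pairs, "rsa", k=6, seed=1, alphas=[0.0, 0.5])
        assert np.bincount(res.fold_assignment).tolist() == [1] * 6

    def test_deterministic_given_seed(self):
        pairs = self._pairs()
        r1 = cross_validate(pairs, "rsa", k=3, seed=9, alphas=[0.0, 0.3])
        r2 = cross_validate(pairs, "rsa", k=3, seed=9, alphas=[0.0, 0.3])
        assert r1.fold_alphas == r2.fold_alphas
        assert r1.pooled_auc01 == pytest.approx(r2.pooled_auc01)

    def test_fewer_pairs_than_folds(self):
        with pytest.raises(ValidationError):
            cross_validate(self._pairs(n=3), "rsa", k=5, seed=0)

    def test_stable_alpha_on_planted_signal(self, small_dataset):
        ds = small_dataset
        pairs = build_pair_windows(ds.proteins, ds.ligands, ds.tracks, ds.binding)
        scalers = build_scalers(ds.backgrounds)
        pdata = [PairData.from_windows(p, scalers) for p in pairs]
        res = cross_validate(pdata, "rsa", k=5, seed=2)
        assert res.alpha_sd <= 0.2  # small dataset: loose bound


class TestPairedModelTest:
    def test_constant_shift_significant(self):
        rng = np.random.default_rng(1)
        b = rng.uniform(0.2, 0.6, 100)
        a = b + 0.05 + rng.normal(0, 0.001, 100)
        t, p = paired_model_test(a, b)
        assert t > 0
        assert p < 1e-10

    def test_antisymmetric_differences_t_zero(self):
        a = np.array([0.5, 0.5, 0.5, 0.5])
        b = np.array([0.4, 0.6, 0.3, 0.7])
        t, p = paired_model_test(a, b)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_five_pair_closed_form(self):
        a = np.array([0.30, 0.45, 0.52, 0.28, 0.61])
        b = np.array([0.25, 0.40, 0.55, 0.20, 0.58])
        d = a - b
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_expected = 2 * stats.t.sf(abs(t_expected), df=len(d) - 1)
        t, p = paired_model_test(a, b)
        assert t == pytest.approx(t_expected, abs=1e-12)
        assert p == pytest.approx(p_expected, abs=1e-12)

    def test_degenerate_pairing_error(self):
        with pytest.raises(ValidationError):
            paired_model_test([0.3, 0.4], [0.3, 0.4])


class TestModelScores:
    def test_coil_rsa_combination(self):
        pair = _toy_pair([0.5, 0.5], 0, features={
            "rsa": np.array([0.2, 0.4]), "coil": np.array([0.6, 0.1])})
        s = model_scores(pair, ModelWeights("coil+rsa", 0.1, 0.5))
        assert s == pytest.approx([0.5 + 0.06 + 0.1, 0.5 + 0.01 + 0.2])
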