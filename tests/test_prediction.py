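import numpy as np
import pandas as pd
import pytest

import entroprint as ep
from entroprint.data import DataError, EntropyProfiles
from entroprint.prediction import (
    CognitiveAbilityRidge,
    per_network_prediction,
    ridge_fit,
)


def make_dataset(n, p, seed=0, n_signal=0, noise_sd=0.0, families=None):
    """Direct design-matrix dataset (profiles + scores) with optional sparse
    planted weights; singleton families by default."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    w = np.zeros(p)
    if n_signal:
        w[rng.choice(p, n_signal, replace=False)] = rng.choice(
            [-1.0, 1.0], n_signal
        )
    y = X @ w + noise_sd * rng.standard_normal(n)
    subjects = [f"S{i:03d}" for i in range(n)]
    if families is None:
        families = [f"F{i:03d}" for i in range(n)]
    prof = EntropyProfiles(X, subjects, [f"R{j:03d}" for j in range(p)])
    scores = pd.DataFrame(
        {"subject_id": subjects, "family_id": families, "g": y}
    )
    return prof, scores, w


class TestRidgeFit:
    def test_hand_solved_two_predictor_system(self):
        # centred X, X'X + I = [[3,1],[1,3]], X'y = [4,5]
        X = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, -1.0]])
        y = np.array([1.0, 2.0, -3.0])
        model = ridge_fit(X, y, lam=1.0)
        np.testing.assert_allclose(model.b, [7 / 8, 11 / 8], atol=1e-12)
        assert model.k == pytest.approx(0.0, abs=1e-12)

    def test_lambda_zero_equals_ols_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 6))
        y = rng.standard_normal(60)
        model = ridge_fit(X, y, 0.0)
        Xc, yc = X - X.mean(0), y - y.mean()
        b_ols = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        np.testing.assert_allclose(model.b, b_ols, atol=1e-10)

    def test_collinear_at_lambda_zero_raises(self):
        X = np.ones((10, 2)) * np.array([1.0, 2.0])
        X[:, 1] = 2 * X[:, 0]  # exact collinearity
        X += np.arange(10)[:, None] * [1.0, 2.0]
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            ridge_fit(X, np.arange(10.0), 0.0)

    def test_huge_penalty_shrinks_to_mean(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 5))
        y = rng.standard_normal(40) + 3.0
        model = ridge_fit(X, y, 1e9)
        assert np.abs(model.b).max() < 1e-6
        np.testing.assert_allclose(model.predict(X), y.mean(), atol=1e-4)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            ridge_fit(np.eye(3), np.arange(3.0), -1.0)


class TestLofov:
    def test_noiseless_linear_signal_recovered(self):
        prof, scores, _ = make_dataset(80, 10, seed=3, n_signal=10)
        res = CognitiveAbilityRidge(prof, scores).fit(n_bootstrap=0)
        assert res.accuracy_r > 0.99

    def test_accuracy_never_negative(self):
        prof, scores, _ = make_dataset(50, 8, seed=4)
        scores["g"] = np.random.default_rng(5).standard_normal(50)
        res = CognitiveAbilityRidge(prof, scores).fit(n_bootstrap=0)
        assert res.accuracy_r >= 0.0

    def test_family_members_never_straddle_folds(self):
        # mutating a held-out subject must not move the fold's model:
        # the sibling in the same test fold keeps an identical prediction
        n = 40
        families = [f"F{i // 2:02d}" for i in range(n)]  # pairs of siblings
        prof, scores, _ = make_dataset(
            n, 6, seed=6, n_signal=6, noise_sd=0.5, families=families
        )
        res1 = CognitiveAbilityRidge(prof, scores).fit(n_bootstrap=0)
        mutated = EntropyProfiles(
            prof.values.copy(), prof.subject_ids, prof.roi_ids
        )
        mutated.values[0] += 10.0  # subject S000, sibling S001
        res2 = CognitiveAbilityRidge(mutated, scores).fit(n_bootstrap=0)
        grid_best = np.argmax(res1.grid_r)
        # compare at the same lambda to isolate the fold-hygiene question
        lam = res1.lambda_grid[grid_best]
        m1 = CognitiveAbilityRidge(prof, scores, lambda_grid=(lam,)).fit(
            n_bootstrap=0
        )
        m2 = CognitiveAbilityRidge(mutated, scores, lambda_grid=(lam,)).fit(
            n_bootstrap=0
        )
        # the sibling shares the held-out fold, whose model is trained
        # without the family: the mutation cannot leak into it
        assert m1.predicted[1] == m2.predicted[1]
        assert m1.predicted[0] != m2.predicted[0]  # mutated subject moves

    def test_single_family_rejected(self):
        prof, scores, _ = make_dataset(10, 3, seed=7)
        scores["family_id"] = "F0"
        with pytest.raises(DataError, match="famil"):
            CognitiveAbilityRidge(prof, scores).fit()

    def test_feature_screening_retains_informative_predictors(self):
        prof, scores, w = make_dataset(150, 30, seed=8, n_signal=5,
                                       noise_sd=0.5)
        res = CognitiveAbilityRidge(
            prof, scores, feature_p_threshold=0.01
        ).fit(n_bootstrap=0)
        assert res.accuracy_r > 0.8
        with pytest.raises(DataError, match="screening"):
            CognitiveAbilityRidge(
                prof, scores, feature_p_threshold=1e-300
            ).fit(n_bootstrap=0)

    def test_weight_ranking_recovers_planted_rois(self):
        prof, scores, w = make_dataset(150, 40, seed=9, n_signal=8,
                                       noise_sd=1.0)
        res = CognitiveAbilityRidge(prof, scores).fit(n_bootstrap=0)
        planted = set(np.flatnonzero(w != 0))
        top = set(np.argsort(res.mean_abs_weight)[::-1][: len(planted)])
        assert len(top & planted) >= 0.8 * len(planted)

    def test_missing_outcome_or_subject_raises(self):
        prof, scores, _ = make_dataset(10, 3, seed=10)
        with pytest.raises(DataError):
            CognitiveAbilityRidge(prof, scores, outcome="nope")
        with pytest.raises(DataError):
            CognitiveAbilityRidge(prof, scores.iloc[:-1], outcome="g")

    def test_summary_reports_key_quantities(self):
        prof, scores, _ = make_dataset(40, 5, seed=11, n_signal=5,
                                       noise_sd=0.5)
        res = CognitiveAbilityRidge(prof, scores).fit(n_bootstrap=50, seed=1)
        text = res.summary()
        assert "accuracy r" in text and "lambda" in text
        lo, hi = res.ci95
        assert lo <= res.r_raw <= hi


class TestPerNetwork:
    def _parcellation(self, roi_ids, networks):
        return pd.DataFrame(
            {"roi_id": roi_ids, "hemisphere": "L", "network": networks}
        )

    def test_signal_network_outranks_noise_network(self):
        rng = np.random.default_rng(12)
        n = 150
        Xa = rng.standard_normal((n, 10))
        Xb = rng.standard_normal((n, 10))
        y = Xa @ np.ones(10) + 0.5 * rng.standard_normal(n)
        prof = EntropyProfiles(
            np.hstack([Xa, Xb]),
            [f"S{i}" for i in range(n)],
            [f"R{j}" for j in range(20)],
        )
        scores = pd.DataFrame(
            {
                "subject_id": prof.subject_ids,
                "family_id": [f"F{i}" for i in range(n)],
                "g": y,
            }
        )
        parc = self._parcellation(
            prof.roi_ids, ["A"] * 10 + ["B"] * 10
        )
        table, results = per_network_prediction(
            prof, scores, parc, outcomes=("g",), n_bootstrap=0, seed=0
        )
        acc = table.set_index("network")["accuracy_r"]
        assert acc["A"] > acc["B"]
        assert table.set_index("network")["significant"]["A"]
        # union of all networks is exactly the whole-cortex prediction
        assert acc["ALL"] == results[("ALL", "g")].accuracy_r

    def test_small_network_skipped_with_warning(self):
        prof, scores, _ = make_dataset(30, 5, seed=13, n_signal=5,
                                       noise_sd=0.5)
        parc = self._parcellation(prof.roi_ids, ["A"] * 4 + ["B"])
        with pytest.warns(UserWarning, match="fewer than 2"):
            table, _ = per_network_prediction(
                prof, scores, parc, outcomes=("g",), n_bootstrap=0,
                include_whole_cortex=False,
            )
        assert set(table["network"]) == {"A"}
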