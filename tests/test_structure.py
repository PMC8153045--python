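import numpy as np
import pandas as pd
import pytest

import entroprint as ep
from entroprint.data import DataError, EntropyProfiles, StructuralProfiles
from entroprint.structure import (
    StructureEntropyModel,
    add_connectivity_properties,
    blueprint_correlations,
    node_strength_degree,
    regional_individual_correlations,
    symmetrize_and_threshold,
)


class TestSymmetrizeThreshold:
    def test_reciprocal_average_retained(self):
        p = np.zeros((2, 2))
        p[0, 1], p[1, 0] = 0.004, 0.002
        conn = symmetrize_and_threshold(p)
        assert conn.w[0, 1] == conn.w[1, 0] == pytest.approx(0.003)

    def test_subthreshold_zeroed(self):
        p = np.zeros((2, 2))
        p[0, 1], p[1, 0] = 0.001, 0.0005
        conn = symmetrize_and_threshold(p)
        assert conn.w[0, 1] == 0.0

    def test_retained_fraction_matches_direct_census(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 0.01, (50, 50))
        thr = float(np.quantile((p + p.T) / 2, 0.9))
        conn = symmetrize_and_threshold(p, threshold=thr)
        w_full = (p + p.T) / 2
        np.fill_diagonal(w_full, 0.0)
        expected = int((w_full >= thr).sum())
        assert int((conn.w > 0).sum()) == expected

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 0.01, (20, 20))
        once = symmetrize_and_threshold(p)
        twice = symmetrize_and_threshold(once.w)
        np.testing.assert_array_equal(once.w, twice.w)

    def test_non_square_raises(self):
        with pytest.raises(DataError):
            symmetrize_and_threshold(np.zeros((3, 4)))


class TestStrengthDegree:
    def test_triangle(self):
        w = np.full((3, 3), 0.1)
        np.fill_diagonal(w, 0.0)
        conn = symmetrize_and_threshold(w, threshold=0.05)
        s, k = node_strength_degree(conn)
        np.testing.assert_allclose(s, 0.2)
        np.testing.assert_array_equal(k, 2)

    def test_isolated_node(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.2
        s, k = node_strength_degree(symmetrize_and_threshold(w, 0.1))
        assert s[2] == 0.0 and k[2] == 0

    def test_random_graph_matches_adjacency_census(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 0.01, (30, 30))
        conn = symmetrize_and_threshold(p, threshold=0.005)
        s, k = node_strength_degree(conn)
        for i in range(30):
            s_manual = sum(conn.w[i, j] for j in range(30))
            k_manual = sum(1 for j in range(30) if conn.w[i, j] > 0)
            assert s[i] == pytest.approx(s_manual)
            assert k[i] == k_manual

    def test_strength_degree_positively_coupled(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 0.01, (60, 60)) * (rng.uniform(size=(60, 60)) < 0.3)
        conn = symmetrize_and_threshold(p, threshold=0.001)
        s, k = node_strength_degree(conn)
        assert np.corrcoef(s, k)[0, 1] > 0.5


class TestBlueprint:
    def test_identical_blueprints_give_unit_r(self):
        bp = np.random.default_rng(4).standard_normal(40)
        table = blueprint_correlations(bp, {"thickness": bp}, n_bootstrap=50,
                                       seed=0)
        assert table["r"].iloc[0] == pytest.approx(1.0)

    def test_planted_loadings_recovered_at_300_rois(self):
        bc = {"thickness": 0.6, "myelin": 0.0, "curv": 0.0, "sulc": 0.0,
              "strength": 0.0, "degree": -0.5}
        cfg = ep.CohortConfig(
            n_subjects=30, n_rois=300, n_timepoints=600, seed=21,
            blueprint_couplings=bc,
        )
        cohort = ep.generate_cohort(cfg)
        p1 = ep.entropy_profiles(cohort.timeseries, session=0)
        p2 = ep.entropy_profiles(cohort.timeseries, session=1)
        keep = ~cohort.truth["noise_mask"]
        en_bp = p1.averaged_with(p2).values.mean(axis=0)[keep]
        struct = add_connectivity_properties(
            cohort.morphometry, cohort.connectivity
        ).select_rois(keep)
        table = blueprint_correlations(
            en_bp,
            {p: struct.values[p].mean(axis=0) for p in struct.properties},
            n_bootstrap=0,
        ).set_index("property")
        assert table.loc["thickness", "r"] == pytest.approx(0.6, abs=0.1)
        assert table.loc["degree", "r"] == pytest.approx(-0.5, abs=0.1)

    def test_independent_property_not_significant(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(10):
            en = rng.standard_normal(50)
            table = blueprint_correlations(
                en, {"x": rng.standard_normal(50)}, n_bootstrap=0
            )
            hits += int(table["significant"].iloc[0])
        assert hits <= 2

    def test_too_few_rois_raises(self):
        with pytest.raises(DataError):
            blueprint_correlations(np.array([1.0, 2.0]), {"x": np.array([1.0, 2.0])})


class TestIndividualCorrelations:
    def _pair(self, n=80, r=30, seed=6):
        rng = np.random.default_rng(seed)
        en = rng.standard_normal((n, r))
        subjects = [f"S{i}" for i in range(n)]
        rois = [f"R{j}" for j in range(r)]
        return en, subjects, rois, rng

    def test_structure_equal_to_entropy_gives_unit_r(self):
        en, subjects, rois, _ = self._pair()
        prof = EntropyProfiles(en, subjects, rois)
        struct = StructuralProfiles({"sulc": en.copy()}, subjects, rois)
        per_roi, _ = regional_individual_correlations(prof, struct)
        np.testing.assert_allclose(per_roi["r"], 1.0)

    def test_independent_property_null_spread(self):
        en, subjects, rois, rng = self._pair(n=120, r=60)
        prof = EntropyProfiles(en, subjects, rois)
        struct = StructuralProfiles(
            {"curv": rng.standard_normal(en.shape)}, subjects, rois
        )
        per_roi, _ = regional_individual_correlations(prof, struct)
        r = per_roi["r"].to_numpy()
        assert abs(r.mean()) < 0.05
        assert r.std() == pytest.approx(1 / np.sqrt(120 - 1), rel=0.35)

    def test_network_planted_coupling_shows_in_network_means(self):
        en, subjects, rois, rng = self._pair(n=100, r=40, seed=7)
        sulc = rng.standard_normal(en.shape)
        networks = np.array(["ATT"] * 10 + ["FP"] * 10 + ["VIS"] * 20)
        coupled = np.isin(networks, ["ATT", "FP"])
        en[:, coupled] += 1.5 * sulc[:, coupled]  # coupling only in ATT/FP
        prof = EntropyProfiles(en, subjects, rois)
        struct = StructuralProfiles({"sulc": sulc}, subjects, rois)
        parc = pd.DataFrame(
            {"roi_id": rois, "hemisphere": "L", "network": networks}
        )
        _, net_means = regional_individual_correlations(prof, struct, parc)
        assert net_means.loc["ATT", "sulc"] > net_means.loc["VIS", "sulc"] + 0.3
        assert net_means.loc["FP", "sulc"] > net_means.loc["VIS", "sulc"] + 0.3


class TestStructureEntropyModel:
    def test_exact_affine_relation_predicts_perfectly(self):
        rng = np.random.default_rng(8)
        n, r = 30, 12
        sulc = rng.standard_normal((n, r))
        en = 1.5 + 0.7 * sulc  # exact per-ROI affine map
        subjects = [f"S{i}" for i in range(n)]
        rois = [f"R{j}" for j in range(r)]
        model = StructureEntropyModel(
            EntropyProfiles(en, subjects, rois),
            StructuralProfiles({"sulc": sulc}, subjects, rois),
            "sulc",
            [f"F{i}" for i in range(n)],
        )
        res = model.fit(n_permutations=50, n_bootstrap=0, seed=0)
        np.testing.assert_allclose(res.per_subject_similarity, 1.0,
                                   atol=1e-10)
        assert res.identification_accuracy == 1.0

    def test_zero_variance_regressor_predicted_by_mean(self):
        rng = np.random.default_rng(9)
        n, r = 20, 5
        sulc = rng.standard_normal((n, r))
        sulc[:, 2] = 1.0  # degenerate ROI
        en = rng.standard_normal((n, r))
        subjects = [f"S{i}" for i in range(n)]
        rois = [f"R{j}" for j in range(r)]
        model = StructureEntropyModel(
            EntropyProfiles(en, subjects, rois),
            StructuralProfiles({"sulc": sulc}, subjects, rois),
            "sulc",
            [f"F{i}" for i in range(n)],
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            res = model.fit(n_permutations=10, n_bootstrap=0, seed=1)
        # the degenerate ROI's predictions are fold means of the entropy
        assert np.isfinite(res.predicted_profiles.values).all()

    def test_unknown_property_raises(self):
        en = np.random.default_rng(10).standard_normal((5, 4))
        subjects = [f"S{i}" for i in range(5)]
        rois = [f"R{j}" for j in range(4)]
        with pytest.raises(DataError, match="unknown property"):
            StructureEntropyModel(
                EntropyProfiles(en, subjects, rois),
                StructuralProfiles({"sulc": en}, subjects, rois),
                "thickness",
                ["F"] * 5,
            )

    def test_blueprint_vs_individual_dissociation(self, small_cohort,
                                                  small_profiles):
        # thickness couples to entropy only through the blueprint: the
        # predicted profiles reproduce the shared shape (high similarity)
        # but carry no individual information (chance identification);
        # sulc drives individual deviations, so identification succeeds
        p1, p2 = small_profiles
        avg = p1.averaged_with(p2)
        keep = ~small_cohort.truth["noise_mask"]
        avg = avg.select_rois(keep)
        struct = add_connectivity_properties(
            small_cohort.morphometry, small_cohort.connectivity
        ).select_rois(keep)
        fams = small_cohort.scores["family_id"].to_numpy()
        res_th = StructureEntropyModel(avg, struct, "thickness", fams).fit(
            n_permutations=100, n_bootstrap=0, seed=2
        )
        res_su = StructureEntropyModel(avg, struct, "sulc", fams).fit(
            n_permutations=100, n_bootstrap=0, seed=3
        )
        # at this small cohort scale the dissociation is qualitative; the
        # quantitative 60% specificity criterion is asserted at N=100 in the
        # acceptance suite
        assert res_th.similarity_mean > 0.4
        assert res_th.identification_accuracy <= 0.1
        assert res_su.identification_accuracy > 0.3
        assert res_su.identification_accuracy > res_th.identification_accuracy
        assert "specificity" in res_su.summary()
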