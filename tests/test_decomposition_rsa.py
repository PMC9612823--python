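import numpy as np
import pandas as pd
import pytest

from transinfer.behaviour_stats import resample_missing
from transinfer.decomposition_rsa import (
    behavioural_covariates,
    build_occurrence_design,
    build_rsa_table,
    copresentation_nuisance,
    decompose_patterns,
    delta1_sensitivity,
    fit_rsa_lmm,
    outlier_threshold,
    pattern_similarity,
    simulation_nuisance,
)
from transinfer.pattern_synth import make_ground_truth, texture_order


def _patterns_from_gt(gt, extra_row=0.0):
    """Wrap ground-truth texture amplitudes as a decomposed-pattern frame."""
    arr = np.vstack([gt.amplitudes, np.full((1, gt.n_voxels), extra_row)])
    names = [f"{s}:{l}" for s, l in texture_order()] + ["trial_type"]
    return pd.DataFrame(arr, index=names)


def _cohort_tables(behaviour, profiles, decay, seed0=0, n_voxels=60):
    pats = {}
    for i, prof in enumerate(profiles):
        gt = make_ground_truth(n_voxels=n_voxels, decay_lambda=decay,
                               seed=seed0 + i)
        pats[prof.id] = _patterns_from_gt(gt)
    return pats


class TestOccurrenceDesign:
    def test_full_rank_and_pseudoinverse_identity(self):
        d = build_occurrence_design()
        mat = d.X.to_numpy()
        assert np.linalg.matrix_rank(mat) == 15
        assert np.abs(d.T @ mat - np.eye(15)).max() < 1e-10

    def test_row_structure(self):
        d = build_occurrence_design()
        row = d.X.loc[("recent", "A>B")]
        assert row["recent:A"] == 1 and row["recent:B"] == 1
        assert row.drop(["recent:A", "recent:B", "trial_type"]).eq(0).all()

    def test_terminal_textures_only_on_premise_rows(self):
        d = build_occurrence_design()
        premise = d.X["trial_type"] < 0
        for col in ("recent:A", "recent:G", "remote:A", "remote:G"):
            assert d.X.loc[~premise, col].eq(0).all()


class TestDecomposition:
    def test_exact_recovery_of_planted_patterns(self):
        d = build_occurrence_design()
        rng = np.random.default_rng(1)
        P = rng.normal(size=(15, 40))
        out = decompose_patterns(d.X.to_numpy() @ P, d)
        assert np.abs(out.to_numpy() - P).max() < 1e-10
        assert out.shape == (15, 40)

    def test_matches_per_voxel_least_squares_oracle(self):
        d = build_occurrence_design()
        rng = np.random.default_rng(2)
        betas = rng.normal(size=(24, 15)) + 0.7  # constant offset included
        out = decompose_patterns(betas, d).to_numpy()
        oracle = np.column_stack(
            [np.linalg.lstsq(d.X.to_numpy(), betas[:, v], rcond=None)[0]
             for v in range(betas.shape[1])]
        )
        assert np.allclose(out, oracle, atol=1e-10)

    def test_shape_and_finiteness_checks(self):
        with pytest.raises(ValueError):
            decompose_patterns(np.ones((23, 5)))
        bad = np.ones((24, 5))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            decompose_patterns(bad)


class TestPatternSimilarity:
    def test_pair_counts(self):
        gt = make_ground_truth(n_voxels=30, seed=3)
        pat = _patterns_from_gt(gt)
        within = pattern_similarity(pat, "within")
        across = pattern_similarity(pat, "across")
        assert len(within) == 20  # C(5,2) pairs x 2 sessions
        assert (within.groupby("session1").size() == 10).all()
        assert len(across) == 25
        assert set(across["distance"]) == {0, 1, 2, 3, 4}
        assert within["distance"].min() == 1

    def test_interior_textures_only(self):
        gt = make_ground_truth(n_voxels=30, seed=4)
        sim = pattern_similarity(_patterns_from_gt(gt), "within")
        labels = set("".join(sim["texture1"].str[-1]) + "".join(sim["texture2"].str[-1]))
        assert labels <= set("BCDEF")

    def test_degenerate_pattern_flagged(self):
        gt = make_ground_truth(n_voxels=30, seed=5)
        pat = _patterns_from_gt(gt)
        pat.loc["recent:B"] = 1.0  # zero variance
        sim = pattern_similarity(pat, "within")
        bad = sim[(sim["texture1"] == "recent:B") | (sim["texture2"] == "recent:B")]
        assert (~bad["valid"]).all()
        assert sim.loc[sim["valid"], "z"].notna().all()

    def test_fisher_z_odd_and_increasing(self):
        gt = make_ground_truth(n_voxels=500, decay_lambda=2.0, seed=6)
        sim = pattern_similarity(_patterns_from_gt(gt), "within")
        # z = atanh(r): reconstruct r and verify monotone transform
        r = np.tanh(sim["z"])
        assert np.all(np.sign(sim["z"]) == np.sign(r))
        order = np.argsort(r.to_numpy())
        assert np.all(np.diff(sim["z"].to_numpy()[order]) >= 0)


class TestNuisancePredictors:
    def test_copresentation_oracle_values(self):
        nu = copresentation_nuisance()
        phi_same = (24 * 1 - 5 * 4) / np.sqrt(5 * 19 * 4 * 20)
        assert nu[frozenset(["recent:B", "recent:C"])] == pytest.approx(
            np.arctanh(phi_same), abs=1e-10
        )
        phi_cross = -20 / np.sqrt(5 * 19 * 4 * 20)
        assert nu[frozenset(["recent:B", "remote:C"])] == pytest.approx(
            np.arctanh(phi_cross), abs=1e-10
        )

    def test_no_self_pairs(self):
        nu = copresentation_nuisance()
        assert all(len(k) == 2 for k in nu)

    def test_simulation_nuisance_deterministic_and_leaky(self, scan_trial_list):
        with pytest.warns(UserWarning):
            a = simulation_nuisance(scan_trial_list, n_iter=30, n_voxels=40, seed=5)
        with pytest.warns(UserWarning):
            b = simulation_nuisance(scan_trial_list, n_iter=30, n_voxels=40, seed=5)
        assert a == b
        # Temporal-proximity leakage: some pair deviates from zero beyond
        # 3 SE of a mean of 30 z-draws (SE ~ 1/sqrt((V-3) n_iter)).
        se = 1.0 / np.sqrt((40 - 3) * 30)
        assert max(abs(v) for v in a.values()) > 3 * se


class TestOutlierRule:
    @pytest.mark.parametrize("n,expected,tol", [(100, 2.7, 0.05), (1000, 3.4, 0.05),
                                                (1, 0.6745, 1e-4)])
    def test_threshold_values(self, n, expected, tol):
        assert outlier_threshold(n) == pytest.approx(expected, abs=tol)

    def test_threshold_increasing_in_n(self):
        ns = [1, 5, 20, 100, 500, 2000, 10000]
        ts = [outlier_threshold(n) for n in ns]
        assert np.all(np.diff(ts) > 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            outlier_threshold(0)


class TestRsaTable:
    def test_row_counts_mirror_study_combinatorics(self, small_cohort):
        behaviour, profiles = small_cohort
        pats = _cohort_tables(behaviour, profiles, decay=2.0)
        within = build_rsa_table(pats, behaviour, "within")
        across = build_rsa_table(pats, behaviour, "across")
        n = len(profiles)
        assert len(within) == n * 20  # 680 at the full 34-participant scale
        assert len(across) == n * 25
        assert "nuisance_copres" in within.columns

    def test_covariates_attach_per_session_within(self, small_cohort):
        behaviour, profiles = small_cohort
        covs = behavioural_covariates(behaviour)
        pats = _cohort_tables(behaviour, profiles, decay=2.0)
        table = build_rsa_table(pats, behaviour, "within")
        row = table.iloc[0]
        expect = covs[(covs["participant"] == row["participant"])
                      & (covs["session"] == row["session"])]
        assert row["accuracy"] == pytest.approx(expect["accuracy"].iloc[0])

    def test_no_accuracy_by_slope_interaction_column(self, small_cohort):
        from transinfer.decomposition_rsa import _rsa_design

        behaviour, profiles = small_cohort
        pats = _cohort_tables(behaviour, profiles, decay=2.0)
        table = build_rsa_table(pats, behaviour, "within")
        X = _rsa_design(table, "within")
        joint = [c for c in X.columns if "accuracy" in c and "slope" in c]
        assert joint == []

    def test_table_row_order_invariance(self, small_cohort):
        behaviour, profiles = small_cohort
        pats = _cohort_tables(behaviour, profiles, decay=2.0)
        table = build_rsa_table(pats, behaviour, "within")
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = fit_rsa_lmm(table, "within", engine="ols")
        b = fit_rsa_lmm(shuffled, "within", engine="ols")
        assert np.allclose(
            a.coefficients["coef"], b.coefficients["coef"], atol=1e-8
        )


class TestRsaModel:
    def test_distance_effect_recovered_from_decaying_patterns(self, small_cohort):
        behaviour, profiles = small_cohort
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            pats = _cohort_tables(behaviour, profiles, decay=2.0,
                                  seed0=100 * rep)
            table = build_rsa_table(pats, behaviour, "within")
            res = fit_rsa_lmm(table, "within")
            hits += res.coefficients.loc["distance", "coef"] < 0
        assert hits >= int(0.9 * n_rep)

    def test_null_patterns_give_calibrated_distance_test(self, small_cohort):
        behaviour, profiles = small_cohort
        rejections = 0
        n_rep = 100
        for rep in range(n_rep):
            pats = _cohort_tables(behaviour, profiles, decay=None,
                                  seed0=1000 + 50 * rep, n_voxels=40)
            table = build_rsa_table(pats, behaviour, "within")
            res = fit_rsa_lmm(table, "within", engine="ols")
            rejections += res.coefficients.loc["distance", "p"] < 0.05
        assert 0.005 <= rejections / n_rep <= 0.15

    def test_outlier_exclusion_fraction_small(self, small_cohort):
        behaviour, profiles = small_cohort
        pats = _cohort_tables(behaviour, profiles, decay=2.0, seed0=7)
        table = build_rsa_table(pats, behaviour, "within")
        res = fit_rsa_lmm(table, "within")
        assert res.n_excluded / (res.n_rows + res.n_excluded) <= 0.02

    def test_delta1_exclusion_drops_8_rows_per_participant(self, small_cohort):
        behaviour, profiles = small_cohort
        pats = _cohort_tables(behaviour, profiles, decay=2.0)
        table = build_rsa_table(pats, behaviour, "within")
        sens = delta1_sensitivity(table, engine="ols")
        assert (sens.n_rows + sens.n_excluded) == len(table) - 8 * len(profiles)

    def test_graded_effect_survives_delta1_exclusion(self, small_cohort):
        behaviour, profiles = small_cohort
        pats = _cohort_tables(behaviour, profiles, decay=2.0, seed0=11)
        table = build_rsa_table(pats, behaviour, "within")
        sens = delta1_sensitivity(table)
        assert sens.coefficients.loc["distance", "coef"] < 0
        assert sens.coefficients.loc["distance", "p"] < 0.05

    def test_delta1_only_effect_disappears_on_exclusion(self, small_cohort):
        # Boost similarity for adjacent (premise-pair) textures only.
        behaviour, profiles = small_cohort
        rng = np.random.default_rng(42)
        ranks = np.arange(7)
        cov = np.eye(7) + 0.5 * (np.abs(ranks[:, None] - ranks[None, :]) == 1)
        chol = np.linalg.cholesky(cov)
        pats = {}
        for prof in profiles:
            amps = np.vstack([chol @ rng.normal(size=(7, 60)) for _ in range(2)])
            arr = np.vstack([amps, np.zeros((1, 60))])
            names = [f"{s}:{l}" for s, l in texture_order()] + ["trial_type"]
            pats[prof.id] = pd.DataFrame(arr, index=names)
        table = build_rsa_table(pats, behaviour, "within")
        full = fit_rsa_lmm(table, "within", engine="ols")
        sens = delta1_sensitivity(table, engine="ols")
        assert full.coefficients.loc["distance", "coef"] < 0
        assert full.coefficients.loc["distance", "p"] < 0.05
        assert abs(sens.coefficients.loc["distance", "t"]) < 2.0
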