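"""Split plans, penalized fits, GRM/GBLUP, CV schemes and comparisons."""

import numpy as np
import pandas as pd
import pytest

from phenoflight.features import FeatureMatrix
from phenoflight.predict import (
    ModelSpec, compare_methods, evaluate, fit_phenomic_model, gblup_predict,
    grm_vanraden, make_split_plan, per_timepoint_gp, run_cv_scheme,
)
from phenoflight.simdata import MarkerSet, SimConfig, simulate, simulate_marker_panel


def marker_set(dosage, genotypes=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    genotypes = genotypes or [f"g{i}" for i in range(n)]
    return MarkerSet(genotypes=genotypes, marker_ids=[f"m{j}" for j in range(m)],
                     dosage=dosage,
                     positions=pd.DataFrame({"marker_id": [f"m{j}" for j in range(m)],
                                             "chrom": 1, "pos": range(m)}),
                     allele_freq=dosage.mean(axis=0) / 2)


class TestSplitPlan:
    def test_partition_sizes(self):
        plan = make_split_plan([f"g{i}" for i in range(10)], 0.7, 5, seed=1)
        for train, test in plan.iterations:
            assert len(train) == 7 and len(test) == 3
            assert not set(train) & set(test)
            assert sorted(train + test) == plan.genotypes

    def test_determinism(self):
        genos = [f"g{i}" for i in range(12)]
        a = make_split_plan(genos, 0.7, 10, seed=3)
        b = make_split_plan(genos, 0.7, 10, seed=3)
        assert a.iterations == b.iterations
        assert a.plan_hash == b.plan_hash
        c = make_split_plan(genos, 0.7, 10, seed=4)
        assert c.plan_hash != a.plan_hash

    def test_floor_rule_118_genotypes(self):
        plan = make_split_plan([f"g{i}" for i in range(118)], 0.7, 2, seed=0)
        for train, test in plan.iterations:
            assert len(train) == 82 and len(test) == 36

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="genotypes"):
            make_split_plan(["a", "b"], 0.7, 5)
        with pytest.raises(ValueError, match="train_frac"):
            make_split_plan([f"g{i}" for i in range(10)], 1.2, 5)


class TestPhenomicModels:
    def make_xy(self, n=40, p=5, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        beta = rng.normal(size=p)
        y = X @ beta + rng.normal(0, 0.5, n)
        return X, y

    def test_ridge_zero_penalty_equals_ols(self):
        X, y = self.make_xy()
        fit = fit_phenomic_model(ModelSpec("ridge", {"penalty": 0.0},
                                           standardize=False, fit_intercept=False), X, y)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.coef_, ols, atol=1e-8)

    def test_ridge_infinite_penalty_predicts_mean(self):
        X, y = self.make_xy()
        fit = fit_phenomic_model(ModelSpec("ridge", {"penalty": 1e12}), X, y)
        assert np.allclose(fit.coef_, 0.0, atol=1e-6)
        assert np.allclose(fit.predict(X), y.mean(), atol=1e-6)

    def test_ridge_matches_closed_form_normal_equations(self):
        """Fixed-penalty ridge equals (X'X + lambda I)^-1 X'y."""
        X, y = self.make_xy(n=40, p=5, seed=2)
        lam = 2.5
        fit = fit_phenomic_model(ModelSpec("ridge", {"penalty": lam},
                                           standardize=False, fit_intercept=False), X, y)
        closed = np.linalg.solve(X.T @ X + lam * np.eye(5), X.T @ y)
        assert np.allclose(fit.coef_, closed, atol=1e-8)

    def test_standardization_uses_training_stats_only(self):
        X, y = self.make_xy(n=30)
        fit = fit_phenomic_model(ModelSpec("ridge", {"penalty": 1.0}), X, y)
        assert np.allclose(fit._mean, X.mean(axis=0))
        X_new = X + 100.0  # shifted test rows must use the training mean
        assert not np.allclose(fit.predict(X_new), fit.predict(X))

    def test_constant_response_rejected_for_penalized(self):
        X, _ = self.make_xy()
        with pytest.raises(ValueError, match="constant"):
            fit_phenomic_model(ModelSpec("ridge"), X, np.ones(40))

    @pytest.mark.parametrize("family", ["lasso", "elasticnet", "randomforest"])
    def test_other_families_fit_and_predict(self, family):
        X, y = self.make_xy(n=50)
        spec = ModelSpec(family, {"n_trees": 50} if family == "randomforest" else {})
        fit = fit_phenomic_model(spec, X, y)
        pred = fit.predict(X)
        assert pred.shape == (50,)
        assert np.corrcoef(pred, y)[0, 1] > 0.3


class TestGRM:
    def test_hand_value_single_marker(self):
        mk = marker_set([[0.0], [2.0]])
        K = grm_vanraden(mk, maf_filter=0.0)
        assert np.allclose(K.grm.to_numpy(), [[2, -2], [-2, 2]])

    def test_duplicated_genotypes_have_equal_rows(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(6, 40)).astype(float)
        dos[3] = dos[0]
        K = grm_vanraden(marker_set(dos)).grm.to_numpy()
        assert np.allclose(K[0], K[3])
        assert K[0, 3] == pytest.approx(K[0, 0])

    def test_symmetric_psd(self):
        rng = np.random.default_rng(1)
        K = grm_vanraden(marker_set(rng.integers(0, 3, (20, 100)).astype(float))).grm.to_numpy()
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_monomorphic_only_fails(self):
        with pytest.raises(ValueError, match="monomorphic|MAF"):
            grm_vanraden(marker_set(np.full((4, 3), 2.0)))


class TestGBLUP:
    def test_equivalence_with_marker_space_rrblup(self):
        """Genotype-space GBLUP equals an independently coded marker-space
        ridge (RR-BLUP) at the matching penalty."""
        cfg = SimConfig(n_parents=14, n_hybrids=50, n_markers=200, seed=2)
        mk = simulate_marker_panel(cfg)
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(size=50), index=mk.genotypes)
        train, test = mk.genotypes[:38], mk.genotypes[38:]
        lam = 0.7
        pred_g = gblup_predict(grm_vanraden(mk), y, train, test, variance_ratio=lam)

        p = mk.dosage.mean(axis=0) / 2
        keep = np.minimum(p, 1 - p) >= 0.025
        Z = mk.dosage[:, keep] - 2 * p[keep]
        c = 2 * np.sum(p[keep] * (1 - p[keep]))
        Zt, Zs = Z[:38], Z[38:]
        yb = y.loc[train].mean()
        a = Zt.T @ np.linalg.solve(Zt @ Zt.T + c * lam * np.eye(38),
                                   y.loc[train].to_numpy() - yb)
        assert np.allclose(pred_g.to_numpy(), Zs @ a + yb, atol=1e-8)

    def test_infinite_shrinkage_predicts_training_mean(self):
        mk = simulate_marker_panel(SimConfig(n_parents=10, n_hybrids=20,
                                             n_markers=100, seed=3))
        y = pd.Series(np.random.default_rng(0).normal(size=20), index=mk.genotypes)
        pred = gblup_predict(grm_vanraden(mk), y, mk.genotypes[:15],
                             mk.genotypes[15:], variance_ratio=1e12)
        assert np.allclose(pred, y.iloc[:15].mean(), atol=1e-4)

    def test_duplicate_of_training_genotype_recovers_phenotype(self):
        """With near-zero shrinkage a test genotype identical to a training
        genotype is predicted at that genotype's phenotype."""
        rng = np.random.default_rng(4)
        dos = rng.integers(0, 3, size=(30, 300)).astype(float)
        dos[29] = dos[0]  # test genotype duplicates train genotype 0
        mk = marker_set(dos)
        y = pd.Series(rng.normal(size=30), index=mk.genotypes)
        pred = gblup_predict(grm_vanraden(mk), y, mk.genotypes[:11],
                             [mk.genotypes[29]], variance_ratio=1e-8)
        assert pred.iloc[0] == pytest.approx(y.iloc[0], abs=1e-5)

    def test_missing_genotype_rejected(self):
        mk = marker_set(np.array([[0.0, 1], [2, 1], [1, 0], [0, 2]]))
        y = pd.Series(np.arange(4.0), index=mk.genotypes)
        with pytest.raises(ValueError, match="absent"):
            gblup_predict(grm_vanraden(mk), y, mk.genotypes[:3], ["nope"])


class TestEvaluate:
    def test_identity_and_sign_flip(self):
        y = np.array([1.0, 2, 3, 5])
        m = evaluate(y, y)
        assert m == {"accuracy": 1.0, "rmse": 0.0, "mae": 0.0, "r2": 1.0}
        assert evaluate(-y, y)["accuracy"] == pytest.approx(-1.0)

    def test_hand_arithmetic(self):
        m = evaluate([1, 2, 3], [2, 2, 5])
        assert m["accuracy"] == pytest.approx(np.sqrt(3) / 2, abs=1e-3)
        assert m["rmse"] == pytest.approx(np.sqrt(5 / 3), abs=1e-4)
        assert m["mae"] == pytest.approx(1.0)

    def test_zero_variance_is_explicit_failure(self):
        with pytest.raises(ValueError, match="zero variance"):
            evaluate([1.0, 1, 1], [1.0, 2, 3])


@pytest.fixture(scope="module")
def cv_fixture():
    cfg = SimConfig(n_parents=16, n_hybrids=40, n_markers=200, n_flights_rgb=4,
                    seed=10, variance_shares={
                        "NGRDI": {"flight": 0.6, "rep_in_flight": 0.1,
                                  "genotype_in_flight": 0.15, "residual": 0.15}})
    trial = simulate(cfg)
    from phenoflight.temporal_model import NestedModelSpec, fit_nested_model
    om = trial.phenomic[trial.phenomic.trial == "OM"]
    blups = fit_nested_model(om, "NGRDI", NestedModelSpec(estimation="anova_mom")).blups
    from phenoflight.features import assemble_feature_matrix
    fm = assemble_feature_matrix({"NGRDI": blups})
    traits = trial.traits
    y_om = traits[traits.trial == "OM"].set_index("genotype")["GY"].astype(float)
    y_sm = traits[traits.trial == "SM"].set_index("genotype")["GY"].astype(float)
    genos = sorted(set(fm.genotypes) & set(y_sm.index))
    plan = make_split_plan(genos, 0.7, 8, seed=99)
    return trial, fm, y_om, y_sm, plan


class TestRunCVScheme:
    def test_cv1_unpenalized_interpolation(self, cv_fixture):
        """CV1 with an unpenalized linear model and p >= n gives training
        accuracy 1 (the overfitting control)."""
        trial, fm, y_om, y_sm, _ = cv_fixture
        rng = np.random.default_rng(0)
        genos = fm.genotypes
        wide = FeatureMatrix(
            values=pd.DataFrame(rng.normal(size=(len(genos), len(genos) + 5)),
                                index=genos),
            platform="TPP_RGB", temporal_columns=[], derived_columns=[])
        plan = make_split_plan(sorted(set(genos) & set(y_sm.index)), 0.7, 3, seed=1)
        res = run_cv_scheme("CV1", ModelSpec("linear"), wide, y_om, y_sm, plan)
        assert np.allclose(res.records.accuracy, 1.0, atol=1e-6)

    def test_cv2_cv4_never_train_on_test_genotypes(self, cv_fixture):
        trial, fm, y_om, y_sm, plan = cv_fixture
        for train, test in plan.iterations:
            assert not set(train) & set(test)
        res2 = run_cv_scheme("CV2", ModelSpec("ridge", {"penalty": 1.0}),
                             fm, y_om, y_sm, plan)
        res4 = run_cv_scheme("CV4", ModelSpec("ridge", {"penalty": 1.0}),
                             fm, y_om, y_sm, plan)
        assert len(res2.records) == plan.n_iter == len(res4.records)

    def test_fixed_ridge_matches_independent_reimplementation(self, cv_fixture):
        """CV2 mean accuracy with a fixed-penalty ridge matches a from-
        scratch numpy reimplementation of the whole loop."""
        trial, fm, y_om, y_sm, plan = cv_fixture
        lam = 3.0
        res = run_cv_scheme("CV2", ModelSpec("ridge", {"penalty": lam}),
                            fm, y_om, y_sm, plan)
        accs = []
        X_all = fm.values
        for train, test in plan.iterations:
            Xt = X_all.loc[train].to_numpy()
            yt = y_om.loc[train].to_numpy()
            mu, sd = Xt.mean(0), Xt.std(0)
            sd[sd < 1e-14] = 1.0
            Xs = (Xt - mu) / sd
            Xc = np.hstack([np.ones((len(train), 1)), Xs])
            pen = np.diag([0.0] + [lam] * Xs.shape[1])
            beta = np.linalg.solve(Xc.T @ Xc + pen, Xc.T @ yt)
            Xtest = (X_all.loc[test].to_numpy() - mu) / sd
            pred = np.hstack([np.ones((len(test), 1)), Xtest]) @ beta
            accs.append(np.corrcoef(pred, y_om.loc[test])[0, 1])
        assert res.mean_accuracy == pytest.approx(np.mean(accs), abs=0.02)

    def test_sm_scheme_requires_sm_data(self, cv_fixture):
        trial, fm, y_om, y_sm, plan = cv_fixture
        with pytest.raises(ValueError, match="SM"):
            run_cv_scheme("CV4", ModelSpec("ridge"), fm, y_om, None, plan)

    def test_scheme_ordering_with_gxe(self, cv_fixture):
        """CV1 >= CV2 >= CV4 in mean accuracy (resubstitution beats held-out
        genotypes, which beat held-out genotypes in a new environment)."""
        trial, fm, y_om, y_sm, plan = cv_fixture
        spec = ModelSpec("ridge", {"penalty": 1.0})
        acc = {s: run_cv_scheme(s, spec, fm, y_om, y_sm, plan).mean_accuracy
               for s in ("CV1", "CV2", "CV4")}
        assert acc["CV1"] >= acc["CV2"] - 0.05
        assert acc["CV2"] >= acc["CV4"] - 0.05


class TestPerTimepointGP:
    def test_shape_and_null_flight(self):
        """Output is trait x flight; a flight with zero genetic share has
        accuracy inside the permutation-null band around zero."""
        profile = [0.0, 1.0, 1.0, 2.0]
        cfg = SimConfig(n_parents=16, n_hybrids=60, n_markers=300, n_flights_rgb=4,
                        seed=21, genetic_profile=profile, plasticity_share=0.0,
                        variance_shares={"NGRDI": {"flight": 0.5, "rep_in_flight": 0.05,
                                                   "genotype_in_flight": 0.3,
                                                   "residual": 0.15}})
        trial = simulate(cfg)
        kernel = grm_vanraden(trial.markers)
        truth = trial.truth.temporal_genetic_values["NGRDI"]
        noisy = truth + np.random.default_rng(0).normal(
            0, 0.02, truth.shape)  # plot-mean noise stand-in
        plan = make_split_plan(trial.markers.genotypes, 0.7, 20, seed=5)
        table = per_timepoint_gp(kernel, {"NGRDI": noisy}, plan)
        assert table.shape == (1, 4)
        null_band = 2.58 / np.sqrt(18 - 2)  # ~99% envelope for r at n_test=18
        assert abs(table.iloc[0, 0]) < null_band

    def test_accuracy_increases_with_genetic_share(self):
        """Mean GP accuracy is ordered by the per-flight genetic share."""
        diffs = []
        for seed in range(3):
            cfg = SimConfig(n_parents=16, n_hybrids=80, n_markers=300,
                            n_flights_rgb=3, seed=seed,
                            genetic_profile=[0.2, 1.0, 2.5], plasticity_share=0.0,
                            variance_shares={"NGRDI": {"flight": 0.5,
                                                       "rep_in_flight": 0.05,
                                                       "genotype_in_flight": 0.3,
                                                       "residual": 0.15}})
            trial = simulate(cfg)
            kernel = grm_vanraden(trial.markers)
            om = trial.phenomic[trial.phenomic.trial == "OM"]
            means = om[om.trait_id == "NGRDI"].groupby(
                ["genotype", "flight_day"], observed=True).value.mean().unstack()
            plan = make_split_plan(trial.markers.genotypes, 0.7, 15, seed=seed)
            table = per_timepoint_gp(kernel, {"NGRDI": means}, plan)
            diffs.append(table.iloc[0].to_numpy())
        mean_acc = np.mean(diffs, axis=0)
        assert mean_acc[0] < mean_acc[1] < mean_acc[2]


class TestCompareMethods:
    def test_self_comparison_is_zero(self, cv_fixture):
        trial, fm, y_om, y_sm, plan = cv_fixture
        res = run_cv_scheme("CV2", ModelSpec("ridge", {"penalty": 1.0}),
                            fm, y_om, y_sm, plan)
        out = compare_methods([res, res])
        assert np.allclose(out.mean_diff_vs_first, 0.0)
        assert (out.diff_ci_low <= 0).all() and (out.diff_ci_high >= 0).all()

    def test_mismatched_plans_rejected(self, cv_fixture):
        trial, fm, y_om, y_sm, plan = cv_fixture
        genos = plan.genotypes
        other = make_split_plan(genos, 0.7, plan.n_iter, seed=plan.seed + 1)
        a = run_cv_scheme("CV2", ModelSpec("ridge", {"penalty": 1.0}),
                          fm, y_om, y_sm, plan)
        b = run_cv_scheme("CV2", ModelSpec("ridge", {"penalty": 1.0}),
                          fm, y_om, y_sm, other)
        with pytest.raises(ValueError, match="not comparable"):
            compare_methods([a, b])
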