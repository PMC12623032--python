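"""Horizon labels, discrimination, calibration, NRI, net benefit, fairness, CV."""

import numpy as np
import pandas as pd
import pytest

from ipirisk.counterfactual_policy import counterfactual_risks
from ipirisk.cox_model import ModelSpec, fit_model
from ipirisk.synthetic_cohorts import (
    calibrate_generating_model,
    default_trial_config,
    generating_model,
    simulate_trial_cohort,
)
from ipirisk.validation_metrics import (
    brier_ipa,
    calibration_by_decile,
    compare_models,
    concordance,
    crossvalidate,
    fairness_metrics,
    horizon_labels,
    kaplan_meier,
    km_survival_at,
    net_benefit,
    nri,
)


def labels_from(times, events, horizon=3.0, scheme="ipcw"):
    return horizon_labels(np.asarray(times, float), np.asarray(events, int),
                          horizon, scheme=scheme)


class TestHorizonLabels:
    def test_no_censoring_schemes_agree_with_unit_weights(self):
        t = [1.0, 2.0, 4.0, 5.0]
        d = [1, 1, 1, 1]
        ipcw = labels_from(t, d)
        excl = labels_from(t, d, scheme="exclude")
        np.testing.assert_allclose(ipcw.weight, 1.0)
        np.testing.assert_allclose(excl.weight, 1.0)
        np.testing.assert_array_equal(ipcw.label, excl.label)
        np.testing.assert_array_equal(ipcw.label, [1, 1, 0, 0])

    def test_censored_exactly_at_horizon_is_event_free_weight_one(self):
        t = [1.0, 2.0, 3.0, 3.0, 3.0]
        d = [1, 1, 0, 0, 0]
        lab = labels_from(t, d)
        np.testing.assert_array_equal(lab.label, [1, 1, 0, 0, 0])
        np.testing.assert_allclose(lab.weight, 1.0)

    def test_weighted_prevalence_matches_km(self):
        # hand fixture: mixed events and censoring before the horizon
        t = [0.5, 1.0, 1.5, 2.0, 2.2, 2.5, 2.7, 3.5, 4.0, 5.0]
        d = [1, 0, 1, 0, 1, 0, 1, 0, 1, 0]
        lab = labels_from(t, d)
        km = kaplan_meier(t, d)
        assert lab.prevalence() == pytest.approx(1 - km_survival_at(km, 3.0), abs=1e-12)

    def test_censored_before_horizon_excluded(self):
        lab = labels_from([1.0, 2.0, 4.0], [0, 1, 0])
        assert not lab.included[0]
        assert lab.weight[0] == 0.0
        assert lab.n_excluded == 1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            labels_from([1.0], [1], horizon=-1)
        with pytest.raises(ValueError):
            horizon_labels(np.array([1.0]), np.array([1]), 3.0, scheme="drop")


class TestConcordance:
    def test_perfect_separation(self):
        lab = labels_from([1, 1, 5, 5], [1, 1, 0, 0])
        out = concordance([0.9, 0.8, 0.1, 0.2], lab, n_boot=50, seed=1)
        assert out["c"] == 1.0

    def test_constant_predictor_is_half(self):
        lab = labels_from([1, 1, 5, 5], [1, 1, 0, 0])
        assert concordance([0.3] * 4, lab, n_boot=0)["c"] == 0.5

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(30)
        for _ in range(5):
            n = int(rng.integers(10, 50))
            t = rng.exponential(3, n)
            d = (rng.random(n) < 0.7).astype(int)
            r = rng.random(n)
            lab = labels_from(t, d)
            got = concordance(r, lab, n_boot=0)["c"]
            # brute force over included pairs with weights
            num = den = 0.0
            for i in range(n):
                for j in range(n):
                    if not (lab.included[i] and lab.included[j]):
                        continue
                    if lab.label[i] == 1 and lab.label[j] == 0:
                        w = lab.weight[i] * lab.weight[j]
                        den += w
                        if r[i] > r[j]:
                            num += w
                        elif r[i] == r[j]:
                            num += 0.5 * w
            if den == 0:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(num / den, abs=1e-12)

    def test_no_cases_undefined(self):
        lab = labels_from([5.0, 5.0], [0, 0])
        out = concordance([0.1, 0.2], lab, n_boot=0)
        assert np.isnan(out["c"])

    def test_bootstrap_reproducible(self):
        rng = np.random.default_rng(31)
        t = rng.exponential(3, 200)
        d = (rng.random(200) < 0.6).astype(int)
        r = rng.random(200)
        lab = labels_from(t, d)
        a = concordance(r, lab, n_boot=100, seed=5)
        b = concordance(r, lab, n_boot=100, seed=5)
        assert a == b


class TestCalibration:
    def test_well_specified_model_on_diagonal(self):
        cfg = calibrate_generating_model(
            0.227, 0.58, 0.31, default_trial_config(n=50_000, seed=32)
        )
        cohort = simulate_trial_cohort(cfg)
        truth = generating_model(cfg)
        risks = truth.predict_risk_frame(cohort, arm=cohort["arm"].to_numpy(object))
        table = calibration_by_decile(
            risks, cohort["time"].to_numpy(), cohort["event"].to_numpy(), 3.0
        )
        assert len(table) == 10
        resid = (table["observed"] - table["mean_predicted"]).abs()
        assert (resid <= 3 * table["observed_se"] + 1e-9).all()

    def test_shifted_predictions_forced_off_diagonal(self):
        cfg = calibrate_generating_model(
            0.227, 0.58, 0.31, default_trial_config(n=20_000, seed=33)
        )
        cohort = simulate_trial_cohort(cfg)
        truth = generating_model(cfg)
        risks = truth.predict_risk_frame(cohort, arm=cohort["arm"].to_numpy(object))
        table = calibration_by_decile(
            np.clip(risks + 0.05, 0, 1), cohort["time"].to_numpy(),
            cohort["event"].to_numpy(), 3.0,
        )
        assert (table["observed"] < table["mean_predicted"]).all()

    def test_single_bin_hand_km(self):
        # 5 subjects, 2 events before horizon, no censoring: observed 0.4
        t = [1.0, 2.0, 4.0, 5.0, 6.0] * 4
        d = [1, 1, 0, 0, 0] * 4
        r = list(np.linspace(0.1, 0.5, 20))
        table = calibration_by_decile(r, t, d, 3.0, n_bins=1)
        assert table["observed"].iloc[0] == pytest.approx(0.4)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            calibration_by_decile([0.1] * 10, [1.0] * 10, [1] * 10, 3.0)


class TestNetBenefit:
    def test_printed_formula_arithmetic(self):
        # TP rate 0.08, FP rate 0.16 at threshold 0.20: NB = 0.08 - 0.16/4 = 0.04
        n = 100
        risks = np.concatenate([np.full(24, 0.9), np.full(76, 0.1)])
        # 8 true positives, 16 false positives among the 24 classified positive
        d = np.concatenate([np.ones(8), np.zeros(16), np.ones(4), np.zeros(72)]).astype(int)
        t = np.where(d == 1, 1.0, 5.0)
        lab = labels_from(t, d)
        out = net_benefit(risks, lab, 0.20)
        assert out["tpr"] == pytest.approx(0.08)
        assert out["fpr"] == pytest.approx(0.16)
        assert out["net_benefit"] == pytest.approx(0.04)

    def test_exchange_rate_one_at_half(self):
        lab = labels_from([1.0, 5.0], [1, 0])
        out = net_benefit([0.9, 0.1], lab, 0.5)
        # NB = TPR - FPR exactly when threshold odds are 1
        assert out["net_benefit"] == pytest.approx(out["tpr"] - out["fpr"])

    def test_boundary_policies(self):
        rng = np.random.default_rng(34)
        n = 500
        t = rng.exponential(4, n)
        d = np.ones(n, dtype=int)
        lab = labels_from(t, d)
        prev = lab.prevalence()
        none_nb = net_benefit(np.zeros(n), lab, 0.2)
        all_nb = net_benefit(np.ones(n), lab, 0.2)
        assert none_nb["net_benefit"] == 0.0
        assert all_nb["net_benefit"] == pytest.approx(prev - (1 - prev) * 0.25)
        assert all_nb["treat_all"] == pytest.approx(all_nb["net_benefit"])

    def test_nb_never_exceeds_prevalence(self):
        rng = np.random.default_rng(35)
        n = 300
        t = rng.exponential(4, n)
        d = (rng.random(n) < 0.8).astype(int)
        r = rng.random(n)
        lab = labels_from(t, d)
        for thr in (0.05, 0.2, 0.4):
            assert net_benefit(r, lab, thr)["net_benefit"] <= lab.prevalence() + 1e-12

    def test_degenerate_thresholds_rejected(self):
        lab = labels_from([1.0, 5.0], [1, 0])
        for thr in (0.0, 1.0):
            with pytest.raises(ValueError):
                net_benefit([0.5, 0.5], lab, thr)


class TestNri:
    def test_identity_reclassification(self):
        rng = np.random.default_rng(36)
        r = rng.random(50)
        t = rng.exponential(4, 50)
        d = (rng.random(50) < 0.7).astype(int)
        lab = labels_from(t, d)
        out = nri(r, r, lab, n_boot=0)
        assert out["event_nri"] == 0.0
        assert out["nonevent_nri"] == 0.0
        assert out["overall_nri"] == 0.0
        off_diag = out["matrix_events"].to_numpy() - np.diag(
            np.diag(out["matrix_events"].to_numpy())
        )
        assert np.all(off_diag == 0)

    def test_hand_counted_components(self):
        # 10 cases: 2 up, 1 down -> event NRI 0.1
        # 20 noncases: 3 down, 1 up -> nonevent NRI 0.1
        old = np.array([0.05] * 10 + [0.05] * 20)
        new = old.copy()
        new[:2] = 0.15       # cases up
        new[2] = 0.05; old[2] = 0.15  # case down
        new[10] = 0.15       # noncase up
        old[11:14] = 0.15    # noncases down
        label = np.array([1] * 10 + [0] * 20)
        t = np.where(label == 1, 1.0, 5.0)
        lab = labels_from(t, label)
        out = nri(new, old, lab, categories=(0.10, 0.20), n_boot=0)
        assert out["event_nri"] == pytest.approx(0.1)
        assert out["nonevent_nri"] == pytest.approx(0.1)
        assert out["overall_nri"] == pytest.approx(0.2)

    def test_matrices_conserve_counts(self):
        rng = np.random.default_rng(37)
        n = 200
        rn, ro = rng.random(n), rng.random(n)
        t = rng.exponential(4, n)
        d = (rng.random(n) < 0.7).astype(int)
        lab = labels_from(t, d)
        out = nri(rn, ro, lab, n_boot=0)
        total = out["matrix_events"].to_numpy().sum() + out["matrix_nonevents"].to_numpy().sum()
        assert total == pytest.approx(lab.weight.sum())
        assert out["overall_nri"] == pytest.approx(
            out["event_nri"] + out["nonevent_nri"], abs=1e-12
        )

    def test_invalid_categories_rejected(self):
        lab = labels_from([1.0, 5.0], [1, 0])
        for cats in ((), (0.2, 0.1), (0.0, 0.5), (0.5, 1.0)):
            with pytest.raises(ValueError):
                nri([0.1, 0.2], [0.1, 0.2], lab, categories=cats)


class TestFairness:
    def test_hand_fixture_gaps(self):
        # group A: TPR 0.8 FPR 0.1; group B: TPR 0.6 FPR 0.1
        label = np.array([1] * 10 + [0] * 10 + [1] * 10 + [0] * 10)
        groups = np.array(["A"] * 20 + ["B"] * 20)
        risks = np.zeros(40)
        risks[:8] = 0.9        # A cases classified positive
        risks[10] = 0.9        # 1/10 A noncases positive
        risks[20:26] = 0.9     # 6/10 B cases positive
        risks[30] = 0.9        # 1/10 B noncases positive
        t = np.where(label == 1, 1.0, 5.0)
        lab = labels_from(t, label)
        out = fairness_metrics(risks, lab, groups, threshold=0.20)
        assert out["per_group"]["A"]["tpr"] == pytest.approx(0.8)
        assert out["per_group"]["B"]["tpr"] == pytest.approx(0.6)
        assert out["equal_opportunity_gap"] == pytest.approx(0.2)
        assert out["equalized_odds_gap"] == pytest.approx(0.2)

    def test_single_group_zero_gaps(self):
        lab = labels_from([1.0, 5.0], [1, 0])
        out = fairness_metrics([0.9, 0.1], lab, np.array(["A", "A"]))
        assert out["equal_opportunity_gap"] == 0.0
        assert out["equalized_odds_gap"] == 0.0

    def test_exchangeable_groups_have_negligible_gaps(self):
        rng = np.random.default_rng(38)
        n = 100_000
        r = rng.random(n)
        d = (rng.random(n) < r * 0.5).astype(int)  # outcome independent of group
        t = np.where(d == 1, rng.uniform(0.1, 2.9, n), 5.0)
        groups = rng.choice(np.array(["w", "x", "y", "z"]), n)
        lab = labels_from(t, d)
        out = fairness_metrics(r, lab, groups, threshold=0.20)
        assert out["equal_opportunity_gap"] < 0.02
        assert out["equalized_odds_gap"] < 0.02

    def test_group_without_cases_flagged(self):
        label = np.array([1, 0, 0, 0])
        t = np.where(label == 1, 1.0, 5.0)
        lab = labels_from(t, label)
        out = fairness_metrics([0.9, 0.1, 0.2, 0.3], lab, np.array(["A", "A", "B", "B"]))
        assert any("no cases" in f for f in out["flags"])
        assert np.isnan(out["per_group"]["B"]["tpr"])


class TestBrierIpa:
    def test_oracle_predictor(self):
        lab = labels_from([1.0, 1.5, 5.0, 5.0], [1, 1, 0, 0])
        out = brier_ipa([1.0, 1.0, 0.0, 0.0], lab)
        assert out["brier"] == 0.0
        assert out["ipa"] == 1.0

    def test_null_model_ipa_zero(self):
        lab = labels_from([1.0, 1.5, 5.0, 5.0], [1, 1, 0, 0])
        out = brier_ipa([0.5] * 4, lab)
        assert out["ipa"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_fixture(self):
        lab = labels_from([1.0, 5.0, 5.0, 5.0], [1, 0, 0, 0])
        r = [0.8, 0.3, 0.2, 0.1]
        expected = np.mean([(1 - 0.8) ** 2, 0.3**2, 0.2**2, 0.1**2])
        assert brier_ipa(r, lab)["brier"] == pytest.approx(expected)

    def test_zero_prevalence_undefined(self):
        lab = labels_from([5.0, 5.0], [0, 0])
        out = brier_ipa([0.1, 0.2], lab)
        assert np.isnan(out["ipa"])


@pytest.fixture(scope="module")
def cv_cohort():
    cfg = calibrate_generating_model(
        0.227, 0.58, 0.31, default_trial_config(n=2000, seed=40)
    )
    return simulate_trial_cohort(cfg), cfg


class TestCrossValidation:
    def test_deterministic_given_seed(self, cv_cohort):
        cohort, _ = cv_cohort
        oof_a, rep_a = crossvalidate(cohort, k=5, seed=3, n_boot=20)
        oof_b, rep_b = crossvalidate(cohort, k=5, seed=3, n_boot=20)
        np.testing.assert_array_equal(oof_a, oof_b)
        assert rep_a["c_statistic"] == rep_b["c_statistic"]

    def test_partition_property(self, cv_cohort):
        cohort, _ = cv_cohort
        oof, rep = crossvalidate(cohort, k=10, seed=4, n_boot=0)
        assert not np.isnan(oof).any()  # every subject scored exactly once
        sizes = rep["fold_sizes"]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == len(cohort)

    def test_cv_c_close_to_external_c(self, cv_cohort):
        cohort, cfg = cv_cohort
        oof, rep = crossvalidate(cohort, k=10, seed=5, n_boot=0)
        external = simulate_trial_cohort(cfg.replace(n=20_000, seed=41))
        fitted = fit_model(cohort)
        ext_risks = fitted.predict_risk_frame(
            external, arm=external["arm"].to_numpy(object)
        )
        lab = labels_from(external["time"], external["event"])
        ext_c = concordance(ext_risks, lab, n_boot=0)["c"]
        assert rep["c_statistic"]["c"] == pytest.approx(ext_c, abs=0.02)

    def test_too_few_folds_rejected(self, cv_cohort):
        with pytest.raises(ValueError):
            crossvalidate(cv_cohort[0], k=1, seed=0)


class TestCompareModels:
    def test_no_interactions_to_exploit(self):
        # equal slopes across arms: individualized model buys nothing
        cfg = default_trial_config(n=2500, seed=42)
        for arm in ("lifestyle", "metformin"):
            cfg.coefficients.arm_slopes[arm] = dict(cfg.coefficients.arm_slopes["placebo"])
        cfg = calibrate_generating_model(0.227, 0.30, 0.30, cfg)
        cohort = simulate_trial_cohort(cfg)
        out = compare_models(cohort, None, seed=1, k=5, n_boot=0)
        c_ind = out["models"]["individualized"]["internal"]["c_statistic"]["c"]
        c_std = out["models"]["nonindividualized"]["internal"]["c_statistic"]["c"]
        assert c_ind == pytest.approx(c_std, abs=0.02)
        assert abs(out["nri_internal"]["overall_nri"]) < 0.05

    def test_strong_interactions_favor_individualized(self):
        cfg = default_trial_config(n=3000, seed=43)
        # exaggerate slope heterogeneity across arms
        cfg.coefficients.arm_slopes["lifestyle"]["fpg"] = -0.8
        cfg.coefficients.arm_slopes["metformin"]["fpg"] = 0.1
        cfg.coefficients.arm_slopes["placebo"]["fpg"] = 1.0
        cfg = calibrate_generating_model(0.227, 0.58, 0.31, cfg)
        cohort = simulate_trial_cohort(cfg)
        external = simulate_trial_cohort(cfg.replace(n=20_000, seed=44))
        out = compare_models(cohort, external, seed=2, k=5, n_boot=0)
        c_ind = out["models"]["individualized"]["external"]["c_statistic"]["c"]
        c_std = out["models"]["nonindividualized"]["external"]["c_statistic"]["c"]
        assert c_ind > c_std
        assert "nri_external" in out

    def test_report_structure_covers_subgroups(self, cv_cohort):
        cohort, _ = cv_cohort
        out = compare_models(cohort, None, seed=3, k=5, n_boot=0)
        for name in ("individualized", "nonindividualized"):
            rep = out["models"][name]["internal"]
            assert "c_by_race_ethnicity" in rep
            assert "c_by_sex" in rep
            assert "fairness_sex" in rep


def test_ipcw_and_exclude_agree_without_precensoring(trial_cohort,
                                                     fitted_trial_model):
    cohort = trial_cohort.head(500).copy()
    cohort["time"] = np.where(cohort["time"] < 3.0, np.where(
        cohort["event"] == 1, cohort["time"], 3.0), cohort["time"])
    risks = fitted_trial_model.predict_risk_frame(
        cohort, arm=cohort["arm"].to_numpy(object)
    )
    t, d = cohort["time"].to_numpy(), cohort["event"].to_numpy()
    lab_i = horizon_labels(t, d, 3.0, scheme="ipcw")
    lab_e = horizon_labels(t, d, 3.0, scheme="exclude")
    assert concordance(risks, lab_i, n_boot=0)["c"] == pytest.approx(
        concordance(risks, lab_e, n_boot=0)["c"], abs=1e-12
    )
    assert net_benefit(risks, lab_i, 0.2)["net_benefit"] == pytest.approx(
        net_benefit(risks, lab_e, 0.2)["net_benefit"], abs=1e-12
    )
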