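"""Diagnostic logistic models, signature, ROC/AUC, model comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nephromark.cohort import (
    DiagnosticModel,
    ModelConfig,
    build_signature,
    compare_models,
    cross_validated_auc,
    fit_logistic,
    read_cohort,
    roc_auc,
    transform_marker,
    univariate_screen,
    write_cohort,
)
from nephromark.screen import DEFAULT_PANEL
from nephromark.synthetic import CohortGenSpec, gen_cohort

MARKERS = DEFAULT_PANEL.marker_names


class TestFitLogistic:
    def test_binary_predictor_matches_two_by_two_log_odds_ratio(self):
        # contingency oracle: a=30 exposed events, b=20, c=15, d=60
        y = np.array([1] * 30 + [0] * 20 + [1] * 15 + [0] * 60)
        x = np.array([1] * 50 + [0] * 75)
        df = pd.DataFrame({"y": y, "x": x})
        res = fit_logistic(df, "y", predictors=("x",))
        expected = math.log((30 * 60) / (20 * 15))
        assert res.params["x"] == pytest.approx(expected, abs=1e-6)

    def test_null_covariate_coefficient_small(self):
        rng = np.random.default_rng(0)
        n = 2000
        df = pd.DataFrame({"y": rng.random(n) < 0.3, "x": rng.normal(size=n)})
        res = fit_logistic(df, "y", predictors=("x",))
        assert abs(res.params["x"]) < 3 * res.bse["x"]

    def test_constant_predictor_named_in_error(self):
        df = pd.DataFrame({"y": [0, 1, 0, 1], "flat": [2.0, 2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="flat"):
            fit_logistic(df, "y", predictors=("flat",))

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"y": [1, 1, 1], "x": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError):
            fit_logistic(df, "y", predictors=("x",))

    def test_separation_flagged_and_ci_suppressed(self):
        df = pd.DataFrame({
            "y": [0] * 20 + [1] * 20,
            "x": list(np.linspace(-2, -1, 20)) + list(np.linspace(1, 2, 20)),
        })
        res = fit_logistic(df, "y", predictors=("x",))
        assert not res.converged or res.separated_predictors
        ci = res.or_conf_int()
        assert ci.loc["x"].isna().all()

    def test_or_ci_contains_point_estimate(self):
        df, _ = gen_cohort(CohortGenSpec(seed=17))
        res = fit_logistic(df, "rejection", predictors=("egfr", "dsa"))
        ci = res.or_conf_int()
        for name in ("egfr", "dsa"):
            assert ci.loc[name, "ci95_low"] <= res.odds_ratios[name] <= ci.loc[name, "ci95_high"]

    def test_marker_transform_uses_half_min_nonzero_delta(self):
        x = pd.Series([0.0, 0.2, 0.4, 1.0])
        out = transform_marker(x)
        assert out[0] == pytest.approx(np.log10(0.1))
        assert out[1] == pytest.approx(np.log10(0.3))

    def test_summary_renders(self):
        df, _ = gen_cohort(CohortGenSpec(seed=1))
        res = fit_logistic(df, "rejection", predictors=("egfr", "dsa"))
        text = res.summary()
        assert "egfr" in text and "odds_ratio" in text
        assert "per 10" in text


class TestUnivariateScreen:
    def test_constant_predictor_recorded_in_table(self):
        df, _ = gen_cohort(CohortGenSpec(seed=2))
        df["flat"] = 1.0
        table = univariate_screen(df, "rejection", ("egfr", "flat"))
        row = table[table.predictor == "flat"].iloc[0]
        assert row["error"] != ""
        assert np.isnan(row["p_value"])
        assert table[table.predictor == "egfr"].iloc[0]["error"] == ""

    def test_planted_informative_marker_ranks_first(self):
        hits = 0
        for seed in range(5):
            spec = CohortGenSpec(
                seed=seed, endothelial_fold=4.0, pan_renal_fold=1.0,
                epithelial_fold=1.0, lesion_rate_nonrejection=0.0,
                dsa_rate_abmr_mixed=0.15,  # markers-only signal
                egfr_mean_rejection=50.0,
            )
            df, _ = gen_cohort(spec)
            table = univariate_screen(
                df, "rejection", (), ("LOC124903692", "PAX2", "ACSL5")
            )
            if table.iloc[0]["predictor"] == "LOC124903692":
                hits += 1
        assert hits >= 4

    def test_binary_predictor_or_matches_contingency_table(self):
        df, _ = gen_cohort(CohortGenSpec(seed=4))
        table = univariate_screen(df, "rejection", ("dsa",))
        a = int((df.dsa & df.rejection).sum())
        b = int((df.dsa & ~df.rejection).sum())
        c = int((~df.dsa & df.rejection).sum())
        d = int((~df.dsa & ~df.rejection).sum())
        expected = (a * d) / (b * c)
        row = table[table.predictor == "dsa"].iloc[0]
        assert row["odds_ratio"] == pytest.approx(expected, rel=1e-6)


class TestSignature:
    def test_single_passing_marker_gives_monotone_score(self):
        spec = CohortGenSpec(seed=5, endothelial_fold=1.0, epithelial_fold=1.0,
                             pan_renal_fold=3.0, lesion_rate_nonrejection=0.0)
        df, _ = gen_cohort(spec)
        sig = build_signature(df, "rejection", ["CTDP1"], alpha=0.05)
        assert sig.members == ["CTDP1"]
        order_marker = df["CTDP1"].rank()
        order_score = pd.Series(sig.score(df)).rank()
        corr = np.corrcoef(order_marker, order_score)[0, 1]
        assert abs(corr) == pytest.approx(1.0)

    def test_planted_members_recovered(self):
        ok = 0
        for seed in range(5):
            spec = CohortGenSpec(seed=seed, endothelial_fold=4.0,
                                 epithelial_fold=1.0, pan_renal_fold=1.0,
                                 lesion_rate_nonrejection=0.0)
            df, truth = gen_cohort(spec)
            endo = [m for m, r in truth["marker_roles"].items() if r == "endothelial"]
            try:
                sig = build_signature(df, "rejection", MARKERS, alpha=0.01)
            except ValueError:
                continue
            if set(sig.members) <= set(endo) and len(sig.members) >= 3:
                ok += 1
        assert ok >= 4

    def test_score_ordering_invariant_to_member_unit_rescaling(self):
        df, _ = gen_cohort(CohortGenSpec(seed=6))
        cfg = ModelConfig(delta=0.0)
        sig = build_signature(df, "rejection", MARKERS, alpha=0.05, config=cfg)
        member = sig.members[0]
        df2 = df.copy()
        df2[member] = df2[member] * 1000.0  # express in different units, refit
        sig2 = build_signature(df2, "rejection", MARKERS, alpha=0.05, config=cfg)
        assert sig2.members == sig.members
        r1 = pd.Series(sig.score(df)).rank()
        r2 = pd.Series(sig2.score(df2)).rank()
        assert np.corrcoef(r1, r2)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_no_passing_marker_raises_helpful_error(self):
        rng = np.random.default_rng(7)
        df, _ = gen_cohort(CohortGenSpec(seed=7))
        df["noise"] = 10 ** rng.normal(0, 0.3, len(df))
        with pytest.raises(ValueError, match="signature-free"):
            build_signature(df, "rejection", ["noise"], alpha=1e-6)


class TestROC:
    def test_perfect_separation_auc_one(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [False, False, False, True, True, True])
        assert r.auc == 1.0

    def test_all_tied_scores_auc_half(self):
        r = roc_auc([5.0] * 10, [True] * 4 + [False] * 6)
        assert r.auc == 0.5

    def test_matches_brute_force_pair_enumeration(self):
        rng = np.random.default_rng(11)
        scores = np.round(rng.normal(size=200), 1)  # rounding forces ties
        labels = rng.random(200) < 0.4
        r = roc_auc(scores, labels)
        pos = scores[labels]
        neg = scores[~labels]
        total = 0.0
        for p in pos:
            for q in neg:
                total += 1.0 if p > q else (0.5 if p == q else 0.0)
        assert r.auc == pytest.approx(total / (len(pos) * len(neg)), abs=1e-12)

    def test_trapezoid_of_curve_equals_rank_auc(self):
        rng = np.random.default_rng(12)
        scores = np.round(rng.normal(size=150), 1)
        labels = rng.random(150) < 0.5
        r = roc_auc(scores, labels)
        area = np.trapezoid(r.sensitivity, 1.0 - r.specificity)
        assert area == pytest.approx(r.auc, abs=1e-12)

    def test_matches_sklearn(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(13)
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.3
        assert roc_auc(scores, labels).auc == pytest.approx(
            sklearn.roc_auc_score(labels, scores), abs=1e-12
        )

    def test_one_class_absent_is_error(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [True, True])

    @given(st.floats(min_value=0.1, max_value=5.0), st.floats(-10, 10))
    @settings(derandomize=True, max_examples=25)
    def test_invariant_under_strictly_monotone_transform(self, a, b):
        rng = np.random.default_rng(14)
        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.5
        if labels.all() or not labels.any():
            labels[0] = True
            labels[1] = False
        base = roc_auc(scores, labels).auc
        assert roc_auc(a * scores + b, labels).auc == pytest.approx(base, abs=1e-12)
        assert roc_auc(np.exp(scores), labels).auc == pytest.approx(base, abs=1e-12)


class TestCompareModels:
    def test_combined_model_dominates_components(self):
        wins = 0
        for seed in range(10):
            df, _ = gen_cohort(CohortGenSpec(seed=seed))
            comp = compare_models(df, "rejection", MARKERS)
            a = comp.aucs["egfr_dsa_signature"]
            if a >= comp.aucs["egfr_dsa"] and a >= comp.aucs["signature"]:
                wins += 1
        assert wins >= 9

    def test_nested_model_auc_not_below_submodel(self):
        df, _ = gen_cohort(CohortGenSpec(seed=15))
        comp = compare_models(df, "rejection", MARKERS)
        assert comp.aucs["egfr_dsa_signature"] >= comp.aucs["egfr_dsa"] - 1e-9

    def test_single_predictor_model_matches_direct_roc(self):
        df, _ = gen_cohort(CohortGenSpec(seed=16))
        comp = compare_models(df, "any_banff_lesion", MARKERS)
        direct = roc_auc(
            df["dsa"].astype(float), df["any_banff_lesion"].astype(bool)
        ).auc
        assert comp.aucs["dsa_only"] == pytest.approx(direct, abs=1e-9)

    def test_label_permutation_gives_null_aucs(self):
        df, _ = gen_cohort(CohortGenSpec(seed=18))
        rng = np.random.default_rng(18)
        df = df.copy()
        df["rejection"] = rng.permutation(df["rejection"].to_numpy())
        df["rejection_subtype"] = np.where(df["rejection"], "ABMR", "none")
        comp = compare_models(df, "rejection", MARKERS, signature_alpha=1.0)
        for auc in comp.aucs.values():
            assert 0.4 <= auc <= 0.72  # in-sample refit inflates the null a bit

    def test_any_lesion_includes_marker_and_dsa_models(self):
        df, _ = gen_cohort(CohortGenSpec(seed=19))
        comp = compare_models(df, "any_banff_lesion", MARKERS)
        assert {"markers_only", "dsa_only"} <= set(comp.aucs)

    def test_cross_validated_auc_runs_and_is_sane(self):
        df, _ = gen_cohort(CohortGenSpec(seed=20))
        auc = cross_validated_auc(df, "rejection", ("egfr", "dsa"), k=5, seed=0)
        assert 0.4 < auc < 1.0


class TestCohortIO:
    def test_round_trip(self, tmp_path):
        df, _ = gen_cohort(CohortGenSpec(seed=21))
        path = tmp_path / "cohort.csv"
        write_cohort(df, path)
        back = read_cohort(path, MARKERS)
        assert back["rejection"].sum() == df["rejection"].sum()
        pd.testing.assert_series_equal(back["egfr"], df["egfr"])

    def test_inconsistent_labels_rejected(self, tmp_path):
        df, _ = gen_cohort(CohortGenSpec(seed=22))
        df.loc[df.index[0], "rejection"] = True
        df.loc[df.index[0], "rejection_subtype"] = "none"
        path = tmp_path / "bad.csv"
        write_cohort(df, path)
        with pytest.raises(ValueError, match="subtype"):
            read_cohort(path)
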