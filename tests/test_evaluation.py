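"""Evaluation framework against brute-force oracles and a pROC cross-check."""

import math

import numpy as np
import pytest

from plqct.classification import classify_dxa, classify_qct
from plqct.errors import DegenerateReferenceError, PLQCTError
from plqct.evaluation import (
    CohortRecord,
    age_stratified_bmd,
    apply_exclusions,
    build_report,
    cohort_summary,
    compute_precision,
    confusion_matrix_3x3,
    pearson_r,
    roc_analysis,
)
from plqct.synthetic_data import CohortModel, generate_cohort


def _rec(pid="p", age=60.0, sex="F", **kw):
    return CohortRecord(patient_id=pid, age=age, sex=sex, **kw)


# ---------------------------------------------------------------------------
# Oracles

def auc_pair_counting(scores, labels):
    """Mann-Whitney AUC with ties counted 1/2 (low score = positive)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p < n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def youden_exhaustive(scores, labels):
    """Best (J, sens, spec, criterion) over every attained cut-off '<= c'."""
    best = (-1.0, 0.0, 0.0, None)
    pos = sum(labels)
    neg = len(labels) - pos
    for c in sorted(set(scores)):
        tp = sum(1 for s, l in zip(scores, labels) if l == 1 and s <= c)
        fp = sum(1 for s, l in zip(scores, labels) if l == 0 and s <= c)
        sens, spec = tp / pos, 1 - fp / neg
        j = sens + spec - 1
        # tie-break toward higher specificity: strict improvement only
        if j > best[0] + 1e-12:
            best = (j, sens, spec, c)
    return best


class TestApplyExclusions:
    def test_partition_and_reason_tally(self):
        roster = [_rec(pid=f"a{i}") for i in range(5)]
        roster += [_rec(pid=f"b{i}", has_ldct=False) for i in range(3)]
        roster += [_rec(pid=f"c{i}", has_t12=False) for i in range(2)]
        roster += [_rec(pid="d0", dxa_complete=False)]
        included, excluded, tally = apply_exclusions(roster)
        assert len(included) == 5 and len(excluded) == 6
        assert tally == {"no_ldct": 3, "no_t12": 2, "dxa_incomplete": 1}
        assert len(included) + len(excluded) == len(roster)

    def test_priority_order_single_reason(self):
        rec = _rec(has_ldct=False, dxa_complete=False)
        _, excluded, tally = apply_exclusions([rec, _rec()])
        assert len(excluded) == 1
        assert excluded[0][1] == "no_ldct"
        assert tally["dxa_incomplete"] == 0

    def test_empty_flags_include_everyone(self):
        included, excluded, _ = apply_exclusions([_rec(), _rec()])
        assert len(included) == 2 and not excluded


class TestCohortSummary:
    def test_two_record_mean_sd(self):
        df = cohort_summary([_rec(age=40.0), _rec(age=60.0)])
        assert df.loc["total", "age_mean"] == pytest.approx(50.0)
        assert df.loc["total", "age_sd"] == pytest.approx(14.142135, abs=1e-4)

    def test_matches_brute_force_on_simulated_cohort(self):
        records, _ = generate_cohort(CohortModel(n=120, seed=2))
        df = cohort_summary(records)
        ages = np.array([r.age for r in records])
        assert df.loc["total", "age_mean"] == pytest.approx(ages.mean())
        assert df.loc["total", "age_sd"] == pytest.approx(ages.std(ddof=1))
        f_ages = np.array([r.age for r in records if r.sex == "F"])
        assert df.loc["F", "age_mean"] == pytest.approx(f_ages.mean())
        assert df.loc["F", "n"] == len(f_ages)


class TestRocAnalysis:
    def test_perfect_separation(self):
        scores = [60, 65, 70, 130, 140, 150]
        labels = [1, 1, 1, 0, 0, 0]
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(1.0)
        assert res.youden_j == pytest.approx(1.0)
        assert res.associated_criterion == 70  # largest positive score

    def test_all_tied_scores_give_half(self):
        res = roc_analysis([100] * 8, [1, 0, 1, 0, 1, 0, 1, 0])
        assert res.auc == pytest.approx(0.5)

    def test_single_class_degenerate(self):
        with pytest.raises(DegenerateReferenceError):
            roc_analysis([1, 2, 3, 4], [1, 1, 1, 1])

    def test_matches_pair_counting_and_exhaustive_youden(self, rng):
        for trial in range(25):
            n = int(rng.integers(12, 40))
            scores = np.round(rng.normal(100, 30, n), 1)
            labels = (scores + rng.normal(0, 25, n) < 100).astype(int)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 1, 0
            res = roc_analysis(list(scores), list(labels))
            assert res.auc == pytest.approx(
                auc_pair_counting(scores, labels), abs=1e-10)
            j, sens, spec, crit = youden_exhaustive(list(scores), list(labels))
            assert res.youden_j == pytest.approx(j, abs=1e-10)
            assert res.associated_criterion == pytest.approx(crit)
            assert res.sensitivity_pct == pytest.approx(sens * 100, abs=1e-9)
            assert res.specificity_pct == pytest.approx(spec * 100, abs=1e-9)
            # internal consistency of J
            assert res.youden_j == pytest.approx(
                res.sensitivity_pct / 100 + res.specificity_pct / 100 - 1,
                abs=1e-9)
            assert res.ci95_low <= res.auc <= res.ci95_high

    def test_delong_ci_matches_pROC_reference(self):
        # frozen cross-check computed with R pROC (ci.auc, method="delong")
        scores = [61, 72, 80, 83, 88, 92, 95, 99, 101, 104,
                  108, 112, 115, 119, 124, 131, 137, 145, 152, 160]
        labels = [1, 1, 1, 0, 1, 1, 0, 1, 0, 0, 1, 0, 0, 1, 0, 0, 0, 0, 0, 0]
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(0.8541666667, abs=1e-9)
        assert res.ci95_low == pytest.approx(0.6852318378, abs=1e-8)
        assert res.ci95_high == pytest.approx(1.0, abs=1e-9)
        assert res.sensitivity_pct == pytest.approx(75.0)
        assert res.specificity_pct == pytest.approx(83.3333333, abs=1e-4)

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(100, 25, 30)
        labels = (rng.random(30) < 0.4).astype(int)
        labels[0], labels[1] = 1, 0
        a1 = roc_analysis(list(scores), list(labels)).auc
        ranks = np.argsort(np.argsort(scores)).astype(float)
        a2 = roc_analysis(list(ranks), list(labels)).auc
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestConfusionMatrix:
    def test_identical_lists_are_diagonal(self):
        cats = ["normal", "osteopenia", "osteoporosis", "normal"]
        df, rates = confusion_matrix_3x3(cats, cats)
        assert np.trace(df.values) == 4
        assert df.values.sum() == 4

    def test_all_disagree_single_cell(self):
        df, _ = confusion_matrix_3x3(["osteoporosis"] * 5, ["normal"] * 5)
        assert df.loc["normal", "osteoporosis"] == 5
        assert df.values.sum() == 5

    def test_matches_direct_tally_and_marginals(self, rng):
        cats = ["normal", "osteopenia", "osteoporosis"]
        for _ in range(25):
            pred = [cats[i] for i in rng.integers(0, 3, 30)]
            ref = [cats[i] for i in rng.integers(0, 3, 30)]
            df, rates = confusion_matrix_3x3(pred, ref)
            for r in cats:
                for p in cats:
                    expect = sum(1 for a, b in zip(pred, ref)
                                 if a == p and b == r)
                    assert df.loc[r, p] == expect
            assert df.values.sum() == 30
            assert sum(rates["pred_rate_pct"].values()) == pytest.approx(100.0)
            assert sum(rates["ref_rate_pct"].values()) == pytest.approx(100.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(PLQCTError):
            confusion_matrix_3x3(["normal"], ["normal", "normal"])


class TestAgeStratifiedBmd:
    def test_bin_edge_membership(self):
        recs = [_rec(age=29.0, qct_vbmd_mgcc=150.0),
                _rec(age=30.0, qct_vbmd_mgcc=140.0)]
        df = age_stratified_bmd(recs)
        f = df[df.sex == "F"].set_index("age_bin")
        assert f.loc["<30", "n"] == 1
        assert f.loc["30-39", "n"] == 1

    def test_single_record_bin_has_undefined_sd(self):
        df = age_stratified_bmd([_rec(age=85.0, qct_vbmd_mgcc=70.0)])
        row = df[(df.sex == "F") & (df.age_bin == ">=80")].iloc[0]
        assert row["mean"] == 70.0
        assert row["sd"] is None or (isinstance(row["sd"], float)
                                     and math.isnan(row["sd"]))

    def test_empty_bins_are_nan_not_zero(self):
        df = age_stratified_bmd([_rec(age=55.0, qct_vbmd_mgcc=100.0)])
        empty = df[(df.sex == "F") & (df.age_bin == "<30")].iloc[0]
        assert empty["n"] == 0
        assert math.isnan(empty["mean"])

    def test_simulated_cohort_bin_means_near_model(self):
        model = CohortModel(n=2500, seed=9)
        records, _ = generate_cohort(model)
        df = age_stratified_bmd(records)
        for _, row in df.iterrows():
            if row["n"] < 25:
                continue
            idx = list(df[df.sex == row["sex"]]["age_bin"]).index(row["age_bin"])
            means = model.bin_means_f if row["sex"] == "F" else model.bin_means_m
            sigma = math.sqrt(model.bin_sd ** 2 + model.qct_noise_sd ** 2)
            se = sigma / math.sqrt(row["n"])
            assert abs(row["mean"] - means[idx]) < 4 * se


class TestComputePrecision:
    def test_identical_repeats(self):
        res = compute_precision({"a": [100.0, 100.0, 100.0]})
        assert res["precision_sd_mgcc"] == 0.0
        assert res["precision_cv_pct"] == 0.0

    def test_hand_arithmetic_two_repeats(self):
        res = compute_precision({"a": [98.0, 102.0]})
        assert res["precision_sd_mgcc"] == pytest.approx(2.828427, abs=1e-5)
        assert res["precision_cv_pct"] == pytest.approx(2.828427, abs=1e-5)

    def test_matches_per_subject_rms_oracle(self, rng):
        data = {f"s{i}": list(rng.normal(100, 3, 3)) for i in range(10)}
        res = compute_precision(data)
        rms = math.sqrt(np.mean([np.var(v, ddof=1) for v in data.values()]))
        grand = np.mean([x for v in data.values() for x in v])
        assert res["precision_sd_mgcc"] == pytest.approx(rms, rel=1e-12)
        assert res["precision_cv_pct"] == pytest.approx(100 * rms / grand,
                                                        rel=1e-12)

    def test_single_repeat_subjects_skipped(self):
        res = compute_precision({"a": [100.0], "b": [99.0, 101.0]})
        assert res["skipped"] == ["a"]
        with pytest.raises(PLQCTError):
            compute_precision({"a": [100.0]})


class TestPearson:
    def test_exact_lines(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_matches_raw_sums_closed_form(self, rng):
        x = rng.normal(0, 1, 25)
        y = 0.5 * x + rng.normal(0, 1, 25)
        n = 25
        sx, sy, sxy = x.sum(), y.sum(), (x * y).sum()
        sxx, syy = (x * x).sum(), (y * y).sum()
        expect = (n * sxy - sx * sy) / math.sqrt(
            (n * sxx - sx ** 2) * (n * syy - sy ** 2))
        assert pearson_r(x, y) == pytest.approx(expect, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(PLQCTError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBuildReport:
    def test_all_sections_populated(self):
        records, _ = generate_cohort(CohortModel(n=400, seed=4))
        report = build_report(records)
        assert report.n_included + report.n_excluded == 400
        assert ("total", "osteoporosis", "spine") in report.roc
        assert report.confusion is not None
        assert report.confusion.values.sum() == report.n_included
        assert report.stratified_bmd is not None
        md = report.to_markdown()
        assert "Confusion matrix" in md

    def test_single_sex_cohort_marks_other_absent(self):
        records, _ = generate_cohort(CohortModel(n=150, seed=6,
                                                 female_fraction=1.0))
        report = build_report(records)
        assert isinstance(report.roc[("men", "osteoporosis", "spine")], str)

    def test_qct_flags_more_osteoporosis_than_dxa(self):
        # DXA inflation produces false negatives; QCT should call a
        # higher osteoporosis proportion than DXA on the same patients
        records, _ = generate_cohort(CohortModel(n=800, seed=7))
        included, _, _ = apply_exclusions(records)
        qct_rate = np.mean([classify_qct(r.qct_vbmd_mgcc) == "osteoporosis"
                            for r in included])
        dxa_rate = np.mean([classify_dxa(r.spine_dxa_t) == "osteoporosis"
                            for r in included])
        assert qct_rate > dxa_rate
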