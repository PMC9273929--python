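"""DXA-referenced evaluation of the QCT measurements.

Reproduces the study's statistical framework on any cohort table:
exclusion flow with reason tally, demographic summaries, ROC analysis
with DeLong 95% CIs and the Youden-optimal associated criterion
(reported as "<= c" because low vBMD marks disease), 3x3 confusion
matrices of QCT against DXA categories, seven-bin age-stratified BMD
trends, and RMS-SD / CV% precision from repeat measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .classification import CATEGORIES, classify_dxa, classify_qct
from .config import ClassificationConfig, EvaluationConfig
from .errors import DegenerateReferenceError, PLQCTError

AGE_BIN_EDGES = (-math.inf, 30, 40, 50, 60, 70, 80, math.inf)
AGE_BIN_LABELS = ("<30", "30-39", "40-49", "50-59", "60-69", "70-79", ">=80")

EXCLUSION_REASONS = ("no_ldct", "no_t12", "dxa_incomplete")


@dataclass
class CohortRecord:
    """One patient: demographics, DXA and QCT results, exclusion flags."""

    patient_id: str
    age: float
    sex: str                                  # M | F
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    bmi: Optional[float] = None
    spine_dxa_t: Optional[float] = None
    fn_dxa_t: Optional[float] = None          # femoral neck
    th_dxa_t: Optional[float] = None          # total hip
    spine_dxa_bmd: Optional[float] = None
    hip_dxa_bmd: Optional[float] = None
    qct_vbmd_mgcc: Optional[float] = None
    device: str = "unknown"
    has_ldct: bool = True
    has_t12: bool = True
    dxa_complete: bool = True

    def __post_init__(self):
        if self.age < 0:
            raise PLQCTError("age must be non-negative", stage="cohort")
        if self.sex not in ("M", "F"):
            raise PLQCTError(f"sex must be M or F, got {self.sex!r}",
                             stage="cohort")

    @property
    def hip_t(self) -> Optional[float]:
        """Hip-site T-score: total hip when present, else femoral neck."""
        return self.th_dxa_t if self.th_dxa_t is not None else self.fn_dxa_t


@dataclass
class ROCResult:
    auc: float
    ci95_low: float
    ci95_high: float
    sensitivity_pct: float
    specificity_pct: float
    youden_j: float
    associated_criterion: float   # vBMD cut-off, direction "<="
    n: int

    def to_dict(self) -> dict:
        return {"auc": self.auc, "ci95": [self.ci95_low, self.ci95_high],
                "sensitivity_pct": self.sensitivity_pct,
                "specificity_pct": self.specificity_pct,
                "youden_j": self.youden_j,
                "associated_criterion": self.associated_criterion,
                "n": self.n}


def apply_exclusions(roster: list[CohortRecord]):
    """Partition a roster into included/excluded with one reason each.

    Reasons are assigned in priority order: no low-dose CT, then T12 not
    imaged, then incomplete DXA; a patient failing several checks is
    excluded exactly once under the highest-priority reason.
    """
    if not roster:
        raise PLQCTError("empty roster", stage="evaluation")
    included, excluded = [], []
    tally = {r: 0 for r in EXCLUSION_REASONS}
    for rec in roster:
        if not rec.has_ldct:
            reason = "no_ldct"
        elif not rec.has_t12:
            reason = "no_t12"
        elif not rec.dxa_complete:
            reason = "dxa_incomplete"
        else:
            included.append(rec)
            continue
        excluded.append((rec, reason))
        tally[reason] += 1
    return included, excluded, tally


def _mean_sd(values: list[float]) -> tuple[float, Optional[float], int]:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    n = arr.size
    if n == 0:
        return math.nan, None, 0
    sd = float(np.std(arr, ddof=1)) if n > 1 else None
    return float(np.mean(arr)), sd, n


def cohort_summary(records: list[CohortRecord]) -> pd.DataFrame:
    """Mean ± sample SD of age/height/weight/BMI by sex and pooled.

    The pooled column is computed over the union of records (so it
    equals the count-weighted combination of the subgroup means).
    """
    if not records:
        raise PLQCTError("empty cohort", stage="evaluation")
    cols = {"age": lambda r: r.age, "height_cm": lambda r: r.height_cm,
            "weight_kg": lambda r: r.weight_kg, "bmi": lambda r: r.bmi}
    rows = []
    for group, members in (("M", [r for r in records if r.sex == "M"]),
                           ("F", [r for r in records if r.sex == "F"]),
                           ("total", list(records))):
        row = {"group": group, "n": len(members)}
        for name, get in cols.items():
            mean, sd, n = _mean_sd([get(r) for r in members])
            row[f"{name}_mean"] = mean
            row[f"{name}_sd"] = sd
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# ROC with DeLong CI

def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    xs = x[order]
    n = x.size
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong_auc_var(pos_scores: np.ndarray, neg_scores: np.ndarray):
    """AUC and its DeLong variance (higher score = positive)."""
    m, n = pos_scores.size, neg_scores.size
    allv = np.concatenate([pos_scores, neg_scores])
    tx = _midrank(pos_scores)
    ty = _midrank(neg_scores)
    tz = _midrank(allv)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    s01 = np.var(v01, ddof=1) if m > 1 else 0.0
    s10 = np.var(v10, ddof=1) if n > 1 else 0.0
    return float(auc), float(s01 / m + s10 / n)


def roc_analysis(scores, labels, config: EvaluationConfig | None = None,
                 rng: np.random.Generator | None = None) -> ROCResult:
    """Empirical ROC of vBMD against a binary reference (1 = diseased).

    Low scores indicate disease, so the classifier family is
    "positive if score <= c" over all attained cut-offs c. AUC is the
    trapezoidal area (equivalently the Mann-Whitney statistic with ties
    counted 1/2); the 95% CI is DeLong by default or a seeded bootstrap.
    The associated criterion maximizes Youden's J = sens + spec - 1;
    ties are broken toward higher specificity.
    """
    cfg = config or EvaluationConfig()
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.size != s.size or y.size == 0:
        raise PLQCTError("scores/labels mismatch", stage="evaluation")
    if len(np.unique(y)) < 2:
        raise DegenerateReferenceError("degenerate reference: single class")

    # negate scores: low vBMD = positive; keep every attained threshold
    fpr, tpr, thr = roc_curve(y, -s, drop_intermediate=False)
    auc, var = _delong_auc_var(-s[y == 1], -s[y == 0])
    if cfg.ci_method == "bootstrap":
        rng = rng or np.random.default_rng(cfg.seed)
        idx = np.arange(y.size)
        reps = []
        for _ in range(cfg.bootstrap_reps):
            b = rng.choice(idx, size=idx.size, replace=True)
            if len(np.unique(y[b])) < 2:
                continue
            a, _ = _delong_auc_var(-s[b][y[b] == 1], -s[b][y[b] == 0])
            reps.append(a)
        lo, hi = np.percentile(reps, [2.5, 97.5])
    else:
        se = math.sqrt(max(var, 0.0))
        lo, hi = auc - 1.959964 * se, auc + 1.959964 * se
    lo, hi = max(0.0, min(lo, auc)), min(1.0, max(hi, auc))

    # drop the "predict none positive" point (J = 0 by construction,
    # and its threshold is not an attained score)
    j = tpr[1:] - fpr[1:]
    jmax = j.max()
    cand = np.flatnonzero(j >= jmax - 1e-12)
    best = cand[np.argmin(fpr[1:][cand])]  # tie -> higher specificity
    return ROCResult(auc=auc,
                     ci95_low=float(lo), ci95_high=float(hi),
                     sensitivity_pct=float(tpr[1:][best] * 100.0),
                     specificity_pct=float((1.0 - fpr[1:][best]) * 100.0),
                     youden_j=float(j[best]),
                     associated_criterion=float(-thr[1:][best]),
                     n=int(y.size))


def confusion_matrix_3x3(pred_categories, ref_categories):
    """3x3 confusion matrix: rows = DXA reference, cols = QCT prediction.

    Category order is fixed (normal, osteopenia, osteoporosis). Returns
    the count matrix as a DataFrame plus per-category diagnosis rates
    (column sums / n, in %) for prediction and reference.
    """
    pred = list(pred_categories)
    ref = list(ref_categories)
    if len(pred) != len(ref):
        raise PLQCTError("prediction/reference length mismatch",
                         stage="evaluation")
    idx = {c: i for i, c in enumerate(CATEGORIES)}
    mat = np.zeros((3, 3), dtype=int)
    for p, r in zip(pred, ref):
        if p not in idx or r not in idx:
            raise PLQCTError(f"unknown category: {p!r}/{r!r}",
                             stage="evaluation")
        mat[idx[r], idx[p]] += 1
    n = mat.sum()
    df = pd.DataFrame(mat, index=list(CATEGORIES), columns=list(CATEGORIES))
    rates = {
        "pred_rate_pct": {c: 100.0 * mat[:, idx[c]].sum() / n for c in CATEGORIES},
        "ref_rate_pct": {c: 100.0 * mat[idx[c], :].sum() / n for c in CATEGORIES},
    }
    return df, rates


def age_stratified_bmd(records: list[CohortRecord],
                       value=lambda r: r.qct_vbmd_mgcc) -> pd.DataFrame:
    """Per-age-bin, per-sex mean/SD/n of a BMD value.

    Seven bins, closed on the left: <30, 30-39, ..., 70-79, >=80. Empty
    bins appear with n = 0 and NaN mean (never a silent zero).
    """
    rows = []
    for sex in ("F", "M"):
        for lab, lo, hi in zip(AGE_BIN_LABELS, AGE_BIN_EDGES[:-1],
                               AGE_BIN_EDGES[1:]):
            members = [value(r) for r in records
                       if r.sex == sex and lo <= r.age < hi
                       and value(r) is not None]
            mean, sd, n = _mean_sd(members)
            rows.append({"sex": sex, "age_bin": lab, "n": n,
                         "mean": mean, "sd": sd})
    return pd.DataFrame(rows)


def compute_precision(repeat_measurements: dict[str, list[float]]):
    """Short-term precision: RMS of per-subject SDs and CV%.

    RMS-SD = sqrt(mean of per-subject variances) over subjects with >= 2
    repeats (the densitometry-standard precision estimate); CV% = RMS-SD
    divided by the grand mean of all used measurements, times 100.
    Subjects with a single measurement are skipped with a warning flag.
    """
    variances, all_values, skipped = [], [], []
    for subject, reps in repeat_measurements.items():
        if len(reps) < 2:
            skipped.append(subject)
            continue
        variances.append(float(np.var(reps, ddof=1)))
        all_values.extend(reps)
    if not variances:
        raise PLQCTError("no subject has >= 2 repeats", stage="evaluation")
    rms_sd = math.sqrt(float(np.mean(variances)))
    grand_mean = float(np.mean(all_values))
    cv_pct = 100.0 * rms_sd / grand_mean
    return {"precision_sd_mgcc": rms_sd, "precision_cv_pct": cv_pct,
            "n_subjects": len(variances), "skipped": skipped}


def pearson_r(x, y) -> float:
    """Product-moment correlation (errors on degenerate input)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise PLQCTError("need >= 3 paired observations", stage="evaluation")
    sxx = float(np.sum((x - x.mean()) ** 2))
    syy = float(np.sum((y - y.mean()) ** 2))
    if sxx == 0 or syy == 0:
        raise PLQCTError("zero variance; correlation undefined",
                         stage="evaluation")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    return sxy / math.sqrt(sxx * syy)


# ---------------------------------------------------------------------------
# Full report

@dataclass
class DiagnosticReport:
    roc: dict = field(default_factory=dict)       # (sex, task, ref) -> ROCResult|str
    confusion: Optional[pd.DataFrame] = None
    diagnosis_rates: dict = field(default_factory=dict)
    stratified_bmd: Optional[pd.DataFrame] = None
    summary: Optional[pd.DataFrame] = None
    exclusion_tally: dict = field(default_factory=dict)
    n_included: int = 0
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "n_included": self.n_included,
            "n_excluded": self.n_excluded,
            "exclusion_tally": self.exclusion_tally,
            "roc": {"|".join(k): (v.to_dict() if isinstance(v, ROCResult) else v)
                    for k, v in self.roc.items()},
            "confusion_matrix": None if self.confusion is None
            else self.confusion.values.tolist(),
            "diagnosis_rates": self.diagnosis_rates,
            "stratified_bmd": None if self.stratified_bmd is None
            else self.stratified_bmd.where(self.stratified_bmd.notna(), None)
                     .to_dict(orient="records"),
            "summary": None if self.summary is None
            else self.summary.where(self.summary.notna(), None)
                     .reset_index().to_dict(orient="records"),
        }

    def to_markdown(self) -> str:
        lines = ["# Diagnostic report", "",
                 f"Included {self.n_included}, excluded {self.n_excluded} "
                 f"({self.exclusion_tally})", ""]
        if self.summary is not None:
            lines += ["## Cohort summary", self.summary.to_string(), ""]
        lines.append("## ROC (low vBMD = positive)")
        for key, res in self.roc.items():
            tag = " / ".join(key)
            if isinstance(res, ROCResult):
                lines.append(
                    f"- {tag}: AUC {res.auc:.2f} "
                    f"({res.ci95_low:.2f}-{res.ci95_high:.2f}), "
                    f"sens {res.sensitivity_pct:.1f}%, "
                    f"spec {res.specificity_pct:.1f}%, J {res.youden_j:.2f}, "
                    f"criterion <= {res.associated_criterion:.1f} mg/cc "
                    f"(n={res.n})")
            else:
                lines.append(f"- {tag}: {res}")
        if self.confusion is not None:
            lines += ["", "## Confusion matrix (rows: DXA, cols: QCT)",
                      self.confusion.to_string()]
        if self.stratified_bmd is not None:
            lines += ["", "## Age-stratified vBMD",
                      self.stratified_bmd.to_string(index=False)]
        return "\n".join(lines) + "\n"


def _reference_t(rec: CohortRecord, reference: str) -> Optional[float]:
    if reference == "spine":
        return rec.spine_dxa_t
    if reference == "hip":
        return rec.hip_t
    if reference == "lower":
        ts = [t for t in (rec.spine_dxa_t, rec.hip_t) if t is not None]
        return min(ts) if ts else None
    raise PLQCTError(f"unknown reference standard: {reference!r}",
                     stage="evaluation")


def build_report(roster: list[CohortRecord],
                 references: tuple[str, ...] = ("hip", "spine", "lower"),
                 confusion_reference: str = "spine",
                 cls_config: ClassificationConfig | None = None,
                 eval_config: EvaluationConfig | None = None) -> DiagnosticReport:
    """Exclusions → summaries → ROC grid → confusion matrix → age strata.

    The ROC grid covers (women, men, total) x (osteoporosis, osteopenia)
    x each reference standard; "osteopenia" is the low-bone-mass task
    (osteopenia or worse vs normal). Degenerate subgroups are reported
    as a message, not a failure.
    """
    cls_cfg = cls_config or ClassificationConfig()
    included, excluded, tally = apply_exclusions(roster)
    report = DiagnosticReport(exclusion_tally=tally,
                              n_included=len(included),
                              n_excluded=len(excluded))
    report.summary = cohort_summary(included) if included else None

    usable = [r for r in included if r.qct_vbmd_mgcc is not None]
    for sex_label, subgroup in (("women", [r for r in usable if r.sex == "F"]),
                                ("men", [r for r in usable if r.sex == "M"]),
                                ("total", usable)):
        for reference in references:
            pairs = [(r.qct_vbmd_mgcc, _reference_t(r, reference))
                     for r in subgroup
                     if _reference_t(r, reference) is not None]
            for task in ("osteoporosis", "osteopenia"):
                key = (sex_label, task, reference)
                if len(pairs) < 4:
                    report.roc[key] = "subgroup absent or too small"
                    continue
                scores = [p[0] for p in pairs]
                if task == "osteoporosis":
                    labels = [int(classify_dxa(p[1], cls_cfg) == "osteoporosis")
                              for p in pairs]
                else:
                    labels = [int(classify_dxa(p[1], cls_cfg) != "normal")
                              for p in pairs]
                try:
                    report.roc[key] = roc_analysis(scores, labels, eval_config)
                except DegenerateReferenceError as exc:
                    report.roc[key] = str(exc)

    conf_pairs = [(classify_qct(r.qct_vbmd_mgcc, cls_cfg),
                   classify_dxa(_reference_t(r, confusion_reference), cls_cfg))
                  for r in usable
                  if _reference_t(r, confusion_reference) is not None]
    if conf_pairs:
        report.confusion, report.diagnosis_rates = confusion_matrix_3x3(
            [p[0] for p in conf_pairs], [p[1] for p in conf_pairs])
    report.stratified_bmd = age_stratified_bmd(usable)
    return report
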