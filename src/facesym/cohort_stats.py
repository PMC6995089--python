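"""Cohort-level diagnostic evaluation of facial-asymmetry measurements.

Per patient, MRI grades each temporomandibular joint (TMJ) on a
three-level scale — not affected, inflammatory activity without osseous
destruction, inflammatory activity with osseous destruction.  A patient
is *asymmetrically* affected when exactly one side carries the finding.
The question the statistics answer: how well do facial-asymmetry
assessments (clinical flags, digital chin score, Hausdorff distances)
predict asymmetrical osseous destruction?

Provided: contingency analysis (uncorrected Pearson chi-squared and
positive predictive value), ROC threshold selection over millimetre
cutoffs with the Youden index, Mann-Whitney U comparisons, univariate
binary logistic regression with the Cox & Snell R², and ICC(2,1)
absolute-agreement repeatability.  No multiple-testing correction is
applied; α = 0.05 throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from .errors import ConvergenceError, ValidationError

#: combined-sample-size cutoff below which Mann-Whitney uses exact enumeration
MANN_WHITNEY_EXACT_MAX_N = 20


class MriStatus(str, Enum):
    """Per-joint MRI grading, three ordered levels."""

    NOT_AFFECTED = "not_affected"
    INFLAMMATION = "inflammation_no_destruction"
    DESTRUCTION = "inflammation_with_destruction"


class Treatment(str, Enum):
    NONE = "none"
    SYSTEMIC = "systemic"
    LOCAL = "local"


@dataclass
class PatientRecord:
    """One patient: MRI grades, clinical flags, treatment, digital metrics."""

    patient_id: str
    mri_left: MriStatus
    mri_right: MriStatus
    clinical_chin_asym: bool
    clinical_gonion_asym: bool
    treatment: Treatment
    chin_mm: float | None = None
    had_mean_mm: float | None = None
    had_max_mm: float | None = None

    def __post_init__(self) -> None:
        self.mri_left = MriStatus(self.mri_left)
        self.mri_right = MriStatus(self.mri_right)
        self.treatment = Treatment(self.treatment)


@dataclass
class ContingencyTable:
    """2×2 counts: rows = MRI asymmetrical destruction (no/yes),
    columns = assessment (negative/positive)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64).reshape(2, 2)

    def validate(self) -> "ContingencyTable":
        if (self.counts < 0).any():
            raise ValidationError("contingency counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValidationError("contingency table is empty")
        return self


@dataclass
class RocResult:
    thresholds_mm: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    selected_threshold_mm: float


@dataclass
class LogisticFit:
    intercept: float
    slope: float
    loglik_model: float
    loglik_null: float
    n: int
    cox_snell_r2: float


def classify_patient_asymmetry(record: PatientRecord) -> tuple[bool, bool]:
    """(asymmetrical inflammation, asymmetrical destruction) flags.

    Destruction is asymmetrical when exactly one joint shows osseous
    destruction; inflammation is asymmetrical when exactly one joint is
    affected at all.
    """
    levels = (record.mri_left, record.mri_right)
    if any(l is None for l in levels):
        raise ValidationError(f"{record.patient_id}: missing MRI level")
    n_destr = sum(l == MriStatus.DESTRUCTION for l in levels)
    n_affected = sum(l != MriStatus.NOT_AFFECTED for l in levels)
    return n_affected == 1, n_destr == 1


def contingency_from_flags(destruction, assessment) -> ContingencyTable:
    """Cross-tabulate asymmetrical-destruction status vs a binary call."""
    destruction = np.asarray(destruction, dtype=bool)
    assessment = np.asarray(assessment, dtype=bool)
    counts = np.array(
        [
            [(~destruction & ~assessment).sum(), (~destruction & assessment).sum()],
            [(destruction & ~assessment).sum(), (destruction & assessment).sum()],
        ]
    )
    return ContingencyTable(counts).validate()


def pearson_chi2(table: ContingencyTable) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-squared on a 2×2 table: (stat, df, p)."""
    table.validate()
    c = table.counts
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        raise ValidationError("chi-squared requires positive row and column margins")
    stat, p, dof, _ = scipy.stats.chi2_contingency(c, correction=False)
    return float(stat), int(dof), float(p)


def positive_predictive_value(table: ContingencyTable) -> float:
    """P(destruction | positive assessment) from the 2×2 counts."""
    table.validate()
    positives = table.counts[:, 1].sum()
    if positives == 0:
        raise ValidationError("PPV undefined: no positive assessments")
    return float(table.counts[1, 1] / positives)


def roc_analysis(
    scores, labels, thresholds=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
) -> RocResult:
    """ROC evaluation of a continuous score against a binary outcome.

    A call is positive when ``score >= threshold``.  Sensitivity and
    specificity are reported on the supplied grid (default 1–6 mm); the
    AUC integrates the full empirical curve over every distinct
    cutpoint, which equals the pair-counting estimator
    P(case > control) + ½·P(tie).  The selected threshold maximizes the
    Youden index (sensitivity + specificity − 1); ties resolve to the
    smallest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D")
    if labels.all() or (~labels).all():
        raise ValidationError("ROC needs both outcome classes present")
    thresholds = np.asarray(thresholds, dtype=float)
    sens = np.array(
        [np.mean(scores[labels] >= t) for t in thresholds]
    )
    spec = np.array(
        [np.mean(scores[~labels] < t) for t in thresholds]
    )
    auc = float(roc_auc_score(labels, scores))
    youden = sens + spec - 1.0
    best = int(np.argmax(youden))  # argmax returns the first (smallest) tie
    return RocResult(
        thresholds_mm=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        selected_threshold_mm=float(thresholds[best]),
    )


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test: (U of group_a, p).

    Midranks handle ties.  For combined n ≤ 20 without ties the p-value
    is exact by enumeration; otherwise the normal approximation with
    tie-corrected variance and no continuity correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("Mann-Whitney requires two non-empty groups")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if a.size + b.size <= MANN_WHITNEY_EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def logistic_fit(outcome, predictor) -> LogisticFit:
    """Univariate binary logistic regression by maximum likelihood.

    Newton/IRLS via statsmodels; reports the fitted and the
    intercept-only log-likelihoods and the Cox & Snell R².  Perfect
    separation is flagged as non-convergence.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValidationError("outcome and predictor must be equal-length 1-D")
    if not np.isfinite(x).all():
        raise ValidationError("predictor contains non-finite values")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all() or len(classes) != 2:
        raise ValidationError("outcome must be binary with both classes present")
    n = len(y)
    if np.ptp(x) == 0:
        # zero-variance predictor: slope MLE is 0, model equals the null
        p = y.mean()
        ll0 = n * (p * math.log(p) + (1 - p) * math.log(1 - p))
        return LogisticFit(
            intercept=float(math.log(p / (1 - p))),
            slope=0.0,
            loglik_model=ll0,
            loglik_null=ll0,
            n=n,
            cox_snell_r2=0.0,
        )
    X = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
    except Exception as exc:
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False) or np.abs(fit.params).max() > 1e3:
        raise ConvergenceError(
            "logistic fit did not converge (possible perfect separation)"
        )
    r2 = cox_snell_r2(fit.llnull, fit.llf, n)
    return LogisticFit(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        loglik_model=float(fit.llf),
        loglik_null=float(fit.llnull),
        n=n,
        cox_snell_r2=r2,
    )


def cox_snell_r2(loglik_null: float, loglik_model: float, n: int) -> float:
    """Cox & Snell coefficient of determination, 1 − exp(2(ℓ₀ − ℓ₁)/n)."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if loglik_model < loglik_null - 1e-9:
        raise ValidationError("model log-likelihood below null log-likelihood")
    return float(1.0 - math.exp(2.0 * (loglik_null - loglik_model) / n))


def icc_absolute(measurements) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    From the ANOVA mean squares of an n-subject × k-repeat table:
    ``(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)``.  A table with no
    variance at all (all values identical) returns 1 by convention.
    """
    X = np.asarray(measurements, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("ICC needs an n>=2 by k>=2 complete table")
    if not np.isfinite(X).all():
        raise ValidationError("ICC table must be complete and finite")
    n, k = X.shape
    if np.ptp(X) == 0:
        return 1.0
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


# ---------------------------------------------------------------------------
# cohort report


@dataclass
class BinaryAssessmentResult:
    """One Table-4-style column: counts, chi-squared p, PPV."""

    name: str
    n_no_destruction: int
    positives_no_destruction: int
    n_destruction: int
    positives_destruction: int
    chi2_p: float | None
    ppv: float | None


@dataclass
class ContinuousComparisonResult:
    """One Table-5-style column: medians, Mann-Whitney p, Cox & Snell R²."""

    name: str
    median_no: float
    iqr_no: float
    median_yes: float
    iqr_yes: float
    mw_p: float | None
    cox_snell_r2: float | None


@dataclass
class CohortReport:
    """Structured analogue of the published descriptive/analytic tables."""

    n_patients: int
    mri_counts: dict[str, int]
    descriptives: dict[str, dict[str, float]]
    clinical_prevalence: dict[str, int]
    binary_assessments: list[BinaryAssessmentResult] = field(default_factory=list)
    continuous_comparisons: list[ContinuousComparisonResult] = field(
        default_factory=list
    )
    treatment_comparisons: list[dict] = field(default_factory=list)
    roc: RocResult | None = None
    digital_positive_count: int | None = None
    chin_threshold_mm: float = 4.0
    not_computable: list[str] = field(default_factory=list)


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        asym_infl, asym_destr = classify_patient_asymmetry(r)
        rows.append(
            {
                "patient_id": r.patient_id,
                "mri_left": r.mri_left.value,
                "mri_right": r.mri_right.value,
                "clinical_chin": bool(r.clinical_chin_asym),
                "clinical_gonion": bool(r.clinical_gonion_asym),
                "treatment": r.treatment.value,
                "chin_mm": r.chin_mm,
                "had_mean_mm": r.had_mean_mm,
                "had_max_mm": r.had_max_mm,
                "asym_inflammation": asym_infl,
                "asym_destruction": asym_destr,
            }
        )
    return pd.DataFrame(rows)


def _descriptives(x: pd.Series) -> dict[str, float]:
    x = x.dropna().astype(float)
    q1, q3 = np.percentile(x, [25, 75])
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "median": float(x.median()),
        "iqr": float(q3 - q1),
        "min": float(x.min()),
        "max": float(x.max()),
    }


def cohort_report(
    records: list[PatientRecord],
    chin_threshold_mm: float = 4.0,
    roc_thresholds=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
) -> CohortReport:
    """Full statistical evaluation of a cohort.

    Emits MRI descriptive counts, asymmetry descriptives, binary
    contingency analyses (clinical gonion/chin and digital chin at the
    configured threshold), continuous Mann-Whitney comparisons with
    Cox & Snell R², treatment comparisons, and the ROC cutpoint scan.
    Sections that a degenerate cohort cannot support are listed under
    ``not_computable`` instead of raising.
    """
    if not records:
        raise ValidationError("cohort is empty")
    df = records_to_frame(records)
    n = len(df)
    report = CohortReport(
        n_patients=n,
        mri_counts=_mri_counts(df),
        descriptives={
            name: _descriptives(df[name])
            for name in ("chin_mm", "had_mean_mm", "had_max_mm")
            if df[name].notna().any()
        },
        clinical_prevalence={
            "clinical_chin": int(df["clinical_chin"].sum()),
            "clinical_gonion": int(df["clinical_gonion"].sum()),
        },
        chin_threshold_mm=chin_threshold_mm,
    )
    has_chin = df["chin_mm"].notna().all()
    if has_chin:
        report.digital_positive_count = int(
            (df["chin_mm"] >= chin_threshold_mm).sum()
        )
    destr = df["asym_destruction"].to_numpy()
    if not (destr.any() and (~destr).any()):
        report.not_computable.extend(
            ["binary_assessments", "continuous_comparisons", "roc"]
        )
        return report

    assessments = [
        ("clinical_gonion", df["clinical_gonion"].to_numpy()),
        ("clinical_chin", df["clinical_chin"].to_numpy()),
    ]
    if has_chin:
        assessments.append(
            (
                f"digital_chin_ge_{chin_threshold_mm:g}mm",
                (df["chin_mm"] >= chin_threshold_mm).to_numpy(),
            )
        )
    for name, calls in assessments:
        table = contingency_from_flags(destr, calls)
        try:
            _, _, p = pearson_chi2(table)
        except ValidationError:
            p = None
        try:
            ppv = positive_predictive_value(table)
        except ValidationError:
            ppv = None
        report.binary_assessments.append(
            BinaryAssessmentResult(
                name=name,
                n_no_destruction=int(table.counts[0].sum()),
                positives_no_destruction=int(table.counts[0, 1]),
                n_destruction=int(table.counts[1].sum()),
                positives_destruction=int(table.counts[1, 1]),
                chi2_p=p,
                ppv=ppv,
            )
        )

    for name in ("chin_mm", "had_mean_mm", "had_max_mm"):
        col = df[name]
        if not col.notna().all():
            report.not_computable.append(f"continuous:{name}")
            continue
        x = col.to_numpy(dtype=float)
        no, yes = x[~destr], x[destr]
        _, mw_p = mann_whitney(yes, no)
        try:
            fit = logistic_fit(destr.astype(float), x)
            r2 = fit.cox_snell_r2
        except ConvergenceError:
            r2 = None
        q = lambda v: float(np.percentile(v, 75) - np.percentile(v, 25))
        report.continuous_comparisons.append(
            ContinuousComparisonResult(
                name=name,
                median_no=float(np.median(no)),
                iqr_no=q(no),
                median_yes=float(np.median(yes)),
                iqr_yes=q(yes),
                mw_p=mw_p,
                cox_snell_r2=r2,
            )
        )

    if has_chin:
        report.roc = roc_analysis(
            df["chin_mm"].to_numpy(dtype=float), destr, roc_thresholds
        )
        report.treatment_comparisons = _treatment_comparisons(
            df, chin_threshold_mm
        )
    return report


def _mri_counts(df: pd.DataFrame) -> dict[str, int]:
    counts = {}
    for side in ("left", "right"):
        col = df[f"mri_{side}"]
        for status in MriStatus:
            counts[f"{side}_{status.value}"] = int((col == status.value).sum())
    counts["both_not_affected"] = int(
        (
            (df["mri_left"] == MriStatus.NOT_AFFECTED.value)
            & (df["mri_right"] == MriStatus.NOT_AFFECTED.value)
        ).sum()
    )
    counts["asym_inflammation"] = int(df["asym_inflammation"].sum())
    counts["asym_destruction"] = int(df["asym_destruction"].sum())
    return counts


def _treatment_comparisons(df: pd.DataFrame, threshold: float) -> list[dict]:
    """Table-6-style contrasts: any treatment and local injections."""
    out = []
    chin = df["chin_mm"].to_numpy(dtype=float)
    positive = chin >= threshold
    for name, treated in (
        ("any_treatment", (df["treatment"] != Treatment.NONE.value).to_numpy()),
        ("local_treatment", (df["treatment"] == Treatment.LOCAL.value).to_numpy()),
    ):
        entry: dict = {
            "name": name,
            "n_untreated": int((~treated).sum()),
            "n_treated": int(treated.sum()),
            "positives_untreated": int(positive[~treated].sum()),
            "positives_treated": int(positive[treated].sum()),
        }
        if treated.any() and (~treated).any():
            entry["median_untreated"] = float(np.median(chin[~treated]))
            entry["median_treated"] = float(np.median(chin[treated]))
            _, entry["mw_p"] = mann_whitney(chin[treated], chin[~treated])
            table = contingency_from_flags(treated, positive)
            try:
                _, _, entry["chi2_p"] = pearson_chi2(table)
            except ValidationError:
                entry["chi2_p"] = None
        out.append(entry)
    return out
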