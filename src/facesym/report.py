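"""Cohort CSV schema and report rendering.

Cohorts travel as CSV with the header ``patient_id, mri_left, mri_right,
clinical_chin, clinical_gonion, treatment, chin_mm, had_mean_mm,
had_max_mm``.  Reports render to JSON (full precision) and Markdown
(display rounding: whole percent, 0.1 mm, two-decimal p-values —
rounding happens only here, never in the computations).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_stats import (
    CohortReport,
    MriStatus,
    PatientRecord,
    Treatment,
)
from .errors import ValidationError

COHORT_COLUMNS = [
    "patient_id",
    "mri_left",
    "mri_right",
    "clinical_chin",
    "clinical_gonion",
    "treatment",
    "chin_mm",
    "had_mean_mm",
    "had_max_mm",
]

_BOOL_MAP = {
    "1": True, "0": False, "true": True, "false": False,
    "yes": True, "no": False,
}


def read_cohort_csv(path) -> list[PatientRecord]:
    """Parse a cohort CSV into validated records; names offending rows."""
    try:
        df = pd.read_csv(path, dtype=str)
    except (OSError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"cannot read cohort CSV {path}: {exc}") from exc
    missing = [c for c in COHORT_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing column(s): " + ", ".join(missing)
        )
    records, bad = [], []
    for i, row in df.iterrows():
        try:
            records.append(_parse_row(row))
        except (ValueError, KeyError) as exc:
            bad.append(f"row {i + 2}: {exc}")  # +2: header + 1-based
    if bad:
        raise ValidationError(f"{path}: invalid rows:\n" + "\n".join(bad))
    if not records:
        raise ValidationError(f"{path}: no patient records")
    return records


def _parse_row(row: pd.Series) -> PatientRecord:
    def boolean(key):
        val = str(row[key]).strip().lower()
        if val not in _BOOL_MAP:
            raise ValueError(f"{key}={row[key]!r} is not a boolean")
        return _BOOL_MAP[val]

    def optional_float(key):
        if key not in row or pd.isna(row[key]) or str(row[key]).strip() == "":
            return None
        return float(row[key])

    return PatientRecord(
        patient_id=str(row["patient_id"]),
        mri_left=MriStatus(str(row["mri_left"]).strip()),
        mri_right=MriStatus(str(row["mri_right"]).strip()),
        clinical_chin_asym=boolean("clinical_chin"),
        clinical_gonion_asym=boolean("clinical_gonion"),
        treatment=Treatment(str(row["treatment"]).strip()),
        chin_mm=optional_float("chin_mm"),
        had_mean_mm=optional_float("had_mean_mm"),
        had_max_mm=optional_float("had_max_mm"),
    )


def write_cohort_csv(records: list[PatientRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "mri_left": r.mri_left.value,
                "mri_right": r.mri_right.value,
                "clinical_chin": int(r.clinical_chin_asym),
                "clinical_gonion": int(r.clinical_gonion_asym),
                "treatment": r.treatment.value,
                "chin_mm": r.chin_mm,
                "had_mean_mm": r.had_mean_mm,
                "had_max_mm": r.had_max_mm,
            }
        )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# rendering


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def report_to_json(report: CohortReport, provenance: dict | None = None) -> str:
    payload = _jsonable(asdict(report))
    if provenance:
        payload["provenance"] = _jsonable(provenance)
    return json.dumps(payload, indent=2)


def _pct(x: float | None) -> str:
    return "n/a" if x is None else f"{round(100 * x):d}%"


def _pval(p: float | None) -> str:
    return "n/a" if p is None else f"{p:.2f}"


def _mm(x: float | None) -> str:
    return "n/a" if x is None else f"{x:.1f}"


def report_to_markdown(report: CohortReport) -> str:
    """Human-readable analogue of the published descriptive tables."""
    n = report.n_patients
    lines = [f"# Cohort asymmetry report (n = {n})", ""]

    lines += ["## MRI status", "", "| finding | n (%) |", "|---|---|"]
    for key, count in report.mri_counts.items():
        lines.append(f"| {key} | {count} ({100 * count / n:.1f}%) |")

    lines += ["", "## Asymmetry assessments", ""]
    lines += ["| clinical flag | n (%) |", "|---|---|"]
    for key, count in report.clinical_prevalence.items():
        lines.append(f"| {key} | {count} ({100 * count / n:.1f}%) |")
    if report.descriptives:
        lines += [
            "",
            "| digital metric | mean (SD) | median (IQR) | range |",
            "|---|---|---|---|",
        ]
        for name, d in report.descriptives.items():
            lines.append(
                f"| {name} | {_mm(d['mean'])} ({_mm(d['sd'])}) "
                f"| {_mm(d['median'])} ({_mm(d['iqr'])}) "
                f"| {_mm(d['min'])}–{_mm(d['max'])} |"
            )
    if report.digital_positive_count is not None:
        c = report.digital_positive_count
        lines.append(
            f"\nDigital chin asymmetry ≥ {report.chin_threshold_mm:g} mm: "
            f"{c} ({100 * c / n:.1f}%)"
        )

    if report.binary_assessments:
        lines += [
            "",
            "## Binary assessments vs asymmetrical osseous destruction",
            "",
            "| assessment | no destr. n (+) | destr. n (+) | chi² p | PPV |",
            "|---|---|---|---|---|",
        ]
        for b in report.binary_assessments:
            lines.append(
                f"| {b.name} | {b.n_no_destruction} ({b.positives_no_destruction}) "
                f"| {b.n_destruction} ({b.positives_destruction}) "
                f"| {_pval(b.chi2_p)} | {_pct(b.ppv)} |"
            )

    if report.continuous_comparisons:
        lines += [
            "",
            "## Continuous metrics vs asymmetrical osseous destruction",
            "",
            "| metric | median (IQR), no | median (IQR), yes | M-W p | Cox & Snell R² |",
            "|---|---|---|---|---|",
        ]
        for c in report.continuous_comparisons:
            r2 = "n/a" if c.cox_snell_r2 is None else f"{100 * c.cox_snell_r2:.1f}%"
            lines.append(
                f"| {c.name} | {_mm(c.median_no)} ({_mm(c.iqr_no)}) "
                f"| {_mm(c.median_yes)} ({_mm(c.iqr_yes)}) "
                f"| {_pval(c.mw_p)} | {r2} |"
            )

    if report.roc is not None:
        r = report.roc
        lines += ["", "## ROC threshold scan (digital chin asymmetry)", ""]
        lines.append(
            f"AUC {r.auc:.3f}; selected threshold {r.selected_threshold_mm:g} mm "
            "(max Youden index)"
        )
        lines += ["", "| threshold (mm) | sensitivity | specificity |", "|---|---|---|"]
        for t, se, sp in zip(r.thresholds_mm, r.sensitivity, r.specificity):
            lines.append(f"| {t:g} | {_pct(se)} | {_pct(sp)} |")

    if report.treatment_comparisons:
        lines += [
            "",
            "## Treatment comparisons (digital chin asymmetry)",
            "",
            "| contrast | untreated n (+) | treated n (+) | chi² p | M-W p |",
            "|---|---|---|---|---|",
        ]
        for t in report.treatment_comparisons:
            lines.append(
                f"| {t['name']} | {t['n_untreated']} ({t['positives_untreated']}) "
                f"| {t['n_treated']} ({t['positives_treated']}) "
                f"| {_pval(t.get('chi2_p'))} | {_pval(t.get('mw_p'))} |"
            )

    if report.not_computable:
        lines += ["", "Not computable for this cohort: "
                  + ", ".join(report.not_computable)]
    return "\n".join(lines) + "\n"


def save_report(
    report: CohortReport,
    out_dir,
    stem: str = "cohort_report",
    provenance: dict | None = None,
) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / f"{stem}.json"
    md_path = out / f"{stem}.md"
    json_path.write_text(report_to_json(report, provenance))
    md_path.write_text(report_to_markdown(report))
    return json_path, md_path
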