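"""Cohort CSV readers/writers, flat configuration, and the analysis pipeline.

Cohorts are stored as two CSV files: a long-format measurement table
(patient_id, site, phase, cortisol, aldosterone — cortisol in µg/dL,
aldosterone in pg/mL, one row per site/phase) and a metadata table keyed by
patient_id (class label when known, eligibility flags, screening labs,
post-operative fields).  Long format was chosen over wide (one column per
site × hormone × phase) for extensibility; a wide-format importer is
provided as a convenience.

``run_pipeline`` orchestrates the full analysis: eligibility filter →
per-patient indices → rule-based classification → group statistics and
ROC/likelihood-ratio threshold tables.  Given the same input, config and
seed, its output is byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import roc as rocmod
from .classify import (PatientMeta, PatientRecord, Subtype, Thresholds,
                       adjudicate, catheterization_success, cohort_filter)
from .indices import Measurement, Phase, Site, compute_index_set

__all__ = [
    "CohortTable",
    "PipelineReport",
    "CohortParseError",
    "records_to_table",
    "table_to_records",
    "read_cohort",
    "read_cohort_wide",
    "write_cohort",
    "scores_from_distributional",
    "run_pipeline",
    "write_report",
    "DEFAULT_CONFIG",
    "read_config",
    "write_default_config",
]

MEASUREMENT_COLUMNS = ["patient_id", "site", "phase", "cortisol", "aldosterone"]

_META_BOOL = ["rt_sampling_complete", "surgery_done_if_uapa", "postop_bp_normal",
              "followup_available"]
_META_FLOAT = ["age", "pac", "pra", "arr", "postop_arr"]
_META_STR = ["sex", "ct_lesion", "subtype"]
META_COLUMNS = ["patient_id"] + _META_FLOAT + _META_BOOL + _META_STR


class CohortParseError(ValueError):
    """A cohort file failed validation; the message names row and column."""


@dataclass
class CohortTable:
    """Long-format measurements plus a per-patient metadata table."""

    measurements: pd.DataFrame
    meta: pd.DataFrame

    def patient_ids(self) -> list[str]:
        return list(dict.fromkeys(self.measurements["patient_id"]))


@dataclass
class PipelineReport:
    per_patient: pd.DataFrame
    exclusion_tally: dict[str, int]
    group_stats: pd.DataFrame
    comparisons: pd.DataFrame
    roc_table: pd.DataFrame
    log: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# record <-> table conversion


def records_to_table(records: list[PatientRecord]) -> CohortTable:
    mrows = [
        {"patient_id": m.patient_id, "site": Site(m.site).value, "phase": Phase(m.phase).value,
         "cortisol": m.cortisol, "aldosterone": m.aldosterone}
        for r in records for m in r.measurements
    ]
    trows = []
    for r in records:
        meta = r.meta
        row: dict = {"patient_id": r.patient_id}
        for c in _META_FLOAT:
            row[c] = getattr(meta, c)
        for c in _META_BOOL:
            row[c] = getattr(meta, c)
        row["sex"] = meta.sex
        row["ct_lesion"] = meta.ct_lesion
        row["subtype"] = meta.subtype.value if meta.subtype is not None else None
        trows.append(row)
    return CohortTable(
        measurements=pd.DataFrame(mrows, columns=MEASUREMENT_COLUMNS),
        meta=pd.DataFrame(trows, columns=META_COLUMNS),
    )


def _opt(v):
    if v is None:
        return None
    if isinstance(v, float) and math.isnan(v):
        return None
    return v


def table_to_records(table: CohortTable) -> list[PatientRecord]:
    meta_by_id = {row["patient_id"]: row for row in table.meta.to_dict("records")}
    records: dict[str, PatientRecord] = {}
    for row in table.measurements.to_dict("records"):
        pid = row["patient_id"]
        if pid not in records:
            mrow = meta_by_id.get(pid, {})
            sub = _opt(mrow.get("subtype"))
            meta = PatientMeta(
                age=_opt(mrow.get("age")), sex=_opt(mrow.get("sex")),
                pac=_opt(mrow.get("pac")), pra=_opt(mrow.get("pra")),
                arr=_opt(mrow.get("arr")),
                rt_sampling_complete=_opt(mrow.get("rt_sampling_complete")),
                surgery_done_if_uapa=_opt(mrow.get("surgery_done_if_uapa")),
                postop_arr=_opt(mrow.get("postop_arr")),
                postop_bp_normal=_opt(mrow.get("postop_bp_normal")),
                followup_available=_opt(mrow.get("followup_available")),
                ct_lesion=_opt(mrow.get("ct_lesion")) or "none",
                subtype=Subtype(sub) if sub else None,
            )
            records[pid] = PatientRecord(pid, [], meta)
        records[pid].measurements.append(Measurement(
            pid, Site(row["site"]), Phase(row["phase"]),
            float(row["cortisol"]), float(row["aldosterone"])))
    return list(records.values())


# ---------------------------------------------------------------------------
# CSV I/O


def _meta_path(path: Union[str, Path]) -> Path:
    path = Path(path)
    return path.with_suffix(".meta.csv")


def write_cohort(table: CohortTable, path: Union[str, Path]) -> None:
    """Write measurements to ``path`` and metadata next to it (``*.meta.csv``)."""
    path = Path(path)
    table.measurements.to_csv(path, index=False)
    table.meta.to_csv(_meta_path(path), index=False)


def read_cohort(path: Union[str, Path], meta_path: Union[str, Path, None] = None) -> CohortTable:
    """Read and validate a cohort; errors name the offending row and column.

    Row numbers in messages are 1-based data rows (the header is row 0).
    """
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _meta_path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing_cols = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortParseError(f"{path}: missing column(s): {', '.join(missing_cols)}")

    valid_sites = {s.value for s in Site}
    valid_phases = {p.value for p in Phase}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.site not in valid_sites:
            raise CohortParseError(f"{path}: row {i}: unknown site {row.site!r}")
        if row.phase not in valid_phases:
            raise CohortParseError(f"{path}: row {i}: unknown phase {row.phase!r}")
        for col in ("cortisol", "aldosterone"):
            v = getattr(row, col)
            try:
                fv = float(v)
            except (TypeError, ValueError):
                fv = math.nan
            if not math.isfinite(fv):
                raise CohortParseError(f"{path}: row {i}: malformed {col} value {v!r}")
    dup = df.duplicated(subset=["patient_id", "site", "phase"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0]) + 1
        raise CohortParseError(f"{path}: row {i}: duplicate (patient_id, site, phase)")

    if meta_path.exists():
        meta = pd.read_csv(meta_path, dtype={"patient_id": str})
        if "patient_id" not in meta.columns:
            raise CohortParseError(f"{meta_path}: missing column patient_id")
        known = set(meta["patient_id"])
        orphans = [p for p in dict.fromkeys(df["patient_id"]) if p not in known]
        if orphans:
            raise CohortParseError(
                f"{meta_path}: patient(s) missing from metadata: {', '.join(orphans[:5])}")
        for col in _META_BOOL:
            if col in meta.columns:
                meta[col] = meta[col].map(
                    lambda v: None if (v is None or (isinstance(v, float) and math.isnan(v)))
                    else bool(v) if isinstance(v, (bool, np.bool_)) else
                    str(v).strip().lower() in ("true", "1", "yes"))
    else:
        meta = pd.DataFrame({"patient_id": list(dict.fromkeys(df["patient_id"]))})
    df["cortisol"] = df["cortisol"].astype(float)
    df["aldosterone"] = df["aldosterone"].astype(float)
    return CohortTable(df, meta)


def read_cohort_wide(path: Union[str, Path]) -> CohortTable:
    """Convenience importer for wide files: one row per patient, columns
    ``{site}_{cortisol|aldosterone}_{phase}`` (e.g. ``lt_adv_cortisol_post_acth``)."""
    path = Path(path)
    wide = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in wide.columns:
        raise CohortParseError(f"{path}: missing column patient_id")
    rows = []
    for i, row in enumerate(wide.to_dict("records"), start=1):
        for site in Site:
            for phase in Phase:
                c_col = f"{site.value}_cortisol_{phase.value}"
                a_col = f"{site.value}_aldosterone_{phase.value}"
                if c_col not in wide.columns or a_col not in wide.columns:
                    raise CohortParseError(f"{path}: missing column {c_col} or {a_col}")
                rows.append({"patient_id": row["patient_id"], "site": site.value,
                             "phase": phase.value, "cortisol": float(row[c_col]),
                             "aldosterone": float(row[a_col])})
    meta_cols = [c for c in wide.columns
                 if not any(c.startswith(s.value) for s in Site)]
    return CohortTable(pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS), wide[meta_cols].copy())


def scores_from_distributional(df: pd.DataFrame) -> pd.DataFrame:
    """Pass-through validation for distributional score tables."""
    for col in ("patient_id", "subtype", "modified_li"):
        if col not in df.columns:
            raise CohortParseError(f"score table missing column {col}")
    return df


# ---------------------------------------------------------------------------
# configuration (flat key/value YAML)

DEFAULT_CONFIG: dict = {
    "si_success": 5.0,
    "li_uapa": 4.0,
    "mli_rt": 0.7,
    "mli_lt": 2.2,
    "phase": Phase.POST_ACTH.value,
    "seed": 0,
    "apply_cohort_filter": True,
    "arr_prefilter": False,  # optional ARR > 200 screening pre-filter
}


def read_config(path: Union[str, Path, None]) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = sorted(set(user) - set(cfg))
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
        cfg.update(user)
    return cfg


def write_default_config(path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(DEFAULT_CONFIG, fh, sort_keys=False)


def thresholds_from_config(cfg: dict) -> Thresholds:
    return Thresholds(si_success=float(cfg["si_success"]), li_uapa=float(cfg["li_uapa"]),
                      mli_rt=float(cfg["mli_rt"]), mli_lt=float(cfg["mli_lt"]))


# ---------------------------------------------------------------------------
# pipeline


def _group_label(row) -> Optional[str]:
    return row if isinstance(row, str) and row else None


def run_pipeline(
    cohort: CohortTable,
    thresholds: Thresholds = Thresholds(),
    phase: Phase = Phase.POST_ACTH,
    apply_filter: bool = True,
    arr_prefilter: bool = False,
) -> PipelineReport:
    """Filter → indices → classification → group statistics → ROC tables.

    Group statistics and ROC rows are computed against the true class labels
    when the metadata carries them (synthetic cohorts), otherwise against
    the pipeline's own calls.  ROC rows cover the three published contrasts:
    conventional LI for UAPA vs IHA (higher positive), modified LI for right
    APA vs rest (lower positive) and left APA vs rest (higher positive).
    """
    log: list[str] = []
    records = table_to_records(cohort)
    log.append(f"patients in: {len(records)}")
    if arr_prefilter:
        records = [r for r in records if r.meta.arr is None or r.meta.arr > 200]
        log.append(f"after ARR>200 pre-filter: {len(records)}")
    if apply_filter:
        included, tally = cohort_filter(records)
        tally_out = {k.value: v for k, v in tally.items()}
        for k, v in tally_out.items():
            if v:
                log.append(f"excluded ({k}): {v}")
    else:
        included, tally_out = records, {}
    log.append(f"patients analyzed: {len(included)}")

    rows = []
    for rec in included:
        idx = compute_index_set(rec.measurements, phase)
        si_right_ok = catheterization_success(idx.si_right, thresholds)
        call = adjudicate(idx, si_right_ok, thresholds)
        rows.append({
            "patient_id": rec.patient_id,
            "true_subtype": rec.meta.subtype.value if rec.meta.subtype else None,
            "arr": rec.meta.arr,
            "si_left": idx.si_left, "si_right": idx.si_right,
            "si_right_ok": si_right_ok,
            "ac_left": idx.ac_left, "ac_right": idx.ac_right, "ac_srt": idx.ac_srt,
            "conventional_li": idx.conventional_li,
            "dominant_side": idx.dominant_side.value,
            "modified_li": idx.modified_li,
            "call": call.label.value, "rule": call.rule.value,
        })
    per_patient = pd.DataFrame(rows)

    group_col = ("true_subtype"
                 if not per_patient.empty and per_patient["true_subtype"].notna().all()
                 else "call")
    if per_patient.empty:
        group_stats = pd.DataFrame(columns=["group", "n"])
        comparisons = pd.DataFrame(columns=["variable", "group_a", "group_b", "u", "p"])
        roc_table = pd.DataFrame(columns=["variable", "target", "direction", "auc",
                                          "threshold", "sensitivity", "specificity",
                                          "lr_positive"])
        return PipelineReport(per_patient, tally_out, group_stats, comparisons, roc_table, log)

    order = [s.value for s in (Subtype.RT_APA, Subtype.LT_APA, Subtype.IHA)]
    grows = []
    for g in order:
        sub = per_patient[per_patient[group_col] == g]
        if sub.empty:
            continue
        grows.append({
            "group": g, "n": len(sub),
            "conventional_li_mean": sub["conventional_li"].mean(),
            "conventional_li_sd": sub["conventional_li"].std(ddof=1),
            "modified_li_mean": sub["modified_li"].mean(),
            "modified_li_sd": sub["modified_li"].std(ddof=1),
            "arr_mean": sub["arr"].mean() if sub["arr"].notna().any() else math.nan,
            "arr_sd": sub["arr"].std(ddof=1) if sub["arr"].notna().any() else math.nan,
        })
    group_stats = pd.DataFrame(grows)

    crows = []
    present = [g for g in order if (per_patient[group_col] == g).sum() >= 2]
    for i, ga in enumerate(present):
        for gb in present[i + 1:]:
            for var in ("conventional_li", "modified_li"):
                a = per_patient.loc[per_patient[group_col] == ga, var].to_numpy()
                b = per_patient.loc[per_patient[group_col] == gb, var].to_numpy()
                u, p = rocmod.rank_sum_test(a, b)
                crows.append({"variable": var, "group_a": ga, "group_b": gb, "u": u, "p": p})
    comparisons = pd.DataFrame(crows, columns=["variable", "group_a", "group_b", "u", "p"])

    contrasts = [
        ("conventional_li", "UAPA", rocmod.Direction.HIGHER_IS_POSITIVE,
         lambda g: g in (Subtype.RT_APA.value, Subtype.LT_APA.value)),
        ("modified_li", Subtype.RT_APA.value, rocmod.Direction.LOWER_IS_POSITIVE,
         lambda g: g == Subtype.RT_APA.value),
        ("modified_li", Subtype.LT_APA.value, rocmod.Direction.HIGHER_IS_POSITIVE,
         lambda g: g == Subtype.LT_APA.value),
    ]
    rrows = []
    for var, target, direction, is_pos in contrasts:
        labels = per_patient[group_col].map(lambda g: int(is_pos(g))).to_numpy()
        if labels.sum() == 0 or labels.sum() == len(labels):
            continue
        scores = per_patient[var].to_numpy()
        curve = rocmod.roc_curve(scores, labels, direction)
        auc = rocmod.auc_rank(scores, labels, direction)
        try:
            choice = rocmod.best_threshold_by_lr(curve)
            thr, sens, spec, lr = (choice.threshold, choice.sensitivity,
                                   choice.specificity, choice.lr_positive)
        except rocmod.NoFiniteLRError:
            thr = sens = spec = lr = math.nan
        rrows.append({"variable": var, "target": target, "direction": direction.value,
                      "auc": auc, "threshold": thr, "sensitivity": sens,
                      "specificity": spec, "lr_positive": lr})
    roc_table = pd.DataFrame(rrows, columns=["variable", "target", "direction", "auc",
                                             "threshold", "sensitivity", "specificity",
                                             "lr_positive"])
    return PipelineReport(per_patient, tally_out, group_stats, comparisons, roc_table, log)


def write_report(report: PipelineReport, outdir: Union[str, Path]) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.per_patient.to_csv(outdir / "per_patient.csv", index=False)
    pd.DataFrame(sorted(report.exclusion_tally.items()),
                 columns=["reason", "n"]).to_csv(outdir / "exclusions.csv", index=False)
    report.group_stats.to_csv(outdir / "group_stats.csv", index=False)
    report.comparisons.to_csv(outdir / "comparisons.csv", index=False)
    report.roc_table.to_csv(outdir / "roc_table.csv", index=False)
    (outdir / "pipeline.log").write_text("\n".join(report.log) + "\n")
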