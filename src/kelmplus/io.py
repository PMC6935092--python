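"""Delimited-text readers and writers for feature tables and cohort metadata.

Dialect: comma- or tab-delimited (auto-detected), UTF-8, decimal point.
Feature tables carry a header row of ROI names with the subject id in the
first column. The cohort table has columns subject_id, sbp, dbp (the grade
is derived, never read). A JSON provenance sidecar records normalization
state on write.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ROIFeatureTable, SubjectMeta, ThicknessStats
from .errors import FormatError
from .registry import validate_roi_names


def _detect_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def _numeric(df: pd.DataFrame, path: Path) -> np.ndarray:
    # astype(float) round-trips IEEE doubles exactly (pd.to_numeric does not)
    try:
        if df.isna().to_numpy().any():
            raise ValueError
        return df.astype(float).to_numpy(dtype=float)
    except (ValueError, TypeError):
        pass
    for r in range(df.shape[0]):
        for c in range(df.shape[1]):
            cell = df.iat[r, c]
            try:
                if pd.isna(cell):
                    raise ValueError
                float(cell)
            except (ValueError, TypeError):
                raise FormatError(
                    f"{path}: non-numeric cell at row {df.index[r]!r}, "
                    f"column {df.columns[c]!r} (value {cell!r})") from None
    raise FormatError(f"{path}: table could not be parsed as numeric")


def read_feature_table(path: str | Path, feature_type: str, *,
                       validate_rois: bool = True) -> ROIFeatureTable:
    """Read a subjects x ROIs table; ROI names are checked against the AAL registry
    (skipped for Network tables, whose columns are pair labels)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate subject id {dup!r}")
    if validate_rois and feature_type != "Network":
        validate_roi_names(df.columns)
    values = _numeric(df, path)
    sidecar = path.with_suffix(path.suffix + ".json")
    normalized = False
    if sidecar.exists():
        normalized = bool(json.loads(sidecar.read_text()).get("normalized", False))
    return ROIFeatureTable(list(df.index), list(df.columns), values, feature_type,
                           normalized=normalized)


def write_feature_table(table: ROIFeatureTable, path: str | Path, *, sep: str = ",") -> None:
    """Write a feature table plus a JSON provenance sidecar."""
    path = Path(path)
    table.to_frame().to_csv(path, sep=sep, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"feature_type": table.feature_type, "normalized": table.normalized,
         "n_subjects": table.n_subjects, "n_columns": len(table.roi_names)}, indent=2))


def read_cohort(path: str | Path) -> list[SubjectMeta]:
    """Read the cohort table (subject_id, sbp, dbp[, age, sex]); grades derived."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype={"subject_id": str})
    required = {"subject_id", "sbp", "dbp"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: cohort table needs columns {sorted(required)}")
    metas = []
    for _, row in df.iterrows():
        metas.append(SubjectMeta(
            subject_id=str(row["subject_id"]), sbp=float(row["sbp"]), dbp=float(row["dbp"]),
            age=float(row["age"]) if "age" in df.columns and pd.notna(row["age"]) else None,
            sex=str(row["sex"]) if "sex" in df.columns and pd.notna(row["sex"]) else None))
    return metas


def write_cohort(metas: list[SubjectMeta], path: str | Path, *, sep: str = ",") -> None:
    rows = [{"subject_id": m.subject_id, "sbp": m.sbp, "dbp": m.dbp, "grade": m.grade,
             "age": m.age, "sex": m.sex} for m in metas]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_thickness_stats(path: str | Path) -> ThicknessStats:
    """Read per-ROI thickness statistics written by :func:`write_thickness_stats`."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0, dtype=str)
    mean_cols = [c for c in df.columns if c.startswith("mean_")]
    var_cols = [c for c in df.columns if c.startswith("var_")]
    rois = [c[len("mean_"):] for c in mean_cols]
    if rois != [c[len("var_"):] for c in var_cols]:
        raise FormatError(f"{path}: mean_/var_ column pairs do not match")
    means = _numeric(df[mean_cols], path)
    variances = _numeric(df[var_cols], path)
    return ThicknessStats(list(df.index), rois, means, variances)


def write_thickness_stats(stats: ThicknessStats, path: str | Path, *, sep: str = ",") -> None:
    cols = {f"mean_{r}": stats.means[:, i] for i, r in enumerate(stats.roi_names)}
    cols.update({f"var_{r}": stats.variances[:, i] for i, r in enumerate(stats.roi_names)})
    pd.DataFrame(cols, index=pd.Index(stats.subject_ids, name="subject_id")).to_csv(
        path, sep=sep, float_format="%.17g")
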