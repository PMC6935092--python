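"""Per-subject normalization of ROI features.

Volumes (GMV, WMV, CSFV) are divided by the subject's total brain volume;
cortical thickness by the subject's standard deviation of thickness across
its ROI values (population SD, divisor n); cortical surface area by the
subject's summed ROI area. Each normalization is guarded against being
applied twice.
"""

from __future__ import annotations

import numpy as np

from .datamodel import ROIFeatureTable, VOLUME_TYPES
from .errors import DegenerateInputError, InvalidInputError


def _require_raw(table: ROIFeatureTable) -> None:
    if table.normalized:
        raise InvalidInputError(
            f"{table.feature_type} table is already normalized; refusing to normalize twice")


def total_brain_volume(gmv: ROIFeatureTable, wmv: ROIFeatureTable,
                       csfv: ROIFeatureTable) -> np.ndarray:
    """Per-subject total brain volume: sum of GMV+WMV+CSFV over all ROIs."""
    for t, kind in ((gmv, "GMV"), (wmv, "WMV"), (csfv, "CSFV")):
        if t.feature_type != kind:
            raise InvalidInputError(f"expected a {kind} table, got {t.feature_type}")
        _require_raw(t)
    return gmv.values.sum(axis=1) + wmv.values.sum(axis=1) + csfv.values.sum(axis=1)


def normalize_volumes(table: ROIFeatureTable, tbv: np.ndarray) -> ROIFeatureTable:
    """Divide each ROI volume by that subject's total brain volume."""
    if table.feature_type not in VOLUME_TYPES:
        raise InvalidInputError(f"normalize_volumes expects a volume table, got {table.feature_type}")
    _require_raw(table)
    tbv = np.asarray(tbv, dtype=float)
    if tbv.shape != (table.n_subjects,):
        raise InvalidInputError(
            f"need one total brain volume per subject ({table.n_subjects}), got shape {tbv.shape}")
    if np.any(~np.isfinite(tbv)) or np.any(tbv <= 0):
        raise InvalidInputError("total brain volume must be positive and finite for every subject")
    return table.with_values(table.values / tbv[:, None], normalized=True)


def normalize_thickness(table: ROIFeatureTable) -> ROIFeatureTable:
    """Divide each subject's thickness row by its within-subject SD across ROIs."""
    if table.feature_type != "Thickness":
        raise InvalidInputError(f"normalize_thickness expects Thickness, got {table.feature_type}")
    _require_raw(table)
    sd = table.values.std(axis=1)  # population SD across the subject's ROI values
    if np.any(sd == 0):
        i = int(np.argmax(sd == 0))
        raise DegenerateInputError(
            f"subject {table.subject_ids[i]!r} has zero thickness variation across ROIs")
    return table.with_values(table.values / sd[:, None], normalized=True)


def normalize_area(table: ROIFeatureTable) -> ROIFeatureTable:
    """Divide each ROI area by that subject's total cortical surface area."""
    if table.feature_type != "Area":
        raise InvalidInputError(f"normalize_area expects Area, got {table.feature_type}")
    _require_raw(table)
    total = table.values.sum(axis=1)
    if np.any(total <= 0):
        i = int(np.argmax(total <= 0))
        raise InvalidInputError(f"subject {table.subject_ids[i]!r} has non-positive total area")
    return table.with_values(table.values / total[:, None], normalized=True)


def normalize_tables(tables: dict[str, ROIFeatureTable],
                     tbv: np.ndarray | None = None) -> dict[str, ROIFeatureTable]:
    """Normalize the five ROI feature tables in one pass.

    When ``tbv`` is not supplied it is computed as each subject's summed
    GMV+WMV+CSFV. Network tables pass through untouched.
    """
    out = dict(tables)
    if tbv is None and all(k in tables for k in VOLUME_TYPES):
        tbv = total_brain_volume(tables["GMV"], tables["WMV"], tables["CSFV"])
    for kind in VOLUME_TYPES:
        if kind in out:
            if tbv is None:
                raise InvalidInputError("total brain volume required to normalize volumes")
            out[kind] = normalize_volumes(out[kind], tbv)
    if "Thickness" in out:
        out["Thickness"] = normalize_thickness(out["Thickness"])
    if "Area" in out:
        out["Area"] = normalize_area(out["Area"])
    return out
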