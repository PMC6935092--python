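"""Core data types and blood-pressure grade assignment.

Blood pressure is graded on the 2017 ACC/AHA four-category scheme:
normal (grade 1), elevated (grade 2), hypertension stage 1 (grade 3) and
hypertension stage 2 (grade 4, folding in hypertensive crisis). Feature
tables hold one morphometric feature type per table, subjects x ROIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .registry import aal_roi_names

#: The five per-ROI feature types plus the thickness-network feature.
FEATURE_TYPES = ("GMV", "WMV", "CSFV", "Thickness", "Area", "Network")

#: Feature types normalised by total brain volume.
VOLUME_TYPES = ("GMV", "WMV", "CSFV")

GRADE_NAMES = {1: "normal", 2: "elevated", 3: "hypertension stage 1", 4: "hypertension stage 2"}


def grade_from_bp(sbp: float, dbp: float) -> int:
    """Assign the 2017 ACC/AHA blood-pressure grade from SBP/DBP in mmHg.

    Grade 1 (normal): SBP < 120 and DBP < 80.
    Grade 2 (elevated): 120 <= SBP <= 129 and DBP < 80.
    Grade 3 (stage 1): SBP 130-139 and/or DBP 80-89.
    Grade 4 (stage 2, incl. crisis): SBP >= 140 and/or DBP >= 90.

    The and/or rules overlap; the highest applicable grade wins, which makes
    the assignment total and monotone in both pressures.
    """
    sbp = float(sbp)
    dbp = float(dbp)
    if not (math.isfinite(sbp) and math.isfinite(dbp)) or sbp <= 0 or dbp <= 0:
        raise InvalidInputError(f"pressures must be positive finite mmHg, got ({sbp}, {dbp})")
    if sbp >= 140 or dbp >= 90:
        return 4
    if sbp >= 130 or dbp >= 80:
        return 3
    if sbp >= 120:
        return 2
    return 1


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject metadata; the grade is derived from (sbp, dbp), never read."""

    subject_id: str
    sbp: float
    dbp: float
    grade: int = field(default=0)
    age: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        derived = grade_from_bp(self.sbp, self.dbp)
        if self.grade == 0:
            object.__setattr__(self, "grade", derived)
        elif self.grade != derived:
            raise InvalidInputError(
                f"subject {self.subject_id}: stated grade {self.grade} inconsistent with "
                f"({self.sbp}, {self.dbp}) mmHg -> grade {derived}"
            )
        if not self.sbp > self.dbp:
            raise InvalidInputError(
                f"subject {self.subject_id}: SBP ({self.sbp}) must exceed DBP ({self.dbp})"
            )


@dataclass
class ROIFeatureTable:
    """Subjects x ROIs matrix for one feature type.

    For ``feature_type="Network"`` the columns are ROI-pair labels
    ("ROIa-ROIb") rather than single ROI names and there are n(n-1)/2 of
    them (3003 for the default 78-node network).
    """

    subject_ids: list[str]
    roi_names: list[str]
    values: np.ndarray
    feature_type: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.roi_names = [str(r) for r in self.roi_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.feature_type not in FEATURE_TYPES:
            raise InvalidInputError(f"unknown feature type {self.feature_type!r}")
        if self.values.ndim != 2:
            raise InvalidInputError("values must be a 2-D subjects x ROIs matrix")
        n, p = self.values.shape
        if n != len(self.subject_ids):
            raise InvalidInputError(f"{n} rows but {len(self.subject_ids)} subject ids")
        if p != len(self.roi_names):
            raise InvalidInputError(f"{p} columns but {len(self.roi_names)} ROI names")
        if len(set(self.subject_ids)) != n:
            raise InvalidInputError("duplicate subject ids")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise InvalidInputError(
                f"non-finite value at subject {self.subject_ids[bad[0]]!r}, "
                f"column {self.roi_names[bad[1]]!r}"
            )
        if self.feature_type != "Network" and not self.normalized and np.any(self.values <= 0):
            bad = np.argwhere(self.values <= 0)[0]
            raise InvalidInputError(
                f"raw {self.feature_type} values must be strictly positive; offending cell "
                f"subject {self.subject_ids[bad[0]]!r}, column {self.roi_names[bad[1]]!r}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.subject_ids, name="subject_id"),
                            columns=self.roi_names)

    def with_values(self, values: np.ndarray, *, normalized: bool | None = None) -> "ROIFeatureTable":
        """Copy with new values (and optionally a new normalization flag)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       normalized=self.normalized if normalized is None else normalized)


@dataclass
class ThicknessStats:
    """Per-subject, per-ROI cortical-thickness summary statistics.

    ``means`` (mm) and ``variances`` (mm^2) are subjects x 90 matrices over
    the ROI's surface vertices; they feed the single-subject morphometric
    network. The upstream segmentation constrains thickness to 1-6.5 mm.
    """

    subject_ids: list[str]
    roi_names: list[str]
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        shape = (len(self.subject_ids), len(self.roi_names))
        if self.means.shape != shape or self.variances.shape != shape:
            raise InvalidInputError(
                f"means/variances must both have shape {shape}; got "
                f"{self.means.shape} and {self.variances.shape}"
            )
        if not (np.all(np.isfinite(self.means)) and np.all(np.isfinite(self.variances))):
            raise InvalidInputError("thickness statistics must be finite")
        if np.any(self.variances < 0):
            raise InvalidInputError("thickness variances must be non-negative")
        if np.any(self.means < 1.0) or np.any(self.means > 6.5):
            raise InvalidInputError("mean thickness outside the plausible 1-6.5 mm range")

    def subset(self, roi_names: list[str]) -> "ThicknessStats":
        """Restrict to the given ROIs (e.g. the 78 cortical ones), preserving order."""
        idx = [self.roi_names.index(r) for r in roi_names]
        return ThicknessStats(self.subject_ids, list(roi_names),
                              self.means[:, idx], self.variances[:, idx])


def check_alignment(*tables: ROIFeatureTable) -> None:
    """Verify all tables share one subject ordering; name the first mismatch."""
    ref = tables[0].subject_ids
    for t in tables[1:]:
        if t.subject_ids != ref:
            for i, (a, b) in enumerate(zip(ref, t.subject_ids)):
                if a != b:
                    from .errors import AlignmentError

                    raise AlignmentError(
                        f"subject row {i} differs between {tables[0].feature_type} ({a!r}) "
                        f"and {t.feature_type} ({b!r})"
                    )
            from .errors import AlignmentError

            raise AlignmentError(
                f"{tables[0].feature_type} has {len(ref)} subjects, "
                f"{t.feature_type} has {len(t.subject_ids)}"
            )


def default_roi_names() -> list[str]:
    """Convenience re-export of the 90 AAL ROI names."""
    return aal_roi_names()
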