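"""Synthetic cohorts with the statistical structure the pipeline assumes.

No public imaging dataset backs this problem (the clinical cohorts are
private), so studies are emulated at the feature level: Gaussian ROI
features with exchangeable inter-ROI correlation and a monotone grade-dose
effect. Volumes, thickness and area in the affected ROIs decrease by
d * (grade - 1) baseline SDs per grade step while CSF volume increases —
mirroring the direction of blood-pressure-related morphometric change —
and SBP/DBP are sampled within each grade's guideline band so the grade
assignment round-trips exactly. Defaults reproduce the study conditions:
73 subjects per grade, four grades, 15 affected ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import ROIFeatureTable, SubjectMeta, ThicknessStats, grade_from_bp
from .errors import InvalidInputError
from .registry import aal_roi_names

#: Baseline (mean, SD) per feature type, in native units before normalization.
DEFAULT_BASELINES = {
    "GMV": (6000.0, 600.0),  # mm^3
    "WMV": (4000.0, 450.0),
    "CSFV": (1500.0, 200.0),
    "Thickness": (2.8, 0.25),  # mm
    "Area": (2500.0, 250.0),  # mm^2
}

#: 15 cortical ROIs carrying the grade effect by default, drawn from regions
#: recurrently implicated in hypertension morphometry (frontal/temporal/
#: parietal association cortex).
DEFAULT_AFFECTED_ROIS = (
    "Frontal_Sup_Orb_R", "Temporal_Sup_L", "Temporal_Sup_R", "Temporal_Mid_L",
    "Angular_L", "Angular_R", "Precuneus_R", "SupraMarginal_L",
    "Temporal_Pole_Sup_R", "Frontal_Inf_Oper_R", "Supp_Motor_Area_L",
    "Supp_Motor_Area_R", "Rectus_R", "Frontal_Mid_L", "Frontal_Inf_Tri_L",
)

#: (SBP low, SBP high, DBP low, DBP high) sampling band per grade; each band
#: lies strictly inside the grade's guideline region.
_BP_BANDS = {
    1: (95.0, 119.0, 55.0, 79.0),
    2: (120.0, 129.0, 60.0, 79.0),
    3: (130.0, 139.0, 70.0, 89.0),
    4: (140.0, 180.0, 90.0, 120.0),
}


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults are the emulated study conditions."""

    n_per_grade: int = 73
    grades: tuple = (1, 2, 3, 4)
    effect_size: float = 1.5  # standardized mean shift per grade step
    affected_rois: tuple = DEFAULT_AFFECTED_ROIS
    rho: float = 0.3  # exchangeable inter-ROI correlation
    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    thickness_var_mean: float = 0.2  # mm^2, per-ROI vertex variance scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise InvalidInputError("effect size must be >= 0")
        if not 0 <= self.rho < 1:
            raise InvalidInputError("rho must lie in [0, 1)")
        if self.n_per_grade < 2:
            raise InvalidInputError("need at least 2 subjects per grade")
        if not set(self.grades) <= {1, 2, 3, 4}:
            raise InvalidInputError(f"grades must be within 1-4, got {self.grades}")


def _correlated_noise(rng, n, p, rho) -> np.ndarray:
    common = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, p))
    return np.sqrt(rho) * common + np.sqrt(1 - rho) * own


def generate_cohort(spec: SyntheticSpec
                    ) -> tuple[dict[str, ROIFeatureTable], ThicknessStats, list[SubjectMeta]]:
    """Generate the five raw ROI tables, thickness statistics and metadata.

    Returns tables keyed GMV/WMV/CSFV/Thickness/Area (unnormalized, strictly
    positive), a ThicknessStats whose per-ROI means equal the Thickness
    table, and one SubjectMeta per subject whose (sbp, dbp) reproduce the
    generating grade under grade_from_bp.
    """
    rois = aal_roi_names()
    missing = [r for r in spec.affected_rois if r not in rois]
    if missing:
        raise InvalidInputError(f"affected ROI(s) not in registry: {missing}")
    affected = np.array([rois.index(r) for r in spec.affected_rois], dtype=int)
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_per_grade * len(spec.grades)
    grades = np.repeat(list(spec.grades), spec.n_per_grade)
    p = len(rois)

    tables: dict[str, ROIFeatureTable] = {}
    subject_ids = [f"S{i:04d}" for i in range(n_total)]
    thickness_values = None
    for kind, (mu, sd) in spec.baselines.items():
        values = mu + sd * _correlated_noise(rng, n_total, p, spec.rho)
        sign = +1.0 if kind == "CSFV" else -1.0
        shift = sign * spec.effect_size * sd * (grades - 1)[:, None]
        values[:, affected] += shift
        if kind == "Thickness":
            values = np.clip(values, 1.0, 6.5)  # segmentation bounds
        else:
            values = np.maximum(values, 0.01 * mu)  # keep strictly positive
        tables[kind] = ROIFeatureTable(subject_ids, rois, values, kind, normalized=False)
        if kind == "Thickness":
            thickness_values = values

    variances = spec.thickness_var_mean * rng.gamma(shape=20.0, scale=1 / 20.0,
                                                    size=(n_total, p))
    stats = ThicknessStats(subject_ids, rois, thickness_values, variances)

    metas = []
    for i, g in enumerate(grades):
        lo_s, hi_s, lo_d, hi_d = _BP_BANDS[int(g)]
        sbp = rng.uniform(lo_s, hi_s)
        dbp = rng.uniform(lo_d, hi_d)
        meta = SubjectMeta(subject_ids[i], round(float(sbp), 1), round(float(dbp), 1))
        assert meta.grade == int(g)  # bands lie strictly inside the grade regions
        metas.append(meta)
    return tables, stats, metas


def labels_from_meta(metas: list[SubjectMeta]) -> np.ndarray:
    return np.array([m.grade for m in metas])


def generate_separable(n_per_class: int, dim: int, separation: float, seed: int = 0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Two isotropic unit-variance Gaussian classes at the given centre distance."""
    if separation < 0:
        raise InvalidInputError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    offset = separation / np.sqrt(dim)
    X0 = rng.standard_normal((n_per_class, dim))
    X1 = rng.standard_normal((n_per_class, dim)) + offset
    X = np.vstack([X0, X1])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]
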