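"""AAL-90 region-of-interest registry.

The Automated Anatomical Labeling (AAL) parcellation used here has 45
labelled regions per hemisphere (90 total). Each entry carries a lobe
annotation and a cortical/sub-cortical flag; the 12 sub-cortical regions
(bilateral hippocampus, amygdala, caudate, putamen, pallidum, thalamus) are
the default exclusion set when building the 78-node cortical-thickness
network. Ordering is region-major: for each base region the left-hemisphere
entry precedes the right one.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InvalidInputError

# (base name, lobe, cortical flag); 45 base regions -> 90 lateralised ROIs
_AAL_BASE: list[tuple[str, str, bool]] = [
    ("Precentral", "central", True),
    ("Frontal_Sup", "frontal", True),
    ("Frontal_Sup_Orb", "frontal", True),
    ("Frontal_Mid", "frontal", True),
    ("Frontal_Mid_Orb", "frontal", True),
    ("Frontal_Inf_Oper", "frontal", True),
    ("Frontal_Inf_Tri", "frontal", True),
    ("Frontal_Inf_Orb", "frontal", True),
    ("Rolandic_Oper", "central", True),
    ("Supp_Motor_Area", "frontal", True),
    ("Olfactory", "frontal", True),
    ("Frontal_Sup_Medial", "frontal", True),
    ("Frontal_Med_Orb", "frontal", True),
    ("Rectus", "frontal", True),
    ("Insula", "insula", True),
    ("Cingulum_Ant", "limbic", True),
    ("Cingulum_Mid", "limbic", True),
    ("Cingulum_Post", "limbic", True),
    ("Hippocampus", "subcortical", False),
    ("ParaHippocampal", "limbic", True),
    ("Amygdala", "subcortical", False),
    ("Calcarine", "occipital", True),
    ("Cuneus", "occipital", True),
    ("Lingual", "occipital", True),
    ("Occipital_Sup", "occipital", True),
    ("Occipital_Mid", "occipital", True),
    ("Occipital_Inf", "occipital", True),
    ("Fusiform", "occipital", True),
    ("Postcentral", "central", True),
    ("Parietal_Sup", "parietal", True),
    ("Parietal_Inf", "parietal", True),
    ("SupraMarginal", "parietal", True),
    ("Angular", "parietal", True),
    ("Precuneus", "parietal", True),
    ("Paracentral_Lobule", "frontal", True),
    ("Caudate", "subcortical", False),
    ("Putamen", "subcortical", False),
    ("Pallidum", "subcortical", False),
    ("Thalamus", "subcortical", False),
    ("Heschl", "temporal", True),
    ("Temporal_Sup", "temporal", True),
    ("Temporal_Pole_Sup", "limbic", True),
    ("Temporal_Mid", "temporal", True),
    ("Temporal_Pole_Mid", "limbic", True),
    ("Temporal_Inf", "temporal", True),
]


@dataclass(frozen=True)
class ROI:
    """One lateralised AAL region."""

    name: str  # e.g. "Temporal_Sup_L"
    hemisphere: str  # "L" or "R"
    lobe: str
    cortical: bool


def aal_registry() -> list[ROI]:
    """Return the ordered 90-entry AAL ROI registry.

    45 regions per hemisphere; left precedes right within each base region.
    """
    rois: list[ROI] = []
    for base, lobe, cortical in _AAL_BASE:
        for hemi in ("L", "R"):
            rois.append(ROI(f"{base}_{hemi}", hemi, lobe, cortical))
    return rois


def aal_roi_names() -> list[str]:
    """Ordered names of the 90 AAL ROIs."""
    return [r.name for r in aal_registry()]


def default_subcortical_exclusion() -> list[str]:
    """The 12 sub-cortical ROIs excluded from the thickness network by default."""
    return [r.name for r in aal_registry() if not r.cortical]


def registry_frame() -> pd.DataFrame:
    """Machine-readable registry export (name, hemisphere, lobe, cortical)."""
    return pd.DataFrame(
        [(r.name, r.hemisphere, r.lobe, r.cortical) for r in aal_registry()],
        columns=["name", "hemisphere", "lobe", "cortical"],
    )


def validate_roi_names(names, registry: list[ROI] | None = None) -> None:
    """Raise if any name is not a registered AAL ROI."""
    known = {r.name for r in (registry if registry is not None else aal_registry())}
    unknown = [n for n in names if n not in known]
    if unknown:
        raise InvalidInputError(f"unknown ROI name(s): {unknown[:5]}")
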