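"""End-to-end glue: raw tables -> normalized matrices -> CV evaluation."""

from __future__ import annotations

import numpy as np

from .datamodel import ROIFeatureTable, SubjectMeta, ThicknessStats, check_alignment
from .ensemble import EnsembleConfig
from .errors import InvalidInputError
from .evaluation import EvaluationReport, repeated_stratified_cv
from .networks import network_feature_table
from .preprocess import normalize_tables


def prepare_features(tables: dict[str, ROIFeatureTable], stats: ThicknessStats | None = None,
                     exclusion: list[str] | None = None
                     ) -> tuple[dict[str, np.ndarray], dict[str, list[str]]]:
    """Normalize the ROI tables and append the thickness-network features.

    Returns (matrices, column names) per feature type, row-aligned across
    types. ``stats`` is required to build the Network feature.
    """
    check_alignment(*tables.values())
    norm = normalize_tables(tables)
    if stats is not None:
        if stats.subject_ids != norm[next(iter(norm))].subject_ids:
            raise InvalidInputError("thickness statistics subjects do not match the tables")
        norm["Network"] = network_feature_table(stats, exclusion=exclusion)
    matrices = {t: tab.values for t, tab in norm.items()}
    names = {t: tab.roi_names for t, tab in norm.items()}
    return matrices, names


def evaluate_cohort(tables: dict[str, ROIFeatureTable], stats: ThicknessStats | None,
                    metas: list[SubjectMeta], config: EnsembleConfig,
                    grades: tuple[int, int] | None = None, n_folds: int = 5,
                    n_repeats: int = 5, seed: int = 0, baseline: bool = False
                    ) -> EvaluationReport:
    """Run the full protocol, optionally restricted to a binary grade pair."""
    matrices, names = prepare_features(tables, stats)
    y = np.array([m.grade for m in metas])
    if grades is not None:
        mask = np.isin(y, grades)
        matrices = {t: M[mask] for t, M in matrices.items()}
        y = y[mask]
    return repeated_stratified_cv(matrices, y, config, n_folds=n_folds,
                                  n_repeats=n_repeats, seed=seed,
                                  feature_names=names, baseline=baseline)
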