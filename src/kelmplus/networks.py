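"""Single-subject morphometric brain networks from cortical-thickness statistics.

Each subject's 78 cortical ROIs (90 minus the 12 sub-cortical ones) become
nodes; the edge between ROIs i and j measures how similar their thickness
distributions are. The default method models each ROI's vertex thicknesses
as a Gaussian N(mu_i, sigma_i^2) and sets the edge to exp(-KLsym), where
KLsym is the mean of the two directed Gaussian Kullback-Leibler divergences
— a similarity in (0, 1] with unit diagonal that consumes exactly the
per-ROI mean and variance. When vertex-level thickness vectors are
available, a Pearson-correlation network is offered instead. The strict
upper triangle of the 78 x 78 matrix, in row-major order, is the subject's
3003-dimensional network feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ROIFeatureTable, ThicknessStats
from .errors import DegenerateInputError, InvalidInputError
from .registry import ROI, aal_registry, default_subcortical_exclusion


@dataclass
class MorphNetwork:
    """A per-subject inter-ROI association matrix."""

    roi_names: list[str]
    matrix: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.roi_names)
        if self.matrix.shape != (n, n):
            raise InvalidInputError(f"matrix shape {self.matrix.shape} does not match {n} ROIs")
        if not np.all(np.isfinite(self.matrix)):
            raise InvalidInputError("network matrix must be finite")


def select_cortical_rois(registry: list[ROI] | None = None,
                         exclusion: list[str] | None = None) -> list[str]:
    """Drop the excluded (default: 12 sub-cortical) ROIs, keeping order.

    The exclusion list is configurable because the boundary between
    "cortical" and "sub-cortical" in ROI-wise studies is a modelling choice.
    """
    registry = registry if registry is not None else aal_registry()
    exclusion = exclusion if exclusion is not None else default_subcortical_exclusion()
    names = [r.name for r in registry]
    missing = [e for e in exclusion if e not in names]
    if missing:
        raise InvalidInputError(f"exclusion name(s) not in registry: {missing}")
    drop = set(exclusion)
    return [n for n in names if n not in drop]


def gaussian_kl_similarity(means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """exp(-symmetrised KL) similarity between per-ROI Gaussians for one subject.

    KL(i||j) = ln(s_j/s_i) + (s_i^2 + (m_i - m_j)^2) / (2 s_j^2) - 1/2,
    symmetrised as the mean of the two directions. Unit diagonal.
    """
    m = np.asarray(means, dtype=float)
    v = np.asarray(variances, dtype=float)
    if np.any(v <= 0):
        i = int(np.argmax(v <= 0))
        raise DegenerateInputError(f"zero thickness variance at ROI index {i}; "
                                   "the Gaussian KL similarity is undefined")
    dm2 = (m[:, None] - m[None, :]) ** 2
    # directed KL(i||j) over the grid, then average with its transpose
    kl = 0.5 * np.log(v[None, :] / v[:, None]) + (v[:, None] + dm2) / (2.0 * v[None, :]) - 0.5
    klsym = 0.5 * (kl + kl.T)
    sim = np.exp(-klsym)
    np.fill_diagonal(sim, 1.0)
    return sim


def build_network(stats: ThicknessStats, subject_id: str, method: str = "gaussian_kl",
                  roi_names: list[str] | None = None,
                  vertex_values: dict[str, np.ndarray] | None = None) -> MorphNetwork:
    """Build one subject's inter-ROI thickness network.

    ``method="gaussian_kl"`` uses the per-ROI (mean, variance) pairs;
    ``method="pearson_vertex"`` needs equal-length vertex-thickness vectors
    per ROI in ``vertex_values``.
    """
    roi_names = roi_names if roi_names is not None else select_cortical_rois()
    if method == "gaussian_kl":
        sub = stats.subset(roi_names)
        i = sub.subject_ids.index(subject_id)
        return MorphNetwork(roi_names, gaussian_kl_similarity(sub.means[i], sub.variances[i]),
                            "gaussian_kl")
    if method == "pearson_vertex":
        if vertex_values is None:
            raise InvalidInputError("pearson_vertex needs vertex-level thickness vectors")
        vecs = [np.asarray(vertex_values[r], dtype=float) for r in roi_names]
        lengths = {len(v) for v in vecs}
        if len(lengths) != 1:
            raise InvalidInputError(f"vertex vectors must share one length, got {sorted(lengths)}")
        mat = np.corrcoef(np.vstack(vecs))
        np.fill_diagonal(mat, 1.0)
        return MorphNetwork(roi_names, mat, "pearson_vertex")
    raise InvalidInputError(f"unknown network method {method!r}")


def vectorize_upper_triangle(net: MorphNetwork | np.ndarray) -> np.ndarray:
    """Strict upper-triangle entries in row-major order; length n(n-1)/2."""
    mat = net.matrix if isinstance(net, MorphNetwork) else np.asarray(net, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise InvalidInputError(f"expected a square matrix, got shape {mat.shape}")
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def write_network(net: MorphNetwork, path, *, sep: str = ",") -> None:
    """Write a network matrix as delimited text with ROI-name headers."""
    import pandas as pd

    pd.DataFrame(net.matrix, index=pd.Index(net.roi_names, name=net.method),
                 columns=net.roi_names).to_csv(path, sep=sep, float_format="%.17g")


def read_network(path, *, sep: str = ",") -> MorphNetwork:
    """Read a network matrix written by :func:`write_network`."""
    import pandas as pd

    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    method = df.index.name or "gaussian_kl"
    return MorphNetwork(list(df.columns), df.astype(float).to_numpy(), method)


def pair_names(roi_names: list[str]) -> list[str]:
    """Column labels "ROIa-ROIb" matching the upper-triangle ordering."""
    n = len(roi_names)
    iu = np.triu_indices(n, k=1)
    return [f"{roi_names[i]}-{roi_names[j]}" for i, j in zip(*iu)]


def network_feature_table(stats: ThicknessStats, method: str = "gaussian_kl",
                          exclusion: list[str] | None = None) -> ROIFeatureTable:
    """Vectorised thickness networks for a whole cohort as a Network feature table."""
    roi_names = select_cortical_rois(exclusion=exclusion)
    if method != "gaussian_kl":
        raise InvalidInputError("cohort-level construction supports gaussian_kl only; "
                                "use build_network per subject for pearson_vertex")
    sub = stats.subset(roi_names)
    rows = [vectorize_upper_triangle(gaussian_kl_similarity(sub.means[i], sub.variances[i]))
            for i in range(len(sub.subject_ids))]
    return ROIFeatureTable(stats.subject_ids, pair_names(roi_names), np.vstack(rows),
                           "Network", normalized=True)
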