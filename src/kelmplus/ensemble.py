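"""Five-member KELM+ voting ensemble under the LUPI paradigm.

One feature type is the main feature; each of the remaining types acts as
privileged information (PI) for one KELM+ member. Per feature type the
pipeline is: two-stage feature selection (t-test then MI) fitted on the
training split, then an empirical kernel map fitted on the selected
training features. Each member trains on the EKM-enhanced main features
with its EKM-enhanced PI features as privileged input. At test time only
the main feature table is consumed (the LUPI contract); the final label is
the majority vote across members, ties broken by the highest summed member
score among the tied classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import InvalidInputError
from .kelm import KELMPlusModel, encode_labels, predict_kelm_plus, train_kelm_plus
from .kernels import EmpiricalKernelMap, KernelSpec, fit_ekm, median_heuristic_gamma
from .selection import SelectionResult, select_features

#: Default ordering of feature types in a six-table cohort.
DEFAULT_FEATURE_ORDER = ("GMV", "WMV", "CSFV", "Thickness", "Area", "Network")


@dataclass
class EnsembleConfig:
    """Configuration for one EKM-KELM+ ensemble.

    ``C_grid``/``eps_grid`` are searched by inner stratified CV when they
    hold more than one value; ``gamma_scale_grid`` multiplies the median
    heuristic. ``include_main_gram=True`` (default) keeps the main Gram in
    the KELM+ weight system — the full KKT solution — so a member whose
    privileged feature carries no usable signal can fall back to plain KELM
    behaviour at large eps; the grids therefore extend eps upward.
    """

    main: str = "GMV"
    pi_types: tuple = ()
    kernel: str = "rbf"  # kernel family for both EKM and KELM+
    alpha: float = 0.05
    k: int | None = None  # post-MI dimensionality; None caps at n_train
    C_grid: tuple = (2.0 ** -5, 2.0 ** -3, 2.0 ** -1, 2.0, 2.0 ** 3, 2.0 ** 5)
    # eps = inf is the exact no-PI limit (KELM+ with the main Gram collapses
    # to plain KELM), letting each member opt out of unhelpful PI.
    eps_grid: tuple = (2.0 ** -3, 1.0, 2.0 ** 3, float("inf"))
    gamma_scale_grid: tuple = (0.5, 1.0, 2.0)
    tuning_folds: int = 5  # inner CV mirrors the outer fivefold convention
    ekm_tol: float = 1e-10
    mi_estimator: str = "knn"
    include_main_gram: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pi_types:
            self.pi_types = tuple(t for t in DEFAULT_FEATURE_ORDER if t != self.main)
        if self.main in self.pi_types:
            raise InvalidInputError(f"main feature {self.main!r} cannot also be PI")
        if not self.pi_types:
            raise InvalidInputError("need at least one PI feature type")


@dataclass
class EnsembleMember:
    """One trained KELM+ member: the PI type it used and its main-feature path."""

    pi_type: str
    model: KELMPlusModel
    C: float
    eps: float
    gamma_scale: float


@dataclass
class EnsembleModel:
    config: EnsembleConfig
    classes: list
    selection_main: SelectionResult
    ekm_main: EmpiricalKernelMap
    members: list[EnsembleMember]
    selections_pi: dict[str, SelectionResult] = field(default_factory=dict)


def _spec_for(kind: str, X: np.ndarray, gamma_scale: float = 1.0) -> KernelSpec:
    if kind == "linear":
        return KernelSpec("linear")
    return KernelSpec("rbf", gamma_scale * median_heuristic_gamma(X))


def _selected(X: np.ndarray, sel: SelectionResult) -> np.ndarray:
    return X[:, sel.selected] if len(sel) else X  # empty selection falls back to all


def train_ensemble(tables: dict[str, np.ndarray], y, config: EnsembleConfig,
                   hyperparams: dict[str, tuple[float, float, float]] | None = None,
                   classes=None) -> EnsembleModel:
    """Train the LUPI ensemble from row-aligned feature matrices.

    ``tables`` maps feature type to a subjects x features matrix (already
    normalized / vectorised); it must contain the main type and every PI
    type. ``hyperparams`` optionally fixes (C, eps, gamma_scale) per PI
    type, bypassing the grids.
    """
    y = np.asarray(y)
    classes = list(classes) if classes is not None else sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise InvalidInputError("need at least two classes to train")
    needed = (config.main, *config.pi_types)
    missing = [t for t in needed if t not in tables]
    if missing:
        raise InvalidInputError(f"missing feature table(s): {missing}")
    n = len(y)
    for t in needed:
        if np.atleast_2d(tables[t]).shape[0] != n:
            raise InvalidInputError(f"table {t!r} has {np.atleast_2d(tables[t]).shape[0]} rows, "
                                    f"labels have {n}")
    T = encode_labels(y, classes)

    sel_main = select_features(tables[config.main], y, config.alpha, config.k,
                               estimator=config.mi_estimator, seed=config.seed)
    X_main_sel = _selected(tables[config.main], sel_main)
    ekm_main = fit_ekm(X_main_sel, _spec_for(config.kernel, X_main_sel), config.ekm_tol)
    Phi_main = ekm_main.transform(X_main_sel)

    members, selections_pi = [], {}
    for pi in config.pi_types:
        sel_pi = select_features(tables[pi], y, config.alpha, config.k,
                                 estimator=config.mi_estimator, seed=config.seed)
        selections_pi[pi] = sel_pi
        X_pi_sel = _selected(tables[pi], sel_pi)
        ekm_pi = fit_ekm(X_pi_sel, _spec_for(config.kernel, X_pi_sel), config.ekm_tol)
        Phi_pi = ekm_pi.transform(X_pi_sel)
        if hyperparams is not None and pi in hyperparams:
            C, eps, gs = hyperparams[pi]
        else:
            C, eps, gs = _tune_member(Phi_main, Phi_pi, y, classes, config)
        model = train_kelm_plus(Phi_main, Phi_pi, T, C, eps,
                                _spec_for(config.kernel, Phi_main, gs),
                                _spec_for(config.kernel, Phi_pi, gs), classes=classes,
                                include_main_gram=config.include_main_gram)
        members.append(EnsembleMember(pi, model, C, eps, gs))
    return EnsembleModel(config, classes, sel_main, ekm_main, members, selections_pi)


def _tune_member(Phi_main, Phi_pi, y, classes, config: EnsembleConfig
                 ) -> tuple[float, float, float]:
    """Inner stratified CV over the (C, eps, gamma_scale) grid for one member."""
    grid = list(product(config.C_grid, config.eps_grid, config.gamma_scale_grid))
    if len(grid) == 1:
        return grid[0]
    return max(grid, key=lambda cfg: member_cv_accuracy(
        Phi_main, Phi_pi, y, classes, *cfg, kernel=config.kernel,
        n_folds=config.tuning_folds, seed=config.seed,
        include_main_gram=config.include_main_gram))


def member_cv_accuracy(Phi_main, Phi_pi, y, classes, C, eps, gamma_scale, *,
                       kernel="rbf", n_folds=3, seed=0,
                       include_main_gram=True) -> float:
    """Mean inner-CV accuracy of a single KELM+ member at fixed hyperparameters."""
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(Phi_main, y):
        T_tr = encode_labels(y[tr], classes)
        model = train_kelm_plus(Phi_main[tr], Phi_pi[tr], T_tr, C, eps,
                                _spec_for(kernel, Phi_main[tr], gamma_scale),
                                _spec_for(kernel, Phi_pi[tr], gamma_scale), classes=classes,
                                include_main_gram=include_main_gram)
        _, pred = predict_kelm_plus(model, Phi_main[te])
        accs.append(float(np.mean(pred == y[te])))
    return float(np.mean(accs))


def tune_hyperparameters(tables: dict[str, np.ndarray], y, config: EnsembleConfig
                         ) -> dict[str, tuple[float, float, float]]:
    """Best (C, eps, gamma_scale) per member by exhaustive inner-CV grid search."""
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    sel_main = select_features(tables[config.main], y, config.alpha, config.k,
                               estimator=config.mi_estimator, seed=config.seed)
    X_main_sel = _selected(tables[config.main], sel_main)
    ekm_main = fit_ekm(X_main_sel, _spec_for(config.kernel, X_main_sel), config.ekm_tol)
    Phi_main = ekm_main.transform(X_main_sel)
    best = {}
    for pi in config.pi_types:
        sel_pi = select_features(tables[pi], y, config.alpha, config.k,
                                 estimator=config.mi_estimator, seed=config.seed)
        X_pi_sel = _selected(tables[pi], sel_pi)
        ekm_pi = fit_ekm(X_pi_sel, _spec_for(config.kernel, X_pi_sel), config.ekm_tol)
        best[pi] = _tune_member(Phi_main, ekm_pi.transform(X_pi_sel), y, classes, config)
    return best


def predict_ensemble(model: EnsembleModel, X_main_test: np.ndarray,
                     return_votes: bool = False):
    """Majority-vote prediction from the main feature table alone.

    Ties (possible only with 3+ classes or an even member count) go to the
    class with the highest summed member score among the tied classes.
    """
    X = np.atleast_2d(np.asarray(X_main_test, dtype=float))
    X_sel = _selected(X, model.selection_main)
    Phi = model.ekm_main.transform(X_sel)
    classes = model.classes
    all_scores = np.zeros((X.shape[0], len(classes)))
    votes = []
    for member in model.members:
        scores, pred = predict_kelm_plus(member.model, Phi)
        all_scores += scores
        votes.append(pred)
    votes = np.array(votes, dtype=object)  # members x samples
    labels = majority_vote(votes, all_scores, classes)
    if return_votes:
        return labels, votes
    return labels


def majority_vote(votes: np.ndarray, summed_scores: np.ndarray, classes: list) -> np.ndarray:
    """Majority label per column of ``votes`` (members x samples).

    Ties go to the tied class with the highest summed member score.
    """
    n = votes.shape[1]
    labels = np.empty(n, dtype=object)
    for i in range(n):
        counts = {c: int(np.sum(votes[:, i] == c)) for c in classes}
        top = max(counts.values())
        tied = [c for c in classes if counts[c] == top]
        if len(tied) == 1:
            labels[i] = tied[0]
        else:
            tied_idx = [classes.index(c) for c in tied]
            labels[i] = classes[tied_idx[int(np.argmax(summed_scores[i, tied_idx]))]]
    return labels
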