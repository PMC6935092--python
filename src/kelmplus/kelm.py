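"""Kernel extreme learning machines, plain and privileged (KELM, ELM+, KELM+).

KELM solves the ELM ridge problem in kernel form: with training Gram matrix
Omega and +/-1 one-vs-all label matrix T, the output weights are

    beta = (I/C + Omega)^{-1} T,          f(x) = k(x, X_train) beta.

Under the LUPI paradigm the privileged features enter only through their
own Gram matrix Omega_tilde. The classical closed form (with a diagonal
ridge added to avoid singularity) is

    beta = (Omega_tilde/eps + I/C)^{-1} (T - (C/eps) Omega_tilde J),

with J an all-ones matrix conformable with T. Carrying the KKT derivation
through in full instead retains the main Gram matrix in the inverted
factor,

    beta = (Omega + Omega_tilde/eps + I/C)^{-1} (T - (C/eps) Omega_tilde J),

which reduces exactly to KELM as the privileged influence vanishes
(Omega_tilde -> 0 or eps -> inf); ``include_main_gram=True`` selects this
variant. Either way prediction uses only the main-feature kernel row
k(x, X_train): privileged data are never consulted at test time. ELM+ is the explicit-random-hidden-layer version (sigmoid
hidden maps); it is retained as a baseline and as the correspondence oracle
for KELM+ (linear kernel on the hidden matrices reproduces it exactly).
Class decisions take the argmax of the score row.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import linalg as sla

from .errors import AlignmentError, InvalidInputError
from .kernels import KernelSpec, gram


def encode_labels(y, classes) -> np.ndarray:
    """+/-1 one-vs-all label matrix, one column per class in the given order."""
    y = np.asarray(y)
    classes = list(classes)
    if len(classes) < 2:
        raise InvalidInputError("need at least two classes in the class order")
    index = {c: j for j, c in enumerate(classes)}
    unknown = [v for v in y if v not in index]
    if unknown:
        raise InvalidInputError(f"label(s) outside the class order: {sorted(set(unknown))[:5]}")
    if len(set(y.tolist())) < 2:
        warnings.warn("only one class present in y; the label matrix is degenerate")
    T = -np.ones((len(y), len(classes)))
    for i, v in enumerate(y):
        T[i, index[v]] = 1.0
    return T


def decode_labels(scores: np.ndarray, classes) -> np.ndarray:
    """argmax decision over the score columns."""
    classes = np.asarray(list(classes), dtype=object)
    return classes[np.argmax(np.asarray(scores), axis=1)]


def _check_T(T: np.ndarray) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    return T


@dataclass
class KELMModel:
    X_train: np.ndarray
    spec: KernelSpec
    C: float
    beta: np.ndarray
    classes: list | None = None


def train_kelm(X: np.ndarray, T: np.ndarray, C: float, spec: KernelSpec,
               classes=None) -> KELMModel:
    """Closed-form KELM training: beta = (I/C + Omega)^{-1} T."""
    if not C > 0:
        raise InvalidInputError(f"C must be positive, got {C}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = _check_T(T)
    if X.shape[0] != T.shape[0]:
        raise AlignmentError(f"{X.shape[0]} samples but {T.shape[0]} label rows")
    omega = gram(X, X, spec)
    A = omega + np.eye(len(X)) / C
    beta = sla.solve(A, T, assume_a="sym")
    return KELMModel(X, spec, C, beta, list(classes) if classes is not None else None)


def predict_kelm(model: KELMModel, X_test: np.ndarray):
    """Score matrix k(X_test, X_train) beta and argmax labels."""
    scores = gram(np.atleast_2d(X_test), model.X_train, model.spec) @ model.beta
    classes = model.classes if model.classes is not None else list(range(scores.shape[1]))
    return scores, decode_labels(scores, classes)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class _HiddenMap:
    """A seeded random affine map followed by a sigmoid."""

    W: np.ndarray
    b: np.ndarray

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(np.atleast_2d(X) @ self.W + self.b)


def _random_hidden(d: int, L: int, rng: np.random.Generator) -> _HiddenMap:
    return _HiddenMap(rng.uniform(-1, 1, (d, L)), rng.uniform(-1, 1, L))


@dataclass
class ELMPlusModel:
    hidden_main: _HiddenMap
    beta: np.ndarray
    C: float
    eps: float
    classes: list | None = None


def _lupi_weights(omega_priv: np.ndarray, T: np.ndarray, C: float, eps: float,
                  omega_main: np.ndarray | None = None) -> np.ndarray:
    """Shared LUPI closed form: ([Omega +] Omega~/eps + I/C)^{-1} (T - (C/eps) Omega~ J)."""
    n, m = T.shape
    A = omega_priv / eps + np.eye(n) / C
    if omega_main is not None:
        A = A + omega_main
    rhs = T - (C / eps) * (omega_priv @ np.ones((n, m)))
    return sla.solve(A, rhs, assume_a="sym")


def train_elm_plus(X: np.ndarray, P_priv: np.ndarray, T: np.ndarray, C: float, eps: float,
                   L: int = 100, L_tilde: int = 100, seed: int = 0,
                   classes=None, include_main_gram: bool = False) -> ELMPlusModel:
    """ELM+ with seeded sigmoid hidden layers for main and privileged features."""
    if not (C > 0 and eps > 0):
        raise InvalidInputError("C and eps must be positive")
    if L < 1 or L_tilde < 1:
        raise InvalidInputError("hidden sizes must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    P_priv = np.atleast_2d(np.asarray(P_priv, dtype=float))
    T = _check_T(T)
    if not (X.shape[0] == P_priv.shape[0] == T.shape[0]):
        raise AlignmentError("main, privileged and label rows must align")
    rng = np.random.default_rng(seed)
    hm = _random_hidden(X.shape[1], L, rng)
    hp = _random_hidden(P_priv.shape[1], L_tilde, rng)
    H, H_tilde = hm(X), hp(P_priv)
    lam = _lupi_weights(H_tilde @ H_tilde.T, T, C, eps,
                        H @ H.T if include_main_gram else None)
    return ELMPlusModel(hm, H.T @ lam, C, eps, list(classes) if classes is not None else None)


def predict_elm_plus(model: ELMPlusModel, X_test: np.ndarray):
    scores = model.hidden_main(X_test) @ model.beta
    classes = model.classes if model.classes is not None else list(range(scores.shape[1]))
    return scores, decode_labels(scores, classes)


@dataclass
class KELMPlusModel:
    X_train: np.ndarray  # main-feature training samples (the only test-time state)
    spec_main: KernelSpec
    C: float
    eps: float
    beta: np.ndarray
    classes: list | None = None


def train_kelm_plus(X_main: np.ndarray, X_priv: np.ndarray, T: np.ndarray, C: float,
                    eps: float, spec_main: KernelSpec, spec_priv: KernelSpec,
                    classes=None, include_main_gram: bool = False) -> KELMPlusModel:
    """KELM+ training: the privileged Gram matrix shapes the output weights.

    With the default ``include_main_gram=False`` the weights depend on the
    privileged kernel only and the main feature enters at prediction time
    through its kernel row; ``include_main_gram=True`` keeps the main Gram
    in the inverted factor (the full KKT solution), making KELM+ degrade
    gracefully to KELM when the privileged information carries no signal.
    """
    if not (C > 0 and eps > 0):
        raise InvalidInputError("C and eps must be positive")
    X_main = np.atleast_2d(np.asarray(X_main, dtype=float))
    X_priv = np.atleast_2d(np.asarray(X_priv, dtype=float))
    T = _check_T(T)
    if not (X_main.shape[0] == X_priv.shape[0] == T.shape[0]):
        raise AlignmentError(
            f"main ({X_main.shape[0]}), privileged ({X_priv.shape[0]}) and label "
            f"({T.shape[0]}) rows must describe the same subjects")
    omega_priv = gram(X_priv, X_priv, spec_priv)
    omega_main = gram(X_main, X_main, spec_main) if include_main_gram else None
    beta = _lupi_weights(omega_priv, T, C, eps, omega_main)
    return KELMPlusModel(X_main, spec_main, C, eps, beta,
                         list(classes) if classes is not None else None)


def predict_kelm_plus(model: KELMPlusModel, X_test: np.ndarray):
    """Scores k(X_test, X_train_main) beta and argmax labels; no privileged input."""
    scores = gram(np.atleast_2d(X_test), model.X_train, model.spec_main) @ model.beta
    classes = model.classes if model.classes is not None else list(range(scores.shape[1]))
    return scores, decode_labels(scores, classes)
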