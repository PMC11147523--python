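"""Kernel Extreme Learning Machine: closed-form kernel ridge classification.

The KELM is a single-hidden-layer feedforward network trained without
iteration.  With an implicit feature map h(x) and one-hot target matrix T,
the output weights solve the regularized least-squares problem

    beta = H^T (H H^T + I/C)^(-1) T,

and with the kernel trick Omega = H H^T, Omega_ij = K(x_i, x_j), the decision
function for a query x is

    f(x) = [K(x, x_1), ..., K(x, x_N)] (Omega + I/C)^(-1) T.

Only the N x m coefficient matrix (Omega + I/C)^(-1) T is stored; the feature
map is never materialized.  The default kernel is the Gaussian RBF

    K(x, y) = exp(-||x - y||^2 / (2 gamma^2)).

C > 0 trades data fit against coefficient shrinkage (larger C = weaker
regularization); gamma > 0 is the kernel bandwidth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve, lstsq
from scipy.spatial.distance import cdist

__all__ = [
    "KELMModel",
    "rbf_kernel",
    "kernel_matrix",
    "kelm_fit",
    "kelm_decision",
    "kelm_predict",
    "save_model",
    "load_model",
]


def rbf_kernel(x: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """Gaussian RBF kernel value exp(-||x-y||^2 / (2 gamma^2)) in (0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    d2 = float(np.sum((x - y) ** 2))
    return float(np.exp(-d2 / (2.0 * gamma**2)))


def kernel_matrix(
    xa: np.ndarray, xb: np.ndarray, gamma: float, kernel: str = "rbf"
) -> np.ndarray:
    """Pairwise kernel matrix with entry (i, j) = K(xa_i, xb_j).

    ``kernel`` is ``"rbf"`` (default) or ``"linear"`` (plain inner products,
    used when the explicit feature map is the identity).
    """
    xa = np.atleast_2d(np.asarray(xa, dtype=float))
    xb = np.atleast_2d(np.asarray(xb, dtype=float))
    if xa.size == 0 or xb.size == 0:
        raise ValueError("empty input to kernel_matrix")
    if xa.shape[1] != xb.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {xa.shape[1]} vs {xb.shape[1]}"
        )
    if kernel == "rbf":
        if gamma <= 0:
            raise ValueError(f"gamma must be positive, got {gamma}")
        d2 = cdist(xa, xb, metric="sqeuclidean")
        return np.exp(-d2 / (2.0 * gamma**2))
    if kernel == "linear":
        return xa @ xb.T
    raise ValueError(f"unknown kernel {kernel!r}")


@dataclass
class KELMModel:
    """Fitted KELM: training inputs, targets, parameters and coefficients.

    ``coef`` is the N x m solution of (Omega + I/C) coef = T.
    """

    x_train: np.ndarray
    t_matrix: np.ndarray
    c_reg: float
    gamma: float
    coef: np.ndarray
    classes: list
    kernel: str = "rbf"


def _one_hot(labels: Sequence) -> tuple[np.ndarray, list]:
    classes = sorted(set(labels), key=lambda c: str(c))
    index = {c: j for j, c in enumerate(classes)}
    t = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        t[i, index[lab]] = 1.0
    return t, classes


def kelm_fit(
    x: np.ndarray,
    labels: Sequence,
    c_reg: float,
    gamma: float,
    kernel: str = "rbf",
) -> KELMModel:
    """Train a KELM by solving the regularized kernel system.

    Builds the one-hot target matrix T and solves the symmetric
    positive-definite system (Omega + I/C) coef = T by Cholesky
    factorization, falling back to a least-squares solve if the
    factorization fails (numerically singular Omega at extreme gamma).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in training inputs")
    if len(labels) != x.shape[0]:
        raise ValueError("label count does not match number of rows")
    if c_reg <= 0:
        raise ValueError(f"c_reg must be positive, got {c_reg}")
    t_matrix, classes = _one_hot(labels)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    omega = kernel_matrix(x, x, gamma, kernel=kernel)
    system = omega + np.eye(x.shape[0]) / c_reg
    try:
        coef = cho_solve(cho_factor(system), t_matrix)
    except LinAlgError:  # pragma: no cover - hit only at pathological gamma
        coef = lstsq(system, t_matrix)[0]
    return KELMModel(
        x_train=x,
        t_matrix=t_matrix,
        c_reg=float(c_reg),
        gamma=float(gamma),
        coef=coef,
        classes=classes,
        kernel=kernel,
    )


def kelm_decision(model: KELMModel, x_new: np.ndarray) -> np.ndarray:
    """Raw Q x m decision scores K(x_new, x_train) @ coef."""
    x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
    if x_new.shape[1] != model.x_train.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: query has {x_new.shape[1]}, "
            f"model expects {model.x_train.shape[1]}"
        )
    k = kernel_matrix(x_new, model.x_train, model.gamma, kernel=model.kernel)
    return k @ model.coef


def kelm_predict(model: KELMModel, x_new: np.ndarray) -> list:
    """Predicted labels: argmax over decision scores, ties to the lowest
    class index in ``model.classes`` order."""
    scores = kelm_decision(model, x_new)
    # np.argmax returns the first maximal index, which is the tie rule.
    idx = np.argmax(scores, axis=1)
    return [model.classes[j] for j in idx]


def save_model(model: KELMModel, directory) -> None:
    """Write a model as a JSON header plus CSV blocks for x_train and coef."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = {
        "c_reg": model.c_reg,
        "gamma": model.gamma,
        "classes": [str(c) for c in model.classes],
        "kernel": model.kernel,
    }
    (directory / "model.json").write_text(json.dumps(header, indent=2))
    np.savetxt(directory / "x_train.csv", model.x_train, delimiter=",")
    np.savetxt(directory / "coef.csv", model.coef, delimiter=",")


def load_model(directory) -> KELMModel:
    """Inverse of :func:`save_model` (classes come back as strings)."""
    directory = Path(directory)
    header = json.loads((directory / "model.json").read_text())
    x_train = np.atleast_2d(np.loadtxt(directory / "x_train.csv", delimiter=","))
    coef = np.loadtxt(directory / "coef.csv", delimiter=",")
    coef = coef.reshape(x_train.shape[0], -1)
    t_matrix = np.zeros_like(coef)  # targets are not stored; reconstructable upstream
    return KELMModel(
        x_train=x_train,
        t_matrix=t_matrix,
        c_reg=header["c_reg"],
        gamma=header["gamma"],
        coef=coef,
        classes=list(header["classes"]),
        kernel=header.get("kernel", "rbf"),
    )
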