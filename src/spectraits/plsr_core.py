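"""Single-response partial least squares regression (PLS1).

This is a from-scratch implementation of the orthogonal-scores (NIPALS)
algorithm.  X and y are mean-centered (no unit-variance scaling by default:
reflectance bands share units, and centering-only is the conventional
default of the orthogonal-scores method); then for each component *a*

    w_a = X'y / ||X'y||        (unit-norm weight)
    t_a = X w_a                (score)
    p_a = X't_a / t_a't_a      (x-loading)
    q_a = y't_a / t_a't_a      (y-loading)
    X <- X - t_a p_a',  y <- y - q_a t_a    (deflation)

Scores are mutually orthogonal by construction.  Regression coefficients for
A components are recovered as

    B = W (P'W)^{-1} q,   intercept = mean(y) - mean(x)'B

so that predictions are ``X B + intercept``.  As A approaches the rank of
the centered X, B converges to the least-squares solution.

Predictions are never clipped to physically admissible ranges; impossible
values (e.g. negative stomatal conductance) are the caller's to flag.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = ["PLSRModel", "fit_pls1", "coefficients", "predict"]

#: deflation stops when ||X'y|| falls below this fraction of its initial norm
_DEFLATION_RTOL = 1e-12


@dataclass
class PLSRModel:
    """Fitted PLS1 factorization.

    Attributes
    ----------
    x_mean, y_mean
        Centering constants.
    W, P
        p × A weight and x-loading matrices; columns of ``W`` are unit norm.
    q
        y-loadings, length A.
    T
        n × A training score matrix (kept for VIP and diagnostics).
    a_max
        Number of components actually extracted.
    selected_a
        Component count chosen by cross-validation (set after fitting).
    wavelengths
        Optional grid labelling the columns of X.
    provenance
        Free-form record (trait, layers, split seed, ...) carried into
        serialization.
    """

    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    T: np.ndarray
    a_max: int
    selected_a: int | None = None
    wavelengths: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.x_mean.size

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc: dict[str, Any] = {
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "q": self.q.tolist(),
            "a_max": int(self.a_max),
            "selected_a": None if self.selected_a is None else int(self.selected_a),
            "wavelengths": None if self.wavelengths is None
                           else np.asarray(self.wavelengths).tolist(),
            "provenance": self.provenance,
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PLSRModel":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        doc = json.loads(text)
        p = len(doc["x_mean"])
        a = doc["a_max"]
        return cls(
            x_mean=np.asarray(doc["x_mean"], dtype=float),
            y_mean=float(doc["y_mean"]),
            W=np.asarray(doc["W"], dtype=float).reshape(p, a),
            P=np.asarray(doc["P"], dtype=float).reshape(p, a),
            q=np.asarray(doc["q"], dtype=float),
            T=np.zeros((0, a)),
            a_max=a,
            selected_a=doc.get("selected_a"),
            wavelengths=None if doc.get("wavelengths") is None
                        else np.asarray(doc["wavelengths"]),
            provenance=doc.get("provenance", {}),
        )


def fit_pls1(X: np.ndarray, y: np.ndarray, a_max: int,
             wavelengths: np.ndarray | None = None,
             provenance: dict | None = None) -> PLSRModel:
    """Fit a PLS1 model with up to ``a_max`` components.

    Extraction stops early (with fewer components) once the covariance
    ``||X'y||`` is numerically exhausted.  A constant y yields a valid
    zero-component model (coefficients zero, intercept mean(y)) with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be a 2-d matrix")
    n, p = X.shape
    if n != y.size:
        raise ValueError(f"X has {n} rows but y has {y.size} entries")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if a_max < 1:
        raise ValueError("a_max must be >= 1")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("NaN values in inputs; impute or drop before fitting")

    a_cap = min(a_max, n - 1, p) if p else 0
    x_mean = X.mean(axis=0) if p else np.zeros(0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.zeros((p, a_cap))
    P = np.zeros((p, a_cap))
    q = np.zeros(a_cap)
    T = np.zeros((n, a_cap))

    s0 = np.linalg.norm(Xc.T @ yc) if p else 0.0
    a = 0
    while a < a_cap:
        s = Xc.T @ yc
        ns = np.linalg.norm(s)
        if ns <= _DEFLATION_RTOL * s0 or ns == 0.0:
            break
        w = s / ns
        t = Xc @ w
        tt = float(t @ t)
        if tt <= 0 or not np.isfinite(tt):
            break
        p_a = Xc.T @ t / tt
        q_a = float(yc @ t) / tt
        W[:, a] = w
        P[:, a] = p_a
        q[a] = q_a
        T[:, a] = t
        Xc -= np.outer(t, p_a)
        yc = yc - q_a * t
        a += 1

    if a == 0:
        warnings.warn(
            "response carries no extractable covariance with X "
            "(constant y?); returning a zero-component model",
            stacklevel=2,
        )
    model = PLSRModel(
        x_mean=x_mean, y_mean=y_mean,
        W=W[:, :a], P=P[:, :a], q=q[:a], T=T[:, :a],
        a_max=a, wavelengths=wavelengths,
        provenance=provenance or {},
    )
    return model


def coefficients(model: PLSRModel, a: int) -> tuple[np.ndarray, float]:
    """Regression vector and intercept for an ``a``-component truncation.

    ``B = W (P'W)^{-1} q`` restricted to the first ``a`` components.  A
    zero-component request (or model) returns B = 0, intercept = mean(y).
    """
    if a == 0 or model.a_max == 0:
        return np.zeros(model.n_features), float(model.y_mean)
    if not 1 <= a <= model.a_max:
        raise ValueError(f"a={a} outside 1..{model.a_max}")
    W = model.W[:, :a]
    P = model.P[:, :a]
    M = P.T @ W
    # P'W is unit upper triangular in exact arithmetic; near-singularity
    # signals numerically redundant components.
    if np.linalg.cond(M) > 1e12:
        raise np.linalg.LinAlgError(
            f"P'W is numerically singular at a={a}; use fewer components"
        )
    B = W @ np.linalg.solve(M, model.q[:a])
    intercept = float(model.y_mean - model.x_mean @ B)
    return B, intercept


def predict(model: PLSRModel, X_new: np.ndarray, a: int | None = None) -> np.ndarray:
    """Predict the response for new spectra at ``a`` components.

    ``a`` defaults to the model's ``selected_a`` (or ``a_max`` if no
    selection has been made).  Raises if the feature grid disagrees.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_features:
        raise ValueError(
            f"X_new has {X_new.shape[1]} bands but the model expects "
            f"{model.n_features}"
        )
    if a is None:
        a = model.selected_a if model.selected_a is not None else model.a_max
    B, intercept = coefficients(model, a)
    return X_new @ B + intercept
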