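"""Model assessment: cross-validation, component selection, jackknife
uncertainty, validation metrics and VIP band importance.

Component selection follows the chemometric convention: the number of
latent components minimizing the cross-validated RMSEP, which under
leave-one-out is a monotone transform of PRESS (``RMSEP = sqrt(PRESS/n)``),
so minimizing either selects the same model; ties break toward fewer
components.

R² is reported as the squared Pearson correlation between observations and
predictions (the convention used when regressing predictions on ground
truth); the 1 − SSE/SST variant is carried alongside for reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .plsr_core import PLSRModel, coefficients, fit_pls1, predict

__all__ = [
    "CVResult", "EvaluationReport", "JackknifeResult", "VIPProfile",
    "cross_validate", "select_components", "jackknife", "jackknife_variance",
    "evaluate", "vip_scores", "important_regions",
]


@dataclass
class CVResult:
    """Cross-validated error as a function of component count (1..A_max)."""

    rmsep_by_a: np.ndarray
    press_by_a: np.ndarray
    scheme: str
    n: int
    selected_a: int | None = None

    def __post_init__(self):
        self.rmsep_by_a = np.asarray(self.rmsep_by_a, dtype=float)
        self.press_by_a = np.asarray(self.press_by_a, dtype=float)
        if self.rmsep_by_a.shape != self.press_by_a.shape:
            raise ValueError("rmsep and press must have equal length")

    @property
    def a_max(self) -> int:
        return self.rmsep_by_a.size


@dataclass
class EvaluationReport:
    """Observed-vs-predicted agreement on one dataset."""

    r2: float
    rmse: float
    bias: float
    bias_pct: float
    n: int
    r2_ss: float = float("nan")   # 1 - SSE/SST, for reference


@dataclass
class JackknifeResult:
    """Delete-one resampling summary of the PLSR coefficient vector."""

    coef_mean: np.ndarray
    coef_se: np.ndarray
    estimate_bias: np.ndarray
    intercept_mean: float
    intercept_se: float
    iterations: int


@dataclass
class VIPProfile:
    """Variable-importance-in-projection scores per wavelength.

    The squares of the scores average to 1, so wavelengths with VIP > 1
    carry above-average weight in the fitted components.
    """

    vip: np.ndarray
    wavelengths: np.ndarray | None = None
    threshold: float = 1.0

    def regions(self, threshold: float | None = None,
                min_width: float = 1.0) -> list[tuple[float, float]]:
        return important_regions(
            self, self.threshold if threshold is None else threshold, min_width
        )


def _fold_indices(n: int, scheme: str, k: int, seed: int) -> list[np.ndarray]:
    if scheme == "loo":
        return [np.array([i]) for i in range(n)]
    if scheme == "kfold":
        k = min(k, n)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        return [np.sort(part) for part in np.array_split(perm, k)]
    raise ValueError(f"unknown CV scheme {scheme!r}")


def cross_validate(X: np.ndarray, y: np.ndarray, a_max: int,
                   scheme: str = "loo", k: int = 10, seed: int = 0) -> CVResult:
    """PRESS / RMSEP over 1..a_max components by refitting per fold.

    For every held-out unit the model is refit on the remainder and the unit
    predicted at each component count; ``PRESS_A`` accumulates squared
    held-out residuals and ``RMSEP_A = sqrt(PRESS_A / n)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("cross-validation needs at least 3 samples")
    feasible = min(n - 2, X.shape[1])  # smallest training fold has >= n - ceil(n/k) rows
    if a_max > feasible:
        warnings.warn(
            f"a_max={a_max} infeasible for n={n}; truncated to {feasible}",
            stacklevel=2,
        )
        a_max = feasible

    press = np.zeros(a_max)
    for held in _fold_indices(n, scheme, k, seed):
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        model = fit_pls1(X[mask], y[mask], a_max)
        for a in range(1, a_max + 1):
            a_eff = min(a, model.a_max)
            yhat = predict(model, X[held], a_eff)
            press[a - 1] += float(np.sum((yhat - y[held]) ** 2))
    rmsep = np.sqrt(press / n)
    cv = CVResult(rmsep, press, scheme=scheme, n=n)
    cv.selected_a = select_components(cv)
    return cv


def select_components(cv: CVResult) -> int:
    """Component count at the smallest RMSEP (equivalently smallest PRESS).

    Exact ties are broken toward fewer components.
    """
    if cv.a_max == 0:
        raise ValueError("empty cross-validation result")
    best = cv.rmsep_by_a.min()
    return int(np.flatnonzero(cv.rmsep_by_a == best)[0]) + 1


def jackknife_variance(delete_one_estimates: np.ndarray, n: int) -> np.ndarray:
    """Standard jackknife variance, ``(n-1)/n * sum((th_i - th_bar)^2)``.

    When only ``m < n`` of the delete-one estimates are supplied the sum is
    rescaled by ``n/m`` so the estimator stays consistent.
    """
    est = np.asarray(delete_one_estimates, dtype=float)
    m = est.shape[0]
    if m < 2:
        raise ValueError("need at least 2 delete-one estimates")
    dev = est - est.mean(axis=0)
    return (n - 1) / n * (n / m) * np.sum(dev ** 2, axis=0)


def jackknife(X: np.ndarray, y: np.ndarray, a: int,
              iterations: int = 1000, seed: int = 0) -> JackknifeResult:
    """Delete-one jackknife of the PLSR coefficient vector.

    With ``iterations >= n`` the resampling is exhaustive over all n units
    (and therefore seed-independent); otherwise a seeded random subset of
    delete-one fits of the requested size is used.  Standard errors use the
    jackknife variance formula with its (n−1)/n factor; the bias estimate is
    ``(n−1) (mean of delete-one estimates − full-sample estimate)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("jackknife needs at least 3 samples")

    def _estimate(Xs, ys):
        if Xs.shape[1] == 0:
            return np.zeros(0), float(np.mean(ys))
        model = fit_pls1(Xs, ys, a) if a >= 1 else None
        if model is None:
            return np.zeros(Xs.shape[1]), float(np.mean(ys))
        a_eff = min(a, model.a_max)
        return coefficients(model, a_eff)

    full_B, full_b0 = _estimate(X, y)

    if iterations >= n:
        leave_out = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        leave_out = np.sort(rng.choice(n, size=iterations, replace=False))

    coefs = np.empty((leave_out.size, X.shape[1]))
    b0s = np.empty(leave_out.size)
    for row, i in enumerate(leave_out):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        coefs[row], b0s[row] = _estimate(X[mask], y[mask])

    coef_var = jackknife_variance(coefs, n) if X.shape[1] else np.zeros(0)
    b0_var = float(jackknife_variance(b0s[:, None], n)[0])
    bias = (n - 1) * (coefs.mean(axis=0) - full_B) if X.shape[1] else np.zeros(0)
    return JackknifeResult(
        coef_mean=coefs.mean(axis=0) if X.shape[1] else np.zeros(0),
        coef_se=np.sqrt(coef_var),
        estimate_bias=bias,
        intercept_mean=float(b0s.mean()),
        intercept_se=float(np.sqrt(b0_var)),
        iterations=int(leave_out.size),
    )


def evaluate(y_obs: np.ndarray, y_pred: np.ndarray) -> EvaluationReport:
    """R² (squared Pearson), RMSE, bias and bias as % of the observed mean."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size != y_pred.size:
        raise ValueError("observed and predicted vectors differ in length")
    n = y_obs.size
    if n < 2:
        raise ValueError("need at least 2 pairs to evaluate")
    resid = y_pred - y_obs
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    bias = float(np.mean(resid))
    obs_mean = float(np.mean(y_obs))
    bias_pct = float(100.0 * bias / obs_mean) if obs_mean != 0 else float("nan")
    if np.std(y_obs) == 0 or np.std(y_pred) == 0:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(y_obs, y_pred)[0, 1] ** 2)
    sst = float(np.sum((y_obs - obs_mean) ** 2))
    r2_ss = float(1.0 - np.sum(resid ** 2) / sst) if sst > 0 else float("nan")
    return EvaluationReport(r2=r2, rmse=rmse, bias=bias, bias_pct=bias_pct,
                            n=n, r2_ss=r2_ss)


def vip_scores(model: PLSRModel, a: int | None = None) -> VIPProfile:
    """VIP score per wavelength for an ``a``-component model.

    With ``SSY_a = q_a^2 t_a't_a`` (response variance captured by component
    a) and unit-norm weights,

        VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a )

    so that ``sum_j VIP_j^2 = p`` exactly.
    """
    if a is None:
        a = model.selected_a if model.selected_a is not None else model.a_max
    if not 1 <= a <= model.a_max:
        raise ValueError(f"a={a} outside 1..{model.a_max}")
    if model.T.shape[0] == 0:
        raise ValueError("model carries no training scores (deserialized?); "
                         "refit before computing VIP")
    p = model.n_features
    ssy = model.q[:a] ** 2 * np.einsum("ij,ij->j", model.T[:, :a], model.T[:, :a])
    total = ssy.sum()
    if total <= 0:
        raise ValueError("zero explained response variance; VIP undefined")
    vip = np.sqrt(p * (model.W[:, :a] ** 2) @ ssy / total)
    return VIPProfile(vip=vip, wavelengths=model.wavelengths)


def important_regions(profile: VIPProfile, threshold: float = 1.0,
                      min_width: float = 1.0) -> list[tuple[float, float]]:
    """Maximal contiguous wavelength runs with VIP above ``threshold``.

    Returned as closed ``[lo, hi]`` intervals in nm (band indices if the
    profile has no grid).  Runs narrower than ``min_width`` nm are dropped.
    """
    wl = (np.asarray(profile.wavelengths, dtype=float)
          if profile.wavelengths is not None
          else np.arange(profile.vip.size, dtype=float))
    above = profile.vip > threshold
    regions: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            regions.append((wl[start], wl[i - 1]))
            start = None
    if start is not None:
        regions.append((wl[start], wl[above.size - 1]))
    return [(lo, hi) for lo, hi in regions if hi - lo + 1 >= min_width]
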