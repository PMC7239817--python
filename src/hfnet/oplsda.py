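"""Two-class orthogonal projections to latent structures discriminant analysis.

Implements the single-response OPLS algorithm: the predictive weight is the
(normalized) covariance direction ``X'y``; each orthogonal component removes
the part of the X-loading orthogonal to the predictive weight, deflating X
by structured variation uncorrelated with the response.  Validation follows
two separable procedures: stratified k-fold cross-validation for Q2 and a
subject bootstrap for per-variable loading confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OplsModel",
    "fit_opls",
    "cross_validate",
    "vip",
    "bootstrap_significance",
    "classify",
]


@dataclass
class OplsModel:
    """Fitted two-class OPLS-DA model.

    Predictive scores ``t`` are exactly orthogonal to every orthogonal score
    column; ``w`` has unit norm; VIPs satisfy ``sum(vip^2) == n_variables``.
    """

    classes: tuple
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    w: np.ndarray           # predictive weight, unit norm
    p_load: np.ndarray      # predictive loading
    t: np.ndarray           # predictive scores
    b: float                # regression of centered y on t
    n_orth: int
    w_orth: np.ndarray      # (K, n_orth)
    p_orth: np.ndarray      # (K, n_orth)
    t_orth: np.ndarray      # (n, n_orth)
    r2y: float
    feature_names: list[str] | None = None
    q2: float | None = None
    boot_ci: pd.DataFrame | None = None
    accuracy: float | None = None

    @property
    def vip(self) -> np.ndarray:
        return vip(self)


def _code_y(y) -> tuple[np.ndarray, tuple]:
    y = np.asarray(y)
    classes = tuple(pd.unique(y))
    if len(classes) != 2:
        raise ValueError(f"OPLS-DA requires exactly two classes, got {classes}")
    # -1/+1 coding; "HF" (or the second label) is coded +1 for readability
    if "HF" in classes:
        neg = [c for c in classes if c != "HF"][0]
        classes = (neg, "HF")
    coded = np.where(y == classes[1], 1.0, -1.0)
    return coded, classes


def _prepare(x, scale: bool = True):
    arr = x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)
    names = list(x.columns) if isinstance(x, pd.DataFrame) else None
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if scale else np.ones(arr.shape[1])
    if np.any(sd == 0):
        raise ValueError("constant column(s) in X")
    return (arr - mean) / sd, mean, sd, names


def fit_opls(x, y, n_orth: int = 1, scale: bool = True) -> OplsModel:
    """Fit an OPLS model with one predictive and ``n_orth`` orthogonal components.

    Iterative extraction: predictive weight ``w ~ X'y``; per orthogonal
    component the X-loading on the predictive scores is split into its
    ``w``-parallel and ``w``-orthogonal parts, and X is deflated by the
    orthogonal score/loading pair.  The final predictive component is fit on
    the deflated X; ``r2y = 1 - RSS/TSS`` of the centered response.
    """
    xs, x_mean, x_sd, names = _prepare(x, scale=scale)
    yc, classes = _code_y(y)
    n, k = xs.shape
    if n <= n_orth + 1:
        raise ValueError(f"n_subjects={n} too small for n_orth={n_orth}")
    if n_orth >= min(n - 1, k):
        raise ValueError(f"n_orth={n_orth} exceeds the rank budget of X ({n}x{k})")
    y_mean = float(yc.mean())
    yc = yc - y_mean

    xd = xs.copy()
    w_os, p_os, t_os = [], [], []
    for _ in range(n_orth):
        w = xd.T @ yc
        w = w / np.linalg.norm(w)
        t = xd @ w
        p = xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break  # no orthogonal variation left
        w_o /= norm
        t_o = xd @ w_o
        p_o = xd.T @ t_o / (t_o @ t_o)
        xd = xd - np.outer(t_o, p_o)
        w_os.append(w_o)
        p_os.append(p_o)
        t_os.append(t_o)

    w = xd.T @ yc
    w = w / np.linalg.norm(w)
    t = xd @ w
    p_load = xd.T @ t / (t @ t)
    b = float((yc @ t) / (t @ t))
    resid = yc - b * t
    r2y = float(1.0 - (resid @ resid) / (yc @ yc))

    n_o = len(w_os)
    model = OplsModel(
        classes=classes,
        x_mean=x_mean, x_sd=x_sd, y_mean=y_mean,
        w=w, p_load=p_load, t=t, b=b,
        n_orth=n_o,
        w_orth=np.column_stack(w_os) if n_o else np.zeros((k, 0)),
        p_orth=np.column_stack(p_os) if n_o else np.zeros((k, 0)),
        t_orth=np.column_stack(t_os) if n_o else np.zeros((n, 0)),
        r2y=r2y,
        feature_names=names,
    )
    pred = classify(model, x)
    model.accuracy = float(np.mean(pred == np.asarray(y)))
    return model


def vip(model: OplsModel) -> np.ndarray:
    """Variable importance in projection.

    With a single predictive component the SSY-weighted VIP formula reduces
    to ``sqrt(K) * |w_j|`` for the unit-norm predictive weight, so
    ``sum(vip^2) == K`` exactly.
    """
    if model.w is None:  # pragma: no cover - dataclass always sets it
        raise ValueError("model is not fitted")
    k = len(model.w)
    return np.sqrt(k) * np.abs(model.w)


def _predict_scores(model: OplsModel, x) -> np.ndarray:
    arr = x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)
    if arr.shape[1] != len(model.x_mean):
        raise ValueError(
            f"dimension mismatch: model has {len(model.x_mean)} variables, "
            f"X_new has {arr.shape[1]}"
        )
    xs = (arr - model.x_mean) / model.x_sd
    for j in range(model.n_orth):
        t_o = xs @ model.w_orth[:, j]
        xs = xs - np.outer(t_o, model.p_orth[:, j])
    return xs @ model.w


def classify(model: OplsModel, x_new) -> np.ndarray:
    """Predict class labels: orthogonal deflation, predictive score,
    threshold at the (centered) class-code midpoint."""
    t_new = _predict_scores(model, x_new)
    y_hat = model.y_mean + model.b * t_new
    return np.where(y_hat >= 0.0, model.classes[1], model.classes[0])


def _stratified_folds(y_coded: np.ndarray, folds: int, rng: np.random.Generator):
    """Fold assignment keeping both classes in every fold."""
    idx = np.arange(len(y_coded))
    assign = np.empty(len(y_coded), dtype=int)
    for cls in (1.0, -1.0):
        members = idx[y_coded == cls]
        if len(members) < folds and len(members) < 2:
            raise ValueError("a class has too few members to stratify")
        perm = rng.permutation(members)
        assign[perm] = np.arange(len(perm)) % folds
    return assign


def cross_validate(
    x,
    y,
    folds: int = 7,
    max_orth: int = 3,
    min_gain: float = 0.01,
    scale: bool = True,
    seed: int = 0,
) -> tuple[float, int]:
    """Cross-validated Q2 with automatic orthogonal-component growth.

    Q2 = 1 - PRESS/SS over stratified held-out folds.  The orthogonal
    component count grows from 0 while Q2 improves by more than ``min_gain``,
    capped at ``max_orth``.  Returns ``(q2, chosen_n_orth)``.
    """
    arr = x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)
    yc, _classes = _code_y(y)
    rng = np.random.default_rng(seed)
    assign = _stratified_folds(yc, folds, rng)

    def q2_for(n_orth: int) -> float:
        press = 0.0
        ss = 0.0
        for f in range(folds):
            test = assign == f
            if not test.any():
                continue
            train = ~test
            if len(np.unique(yc[train])) < 2:
                raise ValueError(f"fold {f}: training split lost a class")
            model = fit_opls(
                arr[train], np.where(yc[train] > 0, "A", "B"), n_orth=n_orth,
                scale=scale,
            )
            # predict centered response for held-out subjects
            t_new = _predict_scores(model, arr[test])
            sign = 1.0 if model.classes[1] == "A" else -1.0
            y_hat = sign * (model.y_mean + model.b * t_new)
            y_true = yc[test]
            press += float(np.sum((y_true - y_hat) ** 2))
            y_train_mean = float(yc[train].mean())
            ss += float(np.sum((y_true - y_train_mean) ** 2))
        return 1.0 - press / ss

    best_q2 = q2_for(0)
    best_n = 0
    for n_orth in range(1, max_orth + 1):
        try:
            q2 = q2_for(n_orth)
        except ValueError:
            break
        if q2 - best_q2 > min_gain:
            best_q2, best_n = q2, n_orth
        else:
            break
    return best_q2, best_n


def bootstrap_significance(
    x,
    y,
    n_boot: int = 1000,
    n_orth: int = 1,
    alpha: float = 0.05,
    scale: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Subject-bootstrap percentile CIs for the predictive loadings.

    Each replicate resamples subjects with replacement (redrawing degenerate
    single-class resamples), refits, and aligns the loading sign to the
    point estimate before pooling.  A variable is flagged significant when
    its CI excludes 0.
    """
    if n_boot < 200:
        raise ValueError("use at least 200 bootstrap replicates")
    arr = x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)
    names = list(x.columns) if isinstance(x, pd.DataFrame) else [
        f"x{j}" for j in range(arr.shape[1])
    ]
    y = np.asarray(y)
    ref = fit_opls(arr, y, n_orth=n_orth, scale=scale)
    rng = np.random.default_rng(seed)
    n = len(y)
    loadings = np.empty((n_boot, arr.shape[1]))
    for i in range(n_boot):
        for _attempt in range(1000):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2 and min(
                np.sum(y[idx] == c) for c in np.unique(y[idx])
            ) >= 2:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not draw a two-class bootstrap resample")
        try:
            m = fit_opls(arr[idx], y[idx], n_orth=n_orth, scale=scale)
        except ValueError:
            # degenerate resample (e.g. constant column); redraw once more
            loadings[i] = np.nan
            continue
        sign = np.sign(np.dot(m.p_load, ref.p_load)) or 1.0
        loadings[i] = sign * m.p_load
    ok = ~np.isnan(loadings).any(axis=1)
    lo = np.nanpercentile(loadings[ok], 100 * alpha / 2, axis=0)
    hi = np.nanpercentile(loadings[ok], 100 * (1 - alpha / 2), axis=0)
    return pd.DataFrame(
        {
            "loading": ref.p_load,
            "ci_low": lo,
            "ci_high": hi,
            "significant": (lo > 0) | (hi < 0),
            "vip": vip(ref),
        },
        index=names,
    )
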