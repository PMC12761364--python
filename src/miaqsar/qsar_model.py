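"""Centered PLS regression (NIPALS) with interpretation vectors.

The descriptor block of an image-based QSAR model has far more pixels than
samples, so the regression of pKi on pixel intensities is fitted with partial
least squares.  NIPALS is used in its deterministic single-response form: the
weight of each component is the (normalized) covariance direction X'y, scores
and loadings follow, and both blocks are deflated.  With a single response the
inner NIPALS loop converges in one step, so no iteration is needed; the
algorithm is exactly reproducible with no random initialization.

X columns and y are mean-centered but not autoscaled — pixel intensities
share one physical scale (0–765), which is the chemometric default for this
descriptor family (autoscaling is available as a flag).

Interpretation exports:

* regression coefficient vector ``b`` (the "b-plot" when refolded to pixels),
* VIP scores, ``VIP_j = sqrt( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a )``
  with ``SSY_a = q_a² t_a't_a`` the response variance captured by component
  ``a``; VIP scores satisfy ``Σ_j VIP_j² = p``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .imaging import DescriptorMatrix

__all__ = [
    "PLSModel",
    "MiaMap",
    "fit_pls",
    "predict",
    "nested_predictions",
    "loo_prediction_matrix",
    "select_components",
    "vip",
    "refold",
    "fit_from_descriptor",
    "save_model",
    "load_model",
]

_DEFLATION_TOL = 1e-12


@dataclass
class PLSModel:
    """Fitted centered NIPALS PLS model for a single response."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # W, (p, A)
    x_loadings: np.ndarray  # P, (p, A)
    y_loadings: np.ndarray  # q, (A,)
    scores: np.ndarray  # T, (n, A)
    coef: np.ndarray  # b, (p,)
    intercept: float
    channel: str | None = None
    kept_columns: np.ndarray | None = None
    autoscaled: bool = False
    x_scale: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return self.coef.size

    @property
    def fitted_values(self) -> np.ndarray:
        return self.y_mean + self.scores @ self.y_loadings


@dataclass(frozen=True)
class MiaMap:
    """An interpretation vector refolded into image space (pruned pixels = NaN)."""

    values: np.ndarray
    kind: Literal["vip", "coefficient"]
    channel: str | None = None


def _prepare(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if X.shape[0] != y.size:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.size} entries")
    return X, y


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    *,
    autoscale: bool = False,
    channel: str | None = None,
    kept_columns: np.ndarray | None = None,
) -> PLSModel:
    """Fit a centered single-response NIPALS PLS model with ``n_components``.

    Raises when the requested component count exceeds what the deflated data
    can support (deflated X norm below 1e-12 or a vanishing covariance
    direction), naming the attainable maximum.
    """
    X, y = _prepare(X, y)
    n, p = X.shape
    if not 1 <= n_components <= n - 1:
        raise ValueError(f"n_components must be in [1, n-1] = [1, {n - 1}], got {n_components}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    x_scale = None
    if autoscale:
        x_scale = Xd.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
        Xd = Xd / x_scale
    yd = y - y_mean

    A = n_components
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    T = np.zeros((n, A))

    for a in range(A):
        if np.linalg.norm(Xd) < _DEFLATION_TOL:
            raise ValueError(
                f"requested {A} components but the deflated descriptor block is exhausted; "
                f"attainable maximum is {a}"
            )
        s = Xd.T @ yd
        s_norm = np.linalg.norm(s)
        if s_norm == 0.0:
            raise ValueError(
                f"requested {A} components but the response is fully deflated; "
                f"attainable maximum is {a}"
            )
        w = s / s_norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < _DEFLATION_TOL:
            raise ValueError(
                f"requested {A} components but component {a + 1} has a degenerate score; "
                f"attainable maximum is {a}"
            )
        p_a = Xd.T @ t / tt
        q_a = float(yd @ t) / tt
        Xd -= np.outer(t, p_a)
        yd = yd - q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t

    # b = W (P'W)^-1 q maps centered X directly to centered y-hat
    rotation = np.linalg.solve((P.T @ W).T, W.T).T
    b = rotation @ q
    if autoscale:
        b = b / x_scale
    intercept = y_mean - float(x_mean @ b)
    return PLSModel(
        n_components=A,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coef=b,
        intercept=intercept,
        channel=channel,
        kept_columns=None if kept_columns is None else np.asarray(kept_columns),
        autoscaled=autoscale,
        x_scale=x_scale,
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict responses: ``y_hat = intercept + X_new · b``."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_features:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns but the model expects {model.n_features}"
        )
    return model.intercept + X_new @ model.coef


def nested_predictions(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predictions of the nested sub-models with 1..A components, shape (m, A).

    NIPALS components are sequential, so one fitted model yields the
    prediction for every smaller component count at no extra cost.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    Xc = X_new - model.x_mean
    if model.autoscaled:
        Xc = Xc / model.x_scale
    m = X_new.shape[0]
    out = np.empty((m, model.n_components))
    acc = np.full(m, model.y_mean)
    for a in range(model.n_components):
        t = Xc @ model.weights[:, a]
        acc = acc + t * model.y_loadings[a]
        Xc = Xc - np.outer(t, model.x_loadings[:, a])
        out[:, a] = acc
    return out


def loo_prediction_matrix(X: np.ndarray, y: np.ndarray, a_max: int, *, autoscale: bool = False) -> np.ndarray:
    """Leave-one-out predictions for every component count 1..a_max, shape (n, a_max).

    Each sample is predicted by a model refitted without it; an ``a_max``
    infeasible for n−1 samples propagates as an error.
    """
    X, y = _prepare(X, y)
    n = X.shape[0]
    if n < 3:
        raise ValueError("leave-one-out requires at least 3 samples")
    out = np.empty((n, a_max))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        sub = fit_pls(X[mask], y[mask], a_max, autoscale=autoscale)
        out[i] = nested_predictions(sub, X[i : i + 1])[0]
        mask[i] = True
    return out


def max_components(X: np.ndarray, y: np.ndarray, a_max: int, *, autoscale: bool = False) -> int:
    """Largest component count (≤ a_max) the data can actually support."""
    X, y = _prepare(X, y)
    for a in range(min(a_max, X.shape[0] - 1), 0, -1):
        try:
            fit_pls(X, y, a, autoscale=autoscale)
            return a
        except ValueError:
            continue
    raise ValueError("no PLS component can be extracted from this data")


def select_components(X: np.ndarray, y: np.ndarray, a_max: int, *, autoscale: bool = False) -> int:
    """Pick the component count minimizing leave-one-out RMSECV.

    ``a_max`` is first capped at what the data (and the n−1-sample LOO fits)
    can support.  Ties (within a 1e-6 relative band, which also absorbs
    floating-point noise on noiseless data) are broken toward the smaller,
    more parsimonious model.
    """
    if a_max < 1:
        raise ValueError("a_max must be >= 1")
    X, y = _prepare(X, y)
    a_max = min(max_components(X, y, a_max, autoscale=autoscale), X.shape[0] - 2)
    preds = loo_prediction_matrix(X, y, a_max, autoscale=autoscale)
    y = np.asarray(y, dtype=float).ravel()
    rmsecv = np.sqrt(np.mean((y[:, None] - preds) ** 2, axis=0))
    best = float(rmsecv.min())
    for a, value in enumerate(rmsecv, start=1):
        if value <= best * (1 + 1e-6) + 1e-12:
            return a
    return int(np.argmin(rmsecv)) + 1  # pragma: no cover - unreachable


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection over kept pixels; mean square is 1."""
    W = model.weights
    p = W.shape[0]
    tt = np.einsum("na,na->a", model.scores, model.scores)
    ssy = model.y_loadings**2 * tt
    if ssy.sum() == 0:
        raise ValueError("model explains no response variance; VIP undefined")
    wnorm = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (wnorm**2 @ ssy) / ssy.sum())


def refold(
    vector: np.ndarray,
    descriptor_meta: DescriptorMatrix,
    kind: Literal["vip", "coefficient"] = "coefficient",
) -> MiaMap:
    """Refold a kept-pixel vector into an interpretation map (MIA plot)."""
    return MiaMap(
        values=descriptor_meta.refold(vector),
        kind=kind,
        channel=descriptor_meta.channel,
    )


def fit_from_descriptor(
    dm: DescriptorMatrix,
    y: np.ndarray,
    n_components: int | None = None,
    a_max: int = 10,
    *,
    autoscale: bool = False,
) -> PLSModel:
    """Fit on a descriptor block, selecting the component count by LOO when unset."""
    if n_components is None:
        n_components = select_components(dm.X, y, min(a_max, dm.X.shape[0] - 2), autoscale=autoscale)
    return fit_pls(
        dm.X, y, n_components, autoscale=autoscale, channel=dm.channel, kept_columns=dm.kept_columns
    )


def save_model(model: PLSModel, prefix: str | Path) -> None:
    prefix = Path(prefix)
    arrays = {
        "x_mean": model.x_mean,
        "weights": model.weights,
        "x_loadings": model.x_loadings,
        "y_loadings": model.y_loadings,
        "scores": model.scores,
        "coef": model.coef,
    }
    if model.kept_columns is not None:
        arrays["kept_columns"] = model.kept_columns
    if model.x_scale is not None:
        arrays["x_scale"] = model.x_scale
    np.savez_compressed(prefix.with_suffix(".npz"), **arrays)
    meta = {
        "n_components": model.n_components,
        "y_mean": model.y_mean,
        "intercept": model.intercept,
        "channel": model.channel,
        "autoscaled": model.autoscaled,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_model(prefix: str | Path) -> PLSModel:
    prefix = Path(prefix)
    arrays = np.load(prefix.with_suffix(".npz"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return PLSModel(
        n_components=int(meta["n_components"]),
        x_mean=arrays["x_mean"],
        y_mean=float(meta["y_mean"]),
        weights=arrays["weights"],
        x_loadings=arrays["x_loadings"],
        y_loadings=arrays["y_loadings"],
        scores=arrays["scores"],
        coef=arrays["coef"],
        intercept=float(meta["intercept"]),
        channel=meta["channel"],
        kept_columns=arrays["kept_columns"] if "kept_columns" in arrays else None,
        autoscaled=bool(meta["autoscaled"]),
        x_scale=arrays["x_scale"] if "x_scale" in arrays else None,
    )
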