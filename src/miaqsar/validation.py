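"""QSAR validation battery: calibration, LOO CV, Y-randomization, bootstrap
external validation with Roy's metrics and Lin's CCC, and Williams-plot
outlier analysis.

The battery mirrors standard chemometric model-quality reporting for
image-based QSAR of a congeneric series.  For each property channel the
bootstrap procedure repeatedly holds out a fraction of the samples (default
25 %, 10 iterations), re-selects the PLS component count on the training
portion by leave-one-out RMSECV, refits, and computes

* calibration: r², RMSEC;
* internal predictivity: q² = 1 − PRESS/SStot, RMSECV (leave-one-out);
* chance-correlation guard: r²_y-rand and the penalty
  ``cr²_p = r · sqrt(r² − mean r²_y-rand)``;
* external predictivity on the holdout: RMSEP, r²_pred (holdout residuals
  against the *training* mean — the Golbraikh–Tropsha convention), Roy's
  avg r²_m / Δr²_m, and Lin's concordance correlation coefficient.

Channel statistics are bootstrap means; the report aggregates the three
channels into Average / Std. Dev. columns and checks the customary cutoffs
(r² ≥ 0.6, cr²_p ≥ 0.5, q² ≥ 0.5, r²_pred ≥ 0.5, avg r²_m ≥ 0.5,
Δr²_m < 0.2, CCC ≥ 0.8).

Moment conventions, stated so results are exactly testable: Lin's CCC uses
population (1/n) moments; Pearson r uses sample (1/(n−1)) moments; the
cross-channel Std. Dev. column uses ddof=1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .qsar_model import (
    PLSModel,
    fit_pls,
    loo_prediction_matrix,
    predict,
    select_components,
)

__all__ = [
    "ChannelStats",
    "ValidationReport",
    "WilliamsPoint",
    "WilliamsResult",
    "IterationStats",
    "BootstrapResult",
    "YRandomizationResult",
    "CUTOFFS",
    "calibration_stats",
    "loo_q2",
    "y_randomization",
    "roy_metrics",
    "ccc",
    "bootstrap_external",
    "williams",
    "build_report",
]

#: Cutoff rules applied to the Average column of the report.
CUTOFFS: dict[str, tuple[str, float]] = {
    "r2": (">=", 0.6),
    "c_r2_p": (">=", 0.5),
    "q2": (">=", 0.5),
    "r2_pred": (">=", 0.5),
    "avg_r2_m": (">=", 0.5),
    "delta_r2_m": ("<", 0.2),
    "ccc": (">=", 0.8),
}

_STAT_ORDER = [
    ("pls_comp", "PLS comp."),
    ("rmsec", "RMSEC"),
    ("r2", "r2"),
    ("rmse_y_rand", "RMSEy-rand"),
    ("r2_y_rand", "r2_y-rand"),
    ("c_r2_p", "c_r2_p"),
    ("rmsecv", "RMSECV"),
    ("q2", "q2"),
    ("rmsep", "RMSEP"),
    ("r2_pred", "r2_pred"),
    ("avg_r2_m", "Avg. r2_m"),
    ("delta_r2_m", "Delta r2_m"),
    ("ccc", "CCC"),
]


@dataclass
class ChannelStats:
    """One column of the validation table (bootstrap means for one channel)."""

    pls_comp: float = math.nan
    rmsec: float = math.nan
    r2: float = math.nan
    rmse_y_rand: float = math.nan
    r2_y_rand: float = math.nan
    c_r2_p: float = math.nan
    rmsecv: float = math.nan
    q2: float = math.nan
    rmsep: float = math.nan
    r2_pred: float = math.nan
    avg_r2_m: float = math.nan
    delta_r2_m: float = math.nan
    ccc: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def calibration_stats(model: PLSModel, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Goodness of fit on the calibration set: (r², RMSEC)."""
    y = np.asarray(y, float).ravel()
    sstot = float(((y - y.mean()) ** 2).sum())
    if sstot == 0:
        raise ValueError("constant response: r2 undefined")
    resid = y - predict(model, X)
    ssres = float((resid**2).sum())
    return 1.0 - ssres / sstot, math.sqrt(ssres / y.size)


def loo_q2(X: np.ndarray, y: np.ndarray, n_components: int) -> tuple[float, float]:
    """Leave-one-out (q², RMSECV) at a fixed component count."""
    y = np.asarray(y, float).ravel()
    preds = loo_prediction_matrix(X, y, n_components)[:, n_components - 1]
    press = float(((y - preds) ** 2).sum())
    sstot = float(((y - y.mean()) ** 2).sum())
    if sstot == 0:
        raise ValueError("constant response: q2 undefined")
    return 1.0 - press / sstot, math.sqrt(press / y.size)


@dataclass(frozen=True)
class YRandomizationResult:
    r2_y_rand: float
    rmse_y_rand: float
    c_r2_p: float
    r2: float
    r2_perm: np.ndarray


def y_randomization(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    n_perm: int = 50,
    seed: int | None = None,
    permutations: Sequence[np.ndarray] | None = None,
) -> YRandomizationResult:
    """Refit on permuted responses to guard against chance correlation.

    ``cr²_p = r · sqrt(r² − mean r²_y-rand)`` with r and r² from the
    unpermuted model; a negative radicand (model no better than chance)
    yields 0 with a warning.  ``permutations`` overrides the random draws —
    useful for deterministic checks.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    model = fit_pls(X, y, n_components)
    r2, _ = calibration_stats(model, X, y)
    r = _pearson(y, predict(model, X))

    if permutations is None:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        permutations = [rng.permutation(y.size) for _ in range(n_perm)]

    r2_vals = np.empty(len(permutations))
    rmse_vals = np.empty(len(permutations))
    for k, perm in enumerate(permutations):
        y_perm = y[np.asarray(perm)]
        m = fit_pls(X, y_perm, n_components)
        r2_vals[k], rmse_vals[k] = calibration_stats(m, X, y_perm)

    mean_r2_rand = float(r2_vals.mean())
    radicand = r2 - mean_r2_rand
    if radicand < 0:
        warnings.warn(
            "mean randomized r2 exceeds the model r2; cr2_p set to 0", stacklevel=2
        )
        c_r2_p = 0.0
    else:
        c_r2_p = r * math.sqrt(radicand)
    return YRandomizationResult(mean_r2_rand, float(rmse_vals.mean()), c_r2_p, r2, r2_vals)


def roy_metrics(y_obs: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float, float]:
    """Roy's external-validation metrics (r²_m, r²_m reverse, average, Δ).

    ``r²_m = r² (1 − sqrt(|r² − r0²|))`` where r0² is the through-origin
    coefficient of determination of observed on predicted; the reverse metric
    swaps the roles.
    """
    y_obs = np.asarray(y_obs, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if y_obs.size < 3:
        raise ValueError("roy_metrics requires at least 3 points")
    if np.ptp(y_obs) == 0 or np.ptp(y_pred) == 0:
        raise ValueError("zero-variance input: Roy's metrics undefined")
    r2 = _pearson(y_obs, y_pred) ** 2

    def _r2m(a: np.ndarray, b: np.ndarray) -> float:
        # through-origin fit of a on b
        k = float(a @ b) / float(b @ b)
        r02 = 1.0 - float(((a - k * b) ** 2).sum()) / float(((a - a.mean()) ** 2).sum())
        return r2 * (1.0 - math.sqrt(abs(r2 - r02)))

    r2_m = _r2m(y_obs, y_pred)
    r2_m_rev = _r2m(y_pred, y_obs)
    return r2_m, r2_m_rev, (r2_m + r2_m_rev) / 2.0, abs(r2_m - r2_m_rev)


def ccc(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population 1/n moments)."""
    y_obs = np.asarray(y_obs, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if y_obs.size < 2 or y_obs.size != y_pred.size:
        raise ValueError("ccc requires two equal-length vectors of length >= 2")
    var_o = float(np.var(y_obs))
    var_p = float(np.var(y_pred))
    if var_o == 0 and var_p == 0:
        raise ValueError("zero variance in both vectors: CCC undefined")
    cov = float(np.mean((y_obs - y_obs.mean()) * (y_pred - y_pred.mean())))
    return 2.0 * cov / (var_o + var_p + (y_obs.mean() - y_pred.mean()) ** 2)


# ---------------------------------------------------------------------------
# Bootstrap external validation
# ---------------------------------------------------------------------------

@dataclass
class IterationStats:
    """All statistics of one bootstrap cycle."""

    test_indices: np.ndarray
    n_components: int
    r2: float
    rmsec: float
    q2: float
    rmsecv: float
    rmsep: float
    r2_pred: float
    avg_r2_m: float
    delta_r2_m: float
    ccc: float
    r2_y_rand: float = math.nan
    rmse_y_rand: float = math.nan
    c_r2_p: float = math.nan

    def cutoff_count(self) -> int:
        values = {k: getattr(self, k) for k, _ in CUTOFFS.items() if hasattr(self, k)}
        count = 0
        for stat, (op, cut) in CUTOFFS.items():
            v = values.get(stat, math.nan)
            if math.isnan(v):
                continue
            count += (v >= cut) if op == ">=" else (v < cut)
        return count

    def cutoff_mean(self) -> float:
        keys = ("r2", "c_r2_p", "q2", "r2_pred", "avg_r2_m", "ccc")
        vals = [getattr(self, k) for k in keys if not math.isnan(getattr(self, k))]
        return float(np.mean(vals)) if vals else math.nan


@dataclass
class BootstrapResult:
    iterations: list[IterationStats]
    stats: ChannelStats
    best_index: int


def bootstrap_external(
    X: np.ndarray,
    y: np.ndarray,
    a_max: int,
    frac: float = 0.25,
    n_iter: int = 10,
    seed: int | None = None,
    n_perm: int = 0,
) -> BootstrapResult:
    """Bootstrap external validation with per-cycle component re-selection.

    Each cycle holds out ``floor(frac·n)`` samples without replacement,
    re-selects the component count on the remainder by LOO RMSECV, refits and
    scores the holdout.  ``n_perm > 0`` additionally runs Y-randomization on
    each training portion so a complete validation-table column can be
    assembled from one call.  The best cycle maximizes the count of
    above-cutoff statistics, tie-broken by their mean.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = y.size
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    n_test = int(math.floor(frac * n))
    if n_test < 3:
        raise ValueError(f"holdout of {n_test} samples is too small (< 3)")
    rng = np.random.default_rng(seed)

    iterations: list[IterationStats] = []
    for _ in range(n_iter):
        test_idx = np.sort(rng.choice(n, size=n_test, replace=False))
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        X_tr, y_tr = X[train_mask], y[train_mask]
        X_te, y_te = X[test_idx], y[test_idx]

        a_cap = min(a_max, X_tr.shape[0] - 2)
        a_star = select_components(X_tr, y_tr, a_cap)
        model = fit_pls(X_tr, y_tr, a_star)
        r2, rmsec = calibration_stats(model, X_tr, y_tr)
        q2, rmsecv = loo_q2(X_tr, y_tr, a_star)

        y_hat = predict(model, X_te)
        rmsep = float(np.sqrt(np.mean((y_te - y_hat) ** 2)))
        denom = float(((y_te - y_tr.mean()) ** 2).sum())
        r2_pred = 1.0 - float(((y_te - y_hat) ** 2).sum()) / denom
        _, _, avg_r2m, delta_r2m = roy_metrics(y_te, y_hat)
        ccc_val = ccc(y_te, y_hat)

        it = IterationStats(
            test_indices=test_idx,
            n_components=a_star,
            r2=r2,
            rmsec=rmsec,
            q2=q2,
            rmsecv=rmsecv,
            rmsep=rmsep,
            r2_pred=r2_pred,
            avg_r2_m=avg_r2m,
            delta_r2_m=delta_r2m,
            ccc=ccc_val,
        )
        if n_perm > 0:
            yr = y_randomization(
                X_tr, y_tr, a_star, n_perm=n_perm, seed=int(rng.integers(2**31))
            )
            it.r2_y_rand = yr.r2_y_rand
            it.rmse_y_rand = yr.rmse_y_rand
            it.c_r2_p = yr.c_r2_p
        iterations.append(it)

    def _mean(attr: str) -> float:
        vals = [getattr(it, attr) for it in iterations]
        return float(np.mean(vals))

    stats = ChannelStats(
        pls_comp=_mean("n_components"),
        rmsec=_mean("rmsec"),
        r2=_mean("r2"),
        rmse_y_rand=_mean("rmse_y_rand"),
        r2_y_rand=_mean("r2_y_rand"),
        c_r2_p=_mean("c_r2_p"),
        rmsecv=_mean("rmsecv"),
        q2=_mean("q2"),
        rmsep=_mean("rmsep"),
        r2_pred=_mean("r2_pred"),
        avg_r2_m=_mean("avg_r2_m"),
        delta_r2_m=_mean("delta_r2_m"),
        ccc=_mean("ccc"),
    )
    best = max(
        range(len(iterations)),
        key=lambda i: (iterations[i].cutoff_count(), iterations[i].cutoff_mean()),
    )
    return BootstrapResult(iterations, stats, best)


# ---------------------------------------------------------------------------
# Williams plot
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilliamsPoint:
    index: int
    id: str
    leverage: float
    studentized_residual: float
    residual_outlier: bool
    high_leverage: bool


@dataclass(frozen=True)
class WilliamsResult:
    points: list[WilliamsPoint]
    residual_threshold: float
    leverage_threshold: float

    def flagged(self) -> list[WilliamsPoint]:
        return [p for p in self.points if p.residual_outlier or p.high_leverage]


def williams(
    model: PLSModel,
    X: np.ndarray,
    y: np.ndarray,
    resid_threshold: float = 2.5,
    leverage_factor: float = 3.0,
    ids: Sequence[str] | None = None,
) -> WilliamsResult:
    """Leverage / studentized-residual analysis in PLS score space.

    ``h_i = 1/n + t_i'(T'T)⁻¹t_i`` (so Σh = A + 1); studentized residual is
    ``e_i / (RMSE · sqrt(1 − h_i))``.  A sample is a residual outlier when its
    |studentized residual| exceeds ``resid_threshold`` (default 2.5) and
    high-leverage when ``h > leverage_factor · (A + 1)/n`` (default factor 3).
    """
    y = np.asarray(y, float).ravel()
    n = y.size
    T = model.scores
    tt = np.einsum("na,na->a", T, T)
    h = 1.0 / n + np.einsum("na,a,na->n", T, 1.0 / tt, T)
    if np.any(h >= 1.0 - 1e-12):
        raise ValueError("a sample has leverage 1 (exact interpolation); Williams analysis degenerate")
    resid = y - predict(model, X)
    rmse = float(np.sqrt(np.mean(resid**2)))
    if rmse == 0:
        raise ValueError("zero residuals: studentized residuals undefined")
    stud = resid / (rmse * np.sqrt(1.0 - h))
    h_star = leverage_factor * (model.n_components + 1) / n
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    points = [
        WilliamsPoint(
            index=i,
            id=ids[i],
            leverage=float(h[i]),
            studentized_residual=float(stud[i]),
            residual_outlier=bool(abs(stud[i]) > resid_threshold),
            high_leverage=bool(h[i] > h_star),
        )
        for i in range(n)
    ]
    return WilliamsResult(points, resid_threshold, h_star)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Per-channel statistics plus cross-channel Average/Std. Dev. and verdicts."""

    channels: dict[str, ChannelStats]
    average: ChannelStats
    std: ChannelStats
    verdicts: dict[str, bool]

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, list[float | str]] = {}
        for name, stats in self.channels.items():
            cols[name] = [getattr(stats, key) for key, _ in _STAT_ORDER]
        cols["Average"] = [getattr(self.average, key) for key, _ in _STAT_ORDER]
        cols["Std. Dev."] = [getattr(self.std, key) for key, _ in _STAT_ORDER]
        verdict_col = []
        for key, _ in _STAT_ORDER:
            if key in CUTOFFS:
                op, cut = CUTOFFS[key]
                mark = "pass" if self.verdicts[key] else "FAIL"
                verdict_col.append(f"{op} {cut} ({mark})")
            else:
                verdict_col.append("-")
        cols["Cut-off"] = verdict_col
        return pd.DataFrame(cols, index=[label for _, label in _STAT_ORDER])

    def to_json_dict(self) -> dict:
        return {
            "channels": {k: v.as_dict() for k, v in self.channels.items()},
            "average": self.average.as_dict(),
            "std": self.std.as_dict(),
            "verdicts": self.verdicts,
        }

    def all_pass(self) -> bool:
        return all(self.verdicts.values())


def build_report(channel_stats: Mapping[str, ChannelStats]) -> ValidationReport:
    """Aggregate per-channel statistics into the cross-channel report.

    Average is the arithmetic mean across channels, Std. Dev. the sample
    (ddof=1) standard deviation; cutoff verdicts are evaluated on the Average
    column.
    """
    if not channel_stats:
        raise ValueError("no channel statistics given")
    keys = [f.name for f in fields(ChannelStats)]
    avg = ChannelStats()
    std = ChannelStats()
    for key in keys:
        vals = np.array([getattr(cs, key) for cs in channel_stats.values()], float)
        setattr(avg, key, float(np.mean(vals)))
        setattr(std, key, float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0)
    verdicts = {}
    for stat, (op, cut) in CUTOFFS.items():
        v = getattr(avg, stat)
        verdicts[stat] = bool(v >= cut) if op == ">=" else bool(v < cut)
    return ValidationReport(dict(channel_stats), avg, std, verdicts)
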