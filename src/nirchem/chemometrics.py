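"""From-scratch PCR and PLS1 calibration with cross-validation diagnostics.

Both regressions operate on mean-centered spectra (X) and a mean-centered
single response (y); no unit-variance scaling is applied, which is the usual
convention for spectroscopic data and keeps loading shapes interpretable as
absorbance patterns.

PCR: principal components from the SVD of centered X, then ordinary least
squares of y on the leading k scores. The component whose score carries the
largest |t| statistic in that regression is the one whose loading is read
for chemical interpretation.

PLS1: the NIPALS algorithm — each weight vector is proportional to the
X–y covariance of the deflated data, so components are steered by the
response rather than by X variance alone. The full regression coefficient
vector b = W (PᵀW)⁻¹ q maps centered spectra directly to predictions and is
the curve whose peaks are interpreted.

Model quality is summarised by r² (as a percentage), RMSEC/RMSEP and the
RPD (sd of the reference values over RMSEP); component counts are chosen by
leave-one-out cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .synth import SpectraSet, WavenumberGrid

__all__ = [
    "CalibrationModel",
    "Diagnostics",
    "fit_pcr",
    "fit_pls",
    "fit",
    "predict",
    "loo_cross_validate",
    "select_components",
    "diagnostics",
    "select_significant_pc",
    "coefficient_profile",
    "holdout_split",
    "matrix_rank",
]

log = logging.getLogger(__name__)

_RANK_RTOL = 1e-10


def matrix_rank(X: np.ndarray) -> int:
    s = np.linalg.svd(X, compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    return int(np.sum(s > s[0] * _RANK_RTOL * max(X.shape)))


@dataclass
class CalibrationModel:
    """A fitted PCR or PLS1 calibration for one constituent."""

    method: str  # "pcr" | "pls"
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    loadings: np.ndarray  # p × k  (P)
    scores: np.ndarray  # n × k  (T)
    coefficients: np.ndarray  # length-p b: ŷ = (x − x_mean)·b + y_mean
    weights: np.ndarray | None = None  # p × k (W, PLS only)
    component_t: np.ndarray | None = None  # PCR: t of each score in the y fit
    component_p: np.ndarray | None = None
    grid: WavenumberGrid | None = None

    @property
    def fitted_values(self) -> np.ndarray:
        return self.scores @ self._gamma + self.y_mean

    def __post_init__(self) -> None:
        # score-space coefficients, recovered by projecting b through P
        self._gamma = np.linalg.lstsq(self.loadings, self.coefficients, rcond=None)[0]


@dataclass
class Diagnostics:
    """Predictive summary in the units the field reports: r² in percent,
    RMSE in the response's own units, RPD dimensionless."""

    n_cal: int
    r2_cal: float
    rmsec: float
    n_val: int | None = None
    r2_val: float | None = None
    rmsep: float | None = None
    rpd: float | None = None
    cv_kind: str | None = None  # loo | holdout


def _center(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on sample count")
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    return X - x_mean, y - y_mean, x_mean, y_mean


def fit_pcr(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    grid: WavenumberGrid | None = None,
) -> CalibrationModel:
    """Principal components regression with k components.

    Components come from the SVD of centered X; each loading's sign is fixed
    so its largest-magnitude element is positive, making the decomposition
    deterministic. y is regressed on the k scores by least squares.
    """
    Xc, yc, x_mean, y_mean = _center(X, y)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * _RANK_RTOL * max(Xc.shape))) if s.size and s[0] > 0 else 0
    if not 1 <= k <= rank:
        raise ValueError(f"k={k} outside [1, rank(X)={rank}]")
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # deterministic sign: largest-|element| of each loading positive
    flip = np.sign(Vt[np.arange(k), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    P = (Vt * flip[:, None]).T  # p × k, orthonormal columns
    T = U * s[None, :] * flip[None, :]  # n × k, orthogonal columns

    # OLS of centered y on the k orthogonal scores
    ss_t = (T**2).sum(axis=0)
    gamma = (T.T @ yc) / ss_t
    resid = yc - T @ gamma
    dof = Xc.shape[0] - 1 - k  # intercept absorbed by centering
    if dof > 0:
        sigma2 = float(resid @ resid) / dof
        se = np.sqrt(sigma2 / ss_t)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, gamma / se, np.inf * np.sign(gamma))
        pvals = 2.0 * sstats.t.sf(np.abs(tvals), dof)
    else:  # saturated fit: significance undefined
        tvals = np.full(k, np.nan)
        pvals = np.full(k, np.nan)

    b = P @ gamma
    return CalibrationModel(
        method="pcr",
        n_components=k,
        x_mean=x_mean,
        y_mean=y_mean,
        loadings=P,
        scores=T,
        coefficients=b,
        component_t=tvals,
        component_p=pvals,
        grid=grid,
    )


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    grid: WavenumberGrid | None = None,
) -> CalibrationModel:
    """PLS1 by NIPALS with k latent components.

    Deterministic for a single response: w_j ∝ X_jᵀ y_j (no iteration or
    random start needed), t_j = X_j w_j, then X and y are deflated by the
    rank-one fit of component j.
    """
    Xc, yc, x_mean, y_mean = _center(X, y)
    if np.allclose(yc, 0.0):
        raise ValueError("y has zero variance; nothing to calibrate")
    rank = matrix_rank(Xc)
    if not 1 <= k <= rank:
        raise ValueError(f"k={k} outside [1, rank(X)={rank}]")
    n, p = Xc.shape
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    T = np.zeros((n, k))
    q = np.zeros(k)
    Xd, yd = Xc.copy(), yc.copy()
    for j in range(k):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError(f"X–y covariance vanished at component {j + 1}")
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        P[:, j] = Xd.T @ t / tt
        q[j] = float(t @ yd) / tt
        W[:, j], T[:, j] = w, t
        Xd = Xd - np.outer(t, P[:, j])
        yd = yd - q[j] * t
    b = W @ np.linalg.solve(P.T @ W, q)
    return CalibrationModel(
        method="pls",
        n_components=k,
        x_mean=x_mean,
        y_mean=y_mean,
        loadings=P,
        scores=T,
        coefficients=b,
        weights=W,
        grid=grid,
    )


def fit(
    X: "SpectraSet | np.ndarray",
    y: np.ndarray,
    method: str,
    k: int,
) -> CalibrationModel:
    """Dispatch on method; accepts a SpectraSet (its grid is retained)."""
    grid = X.grid if isinstance(X, SpectraSet) else None
    A = X.absorbance if isinstance(X, SpectraSet) else X
    if method == "pcr":
        return fit_pcr(A, y, k, grid=grid)
    if method == "pls":
        return fit_pls(A, y, k, grid=grid)
    raise ValueError(f"unknown method {method!r}")


def predict(model: CalibrationModel, X_new: "SpectraSet | np.ndarray") -> np.ndarray:
    if isinstance(X_new, SpectraSet):
        if model.grid is not None and not np.array_equal(
            X_new.grid.values, model.grid.values
        ):
            raise ValueError(
                f"grid mismatch: model expects {len(model.grid)} points "
                f"[{model.grid.start_cm1}, {model.grid.end_cm1}] cm⁻¹"
            )
        A = X_new.absorbance
    else:
        A = np.atleast_2d(np.asarray(X_new, dtype=float))
    if A.shape[1] != model.x_mean.size:
        raise ValueError(
            f"{A.shape[1]} wavenumbers but model was fit on {model.x_mean.size}"
        )
    return (A - model.x_mean) @ model.coefficients + model.y_mean


def _nested_predictions(
    X_train: np.ndarray, y_train: np.ndarray, x_new: np.ndarray, method: str, k_max: int
) -> np.ndarray:
    """Predictions for x_new at every component count 1..k_max, one fit."""
    Xc, yc, x_mean, y_mean = _center(X_train, y_train)
    xq = x_new - x_mean
    out = np.empty(k_max)
    if method == "pcr":
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        flip = np.sign(Vt[np.arange(k_max), np.argmax(np.abs(Vt[:k_max]), axis=1)])
        flip[flip == 0] = 1.0
        V = (Vt[:k_max] * flip[:, None]).T
        T = U[:, :k_max] * s[:k_max] * flip
        gamma = (T.T @ yc) / (T**2).sum(axis=0)
        contrib = (xq @ V) * gamma
        out[:] = y_mean + np.cumsum(contrib)
    elif method == "pls":
        Xd, yd, xd = Xc.copy(), yc.copy(), xq.copy()
        acc = y_mean
        for j in range(k_max):
            w = Xd.T @ yd
            nw = np.linalg.norm(w)
            if nw == 0:
                out[j:] = acc
                break
            w /= nw
            t = Xd @ w
            tt = float(t @ t)
            p = Xd.T @ t / tt
            qj = float(t @ yd) / tt
            tq = float(xd @ w)
            acc += qj * tq
            out[j] = acc
            Xd -= np.outer(t, p)
            yd -= qj * t
            xd -= tq * p
        else:
            pass
    else:
        raise ValueError(f"unknown method {method!r}")
    return out


def loo_cross_validate(
    X: "SpectraSet | np.ndarray",
    y: np.ndarray,
    method: str,
    k_max: int,
) -> pd.DataFrame:
    """Leave-one-out cross-validation over component counts 1..k_max.

    Returns a table with columns k, rmsecv, r2_cv (percent). k_max is
    clipped to what the folds can support (n − 2 after centering).
    """
    A = X.absorbance if isinstance(X, SpectraSet) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = A.shape[0]
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    if np.var(y) == 0:
        warnings.warn("constant response: cross-validation is degenerate")
        return pd.DataFrame({"k": [1], "rmsecv": [0.0], "r2_cv": [np.nan]})
    cap = min(n - 2, matrix_rank(A - A.mean(axis=0)) - 0)
    cap = min(cap, n - 2)
    if k_max > cap:
        log.warning("k_max=%d clipped to %d", k_max, cap)
        k_max = cap
    preds = np.empty((n, k_max))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        preds[i] = _nested_predictions(A[mask], y[mask], A[i], method, k_max)
        mask[i] = True
    rows = []
    for j in range(k_max):
        err = preds[:, j] - y
        rmsecv = float(np.sqrt(np.mean(err**2)))
        r2 = _r2_percent(y, preds[:, j])
        rows.append({"k": j + 1, "rmsecv": rmsecv, "r2_cv": r2})
    return pd.DataFrame(rows)


def select_components(
    cv_table: pd.DataFrame, rule: str = "parsimony", tol: float = 0.02
) -> int:
    """Pick a component count from a cross-validation table.

    parsimony (default): smallest k whose RMSECV is within ``tol`` (2%) of
    the global minimum. minimum: the arg-min itself. Ties go to smaller k.
    """
    if cv_table.empty:
        raise ValueError("empty cross-validation table")
    tab = cv_table.sort_values("k")
    best = tab["rmsecv"].min()
    if rule == "minimum":
        return int(tab.loc[tab["rmsecv"].idxmin(), "k"])
    if rule == "parsimony":
        ok = tab[tab["rmsecv"] <= best * (1.0 + tol)]
        return int(ok["k"].iloc[0])
    raise ValueError(f"unknown rule {rule!r}")


def _r2_percent(y_ref: np.ndarray, y_pred: np.ndarray) -> float:
    if np.std(y_ref) == 0 or np.std(y_pred) == 0:
        return float("nan")
    r = np.corrcoef(y_ref, y_pred)[0, 1]
    return float(100.0 * r * r)


def diagnostics(
    y_ref: np.ndarray,
    y_pred: np.ndarray,
    y_ref_sd: float | None = None,
) -> tuple[float, float, float]:
    """(r²%, RMSE, RPD) for a reference/predicted pair.

    RMSE = √(Σ(ŷ−y)²/n); RPD = sd(y_ref)/RMSE with the n−1 sample sd
    (override via ``y_ref_sd``); r² is the squared Pearson correlation as a
    percentage, so it is invariant to constant offsets in the predictions.
    """
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_ref.size != y_pred.size:
        raise ValueError("length mismatch")
    if y_ref.size < 2:
        raise ValueError("need at least two pairs")
    rmse = float(np.sqrt(np.mean((y_pred - y_ref) ** 2)))
    sd = float(np.std(y_ref, ddof=1)) if y_ref_sd is None else float(y_ref_sd)
    rpd = float("inf") if rmse == 0 else sd / rmse
    return _r2_percent(y_ref, y_pred), rmse, rpd


def select_significant_pc(model: CalibrationModel, y: np.ndarray | None = None) -> int:
    """1-based index of the PCR component most significant for the response.

    Significance is the |t| of each score in the multiple regression of y on
    all fitted scores; ties (and the degenerate all-zero case) resolve to the
    lowest index.
    """
    if model.method != "pcr":
        raise ValueError("significant-component selection applies to PCR models")
    t = model.component_t
    if t is None:
        raise ValueError("model carries no per-component statistics")
    absT = np.abs(np.nan_to_num(t, nan=0.0, posinf=np.inf))
    if np.all(absT == 0):
        warnings.warn("response orthogonal to all scores; defaulting to PC 1")
        return 1
    return int(np.argmax(absT)) + 1


def coefficient_profile(
    model: CalibrationModel, mode: str = "auto"
) -> tuple[np.ndarray, np.ndarray]:
    """The interpretable per-wavenumber curve of a fitted model.

    mode 'pls_b' — the full regression coefficient vector b (PLS models);
    mode 'pcr_loading' — the loading of the most significant component
    (PCR models); 'auto' picks by method. Returns (wavenumbers, values);
    wavenumbers are point indices when the model has no grid.
    """
    if mode == "auto":
        mode = "pls_b" if model.method == "pls" else "pcr_loading"
    if mode == "pls_b":
        if model.method != "pls":
            raise ValueError("pls_b profile requested from a non-PLS model")
        values = model.coefficients
    elif mode == "pcr_loading":
        if model.method != "pcr":
            raise ValueError("pcr_loading profile requested from a non-PCR model")
        values = model.loadings[:, select_significant_pc(model) - 1]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    wn = (
        model.grid.values
        if model.grid is not None
        else np.arange(values.size, dtype=float)
    )
    return wn, np.asarray(values, dtype=float)


def holdout_split(
    chem_values: np.ndarray,
    n_cal: int = 31,
    n_val: int = 6,
    seed: int = 0,
    max_tries: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Random calibration/validation split, redrawn until the two subsets are
    balanced: per constituent, the means differ by < 0.5 pooled sd.

    ``chem_values`` is n × m (m constituents, or a single column).
    """
    V = np.atleast_2d(np.asarray(chem_values, dtype=float))
    if V.shape[0] == 1:
        V = V.T
    n = V.shape[0]
    if n_cal + n_val != n:
        raise ValueError(f"split {n_cal}+{n_val} does not cover {n} samples")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        perm = rng.permutation(n)
        cal, val = np.sort(perm[:n_cal]), np.sort(perm[n_cal:])
        ok = True
        for j in range(V.shape[1]):
            s1, s2 = V[cal, j], V[val, j]
            pooled = np.sqrt(
                ((s1.size - 1) * s1.var(ddof=1) + (s2.size - 1) * s2.var(ddof=1))
                / (s1.size + s2.size - 2)
            )
            if pooled > 0 and abs(s1.mean() - s2.mean()) >= 0.5 * pooled:
                ok = False
                break
        if ok:
            return cal, val
    raise RuntimeError(f"no balanced split found in {max_tries} draws")
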