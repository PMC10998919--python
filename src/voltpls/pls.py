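"""Partial least squares regression (NIPALS) with leave-one-out validation.

Implements the multivariate calibration Y = X·B + E used to resolve
overlapping voltammetric signals into per-analyte concentrations: NIPALS
with deflation of both blocks, mean-centering only (features share current
units), leave-one-out cross-validated RMSECV curves, parsimonious
latent-variable selection, and the standard RMSEC/RMSEP/R²_pred metrics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSModel",
    "RmsecvCurve",
    "ValidationReport",
    "fit_pls",
    "loo_rmsecv",
    "predict",
    "prediction_metrics",
    "select_n_lv",
    "validation_metrics",
]

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500
# Deflated-block norm below this fraction of the initial norm counts as
# exhausted rank.
_RANK_EPS = 1e-12


def _as_2d(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


def _nipals(x: np.ndarray, y: np.ndarray, n_components: int):
    """Core NIPALS on pre-centered blocks; may stop early at exhausted rank.

    Initialization is deterministic: the Y-residual column of maximal
    variance.  Returns (W, P, Q, T, n_achieved).
    """
    x = x.copy()
    y = y.copy()
    n, p = x.shape
    q_dim = y.shape[1]
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((q_dim, n_components))
    T = np.zeros((n, n_components))
    x_norm0 = max(np.linalg.norm(x), 1.0)
    achieved = 0
    for a in range(n_components):
        if np.linalg.norm(x) <= _RANK_EPS * x_norm0:
            break
        u = y[:, int(np.argmax(y.var(axis=0)))].copy()
        if not np.any(u):
            break
        w = x.T @ u
        w_norm = np.linalg.norm(w)
        if w_norm == 0:
            break
        w /= w_norm
        for _ in range(_NIPALS_MAX_ITER):
            t = x @ w
            q_vec = y.T @ t / (t @ t)
            u = y @ q_vec / (q_vec @ q_vec)
            w_new = x.T @ u
            w_new /= np.linalg.norm(w_new)
            delta = np.linalg.norm(w_new - w)
            w = w_new
            if delta < _NIPALS_TOL:
                break
        t = x @ w
        tt = float(t @ t)
        if tt <= _RANK_EPS * x_norm0**2:
            break
        p_vec = x.T @ t / tt
        q_vec = y.T @ t / tt
        x -= np.outer(t, p_vec)
        y -= np.outer(t, q_vec)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_vec, q_vec, t
        achieved = a + 1
    return W[:, :achieved], P[:, :achieved], Q[:, :achieved], T[:, :achieved], achieved


def _coefficients(W: np.ndarray, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """B = W (PᵀW)⁻¹ Qᵀ, so that ŷ = (x − x̄)·B + ȳ."""
    return W @ np.linalg.solve(P.T @ W, Q.T)


@dataclass
class PLSModel:
    """Fitted PLS model: centering vectors, per-LV vectors and coefficients."""

    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray      # features × n_lv
    x_loadings: np.ndarray   # features × n_lv
    y_loadings: np.ndarray   # targets × n_lv
    x_scores: np.ndarray     # samples × n_lv
    coef: np.ndarray         # features × targets
    n_lv: int
    target_names: tuple[str, ...] | None = None

    def predict(self, x_new) -> np.ndarray:
        return predict(self, x_new)

    def to_json_dict(self) -> dict:
        return {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean.tolist(),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_scores": self.x_scores.tolist(),
            "coef": self.coef.tolist(),
            "n_lv": self.n_lv,
            "target_names": list(self.target_names) if self.target_names else None,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PLSModel":
        return cls(
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=np.asarray(d["y_mean"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            x_scores=np.asarray(d["x_scores"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            n_lv=int(d["n_lv"]),
            target_names=tuple(d["target_names"]) if d.get("target_names") else None,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh)

    @classmethod
    def load(cls, path) -> "PLSModel":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def fit_pls(x, y, n_lv: int, target_names=None) -> PLSModel:
    """Fit a NIPALS PLS model with ``n_lv`` latent variables.

    Both blocks are mean-centered (no variance scaling).  Requesting more
    components than ``min(samples − 1, features)`` — or more than the data
    can supply — is rejected with the attainable maximum.
    """
    x = _as_2d(x)
    y = _as_2d(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have matching rows")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("x and y must not contain missing values")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    attainable = min(x.shape[0] - 1, x.shape[1])
    if n_lv > attainable:
        raise ValueError(
            f"n_lv = {n_lv} exceeds the attainable maximum of {attainable} "
            f"for {x.shape[0]} samples × {x.shape[1]} features"
        )
    x_mean = x.mean(axis=0)
    y_mean = y.mean(axis=0)
    W, P, Q, T, achieved = _nipals(x - x_mean, y - y_mean, n_lv)
    if achieved < n_lv:
        raise ValueError(
            f"n_lv = {n_lv} exceeds the attainable maximum of {achieved} "
            "for this data (rank exhausted)"
        )
    coef = _coefficients(W, P, Q)
    return PLSModel(
        x_mean, y_mean, W, P, Q, T, coef, n_lv,
        tuple(target_names) if target_names is not None else None,
    )


def predict(model: PLSModel, x_new) -> np.ndarray:
    """ŷ = (x − x̄)·B + ȳ; negative predictions are reported as-is.

    A 1-D input is interpreted as a single sample (one feature row).
    """
    x_new = np.asarray(x_new, dtype=float)
    if x_new.ndim == 1:
        x_new = x_new[None, :]
    if x_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"feature count {x_new.shape[1]} does not match training "
            f"({model.x_mean.size})"
        )
    return (x_new - model.x_mean) @ model.coef + model.y_mean


def _rmse(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean((y_true - y_pred) ** 2, axis=0))


def _pool(per_target: np.ndarray) -> float:
    """Pool per-analyte errors in quadrature (root mean of squares)."""
    return float(np.sqrt(np.mean(np.asarray(per_target) ** 2)))


@dataclass
class RmsecvCurve:
    """Leave-one-out RMSECV as a function of latent-variable count."""

    per_target: np.ndarray          # n_lv × targets
    pooled: np.ndarray              # n_lv
    target_names: tuple[str, ...] | None = None


def loo_rmsecv(x, y, max_lv: int, target_names=None) -> RmsecvCurve:
    """Leave-one-out RMSECV for every LV count from 1 to ``max_lv``.

    Each sample is held out in turn, the model refit on the remainder, and
    the held-out prediction error accumulated.  ``max_lv`` beyond what n−1
    training samples support is truncated with a warning.  If deflation
    exhausts the rank of a training subset early, higher-LV predictions
    reuse the deepest attainable model (they cannot change further).
    """
    x = _as_2d(x)
    y = _as_2d(y)
    n, p = x.shape
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    limit = min(n - 2, p)
    if max_lv > limit:
        warnings.warn(
            f"max_lv = {max_lv} truncated to {limit} (leave-one-out refits "
            f"have only {n - 1} samples)",
            stacklevel=2,
        )
        max_lv = limit
    sq_err = np.zeros((max_lv, y.shape[1]))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        x_tr, y_tr = x[mask], y[mask]
        x_mean = x_tr.mean(axis=0)
        y_mean = y_tr.mean(axis=0)
        W, P, Q, _, achieved = _nipals(x_tr - x_mean, y_tr - y_mean, max_lv)
        for a in range(1, max_lv + 1):
            k = min(a, achieved)
            coef = _coefficients(W[:, :k], P[:, :k], Q[:, :k])
            pred = (x[i] - x_mean) @ coef + y_mean
            sq_err[a - 1] += (pred - y[i]) ** 2
    per_target = np.sqrt(sq_err / n)
    pooled = np.sqrt(np.mean(sq_err / n, axis=1))
    return RmsecvCurve(per_target, pooled,
                       tuple(target_names) if target_names is not None else None)


def select_n_lv(curve, rel_window: float = 0.02) -> int:
    """Smallest LV count whose pooled RMSECV is within 2% of the minimum."""
    pooled = curve.pooled if isinstance(curve, RmsecvCurve) else np.asarray(curve, float)
    if pooled.size == 0:
        raise ValueError("empty RMSECV curve")
    threshold = (1.0 + rel_window) * pooled.min()
    return int(np.argmax(pooled <= threshold)) + 1


def prediction_metrics(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    """Per-target (RMSE, R² = 1 − SS_res/SS_tot)."""
    y_true = _as_2d(y_true)
    y_pred = _as_2d(y_pred)
    rmse = _rmse(y_true, y_pred)
    ss_res = np.sum((y_true - y_pred) ** 2, axis=0)
    ss_tot = np.sum((y_true - y_true.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    return rmse, r2


@dataclass
class ValidationReport:
    """RMSEC / RMSECV / RMSEP / R²_pred per analyte for one fitted model."""

    n_lv: int
    rmsec: np.ndarray
    rmsep: np.ndarray | None = None
    r2_pred: np.ndarray | None = None
    rmsecv: np.ndarray | None = None
    rmsecv_curve: RmsecvCurve | None = None
    target_names: tuple[str, ...] | None = None

    def _named(self, values) -> dict:
        if values is None:
            return {}
        names = self.target_names or tuple(
            f"target{i}" for i in range(len(values))
        )
        return {n: float(v) for n, v in zip(names, values)}

    def to_dict(self) -> dict:
        out = {
            "n_lv": self.n_lv,
            "rmsec_uM": self._named(self.rmsec),
            "rmsec_pooled_uM": _pool(self.rmsec),
        }
        if self.rmsecv is not None:
            out["rmsecv_uM"] = self._named(self.rmsecv)
        if self.rmsecv_curve is not None:
            out["rmsecv_pooled_curve_uM"] = [float(v) for v in self.rmsecv_curve.pooled]
        if self.rmsep is not None:
            out["rmsep_uM"] = self._named(self.rmsep)
            out["rmsep_pooled_uM"] = _pool(self.rmsep)
            out["r2_pred"] = self._named(self.r2_pred)
        return out


def validation_metrics(
    model: PLSModel,
    x_train,
    y_train,
    x_test=None,
    y_test=None,
    rmsecv_curve: RmsecvCurve | None = None,
) -> ValidationReport:
    """RMSEC on the training set; RMSEP and R²_pred on the test set.

    With an empty/absent test set the prediction metrics are reported
    absent rather than zero.
    """
    y_train = _as_2d(y_train)
    rmsec, _ = prediction_metrics(y_train, predict(model, x_train))
    rmsep = r2_pred = None
    if x_test is not None and y_test is not None and _as_2d(y_test).shape[0] > 0:
        rmsep, r2_pred = prediction_metrics(_as_2d(y_test), predict(model, x_test))
    rmsecv = None
    if rmsecv_curve is not None:
        idx = min(model.n_lv, rmsecv_curve.pooled.size) - 1
        rmsecv = rmsecv_curve.per_target[idx]
    return ValidationReport(
        n_lv=model.n_lv,
        rmsec=rmsec,
        rmsep=rmsep,
        r2_pred=r2_pred,
        rmsecv=rmsecv,
        rmsecv_curve=rmsecv_curve,
        target_names=model.target_names,
    )
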