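"""Predictive assessment: r2, adjusted r2, Q2_LOO and Q2_LOSO.

Q2_LOO is the PRESS-based predictive R2 from leave-one-row-out
cross-validation:

    Q2_LOO = 1 - sum_l (y_l - yhat_{l,-l})^2 / sum_l (y_l - ybar)^2,

where yhat_{l,-l} is the prediction of row l from the model fitted
without row l and ybar is the mean of all used responses.  For least
squares the fold predictions follow from the hat-matrix identity
e_l / (1 - h_l) without refitting; a brute-force refit path exists and
the two agree to numerical precision (tested).

Q2_LOSO leaves out one *solute* at a time — every replicate, every
treatment cell — before predicting that solute's rows.  With replicates
present, LOO leaves the model nearly full knowledge of the held-out
solute (its siblings remain in the training fold), which inflates
Q2_LOO; LOSO is the honest measure of how the model predicts chemically
new solutes.  Duplicating every row leaves Q2_LOSO exactly unchanged
while pushing Q2_LOO toward r2 (property-tested).

Rows whose fold prediction is unavailable (leverage 1, or the row loads
on a coefficient inestimable from the training fold) are excluded from
numerator and denominator and counted in ``n_unpredictable``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ObservationSet
from .exceptions import EstimabilityError, UndefinedStatisticError
from .models import ModelSpec, build_design, fit_ols, lstsq_rank_revealing

__all__ = [
    "CVResult",
    "q2_loo",
    "q2_loso",
    "loo_predictions_matrix",
    "loso_predictions_matrix",
    "fit_statistics_table",
]

#: A fold is unpredictable when its leverage is this close to 1.
_LEVERAGE_TOL = 1e-8


@dataclass
class CVResult:
    """A cross-validated Q2 with bookkeeping of unusable folds."""

    q2: float
    n_used: int
    n_unpredictable: int
    per_solute_press: pd.Series | None = None


def loo_predictions_matrix(X: np.ndarray, y: np.ndarray,
                           method: str = "hat") -> np.ndarray:
    """Leave-one-row-out predictions for an arbitrary design matrix.

    ``method='hat'`` uses the closed-form identity
    yhat_{l,-l} = y_l - e_l / (1 - h_l); ``method='refit'`` refits n
    times (slow; kept as the independent check and as the fallback for
    degenerate folds).  Unpredictable folds are NaN.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if method == "hat":
        core = lstsq_rank_revealing(X, y)
        denom = 1.0 - core.leverage
        ok = denom > _LEVERAGE_TOL
        pred = np.full(len(y), np.nan)
        pred[ok] = y[ok] - core.resid[ok] / denom[ok]
        return pred
    if method != "refit":
        raise ValueError(f"unknown method {method!r}")
    pred = np.full(n, np.nan)
    idx = np.arange(n)
    for l in range(n):
        train = idx != l
        try:
            core = lstsq_rank_revealing(X[train], y[train])
        except EstimabilityError:
            continue
        x_l = X[l]
        if core.dropped.size and np.any(x_l[core.dropped] != 0):
            continue  # row needs a coefficient the fold cannot estimate
        pred[l] = x_l[core.retained] @ core.beta[core.retained]
    return pred


def loso_predictions_matrix(X: np.ndarray, y: np.ndarray,
                            groups: np.ndarray) -> np.ndarray:
    """Leave-one-group-out predictions (one genuine refit per group)."""
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    pred = np.full(len(y), np.nan)
    for g in pd.unique(groups):
        test = groups == g
        train = ~test
        try:
            core = lstsq_rank_revealing(X[train], y[train])
        except EstimabilityError:
            continue
        Xt = X[test]
        ok = np.ones(Xt.shape[0], dtype=bool)
        if core.dropped.size:
            ok &= ~(Xt[:, core.dropped] != 0).any(axis=1)
        p = Xt[:, core.retained] @ core.beta[core.retained]
        p[~ok] = np.nan
        pred[test] = p
    return pred


def _q2_from_predictions(y: np.ndarray, pred: np.ndarray,
                         groups: np.ndarray | None = None) -> CVResult:
    used = np.isfinite(pred)
    n_unpred = int((~used).sum())
    if used.sum() < 2:
        raise UndefinedStatisticError("fewer than 2 predictable rows")
    yu = y[used]
    ybar = yu.mean()
    denom = float(((yu - ybar) ** 2).sum())
    if denom <= 0:
        raise UndefinedStatisticError(
            "all used responses are identical; Q2 denominator is zero"
        )
    err2 = (y[used] - pred[used]) ** 2
    per_solute = None
    if groups is not None:
        per_solute = (
            pd.Series(err2, index=pd.Index(groups[used], name="solute_id"))
            .groupby(level=0).sum()
        )
    return CVResult(
        q2=1.0 - float(err2.sum()) / denom,
        n_used=int(used.sum()),
        n_unpredictable=n_unpred,
        per_solute_press=per_solute,
    )


def q2_loo(obs: ObservationSet, spec: ModelSpec, method: str = "hat") -> CVResult:
    """Leave-one-row-out Q2 for one LFER variant on one dataset."""
    design = build_design(obs, spec)
    y = obs.data["log_k"].to_numpy(dtype=float)
    pred = loo_predictions_matrix(design.matrix, y, method=method)
    return _q2_from_predictions(y, pred)


def q2_loso(obs: ObservationSet, spec: ModelSpec) -> CVResult:
    """Leave-one-solute-out Q2 (replicate-aware; one refit per solute)."""
    design = build_design(obs, spec)
    y = obs.data["log_k"].to_numpy(dtype=float)
    groups = obs.data["solute_id"].to_numpy()
    pred = loso_predictions_matrix(design.matrix, y, groups)
    return _q2_from_predictions(y, pred, groups=groups)


def fit_statistics_table(obs: ObservationSet,
                         variants: tuple[str, ...] = ("single", "crossed", "nested"),
                         ) -> pd.DataFrame:
    """One row of fit statistics per LFER variant.

    Columns: r2, adj_r2, q2_loo, q2_loso plus the counts of rows whose
    cross-validated prediction was unavailable.
    """
    rows = []
    y = obs.data["log_k"].to_numpy(dtype=float)
    for variant in variants:
        spec = ModelSpec(variant=variant)
        design = build_design(obs, spec)
        fit = fit_ols(design, y)
        loo = q2_loo(obs, spec)
        loso = q2_loso(obs, spec)
        rows.append({
            "model": variant,
            "r2": fit.r2,
            "adj_r2": fit.adj_r2,
            "q2_loo": loo.q2,
            "q2_loso": loso.q2,
            "n_unpredictable_loo": loo.n_unpredictable,
            "n_unpredictable_loso": loso.n_unpredictable,
        })
    return pd.DataFrame(rows).set_index("model")
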