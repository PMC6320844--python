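"""Design matrices and OLS fits for the three LFER variants.

An LFER (linear free-energy relationship) regresses log10 K on the five
Abraham descriptors E, S, A, B, V.  Three variants are supported:

``single``
    One coefficient block: log K = b0 + b1 E + b2 S + b3 A + b4 B + b5 V.
``crossed``
    Cell-means expansion over the full (MWF, MWF conc, solute conc)
    factorial: an independent 6-coefficient block per treatment cell,
    up to 90 x 6 = 540 columns.  Dummy products activate exactly one
    block per observation.
``nested``
    Solute concentration treated as a numeric regressor nested within
    (MWF, MWF conc): an independent 7-coefficient block — intercept,
    E, S, A, B, V, and t = log10(solute concentration) — per (MWF,
    MWF conc) cell, up to 15 x 7 = 105 columns.

Cell-means coding is used throughout: a full block per cell, no shared
intercept, no reference level, so every coefficient is that cell's own
partial slope rather than an offset.  Blocks are row-disjoint, hence
the cross-product matrix is block-diagonal and joint estimates coincide
with independent per-cell fits (property-tested against that oracle).

Rank deficiency (e.g. a cell whose solutes all share A = 0) is handled
by a rank-revealing pivoted QR with relative tolerance 1e-10; dropped
columns are reported, never silently imputed.  Standard errors use the
fit's pooled residual variance; confidence intervals use Student-t
quantiles at the residual degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .data import DESCRIPTOR_NAMES, ObservationSet, cell_sort_key
from .exceptions import EstimabilityError

__all__ = [
    "ModelSpec",
    "ColumnInfo",
    "DesignMatrix",
    "FitResult",
    "build_design",
    "fit_ols",
    "fit_per_cell",
    "predict",
    "lstsq_rank_revealing",
]

#: Default relative tolerance for declaring a design column collinear.
RANK_RTOL = 1e-10


@dataclass(frozen=True)
class ModelSpec:
    """Which LFER variant to fit, with which descriptors and CI level."""

    variant: str = "nested"
    descriptors: tuple[str, ...] = DESCRIPTOR_NAMES
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.variant not in ("single", "crossed", "nested"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class ColumnInfo:
    """One design column: a descriptor ('intercept', 'E', ..., 'V', 't')
    and the treatment cell it belongs to (None for the single variant;
    (mwf, mwf_conc) for nested; (mwf, mwf_conc, solute_conc) for crossed)."""

    descriptor: str
    cell: tuple | None = None

    def label(self) -> str:
        if self.cell is None:
            return self.descriptor
        return "/".join(f"{c:g}" if isinstance(c, float) else str(c) for c in self.cell) \
            + f":{self.descriptor}"


@dataclass
class DesignMatrix:
    """Numeric design matrix with per-column and per-row metadata."""

    matrix: np.ndarray
    columns: tuple[ColumnInfo, ...]
    row_meta: pd.DataFrame
    spec: ModelSpec

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def cells(self) -> list[tuple]:
        out, seen = [], set()
        for c in self.columns:
            if c.cell is not None and c.cell not in seen:
                seen.add(c.cell)
                out.append(c.cell)
        return out

    def without_descriptor(self, descriptor: str) -> "DesignMatrix":
        """Copy of the design with every column of one descriptor removed
        (used to build the reduced model of the partition-theory F test)."""
        keep = [i for i, c in enumerate(self.columns) if c.descriptor != descriptor]
        return DesignMatrix(
            matrix=self.matrix[:, keep],
            columns=tuple(self.columns[i] for i in keep),
            row_meta=self.row_meta,
            spec=self.spec,
        )

    def row_cells(self) -> list[tuple | None]:
        """The active cell of each row under this variant."""
        if self.spec.variant == "single":
            return [None] * len(self.row_meta)
        if self.spec.variant == "nested":
            return [
                (r.mwf, r.mwf_conc) for r in self.row_meta.itertuples(index=False)
            ]
        return [
            (r.mwf, r.mwf_conc, r.solute_conc)
            for r in self.row_meta.itertuples(index=False)
        ]


def build_design(obs: ObservationSet, spec: ModelSpec) -> DesignMatrix:
    """Assemble the design matrix for one LFER variant.

    Only populated cells contribute columns; each observation has
    nonzero entries in exactly one block, with the block intercept
    exactly 1.
    """
    if len(obs) == 0:
        raise ValueError("cannot build a design from an empty ObservationSet")
    merged = obs.merged()
    n = len(merged)
    base_cols = ("intercept",) + spec.descriptors
    base = np.column_stack(
        [np.ones(n)] + [merged[d].to_numpy(dtype=float) for d in spec.descriptors]
    )
    if spec.variant == "single":
        columns = tuple(ColumnInfo(d) for d in base_cols)
        return DesignMatrix(base, columns, _row_meta(merged), spec)

    if spec.variant == "nested":
        base = np.column_stack([base, merged["t"].to_numpy(dtype=float)])
        base_cols = base_cols + ("t",)
        cell_of_row = list(zip(merged["mwf"], merged["mwf_conc"]))
    else:  # crossed
        cell_of_row = list(zip(merged["mwf"], merged["mwf_conc"], merged["solute_conc"]))

    cells = sorted(set(cell_of_row), key=cell_sort_key)
    block = {c: i for i, c in enumerate(cells)}
    b = len(base_cols)
    X = np.zeros((n, b * len(cells)))
    idx = np.array([block[c] for c in cell_of_row])
    rows = np.arange(n)
    for d in range(b):
        X[rows, idx * b + d] = base[:, d]
    columns = tuple(
        ColumnInfo(d, cell) for cell in cells for d in base_cols
    )
    return DesignMatrix(X, columns, _row_meta(merged), spec)


def _row_meta(merged: pd.DataFrame) -> pd.DataFrame:
    return merged[
        ["solute_id", "mwf", "mwf_conc", "solute_conc", "replicate"]
    ].reset_index(drop=True)


def lstsq_rank_revealing(X: np.ndarray, y: np.ndarray, rtol: float = RANK_RTOL):
    """Least squares via pivoted QR with rank-revealing column dropping.

    Returns a namespace with: ``beta`` (length-p, NaN at dropped
    columns), ``retained``/``dropped`` (original column indices),
    ``fitted``, ``resid``, ``sse``, ``df_resid``, ``cov_diag`` (unscaled
    (X'X)^-1 diagonal, NaN at dropped), ``leverage`` (hat diagonal) and
    ``rank``.  Raises :class:`EstimabilityError` when no residual degree
    of freedom remains.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    Q, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    rdiag = np.abs(np.diag(R))
    rank = int(np.sum(rdiag > rtol * rdiag[0])) if rdiag.size and rdiag[0] > 0 else 0
    if rank == 0:
        raise EstimabilityError("design matrix has rank 0")
    if n - rank < 1:
        raise EstimabilityError(
            f"no residual degrees of freedom: {n} rows for rank {rank}"
        )
    R1 = R[:rank, :rank]
    qty = Q.T @ y
    beta_r = scipy.linalg.solve_triangular(R1, qty[:rank])
    fitted = Q[:, :rank] @ qty[:rank]
    resid = y - fitted
    sse = float(resid @ resid)
    R1inv = scipy.linalg.solve_triangular(R1, np.eye(rank))
    cov_r = np.einsum("ij,kj->ik", R1inv, R1inv)  # (X_r'X_r)^-1 in pivot order
    retained = piv[:rank]
    dropped = piv[rank:]
    beta = np.full(p, np.nan)
    beta[retained] = beta_r
    cov_diag = np.full(p, np.nan)
    cov_diag[retained] = np.diag(cov_r)
    leverage = np.einsum("ij,ij->i", Q[:, :rank], Q[:, :rank])
    return SimpleNamespace(
        beta=beta, retained=retained, dropped=dropped, fitted=fitted,
        resid=resid, sse=sse, df_resid=n - rank, cov_diag=cov_diag,
        leverage=leverage, rank=rank,
    )


@dataclass
class FitResult:
    """An OLS fit of one LFER design.

    Coefficient arrays are aligned with ``columns``; entries for columns
    dropped as collinear are NaN and also listed in ``dropped_columns``.
    ``sigma2`` is the pooled residual variance of this (single) fit.
    """

    spec: ModelSpec
    columns: tuple[ColumnInfo, ...]
    coef: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    dropped_columns: tuple[ColumnInfo, ...]
    retained_idx: np.ndarray
    sigma2: float
    sse: float
    df_resid: int
    nobs: int
    r2: float
    adj_r2: float
    residuals: np.ndarray = field(repr=False, default=None)
    leverage: np.ndarray = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)

    def coef_table(self) -> pd.DataFrame:
        """Tidy coefficient table: cell, descriptor, estimate, se, ci."""
        cells = [
            "" if c.cell is None
            else "/".join(f"{v:g}" if isinstance(v, float) else str(v) for v in c.cell)
            for c in self.columns
        ]
        return pd.DataFrame({
            "cell": cells,
            "descriptor": [c.descriptor for c in self.columns],
            "estimate": self.coef,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        })

    def get(self, descriptor: str, cell: tuple | None = None) -> dict:
        """Estimate/se/ci for one column, looked up by metadata."""
        target = ColumnInfo(descriptor, cell)
        for i, c in enumerate(self.columns):
            if c == target:
                return {
                    "estimate": self.coef[i], "se": self.se[i],
                    "ci_low": self.ci_low[i], "ci_high": self.ci_high[i],
                }
        raise KeyError(f"no column {target}")


def fit_ols(design: DesignMatrix, response: np.ndarray,
            ci_level: float | None = None, rtol: float = RANK_RTOL) -> FitResult:
    """Fit one LFER design by ordinary least squares.

    r2 is computed about the grand mean of the response, so it is
    comparable across variants even though the cell-means designs carry
    no global intercept.
    """
    y = np.asarray(response, dtype=float)
    if ci_level is None:
        ci_level = design.spec.ci_level
    core = lstsq_rank_revealing(design.matrix, y, rtol=rtol)
    sigma2 = core.sse / core.df_resid
    se = np.sqrt(sigma2 * core.cov_diag)
    tcrit = stats.t.ppf(0.5 + ci_level / 2, core.df_resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - core.sse / tss if tss > 0 else np.nan
    n = len(y)
    adj_r2 = (
        1.0 - (1.0 - r2) * (n - 1) / core.df_resid if tss > 0 else np.nan
    )
    return FitResult(
        spec=design.spec,
        columns=design.columns,
        coef=core.beta,
        se=se,
        ci_low=core.beta - tcrit * se,
        ci_high=core.beta + tcrit * se,
        dropped_columns=tuple(design.columns[i] for i in sorted(core.dropped)),
        retained_idx=np.sort(core.retained),
        sigma2=sigma2,
        sse=core.sse,
        df_resid=core.df_resid,
        nobs=n,
        r2=r2,
        adj_r2=adj_r2,
        residuals=core.resid,
        leverage=core.leverage,
        fitted=core.fitted,
    )


@dataclass
class PerCellFits:
    """Separate single-LFER fits for each treatment cell (each with its
    own residual variance), plus the cells skipped and why."""

    fits: dict[tuple, FitResult]
    skipped: list[tuple[tuple, str]]


def fit_per_cell(obs: ObservationSet, ci_level: float = 0.95,
                 min_rows: int = 7) -> PerCellFits:
    """Fit the single LFER separately within every populated cell.

    A cell needs at least ``min_rows`` rows (6 parameters + 1 residual
    df by default); under-populated or inestimable cells are skipped
    with a reason rather than raising.
    """
    spec = ModelSpec(variant="single", ci_level=ci_level)
    fits: dict[tuple, FitResult] = {}
    skipped: list[tuple[tuple, str]] = []
    df = obs.data
    for cell in obs.cells():
        mask = (
            (df["mwf"] == cell[0])
            & (df["mwf_conc"] == cell[1])
            & (df["solute_conc"] == cell[2])
        )
        sub = obs.subset(mask.to_numpy())
        if len(sub) < min_rows:
            skipped.append((cell, f"insufficient df ({len(sub)} rows < {min_rows})"))
            continue
        design = build_design(sub, spec)
        try:
            fits[cell] = fit_ols(design, sub.data["log_k"].to_numpy())
        except EstimabilityError as err:
            skipped.append((cell, f"inestimable: {err}"))
    return PerCellFits(fits=fits, skipped=skipped)


def predict(fit: FitResult, new_obs: ObservationSet) -> np.ndarray:
    """Predicted log K for new rows under a fitted model.

    A prediction is NaN (flagged absent) when the row's treatment cell
    has no block in the fit, or the row loads on a column that was
    dropped for collinearity during training — in either case the
    required coefficient is inestimable from the training data.
    """
    nd = build_design(new_obs, fit.spec)
    pos = {c: i for i, c in enumerate(fit.columns)}
    n_new = nd.matrix.shape[0]
    X = np.zeros((n_new, len(fit.columns)))
    absent = np.zeros(n_new, dtype=bool)
    for j, col in enumerate(nd.columns):
        i = pos.get(col)
        if i is None:
            absent |= nd.matrix[:, j] != 0
        else:
            X[:, i] = nd.matrix[:, j]
    dropped_idx = [pos[c] for c in fit.dropped_columns]
    if dropped_idx:
        absent |= (X[:, dropped_idx] != 0).any(axis=1)
    ret = fit.retained_idx
    yhat = X[:, ret] @ fit.coef[ret]
    yhat[absent] = np.nan
    return yhat
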