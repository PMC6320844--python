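"""Hypothesis battery for the partition theory.

The partition theory holds that K_MCF/mix does not depend on the
starting solute concentration.  Under the nested LFER (an independent
block per (MWF, MWF concentration) cell with a slope b6_ij on
t = log10 solute concentration) the theory is exactly the null

    H0: b6_ij = 0 for all i = 1..5, j = 1..3.

Three views are provided:

* a global extra-sum-of-squares F test of the nested model against the
  reduced model with every t column removed;
* per-cell t tests of each b6_ij from the pooled single-model fit,
  Bonferroni-corrected at alpha/15 (the divisor stays at the design's
  15 cells by default even when some cells are inestimable; an option
  divides by the number actually tested);
* the same pair of tests repeated on subsets of solute concentrations,
  emitting one report row per subset in the shape
  "subset | global p | supporting cells (n) | violating cells (n)".

Per-cell tests come from the pooled fit, not per-cell refits, because
the hypothesis is stated on the single nested model (recorded in the
output metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import MWF_CONC_LEVELS, MWF_LEVELS, ObservationSet
from .exceptions import DegenerateTestError, ValidationError
from .models import ColumnInfo, ModelSpec, build_design, fit_ols

__all__ = [
    "CellTestResult",
    "TheoryTestReport",
    "test_global",
    "test_per_cell",
    "test_partition_theory",
    "subset_analysis",
    "DEFAULT_SUBSETS",
    "report_table",
]

#: Solute-concentration subsets examined by default (ppm); None = all six.
DEFAULT_SUBSETS: tuple[tuple[float, ...] | None, ...] = (
    None,
    (0.01, 0.05, 0.1, 0.5, 1.0),
    (0.01, 0.05, 0.1, 0.5),
    (0.01, 0.05, 0.1),
    (0.05, 0.1, 0.5),
    (0.01, 0.05),
    (0.05, 0.1),
)

#: Cells in the full design, hence the default Bonferroni divisor (15).
N_DESIGN_CELLS = len(MWF_LEVELS) * len(MWF_CONC_LEVELS)


@dataclass(frozen=True)
class CellTestResult:
    """t test of b6_ij = 0 for one (MWF, MWF concentration) cell."""

    cell: tuple[str, float]
    n_obs: int
    estimate: float
    se: float
    t_stat: float
    p_value: float
    significant: bool
    estimable: bool = True
    reason: str = ""

    def label(self) -> str:
        return f"{self.cell[0]}/{self.cell[1]:g}"


@dataclass
class TheoryTestReport:
    """Joint report of the global F test and the per-cell t tests."""

    subset: tuple[float, ...] | None
    global_f: float | None
    global_df: tuple[int, int] | None
    global_p: float | None
    per_cell: list[CellTestResult] = field(default_factory=list)
    alpha: float = 0.05
    n_cells_tested: int = N_DESIGN_CELLS
    notes: str = "per-cell t tests from the pooled nested-model fit"

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_cells_tested

    def insignificant_cells(self) -> list[tuple[str, int]]:
        """Cells supporting the partition theory (p >= alpha/divisor)."""
        return [
            (c.label(), c.n_obs)
            for c in self.per_cell if c.estimable and not c.significant
        ]

    def significant_cells(self) -> list[tuple[str, int]]:
        """Cells violating the partition theory (p < alpha/divisor)."""
        return [
            (c.label(), c.n_obs)
            for c in self.per_cell if c.estimable and c.significant
        ]


def _nested_fit(obs: ObservationSet):
    spec = ModelSpec(variant="nested")
    design = build_design(obs, spec)
    y = obs.data["log_k"].to_numpy(dtype=float)
    return design, y, fit_ols(design, y)


def test_global(obs: ObservationSet, alpha: float = 0.05) -> TheoryTestReport:
    """Extra-sum-of-squares F test of all solute-concentration slopes.

    Full model: the nested LFER.  Reduced model: the same design with
    every t column removed.  The numerator df is the number of t
    columns actually estimable in the full fit.
    """
    design, y, fit_full = _nested_fit(obs)
    n_t_retained = sum(
        1 for i in fit_full.retained_idx if design.columns[i].descriptor == "t"
    )
    if n_t_retained == 0:
        raise DegenerateTestError(
            "no estimable solute-concentration column: full and reduced "
            "models coincide (single concentration level per cell?)"
        )
    reduced = design.without_descriptor("t")
    fit_red = fit_ols(reduced, y)
    q = n_t_retained
    f_stat = ((fit_red.sse - fit_full.sse) / q) / (fit_full.sse / fit_full.df_resid)
    p = float(stats.f.sf(f_stat, q, fit_full.df_resid))
    return TheoryTestReport(
        subset=None,
        global_f=float(f_stat),
        global_df=(q, fit_full.df_resid),
        global_p=p,
        alpha=alpha,
    )


def test_per_cell(obs: ObservationSet, alpha: float = 0.05,
                  bonferroni: str = "fixed") -> TheoryTestReport:
    """t tests of each b6_ij from the pooled nested fit.

    ``bonferroni='fixed'`` divides alpha by the design's 15 cells (the
    conventional choice even if some cells are inestimable);
    ``'tested'`` divides by the number of cells actually tested.
    """
    if bonferroni not in ("fixed", "tested"):
        raise ValueError("bonferroni must be 'fixed' or 'tested'")
    design, y, fit = _nested_fit(obs)
    counts = design.row_meta.groupby(["mwf", "mwf_conc"]).size()
    cells = [c for c in design.cells()]
    retained = set(fit.retained_idx)
    col_pos = {c: i for i, c in enumerate(fit.columns)}
    raw = []
    for cell in cells:
        i = col_pos.get(ColumnInfo("t", cell))
        n_obs = int(counts.loc[cell])
        if i is None or i not in retained:
            raw.append((cell, n_obs, None))
            continue
        t_stat = fit.coef[i] / fit.se[i]
        p = 2.0 * float(stats.t.sf(abs(t_stat), fit.df_resid))
        raw.append((cell, n_obs, (fit.coef[i], fit.se[i], t_stat, p)))
    n_tested = sum(1 for _, _, r in raw if r is not None)
    divisor = N_DESIGN_CELLS if bonferroni == "fixed" else n_tested
    per_cell = []
    for cell, n_obs, r in raw:
        if r is None:
            per_cell.append(CellTestResult(
                cell=cell, n_obs=n_obs, estimate=np.nan, se=np.nan,
                t_stat=np.nan, p_value=np.nan, significant=False,
                estimable=False,
                reason="t column inestimable (constant within cell)",
            ))
        else:
            est, se, t_stat, p = r
            per_cell.append(CellTestResult(
                cell=cell, n_obs=n_obs, estimate=float(est), se=float(se),
                t_stat=float(t_stat), p_value=p,
                significant=p < alpha / divisor,
            ))
    return TheoryTestReport(
        subset=None, global_f=None, global_df=None, global_p=None,
        per_cell=per_cell, alpha=alpha, n_cells_tested=divisor,
    )


def test_partition_theory(obs: ObservationSet, alpha: float = 0.05,
                          bonferroni: str = "fixed") -> TheoryTestReport:
    """Global F test and per-cell t tests combined into one report."""
    g = test_global(obs, alpha=alpha)
    c = test_per_cell(obs, alpha=alpha, bonferroni=bonferroni)
    c.global_f, c.global_df, c.global_p = g.global_f, g.global_df, g.global_p
    return c


def subset_analysis(obs: ObservationSet,
                    subsets: tuple[tuple[float, ...] | None, ...] = DEFAULT_SUBSETS,
                    alpha: float = 0.05,
                    bonferroni: str = "fixed") -> list[TheoryTestReport]:
    """Repeat the partition-theory tests on solute-concentration subsets.

    Each subset must span at least two distinct concentration levels,
    otherwise the slope on t is inestimable in every cell and the
    subset is rejected.
    """
    reports = []
    for subset in subsets:
        if subset is not None and len(set(subset)) < 2:
            raise ValidationError(
                f"subset {subset} has fewer than 2 distinct solute "
                "concentrations; the concentration slope is inestimable"
            )
        if subset is None:
            sub = obs
        else:
            mask = obs.data["solute_conc"].isin(subset).to_numpy()
            sub = obs.subset(mask)
        report = test_partition_theory(sub, alpha=alpha, bonferroni=bonferroni)
        report.subset = subset
        reports.append(report)
    return reports


def _fmt_cells(cells: list[tuple[str, int]]) -> str:
    return "; ".join(f"{label}({n})" for label, n in cells)


def report_table(reports: list[TheoryTestReport]) -> pd.DataFrame:
    """Tabulate subset reports: one row per subset with the global
    p-value and the supporting/violating cells (with their n)."""
    rows = []
    for r in reports:
        subset = "all" if r.subset is None else ", ".join(f"{c:g}" for c in r.subset)
        rows.append({
            "subset": subset,
            "global_p": r.global_p,
            "insignificant_cells": _fmt_cells(r.insignificant_cells()),
            "significant_cells": _fmt_cells(r.significant_cells()),
            "bonferroni_threshold": r.threshold,
        })
    return pd.DataFrame(rows)
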