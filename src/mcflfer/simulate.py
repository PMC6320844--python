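"""Synthetic observation sets with the study's statistical structure.

The raw measurements behind the analysis are not public, so every
pipeline stage is exercised on generated data that emulates the study
design: 37 solutes (the packaged descriptor set) x 90 treatment cells
(5 MWFs x 3 MWF concentrations x 6 solute concentrations) x up to 3
replicates, with independent missing-completely-at-random dropout
calibrated so that the default retention (1 - 0.535 = 0.465) matches
the observed 4646 of 9990 possible rows.

Responses come from the nested LFER as the generating model: for a row
of solute l in cell (i, j) at log concentration t,

    log K = b0_ij + b1_ij E_l + ... + b5_ij V_l + b6_ij t + eps,
    eps ~ Normal(0, noise_sd^2).

The default coefficient table is a fixed, versioned choice with the
qualitative sign structure the analysis is designed to detect: positive
volume (V) slopes, negative acidity/basicity (A, B) slopes, an E slope
that changes sign across mineral-oil concentrations, and concentration
slopes b6 that are negative everywhere except exactly three null cells
(MO/0.05, PEG/5, SYN/0.05).  A crossed-factors generator is available
for robustness studies.

Noise is applied on the log10 scale only; concentrations are noise-free
on the exact study grid.  noise_sd defaults to 0.25 log10 units — a
calibration choice giving within-cell scatter small relative to the
between-solute spread, not an estimate from the original study.
Identical (config, seed) pairs produce byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    DESCRIPTOR_NAMES,
    MWF_CONC_LEVELS,
    MWF_LEVELS,
    SOLUTE_CONC_LEVELS,
    ObservationSet,
    load_solute_table,
)
from .exceptions import ConfigError
from .models import ColumnInfo, ModelSpec, build_design, fit_ols

__all__ = [
    "GeneratorConfig",
    "GeneratorTruth",
    "default_truth",
    "default_config",
    "crossed_truth_from_nested",
    "generate",
    "recovery_study",
]

_BETA_COLS = tuple(f"beta{d}" for d in range(7))
#: Maps a design-column descriptor to its generating coefficient.
_COEF_OF_DESCRIPTOR = {
    "intercept": "beta0", "E": "beta1", "S": "beta2", "A": "beta3",
    "B": "beta4", "V": "beta5", "t": "beta6",
}

# One row per (MWF, MWF concentration) cell: beta0..beta5 for the
# intercept and E, S, A, B, V, and beta6 for t = log10(solute conc).
# Fixed by design: b6 = 0 in exactly MO/0.05, PEG/5 and SYN/0.05.
_DEFAULT_TRUTH_ROWS = [
    # mwf, mwf_conc, b0,   b1(E), b2(S), b3(A), b4(B), b5(V), b6(t)
    ("MO",   0.05, 0.2,  1.5, -1.6, -1.9, -0.5, 1.6,  0.0),
    ("MO",   0.5,  0.4,  0.3, -1.0, -1.4, -1.2, 2.0, -0.30),
    ("MO",   5.0,  0.6, -0.9, -0.4, -0.9, -2.0, 2.4, -0.50),
    ("PEG",  0.05, 0.5,  0.8, -0.8, -1.0, -0.9, 1.8, -0.25),
    ("PEG",  0.5,  0.7,  0.5, -0.8, -1.0, -1.0, 1.7, -0.20),
    ("PEG",  5.0,  0.9,  0.2, -0.7, -0.9, -1.1, 1.6,  0.0),
    ("SO",   0.05, 0.3,  0.6, -1.4, -1.8, -1.0, 2.4, -0.20),
    ("SO",   0.5,  0.6,  0.2, -0.9, -1.2, -1.0, 1.8, -0.35),
    ("SO",   5.0,  1.0, -0.1, -0.3, -0.6, -1.0, 1.2, -0.50),
    ("SYN",  0.05, 0.4,  0.7, -0.9, -1.2, -0.8, 2.2,  0.0),
    ("SYN",  0.5,  0.8,  0.4, -0.9, -1.1, -0.9, 1.6, -0.25),
    ("SYN",  5.0,  1.2,  0.1, -0.8, -1.0, -1.0, 1.0, -0.30),
    ("SSYN", 0.05, 0.5,  0.9, -1.5, -1.3, -0.9, 2.3, -0.20),
    ("SSYN", 0.5,  0.9,  0.5, -1.0, -1.1, -1.0, 1.7, -0.25),
    ("SSYN", 5.0,  1.3,  0.0, -0.5, -0.9, -1.1, 1.1, -0.35),
]


def default_truth() -> pd.DataFrame:
    """The versioned default nested-model coefficient table."""
    return pd.DataFrame(
        _DEFAULT_TRUTH_ROWS, columns=["mwf", "mwf_conc", *_BETA_COLS]
    )


@dataclass
class GeneratorConfig:
    """Inputs for one synthetic-data generation run.

    ``coefficients`` is keyed by (mwf, mwf_conc) with columns
    beta0..beta6 for the nested generating model, or by
    (mwf, mwf_conc, solute_conc) with beta0..beta5 when
    ``variant='crossed'``.  ``dropout`` is the probability each
    replicate is missing (independent Bernoulli per row).
    """

    seed: int
    coefficients: pd.DataFrame = field(default_factory=default_truth)
    solute_ids: tuple[int, ...] | None = None  # None = all in descriptor table
    mwfs: tuple[str, ...] = MWF_LEVELS
    mwf_concs: tuple[float, ...] = MWF_CONC_LEVELS
    solute_concs: tuple[float, ...] = SOLUTE_CONC_LEVELS
    replicates: int = 3
    noise_sd: float = 0.25
    dropout: float = 0.535
    variant: str = "nested"
    descriptors: pd.DataFrame | None = None  # None = packaged fixture

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is required; silent nondeterminism is not")
        if not 0 <= self.dropout < 1:
            raise ConfigError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.replicates < 1:
            raise ConfigError("need at least 1 replicate")
        if self.variant not in ("nested", "crossed"):
            raise ConfigError(f"unknown generator variant {self.variant!r}")


@dataclass
class GeneratorTruth:
    """What actually generated a dataset: coefficients, seed, counts."""

    coefficients: pd.DataFrame
    seed: int
    variant: str
    noise_sd: float
    dropout: float
    n_rows: int
    cell_counts: pd.Series


def default_config(seed: int, **overrides) -> GeneratorConfig:
    """The study-defaults configuration with field overrides."""
    return GeneratorConfig(seed=seed, **overrides)


def crossed_truth_from_nested(nested: pd.DataFrame,
                              solute_concs: tuple[float, ...] = SOLUTE_CONC_LEVELS,
                              ) -> pd.DataFrame:
    """Expand a nested coefficient table to per-(i,j,k) crossed blocks.

    The crossed intercept absorbs the concentration effect:
    beta0_ijk = beta0_ij + beta6_ij * log10(conc_k); slopes are copied.
    Perturb the result to study genuinely crossed data.
    """
    rows = []
    for r in nested.itertuples(index=False):
        for conc in solute_concs:
            rows.append({
                "mwf": r.mwf, "mwf_conc": r.mwf_conc, "solute_conc": conc,
                "beta0": r.beta0 + r.beta6 * np.log10(conc),
                "beta1": r.beta1, "beta2": r.beta2, "beta3": r.beta3,
                "beta4": r.beta4, "beta5": r.beta5,
            })
    return pd.DataFrame(rows)


def _check_coefficients(config: GeneratorConfig) -> pd.DataFrame:
    coef = config.coefficients
    if config.variant == "nested":
        key = ["mwf", "mwf_conc"]
        needed = {(m, c) for m in config.mwfs for c in config.mwf_concs}
        cols = list(_BETA_COLS)
    else:
        key = ["mwf", "mwf_conc", "solute_conc"]
        needed = {
            (m, c, s)
            for m in config.mwfs for c in config.mwf_concs
            for s in config.solute_concs
        }
        cols = list(_BETA_COLS[:6])
    missing_cols = [c for c in key + cols if c not in coef.columns]
    if missing_cols:
        raise ConfigError(f"coefficient table missing column(s): {missing_cols}")
    have = {tuple(r) for r in coef[key].itertuples(index=False)}
    missing = needed - have
    if missing:
        raise ConfigError(f"coefficient table missing cell(s): {sorted(missing)[:5]}...")
    return coef[key + cols]


def generate(config: GeneratorConfig) -> tuple[ObservationSet, GeneratorTruth]:
    """Draw one synthetic observation set.

    Builds the full (solute x cell x replicate) grid, applies
    independent dropout, evaluates the generating model's mean from the
    descriptor table, and adds Gaussian noise on the log10 scale.
    """
    coef = _check_coefficients(config)
    descriptors = (
        load_solute_table() if config.descriptors is None else config.descriptors
    )
    if config.solute_ids is None:
        solutes = tuple(int(s) for s in descriptors["solute_id"])
    else:
        solutes = tuple(config.solute_ids)
        known = set(descriptors["solute_id"])
        if not set(solutes) <= known:
            raise ConfigError(f"solute_ids without descriptors: {sorted(set(solutes) - known)}")

    grid = pd.MultiIndex.from_product(
        [solutes, config.mwfs, config.mwf_concs, config.solute_concs,
         range(1, config.replicates + 1)],
        names=["solute_id", "mwf", "mwf_conc", "solute_conc", "replicate"],
    ).to_frame(index=False)

    rng = np.random.default_rng(config.seed)
    keep = rng.random(len(grid)) >= config.dropout
    df = grid.loc[keep].reset_index(drop=True)
    df["t"] = np.log10(df["solute_conc"].to_numpy(dtype=float))

    merge_key = ["mwf", "mwf_conc"] if config.variant == "nested" else \
        ["mwf", "mwf_conc", "solute_conc"]
    df = df.merge(coef, on=merge_key, how="left", validate="m:1")
    df = df.merge(
        descriptors[["solute_id", *DESCRIPTOR_NAMES]], on="solute_id",
        how="left", validate="m:1",
    )
    mean = (
        df["beta0"]
        + df["beta1"] * df["E"] + df["beta2"] * df["S"] + df["beta3"] * df["A"]
        + df["beta4"] * df["B"] + df["beta5"] * df["V"]
    )
    if config.variant == "nested":
        mean = mean + df["beta6"] * df["t"]
    noise = rng.normal(0.0, config.noise_sd, len(df)) if config.noise_sd > 0 \
        else np.zeros(len(df))
    df["log_k"] = mean.to_numpy() + noise

    data = df[
        ["solute_id", "mwf", "mwf_conc", "solute_conc", "t", "replicate", "log_k"]
    ].copy()
    obs = ObservationSet(data=data, descriptors=descriptors)
    cell_counts = data.groupby(["mwf", "mwf_conc", "solute_conc"]).size()
    truth = GeneratorTruth(
        coefficients=config.coefficients.copy(),
        seed=config.seed,
        variant=config.variant,
        noise_sd=config.noise_sd,
        dropout=config.dropout,
        n_rows=len(data),
        cell_counts=cell_counts,
    )
    return obs, truth


def true_coefficient(truth_table: pd.DataFrame, col: ColumnInfo) -> float:
    """Generating value for one nested-design column."""
    beta = _COEF_OF_DESCRIPTOR[col.descriptor]
    mwf, mwf_conc = col.cell
    row = truth_table[
        (truth_table["mwf"] == mwf) & (truth_table["mwf_conc"] == mwf_conc)
    ]
    return float(row[beta].iloc[0])


def recovery_study(config: GeneratorConfig, n_reps: int,
                   ci_level: float = 0.95) -> pd.DataFrame:
    """Repeated generate -> fit cycles for the nested model.

    Returns one row per (cell, descriptor) coefficient with the
    generating value, mean estimate, bias, RMSE, and the empirical
    coverage of the ``ci_level`` confidence intervals across the
    replications where the coefficient was estimable.

    Replication seeds are spawned deterministically from ``config.seed``.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    if config.variant != "nested":
        raise ConfigError("recovery_study targets the nested generating model")
    child_seeds = np.random.SeedSequence(config.seed).generate_state(n_reps)
    spec = ModelSpec(variant="nested", ci_level=ci_level)
    est: dict[ColumnInfo, list[float]] = {}
    cover: dict[ColumnInfo, list[bool]] = {}
    for s in child_seeds:
        cfg = dataclasses.replace(config, seed=int(s))
        obs, truth = generate(cfg)
        design = build_design(obs, spec)
        fit = fit_ols(design, obs.data["log_k"].to_numpy())
        for i in fit.retained_idx:
            col = design.columns[i]
            tv = true_coefficient(truth.coefficients, col)
            est.setdefault(col, []).append(float(fit.coef[i]))
            cover.setdefault(col, []).append(
                bool(fit.ci_low[i] <= tv <= fit.ci_high[i])
            )
    rows = []
    for col, values in est.items():
        tv = true_coefficient(config.coefficients, col)
        v = np.asarray(values)
        rows.append({
            "mwf": col.cell[0],
            "mwf_conc": col.cell[1],
            "descriptor": col.descriptor,
            "true": tv,
            "mean_estimate": v.mean(),
            "bias": v.mean() - tv,
            "rmse": float(np.sqrt(((v - tv) ** 2).mean())),
            "coverage": float(np.mean(cover[col])),
            "n_estimable": len(v),
        })
    return pd.DataFrame(rows)
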