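"""Domain tables: solute descriptors, observations, validation.

The unit of record is one replicate measurement of log10 K_MCF/mix for
one solute in one *treatment cell* — a (metalworking fluid, MWF
concentration, solute concentration) combination.  The study design has
5 MWFs x 3 MWF concentrations x 6 solute concentrations = 90 cells, 37
solutes, and up to 3 replicates, i.e. at most 9990 rows.

The canonical interchange format is long-format CSV with a header, one
row per replicate.  ``t`` (log10 of solute concentration, the nested
model's within-cell regressor) is always recomputed from
``solute_conc`` and never trusted from file.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError
from .partition import partition_arrays

__all__ = [
    "MWF_LEVELS",
    "MWF_CONC_LEVELS",
    "SOLUTE_CONC_LEVELS",
    "DESCRIPTOR_NAMES",
    "N_CELLS",
    "SoluteDescriptors",
    "ObservationSet",
    "ValidationReport",
    "load_solute_table",
    "solute_record",
    "load_observations",
    "write_observations",
    "validate_observations",
]

#: MWF bases in design order (index i = 1..5): mineral oil, polyethylene
#: glycol-200, soluble oil, synthetic oil, semi-synthetic oil.
MWF_LEVELS: tuple[str, ...] = ("MO", "PEG", "SO", "SYN", "SSYN")
#: MWF concentrations in percent (index j = 1..3).
MWF_CONC_LEVELS: tuple[float, ...] = (0.05, 0.5, 5.0)
#: Solute concentrations in ppm == ug/mL (index k = 1..6).
SOLUTE_CONC_LEVELS: tuple[float, ...] = (0.01, 0.05, 0.1, 0.5, 1.0, 5.0)
#: Abraham solvation descriptors used as predictors.
DESCRIPTOR_NAMES: tuple[str, ...] = ("E", "S", "A", "B", "V")
#: Number of treatment cells in the full design.
N_CELLS = len(MWF_LEVELS) * len(MWF_CONC_LEVELS) * len(SOLUTE_CONC_LEVELS)

_DESCRIPTOR_COLUMNS = ("solute_id", "name") + DESCRIPTOR_NAMES
_OBS_KEY = ("solute_id", "mwf", "mwf_conc", "solute_conc", "replicate")
_OBS_COLUMNS = ("solute_id", "mwf", "mwf_conc", "solute_conc", "t", "replicate", "log_k")
_RAW_QUARTET = ("n0", "C0", "Vd", "Vm")


@dataclass(frozen=True)
class SoluteDescriptors:
    """One solute's identity and Abraham descriptors.

    E: excess molar refractivity; S: dipolarity/polarizability;
    A: hydrogen-bond acidity; B: hydrogen-bond basicity;
    V: McGowan characteristic volume.  All dimensionless.
    """

    solute_id: int
    name: str
    E: float
    S: float
    A: float
    B: float
    V: float


@dataclass
class ValidationReport:
    """Counts and row-level problems found in an observation set."""

    n_rows: int
    n_cells_populated: int
    n_cells_empty: int
    offending_rows: list[tuple[int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.offending_rows


@dataclass
class ObservationSet:
    """Long table of replicate measurements plus the descriptor table.

    ``data`` columns: solute_id, mwf, mwf_conc, solute_conc, t,
    replicate, log_k.  Every solute_id in ``data`` resolves to a row of
    ``descriptors``; rows that failed that lookup (or carried an
    undefined response) live in ``rejected`` with a reason column.
    """

    data: pd.DataFrame
    descriptors: pd.DataFrame
    rejected: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_solutes(self) -> int:
        return self.data["solute_id"].nunique()

    def cells(self) -> list[tuple[str, float, float]]:
        """Populated (mwf, mwf_conc, solute_conc) cells in design order."""
        seen = {
            (r.mwf, r.mwf_conc, r.solute_conc)
            for r in self.data.itertuples(index=False)
        }
        return sorted(seen, key=cell_sort_key)

    def subset(self, mask) -> "ObservationSet":
        """New ObservationSet keeping rows where ``mask`` is True."""
        return ObservationSet(
            data=self.data.loc[np.asarray(mask)].reset_index(drop=True),
            descriptors=self.descriptors,
        )

    def merged(self) -> pd.DataFrame:
        """Observations joined with their descriptor values, row order kept."""
        out = self.data.merge(
            self.descriptors[["solute_id", *DESCRIPTOR_NAMES]],
            on="solute_id",
            how="left",
            validate="m:1",
        )
        if out[list(DESCRIPTOR_NAMES)].isna().any().any():
            missing = sorted(
                set(self.data["solute_id"]) - set(self.descriptors["solute_id"])
            )
            raise ValidationError(f"solute_ids without descriptors: {missing}")
        return out


def cell_sort_key(cell: tuple) -> tuple:
    """Design order: MWF index i, then MWF concentration j, then (if
    present) solute concentration k."""
    mwf = cell[0]
    key = [MWF_LEVELS.index(mwf) if mwf in MWF_LEVELS else len(MWF_LEVELS)]
    key.extend(cell[1:])
    return tuple(key)


def _packaged_fixture():
    return importlib.resources.files("mcflfer").joinpath(
        "fixtures/solute_descriptors.csv"
    )


def load_solute_table(path=None) -> pd.DataFrame:
    """Read a solute descriptor table (the packaged 37-solute set by default).

    Parameters
    ----------
    path
        CSV with columns solute_id, name, E, S, A, B, V.  ``None`` loads
        the packaged descriptor fixture.

    Returns
    -------
    DataFrame with one row per solute, validated against the descriptor
    invariants (E, S, V > 0; A, B >= 0; unique solute_id).
    """
    src = _packaged_fixture() if path is None else path
    try:
        if path is None:
            with src.open("r", encoding="utf-8") as fh:
                df = pd.read_csv(fh)
        else:
            df = pd.read_csv(src)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"descriptor table is empty: {src}") from None
    missing = [c for c in _DESCRIPTOR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"descriptor table missing column(s): {missing}")
    df = df[list(_DESCRIPTOR_COLUMNS)].copy()
    for col in ("solute_id",) + DESCRIPTOR_NAMES:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rows = [int(i) + 2 for i in df.index[bad]]  # 1-based incl. header
            raise SchemaError(f"non-numeric value in column {col!r}, file row(s) {rows}")
        if coerced.isna().any():
            rows = [int(i) + 2 for i in df.index[coerced.isna()]]
            raise SchemaError(f"missing value in column {col!r}, file row(s) {rows}")
        df[col] = coerced
    df["solute_id"] = df["solute_id"].astype(int)
    if df["solute_id"].duplicated().any():
        dups = sorted(df.loc[df["solute_id"].duplicated(), "solute_id"])
        raise ValidationError(f"duplicate solute_id(s): {dups}")
    if (df[["E", "S", "V"]] <= 0).any().any() or (df[["A", "B"]] < 0).any().any():
        raise ValidationError("descriptor invariants violated: need E,S,V > 0 and A,B >= 0")
    return df.reset_index(drop=True)


def solute_record(table: pd.DataFrame, solute_id: int) -> SoluteDescriptors:
    """One solute's record from a descriptor table."""
    hit = table.loc[table["solute_id"] == solute_id]
    if hit.empty:
        raise KeyError(f"solute_id {solute_id} not in descriptor table")
    r = hit.iloc[0]
    return SoluteDescriptors(
        solute_id=int(r["solute_id"]), name=str(r["name"]),
        E=float(r["E"]), S=float(r["S"]), A=float(r["A"]),
        B=float(r["B"]), V=float(r["V"]),
    )


def _snap_levels(values: pd.Series, levels: tuple[float, ...], label: str,
                 permissive: bool) -> pd.Series:
    """Snap near-matches onto canonical level floats; reject off-grid values."""
    vals = pd.to_numeric(values, errors="coerce")
    if vals.isna().any():
        rows = list(values.index[vals.isna()])
        raise SchemaError(f"non-numeric {label} in row(s) {rows}")
    arr = vals.to_numpy(dtype=float)
    out = arr.copy()
    matched = np.zeros(len(arr), dtype=bool)
    for lev in levels:
        hit = np.isclose(arr, lev, rtol=1e-9, atol=0.0)
        out[hit] = lev
        matched |= hit
    if not matched.all() and not permissive:
        bad = sorted(set(np.round(arr[~matched], 12)))
        raise ValidationError(
            f"{label} value(s) {bad} outside the declared levels {levels}; "
            "pass permissive=True to accept off-grid levels"
        )
    return pd.Series(out, index=values.index)


def observations_from_frame(df: pd.DataFrame, descriptors: pd.DataFrame,
                            permissive: bool = False) -> ObservationSet:
    """Build a validated :class:`ObservationSet` from a raw long table.

    ``t`` is recomputed as log10(solute_conc).  Rows whose solute_id has
    no descriptor record, or whose log_k is undefined, are moved to
    ``rejected`` with a reason.
    """
    required = ("solute_id", "mwf", "mwf_conc", "solute_conc", "replicate", "log_k")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"observation table missing column(s): {missing}")
    df = df.copy().reset_index(drop=True)
    df["mwf"] = df["mwf"].astype(str).str.strip()
    bad_mwf = ~df["mwf"].isin(MWF_LEVELS)
    if bad_mwf.any() and not permissive:
        raise ValidationError(
            f"mwf value(s) {sorted(df.loc[bad_mwf, 'mwf'].unique())} outside "
            f"the declared levels {MWF_LEVELS}"
        )
    df["mwf_conc"] = _snap_levels(df["mwf_conc"], MWF_CONC_LEVELS, "mwf_conc", permissive)
    df["solute_conc"] = _snap_levels(
        df["solute_conc"], SOLUTE_CONC_LEVELS, "solute_conc", permissive
    )
    if (df["solute_conc"] <= 0).any():
        raise ValidationError("solute_conc must be positive (t = log10 conc)")
    df["solute_id"] = pd.to_numeric(df["solute_id"], errors="coerce")
    if df["solute_id"].isna().any():
        raise SchemaError("non-numeric solute_id")
    df["solute_id"] = df["solute_id"].astype(int)
    df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce").astype("Int64")
    df["log_k"] = pd.to_numeric(df["log_k"], errors="coerce")
    df["t"] = np.log10(df["solute_conc"].to_numpy(dtype=float))

    reasons = pd.Series("", index=df.index, dtype=object)
    known = set(descriptors["solute_id"])
    reasons[~df["solute_id"].isin(known)] = "solute_id has no descriptor record"
    undef = df["log_k"].isna() & (reasons == "")
    reasons[undef] = "log_k undefined (k = 0 or missing)"
    bad = reasons != ""
    rejected = None
    if bad.any():
        rejected = df.loc[bad].assign(reason=reasons[bad]).reset_index(drop=True)
        warnings.warn(
            f"rejected {int(bad.sum())} observation row(s): "
            f"{sorted(rejected['reason'].unique())}",
            stacklevel=2,
        )
    keep = df.loc[~bad, list(_OBS_COLUMNS)].reset_index(drop=True)
    keep["replicate"] = keep["replicate"].astype(int)
    return ObservationSet(data=keep, descriptors=descriptors, rejected=rejected)


def load_observations(path, descriptors: pd.DataFrame | None = None,
                      permissive: bool = False) -> ObservationSet:
    """Read a long-format observation CSV.

    The file must carry either a ``log_k`` column or the raw extraction
    quartet ``n0, C0, Vd, Vm`` (converted via the partition formula,
    with log10 taken afterwards).
    """
    if descriptors is None:
        descriptors = load_solute_table()
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"observation table is empty: {path}") from None
    if "log_k" not in df.columns:
        if all(c in df.columns for c in _RAW_QUARTET):
            k, log_k = partition_arrays(
                df["n0"], df["C0"], df["Vd"], df["Vm"]
            )
            df["k"] = k
            df["log_k"] = log_k
        else:
            raise SchemaError(
                "observation table needs either a 'log_k' column or the raw "
                f"quartet {_RAW_QUARTET}"
            )
    return observations_from_frame(df, descriptors, permissive=permissive)


def write_observations(obs: ObservationSet, path) -> None:
    """Write the canonical long-format CSV (12 significant digits)."""
    obs.data[list(_OBS_COLUMNS)].to_csv(path, index=False, float_format="%.12g")


def validate_observations(obs: ObservationSet) -> ValidationReport:
    """Audit an observation set; reports problems, never raises.

    Counts populated/empty cells against the study's 90-cell grid and
    flags duplicate replicate keys, off-grid levels, missing descriptor
    links and non-finite responses.
    """
    df = obs.data
    offending: list[tuple[int, str]] = []
    grid = {
        (m, mc, sc)
        for m in MWF_LEVELS for mc in MWF_CONC_LEVELS for sc in SOLUTE_CONC_LEVELS
    }
    populated = set()
    known = set(obs.descriptors["solute_id"])
    dup = df.duplicated(subset=list(_OBS_KEY), keep="first")
    for idx, row in df.iterrows():
        cell = (row["mwf"], row["mwf_conc"], row["solute_conc"])
        if cell in grid:
            populated.add(cell)
        else:
            offending.append((int(idx), f"cell {cell} outside the study grid"))
        if dup.loc[idx]:
            offending.append((int(idx), "duplicate (solute, cell, replicate) key"))
        if row["solute_id"] not in known:
            offending.append((int(idx), "solute_id has no descriptor record"))
        if not np.isfinite(row["log_k"]):
            offending.append((int(idx), "non-finite log_k"))
        if not np.isclose(row["t"], np.log10(row["solute_conc"]), rtol=0, atol=1e-12):
            offending.append((int(idx), "t inconsistent with solute_conc"))
    return ValidationReport(
        n_rows=len(df),
        n_cells_populated=len(populated),
        n_cells_empty=N_CELLS - len(populated),
        offending_rows=offending,
    )
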