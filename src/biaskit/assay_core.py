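"""Data model, validation and CSV I/O for assay tables.

Three tidy input schemas are supported (header names are fixed):

``cr``
    ligand, pathway, assay, concentration_M, replicate, response
``bret``
    well, ligand, concentration_M, time_min, donor, acceptor, is_vehicle
``decay``
    compound, matrix, time_min, percent_remaining, protein_mg_per_uL

Concentrations are stored internally in molar.  A ``concentration_<unit>``
column with any of the suffixes M, mM, uM (or µM), nM, pM is accepted in
place of ``concentration_M`` and converted exactly on load.  All
log-transformed quantities elsewhere in the package are base-10
(pEC50 = -log10(EC50 in M)).

Replicates are kept as individual observations, never pre-averaged: the
fitting modules decide how to pool, and the bias error propagation needs
replicate-level information.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("biaskit")

__all__ = [
    "AssayError",
    "SchemaError",
    "ValidationError",
    "ConcentrationResponse",
    "TimeCourse",
    "DecaySeries",
    "CONCENTRATION_UNITS",
    "load_assay_table",
    "write_results",
    "results_to_frame",
]


class AssayError(Exception):
    """Base class for all biaskit errors."""


class SchemaError(AssayError):
    """An input table does not match the declared schema."""


class ValidationError(AssayError):
    """An input value violates a domain invariant."""


#: Exact molar scale factors for the supported concentration-column suffixes.
CONCENTRATION_UNITS: dict[str, float] = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}

CR_COLUMNS = ["ligand", "pathway", "assay", "concentration_M", "replicate", "response"]
BRET_COLUMNS = ["well", "ligand", "concentration_M", "time_min", "donor", "acceptor", "is_vehicle"]
DECAY_COLUMNS = ["compound", "matrix", "time_min", "percent_remaining", "protein_mg_per_uL"]

ASSAY_KINDS = ("cAMP_inhibition", "cAMP_accumulation", "bret_cr", "binding_competition")


@dataclass
class ConcentrationResponse:
    """One ligand x pathway x assay family of replicate responses.

    ``responses`` holds one 1-D array of replicate observations per
    concentration, aligned with ``concentrations`` (ascending, molar).
    Replicate counts may differ between concentrations.
    """

    ligand_id: str
    pathway_id: str
    assay_kind: str
    concentrations: np.ndarray
    responses: list[np.ndarray]
    response_units: str = "au"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.ndim != 1 or conc.size == 0:
            raise ValidationError("concentrations must be a non-empty 1-D array")
        if np.any(conc <= 0) or not np.all(np.isfinite(conc)):
            raise ValidationError(
                f"{self.ligand_id}/{self.pathway_id}: concentrations must be "
                "strictly positive and finite"
            )
        if len(self.responses) != conc.size:
            raise ValidationError("responses must align with concentrations")
        resp = [np.atleast_1d(np.asarray(r, dtype=float)) for r in self.responses]
        order = np.argsort(conc)
        self.concentrations = conc[order]
        self.responses = [resp[i] for i in order]
        for c, r in zip(self.concentrations, self.responses):
            if not np.any(np.isfinite(r)):
                raise ValidationError(
                    f"{self.ligand_id}/{self.pathway_id}: no finite response at "
                    f"concentration {c:g} M"
                )

    @property
    def n_concentrations(self) -> int:
        return int(self.concentrations.size)

    @property
    def replicate_counts(self) -> np.ndarray:
        return np.array([int(np.isfinite(r).sum()) for r in self.responses])

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """All finite observations as (concentration, response) pairs."""
        xs, ys = [], []
        for c, r in zip(self.concentrations, self.responses):
            keep = np.isfinite(r)
            xs.append(np.full(int(keep.sum()), c))
            ys.append(r[keep])
        return np.concatenate(xs), np.concatenate(ys)

    def mean_responses(self) -> np.ndarray:
        return np.array([float(np.nanmean(r)) for r in self.responses])

    def with_responses(self, responses: list[np.ndarray], **meta: Any) -> "ConcentrationResponse":
        new_meta = {**self.meta, **meta}
        return ConcentrationResponse(
            ligand_id=self.ligand_id,
            pathway_id=self.pathway_id,
            assay_kind=self.assay_kind,
            concentrations=self.concentrations.copy(),
            responses=[np.asarray(r, dtype=float) for r in responses],
            response_units=self.response_units,
            meta=new_meta,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c, r in zip(self.concentrations, self.responses):
            for i, v in enumerate(r, start=1):
                rows.append(
                    {
                        "ligand": self.ligand_id,
                        "pathway": self.pathway_id,
                        "assay": self.assay_kind,
                        "concentration_M": c,
                        "replicate": i,
                        "response": v,
                    }
                )
        return pd.DataFrame(rows, columns=CR_COLUMNS)


@dataclass
class TimeCourse:
    """Raw donor/acceptor emission trace for one well."""

    well_id: str
    ligand_id: str
    concentration: float
    times: np.ndarray
    donor_emission: np.ndarray
    acceptor_emission: np.ndarray
    is_vehicle: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.donor_emission, dtype=float)
        a = np.asarray(self.acceptor_emission, dtype=float)
        if not (t.size == d.size == a.size) or t.size == 0:
            raise ValidationError(f"well {self.well_id}: times/emissions must align")
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"well {self.well_id}: times must be strictly increasing")
        if np.any(d < 0) or np.any(a < 0):
            raise ValidationError(f"well {self.well_id}: emissions must be non-negative")
        if self.is_vehicle and np.isfinite(self.concentration) and self.concentration > 0:
            raise ValidationError(f"well {self.well_id}: vehicle rows carry no ligand concentration")
        self.times, self.donor_emission, self.acceptor_emission = t, d, a


@dataclass
class DecaySeries:
    """% compound remaining versus time in one stability matrix."""

    compound_id: str
    matrix_id: str
    times: np.ndarray
    percent_remaining: np.ndarray
    protein_concentration: float | None = None  # mg protein per uL
    t0_tolerance: float = 10.0  # percentage points around 100 at time 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.percent_remaining, dtype=float)
        if t.size != p.size or t.size == 0:
            raise ValidationError(f"{self.compound_id}: times/percent_remaining must align")
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"{self.compound_id}: times must be strictly increasing")
        if t[0] != 0:
            raise ValidationError(f"{self.compound_id}: series must include time 0")
        if abs(p[0] - 100.0) > self.t0_tolerance:
            raise ValidationError(
                f"{self.compound_id}: percent remaining at t=0 is {p[0]:g}, "
                f"expected 100 within +/-{self.t0_tolerance:g}"
            )
        self.times, self.percent_remaining = t, p


def _molar_column(df: pd.DataFrame, path: str) -> pd.Series:
    """Locate the concentration column and convert it to molar exactly."""
    for unit, scale in CONCENTRATION_UNITS.items():
        col = f"concentration_{unit}"
        if col in df.columns:
            return df[col].astype(float) * scale
    raise SchemaError(
        f"{path}: missing mandatory column 'concentration_M' "
        f"(or a unit-suffixed variant {sorted(set(CONCENTRATION_UNITS))})"
    )


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def _load_cr(df: pd.DataFrame, path: str) -> list[ConcentrationResponse]:
    _require_columns(df, [c for c in CR_COLUMNS if c != "concentration_M"], path)
    df = df.copy()
    df["concentration_M"] = _molar_column(df, path)
    bad = df.index[df["concentration_M"] <= 0]
    if len(bad):
        raise ValidationError(f"{path}: non-positive concentration at row index {bad[0]}")
    n_bad = int((~np.isfinite(df["response"].astype(float))).sum())
    if n_bad:
        logger.info("%s: dropped %d rows with non-finite response", path, n_bad)
        df = df[np.isfinite(df["response"].astype(float))]
    out: list[ConcentrationResponse] = []
    for (ligand, pathway, assay), g in df.groupby(["ligand", "pathway", "assay"], sort=False):
        conc = np.array(sorted(g["concentration_M"].unique()))
        responses = [
            g.loc[g["concentration_M"] == c, "response"].to_numpy(dtype=float) for c in conc
        ]
        out.append(
            ConcentrationResponse(
                ligand_id=str(ligand),
                pathway_id=str(pathway),
                assay_kind=str(assay),
                concentrations=conc,
                responses=responses,
            )
        )
    return out


def _load_bret(df: pd.DataFrame, path: str) -> list[TimeCourse]:
    _require_columns(df, [c for c in BRET_COLUMNS if c != "concentration_M"], path)
    df = df.copy()
    df["concentration_M"] = _molar_column(df, path)
    out: list[TimeCourse] = []
    for well, g in df.groupby("well", sort=False):
        g = g.sort_values("time_min")
        is_vehicle = bool(g["is_vehicle"].iloc[0])
        conc = float(g["concentration_M"].iloc[0]) if not is_vehicle else float("nan")
        out.append(
            TimeCourse(
                well_id=str(well),
                ligand_id=str(g["ligand"].iloc[0]),
                concentration=conc,
                times=g["time_min"].to_numpy(dtype=float),
                donor_emission=g["donor"].to_numpy(dtype=float),
                acceptor_emission=g["acceptor"].to_numpy(dtype=float),
                is_vehicle=is_vehicle,
            )
        )
    return out


def _load_decay(df: pd.DataFrame, path: str) -> list[DecaySeries]:
    _require_columns(df, [c for c in DECAY_COLUMNS if c != "protein_mg_per_uL"], path)
    out: list[DecaySeries] = []
    for (compound, matrix), g in df.groupby(["compound", "matrix"], sort=False):
        g = g.sort_values("time_min")
        protein = None
        if "protein_mg_per_uL" in g.columns:
            vals = g["protein_mg_per_uL"].dropna().unique()
            if len(vals):
                protein = float(vals[0])
        out.append(
            DecaySeries(
                compound_id=str(compound),
                matrix_id=str(matrix),
                times=g["time_min"].to_numpy(dtype=float),
                percent_remaining=g["percent_remaining"].to_numpy(dtype=float),
                protein_concentration=protein,
            )
        )
    return out


_LOADERS = {"cr": _load_cr, "bret": _load_bret, "decay": _load_decay}


def load_assay_table(path: str | Path, schema: str):
    """Load a tidy assay CSV into typed records.

    Parameters
    ----------
    path
        CSV file with one of the fixed schemas.
    schema
        One of ``"cr"``, ``"bret"``, ``"decay"``.

    Returns
    -------
    list of :class:`ConcentrationResponse`, :class:`TimeCourse` or
    :class:`DecaySeries`, grouped by their natural keys.
    """
    if schema not in _LOADERS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(_LOADERS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return _LOADERS[schema](df, str(path))


def results_to_frame(results: Iterable[Any]) -> pd.DataFrame:
    """Convert a list of result dataclasses to a tidy DataFrame.

    Each result type provides ``to_record()``; plain dicts and DataFrames
    pass through.
    """
    results = list(results) if not isinstance(results, pd.DataFrame) else results
    if isinstance(results, pd.DataFrame):
        if results.empty:
            raise ValidationError("refusing to write an empty results table")
        return results
    if not results:
        raise ValidationError("refusing to write an empty results table")
    records = []
    for r in results:
        if isinstance(r, dict):
            records.append(r)
        elif hasattr(r, "to_record"):
            records.append(r.to_record())
        elif dataclasses.is_dataclass(r):
            records.append(dataclasses.asdict(r))
        else:
            raise ValidationError(f"cannot serialise result of type {type(r).__name__}")
    return pd.DataFrame(records)


def write_results(results: Iterable[Any] | pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Write stage outputs to a tidy CSV, one row per result.

    Floats are written with 12 significant digits so that estimates
    round-trip through :func:`pandas.read_csv` without loss at that
    precision.  Returns the frame that was written.
    """
    frame = results_to_frame(results)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.12g")
    return frame
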