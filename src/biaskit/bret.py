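"""Reduction of BRET time-courses to concentration-response inputs.

Two assay families share this path:

* beta-arrestin recruitment: acceptor/donor = 530 nm / 450 nm emission;
  ligand-induced delta-BRET is the ligand ratio minus the vehicle ratio,
  read out at 5 min (the maximum response).
* TRUPATH G-protein dissociation: GFP2 (515 nm) over Rluc8 (400 nm) net
  BRET; receptor activation *dissociates* Galpha from Gbetagamma so the
  corrected ratio falls — the extracted concentration-response is fitted
  downstream with direction = inhibition.  Read-out at 11 min after
  baseline correction.

Baseline correction subtracts the mean of pre-addition readings (all
points at or before the ligand-addition time; by default just the first
sample), per well.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from biaskit.assay_core import AssayError, ConcentrationResponse, TimeCourse

logger = logging.getLogger("biaskit")

__all__ = ["BretSeries", "compute_ratio", "delta_bret", "extract_cr_at_time"]

#: Read-out times (minutes) used for fixed-time concentration-responses.
DEFAULT_TIMEPOINT = {"arrestin": 5.0, "trupath": 11.0}
#: Nearest-time matching tolerance (minutes); the acquisition grid is 1 min.
TIME_TOLERANCE = 0.5


@dataclass
class BretSeries:
    """Acceptor/donor ratio trace, optionally vehicle- and baseline-corrected."""

    ligand_id: str
    concentration: float
    times: np.ndarray
    ratio: np.ndarray
    delta: np.ndarray | None = None  # ligand ratio - vehicle ratio
    corrected: np.ndarray | None = None  # delta minus pre-addition baseline
    assay: str = "arrestin"
    is_vehicle: bool = False


def compute_ratio(tc: TimeCourse, assay: str = "arrestin") -> BretSeries:
    """Per-time acceptor/donor emission ratio.

    Time points with zero donor emission are masked (NaN) with a warning;
    the ratio is undefined there.
    """
    donor = tc.donor_emission
    ratio = np.full_like(donor, np.nan, dtype=float)
    ok = donor > 0
    if not np.all(ok):
        warnings.warn(
            f"well {tc.well_id}: {int((~ok).sum())} time point(s) with zero donor "
            "emission masked",
            RuntimeWarning,
            stacklevel=2,
        )
    ratio[ok] = tc.acceptor_emission[ok] / donor[ok]
    return BretSeries(
        ligand_id=tc.ligand_id,
        concentration=tc.concentration,
        times=tc.times.copy(),
        ratio=ratio,
        assay=assay,
        is_vehicle=tc.is_vehicle,
    )


def delta_bret(
    ligand: BretSeries,
    vehicle: BretSeries,
    baseline_time: float | None = None,
) -> BretSeries:
    """Ligand-induced delta-BRET: ligand ratio minus vehicle ratio, baseline-corrected.

    The vehicle trace must share the ligand trace's time grid.  After
    vehicle subtraction the mean of all pre-addition points (times <=
    ``baseline_time``; default: the first sample only) is subtracted so
    the corrected series starts at ~0.
    """
    if ligand.times.size != vehicle.times.size or not np.allclose(
        ligand.times, vehicle.times, atol=1e-9
    ):
        raise AssayError(
            f"time grids of ligand {ligand.ligand_id!r} and vehicle do not match"
        )
    diff = ligand.ratio - vehicle.ratio
    if baseline_time is None:
        base_mask = np.zeros(ligand.times.size, dtype=bool)
        base_mask[0] = True
    else:
        base_mask = ligand.times <= baseline_time
        if not np.any(base_mask):
            base_mask[0] = True
    baseline = float(np.nanmean(diff[base_mask]))
    corrected = diff - baseline
    return BretSeries(
        ligand_id=ligand.ligand_id,
        concentration=ligand.concentration,
        times=ligand.times.copy(),
        ratio=ligand.ratio.copy(),
        delta=diff,
        corrected=corrected,
        assay=ligand.assay,
    )


def extract_cr_at_time(
    series: list[BretSeries],
    t: float | None = None,
    assay: str | None = None,
) -> ConcentrationResponse:
    """Fixed-time concentration-response from corrected BRET traces.

    One response per concentration, taken as the corrected value at the
    time point nearest ``t`` (within 0.5 min — exact on the 1-min
    acquisition grid).  Defaults: t = 5 min for arrestin recruitment (the
    maximum response), t = 11 min for TRUPATH.  Output feeds
    :func:`biaskit.dose_response.fit_logistic3`.
    """
    if not series:
        raise AssayError("no BRET series supplied")
    assay = assay or series[0].assay
    if t is None:
        t = DEFAULT_TIMEPOINT[assay]
    by_conc: dict[float, list[float]] = {}
    for s in series:
        if s.is_vehicle:
            continue
        if s.corrected is None:
            raise AssayError(f"series {s.ligand_id!r} has no corrected trace; run delta_bret first")
        idx = int(np.argmin(np.abs(s.times - t)))
        if abs(s.times[idx] - t) > TIME_TOLERANCE:
            raise AssayError(
                f"time point {t} min outside series range or grid (nearest "
                f"{s.times[idx]} min)"
            )
        by_conc.setdefault(float(s.concentration), []).append(float(s.corrected[idx]))
    conc = np.array(sorted(by_conc))
    responses = [np.array(by_conc[c]) for c in conc]
    return ConcentrationResponse(
        ligand_id=series[0].ligand_id,
        pathway_id=assay,
        assay_kind="bret_cr",
        concentrations=conc,
        responses=responses,
        response_units="delta BRET",
        meta={"timepoint_min": t},
    )
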