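"""Stability metrics: first-order half-life and apparent intrinsic clearance.

Metabolic stability series report % parent compound remaining at 0, 15,
30, 45, 60 min.  Assuming first-order kinetics, the elimination rate k is
the negative slope of ln(% remaining) versus time over the initial linear
range, t1/2 = 0.693/k, and the apparent intrinsic clearance of a
microsomal incubation is

    CL_int = 0.693 / (t1/2 * protein concentration [mg protein/uL])

in uL/min/mg.  The constant 0.693 (rather than ln 2 to full precision) is
the conventional rounded value used in clearance arithmetic; it is
configurable.

A compound that barely declines over the observation window (< 10% fitted
decline) is reported as censored: t1/2 greater than the last time point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from biaskit.assay_core import AssayError, DecaySeries

__all__ = ["DecayResult", "LN2", "fit_half_life", "intrinsic_clearance"]

#: Rounded ln 2 used throughout the half-life / clearance arithmetic.
LN2 = 0.693

#: Minimum R^2 for the "initial linear range" prefix selection.
LINEAR_R2 = 0.95
#: Fitted decline below this fraction over the window censors the result.
CENSOR_DECLINE_FRACTION = 0.10


@dataclass
class DecayResult:
    """First-order decay parameters for one compound in one matrix."""

    compound_id: str
    matrix_id: str
    k: float  # per minute
    t_half: float  # minutes
    clint: float = float("nan")  # uL/min/mg
    protein_concentration: float | None = None
    n_points_used: int = 0
    censored: bool = False
    censor_limit: float = float("nan")  # t_half > this many minutes when censored

    def to_record(self) -> dict:
        return {
            "compound": self.compound_id,
            "matrix": self.matrix_id,
            "k_per_min": self.k,
            "t_half_min": self.t_half,
            "clint_uL_min_mg": self.clint,
            "n_points_used": self.n_points_used,
            "censored": self.censored,
            "censor_limit_min": self.censor_limit,
        }


def _initial_linear_prefix(times: np.ndarray, log_pct: np.ndarray) -> int:
    """Longest prefix (>= 3 points) whose ln-linear fit has R^2 >= LINEAR_R2."""
    n = times.size
    best = n
    for m in range(n, 2, -1):
        r = linregress(times[:m], log_pct[:m])
        if r.rvalue**2 >= LINEAR_R2:
            return m
    return best  # fall back to all points


def fit_half_life(series: DecaySeries, ln2: float = LN2) -> DecayResult:
    """First-order half-life from ln(% remaining) versus time.

    Linear regression over the initial linear range (longest prefix with
    R^2 >= 0.95, minimum 3 points; all points when none qualifies) gives
    k = -slope and t1/2 = 0.693/k.  If the fitted decline over the
    observation window is < 10%, or % remaining does not decrease, the
    result is censored as t1/2 > last time point.  When a protein
    concentration is attached, CL_int is computed as well.
    """
    t, pct = series.times, series.percent_remaining
    if t.size < 3:
        raise AssayError(f"{series.compound_id}: need >= 3 time points including t=0")
    keep = pct > 0
    if not np.all(keep):
        warnings.warn(
            f"{series.compound_id}: {int((~keep).sum())} non-positive %-remaining "
            "point(s) excluded from the log fit",
            RuntimeWarning,
            stacklevel=2,
        )
    t, pct = t[keep], pct[keep]
    if t.size < 3:
        raise AssayError(f"{series.compound_id}: fewer than 3 usable time points")
    log_pct = np.log(pct)
    m = _initial_linear_prefix(t, log_pct)
    reg = linregress(t[:m], log_pct[:m])
    k = -float(reg.slope)
    window = float(series.times[-1])
    censored = False
    if k <= 0:
        warnings.warn(
            f"{series.compound_id}: % remaining does not decline; reporting "
            f"t1/2 > {window:g} min",
            RuntimeWarning,
            stacklevel=2,
        )
        censored = True
    else:
        fitted_decline = 1.0 - np.exp(-k * window)
        censored = fitted_decline < CENSOR_DECLINE_FRACTION
    if censored:
        result = DecayResult(
            compound_id=series.compound_id,
            matrix_id=series.matrix_id,
            k=float("nan"),
            t_half=float("nan"),
            protein_concentration=series.protein_concentration,
            n_points_used=m,
            censored=True,
            censor_limit=window,
        )
        if series.protein_concentration:
            # censored t1/2 > window puts an upper bound on clearance
            result.clint = intrinsic_clearance(window, series.protein_concentration, ln2=ln2)
        return result
    t_half = ln2 / k
    result = DecayResult(
        compound_id=series.compound_id,
        matrix_id=series.matrix_id,
        k=k,
        t_half=t_half,
        protein_concentration=series.protein_concentration,
        n_points_used=m,
    )
    if series.protein_concentration:
        result.clint = intrinsic_clearance(t_half, series.protein_concentration, ln2=ln2)
    return result


def intrinsic_clearance(t_half: float, protein_concentration: float, ln2: float = LN2) -> float:
    """Apparent intrinsic clearance in uL/min/mg.

    ``CL_int = 0.693 / (t1/2 * protein_concentration)`` with t1/2 in
    minutes and protein concentration in mg protein per uL (0.0001 mg/uL
    for a standard 0.1 mg/mL microsomal incubation).
    """
    if not (t_half > 0) or not (protein_concentration > 0):
        raise ValueError("t_half and protein_concentration must be positive")
    return ln2 / (t_half * protein_concentration)
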