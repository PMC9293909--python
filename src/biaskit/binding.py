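"""Equilibrium binding analysis: saturation K_d, one- and two-site competition K_i.

Competition IC50s are converted to inhibition constants with the
Cheng-Prusoff relation

    K_i = IC50 / (1 + [L] / K_d)

where [L] is the tracer concentration and K_d its equilibrium dissociation
constant.  One-site displacement is a 3PL fit (fixed Hill slope -1 in log
concentration); biphasic displacement is fitted with a shared-plateau
two-site model

    y = bottom + (top - bottom) * [ f / (1 + [C]/IC50_high)
                                  + (1 - f) / (1 + [C]/IC50_low) ]

yielding the high-affinity fraction f and a K_i per phase.  A two-site fit
that collapses (the two phases within 0.3 log units) falls back to
one-site.

Tracer defaults used in the study this pipeline was built around are
shipped in :data:`TRACER_DEFAULTS` and are overridable everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import f as f_dist

from biaskit.assay_core import AssayError, ConcentrationResponse
from biaskit.dose_response import InsufficientDataError, fit_logistic3

__all__ = [
    "BindingResult",
    "NoDisplacementError",
    "TRACER_DEFAULTS",
    "cheng_prusoff",
    "fit_saturation",
    "fit_competition_one_site",
    "fit_competition_two_site",
    "two_site_displacement",
]

#: Tracer constants (molar) from the radioligand and NanoBRET binding assays:
#: the antagonist radiotracer DPCPX used at 1 nM around its 1.23 nM K_d, the
#: fluorescent antagonist CA200645 at 25 nM, and the fluorescent agonist
#: NECA-TAMRA used at its K_d of 15.2 uM.
TRACER_DEFAULTS: dict[str, dict[str, float]] = {
    "DPCPX": {"concentration": 1e-9, "kd": 1.23e-9},
    "CA200645": {"concentration": 25e-9, "kd": 25e-9},
    "NECA-TAMRA": {"concentration": 15.2e-6, "kd": 15.2e-6},
}

#: Two phases closer than this (log10 units) are treated as one site.
COLLAPSE_LOG_THRESHOLD = 0.3


class NoDisplacementError(AssayError):
    """Competition data show no measurable displacement."""


@dataclass
class BindingResult:
    """Affinity estimates from one binding experiment."""

    ligand_id: str
    model: str  # saturation | one_site | two_site
    tracer_id: str = ""
    tracer_concentration: float = float("nan")
    tracer_kd: float = float("nan")
    kd: float = float("nan")  # saturation
    bmax: float = float("nan")
    ki: float = float("nan")  # one-site
    frac_high: float = float("nan")  # two-site
    ki_high: float = float("nan")
    ki_low: float = float("nan")
    nonspecific: float = float("nan")
    sems: dict[str, float] = field(default_factory=dict)
    f_statistic: float = float("nan")  # two-site vs one-site extra-SS F
    f_pvalue: float = float("nan")
    note: str = ""

    @property
    def pki(self) -> float:
        return -np.log10(self.ki) if np.isfinite(self.ki) else float("nan")

    @property
    def pkd(self) -> float:
        return -np.log10(self.kd) if np.isfinite(self.kd) else float("nan")

    def to_record(self) -> dict:
        return {
            "ligand": self.ligand_id,
            "model": self.model,
            "tracer": self.tracer_id,
            "kd_M": self.kd,
            "bmax": self.bmax,
            "ki_M": self.ki,
            "pki": self.pki,
            "frac_high": self.frac_high,
            "ki_high_M": self.ki_high,
            "ki_low_M": self.ki_low,
            "f_statistic": self.f_statistic,
            "f_pvalue": self.f_pvalue,
            "note": self.note,
        }


def cheng_prusoff(ic50: float, tracer_conc: float, tracer_kd: float) -> float:
    """Convert a competition IC50 (molar) to K_i via Cheng-Prusoff.

    ``K_i = IC50 / (1 + [L]/K_d)``.  With no tracer occupancy ([L] = 0)
    K_i equals the IC50; at [L] = K_d it is half of it.
    """
    if not (ic50 > 0) or not (tracer_kd > 0):
        raise ValueError("ic50 and tracer_kd must be positive")
    if tracer_conc < 0:
        raise ValueError("tracer concentration must be non-negative")
    return ic50 / (1.0 + tracer_conc / tracer_kd)


def fit_saturation(
    tracer_conc: np.ndarray,
    total_bound: np.ndarray,
    nonspecific: np.ndarray | None = None,
) -> BindingResult:
    """Saturation binding: specific = Bmax * [L] / (K_d + [L]).

    ``nonspecific`` is a matched series (same tracer concentrations)
    subtracted before fitting; where it exceeds total binding the specific
    signal is clipped at 0 with a warning note.
    """
    x = np.asarray(tracer_conc, dtype=float)
    y = np.asarray(total_bound, dtype=float)
    if x.size < 5:
        raise InsufficientDataError(f"need >= 5 tracer concentrations, got {x.size}")
    note = ""
    if nonspecific is not None:
        ns = np.asarray(nonspecific, dtype=float)
        specific = y - ns
        if np.any(specific < 0):
            note = "nonspecific exceeded total at some points; clipped at 0"
            specific = np.clip(specific, 0.0, None)
    else:
        specific = y

    # log-Kd parameterisation keeps the problem well scaled against Bmax
    def hyperbola(l, bmax, log_kd):
        return bmax * l / (10.0**log_kd + l)

    popt, pcov = curve_fit(
        hyperbola, x, specific,
        p0=[float(np.max(specific)), float(np.log10(np.median(x)))],
        maxfev=20000,
    )
    perr = np.sqrt(np.diag(pcov))
    kd = 10.0 ** float(popt[1])
    return BindingResult(
        ligand_id="tracer",
        model="saturation",
        kd=kd,
        bmax=float(popt[0]),
        sems={"bmax": float(perr[0]), "log_kd": float(perr[1])},
        note=note,
    )


def fit_competition_one_site(
    cr: ConcentrationResponse,
    tracer_conc: float,
    tracer_kd: float,
) -> BindingResult:
    """One-site competition: 3PL displacement fit, then Cheng-Prusoff.

    The displacement curve (bound signal versus competitor concentration)
    is fitted with the 3PL inhibition model — top and bottom plateaus free
    — and the fitted IC50 converted to K_i; pKi = -log10(K_i in M).
    """
    fit = fit_logistic3(cr, direction="inhibition",
                        window=_span(cr), nr_threshold_fraction=0.1)
    if fit.nr_flag:
        raise NoDisplacementError(f"{cr.ligand_id}: no displacement detected")
    ic50 = 10.0 ** (-fit.p_half)
    ki = cheng_prusoff(ic50, tracer_conc, tracer_kd)
    # IC50 -> Ki is a constant scale, so the log-scale SEM carries over
    return BindingResult(
        ligand_id=cr.ligand_id,
        model="one_site",
        tracer_id=str(cr.meta.get("tracer", "")),
        tracer_concentration=tracer_conc,
        tracer_kd=tracer_kd,
        ki=float(ki),
        sems={"pki": fit.sems.get("p_half", float("nan"))},
        nonspecific=fit.bottom,
    )


def _span(cr: ConcentrationResponse) -> float:
    """Observed signal span, used as NR window for un-normalised binding data."""
    _, y = cr.pooled()
    lo, hi = float(np.min(y)), float(np.max(y))
    return hi - lo if hi > lo else 1.0


def two_site_displacement(
    conc: np.ndarray,
    top: float,
    bottom: float,
    frac_high: float,
    ic50_high: float,
    ic50_low: float,
) -> np.ndarray:
    """Shared-plateau biphasic displacement curve (forward model)."""
    c = np.asarray(conc, dtype=float)
    high = frac_high / (1.0 + c / ic50_high)
    low = (1.0 - frac_high) / (1.0 + c / ic50_low)
    return bottom + (top - bottom) * (high + low)


def fit_competition_two_site(
    cr: ConcentrationResponse,
    tracer_conc: float,
    tracer_kd: float,
) -> BindingResult:
    """Two-site (biphasic) competition with shared plateaus.

    Initialised from a one-site fit split +/- 1 log unit; the
    high-affinity fraction is bounded to [0.02, 0.98] during optimisation
    and collapse (phases within 0.3 log units or a boundary fraction) is
    detected afterwards, falling back to the one-site result with a note.
    An extra-sum-of-squares F statistic compares the two models.
    """
    if cr.n_concentrations < 8:
        raise InsufficientDataError(
            f"{cr.ligand_id}: need >= 8 concentrations spanning both phases, "
            f"got {cr.n_concentrations}"
        )
    one_site = fit_competition_one_site(cr, tracer_conc, tracer_kd)
    lf = fit_logistic3(cr, direction="inhibition", window=_span(cr))
    ic50_mid = 10.0 ** (-lf.p_half)
    x, y = cr.pooled()

    params = lmfit.Parameters()
    params.add("top", value=lf.top)
    params.add("bottom", value=lf.bottom)
    params.add("frac_high", value=0.5, min=0.02, max=0.98)
    params.add("log_ic50_high", value=float(np.log10(ic50_mid)) - 1.0,
               min=float(np.log10(x.min())) - 4.0, max=float(np.log10(x.max())) + 4.0)
    # the low phase sits above the high phase by a non-negative log offset
    params.add("log_split", value=2.0, min=0.0, max=8.0)
    params.add("log_ic50_low", expr="log_ic50_high + log_split")

    def residual(p):
        mu = two_site_displacement(
            x, p["top"].value, p["bottom"].value, p["frac_high"].value,
            10.0 ** p["log_ic50_high"].value, 10.0 ** p["log_ic50_low"].value,
        )
        return y - mu

    result = lmfit.minimize(residual, params, method="leastsq", max_nfev=50000)
    p = result.params
    rss2 = float(np.sum(result.residual**2))
    rss1 = lf.residual_sum_squares
    df1, df2 = y.size - 3, y.size - 5
    if rss2 > 0 and df2 > 0 and rss1 >= rss2:
        f_stat = ((rss1 - rss2) / 2.0) / (rss2 / df2)
        f_p = float(f_dist.sf(f_stat, 2, df2))
    else:
        f_stat, f_p = float("nan"), float("nan")

    log_split = float(p["log_split"].value)
    frac = float(p["frac_high"].value)
    collapsed = log_split < COLLAPSE_LOG_THRESHOLD or frac <= 0.021 or frac >= 0.979
    if collapsed:
        one_site.note = (
            f"two-site fit collapsed (phase separation {log_split:.2f} log, "
            f"frac_high {frac:.2f}); one-site result reported"
        )
        one_site.f_statistic, one_site.f_pvalue = f_stat, f_p
        return one_site

    ki_high = cheng_prusoff(10.0 ** float(p["log_ic50_high"].value), tracer_conc, tracer_kd)
    ki_low = cheng_prusoff(10.0 ** float(p["log_ic50_low"].value), tracer_conc, tracer_kd)

    def _stderr(name):
        se = p[name].stderr
        return float(se) if se is not None else float("nan")

    return BindingResult(
        ligand_id=cr.ligand_id,
        model="two_site",
        tracer_id=str(cr.meta.get("tracer", "")),
        tracer_concentration=tracer_conc,
        tracer_kd=tracer_kd,
        frac_high=frac,
        ki_high=float(ki_high),
        ki_low=float(ki_low),
        sems={
            "frac_high": _stderr("frac_high"),
            "log_ki_high": _stderr("log_ic50_high"),
            "log_ki_low": _stderr("log_ic50_low"),
        },
        f_statistic=f_stat,
        f_pvalue=f_p,
    )
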