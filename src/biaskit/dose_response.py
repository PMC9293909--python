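"""Three-parameter logistic (3PL) concentration-response fitting.

The model has a fixed Hill slope of 1 and three free parameters — top,
bottom and log10 EC50:

    y = bottom + (top - bottom) / (1 + 10^(s * (log10[A] - log10 EC50)))

with sign ``s = -1`` for stimulation (response rises with agonist) and
``s = +1`` for inhibition (response falls, as in forskolin-stimulated cAMP
inhibition or competition-binding displacement).  Fitting is unweighted
least squares over all replicate observations in log-concentration space.

cAMP responses are normalised to a forskolin concentration-response curve
run in parallel, so the assay window is 0-100% of the fitted forskolin
maximum.  A curve whose fitted response range is below a configurable
fraction of that window is flagged NR ("no measurable response") and
excluded from operational-model fitting downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from biaskit.assay_core import AssayError, ConcentrationResponse

__all__ = [
    "InsufficientDataError",
    "NormalizationError",
    "LogisticFit",
    "logistic3",
    "fit_logistic3",
    "normalize_to_forskolin",
    "classify_nr",
    "summarize_panel",
]

#: Default assay window (forskolin-normalised %), used by the NR rule.
DEFAULT_WINDOW = 100.0
#: Default NR threshold as a fraction of the assay window.
DEFAULT_NR_FRACTION = 0.1


class InsufficientDataError(AssayError):
    """Too few distinct concentrations to fit the requested model."""


class NormalizationError(AssayError):
    """The forskolin reference curve cannot define a window."""


@dataclass
class LogisticFit:
    """Fitted 3PL parameters with asymptotic standard errors.

    ``p_half`` is pEC50 for stimulation or pIC50 for inhibition, in
    -log10(M).  ``response_range`` is the signed fitted change from zero
    to saturating ligand: positive for stimulation, negative for
    inhibition.
    """

    ligand_id: str
    pathway_id: str
    p_half: float
    top: float
    bottom: float
    direction: str
    sems: dict[str, float] = field(default_factory=dict)
    n_points: int = 0
    residual_sum_squares: float = float("nan")
    converged: bool = False
    nr_flag: bool = False
    sems_available: bool = True
    #: fitted response change across the *observed* concentration range
    #: (can be much smaller than |top - bottom| when EC50 sits outside it)
    fitted_data_span: float = float("nan")

    @property
    def response_range(self) -> float:
        sign = 1.0 if self.direction == "stimulation" else -1.0
        return sign * (self.top - self.bottom)

    @property
    def ec50(self) -> float:
        return 10.0 ** (-self.p_half)

    def predict(self, concentrations: np.ndarray) -> np.ndarray:
        sign = -1.0 if self.direction == "stimulation" else 1.0
        logx = np.log10(np.asarray(concentrations, dtype=float))
        return logistic3(logx, self.top, self.bottom, -self.p_half, sign)

    def to_record(self) -> dict:
        return {
            "ligand": self.ligand_id,
            "pathway": self.pathway_id,
            "p_half": self.p_half,
            "top": self.top,
            "bottom": self.bottom,
            "response_range": self.response_range,
            "direction": self.direction,
            "sem_p_half": self.sems.get("p_half", float("nan")),
            "sem_top": self.sems.get("top", float("nan")),
            "sem_bottom": self.sems.get("bottom", float("nan")),
            "n_points": self.n_points,
            "rss": self.residual_sum_squares,
            "converged": self.converged,
            "nr_flag": self.nr_flag,
        }


def logistic3(logx: np.ndarray, top: float, bottom: float, log_ec50: float, sign: float) -> np.ndarray:
    """3PL mean response at log10 concentration ``logx``."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (sign * (logx - log_ec50)))


def _infer_direction(logx: np.ndarray, means: np.ndarray) -> str:
    slope = np.polyfit(logx, means, 1)[0]
    return "stimulation" if slope >= 0 else "inhibition"


def fit_logistic3(
    cr: ConcentrationResponse,
    direction: str = "auto",
    nr_threshold_fraction: float = DEFAULT_NR_FRACTION,
    window: float | None = None,
) -> LogisticFit:
    """Fit a 3PL curve to one concentration-response family.

    Parameters
    ----------
    cr
        Replicate observations at >= 4 distinct concentrations.
    direction
        ``"stimulation"``, ``"inhibition"`` or ``"auto"`` (inferred from
        the sign of the response trend).
    nr_threshold_fraction, window
        Passed to :func:`classify_nr`; ``window=None`` uses the
        forskolin-normalised 100% window.

    Notes
    -----
    Initialisation takes bottom/top from the extreme concentration-mean
    responses and log EC50 from the concentration bracketing the
    half-range; log EC50 is bounded to the data range +/- 2 log units.
    A fit that fails to converge is returned with ``nr_flag`` set rather
    than raising.
    """
    if cr.n_concentrations < 4:
        raise InsufficientDataError(
            f"{cr.ligand_id}/{cr.pathway_id}: need >= 4 distinct concentrations, "
            f"got {cr.n_concentrations}"
        )
    x, y = cr.pooled()
    logx = np.log10(x)
    means = cr.mean_responses()
    log_conc = np.log10(cr.concentrations)
    if direction == "auto":
        direction = _infer_direction(log_conc, means)
    if direction not in ("stimulation", "inhibition"):
        raise ValueError(f"unknown direction {direction!r}")
    sign = -1.0 if direction == "stimulation" else 1.0

    # response at low conc is the first mean, at high conc the last
    low, high = means[0], means[-1]
    top0, bottom0 = (high, low) if direction == "stimulation" else (low, high)
    if math.isclose(top0, bottom0, abs_tol=1e-300):
        top0, bottom0 = bottom0 + 1.0, bottom0
    half = 0.5 * (top0 + bottom0)
    # concentration whose mean response is nearest the half-range
    log_ec50_0 = float(log_conc[np.argmin(np.abs(means - half))])
    lo, hi = log_conc[0] - 2.0, log_conc[-1] + 2.0
    log_ec50_0 = min(max(log_ec50_0, lo), hi)

    def model(lx, top, bottom, log_ec50):
        return logistic3(lx, top, bottom, log_ec50, sign)

    span = abs(top0 - bottom0)
    try:
        popt, pcov = curve_fit(
            model,
            logx,
            y,
            p0=[top0, bottom0, log_ec50_0],
            bounds=([-np.inf, -np.inf, lo], [np.inf, np.inf, hi]),
            maxfev=20000,
        )
        converged = True
    except (RuntimeError, ValueError):
        fit = LogisticFit(
            ligand_id=cr.ligand_id,
            pathway_id=cr.pathway_id,
            p_half=float("nan"),
            top=float(np.max(means)),
            bottom=float(np.min(means)),
            direction=direction,
            n_points=y.size,
            converged=False,
            nr_flag=True,
            sems_available=False,
        )
        return fit

    top, bottom, log_ec50 = (float(v) for v in popt)
    resid = y - model(logx, *popt)
    rss = float(resid @ resid)
    perr = np.sqrt(np.diag(pcov))
    sems_available = bool(np.all(np.isfinite(perr)))
    sems = {
        "top": float(perr[0]),
        "bottom": float(perr[1]),
        "p_half": float(perr[2]),  # SE of log10 EC50 equals SE of pEC50
    }
    fit = LogisticFit(
        ligand_id=cr.ligand_id,
        pathway_id=cr.pathway_id,
        p_half=-log_ec50,
        top=top,
        bottom=bottom,
        direction=direction,
        sems=sems if sems_available else {},
        n_points=y.size,
        residual_sum_squares=rss,
        converged=converged,
        sems_available=sems_available,
    )
    pred_ends = fit.predict(np.array([cr.concentrations[0], cr.concentrations[-1]]))
    fit.fitted_data_span = float(pred_ends[1] - pred_ends[0])
    fit.nr_flag = classify_nr(fit, nr_threshold_fraction, window=window)
    return fit


def classify_nr(
    fit: LogisticFit,
    threshold_fraction: float = DEFAULT_NR_FRACTION,
    window: float | None = None,
) -> bool:
    """Flag a fit as NR ("no measurable response").

    A curve is NR when its fitted |response range| is strictly below
    ``threshold_fraction`` of the assay window, or when the fit failed to
    converge.  The range is measured across the observed concentration
    grid when available (a noise-only curve can fit a large extrapolated
    top - bottom with EC50 outside the tested range while staying flat
    over it); |top - bottom| is the fallback.  The default window is the
    forskolin-normalised 100%.
    """
    if not fit.converged:
        return True
    w = DEFAULT_WINDOW if window is None else window
    span = fit.fitted_data_span if np.isfinite(fit.fitted_data_span) else fit.response_range
    return abs(span) < threshold_fraction * w


def normalize_to_forskolin(
    cr: ConcentrationResponse, forskolin_curve: ConcentrationResponse
) -> ConcentrationResponse:
    """Re-express raw cAMP responses as % of the fitted forskolin maximum.

    The forskolin curve (run in parallel on the same plate) is fitted with
    the 3PL model; each raw response becomes ``100 * raw / top_fsk``.  The
    normalisation constant is recorded in ``meta``.
    """
    fsk = fit_logistic3(forskolin_curve, direction="stimulation")
    if fsk.nr_flag or not np.isfinite(fsk.top) or fsk.top == 0:
        raise NormalizationError(
            f"forskolin curve {forskolin_curve.ligand_id} has no measurable window"
        )
    scale = 100.0 / fsk.top
    responses = [r * scale for r in cr.responses]
    out = cr.with_responses(responses, forskolin_top=fsk.top, normalized="forskolin")
    out.response_units = "% forskolin"
    return out


def summarize_panel(fits: list[LogisticFit]) -> pd.DataFrame:
    """Tidy agonist x pathway summary of E_max and potency.

    One row per fit with ``emax_pct`` (= |response range|), ``p_half`` and
    an ``NR`` marker; pivot on (ligand, pathway) for heatmap-style
    matrices of the kind used to compare Galpha-subunit activation
    profiles.
    """
    if not fits:
        raise InsufficientDataError("no fits to summarise")
    rows = []
    for f in fits:
        rows.append(
            {
                "ligand": f.ligand_id,
                "pathway": f.pathway_id,
                "emax_pct": float("nan") if f.nr_flag else abs(f.response_range),
                "p_half": float("nan") if f.nr_flag else f.p_half,
                "nr": f.nr_flag,
            }
        )
    return pd.DataFrame(rows)
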