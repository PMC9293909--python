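"""Global operational-model fitting and delta-log(tau/KA) bias factors.

The Black-Leff operational model expresses the response to agonist
concentration [A] through an efficacy parameter tau and a functional
equilibrium dissociation constant K_A:

    E([A]) = basal + (Em - basal) * tau^n [A]^n / ((K_A + [A])^n + tau^n [A]^n)

Within one transduction pathway the system parameters Em (maximal system
response), basal and the transducer slope n are shared across agonists,
while (log tau, log K_A) are estimated per agonist — the global fit that
makes log K_A identifiable even for full agonists, provided at least one
partial agonist anchors Em.

Agonist bias is the transduction coefficient log(tau/K_A) expressed
relative to a reference agonist within the same pathway:

    delta log(tau/K_A) = log(tau/K_A)_ligand - log(tau/K_A)_reference

with the error of this composite propagated as the root sum of squares of
the two transduction-coefficient SEMs:

    pooled SEM = sqrt(SEM_A^2 + SEM_B^2)

Agonist/pathway combinations with no measurable response (NR) are excluded
from the global fit and propagated as NR in the bias table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from biaskit.assay_core import AssayError, ConcentrationResponse
from biaskit.dose_response import DEFAULT_NR_FRACTION, DEFAULT_WINDOW, fit_logistic3

logger = logging.getLogger("biaskit")

__all__ = [
    "OperationalFit",
    "BiasResult",
    "operational_response",
    "fit_operational_global",
    "compute_bias",
    "bootstrap_bias_sem",
    "goa_gob_concordance",
    "cross_pathway_bias",
]


class MissingReferenceError(AssayError):
    """The reference agonist is absent or NR in the pathway."""


class EmptyFitError(AssayError):
    """No non-NR agonist is available to fit."""


class PairingError(AssayError):
    """Concentration grids of a matched pair do not align."""


@dataclass
class OperationalFit:
    """Per-agonist operational-model parameters from a global pathway fit."""

    ligand_id: str
    pathway_id: str
    log_tau: float
    log_ka: float
    sems: dict[str, float] = field(default_factory=dict)
    shared_em: float = float("nan")
    shared_basal: float = float("nan")
    slope_n: float = 1.0
    nr_flag: bool = False
    sems_available: bool = True

    @property
    def log_tau_over_ka(self) -> float:
        return self.log_tau - self.log_ka

    @property
    def ec50(self) -> float:
        """Closed-form EC50; exact for n = 1 (EC50 = K_A / (1 + tau))."""
        ka, tau = 10.0**self.log_ka, 10.0**self.log_tau
        n = self.slope_n
        denom = (2.0 + tau**n) ** (1.0 / n) - 1.0
        return ka / denom

    def to_record(self) -> dict:
        return {
            "ligand": self.ligand_id,
            "pathway": self.pathway_id,
            "log_tau": self.log_tau,
            "log_ka": self.log_ka,
            "log_tau_over_ka": float("nan") if self.nr_flag else self.log_tau_over_ka,
            "sem_log_tau": self.sems.get("log_tau", float("nan")),
            "sem_log_ka": self.sems.get("log_ka", float("nan")),
            "sem_log_tau_over_ka": self.sems.get("log_tau_over_ka", float("nan")),
            "shared_em": self.shared_em,
            "shared_basal": self.shared_basal,
            "slope_n": self.slope_n,
            "nr_flag": self.nr_flag,
        }


@dataclass
class BiasResult:
    """delta-log(tau/K_A) of one ligand versus the reference agonist."""

    ligand_id: str
    pathway_id: str
    reference_id: str
    delta_log_tau_over_ka: float
    sem_ligand: float
    sem_reference: float
    nr_flag: bool = False

    @property
    def pooled_sem(self) -> float:
        return float(np.sqrt(self.sem_ligand**2 + self.sem_reference**2))

    @property
    def bias_factor(self) -> float:
        return 10.0**self.delta_log_tau_over_ka

    def to_record(self) -> dict:
        return {
            "ligand": self.ligand_id,
            "pathway": self.pathway_id,
            "reference": self.reference_id,
            "delta_log_tau_over_ka": self.delta_log_tau_over_ka,
            "pooled_sem": self.pooled_sem,
            "bias_factor": self.bias_factor,
            "nr_flag": self.nr_flag,
        }


def operational_response(
    conc: np.ndarray,
    log_tau: float,
    log_ka: float,
    em: float = 100.0,
    basal: float = 0.0,
    slope_n: float = 1.0,
) -> np.ndarray:
    """Operational-model mean response at molar concentrations ``conc``."""
    a = np.asarray(conc, dtype=float)
    tau_n = (10.0**log_tau) ** slope_n
    ka = 10.0**log_ka
    num = tau_n * a**slope_n
    return basal + (em - basal) * num / ((ka + a) ** slope_n + num)


def _classify_panel(
    panel: list[ConcentrationResponse],
    nr_threshold_fraction: float,
    window: float,
) -> tuple[list[ConcentrationResponse], list[ConcentrationResponse]]:
    active, silent = [], []
    for cr in panel:
        fit = fit_logistic3(cr, direction="auto", nr_threshold_fraction=nr_threshold_fraction,
                            window=window)
        (silent if fit.nr_flag else active).append(cr)
    return active, silent


def _global_minimize(
    active: list[ConcentrationResponse],
    fix_slope: float | None,
    window: float,
    em_anchor_weight: float = 1.0,
) -> lmfit.minimizer.MinimizerResult:
    params = lmfit.Parameters()
    all_y = np.concatenate([cr.pooled()[1] for cr in active])
    log_lo = min(np.log10(cr.concentrations[0]) for cr in active) - 4.0
    log_hi = max(np.log10(cr.concentrations[-1]) for cr in active) + 4.0
    params.add("em", value=float(np.max(all_y)), min=0.1 * window, max=10.0 * window)
    params.add("basal", value=float(min(np.min(all_y), 0.0)), min=-window, max=0.5 * window)
    if fix_slope is None:
        params.add("n", value=1.0, min=0.2, max=5.0)
    else:
        params.add("n", value=fix_slope, vary=False)
    for i, cr in enumerate(active):
        # EC50-anchored initial guesses from a per-agonist logistic fit
        lf = fit_logistic3(cr, direction="auto")
        top = abs(lf.response_range)
        frac = min(max(top / max(np.max(all_y), 1e-9), 0.05), 0.95)
        tau0 = frac / (1.0 - frac)
        log_ka0 = -lf.p_half + np.log10(1.0 + tau0) if np.isfinite(lf.p_half) else 0.5 * (log_lo + log_hi)
        params.add(f"log_tau_{i}", value=float(np.log10(tau0)), min=-3.0, max=5.0)
        params.add(f"log_ka_{i}", value=float(np.clip(log_ka0, log_lo, log_hi)),
                   min=log_lo, max=log_hi)

    def residual(p):
        out = []
        for i, cr in enumerate(active):
            x, y = cr.pooled()
            mu = operational_response(
                x, p[f"log_tau_{i}"].value, p[f"log_ka_{i}"].value,
                p["em"].value, p["basal"].value, p["n"].value,
            )
            out.append(y - mu)
        # With n = 1 the operational curve is an exact logistic, leaving
        # (Em, tau, K_A) on a one-dimensional ridge that the data cannot
        # resolve; delta-log(tau/K_A) is invariant along it.  A weak anchor
        # of Em to the assay window selects a unique, reproducible point.
        out.append(np.atleast_1d(em_anchor_weight * (p["em"].value - window)))
        return np.concatenate(out)

    return lmfit.minimize(
        residual, params, method="leastsq", max_nfev=100000,
        ftol=1e-14, xtol=1e-14, gtol=1e-14,
    )


def fit_operational_global(
    panel: list[ConcentrationResponse],
    nr_threshold_fraction: float = DEFAULT_NR_FRACTION,
    window: float = DEFAULT_WINDOW,
    slope_mode: str = "auto",
    em_anchor_weight: float = 1.0,
) -> list[OperationalFit]:
    """Fit the operational model jointly to all agonists of one pathway.

    Em, basal and the transducer slope n are shared across agonists;
    (log tau, log K_A) are per agonist.  Responses must be normalised to a
    common window (default 0-100%) and expressed so that agonist effect
    increases the response (e.g. % inhibition of forskolin-stimulated
    cAMP).

    ``slope_mode`` is ``"fixed"`` (n = 1), ``"free"``, or ``"auto"``:
    fit n freely, then refit with n = 1 when its 95% confidence interval
    includes 1.

    With n = 1 the model is an exact logistic in [A], so the data
    constrain only (Em * tau/(1+tau), K_A/(1+tau)) per agonist and Em
    itself lies on a flat ridge; ``em_anchor_weight`` adds one weak
    residual pulling Em toward the window to select a unique point on
    that ridge.  Bias deltas are invariant to the choice because the
    shared Em shifts every agonist's log(tau/K_A) identically.  The
    default weight 1.0 makes the anchor count like a single replicate
    observation of the window maximum, keeping the reported SEMs finite
    without materially constraining an identifiable fit.

    NR agonists are excluded from the joint fit and returned with
    ``nr_flag`` set and no numeric parameters.
    """
    if not panel:
        raise EmptyFitError("empty agonist panel")
    if any(cr.pathway_id != panel[0].pathway_id for cr in panel):
        raise AssayError("fit_operational_global expects a single pathway")
    active, silent = _classify_panel(panel, nr_threshold_fraction, window)
    if not active:
        raise EmptyFitError(
            f"all agonists NR in pathway {panel[0].pathway_id!r}; nothing to fit"
        )

    if slope_mode == "fixed":
        result = _global_minimize(active, 1.0, window, em_anchor_weight)
    elif slope_mode == "free":
        result = _global_minimize(active, None, window, em_anchor_weight)
    elif slope_mode == "auto":
        result = _global_minimize(active, None, window, em_anchor_weight)
        n_par = result.params["n"]
        if n_par.stderr is None or abs(n_par.value - 1.0) <= 1.96 * n_par.stderr:
            result = _global_minimize(active, 1.0, window, em_anchor_weight)
    else:
        raise ValueError(f"unknown slope_mode {slope_mode!r}")

    covar = getattr(result, "covar", None)
    sems_available = covar is not None and np.all(np.isfinite(covar))
    if not sems_available:
        warnings.warn(
            f"pathway {active[0].pathway_id!r}: joint covariance unavailable or "
            "singular; parameter SEMs flagged unavailable",
            RuntimeWarning,
            stacklevel=2,
        )
    p = result.params
    taus = [p[f"log_tau_{i}"].value for i in range(len(active))]
    if taus and min(taus) > 1.0:
        warnings.warn(
            "no partial agonist in the panel (all tau > 10); log K_A is weakly "
            "identified in the global fit",
            RuntimeWarning,
            stacklevel=2,
        )

    def _cov(name_a: str, name_b: str) -> float:
        if not sems_available:
            return float("nan")
        names = result.var_names
        if name_a not in names or name_b not in names:
            return 0.0
        return float(covar[names.index(name_a), names.index(name_b)])

    fits: list[OperationalFit] = []
    for i, cr in enumerate(active):
        lt, lk = f"log_tau_{i}", f"log_ka_{i}"
        var_t, var_k, cov_tk = _cov(lt, lt), _cov(lk, lk), _cov(lt, lk)
        var_ratio = var_t + var_k - 2.0 * cov_tk
        sems = {
            "log_tau": float(np.sqrt(var_t)) if sems_available else float("nan"),
            "log_ka": float(np.sqrt(var_k)) if sems_available else float("nan"),
            "log_tau_over_ka": float(np.sqrt(max(var_ratio, 0.0)))
            if sems_available
            else float("nan"),
        }
        fits.append(
            OperationalFit(
                ligand_id=cr.ligand_id,
                pathway_id=cr.pathway_id,
                log_tau=float(p[lt].value),
                log_ka=float(p[lk].value),
                sems=sems,
                shared_em=float(p["em"].value),
                shared_basal=float(p["basal"].value),
                slope_n=float(p["n"].value),
                sems_available=sems_available,
            )
        )
    for cr in silent:
        fits.append(
            OperationalFit(
                ligand_id=cr.ligand_id,
                pathway_id=cr.pathway_id,
                log_tau=float("nan"),
                log_ka=float("nan"),
                sems={},
                nr_flag=True,
                sems_available=False,
            )
        )
    return fits


def compute_bias(fits: list[OperationalFit], reference_id: str) -> list[BiasResult]:
    """delta-log(tau/K_A) of each ligand versus the reference, per pathway.

    The reference compared with itself gives exactly 0 with pooled SEM
    sqrt(2) x its own SEM.  NR ligands propagate NR (no numeric delta).
    """
    by_pathway: dict[str, list[OperationalFit]] = {}
    for f in fits:
        by_pathway.setdefault(f.pathway_id, []).append(f)
    out: list[BiasResult] = []
    for pathway, group in by_pathway.items():
        refs = [f for f in group if f.ligand_id == reference_id]
        if not refs or refs[0].nr_flag:
            raise MissingReferenceError(
                f"reference agonist {reference_id!r} absent or NR in pathway {pathway!r}"
            )
        ref = refs[0]
        ref_sem = ref.sems.get("log_tau_over_ka", float("nan"))
        for f in group:
            if f.nr_flag:
                out.append(
                    BiasResult(f.ligand_id, pathway, reference_id,
                               float("nan"), float("nan"), ref_sem, nr_flag=True)
                )
                continue
            delta = 0.0 if f is ref else f.log_tau_over_ka - ref.log_tau_over_ka
            out.append(
                BiasResult(
                    ligand_id=f.ligand_id,
                    pathway_id=pathway,
                    reference_id=reference_id,
                    delta_log_tau_over_ka=delta,
                    sem_ligand=f.sems.get("log_tau_over_ka", float("nan")),
                    sem_reference=ref_sem,
                )
            )
    return out


def bootstrap_bias_sem(
    panel: list[ConcentrationResponse],
    reference_id: str,
    n_boot: int = 500,
    seed: int | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Seeded bootstrap SEM of delta-log(tau/K_A) over replicates.

    Replicates are resampled with replacement within each concentration,
    the global fit and bias computation are rerun, and the standard
    deviation of the bootstrap deltas estimates the SEM — an alternative
    to the asymptotic covariance.
    """
    rng = np.random.default_rng(seed)
    deltas: dict[str, list[float]] = {}
    for _ in range(n_boot):
        resampled = []
        for cr in panel:
            responses = [rng.choice(r, size=r.size, replace=True) for r in cr.responses]
            resampled.append(cr.with_responses(responses))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            try:
                fits = fit_operational_global(resampled, **fit_kwargs)
                bias = compute_bias(fits, reference_id)
            except AssayError:
                continue
        for b in bias:
            if not b.nr_flag:
                deltas.setdefault(b.ligand_id, []).append(b.delta_log_tau_over_ka)
    rows = [
        {
            "ligand": ligand,
            "pathway": panel[0].pathway_id,
            "bootstrap_sem": float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"),
            "n_boot_ok": len(v),
        }
        for ligand, v in deltas.items()
    ]
    return pd.DataFrame(rows)


def goa_gob_concordance(
    cr_goa: ConcentrationResponse, cr_gob: ConcentrationResponse
) -> pd.DataFrame:
    """Paired per-concentration responses on two pathways for a unity plot.

    Returns one row per concentration with the mean response on each
    pathway and the signed deviation from the line of unity
    (``response_b - response_a``); identical coupling on both pathways
    gives all-zero deviations, a silent pathway puts every point on one
    side of the line.
    """
    if cr_goa.ligand_id != cr_gob.ligand_id:
        raise PairingError(
            f"ligand mismatch: {cr_goa.ligand_id!r} vs {cr_gob.ligand_id!r}"
        )
    if cr_goa.n_concentrations != cr_gob.n_concentrations or not np.allclose(
        cr_goa.concentrations, cr_gob.concentrations, rtol=1e-9
    ):
        raise PairingError("concentration grids do not match")
    mean_a, mean_b = cr_goa.mean_responses(), cr_gob.mean_responses()
    return pd.DataFrame(
        {
            "ligand": cr_goa.ligand_id,
            "concentration_M": cr_goa.concentrations,
            f"response_{cr_goa.pathway_id}": mean_a,
            f"response_{cr_gob.pathway_id}": mean_b,
            "deviation_from_unity": mean_b - mean_a,
        }
    )


def cross_pathway_bias(
    bias_a: list[BiasResult], bias_b: list[BiasResult]
) -> pd.DataFrame:
    """Optional delta-delta-log(tau/K_A) between two pathways.

    Subtracts the within-pathway deltas of matching ligands
    (pathway_b - pathway_a); pooled SEM is again the root sum of squares.
    """
    a_by_ligand = {b.ligand_id: b for b in bias_a}
    rows = []
    for b in bias_b:
        a = a_by_ligand.get(b.ligand_id)
        if a is None:
            continue
        nr = a.nr_flag or b.nr_flag
        rows.append(
            {
                "ligand": b.ligand_id,
                "pathway_a": a.pathway_id,
                "pathway_b": b.pathway_id,
                "dd_log_tau_over_ka": float("nan")
                if nr
                else b.delta_log_tau_over_ka - a.delta_log_tau_over_ka,
                "pooled_sem": float("nan")
                if nr
                else float(np.sqrt(a.pooled_sem**2 + b.pooled_sem**2)),
                "nr_flag": nr,
            }
        )
    return pd.DataFrame(rows)
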