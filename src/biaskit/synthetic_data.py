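"""Seeded synthetic-assay generators with known ground truth.

Every input the pipeline consumes can be generated here: operational-model
concentration-response panels (including zero-efficacy NR agonists),
mono- and biphasic competition-binding displacement, BRET time-courses
with vehicle baselines, and first-order decay series.  The forward mean
models are the same functions the fitting modules use
(:func:`biaskit.operational_bias.operational_response`,
:func:`biaskit.binding.two_site_displacement`), so generator and fitter
share a single source of truth; the test suite re-derives the operational
mean independently to guard that function.

All generators are pure functions of (spec, seed): the same seed yields
byte-identical tables.  Noise is i.i.d. Gaussian on the response scale
(optionally proportional), reflecting replicate scatter reported as
mean +/- SEM.

The default panel mirrors the study design this package was built around:
five adenosine-receptor agonists against six Galpha-subunit pathways on a
1 pM - 100 uM half-log agonist grid, with one agonist (the BnOCPA-like
probe) active only at the Gob pathway and silent everywhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from biaskit.assay_core import ConcentrationResponse, DecaySeries, TimeCourse
from biaskit.binding import two_site_displacement
from biaskit.operational_bias import operational_response
from biaskit.pk import LN2

__all__ = [
    "PanelSpec",
    "default_concentration_grid",
    "paper_like_panel_spec",
    "simulate_cr_panel",
    "simulate_competition",
    "simulate_bret",
    "simulate_decay",
]


def default_concentration_grid(
    low: float = 1e-12, high: float = 1e-4, per_decade: int = 2
) -> np.ndarray:
    """Half-log agonist grid from 1 pM to 100 uM (17 concentrations)."""
    n = int(round(per_decade * math.log10(high / low))) + 1
    return np.logspace(math.log10(low), math.log10(high), n)


@dataclass
class PanelSpec:
    """Ground truth for a multi-agonist, multi-pathway assay panel.

    ``truth`` maps agonist -> pathway -> (log_tau, log_ka); a ``None``
    entry marks a zero-efficacy (NR) combination whose responses are pure
    basal + noise.  ``noise_sd`` is in % of the assay window.
    """

    truth: dict[str, dict[str, tuple[float, float] | None]]
    em: float = 100.0
    basal: float = 0.0
    slope_n: float = 1.0
    concentrations: np.ndarray = field(default_factory=default_concentration_grid)
    replicates: int = 3
    noise_sd: float = 2.0
    proportional_noise: bool = False
    seed: int = 0

    @property
    def agonists(self) -> list[str]:
        return list(self.truth)

    @property
    def pathways(self) -> list[str]:
        first = next(iter(self.truth.values()))
        return list(first)


def paper_like_panel_spec(seed: int = 0, replicates: int = 6, noise_sd: float = 2.0) -> PanelSpec:
    """The default study-like panel: 5 agonists x 6 Galpha pathways.

    Coupling pattern: the reference agonist (adenosine-like) activates
    Goa, Gob and Gz; two prototypical agonists add Gi2; one adds Gi1; and
    the Gob-selective probe activates *only* Gob — the hallmark pattern of
    a Galpha-subunit-selective agonist.  Six replicates per concentration
    match typical cAMP assay repeats.
    """
    NR = None
    truth: dict[str, dict[str, tuple[float, float] | None]] = {
        "adenosine": {
            "Gi1": NR, "Gi2": NR, "Gi3": NR,
            "Goa": (0.9, -6.8), "Gob": (0.9, -6.9), "Gz": (0.5, -6.5),
        },
        "CPA": {
            "Gi1": NR, "Gi2": (0.4, -7.2), "Gi3": NR,
            "Goa": (1.0, -7.6), "Gob": (1.0, -7.5), "Gz": NR,
        },
        "NECA": {
            "Gi1": NR, "Gi2": (0.5, -6.9), "Gi3": NR,
            "Goa": (0.9, -7.0), "Gob": (0.8, -7.1), "Gz": NR,
        },
        "HOCPA": {
            "Gi1": (0.3, -7.0), "Gi2": NR, "Gi3": NR,
            "Goa": (0.8, -7.3), "Gob": (0.9, -7.4), "Gz": NR,
        },
        "BnOCPA": {
            "Gi1": NR, "Gi2": NR, "Gi3": NR,
            "Goa": NR, "Gob": (0.7, -7.8), "Gz": NR,
        },
    }
    return PanelSpec(truth=truth, replicates=replicates, noise_sd=noise_sd, seed=seed)


def _noise(rng: np.random.Generator, mean: np.ndarray, spec: PanelSpec) -> np.ndarray:
    if spec.noise_sd == 0:
        return np.zeros_like(mean)
    sd = spec.noise_sd * (spec.em - spec.basal) / 100.0
    if spec.proportional_noise:
        scale = sd * np.maximum(np.abs(mean), 1e-12) / max(abs(spec.em), 1e-12)
        return rng.normal(0.0, 1.0, size=mean.shape) * scale
    return rng.normal(0.0, sd, size=mean.shape)


def simulate_cr_panel(spec: PanelSpec) -> list[ConcentrationResponse]:
    """Operational-model concentration-response panel with Gaussian noise.

    Returns one :class:`ConcentrationResponse` per (agonist, pathway),
    with the injected ground truth recorded in ``meta`` for recovery
    tests.  NR combinations generate basal + noise only.
    """
    if not spec.truth:
        raise ValueError("empty agonist list")
    rng = np.random.default_rng(spec.seed)
    conc = np.asarray(spec.concentrations, dtype=float)
    out: list[ConcentrationResponse] = []
    for agonist, pathways in spec.truth.items():
        for pathway, params in pathways.items():
            if params is None:
                mean = np.full(conc.size, spec.basal)
                meta = {"truth_nr": True}
            else:
                log_tau, log_ka = params
                mean = operational_response(
                    conc, log_tau, log_ka, spec.em, spec.basal, spec.slope_n
                )
                meta = {
                    "truth_nr": False,
                    "truth_log_tau": log_tau,
                    "truth_log_ka": log_ka,
                    "truth_em": spec.em,
                    "truth_basal": spec.basal,
                    "truth_slope_n": spec.slope_n,
                }
            draws = np.tile(mean, (spec.replicates, 1)) + _noise(
                rng, np.tile(mean, (spec.replicates, 1)), spec
            )
            out.append(
                ConcentrationResponse(
                    ligand_id=agonist,
                    pathway_id=pathway,
                    assay_kind="cAMP_inhibition",
                    concentrations=conc.copy(),
                    responses=[draws[:, j] for j in range(conc.size)],
                    response_units="% window",
                    meta=meta,
                )
            )
    return out


def simulate_competition(
    model: str,
    ligand_id: str = "competitor",
    ki: float = 1e-8,
    frac_high: float = 0.5,
    ki_high: float = 3.8e-9,
    ki_low: float = 1e-6,
    tracer_conc: float = 1e-9,
    tracer_kd: float = 1.23e-9,
    top: float = 100.0,
    bottom: float = 0.0,
    concentrations: np.ndarray | None = None,
    replicates: int = 3,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> ConcentrationResponse:
    """Competition-binding displacement data from known affinities.

    ``model`` is ``"one_site"`` or ``"two_site"``.  True K_i values are
    converted to IC50s through the inverse Cheng-Prusoff relation
    (IC50 = K_i * (1 + [L]/K_d)) before forward simulation, so fitting
    plus Cheng-Prusoff recovers the injected K_i exactly at zero noise.
    """
    rng = np.random.default_rng(seed)
    conc = (
        np.asarray(concentrations, dtype=float)
        if concentrations is not None
        else default_concentration_grid(1e-11, 1e-4)
    )
    occupancy = 1.0 + tracer_conc / tracer_kd
    if model == "one_site":
        ic50 = ki * occupancy
        mean = two_site_displacement(conc, top, bottom, 1.0, ic50, ic50)
        meta = {"truth_ki": ki, "model": model}
    elif model == "two_site":
        ic50_h, ic50_l = ki_high * occupancy, ki_low * occupancy
        mean = two_site_displacement(conc, top, bottom, frac_high, ic50_h, ic50_l)
        meta = {
            "truth_frac_high": frac_high,
            "truth_ki_high": ki_high,
            "truth_ki_low": ki_low,
            "model": model,
        }
    else:
        raise ValueError(f"unknown competition model {model!r}")
    meta.update({"tracer_conc": tracer_conc, "tracer_kd": tracer_kd})
    sd = noise_sd * (top - bottom) / 100.0
    draws = np.tile(mean, (replicates, 1))
    if sd > 0:
        draws = draws + rng.normal(0.0, sd, size=draws.shape)
    return ConcentrationResponse(
        ligand_id=ligand_id,
        pathway_id="binding",
        assay_kind="binding_competition",
        concentrations=conc.copy(),
        responses=[draws[:, j] for j in range(conc.size)],
        response_units="% specific binding",
        meta=meta,
    )


def simulate_bret(
    truth: dict[float, tuple[float, float]],
    ligand_id: str = "agonist",
    assay: str = "arrestin",
    base_ratio: float = 1.0,
    vehicle_drift: float = 0.0,
    donor_level: float = 1000.0,
    duration_min: float = 60.0,
    noise_sd: float = 0.002,
    seed: int = 0,
) -> list[TimeCourse]:
    """BRET time-courses on a 1-min grid over 1 h, plus a vehicle well.

    ``truth`` maps concentration (M) -> (plateau, rate per min); the
    ligand-induced ratio change is a mono-exponential approach
    plateau * (1 - exp(-rate * t)) on top of the shared baseline ratio.
    For TRUPATH-style dissociation pass negative plateaus: activation
    *reduces* the net BRET ratio.  ``vehicle_drift`` adds a slow linear
    ratio drift common to all wells.  Donor emission is constant; the
    acceptor channel carries signal and noise.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_min + 1e-9, 1.0)
    drift = base_ratio + vehicle_drift * times

    def make_well(well_id, conc, signal, is_vehicle=False):
        ratio = drift + signal
        if noise_sd > 0:
            ratio = ratio + rng.normal(0.0, noise_sd, size=times.size)
        return TimeCourse(
            well_id=well_id,
            ligand_id=ligand_id if not is_vehicle else "vehicle",
            concentration=conc,
            times=times.copy(),
            donor_emission=np.full(times.size, donor_level),
            acceptor_emission=np.clip(ratio, 0.0, None) * donor_level,
            is_vehicle=is_vehicle,
        )

    wells = [make_well("vehicle", float("nan"), np.zeros_like(times), is_vehicle=True)]
    for i, (conc, (plateau, rate)) in enumerate(sorted(truth.items())):
        signal = plateau * (1.0 - np.exp(-rate * times))
        wells.append(make_well(f"well_{i:02d}", float(conc), signal))
    return wells


def simulate_decay(
    t_half: float,
    compound_id: str = "compound",
    matrix_id: str = "microsomes",
    grid: np.ndarray | None = None,
    protein_concentration: float | None = 0.0001,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DecaySeries:
    """First-order % remaining series on the standard 0-60 min grid.

    The decay constant is derived with the same rounded ln 2 the fitting
    side uses (k = 0.693 / t1/2), so noiseless generate-and-fit round
    trips are exact.  ``noise_sd`` is in percentage points; time 0 is
    left at exactly 100%.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(grid, dtype=float) if grid is not None else np.array([0.0, 15.0, 30.0, 45.0, 60.0])
    pct = 100.0 * np.exp(-(LN2 / t_half) * t)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=t.size)
        noise[0] = 0.0
        pct = np.clip(pct + noise, 1e-6, None)
    return DecaySeries(
        compound_id=compound_id,
        matrix_id=matrix_id,
        times=t,
        percent_remaining=pct,
        protein_concentration=protein_concentration,
    )
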