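"""End-to-end pipeline: raw/simulated tables -> fits -> bias/binding/Schild/PK reports.

A :class:`PipelineConfig` (YAML-friendly) names the stages to run and their
options.  Each stage writes a tidy CSV into the output directory and the
config itself is echoed alongside for provenance.  With no input files the
``simulate`` stage produces the full study-like synthetic bundle first, so
``stages: [simulate, dose_response, bias, binding, schild, bret, pk]`` is a
complete deterministic run from a single seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from biaskit import binding as binding_mod
from biaskit import bret as bret_mod
from biaskit import pk as pk_mod
from biaskit import synthetic_data
from biaskit.assay_core import AssayError, load_assay_table, write_results
from biaskit.dose_response import fit_logistic3, summarize_panel
from biaskit.operational_bias import compute_bias, fit_operational_global
from biaskit.schild import schild_from_fits

logger = logging.getLogger("biaskit")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

KNOWN_STAGES = ("simulate", "dose_response", "bias", "binding", "schild", "bret", "pk")


class PipelineError(AssayError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run."""

    stages: list[str]
    output_dir: str = "results/pipeline"
    seed: int = 0
    inputs: dict[str, str] = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    dose_response: dict = field(default_factory=dict)
    bias: dict = field(default_factory=dict)
    binding: dict = field(default_factory=dict)
    schild: dict = field(default_factory=dict)
    bret: dict = field(default_factory=dict)
    pk: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stages:
            raise PipelineError("empty stage list")
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            raise PipelineError(f"unknown stage(s) {unknown}; expected {list(KNOWN_STAGES)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise PipelineError(f"unknown config key(s) {sorted(bad)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def _stage_simulate(cfg: PipelineConfig, outdir: Path, bundle: dict) -> pd.DataFrame:
    opts = dict(cfg.simulate)
    spec = synthetic_data.paper_like_panel_spec(
        seed=cfg.seed,
        replicates=int(opts.get("replicates", 6)),
        noise_sd=float(opts.get("noise_sd", 2.0)),
    )
    panel = synthetic_data.simulate_cr_panel(spec)
    bundle["cr"] = panel
    bundle["panel_spec"] = spec
    frame = pd.concat([cr.to_frame() for cr in panel], ignore_index=True)
    frame.to_csv(outdir / "simulated_cr.csv", index=False, float_format="%.12g")
    bundle["competition"] = synthetic_data.simulate_competition(
        "two_site", ligand_id="probe", seed=cfg.seed + 1,
        **{k: v for k, v in opts.items() if k in
           ("frac_high", "ki_high", "ki_low", "tracer_conc", "tracer_kd")},
    )
    bundle["decay"] = [
        synthetic_data.simulate_decay(60.0, compound_id="probe", seed=cfg.seed + 2),
        synthetic_data.simulate_decay(30.0, compound_id="reference_1", seed=cfg.seed + 3),
    ]
    truth = {c: (0.05, 0.8) for c in np.logspace(-10, -6, 9)}
    bundle["bret"] = synthetic_data.simulate_bret(
        truth, ligand_id="probe", assay="arrestin", seed=cfg.seed + 4
    )
    return frame


def _stage_dose_response(cfg: PipelineConfig, outdir: Path, bundle: dict) -> pd.DataFrame:
    if "cr" not in bundle:
        path = cfg.inputs.get("cr")
        if path is None:
            raise PipelineError("dose_response: no concentration-response input available")
        bundle["cr"] = load_assay_table(path, "cr")
    opts = dict(cfg.dose_response)
    fits = [
        fit_logistic3(
            cr,
            direction=opts.get("direction", "auto"),
            nr_threshold_fraction=float(opts.get("nr_threshold_fraction", 0.1)),
        )
        for cr in bundle["cr"]
    ]
    bundle["fits"] = fits
    write_results(fits, outdir / "logistic_fits.csv")
    summary = summarize_panel(fits)
    summary.to_csv(outdir / "panel_summary.csv", index=False, float_format="%.12g")
    return summary


def _stage_bias(cfg: PipelineConfig, outdir: Path, bundle: dict) -> pd.DataFrame:
    if "cr" not in bundle:
        raise PipelineError("bias: run dose_response/simulate first or provide cr input")
    opts = dict(cfg.bias)
    reference = opts.get("reference", "adenosine")
    pathways = opts.get("pathways")
    by_pathway: dict[str, list] = {}
    for cr in bundle["cr"]:
        by_pathway.setdefault(cr.pathway_id, []).append(cr)
    all_bias = []
    op_fits = []
    for pathway, panel in by_pathway.items():
        if pathways and pathway not in pathways:
            continue
        try:
            fits = fit_operational_global(panel, slope_mode=opts.get("slope_mode", "auto"))
        except AssayError as exc:
            logger.warning("bias: skipping pathway %s (%s)", pathway, exc)
            continue
        op_fits.extend(fits)
        all_bias.extend(compute_bias(fits, reference))
    if not all_bias:
        raise PipelineError("bias: no pathway could be fitted")
    write_results(op_fits, outdir / "operational_fits.csv")
    return write_results(all_bias, outdir / "bias.csv")


def _stage_binding(cfg: PipelineConfig, outdir: Path, bundle: dict) -> pd.DataFrame:
    opts = dict(cfg.binding)
    if "competition" not in bundle:
        path = cfg.inputs.get("binding")
        if path is None:
            raise PipelineError("binding: no competition input available")
        bundle["competition"] = load_assay_table(path, "cr")[0]
    cr = bundle["competition"]
    tracer_conc = float(opts.get("tracer_conc", cr.meta.get("tracer_conc", 1e-9)))
    tracer_kd = float(opts.get("tracer_kd", cr.meta.get("tracer_kd", 1.23e-9)))
    model = opts.get("model", cr.meta.get("model", "one_site"))
    if model == "two_site":
        res = binding_mod.fit_competition_two_site(cr, tracer_conc, tracer_kd)
    else:
        res = binding_mod.fit_competition_one_site(cr, tracer_conc, tracer_kd)
    return write_results([res], outdir / "binding.csv")


def _stage_schild(cfg: PipelineConfig, outdir: Path, bundle: dict) -> pd.DataFrame:
    opts = dict(cfg.schild)
    antagonist_conc = float(opts.get("antagonist_conc", 1.13e-7))
    kd_true = float(opts.get("simulated_kd", 1.13e-7))
    agonist = opts.get("agonist", "adenosine")
    pathway = opts.get("pathway", "Goa")
    ctrl = next(
        (f for f in bundle.get("fits", [])
         if f.ligand_id == agonist and f.pathway_id == pathway and not f.nr_flag),
        None,
    )
    if ctrl is None:
        raise PipelineError(f"schild: no control fit for {agonist}/{pathway}")
    # simulate the antagonist-shifted curve from the control fit
    shift = 1.0 + antagonist_conc / kd_true
    cr_src = next(
        cr for cr in bundle["cr"] if cr.ligand_id == agonist and cr.pathway_id == pathway
    )
    rng = np.random.default_rng(cfg.seed + 5)
    from biaskit.operational_bias import operational_response  # local to avoid cycle

    meta = cr_src.meta
    mean = operational_response(
        cr_src.concentrations / shift,
        meta.get("truth_log_tau", 0.9),
        meta.get("truth_log_ka", -6.8),
        meta.get("truth_em", 100.0),
        meta.get("truth_basal", 0.0),
    )
    noise_sd = float(opts.get("noise_sd", 2.0))
    responses = [
        mean[j] + rng.normal(0.0, noise_sd, size=len(cr_src.responses[j]))
        for j in range(cr_src.n_concentrations)
    ]
    cr_antag = cr_src.with_responses(responses, antagonist_conc=antagonist_conc)
    fit_antag = fit_logistic3(cr_antag, direction="auto")
    result = schild_from_fits(ctrl, fit_antag, antagonist_conc, antagonist_id="probe")
    return write_results([result], outdir / "schild.csv")


def _stage_bret(cfg: PipelineConfig, outdir: Path, bundle: dict) -> pd.DataFrame:
    opts = dict(cfg.bret)
    if "bret" not in bundle:
        path = cfg.inputs.get("bret")
        if path is None:
            raise PipelineError("bret: no time-course input available")
        bundle["bret"] = load_assay_table(path, "bret")
    assay = opts.get("assay", "arrestin")
    wells = bundle["bret"]
    vehicle = next((w for w in wells if w.is_vehicle), None)
    if vehicle is None:
        raise PipelineError("bret: no vehicle well found")
    vehicle_series = bret_mod.compute_ratio(vehicle, assay=assay)
    series = [
        bret_mod.delta_bret(bret_mod.compute_ratio(w, assay=assay), vehicle_series)
        for w in wells
        if not w.is_vehicle
    ]
    cr = bret_mod.extract_cr_at_time(series, t=opts.get("time"), assay=assay)
    fit = fit_logistic3(cr, direction="auto", window=abs(float(np.ptp(cr.mean_responses()))) or 1.0)
    frame = write_results([fit], outdir / "bret_fits.csv")
    return frame


def _stage_pk(cfg: PipelineConfig, outdir: Path, bundle: dict) -> pd.DataFrame:
    if "decay" not in bundle:
        path = cfg.inputs.get("decay")
        if path is None:
            raise PipelineError("pk: no decay input available")
        bundle["decay"] = load_assay_table(path, "decay")
    results = [pk_mod.fit_half_life(s) for s in bundle["decay"]]
    return write_results(results, outdir / "pk.csv")


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "dose_response": _stage_dose_response,
    "bias": _stage_bias,
    "binding": _stage_binding,
    "schild": _stage_schild,
    "bret": _stage_bret,
    "pk": _stage_pk,
}


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run the configured stages in order and write per-stage CSVs.

    Returns a mapping stage name -> output DataFrame.  Any stage error is
    re-raised as :class:`PipelineError` naming the failing stage.  The
    config is echoed to ``<output_dir>/config.yaml`` for provenance.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    bundle: dict = {}
    outputs: dict[str, pd.DataFrame] = {}
    for stage in config.stages:
        logger.info("running stage %s", stage)
        try:
            outputs[stage] = _STAGE_FNS[stage](config, outdir, bundle)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return outputs
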