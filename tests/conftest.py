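import numpy as np
import pytest

from biaskit.assay_core import ConcentrationResponse
from biaskit.operational_bias import operational_response


def make_cr(
    concentrations,
    responses,
    ligand="L",
    pathway="P",
    assay="cAMP_inhibition",
    **meta,
):
    """Build a ConcentrationResponse from per-concentration replicate lists."""
    return ConcentrationResponse(
        ligand_id=ligand,
        pathway_id=pathway,
        assay_kind=assay,
        concentrations=np.asarray(concentrations, dtype=float),
        responses=[np.atleast_1d(np.asarray(r, dtype=float)) for r in responses],
        meta=meta,
    )


def logistic_cr(
    p_half=7.0,
    top=100.0,
    bottom=0.0,
    direction="stimulation",
    n_conc=8,
    replicates=1,
    span=3.0,
    noise_sd=0.0,
    rng=None,
    **kwargs,
):
    """Noisy 3PL data centred on p_half, spanning p_half +/- span decades."""
    conc = np.logspace(-p_half - span, -p_half + span, n_conc)
    sign = -1.0 if direction == "stimulation" else 1.0
    mean = bottom + (top - bottom) / (1.0 + 10.0 ** (sign * (np.log10(conc) + p_half)))
    rng = rng or np.random.default_rng(0)
    resp = []
    for m in mean:
        draws = np.full(replicates, m)
        if noise_sd > 0:
            draws = draws + rng.normal(0.0, noise_sd, size=replicates)
        resp.append(draws)
    return make_cr(conc, resp, **kwargs)


def operational_cr(
    log_tau,
    log_ka,
    em=100.0,
    basal=0.0,
    slope_n=1.0,
    conc=None,
    replicates=1,
    noise_sd=0.0,
    rng=None,
    **kwargs,
):
    """Noisy operational-model data with known ground truth."""
    if conc is None:
        conc = np.logspace(-12, -4, 17)
    mean = operational_response(conc, log_tau, log_ka, em, basal, slope_n)
    rng = rng or np.random.default_rng(0)
    resp = []
    for m in mean:
        draws = np.full(replicates, m)
        if noise_sd > 0:
            draws = draws + rng.normal(0.0, noise_sd, size=replicates)
        resp.append(draws)
    return make_cr(conc, resp, **kwargs)


@pytest.fixture
def two_agonist_panel():
    """Noiseless full + partial agonist panel: identifiable global fit."""
    full = operational_cr(1.0, -7.0, ligand="full", pathway="Gob")
    partial = operational_cr(0.0, -6.0, ligand="partial", pathway="Gob")
    return [full, partial]
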