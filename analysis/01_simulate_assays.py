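#!/usr/bin/env python
"""Generate the synthetic assay bundle every later step consumes.

Writes, under results/data/:
  cr_panel.csv       5 agonists x 6 Galpha pathways, operational-model
                     concentration-responses (the probe agonist is active
                     only at Gob), 6 replicates, noise SD 2% of window
  competition.csv    biphasic agonist-tracer displacement (3.8 nM / 1 uM)
  bret_arrestin.csv  1-min x 60-min BRET time-courses + vehicle well
  decay.csv          microsomal/plasma %-remaining series
"""

import numpy as np
import pandas as pd

from biaskit import synthetic_data as sd

SEED = 1
OUT = "results/data"


def main():
    import pathlib

    out = pathlib.Path(OUT)
    out.mkdir(parents=True, exist_ok=True)

    spec = sd.paper_like_panel_spec(seed=SEED)
    panel = sd.simulate_cr_panel(spec)
    frame = pd.concat([cr.to_frame() for cr in panel], ignore_index=True)
    frame.to_csv(out / "cr_panel.csv", index=False, float_format="%.12g")
    n_nr = sum(cr.meta.get("truth_nr", False) for cr in panel)
    print(f"cr_panel.csv: {len(panel)} curves ({n_nr} zero-efficacy), "
          f"{len(frame)} observations")

    comp = sd.simulate_competition(
        "two_site", ligand_id="probe", frac_high=0.5, ki_high=3.8e-9,
        ki_low=1e-6, tracer_conc=15.2e-6, tracer_kd=15.2e-6,
        noise_sd=1.0, replicates=4, seed=SEED + 1,
    )
    comp.to_frame().to_csv(out / "competition.csv", index=False, float_format="%.12g")
    print(f"competition.csv: biphasic displacement, {comp.n_concentrations} concentrations")

    conc = np.logspace(-10, -6, 9)
    wells = sd.simulate_bret(
        {c: (0.08 * c / (c + 1e-8), 0.9) for c in conc},
        ligand_id="probe", assay="arrestin", seed=SEED + 2,
    )
    rows = []
    for w in wells:
        for t, d, a in zip(w.times, w.donor_emission, w.acceptor_emission):
            rows.append({"well": w.well_id, "ligand": w.ligand_id,
                         "concentration_M": w.concentration, "time_min": t,
                         "donor": d, "acceptor": a, "is_vehicle": w.is_vehicle})
    pd.DataFrame(rows).to_csv(out / "bret_arrestin.csv", index=False, float_format="%.12g")
    print(f"bret_arrestin.csv: {len(wells)} wells x {wells[0].times.size} time points")

    decays = [
        sd.simulate_decay(60.0, compound_id="probe", matrix_id="microsomes",
                          noise_sd=1.0, seed=SEED + 3),
        sd.simulate_decay(33.0, compound_id="verapamil_like", matrix_id="plasma",
                          protein_concentration=None, noise_sd=1.0, seed=SEED + 4),
        sd.simulate_decay(10.0, compound_id="terfenadine_like", matrix_id="plasma",
                          protein_concentration=None, noise_sd=1.0, seed=SEED + 5),
        sd.simulate_decay(5000.0, compound_id="probe", matrix_id="PBS",
                          protein_concentration=None, noise_sd=0.5, seed=SEED + 6),
    ]
    rows = []
    for s in decays:
        for t, p in zip(s.times, s.percent_remaining):
            rows.append({"compound": s.compound_id, "matrix": s.matrix_id,
                         "time_min": t, "percent_remaining": p,
                         "protein_mg_per_uL": s.protein_concentration})
    pd.DataFrame(rows).to_csv(out / "decay.csv", index=False, float_format="%.12g")
    print(f"decay.csv: {len(decays)} series on the 0-60 min grid")


if __name__ == "__main__":
    main()
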