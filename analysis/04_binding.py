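#!/usr/bin/env python
"""Equilibrium binding: saturation K_d, one-site and two-site competition.

Fits a noiseless saturation curve at the radiotracer's 1.23 nM K_d as a
self-check, converts a one-site IC50 with Cheng-Prusoff at the 1 nM / 1.23
nM tracer constants, and fits the simulated biphasic agonist-tracer
displacement (results/data/competition.csv) with the shared-plateau
two-site model.  Writes results/binding.csv.
"""

import numpy as np

from biaskit.assay_core import load_assay_table, write_results
from biaskit.binding import cheng_prusoff, fit_competition_two_site, fit_saturation


def main():
    l = np.logspace(-10.5, -7.5, 8)
    sat = fit_saturation(l, 1000.0 * l / (1.23e-9 + l))
    print(f"saturation: Kd {sat.kd * 1e9:.3f} nM, Bmax {sat.bmax:.1f}")

    ki = cheng_prusoff(1.813e-9, tracer_conc=1e-9, tracer_kd=1.23e-9)
    print(f"one-site Cheng-Prusoff: IC50 1.813 nM -> Ki {ki * 1e9:.3f} nM "
          f"(pKi {-np.log10(ki):.2f})")

    comp = load_assay_table("results/data/competition.csv", "cr")[0]
    res = fit_competition_two_site(comp, tracer_conc=15.2e-6, tracer_kd=15.2e-6)
    print(f"two-site: frac_high {res.frac_high:.2f}, "
          f"Ki(high) {res.ki_high * 1e9:.2f} nM, Ki(low) {res.ki_low * 1e6:.2f} uM, "
          f"F vs one-site {res.f_statistic:.1f} (p {res.f_pvalue:.2g})")
    write_results([sat, res], "results/binding.csv")


if __name__ == "__main__":
    main()
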