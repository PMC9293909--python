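#!/usr/bin/env python
"""Fit 3-parameter logistic curves to every agonist x pathway combination.

Reads results/data/cr_panel.csv, fits each curve, and writes
  results/logistic_fits.csv   per-curve pEC50/top/bottom with SEMs
  results/panel_summary.csv   agonist x pathway E_max / pEC50 matrix rows
The probe agonist should come out NR everywhere except the Gob pathway.
"""

from biaskit.assay_core import load_assay_table, write_results
from biaskit.dose_response import fit_logistic3, summarize_panel


def main():
    curves = load_assay_table("results/data/cr_panel.csv", "cr")
    fits = [fit_logistic3(cr, direction="auto") for cr in curves]
    write_results(fits, "results/logistic_fits.csv")
    summary = summarize_panel(fits)
    summary.to_csv("results/panel_summary.csv", index=False, float_format="%.12g")

    nr = summary[summary.nr]
    print(f"fitted {len(fits)} curves; {len(nr)} NR combinations:")
    for _, row in nr.iterrows():
        print(f"  {row.ligand} at {row.pathway}: no measurable response")
    active = summary[~summary.nr]
    print("\nactive combinations (E_max %, pEC50):")
    for _, row in active.iterrows():
        print(f"  {row.ligand:10s} {row.pathway:4s}  "
              f"E_max {row.emax_pct:5.1f}%  pEC50 {row.p_half:.2f}")


if __name__ == "__main__":
    main()
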