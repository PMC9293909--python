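#!/usr/bin/env python
"""Stability metrics: first-order half-lives and intrinsic clearance.

Reads results/data/decay.csv and fits ln(% remaining) vs time per
compound/matrix.  The microsomal probe series carries a protein
concentration, so CL_int = 0.693/(t1/2 x 0.0001 mg/uL) is attached; the
PBS series barely declines and is reported as censored (t1/2 beyond the
observation window).

Writes results/pk.csv.
"""

import warnings

from biaskit.assay_core import load_assay_table, write_results
from biaskit.pk import fit_half_life


def main():
    series = load_assay_table("results/data/decay.csv", "decay")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        results = [fit_half_life(s) for s in series]
    frame = write_results(results, "results/pk.csv")
    for _, row in frame.iterrows():
        if row.censored:
            print(f"  {row['compound']:16s} {row['matrix']:10s} "
                  f"t1/2 > {row.censor_limit_min:.0f} min (censored)")
        else:
            clint = ("" if not row.clint_uL_min_mg == row.clint_uL_min_mg
                     else f", CL_int {row.clint_uL_min_mg:.1f} uL/min/mg")
            print(f"  {row['compound']:16s} {row['matrix']:10s} "
                  f"t1/2 {row.t_half_min:.1f} min{clint}")


if __name__ == "__main__":
    main()
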