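# biaskit

Quantitative pharmacology of G-protein-biased GPCR agonism.

Some agonists do not simply turn a receptor on: they steer it. A compound
can activate the adenosine A1 receptor through one inhibitory Gα subunit
(Gob) while being completely silent — or even acting as an antagonist — at
its closest relative (Goa). Establishing that claim quantitatively takes a
chain of analyses over plate-reader assays, and `biaskit` implements that
chain as a tested Python library for pharmacologists working on ligand
bias:

- **Dose–response**: three-parameter logistic fits (fixed Hill slope,
  pEC50/pIC50, response range) with forskolin-window normalisation and an
  explicit "no measurable response" (NR) classifier.
- **Operational bias**: global Black–Leff operational-model fits per
  pathway — E([A]) = basal + (Em−basal)·τⁿ[A]ⁿ/((K_A+[A])ⁿ+τⁿ[A]ⁿ) with
  Em, basal, n shared across agonists — and bias factors
  Δlog(τ/K_A) = log(τ/K_A)_ligand − log(τ/K_A)_reference with pooled
  SEM = √(SEM_A² + SEM_B²).
- **Binding**: saturation K_d, one-site competition K_i via Cheng–Prusoff
  (K_i = IC50/(1+[L]/K_d)), and biphasic two-site competition
  (fraction-high, K_i high/low, F-test vs one-site).
- **Schild**: single-dose analysis D′/D = 1 + [A]·K₂ converting an
  agonist-curve shift into the antagonist's K_d and pK_d.
- **BRET**: reduction of β-arrestin and TRUPATH G-protein-dissociation
  time-courses (acceptor/donor ratios, vehicle and baseline correction,
  fixed-time read-out) into dose–response inputs.
- **Stability**: first-order half-lives from %-remaining series and
  intrinsic clearance CL_int = 0.693/(t½ × mg protein/µL).
- **Synthetic assays**: seeded generators with known ground truth for every
  input above, so the whole chain is testable without raw plate data.

All stages consume and emit tidy CSV tables (schemas in
`biaskit.assay_core`); concentrations are molar internally and every log
quantity is base 10. See `docs/methods.md` for models, defaults and
numerical choices.

## Worked example

The numbered scripts under `analysis/` run the full study-like analysis on
synthetic assays (seeded, deterministic). `01_simulate_assays.py` writes a
5-agonist × 6-pathway concentration–response panel in which the probe
agonist ("BnOCPA") has efficacy only at Gob, plus binding, BRET and decay
tables. `03_operational_bias.py` then fits the operational model globally
at Goa and Gob and prints:

```
delta-log(tau/KA) vs adenosine (pooled SEM):
  adenosine  Goa   +0.000 +/- 0.021 (bias factor 1.00)
  CPA        Goa   +0.910 +/- 0.020 (bias factor 8.13)
  NECA       Goa   +0.200 +/- 0.021 (bias factor 1.59)
  HOCPA      Goa   +0.397 +/- 0.021 (bias factor 2.49)
  BnOCPA     Goa   NR
  adenosine  Gob   +0.000 +/- 0.020 (bias factor 1.00)
  CPA        Gob   +0.675 +/- 0.019 (bias factor 4.73)
  NECA       Gob   +0.082 +/- 0.020 (bias factor 1.21)
  HOCPA      Gob   +0.489 +/- 0.020 (bias factor 3.09)
  BnOCPA     Gob   +0.677 +/- 0.020 (bias factor 4.75)
```

Each row is one agonist's transduction coefficient relative to the
reference agonist (adenosine) in that pathway: CPA transduces Goa ~8-fold
more efficiently than adenosine, while the probe produces *no measurable
response* at Goa yet carries a finite, well-determined bias factor at Gob —
the signature of a Gα-subunit-selective agonist (injected truth for that
cell: Δ = 0.70; the fit returns 0.68 ± 0.02 under 2%-of-window noise).

`05_schild.py` treats the probe as an antagonist of the reference agonist
at Goa and recovers its affinity from the EC50 shift:

```
dose ratio D'/D = 3.14 at [A] = 250 nM
antagonist Kd = 117 nM (pKd 6.9) [simulated truth 113 nM]
```

and `07_stability.py` turns decay series into half-lives and clearance:

```
  probe            microsomes t1/2 58.2 min, CL_int 119.1 uL/min/mg
  verapamil_like   plasma     t1/2 34.2 min
  terfenadine_like plasma     t1/2 11.0 min
  probe            PBS        t1/2 > 60 min (censored)
```

The same operations are available programmatically
(`biaskit.fit_logistic3`, `fit_operational_global`, `compute_bias`,
`cheng_prusoff`, `single_dose_schild`, `fit_half_life`, …), through the
YAML-configured pipeline (`biaskit.run_pipeline`), and as a CLI
(`biaskit fit-cr|bias|binding|schild|bret|pk|simulate|run`).

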