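# Methods

`biaskit` quantifies how selectively a GPCR agonist couples its receptor to
individual transduction pathways — here, the adenosine A1 receptor against
the six inhibitory Galpha subunits (Gi1, Gi2, Gi3, Goa, Gob, Gz), beta-arrestin
recruitment and direct G-protein dissociation — and carries the supporting
binding, antagonism and stability analyses. This note records the models,
their assumptions, the defaults that matter, and the numerical choices.

## Concentration–response model

All functional curves are fitted with a three-parameter logistic (3PL) with
the Hill slope fixed at 1:

    y = bottom + (top − bottom) / (1 + 10^(s·(log10[A] − log10 EC50)))

with s = −1 for stimulation and s = +1 for inhibition, by unweighted least
squares over all replicate observations (replicates are never pre-averaged;
the error propagation downstream needs them). Fitting is in log10
concentration; log EC50 is bounded to the tested range ± 2 log units;
initial top/bottom come from the extreme concentration means and the initial
log EC50 from the concentration nearest the half-range. Parameter SEMs are
asymptotic (from the covariance of the fit); the SE of log10 EC50 is the SE
of pEC50 directly.

cAMP responses are normalised to a forskolin curve run in parallel: each raw
response becomes 100 × raw / top_fsk, where top_fsk is the fitted 3PL
maximum of the forskolin curve, so the assay window is 0–100%.

**NR rule.** An agonist/pathway combination is "no measurable response"
(NR) when the *fitted response change across the observed concentration
grid* is strictly below 10% of the window (default, configurable), or when
the fit does not converge. The span is measured on the data grid rather than
as |top − bottom| because on noise-only curves the optimiser can place EC50
outside the tested range and inflate the extrapolated plateaus while the
curve stays flat over the data. The strict inequality keeps a curve exactly
at threshold.

## Operational model and bias factors

Within one pathway the Black–Leff operational model is fitted globally
across agonists:

    E([A]) = basal + (Em − basal)·τⁿ[A]ⁿ / ((K_A + [A])ⁿ + τⁿ[A]ⁿ)

with Em, basal and the transducer slope n shared across agonists and
(log τ, log K_A) per agonist. NR agonists are excluded and propagated as NR.
The transduction coefficient is log(τ/K_A); bias versus the reference
agonist (adenosine in the study design) is

    Δlog(τ/K_A) = log(τ/K_A)_ligand − log(τ/K_A)_reference,
    pooled SEM  = √(SEM_ligand² + SEM_reference²).

**Slope handling** (`slope_mode`, default `"auto"`): n is fitted as a shared
free parameter; if its 95% CI includes 1 the model is refitted with n = 1.
`"fixed"` and `"free"` force either branch.

**Identifiability and the Em anchor.** For n = 1 the operational curve is an
exact logistic with observable top = Em·τ/(1+τ) and EC50 = K_A/(1+τ): m
curves give 2m constraints for 2m + 2 parameters, so (Em, τᵢ, K_Aᵢ) lie on a
one-dimensional likelihood ridge that no amount of data resolves — sharing
Em across agonists, with or without a partial agonist, does not break it.
Crucially, a move along the ridge shifts every agonist's log(τ/K_A) by the
same −Δlog Em, so Δlog(τ/K_A) is exactly ridge-invariant. Because responses
are window-normalised, the fit adds one weak residual
`em_anchor_weight · (Em − window)` (default weight 1.0, i.e. the anchor
counts like a single replicate observation of the window maximum). This
selects a unique, reproducible ridge point, leaves bias deltas untouched,
keeps the asymptotic SEMs finite, and is negligible whenever n ≠ 1 makes Em
identifiable from shape. Setting `em_anchor_weight=0` recovers the pure
likelihood (with a flat ridge at n = 1).

SEMs of log(τ/K_A) use the joint covariance including the log τ/log K_A
cross term. A seeded bootstrap over replicates (`bootstrap_bias_sem`,
default 500 resamples) is available as an alternative error estimate. Bias
is computed within-pathway; a cross-pathway ΔΔlog(τ/K_A) helper is provided
as an optional extra.

## Binding

- **Cheng–Prusoff**: K_i = IC50 / (1 + [L]/K_d) for tracer concentration
  [L] and tracer K_d. Shipped tracer defaults: DPCPX 1 nM with K_d 1.23 nM;
  CA200645 working concentration 25 nM (its K_d is not established here, so
  the concentration doubles as placeholder — override for quantitative
  work); NECA-TAMRA used at its K_d of 15.2 µM.
- **Saturation**: specific = Bmax·[L]/(K_d+[L]) after nonspecific
  subtraction (clipped at 0 with a note if nonspecific exceeds total),
  fitted in log10 K_d parameterisation for conditioning.
- **One-site competition**: a 3PL displacement fit (plateaus free) followed
  by Cheng–Prusoff on the fitted IC50; pKi = −log10 K_i. IC50→K_i is a
  constant scale, so the pIC50 SE carries over to pKi.
- **Two-site competition** (biphasic displacement, shared plateaus):
  y = bottom + (top−bottom)·[f/(1+[C]/IC50_high) + (1−f)/(1+[C]/IC50_low)].
  Initialised from the one-site fit split ±1 log; f bounded to [0.02, 0.98]
  during optimisation; the low phase is parameterised as the high phase plus
  a non-negative log offset so K_i(high) ≤ K_i(low) by construction. A fit
  whose phases end up within 0.3 log units (or with f at a bound) is
  declared collapsed and the one-site result is returned with a note. An
  extra-sum-of-squares F statistic against the one-site fit is reported.

## Schild analysis

Single-dose form: a fixed antagonist concentration [A] shifting the agonist
EC50 from D to D′ gives K₂ = (D′/D − 1)/[A], K_d = 1/K₂, pK_d = −log10 K_d
(reported at 1 decimal by default). D′/D ≤ 1 is a hard error (no antagonism
detected). Several antagonist concentrations are summarised as the
unweighted mean pK_d ± SEM; a slope-constrained Schild regression is out of
scope because the single-dose equation is the study's method.

## BRET reduction

Ratios are acceptor/donor per time point (zero-donor points masked with a
warning). Ligand-induced ΔBRET subtracts the vehicle well's ratio on the
same time grid, then a per-well baseline: the mean of pre-addition readings,
by default the first sample (the acquisition grid is 1 min). Both the
vehicle-subtracted (`delta`) and baseline-corrected (`corrected`) traces are
kept. Fixed-time concentration–responses take the corrected value nearest
the read-out time (tolerance 0.5 min): 5 min for arrestin recruitment (the
maximum response), 11 min for TRUPATH. TRUPATH activation *reduces* the net
BRET ratio (Gα–Gβγ dissociation); the sign is preserved and the extracted
curve is fitted with direction = inhibition.

## Stability metrics

t½ assumes first-order kinetics: k is the negative slope of ln(% remaining)
vs time over the *initial linear range* — the longest prefix of ≥ 3 points
whose ln-linear fit has R² ≥ 0.95, falling back to all points — and
t½ = 0.693/k. A series whose fitted decline over the observation window is
below 10% (or which does not decline) is censored as t½ > last time point.
Intrinsic clearance is CL_int = 0.693/(t½ × protein concentration) in
µL/min/mg, with protein in mg/µL (0.0001 for a 0.1 mg/mL incubation). The
rounded constant 0.693 (not ln 2 to machine precision) reproduces the
conventional clearance arithmetic and is used consistently on both the
generator and fitting sides, so noiseless round trips are exact; it is
configurable to ln 2.

## Synthetic data

Generators are pure functions of (spec, seed) — identical seeds give
byte-identical tables — and share their forward mean models with the
fitting code (the test suite re-derives the operational mean independently
to guard that single source of truth). Noise is i.i.d. Gaussian on the
response scale, default SD 2% of the assay window, reflecting replicate
scatter reported as mean ± SEM; a proportional-noise option exists but
heteroscedasticity was not modelled. Default grids mirror the study design:
agonist concentrations 1 pM–100 µM at half-log spacing (17 points), BRET on
a 1-min × 60-min grid, decay at 0/15/30/45/60 min.

The default panel (`paper_like_panel_spec`) is 5 agonists × 6 Gα pathways
with 6 replicates: a reference agonist coupling to Goa/Gob/Gz, prototypical
agonists adding Gi2 or Gi1, and a probe agonist with efficacy *only* at Gob
— the hallmark pattern of a Gα-subunit-selective agonist, including its
zero-efficacy (NR) combinations. Ground-truth (log τ, log K_A) values are
fixed plausible magnitudes (τ between 2 and 10, K_A 16 nM–320 nM); they are
conditions of the simulation study, not estimates of the real compounds.

What passing tests show — and don't. Recovery tests certify that the
estimators return the injected truth under Gaussian replicate noise at the
study's design sizes (median |pEC50 error| ≈ 0.016 over 200 seeds; median
|Δlog(τ/K_A) error| ≈ 0.02 over 100 panels). Real plate data add features
the generator does not emulate: plate-position and edge effects, drift,
heteroscedastic and occasionally non-Gaussian error, compound solubility
limits, and receptor-reserve differences between transfections. Results on
real data therefore inherit the model assumptions, not the simulated error
rates.

## Degenerate inputs and tie-breaks

Flat curves → NR (never an exception from `fit_logistic3`); all-NR panels →
`EmptyFitError`; singular covariance → fit returned with SEMs flagged
unavailable and a warning; two-site collapse → one-site fallback with note;
non-positive % remaining → excluded from the log fit with a warning;
nonspecific > total → clipped at 0 with a note; zero-donor BRET points →
masked. Exact threshold cases are kept (NR and collapse use strict
inequalities).

## Known limitations

- The operational Em is set by convention (window anchor) when n = 1; only
  Δlog(τ/K_A), not absolute log τ or log K_A, should be interpreted
  quantitatively from full-agonist-only panels.
- Arrestin-pathway bias factors are out of scope (the receptor studied
  recruits no arrestin; such curves only pass through the NR classifier).
- Kinetic binding, allosteric models, Hill-slope estimation in the 3PL, and
  full Schild-plot slope testing are out of scope.
- The two-site model assumes plateaus shared between phases.
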