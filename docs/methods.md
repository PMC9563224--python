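# Methods

## Scope and model

oleosafe evaluates one oil sample end to end: lipid nutritional-quality
indices from its fatty-acid composition, detection-limit-aware screening of
its trace-element panel against regulatory tables, the ingestion-only
exposure chain (chronic daily intake → hazard quotient → hazard index;
chronic daily intake → cancer risk), and closed-form inverse solves for the
maximum daily oil intake compatible with a hazard-index or cancer-risk
target. Laboratory data acquisition (chromatography, ICP OES calibration,
thermal/optical analysis) is out of scope: the package consumes the reported
tables, including each element's LOD/LOQ.

## Fatty-acid handling

Species are identified by the `C<chain>:<db>[n<family>][c|t]` shorthand;
the parser accepts `n` or `ω` and upper/lower case, and the formatter is its
exact inverse (property-tested round trip). Classification is purely by
double-bond count: 0 → SFA, 1 → MUFA, ≥2 → PUFA. ω3/ω6 sums use the parsed
family tag; species printed without one receive a bundled default
(palmitoleic → n7, gondoic → n9, docosadienoic → n6, heptadecenoic left
unassigned) that callers can override per species. Only n3/n6 membership
enters any formula; the docosadienoic → n6 default moves TI by < 0.001 on
the bundled oil, and the choice is surfaced rather than hard-coded.

The three indices (AI, TI, HH — formulas in the README) are computed at full
double precision; species absent from a profile contribute zero, which keeps
the indices finite exactly when their denominators are positive (a zero
denominator raises a domain error rather than returning NaN). The TI
denominator is `0.5·ΣMUFA + 0.5·Σω6 + 3·Σω3` with no ω3/ω6 ratio term —
some older TI definitions include one; this implementation follows the
three-term form. Report rounding (2 d.p. for indices, half-up) is applied
only at the presentation layer.

Profile validity: shorthands unique, percents ≥ 0, and the total within
100 ± 0.5% by default — printed tables round each row, so an exact 100 is
unattainable; the check can be disabled for partial or rescaled profiles,
which the scale-invariance of the indices makes harmless. Where a source
table and its surrounding prose disagree on a percent (e.g. stearic 3.13 vs
3.17), the bundled dataset carries the table value, because the table's own
class sums verify against it.

## Element censoring and limit comparison

A raw reading is `below_lod` if raw < LOD, `detected_below_loq` if
LOD ≤ raw < LOQ, and `quantified` if raw ≥ LOQ. Both boundary conventions
(closed below at LOD, closed at LOQ) are deterministic choices documented
here; the underlying convention in instrument reports is ambiguous.
Censoring is monotone in the raw value by construction.

FAO/WHO comparison is concentration vs concentration (percent of limit; a
value exactly at the limit is 100% and does not exceed). DRI/AI values are
intakes (mg/day) and are not commensurable with a concentration without an
intake assumption, so that comparison takes an explicit oil intake in g/day
and compares C × IR against the cohort's DRI/AI. Non-quantified elements are
flagged not-evaluable rather than scored zero. The spike-recovery QC passes
on the closed 80–110% interval, with a 1-ulp tolerance at the boundaries so
an exact 110% recovery cannot fail to floating-point rounding.

## Exposure chain and units

CDI = C·IR·EF·ED/(BW·AT). Defaults EF = 365 days/year and AT = ED·365 days
cancel the prefactor, so CDI = C·IR/BW independent of ED; non-default
EF/ED/AT are supported. The default `paper_faithful` unit mode enters IR
numerically in g/day with no g→kg conversion — this is the convention under
which published HQ/HI grids in the food-risk literature (including the
bundled reference grid) are reproducible, and it is verified numerically in
the tests. `si_strict` converts IR to kg/day; every CDI, HQ, HI and CR is
then exactly 1000× smaller, and the invariant is property-tested. The mode
is a reporting convention: conclusions must compare like with like.

HI sums HQ over quantified elements that have an RfD; elements lacking an
RfD are listed as excluded, never silently zeroed. Censored elements
contribute nothing by default; an optional LOD/2 substitution mode is
provided and labelled in the result. Cancer risk is CDI·SF per element with
a slope factor, classified below-range (< 10⁻⁶), acceptable (10⁻⁶–10⁻⁴) or
inadmissible (> 10⁻⁴). On the bundled dataset the Cr cancer risk
(≈2.8×10⁻⁴ at the reference intakes) is classified inadmissible even though
those intakes were chosen to satisfy HI < 1; the report presents both
numbers and lets the classification stand — the two criteria genuinely
conflict for this sample, and the CR-constrained safe intake is accordingly
the binding one.

Inverse solves exploit exact linearity in IR: IR* = target / (value at
IR = 1). The forward/inverse round trip is exact to 1e-12 relative
(property-tested on random panels). With no carcinogen in the panel the CR
solve returns an explicit unbounded (infinite) result. The bundled HI
target is 0.99, matching the convention of reporting safe intakes just
under HI = 1; it is an argument, not a constant.

A reproduction note: the bundled reference grid prints HI = 0.99 for all
three cohorts, but the sum of its own 30-y HQ cells is 0.99545, which
rounds half-up to 1.00 — the printed column evidently truncates. Tests
therefore assert HI < 1 and truncation to 0.99 for the 18-y/30-y cohorts
and exact 2-d.p. rounding (0.99) only at 8 y. Similarly the printed 18-y Cr
cancer risk (2.9×10⁻⁴) recomputes to 2.849×10⁻⁴; the 8-y and 30-y cells
match at 2 s.f. and the 18-y cell is checked to within one unit in the
second significant figure.

## Synthetic data

The generator exists so every stage is testable without measurements.
Fatty-acid profiles are drawn from a gamma-simplex (Dirichlet-type)
distribution centred on the bundled template: independent
Gamma(mean_i/dispersion) draws renormalised to 100, so percents are
non-negative, sum to 100 exactly, and dispersion → 0 degenerates to the
template. The default dispersion 0.01 puts per-species spreads at the scale
of replicate GC-FID standard deviations (tenths of a percent for major
species). Element concentrations are normal truncated at zero around the
template mean ± SD — the printed SDs are ~1% of the means, so truncation is
negligible and moments stay simple; a lognormal would be the alternative if
SDs were large. `censor_fraction` pushes elements below their LOD to
exercise the censoring path. All draws flow from one integer seed via
`numpy.random.default_rng`.

What the generator does *not* emulate: inter-sample correlation between
elements, instrument drift, spectral interference, or real compositional
covariance beyond the simplex constraint. Passing the parameter-recovery
tests (mean HI over 1,000 noisy panels within 3 SE of the zero-noise HI)
shows the pipeline is unbiased under the generator's assumptions, not that
real oils satisfy them.

## Numerical and design choices

- All internal arithmetic is full double precision; `rounding.round_dp` /
  `round_sig` (decimal half-up) exist solely for report rendering.
- Codex compliance uses closed intervals (boundary values pass), point-value
  verdicts by default, and an optional strict mode that fails a parameter
  whose value ± SD straddles a bound. Unit strings must match exactly.
- Domain errors (zero denominators, empty panels, no element with an RfD)
  raise typed exceptions; the CLI maps parse/validation errors to exit
  code 2 and domain errors to 3.
- The acceptance script's quantities are all deterministic closed-form
  computations on the bundled tables (16 fatty-acid species, 13 panel
  elements), so they run in milliseconds; its `--seed` flag is accepted for
  interface uniformity and would drive the synthetic generators only.
- Monte-Carlo test sizes (200 profiles for the unsaturation band, 1,000
  panels for mean-HI recovery) were chosen as the smallest sizes at which
  the 3-SE criteria are meaningful.

## Known limitations

- Ingestion is the only exposure pathway; no dermal/inhalation terms.
- The DRI/AI comparison requires the caller's intake assumption; the
  package does not pick a "representative" consumption for it beyond the
  bundled reference scenarios.
- The bundled limit tables record provenance strings but do not resolve the
  underlying standards documents; users with jurisdiction-specific limits
  should supply their own YAML.
- Compositional SDs in the bundled table are carried for display but not
  propagated into index uncertainty; uncertainty propagation would require
  the full covariance of the compositional measurement, which is not
  reported.
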