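# Methods

This note records the models the package implements, the defaults it
ships, and the numerical and design choices made where the methodology
left room — in the package's own words, for maintainers and reviewers.

## Scope and data model

The unit of analysis is a per-sample table of total concentrations
(mg/kg dry weight) of six potentially toxic elements — As, Cd, Pb, Cr, Ni,
Cu, optionally Fe — with one land-use code per sample from an 11-code
registry (PA, PG, M, BF, IA, PP, MW, BS, PS, RA, WDA). All indices and
risk quantities are computed per land use from site-mean concentrations;
this matches how soil-survey reports chain summary tables into indices,
and a per-sample option exists where it makes sense (PLI, health risk).
Cells reported below the method detection limit (MDL) are flagged and
carried at MDL/2 by default (configurable to MDL or zero); the substitution
policy matters only for summary statistics, since the PMF stage has its own
detection-limit rules.

Reference quantities live in a `ReferenceSet`: geochemical backgrounds
(strictly positive, defaults As 4.90, Cd 0.30, Pb 20, Cr 41, Ni 22,
Cu 27 mg/kg), Hakanson toxic-response factors (As 10, Cd 30, Pb 5, Cr 2,
Ni 6, Cu 5), and four regulatory standards tables (Dutch DSQS, Canadian
CSQS, toxicity reference values TRV, Australian ASQS). Everything is a
plain CSV/YAML file and overridable.

## Pollution and ecological-risk indices

Per element and site: CF = C/B; Igeo = log2(C/(1.5·B)) with the classical
1.5 background-spread buffer; EF double-normalises by iron,
(C/Fe)_sample / (B/Fe)_background, and therefore requires sample Fe and a
background Fe value (none is shipped — the survey area's Fe background was
not published, so EF is available only when the user supplies both).
Site level: C_d = ΣCF, PLI = geometric mean of the CFs, E_r = T_r·CF and
PERI = ΣE_r.

Category schemes are data (`schemes.yaml`), not code. Two points needed a
decision:

- **C_d bins.** The survey's printed labels (4.42 "Low", 7.03 "Moderate",
  9.93 "Moderate", 10.29 "Considerable", 20.16 "High") are inconsistent
  with Hakanson's classical 8/16/32 cutoffs. The shipped `cd_study`
  scheme uses 6/10/20, the unique round-number bin set consistent with
  all eleven printed labels; `cd_hakanson` ships alongside and is the
  sensible default for new study areas.
- **PERI bins.** The printed labels again contradict the classical
  150/300/600 scheme (163.49 is "Considerable" but 283.22 "Very high").
  `peri_study` uses Moderate < 150 ≤ Considerable < 200 ≤ Very high; any
  boundary in (164, 283) reproduces the labels, and 200 was fixed once as
  the midpoint-ish round number. `peri_hakanson` ships alongside.
  Per-element E_r uses the classical 40/80/160/320 bins, which match all
  printed per-element behaviour.

Bins are lower-inclusive everywhere (a value on a boundary takes the upper
label), bins cover the index's domain, and out-of-domain values raise
rather than silently clamp. Igeo of a zero concentration raises by
default (real soils are never exactly zero); a `-inf` sentinel is
available by flag.

### Fidelity to the published tables

`reproduce_paper_tables()` recomputes all 220 CF, C_d, Igeo, E_r and PERI
cells from the shipped site means. 219 agree with the published values
within ±0.01 absolute or ±1 % relative (whichever is larger — the slack
absorbs the survey's rounding of means to two decimals before the indices
were recomputed here). The single exception is the playground (PG)
cadmium Igeo: the published 0.78 back-computes only from an unrounded
mean ≈ 0.775 mg/kg (which also explains the printed CF 2.58 and
E_r 77.5 exactly), while the published rounded mean 0.78 mg/kg gives
log2(0.78/0.45) = 0.7935. The discrepancy is an artefact of publication
rounding, is flagged by the comparison report, and is left as a documented
failure rather than papered over with a wider tolerance. Both category
columns (C_d level, PERI level) agree for all eleven sites, as does the
full descending PERI ranking (MW > IA > BS > WDA > BF > M > PS > PP > PA >
PG > RA).

The published PLI chart (range 0.48–2.82) cannot be reproduced exactly
because it was evidently computed from per-sample values that were never
published; site-mean CFs give 0.494–2.769, within 5 % at both extremes,
and the package documents `pli_basis="per_sample"` as the alternative.

## Human health risk

The dose equations and every exposure parameter (`exposure.yaml`) follow
the USEPA soil pathway defaults for a child (BW 15 kg, IRS 200 mg/d,
InhR 10 m³/d, SA 2100 cm², AF 0.2 mg/cm², ED 6 y) and an adult (70 kg,
100 mg/d, 20 m³/d, 5800 cm², 0.07 mg/cm², 30 y), both with EFr 350 d/y,
ABS 0.1, PEF 1.3e9 m³/kg, CFu 1e-6 kg/mg, and averaging time 365·ED days
for non-carcinogens and 365·70 days for carcinogens. Two consequences are
useful invariants: the non-carcinogenic CDI is independent of ED (the
365·ED cancels), and the child/adult inhalation dose ratio is exactly
(10/15)/(20/70) = 7/3 ≈ 2.33 for every element and concentration.

A **dermal exposure ratio** FE = 0.61 appears in the exposure tables but
not in the dermal dose equation as printed in the methodology this package
follows; the equation is implemented as printed (FE unused) with
`use_dermal_exposure_ratio=True` to multiply it in. The dangling parameter
is deliberate transparency, not an endorsement.

**Toxicity constants.** The methodology's own RfD/CSF table was published
only in an unavailable supplement, so `toxicity.yaml` ships standard USEPA
compilation values: oral RfDs As 3.0e-4, Cd 1.0e-3, Pb 3.5e-3, Cr 3.0e-3,
Ni 2.0e-2, Cu 4.0e-2 mg/kg/day, and oral CSFs for the three carcinogens
assessed (As 1.5, Cd 6.1, Pb 8.5e-3 (mg/kg/day)⁻¹). Dermal and inhalation
routes fall back to the oral value (flagged in the report) unless
route-specific entries or a gastrointestinal absorption fraction are
configured. An element/route with no RfD is an explicit "not assessed"
outcome excluded from HI with a note — never a zero. Because the
toxicity table is a package default rather than the survey's own, the
published cancer-risk magnitudes are reproduced in structure (routes,
receptors, orderings, window flags), not in value; the published CR table
is in any case not derivable from the printed equations and parameters
(hand-substitution gives values ~100× smaller than printed for As
ingestion), so no numeric CR target is asserted anywhere.

## PMF receptor model

The model: X = G·F + E with G (samples × factors) and F (factors ×
elements) nonnegative, fitted by minimising Q = Σ((X − GF)/α)². The
objective as sometimes written omits the square on e/α; an unsquared sum
is unbounded below and incompatible with "lowest Q" model selection, so
the conventional squared form is implemented.

- **Uncertainties.** α = (5/6)·MDL where X ≤ MDL (boundary inclusive),
  α = 0.05·X + MDL above. Shipped MDLs: As 3e-4 and Cd 4e-3 mg/kg
  (instrument values), 0.04 mg/kg for Pb/Cr/Ni/Cu (mid-point of the
  reported 0.013–0.070 collective range; at mg/kg-scale concentrations
  the choice is immaterial). X-matrix cells at or below MDL enter as
  MDL/2.
- **Optimiser.** Weighted multiplicative updates (Lee–Seung form with
  weights 1/α²), which keep nonnegativity exactly and decrease Q
  monotonically; a 1e-12 denominator guard prevents division by zero.
  Initial G ~ U(0.5, 1.5), F ~ U(0.5, 1.5)·(column mean / k), so the
  initial product is on the data's scale. Convergence: relative ΔQ per
  iteration ≤ 1e-8 (tighter values only micro-step without changing any
  reported quantity) or Q below an absolute floor of 1e-12 per cell
  (reached on noise-free data of exact rank). Default cap 3000
  iterations; a run that meets neither criterion is recorded as
  unconverged, and only if *all* runs fail does `fit` raise (carrying the
  Q trajectory).
- **Run protocol.** Default 20 random restarts seeded from one root seed;
  the converged run with the lowest robust Q wins; `fit_scan` sweeps
  factor numbers 3–6. Robust Q caps each cell's contribution at
  threshold² (default threshold 4 on the scaled residual) so ill-fit
  cells cannot dominate model selection.
- **Ambiguities.** Scale indeterminacy is fixed by normalising G columns
  to unit mean (G dimensionless, F in concentration units). Permutation
  indeterminacy is resolved only in validation, by best-permutation
  cosine matching of profiles (`match_factors`). No rotational (Fpeak) or
  bootstrap machinery is included.
- **Diagnostics.** q_true, q_robust, per-run table, scaled residuals,
  per-element R² (squared Pearson correlation of observed vs
  reconstructed columns), per-element factor contribution percentages
  (shares of reconstructed mass; rows sum to 100).

Known limitation: multiplicative updates decay factor-mixing terms that
sit on the nonnegativity boundary only hyperbolically, so even on exactly
separable data a converged run retains ~1–3 % cross-factor mixing in the
contribution percentages. Validation therefore asserts clean splits to
within a few points, and the 3-source recovery checks use a ±10-point
band, which the fits meet with roughly half that error.

## Synthetic data

`generate_study_table` emulates the survey design: 11 land uses with
sample counts 3, 8, 8, 8, 4, 8, 8, 3, 8, 8, 5 (71 samples), each element
drawn independently from a truncated normal matched to the site's
published mean, SD and observed range. Truncation shifts the realised
mean, so the location parameter is re-centred by a bracketing root solve
on the truncated-normal mean (the truncated mean is strictly increasing
in the location, so brentq is exact to 1e-10; a fixed-point update was
tried first and converges too slowly under heavy truncation to be
usable). The SD is not re-matched: under two-sided truncation the
realised SD runs below its nominal value, which is accepted as the price
of honouring the published range exactly. Draws go through the inverse
CDF of per-element uniforms, so a fixed seed gives byte-identical tables
and an optional Gaussian copula can impose cross-element correlation
(a test harness feature; the survey published no correlation structure).
Per-site child seeds are spawned from the root seed, so one site's draws
never depend on another's.

What the generator does *not* emulate: spatial structure, seasonal
variation, analytical error structure, or the survey's actual per-sample
values (never published). Tests passing on synthetic tables therefore
validate the computational chain, not claims about the study area.

`generate_mixture` produces PMF validation data X = G·F·(1 + ε) with
known ground truth: three contrasted source archetypes (traffic/metal
working dominated by Pb and Cu; geogenic dominated by Cr; mixed urban
waste dominated by As, Cd, Ni), contributions drawn i.i.d. Gamma(0.8)
scaled to unit mean — heavy-tailed source strengths (CV ≈ 1.1) typical of
receptor data and strong enough that 5 % multiplicative noise leaves
every element's X-vs-GF R² above 0.99 — and values floored at MDL/2.

## Pipeline

`run_pipeline` chains all stages on a real or synthetic table and writes
one CSV per stage plus a JSON manifest carrying the seed, parameter hash,
package version and PMF diagnostics; every CSV header repeats the seed
and hash. Runs abort on the first failing stage with the stage named and
partial outputs removed, and are deterministic for a fixed config and
seed. Stage defaults (3 factors, 20 runs) suit the 71-sample scale; all
are configurable.

## Problem sizes used in validation

The shipped validation suite and `scripts/acceptance.py` use: the full
220-cell index comparison (deterministic, < 1 s); PMF exact-rank checks
at 40×6 cells; 3-source recovery at 200 samples × 20 runs; generator
mean-recovery at n = 10,000 per site (3-SE band on the realised standard
error). These sizes give stable stochastic margins (share recovery errors
of 5–8 points against the 10-point band across seeds) while keeping the
whole suite under half a minute.
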