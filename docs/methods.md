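# Methods

## Scope and model

`cumob` quantifies the copper economy of the methane-oxidation zone (MOZ) of
a seasonally stratified lake. The analysis chain is deliberately modular:

1. **Profiles** (`cumob.profiles`) — depth series on an irregular grid
   (metres below surface, positive down, 0 at the air–water interface), one
   unit per profile, per-point censoring flags (`ok`, `below_LOD`,
   `not_quantifiable`, `estimated_below_LOQ`, `negative_particulate`).
   Areal pools are trapezoidal integrals on the native grid with linearly
   interpolated boundary values; integration never extrapolates.
2. **DGT** (`cumob.dgt`) — Davison inversion C = MΔg/(DAt) of passive-
   sampler eluates, with blank subtraction and Grubbs screening.
3. **Zonation** (`cumob.zonation`) — rule-based MOZ/oxycline detection, or
   user-supplied zone bounds (published zone tables are first-class inputs).
4. **Transport** (`cumob.transport`) — Fickian fluxes J = K_z|dC/dz| from
   OLS gradients.
5. **Census** (`cumob.census`) — copy-number-corrected absolute abundances
   and qPCR quantification with LOD/LOQ censoring.
6. **Budget** (`cumob.budget`) — particulate Cu, the extended-Redfield cell
   quota, pools, accumulation times, underestimation factors.
7. **Zone statistics** (`cumob.zone_stats`) — the three-zone comparison
   procedure.
8. **Synthetic data** (`cumob.synthetic`) — a campaign generator with
   closed-form ground truth, used throughout the test suite.

Key physical assumptions: vertical transport is purely turbulent-diffusive
with a single K_z (default 10⁻⁶ m² s⁻¹); concentration gradients are locally
linear over the regression window; the DGT diffusive boundary layer is
negligibly thin; in-zone production (e.g. photosynthetic O₂) is not
corrected for, so O₂ fluxes into the MOZ are lower bounds.

## Parameters that matter

| Parameter | Default | Unit | Notes |
|---|---|---|---|
| K_z | 1e-6 | m² s⁻¹ | metalimnion of a small wind-sheltered lake; configurable |
| DGT Δg | 0.93e-3 | m | 0.8 mm gel + 0.13 mm filter |
| DGT window area | 3.1416e-4 | m² | 2 cm diameter disc |
| Elution factor f_e | 0.8 | – | Chelex-100 / 1 M HNO₃ convention; configurable per analyte |
| D (Cu, gel, 25 °C) | 6.23e-10 | m² s⁻¹ | bundled default table; linear T-correction 2.3 %/°C applied only when a temperature is given |
| O₂ detection limits | 125 / 20 | nM | normal / trace optode |
| PAR detection limit | 0.1 | µmol m⁻² s⁻¹ | fixes the MOZ bottom |
| CH₄ threshold rule | mean + 3·sd, floor 2× mean | – | "begins to accumulate" made operational; k and the epilimnion cutoff are configurable |
| 16S copies/genome | 5.8 / 2.2 / 4.2 | – | gamma-MOB / alpha-MOB / other |
| pmoA, mmoX copies/cell | 2 / 1 | – | mmoX single-copy is a convention, exposed as a knob |
| Cell diameter | 2 | µm | spherical MOB cell |
| C per biovolume | 6.4 | fmol C µm⁻³ | |
| Cu per pMMO | 2–15 | atoms | structural range |
| pMMO per cell | 1000–4000 | enzymes | membrane-packing estimate |
| Grubbs screen | two-sided, α = 0.05, 1 pass | – | at n = 3 the test is nearly degenerate (max attainable G = 2/√3 ≈ 1.1547 vs critical 1.1543); expect no removals from triplicates |

The "mean" cellular quota is the product of the two range midpoints
(8.5 × 2500 atoms = 3.53×10⁻²⁰ mol), which rounds to the quotable
4×10⁻²⁰ mol Cu cell⁻¹; the midpoint of the atom-count range (31 000 atoms)
and the geometric mean are available via `QuotaModel(quota_mode=...)`. All
budget reports round the quota to one significant figure (the precision at
which it is defensible) while retaining full precision internally.

The community-average 16S copy number in the denominator of functional-gene
relative abundances defaults to 4.2 ("other bacteria"); it is a config knob
because the choice is genuinely open.

## What the synthetic generator emulates — and what it does not

`LakeScenario` produces campaigns whose deterministic curves are
parameterised *by their crossings*: O₂ is a sigmoid that crosses 20 nM
exactly at the declared oxycline; CH₄ is flat at the epilimnetic background
(default 0.5 µM) and rises exponentially to the sediment-side maximum
(default 400 µM) such that it crosses twice-background exactly at the
declared MOZ top; PAR decays exponentially and crosses 0.1 µmol m⁻² s⁻¹
exactly at the MOZ bottom; dissolved Cu declines linearly from 14 nM to a
1 nM floor at the MOZ top (DGT-labile fraction = 0.1 of dissolved);
particulate Cu is a Gaussian bump (5 nM peak) centred in the MOZ over a
0.5 nM baseline; MOB cells are a Gaussian peak (2×10⁷ cells L⁻¹, σ = 0.5 m)
just below the oxycline over ~10⁹ background bacteria. These scales match
the campaign ranges of a eutrophic subalpine lake in summer stratification.
Because every crossing is closed-form, the scenario doubles as a
ground-truth oracle (`GroundTruth`): zone bounds, gradients, fluxes, pools
and cell integrals are all analytic.

Observation noise is multiplicative log-normal (mean-unbiased, CV 5 %,
triplicates) for concentrations; qPCR adds normal noise in Cp space
(SD 0.15 cycles) with Poisson-distributed realised template copies, which
reproduces the replicate-scatter blow-up at few-copy dilutions that defines
the LOQ. OTU tables are multinomial at finite read depth;
`read_depth=None` emits exact expected counts (the infinite-depth limit),
in which case the census round-trips to machine precision.

Passing tests on these campaigns therefore demonstrate *procedural*
correctness — detector calibration, unit handling, estimator bias — under
the stated noise model. They do not demonstrate robustness to features the
generator omits: secondary particulate peaks outside the MOZ, internal
waves and temporal aliasing between casts, DGT speciation artefacts
(strong organic complexes that pass 0.45 µm but are not resin-labile),
primer bias beyond a constant factor, or depth-correlated noise. The
generator's constant factor-30 *pmoA* detection bias and 160-fold
*pmoA*:*mmoX* ratio are calibration conveniences, not predictions.

## Numerical choices

- **Integration**: trapezoid on the native irregular grid (exact for
  piecewise-linear profiles; additivity to 1e-12 relative). Censored points
  contribute zero and are counted in the result metadata — pools are
  conservative and their provenance explicit.
- **Crossings**: linear interpolation for CH₄ and O₂; log-linear for PAR
  (exact for exponential light decay). Points flagged `below_LOD` are kept
  as crossing evidence with their value clamped just below the detection
  limit — discarding them would blind the detectors to the very signal that
  defines the boundaries.
- **Gradient windows**: default from the epilimnetic maximum down to the
  first depth whose value comes within 3 replicate-SDs of the within-MOZ
  minimum. The allowance is deliberately generous: ending early on a linear
  decline leaves the OLS slope unbiased, while including depleted-plateau
  points biases it low (up to −18 % without the allowance at 5 % CV).
  Windows are always overridable per analyte.
- **qPCR censoring order**: per-replicate detection (Cp < LOD-Cp and a clean
  melt), then ≥2-of-3 non-detections, then replicate spread > 0.5 cycles,
  then the LOQ rule; quantification uses the arithmetic mean of detected
  replicate Cp values (rules operate in Cp space). Below-LOQ samples are
  estimated by curve extrapolation unless extrapolation is disabled.
- **Zone statistics**: Shapiro–Wilk per zone group (the literal reading of
  the procedure), ANOVA + Tukey HSD when all groups pass at α, else
  Kruskal–Wallis + pairwise Mann–Whitney (unadjusted by default; Bonferroni
  available). Constant groups short-circuit to the trivial no-difference
  result.
- **Degenerate inputs**: zero-thickness zones integrate to 0; constant
  profiles fit slope 0 with R² = 1 by convention; zero-variance replicate
  sets skip the Grubbs test; a fully oxic column yields a `None` oxycline
  rather than a fabricated depth.
- **Rounding for reports**: accumulation times to integer days, MOB pools
  to one significant figure, mirroring how such budget tables are printed;
  machine-precision values are always available in the DataFrame/JSON.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 20 seeded synthetic
campaigns (~32-point grids, triplicate observations) for recovery checks;
1000 triplicate samples for qPCR accuracy; 200 multinomial OTU tables at
10⁴ reads for census unbiasedness; 2000 simulated three-zone null datasets
(n = 10 per zone) for the type-I error. These sizes give Monte-Carlo
standard errors comfortably below the tolerances they check.

## Known limitations

- Accumulation times assume a static pool fed by a constant diffusive flux:
  no settling losses, no in-zone scavenging kinetics, no time dependence.
- The census cannot separate active from dormant cells; "MOB cells" means
  16S-classified cell equivalents.
- Fluxes use a single campaign-wide K_z; microstructure-derived or
  depth-dependent diffusivities are out of scope.
- The three-zone statistics ignore vertical autocorrelation between
  neighbouring depths; p-values are anti-conservative in that respect.
- The qPCR recovery of single samples at 0.15-cycle replicate noise has a
  ~10 % relative SD (triplicate means); about 90 % of samples land within
  10 % of truth — an intrinsic property of the log-linear error model, not
  an implementation artefact (the suite checks the empirical fraction
  against this closed-form prediction).
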