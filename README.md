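# cumob — copper–methane budgets for stratified lakes

Aerobic methane-oxidizing bacteria (MOB) consume most of the methane rising
from lake sediments before it reaches the atmosphere. Their workhorse enzyme,
the particulate methane monooxygenase (pMMO), is copper-dependent — yet in
many stratified lakes the bioavailable copper at the depths where methane is
oxidized sits at low-nanomolar levels. `cumob` is a tested pipeline for
quantifying that tension: it turns depth-resolved chemistry (O₂, CH₄, light,
copper fractions), DGT passive-sampler deployments and a 16S/qPCR microbial
census into a per-campaign copper budget of the methane-oxidation zone —
zone-integrated particulate-copper pools, diffusive copper supply fluxes,
pool build-up (accumulation) times, and the share of particulate copper that
MOB biomass itself can account for.

It is written for aquatic biogeochemists and microbial ecologists working
with water-column profile data from seasonally stratified lakes.

## What it computes

**DGT inversion.** A DGT (diffusive gradients in thin films) sampler
accumulates labile metal on a Chelex resin behind a diffusive gel. The
time-averaged labile concentration follows the Davison relation

    C = M·Δg / (D·A·t),    M = c_eluate·(V_gel + V_eluent) / f_e

with accumulated mass M, diffusive path Δg (0.93 mm), gel diffusion
coefficient D, window area A (2 cm disc) and deployment time t. Blank
subtraction and a two-sided Grubbs outlier screen precede replicate
aggregation.

**Zonation.** The methane-oxidation zone (MOZ) runs from where CH₄ first
accumulates above its epilimnetic background (threshold
max(mean + 3·sd, 2·mean)) down to where photosynthetically active radiation
drops below its 0.1 µmol m⁻² s⁻¹ detection limit (interpolated in log-PAR).
The oxycline is the shallowest depth with O₂ below the 20 nM trace-optode
limit. The column partitions into oxic / methane-oxidation / anoxic zones.

**Transport.** Vertical turbulent-diffusive fluxes follow Fick's law,
J = K_z·|dC/dz|, with the gradient from OLS over a depth window and
K_z = 10⁻⁶ m² s⁻¹, the canonical value for a quiescent lake metalimnion.

**Census.** 16S read fractions become absolute cells via total 16S copies
and per-group copy numbers (5.8 Gammaproteobacteria, 2.2
Alphaproteobacteria, 4.2 other). qPCR of the marker genes *pmoA* (pMMO, 2
copies/cell) and *mmoX* (soluble MMO, 1 copy/cell) is calibrated on plasmid
dilution series (E = 10^(−1/slope)) with full LOD/LOQ censoring in Cp space.

**Cell quota (extended Redfield).** A 2 µm spherical MOB cell at
6.4 fmol C µm⁻³ holds 0.03 pmol C. With 2–15 Cu per pMMO and 1000–4000 pMMO
per cell it binds 2000–60 000 Cu atoms — a mean of 4×10⁻²⁰ mol Cu cell⁻¹ and
a Cu:C stoichiometry of ~10⁻⁶. Multiplying by the zone-integrated cell count
gives the MOB-bound particulate-copper pool; dividing the *measured* pool by
a supply flux gives its accumulation time.

## Worked example

The bundled published campaign summaries for Rotsee (a small eutrophic
Swiss lake, four campaigns across three stratification seasons) drive the
budget directly:

```sh
$ cumob budget --published --out budget_out
campaign  mob_cupart_pool_nmol_m2  accumulation_time_cu_dgt_d_rounded  accumulation_time_cu_diss_d_rounded  underestimation_factor
 2013-06                   15.200                                 216                                   21              269.736842
 2013-08                    2.200                                 437                                   39             5954.545455
 2014-09                    2.640                                 260                                    6             1969.696970
 2015-09                    0.112                                  60                                    6            21428.571429
```

Reading the table: building the measured particulate-Cu pools from the
*dissolved*-copper supply would take only 6–39 days — far less than the
60–160 days of elapsed stratification — whereas the *DGT-labile* (directly
bioavailable) supply would need 60–437 days, longer than the stratification
itself in three of four campaigns. And the copper bound in MOB biomass
(0.1–15 nmol m⁻²) undershoots the measured particulate pools by a factor of
~270–21 000: MOB are copper-hungry, but they are a minor constituent of
particulate copper — phytoplankton, with 10²–10⁴ times more Cu per cell, is
the prime suspect for the rest.

A fully synthetic campaign with known ground truth exercises every stage:

```sh
cumob simulate --seed 11 --out simulated
cumob budget --from-simulation simulated --out budget_sim
cumob zones --profiles simulated/profiles.tsv
cumob stats --profiles simulated/profiles.tsv --analyte Cu --fraction DGT
```

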