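"""Physical constants and default parameter values used across the pipeline.

All quantities are SI unless the name says otherwise. Defaults that stand in
for values a field campaign would supply (diffusion coefficients, elution
factor) are clearly marked and overridable wherever they are consumed.
"""

#: Avogadro constant, mol^-1 (CODATA 2018 exact value).
AVOGADRO = 6.02214076e23

SECONDS_PER_DAY = 86_400.0

#: Molar masses, g mol^-1 (IUPAC 2021 standard atomic weights).
MOLAR_MASS_G_PER_MOL = {
    "Cu": 63.546,
    "Fe": 55.845,
    "Mn": 54.938,
    "Zn": 65.38,
    "Cd": 112.414,
    "Pb": 207.2,
}

#: Vertical turbulent diffusion coefficient, m^2 s^-1, typical of a small
#: stratified lake's metalimnion; the site-specific value used throughout.
DEFAULT_KZ_M2_PER_S = 1e-6

#: Free-solution / DGT-gel diffusion coefficients at 25 degC, m^2 s^-1.
#: Defaults only (DGT Research compilation); supply deployment-temperature
#: values for quantitative work.
DGT_DIFFUSION_COEFF_25C = {
    "Cu": 6.23e-10,
    "Fe": 5.36e-10,
    "Mn": 5.85e-10,
    "Zn": 6.08e-10,
    "Cd": 6.09e-10,
    "Pb": 7.33e-10,
}

#: Fractional change of the gel diffusion coefficient per degC, used by the
#: linear temperature-correction hook (viscosity effect, ~2.3 %/degC).
DGT_D_TEMP_SLOPE_PER_C = 0.023
DGT_D_REFERENCE_TEMP_C = 25.0

#: DGT geometry defaults: 0.8 mm diffusive gel + 0.13 mm filter, 2 cm window.
DGT_DELTA_G_M = 0.93e-3
DGT_WINDOW_AREA_M2 = 3.1416e-4  # pi * (0.01 m)^2

#: Chelex-100 / 1 M HNO3 elution factor default.
DGT_ELUTION_FACTOR = 0.8

#: Instrument detection limits.
O2_DETECTION_LIMIT_NORMAL_NM = 125.0
O2_DETECTION_LIMIT_TRACE_NM = 20.0
PAR_DETECTION_LIMIT = 0.1  # umol photons m^-2 s^-1
CH4_DETECTION_LIMIT_NM = 10.0

#: 16S rRNA copies per genome by coarse taxonomic group.
COPIES_16S_PER_GENOME = {
    "gamma_MOB": 5.8,
    "alpha_MOB": 2.2,
    "other": 4.2,
}

#: Marker-gene copies per methanotroph cell.
PMOA_COPIES_PER_CELL = 2.0
MMOX_COPIES_PER_CELL = 1.0
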