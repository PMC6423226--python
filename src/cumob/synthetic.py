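"""Synthetic stratified-lake campaigns with closed-form ground truth.

The generator emulates the statistical structure the analysis assumes: a
sigmoidal O2 decline to a sharp oxycline, methane accumulating exponentially
below the top of the methane-oxidation zone (MOZ) towards a high sediment
source, exponential light (PAR) attenuation, dissolved copper declining
linearly from a surface source to depletion at the MOZ top (with the
DGT-labile fraction a fixed ratio of it), a Gaussian particulate-copper peak
inside the MOZ, and a Gaussian methanotroph abundance peak just below the
oxycline. Observation noise is multiplicative log-normal (triplicates);
qPCR plates add normal noise in Cp space with Poisson template sampling.

Every deterministic curve is parameterised so that the scenario's declared
zone bounds are the exact analytic crossings the detectors look for, which
makes the scenario a ground-truth oracle for the whole pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from . import constants as c
from .census import CopyNumberTable
from .errors import ParameterError, ValidationError
from .profiles import Campaign, DepthProfile

__all__ = [
    "LakeScenario",
    "GroundTruth",
    "generate_campaign",
    "generate_qpcr_plate",
    "generate_otu_table",
    "generate_dgt_table",
]


@dataclass
class LakeScenario:
    """Parameters of one synthetic campaign.

    Depth structure in metres; concentration scales match a small eutrophic
    lake in summer stratification: ~400 uM O2 at the surface, hundreds of uM
    CH4 over the sediment with sub-uM epilimnetic residual, low-nM dissolved
    copper with the DGT-labile fraction roughly a tenth of it, a few nM of
    particulate copper peaking in the MOZ, and methanotroph peaks of
    10^6-10^8 cells per litre against ~10^9 background bacteria.
    """

    max_depth: float = 16.0
    oxycline_depth: float = 7.0
    moz_top: float = 7.0
    moz_bottom: float = 9.0
    grid_fine: float = 0.25
    grid_coarse: float = 1.0
    surface_o2_um: float = 400.0
    o2_sigmoid_width: float = 0.15
    epilimnion_ch4_um: float = 0.5
    bottom_ch4_um: float = 400.0
    surface_par: float = 200.0
    cu_diss_surface_nm: float = 14.0
    cu_diss_min_nm: float = 1.0
    dgt_fraction: float = 0.1
    cu_part_baseline_nm: float = 0.5
    cu_part_peak_nm: float = 5.0
    cu_part_width_m: float | None = None      # default: MOZ thickness / 6
    mob_peak_cells_l: float = 2e7
    mob_background_cells_l: float = 1e5
    mob_peak_depth: float | None = None       # default: oxycline + 0.5 m
    mob_peak_width_m: float = 0.5
    mob_gamma_fraction: float = 0.9           # gamma vs alpha split of MOB
    other_cells_l: float = 1e9
    verr_cells_l: float = 2e6                 # verrucomicrobia (excluded group)
    pmoa_detection_bias: float = 30.0         # 16S-derived cells / pmoA cells
    pmoa_to_mmox_ratio: float = 160.0
    noise_cv: float = 0.05
    n_replicates: int = 3
    qpcr_curve_slope: float = -3.3219         # perfect doubling, E = 2
    qpcr_curve_intercept: float = 38.0
    qpcr_noise_sd_cp: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.moz_top < self.moz_bottom <= self.max_depth):
            raise ValidationError("MOZ must lie inside (0, max_depth]")
        if self.oxycline_depth > self.moz_bottom:
            raise ValidationError("oxycline below the MOZ bottom is inconsistent")
        for name in (
            "surface_o2_um", "epilimnion_ch4_um", "bottom_ch4_um", "surface_par",
            "cu_diss_surface_nm", "mob_peak_cells_l", "other_cells_l",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.bottom_ch4_um <= 2 * self.epilimnion_ch4_um:
            raise ValidationError("bottom CH4 must exceed twice the background")

    # -- derived curve parameters -------------------------------------------

    @property
    def par_attenuation_k(self) -> float:
        """Attenuation making PAR cross its detection limit at the MOZ bottom."""
        return math.log(self.surface_par / c.PAR_DETECTION_LIMIT) / self.moz_bottom

    @property
    def ch4_scale_m(self) -> float:
        """e-folding depth of the CH4 rise (fixes the 2x-background crossing
        exactly at the MOZ top)."""
        return (self.max_depth - self.moz_top) / math.log(
            self.bottom_ch4_um / (2 * self.epilimnion_ch4_um)
        )

    @property
    def ch4_onset_depth(self) -> float:
        """Depth where CH4 departs from the epilimnetic background."""
        return self.moz_top - self.ch4_scale_m * math.log(2.0)

    @property
    def epi_cutoff(self) -> float:
        """Depth above which the water column is unambiguously epilimnetic."""
        return min(self.oxycline_depth - 2.0, self.ch4_onset_depth)

    @property
    def cu_part_center(self) -> float:
        return 0.5 * (self.moz_top + self.moz_bottom)

    @property
    def cu_part_sigma(self) -> float:
        if self.cu_part_width_m is not None:
            return self.cu_part_width_m
        return (self.moz_bottom - self.moz_top) / 6.0

    @property
    def mob_center(self) -> float:
        if self.mob_peak_depth is not None:
            return self.mob_peak_depth
        return self.oxycline_depth + 0.5

    # -- noiseless curves ----------------------------------------------------

    def depth_grid(self) -> np.ndarray:
        """Irregular sampling grid: coarse steps with fine resolution from
        2 m above the oxycline to 1 m below the MOZ bottom."""
        fine_lo = max(self.oxycline_depth - 2.0, 0.0)
        fine_hi = min(self.moz_bottom + 1.0, self.max_depth)
        pieces = [
            np.arange(0.0, fine_lo, self.grid_coarse),
            np.arange(fine_lo, fine_hi, self.grid_fine),
            np.arange(fine_hi, self.max_depth, self.grid_coarse),
            [self.max_depth],
        ]
        return np.unique(np.round(np.concatenate(pieces), 6))

    def o2(self, z):
        """Sigmoid decline calibrated so the trace-optode detection limit
        (20 nM) is crossed exactly at the oxycline depth."""
        dl = c.O2_DETECTION_LIMIT_TRACE_NM * 1e-3  # uM
        w = self.o2_sigmoid_width
        z_mid = self.oxycline_depth + w * math.log(dl / (self.surface_o2_um - dl))
        return self.surface_o2_um * expit((z_mid - np.asarray(z, float)) / w)

    def ch4(self, z):
        z = np.asarray(z, dtype=float)
        bg = self.epilimnion_ch4_um
        rise = bg * np.exp((z - self.ch4_onset_depth) / self.ch4_scale_m)
        return np.where(z <= self.ch4_onset_depth, bg, np.minimum(rise, self.bottom_ch4_um))

    def par(self, z):
        return self.surface_par * np.exp(-self.par_attenuation_k * np.asarray(z, float))

    def cu_diss(self, z):
        z = np.asarray(z, dtype=float)
        s, m = self.cu_diss_surface_nm, self.cu_diss_min_nm
        lin = s + (m - s) * z / self.moz_top
        return np.where(z <= self.moz_top, lin, m)

    def cu_dgt(self, z):
        return self.dgt_fraction * self.cu_diss(z)

    def cu_part(self, z):
        z = np.asarray(z, dtype=float)
        return self.cu_part_baseline_nm + self.cu_part_peak_nm * np.exp(
            -0.5 * ((z - self.cu_part_center) / self.cu_part_sigma) ** 2
        )

    def cu_total(self, z):
        return self.cu_diss(z) + self.cu_part(z)

    def mob_cells(self, z):
        z = np.asarray(z, dtype=float)
        return self.mob_background_cells_l + self.mob_peak_cells_l * np.exp(
            -0.5 * ((z - self.mob_center) / self.mob_peak_width_m) ** 2
        )

    def total_cells(self, z):
        return self.other_cells_l + self.mob_cells(z)

    def sixteen_s_copies(
        self,
        z,
        copy_table: CopyNumberTable | None = None,
        include_excluded: bool = True,
    ):
        """Total bacterial 16S gene copies per litre.

        qPCR measures the whole community (*include_excluded* True); the
        census denominator after dropping the verrucomicrobial group is the
        *include_excluded=False* value (the two differ by the small
        verrucomicrobial share).
        """
        ct = copy_table or CopyNumberTable()
        mob = self.mob_cells(z)
        total = (
            self.mob_gamma_fraction * mob * ct["gamma_MOB"]
            + (1 - self.mob_gamma_fraction) * mob * ct["alpha_MOB"]
            + self.other_cells_l * ct["other"]
        )
        if include_excluded:
            total = total + self.verr_cells_l * ct["other"]
        return total

    def pmoa_copies(self, z):
        """pmoA copies per litre, including the detection bias relative to
        the 16S-derived census."""
        return self.mob_cells(z) * c.PMOA_COPIES_PER_CELL / self.pmoa_detection_bias

    def mmox_copies(self, z):
        return self.pmoa_copies(z) / (
            c.PMOA_COPIES_PER_CELL * self.pmoa_to_mmox_ratio
        ) * c.MMOX_COPIES_PER_CELL


def _gauss_integral(amplitude, center, sigma, a, b) -> float:
    """Closed-form integral of a Gaussian bump over [a, b]."""
    return amplitude * sigma * math.sqrt(2 * math.pi) * (
        ndtr((b - center) / sigma) - ndtr((a - center) / sigma)
    )


@dataclass
class GroundTruth:
    """Noiseless quantities of one scenario, all in closed form."""

    oxycline_depth: float
    moz_top: float
    moz_bottom: float
    epi_cutoff: float
    ch4_background_um: float
    ch4_threshold_um: float
    cu_diss_slope_nm_per_m: float
    cu_diss_flux_nmol_m2_d: float
    cu_dgt_slope_nm_per_m: float
    cu_dgt_flux_nmol_m2_d: float
    cu_gradient_window: tuple[float, float]
    cupart_pool_nmol_m2: float
    mob_integral_cells_m2: float
    total_cells_integral_m2: float
    mob_relative_pct: float
    mob_cu_pool_nmol_m2: float
    group_fractions: dict[str, float]
    qpcr_slope: float
    qpcr_intercept: float
    kz_m2_s: float = c.DEFAULT_KZ_M2_PER_S

    def to_dict(self) -> dict:
        return asdict(self)


def ground_truth(scenario: LakeScenario, quota_mol_per_cell: float = 4e-20) -> GroundTruth:
    s = scenario
    slope_diss = -(s.cu_diss_surface_nm - s.cu_diss_min_nm) / s.moz_top
    flux_factor = c.DEFAULT_KZ_M2_PER_S * c.SECONDS_PER_DAY * 1e3  # nM/m -> nmol
    a, b = s.moz_top, s.moz_bottom
    cupart_pool = 1e3 * (
        s.cu_part_baseline_nm * (b - a)
        + _gauss_integral(s.cu_part_peak_nm, s.cu_part_center, s.cu_part_sigma, a, b)
    )
    mob_int = 1e3 * (
        s.mob_background_cells_l * (b - a)
        + _gauss_integral(s.mob_peak_cells_l, s.mob_center, s.mob_peak_width_m, a, b)
    )
    total_int = mob_int + 1e3 * s.other_cells_l * (b - a)
    return GroundTruth(
        oxycline_depth=s.oxycline_depth,
        moz_top=s.moz_top,
        moz_bottom=s.moz_bottom,
        epi_cutoff=s.epi_cutoff,
        ch4_background_um=s.epilimnion_ch4_um,
        ch4_threshold_um=2 * s.epilimnion_ch4_um,
        cu_diss_slope_nm_per_m=slope_diss,
        cu_diss_flux_nmol_m2_d=abs(slope_diss) * flux_factor,
        cu_dgt_slope_nm_per_m=slope_diss * s.dgt_fraction,
        cu_dgt_flux_nmol_m2_d=abs(slope_diss) * s.dgt_fraction * flux_factor,
        cu_gradient_window=(0.0, s.moz_top),
        cupart_pool_nmol_m2=cupart_pool,
        mob_integral_cells_m2=mob_int,
        total_cells_integral_m2=total_int,
        mob_relative_pct=100.0 * mob_int / total_int,
        mob_cu_pool_nmol_m2=mob_int * quota_mol_per_cell * 1e9,
        group_fractions={
            "gamma_MOB": s.mob_gamma_fraction,
            "alpha_MOB": 1 - s.mob_gamma_fraction,
        },
        qpcr_slope=s.qpcr_curve_slope,
        qpcr_intercept=s.qpcr_curve_intercept,
    )


def _noisy_triplicates(rng, values, cv, n):
    """Mean/SD of n multiplicative log-normal replicates (mean-unbiased)."""
    values = np.asarray(values, dtype=float)
    if cv == 0:
        return values.copy(), np.zeros_like(values)
    sigma = math.sqrt(math.log(1 + cv**2))
    draws = values[None, :] * np.exp(
        rng.normal(0.0, sigma, size=(n, values.size)) - sigma**2 / 2
    )
    return draws.mean(axis=0), draws.std(axis=0, ddof=1)


def generate_campaign(
    scenario: LakeScenario | None = None,
) -> tuple[Campaign, GroundTruth]:
    """Generate one noisy campaign plus its closed-form ground truth.

    The campaign holds O2, CH4 and PAR profiles, dissolved / DGT / total
    copper, and 16S-census cell profiles (MOB and total bacteria), each the
    mean of triplicate multiplicative log-normal draws with the scenario's
    CV. Values below the declared detection limits are flagged
    ``below_LOD``. The same seed always yields the identical campaign.
    """
    s = scenario or LakeScenario()
    rng = np.random.default_rng(s.seed)
    z = s.depth_grid()
    camp = Campaign(
        id=f"synthetic-{s.seed}",
        detection_limits={
            "O2": c.O2_DETECTION_LIMIT_TRACE_NM,
            "PAR": c.PAR_DETECTION_LIMIT,
            "CH4": c.CH4_DETECTION_LIMIT_NM,
        },
    )

    specs = [
        ("O2", "na", s.o2(z), "uM", c.O2_DETECTION_LIMIT_TRACE_NM * 1e-3),
        ("CH4", "na", s.ch4(z), "uM", c.CH4_DETECTION_LIMIT_NM * 1e-3),
        ("PAR", "na", s.par(z), "umol m-2 s-1", c.PAR_DETECTION_LIMIT),
        ("Cu", "dissolved", s.cu_diss(z), "nM", None),
        ("Cu", "DGT", s.cu_dgt(z), "nM", None),
        ("Cu", "total", s.cu_total(z), "nM", None),
        ("MOB_cells", "na", s.mob_cells(z), "cells L-1", None),
        ("total_cells", "na", s.total_cells(z), "cells L-1", None),
    ]
    for analyte, fraction, truth, unit, dl in specs:
        mean, sd = _noisy_triplicates(rng, truth, s.noise_cv, s.n_replicates)
        flags = np.full(z.shape, "ok", dtype=object)
        if dl is not None:
            flags[mean < dl] = "below_LOD"
        camp.add(
            DepthProfile(
                analyte=analyte,
                fraction=fraction,
                depths=z,
                values=mean,
                unit=unit,
                sds=sd,
                n_replicates=np.full(z.shape, s.n_replicates),
                flags=flags,
            )
        )
    return camp, ground_truth(s)


# -- qPCR plate --------------------------------------------------------------

STANDARD_COPIES = tuple(5.0 * 10**k for k in range(7, -1, -1))


def generate_qpcr_plate(
    true_copies_by_depth: dict[float, float],
    target: str = "pmoA",
    slope: float = -3.3219,
    intercept: float = 38.0,
    noise_sd_cp: float = 0.15,
    seed: int = 0,
    n_sample_reps: int = 3,
    n_standard_reps: int = 4,
    n_blanks: int = 3,
    blank_cp: float = 37.5,
    contamination_fraction: float = 0.0,
    poisson_template: bool = True,
    campaign: str = "synthetic",
) -> pd.DataFrame:
    """Simulate a qPCR plate: dilution-series standards, blanks, samples.

    Standards run the 5e7..5e0 copies-per-reaction series in quadruplicate;
    samples run in triplicate with Cp = intercept + slope*log10(copies) +
    N(0, noise_sd_cp). With *poisson_template* the realised template copies
    are Poisson-distributed around the nominal value, which reproduces the
    replicate-scatter blow-up at few-copy dilutions that drives the limit of
    quantification. Zero realised copies give no amplification (missing Cp).
    A *contamination_fraction* of wells gets a bad melt flag.
    """
    if noise_sd_cp < 0:
        raise ParameterError("noise_sd_cp must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []

    def draw_cp(nominal_copies: float) -> float:
        n = (
            rng.poisson(nominal_copies)
            if poisson_template and nominal_copies < 1e6
            else nominal_copies
        )
        if n <= 0:
            return math.nan
        return intercept + slope * math.log10(n) + rng.normal(0.0, noise_sd_cp)

    def melt_flag() -> bool:
        return not (contamination_fraction > 0 and rng.random() < contamination_fraction)

    for level in STANDARD_COPIES:
        for rep in range(n_standard_reps):
            rows.append(
                dict(
                    target=target, campaign=campaign, depth_m=math.nan,
                    replicate=rep + 1, cp=draw_cp(level), melt_ok=True,
                    is_blank=False, is_standard=True, standard_copies=level,
                )
            )
    for rep in range(n_blanks):
        rows.append(
            dict(
                target=target, campaign=campaign, depth_m=math.nan,
                replicate=rep + 1,
                cp=blank_cp + abs(rng.normal(0.0, 0.3)),
                melt_ok=True, is_blank=True, is_standard=False,
                standard_copies=math.nan,
            )
        )
    for depth in sorted(true_copies_by_depth):
        copies = true_copies_by_depth[depth]
        for rep in range(n_sample_reps):
            rows.append(
                dict(
                    target=target, campaign=campaign, depth_m=float(depth),
                    replicate=rep + 1,
                    cp=draw_cp(copies) if copies > 0 else math.nan,
                    melt_ok=melt_flag(), is_blank=False, is_standard=False,
                    standard_copies=math.nan,
                )
            )
    return pd.DataFrame(rows)


# -- OTU table ---------------------------------------------------------------

def generate_otu_table(
    scenario: LakeScenario,
    read_depth: int | None = 50_000,
    n_background_otus: int = 200,
    seed: int | None = None,
    copy_table: CopyNumberTable | None = None,
) -> pd.DataFrame:
    """Simulate a taxa x depth OTU count table for the scenario's community.

    Expected read fractions are proportional to cells times 16S copies per
    genome, inverting the census correction. Counts are multinomial at
    *read_depth* reads per depth; ``read_depth=None`` emits exact expected
    counts (the infinite-depth limit, scaled to 1e6 reads) so the census
    round-trips without sampling error. Background OTUs share the non-MOB
    reads with a geometric abundance profile; a small verrucomicrobial OTU
    (flagged for exclusion) is included to exercise the exclusion rule.
    """
    ct = copy_table or CopyNumberTable()
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    z = scenario.depth_grid()
    # 16S-census depths: every other fine point is plenty
    depths = z[::2]

    groups = ["gamma_MOB", "alpha_MOB", "other"]
    otus = [
        {"otu_id": "OTU_gamma_1", "taxonomy": "Gammaproteobacteria;Methylococcales", "group": "gamma_MOB"},
        {"otu_id": "OTU_alpha_1", "taxonomy": "Alphaproteobacteria;Methylocystaceae", "group": "alpha_MOB"},
        {"otu_id": "OTU_verr_1", "taxonomy": "Verrucomicrobia;Methylacidiphilales", "group": "verrucomicrobia_excluded"},
    ]
    bg_weights = 0.7 ** np.arange(n_background_otus)
    bg_weights /= bg_weights.sum()
    for i in range(n_background_otus):
        otus.append(
            {"otu_id": f"OTU_bg_{i+1:04d}", "taxonomy": "Bacteria;other", "group": "other"}
        )
    table = pd.DataFrame(otus)

    for depth in depths:
        mob = float(scenario.mob_cells(depth))
        cells = {
            "gamma_MOB": scenario.mob_gamma_fraction * mob,
            "alpha_MOB": (1 - scenario.mob_gamma_fraction) * mob,
            "verrucomicrobia_excluded": scenario.verr_cells_l,
            "other": scenario.other_cells_l,
        }
        # expected read share: cells x 16S copies per genome (verrucomicrobia
        # carry the generic copy number)
        weights = np.array(
            [cells[g] * ct.copies.get(g, ct["other"]) for g in
             ("gamma_MOB", "alpha_MOB", "verrucomicrobia_excluded", "other")]
        )
        fractions = weights / weights.sum()
        per_otu = np.concatenate(
            (fractions[:3], fractions[3] * bg_weights)
        )
        if read_depth is None:
            counts = per_otu * 1e6
        else:
            counts = rng.multinomial(read_depth, per_otu / per_otu.sum())
        table[f"{depth:g}"] = counts
    return table


# -- DGT deployment table ----------------------------------------------------

def generate_dgt_table(
    scenario: LakeScenario,
    analyte: str = "Cu",
    t_deploy_d: float = 2.0,
    n_replicates: int = 3,
    n_controls: int = 2,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a DGT eluate table consistent with the scenario's labile
    copper profile (forward Davison accumulation, then elution)."""
    from .dgt import DGTDeployment

    s = scenario
    rng = np.random.default_rng((s.seed if seed is None else seed) + 1)
    z = s.depth_grid()[1::2]
    molar_mass = c.MOLAR_MASS_G_PER_MOL[analyte]
    rows = []
    sigma = math.sqrt(math.log(1 + s.noise_cv**2))
    for depth in z:
        conc_nm = float(s.cu_dgt(depth))
        dep = DGTDeployment(
            depth=float(depth), analyte=analyte,
            t_deploy=t_deploy_d * c.SECONDS_PER_DAY,
        )
        m_mol = conc_nm * 1e-6 * dep.D * dep.A * dep.t_deploy / dep.delta_g
        eluate_ug_l = (
            m_mol * molar_mass * 1e6 * c.DGT_ELUTION_FACTOR / (dep.V_gel + dep.V_eluent)
        )
        for rep in range(n_replicates):
            noisy = eluate_ug_l * math.exp(rng.normal(0, sigma) - sigma**2 / 2)
            rows.append(
                dict(
                    campaign=f"synthetic-{s.seed}", depth_m=float(depth),
                    analyte=analyte, replicate_id=rep + 1,
                    eluate_conc=noisy, eluate_unit="ug/L",
                    V_gel_mL=0.15, V_eluent_mL=1.35,
                    t_deploy_d=t_deploy_d, is_control=False,
                )
            )
    for rep in range(n_controls):
        rows.append(
            dict(
                campaign=f"synthetic-{s.seed}", depth_m=math.nan,
                analyte=analyte, replicate_id=rep + 1,
                eluate_conc=0.0, eluate_unit="ug/L",
                V_gel_mL=0.15, V_eluent_mL=1.35,
                t_deploy_d=t_deploy_d, is_control=True,
            )
        )
    return pd.DataFrame(rows)
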