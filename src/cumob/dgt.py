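"""Diffusive gradients in thin films (DGT) passive-sampler inversion.

A DGT unit accumulates labile metal species on a Chelex resin behind a
diffusive gel. The time-averaged labile ("bioavailable") concentration at
the deployment depth follows from the accumulated mass M via the Davison
relation

    C = M * delta_g / (D * A * t)

with delta_g the diffusive path (gel + filter), D the diffusion coefficient
of the analyte in the gel, A the exposure-window area and t the deployment
time. The diffusive boundary layer at the window is treated as negligibly
thin. Laboratory controls provide a blank mass; replicate eluates are
screened for outliers with a two-sided Grubbs test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import constants as c
from .errors import (
    ConfigurationError,
    ParameterError,
    SampleSizeError,
)
from .profiles import Campaign, DepthProfile

__all__ = [
    "DGTDeployment",
    "accumulated_mass",
    "dgt_concentration",
    "blank_correct",
    "grubbs_screen",
    "diffusion_coefficient",
    "read_dgt_table",
    "process_dgt_table",
]


@dataclass
class DGTDeployment:
    """Geometry and timing of one DGT sampler unit.

    Attributes
    ----------
    depth : m below surface.
    analyte : element symbol (``Cu``, ``Fe``, ``Mn``).
    t_deploy : deployment duration, seconds.
    delta_g : diffusive path thickness (gel + filter), m.
    A : exposure window area, m^2.
    D : analyte diffusion coefficient in the gel, m^2 s^-1.
    eluate_conc : analyte mass concentration in the eluate, ug L^-1.
    V_gel, V_eluent : resin-gel and eluent volumes, L.
    f_e : elution factor in (0, 1].
    is_control : True for laboratory blanks.
    """

    depth: float
    analyte: str
    t_deploy: float
    eluate_conc: float = 0.0
    delta_g: float = c.DGT_DELTA_G_M
    A: float = c.DGT_WINDOW_AREA_M2
    D: float | None = None
    V_gel: float = 0.15e-3
    V_eluent: float = 1.35e-3
    f_e: float = c.DGT_ELUTION_FACTOR
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.D is None:
            self.D = diffusion_coefficient(self.analyte)
        if self.t_deploy <= 0 or self.delta_g <= 0 or self.A <= 0 or self.D <= 0:
            raise ParameterError("t_deploy, delta_g, A and D must be positive")
        if not (0 < self.f_e <= 1):
            raise ParameterError(f"elution factor f_e={self.f_e} outside (0, 1]")
        if self.eluate_conc < 0:
            raise ParameterError("eluate concentration must be >= 0")


def diffusion_coefficient(analyte: str, temperature_c: float | None = None) -> float:
    """Default gel diffusion coefficient for *analyte*, m^2 s^-1.

    Bundled 25 degC values with an optional linear temperature correction
    (~2.3 % per degC). These are generic defaults; supply measured values for
    quantitative work.
    """
    try:
        d25 = c.DGT_DIFFUSION_COEFF_25C[analyte]
    except KeyError:
        raise ParameterError(
            f"no default diffusion coefficient for {analyte!r}; supply D explicitly"
        ) from None
    if temperature_c is None:
        return d25
    d = d25 * (1 + c.DGT_D_TEMP_SLOPE_PER_C * (temperature_c - c.DGT_D_REFERENCE_TEMP_C))
    if d <= 0:
        raise ParameterError(f"temperature correction gives non-physical D={d}")
    return d


def accumulated_mass(
    eluate_conc: float,
    V_gel: float,
    V_eluent: float,
    f_e: float,
    molar_mass: float,
) -> float:
    """Mass of analyte accumulated on the resin, in moles.

    ``M = eluate_conc * (V_gel + V_eluent) / f_e`` with the eluate
    concentration in ug L^-1 and volumes in litres; converted to moles via
    *molar_mass* (g mol^-1).
    """
    if V_gel <= 0 or V_eluent <= 0:
        raise ParameterError("gel and eluent volumes must be positive")
    if not (0 < f_e <= 1):
        raise ParameterError(f"elution factor f_e={f_e} outside (0, 1]")
    if eluate_conc < 0:
        raise ParameterError("eluate concentration must be >= 0")
    mass_ug = eluate_conc * (V_gel + V_eluent) / f_e
    return mass_ug * 1e-6 / molar_mass


def dgt_concentration(deployment: DGTDeployment, M: float) -> float:
    """Time-averaged labile concentration, nM, from accumulated moles *M*.

    ``C = M * delta_g / (D * A * t)`` in mol m^-3, reported in nM
    (1 mol m^-3 = 1e6 nM).
    """
    if M < 0:
        raise ParameterError("accumulated mass must be >= 0")
    d = deployment
    c_mol_m3 = M * d.delta_g / (d.D * d.A * d.t_deploy)
    return c_mol_m3 * 1e6


def blank_correct(
    sample_masses,
    control_masses,
    *,
    disabled: bool = False,
):
    """Subtract the mean laboratory-control mass from each sample mass.

    Returns ``(corrected, clamped)`` where *clamped* marks samples whose
    corrected mass was negative and was clamped to zero.
    """
    samples = np.asarray(sample_masses, dtype=float)
    if disabled:
        return samples.copy(), np.zeros(samples.shape, dtype=bool)
    controls = np.asarray(control_masses, dtype=float)
    if controls.size == 0:
        raise ConfigurationError(
            "no control (blank) deployments; pass disabled=True to skip "
            "blank correction explicitly"
        )
    corrected = samples - controls.mean()
    clamped = corrected < 0
    corrected = np.where(clamped, 0.0, corrected)
    return corrected, clamped


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_screen(replicates, alpha: float = 0.05, passes: int = 1):
    """Two-sided Grubbs outlier screen on replicate values.

    At most one value is removed per pass (single pass by default). With zero
    variance no removal occurs. Returns ``(retained values, removed indices
    into the original array)``.
    """
    x = np.asarray(replicates, dtype=float)
    if x.size < 3:
        raise SampleSizeError(f"Grubbs test needs >= 3 replicates, got {x.size}")
    if not (0 < alpha < 0.5):
        raise ParameterError(f"alpha={alpha} outside (0, 0.5)")
    idx = np.arange(x.size)
    removed: list[int] = []
    for _ in range(passes):
        if x.size < 3:
            break
        sd = x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - x.mean())
        g = dev.max() / sd
        if g > grubbs_critical_value(x.size, alpha):
            k = int(dev.argmax())
            removed.append(int(idx[k]))
            x = np.delete(x, k)
            idx = np.delete(idx, k)
        else:
            break
    return x, removed


# -- table-level processing --------------------------------------------------

DGT_COLUMNS = (
    "campaign", "depth_m", "analyte", "replicate_id", "eluate_conc",
    "eluate_unit", "V_gel_mL", "V_eluent_mL", "t_deploy_d", "is_control",
)


def read_dgt_table(path) -> pd.DataFrame:
    """Read the DGT deployment TSV (see :data:`DGT_COLUMNS`; ``temp_C`` and
    ``f_e`` optional)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [col for col in DGT_COLUMNS if col not in df.columns]
    if missing:
        from .errors import SchemaError

        raise SchemaError(f"{path}: missing DGT column(s) {missing}")
    return df


def process_dgt_table(
    df: pd.DataFrame,
    campaign: Campaign | None = None,
    alpha: float = 0.05,
    blank_correction: bool = True,
) -> dict[str, DepthProfile]:
    """Reduce a DGT deployment table to per-analyte DGT concentration profiles.

    Per (analyte, depth): eluate concentrations -> accumulated moles ->
    blank subtraction (mean of that analyte's controls) -> Grubbs screen
    (when >= 3 replicates) -> Davison inversion per replicate -> mean +- SD.
    Profiles are merged into *campaign* (fraction ``DGT``) when given.
    """
    out: dict[str, DepthProfile] = {}
    for analyte, adf in df.groupby("analyte", sort=False):
        molar_mass = c.MOLAR_MASS_G_PER_MOL.get(str(analyte))
        if molar_mass is None:
            raise ParameterError(f"no molar mass for analyte {analyte!r}")

        def row_mass(row) -> float:
            f_e = float(row["f_e"]) if "f_e" in row and pd.notna(row.get("f_e")) else c.DGT_ELUTION_FACTOR
            return accumulated_mass(
                float(row["eluate_conc"]),
                float(row["V_gel_mL"]) * 1e-3,
                float(row["V_eluent_mL"]) * 1e-3,
                f_e,
                molar_mass,
            )

        controls = adf[adf["is_control"].astype(bool)]
        control_masses = np.array([row_mass(r) for _, r in controls.iterrows()])
        samples = adf[~adf["is_control"].astype(bool)]

        depths, means, sds, ns = [], [], [], []
        for depth, g in samples.groupby("depth_m", sort=True):
            masses = np.array([row_mass(r) for _, r in g.iterrows()])
            masses, _ = blank_correct(
                masses, control_masses, disabled=not blank_correction
            )
            if masses.size >= 3:
                masses, _ = grubbs_screen(masses, alpha=alpha)
            temp = g["temp_C"].iloc[0] if "temp_C" in g and pd.notna(g["temp_C"].iloc[0]) else None
            concs = []
            for m, (_, row) in zip(masses, g.iterrows(), strict=False):
                dep = DGTDeployment(
                    depth=float(depth),
                    analyte=str(analyte),
                    t_deploy=float(row["t_deploy_d"]) * c.SECONDS_PER_DAY,
                    D=diffusion_coefficient(str(analyte), temp),
                )
                concs.append(dgt_concentration(dep, m))
            concs = np.asarray(concs)
            depths.append(float(depth))
            means.append(float(concs.mean()))
            sds.append(float(concs.std(ddof=1)) if concs.size > 1 else 0.0)
            ns.append(concs.size)

        prof = DepthProfile(
            analyte=str(analyte),
            fraction="DGT",
            depths=np.array(depths),
            values=np.array(means),
            unit="nM",
            sds=np.array(sds),
            n_replicates=np.array(ns),
        )
        out[str(analyte)] = prof
        if campaign is not None:
            campaign.add(prof)
    return out
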