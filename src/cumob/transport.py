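"""Vertical turbulent-diffusive flux estimation from concentration gradients.

Fick's first law with a vertical turbulent (eddy) diffusion coefficient Kz:
the flux into a zone is J = Kz * |dC/dz|, with the gradient obtained by
ordinary least squares over a depth window. The default Kz of 1e-6 m^2 s^-1
is typical of the quiescent metalimnion of a small stratified lake.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import constants as c
from .errors import ParameterError, WindowError
from .profiles import DepthProfile

__all__ = [
    "FluxEstimate",
    "fit_gradient",
    "diffusive_flux",
    "default_gradient_window",
    "flux_from_profile",
]

#: flux-unit conversion per concentration unit: (output unit, factor applied
#: to Kz[m^2/s] * slope[unit/m] * 86400 s/d).
_FLUX_UNITS = {
    "nM": ("nmol m-2 d-1", 1e3),   # nM/m = umol m^-4 -> umol m^-2 d^-1 -> nmol
    "uM": ("mmol m-2 d-1", 1.0),   # uM/m = mmol m^-4 -> mmol m^-2 d^-1
}


@dataclass
class FluxEstimate:
    """A diffusive-flux estimate with its regression diagnostics."""

    analyte: str
    fraction: str
    window: tuple[float, float]
    slope: float            # concentration unit per metre
    slope_se: float
    intercept: float
    r_squared: float
    Kz: float               # m^2 s^-1
    flux: float             # magnitude, in flux_unit
    flux_unit: str
    direction: str          # "downward" | "upward"


def fit_gradient(
    profile: DepthProfile,
    window: tuple[float, float],
) -> tuple[float, float, float, float]:
    """OLS of concentration on depth over *window* (inclusive bounds).

    Returns ``(slope, intercept, slope_se, r_squared)`` with the slope in
    profile units per metre. Censored points are excluded.
    """
    top, bottom = float(window[0]), float(window[1])
    sel = (
        (profile.depths >= top)
        & (profile.depths <= bottom)
        & (profile.flags == "ok")
    )
    z, v = profile.depths[sel], profile.values[sel]
    if z.size < 2:
        raise WindowError(
            f"{profile.analyte}/{profile.fraction}: only {z.size} uncensored "
            f"point(s) in window [{top}, {bottom}] m; need >= 2"
        )
    if np.ptp(z) == 0:
        raise WindowError("zero depth variance in regression window")
    res = stats.linregress(z, v)
    r2 = float(res.rvalue**2) if np.ptp(v) > 0 else 1.0
    if np.ptp(v) == 0:  # constant profile: slope 0, perfect fit
        return 0.0, float(v[0]), 0.0, 1.0
    return float(res.slope), float(res.intercept), float(res.stderr), r2


def diffusive_flux(
    slope: float,
    Kz: float = c.DEFAULT_KZ_M2_PER_S,
    unit: str = "nM",
    analyte: str = "",
    fraction: str = "na",
    window: tuple[float, float] = (np.nan, np.nan),
    slope_se: float = np.nan,
    intercept: float = np.nan,
    r_squared: float = np.nan,
) -> FluxEstimate:
    """Fickian flux from a concentration gradient.

    ``J = Kz * |slope| * 86400`` converted to nmol m^-2 d^-1 for nM-per-metre
    gradients (metals) and mmol m^-2 d^-1 for uM-per-metre gradients (gases).
    A negative slope (concentration decreasing downward) is a downward flux.
    """
    if Kz <= 0:
        raise ParameterError(f"Kz must be positive, got {Kz}")
    from . import units as _units

    cu = _units.canonical(unit)
    try:
        flux_unit, factor = _FLUX_UNITS[cu]
    except KeyError:
        raise ParameterError(
            f"no flux-unit convention for concentration unit {unit!r}"
        ) from None
    flux = Kz * abs(slope) * c.SECONDS_PER_DAY * factor
    return FluxEstimate(
        analyte=analyte,
        fraction=fraction,
        window=(float(window[0]), float(window[1])),
        slope=float(slope),
        slope_se=float(slope_se),
        intercept=float(intercept),
        r_squared=float(r_squared),
        Kz=Kz,
        flux=float(flux),
        flux_unit=flux_unit,
        direction="downward" if slope <= 0 else "upward",
    )


def default_gradient_window(
    profile: DepthProfile,
    moz,
) -> tuple[float, float]:
    """Default regression window for a solute supplied from above.

    From the depth of the profile's epilimnetic maximum (above the MOZ top)
    down to the first depth at or below the MOZ top where the profile reaches
    its within-MOZ minimum — i.e. from the surface source down to depletion.
    "Reaches the minimum" allows three replicate standard deviations of
    slack (median in-zone SD): noisy points on the depleted plateau must not
    drag the window deep into the zone and flatten the fitted gradient.
    Stopping early on a linear decline leaves the slope unbiased, so the
    allowance errs on the generous side.
    """
    top_moz = moz.top if hasattr(moz, "top") else float(moz[0])
    bottom_moz = moz.bottom if hasattr(moz, "bottom") else float(moz[1])
    ok = profile.flags == "ok"
    z, v = profile.depths[ok], profile.values[ok]
    epi = z <= top_moz
    if not epi.any():
        raise WindowError("no uncensored points above the MOZ top")
    zmax_val = z[epi][int(np.argmax(v[epi]))]
    inzone = (z >= top_moz) & (z <= bottom_moz)
    if not inzone.any():
        raise WindowError("no uncensored points inside the MOZ")
    allowance = 0.0
    if profile.sds is not None:
        sds_zone = profile.sds[ok][inzone]
        sds_zone = sds_zone[np.isfinite(sds_zone)]
        if sds_zone.size:
            allowance = 3.0 * float(np.median(sds_zone))
    vmin = float(np.min(v[inzone]))
    depleted = inzone & (v <= vmin + allowance)
    zmin_val = z[depleted][0]
    if zmin_val <= zmax_val:
        raise WindowError("degenerate gradient window (minimum above maximum)")
    return float(zmax_val), float(zmin_val)


def flux_from_profile(
    profile: DepthProfile,
    window: tuple[float, float],
    Kz: float = c.DEFAULT_KZ_M2_PER_S,
) -> FluxEstimate:
    """Fit the gradient over *window* and convert it to a flux."""
    slope, intercept, se, r2 = fit_gradient(profile, window)
    return diffusive_flux(
        slope,
        Kz,
        unit=profile.unit,
        analyte=profile.analyte,
        fraction=profile.fraction,
        window=window,
        slope_se=se,
        intercept=intercept,
        r_squared=r2,
    )


def flux_table(estimates, campaign_id: str = "") -> pd.DataFrame:
    """Tabulate flux estimates in the on-disk TSV layout."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "campaign": campaign_id,
                "analyte": e.analyte,
                "fraction": e.fraction,
                "window_top_m": e.window[0],
                "window_bottom_m": e.window[1],
                "slope": e.slope,
                "slope_se": e.slope_se,
                "r2": e.r_squared,
                "Kz": e.Kz,
                "flux": e.flux,
                "flux_unit": e.flux_unit,
                "direction": e.direction,
            }
        )
    return pd.DataFrame(rows)
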