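"""Depth-resolved campaign data: containers, I/O, interpolation, integration.

A :class:`DepthProfile` holds one analyte/fraction series on a strictly
increasing depth grid (metres below surface, positive down, 0 at the
air-water interface). A :class:`Campaign` bundles all profiles of one field
campaign. Areal pools over a depth interval are computed with the trapezoidal
rule on the native (possibly irregular) grid, with linearly interpolated
values at the interval boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import units as _units
from .errors import (
    CensoringError,
    ExtrapolationError,
    SchemaError,
    UnitError,
    ValidationError,
)

logger = logging.getLogger(__name__)

FRACTIONS = ("total", "dissolved", "DGT", "particulate", "na")
CENSOR_FLAGS = (
    "ok",
    "below_LOD",
    "not_quantifiable",
    "estimated_below_LOQ",
    "negative_particulate",
)

#: Required columns of the long-format profile table.
PROFILE_COLUMNS = ("campaign", "depth_m", "analyte", "fraction", "value", "unit")
OPTIONAL_COLUMNS = ("sd", "n", "flag")


@dataclass
class DepthProfile:
    """One analyte/fraction series along a depth grid.

    Parameters
    ----------
    analyte
        Analyte label (``O2``, ``CH4``, ``PAR``, ``Cu``, ``MOB_cells``, ...).
    fraction
        Operational fraction: ``total``, ``dissolved``, ``DGT``,
        ``particulate`` or ``na`` for analytes without one.
    depths
        Metres below surface, strictly increasing, >= 0.
    values
        Measured values in ``unit``; one unit per profile.
    sds
        Replicate standard deviations, same unit, >= 0; optional.
    n_replicates
        Replicate count per point; optional.
    flags
        Per-point censoring flag, one of :data:`CENSOR_FLAGS`.
    """

    analyte: str
    fraction: str
    depths: np.ndarray
    values: np.ndarray
    unit: str
    sds: np.ndarray | None = None
    n_replicates: np.ndarray | None = None
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.unit = _units.canonical(self.unit)
        if self.fraction not in FRACTIONS:
            raise ValidationError(
                f"unknown fraction {self.fraction!r}; expected one of {FRACTIONS}"
            )
        if self.depths.ndim != 1 or self.depths.shape != self.values.shape:
            raise ValidationError("depths and values must be 1-D and equal length")
        if self.depths.size == 0:
            raise ValidationError(f"{self.analyte}/{self.fraction}: empty profile")
        if np.any(self.depths < 0):
            raise ValidationError("depths must be >= 0 (metres below surface)")
        if np.any(np.diff(self.depths) <= 0):
            bad = self.depths[1:][np.diff(self.depths) <= 0]
            raise ValidationError(
                f"{self.analyte}/{self.fraction}: depths not strictly increasing "
                f"(offending depths: {bad.tolist()})"
            )
        if self.flags is None:
            self.flags = np.full(self.depths.shape, "ok", dtype=object)
        else:
            self.flags = np.asarray(self.flags, dtype=object)
            unknown = set(self.flags) - set(CENSOR_FLAGS)
            if unknown:
                raise ValidationError(f"unknown censor flags: {sorted(unknown)}")
        ok = self.flags == "ok"
        if not np.all(np.isfinite(self.values[ok])):
            raise ValidationError(
                f"{self.analyte}/{self.fraction}: non-finite value with flag 'ok'"
            )
        if self.sds is not None:
            self.sds = np.asarray(self.sds, dtype=float)
            if self.sds.shape != self.depths.shape:
                raise ValidationError("sds must match depths in length")
            if np.any(self.sds[np.isfinite(self.sds)] < 0):
                raise ValidationError("sds must be >= 0")
        if self.n_replicates is not None:
            self.n_replicates = np.asarray(self.n_replicates)
        if self.analyte == "PAR" and np.any(self.values[ok] < 0):
            raise ValidationError("PAR values must be >= 0")
        if self.fraction != "particulate":
            neg = ok & (self.values < 0)
            if np.any(neg):
                raise ValidationError(
                    f"{self.analyte}/{self.fraction}: negative concentrations are "
                    "only allowed for the particulate fraction (and must be flagged)"
                )

    # -- basic queries ------------------------------------------------------

    @property
    def zmin(self) -> float:
        return float(self.depths[0])

    @property
    def zmax(self) -> float:
        return float(self.depths[-1])

    def interpolate(self, z: float) -> float:
        """Piecewise-linear value at depth *z* (exact at grid nodes).

        Raises
        ------
        ExtrapolationError
            If *z* lies outside the measured depth range.
        CensoringError
            If a bracketing grid point is censored.
        """
        z = float(z)
        if z < self.zmin or z > self.zmax:
            raise ExtrapolationError(
                f"depth {z} m outside measured range "
                f"[{self.zmin}, {self.zmax}] m for {self.analyte}/{self.fraction}"
            )
        i = int(np.searchsorted(self.depths, z, side="right"))
        lo = max(i - 1, 0)
        hi = min(i, self.depths.size - 1)
        if z == self.depths[lo]:
            hi = lo
        for j in {lo, hi}:
            if self.flags[j] != "ok":
                raise CensoringError(
                    f"{self.analyte}/{self.fraction}: bracketing point at "
                    f"{self.depths[j]} m is censored ({self.flags[j]})"
                )
        return float(np.interp(z, self.depths, self.values))

    def to_frame(self) -> pd.DataFrame:
        """Long-format view of the profile."""
        return pd.DataFrame(
            {
                "depth_m": self.depths,
                "analyte": self.analyte,
                "fraction": self.fraction,
                "value": self.values,
                "sd": self.sds if self.sds is not None else np.nan,
                "n": self.n_replicates if self.n_replicates is not None else np.nan,
                "unit": self.unit,
                "flag": self.flags,
            }
        )


@dataclass
class IntegralResult:
    """Areal pool from :func:`integrate_zone`, with censoring provenance."""

    value: float
    unit: str
    n_censored: int = 0

    def __float__(self) -> float:
        return float(self.value)


@dataclass
class Campaign:
    """All depth profiles of one sampling campaign.

    ``profiles`` is keyed by ``(analyte, fraction)``; detection limits are in
    the unit of the corresponding profile.
    """

    id: str
    profiles: dict[tuple[str, str], DepthProfile] = field(default_factory=dict)
    date: str | None = None
    stratification_days: float | None = None
    detection_limits: dict[str, float] = field(default_factory=dict)

    def add(self, profile: DepthProfile) -> None:
        self.profiles[(profile.analyte, profile.fraction)] = profile

    def get(self, analyte: str, fraction: str = "na") -> DepthProfile:
        try:
            return self.profiles[(analyte, fraction)]
        except KeyError:
            raise KeyError(
                f"campaign {self.id!r} has no profile ({analyte}, {fraction})"
            ) from None

    @property
    def max_depth(self) -> float:
        return max(p.zmax for p in self.profiles.values())


def _zone_bounds(zone) -> tuple[float, float]:
    """Accept a Zone-like object (``.top``/``.bottom``) or a 2-tuple."""
    if hasattr(zone, "top") and hasattr(zone, "bottom"):
        return float(zone.top), float(zone.bottom)
    top, bottom = zone
    return float(top), float(bottom)


def integrate_zone(profile: DepthProfile, zone) -> IntegralResult:
    """Areal pool of *profile* over a depth interval (trapezoidal rule).

    Censored points (any flag other than ``ok``) contribute zero to the
    integral and are counted in the result's ``n_censored``; boundary values
    are linearly interpolated on that zero-filled series. Zone bounds must
    lie inside the measured grid — no extrapolation.

    Returns
    -------
    IntegralResult
        With ``unit`` e.g. ``nmol m-2`` for an nM profile, ``cells m-2`` for
        cells L^-1 (see :mod:`cumob.units`).
    """
    top, bottom = _zone_bounds(zone)
    if bottom < top:
        raise ValidationError(f"zone top {top} m below bottom {bottom} m")
    out_unit, factor = _units.areal_unit(profile.unit)
    if top < profile.zmin or bottom > profile.zmax:
        raise ExtrapolationError(
            f"zone [{top}, {bottom}] m extends beyond the measured grid "
            f"[{profile.zmin}, {profile.zmax}] m"
        )
    censored = profile.flags != "ok"
    if np.all(censored):
        raise CensoringError(
            f"{profile.analyte}/{profile.fraction}: all points censored"
        )
    if top == bottom:
        return IntegralResult(0.0, out_unit, 0)
    vals = np.where(censored, 0.0, profile.values)
    inside = (profile.depths > top) & (profile.depths < bottom)
    z = np.concatenate(([top], profile.depths[inside], [bottom]))
    v = np.concatenate(
        (
            [np.interp(top, profile.depths, vals)],
            vals[inside],
            [np.interp(bottom, profile.depths, vals)],
        )
    )
    raw = float(np.trapezoid(v, z))
    n_cens = int(np.count_nonzero(censored & inside))
    if n_cens:
        logger.warning(
            "%s/%s: %d censored point(s) inside [%g, %g] m contributed 0",
            profile.analyte, profile.fraction, n_cens, top, bottom,
        )
    return IntegralResult(raw * factor, out_unit, n_cens)


# -- I/O ---------------------------------------------------------------------

def read_profile_table(
    path,
    dialect: Mapping[str, str] | None = None,
    campaign: str | None = None,
    stratification_days: Mapping[str, float] | None = None,
) -> Campaign:
    """Read a long-format profile TSV/CSV into a :class:`Campaign`.

    Parameters
    ----------
    path
        File with header columns ``campaign, depth_m, analyte, fraction,
        value, unit`` and optional ``sd, n, flag``; tab- or comma-separated.
    dialect
        Optional mapping of canonical column name -> foreign header name.
    campaign
        Select one campaign label when the file holds several; required in
        that case.
    stratification_days
        Optional map campaign id -> days since onset of stratification.
    """
    campaigns = read_profile_tables(path, dialect, stratification_days)
    if campaign is not None:
        try:
            return campaigns[campaign]
        except KeyError:
            raise ValidationError(
                f"campaign {campaign!r} not in file (found {sorted(campaigns)})"
            ) from None
    if len(campaigns) != 1:
        raise ValidationError(
            f"file holds {len(campaigns)} campaigns {sorted(campaigns)}; "
            "pass campaign= to select one"
        )
    return next(iter(campaigns.values()))


def read_profile_tables(
    path,
    dialect: Mapping[str, str] | None = None,
    stratification_days: Mapping[str, float] | None = None,
) -> dict[str, Campaign]:
    """Read a long-format profile table holding one or more campaigns."""
    import csv as _csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, _csv.Error):
        raise SchemaError(f"{path}: empty or undelimited file") from None
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    for unit in df["unit"].unique():
        _units.canonical(str(unit))  # raises UnitError on unknown strings

    dup = df.duplicated(subset=["campaign", "analyte", "fraction", "depth_m"])
    if dup.any():
        rows = df.loc[dup, ["campaign", "analyte", "fraction", "depth_m"]]
        raise ValidationError(
            "duplicate (campaign, analyte, fraction, depth) rows:\n"
            + rows.to_string(index=False)
        )

    out: dict[str, Campaign] = {}
    for cid, cdf in df.groupby("campaign", sort=False):
        camp = Campaign(id=str(cid))
        if stratification_days and str(cid) in stratification_days:
            camp.stratification_days = float(stratification_days[str(cid)])
        for (analyte, fraction), g in cdf.groupby(["analyte", "fraction"], sort=False):
            g = g.sort_values("depth_m")
            unit_set = set(g["unit"].astype(str))
            if len(unit_set) > 1:
                raise UnitError(
                    f"{analyte}/{fraction}: mixed units {sorted(unit_set)}"
                )
            sds = g["sd"].to_numpy(float) if "sd" in g else None
            ns = g["n"].to_numpy() if "n" in g else None
            flags = (
                g["flag"].fillna("ok").replace("", "ok").to_numpy(object)
                if "flag" in g
                else None
            )
            camp.add(
                DepthProfile(
                    analyte=str(analyte),
                    fraction=str(fraction),
                    depths=g["depth_m"].to_numpy(float),
                    values=g["value"].to_numpy(float),
                    unit=unit_set.pop(),
                    sds=sds,
                    n_replicates=ns,
                    flags=flags,
                )
            )
        out[str(cid)] = camp
    return out


def write_profile_table(campaigns: Sequence[Campaign] | Campaign, path) -> None:
    """Write one or more campaigns back to the long-format TSV."""
    if isinstance(campaigns, Campaign):
        campaigns = [campaigns]
    frames = []
    for camp in campaigns:
        for prof in camp.profiles.values():
            f = prof.to_frame()
            f.insert(0, "campaign", camp.id)
            frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
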