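"""Water-column zonation: oxycline, methane-oxidation zone, three-zone split.

The methane-oxidation zone (MOZ) is the depth interval where methane is
available above its epilimnetic background and an oxidant source (dissolved
oxygen or light driving oxygenic photosynthesis) is still present: its top is
where CH4 first begins to accumulate, its bottom where photosynthetically
active radiation (PAR) falls below the sensor detection limit. The water
column is then partitioned into oxic / methane-oxidation / anoxic zones for
zone-wise statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as c
from .errors import ValidationError, ZonationError
from .profiles import DepthProfile

__all__ = [
    "Zone",
    "epilimnetic_background",
    "detect_moz",
    "detect_oxycline",
    "partition_zones",
]

ZONE_LABELS = ("oxic", "methane_oxidation", "anoxic")


@dataclass
class Zone:
    """Contiguous depth interval with a zonation label.

    ``provenance`` records which rule fixed each boundary (e.g.
    ``ch4_threshold_crossing``, ``par_below_detection``).
    """

    top: float
    bottom: float
    label: str = "methane_oxidation"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in ZONE_LABELS:
            raise ValidationError(f"unknown zone label {self.label!r}")
        if self.top > self.bottom:
            raise ValidationError(
                f"zone top {self.top} m deeper than bottom {self.bottom} m"
            )

    @property
    def thickness(self) -> float:
        return self.bottom - self.top


def epilimnetic_background(
    ch4: DepthProfile,
    epi_max_depth: float,
    k: float = 3.0,
) -> tuple[float, float]:
    """Epilimnetic CH4 background and accumulation threshold.

    Background is the mean of CH4 values shallower than *epi_max_depth*; the
    accumulation threshold is ``max(background + k*sd, 2*background)`` — the
    factor-two floor guards against near-zero replicate scatter.

    Returns ``(background, threshold)`` in the profile's unit.
    """
    sel = (ch4.depths <= epi_max_depth) & (ch4.flags == "ok")
    vals = ch4.values[sel]
    if vals.size < 2:
        raise ZonationError(
            f"need >= 2 epilimnetic CH4 points above {epi_max_depth} m, "
            f"found {vals.size}"
        )
    background = float(vals.mean())
    sd = float(vals.std(ddof=1))
    threshold = max(background + k * sd, 2.0 * background)
    return background, threshold


def _first_upcrossing(depths, values, threshold):
    """Shallowest depth where a linearly interpolated series crosses up
    through *threshold*; None if it never does."""
    above = values >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(depths[0])
    z0, z1 = depths[i - 1], depths[i]
    v0, v1 = values[i - 1], values[i]
    return float(z0 + (threshold - v0) / (v1 - v0) * (z1 - z0))


def detect_moz(
    ch4: DepthProfile,
    par: DepthProfile,
    threshold: float,
    par_dl: float = c.PAR_DETECTION_LIMIT,
) -> Zone:
    """Detect the methane-oxidation zone.

    Top: shallowest linear crossing of CH4 above *threshold*. Bottom: deepest
    depth with PAR >= *par_dl*; the crossing is interpolated in log-PAR space
    (light attenuates exponentially). If PAR is still above the detection
    limit at the deepest measurement the bottom is clamped there and flagged
    ``light-to-bottom``.
    """
    if par_dl <= 0:
        raise ZonationError(f"PAR detection limit must be positive, got {par_dl}")
    ok = ch4.flags == "ok"
    top = _first_upcrossing(ch4.depths[ok], ch4.values[ok], threshold)
    if top is None:
        raise ZonationError(
            f"CH4 never exceeds the accumulation threshold {threshold} "
            f"{ch4.unit}: empty methane-oxidation zone"
        )
    # PAR points flagged below_LOD are by definition below the detection
    # limit: keep them as crossing evidence rather than dropping them.
    flagged = par.flags == "below_LOD"
    usable = (par.flags == "ok") | flagged
    pz = par.depths[usable]
    pv = np.where(
        flagged[usable],
        np.minimum(par.values[usable], par_dl * (1 - 1e-9)),
        par.values[usable],
    )
    pv = np.maximum(pv, 1e-300)  # log-space interpolation needs positivity
    prov = {"top": "ch4_threshold_crossing"}
    below = pv < par_dl
    if not below.any():
        bottom = float(pz[-1])
        prov["bottom"] = "light-to-bottom"
    else:
        i = int(np.argmax(below))
        if i == 0:
            bottom = float(pz[0])
            prov["bottom"] = "par_below_detection_at_top"
        else:
            z0, z1 = pz[i - 1], pz[i]
            v0, v1 = np.log(pv[i - 1]), np.log(pv[i])
            bottom = float(z0 + (np.log(par_dl) - v0) / (v1 - v0) * (z1 - z0))
            prov["bottom"] = "par_below_detection"
    if bottom < top:
        raise ZonationError(
            f"PAR extinguishes at {bottom:.2f} m above the CH4 accumulation "
            f"depth {top:.2f} m: empty methane-oxidation zone"
        )
    return Zone(top=top, bottom=bottom, label="methane_oxidation", provenance=prov)


def detect_oxycline(
    o2: DepthProfile,
    o2_dl: float = c.O2_DETECTION_LIMIT_TRACE_NM,
) -> float | None:
    """Shallowest depth where interpolated O2 drops below *o2_dl*.

    *o2_dl* is given in nM (trace-optode limit 20 nM by default) and is
    converted to the profile's unit. Returns None when the water column is
    oxic throughout (no-oxycline case).
    """
    from . import units as _units

    dl = _units.convert(o2_dl, "nM", o2.unit)
    # below_LOD points are direct evidence of sub-detection oxygen
    flagged = o2.flags == "below_LOD"
    usable = (o2.flags == "ok") | flagged
    z = o2.depths[usable]
    v = np.where(
        flagged[usable],
        np.minimum(o2.values[usable], dl * (1 - 1e-9)),
        o2.values[usable],
    )
    below = v < dl
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0:
        return float(z[0])
    z0, z1 = z[i - 1], z[i]
    v0, v1 = v[i - 1], v[i]
    return float(z0 + (dl - v0) / (v1 - v0) * (z1 - z0))


def partition_zones(
    oxycline: float | None,
    moz: Zone,
    max_depth: float,
) -> list[Zone]:
    """Partition [0, max_depth] into oxic / methane-oxidation / anoxic zones.

    The oxic zone runs from the surface to the MOZ top: a gap between the
    oxycline and the MOZ top is assigned to the oxic zone, and an overlap
    (oxycline deeper than the MOZ top) is resolved in favour of the MOZ.
    """
    if moz.bottom > max_depth:
        raise ValidationError(
            f"MOZ bottom {moz.bottom} m exceeds max depth {max_depth} m"
        )
    top = moz.top
    prov_oxic = {"bottom": "moz_top"}
    if oxycline is not None and oxycline < top:
        prov_oxic["note"] = "gap between oxycline and MOZ top assigned to oxic"
    elif oxycline is not None and oxycline > top:
        prov_oxic["note"] = "oxycline below MOZ top; overlap resolved to MOZ"
    oxic = Zone(0.0, top, "oxic", prov_oxic)
    anoxic = Zone(moz.bottom, max_depth, "anoxic", {"top": "moz_bottom"})
    return [oxic, moz, anoxic]
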