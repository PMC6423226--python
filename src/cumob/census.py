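"""Absolute methanotroph census from 16S amplicon and qPCR data.

Relative MOB abundances from an OTU table are translated into absolute cell
numbers with total bacterial 16S rRNA gene copies as the community-size
proxy, corrected for lineage-specific 16S copy numbers per genome (5.8 for
Gammaproteobacteria, 2.2 for Alphaproteobacteria, 4.2 for other bacteria).
Functional genes (pmoA for the copper-dependent particulate methane
monooxygenase, mmoX for the iron-dependent soluble form) are quantified by
qPCR against plasmid standard curves, with explicit limit-of-detection /
limit-of-quantification censoring in Cp (crossing-point) space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import constants as c
from .errors import (
    CurveError,
    MappingError,
    ParameterError,
    SampleSizeError,
    ValidationError,
)

__all__ = [
    "CopyNumberTable",
    "StandardCurve",
    "QPCRSample",
    "fit_standard_curve",
    "lod_from_blanks",
    "apply_censoring",
    "quantify",
    "copies_per_litre",
    "absolute_group_cells",
    "pmoa_cell_equivalents",
    "pmoa_relative",
    "census_diagnostics",
    "census_from_otu_table",
]


@dataclass
class CopyNumberTable:
    """16S rRNA copies per genome by coarse taxonomic group."""

    copies: dict[str, float] = field(
        default_factory=lambda: dict(c.COPIES_16S_PER_GENOME)
    )

    def __post_init__(self) -> None:
        for group, n in self.copies.items():
            if n <= 0:
                raise ValidationError(f"copy number for {group!r} must be > 0")

    def __getitem__(self, group: str) -> float:
        try:
            return self.copies[group]
        except KeyError:
            raise MappingError(
                f"no 16S copy-number entry for group {group!r}"
            ) from None


@dataclass
class StandardCurve:
    """qPCR calibration: Cp = intercept + slope * log10(copies per reaction).

    ``efficiency`` is E = 10^(-1/slope) (2.0 for perfect doubling);
    ``loq_copies`` is the lowest standard dilution whose quadruplicate Cp SD
    is < 0.5 (None when no dilution qualifies); ``loq_cp`` the Cp at that
    dilution on the fitted curve.
    """

    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    loq_copies: float | None = None
    loq_cp: float | None = None

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise CurveError(f"standard-curve slope must be negative, got {self.slope}")
        if not (1.0 < self.efficiency <= 2.2):
            import warnings

            warnings.warn(
                f"qPCR efficiency {self.efficiency:.3f} outside the sanity band "
                "(1, 2.2]",
                stacklevel=2,
            )


@dataclass
class QPCRSample:
    """One sample x target qPCR measurement (triplicate Cp values)."""

    target: str
    depth: float
    cp_replicates: np.ndarray
    melt_ok: np.ndarray
    status: str = "quantified"
    copies_per_reaction: float | None = None
    copies_per_litre: float | None = None


def fit_standard_curve(
    dilution_copies,
    cp_replicates,
    loq_sd_limit: float = 0.5,
) -> StandardCurve:
    """Fit the calibration curve from a serial dilution of plasmid standards.

    Parameters
    ----------
    dilution_copies
        Copies per reaction of each dilution level (>= 3 levels spanning >= 2
        orders of magnitude).
    cp_replicates
        Sequence of replicate Cp arrays (quadruplicates by design), one per
        dilution level; levels where no replicate amplified may be all-NaN
        and are dropped from the fit.
    """
    copies = np.asarray(dilution_copies, dtype=float)
    reps = [np.asarray(r, dtype=float) for r in cp_replicates]
    if copies.size != len(reps):
        raise ValidationError("one replicate set per dilution level required")
    means = np.array([np.nanmean(r) if np.isfinite(r).any() else np.nan for r in reps])
    usable = np.isfinite(means)
    if usable.sum() < 3:
        raise SampleSizeError("need >= 3 usable dilution levels")
    if np.ptp(np.log10(copies[usable])) < 2:
        raise ValidationError("dilution series must span >= 2 orders of magnitude")
    res = stats.linregress(np.log10(copies[usable]), means[usable])
    if res.slope >= 0:
        raise CurveError(f"non-negative standard-curve slope {res.slope:.3f}")
    efficiency = 10 ** (-1.0 / res.slope)
    # LOQ: lowest (fewest-copy) dilution whose replicate Cp SD < loq_sd_limit
    loq_copies = loq_cp = None
    order = np.argsort(copies)
    for i in order:
        r = reps[i][np.isfinite(reps[i])]
        if r.size >= 2 and r.std(ddof=1) < loq_sd_limit:
            loq_copies = float(copies[i])
            loq_cp = float(res.intercept + res.slope * np.log10(loq_copies))
            break
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=float(efficiency),
        r_squared=float(res.rvalue**2),
        loq_copies=loq_copies,
        loq_cp=loq_cp,
    )


def lod_from_blanks(blank_cps, default: float = 40.0) -> float:
    """Limit of detection: the highest (earliest-amplifying) crossing point
    observed in PCR or extraction blanks; *default* when no blank amplified.

    In Cp space "highest crossing point" means the smallest Cp value — any
    sample amplifying at or later than the worst blank is indistinguishable
    from contamination.
    """
    b = np.asarray(blank_cps, dtype=float)
    b = b[np.isfinite(b)]
    if b.size == 0:
        return default
    return float(b.min())


def apply_censoring(
    sample: QPCRSample,
    curve: StandardCurve,
    lod_cp: float,
    rep_spread_limit: float = 0.5,
    allow_extrapolation_below_loq: bool = True,
) -> str:
    """Assign the censoring status of a qPCR sample and store it.

    Rules, applied in order:

    * a replicate is *not detected* if its Cp >= *lod_cp* or its melt curve
      is not clean;
    * all replicates not detected -> ``not_detected``;
    * >= 2 of 3 replicates not detected -> ``not_quantifiable``;
    * detected replicates spreading more than *rep_spread_limit* cycles ->
      ``not_quantifiable``;
    * mean Cp beyond the LOQ Cp -> ``estimated_below_LOQ`` when standard-curve
      extrapolation is allowed, else ``not_quantifiable``;
    * otherwise ``quantified``.
    """
    cps = np.asarray(sample.cp_replicates, dtype=float)
    melt = np.asarray(sample.melt_ok, dtype=bool)
    if cps.size == 0:
        raise ValidationError("sample has no replicates")
    detected = np.isfinite(cps) & (cps < lod_cp) & melt
    n_nd = int((~detected).sum())
    if detected.sum() == 0:
        sample.status = "not_detected"
        return sample.status
    if cps.size >= 3 and n_nd >= 2:
        sample.status = "not_quantifiable"
        return sample.status
    det = cps[detected]
    if det.max() - det.min() > rep_spread_limit:
        sample.status = "not_quantifiable"
        return sample.status
    mean_cp = float(det.mean())
    beyond_loq = curve.loq_cp is not None and mean_cp > curve.loq_cp
    if curve.loq_cp is None:
        # no dilution satisfied the LOQ rule: best case is an estimate
        sample.status = "estimated_below_LOQ"
    elif beyond_loq:
        sample.status = (
            "estimated_below_LOQ" if allow_extrapolation_below_loq
            else "not_quantifiable"
        )
    else:
        sample.status = "quantified"
    return sample.status


def quantify(cp_mean: float, curve: StandardCurve) -> float:
    """Copies per reaction from a mean Cp: ``10^((Cp - intercept)/slope)``."""
    return float(10 ** ((cp_mean - curve.intercept) / curve.slope))


def copies_per_litre(
    copies_per_reaction: float,
    template_volume_per_reaction: float,
    extract_volume: float,
    filtered_volume_l: float,
) -> float:
    """Scale reaction copies to copies per litre of lake water.

    ``copies * (extract_volume / template_volume) / filtered_volume``; the
    two extract volumes must share a unit, the filtered volume is in litres.
    """
    if template_volume_per_reaction <= 0 or extract_volume <= 0 or filtered_volume_l <= 0:
        raise ParameterError("all volumes must be positive")
    return (
        copies_per_reaction
        * (extract_volume / template_volume_per_reaction)
        / filtered_volume_l
    )


def absolute_group_cells(
    read_fraction_by_group: dict[str, float],
    total_16s_copies_per_litre: float,
    copy_table: CopyNumberTable | None = None,
) -> dict[str, float]:
    """Cells per litre per taxonomic group from 16S read fractions.

    ``cells_g = fraction_g * total_copies / copies_per_genome_g``. The
    returned dict carries one entry per input group plus ``_total`` (summed
    bacterial cells over all groups).
    """
    copy_table = copy_table or CopyNumberTable()
    if total_16s_copies_per_litre < 0:
        raise ValidationError("total 16S copies must be >= 0")
    fr = read_fraction_by_group
    s = sum(fr.values())
    if any(f < 0 or f > 1 for f in fr.values()) or s > 1 + 1e-9:
        raise ValidationError(f"read fractions must lie in [0,1] and sum <= 1 (sum={s})")
    cells = {
        g: f * total_16s_copies_per_litre / copy_table[g] for g, f in fr.items()
    }
    cells["_total"] = sum(cells.values())
    return cells


def pmoa_cell_equivalents(
    pmoa_copies_per_litre: float,
    copies_per_cell: float = c.PMOA_COPIES_PER_CELL,
) -> float:
    """MOB cell equivalents from pmoA copies (2 pmoA copies per cell)."""
    if pmoa_copies_per_litre < 0:
        raise ValidationError("copies must be >= 0")
    return pmoa_copies_per_litre / copies_per_cell


def pmoa_relative(
    pmoa_copies_per_litre: float,
    total_16s_copies_per_litre: float,
    copy_table: CopyNumberTable | None = None,
    copies_per_cell: float = c.PMOA_COPIES_PER_CELL,
    community_avg_group: str = "other",
) -> float:
    """Fraction of bacterial cells carrying pmoA (or mmoX with 1 copy/cell).

    Total cells are approximated as total 16S copies divided by the
    community-average copy number (the "other bacteria" value by default).
    Returns NaN (flagged) when the 16S total is zero.
    """
    copy_table = copy_table or CopyNumberTable()
    if total_16s_copies_per_litre == 0:
        return float("nan")
    total_cells = total_16s_copies_per_litre / copy_table[community_avg_group]
    return (pmoa_copies_per_litre / copies_per_cell) / total_cells


def census_diagnostics(
    mob_cells: np.ndarray,
    pmoa_cells: np.ndarray,
    pmoa_rel: np.ndarray | None = None,
    mmox_rel: np.ndarray | None = None,
) -> dict:
    """Cross-method agreement diagnostics on depth-matched census profiles.

    Returns the squared Pearson correlation between 16S-derived MOB cells
    and pmoA cell equivalents (NaN pairs dropped; None when a series is
    constant), the mean 16S/pmoA abundance ratio (both in cell space and raw
    copy space differ only by the copies-per-cell constant), and, when
    relative-abundance series are given, the mean pmoA/mmoX ratio over
    depths where both are quantified.
    """
    x = np.asarray(mob_cells, dtype=float)
    y = np.asarray(pmoa_cells, dtype=float)
    m = np.isfinite(x) & np.isfinite(y)
    if m.sum() < 3:
        raise SampleSizeError("need >= 3 matched depths")
    x, y = x[m], y[m]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r2 = None
    else:
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = x / y
    ratios = ratios[np.isfinite(ratios)]
    out = {
        "r_squared": r2,
        "mean_16s_to_pmoa_cell_ratio": float(ratios.mean()) if ratios.size else None,
    }
    if pmoa_rel is not None and mmox_rel is not None:
        pr = np.asarray(pmoa_rel, dtype=float)
        mr = np.asarray(mmox_rel, dtype=float)
        mm = np.isfinite(pr) & np.isfinite(mr) & (mr > 0)
        out["mean_pmoa_to_mmox_ratio"] = (
            float((pr[mm] / mr[mm]).mean()) if mm.any() else None
        )
    return out


# -- OTU-table level ---------------------------------------------------------

def census_from_otu_table(
    otu: pd.DataFrame,
    total_16s_by_depth: dict[float, float],
    copy_table: CopyNumberTable | None = None,
    exclude_groups: tuple[str, ...] = ("verrucomicrobia_excluded",),
) -> pd.DataFrame:
    """Absolute group cell profiles from an OTU count table.

    *otu* has columns ``otu_id, taxonomy, group`` and one count column per
    depth (header = depth in metres as text). Verrucomicrobial OTUs are
    excluded before computing read fractions (exclusion flag group). Returns
    a tidy frame with columns ``depth_m, group, cells_per_l, read_fraction``
    plus a ``total`` group row per depth.
    """
    copy_table = copy_table or CopyNumberTable()
    meta_cols = {"otu_id", "taxonomy", "group"}
    depth_cols = [col for col in otu.columns if col not in meta_cols]
    keep = ~otu["group"].isin(exclude_groups)
    records = []
    for col in depth_cols:
        depth = float(col)
        counts = otu.loc[keep].groupby("group")[col].sum()
        total_reads = counts.sum()
        if total_reads == 0:
            continue
        fractions = {g: counts_g / total_reads for g, counts_g in counts.items()}
        total_copies = total_16s_by_depth[depth]
        cells = absolute_group_cells(fractions, total_copies, copy_table)
        for g, f in fractions.items():
            records.append(
                {
                    "depth_m": depth,
                    "group": g,
                    "read_fraction": float(f),
                    "cells_per_l": cells[g],
                }
            )
        records.append(
            {
                "depth_m": depth,
                "group": "total",
                "read_fraction": 1.0,
                "cells_per_l": cells["_total"],
            }
        )
    return pd.DataFrame.from_records(records)


def process_qpcr_plate(
    plate: pd.DataFrame,
    template_volume_per_reaction: float = 2.0,
    extract_volume: float = 100.0,
    filtered_volume_l: float = 1.0,
) -> dict[str, pd.DataFrame]:
    """Reduce a qPCR plate table to per-target censored copy profiles.

    *plate* columns: ``target, campaign, depth_m, replicate, cp, melt_ok,
    is_blank, is_standard, standard_copies``. Standards (quadruplicates over
    the dilution series) give the curve and LOQ; blanks give the LOD;
    samples (triplicates) are censored and quantified. Returns one tidy
    frame per target with columns ``depth_m, status, copies_per_reaction,
    copies_per_l, mean_cp``.
    """
    out: dict[str, pd.DataFrame] = {}
    for target, tdf in plate.groupby("target", sort=False):
        std = tdf[tdf["is_standard"].astype(bool)]
        levels = sorted(std["standard_copies"].dropna().unique())
        curve = fit_standard_curve(
            levels,
            [std.loc[std["standard_copies"] == lv, "cp"].to_numpy() for lv in levels],
        )
        lod = lod_from_blanks(tdf.loc[tdf["is_blank"].astype(bool), "cp"].to_numpy())
        rows = []
        samp = tdf[~tdf["is_blank"].astype(bool) & ~tdf["is_standard"].astype(bool)]
        for depth, g in samp.groupby("depth_m", sort=True):
            s = QPCRSample(
                target=str(target),
                depth=float(depth),
                cp_replicates=g["cp"].to_numpy(float),
                melt_ok=g["melt_ok"].to_numpy(bool),
            )
            status = apply_censoring(s, curve, lod)
            copies = cpl = np.nan
            if status in ("quantified", "estimated_below_LOQ"):
                cps = s.cp_replicates
                det = np.isfinite(cps) & (cps < lod) & s.melt_ok
                copies = quantify(float(cps[det].mean()), curve)
                cpl = copies_per_litre(
                    copies, template_volume_per_reaction, extract_volume,
                    filtered_volume_l,
                )
            rows.append(
                {
                    "depth_m": float(depth),
                    "status": status,
                    "copies_per_reaction": copies,
                    "copies_per_l": cpl,
                    "mean_cp": (
                        float(np.nanmean(s.cp_replicates))
                        if np.isfinite(s.cp_replicates).any()
                        else np.nan
                    ),
                }
            )
        frame = pd.DataFrame(rows)
        frame.attrs["curve"] = curve
        frame.attrs["lod_cp"] = lod
        out[str(target)] = frame
    return out
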