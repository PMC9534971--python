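"""Region-coupled quantification of coculture well mosaics.

Implements the per-region statistics read out from a segmented well:
area coverage per zone and region class, SMC proliferation percentage per
region (DAPI / ERG1 / Ki-67 logic), the island-normalized cell-tracker
intensity that reports SMC multilayering, radial intensity profiles with
fibronectin-to-SMC ratio, and one-way ANOVA + Tukey HSD group comparisons.

Conventions shared by all statistics:

* nuclei are assigned to a zone and region class by their centroid pixel;
* channel background is the median over outside-well pixels;
* ratio statistics are computed on background-subtracted raw intensities
  and are therefore invariant to a global multiplicative gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps
from skimage.feature import peak_local_max

from .geometry import WellGeometry, ZONE_CENTER, ZONE_PERIPHERY, ZONES
from .regions import CLASS_NAMES, ISLAND, OUTSIDE, RegionLabelMap, class_fractions

CLASSES = ("island", "network", "gap")


class QuantError(ValueError):
    pass


def _labels_of(labelmap) -> np.ndarray:
    return labelmap.labels if isinstance(labelmap, RegionLabelMap) else np.asarray(labelmap)


def estimate_background(channel: np.ndarray, geom: WellGeometry) -> float:
    """Per-channel background: median over outside-well pixels."""
    outside = geom.zone_map(channel.shape) == 0
    if not outside.any():
        return 0.0
    return float(np.median(np.asarray(channel, dtype=float)[outside]))


# ----------------------------------------------------------------------
# coverage
# ----------------------------------------------------------------------


def coverage_fractions(
    labelmap: RegionLabelMap | np.ndarray,
    geom: WellGeometry,
    n_sector_rois: int | None = None,
) -> dict:
    """Area fraction of each region class per zone, plus total EC coverage.

    ``fraction = class pixels / zone pixels``; the three class fractions
    sum to 1 per zone (partition).  Total EC coverage is island + network.
    With ``n_sector_rois`` the same fractions are also reported for equal
    annular-sector ROIs within each zone, exposing the local variance of
    coverage.

    Returns a dict with a tidy per-(zone, class) ``table`` (DataFrame),
    ``total_ec`` per zone and for the whole well, and optionally ``rois``.
    """
    labels = _labels_of(labelmap)
    zone = geom.zone_map(labels.shape)
    rows = []
    total_ec: dict[str, float] = {}
    for zcode, zname in ((ZONE_CENTER, "center"), (ZONE_PERIPHERY, "periphery")):
        zmask = zone == zcode
        if not zmask.any():
            raise QuantError(f"zone {zname!r} contains no pixels")
        fr = class_fractions(labels, zmask)
        for cname in CLASSES:
            rows.append({"zone": zname, "region_class": cname, "area_fraction": fr[cname]})
        total_ec[zname] = fr["island"] + fr["network"]
    whole = class_fractions(labels, zone > 0)
    total_ec["well"] = whole["island"] + whole["network"]

    out = {"table": pd.DataFrame(rows), "total_ec": total_ec}
    if n_sector_rois:
        out["rois"] = _sector_roi_fractions(labels, zone, geom, n_sector_rois)
    return out


def _sector_roi_fractions(labels, zone, geom: WellGeometry, n_sectors: int) -> pd.DataFrame:
    cx, cy = geom.center_xy
    yy, xx = np.indices(labels.shape)
    theta = np.mod(np.arctan2(yy - cy, xx - cx), 2 * np.pi)
    sector = np.minimum((theta / (2 * np.pi) * n_sectors).astype(int), n_sectors - 1)
    rows = []
    for zcode, zname in ((ZONE_CENTER, "center"), (ZONE_PERIPHERY, "periphery")):
        for s in range(n_sectors):
            sel = (zone == zcode) & (sector == s)
            if not sel.any():
                continue
            fr = class_fractions(labels, sel)
            for cname in CLASSES:
                rows.append(
                    {
                        "zone": zname,
                        "roi": s,
                        "region_class": cname,
                        "area_fraction": fr[cname],
                    }
                )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# nuclei
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class NucleusDetectionParams:
    smooth_sigma_px: float = 1.2
    min_separation_px: int = 3
    threshold_nmads: float = 6.0  # peak threshold above background, in MADs
    marker_disk_px: int = 0  # radius for per-nucleus marker readout
    marker_threshold_nmads: float = 10.0


def _robust_threshold(channel, geom, nmads) -> float:
    outside = geom.zone_map(channel.shape) == 0
    ref = np.asarray(channel, dtype=float)[outside if outside.any() else slice(None)]
    med = float(np.median(ref))
    mad = float(np.median(np.abs(ref - med))) * 1.4826
    return med + nmads * max(mad, 1e-6)


def detect_nuclei(
    dapi: np.ndarray,
    erg1: np.ndarray | None = None,
    ki67: np.ndarray | None = None,
    geom: WellGeometry | None = None,
    params: NucleusDetectionParams = NucleusDetectionParams(),
) -> pd.DataFrame:
    """Detect nuclei on the DAPI channel and read identity/proliferation flags.

    Nuclei are local maxima of the smoothed DAPI signal above a robust
    background threshold with a minimum separation.  ``is_EC`` is set when
    the mean ERG1 signal in a small disk around the centroid exceeds its
    robust threshold; ``is_proliferative`` likewise from Ki-67.  Missing
    marker channels yield all-False flags (and are reported by the
    pipeline as missing).  Returns a DataFrame with columns
    ``x_px, y_px, is_EC, is_proliferative``; zero nuclei is a valid result.
    """
    dapi = np.asarray(dapi, dtype=float)
    if geom is None:
        # fall back to a whole-frame geometry for thresholding purposes
        h, w = dapi.shape
        geom = WellGeometry((w / 2, h / 2), min(h, w) / 2 - 1)
    smoothed = ndi.gaussian_filter(dapi, params.smooth_sigma_px)
    thr = _robust_threshold(dapi, geom, params.threshold_nmads)
    peaks = peak_local_max(
        smoothed,
        min_distance=params.min_separation_px,
        threshold_abs=thr,
        exclude_border=False,
    )
    if peaks.size == 0:
        return pd.DataFrame(columns=["x_px", "y_px", "is_EC", "is_proliferative"])
    inwell = geom.zone_map(dapi.shape) > 0
    keep = inwell[peaks[:, 0], peaks[:, 1]]
    peaks = peaks[keep]

    xs = peaks[:, 1].astype(float)
    ys = peaks[:, 0].astype(float)

    def flag(channel) -> np.ndarray:
        if channel is None:
            return np.zeros(len(peaks), dtype=bool)
        ch = ndi.gaussian_filter(np.asarray(channel, dtype=float), 1.0)
        thr_m = _robust_threshold(channel, geom, params.marker_threshold_nmads)
        r = params.marker_disk_px
        vals = np.empty(len(peaks))
        for i, (y, x) in enumerate(peaks):
            y0, y1 = max(y - r, 0), min(y + r + 1, ch.shape[0])
            x0, x1 = max(x - r, 0), min(x + r + 1, ch.shape[1])
            vals[i] = ch[y0:y1, x0:x1].max()
        return vals >= thr_m

    return pd.DataFrame(
        {
            "x_px": xs,
            "y_px": ys,
            "is_EC": flag(erg1),
            "is_proliferative": flag(ki67),
        }
    )


def assign_nuclei(
    nuclei: pd.DataFrame, labelmap: RegionLabelMap | np.ndarray, geom: WellGeometry
) -> pd.DataFrame:
    """Attach ``zone`` and ``region_class`` columns from the centroid pixel."""
    labels = _labels_of(labelmap)
    zone = geom.zone_map(labels.shape)
    out = nuclei.copy()
    if len(out) == 0:
        out["zone"] = pd.Series(dtype=object)
        out["region_class"] = pd.Series(dtype=object)
        return out
    xi = np.clip(np.rint(out["x_px"].to_numpy()).astype(int), 0, labels.shape[1] - 1)
    yi = np.clip(np.rint(out["y_px"].to_numpy()).astype(int), 0, labels.shape[0] - 1)
    out["zone"] = np.array(["outside", "center", "periphery"])[zone[yi, xi]]
    out["region_class"] = [CLASS_NAMES.get(int(c), "outside") for c in labels[yi, xi]]
    return out


def proliferation_by_region(
    nuclei: pd.DataFrame,
    labelmap: RegionLabelMap | np.ndarray | None = None,
    geom: WellGeometry | None = None,
    n_min: int = 20,
) -> pd.DataFrame:
    """Percentage of proliferative (Ki-67+) SMC nuclei per (zone, class).

    SMC nuclei are the ERG1-negative (``is_EC == False``) nuclei.  Classes
    with fewer than ``n_min`` SMC nuclei are reported with ``NaN`` (missing,
    not zero).  If ``labelmap``/``geom`` are given and the table lacks
    zone/region columns, nuclei are assigned first.
    """
    if "zone" not in nuclei.columns or "region_class" not in nuclei.columns:
        if labelmap is None or geom is None:
            raise QuantError("nuclei lack zone/region columns; pass labelmap and geom")
        nuclei = assign_nuclei(nuclei, labelmap, geom)
    smc = nuclei[(~nuclei["is_EC"].astype(bool)) & (nuclei["zone"] != "outside")]
    rows = []
    for zname in ZONES:
        for cname in CLASSES:
            sel = smc[(smc["zone"] == zname) & (smc["region_class"] == cname)]
            n = len(sel)
            pct = (
                100.0 * float(sel["is_proliferative"].astype(bool).sum()) / n
                if n >= n_min
                else float("nan")
            )
            rows.append(
                {"zone": zname, "region_class": cname, "smc_prolif_pct": pct, "n_smc": n}
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# SMC layering
# ----------------------------------------------------------------------


def smc_layering_index(
    cell_tracker: np.ndarray,
    labelmap: RegionLabelMap | np.ndarray,
    geom: WellGeometry,
) -> pd.DataFrame:
    """Island-normalized cell-tracker intensity per (zone, class).

    The cytoplasmic cell-tracker intensity is approximately constant per
    cell, so the mean background-subtracted intensity over a region scales
    with the local number of stacked cells.  Normalizing by the mean over
    island pixels of the same zone sets the single-layer reference to 1;
    corrugated (multilayered) regions report values near the layer count.
    Zones without island pixels fall back to the whole-well mean with
    ``normalized_by = "well"``.
    """
    img = np.asarray(cell_tracker, dtype=float)
    labels = _labels_of(labelmap)
    zone = geom.zone_map(img.shape)
    bg = estimate_background(img, geom)
    sub = img - bg

    rows = []
    inwell = zone > 0
    well_mean = float(sub[inwell].mean()) if inwell.any() else float("nan")
    for zcode, zname in ((ZONE_CENTER, "center"), (ZONE_PERIPHERY, "periphery")):
        zmask = zone == zcode
        island_sel = zmask & (labels == ISLAND)
        if island_sel.any():
            denom = float(sub[island_sel].mean())
            norm_by = "island"
        else:
            denom = well_mean
            norm_by = "well"
        for cname in CLASSES:
            sel = zmask & (labels == (
                {"island": 1, "network": 2, "gap": 0}[cname]
            ))
            val = float(sub[sel].mean()) / denom if sel.any() and denom else float("nan")
            rows.append(
                {
                    "zone": zname,
                    "region_class": cname,
                    "smc_intensity_norm": val,
                    "normalized_by": norm_by,
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# radial profiles
# ----------------------------------------------------------------------


def radial_profiles(
    smc: np.ndarray | None,
    fn: np.ndarray | None,
    labelmap: RegionLabelMap | np.ndarray,
    geom: WellGeometry,
    n_bins: int = 30,
    smc_floor: float = 1.0,
) -> pd.DataFrame:
    """Radial intensity and occupancy profiles from rim to center.

    The well is divided into ``n_bins`` annular bins, bin 0 at the rim
    (periphery) and the last bin at the center.  Per bin: mean SMC and Fn
    intensities (background-subtracted), the same min-max rescaled to a
    0–255 scale across the profile, class occupancy fractions from the
    region labels, and ``fn_over_smc`` computed on the raw
    background-subtracted values (``NaN`` where SMC falls below
    ``smc_floor``, and for constant profiles the rescaled value is 0).
    Empty bins are omitted.
    """
    if n_bins < 10:
        raise QuantError("n_bins must be >= 10")
    labels = _labels_of(labelmap)
    rmap = geom.radius_map(labels.shape)
    inwell = labels != OUTSIDE
    # bin 0 = rim: invert the normalized radius
    frac = 1.0 - np.clip(rmap / geom.radius_px, 0.0, 1.0)
    bins = np.minimum((frac * n_bins).astype(int), n_bins - 1)

    rows = []
    for b in range(n_bins):
        sel = inwell & (bins == b)
        n = int(sel.sum())
        if n == 0:
            continue
        row = {
            "bin_index": b,
            "r_mid_px": float(geom.radius_px * (1.0 - (b + 0.5) / n_bins)),
            "n_px": n,
        }
        for cname, code in (("island", 1), ("network", 2), ("gap", 0)):
            row[f"frac_{cname}"] = float((labels[sel] == code).sum()) / n
        rows.append((sel, row))

    df = pd.DataFrame([r for _, r in rows])

    for name, channel in (("smc", smc), ("fn", fn)):
        if channel is None:
            df[f"{name}_raw"] = np.nan
            df[f"{name}_0_255"] = np.nan
            continue
        img = np.asarray(channel, dtype=float) - estimate_background(channel, geom)
        vals = np.array([float(img[sel].mean()) for sel, _ in rows])
        df[f"{name}_raw"] = vals
        span = vals.max() - vals.min()
        df[f"{name}_0_255"] = (
            255.0 * (vals - vals.min()) / span if span > 0 else np.zeros_like(vals)
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = df["fn_raw"] / df["smc_raw"]
    ratio[df["smc_raw"] < smc_floor] = np.nan
    df["fn_over_smc"] = ratio
    return df


# ----------------------------------------------------------------------
# group statistics
# ----------------------------------------------------------------------

#: significance-star thresholds (upper p bound -> stars), as printed in the
#: source figure captions.
STAR_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (0.001, "****"),
    (0.01, "***"),
    (0.1, "**"),
    (0.5, "*"),
)


def p_to_stars(p: float, thresholds=STAR_THRESHOLDS) -> str:
    if not np.isfinite(p):
        return "na"
    for bound, stars in thresholds:
        if p < bound:
            return stars
    return "ns"


@dataclass
class GroupComparison:
    f_statistic: float
    p_value: float
    table: pd.DataFrame  # pairwise Tukey HSD contrasts
    degenerate: bool = False


def compare_groups(samples: dict[str, np.ndarray]) -> GroupComparison:
    """One-way ANOVA followed by Tukey's HSD across named groups.

    ``samples`` maps group name to a 1-D array of observations (>= 2 groups
    with >= 2 observations each).  The Tukey table reports the family-wise
    adjusted p-value and significance stars for every pairwise contrast.
    When every group has zero variance and identical means the comparison
    is degenerate and reported as such.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    names = list(samples)
    if len(names) < 2:
        raise QuantError("compare_groups requires at least two groups")
    arrays = [np.asarray(samples[k], dtype=float).ravel() for k in names]
    if any(a.size < 2 for a in arrays):
        raise QuantError("every group needs at least two observations")

    pooled = np.concatenate(arrays)
    degenerate = bool(np.ptp(pooled) == 0)
    if degenerate:
        empty = pd.DataFrame(
            columns=["group1", "group2", "meandiff", "p_adj", "stars", "reject"]
        )
        return GroupComparison(float("nan"), float("nan"), empty, degenerate=True)

    with np.errstate(divide="ignore", invalid="ignore"):
        f, p = sps.f_oneway(*arrays)

    values = pooled
    groups = np.concatenate([[k] * a.size for k, a in zip(names, arrays)])
    res = pairwise_tukeyhsd(values, groups)
    tbl = pd.DataFrame(
        res.summary().data[1:], columns=[c.lower() for c in res.summary().data[0]]
    )
    tbl = tbl.rename(columns={"p-adj": "p_adj"})
    tbl["p_adj"] = res.pvalues  # full precision (summary rounds)
    tbl["stars"] = [p_to_stars(v) for v in res.pvalues]
    return GroupComparison(float(f), float(p), tbl, degenerate=False)
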