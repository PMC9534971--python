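"""Texture classification of the EC channel into island / network / gap.

The endothelial layer of a coculture mosaic presents two EC-positive
textures: confluent cobblestone *islands* (dense, compact coverage) and
cord-like *networks* of elongated cells (thin, filamentous coverage);
EC-negative in-well area is *gap*.  The classifier here is a transparent
stand-in for proprietary texture analysis, built on two auditable
features:

* an *EC-thickness* feature — the distance transform of the binarized EC
  mask.  Network cords are at most 1-2 cell diameters wide, so no cord
  pixel lies deeper than ``cord_halfwidth_px`` inside the EC foreground,
  whereas island bodies reach depths of ``island_min_halfwidth_px`` and
  beyond.  Island area is recovered by hysteresis: connected components of
  ``depth >= cord_halfwidth_px`` that contain an island-deep seed, dilated
  back by the same radius to restore the eroded rim;
* a *cord-elongation* feature (skeleton length / mean width) that demotes
  island candidates whose shape is filamentous.

A local-coverage density feature settles the degenerate case where no
confident island seed exists (e.g. a fully confluent or fully cord-like
well).  All parameters are exposed in :class:`SegmentationParams` and can
be calibrated against generator ground truth with :func:`calibrate_params`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from itertools import product

import numpy as np
import yaml
from scipy import ndimage as ndi
from skimage.filters import threshold_local, threshold_otsu
from skimage.morphology import disk, skeletonize

from .geometry import WellGeometry, ZONE_CENTER, ZONE_PERIPHERY
from .regions import GAP, ISLAND, NETWORK, OUTSIDE, RegionLabelMap


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of EC binarization and region classification.

    ``cord_halfwidth_px`` is the maximum half-width of a network cord (in
    pixels); EC pixels deeper than this form island bodies, and bodies
    containing pixels deeper than ``island_min_halfwidth_px`` are accepted
    as islands.  ``density_window_px`` / ``island_density_min`` drive the
    local-coverage fallback for wells without any island-deep seed.
    Defaults were calibrated against the synthetic generator's default
    textures (4 um/px; EC cells ~30 um).
    """

    ec_threshold_method: str = "otsu"  # {otsu, adaptive, fixed}
    fixed_threshold: float = 50.0
    smooth_sigma_px: float = 0.5
    cord_halfwidth_px: int = 12
    island_min_halfwidth_px: int = 18
    density_window_px: int = 31
    island_density_min: float = 0.5
    cord_elongation_min: float = 15.0
    min_object_px: int = 400
    closing_radius_px: int = 1
    hole_area_px: int = 64

    def __post_init__(self) -> None:
        if self.ec_threshold_method not in ("otsu", "adaptive", "fixed"):
            raise ValueError("ec_threshold_method must be otsu, adaptive or fixed")
        if self.density_window_px < 3:
            raise ValueError("density_window_px must be >= 3")
        if not (0.0 <= self.island_density_min <= 1.0):
            raise ValueError("island_density_min must lie in [0, 1]")
        if not (0 < self.cord_halfwidth_px <= self.island_min_halfwidth_px):
            raise ValueError("need 0 < cord_halfwidth_px <= island_min_halfwidth_px")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SegmentationParams":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def binarize_ec(
    ec_channel: np.ndarray,
    geom: WellGeometry | None = None,
    params: SegmentationParams = SegmentationParams(),
) -> np.ndarray:
    """Binarize the EC channel into an EC-positive foreground mask.

    Gaussian smoothing, a global (Otsu), local-adaptive, or fixed
    threshold, morphological closing and small-hole filling.  A constant
    image yields an empty mask.  With ``method="otsu"`` the result is
    invariant to adding a constant offset to the input.
    """
    img = ndi.gaussian_filter(np.asarray(ec_channel, dtype=float), params.smooth_sigma_px)
    inwell = None
    if geom is not None:
        inwell = geom.zone_map(img.shape) > 0
    vals = img[inwell] if inwell is not None else img.ravel()

    if params.ec_threshold_method == "fixed":
        mask = img > params.fixed_threshold
    elif params.ec_threshold_method == "adaptive":
        block = params.density_window_px * 4 + 1
        mask = img > threshold_local(img, block_size=block, method="gaussian")
    else:
        if np.ptp(vals) == 0:
            return np.zeros(img.shape, dtype=bool)
        # reference background statistics: outside-well pixels when the
        # geometry is known, else the dimmest decile of the image
        if inwell is not None and (~inwell).any():
            ref = img[~inwell]
        else:
            ref = vals[vals <= np.quantile(vals, 0.1)]
        bg_med = float(np.median(ref))
        bg_sd = 1.4826 * float(np.median(np.abs(ref - bg_med))) + 1e-6
        thr = float(threshold_otsu(vals))
        below, above = vals[vals <= thr], vals[vals > thr]
        if above.size == 0 or float(above.mean()) - bg_med < 6.0 * bg_sd:
            # the "foreground" class is indistinguishable from background
            return np.zeros(img.shape, dtype=bool)
        if below.size and float(np.median(below)) > bg_med + 6.0 * bg_sd:
            # nearly confluent signal: Otsu split two signal textures, not
            # signal vs background — fall back to a background-referenced
            # threshold
            thr = bg_med + 6.0 * bg_sd
        mask = img > thr

    if inwell is not None:
        mask &= inwell
    if params.closing_radius_px > 0:
        se = disk(params.closing_radius_px)
        mask = ndi.binary_closing(mask, structure=se)
        if inwell is not None:
            mask &= inwell
    if params.hole_area_px > 0:
        mask = _fill_small_holes(mask, params.hole_area_px)
    # drop speckle well below the object-size floor
    mask = _remove_small(mask, max(params.min_object_px // 8, 1))
    return mask


def _remove_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    lab, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_px) + 1
    return np.isin(lab, keep)


def _fill_small_holes(mask: np.ndarray, max_px: int) -> np.ndarray:
    holes = ~mask
    lab, n = ndi.label(holes)
    if n == 0:
        return mask
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    border = np.unique(
        np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])
    )
    fill = np.flatnonzero(sizes <= max_px) + 1
    fill = np.setdiff1d(fill, border)
    return mask | np.isin(lab, fill)


def _elongation_ratio(comp_mask: np.ndarray) -> float:
    """Skeleton-length^2 / area (equals length/width for uniform cords)."""
    area = int(comp_mask.sum())
    if area == 0:
        return 0.0
    skel = skeletonize(comp_mask)
    length = int(skel.sum())
    return length * length / area


def classify_regions(
    ec_mask: np.ndarray,
    geom: WellGeometry,
    params: SegmentationParams = SegmentationParams(),
) -> RegionLabelMap:
    """Classify a binary EC mask into island / network / gap per pixel.

    Island bodies are recovered by thickness hysteresis on the EC distance
    transform (see module docstring); the remaining EC pixels are network
    and EC-negative in-well pixels are gap.  Island candidates with
    cord-like elongation are demoted to network, and components smaller
    than ``min_object_px`` are merged into their surrounding class.
    """
    ec_mask = np.asarray(ec_mask, dtype=bool)
    zone = geom.zone_map(ec_mask.shape)
    inwell = zone > 0
    ec = ec_mask & inwell

    labels = np.full(ec_mask.shape, OUTSIDE, dtype=np.uint8)
    labels[inwell] = GAP
    if ec.any():
        depth = ndi.distance_transform_edt(ec)
        dens = ndi.uniform_filter(ec.astype(float), size=params.density_window_px)
        body = depth >= params.cord_halfwidth_px
        island_pix = np.zeros_like(ec)
        if body.any():
            lab, _ = ndi.label(body)
            seeds = np.unique(lab[depth >= params.island_min_halfwidth_px])
            seeds = seeds[seeds > 0]
            if seeds.size:
                comp = np.isin(lab, seeds)
                # reclaim the rim eroded by the thickness criterion, gated
                # by the local-coverage feature so that cords touching the
                # island are not swallowed
                ring = ndi.binary_dilation(comp, disk(params.cord_halfwidth_px)) & ec
                island_pix = comp | (ring & (dens >= params.island_density_min))
        if not island_pix.any():
            # degenerate well (single texture): decide by overall coverage
            if float(dens[ec].mean()) >= params.island_density_min:
                island_pix = ec
        labels[island_pix] = ISLAND
        labels[ec & ~island_pix] = NETWORK

        labels = _reclassify_elongated(labels, depth, params)
        labels = _absorb_small_components(labels, params.min_object_px)

    return RegionLabelMap(labels, provenance={"params": params.to_dict()})


def _reclassify_elongated(
    labels: np.ndarray, depth: np.ndarray, params: SegmentationParams
) -> np.ndarray:
    """Demote filamentous island candidates that lack an island-deep core.

    Components admitted through the thickness hysteresis are compact by
    construction; the elongation feature guards the fallback path only.
    """
    comp, n = ndi.label(labels == ISLAND)
    if n == 0:
        return labels
    objects = ndi.find_objects(comp)
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = comp[sl] == i
        if int(sub.sum()) < params.min_object_px:
            continue
        if float(depth[sl][sub].max()) >= params.island_min_halfwidth_px:
            continue
        if _elongation_ratio(sub) >= params.cord_elongation_min:
            view = labels[sl]
            view[sub] = NETWORK
    return labels


def _absorb_small_components(labels: np.ndarray, min_px: int) -> np.ndarray:
    """Merge small island/network components into their surrounding class."""
    for cls in (ISLAND, NETWORK):
        comp, n = ndi.label(labels == cls)
        if n == 0:
            continue
        sizes = ndi.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_px) + 1
        objects = ndi.find_objects(comp)
        for i in small:
            sl = objects[i - 1]
            if sl is None:
                continue
            sl = tuple(
                slice(max(s.start - 1, 0), min(s.stop + 1, dim))
                for s, dim in zip(sl, labels.shape)
            )
            sub = comp[sl] == i
            ring = ndi.binary_dilation(sub) & ~sub
            neighbors = labels[sl][ring]
            neighbors = neighbors[neighbors != OUTSIDE]
            if neighbors.size == 0:
                continue
            counts = np.bincount(neighbors, minlength=3)
            counts[cls] = 0
            labels[sl][sub] = int(np.argmax(counts))
    return labels


# ----------------------------------------------------------------------
# evaluation and calibration
# ----------------------------------------------------------------------


def per_class_jaccard(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Jaccard index (IoU) of each region class between two label maps."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    out = {}
    for code, name in ((ISLAND, "island"), (NETWORK, "network"), (GAP, "gap")):
        p = pred == code
        t = truth == code
        union = int((p | t).sum())
        out[name] = float((p & t).sum()) / union if union else float("nan")
    return out


def _mean_jaccard(pred: np.ndarray, truth: np.ndarray) -> float:
    vals = [v for v in per_class_jaccard(pred, truth).values() if np.isfinite(v)]
    return float(np.mean(vals)) if vals else 0.0


def calibrate_params(
    training: list[tuple[np.ndarray, RegionLabelMap, WellGeometry]],
    grid: dict[str, list] | None = None,
    base: SegmentationParams = SegmentationParams(),
) -> tuple[SegmentationParams, dict]:
    """Grid search maximizing mean per-class Jaccard against ground truth.

    ``training`` is a list of ``(ec_channel, gt_labelmap, geometry)``
    triples.  The search is deterministic: grid points are evaluated in a
    fixed order and ties keep the earlier point.  Returns the best
    parameters and a report with the achieved score and a ``degenerate``
    flag when the ground truth contains a single class.
    """
    if not training:
        raise ValueError("calibrate_params requires at least one training scene")
    if grid is None:
        grid = {
            "cord_halfwidth_px": [10, 12, 14],
            "island_min_halfwidth_px": [16, 18, 20],
        }
    degenerate = all(
        len(np.unique(gt.labels[gt.in_well()])) < 2 for _, gt, _ in training
    )
    masks = [
        (binarize_ec(ec, geom, base), gt, geom) for ec, gt, geom in training
    ]
    keys = sorted(grid)
    best_params, best_score = base, -1.0
    for combo in product(*(grid[k] for k in keys)):
        try:
            params = replace(base, **dict(zip(keys, combo)))
        except ValueError:
            continue
        scores = [
            _mean_jaccard(classify_regions(m, geom, params).labels, gt.labels)
            for m, gt, geom in masks
        ]
        score = float(np.mean(scores))
        if score > best_score + 1e-12:
            best_params, best_score = params, score
    report = {"mean_jaccard": best_score, "degenerate": degenerate, "n_scenes": len(training)}
    return best_params, report


# ----------------------------------------------------------------------
# flow alignment
# ----------------------------------------------------------------------


def alignment_order(
    ec_channel: np.ndarray,
    labelmap: RegionLabelMap | np.ndarray,
    geom: WellGeometry,
    tensor_sigma: float = 3.0,
    energy_floor: float = 1e-3,
) -> dict[str, float]:
    """Flow-alignment order parameter of the island texture, per zone.

    Local texture orientation is estimated from the structure tensor of
    the EC signal; the order parameter is the mean of ``cos(2 * dtheta)``
    over island pixels, where ``dtheta`` is the unsigned angle between the
    local structure orientation and the tangential flow direction.  1 is
    perfect tangential alignment, 0 isotropy, -1 radial alignment.  Zones
    without island pixels (or without oriented texture) report ``nan``.
    """
    from skimage.feature import structure_tensor

    labels = labelmap.labels if isinstance(labelmap, RegionLabelMap) else np.asarray(labelmap)
    img = np.asarray(ec_channel, dtype=float)
    Arr, Arc, Acc = structure_tensor(img, sigma=tensor_sigma, order="rc")
    # dominant-gradient double angle in (x=col, y=row) frame:
    #   Axx=<gx^2>=Acc, Ayy=<gy^2>=Arr, Axy=Arc
    energy = np.hypot(Acc - Arr, 2 * Arc)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos2g = (Acc - Arr) / energy
        sin2g = 2 * Arc / energy
    # structure orientation is perpendicular to the gradient: rotate the
    # double angle by pi (negate both components)
    cos2s, sin2s = -cos2g, -sin2g

    theta_t = geom.tangent_angle_map(img.shape)
    cos2t = np.cos(2 * theta_t)
    sin2t = np.sin(2 * theta_t)
    cos2d = cos2s * cos2t + sin2s * sin2t

    scale = float(np.median(energy[labels != OUTSIDE])) if (labels != OUTSIDE).any() else 0.0
    valid = energy > energy_floor * max(scale, 1e-30)

    # keep clear of edge artifacts: erode the island mask so island/gap
    # boundary gradients do not contribute, and exclude the band at the
    # well rim, whose circular edge would register as spurious tangential
    # alignment
    margin = int(np.ceil(2 * tensor_sigma))
    island = ndi.binary_erosion(labels == ISLAND, iterations=margin)
    rmap = geom.radius_map(img.shape)
    interior = rmap <= geom.radius_px - 4 * tensor_sigma

    zone = geom.zone_map(img.shape)
    out: dict[str, float] = {}
    for zcode, zname in ((ZONE_CENTER, "center"), (ZONE_PERIPHERY, "periphery")):
        sel = (zone == zcode) & island & interior & valid & np.isfinite(cos2d)
        out[zname] = float(cos2d[sel].mean()) if sel.any() else float("nan")
    return out
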