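"""Synthetic well-mosaic generator with full ground truth.

Emulates the imaging readout of an endothelial/smooth-muscle direct-contact
coculture in one well of a 6-well plate on an orbital shaker: a circular
well imaged as a stitched multi-channel mosaic in which the endothelial
(EC) layer is a patchwork of confluent cobblestone *islands*, cord-like
*networks* of elongated cells, and bare *gaps* exposing the smooth-muscle
(SMC) layer.  In defected (gap/network) regions the SMC layer locally
thickens into 2–3-cell-deep corrugated ridges (elevated cell-tracker
intensity) and incorporates labeled plasma fibronectin into fibers; under
confluent islands both are absent.  Under shear, structures at the well
periphery align tangentially with the flow; in the center and in static
cultures orientation is random.

Every scene ships its ground truth — the region label map, the nucleus
table with EC/SMC identity and proliferation flags, and the corrugation
and fibronectin masks — so that segmentation and quantification can be
validated against known targets.

Region area fractions are enforced per zone by quantile-thresholding
smooth Gaussian random fields, so the generated fractions match the
configured targets to within a few pixels regardless of seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .geometry import WellGeometry, ZONE_CENTER, ZONE_PERIPHERY, GeometryError
from .io import ChannelStack, write_stack, write_labelmap, write_table
from .regions import GAP, ISLAND, NETWORK, OUTSIDE, CLASS_NAMES, RegionLabelMap

ZONES = ("center", "periphery")
CLASSES = ("island", "network", "gap")

MODELS = (
    "quiescent",
    "IH_low_density",
    "high_density",
    "monoculture_EC",
    "monoculture_SMC",
)
CONDITIONS = ("shear", "static")


class ConfigError(ValueError):
    """Raised for invalid scene configurations."""


def _per_zone(value) -> dict[str, float]:
    if isinstance(value, dict):
        missing = set(ZONES) - set(value)
        if missing:
            raise ConfigError(f"per-zone fraction missing zones {sorted(missing)}")
        return {z: float(value[z]) for z in ZONES}
    return {z: float(value) for z in ZONES}


def _default_prolif_rates() -> dict[str, dict[str, float]]:
    # Defected-region SMC proliferation exceeds island-region proliferation
    # (gaps ~30%, networks ~25%, below islands ~5%), in both zones.
    return {z: {"island": 0.05, "network": 0.25, "gap": 0.30} for z in ZONES}


@dataclass
class NoiseParams:
    """Acquisition noise: shot noise, read noise, and stitching vignette.

    ``poisson_scale`` is the photon count per intensity unit (shot noise is
    applied as Poisson at ``img * scale`` then rescaled); ``gaussian_sd``
    is additive read noise in intensity units; the vignette multiplies each
    square stitching tile by ``1 + U(-amp, amp)``, emulating the
    rectangular grid pattern of stitched mosaics.
    """

    poisson_scale: float = 0.8
    gaussian_sd: float = 2.0
    vignette_amplitude: float = 0.05
    stitch_grid_period_px: int = 256
    background_level: float = 8.0


@dataclass
class SceneConfig:
    """Full parameterization of one synthetic well scene.

    Fractions are target area fractions *per zone* (scalar values apply to
    both zones); ``island_fraction + network_fraction`` must not exceed 1
    in any zone.  ``corrugation_multiplier`` is the cell-tracker intensity
    fold-change on corrugated ridges (2–3-cell-thick SMC regions), and
    ``corrugation_coverage`` the fraction of the defected (gap+network)
    area occupied by ridges.  ``prolif_rates`` maps zone -> region class ->
    per-nucleus Bernoulli proliferation probability for SMC nuclei.
    """

    canvas_px: int = 1024
    well_radius_px: float = 480.0
    pixel_size_um: float = 4.0
    model: str = "IH_low_density"
    condition: str = "shear"
    island_fraction: dict[str, float] = field(
        default_factory=lambda: {"center": 0.15, "periphery": 0.30}
    )
    network_fraction: dict[str, float] = field(
        default_factory=lambda: {"center": 0.30, "periphery": 0.25}
    )
    split_fraction: float = 0.5
    corrugation_multiplier: float = 2.5
    corrugation_coverage: float = 0.85
    prolif_rates: dict[str, dict[str, float]] = field(default_factory=_default_prolif_rates)
    ec_prolif_rate: float = 0.05
    # cell-scale texture parameters (micrometres)
    ec_cell_diameter_um: float = 30.0
    smc_cell_diameter_um: float = 40.0
    # rendering levels (camera counts above background)
    ec_interior_level: float = 110.0
    ec_membrane_level: float = 80.0
    ec_network_level: float = 140.0
    smc_base_level: float = 90.0
    smc_texture_amp: float = 0.08
    fn_level: float = 150.0
    nucleus_peak: float = 160.0
    nucleus_sigma_px: float = 1.8
    alignment_strength: float = 0.5
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.noise, dict):
            self.noise = NoiseParams(**self.noise)
        self.island_fraction = _per_zone(self.island_fraction)
        self.network_fraction = _per_zone(self.network_fraction)
        if self.model not in MODELS:
            raise ConfigError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.condition not in CONDITIONS:
            raise ConfigError(f"unknown condition {self.condition!r}")
        for z in ZONES:
            fi, fn = self.island_fraction[z], self.network_fraction[z]
            if not (0.0 <= fi <= 1.0 and 0.0 <= fn <= 1.0):
                raise ConfigError(f"fractions for zone {z!r} must lie in [0, 1]")
            if fi + fn > 1.0 + 1e-12:
                raise ConfigError(
                    f"island_fraction + network_fraction > 1 in zone {z!r}"
                )
        for z, per_class in self.prolif_rates.items():
            for c, p in per_class.items():
                if not (0.0 <= p <= 1.0):
                    raise ConfigError(f"prolif_rates[{z}][{c}] outside [0, 1]")
        if not (0.0 <= self.ec_prolif_rate <= 1.0):
            raise ConfigError("ec_prolif_rate outside [0, 1]")
        if self.corrugation_multiplier < 1.0:
            raise ConfigError("corrugation_multiplier must be >= 1")
        if not (0.0 <= self.corrugation_coverage <= 1.0):
            raise ConfigError("corrugation_coverage outside [0, 1]")
        if 2 * (self.well_radius_px + 4) > self.canvas_px:
            raise GeometryError("well larger than canvas")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        return cls(**copy.deepcopy(d))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def geometry(self) -> WellGeometry:
        c = self.canvas_px / 2.0
        return WellGeometry(
            center_xy=(c, c),
            radius_px=self.well_radius_px,
            pixel_size_um=self.pixel_size_um,
            split_fraction=self.split_fraction,
        )


@dataclass
class GroundTruth:
    """Known truth for one generated scene."""

    region_labels: RegionLabelMap
    nuclei: pd.DataFrame
    corrugation_mask: np.ndarray
    fn_mask: np.ndarray
    config: SceneConfig


def model_config(
    model: str,
    condition: str = "shear",
    seed: int = 0,
    canvas_px: int = 1024,
    **overrides,
) -> SceneConfig:
    """Preset scene configuration for one coculture model x flow condition.

    The presets encode the qualitative outcomes of the three coculture
    models after 3 days: the quiescent model reaches a near-confluent EC
    layer with few central defects and uniformly low SMC proliferation;
    the low-density (intimal-hyperplasia) model retains a defected EC
    layer with islands coexisting with networks and gaps, elevated SMC
    proliferation and corrugated SMC ridges in defects; the high-density
    model is confluent at the periphery with small central gaps and low
    proliferation except in those central gaps.  Static presets shift the
    balance from islands toward networks relative to shear (the
    network-to-island transition is delayed without flow).
    """
    shear = condition == "shear"
    radius = canvas_px * 480.0 / 1024.0
    kw: dict = dict(
        model=model,
        condition=condition,
        seed=seed,
        canvas_px=canvas_px,
        well_radius_px=radius,
    )
    low = {z: {"island": 0.05, "network": 0.05, "gap": 0.05} for z in ZONES}
    if model == "quiescent":
        kw.update(
            island_fraction={"center": 0.85, "periphery": 0.95},
            network_fraction={"center": 0.03, "periphery": 0.01},
            corrugation_multiplier=1.0,
            corrugation_coverage=0.0,
            prolif_rates=low,
        )
    elif model == "IH_low_density":
        kw.update(
            island_fraction=(
                {"center": 0.15, "periphery": 0.30}
                if shear
                else {"center": 0.10, "periphery": 0.15}
            ),
            network_fraction=(
                {"center": 0.30, "periphery": 0.25}
                if shear
                else {"center": 0.40, "periphery": 0.40}
            ),
            corrugation_multiplier=2.5,
            corrugation_coverage=0.85,
        )
    elif model == "high_density":
        rates = {z: {"island": 0.05, "network": 0.05, "gap": 0.05} for z in ZONES}
        rates["center"]["gap"] = 0.25
        kw.update(
            island_fraction=(
                {"center": 0.75, "periphery": 0.92}
                if shear
                else {"center": 0.55, "periphery": 0.70}
            ),
            network_fraction=(
                {"center": 0.05, "periphery": 0.03}
                if shear
                else {"center": 0.15, "periphery": 0.12}
            ),
            corrugation_multiplier=1.0,
            corrugation_coverage=0.0,
            prolif_rates=rates,
        )
    elif model == "monoculture_EC":
        kw.update(
            island_fraction={"center": 0.35, "periphery": 0.60},
            network_fraction={"center": 0.25, "periphery": 0.15},
            smc_base_level=0.0,
            corrugation_multiplier=1.0,
            corrugation_coverage=0.0,
        )
    elif model == "monoculture_SMC":
        kw.update(
            island_fraction=0.0,
            network_fraction=0.0,
            corrugation_multiplier=1.0,
            corrugation_coverage=0.0,
            prolif_rates={z: {c: 0.08 for c in CLASSES} for z in ZONES},
        )
    else:
        raise ConfigError(f"unknown model {model!r}")
    kw.update(overrides)
    return SceneConfig(**kw)


# ----------------------------------------------------------------------
# random fields
# ----------------------------------------------------------------------


def _isotropic_field(shape, rng, sigma: float) -> np.ndarray:
    return ndi.gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")


def _tangential_field(
    shape, geom: WellGeometry, rng, sigma_r: float = 4.0, sigma_t: float = 40.0
) -> np.ndarray:
    """Random field with tangentially elongated correlation (polar smoothing).

    Noise is laid out on an (r, theta) grid, smoothed strongly along theta
    and weakly along r, and mapped back to the image grid, producing
    streaks that follow the circumferential flow direction.
    """
    nr = int(np.ceil(geom.radius_px)) + 4
    nt = 2048
    pol = rng.standard_normal((nr, nt))
    pol = ndi.gaussian_filter1d(pol, sigma_t, axis=1, mode="wrap")
    pol = ndi.gaussian_filter1d(pol, sigma_r, axis=0, mode="nearest")
    cx, cy = geom.center_xy
    yy, xx = np.indices(shape)
    r = np.hypot(xx - cx, yy - cy)
    th = np.mod(np.arctan2(yy - cy, xx - cx), 2 * np.pi)
    coords = np.stack([np.clip(r, 0, nr - 1), th / (2 * np.pi) * nt])
    return ndi.map_coordinates(pol, coords, order=1, mode="grid-wrap")


def _standardize(f: np.ndarray, where: np.ndarray) -> np.ndarray:
    vals = f[where]
    sd = vals.std()
    return (f - vals.mean()) / (sd if sd > 0 else 1.0)


def _oriented_defect_field(shape, geom, zone, rng, condition: str) -> np.ndarray:
    """Field used to place corrugated ridges: tangentially elongated in the
    periphery under shear, isotropic otherwise."""
    iso = _isotropic_field(shape, rng, 10.0)
    if condition == "shear":
        tang = _tangential_field(shape, geom, rng)
        return np.where(zone == ZONE_PERIPHERY, tang, iso)
    return iso


# ----------------------------------------------------------------------
# region label construction
# ----------------------------------------------------------------------


def _sample_region_labels(zone: np.ndarray, rng, config: SceneConfig) -> np.ndarray:
    """Quantile-thresholded random fields -> label map with exact fractions.

    Islands are the upper level set of a long-correlation field (compact
    blobs); networks are a band around the median level set of a
    shorter-correlation field restricted to non-island area (elongated,
    branching cords — level-set bands of a smooth field form connected
    webs).  Thresholds are per-zone quantiles, so area fractions hit the
    configured targets to pixel resolution.
    """
    shape = zone.shape
    scale = config.canvas_px / 1024.0
    f_isl = _isotropic_field(shape, rng, 60.0 * scale)
    f_net = _isotropic_field(shape, rng, 15.0 * scale)

    labels = np.full(shape, OUTSIDE, dtype=np.uint8)
    labels[zone > 0] = GAP
    for zcode, zname in ((ZONE_CENTER, "center"), (ZONE_PERIPHERY, "periphery")):
        zmask = zone == zcode
        n_zone = int(zmask.sum())
        if n_zone == 0:
            continue
        fi = config.island_fraction[zname]
        fn = config.network_fraction[zname]
        if fi > 0:
            if fi >= 1.0:
                labels[zmask] = ISLAND
            else:
                # raw level set, then shape regularization: smoothing the
                # binary indicator and re-thresholding at the same per-zone
                # quantile rounds off sub-cellular arms and necks (island
                # patches are confluent, hence compact) while keeping the
                # area fraction exact
                thr = np.quantile(f_isl[zmask], 1.0 - fi)
                raw = ndi.gaussian_filter(
                    (f_isl >= thr).astype(float), 16.0 * scale, mode="nearest"
                )
                thr2 = np.quantile(raw[zmask], 1.0 - fi)
                labels[zmask & (raw >= thr2)] = ISLAND
        rem = zmask & (labels == GAP)
        n_rem = int(rem.sum())
        if fn > 0 and n_rem > 0:
            target = min(int(round(fn * n_zone)), n_rem)
            band = _contour_band(f_net, rem, target, cord_halfwidth=5.5)
            labels[band] = NETWORK
    return labels


def _contour_band(
    f: np.ndarray, rem: np.ndarray, target_px: int, cord_halfwidth: float
) -> np.ndarray:
    """Constant-width cord web covering ``target_px`` pixels of ``rem``.

    Cords are bands of half-width ``cord_halfwidth`` around level sets of
    the smooth field ``f`` (first-order distance to the contour,
    ``|f - c| / |grad f|``).  Levels are added symmetrically around the
    median until the target area is reached; the last level is truncated
    at the exact pixel count, so the area fraction is hit to pixel
    resolution while every cord keeps the same width (1-2 cell diameters).
    """
    gy, gx = np.gradient(f)
    gmag = np.hypot(gx, gy) + 1e-9
    vals = f[rem]
    med = float(np.median(vals))
    sd = float(vals.std()) or 1.0
    levels = [med]
    for k in range(1, 16):
        levels += [med + 0.8 * k * sd, med - 0.8 * k * sd]
    got = np.zeros(f.shape, dtype=bool)
    count = 0
    for c in levels:
        d = np.abs(f - c) / gmag
        band = rem & ~got & (d <= cord_halfwidth)
        nb = int(band.sum())
        if nb == 0:
            continue
        if count + nb >= target_px:
            need = target_px - count
            kth = np.partition(d[band], need - 1)[need - 1]
            band &= d <= kth
            got |= band
            break
        got |= band
        count += nb
    return got


# ----------------------------------------------------------------------
# point processes
# ----------------------------------------------------------------------


class _PointThinner:
    """Greedy minimum-separation thinning on a uniform grid hash."""

    def __init__(self, spacing: float):
        self.cell = max(spacing, 1.0) / np.sqrt(2.0)
        self.grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
        self.points: list[tuple[float, float]] = []

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return (int(x // self.cell), int(y // self.cell))

    def try_add(self, x: float, y: float, spacing: float) -> bool:
        kx, ky = self._key(x, y)
        reach = int(np.ceil(spacing / self.cell))
        s2 = spacing * spacing
        for ix in range(kx - reach, kx + reach + 1):
            for iy in range(ky - reach, ky + reach + 1):
                for px, py in self.grid.get((ix, iy), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < s2:
                        return False
        self.grid.setdefault((kx, ky), []).append((x, y))
        self.points.append((x, y))
        return True


def _sample_points_in_mask(
    mask: np.ndarray, spacing: float, rng, thinner: _PointThinner, oversample: float = 4.0
) -> np.ndarray:
    """Random points inside ``mask`` with minimum separation ``spacing``.

    Candidates are uniform over mask pixels (with sub-pixel jitter) and
    kept greedily; the achieved density approaches the random
    sequential-adsorption limit (~0.65 / spacing^2).
    """
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return np.empty((0, 2))
    n_cand = int(oversample * idx.size / max(spacing * spacing, 1.0)) + 1
    pick = rng.choice(idx, size=n_cand, replace=True)
    ys, xs = np.unravel_index(pick, mask.shape)
    xs = xs + rng.random(n_cand) - 0.5
    ys = ys + rng.random(n_cand) - 0.5
    start = len(thinner.points)
    for x, y in zip(xs, ys):
        thinner.try_add(float(x), float(y), spacing)
    return np.array(thinner.points[start:]) if len(thinner.points) > start else np.empty((0, 2))


def _sample_nuclei(
    labels: np.ndarray,
    zone: np.ndarray,
    corrugation: np.ndarray,
    ec_seeds: np.ndarray,
    config: SceneConfig,
    rng,
) -> pd.DataFrame:
    """Nucleus table: EC nuclei under EC signal, SMC nuclei across the well
    (denser on corrugated ridges), proliferation flags Bernoulli per
    (zone, region class).

    The SMC layer sits *below* the endothelium, so SMC nuclei are present
    across the whole well, including under EC islands; in the projected
    image they keep a small lateral clearance from EC nuclei so that both
    remain resolvable.
    """
    px = config.pixel_size_um
    ec_spacing = 0.85 * config.ec_cell_diameter_um / px
    smc_spacing = 0.85 * config.smc_cell_diameter_um / px
    cross_clearance = 0.8 * ec_spacing
    ec_thinner = _PointThinner(ec_spacing)

    ec_pts: list[np.ndarray] = []
    # island EC nuclei at the cobblestone cell centers
    for x, y in ec_seeds:
        if ec_thinner.try_add(float(x), float(y), ec_spacing * 0.8):
            ec_pts.append((x, y))
    ec_pts = [np.array(ec_pts).reshape(-1, 2)]
    # network EC nuclei along the cords
    net_pts = _sample_points_in_mask(labels == NETWORK, ec_spacing, rng, ec_thinner)
    ec_pts.append(net_pts)
    ec_xy = np.vstack(ec_pts)

    smc_xy = np.empty((0, 2))
    if config.smc_base_level > 0:
        inwell = zone > 0
        smc_thinner = _PointThinner(cross_clearance)
        ec_tree = cKDTree(ec_xy) if len(ec_xy) else None

        def sample_smc(mask, spacing):
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                return np.empty((0, 2))
            n_cand = int(4.0 * idx.size / max(spacing * spacing, 1.0)) + 1
            pick = rng.choice(idx, size=n_cand, replace=True)
            ys, xs = np.unravel_index(pick, mask.shape)
            xs = xs + rng.random(n_cand) - 0.5
            ys = ys + rng.random(n_cand) - 0.5
            if ec_tree is not None:
                d, _ = ec_tree.query(np.column_stack([xs, ys]), k=1, workers=-1)
                keep = d >= cross_clearance
                xs, ys = xs[keep], ys[keep]
            start = len(smc_thinner.points)
            for x, y in zip(xs, ys):
                smc_thinner.try_add(float(x), float(y), spacing)
            pts = smc_thinner.points[start:]
            return np.array(pts) if pts else np.empty((0, 2))

        smc_xy = sample_smc(inwell, smc_spacing)
        # corrugated ridges are 2-3 cells deep: extra nuclei on the ridges
        if corrugation.any():
            extra = sample_smc(corrugation, smc_spacing * 0.75)
            smc_xy = np.vstack([smc_xy, extra]) if extra.size else smc_xy

    xy = np.vstack([ec_xy, smc_xy])
    is_ec = np.zeros(len(xy), dtype=bool)
    is_ec[: len(ec_xy)] = True
    if len(xy) == 0:
        return pd.DataFrame(
            columns=["x_px", "y_px", "is_EC", "is_proliferative", "zone", "region_class"]
        )

    xi = np.clip(np.rint(xy[:, 0]).astype(int), 0, labels.shape[1] - 1)
    yi = np.clip(np.rint(xy[:, 1]).astype(int), 0, labels.shape[0] - 1)
    zname = np.array(["outside", "center", "periphery"])[zone[yi, xi]]
    cname = np.array([CLASS_NAMES.get(int(c), "outside") for c in labels[yi, xi]])

    p = np.full(len(xy), config.ec_prolif_rate)
    for i in np.flatnonzero(~is_ec):
        z, c = zname[i], cname[i]
        if z in config.prolif_rates and c in config.prolif_rates[z]:
            p[i] = config.prolif_rates[z][c]
        else:
            p[i] = 0.0
    prolif = rng.random(len(xy)) < p

    df = pd.DataFrame(
        {
            "x_px": xy[:, 0],
            "y_px": xy[:, 1],
            "is_EC": is_ec,
            "is_proliferative": prolif,
            "zone": zname,
            "region_class": cname,
        }
    )
    # nuclei outside the well are artefacts of rounding at the rim; drop
    return df[df["zone"] != "outside"].reset_index(drop=True)


# ----------------------------------------------------------------------
# channel rendering
# ----------------------------------------------------------------------


def _render_nuclei_channel(
    shape, xy: np.ndarray, config: SceneConfig, rng
) -> np.ndarray:
    if len(xy) == 0:
        return np.zeros(shape, dtype=float)
    img = np.zeros(shape, dtype=float)
    sigma = config.nucleus_sigma_px
    amp = config.nucleus_peak * 2 * np.pi * sigma**2 * rng.uniform(0.8, 1.2, len(xy))
    xi = np.clip(np.rint(xy[:, 0]).astype(int), 0, shape[1] - 1)
    yi = np.clip(np.rint(xy[:, 1]).astype(int), 0, shape[0] - 1)
    np.add.at(img, (yi, xi), amp)
    return ndi.gaussian_filter(img, sigma, mode="constant")


def _voronoi_membrane(
    island: np.ndarray, seeds: np.ndarray, border_px: float = 2.0
) -> np.ndarray:
    """Cobblestone membrane signal: bright borders between Voronoi cells.

    For each island pixel the difference between the distances to the two
    nearest cell centers is small on inter-cell borders; an exponential
    falloff turns it into a soft membrane indicator in [0, 1].
    """
    out = np.zeros(island.shape, dtype=float)
    if len(seeds) < 2 or not island.any():
        return out
    ys, xs = np.nonzero(island)
    tree = cKDTree(seeds)
    d, _ = tree.query(np.column_stack([xs, ys]), k=2, workers=-1)
    margin = d[:, 1] - d[:, 0]
    out[ys, xs] = np.exp(-((margin / border_px) ** 2))
    return out


def _render_ec(
    labels: np.ndarray,
    zone: np.ndarray,
    geom: WellGeometry,
    seeds: np.ndarray,
    config: SceneConfig,
    rng,
) -> np.ndarray:
    island = labels == ISLAND
    network = labels == NETWORK
    ec = np.zeros(labels.shape, dtype=float)
    if island.any():
        ec[island] = config.ec_interior_level
        membrane = _voronoi_membrane(island, seeds)
        ec += config.ec_membrane_level * membrane
    if network.any():
        tex = 0.85 + 0.3 * (
            _standardize(_isotropic_field(labels.shape, rng, 3.0), network) * 0.25 + 0.5
        )
        ec[network] = config.ec_network_level * tex[network]
    if config.condition == "shear" and island.any():
        # tangential intensity modulation at the periphery: encodes flow
        # alignment of the island cells as an oriented texture component
        tang = _standardize(_tangential_field(labels.shape, geom, rng), zone > 0)
        mod = 1.0 + config.alignment_strength * np.tanh(tang)
        sel = island & (zone == ZONE_PERIPHERY)
        ec[sel] *= mod[sel]
    return ndi.gaussian_filter(ec, 1.0, mode="nearest")


def _apply_noise(
    img: np.ndarray, rng, noise: NoiseParams, gain_map: np.ndarray | None
) -> np.ndarray:
    out = img + noise.background_level
    if gain_map is not None:
        out = out * gain_map
    if noise.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * noise.poisson_scale) / noise.poisson_scale
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, out.shape)
    return np.clip(out, 0, None).astype(np.float32)


def _stitch_gain_map(shape, rng, noise: NoiseParams) -> np.ndarray | None:
    if noise.vignette_amplitude <= 0:
        return None
    p = max(int(noise.stitch_grid_period_px), 8)
    ny = shape[0] // p + 1
    nx = shape[1] // p + 1
    tiles = 1.0 + noise.vignette_amplitude * rng.uniform(-1, 1, (ny, nx))
    return np.kron(tiles, np.ones((p, p)))[: shape[0], : shape[1]]


# ----------------------------------------------------------------------
# scene assembly
# ----------------------------------------------------------------------


def generate_scene(config: SceneConfig) -> tuple[ChannelStack, GroundTruth]:
    """Generate one synthetic well mosaic and its ground truth.

    Deterministic: identical config (including seed) yields bit-identical
    output.  Channel order is ``(EC, SMC, Fn, DAPI, Ki67, ERG1)``.
    """
    geom = config.geometry()
    shape = (config.canvas_px, config.canvas_px)
    zone = geom.zone_map(shape)
    inwell = zone > 0

    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_labels, rng_pts, rng_ec, rng_smc, rng_fn, rng_nuc, rng_noise = (
        np.random.default_rng(s) for s in streams
    )

    labels = _sample_region_labels(zone, rng_labels, config)
    island = labels == ISLAND
    network = labels == NETWORK
    defect = inwell & ~island

    # corrugated SMC ridges: only under defects, periphery-biased
    # orientation under shear, covering `corrugation_coverage` of the
    # defected area per zone
    corr = np.zeros(shape, dtype=bool)
    if config.corrugation_coverage > 0 and config.corrugation_multiplier > 1:
        fld = _oriented_defect_field(shape, geom, zone, rng_smc, config.condition)
        for zcode in (ZONE_CENTER, ZONE_PERIPHERY):
            dz = defect & (zone == zcode)
            if dz.sum() == 0:
                continue
            thr = np.quantile(fld[dz], 1.0 - config.corrugation_coverage)
            corr |= dz & (fld >= thr)

    # fibronectin fibers: thin band web restricted to defected regions
    fnf = _isotropic_field(shape, rng_fn, 5.0)
    fn_mask = np.zeros(shape, dtype=bool)
    if defect.any() and config.fn_level > 0:
        dev = np.abs(fnf - np.median(fnf[inwell]))
        w = np.quantile(dev[defect], 0.35)
        fn_mask = defect & (dev <= w)

    # cobblestone cell centers (island Voronoi seeds; reused as EC nuclei)
    ec_spacing = 0.85 * config.ec_cell_diameter_um / config.pixel_size_um
    seed_thinner = _PointThinner(ec_spacing)
    seeds = _sample_points_in_mask(
        ndi.binary_dilation(island, iterations=2), ec_spacing, rng_pts, seed_thinner
    )
    seeds_in_island = (
        seeds[island[np.clip(np.rint(seeds[:, 1]).astype(int), 0, shape[0] - 1),
                     np.clip(np.rint(seeds[:, 0]).astype(int), 0, shape[1] - 1)]]
        if len(seeds)
        else np.empty((0, 2))
    )

    nuclei = _sample_nuclei(labels, zone, corr, seeds_in_island, config, rng_nuc)

    # --- channels -------------------------------------------------------
    ec = _render_ec(labels, zone, geom, seeds, config, rng_ec)

    smc = np.zeros(shape, dtype=float)
    if config.smc_base_level > 0:
        base_tex = 1.0 + config.smc_texture_amp * _standardize(
            _isotropic_field(shape, rng_smc, 30.0), inwell
        )
        ridge = ndi.gaussian_filter(corr.astype(float), 2.0, mode="nearest")
        smc[inwell] = (
            config.smc_base_level
            * base_tex[inwell]
            * (1.0 + (config.corrugation_multiplier - 1.0) * ridge[inwell])
        )

    fn = np.zeros(shape, dtype=float)
    if fn_mask.any():
        rel = smc / config.smc_base_level if config.smc_base_level > 0 else np.ones(shape)
        fib_tex = 0.7 + 0.3 * rng_fn.random(shape)
        fn[fn_mask] = config.fn_level * fib_tex[fn_mask] * rel[fn_mask]
        fn = ndi.gaussian_filter(fn, 1.0, mode="nearest")

    xy_all = nuclei[["x_px", "y_px"]].to_numpy()
    dapi = _render_nuclei_channel(shape, xy_all, config, rng_nuc)
    erg1 = _render_nuclei_channel(
        shape, xy_all[nuclei["is_EC"].to_numpy()], config, rng_nuc
    )
    ki67 = _render_nuclei_channel(
        shape, xy_all[nuclei["is_proliferative"].to_numpy()], config, rng_nuc
    )
    ec = ec + 0.6 * erg1  # composite junction + EC-nuclear stain

    gain = _stitch_gain_map(shape, rng_noise, config.noise)
    channels = [
        _apply_noise(img, rng_noise, config.noise, gain)
        for img in (ec, smc, fn, dapi, ki67, erg1)
    ]
    stack = ChannelStack(
        np.stack(channels),
        ("EC", "SMC", "Fn", "DAPI", "Ki67", "ERG1"),
        pixel_size_um=config.pixel_size_um,
        metadata={"model": config.model, "condition": config.condition,
                  "seed": int(config.seed)},
    )
    gt = GroundTruth(
        region_labels=RegionLabelMap(labels, provenance={"generator": config.to_dict()}),
        nuclei=nuclei,
        corrugation_mask=corr,
        fn_mask=fn_mask,
        config=config,
    )
    return stack, gt


def generate_time_series(
    base: SceneConfig,
    schedule: list[dict],
    enforce_transition: bool = True,
    conserve_total: bool = False,
    total_tolerance: float = 0.05,
) -> list[tuple[ChannelStack, GroundTruth]]:
    """Generate a per-day series of scenes sharing the well geometry.

    ``schedule`` holds per-day overrides of ``island_fraction`` and/or
    ``network_fraction``.  With ``enforce_transition`` the series must
    follow the network-to-island transition (island fraction non-decreasing
    and network fraction non-increasing in every zone); with
    ``conserve_total`` the per-zone total EC fraction must stay within
    ``total_tolerance`` of day 0.  Geometry overrides are rejected.
    """
    if not schedule:
        raise ConfigError("schedule must be non-empty")
    geometry_keys = {"canvas_px", "well_radius_px", "pixel_size_um", "split_fraction"}
    configs: list[SceneConfig] = []
    for day, overrides in enumerate(schedule):
        bad = geometry_keys & set(overrides)
        if bad:
            raise ConfigError(f"schedule entry {day} overrides geometry: {sorted(bad)}")
        cfg = replace(
            base,
            island_fraction=_per_zone(overrides.get("island_fraction", base.island_fraction)),
            network_fraction=_per_zone(
                overrides.get("network_fraction", base.network_fraction)
            ),
            seed=int(overrides.get("seed", base.seed + day)),
        )
        configs.append(cfg)

    for z in ZONES:
        isl = [c.island_fraction[z] for c in configs]
        net = [c.network_fraction[z] for c in configs]
        if enforce_transition:
            if any(b < a - 1e-12 for a, b in zip(isl, isl[1:])):
                raise ConfigError(
                    f"island fraction decreases in zone {z!r}; the network-to-island "
                    "transition requires non-decreasing island coverage"
                )
            if any(b > a + 1e-12 for a, b in zip(net, net[1:])):
                raise ConfigError(f"network fraction increases in zone {z!r}")
        if conserve_total:
            totals = [i + n for i, n in zip(isl, net)]
            if max(totals) - min(totals) > total_tolerance:
                raise ConfigError(
                    f"total EC fraction drifts by more than {total_tolerance} in zone {z!r}"
                )
    return [generate_scene(cfg) for cfg in configs]


def save_scene(outdir, stack: ChannelStack, gt: GroundTruth, stem: str = "scene") -> dict:
    """Write a scene to disk: TIFF stack, label-map PNG, nuclei CSV, config YAML."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": write_stack(outdir / f"{stem}.tif", stack),
        "labels": write_labelmap(outdir / f"{stem}_labels.png", gt.region_labels),
        "nuclei": write_table(outdir / f"{stem}_nuclei.csv", gt.nuclei),
        "config": outdir / f"{stem}_config.yaml",
    }
    gt.config.to_yaml(paths["config"])
    return paths
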