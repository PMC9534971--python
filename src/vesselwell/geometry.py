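"""Circular-well geometry: center/periphery zoning and the flow-direction field.

On an orbital shaker the flow regime differs between the rim of the well
(pulsatile, near-unidirectional, tangential) and its center (disturbed,
multidirectional).  Analyses therefore split every well into two annular
zones at a fixed fraction of the radius — by default the middle of the
radial position, so the ``center`` zone is the disk ``r < 0.5 R`` and the
``periphery`` the annulus ``0.5 R <= r <= R``.

Conventions
-----------
* Points are ``(x, y)`` pairs in pixel units with ``x`` = column and
  ``y`` = row (origin top-left, row-major images).
* The flow direction is the counter-clockwise tangent (as seen with the
  y-axis pointing up): due east of the center the flow points north.
* Pixels at exactly the split radius belong to the periphery (outward
  tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml

ZONE_OUTSIDE: int = 0
ZONE_CENTER: int = 1
ZONE_PERIPHERY: int = 2

ZONE_NAMES: dict[int, str] = {
    ZONE_OUTSIDE: "outside",
    ZONE_CENTER: "center",
    ZONE_PERIPHERY: "periphery",
}
ZONES: tuple[str, str] = ("center", "periphery")


class GeometryError(ValueError):
    """Raised when a well disk cannot be located or parameters are invalid."""


@dataclass(frozen=True)
class WellGeometry:
    """Circular well with a radial center/periphery partition.

    Parameters
    ----------
    center_xy
        Well center ``(x, y)`` in pixels.
    radius_px
        Well radius in pixels, ``> 0``.
    pixel_size_um
        Physical pixel size, micrometres per pixel.
    split_fraction
        Radial fraction separating center from periphery, in ``(0, 1)``.
    truncated
        True when the well disk was fitted from a partially visible disk
        (touching the image border); the radius then reflects visible area
        only.
    """

    center_xy: tuple[float, float]
    radius_px: float
    pixel_size_um: float = 1.0
    split_fraction: float = 0.5
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise GeometryError("radius_px must be positive")
        if not (0.0 < self.split_fraction < 1.0):
            raise GeometryError("split_fraction must lie strictly between 0 and 1")
        if self.pixel_size_um <= 0:
            raise GeometryError("pixel_size_um must be positive")

    # -- coordinates -----------------------------------------------------

    def radial_distance(self, points: np.ndarray) -> np.ndarray:
        """Euclidean distance of ``(x, y)`` points from the well center (px)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cx, cy = self.center_xy
        return np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)

    def radius_map(self, shape: tuple[int, int]) -> np.ndarray:
        """Per-pixel radial distance from the center for an image of ``shape``."""
        cx, cy = self.center_xy
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        return np.hypot(xx - cx, yy - cy)

    # -- zoning ----------------------------------------------------------

    def zone_of(self, points: np.ndarray) -> np.ndarray:
        """Zone label for each ``(x, y)`` point.

        Returns an array of strings in ``{"center", "periphery", "outside"}``.
        A point at exactly ``split_fraction * R`` is periphery; a point at
        exactly ``R`` is in-well.
        """
        r = self.radial_distance(points)
        codes = self._zone_codes(r)
        return np.array([ZONE_NAMES[c] for c in codes])

    def zone_map(self, shape: tuple[int, int]) -> np.ndarray:
        """Per-pixel zone codes (``ZONE_OUTSIDE/CENTER/PERIPHERY``)."""
        return self._zone_codes(self.radius_map(shape))

    def _zone_codes(self, r: np.ndarray) -> np.ndarray:
        split = self.split_fraction * self.radius_px
        codes = np.full(np.shape(r), ZONE_OUTSIDE, dtype=np.uint8)
        codes[np.asarray(r) <= self.radius_px] = ZONE_PERIPHERY
        codes[np.asarray(r) < split] = ZONE_CENTER
        return codes

    # -- flow ------------------------------------------------------------

    def flow_direction(self, points: np.ndarray, eps: float = 1e-9) -> np.ndarray:
        """Unit tangent (counter-clockwise) at each ``(x, y)`` point.

        Returns an ``(n, 2)`` array of unit vectors in image coordinates
        (``y`` increases downward, so "north" is ``(0, -1)``).  Within
        ``eps`` of the center the direction is undefined and ``(nan, nan)``
        is returned.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cx, cy = self.center_xy
        dx = pts[:, 0] - cx
        dy = pts[:, 1] - cy
        r = np.hypot(dx, dy)
        out = np.empty_like(pts)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, 0] = dy / r
            out[:, 1] = -dx / r
        out[r < eps] = np.nan
        return out

    def tangent_angle_map(self, shape: tuple[int, int]) -> np.ndarray:
        """Per-pixel angle (radians) of the tangential flow direction.

        Angle measured in image coordinates from the +x axis toward +y
        (downward); only meaningful modulo pi for unsigned comparisons.
        """
        cx, cy = self.center_xy
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        return np.arctan2(-(xx - cx), (yy - cy) + 0.0 * xx)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "center_xy": [float(self.center_xy[0]), float(self.center_xy[1])],
            "radius_px": float(self.radius_px),
            "pixel_size_um": float(self.pixel_size_um),
            "split_fraction": float(self.split_fraction),
            "truncated": bool(self.truncated),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WellGeometry":
        return cls(
            center_xy=tuple(d["center_xy"]),
            radius_px=d["radius_px"],
            pixel_size_um=d.get("pixel_size_um", 1.0),
            split_fraction=d.get("split_fraction", 0.5),
            truncated=d.get("truncated", False),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "WellGeometry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_split(self, split_fraction: float) -> "WellGeometry":
        return replace(self, split_fraction=split_fraction)


def fit_well(
    image: np.ndarray,
    *,
    pixel_size_um: float = 1.0,
    split_fraction: float = 0.5,
    threshold: float | None = None,
) -> WellGeometry:
    """Locate the circular well in an image or mask.

    Accepts either a boolean well mask, a single channel, or a channel
    stack (``(C, H, W)``; max-projected).  The disk is found by
    thresholding (Otsu unless ``threshold`` is given), taking the largest
    connected component, and reading off its centroid and equivalent-area
    radius.

    Raises
    ------
    GeometryError
        If no foreground disk is present.
    """
    from scipy import ndimage as ndi
    from skimage.filters import threshold_otsu

    arr = np.asarray(image)
    if arr.ndim == 3:
        arr = arr.max(axis=0)
    if arr.ndim != 2:
        raise GeometryError("expected a 2-D image, mask, or (C, H, W) stack")

    if arr.dtype == bool:
        mask = arr
    else:
        arr = arr.astype(float)
        if threshold is None:
            if np.ptp(arr) == 0:
                raise GeometryError("constant image: no well disk found")
            threshold = threshold_otsu(arr)
        mask = arr > threshold

    if not mask.any():
        raise GeometryError("no foreground pixels: no well disk found")

    lab, n = ndi.label(mask)
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        mask = lab == keep

    ys, xs = np.nonzero(mask)
    area = xs.size
    center = (float(xs.mean()), float(ys.mean()))
    radius = float(np.sqrt(area / np.pi))
    touches = (
        ys.min() == 0
        or xs.min() == 0
        or ys.max() == mask.shape[0] - 1
        or xs.max() == mask.shape[1] - 1
    )
    return WellGeometry(
        center_xy=center,
        radius_px=radius,
        pixel_size_um=pixel_size_um,
        split_fraction=split_fraction,
        truncated=bool(touches),
    )
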