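"""Region-class label conventions shared by the generator and the segmenter.

A well mosaic is partitioned per pixel into three mutually exclusive classes:

``gap``
    In-well area with no endothelial coverage (the smooth-muscle layer is
    exposed).
``island``
    Confluent 2D endothelial patch with cobblestone morphology.
``network``
    Cord-like assembly of elongated endothelial cells.

Pixels outside the circular well carry the sentinel ``OUTSIDE``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GAP: int = 0
ISLAND: int = 1
NETWORK: int = 2
OUTSIDE: int = 255

CLASS_NAMES: dict[int, str] = {GAP: "gap", ISLAND: "island", NETWORK: "network"}
CLASS_CODES: dict[str, int] = {v: k for k, v in CLASS_NAMES.items()}

#: display palette for label-map exports (RGB); islands purple, networks
#: green, gaps black, outside dark gray — mirrors the usual rendering of
#: texture-classified mosaics.
PALETTE: dict[int, tuple[int, int, int]] = {
    GAP: (0, 0, 0),
    ISLAND: (150, 40, 180),
    NETWORK: (40, 180, 60),
    OUTSIDE: (60, 60, 60),
}


@dataclass
class RegionLabelMap:
    """Per-pixel region classification of one well.

    Parameters
    ----------
    labels
        ``uint8`` array; values in ``{GAP, ISLAND, NETWORK, OUTSIDE}``.
    provenance
        Free-form record of the parameters that produced the map
        (segmentation parameters, or the generator config for ground truth).
    """

    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        valid = np.isin(self.labels, [GAP, ISLAND, NETWORK, OUTSIDE])
        if not valid.all():
            bad = np.unique(self.labels[~valid])
            raise ValueError(f"label map contains unknown classes {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def mask(self, cls: int | str) -> np.ndarray:
        code = CLASS_CODES[cls] if isinstance(cls, str) else int(cls)
        return self.labels == code

    def in_well(self) -> np.ndarray:
        return self.labels != OUTSIDE


def class_fractions(labels: np.ndarray, where: np.ndarray | None = None) -> dict[str, float]:
    """Area fraction of each region class over ``where`` (default: in-well).

    Fractions sum to 1 over {island, network, gap} by the partition property.
    """
    labels = np.asarray(labels)
    if where is None:
        where = labels != OUTSIDE
    n = int(where.sum())
    if n == 0:
        raise ValueError("empty region: no in-well pixels selected")
    return {
        name: float(np.count_nonzero(labels[where] == code)) / n
        for code, name in CLASS_NAMES.items()
    }
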