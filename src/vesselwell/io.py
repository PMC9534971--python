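"""Reading and writing well mosaics, label maps, and tables.

A well is stored as a multi-page TIFF with one page per channel and a JSON
metadata block (channel names, pixel size) in the image description, or as
a directory of per-channel TIFFs with a ``manifest.yaml``.  Channel roles
are fixed names; the fibronectin and proliferation channels are optional
and their absence is flagged rather than fatal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml
from PIL import Image

from .regions import PALETTE, RegionLabelMap

#: Recognised channel roles.  EC is the composite junction+nuclear
#: endothelial signal (VE-cadherin + ERG1); SMC the cytoplasmic cell-tracker
#: dye; Fn the labeled plasma fibronectin; DAPI all nuclei; Ki67
#: proliferating nuclei; ERG1 endothelial nuclei.
CHANNEL_ROLES: tuple[str, ...] = ("EC", "SMC", "Fn", "DAPI", "Ki67", "ERG1")
OPTIONAL_CHANNELS: frozenset[str] = frozenset({"Fn", "Ki67"})


class FormatError(ValueError):
    """Raised for malformed stacks, manifests or label maps."""


@dataclass
class ChannelStack:
    """Registered multi-channel image of one well.

    ``data`` has shape ``(n_channels, H, W)``; ``channel_names`` gives the
    role of each page.  All channels share the pixel grid (registered
    acquisition), so a single well geometry applies to every channel.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_um: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 3:
            raise FormatError("stack data must have shape (channels, H, W)")
        if len(self.channel_names) != self.data.shape[0]:
            raise FormatError("channel_names length must match the first axis")
        unknown = set(self.channel_names) - set(CHANNEL_ROLES)
        if unknown:
            raise FormatError(f"unknown channel role(s): {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def has(self, name: str) -> bool:
        return name in self.channel_names

    @property
    def missing_channels(self) -> tuple[str, ...]:
        return tuple(r for r in CHANNEL_ROLES if r not in self.channel_names)

    def channel(self, name: str) -> np.ndarray:
        """Return one channel by role; raises ``KeyError`` if absent."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present in stack") from None
        return self.data[idx]

    def get(self, name: str) -> np.ndarray | None:
        return self.channel(name) if self.has(name) else None


def write_stack(path: str | Path, stack: ChannelStack) -> Path:
    """Write a stack as a multi-page TIFF with JSON metadata."""
    path = Path(path)
    meta = {
        "channels": list(stack.channel_names),
        "pixel_size_um": float(stack.pixel_size_um),
        **stack.metadata,
    }
    data = stack.data
    if data.dtype.kind == "f":
        data = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, description=json.dumps(meta), photometric="minisblack")
    return path


def read_stack(path: str | Path) -> ChannelStack:
    """Read a multi-channel well stack.

    ``path`` may be a multi-page TIFF (channel names in a JSON image
    description) or a directory containing ``manifest.yaml`` mapping
    channel roles to per-channel TIFF files.

    Raises
    ------
    FormatError
        For unknown channel roles or mismatched channel dimensions.
    """
    path = Path(path)
    if path.is_dir():
        return _read_stack_dir(path)

    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description or "{}"
    except Exception as exc:  # corrupt file
        raise FormatError(f"read_stack: cannot read TIFF {path}: {exc}") from exc
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    if data.ndim == 2:
        data = data[None]
    names = meta.pop("channels", None)
    if names is None:
        names = list(CHANNEL_ROLES[: data.shape[0]])
    pixel_size = float(meta.pop("pixel_size_um", 1.0))
    return ChannelStack(data, tuple(names), pixel_size, metadata=meta)


def _read_stack_dir(path: Path) -> ChannelStack:
    manifest = path / "manifest.yaml"
    if not manifest.exists():
        raise FormatError(f"read_stack: directory {path} has no manifest.yaml")
    with open(manifest) as fh:
        man = yaml.safe_load(fh)
    channels = man.get("channels", {})
    names, planes = [], []
    for name, fname in channels.items():
        img = tifffile.imread(path / fname)
        if img.ndim != 2:
            raise FormatError(f"channel file {fname} is not a single 2-D image")
        names.append(name)
        planes.append(img)
    if not planes:
        raise FormatError(f"manifest {manifest} lists no channels")
    shapes = {p.shape for p in planes}
    if len(shapes) > 1:
        raise FormatError(f"mismatched channel dimensions: {sorted(shapes)}")
    return ChannelStack(
        np.stack(planes),
        tuple(names),
        float(man.get("pixel_size_um", 1.0)),
        metadata={k: v for k, v in man.items() if k not in ("channels", "pixel_size_um")},
    )


# -- label maps ---------------------------------------------------------


def write_labelmap(path: str | Path, labelmap: RegionLabelMap) -> Path:
    """Write a region label map as an indexed (palette) PNG."""
    path = Path(path)
    img = Image.fromarray(labelmap.labels.astype(np.uint8), mode="P")
    palette = [0] * 768
    for code, rgb in PALETTE.items():
        palette[3 * code : 3 * code + 3] = rgb
    img.putpalette(palette)
    img.save(path)
    return path


def read_labelmap(path: str | Path) -> RegionLabelMap:
    img = Image.open(path)
    return RegionLabelMap(np.asarray(img, dtype=np.uint8))


# -- tables with provenance headers -------------------------------------


def write_table(path: str | Path, df, header_lines: list[str] | None = None) -> Path:
    """Write a DataFrame as CSV with ``#``-prefixed provenance header lines."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.10g")
    return path
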