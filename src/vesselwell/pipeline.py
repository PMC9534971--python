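"""End-to-end pipeline: stack -> geometry -> segmentation -> quantification.

The pipeline composes the library stages in the order a well is analyzed:
locate the well disk, binarize and texture-classify the EC channel, detect
nuclei, and compute coverage, proliferation, layering, radial-profile and
alignment statistics, together with the orbital-shaker shear summary.
Every artifact is written with a provenance header (package version,
configuration hash, seed), so identical configurations produce
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import WellGeometry, fit_well
from .hemodynamics import ShearModel, zone_shear_summary
from .io import ChannelStack, read_stack, write_labelmap, write_table
from .quantify import (
    NucleusDetectionParams,
    assign_nuclei,
    coverage_fractions,
    detect_nuclei,
    proliferation_by_region,
    radial_profiles,
    smc_layering_index,
)
from .regions import RegionLabelMap
from .segmentation import SegmentationParams, alignment_order, binarize_ec, classify_regions

log = logging.getLogger("vesselwell")


class StageError(RuntimeError):
    """Wraps a failure with the pipeline stage name and input fingerprint."""

    def __init__(self, stage: str, fingerprint: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on input {fingerprint}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything needed for one end-to-end run.

    Exactly one of ``input_stack`` (path to a stack on disk) or
    ``simulate`` (a scene-configuration mapping for the synthetic
    generator) must be provided.
    """

    output_dir: str = "vesselwell_out"
    input_stack: str | None = None
    simulate: dict | None = None
    split_fraction: float = 0.5
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    nucleus_detection: NucleusDetectionParams = field(default_factory=NucleusDetectionParams)
    n_bins: int = 30
    n_min_nuclei: int = 20
    n_sector_rois: int | None = 8
    shear: ShearModel = field(default_factory=ShearModel)
    seed: int = 0
    log_level: str = "INFO"
    use_ground_truth_nuclei: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.segmentation, dict):
            self.segmentation = SegmentationParams(**self.segmentation)
        if isinstance(self.nucleus_detection, dict):
            self.nucleus_detection = NucleusDetectionParams(**self.nucleus_detection)
        if isinstance(self.shear, dict):
            self.shear = ShearModel(**self.shear)
        if (self.input_stack is None) == (self.simulate is None):
            raise ValueError("provide exactly one of input_stack or simulate")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        # fingerprint the analysis parameters; output location is not part
        # of the scientific configuration
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class QuantReport:
    """All quantities computed for one well."""

    coverage: pd.DataFrame
    coverage_rois: pd.DataFrame | None
    total_ec: dict
    proliferation: pd.DataFrame
    layering: pd.DataFrame
    profiles: pd.DataFrame
    alignment: dict
    shear: dict
    missing_channels: tuple[str, ...]
    provenance: dict


def _header(config: PipelineConfig) -> list[str]:
    return [
        f"vesselwell {__version__}",
        f"config_hash {config.config_hash()}",
        f"seed {config.seed}",
    ]


def run_pipeline(
    config: PipelineConfig, write: bool = True
) -> tuple[QuantReport, RegionLabelMap, WellGeometry]:
    """Execute the full analysis for one well and write artifacts.

    Returns the report, the segmented label map, and the fitted geometry.
    With ``write=False`` nothing is written to disk.
    """
    logging.basicConfig(level=config.log_level, format="%(name)s %(message)s")
    outdir = Path(config.output_dir)

    gt = None
    if config.simulate is not None:
        from .synthetic import SceneConfig, generate_scene

        scene_cfg = SceneConfig.from_dict({**config.simulate, "seed": config.seed})
        log.info("stage=simulate model=%s seed=%d", scene_cfg.model, config.seed)
        stack, gt = generate_scene(scene_cfg)
        geom = scene_cfg.geometry().with_split(config.split_fraction)
    else:
        try:
            stack = read_stack(config.input_stack)
        except Exception as exc:
            raise StageError("read_stack", str(config.input_stack), exc) from exc
        log.info("stage=read_stack channels=%s", ",".join(stack.channel_names))
        try:
            geom = fit_well(
                stack.data,
                pixel_size_um=stack.pixel_size_um,
                split_fraction=config.split_fraction,
            )
        except Exception as exc:
            raise StageError("fit_well", str(config.input_stack), exc) from exc

    fingerprint = config.config_hash()

    try:
        ec = stack.channel("EC")
        ec_mask = binarize_ec(ec, geom, config.segmentation)
        labelmap = classify_regions(ec_mask, geom, config.segmentation)
    except Exception as exc:
        raise StageError("segmentation", fingerprint, exc) from exc
    log.info("stage=segmentation done")

    try:
        if config.use_ground_truth_nuclei and gt is not None:
            nuclei = gt.nuclei.copy()
        else:
            nuclei = detect_nuclei(
                stack.channel("DAPI"),
                stack.get("ERG1"),
                stack.get("Ki67"),
                geom,
                config.nucleus_detection,
            )
        nuclei = assign_nuclei(nuclei, labelmap, geom)
    except Exception as exc:
        raise StageError("detect_nuclei", fingerprint, exc) from exc
    log.info("stage=detect_nuclei n=%d", len(nuclei))

    try:
        cov = coverage_fractions(labelmap, geom, config.n_sector_rois)
        prolif = proliferation_by_region(nuclei, n_min=config.n_min_nuclei)
        layering = smc_layering_index(stack.channel("SMC"), labelmap, geom)
        profiles = radial_profiles(
            stack.get("SMC"), stack.get("Fn"), labelmap, geom, config.n_bins
        )
        align = alignment_order(ec, labelmap, geom)
    except Exception as exc:
        raise StageError("quantify", fingerprint, exc) from exc
    log.info("stage=quantify done")

    shear = zone_shear_summary(config.shear, geom)

    report = QuantReport(
        coverage=cov["table"],
        coverage_rois=cov.get("rois"),
        total_ec=cov["total_ec"],
        proliferation=prolif,
        layering=layering,
        profiles=profiles,
        alignment=align,
        shear=shear,
        missing_channels=stack.missing_channels,
        provenance={
            "version": __version__,
            "config_hash": fingerprint,
            "seed": config.seed,
        },
    )

    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        hdr = _header(config)
        region = report.coverage.merge(
            report.proliferation, on=["zone", "region_class"]
        ).merge(report.layering, on=["zone", "region_class"])
        write_table(outdir / "region_table.csv", region, hdr)
        write_table(outdir / "profile_table.csv", report.profiles, hdr)
        if report.coverage_rois is not None:
            write_table(outdir / "roi_table.csv", report.coverage_rois, hdr)
        write_table(outdir / "nuclei.csv", nuclei, hdr)
        write_labelmap(outdir / "region_labels.png", labelmap)
        with open(outdir / "summary.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "provenance": report.provenance,
                    "total_ec": report.total_ec,
                    "alignment": {
                        k: (None if not np.isfinite(v) else float(v))
                        for k, v in report.alignment.items()
                    },
                    "shear": report.shear,
                    "missing_channels": list(report.missing_channels),
                },
                fh,
                sort_keys=False,
            )
        config.to_yaml(outdir / "config_echo.yaml")
        log.info("stage=write outdir=%s", outdir)

    return report, labelmap, geom
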