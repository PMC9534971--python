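"""Fixture scenes and recovery checks binding generator truth to pipeline output.

The fixture set spans the three coculture models (quiescent, low-density
IH, high-density) under shear and static conditions.  The recovery report
re-derives every directional pattern the models encode — defected EC layer
in the IH model versus confluent high-density layer, elevated SMC
proliferation and multilayering in defects, island gain under shear —
through the *full* pipeline (segmentation + nucleus detection +
quantification), and verifies parameter recovery (area fractions,
proliferation rates, layering index) against the generator's ground truth.

Fixture effect sizes are deliberately large so that recovery is
unambiguous at desk scale; the checks validate machinery, not biological
magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import (
    assign_nuclei,
    coverage_fractions,
    detect_nuclei,
    proliferation_by_region,
    smc_layering_index,
)
from .segmentation import SegmentationParams, binarize_ec, classify_regions
from .synthetic import SceneConfig, generate_scene, model_config, save_scene

FIXTURE_SPECS: tuple[tuple[str, str, str], ...] = (
    ("quiescent_shear", "quiescent", "shear"),
    ("quiescent_static", "quiescent", "static"),
    ("ih_shear", "IH_low_density", "shear"),
    ("ih_static", "IH_low_density", "static"),
    ("highdensity_shear", "high_density", "shear"),
    ("highdensity_static", "high_density", "static"),
)


@dataclass
class FixtureSet:
    """Named scene configurations (and optionally their on-disk paths)."""

    configs: dict[str, SceneConfig]
    paths: dict[str, dict] = field(default_factory=dict)


def fixture_configs(canvas_px: int = 768, base_seed: int = 100) -> dict[str, SceneConfig]:
    """Deterministic fixture configurations for the six model x condition cells."""
    return {
        name: model_config(model, condition, seed=base_seed + i, canvas_px=canvas_px)
        for i, (name, model, condition) in enumerate(FIXTURE_SPECS)
    }


def build_fixtures(
    outdir: str | Path, canvas_px: int = 768, base_seed: int = 100
) -> FixtureSet:
    """Generate and write the fixture scenes; bit-identical on rebuild."""
    outdir = Path(outdir)
    configs = fixture_configs(canvas_px, base_seed)
    paths = {}
    for name, cfg in configs.items():
        stack, gt = generate_scene(cfg)
        paths[name] = save_scene(outdir / name, stack, gt, stem=name)
    return FixtureSet(configs=configs, paths=paths)


@dataclass
class FixtureResult:
    config: SceneConfig
    coverage: pd.DataFrame
    total_ec: dict
    proliferation: pd.DataFrame
    layering: pd.DataFrame
    gt_fractions: dict


def analyze_fixture(
    cfg: SceneConfig, params: SegmentationParams = SegmentationParams()
) -> FixtureResult:
    """Run generation + segmentation + detection + quantification for one scene."""
    from .regions import class_fractions

    stack, gt = generate_scene(cfg)
    geom = cfg.geometry()
    mask = binarize_ec(stack.channel("EC"), geom, params)
    labelmap = classify_regions(mask, geom, params)
    nuclei = detect_nuclei(
        stack.channel("DAPI"), stack.get("ERG1"), stack.get("Ki67"), geom
    )
    nuclei = assign_nuclei(nuclei, labelmap, geom)
    cov = coverage_fractions(labelmap, geom)
    prolif = proliferation_by_region(nuclei)
    layering = smc_layering_index(stack.channel("SMC"), labelmap, geom)

    zone = geom.zone_map(gt.region_labels.shape)
    gt_fr = {
        zname: class_fractions(gt.region_labels.labels, zone == zcode)
        for zcode, zname in ((1, "center"), (2, "periphery"))
    }
    return FixtureResult(cfg, cov["table"], cov["total_ec"], prolif, layering, gt_fr)


def _cov(res: FixtureResult, zone: str, cls: str) -> float:
    t = res.coverage
    return float(
        t[(t["zone"] == zone) & (t["region_class"] == cls)]["area_fraction"].iloc[0]
    )


def _prolif(res: FixtureResult, zone: str, cls: str) -> float:
    t = res.proliferation
    return float(
        t[(t["zone"] == zone) & (t["region_class"] == cls)]["smc_prolif_pct"].iloc[0]
    )


def _layer(res: FixtureResult, zone: str, cls: str) -> float:
    t = res.layering
    return float(
        t[(t["zone"] == zone) & (t["region_class"] == cls)]["smc_intensity_norm"].iloc[0]
    )


def run_recovery_report(
    fixtures: FixtureSet | dict[str, SceneConfig] | None = None,
    params: SegmentationParams = SegmentationParams(),
) -> pd.DataFrame:
    """Evaluate all fixture invariants; returns a verdict table.

    Columns: ``check``, ``passed``, ``detail``.  An empty fixture mapping
    yields an empty report.
    """
    if fixtures is None:
        fixtures = fixture_configs()
    configs = fixtures.configs if isinstance(fixtures, FixtureSet) else dict(fixtures)
    if not configs:
        return pd.DataFrame(columns=["check", "passed", "detail"])

    results = {name: analyze_fixture(cfg, params) for name, cfg in configs.items()}
    rows: list[dict] = []

    def check(name: str, passed: bool, detail: str) -> None:
        rows.append({"check": name, "passed": bool(passed), "detail": detail})

    # ground-truth fraction fidelity for every fixture
    for name, res in results.items():
        errs = [
            abs(res.gt_fractions[z][c] - target[z])
            for c, target in (
                ("island", res.config.island_fraction),
                ("network", res.config.network_fraction),
            )
            for z in ("center", "periphery")
        ]
        check(
            f"gt_fractions_match_config[{name}]",
            max(errs) <= 0.03,
            f"max abs error {max(errs):.4f}",
        )

    # pipeline fraction recovery on every fixture
    for name, res in results.items():
        errs = []
        for z in ("center", "periphery"):
            errs.append(abs(_cov(res, z, "island") - res.config.island_fraction[z]))
            errs.append(abs(_cov(res, z, "network") - res.config.network_fraction[z]))
        check(
            f"pipeline_fraction_recovery[{name}]",
            max(errs) <= 0.05,
            f"max abs error {max(errs):.4f}",
        )

    if {"ih_shear", "highdensity_shear"} <= results.keys():
        ih, hd = results["ih_shear"], results["highdensity_shear"]
        ih_defect = _cov(ih, "periphery", "gap") + _cov(ih, "periphery", "network")
        hd_defect = _cov(hd, "periphery", "gap") + _cov(hd, "periphery", "network")
        check(
            "ih_periphery_more_defected_than_highdensity",
            ih_defect > hd_defect,
            f"IH {ih_defect:.3f} vs high-density {hd_defect:.3f}",
        )

        # proliferation pattern: defects exceed islands in both zones (IH)
        ok = all(
            _prolif(ih, z, c) > _prolif(ih, z, "island")
            for z in ("center", "periphery")
            for c in ("gap", "network")
        )
        check(
            "ih_prolif_defects_exceed_islands",
            ok,
            "; ".join(
                f"{z}:{c}={_prolif(ih, z, c):.1f}%"
                for z in ("center", "periphery")
                for c in ("island", "network", "gap")
            ),
        )

        # high-density: low everywhere except central gaps
        center_gap = _prolif(hd, "center", "gap")
        others = [
            _prolif(hd, z, c)
            for z in ("center", "periphery")
            for c in ("island", "network", "gap")
            if not (z == "center" and c == "gap")
            and np.isfinite(_prolif(hd, z, c))
        ]
        check(
            "highdensity_prolif_low_except_center_gaps",
            np.isfinite(center_gap) and all(center_gap > o for o in others),
            f"center gap {center_gap:.1f}% vs others max "
            f"{max(others):.1f}%" if others else "no other regions reported",
        )

        # layering: IH defects multilayered at periphery, high-density flat
        ih_layer = max(_layer(ih, "periphery", "gap"), _layer(ih, "periphery", "network"))
        hd_layers = [
            _layer(hd, z, c)
            for z in ("center", "periphery")
            for c in ("island", "network", "gap")
            if np.isfinite(_layer(hd, z, c))
        ]
        check(
            "ih_periphery_layering_above_1",
            ih_layer > 1.2,
            f"max defect layering {ih_layer:.2f}",
        )
        check(
            "highdensity_layering_flat",
            all(abs(v - 1.0) <= 0.2 for v in hd_layers),
            f"range [{min(hd_layers):.2f}, {max(hd_layers):.2f}]",
        )

    if {"ih_shear", "ih_static"} <= results.keys():
        sh, st = results["ih_shear"], results["ih_static"]
        isl_ok = _cov(sh, "periphery", "island") > _cov(st, "periphery", "island")
        net_ok = _cov(sh, "periphery", "network") < _cov(st, "periphery", "network")
        check(
            "shear_promotes_islands_over_networks",
            isl_ok and net_ok,
            f"island shear {_cov(sh, 'periphery', 'island'):.3f} vs static "
            f"{_cov(st, 'periphery', 'island'):.3f}; network shear "
            f"{_cov(sh, 'periphery', 'network'):.3f} vs static "
            f"{_cov(st, 'periphery', 'network'):.3f}",
        )

    return pd.DataFrame(rows)


def write_verdicts(report: pd.DataFrame, path: str | Path) -> int:
    """Write the verdict CSV; returns 0 when all checks passed, 1 otherwise."""
    report.to_csv(path, index=False)
    return 0 if bool(report["passed"].all()) else (1 if len(report) else 0)
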