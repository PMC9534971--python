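"""Synthetic scene generator: fraction targets, determinism, ground-truth
invariants, nuclei statistics, time series."""

import numpy as np
import pandas as pd
import pytest

from vesselwell.geometry import GeometryError
from vesselwell.regions import GAP, ISLAND, NETWORK, OUTSIDE, class_fractions
from vesselwell.synthetic import (
    ConfigError,
    NoiseParams,
    SceneConfig,
    generate_scene,
    generate_time_series,
    model_config,
    save_scene,
)


def _zone_fractions(cfg, gt):
    zone = cfg.geometry().zone_map(gt.region_labels.shape)
    return {
        z: class_fractions(gt.region_labels.labels, zone == code)
        for z, code in (("center", 1), ("periphery", 2))
    }


class TestFractions:
    def test_gt_fractions_hit_configured_targets(self, ih_medium):
        cfg, _, gt = ih_medium
        fr = _zone_fractions(cfg, gt)
        for z in ("center", "periphery"):
            assert fr[z]["island"] == pytest.approx(cfg.island_fraction[z], abs=0.03)
            assert fr[z]["network"] == pytest.approx(cfg.network_fraction[z], abs=0.03)

    @pytest.mark.parametrize("seed", [11, 12])
    def test_fraction_targets_for_fresh_seeds(self, seed):
        cfg = SceneConfig(
            canvas_px=512,
            well_radius_px=240,
            island_fraction={"center": 0.1, "periphery": 0.4},
            network_fraction={"center": 0.35, "periphery": 0.15},
            seed=seed,
        )
        _, gt = generate_scene(cfg)
        fr = _zone_fractions(cfg, gt)
        for z in ("center", "periphery"):
            assert fr[z]["island"] == pytest.approx(cfg.island_fraction[z], abs=0.03)
            assert fr[z]["network"] == pytest.approx(cfg.network_fraction[z], abs=0.03)

    def test_labels_partition_the_well(self, ih_small):
        cfg, _, gt = ih_small
        zone = cfg.geometry().zone_map(gt.region_labels.shape)
        labels = gt.region_labels.labels
        assert ((labels == OUTSIDE) == (zone == 0)).all()
        assert np.isin(labels[zone > 0], [GAP, ISLAND, NETWORK]).all()


class TestDeterminismAndDegenerate:
    def test_same_seed_bit_identical(self):
        cfg = model_config("IH_low_density", "shear", seed=9, canvas_px=384)
        s1, g1 = generate_scene(cfg)
        s2, g2 = generate_scene(cfg)
        assert np.array_equal(s1.data, s2.data)
        assert np.array_equal(g1.region_labels.labels, g2.region_labels.labels)
        pd.testing.assert_frame_equal(g1.nuclei, g2.nuclei)

    def test_different_seed_differs(self):
        a, _ = generate_scene(model_config("IH_low_density", "shear", seed=1, canvas_px=384))
        b, _ = generate_scene(model_config("IH_low_density", "shear", seed=2, canvas_px=384))
        assert not np.array_equal(a.data, b.data)

    def test_empty_ec_scene_is_background_only(self):
        cfg = SceneConfig(
            canvas_px=384, well_radius_px=180, island_fraction=0.0, network_fraction=0.0, seed=5
        )
        stack, gt = generate_scene(cfg)
        assert int(gt.nuclei["is_EC"].sum()) == 0
        ec = stack.channel("EC")
        inwell = cfg.geometry().zone_map(ec.shape) > 0
        # EC channel carries only background + noise
        assert float(np.median(ec[inwell])) < 3 * cfg.noise.background_level

    def test_well_larger_than_canvas_rejected(self):
        with pytest.raises(GeometryError):
            SceneConfig(canvas_px=256, well_radius_px=200)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(island_fraction=0.7, network_fraction=0.5),
            dict(island_fraction=-0.1),
            dict(corrugation_multiplier=0.5),
            dict(model="mystery"),
            dict(condition="vortex"),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises((ConfigError, ValueError)):
            SceneConfig(canvas_px=384, well_radius_px=180, **bad)


class TestGroundTruthInvariants:
    def test_corrugation_only_under_defects(self, ih_medium):
        _, _, gt = ih_medium
        island = gt.region_labels.labels == ISLAND
        assert not (gt.corrugation_mask & island).any()

    def test_fibronectin_restricted_to_defects(self, ih_medium):
        _, _, gt = ih_medium
        island = gt.region_labels.labels == ISLAND
        assert not (gt.fn_mask & island).any()
        assert gt.fn_mask.any()

    def test_ec_nuclei_only_under_ec_signal(self, ih_medium):
        _, _, gt = ih_medium
        ec_nuc = gt.nuclei[gt.nuclei["is_EC"]]
        assert set(ec_nuc["region_class"]) <= {"island", "network"}

    def test_smc_nuclei_present_under_all_classes(self, ih_medium):
        _, _, gt = ih_medium
        smc = gt.nuclei[~gt.nuclei["is_EC"]]
        counts = smc.groupby("region_class").size()
        assert set(counts.index) >= {"island", "network", "gap"}
        assert (counts >= 20).all()

    def test_prolif_rates_concentrate_on_targets(self, ih_medium):
        # binomial concentration: empirical rate within 3 SD of the target
        cfg, _, gt = ih_medium
        smc = gt.nuclei[~gt.nuclei["is_EC"]]
        for (z, c), grp in smc.groupby(["zone", "region_class"]):
            p = cfg.prolif_rates[z][c]
            n = len(grp)
            if n < 200:
                continue
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(grp["is_proliferative"].mean() - p) <= 3 * sd + 1e-9

    def test_global_gain_leaves_ground_truth_unchanged(self):
        # gain acts on the rendered channels only; ground truth depends on
        # the configuration alone
        cfg = model_config("IH_low_density", "shear", seed=4, canvas_px=384)
        stack, gt = generate_scene(cfg)
        scaled = stack.data * 1.7
        assert scaled.shape == stack.data.shape
        _, gt2 = generate_scene(cfg)
        assert np.array_equal(gt.region_labels.labels, gt2.region_labels.labels)


class TestTimeSeries:
    SCHEDULE = [
        {"island_fraction": 0.05, "network_fraction": 0.45},
        {"island_fraction": 0.25, "network_fraction": 0.25},
        {"island_fraction": 0.40, "network_fraction": 0.10},
    ]

    def test_fractions_follow_schedule(self):
        base = model_config("IH_low_density", "shear", seed=3, canvas_px=384)
        series = generate_time_series(base, self.SCHEDULE, conserve_total=True)
        assert len(series) == 3
        for (_, gt), day in zip(series, self.SCHEDULE):
            fr = class_fractions(gt.region_labels.labels)
            assert fr["island"] == pytest.approx(day["island_fraction"], abs=0.03)
            assert fr["network"] == pytest.approx(day["network_fraction"], abs=0.03)

    def test_single_entry_equals_generate_scene(self):
        base = model_config("IH_low_density", "shear", seed=3, canvas_px=384)
        (stack, _), = generate_time_series(base, [{}])
        ref, _ = generate_scene(base)
        assert np.array_equal(stack.data, ref.data)

    def test_decreasing_island_rejected_under_transition(self):
        base = model_config("IH_low_density", "shear", seed=3, canvas_px=384)
        bad = [{"island_fraction": 0.3}, {"island_fraction": 0.1}]
        with pytest.raises(ConfigError):
            generate_time_series(base, bad)

    def test_geometry_override_rejected(self):
        base = model_config("IH_low_density", "shear", seed=3, canvas_px=384)
        with pytest.raises(ConfigError):
            generate_time_series(base, [{"well_radius_px": 100}])

    def test_empty_schedule_rejected(self):
        base = model_config("IH_low_density", "shear", seed=3, canvas_px=384)
        with pytest.raises(ConfigError):
            generate_time_series(base, [])


def test_config_yaml_round_trip(tmp_path):
    cfg = model_config("high_density", "static", seed=7, canvas_px=384)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    assert SceneConfig.from_yaml(path) == cfg


def test_save_scene_writes_all_artifacts(tmp_path, ih_small):
    cfg, stack, gt = ih_small
    paths = save_scene(tmp_path, stack, gt)
    for key in ("stack", "labels", "nuclei", "config"):
        assert paths[key].exists()
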