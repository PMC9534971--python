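"""Region quantification: coverage, nuclei, proliferation, layering,
profiles, and group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial import cKDTree

from vesselwell.geometry import WellGeometry
from vesselwell.quantify import (
    QuantError,
    assign_nuclei,
    compare_groups,
    coverage_fractions,
    detect_nuclei,
    p_to_stars,
    proliferation_by_region,
    radial_profiles,
    smc_layering_index,
)
from vesselwell.regions import GAP, ISLAND, NETWORK, OUTSIDE
from vesselwell.synthetic import NoiseParams, SceneConfig, generate_scene, model_config


@pytest.fixture(scope="module")
def gt_labelmap_geom(ih_medium):
    cfg, stack, gt = ih_medium
    return cfg, stack, gt, cfg.geometry()


class TestCoverage:
    def test_fractions_match_gt_exactly(self, gt_labelmap_geom):
        cfg, _, gt, geom = gt_labelmap_geom
        cov = coverage_fractions(gt.region_labels, geom)
        t = cov["table"]
        for z in ("center", "periphery"):
            for cname, target in (
                ("island", cfg.island_fraction[z]),
                ("network", cfg.network_fraction[z]),
            ):
                got = float(
                    t[(t["zone"] == z) & (t["region_class"] == cname)]["area_fraction"].iloc[0]
                )
                assert got == pytest.approx(target, abs=0.005)
            zone_sum = t[t["zone"] == z]["area_fraction"].sum()
            assert zone_sum == pytest.approx(1.0, abs=1e-12)

    def test_total_ec_is_island_plus_network(self, gt_labelmap_geom):
        cfg, _, gt, geom = gt_labelmap_geom
        cov = coverage_fractions(gt.region_labels, geom)
        t = cov["table"]
        for z in ("center", "periphery"):
            parts = {
                c: float(
                    t[(t["zone"] == z) & (t["region_class"] == c)]["area_fraction"].iloc[0]
                )
                for c in ("island", "network")
            }
            assert cov["total_ec"][z] == pytest.approx(parts["island"] + parts["network"])

    def test_all_gap_map(self):
        geom = WellGeometry((192.0, 192.0), 180.0)
        labels = np.full((384, 384), OUTSIDE, dtype=np.uint8)
        labels[geom.zone_map(labels.shape) > 0] = GAP
        t = coverage_fractions(labels, geom)["table"]
        gaps = t[t["region_class"] == "gap"]["area_fraction"]
        assert (gaps == 1.0).all()

    def test_sector_rois_reported(self, gt_labelmap_geom):
        _, _, gt, geom = gt_labelmap_geom
        rois = coverage_fractions(gt.region_labels, geom, n_sector_rois=8)["rois"]
        assert set(rois["zone"]) == {"center", "periphery"}
        assert rois.groupby(["zone", "roi"])["area_fraction"].sum().round(9).eq(1.0).all()


class TestNuclei:
    def test_detection_recall_precision_on_resolvable_scene(self):
        cfg = model_config(
            "monoculture_SMC", "shear", seed=5, canvas_px=1024, smc_cell_diameter_um=55.0
        )
        stack, gt = generate_scene(cfg)
        det = detect_nuclei(
            stack.channel("DAPI"), stack.channel("ERG1"), stack.channel("Ki67"), cfg.geometry()
        )
        assert len(gt.nuclei) >= 2500
        d, _ = cKDTree(det[["x_px", "y_px"]].to_numpy()).query(
            gt.nuclei[["x_px", "y_px"]].to_numpy(), k=1
        )
        recall = (d <= 5).mean()
        d2, _ = cKDTree(gt.nuclei[["x_px", "y_px"]].to_numpy()).query(
            det[["x_px", "y_px"]].to_numpy(), k=1
        )
        precision = (d2 <= 5).mean()
        assert recall >= 0.9 and precision >= 0.9

    def test_marker_flags_accurate_on_coculture(self, gt_labelmap_geom):
        _, stack, gt, geom = gt_labelmap_geom
        det = detect_nuclei(
            stack.channel("DAPI"), stack.channel("ERG1"), stack.channel("Ki67"), geom
        )
        d, idx = cKDTree(det[["x_px", "y_px"]].to_numpy()).query(
            gt.nuclei[["x_px", "y_px"]].to_numpy(), k=1
        )
        matched = d <= 3
        gm = gt.nuclei[matched]
        dm = det.iloc[idx[matched]]
        ec_acc = (gm["is_EC"].to_numpy() == dm["is_EC"].to_numpy()).mean()
        assert ec_acc >= 0.95

    def test_blank_channels_give_empty_table(self):
        geom = WellGeometry((192.0, 192.0), 180.0)
        rng = np.random.default_rng(0)
        blank = 8 + rng.normal(0, 2, (384, 384))
        det = detect_nuclei(blank, blank, blank, geom)
        assert len(det) == 0

    def test_missing_marker_channels_yield_false_flags(self, ih_small):
        cfg, stack, _ = ih_small
        det = detect_nuclei(stack.channel("DAPI"), None, None, cfg.geometry())
        assert len(det) > 0
        assert not det["is_EC"].any()
        assert not det["is_proliferative"].any()


class TestProliferation:
    def test_simple_ratio(self):
        nuclei = pd.DataFrame(
            {
                "x_px": np.zeros(100),
                "y_px": np.zeros(100),
                "is_EC": False,
                "is_proliferative": [True] * 10 + [False] * 90,
                "zone": "periphery",
                "region_class": "gap",
            }
        )
        t = proliferation_by_region(nuclei)
        row = t[(t["zone"] == "periphery") & (t["region_class"] == "gap")]
        assert float(row["smc_prolif_pct"].iloc[0]) == pytest.approx(10.0)

    def test_recovers_configured_rates_within_binomial_error(self, gt_labelmap_geom):
        cfg, _, gt, _ = gt_labelmap_geom
        t = proliferation_by_region(gt.nuclei)
        for _, row in t.iterrows():
            if not np.isfinite(row["smc_prolif_pct"]) or row["n_smc"] < 200:
                continue
            p = cfg.prolif_rates[row["zone"]][row["region_class"]]
            sd = 100 * np.sqrt(p * (1 - p) / row["n_smc"])
            assert abs(row["smc_prolif_pct"] - 100 * p) <= 3 * sd

    def test_small_n_reported_missing_not_zero(self):
        nuclei = pd.DataFrame(
            {
                "x_px": [0.0] * 5,
                "y_px": [0.0] * 5,
                "is_EC": False,
                "is_proliferative": False,
                "zone": "center",
                "region_class": "island",
            }
        )
        t = proliferation_by_region(nuclei, n_min=20)
        row = t[(t["zone"] == "center") & (t["region_class"] == "island")]
        assert np.isnan(row["smc_prolif_pct"].iloc[0])
        assert int(row["n_smc"].iloc[0]) == 5

    def test_assignment_required_when_columns_absent(self):
        nuclei = pd.DataFrame({"x_px": [1.0], "y_px": [1.0], "is_EC": [False],
                               "is_proliferative": [False]})
        with pytest.raises(QuantError):
            proliferation_by_region(nuclei)


@pytest.fixture(scope="module")
def gaps_only_scene():
    cfg = SceneConfig(
        canvas_px=768,
        well_radius_px=360,
        island_fraction=0.35,
        network_fraction=0.0,
        corrugation_multiplier=2.5,
        corrugation_coverage=0.85,
        seed=4,
    )
    stack, gt = generate_scene(cfg)
    return cfg, stack, gt


class TestLayering:
    def test_corrugated_gaps_read_between_2_and_3(self, gaps_only_scene):
        cfg, stack, gt = gaps_only_scene
        t = smc_layering_index(stack.channel("SMC"), gt.region_labels, cfg.geometry())
        for z in ("center", "periphery"):
            val = float(
                t[(t["zone"] == z) & (t["region_class"] == "gap")]["smc_intensity_norm"].iloc[0]
            )
            assert 2.0 <= val <= 3.0

    def test_island_reference_is_one(self, gaps_only_scene):
        cfg, stack, gt = gaps_only_scene
        t = smc_layering_index(stack.channel("SMC"), gt.region_labels, cfg.geometry())
        islands = t[t["region_class"] == "island"]["smc_intensity_norm"]
        assert (islands == 1.0).all()

    def test_uniform_field_reads_one_everywhere(self):
        cfg = SceneConfig(
            canvas_px=768,
            well_radius_px=360,
            island_fraction=0.35,
            network_fraction=0.2,
            corrugation_coverage=0.0,
            corrugation_multiplier=1.0,
            smc_texture_amp=0.0,
            noise=NoiseParams(vignette_amplitude=0.0),
            seed=4,
        )
        stack, gt = generate_scene(cfg)
        t = smc_layering_index(stack.channel("SMC"), gt.region_labels, cfg.geometry())
        assert np.allclose(t["smc_intensity_norm"], 1.0, atol=0.02)

    def test_gain_invariance(self, gaps_only_scene):
        cfg, stack, gt = gaps_only_scene
        t1 = smc_layering_index(stack.channel("SMC"), gt.region_labels, cfg.geometry())
        t2 = smc_layering_index(2.0 * stack.channel("SMC"), gt.region_labels, cfg.geometry())
        assert np.allclose(
            t1["smc_intensity_norm"].to_numpy(dtype=float),
            t2["smc_intensity_norm"].to_numpy(dtype=float),
            equal_nan=True,
        )


class TestRadialProfiles:
    def test_minmax_scale_contract(self, gt_labelmap_geom):
        _, stack, gt, geom = gt_labelmap_geom
        df = radial_profiles(stack.channel("SMC"), stack.channel("Fn"), gt.region_labels, geom, 20)
        for col in ("smc_0_255", "fn_0_255"):
            assert float(df[col].max()) == pytest.approx(255.0)
            assert float(df[col].min()) == pytest.approx(0.0)

    def test_fn_over_smc_tracks_defected_bins(self, gt_labelmap_geom):
        # fibronectin is deposited only outside islands, so the Fn/SMC
        # ratio is higher where islands occupy less of the annulus
        _, stack, gt, geom = gt_labelmap_geom
        df = radial_profiles(stack.channel("SMC"), stack.channel("Fn"), gt.region_labels, geom, 20)
        df = df.dropna(subset=["fn_over_smc"])
        lo = df[df["frac_island"] <= df["frac_island"].quantile(0.3)]["fn_over_smc"].mean()
        hi = df[df["frac_island"] >= df["frac_island"].quantile(0.7)]["fn_over_smc"].mean()
        assert lo > hi

    def test_uniform_channels_give_flat_profiles(self):
        geom = WellGeometry((192.0, 192.0), 180.0)
        labels = np.full((384, 384), OUTSIDE, dtype=np.uint8)
        labels[geom.zone_map(labels.shape) > 0] = GAP
        flat = np.full((384, 384), 40.0)
        df = radial_profiles(flat, flat, labels, geom, 12)
        assert np.allclose(df["smc_0_255"], 0.0)

    def test_bins_ordered_rim_to_center(self, gt_labelmap_geom):
        _, stack, gt, geom = gt_labelmap_geom
        df = radial_profiles(stack.channel("SMC"), None, gt.region_labels, geom, 15)
        assert df["r_mid_px"].is_monotonic_decreasing

    def test_too_few_bins_rejected(self, gt_labelmap_geom):
        _, stack, gt, geom = gt_labelmap_geom
        with pytest.raises(QuantError):
            radial_profiles(stack.channel("SMC"), None, gt.region_labels, geom, 5)


class TestGroupComparison:
    def test_type_i_error_rate_controlled(self):
        # two samples from one distribution: ANOVA should reject rarely
        rng = np.random.default_rng(0)
        rejected = 0
        for _ in range(100):
            res = compare_groups({"a": rng.normal(0, 1, 20), "b": rng.normal(0, 1, 20)})
            rejected += res.p_value < 0.05
        assert rejected <= 10

    def test_separated_constant_groups(self):
        res = compare_groups({"a": np.zeros(3), "b": np.ones(3)})
        assert res.p_value < 1e-6
        assert not res.degenerate

    def test_tukey_adjustment_never_below_unadjusted_p(self):
        # family-wise adjustment can only raise the p of a contrast
        # relative to the unadjusted test on the same pooled-variance
        # statistic (pooled MSE over all groups, df = N - k)
        rng = np.random.default_rng(3)
        samples = {k: rng.normal(m, 1, 15) for k, m in (("a", 0), ("b", 0.5), ("c", 2))}
        arrays = list(samples.values())
        n = sum(a.size for a in arrays)
        k = len(arrays)
        mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / (n - k)
        res = compare_groups(samples)
        for _, row in res.table.iterrows():
            a, b = samples[row["group1"]], samples[row["group2"]]
            se = np.sqrt(mse * (1 / a.size + 1 / b.size))
            t_stat = abs(a.mean() - b.mean()) / se
            p_unadj = 2 * sps.t.sf(t_stat, n - k)
            assert row["p_adj"] >= p_unadj - 1e-9

    def test_fully_degenerate_reported(self):
        res = compare_groups({"a": np.zeros(3), "b": np.zeros(4)})
        assert res.degenerate
        assert np.isnan(res.p_value)

    def test_too_few_groups_or_observations_rejected(self):
        with pytest.raises(QuantError):
            compare_groups({"a": np.zeros(3)})
        with pytest.raises(QuantError):
            compare_groups({"a": np.zeros(3), "b": np.zeros(1)})

    @pytest.mark.parametrize(
        "p,stars",
        [(5e-4, "****"), (5e-3, "***"), (0.05, "**"), (0.3, "*"), (0.7, "ns"), (float("nan"), "na")],
    )
    def test_star_mapping(self, p, stars):
        assert p_to_stars(p) == stars


def test_assign_nuclei_by_centroid(ih_small):
    cfg, _, gt = ih_small
    bare = gt.nuclei[["x_px", "y_px", "is_EC", "is_proliferative"]]
    assigned = assign_nuclei(bare, gt.region_labels, cfg.geometry())
    assert (assigned["zone"].to_numpy() == gt.nuclei["zone"].to_numpy()).all()
    assert (assigned["region_class"].to_numpy() == gt.nuclei["region_class"].to_numpy()).all()
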