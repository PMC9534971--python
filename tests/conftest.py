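"""Shared synthetic scenes (session-scoped: generation is the slow part)."""

from __future__ import annotations

import pytest

from vesselwell.synthetic import generate_scene, model_config


@pytest.fixture(scope="session")
def ih_small():
    """Low-density (IH) coculture scene at 512 px, shear."""
    cfg = model_config("IH_low_density", "shear", seed=3, canvas_px=512)
    stack, gt = generate_scene(cfg)
    return cfg, stack, gt


@pytest.fixture(scope="session")
def ih_medium():
    """Low-density (IH) coculture scene at 768 px, shear."""
    cfg = model_config("IH_low_density", "shear", seed=2, canvas_px=768)
    stack, gt = generate_scene(cfg)
    return cfg, stack, gt


@pytest.fixture(scope="session")
def ih_static_medium():
    cfg = model_config("IH_low_density", "static", seed=2, canvas_px=768)
    stack, gt = generate_scene(cfg)
    return cfg, stack, gt
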