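"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

import fearcal as fc
from fearcal import synth


@pytest.fixture(scope="session")
def protocols():
    return fc.build_all_protocols(seed=2)


@pytest.fixture(scope="session")
def conditioning(protocols):
    return protocols["conditioning"]


@pytest.fixture(scope="session")
def planted_population(conditioning):
    """100 cells, half stable US + CS+ responders, half null, amplitude 3 sd."""
    cfg = synth.SynthConfig(cells_per_animal=100, seed=5)
    cfg.us_proportions = {"activated_stable": 0.5, "null": 0.5}
    cfg.cs_plus_proportions = {"stable_activated": 0.5, "null": 0.5}
    cfg.cs_minus_proportions = {"null": 1.0}
    cfg.xday_proportions = {"null": 1.0}
    pop, gt = synth.generate_population(cfg, {"conditioning": conditioning}, seed=5)
    return pop, gt


@pytest.fixture(scope="session")
def archetype_population(conditioning):
    """400 cells over six equally mixed US archetypes at amplitude 3 sd."""
    six = {a: 1 / 6 for a in ("activated_stable", "activated_down", "activated_up",
                              "inhibited_stable", "inhibited_up", "us_off")}
    cfg = synth.SynthConfig(cells_per_animal=400, seed=11)
    cfg.us_proportions = six
    cfg.cs_plus_proportions = {"null": 1.0}
    cfg.cs_minus_proportions = {"null": 1.0}
    cfg.xday_proportions = {"null": 1.0}
    pop, gt = synth.generate_population(cfg, {"conditioning": conditioning}, seed=11)
    return pop, gt, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
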