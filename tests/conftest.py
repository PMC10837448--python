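import numpy as np
import pytest

from laminar_mvpa import (
    ConditionEffect,
    SubjectConfig,
    VisualFieldGrid,
    simulate_subject,
)


def null_effects():
    """No colour information in any condition."""
    return {c: ConditionEffect(0.0, None) for c in
            ("perception", "imagery", "illusory", "amodal", "mock")}


def laminar_effects(effect=0.02):
    """Deep imagery signal, superficial illusory signal, nothing else."""
    return {
        "perception": ConditionEffect(effect, (0.0, 1.0)),
        "imagery": ConditionEffect(effect, (0.0, 0.3)),
        "illusory": ConditionEffect(effect, (0.7, 1.0)),
        "amodal": ConditionEffect(0.0, None),
        "mock": ConditionEffect(0.0, None),
    }


@pytest.fixture(scope="session")
def small_grid():
    return VisualFieldGrid(half_extent=6.0, n_pixels_per_side=16)


@pytest.fixture(scope="session")
def signal_subject():
    """One subject with the default (study-like) effect layout."""
    cfg = SubjectConfig(n_columns=16, grid=VisualFieldGrid(6.0, 16))
    return simulate_subject(cfg, seed=11)


@pytest.fixture(scope="session")
def null_subject():
    cfg = SubjectConfig(
        n_columns=16, grid=VisualFieldGrid(6.0, 16), effects=null_effects()
    )
    return simulate_subject(cfg, seed=12)


@pytest.fixture(scope="session")
def noiseless_laminar_subject():
    cfg = SubjectConfig(
        n_columns=12,
        grid=VisualFieldGrid(6.0, 16),
        noise_frac=0.0,
        effects=laminar_effects(),
    )
    return simulate_subject(cfg, seed=13)
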