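import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from octvit import PhantomConfig, generate_phantom


def small_phantom_config(**overrides) -> PhantomConfig:
    """A reduced-geometry phantom (same physics, fewer/smaller frames)."""
    defaults = dict(
        height_px=320,
        width_px=512,
        n_frames=2,
        ilm_row_mean=180,
        curve_amplitude_px=10.0,
        curve_period_px=256.0,
        retina_thickness_px=80,
        rpe_thickness_px=16,
        seed=0,
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@pytest.fixture
def step_frame() -> np.ndarray:
    """Noise-free layered frame: vitreous 0.05, retina 0.6 (rows 100–140),
    RPE 0.95 (rows 141–160), dark below."""
    f = np.full((220, 64), 0.05)
    f[100:141] = 0.6
    f[141:161] = 0.95
    return f


@pytest.fixture
def small_phantom():
    cfg = small_phantom_config(
        class_counts={"isolated": 3, "non_activated": 4, "activated": 4, "complex": 3},
        seed=7,
    )
    return cfg, *generate_phantom(cfg)
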