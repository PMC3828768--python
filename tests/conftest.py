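"""Shared synthetic fixtures; everything is generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from tipulse import SynthConfig, default_rois, generate_frames, generate_trace

SHORT_STIMULI = (30.0, 60.0, 90.0)


@pytest.fixture(scope="session")
def ti_trace():
    """Full-length TI trace with visual-stimulus suppression, seed 7."""
    cfg = SynthConfig.preset("ti_visual", seed=7)
    trace, gt = generate_trace(cfg)
    return cfg, trace, gt


@pytest.fixture(scope="session")
def ti_frames():
    """Short TI frame stack (3 stimuli) with startle blob."""
    cfg = SynthConfig.preset(
        "ti_visual", seed=3, duration_s=130.0, stimulus_times_s=SHORT_STIMULI
    )
    stack, gt = generate_frames(cfg)
    return cfg, stack, gt


@pytest.fixture(scope="session")
def awake_frames():
    """Short awake frame stack with spontaneous midleg movements."""
    cfg = SynthConfig.preset(
        "awake_visual", seed=2, duration_s=130.0, stimulus_times_s=SHORT_STIMULI,
        movement_times_s=(12.0, 47.0, 101.0),
    )
    stack, gt = generate_frames(cfg)
    return cfg, stack, gt


@pytest.fixture(scope="session")
def rois():
    return default_rois()


def pure_tone(freq_hz: float, fps: float = 29.97, duration_s: float = 60.0,
              amplitude: float = 10.0, baseline: float = 128.0) -> np.ndarray:
    t = np.arange(int(round(duration_s * fps))) / fps
    return baseline + amplitude * np.sin(2 * np.pi * freq_hz * t)
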