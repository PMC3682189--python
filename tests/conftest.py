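"""Shared fixtures: micro-scale synthetic subjects and configs.

All fixtures are generated programmatically; grids and ROIs are kept
small so the whole suite, including the cohort-level statistical checks,
runs quickly on one CPU.
"""

from __future__ import annotations

import numpy as np
import pytest

from mtldecode.prep import preprocess_subject
from mtldecode.synth import RoiSpec, SynthConfig, simulate_run


def single_roi_config(
    amplitude: float = 1.0,
    seed: int = 0,
    n_per_class: int = 12,
    radii: tuple[float, float, float] = (1.5, 1.5, 1.0),
) -> SynthConfig:
    """One signal-bearing HC-like ROI (11 voxels) on a 16x16x10 grid."""
    return SynthConfig(
        grid_shape=(16, 16, 10),
        n_trials_per_class=n_per_class,
        inter_trial_gap_s=3.0,
        cue_duration_s=1.0,
        signal_amplitude=amplitude,
        noise_sd=1.0,
        roi_specs=[RoiSpec("HC", "R", (8, 8, 5), radii, True)],
        seed=seed,
    )


def cohort_synth_config(n_per_class: int = 6, hc_left_silent: bool = True) -> SynthConfig:
    """Six MTL-like micro ROIs; optionally a silent (sclerotic) left HC."""
    rois = [
        RoiSpec("HC", "L", (4, 4, 4), (1.5, 1.5, 1.0), not hc_left_silent),
        RoiSpec("HC", "R", (12, 4, 4), (1.5, 1.5, 1.0), True),
        RoiSpec("EPC", "L", (4, 11, 4), (1.5, 1.5, 1.0), True),
        RoiSpec("EPC", "R", (12, 11, 4), (1.5, 1.5, 1.0), True),
        RoiSpec("PHC", "L", (4, 18, 4), (1.5, 1.5, 1.0), True),
        RoiSpec("PHC", "R", (12, 18, 4), (1.5, 1.5, 1.0), True),
    ]
    return SynthConfig(
        grid_shape=(16, 22, 8),
        n_trials_per_class=n_per_class,
        inter_trial_gap_s=3.0,
        cue_duration_s=1.0,
        signal_amplitude=1.0,
        noise_sd=1.0,
        roi_specs=rois,
    )


def decode_single_roi(amplitude: float, seed: int, n_per_class: int = 12, **decoder_kw):
    """Simulate -> preprocess -> LOTO-decode the single micro ROI."""
    from mtldecode.decoding import SearchlightDecoder

    sub = simulate_run(single_roi_config(amplitude, seed, n_per_class))
    pats = preprocess_subject(sub.run, sub.trials, sub.rois, apply_filter=False)["HC_R"]
    return SearchlightDecoder(pats, **decoder_kw).fit()


@pytest.fixture(scope="session")
def signal_subject():
    """A simulated subject with one strongly signal-bearing ROI."""
    return simulate_run(single_roi_config(amplitude=1.0, seed=11))


@pytest.fixture(scope="session")
def signal_patterns(signal_subject):
    return preprocess_subject(
        signal_subject.run, signal_subject.trials, signal_subject.rois,
        apply_filter=False,
    )["HC_R"]


@pytest.fixture(scope="session")
def null_patterns():
    """Pipeline-preprocessed patterns of a no-signal (amplitude 0) subject."""
    sub = simulate_run(single_roi_config(amplitude=0.0, seed=99))
    return preprocess_subject(sub.run, sub.trials, sub.rois, apply_filter=False)[
        "HC_R"
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
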