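"""Shared fixtures: fast stimuli and a small simulated experiment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from loudmatch import analysis, signals, synthetic

FAST_FS = 16000.0  # keeps FFT sizes small; all study bands are below 4.4 kHz


@pytest.fixture(scope="session")
def tbn250():
    return signals.make_named_stimulus("tbn250", sample_rate=FAST_FS)


@pytest.fixture(scope="session")
def uen17():
    return signals.make_named_stimulus("uen17", sample_rate=FAST_FS)


@pytest.fixture(scope="session")
def small_experiment() -> pd.DataFrame:
    """Default scenario, 6 subjects per site (3 cross-site), full factorial."""
    return synthetic.simulate_default_experiment(
        seed=7,
        n_per_site=6,
        cross_site_subjects=3,
        stim_config=synthetic.StimulusConfig(sample_rate=FAST_FS),
    )


@pytest.fixture(scope="session")
def small_mismatch(small_experiment) -> pd.DataFrame:
    return analysis.compute_mismatch(small_experiment)


def make_mismatch_frame(
    n_subjects: int = 8,
    effects=None,
    noise_sd: float = 1.0,
    seed: int = 0,
    rooms=synthetic.ROOM_SITES,
    stimuli=synthetic.STIMULI,
    modes=synthetic.MODES,
) -> pd.DataFrame:
    """Hand-built mismatch table: optional per-(room, stimulus, mode) shifts plus noise."""
    rng = np.random.default_rng(seed)
    effects = effects or {}
    rows = []
    for s in range(n_subjects):
        for room in rooms:
            for stim in stimuli:
                for mode in modes:
                    shift = effects.get((room, stim, mode), 0.0)
                    rows.append(
                        (
                            f"S{s:02d}",
                            synthetic.ROOM_SITES.get(room, ""),
                            room,
                            stim,
                            mode,
                            shift + rng.normal(0, noise_sd),
                        )
                    )
    return pd.DataFrame(
        rows, columns=["subject", "site", "room", "stimulus", "mode", "mismatch"]
    )
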