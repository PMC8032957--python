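"""Binaural presentation modes with prescribed interaural coherence (IC).

The headphone stimulus is presented in one of four modes: monaural (left
ear only), diotic (IC = 1), uncorrelated (IC = 0), or IC-matched, where the
interaural coherence is matched to that measured for loudspeaker
presentation in the room.  Intermediate coherences are produced by mixing
two independent noises.  Two generator variants are provided:

* ``symmetric_generator`` — left/right are sum and difference mixtures of
  the two noises with weights sqrt((1±c)/2);
* ``left_preserving_generator`` — the left channel is the original
  stimulus itself (matching the convention that the loudspeaker signal is
  identical to the left-ear headphone signal) and the right channel is
  ``c*s + sqrt(1-c^2)*n2``.

The left-preserving variant is the default in experiment simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from loudmatch.signals import AnalysisWindow, Stimulus

MODES = ("monaural", "diotic", "ic_matched", "uncorrelated")

#: deterministic seed offset for the independent right-channel noise
RIGHT_CHANNEL_SEED_OFFSET = 1000


@dataclass(frozen=True)
class CoherenceProfile:
    """Per-third-octave-band interaural coherence of a room.

    ``spread`` optionally records the standard deviation of the coherence
    across measurement positions around the reference head position.
    """

    band_centers: tuple[float, ...]
    ic_values: tuple[float, ...]
    spread: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.band_centers) != len(self.ic_values):
            raise ValueError("band_centers and ic_values must have equal length")
        if self.spread is not None and len(self.spread) != len(self.ic_values):
            raise ValueError("spread length mismatch")
        if any(abs(v) > 1 for v in self.ic_values):
            raise ValueError("|interaural coherence| cannot exceed 1")

    def at(self, frequency: float) -> float:
        """Coherence at a frequency, log-frequency interpolation between bands."""
        centers = np.asarray(self.band_centers)
        return float(
            np.interp(np.log2(frequency), np.log2(centers), np.asarray(self.ic_values))
        )

    def stimulus_coherence(self, stimulus: Stimulus) -> float:
        """Scalar coherence for a stimulus.

        Narrowband: profile value at the center frequency.  Broadband: the
        energy-weighted mean across the stimulus bands — with equal band
        energies this is the plain mean of the per-band profile values.
        """
        if stimulus.band_spec.kind == "third_octave":
            return self.at(stimulus.band_spec.center_frequency)
        edges = np.asarray(stimulus.band_spec.band_edges)
        centers = np.sqrt(edges[:-1] * edges[1:])
        vals = np.array([self.at(f) for f in centers])
        return float(np.mean(vals))  # equal band energies by construction


@dataclass
class BinauralStimulus:
    """Left/right channel pair with its presentation mode and target IC."""

    left: Stimulus
    right: Stimulus
    mode: str
    target_ic: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.left.sample_rate != self.right.sample_rate:
            raise ValueError("channels must share the sample rate")
        if self.left.samples.size != self.right.samples.size:
            raise ValueError("channels must share the length")


def _check_pair(n1: np.ndarray, n2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if n1.shape != n2.shape:
        raise ValueError("the two noises must have the same length")
    return n1, n2


def symmetric_generator(
    n1: np.ndarray, n2: np.ndarray, target_ic: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mix two independent noises into a pair with expected correlation c.

    left = a*n1 + b*n2, right = a*n1 - b*n2 with a = sqrt((1+c)/2) and
    b = sqrt((1-c)/2); each channel keeps the input variance.
    """
    n1, n2 = _check_pair(n1, n2)
    c = float(target_ic)
    if not (0 <= c <= 1):
        raise ValueError("target coherence must lie in [0, 1]")
    a = np.sqrt((1 + c) / 2)
    b = np.sqrt((1 - c) / 2)
    return a * n1 + b * n2, a * n1 - b * n2


def left_preserving_generator(
    s: np.ndarray, n2: np.ndarray, target_ic: float
) -> tuple[np.ndarray, np.ndarray]:
    """Coherence generator that leaves the left channel equal to ``s``.

    right = c*s + sqrt(1-c^2)*n2, so the right channel keeps the variance
    of ``s`` (for equal-variance inputs) and correlates with it at c.
    """
    s, n2 = _check_pair(s, n2)
    c = float(target_ic)
    if not (0 <= c <= 1):
        raise ValueError("target coherence must lie in [0, 1]")
    return s.copy(), c * s + np.sqrt(1 - c**2) * n2


def _matched_noise(stimulus: Stimulus, seed: int) -> Stimulus:
    """Independent noise with the same band spec, duration and RMS."""
    from loudmatch import signals as _sig

    spec = stimulus.band_spec
    if spec.kind == "third_octave":
        fresh = _sig.make_third_octave_noise(
            spec.center_frequency, stimulus.duration, stimulus.sample_rate, seed
        )
    else:
        fresh = _sig.make_uen(
            spec.band_edges, stimulus.duration, stimulus.sample_rate, seed
        )
    rms = np.sqrt(np.mean(stimulus.samples**2))
    fresh_rms = np.sqrt(np.mean(fresh.samples**2))
    fresh = replace(fresh, samples=fresh.samples * (rms / fresh_rms))
    if stimulus.ramp_duration > 0:
        fresh = _sig.apply_ramps(fresh, stimulus.ramp_duration)
    return fresh


def make_presentation(
    stimulus: Stimulus,
    mode: str,
    room_profile: CoherenceProfile | float | None = None,
    seed: int | None = None,
    generator: str = "left_preserving",
) -> BinauralStimulus:
    """Route a stimulus through one of the four headphone presentation modes.

    ``room_profile`` (a :class:`CoherenceProfile` or a scalar coherence) is
    required for the ``ic_matched`` mode.  The independent right-channel
    noise is seeded deterministically from the stimulus seed.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if seed is None:
        seed = stimulus.rng_seed + RIGHT_CHANNEL_SEED_OFFSET

    if mode == "monaural":
        silent = replace(stimulus, samples=np.zeros_like(stimulus.samples))
        return BinauralStimulus(stimulus, silent, mode, target_ic=None)
    if mode == "diotic":
        return BinauralStimulus(
            stimulus, replace(stimulus, samples=stimulus.samples.copy()), mode, 1.0
        )

    if mode == "uncorrelated":
        c = 0.0
    else:  # ic_matched
        if room_profile is None:
            raise ValueError("ic_matched mode requires a room coherence profile")
        if isinstance(room_profile, CoherenceProfile):
            c = room_profile.stimulus_coherence(stimulus)
        else:
            c = float(room_profile)
        c = min(max(c, 0.0), 1.0)

    n2 = _matched_noise(stimulus, seed)
    if generator == "left_preserving":
        left, right = left_preserving_generator(stimulus.samples, n2.samples, c)
    elif generator == "symmetric":
        left, right = symmetric_generator(stimulus.samples, n2.samples, c)
    else:
        raise ValueError(f"unknown generator {generator!r}")
    return BinauralStimulus(
        replace(stimulus, samples=left), replace(stimulus, samples=right), mode, c
    )


def zero_lag_ic(
    left: np.ndarray | Stimulus,
    right: np.ndarray | Stimulus,
    window: AnalysisWindow | None = None,
    sample_rate: float | None = None,
) -> float:
    """Normalized zero-lag cross-correlation (Pearson r) of the two channels."""
    if isinstance(left, Stimulus):
        sample_rate = left.sample_rate
        if window is None:
            window = left.default_window()
        left = left.samples
    if isinstance(right, Stimulus):
        right = right.samples
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.size != right.size:
        raise ValueError("channels must have equal length")
    if window is not None:
        sl = window.indices(left.size, sample_rate)
        left, right = left[sl], right[sl]
    if np.all(left == 0) or np.all(right == 0):
        raise ValueError("cannot estimate coherence of a silent channel")
    left = left - left.mean()
    right = right - right.mean()
    return float(np.dot(left, right) / np.sqrt(np.dot(left, left) * np.dot(right, right)))


def iacc(
    left: np.ndarray, right: np.ndarray, sample_rate: float, max_lag: float = 0.001
) -> float:
    """Interaural cross-correlation coefficient over lags within ±max_lag s.

    The room-acoustics convention: maximum of the absolute normalized
    cross-correlation over a small lag range (default ±1 ms).
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.size != right.size:
        raise ValueError("channels must have equal length")
    if max_lag >= left.size / sample_rate:
        raise ValueError("max_lag must be shorter than the signal duration")
    left = left - left.mean()
    right = right - right.mean()
    norm = np.sqrt(np.dot(left, left) * np.dot(right, right))
    if norm == 0:
        raise ValueError("cannot estimate IACC of a silent channel")
    n_lag = int(round(max_lag * sample_rate))
    best = 0.0
    for lag in range(-n_lag, n_lag + 1):
        if lag >= 0:
            c = np.dot(left[lag:], right[: right.size - lag])
        else:
            c = np.dot(left[:lag], right[-lag:])
        best = max(best, abs(c) / norm)
    return float(best)


def band_ic_profile(
    left: np.ndarray,
    right: np.ndarray,
    sample_rate: float,
    band_centers: tuple[float, ...],
    max_lag: float = 0.001,
) -> CoherenceProfile:
    """IACC per third-octave band: band-filter both channels, then correlate."""
    from scipy.signal import butter, sosfiltfilt

    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    values = []
    for fc in band_centers:
        lo, hi = fc * 2 ** (-1 / 6), fc * 2 ** (1 / 6)
        if hi >= sample_rate / 2:
            raise ValueError(f"band at {fc:.0f} Hz exceeds the Nyquist frequency")
        sos = butter(4, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
        lb = sosfiltfilt(sos, left)
        rb = sosfiltfilt(sos, right)
        values.append(iacc(lb, rb, sample_rate, max_lag))
    return CoherenceProfile(tuple(band_centers), tuple(values))
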