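"""Stimulus synthesis, ramping, level calibration and equal-loudness contours.

Four stimuli are used throughout: three one-third-octave band noises with
center frequencies 250 Hz, 1 kHz and 4 kHz (``tbn250``, ``tbn1000``,
``tbn4000``) and a broadband "unified excitation noise" with equal energy in
17 critical (Bark) bands (``uen17``).  Noises are synthesised in the
frequency domain — independent complex-Gaussian bins inside the band, zero
outside — which gives exact band limits and a naturally fluctuating temporal
envelope (the narrowband envelopes are deliberately not flattened).

Levels are expressed in dB SPL re 20 µPa and always computed over an
analysis window that excludes the onset/offset ramps and, optionally, a
reverberant tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

P_REF = 20e-6
"""Reference pressure, 20 µPa."""

#: Zwicker critical-band (Bark) edges for bands 2-18: 17 bands spanning
#: 100 Hz ... 4.4 kHz, the default band set of the broadband stimulus.
ZWICKER_CB_EDGES_17 = (
    100.0, 200.0, 300.0, 400.0, 510.0, 630.0, 770.0, 920.0, 1080.0,
    1270.0, 1480.0, 1720.0, 2000.0, 2320.0, 2700.0, 3150.0, 3700.0, 4400.0,
)

#: Pure-tone frequency used for the 65-phon calibration of each stimulus
#: (the broadband noise is calibrated at 1 kHz).
CALIBRATION_FREQUENCY = {
    "tbn250": 250.0,
    "tbn1000": 1000.0,
    "tbn4000": 4000.0,
    "uen17": 1000.0,
}

#: Frozen-stimulus seeds: the same waveform is reused across trials of a
#: condition, only its level changes.
DEFAULT_STIMULUS_SEEDS = {"tbn250": 11, "tbn1000": 12, "tbn4000": 13, "uen17": 14}

DEFAULT_SAMPLE_RATE = 44100.0
DEFAULT_DURATION = 1.0
DEFAULT_RAMP = 0.020


@dataclass(frozen=True)
class BandSpec:
    """Spectral support of a stimulus.

    ``third_octave`` bands have edges ``fc * 2**(-1/6)`` and
    ``fc * 2**(+1/6)``; ``critical_band_union`` stimuli carry an ascending
    list of band edges whose union is the spectral support.
    """

    kind: str  # "third_octave" | "critical_band_union"
    center_frequency: float | None = None
    band_edges: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind == "third_octave":
            if self.center_frequency is None or self.center_frequency <= 0:
                raise ValueError("third_octave band requires a positive center frequency")
        elif self.kind == "critical_band_union":
            edges = np.asarray(self.band_edges, dtype=float)
            if edges.ndim != 1 or edges.size < 2:
                raise ValueError("critical_band_union requires at least two band edges")
            if np.any(np.diff(edges) <= 0):
                raise ValueError("band edges must be strictly ascending")
        else:
            raise ValueError(f"unknown band kind {self.kind!r}")

    @property
    def edges(self) -> tuple[float, float]:
        """Overall (lowest, highest) edge of the spectral support in Hz."""
        if self.kind == "third_octave":
            fc = float(self.center_frequency)
            return fc * 2 ** (-1 / 6), fc * 2 ** (1 / 6)
        return float(self.band_edges[0]), float(self.band_edges[-1])


@dataclass(frozen=True)
class AnalysisWindow:
    """Time window over which levels are computed, in seconds.

    Ramps and possible reverberant tails are excluded from all level
    calculations; ``tail_exclusion`` extends the excluded region before the
    fall ramp (used for room-convolved signals).
    """

    start: float
    end: float
    excludes_ramps: bool = True
    tail_exclusion: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid analysis window [{self.start}, {self.end}]")
        if self.tail_exclusion < 0:
            raise ValueError("tail_exclusion must be >= 0")

    def indices(self, n_samples: int, sample_rate: float) -> slice:
        """Sample slice of the window (tail exclusion shortens the end)."""
        i0 = int(round(self.start * sample_rate))
        i1 = int(round((self.end - self.tail_exclusion) * sample_rate))
        i1 = min(i1, n_samples)
        if i1 <= i0:
            raise ValueError("analysis window is empty for this signal")
        return slice(i0, i1)


@dataclass
class Stimulus:
    """A (possibly calibrated) noise waveform with its synthesis metadata."""

    samples: np.ndarray
    sample_rate: float
    band_spec: BandSpec
    rng_seed: int
    name: str = "custom"
    ramp_duration: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("stimulus samples must be finite")
        if self.duration < 2 * self.ramp_duration:
            raise ValueError("total duration must be at least twice the ramp duration")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def default_window(self, tail_exclusion: float = 0.0) -> AnalysisWindow:
        """Analysis window excluding the ramps (and an optional tail)."""
        return AnalysisWindow(
            start=self.ramp_duration,
            end=self.duration - self.ramp_duration,
            excludes_ramps=True,
            tail_exclusion=tail_exclusion,
        )


def _band_noise_spectrum(
    freqs: np.ndarray, bands: Sequence[tuple[float, float]], rng: np.random.Generator
) -> np.ndarray:
    """Half-spectrum with unit total power per band, zero outside all bands."""
    spec = np.zeros(freqs.size, dtype=complex)
    for f_lo, f_hi in bands:
        sel = (freqs >= f_lo) & (freqs < f_hi)
        n_bins = int(np.count_nonzero(sel))
        if n_bins == 0:
            raise ValueError(f"band [{f_lo:.1f}, {f_hi:.1f}] Hz contains no FFT bins")
        z = rng.standard_normal(n_bins) + 1j * rng.standard_normal(n_bins)
        # exact per-band power normalisation -> equal realised band energies
        z /= np.sqrt(np.sum(np.abs(z) ** 2))
        spec[sel] = z
    return spec


def _synthesize(
    bands: Sequence[tuple[float, float]],
    duration: float,
    sample_rate: float,
    seed: int,
) -> np.ndarray:
    if duration <= 0:
        raise ValueError("duration must be positive")
    nyquist = sample_rate / 2
    for f_lo, f_hi in bands:
        if f_hi >= nyquist:
            raise ValueError(
                f"band edge {f_hi:.1f} Hz is not below the Nyquist frequency "
                f"({nyquist:.1f} Hz at fs={sample_rate:.0f} Hz)"
            )
    n = int(round(duration * sample_rate))
    freqs = np.fft.rfftfreq(n, 1 / sample_rate)
    rng = np.random.default_rng(seed)
    spec = _band_noise_spectrum(freqs, bands, rng)
    x = np.fft.irfft(spec, n=n)
    # normalise to unit RMS; absolute level is set later by calibrate_level
    return x / np.sqrt(np.mean(x**2))


def make_third_octave_noise(
    center_frequency: float,
    duration: float = DEFAULT_DURATION,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
    name: str = "custom",
) -> Stimulus:
    """One-third-octave band noise with a naturally fluctuating envelope.

    Spectral energy is confined exactly to ``[fc * 2**(-1/6), fc * 2**(1/6)]``;
    the same seed yields a bit-identical waveform.
    """
    spec = BandSpec("third_octave", center_frequency=center_frequency)
    x = _synthesize([spec.edges], duration, sample_rate, seed)
    return Stimulus(x, sample_rate, spec, seed, name=name)


def make_uen(
    band_edges: Sequence[float] = ZWICKER_CB_EDGES_17,
    duration: float = DEFAULT_DURATION,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
    name: str = "uen17",
) -> Stimulus:
    """Broadband noise with equal energy in each critical band.

    With the default Zwicker Bark-band edges this is the 17-band "unified
    excitation noise"; the realised energies of the bands are equalised
    exactly in the frequency domain.
    """
    spec = BandSpec("critical_band_union", band_edges=tuple(float(e) for e in band_edges))
    edges = np.asarray(spec.band_edges)
    bands = list(zip(edges[:-1], edges[1:]))
    x = _synthesize(bands, duration, sample_rate, seed)
    return Stimulus(x, sample_rate, spec, seed, name=name)


def make_named_stimulus(
    name: str,
    duration: float = DEFAULT_DURATION,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    seed: int | None = None,
    ramp_duration: float = DEFAULT_RAMP,
) -> Stimulus:
    """Build one of the four study stimuli (ramped, uncalibrated).

    ``seed=None`` uses the frozen-stimulus seed of that condition.
    """
    if name not in CALIBRATION_FREQUENCY:
        raise ValueError(f"unknown stimulus {name!r}; expected one of {sorted(CALIBRATION_FREQUENCY)}")
    if seed is None:
        seed = DEFAULT_STIMULUS_SEEDS[name]
    if name == "uen17":
        stim = make_uen(duration=duration, sample_rate=sample_rate, seed=seed, name=name)
    else:
        fc = CALIBRATION_FREQUENCY[name]
        stim = make_third_octave_noise(fc, duration, sample_rate, seed, name=name)
    return apply_ramps(stim, ramp_duration)


def apply_ramps(stimulus: Stimulus, ramp_duration: float) -> Stimulus:
    """Apply raised-cosine (Hann) rise and fall ramps of the given duration."""
    if ramp_duration < 0:
        raise ValueError("ramp duration must be >= 0")
    if 2 * ramp_duration > stimulus.duration:
        raise ValueError("ramps longer than half the stimulus duration")
    if ramp_duration == 0:
        return replace(stimulus, samples=stimulus.samples.copy())
    n_ramp = int(round(ramp_duration * stimulus.sample_rate))
    x = stimulus.samples.copy()
    t = np.arange(n_ramp) / n_ramp
    gain = 0.5 * (1 - np.cos(np.pi * t))  # 0 -> 1
    x[:n_ramp] *= gain
    x[-n_ramp:] *= gain[::-1]
    return replace(stimulus, samples=x, ramp_duration=ramp_duration)


def rms_level_db(
    waveform: Stimulus | np.ndarray,
    window: AnalysisWindow | None = None,
    sample_rate: float | None = None,
) -> float:
    """Level in dB SPL re 20 µPa over the analysis window only."""
    if isinstance(waveform, Stimulus):
        if sample_rate is None:
            sample_rate = waveform.sample_rate
        if window is None:
            window = waveform.default_window()
        x = waveform.samples
    else:
        x = np.asarray(waveform, dtype=float)
        if sample_rate is None:
            raise ValueError("sample_rate is required for bare arrays")
        if window is None:
            window = AnalysisWindow(0.0, x.size / sample_rate, excludes_ramps=False)
    seg = x[window.indices(x.size, sample_rate)]
    rms = np.sqrt(np.mean(seg**2))
    if rms == 0:
        raise ValueError("analysis window is silent")
    return 20 * np.log10(rms / P_REF)


def calibrate_level(
    stimulus: Stimulus,
    target_level: float,
    window: AnalysisWindow | None = None,
) -> Stimulus:
    """Scale the waveform so its windowed RMS level equals ``target_level`` dB SPL."""
    current = rms_level_db(stimulus, window)
    scale = 10 ** ((target_level - current) / 20)
    return replace(stimulus, samples=stimulus.samples * scale)


# --- ISO 226:2003 equal-loudness contours ---------------------------------

_ISO226_F = np.array([
    20, 25, 31.5, 40, 50, 63, 80, 100, 125, 160, 200, 250, 315, 400, 500,
    630, 800, 1000, 1250, 1600, 2000, 2500, 3150, 4000, 5000, 6300, 8000,
    10000, 12500,
], dtype=float)

_ISO226_AF = np.array([
    0.532, 0.506, 0.480, 0.455, 0.432, 0.409, 0.387, 0.367, 0.349, 0.330,
    0.315, 0.301, 0.288, 0.276, 0.267, 0.259, 0.253, 0.250, 0.246, 0.244,
    0.243, 0.243, 0.243, 0.242, 0.242, 0.245, 0.254, 0.271, 0.301,
])

_ISO226_LU = np.array([
    -31.6, -27.2, -23.0, -19.1, -15.9, -13.0, -10.3, -8.1, -6.2, -4.5,
    -3.1, -2.0, -1.1, -0.4, 0.0, 0.3, 0.5, 0.0, -2.7, -4.1, -1.0, 1.7,
    2.5, 1.2, -2.1, -7.1, -11.2, -10.7, -3.1,
])

_ISO226_TF = np.array([
    78.5, 68.7, 59.5, 51.1, 44.0, 37.5, 31.5, 26.5, 22.1, 17.9, 14.4,
    11.4, 8.6, 6.2, 4.4, 3.0, 2.2, 0.0, -2.4, -3.5, -1.7, 2.5, 1.2,
    -4.2, 1.2, 1.4, -1.1, -1.6, 4.3,
])


def phon_to_spl(loudness_level: float, frequency: float) -> float:
    """Sound pressure level of a pure tone with the given loudness level.

    Implements the ISO 226:2003 equal-loudness contour equation with the
    standard's tabulated frequency parameters (``alpha_f``, ``L_U``,
    ``T_f``), linearly interpolated on a log-frequency axis between
    tabulated frequencies.  At 1 kHz the phon scale is the SPL of the
    equally loud 1 kHz tone by definition, so the identity is returned
    exactly there (the analytic contour deviates from it by < 0.1 dB).
    """
    if not (_ISO226_F[0] <= frequency <= _ISO226_F[-1]):
        raise ValueError(
            f"frequency {frequency:.1f} Hz outside the tabulated range "
            f"[{_ISO226_F[0]:.0f}, {_ISO226_F[-1]:.0f}] Hz"
        )
    if not (0 <= loudness_level <= 90):
        raise ValueError("loudness level outside the contour validity range (0-90 phon)")
    if frequency == 1000.0:
        return float(loudness_level)
    logf = np.log2(frequency)
    grid = np.log2(_ISO226_F)
    af = float(np.interp(logf, grid, _ISO226_AF))
    lu = float(np.interp(logf, grid, _ISO226_LU))
    tf = float(np.interp(logf, grid, _ISO226_TF))
    a_f = 4.47e-3 * (10 ** (0.025 * loudness_level) - 1.15) + (
        0.4 * 10 ** ((tf + lu) / 10 - 9)
    ) ** af
    return float((10.0 / af) * np.log10(a_f) - lu + 94.0)
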