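"""Eardrum sound pressure levels through transfer functions.

Headphone presentation levels are obtained by filtering the headphone
stimulus with each of the (typically eight, re-seated) headphone transfer
function (HpTF) instances, computing the RMS per instance, averaging the
RMS values, and converting to dB SPL.  Loudspeaker presentation levels are
obtained from the calibrated free-field waveform and a head-related
transfer function (HRTF): the frontal free-field HRTF in anechoic rooms,
and in reverberant rooms a "room-matched" HRTF — a power-domain weighted
average of the free-field and diffuse-field HRTF magnitudes,

    |H_room|^2 = (1 - w) |H_ff|^2 + w |H_df|^2,

whose scalar weight ``w`` is fitted per room to reference-head (KEMAR)
measurements of the stimulus levels at the eardrum, optionally extended by
a per-band heuristic correction (measured minus modeled level) for rooms
with prominent early reflections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from loudmatch.binaural import BinauralStimulus, CoherenceProfile
from loudmatch.signals import P_REF, AnalysisWindow, Stimulus, rms_level_db

logger = logging.getLogger(__name__)

TF_KINDS = ("hptf", "hrtf_free", "hrtf_diffuse", "room_matched")

#: frequency range in which the eardrum-level model is considered valid
VALID_RANGE_HZ = (250.0, 4000.0)


@dataclass
class TransferFunction:
    """A frequency response on an ascending grid covering 100 Hz - 8 kHz.

    ``response`` may be complex (phase-bearing, usable for filtering a
    waveform directly) or real non-negative (magnitude-only, e.g. after
    power averaging; applied in the spectral-energy domain with zero
    phase).  ``azimuth``/``elevation`` (degrees) identify the incidence
    direction of HRTF instances.
    """

    frequency_grid: np.ndarray
    response: np.ndarray
    kind: str
    ear: str = "left"
    reference: str = ""
    azimuth: float | None = None
    elevation: float | None = None

    def __post_init__(self) -> None:
        self.frequency_grid = np.asarray(self.frequency_grid, dtype=float)
        self.response = np.asarray(self.response)
        if self.kind not in TF_KINDS:
            raise ValueError(f"unknown transfer-function kind {self.kind!r}")
        if self.ear not in ("left", "right"):
            raise ValueError("ear must be 'left' or 'right'")
        if self.frequency_grid.ndim != 1 or np.any(np.diff(self.frequency_grid) <= 0):
            raise ValueError("frequency grid must be strictly ascending")
        if self.frequency_grid[0] > 100.0 or self.frequency_grid[-1] < 8000.0:
            raise ValueError("frequency grid must cover at least 100 Hz - 8 kHz")
        if self.response.shape != self.frequency_grid.shape:
            raise ValueError("response and frequency grid shapes differ")
        if not np.all(np.isfinite(np.abs(self.response))):
            raise ValueError("transfer-function magnitudes must be finite")
        if self.is_magnitude and np.any(self.response.real < 0):
            raise ValueError("magnitude-only responses must be non-negative")

    @property
    def is_magnitude(self) -> bool:
        return not np.iscomplexobj(self.response)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.response)

    def magnitude_at(self, frequencies: np.ndarray) -> np.ndarray:
        """Magnitude interpolated in the log-magnitude / log-frequency plane."""
        frequencies = np.asarray(frequencies, dtype=float)
        mag = np.maximum(self.magnitude, 1e-12)
        logm = np.interp(
            np.log2(np.maximum(frequencies, 1e-3)),
            np.log2(self.frequency_grid),
            20 * np.log10(mag),
        )
        return 10 ** (logm / 20)

    def sampled(self, frequencies: np.ndarray) -> np.ndarray:
        """Complex (or zero-phase) response on an arbitrary frequency grid.

        Complex responses are interpolated in magnitude and unwrapped
        phase, which preserves |H| between grid points (linear
        interpolation of real/imaginary parts would not).
        """
        if self.is_magnitude:
            return self.magnitude_at(frequencies).astype(complex)
        mag = np.interp(frequencies, self.frequency_grid, np.abs(self.response))
        phase = np.interp(
            frequencies, self.frequency_grid, np.unwrap(np.angle(self.response))
        )
        return mag * np.exp(1j * phase)


def flat_tf(gain_db: float = 0.0, kind: str = "hptf", ear: str = "left") -> TransferFunction:
    """Frequency-flat magnitude response at the given gain (test/fixture aid)."""
    grid = np.array([20.0, 100.0, 1000.0, 8000.0, 20000.0])
    return TransferFunction(grid, np.full(5, 10 ** (gain_db / 20)), kind, ear)


@dataclass
class TransferFunctionSet:
    """Instances of one transfer-function kind sharing grid and reference.

    HpTF sets hold the re-seating repetitions (eight by default); HRTF sets
    hold incidence directions.
    """

    instances: list[TransferFunction]
    subject_id: str = ""
    side: str = "left"

    def __post_init__(self) -> None:
        if not self.instances:
            raise ValueError("a transfer-function set needs at least one instance")
        grid = self.instances[0].frequency_grid
        for tf in self.instances[1:]:
            if tf.frequency_grid.shape != grid.shape or not np.allclose(
                tf.frequency_grid, grid
            ):
                raise ValueError("all instances must share the frequency grid")
            if tf.kind != self.instances[0].kind:
                raise ValueError("all instances must share the kind")

    @property
    def frequency_grid(self) -> np.ndarray:
        return self.instances[0].frequency_grid

    @property
    def kind(self) -> str:
        return self.instances[0].kind


@dataclass
class RoomModel:
    """Acoustic summary of a presentation room.

    ``mix_weight`` is the free/diffuse weight of the room-matched HRTF
    (0 = purely frontal free field, anechoic; 1 = fully diffuse);
    ``band_correction`` maps third-octave band centers (Hz) to dB offsets
    of the heuristic correction (empty = none).
    """

    name: str
    t30: float
    mix_weight: float
    band_correction: dict[float, float] = field(default_factory=dict)
    coherence_profile: CoherenceProfile | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.mix_weight <= 1):
            raise ValueError("mix weight must lie in [0, 1]")
        if self.t30 < 0:
            raise ValueError("reverberation time must be >= 0")
        if any(not np.isfinite(v) for v in self.band_correction.values()):
            raise ValueError("band corrections must be finite")

    @property
    def is_anechoic(self) -> bool:
        return self.t30 <= 0.1


@dataclass
class EardrumLevels:
    """Per-ear dB SPL at the eardrum for one source and condition."""

    left: float | None
    right: float | None
    source: str  # "headphone" | "loudspeaker"
    condition: str = ""

    def __post_init__(self) -> None:
        for v in (self.left, self.right):
            if v is not None and not np.isfinite(v):
                raise ValueError("eardrum levels must be finite where defined")


# --- averaging and the room-matched model ---------------------------------


def power_average(tf_set: TransferFunctionSet) -> TransferFunction:
    """Power-spectrum average across instances; magnitude-only result."""
    mags = np.stack([tf.magnitude for tf in tf_set.instances])
    avg = np.sqrt(np.mean(mags**2, axis=0))
    proto = tf_set.instances[0]
    return TransferFunction(
        proto.frequency_grid.copy(), avg, proto.kind, proto.ear, proto.reference
    )


def diffuse_field_hrtf(
    hrtf_set: TransferFunctionSet, solid_angle_weighted: bool = True
) -> TransferFunction:
    """Diffuse-field HRTF: power average over directions.

    With ``solid_angle_weighted`` and instances carrying elevation angles,
    each direction is weighted by cos(elevation), the solid-angle density
    of a regular azimuth-elevation grid; otherwise (or when angles are
    missing) an unweighted average is used and a warning is logged.
    """
    if len(hrtf_set.instances) < 2:
        raise ValueError("diffuse-field averaging needs at least two directions")
    mags = np.stack([tf.magnitude for tf in hrtf_set.instances])
    weights = None
    if solid_angle_weighted:
        elevations = [tf.elevation for tf in hrtf_set.instances]
        if any(e is None for e in elevations):
            logger.warning(
                "incidence angles missing; falling back to unweighted diffuse-field average"
            )
        else:
            weights = np.cos(np.radians(np.asarray(elevations, dtype=float)))
            weights = weights / weights.sum()
    if weights is None:
        avg = np.mean(mags**2, axis=0)
    else:
        avg = np.tensordot(weights, mags**2, axes=1)
    proto = hrtf_set.instances[0]
    return TransferFunction(
        proto.frequency_grid.copy(),
        np.sqrt(avg),
        "hrtf_diffuse",
        proto.ear,
        proto.reference,
    )


def _correction_db(
    band_correction: Mapping[float, float], frequencies: np.ndarray
) -> np.ndarray:
    if not band_correction:
        return np.zeros(np.asarray(frequencies).shape)
    centers = np.array(sorted(band_correction))
    offsets = np.array([band_correction[c] for c in centers])
    return np.interp(
        np.log2(np.maximum(frequencies, 1e-3)), np.log2(centers), offsets
    )


def room_matched_hrtf(
    ff: TransferFunction,
    df: TransferFunction,
    w: float,
    correction: Mapping[float, float] | None = None,
) -> TransferFunction:
    """Power-domain mix of free- and diffuse-field magnitudes plus correction."""
    if not (0 <= w <= 1):
        raise ValueError("weight must lie in [0, 1]")
    if ff.frequency_grid.shape != df.frequency_grid.shape or not np.allclose(
        ff.frequency_grid, df.frequency_grid
    ):
        raise ValueError("free- and diffuse-field responses must share the grid")
    mag = np.sqrt((1 - w) * ff.magnitude**2 + w * df.magnitude**2)
    if correction:
        mag = mag * 10 ** (_correction_db(correction, ff.frequency_grid) / 20)
    return TransferFunction(
        ff.frequency_grid.copy(), mag, "room_matched", ff.ear, ff.reference
    )


def _filtered_mean_square(x: np.ndarray, sample_rate: float, tf: TransferFunction) -> float:
    """Mean square of the TF-filtered signal, by Parseval over the full signal."""
    n = x.size
    spec = np.fft.rfft(x)
    h = np.abs(tf.sampled(np.fft.rfftfreq(n, 1 / sample_rate)))
    power = np.abs(spec * h) ** 2
    # rfft Parseval: double all bins except DC (and Nyquist for even n)
    scale = np.full(power.size, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    return float(np.sum(scale * power) / n**2)


def fit_room_weight(
    ff: TransferFunction,
    df: TransferFunction,
    measured_band_levels: Mapping[str, float],
    stimuli: Sequence[Stimulus],
) -> tuple[float, dict[str, float]]:
    """Fit the free/diffuse mix weight to reference-head eardrum levels.

    ``measured_band_levels`` maps stimulus names to the measured dB SPL at
    the reference head's eardrum for calibrated ``stimuli``.  The scalar
    weight minimising the sum of squared dB errors is found by a 1e-3 grid
    search followed by bounded local refinement; per-stimulus residuals
    (measured - modeled, dB) are returned alongside.
    """
    stim_by_name = {s.name: s for s in stimuli}
    missing = set(measured_band_levels) - set(stim_by_name)
    if missing:
        raise ValueError(f"no stimulus provided for measured levels: {sorted(missing)}")
    if not measured_band_levels:
        raise ValueError("at least one measured band level is required")

    names = sorted(measured_band_levels)
    a = np.empty(len(names))  # free-field filtered mean square per stimulus
    b = np.empty(len(names))  # diffuse-field filtered mean square
    meas = np.array([measured_band_levels[k] for k in names])
    for i, name in enumerate(names):
        s = stim_by_name[name]
        a[i] = _filtered_mean_square(s.samples, s.sample_rate, ff)
        b[i] = _filtered_mean_square(s.samples, s.sample_rate, df)

    def sse(w: float) -> float:
        modeled = 10 * np.log10(((1 - w) * a + w * b) / P_REF**2)
        return float(np.sum((meas - modeled) ** 2))

    grid = np.linspace(0.0, 1.0, 1001)
    errors = np.array([sse(w) for w in grid])
    w0 = grid[int(np.argmin(errors))]
    lo, hi = max(0.0, w0 - 1e-3), min(1.0, w0 + 1e-3)
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6})
    w_hat = float(np.clip(res.x if res.fun <= sse(w0) else w0, 0.0, 1.0))

    modeled = 10 * np.log10(((1 - w_hat) * a + w_hat * b) / P_REF**2)
    residuals = {name: float(m - mo) for name, m, mo in zip(names, meas, modeled)}
    if np.allclose(a, b):
        logger.info("free- and diffuse-field predictions identical; weight not identifiable, returning 0")
        w_hat = 0.0
    return w_hat, residuals


def heuristic_correction(
    estimated_levels: Mapping[float, float], measured_levels: Mapping[float, float]
) -> dict[float, float]:
    """Per-band dB offsets (measured minus estimated) zeroing the model error."""
    if set(estimated_levels) != set(measured_levels):
        raise ValueError("estimated and measured levels must cover the same bands")
    return {
        band: float(measured_levels[band] - estimated_levels[band])
        for band in sorted(estimated_levels)
    }


# --- eardrum levels --------------------------------------------------------


def _apply_tf(x: np.ndarray, sample_rate: float, tf: TransferFunction) -> np.ndarray:
    """Filter a waveform with a transfer function (spectral multiplication)."""
    n = x.size
    freqs = np.fft.rfftfreq(n, 1 / sample_rate)
    return np.fft.irfft(np.fft.rfft(x) * tf.sampled(freqs), n=n)


def eardrum_level(
    stimulus_waveform: Stimulus | BinauralStimulus,
    tf_instances: TransferFunctionSet | Mapping[str, TransferFunctionSet],
    window: AnalysisWindow | None = None,
) -> EardrumLevels:
    """Headphone eardrum level: filter with every HpTF instance, average RMS.

    For each ear the waveform is filtered with each transfer-function
    instance, the windowed RMS computed per instance, the RMS values
    averaged arithmetically, and converted to dB SPL.  Monaural
    presentations yield a level only for the presented (left) ear.
    """
    if isinstance(stimulus_waveform, BinauralStimulus):
        channels = {"left": stimulus_waveform.left, "right": stimulus_waveform.right}
        monaural = stimulus_waveform.mode == "monaural"
        condition = stimulus_waveform.mode
    else:
        channels = {"left": stimulus_waveform}
        monaural = True
        condition = ""
    if isinstance(tf_instances, TransferFunctionSet):
        tf_sets = {"left": tf_instances}
    else:
        tf_sets = dict(tf_instances)

    levels: dict[str, float | None] = {"left": None, "right": None}
    for ear, stim in channels.items():
        if monaural and ear == "right":
            continue
        if ear not in tf_sets:
            raise ValueError(f"no transfer functions supplied for the {ear} ear")
        if np.all(stim.samples == 0):
            raise ValueError(f"silent stimulus on the {ear} channel")
        win = window if window is not None else stim.default_window()
        sl = win.indices(stim.samples.size, stim.sample_rate)
        rms_values = []
        for tf in tf_sets[ear].instances:
            y = _apply_tf(stim.samples, stim.sample_rate, tf)
            rms_values.append(np.sqrt(np.mean(y[sl] ** 2)))
        levels[ear] = float(20 * np.log10(np.mean(rms_values) / P_REF))
    return EardrumLevels(levels["left"], levels["right"], "headphone", condition)


def loudspeaker_eardrum_level(
    stimulus: Stimulus,
    room: RoomModel | None,
    ff: Mapping[str, TransferFunction],
    df: Mapping[str, TransferFunction] | None = None,
    window: AnalysisWindow | None = None,
) -> EardrumLevels:
    """Loudspeaker eardrum level through the (room-matched) HRTF.

    ``stimulus`` must be calibrated to the known free-field level.  With
    ``room`` None or anechoic the frontal free-field HRTF is applied
    directly; otherwise the room-matched model with the room's weight and
    band correction is used (requires diffuse-field HRTFs).
    """
    use_room_model = room is not None and not room.is_anechoic
    if use_room_model and df is None:
        raise ValueError(f"room {room.name!r} is not anechoic: diffuse-field HRTFs required")
    win = window if window is not None else stimulus.default_window()
    sl = win.indices(stimulus.samples.size, stimulus.sample_rate)
    levels: dict[str, float] = {}
    for ear in ("left", "right"):
        tf = ff[ear]
        if use_room_model:
            tf = room_matched_hrtf(ff[ear], df[ear], room.mix_weight, room.band_correction)
        y = _apply_tf(stimulus.samples, stimulus.sample_rate, tf)
        levels[ear] = float(20 * np.log10(np.sqrt(np.mean(y[sl] ** 2)) / P_REF))
    name = room.name if room is not None else "anechoic"
    return EardrumLevels(levels["left"], levels["right"], "loudspeaker", name)
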