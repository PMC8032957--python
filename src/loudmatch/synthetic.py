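"""Synthetic listeners, ears, rooms and fully simulated experiments.

Everything downstream of the measurement hardware is testable without
downloads: this module generates parametric virtual listeners with a
condition-dependent internal equal-loudness point, synthetic headphone and
head-related transfer functions with realistic between-/within-subject
spread, room models with coherence profiles derived from the ideal diffuse
field, and a full factorial experiment (rooms x stimuli x presentation
modes x subjects) run through the real staircase and eardrum-level code.

The virtual listener is an *inverse* model of the observed mismatch
structure, not a loudness model: its internal equal-loudness headphone
playback level for a condition is

    L_int = L_eq0 + base_mismatch(room, stimulus)
            - ic_slope * (room_ic - hp_ic)
            + monaural_gain * [mode == monaural]

where ``L_eq0`` is the playback level that would equalise the eardrum
levels exactly, and each trial's verdict is "headphone louder" iff the
presented level plus Gaussian decision noise exceeds ``L_int``.  Monaural
trials carry no coherence term.  The default scenario parameters emulate
the qualitative structure of the study (mismatch of several dB at 250 Hz /
1 kHz vanishing for broadband noise, a 5-9 dB monaural extra level, a
between-anechoic-room offset); they are scenario values, not ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from loudmatch import signals as sig
from loudmatch.binaural import CoherenceProfile, make_presentation
from loudmatch.ear_transfer import (
    RoomModel,
    TransferFunction,
    TransferFunctionSet,
    eardrum_level,
    loudspeaker_eardrum_level,
)
from loudmatch.staircase import (
    HEADPHONE_LOUDER,
    LOUDSPEAKER_LOUDER,
    StaircaseConfig,
    bracketing_start,
    run_staircase,
)

SPEED_OF_SOUND = 343.0  # m/s
DEFAULT_EAR_SPACING = 0.17  # m

STIMULI = ("tbn250", "tbn1000", "tbn4000", "uen17")
MODES = ("monaural", "diotic", "ic_matched", "uncorrelated")
ROOM_SITES = {
    "OL_anechoic": "OL",
    "OL_earpiecelab": "OL",
    "AC_anechoic": "AC",
    "AC_teakitchen": "AC",
}

RESULTS_COLUMNS = (
    "subject", "site", "room", "stimulus", "mode",
    "hp_level_eardrum_left", "hp_level_eardrum_right",
    "ls_level_eardrum_left", "ls_level_eardrum_right",
    "converged", "seed", "implanted_mismatch",
)

THIRD_OCTAVE_CENTERS = (
    100.0, 125.0, 160.0, 200.0, 250.0, 315.0, 400.0, 500.0, 630.0, 800.0,
    1000.0, 1250.0, 1600.0, 2000.0, 2500.0, 3150.0, 4000.0, 5000.0,
    6300.0, 8000.0,
)


# --- listener traits -------------------------------------------------------


@dataclass
class ListenerTrait:
    """Parametric traits of one virtual listener.

    ``base_mismatch`` maps (room, stimulus) to the implanted
    headphone-minus-loudspeaker eardrum-level offset at equal loudness for
    diotic presentation in a coherence-1 room; ``ic_slope`` scales how the
    mismatch grows as the headphone coherence exceeds the room coherence;
    ``monaural_gain`` is the extra level needed monaurally (the
    binaural-summation analog).
    """

    subject_id: str
    base_mismatch: dict[tuple[str, str], float]
    ic_slope: float
    monaural_gain: float
    decision_noise_sd: float

    def __post_init__(self) -> None:
        if self.decision_noise_sd <= 0:
            raise ValueError("decision noise SD must be positive")
        if self.monaural_gain < 0:
            raise ValueError("monaural gain must be >= 0")


@dataclass(frozen=True)
class TraitConfig:
    """Population distributions of the listener traits (all dB)."""

    stimulus_mismatch: dict[str, float] = field(
        default_factory=lambda: {"tbn250": 6.0, "tbn1000": 5.0, "tbn4000": 1.0, "uen17": 0.0}
    )
    room_offset: dict[str, float] = field(
        default_factory=lambda: {
            "OL_anechoic": 0.0, "AC_anechoic": 2.6,
            "OL_earpiecelab": 0.0, "AC_teakitchen": 0.0,
        }
    )
    base_subject_sd: float = 2.0
    ic_slope_mean: float = 4.0
    ic_slope_sd: float = 1.0
    monaural_gain_mean: float = 7.0
    monaural_gain_sd: float = 1.0
    decision_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.base_subject_sd, self.ic_slope_sd, self.monaural_gain_sd):
            if v < 0:
                raise ValueError("trait standard deviations must be >= 0")
        if self.decision_noise_sd <= 0:
            raise ValueError("decision noise SD must be positive")


def null_trait_config(decision_noise_sd: float = 1.0) -> TraitConfig:
    """All implanted effects zero: only decision noise remains."""
    return TraitConfig(
        stimulus_mismatch={s: 0.0 for s in STIMULI},
        room_offset={r: 0.0 for r in ROOM_SITES},
        base_subject_sd=0.0,
        ic_slope_mean=0.0, ic_slope_sd=0.0,
        monaural_gain_mean=0.0, monaural_gain_sd=0.0,
        decision_noise_sd=decision_noise_sd,
    )


def make_population(
    n: int,
    trait_config: TraitConfig = TraitConfig(),
    seed: int = 0,
    rooms: tuple[str, ...] = tuple(ROOM_SITES),
    stimuli: tuple[str, ...] = STIMULI,
    id_prefix: str = "S",
) -> list[ListenerTrait]:
    """Draw a reproducible population of virtual listeners."""
    if n < 1:
        raise ValueError("population size must be >= 1")
    unknown = set(stimuli) - set(trait_config.stimulus_mismatch)
    if unknown:
        raise ValueError(f"no mismatch mean configured for stimuli {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    population = []
    for i in range(n):
        shift = rng.normal(0.0, trait_config.base_subject_sd) if trait_config.base_subject_sd else 0.0
        base = {
            (room, stim): trait_config.stimulus_mismatch[stim]
            + trait_config.room_offset.get(room, 0.0)
            + shift
            for room in rooms
            for stim in stimuli
        }
        ic_slope = rng.normal(trait_config.ic_slope_mean, trait_config.ic_slope_sd)
        gain = max(0.0, rng.normal(trait_config.monaural_gain_mean, trait_config.monaural_gain_sd))
        population.append(
            ListenerTrait(
                subject_id=f"{id_prefix}{i + 1:02d}",
                base_mismatch=base,
                ic_slope=float(ic_slope),
                monaural_gain=float(gain),
                decision_noise_sd=trait_config.decision_noise_sd,
            )
        )
    return population


# --- synthetic ears --------------------------------------------------------


@dataclass
class SyntheticEarSet:
    """HpTF repetitions and free/diffuse-field HRTFs of one subject."""

    subject_id: str
    hptf: dict[str, TransferFunctionSet]  # ear -> 8 instances
    hrtf_free: dict[str, TransferFunction]
    hrtf_diffuse: dict[str, TransferFunction]


@dataclass(frozen=True)
class EarConfig:
    """Targets of the synthetic transfer-function generator (dB)."""

    n_hptf_instances: int = 8
    between_subject_sd: float = 3.0
    within_subject_sd: float = 1.0
    within_subject_sd_high: float = 3.0  # above 4 kHz, repositioning hits harder
    n_grid: int = 64
    f_lo: float = 50.0
    f_hi: float = 16000.0


def _smooth_random_db(
    rng: np.random.Generator, theta: np.ndarray, sd: np.ndarray | float, n_components: int = 8
) -> np.ndarray:
    """Stationary smooth Gaussian-like curve with exact pointwise SD.

    Random-phase cosine series: each of the ``n_components`` equal-amplitude
    cosines contributes variance 1/2, so the summed curve has unit variance
    at every frequency point before scaling by ``sd``.
    """
    out = np.zeros_like(theta)
    for k in range(1, n_components + 1):
        phase = rng.uniform(0, 2 * np.pi)
        out += np.cos(2 * np.pi * (0.35 * k) * theta + phase)
    return sd * out * np.sqrt(2.0 / n_components)


def make_synthetic_ears(
    subject_id: str, seed: int, config: EarConfig = EarConfig()
) -> SyntheticEarSet:
    """Smooth synthetic HpTFs (with re-seating jitter) and HRTFs for one subject.

    Log-magnitude curves ride on an ear-canal-resonance peak near 2.5 kHz;
    the eight HpTF instances differ by low-variance jitter below 4 kHz and
    larger jitter above, emulating headphone repositioning.
    """
    rng = np.random.default_rng(seed)
    grid = np.geomspace(config.f_lo, config.f_hi, config.n_grid)
    theta = (np.log2(grid) - np.log2(config.f_lo)) / (
        np.log2(config.f_hi) - np.log2(config.f_lo)
    )
    resonance = 12.0 * np.exp(-0.5 * ((np.log2(grid / 2500.0)) / 0.6) ** 2)

    within_sd = np.where(grid < 4000.0, config.within_subject_sd, config.within_subject_sd_high)

    hptf: dict[str, TransferFunctionSet] = {}
    hrtf_free: dict[str, TransferFunction] = {}
    hrtf_diffuse: dict[str, TransferFunction] = {}
    for ear in ("left", "right"):
        subject_curve = resonance + _smooth_random_db(rng, theta, config.between_subject_sd)
        instances = []
        for _ in range(config.n_hptf_instances):
            jitter = _smooth_random_db(rng, theta, within_sd)
            mag = 10 ** ((subject_curve + jitter) / 20)
            instances.append(
                TransferFunction(grid.copy(), mag, "hptf", ear, "headphone voltage -> eardrum pressure")
            )
        hptf[ear] = TransferFunctionSet(instances, subject_id, ear)

        # frontal free field: ~0 dB at low frequency (negligible head shadow),
        # pinna/concha gain toward 3 kHz, individual deviation of ~2 dB
        ff_shape = 4.0 * np.exp(-0.5 * ((np.log2(grid / 3000.0)) / 0.8) ** 2)
        ff = ff_shape + _smooth_random_db(rng, theta, 2.0)
        hrtf_free[ear] = TransferFunction(
            grid.copy(), 10 ** (ff / 20), "hrtf_free", ear, "free-field pressure -> eardrum pressure"
        )
        # diffuse field: smoother, slightly broader gain
        df_shape = 5.0 * np.exp(-0.5 * ((np.log2(grid / 2800.0)) / 1.1) ** 2)
        df = df_shape + _smooth_random_db(rng, theta, 1.5, n_components=5)
        hrtf_diffuse[ear] = TransferFunction(
            grid.copy(), 10 ** (df / 20), "hrtf_diffuse", ear, "diffuse-field pressure -> eardrum pressure"
        )
    return SyntheticEarSet(subject_id, hptf, hrtf_free, hrtf_diffuse)


# --- rooms -----------------------------------------------------------------


def make_room_model(
    name: str,
    t30: float,
    ear_spacing: float = DEFAULT_EAR_SPACING,
    direct_to_reverberant_ratio: float = 1.0,
    band_centers: tuple[float, ...] = THIRD_OCTAVE_CENTERS,
) -> RoomModel:
    """Room model with an ideal-diffuse-field coherence profile.

    The interaural coherence per third-octave band mixes the fully coherent
    direct sound with the ideal diffuse field, |sinc| coherence of two
    points spaced ``ear_spacing`` apart:

        IC(f) = (DRR + |sin(x)/x|) / (DRR + 1),  x = 2 pi f d / c

    clipped to [0, 1].  Anechoic rooms (DRR -> infinity) give IC = 1 in all
    bands; the free/diffuse mix weight of the room-matched HRTF model is
    the diffuse energy fraction 1 / (1 + DRR).
    """
    if t30 < 0 or ear_spacing <= 0:
        raise ValueError("t30 must be >= 0 and ear spacing positive")
    if direct_to_reverberant_ratio < 0:
        raise ValueError("direct-to-reverberant ratio must be >= 0")
    drr = direct_to_reverberant_ratio
    centers = np.asarray(band_centers)
    x = 2 * np.pi * centers * ear_spacing / SPEED_OF_SOUND
    sinc = np.abs(np.sinc(x / np.pi))  # numpy sinc is sin(pi t)/(pi t)
    with np.errstate(over="ignore"):
        ic = np.clip((drr + sinc) / (drr + 1.0), 0.0, 1.0)
    profile = CoherenceProfile(tuple(centers), tuple(float(v) for v in ic))
    w = 1.0 / (1.0 + drr)
    return RoomModel(name=name, t30=t30, mix_weight=w, coherence_profile=profile)


def default_rooms() -> dict[str, RoomModel]:
    """The four study rooms: two anechoic chambers and two reverberant rooms."""
    return {
        "OL_anechoic": make_room_model("OL_anechoic", t30=0.06, direct_to_reverberant_ratio=1e9),
        "AC_anechoic": make_room_model("AC_anechoic", t30=0.06, direct_to_reverberant_ratio=1e9),
        "OL_earpiecelab": make_room_model("OL_earpiecelab", t30=0.395, direct_to_reverberant_ratio=0.25),
        "AC_teakitchen": make_room_model("AC_teakitchen", t30=0.574, direct_to_reverberant_ratio=0.15),
    }


# --- the virtual listener --------------------------------------------------


@dataclass(frozen=True)
class Condition:
    """One cell of the factorial design, with the coherences in force."""

    room: str
    stimulus: str
    mode: str
    room_ic: float
    hp_ic: float | None  # None for monaural


def internal_match_level(trait: ListenerTrait, condition: Condition, ls_internal_level: float) -> float:
    """The listener's internal equal-loudness headphone playback level."""
    level = ls_internal_level + trait.base_mismatch[(condition.room, condition.stimulus)]
    if condition.mode == "monaural":
        level += trait.monaural_gain
    elif condition.hp_ic is not None:
        level -= trait.ic_slope * (condition.room_ic - condition.hp_ic)
    return level


def simulate_responder(
    trait: ListenerTrait,
    condition: Condition,
    ls_internal_level: float,
    rng: np.random.Generator,
):
    """Trial-by-trial verdict function of the virtual listener."""
    target = internal_match_level(trait, condition, ls_internal_level)

    def respond(hp_level: float) -> str:
        noisy = hp_level + rng.normal(0.0, trait.decision_noise_sd)
        return HEADPHONE_LOUDER if noisy > target else LOUDSPEAKER_LOUDER

    return respond


# --- experiment design and simulation -------------------------------------


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout: rooms x stimuli x modes, subjects per site."""

    rooms: tuple[str, ...] = tuple(ROOM_SITES)
    stimuli: tuple[str, ...] = STIMULI
    modes: tuple[str, ...] = MODES
    n_per_site: int = 27
    cross_site_subjects: int = 14
    sites: dict[str, str] = field(default_factory=lambda: dict(ROOM_SITES))

    def __post_init__(self) -> None:
        if self.cross_site_subjects > self.n_per_site:
            raise ValueError("cross-site subset cannot exceed the per-site count")
        missing = set(self.rooms) - set(self.sites)
        if missing:
            raise ValueError(f"rooms without a site assignment: {sorted(missing)}")

    @property
    def site_names(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.sites[r] for r in self.rooms)))

    @property
    def n_subjects_total(self) -> int:
        n_sites = len(self.site_names)
        return self.cross_site_subjects + n_sites * (self.n_per_site - self.cross_site_subjects)

    def subject_rooms(self, subject_index: int) -> tuple[str, ...]:
        """Rooms a subject visits: all rooms for cross-site subjects, else
        the rooms of their home site."""
        if subject_index < self.cross_site_subjects:
            return self.rooms
        k = subject_index - self.cross_site_subjects
        per_site = self.n_per_site - self.cross_site_subjects
        site = self.site_names[k // per_site] if per_site else self.site_names[0]
        return tuple(r for r in self.rooms if self.sites[r] == site)


@dataclass(frozen=True)
class StimulusConfig:
    """Waveform parameters of the study stimuli."""

    duration: float = sig.DEFAULT_DURATION
    sample_rate: float = sig.DEFAULT_SAMPLE_RATE
    ramp_duration: float = sig.DEFAULT_RAMP
    phon: float = 65.0


@dataclass
class Acoustics:
    """Precomputed per-subject acoustic gains, reusable across replicates.

    ``hp_gain[(subject, stimulus)]`` maps headphone playback level (dB of
    the waveform fed to the HpTF) to left/right eardrum level offsets;
    ``ls_level[(subject, room, stimulus)]`` holds the loudspeaker eardrum
    levels of the calibrated stimulus.
    """

    stimuli: dict[str, sig.Stimulus]
    free_field_level: dict[str, float]
    hp_gain: dict[tuple[str, str], tuple[float, float]]
    ls_level: dict[tuple[str, str, str], tuple[float, float]]


def compute_acoustics(
    design: ExperimentDesign,
    population: list[ListenerTrait],
    ears: dict[str, SyntheticEarSet],
    rooms: dict[str, RoomModel],
    stim_config: StimulusConfig = StimulusConfig(),
) -> Acoustics:
    """Run the transfer-function machinery once per subject and condition cell."""
    ref_level = 80.0  # arbitrary reference; gains are level-equivariant
    stimuli: dict[str, sig.Stimulus] = {}
    free_field_level: dict[str, float] = {}
    for name in design.stimuli:
        stim = sig.make_named_stimulus(
            name, stim_config.duration, stim_config.sample_rate,
            ramp_duration=stim_config.ramp_duration,
        )
        level = sig.phon_to_spl(stim_config.phon, sig.CALIBRATION_FREQUENCY[name])
        stimuli[name] = sig.calibrate_level(stim, level)
        free_field_level[name] = level

    hp_gain: dict[tuple[str, str], tuple[float, float]] = {}
    ls_level: dict[tuple[str, str, str], tuple[float, float]] = {}
    for idx, trait in enumerate(population):
        ear = ears[trait.subject_id]
        for name in design.stimuli:
            ref_stim = sig.calibrate_level(stimuli[name], ref_level)
            gains = []
            for side in ("left", "right"):
                lv = eardrum_level(ref_stim, ear.hptf[side]).left
                gains.append(lv - ref_level)
            hp_gain[(trait.subject_id, name)] = (gains[0], gains[1])
        for room_name in design.subject_rooms(idx):
            room = rooms[room_name]
            for name in design.stimuli:
                levels = loudspeaker_eardrum_level(
                    stimuli[name], room, ear.hrtf_free, ear.hrtf_diffuse
                )
                ls_level[(trait.subject_id, room_name, name)] = (levels.left, levels.right)
    return Acoustics(stimuli, free_field_level, hp_gain, ls_level)


def simulate_experiment(
    design: ExperimentDesign,
    population: list[ListenerTrait],
    ears: dict[str, SyntheticEarSet],
    rooms: dict[str, RoomModel],
    config: StaircaseConfig = StaircaseConfig(),
    seed: int = 0,
    stim_config: StimulusConfig = StimulusConfig(),
    acoustics: Acoustics | None = None,
) -> pd.DataFrame:
    """Simulate every subject x condition of the design; one row each.

    For each cell: calibrate the stimulus, derive the room and headphone
    coherences of the presentation mode, run the adaptive staircase against
    the virtual listener, and convert the converged playback level to
    eardrum levels through the subject's HpTFs; the loudspeaker eardrum
    level comes from the (room-matched) HRTF path.  Fully reproducible from
    the seed; unconverged staircases are flagged in their rows, not dropped.
    The ``implanted_mismatch`` column records the listener's true mismatch
    for the cell (a diagnostic for parameter-recovery checks; the analysis
    ignores it).
    """
    if acoustics is None:
        acoustics = compute_acoustics(design, population, ears, rooms, stim_config)
    master = np.random.default_rng(seed)
    rows = []
    for idx, trait in enumerate(population):
        for room_name in design.subject_rooms(idx):
            room = rooms[room_name]
            site = design.sites[room_name]
            for stim_name in design.stimuli:
                stim = acoustics.stimuli[stim_name]
                room_ic = room.coherence_profile.stimulus_coherence(stim)
                ls_left, ls_right = acoustics.ls_level[(trait.subject_id, room_name, stim_name)]
                g_left, g_right = acoustics.hp_gain[(trait.subject_id, stim_name)]
                ls_internal = ls_left - g_left  # playback level equalising left-ear levels
                for mode in design.modes:
                    hp_ic = {
                        "monaural": None, "diotic": 1.0,
                        "uncorrelated": 0.0, "ic_matched": room_ic,
                    }[mode]
                    condition = Condition(room_name, stim_name, mode, room_ic, hp_ic)
                    cond_seed = int(master.integers(0, 2**31 - 1))
                    rng = np.random.default_rng(cond_seed)
                    responder = simulate_responder(trait, condition, ls_internal, rng)
                    expected = internal_match_level(trait, condition, ls_internal)
                    start = bracketing_start(expected, config.start_offset_range, rng)
                    _, match = run_staircase(responder, config, start)
                    hp_left = match.hp_level + g_left
                    hp_right = match.hp_level + g_right if mode != "monaural" else np.nan
                    rows.append(
                        (
                            trait.subject_id, site, room_name, stim_name, mode,
                            hp_left, hp_right, ls_left, ls_right,
                            match.converged, cond_seed, expected - ls_internal,
                        )
                    )
    return pd.DataFrame(rows, columns=list(RESULTS_COLUMNS))


def default_population_and_ears(
    design: ExperimentDesign,
    trait_config: TraitConfig = TraitConfig(),
    seed: int = 0,
    ear_config: EarConfig = EarConfig(),
) -> tuple[list[ListenerTrait], dict[str, SyntheticEarSet]]:
    """Population with cross-site/site-exclusive subject ids, plus their ears.

    Cross-site subjects keep one identity (and one set of ears and traits)
    at both sites; the room-level offsets of the trait configuration carry
    any site effect.
    """
    n_total = design.n_subjects_total
    population = make_population(
        n_total, trait_config, seed, rooms=design.rooms, stimuli=design.stimuli
    )
    rng = np.random.default_rng(seed + 1)
    ears = {
        t.subject_id: make_synthetic_ears(t.subject_id, int(rng.integers(0, 2**31 - 1)))
        for t in population
    }
    return population, ears


def simulate_default_experiment(
    seed: int = 0,
    n_per_site: int = 27,
    cross_site_subjects: int = 14,
    trait_config: TraitConfig = TraitConfig(),
    stim_config: StimulusConfig = StimulusConfig(),
    staircase_config: StaircaseConfig = StaircaseConfig(),
) -> pd.DataFrame:
    """One call from scenario to results table under the default design."""
    design = ExperimentDesign(n_per_site=n_per_site, cross_site_subjects=cross_site_subjects)
    population, ears = default_population_and_ears(design, trait_config, seed)
    rooms = default_rooms()
    return simulate_experiment(
        design, population, ears, rooms, staircase_config, seed, stim_config
    )
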