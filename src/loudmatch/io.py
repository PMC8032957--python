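"""File formats, run configuration, manifests, and the pipeline runner.

Conventions: WAV is 32-bit float with the header sample rate authoritative;
tabular data is comma-separated UTF-8 with a header row and '.' decimals,
dB values written at 3 decimal places; transfer-function sets are read
either from SOFA files (HDF5 container) or from a directory of
impulse-response WAVs with a YAML manifest; every run writes a manifest
recording seeds, versions, inputs and the command line so outputs can be
reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from loudmatch.binaural import CoherenceProfile
from loudmatch.ear_transfer import TransferFunction, TransferFunctionSet
from loudmatch.signals import BandSpec, Stimulus
from loudmatch.synthetic import RESULTS_COLUMNS

logger = logging.getLogger(__name__)


# --- WAV + manifest --------------------------------------------------------


def write_wav(path: str | Path, samples: np.ndarray, sample_rate: float) -> None:
    """Write a float32 WAV (mono: 1-D array; stereo: shape (n, 2))."""
    wavfile.write(str(path), int(round(sample_rate)), np.asarray(samples, dtype=np.float32))


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a WAV; returns float64 samples and the header sample rate."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.dtype.kind == "i":  # integer PCM -> full-scale floats
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(rate)


def write_stimulus(directory: str | Path, stimulus: Stimulus, level_db: float | None = None) -> Path:
    """Write a stimulus WAV with a sidecar metadata manifest; returns the WAV path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    wav_path = directory / f"{stimulus.name}.wav"
    write_wav(wav_path, stimulus.samples, stimulus.sample_rate)
    band = dataclasses.asdict(stimulus.band_spec)
    if band.get("center_frequency") is not None:
        band["center_frequency"] = float(band["center_frequency"])
    if band.get("band_edges") is not None:
        band["band_edges"] = [float(e) for e in band["band_edges"]]
    meta = {
        "name": stimulus.name,
        "sample_rate": float(stimulus.sample_rate),
        "ramp_duration": float(stimulus.ramp_duration),
        "rng_seed": int(stimulus.rng_seed),
        "band_spec": band,
        "calibrated_level_db_spl": None if level_db is None else float(level_db),
    }
    (directory / f"{stimulus.name}.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return wav_path


def read_stimulus(directory: str | Path, name: str) -> Stimulus:
    """Read a stimulus WAV and its sidecar manifest back into a Stimulus."""
    directory = Path(directory)
    meta = yaml.safe_load((directory / f"{name}.yaml").read_text())
    samples, rate = read_wav(directory / f"{name}.wav")
    spec_dict = meta["band_spec"]
    if spec_dict.get("band_edges") is not None:
        spec_dict["band_edges"] = tuple(spec_dict["band_edges"])
    return Stimulus(
        samples=samples,
        sample_rate=rate,
        band_spec=BandSpec(**spec_dict),
        rng_seed=meta["rng_seed"],
        name=meta["name"],
        ramp_duration=meta["ramp_duration"],
    )


# --- tabular formats -------------------------------------------------------

LEVEL_COLUMNS = (
    "hp_level_eardrum_left", "hp_level_eardrum_right",
    "ls_level_eardrum_left", "ls_level_eardrum_right",
)


def write_results_csv(path: str | Path, results: pd.DataFrame) -> None:
    """Write a results table; dB columns at 3 decimal places."""
    out = results.copy()
    for col in LEVEL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].round(3)
    out.to_csv(path, index=False)


def read_results_csv(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a results table.

    ``column_map`` maps the file's column names to the canonical schema
    (used for externally deposited tables); missing required columns or
    non-numeric levels are rejected with row diagnostics.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    required = ["subject", "room", "stimulus", "mode", "hp_level_eardrum_left", "ls_level_eardrum_left"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"results table is missing required columns: {missing}")
    for col in LEVEL_COLUMNS:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric values in column {col!r} at rows {list(df.index[bad][:10])}"
            )
        df[col] = coerced
    if "site" not in df.columns:
        df["site"] = ""
    return df


def write_coherence_csv(path: str | Path, profile: CoherenceProfile) -> None:
    df = pd.DataFrame({"band_center_hz": profile.band_centers, "ic": profile.ic_values})
    if profile.spread is not None:
        df["spread"] = profile.spread
    df.to_csv(path, index=False)


def read_coherence_csv(path: str | Path) -> CoherenceProfile:
    df = pd.read_csv(path)
    spread = tuple(df["spread"]) if "spread" in df.columns else None
    return CoherenceProfile(tuple(df["band_center_hz"]), tuple(df["ic"]), spread)


# --- transfer functions ----------------------------------------------------


def _tf_from_impulse_response(
    ir: np.ndarray, sample_rate: float, kind: str, ear: str, **kw
) -> TransferFunction:
    grid = np.fft.rfftfreq(ir.size, 1 / sample_rate)
    return TransferFunction(grid, np.fft.rfft(ir), kind, ear, **kw)


def write_tf_set_wav(directory: str | Path, tf_sets: dict[str, TransferFunctionSet],
                     sample_rate: float, n_taps: int = 4096) -> None:
    """Write transfer-function sets as impulse-response WAVs plus a manifest.

    Responses are resampled onto the rfft grid of ``n_taps`` samples; the
    manifest lists one entry (file, ear, kind, index) per instance.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    grid = np.fft.rfftfreq(n_taps, 1 / sample_rate)
    for ear, tf_set in tf_sets.items():
        for i, tf in enumerate(tf_set.instances):
            ir = np.fft.irfft(tf.sampled(grid), n=n_taps)
            fname = f"{tf.kind}_{ear}_{i:02d}.wav"
            write_wav(directory / fname, ir, sample_rate)
            entries.append({"file": fname, "ear": ear, "kind": tf.kind, "index": i})
    manifest = {"format": "wav_manifest", "sample_rate": sample_rate, "instances": entries}
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))


def _read_tf_wav_manifest(directory: Path) -> dict[str, TransferFunctionSet]:
    manifest_path = directory / "manifest.yaml"
    if not manifest_path.exists():
        raise ValueError(f"no manifest.yaml in {directory}")
    manifest = yaml.safe_load(manifest_path.read_text())
    if manifest.get("format") != "wav_manifest":
        raise ValueError(f"unsupported manifest format {manifest.get('format')!r}")
    rate = float(manifest["sample_rate"])
    by_ear: dict[str, list[TransferFunction]] = {}
    for entry in manifest["instances"]:
        ir, file_rate = read_wav(directory / entry["file"])
        if file_rate != rate:
            raise ValueError(f"sample-rate mismatch in {entry['file']}")
        by_ear.setdefault(entry["ear"], []).append(
            _tf_from_impulse_response(ir, rate, entry["kind"], entry["ear"])
        )
    return {ear: TransferFunctionSet(tfs, side=ear) for ear, tfs in by_ear.items()}


def _read_sofa(path: Path) -> dict[str, TransferFunctionSet]:
    """Read a SOFA (netCDF-4/HDF5) file of impulse responses.

    Receivers are assigned to ears by the sign of the y-coordinate of
    ``ReceiverPosition`` (positive y = left ear in the SOFA cartesian
    frame); measurements become instances carrying the source direction.
    """
    import h5py

    with h5py.File(path, "r") as f:
        conventions = f.attrs.get("SOFAConventions", b"")
        if isinstance(conventions, bytes):
            conventions = conventions.decode()
        if conventions not in ("SimpleFreeFieldHRIR", "GeneralFIR", "SimpleHeadphoneIR"):
            raise ValueError(f"unsupported SOFA convention {conventions!r}")
        ir = np.asarray(f["Data.IR"])  # (M, R, N)
        rate = float(np.ravel(f["Data.SamplingRate"])[0])
        receivers = np.atleast_2d(np.asarray(f["ReceiverPosition"]))
        if receivers.ndim == 3:
            receivers = receivers[:, :, 0]
        source = np.atleast_2d(np.asarray(f["SourcePosition"])) if "SourcePosition" in f else None
    if ir.ndim != 3:
        raise ValueError("Data.IR must have shape (measurements, receivers, samples)")
    kind = "hptf" if conventions == "SimpleHeadphoneIR" else "hrtf_free"
    out: dict[str, list[TransferFunction]] = {}
    for r in range(ir.shape[1]):
        ear = "left" if receivers[r, 1] >= 0 else "right"
        for m in range(ir.shape[0]):
            kw = {}
            if source is not None and kind.startswith("hrtf"):
                kw = {"azimuth": float(source[m, 0]), "elevation": float(source[m, 1])}
            out.setdefault(ear, []).append(
                _tf_from_impulse_response(ir[m, r], rate, kind, ear, **kw)
            )
    return {ear: TransferFunctionSet(tfs, side=ear) for ear, tfs in out.items()}


def read_transfer_functions(path: str | Path, format: str | None = None) -> dict[str, TransferFunctionSet]:
    """Read transfer functions from SOFA or a WAV+manifest directory.

    Returns a mapping ear -> :class:`TransferFunctionSet`.  The format is
    inferred from the path when not given (directory = wav_manifest, file =
    sofa).
    """
    path = Path(path)
    if format is None:
        format = "wav_manifest" if path.is_dir() else "sofa"
    if format == "wav_manifest":
        return _read_tf_wav_manifest(path)
    if format == "sofa":
        return _read_sofa(path)
    raise ValueError(f"unknown transfer-function format {format!r}")


# --- run configuration, manifest, pipeline --------------------------------


@dataclass
class RunConfig:
    """Scenario and execution parameters of one pipeline run."""

    seed: int = 0
    n_per_site: int = 27
    cross_site_subjects: int = 14
    scenario: str = "default"  # "default" | "null"
    decision_noise_sd: float = 1.0
    duration: float = 1.0
    sample_rate: float = 44100.0
    ramp_ms: float = 20.0
    phon: float = 65.0
    ear_convention: str = "left"
    out_dir: str = "run_output"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def write_manifest(path: str | Path, config: RunConfig, outputs: dict[str, Path]) -> None:
    """Record everything needed to re-run the outputs bit-identically."""
    import loudmatch

    manifest = {
        "package_version": loudmatch.__version__,
        "python": sys.version.split()[0],
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "command_line": " ".join(sys.argv),
        "config": dataclasses.asdict(config),
        "outputs": {
            name: {
                "path": str(p),
                "sha256": hashlib.sha256(Path(p).read_bytes()).hexdigest(),
            }
            for name, p in outputs.items()
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2))


def run_pipeline(config: RunConfig) -> Path:
    """Generate stimuli, simulate the experiment, analyse, write a manifest.

    Stages run in order; any stage failure propagates with the stage named.
    Returns the output directory.
    """
    from loudmatch import analysis, signals, synthetic

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "gen-stimuli"
    try:
        stim_cfg = synthetic.StimulusConfig(
            duration=config.duration,
            sample_rate=config.sample_rate,
            ramp_duration=config.ramp_ms / 1000,
            phon=config.phon,
        )
        stim_dir = out / "stimuli"
        for name in synthetic.STIMULI:
            stim = signals.make_named_stimulus(
                name, config.duration, config.sample_rate, ramp_duration=stim_cfg.ramp_duration
            )
            level = signals.phon_to_spl(config.phon, signals.CALIBRATION_FREQUENCY[name])
            stim = signals.calibrate_level(stim, level)
            outputs[f"stimulus_{name}"] = write_stimulus(stim_dir, stim, level)

        stage = "simulate-experiment"
        traits = (
            synthetic.null_trait_config(config.decision_noise_sd)
            if config.scenario == "null"
            else synthetic.TraitConfig(decision_noise_sd=config.decision_noise_sd)
        )
        results = synthetic.simulate_default_experiment(
            seed=config.seed,
            n_per_site=config.n_per_site,
            cross_site_subjects=config.cross_site_subjects,
            trait_config=traits,
            stim_config=stim_cfg,
        )
        results_path = out / "results.csv"
        write_results_csv(results_path, results)
        outputs["results"] = results_path

        stage = "analyze"
        reports = analyze_to_dir(results, out / "reports", config.ear_convention)
        outputs.update(reports)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    write_manifest(manifest_path, config, outputs)
    return out


def analyze_to_dir(
    results: pd.DataFrame, report_dir: str | Path, ear_convention: str = "left"
) -> dict[str, Path]:
    """Run the full analysis battery and write tidy CSV reports + a summary."""
    from loudmatch import analysis

    report_dir = Path(report_dir)
    report_dir.mkdir(parents=True, exist_ok=True)
    mismatch = analysis.compute_mismatch(results, ear_convention)
    outputs: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        p = report_dir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6g")
        outputs[name] = p

    _write("mismatch", mismatch)
    cond = analysis.condition_tests(mismatch)
    _write("condition_tests", cond)
    n_subjects_per_cond = cond["n"].min()
    lines = [f"{len(mismatch)} mismatch rows; {len(cond)} conditions tested"]
    if n_subjects_per_cond >= 2:
        anova = analysis.three_way_anova(mismatch)
        _write("anova", anova)
        contrasts = analysis.room_marginal_contrasts(mismatch)
        _write("room_contrasts", contrasts)
        modes = analysis.mode_pairwise_tests(mismatch)
        _write("mode_tests", modes)
        corr = analysis.diotic_vs_matched_correlation(mismatch)
        _write("diotic_vs_matched", corr)
        lines += [
            f"significant conditions (Bonferroni-64): {int(cond['significant'].sum())}/{len(cond)}",
            "ANOVA: " + "; ".join(
                f"{row.term} F({row.df_num},{row.df_den})={row.F:.1f} p={row.p:.3g}"
                for row in anova.itertuples()
            ),
            "room contrasts: " + "; ".join(
                f"{row.pair}: {row.delta:+.2f}±{row.se:.2f} dB p_adj={row.p_adjusted:.3g}"
                for row in contrasts.itertuples()
            ),
        ]
    else:
        logger.warning("fewer than 2 subjects per condition; inferential tests skipped")
        lines.append("inferential tests skipped (need >= 2 subjects per condition)")
    summary_path = report_dir / "summary.txt"
    summary_path.write_text("\n".join(lines) + "\n")
    outputs["summary"] = summary_path
    return outputs
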