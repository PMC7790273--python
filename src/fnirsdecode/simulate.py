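"""Synthetic fNIRS cohorts with planted affective effects and ground truth.

Each simulated subject gets, per task, a trial schedule (5 positive / 10
neutral / 5 negative 30-s blocks with 2-s baselines and 2-4-s gaps), clean
concentration responses (condition-dependent amplitudes convolved with a
canonical double-gamma HRF), structured physiological noise (Mayer waves
~0.1 Hz, respiration 0.3 Hz, subject-specific cardiac 0.8-1.2 Hz, white
noise, linear drift), subjective valence/arousal ratings drawn from the
study's pooled means/sds, and a 16-item mood scale before and after.

The default effect map plants deoxyhemoglobin effects on three frontal
channels: positive trials raise dHbR on channel 6-7 while neutral trials
raise dHbR on channels 5-4 and 4-4 (opposing directions, so the decoder must
recover both).  Two sources of realistic variability are treated as noise
amplitudes: a per-subject effect-size multiplier and per-trial amplitude
jitter; both are Gaussian and both are zero in the clean-signal limit.

Raw intensities are produced by the exact algebraic inverse of the
modified Beer-Lambert conversion used in preprocessing, around per-channel
baseline intensities drawn log-uniformly (only intensity ratios matter).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats

from . import io as fio
from .datatypes import (
    ConcentrationRecord,
    MoodScores,
    N_MOOD_ITEMS,
    OpticalRecording,
    TRIAL_COUNTS,
    validate_trial_table,
)
from .errors import ScheduleError, ValidationError
from .montage import Montage, default_montage
from .optics import mbll_forward_od

DEFAULT_FS_HZ = 5.2083

#: pooled valence/arousal means +- sd per (task, condition), 1-9 scale
RATING_PARAMS = {
    ("reactive", "negative"): {"valence": (2.52, 1.38), "arousal": (6.05, 1.34)},
    ("reactive", "neutral"): {"valence": (5.11, 0.73), "arousal": (2.71, 1.29)},
    ("reactive", "positive"): {"valence": (6.79, 0.92), "arousal": (4.82, 1.60)},
    ("active", "negative"): {"valence": (2.57, 0.97), "arousal": (5.85, 1.71)},
    ("active", "neutral"): {"valence": (4.84, 0.24), "arousal": (2.09, 1.39)},
    ("active", "positive"): {"valence": (7.20, 0.77), "arousal": (5.67, 1.75)},
}

#: planted effect amplitude, micromolar (peak block response); calibrated so
#: scaled-down cohorts land in the study's accuracy regime (see docs/methods.md)
DEFAULT_EFFECT_UM = 0.08


def default_effect_map(amplitude_um: float = DEFAULT_EFFECT_UM) -> dict:
    """(channel, chromophore, condition) -> planted peak amplitude in uM."""
    return {
        ("6-7", "HbR", "positive"): amplitude_um,
        ("5-4", "HbR", "neutral"): amplitude_um,
        ("4-4", "HbR", "neutral"): amplitude_um,
    }


@dataclass(frozen=True)
class NoiseParams:
    """Amplitudes of the structured noise terms, micromolar unless noted."""

    mayer_amp_um: float = 0.2
    mayer_freq_hz: float = 0.1
    resp_amp_um: float = 0.15
    resp_freq_hz: float = 0.3
    cardiac_amp_um: float = 0.25
    cardiac_freq_range_hz: tuple[float, float] = (0.8, 1.2)
    white_sd_um: float = 0.25
    drift_slope_sd_um_per_s: float = 0.002
    hbo_scale: float = 2.0  # physiological noise is stronger in HbO
    trial_jitter_sd: float = 0.45  # multiplicative, per trial
    subject_effect_sd: float = 0.5  # multiplicative, per subject (truncated at 0)

    def __post_init__(self) -> None:
        for name in ("mayer_amp_um", "resp_amp_um", "cardiac_amp_um",
                     "white_sd_um", "drift_slope_sd_um_per_s", "hbo_scale",
                     "trial_jitter_sd", "subject_effect_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"noise amplitude {name} must be >= 0")

    def silent(self) -> "NoiseParams":
        """All noise amplitudes zero (the clean-signal limit)."""
        return NoiseParams(mayer_amp_um=0, resp_amp_um=0, cardiac_amp_um=0,
                           white_sd_um=0, drift_slope_sd_um_per_s=0,
                           trial_jitter_sd=0, subject_effect_sd=0,
                           mayer_freq_hz=self.mayer_freq_hz,
                           resp_freq_hz=self.resp_freq_hz,
                           cardiac_freq_range_hz=self.cardiac_freq_range_hz,
                           hbo_scale=self.hbo_scale)


@dataclass(frozen=True)
class SimParams:
    """Study-level simulation parameters (two cohorts, both tasks)."""

    n_subjects_train: int = 49
    n_subjects_test: int = 20
    fs_hz: float = DEFAULT_FS_HZ
    tasks: tuple[str, ...] = ("reactive", "active")
    trial_counts: dict = field(default_factory=lambda: dict(TRIAL_COUNTS))
    stim_duration_s: float = 30.0
    baseline_s: float = 2.0
    gap_range_s: tuple[float, float] = (2.0, 4.0)
    lead_in_s: float = 30.0
    tail_s: float = 30.0
    effect_map: dict = field(default_factory=default_effect_map)
    noise: NoiseParams = field(default_factory=NoiseParams)
    rating_params: dict = field(default_factory=lambda: dict(RATING_PARAMS))
    i0_range: tuple[float, float] = (0.1, 1.0)
    seed: int = 0


@dataclass
class GroundTruth:
    """What was actually planted for one simulated subject/task."""

    effect_map_used: dict  # amplitudes after the subject multiplier
    subject_multiplier: float
    conditions: list
    clean_dhbo: np.ndarray
    clean_dhbr: np.ndarray


def double_gamma_hrf(t: np.ndarray, peak_s: float = 6.0, undershoot_s: float = 16.0,
                     ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (unit-integral lobes)."""
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, peak_s) - ratio * stats.gamma.pdf(t, undershoot_s)
    return h


def hrf_kernel(fs_hz: float, length_s: float = 32.0) -> np.ndarray:
    """Sampled HRF kernel including the dt factor, for direct convolution."""
    t = np.arange(0, length_s, 1.0 / fs_hz)
    return double_gamma_hrf(t) / fs_hz


def generate_ratings(task: str, condition: str, rng: np.random.Generator,
                     rating_params: dict | None = None) -> tuple[float, float]:
    """One (valence, arousal) draw from the pooled Gaussians, clipped to [1, 9]."""
    params = RATING_PARAMS if rating_params is None else rating_params
    if (task, condition) not in params:
        raise KeyError(f"no rating parameters for ({task!r}, {condition!r})")
    spec = params[(task, condition)]
    vals = []
    for dim in ("valence", "arousal"):
        m, sd = spec[dim]
        vals.append(float(np.clip(rng.normal(m, sd), 1.0, 9.0)))
    return vals[0], vals[1]


def simulate_trial_table(params: SimParams, task: str,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Random trial order, onsets with 2-s baselines and uniform 2-4-s gaps."""
    conditions = [c for c, n in sorted(params.trial_counts.items()) for _ in range(n)]
    rng.shuffle(conditions)
    rows = []
    t = params.lead_in_s
    for cond in conditions:
        t += params.baseline_s
        val, aro = generate_ratings(task, cond, rng, params.rating_params)
        rows.append({"onset_s": t, "duration_s": params.stim_duration_s,
                     "task": task, "condition": cond,
                     "valence_rating": val, "arousal_rating": aro})
        t += params.stim_duration_s
        t += rng.uniform(*params.gap_range_s)
    return validate_trial_table(pd.DataFrame(rows))


def _record_n_samples(params: SimParams, trials: pd.DataFrame) -> int:
    end = trials["onset_s"].iloc[-1] + params.stim_duration_s + params.tail_s
    return int(np.ceil(end * params.fs_hz))


def simulate_concentrations(params: SimParams, subject_seed, task: str = "active",
                            montage: Montage | None = None,
                            ) -> tuple[ConcentrationRecord, pd.DataFrame, GroundTruth]:
    """Simulate one subject's concentration record for one task.

    ``subject_seed`` may be an int, a SeedSequence, or a Generator.  The
    returned ground truth holds the pre-noise clean series and the effect
    amplitudes actually used (after the subject multiplier).
    """
    rng = np.random.default_rng(subject_seed)
    montage = montage or default_montage()
    trials = simulate_trial_table(params, task, rng)
    n = _record_n_samples(params, trials)
    fs = params.fs_hz
    kern = hrf_kernel(fs)
    if trials["onset_s"].iloc[-1] + params.stim_duration_s > n / fs:
        raise ScheduleError("trial schedule exceeds record length")

    names = montage.names
    chrom_index = {"HbO": 0, "HbR": 1}
    noise = params.noise
    # responder heterogeneity: non-negative effect scaling (a disengaged
    # subject shows no response rather than an inverted one)
    subject_mult = max(1.0 + rng.normal(0.0, noise.subject_effect_sd), 0.0)
    jitter = 1.0 + rng.normal(0.0, noise.trial_jitter_sd, size=len(trials))

    # clean condition-dependent responses
    clean = np.zeros((2, montage.n_channels, n))
    onsets = (trials["onset_s"].to_numpy() * fs).astype(int)
    n_stim = int(round(params.stim_duration_s * fs))
    effect_used = {}
    for (ch, chrom, cond), amp in params.effect_map.items():
        if ch not in names:
            raise ValidationError(f"effect map names unknown channel {ch!r}")
        ci = names.index(ch)
        amp_s = amp * subject_mult
        effect_used[(ch, chrom, cond)] = amp_s
        box = np.zeros(n)
        for ti, (start, cond_t) in enumerate(zip(onsets, trials["condition"])):
            if cond_t == cond:
                box[start:start + n_stim] += amp_s * jitter[ti]
        # kern carries the dt factor, so a unit boxcar peaks near 1
        resp = signal.fftconvolve(box, kern)[:n]
        clean[chrom_index[chrom], ci] += resp

    gt = GroundTruth(effect_map_used=effect_used, subject_multiplier=subject_mult,
                     conditions=trials["condition"].tolist(),
                     clean_dhbo=clean[0].copy(), clean_dhbr=clean[1].copy())

    # structured noise, shared construction for both chromophores
    t = np.arange(n) / fs
    sig = clean.copy()
    cardiac_f = rng.uniform(*noise.cardiac_freq_range_hz)
    for (amp, freq) in ((noise.mayer_amp_um, noise.mayer_freq_hz),
                        (noise.resp_amp_um, noise.resp_freq_hz),
                        (noise.cardiac_amp_um, cardiac_f)):
        phases = rng.uniform(0, 2 * np.pi, size=(2, montage.n_channels, 1))
        sig += amp * np.sin(2 * np.pi * freq * t[np.newaxis, np.newaxis, :] + phases)
    sig += rng.normal(0.0, noise.white_sd_um, size=sig.shape)
    slopes = rng.normal(0.0, noise.drift_slope_sd_um_per_s,
                        size=(2, montage.n_channels, 1))
    sig += slopes * (t - t.mean())[np.newaxis, np.newaxis, :]
    sig[0] = clean[0] + (sig[0] - clean[0]) * noise.hbo_scale

    conc = ConcentrationRecord(sig[0], sig[1], fs, subject_id="", montage=montage)
    return conc, trials, gt


def forward_mbll(conc: ConcentrationRecord, montage: Montage,
                 i0: np.ndarray, dpf=(7.25, 6.38)) -> OpticalRecording:
    """Concentrations -> raw intensities, exact inverse of the MBLL stage.

    ``i0`` is the per-wavelength, per-channel baseline intensity, shape
    ``(2, n_channels)``; arbitrary positive units (the MBLL uses only ratios).
    """
    i0 = np.asarray(i0, dtype=float)
    if i0.shape != (2, montage.n_channels):
        raise ValidationError(f"i0 must be (2, {montage.n_channels})")
    if not (i0 > 0).all():
        raise ValidationError("baseline intensities must be strictly positive")
    d_cm = montage.distance_mm / 10.0
    dod = mbll_forward_od(conc.dhbo, conc.dhbr, d_cm=d_cm, dpf=dpf,
                          wavelengths=montage.wavelengths_nm)
    intensities = i0[:, :, np.newaxis] * np.power(10.0, -dod)
    return OpticalRecording(intensities, conc.fs_hz, conc.subject_id, montage)


def _draw_i0(rng: np.random.Generator, params: SimParams, montage: Montage):
    lo, hi = params.i0_range
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=(2, montage.n_channels)))


def _mood_pair(rng: np.random.Generator, subject_id: str) -> list[MoodScores]:
    draws = rng.integers(0, 11, size=(2, N_MOOD_ITEMS))
    return [MoodScores(subject_id, "pre", draws[0].astype(float)),
            MoodScores(subject_id, "post", draws[1].astype(float))]


def simulate_cohorts(params: SimParams, out_dir: str | Path) -> dict:
    """Write the two independent cohorts to disk; returns the manifest.

    The train and test cohorts share ``params`` but no random draws (spawned
    seed streams).  Identical seeds reproduce byte-identical trees; the
    manifest records a sha256 for every written file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = default_montage()
    master = np.random.SeedSequence(params.seed)
    cohort_seeds = master.spawn(2)
    manifest = {"seed": params.seed, "fs_hz": params.fs_hz,
                "tasks": list(params.tasks), "cohorts": {}, "files": {}}

    for cohort, n_subj, css in (("train", params.n_subjects_train, cohort_seeds[0]),
                                ("test", params.n_subjects_test, cohort_seeds[1])):
        subj_seeds = css.spawn(n_subj)
        manifest["cohorts"][cohort] = {}
        for i in range(n_subj):
            subject_id = f"{cohort}-{i + 1:02d}"
            sdir = out / cohort / subject_id
            # independent streams per concern so task list changes don't
            # reshuffle mood/baseline draws
            streams = subj_seeds[i].spawn(2 + len(params.tasks))
            aux_rng = np.random.default_rng(streams[0])
            entry = {"recordings": {}, "events": {}}
            for ti, task in enumerate(params.tasks):
                conc, trials, _gt = simulate_concentrations(
                    params, streams[2 + ti], task, montage)
                conc.subject_id = subject_id
                i0 = _draw_i0(aux_rng, params, montage)
                rec = forward_mbll(conc, montage, i0)
                rec_dir = fio.write_recording(rec, sdir / f"rec_{task}")
                ev_path = fio.write_events(trials, sdir / f"events_{task}.tsv")
                entry["recordings"][task] = str(rec_dir.relative_to(out))
                entry["events"][task] = str(ev_path.relative_to(out))
            mood_rng = np.random.default_rng(streams[1])
            mood_path = fio.write_mood(_mood_pair(mood_rng, subject_id),
                                       sdir / "mood.tsv")
            entry["mood"] = str(mood_path.relative_to(out))
            manifest["cohorts"][cohort][subject_id] = entry

    for fpath in sorted(out.rglob("*")):
        if fpath.is_file() and fpath.name != "manifest.json":
            digest = hashlib.sha256(fpath.read_bytes()).hexdigest()
            manifest["files"][str(fpath.relative_to(out))] = digest
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def scaled_params(n_train: int, n_test: int, seed: int = 0,
                  tasks: tuple[str, ...] = ("active",), **overrides) -> SimParams:
    """Convenience constructor for desk-scale cohorts (fewer subjects/tasks)."""
    return replace(SimParams(seed=seed), n_subjects_train=n_train,
                   n_subjects_test=n_test, tasks=tasks, **overrides)
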