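"""In-memory containers for recordings, trials, segments and mood scales.

Conventions fixed here and relied on everywhere else:

* time is in seconds, trial windows are half-open ``[onset, onset + duration)``;
* channel order is the montage order; wavelength axis is ``(760, 850)``;
* concentrations are micromolar changes from baseline (dHbO / dHbR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .montage import Montage, default_montage

CONDITIONS = ("positive", "negative", "neutral")
TASKS = ("reactive", "active")

#: default per-task trial mix: 5 positive, 10 neutral, 5 negative
TRIAL_COUNTS = {"positive": 5, "neutral": 10, "negative": 5}

EVENT_COLUMNS = [
    "onset_s",
    "duration_s",
    "task",
    "condition",
    "valence_rating",
    "arousal_rating",
]

N_MOOD_ITEMS = 16  # the scale lists 15 adjectives but 16 measures are corrected for
MOOD_SCALE = (0, 10)  # eleven-point Likert


@dataclass
class OpticalRecording:
    """Raw dual-wavelength light intensities for one subject.

    ``intensities`` has shape ``(2, n_channels, n_samples)`` with the
    wavelength axis ordered as ``montage.wavelengths_nm``.  Intensities must
    be strictly positive: optical density takes their logarithm later.
    """

    intensities: np.ndarray
    fs_hz: float
    subject_id: str
    montage: Montage = field(default_factory=default_montage)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3 or self.intensities.shape[0] != 2:
            raise ValidationError(
                f"intensities must be (2, n_channels, n_samples), got {self.intensities.shape}"
            )
        if self.intensities.shape[1] != self.montage.n_channels:
            raise ValidationError(
                f"{self.intensities.shape[1]} channels but montage has {self.montage.n_channels}"
            )
        if self.fs_hz <= 0:
            raise ValidationError("fs_hz must be > 0")
        bad = np.argwhere(~(self.intensities > 0))
        if bad.size:
            w, c, s = bad[0]
            raise ValidationError(
                f"nonpositive intensity at wavelength index {w}, "
                f"channel {self.montage.names[c]}, sample {s}"
            )

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class ConcentrationRecord:
    """Chromophore concentration changes (micromolar) per channel over time."""

    dhbo: np.ndarray
    dhbr: np.ndarray
    fs_hz: float
    subject_id: str
    montage: Montage = field(default_factory=default_montage)

    def __post_init__(self) -> None:
        self.dhbo = np.asarray(self.dhbo, dtype=float)
        self.dhbr = np.asarray(self.dhbr, dtype=float)
        if self.dhbo.shape != self.dhbr.shape or self.dhbo.ndim != 2:
            raise ValidationError("dHbO and dHbR must be equal-shaped (channels, samples)")
        if self.dhbo.shape[0] != self.montage.n_channels:
            raise ValidationError("channel count does not match montage")
        if not (np.isfinite(self.dhbo).all() and np.isfinite(self.dhbr).all()):
            raise ValidationError("concentrations must be finite")
        if self.fs_hz <= 0:
            raise ValidationError("fs_hz must be > 0")

    @property
    def n_samples(self) -> int:
        return self.dhbo.shape[1]


@dataclass
class TrialSegment:
    """One 30-s trial window cut out of a concentration record."""

    condition: str
    task: str
    dhbo_seg: np.ndarray
    dhbr_seg: np.ndarray
    trial_index: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.dhbo_seg.shape != self.dhbr_seg.shape:
            raise ValidationError("segment chromophore planes differ in shape")


@dataclass
class MoodScores:
    """One administration of the 16-item, eleven-point mood scale."""

    subject_id: str
    timepoint: str  # "pre" or "post"
    items: np.ndarray

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=float)
        if self.items.shape != (N_MOOD_ITEMS,):
            raise ValidationError(f"mood scale must have {N_MOOD_ITEMS} items")
        if self.timepoint not in ("pre", "post"):
            raise ValidationError(f"timepoint must be pre/post, got {self.timepoint!r}")
        lo, hi = MOOD_SCALE
        if ((self.items < lo) | (self.items > hi)).any():
            raise ValidationError(f"mood items must lie in [{lo}, {hi}]")


def validate_trial_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise an events table (the TrialTable contract).

    Returns the table sorted by onset with a fresh index.  Raises
    :class:`ValidationError` on unknown labels, out-of-range ratings or
    overlapping trials.
    """
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"events table missing columns: {missing}")
    t = table.copy().sort_values("onset_s").reset_index(drop=True)
    for col in ("onset_s", "duration_s", "valence_rating", "arousal_rating"):
        t[col] = t[col].astype(float)
    if not t["condition"].isin(CONDITIONS).all():
        bad = sorted(set(t["condition"]) - set(CONDITIONS))
        raise ValidationError(f"unknown condition value(s): {bad}")
    if not t["task"].isin(TASKS).all():
        bad = sorted(set(t["task"]) - set(TASKS))
        raise ValidationError(f"unknown task value(s): {bad}")
    for col in ("valence_rating", "arousal_rating"):
        v = t[col].to_numpy(dtype=float)
        if ((v < 1) | (v > 9)).any():
            raise ValidationError(f"{col} outside [1, 9]")
    if (t["duration_s"].to_numpy(dtype=float) <= 0).any():
        raise ValidationError("durations must be positive")
    # non-overlap within each task block
    for _, block in t.groupby("task", sort=False):
        on = block["onset_s"].to_numpy(dtype=float)
        du = block["duration_s"].to_numpy(dtype=float)
        if (np.diff(on) <= 0).any():
            raise ValidationError("trial onsets must be strictly increasing")
        if ((on[:-1] + du[:-1]) > on[1:]).any():
            raise ValidationError("trials overlap")
    return t
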