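"""Mean-concentration features: one value per channel and chromophore per trial.

Each 30-s segment is reduced with the average of moving 2-s window means at
50% overlap; the per-subject table has 64 columns for the default montage
(HbO block in montage channel order, then the HbR block) plus the label
columns ``subject_id, task, condition, trial_index``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .montage import Montage

META_COLUMNS = ["subject_id", "task", "condition", "trial_index"]

CHROMOPHORES = ("HbO", "HbR")


def feature_columns(montage: Montage) -> list[str]:
    """Fixed column order: ``<channel>_HbO`` block then ``<channel>_HbR`` block."""
    return [f"{name}_{ch}" for ch in CHROMOPHORES for name in montage.names]


def windowed_mean(series: np.ndarray, fs_hz: float, win_s: float = 2.0,
                  overlap: float = 0.5) -> float:
    """Average of means over full sliding windows (win rounded to samples).

    Window length ``w = round(win_s * fs)`` samples, hop ``floor(w * (1 -
    overlap))``; trailing samples not covered by a full window are ignored.
    """
    series = np.asarray(series, dtype=float)
    w = int(round(win_s * fs_hz))
    if w < 1 or series.shape[-1] < w:
        raise ValidationError(
            f"series of {series.shape[-1]} samples shorter than one {w}-sample window"
        )
    hop = max(1, int(np.floor(w * (1.0 - overlap))))
    starts = np.arange(0, series.shape[-1] - w + 1, hop)
    csum = np.concatenate([np.zeros(series.shape[:-1] + (1,)),
                           np.cumsum(series, axis=-1)], axis=-1)
    means = (csum[..., starts + w] - csum[..., starts]) / w
    return means.mean(axis=-1)


def n_windows(n_samples: int, fs_hz: float, win_s: float = 2.0,
              overlap: float = 0.5) -> int:
    """Number of full windows the averager uses for a segment of given length."""
    w = int(round(win_s * fs_hz))
    hop = max(1, int(np.floor(w * (1.0 - overlap))))
    return (n_samples - w) // hop + 1


def build_feature_table(segments, montage: Montage, fs_hz: float,
                        win_s: float = 2.0, overlap: float = 0.5) -> pd.DataFrame:
    """One row per trial segment, 2 x n_channels feature columns.

    Segment channel counts must match the montage; labels are carried over
    from the trial table that produced the segments.
    """
    cols = feature_columns(montage)
    rows = []
    for seg in segments:
        if seg.dhbo_seg.shape[0] != montage.n_channels:
            raise ValidationError(
                f"segment has {seg.dhbo_seg.shape[0]} channels, montage "
                f"{montage.n_channels}"
            )
        vals = np.concatenate([
            windowed_mean(seg.dhbo_seg, fs_hz, win_s, overlap),
            windowed_mean(seg.dhbr_seg, fs_hz, win_s, overlap),
        ])
        row = {"subject_id": seg.subject_id, "task": seg.task,
               "condition": seg.condition, "trial_index": seg.trial_index}
        row.update(dict(zip(cols, vals)))
        rows.append(row)
    table = pd.DataFrame(rows, columns=META_COLUMNS + cols)
    if table[cols].isna().any().any():
        raise ValidationError("feature table contains missing values")
    return table
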