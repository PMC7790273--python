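"""End-to-end glue: simulated or on-disk cohorts -> per-trial feature tables.

Two equivalent routes produce the same 64-column feature tables: the
in-memory route (simulate -> forward optics -> preprocess -> features,
nothing written) and the on-disk route (read a cohort directory written by
:func:`fnirsdecode.simulate.simulate_cohorts`).  Both use the identical seed
tree, so a given master seed yields the same cohort either way up to TSV
rounding.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .features import build_feature_table
from .montage import default_montage
from .preprocess import preprocess_recording, segment_trials
from .simulate import SimParams, _draw_i0, forward_mbll, simulate_concentrations


def subject_features(rec, trials) -> pd.DataFrame:
    """Preprocess one raw recording and reduce its trials to feature rows."""
    conc = preprocess_recording(rec)
    segments = segment_trials(conc, trials)
    return build_feature_table(segments, rec.montage, rec.fs_hz)


def simulate_feature_tables(params: SimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """In-memory pipeline for both cohorts; returns (train, test) tables."""
    montage = default_montage()
    master = np.random.SeedSequence(params.seed)
    cohort_seeds = master.spawn(2)
    tables = []
    for cohort, n_subj, css in (("train", params.n_subjects_train, cohort_seeds[0]),
                                ("test", params.n_subjects_test, cohort_seeds[1])):
        subj_seeds = css.spawn(n_subj)
        frames = []
        for i in range(n_subj):
            subject_id = f"{cohort}-{i + 1:02d}"
            streams = subj_seeds[i].spawn(2 + len(params.tasks))
            aux_rng = np.random.default_rng(streams[0])
            for ti, task in enumerate(params.tasks):
                conc, trials, _ = simulate_concentrations(
                    params, streams[2 + ti], task, montage)
                conc.subject_id = subject_id
                rec = forward_mbll(conc, montage, _draw_i0(aux_rng, params, montage))
                frames.append(subject_features(rec, trials))
        tables.append(pd.concat(frames, ignore_index=True))
    return tables[0], tables[1]


def features_from_cohort_dir(root: str | Path, cohort: str) -> pd.DataFrame:
    """Read one cohort of a simulated dataset directory and build features."""
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    frames = []
    for subject_id in sorted(manifest["cohorts"][cohort]):
        entry = manifest["cohorts"][cohort][subject_id]
        for task, rec_rel in sorted(entry["recordings"].items()):
            rec = fio.read_recording(root / rec_rel)
            trials = fio.read_events(root / entry["events"][task])
            frames.append(subject_features(rec, trials))
    return pd.concat(frames, ignore_index=True)
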