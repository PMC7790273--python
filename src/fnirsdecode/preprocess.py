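"""Raw intensities -> band-limited chromophore concentrations -> trial segments.

Stage order (fixed): band-pass FIR on each wavelength's intensity record,
whole-record linear detrend, optical density against the whole-record mean,
modified Beer-Lambert inversion, segmentation into 30-s trial windows.

Because the band-pass rejects DC, the filter and detrend act on the intensity
fluctuation around the per-channel whole-record mean ``I0``; optical density
is then computed from ``I0 + fluctuation``.  For the small fluctuations fNIRS
produces this is the standard linear-regime reading of "filter the raw data".
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .datatypes import ConcentrationRecord, OpticalRecording, TrialSegment
from .errors import FilterLengthError, SegmentationError, ValidationError
from .optics import DEFAULT_DPF, mbll_inverse

#: Hamming-window FIR design constant: transition width ~ 3.3 / numtaps (normalised)
_HAMMING_TW = 3.3

DEFAULT_BAND_HZ = (0.01, 0.1)
DEFAULT_TRANSITION_HZ = 0.02


def design_bandpass(fs_hz: float, low_hz: float = 0.01, high_hz: float = 0.1,
                    transition_hz: float = DEFAULT_TRANSITION_HZ) -> np.ndarray:
    """Design the linear-phase (symmetric, odd-length) band-pass FIR kernel."""
    if fs_hz <= 2 * high_hz:
        raise ValidationError("sampling rate must exceed twice the upper band edge")
    numtaps = int(np.ceil(_HAMMING_TW * fs_hz / transition_hz))
    numtaps += 1 - numtaps % 2  # force odd -> type-I linear phase
    h = signal.firwin(numtaps, [low_hz, high_hz], pass_zero=False,
                      window="hamming", fs=fs_hz)
    # zero-sum taps: exact DC null (constant inputs map to ~0, not -46 dB)
    return h - h.mean()


def bandpass_fir(x: np.ndarray, fs_hz: float, low_hz: float = 0.01,
                 high_hz: float = 0.1,
                 transition_hz: float = DEFAULT_TRANSITION_HZ) -> np.ndarray:
    """Zero-net-phase band-pass: symmetric FIR + group-delay compensation.

    ``x`` is ``(..., n_samples)``; each trailing-axis series is filtered
    independently with reflection padding at the edges.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    h = design_bandpass(fs_hz, low_hz, high_hz, transition_hz)
    n = x.shape[-1]
    if n <= 3 * len(h):
        raise FilterLengthError(
            f"record of {n} samples is too short for the {len(h)}-tap filter; "
            f"need more than {3 * len(h)} samples"
        )
    pad = len(h) // 2
    xp = np.concatenate([x[..., 1:pad + 1][..., ::-1], x,
                         x[..., -pad - 1:-1][..., ::-1]], axis=-1)
    # symmetric kernel + centred 'same' convolution = zero phase shift
    y = signal.fftconvolve(xp, h[np.newaxis, :], mode="same", axes=-1)
    y = y[..., pad:pad + n]
    return y[0] if squeeze else y


def detrend_whole(x: np.ndarray) -> np.ndarray:
    """Remove the least-squares straight line over the full record, per channel."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValidationError("detrend needs at least 2 samples")
    return signal.detrend(x, axis=-1, type="linear")


def optical_density(intensity: np.ndarray, i0: np.ndarray) -> np.ndarray:
    """dOD(t) = -log10(I(t) / I0) with strict positivity validation."""
    intensity = np.asarray(intensity, dtype=float)
    i0 = np.asarray(i0, dtype=float)
    if not (i0 > 0).all():
        raise ValidationError("baseline intensities must be strictly positive")
    if not (intensity > 0).all():
        raise ValidationError("intensities must be strictly positive for log")
    return -np.log10(intensity / i0[..., np.newaxis])


def mbll_concentrations(dod_760: np.ndarray, dod_850: np.ndarray, d_cm: float,
                        dpf=DEFAULT_DPF) -> tuple[np.ndarray, np.ndarray]:
    """Solve the per-sample 2x2 Beer-Lambert system; returns micromolar dHbO, dHbR."""
    dod = np.stack([np.asarray(dod_760, dtype=float),
                    np.asarray(dod_850, dtype=float)])
    return mbll_inverse(dod, d_cm=d_cm, dpf=dpf)


def preprocess_recording(rec: OpticalRecording, low_hz: float = 0.01,
                         high_hz: float = 0.1,
                         transition_hz: float = DEFAULT_TRANSITION_HZ,
                         dpf=DEFAULT_DPF) -> ConcentrationRecord:
    """Full chain: filter -> detrend -> optical density -> MBLL."""
    i0 = rec.intensities.mean(axis=-1)  # (2, n_channels)
    dod = np.empty_like(rec.intensities)
    for wi in range(2):
        fluct = bandpass_fir(rec.intensities[wi], rec.fs_hz, low_hz, high_hz,
                             transition_hz)
        fluct = detrend_whole(fluct)
        dod[wi] = optical_density(i0[wi][:, np.newaxis] + fluct, i0[wi])
    d_cm = rec.montage.distance_mm / 10.0
    dhbo, dhbr = mbll_concentrations(dod[0], dod[1], d_cm=d_cm, dpf=dpf)
    return ConcentrationRecord(dhbo, dhbr, rec.fs_hz, rec.subject_id, rec.montage)


def segment_trials(conc: ConcentrationRecord, trials, duration_s: float = 30.0):
    """Cut half-open ``[onset, onset + duration)`` windows out of the record.

    ``trials`` is a validated events DataFrame.  Window length is
    ``floor(duration * fs)`` samples (156 at the default 5.2083 Hz).
    """
    n_win = int(np.floor(duration_s * conc.fs_hz))
    segments: list[TrialSegment] = []
    for idx, row in trials.reset_index(drop=True).iterrows():
        start = int(np.floor(row["onset_s"] * conc.fs_hz))
        stop = start + n_win
        if start < 0 or stop > conc.n_samples:
            raise SegmentationError(
                f"trial {idx} window [{start}, {stop}) outside record "
                f"of {conc.n_samples} samples"
            )
        segments.append(
            TrialSegment(
                condition=row["condition"],
                task=row["task"],
                dhbo_seg=conc.dhbo[:, start:stop].copy(),
                dhbr_seg=conc.dhbr[:, start:stop].copy(),
                trial_index=int(idx),
                subject_id=conc.subject_id,
            )
        )
    return segments
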