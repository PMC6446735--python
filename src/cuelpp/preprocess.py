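"""Offline signal conditioning.

Low-pass filtering (zero-phase windowed-sinc FIR), bad-sensor interpolation
(inverse-distance k-nearest neighbours), average referencing, segmentation
and baseline correction. All operations are linear and length-preserving.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Sequence, Tuple, Union

import numpy as np
from scipy import fft as sfft
from scipy import signal as sps

from .config import AnalysisConfig, DEFAULT_CONFIG
from .data_model import EpochSet, EventTable, Recording, SensorMontage, ValidationError

log = logging.getLogger(__name__)

ArrayLike = Union[Recording, EpochSet]


# ---------------------------------------------------------------------------
# low-pass filter
# ---------------------------------------------------------------------------

def design_lowpass(rate: float, cutoff_hz: float) -> np.ndarray:
    """Windowed-sinc low-pass FIR with ~0.25 x cutoff transition band.

    Returns the single-pass taps; application is zero-phase (forward and
    time-reversed pass), so the effective magnitude response is squared.
    DC gain is exactly 1 on each pass.
    """
    if cutoff_hz >= rate / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    transition = 0.25 * cutoff_hz
    numtaps = int(np.ceil(3.3 * rate / transition))
    numtaps += 1 - numtaps % 2          # odd length -> integer group delay
    band_mid = min(cutoff_hz + transition / 2.0, 0.49 * rate)
    return sps.firwin(numtaps, band_mid, fs=rate, window="hamming")


def _zero_phase_fir(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Zero-phase FIR filtering along the last axis.

    Equivalent to filtfilt for a symmetric FIR: one convolution with the
    autocorrelation kernel conv(b, b[::-1]), with odd-reflection padding at
    both ends to suppress edge transients.
    """
    kernel = np.convolve(taps, taps[::-1])
    half = (kernel.size - 1) // 2
    n = data.shape[-1]
    pad = min(half, n - 1)
    left = 2 * data[..., :1] - data[..., pad:0:-1]
    right = 2 * data[..., -1:] - data[..., -2:-pad - 2:-1]
    padded = np.concatenate([left, data, right], axis=-1)
    lead_shape = padded.shape[:-1]
    flat = padded.reshape(-1, padded.shape[-1])
    nfft = sfft.next_fast_len(flat.shape[-1] + kernel.size - 1, real=True)
    K = sfft.rfft(kernel, nfft)
    full = sfft.irfft(sfft.rfft(flat, nfft, axis=-1) * K, nfft, axis=-1)
    # full convolution: the output aligned with data[j] sits at pad + j + half
    out = full[:, pad + half:pad + half + n]
    return np.ascontiguousarray(out).reshape(lead_shape + (n,))


def lowpass_filter(obj: ArrayLike, cutoff_hz: float | None = None) -> ArrayLike:
    """Zero-phase low-pass filter a Recording or EpochSet (default 30 Hz).

    Continuous recordings are filtered as a whole; epoched data are filtered
    per epoch (edge transients stay within a filter half-width of the epoch
    boundaries, well outside the LPP window).
    """
    cutoff = DEFAULT_CONFIG.filter_cutoff_hz if cutoff_hz is None else cutoff_hz
    taps = design_lowpass(obj.rate, cutoff)
    filtered = _zero_phase_fir(obj.data, taps)
    if isinstance(obj, Recording):
        return Recording(filtered, obj.rate, obj.montage, obj.events)
    return obj.copy_with(filtered)


# ---------------------------------------------------------------------------
# bad-sensor interpolation
# ---------------------------------------------------------------------------

def interpolate_bad_sensors(
    obj: ArrayLike,
    bad_ids: Sequence[str],
    montage: SensorMontage | None = None,
    k: int = 4,
) -> ArrayLike:
    """Replace each bad sensor by the inverse-distance-weighted mean of its
    k nearest good sensors. Good sensors are untouched."""
    montage = montage or obj.montage
    bad_ids = [str(b) for b in bad_ids]
    if not bad_ids:
        return obj
    unknown = set(bad_ids) - set(montage.labels)
    if unknown:
        raise ValidationError(f"bad sensors not in montage: {sorted(unknown)}")
    bad_idx = np.array([montage.index_of(b) for b in bad_ids])
    good_idx = np.array([i for i in range(montage.n_sensors) if i not in set(bad_idx)])
    if good_idx.size < 3:
        raise ValidationError("at least 3 good sensors are required")

    data = obj.data.copy()
    sensor_axis = 0 if isinstance(obj, Recording) else 1
    for bi in bad_idx:
        d = np.linalg.norm(
            montage.positions[good_idx] - montage.positions[bi], axis=1
        )
        order = np.argsort(d)[: min(k, good_idx.size)]
        nearest = good_idx[order]
        dist = np.maximum(d[order], 1e-12)
        w = 1.0 / dist
        w /= w.sum()
        src = np.take(data, nearest, axis=sensor_axis)
        wshape = [1] * data.ndim
        wshape[sensor_axis] = w.size
        rep = (src * w.reshape(wshape)).sum(axis=sensor_axis)
        if sensor_axis == 0:
            data[bi] = rep
        else:
            data[:, bi] = rep
    if isinstance(obj, Recording):
        return Recording(data, obj.rate, obj.montage, obj.events)
    return obj.copy_with(data)


# ---------------------------------------------------------------------------
# average reference
# ---------------------------------------------------------------------------

def average_reference(obj: ArrayLike) -> ArrayLike:
    """Re-reference to the instantaneous mean across sensors (idempotent)."""
    sensor_axis = 0 if isinstance(obj, Recording) else 1
    if obj.data.shape[sensor_axis] < 2:
        raise ValidationError("average reference needs at least 2 sensors")
    data = obj.data - obj.data.mean(axis=sensor_axis, keepdims=True)
    if isinstance(obj, Recording):
        return Recording(data, obj.rate, obj.montage, obj.events)
    return obj.copy_with(data)


# ---------------------------------------------------------------------------
# segmentation and baseline
# ---------------------------------------------------------------------------

def segment_epochs(
    recording: Recording,
    events: EventTable | None = None,
    window_ms: Tuple[float, float] = DEFAULT_CONFIG.epoch_window_ms,
    participant_id: str = "",
) -> EpochSet:
    """Cut picture-onset-locked epochs out of a continuous recording.

    Epoch sample j of event i is recording sample ``onset_i + start + j``
    where ``start`` is the (negative) window start in samples. Events too
    close to the recording edge are skipped with a warning.
    """
    events = events if events is not None else recording.events
    if events is None:
        raise ValidationError("no events supplied")
    rate = recording.rate
    start = int(round(window_ms[0] * rate / 1000.0))
    n_samples = int(round((window_ms[1] - window_ms[0]) * rate / 1000.0))
    n_total = recording.data.shape[1]

    kept, cats = [], []
    for onset, cat in zip(events.onsets, events.categories):
        lo = onset + start
        hi = lo + n_samples
        if lo < 0 or hi > n_total:
            log.warning(
                "event at sample %d does not fit the epoch window; skipped", onset
            )
            continue
        kept.append(recording.data[:, lo:hi])
        cats.append(cat)
    if kept:
        data = np.stack(kept, axis=0)          # (trials, sensors, time)
    else:
        data = np.empty((0, recording.montage.n_sensors, n_samples))
    time_axis = window_ms[0] + np.arange(n_samples) * 1000.0 / rate
    return EpochSet(
        data=data,
        time_axis=time_axis,
        categories=np.asarray(cats, dtype=object),
        montage=recording.montage,
        rate=rate,
        participant_id=participant_id,
    )


def baseline_correct(
    epochs: EpochSet,
    baseline_ms: Tuple[float, float] = DEFAULT_CONFIG.baseline_ms,
) -> EpochSet:
    """Subtract the per-trial, per-sensor mean over the baseline window."""
    t = epochs.time_axis
    mask = (t >= baseline_ms[0]) & (t < baseline_ms[1])
    if not mask.any():
        raise ValidationError("baseline window lies outside the epoch")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.copy_with(epochs.data - base)


def detect_bad_sensors(
    sensor_flags: np.ndarray,
    montage: SensorMontage,
    fraction: float = DEFAULT_CONFIG.bad_sensor_fraction,
) -> List[str]:
    """Sensors flagged in more than ``fraction`` of segments are declared bad.

    This re-expresses, at epoch granularity, the rule of interpolating
    channels contaminated for more than half of the recording.
    """
    if sensor_flags.size == 0:
        return []
    frac = sensor_flags.mean(axis=0)
    return [montage.labels[i] for i in np.nonzero(frac > fraction)[0]]
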