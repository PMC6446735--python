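"""Rule-based artifact detection, segment rejection and participant retention.

Four per-sensor rules, applied to baseline-corrected epochs:

1. amplitude excursion: any sample above +100 µV or below −100 µV
2. segment range: max − min over the whole segment larger than 100 µV
3. step: absolute difference between two contiguous samples above 25 µV
4. flatline: less than 0.5 µV variation sustained for more than 100 ms
   (at 250 Hz: any window of 26 or more consecutive samples whose
   max − min stays below the band)

All exclusion inequalities are strict, so boundary cases pass: a segment is
dropped only when the flagged-sensor fraction *exceeds* 10%, and a
participant is excluded only when some category retains *fewer than* 20% of
its possible trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .config import AnalysisConfig, DEFAULT_CONFIG, CATEGORIES
from .data_model import EpochSet, ValidationError

RULE_AMPLITUDE = 1
RULE_RANGE = 2
RULE_STEP = 3
RULE_FLATLINE = 4


@dataclass
class QCMask:
    """QC decisions for one participant's epochs."""

    sensor_flags: np.ndarray      # (trials, sensors) bool
    rule_bits: np.ndarray         # (trials, sensors) uint8 bitmask, bit r-1 = rule r
    segment_keep: np.ndarray      # (trials,) bool
    participant_keep: bool = True

    def flagged_fraction(self) -> np.ndarray:
        return self.sensor_flags.mean(axis=1)


def flag_sensor_artifacts(
    data: np.ndarray,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Tuple[np.ndarray, np.ndarray]:
    """Apply the four artifact rules to epoched data.

    Parameters
    ----------
    data : (trials, sensors, time) or (sensors, time) voltage array, µV.

    Returns
    -------
    flags : bool array (trials, sensors) — any rule fired
    rule_bits : uint8 array (trials, sensors) — bit r−1 set iff rule r fired
    """
    x = np.asarray(data, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    if x.shape[-1] < 2:
        raise ValidationError("epochs must have at least 2 samples")

    bits = np.zeros(x.shape[:2], dtype=np.uint8)

    # rule 1: amplitude excursion (strict)
    r1 = np.any(np.abs(x) > config.amp_limit_uv, axis=2)
    bits |= np.uint8(1 << (RULE_AMPLITUDE - 1)) * r1

    # rule 2: whole-segment range (strict)
    r2 = (x.max(axis=2) - x.min(axis=2)) > config.range_limit_uv
    bits |= np.uint8(1 << (RULE_RANGE - 1)) * r2

    # rule 3: contiguous-sample step (strict)
    r3 = np.any(np.abs(np.diff(x, axis=2)) > config.step_limit_uv, axis=2)
    bits |= np.uint8(1 << (RULE_STEP - 1)) * r3

    # rule 4: sustained flatline — sliding-window max−min below the band
    w = config.flat_min_samples
    if x.shape[-1] >= w:
        hi = maximum_filter1d(x, size=w, axis=2, mode="nearest", origin=-(w // 2))
        lo = minimum_filter1d(x, size=w, axis=2, mode="nearest", origin=-(w // 2))
        n_starts = x.shape[-1] - w + 1
        r4 = np.any(
            (hi - lo)[..., :n_starts] < config.flat_band_uv, axis=2
        )
        bits |= np.uint8(1 << (RULE_FLATLINE - 1)) * r4

    flags = bits > 0
    if squeeze:
        return flags[0], bits[0]
    return flags, bits


def reject_segments(
    sensor_flags: np.ndarray,
    drop_fraction: float = DEFAULT_CONFIG.segment_drop_fraction,
) -> np.ndarray:
    """Keep a segment unless the flagged-sensor fraction strictly exceeds
    ``drop_fraction``."""
    if not 0.0 < drop_fraction < 1.0:
        raise ValidationError("drop_fraction must be in (0, 1)")
    flags = np.asarray(sensor_flags, dtype=bool)
    return flags.mean(axis=1) <= drop_fraction


def participant_retention(
    trial_counts: Mapping[str, int],
    possible_counts: Mapping[str, int],
    retention_fraction: float = DEFAULT_CONFIG.retention_fraction,
) -> bool:
    """A participant is kept unless, in any category, the retained fraction
    of possible trials falls strictly below ``retention_fraction``."""
    missing = set(possible_counts) - set(trial_counts)
    if missing:
        raise ValidationError(f"categories missing from trial counts: {sorted(missing)}")
    missing = set(trial_counts) - set(possible_counts)
    if missing:
        raise ValidationError(f"categories missing from possible counts: {sorted(missing)}")
    for cat, possible in possible_counts.items():
        if possible <= 0:
            raise ValidationError(f"possible count for '{cat}' must be > 0")
        if trial_counts[cat] / possible < retention_fraction:
            return False
    return True


def compute_qc(
    epochs: EpochSet,
    config: AnalysisConfig = DEFAULT_CONFIG,
    possible_counts: Mapping[str, int] | None = None,
) -> QCMask:
    """Full QC for one participant: per-sensor flags, segment rejection, and
    the retention decision (against ``possible_counts`` when supplied,
    otherwise against the epoch set's own per-category counts)."""
    flags, bits = flag_sensor_artifacts(epochs.data, config)
    keep = reject_segments(flags, config.segment_drop_fraction)

    cats = epochs.categories
    present = sorted(set(cats))
    kept_counts = {c: int(np.sum(keep & (cats == c))) for c in present}
    if possible_counts is None:
        possible_counts = {c: int(np.sum(cats == c)) for c in present}
    participant_keep = participant_retention(
        {c: kept_counts.get(c, 0) for c in possible_counts},
        dict(possible_counts),
        config.retention_fraction,
    )
    return QCMask(
        sensor_flags=flags,
        rule_bits=bits,
        segment_keep=keep,
        participant_keep=participant_keep,
    )
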