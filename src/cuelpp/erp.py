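"""Category-wise ERP averaging and LPP extraction.

The LPP (late positive potential) is the mean voltage over the 10
centroparietal ROI sensors in the half-open 400–800 ms window after picture
onset (100 samples at 250 Hz), computed on the per-category average ERP.
Segments are kept or dropped whole: a flagged sensor inside a kept segment
is not masked from the average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .config import CATEGORIES, DEFAULT_CONFIG, AnalysisConfig
from .data_model import EpochSet, LPPTable, SensorMontage, ValidationError
from .qc import QCMask


@dataclass
class CategoryAverage:
    """Average ERP waveform (sensors x time, µV) for one picture category."""

    participant_id: str
    category: str
    waveform: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValidationError("a category average needs at least one trial")


def average_by_category(
    epochs: EpochSet,
    qc_mask=None,
) -> Dict[str, CategoryAverage]:
    """Arithmetic mean over kept trials, per category present in the epochs.

    ``qc_mask`` may be a :class:`~cuelpp.qc.QCMask` or a per-trial boolean
    keep vector; omitted, every trial is used.
    """
    if qc_mask is None:
        keep = np.ones(epochs.n_trials, dtype=bool)
    elif hasattr(qc_mask, "segment_keep"):
        keep = np.asarray(qc_mask.segment_keep, dtype=bool)
    else:
        keep = np.asarray(qc_mask, dtype=bool)
    out: Dict[str, CategoryAverage] = {}
    for cat in sorted(set(epochs.categories)):
        sel = keep & (epochs.categories == cat)
        n = int(sel.sum())
        if n == 0:
            raise ValidationError(
                f"no kept trials for category '{cat}' of participant "
                f"'{epochs.participant_id}' (retention rule should have excluded them)"
            )
        out[cat] = CategoryAverage(
            participant_id=epochs.participant_id,
            category=cat,
            waveform=epochs.data[sel].mean(axis=0),
            n_trials=n,
        )
    return out


def extract_lpp(
    average: CategoryAverage,
    montage: SensorMontage,
    time_axis: np.ndarray,
    window_ms: Tuple[float, float] = DEFAULT_CONFIG.lpp_window_ms,
) -> float:
    """Mean voltage over ROI sensors and the [400, 800) ms window, µV."""
    if average.waveform.shape[0] != montage.n_sensors:
        raise ValidationError("waveform sensors do not match montage")
    t = np.asarray(time_axis, dtype=float)
    mask = (t >= window_ms[0]) & (t < window_ms[1])
    if not mask.any():
        raise ValidationError("LPP window lies outside the epoch")
    roi = montage.roi_indices
    return float(average.waveform[np.ix_(roi, np.nonzero(mask)[0])].mean())


def build_lpp_table(
    participant_averages: Mapping[str, Mapping[str, CategoryAverage]],
    montage: SensorMontage,
    time_axis: np.ndarray,
    window_ms: Tuple[float, float] = DEFAULT_CONFIG.lpp_window_ms,
) -> pd.DataFrame:
    """Assemble the per-participant 8-category LPP table (µV) with trial counts.

    Input is ``{participant_id: {category: CategoryAverage}}``; all 8
    categories must be present for every participant. Rows are sorted by
    participant id so the result is invariant to input order. Ipsatized
    columns are added by :func:`cuelpp.cluster.ipsatize_table`.
    """
    rows = {}
    for pid in sorted(participant_averages):
        averages = participant_averages[pid]
        missing = set(CATEGORIES) - set(averages)
        if missing:
            raise ValidationError(
                f"participant '{pid}' is missing categories {sorted(missing)}"
            )
        row = {}
        for cat in CATEGORIES:
            row[f"lpp_{cat}"] = extract_lpp(averages[cat], montage, time_axis, window_ms)
            row[f"n_{cat}"] = averages[cat].n_trials
        rows[pid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "participant_id"
    return df
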