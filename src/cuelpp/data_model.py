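"""Domain types and file I/O for epoched EEG, events, montages and tables.

Conventions
-----------
* sample indices are 0-based; time windows are half-open ``[start, end)`` ms
* event onsets are given in samples, never milliseconds
* epochs are stored as a binary ``.npy`` array (trials x sensors x time,
  float64 microvolts) with a JSON sidecar header carrying shape, rate,
  sensor labels, per-trial categories and the time axis
* all tabular formats are tab-separated text with a header row
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import CATEGORIES, ROI_SENSOR_LABELS

__all__ = [
    "SensorMontage",
    "EventTable",
    "Recording",
    "EpochSet",
    "LPPTable",
    "OutcomeTable",
    "default_montage",
    "read_event_table",
    "write_event_table",
    "read_montage",
    "write_montage",
    "read_outcome_table",
    "write_outcome_table",
    "read_epochs",
    "write_epochs",
    "read_lpp_table",
    "write_lpp_table",
    "write_tables",
]


class FormatError(ValueError):
    """A file does not match the expected tabular layout."""


class ValidationError(ValueError):
    """Values violate a domain invariant."""


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------

@dataclass
class SensorMontage:
    """Sensor labels, unit-sphere positions, and the centroparietal ROI."""

    labels: Sequence[str]
    positions: np.ndarray          # (n_sensors, 3)
    roi: Sequence[str]             # subset of labels

    def __post_init__(self) -> None:
        self.labels = [str(s) for s in self.labels]
        self.positions = np.asarray(self.positions, dtype=float)
        self.roi = [str(s) for s in self.roi]
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("sensor labels must be unique")
        if self.positions.shape != (len(self.labels), 3):
            raise ValidationError("positions must be (n_sensors, 3)")
        if not self.roi:
            raise ValidationError("ROI must be non-empty")
        missing = set(self.roi) - set(self.labels)
        if missing:
            raise ValidationError(f"ROI sensors not in montage: {sorted(missing)}")

    @property
    def n_sensors(self) -> int:
        return len(self.labels)

    @property
    def roi_indices(self) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.labels)}
        return np.array([index[s] for s in self.roi], dtype=int)

    def index_of(self, label: str) -> int:
        return self.labels.index(str(label))


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic, roughly uniform layout of n points on the upper
    hemisphere of the unit sphere (a stand-in head geometry)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 0.98 * i / max(n - 1, 1)          # z in (0, 1]
    r = np.sqrt(np.clip(1.0 - z ** 2, 0.0, 1.0))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def default_montage(n_sensors: int = 129, n_roi: int = 10) -> SensorMontage:
    """Default dense montage.

    With 129 sensors the ROI carries the conventional centroparietal labels
    (7, 31, 37, 54, 55, 79, 80, 87, 106, 129); smaller montages (useful for
    tests) get plain numeric labels with the ROI nearest a centroparietal
    reference point.
    """
    if n_sensors < max(n_roi, 4):
        raise ValidationError("montage too small")
    pos = _fibonacci_hemisphere(n_sensors)
    ref = np.array([0.0, -0.35, 0.94])
    ref /= np.linalg.norm(ref)
    d = np.linalg.norm(pos - ref, axis=1)
    roi_idx = np.argsort(d)[:n_roi]

    labels = [""] * n_sensors
    if n_sensors == 129 and n_roi == len(ROI_SENSOR_LABELS):
        roi_labels = list(ROI_SENSOR_LABELS)
    else:
        roi_labels = [str(k + 1) for k in range(n_roi)]
    for lab, idx in zip(roi_labels, roi_idx):
        labels[idx] = lab
    pool = (str(k) for k in range(1, n_sensors + 1) if str(k) not in set(roi_labels))
    for i in range(n_sensors):
        if not labels[i]:
            labels[i] = next(pool)
    return SensorMontage(labels=labels, positions=pos, roi=roi_labels)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ("trial_id", "onset_sample", "category", "block")


@dataclass
class EventTable:
    """Stimulus events: trial id, onset (samples), category, block."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        for col in EVENT_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"event table is missing column '{col}'")
        df = df.loc[:, list(EVENT_COLUMNS)].reset_index(drop=True)
        bad = set(df["category"]) - set(CATEGORIES)
        if bad:
            raise ValidationError(
                f"unknown categories {sorted(bad)}; legal labels are {list(CATEGORIES)}"
            )
        onsets = df["onset_sample"].to_numpy()
        if np.any(onsets < 0):
            raise ValidationError("event onsets must be >= 0")
        if len(onsets) > 1 and np.any(np.diff(onsets) <= 0):
            raise ValidationError("event onsets must be strictly increasing")
        df = df.astype(
            {"trial_id": int, "onset_sample": int, "category": str, "block": int}
        )
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    @property
    def onsets(self) -> np.ndarray:
        return self.table["onset_sample"].to_numpy()

    @property
    def categories(self) -> np.ndarray:
        return self.table["category"].to_numpy()


def read_event_table(path) -> EventTable:
    df = pd.read_csv(path, sep="\t")
    return EventTable(df)


def write_event_table(events: EventTable, path) -> None:
    events.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# recording / epochs
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Continuous multi-sensor voltage data (sensors x samples, microvolts)."""

    data: np.ndarray
    rate: float
    montage: SensorMontage
    events: Optional[EventTable] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("recording data must be sensors x samples")
        if self.data.shape[0] != self.montage.n_sensors:
            raise ValidationError("data rows must match montage sensors")
        if self.rate <= 0:
            raise ValidationError("rate must be positive")


@dataclass
class EpochSet:
    """Epoched voltage data: trials x sensors x time (microvolts).

    ``time_axis`` is in ms relative to picture onset; with the default
    window it runs −100..+1096 in 4 ms steps (300 samples) and index 25
    corresponds to t = 0.
    """

    data: np.ndarray
    time_axis: np.ndarray
    categories: np.ndarray
    montage: SensorMontage
    rate: float = 250.0
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.categories = np.asarray(self.categories, dtype=object)
        if self.data.ndim != 3:
            raise ValidationError("epoch data must be trials x sensors x time")
        if self.data.shape[2] != self.time_axis.size:
            raise ValidationError("time axis length must match data")
        if self.data.shape[0] != self.categories.size:
            raise ValidationError("one category label per trial required")
        if self.data.shape[1] != self.montage.n_sensors:
            raise ValidationError("sensor dimension must match montage")
        bad = set(self.categories) - set(CATEGORIES)
        if bad:
            raise ValidationError(f"unknown categories {sorted(bad)}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy_with(self, data: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=data,
            time_axis=self.time_axis,
            categories=self.categories,
            montage=self.montage,
            rate=self.rate,
            participant_id=self.participant_id,
        )


def write_epochs(epochs: EpochSet, base_path) -> None:
    """Write an epoch container: ``<base>.npy`` + ``<base>.json`` header."""
    base = Path(base_path)
    np.save(base.with_suffix(".npy"), epochs.data)
    header = {
        "participant_id": epochs.participant_id,
        "rate": epochs.rate,
        "shape": list(epochs.data.shape),
        "time_axis_ms": epochs.time_axis.tolist(),
        "categories": epochs.categories.tolist(),
        "sensor_labels": list(epochs.montage.labels),
        "roi": list(epochs.montage.roi),
        "positions": epochs.montage.positions.tolist(),
    }
    base.with_suffix(".json").write_text(json.dumps(header))


def read_epochs(base_path) -> EpochSet:
    base = Path(base_path)
    data = np.load(base.with_suffix(".npy"))
    header = json.loads(base.with_suffix(".json").read_text())
    montage = SensorMontage(
        labels=header["sensor_labels"],
        positions=np.asarray(header["positions"]),
        roi=header["roi"],
    )
    return EpochSet(
        data=data,
        time_axis=np.asarray(header["time_axis_ms"]),
        categories=np.asarray(header["categories"], dtype=object),
        montage=montage,
        rate=header["rate"],
        participant_id=header["participant_id"],
    )


# ---------------------------------------------------------------------------
# LPP and outcome tables
# ---------------------------------------------------------------------------

@dataclass
class LPPTable:
    """Per-participant LPP means (µV), ipsatized profiles, and trial counts.

    Backed by a DataFrame indexed by participant with columns
    ``lpp_<category>``, ``z_<category>`` and ``n_<category>`` in the fixed
    category order.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        cols = (
            [f"lpp_{c}" for c in CATEGORIES]
            + [f"z_{c}" for c in CATEGORIES]
            + [f"n_{c}" for c in CATEGORIES]
        )
        missing = [c for c in cols if c not in self.table.columns]
        if missing:
            raise FormatError(f"LPP table missing columns {missing}")
        self.table = self.table.loc[:, cols]
        z = self.z_matrix
        if len(self.table):
            mean = z.mean(axis=1)
            sd = z.std(axis=1, ddof=1)
            if not (np.all(np.abs(mean) < 1e-9) and np.all(np.abs(sd - 1) < 1e-9)):
                raise ValidationError(
                    "ipsatized profiles must have mean 0 and sample SD 1"
                )

    @property
    def participants(self) -> list:
        return list(self.table.index)

    @property
    def lpp_matrix(self) -> np.ndarray:
        return self.table[[f"lpp_{c}" for c in CATEGORIES]].to_numpy(dtype=float)

    @property
    def z_matrix(self) -> np.ndarray:
        return self.table[[f"z_{c}" for c in CATEGORIES]].to_numpy(dtype=float)


OUTCOME_COLUMNS = ("candies", "age", "gender", "bmi", "pre_hunger", "paired_content")


@dataclass
class OutcomeTable:
    """Per-participant candy counts and covariates."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        for col in OUTCOME_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"outcome table is missing column '{col}'")
        if np.any(df["candies"].to_numpy() < 0):
            raise ValidationError("candy counts must be non-negative")
        for col in ("age", "bmi", "pre_hunger"):
            if not np.all(np.isfinite(df[col].to_numpy(dtype=float))):
                raise ValidationError(f"covariate '{col}' must be finite")
        bad = set(df["paired_content"]) - {"sweet", "savory"}
        if bad:
            raise ValidationError(f"paired_content must be sweet/savory, got {bad}")
        df = df.astype(
            {"candies": int, "age": float, "bmi": float, "pre_hunger": float}
        )
        self.table = df

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"   # 12 significant digits for reals


def write_montage(montage: SensorMontage, path) -> None:
    roi = set(montage.roi)
    df = pd.DataFrame(
        {
            "sensor_id": montage.labels,
            "x": montage.positions[:, 0],
            "y": montage.positions[:, 1],
            "z": montage.positions[:, 2],
            "is_roi": [int(s in roi) for s in montage.labels],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_montage(path) -> SensorMontage:
    df = pd.read_csv(path, sep="\t", dtype={"sensor_id": str})
    for col in ("sensor_id", "x", "y", "z", "is_roi"):
        if col not in df.columns:
            raise FormatError(f"montage table is missing column '{col}'")
    roi = df.loc[df["is_roi"].astype(int) == 1, "sensor_id"].tolist()
    return SensorMontage(
        labels=df["sensor_id"].tolist(),
        positions=df[["x", "y", "z"]].to_numpy(dtype=float),
        roi=roi,
    )


def write_outcome_table(outcomes: OutcomeTable, path) -> None:
    outcomes.table.to_csv(
        path, sep="\t", index_label="participant_id", float_format=_FLOAT_FMT
    )


def read_outcome_table(path) -> OutcomeTable:
    df = pd.read_csv(path, sep="\t", index_col="participant_id")
    return OutcomeTable(df)


def write_lpp_table(lpp: LPPTable, path) -> None:
    lpp.table.to_csv(
        path, sep="\t", index_label="participant_id", float_format=_FLOAT_FMT
    )


def read_lpp_table(path) -> LPPTable:
    df = pd.read_csv(path, sep="\t", index_col="participant_id")
    return LPPTable(df)


def write_tables(
    out_dir,
    lpp_table: Optional[LPPTable] = None,
    cluster_solution=None,
    outcome_table: Optional[OutcomeTable] = None,
    stats_report: Optional[Mapping] = None,
) -> Dict[str, Path]:
    """Write the participant-level result tables and the statistics report.

    Returns a mapping of artifact name to path. Integers round-trip
    bit-for-bit; reals to 12 significant digits.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    if lpp_table is not None:
        p = out / "lpp_table.tsv"
        write_lpp_table(lpp_table, p)
        written["lpp_table"] = p
    if outcome_table is not None:
        p = out / "outcomes.tsv"
        write_outcome_table(outcome_table, p)
        written["outcomes"] = p
    if cluster_solution is not None:
        p = out / "assignments.tsv"
        cluster_solution.assignments_frame().to_csv(p, sep="\t", index=False)
        written["assignments"] = p
    if stats_report is not None:
        p = out / "stats.json"
        p.write_text(json.dumps(stats_report, indent=2, default=_jsonify))
        written["stats"] = p
    return written


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
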