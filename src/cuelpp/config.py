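"""Analysis configuration: every numeric constant of the pipeline in one place.

The defaults reproduce the standard cued-food-delivery ERP protocol: 250 Hz
sampling, 30 Hz offline low-pass, −100..1100 ms epochs with a −100..0 ms
baseline, the four rule-based artifact criteria, the 10%/20% segment and
participant exclusion thresholds, and the 400–800 ms centroparietal LPP
window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence, Tuple

#: Fixed stimulus-category order used for every 8-vector, table and report.
CATEGORIES: Tuple[str, ...] = (
    "food_paired",
    "erotica",
    "romantic",
    "food_unpaired",
    "neutral",
    "pollution",
    "violence",
    "mutilation",
)

#: Labels of the 10 centroparietal region-of-interest sensors in the default
#: 129-sensor net.
ROI_SENSOR_LABELS: Tuple[str, ...] = (
    "7", "31", "37", "54", "55", "79", "80", "87", "106", "129",
)

#: Per-block stimulus composition of the cued food delivery task
#: (55 images per block, 6 blocks).
BLOCK_COMPOSITION = {
    "food_paired": 10,
    "food_unpaired": 10,
    "erotica": 5,
    "romantic": 5,
    "neutral": 10,
    "pollution": 5,
    "violence": 5,
    "mutilation": 5,
}

N_BLOCKS = 6

#: Trials per category available to a participant over the whole task.
POSSIBLE_TRIALS = {c: n * N_BLOCKS for c, n in BLOCK_COMPOSITION.items()}


@dataclass
class AnalysisConfig:
    """All tunables of the analysis pipeline with protocol defaults."""

    rate: float = 250.0                     # samples/s
    filter_cutoff_hz: float = 30.0          # offline low-pass
    epoch_window_ms: Tuple[float, float] = (-100.0, 1100.0)   # half-open [a, b)
    baseline_ms: Tuple[float, float] = (-100.0, 0.0)
    lpp_window_ms: Tuple[float, float] = (400.0, 800.0)

    # artifact rules (rule ids 1-4)
    amp_limit_uv: float = 100.0             # rule 1: |x| > limit
    range_limit_uv: float = 100.0           # rule 2: max-min over segment > limit
    step_limit_uv: float = 25.0             # rule 3: contiguous-sample jump > limit
    flat_band_uv: float = 0.5               # rule 4: variation < band ...
    flat_min_ms: float = 100.0              # ... for more than this duration

    segment_drop_fraction: float = 0.10     # drop segment if flagged frac > this
    retention_fraction: float = 0.20        # drop participant if any category < this
    bad_sensor_fraction: float = 0.50       # interpolate sensor flagged in > this frac
    interp_k: int = 4                       # nearest good sensors for interpolation

    k_min: int = 1
    k_max: int = 6
    kmeans_restarts: int = 50
    gap_n_reference: int = 25
    gap_restarts: int = 10                  # restarts per reference fit
    k_criterion: str = "gap"                # gap | silhouette, used when they disagree
    seed: int = 7

    bonferroni_family: int = 8              # pairwise category comparisons
    glm_covariates: Sequence[str] = ("age", "gender", "bmi", "pre_hunger")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not self.filter_cutoff_hz < self.rate / 2:
            raise ValueError("filter cutoff must be below the Nyquist frequency")
        a, b = self.epoch_window_ms
        if not a < b:
            raise ValueError("epoch window must be increasing")
        for name in ("baseline_ms", "lpp_window_ms"):
            lo, hi = getattr(self, name)
            if not (a <= lo < hi <= b):
                raise ValueError(f"{name} must lie within the epoch window")
        for name in ("segment_drop_fraction", "retention_fraction",
                     "bad_sensor_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("k range must satisfy 1 <= k_min <= k_max")
        if self.k_criterion not in ("gap", "silhouette"):
            raise ValueError("k_criterion must be 'gap' or 'silhouette'")
        if self.kmeans_restarts < 1 or self.gap_restarts < 1:
            raise ValueError("restart counts must be >= 1")
        if self.gap_n_reference < 10:
            raise ValueError("gap statistic needs at least 10 reference sets")

    # -- sample-index helpers ------------------------------------------------

    def ms_to_offset(self, t_ms: float) -> int:
        """Sample offset of time ``t_ms`` relative to the epoch start."""
        return int(round((t_ms - self.epoch_window_ms[0]) * self.rate / 1000.0))

    def window_slice(self, window_ms: Tuple[float, float]) -> slice:
        """Half-open sample slice of a time window inside the epoch."""
        return slice(self.ms_to_offset(window_ms[0]), self.ms_to_offset(window_ms[1]))

    @property
    def n_epoch_samples(self) -> int:
        a, b = self.epoch_window_ms
        return int(round((b - a) * self.rate / 1000.0))

    @property
    def flat_min_samples(self) -> int:
        """Shortest run length (in samples) that spans *more than* flat_min_ms.

        At 250 Hz a sample lasts 4 ms, so a run must contain at least 26
        samples (spanning 100 ms from first to last) to exceed 100 ms.
        """
        return int(self.flat_min_ms * self.rate / 1000.0) + 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["glm_covariates"] = list(self.glm_covariates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise KeyError(
                f"unknown config keys {sorted(unknown)}; valid keys: {sorted(known)}"
            )
        kwargs = dict(d)
        for key in ("epoch_window_ms", "baseline_ms", "lpp_window_ms"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "glm_covariates" in kwargs:
            kwargs["glm_covariates"] = tuple(kwargs["glm_covariates"])
        return cls(**kwargs)


DEFAULT_CONFIG = AnalysisConfig()
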