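"""Synthetic cohorts for the cued food delivery task.

Generates everything the pipeline consumes, with known ground truth:

* task schedules — 6 blocks of 55 images over 8 categories with the exact
  per-block composition, no more than two consecutive images of the same
  category, and onset spacing from trial durations plus a random 500–2000 ms
  intertrial interval;
* epoched EEG — per trial, a category-specific raised-cosine LPP bump on
  [400, 800) ms, spatially weighted by a centroparietal topography, plus
  independent 1/f-shaped noise per sensor;
* injected artifacts of the four kinds the QC rules look for;
* candy-count outcomes — negative-binomial counts whose mean depends on the
  latent brain-reactivity profile (C>P vs P>C), plus profile-independent
  covariates.

Two latent profiles drive the amplitude structure: C>P participants respond
more to food-paired cues than to erotica, P>C participants the reverse; both
show the usual arousal gradient (erotica & mutilation > romantic & violence >
neutral & pollution) and food-unpaired ~ neutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterator, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import fft as sfft

from .config import (
    BLOCK_COMPOSITION,
    CATEGORIES,
    DEFAULT_CONFIG,
    N_BLOCKS,
    POSSIBLE_TRIALS,
    AnalysisConfig,
)
from .data_model import (
    EpochSet,
    EventTable,
    OutcomeTable,
    SensorMontage,
    ValidationError,
    default_montage,
)

PROFILES = ("CP", "PC")

#: Default LPP bump peak amplitudes (µV, at unit ROI-mean topography weight).
#: The extracted LPP equals half the peak (window mean of the raised cosine).
#: Values chosen to give the arousal gradient, food_paired > erotica for C>P
#: and the reverse for P>C, and food_unpaired ~ neutral, at magnitudes
#: typical of picture-viewing LPPs.
DEFAULT_AMPLITUDE_MAP: Dict[str, Dict[str, float]] = {
    "CP": {
        "food_paired": 16.0, "erotica": 11.0, "romantic": 6.0,
        "food_unpaired": 3.5, "neutral": 3.5, "pollution": 3.5,
        "violence": 6.0, "mutilation": 13.0,
    },
    "PC": {
        "food_paired": 7.0, "erotica": 13.0, "romantic": 6.0,
        "food_unpaired": 3.5, "neutral": 3.5, "pollution": 3.5,
        "violence": 6.0, "mutilation": 13.0,
    },
}

#: Default per-trial-x-sensor artifact probabilities by kind.
DEFAULT_ARTIFACT_RATES: Dict[str, float] = {
    "excursion": 0.003,
    "jump": 0.002,
    "range": 0.001,
    "flatline": 0.002,
}

#: Default mean candy counts per latent profile (C>P eat ~2.5x more).
DEFAULT_OUTCOME_MEANS: Dict[str, float] = {"CP": 20.0, "PC": 8.0}


@dataclass
class CohortSpec:
    """Generating parameters of a synthetic cohort."""

    n_cp: int = 20
    n_pc: int = 29
    amplitude_map: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {p: dict(m) for p, m in DEFAULT_AMPLITUDE_MAP.items()}
    )
    noise_sd: float = 8.0                       # µV per sensor per sample
    subject_gain_log_sd: float = 0.12           # lognormal overall-amplitude gain
    subject_amp_jitter_sd: float = 0.5          # µV per category, per subject
    subject_offset_sd: float = 2.0              # µV additive LPP offset per subject
    artifact_rates: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARTIFACT_RATES)
    )
    outcome_means: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_MEANS)
    )
    outcome_dispersion: float = 1.5
    n_sensors: int = 129              # montage size; 129 keeps the standard ROI labels
    n_roi: int = 10
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_cp < 0 or self.n_pc < 0:
            raise ValidationError("cohort counts must be >= 0")
        for prof, amps in self.amplitude_map.items():
            if prof not in PROFILES:
                raise ValidationError(f"unknown profile '{prof}'")
            if set(amps) != set(CATEGORIES):
                raise ValidationError(f"amplitude map for '{prof}' must cover all categories")
            if not all(np.isfinite(list(amps.values()))):
                raise ValidationError("amplitudes must be finite")
        for kind, r in self.artifact_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValidationError(f"artifact rate '{kind}' must be in [0, 1]")
        if sum(self.artifact_rates.values()) > 1.0:
            raise ValidationError("artifact rates must sum to at most 1")
        if any(m <= 0 for m in self.outcome_means.values()):
            raise ValidationError("outcome means must be positive")
        if self.outcome_dispersion < 1.0:
            raise ValidationError("under-dispersion (< 1) is unsupported")

    @property
    def n_total(self) -> int:
        return self.n_cp + self.n_pc

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Latent profile membership and generating parameters, the oracle for
    recovery tests."""

    frame: pd.DataFrame              # index participant_id; profile, paired_content,
                                     # gain, offset, amp_<category>
    amplitude_map: Dict[str, Dict[str, float]]
    outcome_means: Dict[str, float]
    outcome_dispersion: float

    @property
    def participants(self) -> list:
        return list(self.frame.index)

    def profile_of(self, pid: str) -> str:
        return str(self.frame.loc[pid, "profile"])


# ---------------------------------------------------------------------------
# task schedule
# ---------------------------------------------------------------------------

TRIAL_DURATION_MS = 2200.0
CONSUMPTION_DELAY_MS = (1000.0, 3000.0)   # uniform, food-paired trials only
ITI_MS = (500.0, 2000.0)
_MAX_SHUFFLES = 1000


def _block_order(rng: np.random.Generator, prev_tail: Sequence[str] = ()) -> list:
    """One block's category sequence with no run longer than 2, including
    runs continuing across the boundary from the previous block's tail."""
    items = [c for c, n in BLOCK_COMPOSITION.items() for _ in range(n)]
    tail = list(prev_tail)[-2:]
    for _ in range(_MAX_SHUFFLES):
        order = list(rng.permutation(items))
        seq = tail + order
        run, ok = 1, True
        for a, b in zip(seq, seq[1:]):
            run = run + 1 if a == b else 1
            if run > 2:
                ok = False
                break
        if ok:
            return order
    raise RuntimeError(
        "could not build a block order without 3+ same-category runs "
        f"after {_MAX_SHUFFLES} shuffles"
    )


def build_task_schedule(
    seed,
    paired_content: str = "sweet",
    rate: float = 250.0,
) -> EventTable:
    """Full 6-block, 330-trial schedule with sample-resolution onsets.

    ``paired_content`` chooses which food category (sweet or savory) is the
    reward-predictive one; its trials are labelled ``food_paired`` and the
    other food category's ``food_unpaired``. The composition already uses
    these roles, so the per-block counts are exact by construction.
    """
    if paired_content not in ("sweet", "savory"):
        raise ValidationError("paired_content must be 'sweet' or 'savory'")
    rng = np.random.default_rng(seed)
    rows = []
    cursor = int(round(0.5 * rate))        # lead-in before the first picture
    trial_id = 0
    tail: list = []
    for block in range(1, N_BLOCKS + 1):
        order = _block_order(rng, tail)
        tail = order[-2:]
        for cat in order:
            rows.append(
                {
                    "trial_id": trial_id,
                    "onset_sample": cursor,
                    "category": cat,
                    "block": block,
                }
            )
            trial_id += 1
            duration = TRIAL_DURATION_MS
            if cat == "food_paired":
                duration += rng.uniform(*CONSUMPTION_DELAY_MS)
            iti = rng.uniform(*ITI_MS)
            cursor += int(round((duration + iti) * rate / 1000.0))
    return EventTable(pd.DataFrame(rows))


def max_run_length(categories: Sequence[str]) -> int:
    best = run = 1
    for a, b in zip(categories, categories[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


# ---------------------------------------------------------------------------
# signal model
# ---------------------------------------------------------------------------

def lpp_bump(time_axis_ms: np.ndarray,
             window_ms: Tuple[float, float] = (400.0, 800.0)) -> np.ndarray:
    """Unit-peak raised cosine supported on the half-open LPP window."""
    t = np.asarray(time_axis_ms, dtype=float)
    lo, hi = window_ms
    shape = np.zeros_like(t)
    inside = (t >= lo) & (t < hi)
    phase = 2.0 * np.pi * (t[inside] - lo) / (hi - lo)
    shape[inside] = 0.5 * (1.0 - np.cos(phase))
    return shape


def centroparietal_topography(montage: SensorMontage, width: float = 0.45) -> np.ndarray:
    """Spatial weights peaking over the centroparietal ROI.

    A Gaussian of the great-circle-ish chordal distance from the ROI
    centroid, made zero-mean across sensors (average-reference-consistent)
    and normalized so the ROI-mean weight is exactly 1. With this
    normalization the extracted LPP of a noise-free bump of peak ``a``
    equals ``a`` times the window mean of the bump shape.
    """
    pos = montage.positions
    center = pos[montage.roi_indices].mean(axis=0)
    center /= np.linalg.norm(center)
    d = np.linalg.norm(pos - center, axis=1)
    w = np.exp(-(d ** 2) / (2.0 * width ** 2))
    w = w - w.mean()
    roi_mean = w[montage.roi_indices].mean()
    if roi_mean <= 0:
        raise ValidationError("degenerate topography: ROI mean weight <= 0")
    return w / roi_mean


def _pink_kernel(n_time: int, rate: float) -> Tuple[np.ndarray, float]:
    """rFFT amplitude shaping for 1/f (power) noise and the scale that gives
    unit per-sample SD for unit-variance white input."""
    freqs = np.fft.rfftfreq(n_time, d=1.0 / rate)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    power = amp ** 2
    if n_time % 2 == 0:
        total = 2.0 * power[1:-1].sum() + power[-1] + power[0]
    else:
        total = 2.0 * power[1:].sum() + power[0]
    scale = 1.0 / math.sqrt(total / n_time)
    return amp, scale


def pink_noise(
    rng: np.random.Generator,
    shape: Tuple[int, ...],
    n_time: int,
    rate: float,
    sd: float,
) -> np.ndarray:
    """1/f-shaped noise with the requested per-sample SD along the last axis."""
    amp, scale = _pink_kernel(n_time, rate)
    white = rng.standard_normal(shape + (n_time,))
    flat = white.reshape(-1, n_time)
    spec = sfft.rfft(flat, axis=-1) * amp
    out = sfft.irfft(spec, n=n_time, axis=-1) * (scale * sd)
    return out.reshape(shape + (n_time,))


def noise_autocovariance(n_time: int, rate: float, sd: float) -> np.ndarray:
    """Exact (circular) autocovariance of the generated noise."""
    amp, scale = _pink_kernel(n_time, rate)
    power_half = (amp * scale * sd) ** 2
    if n_time % 2 == 0:
        full = np.concatenate([power_half, power_half[-2:0:-1]])
    else:
        full = np.concatenate([power_half, power_half[-1:0:-1]])
    return np.fft.ifft(full).real


def lpp_trial_noise_sd(
    noise_sd: float,
    config: AnalysisConfig = DEFAULT_CONFIG,
    n_roi: int = 10,
) -> float:
    """Analytic SD of a single-trial LPP estimate under the noise model.

    The estimate is (mean over the 100 LPP-window samples) − (mean over the
    25 baseline samples), averaged over ``n_roi`` independent sensors. Uses
    the exact spectral form of the generated noise; the small variance
    reductions from the 30 Hz filter and the average reference are ignored,
    so this is slightly conservative.
    """
    n = config.n_epoch_samples
    v = np.zeros(n)
    lpp = config.window_slice(config.lpp_window_ms)
    base = config.window_slice(config.baseline_ms)
    v[lpp] = 1.0 / (lpp.stop - lpp.start)
    v[base] -= 1.0 / (base.stop - base.start)
    amp, scale = _pink_kernel(n, config.rate)
    power_half = (amp * scale * noise_sd) ** 2
    if n % 2 == 0:
        full = np.concatenate([power_half, power_half[-2:0:-1]])
    else:
        full = np.concatenate([power_half, power_half[-1:0:-1]])
    V = np.fft.fft(v)
    var = float(np.sum(full * np.abs(V) ** 2) / n)
    return math.sqrt(var / n_roi)


def expected_lpp(
    amplitudes: Mapping[str, float],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Dict[str, float]:
    """Closed-form noise-free LPP per category: peak x window-mean of bump."""
    t = config.epoch_window_ms[0] + np.arange(config.n_epoch_samples) * 1000.0 / config.rate
    shape = lpp_bump(t, config.lpp_window_ms)
    sl = config.window_slice(config.lpp_window_ms)
    mean_shape = float(shape[sl].mean())
    return {c: a * mean_shape for c, a in amplitudes.items()}


def simulate_epochs(
    schedule: EventTable,
    profile: str,
    amplitude_map: Mapping[str, Mapping[str, float]],
    noise_sd: float,
    montage: SensorMontage,
    seed,
    config: AnalysisConfig = DEFAULT_CONFIG,
    participant_id: str = "",
) -> EpochSet:
    """Epoched EEG for one participant under a latent profile.

    Each trial carries a raised-cosine bump on [400, 800) ms with the
    category's peak amplitude, weighted by the centroparietal topography,
    plus independent 1/f noise per sensor. The baseline interval has zero
    expected mean.
    """
    if profile not in amplitude_map:
        raise ValidationError(f"unknown profile '{profile}'")
    amps = amplitude_map[profile]
    missing = set(schedule.categories) - set(amps)
    if missing:
        raise ValidationError(f"amplitude map missing categories {sorted(missing)}")

    n = config.n_epoch_samples
    t = config.epoch_window_ms[0] + np.arange(n) * 1000.0 / config.rate
    shape = lpp_bump(t, config.lpp_window_ms)
    topo = centroparietal_topography(montage)

    cats = schedule.categories
    peak = np.array([amps[c] for c in cats])
    data = peak[:, None, None] * topo[None, :, None] * shape[None, None, :]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + pink_noise(
            rng, (len(cats), montage.n_sensors), n, config.rate, noise_sd
        )
    return EpochSet(
        data=data,
        time_axis=t,
        categories=cats,
        montage=montage,
        rate=config.rate,
        participant_id=participant_id,
    )


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

ARTIFACT_KINDS = ("excursion", "jump", "range", "flatline")


def inject_artifacts(
    epochs: EpochSet,
    artifact_rates: Mapping[str, float],
    seed,
) -> Tuple[EpochSet, pd.DataFrame]:
    """Inject artifacts into randomly selected trial x sensor cells.

    Each selected cell receives exactly one artifact kind:

    * ``excursion`` — a 10-sample plateau beyond ±100 µV (blink-like fronto-
      temporal excursions are folded into this kind)
    * ``jump`` — a 30–60 µV step between contiguous samples
    * ``range`` — a slow full-segment ramp sweeping > 100 µV peak-to-peak
      with small per-sample increments
    * ``flatline`` — a > 100 ms window replaced by a constant with < 0.2 µV
      jitter

    Returns the modified epochs and an injection log (trial, sensor,
    sensor_label, kind) for oracle tests. Zero rates return the input
    unchanged.
    """
    unknown = set(artifact_rates) - set(ARTIFACT_KINDS)
    if unknown:
        raise ValidationError(f"unknown artifact kinds {sorted(unknown)}")
    rates = {k: float(artifact_rates.get(k, 0.0)) for k in ARTIFACT_KINDS}
    for k, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise ValidationError(f"rate for '{k}' must be in [0, 1]")
    if sum(rates.values()) > 1.0:
        raise ValidationError("artifact rates must sum to at most 1")
    if all(r == 0.0 for r in rates.values()):
        return epochs, pd.DataFrame(columns=["trial", "sensor", "sensor_label", "kind"])

    rng = np.random.default_rng(seed)
    n_trials, n_sensors, n = epochs.data.shape
    u = rng.random((n_trials, n_sensors))
    edges = np.cumsum([rates[k] for k in ARTIFACT_KINDS])
    kind_index = np.searchsorted(edges, u, side="right")   # 4 = no artifact

    data = epochs.data.copy()
    log_rows = []
    for ti, si in zip(*np.nonzero(kind_index < len(ARTIFACT_KINDS))):
        kind = ARTIFACT_KINDS[kind_index[ti, si]]
        x = data[ti, si]
        if kind == "excursion":
            s = rng.integers(5, n - 15)
            x[s:s + 10] = rng.choice([-1.0, 1.0]) * rng.uniform(110.0, 150.0)
        elif kind == "jump":
            s = rng.integers(5, n - 5)
            x[s:] += rng.choice([-1.0, 1.0]) * rng.uniform(30.0, 60.0)
        elif kind == "range":
            sweep = rng.choice([-1.0, 1.0]) * rng.uniform(110.0, 150.0)
            x += np.linspace(-sweep / 2.0, sweep / 2.0, n)
        else:  # flatline
            length = int(rng.integers(30, 41))
            s = int(rng.integers(5, n - length - 5))
            x[s:s + length] = x[s] + rng.uniform(-0.09, 0.09, size=length)
        log_rows.append(
            {
                "trial": int(ti),
                "sensor": int(si),
                "sensor_label": epochs.montage.labels[si],
                "kind": kind,
            }
        )
    log = pd.DataFrame(log_rows, columns=["trial", "sensor", "sensor_label", "kind"])
    return epochs.copy_with(data), log


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

def simulate_outcomes(
    truth: GroundTruth,
    outcome_means: Optional[Mapping[str, float]] = None,
    dispersion: Optional[float] = None,
    seed=0,
    covariate_model: str = "independent",
) -> OutcomeTable:
    """Candy counts and covariates for every participant in the ground truth.

    Counts are negative binomial with mean ``outcome_means[profile]`` and
    variance ``dispersion x mean`` (dispersion 1 degenerates to Poisson);
    the negative binomial realizes the quasi-Poisson mean-variance relation
    with an actual sampling distribution. Covariates (age, gender, BMI,
    pre-task hunger) are drawn independently of profile under the default
    covariate model.
    """
    means = dict(outcome_means if outcome_means is not None else truth.outcome_means)
    phi = float(dispersion if dispersion is not None else truth.outcome_dispersion)
    if any(m <= 0 for m in means.values()):
        raise ValidationError("outcome means must be positive")
    if phi < 1.0:
        raise ValidationError("under-dispersion (< 1) is unsupported")
    if covariate_model != "independent":
        raise ValidationError("only the 'independent' covariate model is built in")

    rng = np.random.default_rng(seed)
    rows = {}
    for pid in truth.participants:
        profile = truth.profile_of(pid)
        mu = means[profile]
        if phi == 1.0:
            candies = int(rng.poisson(mu))
        else:
            r = mu / (phi - 1.0)
            candies = int(rng.negative_binomial(r, r / (r + mu)))
        rows[pid] = {
            "candies": candies,
            "age": int(rng.integers(24, 66)),
            "gender": "female" if rng.random() < 0.45 else "male",
            "bmi": float(np.clip(rng.normal(31.0, 5.0), 18.0, 55.0)),
            "pre_hunger": float(np.clip(rng.normal(-4.4, 18.0), -50.0, 50.0)),
            "paired_content": str(truth.frame.loc[pid, "paired_content"]),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "participant_id"
    return OutcomeTable(df)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _spawn_seeds(seed: int, n: int, stream: int) -> list:
    ss = np.random.SeedSequence([int(seed), int(stream)])
    return list(ss.spawn(n))


def cohort_ground_truth(spec: CohortSpec) -> GroundTruth:
    """Latent profiles, counterbalanced paired content, and per-subject
    amplitude parameters (overall gain, per-category jitter, LPP offset)."""
    n = spec.n_total
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    profiles = ["CP"] * spec.n_cp + ["PC"] * spec.n_pc
    rows = {}
    for i, prof in enumerate(profiles):
        pid = f"p{i + 1:03d}"
        gain = float(np.exp(rng.normal(0.0, spec.subject_gain_log_sd)))
        offset = float(rng.normal(0.0, spec.subject_offset_sd))
        base = spec.amplitude_map[prof]
        row = {
            "profile": prof,
            "paired_content": "sweet" if i % 2 == 0 else "savory",
            "gain": gain,
            "offset": offset,
        }
        for cat in CATEGORIES:
            jitter = rng.normal(0.0, spec.subject_amp_jitter_sd)
            row[f"amp_{cat}"] = gain * (base[cat] + jitter)
        rows[pid] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "participant_id"
    return GroundTruth(
        frame=frame,
        amplitude_map={p: dict(m) for p, m in spec.amplitude_map.items()},
        outcome_means=dict(spec.outcome_means),
        outcome_dispersion=spec.outcome_dispersion,
    )


def participant_amplitudes(truth: GroundTruth, pid: str) -> Dict[str, float]:
    return {c: float(truth.frame.loc[pid, f"amp_{c}"]) for c in CATEGORIES}


@dataclass
class CohortResult:
    """A generated cohort. Epoch sets are produced lazily, one participant at
    a time, because a full 129-sensor cohort does not fit in memory."""

    spec: CohortSpec
    truth: GroundTruth
    outcomes: OutcomeTable
    montage: SensorMontage

    def epoch_sets(self) -> Iterator[Tuple[EpochSet, EventTable, pd.DataFrame]]:
        """Yield (epochs-with-artifacts, schedule, injection log) per
        participant, deterministically from the spec seed."""
        pids = self.truth.participants
        seeds = _spawn_seeds(self.spec.seed, len(pids), stream=1)
        for pid, ss in zip(pids, seeds):
            child = ss.spawn(3)
            paired = str(self.truth.frame.loc[pid, "paired_content"])
            schedule = build_task_schedule(child[0], paired_content=paired)
            amps = participant_amplitudes(self.truth, pid)
            epochs = simulate_epochs(
                schedule,
                profile=str(self.truth.frame.loc[pid, "profile"]),
                amplitude_map={str(self.truth.frame.loc[pid, "profile"]): amps},
                noise_sd=self.spec.noise_sd,
                montage=self.montage,
                seed=child[1],
                participant_id=pid,
            )
            epochs, log = inject_artifacts(epochs, self.spec.artifact_rates, child[2])
            yield epochs, schedule, log


def generate_cohort(
    spec: CohortSpec,
    montage: Optional[SensorMontage] = None,
) -> CohortResult:
    """Assemble a full synthetic cohort with ground truth and outcomes.

    All sub-generators are seeded deterministically from ``spec.seed``, so
    identical specs produce bit-identical cohorts.
    """
    montage = montage or default_montage(spec.n_sensors, spec.n_roi)
    truth = cohort_ground_truth(spec)
    outcomes = simulate_outcomes(
        truth, seed=np.random.SeedSequence([int(spec.seed), 2])
    )
    return CohortResult(spec=spec, truth=truth, outcomes=outcomes, montage=montage)


def simulate_lpp_cohort(
    spec: CohortSpec,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Tuple[pd.DataFrame, GroundTruth]:
    """Cohort directly at the LPP-table stage.

    Uses the same per-subject amplitude parameters as the full EEG path and
    adds per-category measurement noise with the analytic single-trial LPP
    SD divided by sqrt(trials per category) — i.e. what the pipeline's
    averaging would leave, assuming all trials retained. Returns the raw LPP
    DataFrame (lpp_/n_ columns) and the ground truth.
    """
    truth = cohort_ground_truth(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 3]))
    sd1 = lpp_trial_noise_sd(spec.noise_sd, config)
    t = config.epoch_window_ms[0] + np.arange(config.n_epoch_samples) * 1000.0 / config.rate
    sl = config.window_slice(config.lpp_window_ms)
    mean_shape = float(lpp_bump(t, config.lpp_window_ms)[sl].mean())

    rows = {}
    for pid in truth.participants:
        offset = float(truth.frame.loc[pid, "offset"])
        row = {}
        for cat in CATEGORIES:
            n_tr = POSSIBLE_TRIALS[cat]
            mean = float(truth.frame.loc[pid, f"amp_{cat}"]) * mean_shape + offset
            row[f"lpp_{cat}"] = mean + rng.normal(0.0, sd1 / math.sqrt(n_tr))
            row[f"n_{cat}"] = n_tr
        rows[pid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "participant_id"
    return df, truth
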