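"""End-to-end orchestration: simulate → preprocess → QC → LPP → cluster → stats.

Each stage is a pure function over the domain types; the CLI persists
intermediate artifacts, while :func:`run_cohort_pipeline` streams
participants through the EEG stages one at a time (a full dense-montage
cohort does not fit in memory) and produces identical downstream results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .config import CATEGORIES, POSSIBLE_TRIALS, AnalysisConfig, DEFAULT_CONFIG
from .cluster import (
    ClusterSolution,
    KSelectionDiagnostics,
    ipsatize_table,
    kmeans_fit,
    label_profiles,
    select_k,
    LABEL_CP,
    LABEL_PC,
)
from .data_model import (
    EpochSet,
    LPPTable,
    OutcomeTable,
    SensorMontage,
    ValidationError,
    write_tables,
)
from .erp import average_by_category, build_lpp_table
from .preprocess import (
    average_reference,
    baseline_correct,
    detect_bad_sensors,
    interpolate_bad_sensors,
    lowpass_filter,
)
from .qc import compute_qc, flag_sensor_artifacts, reject_segments, participant_retention
from .stats import (
    covariate_balance,
    group_by_category_test,
    mann_whitney_u,
    pairwise_group_comparisons,
    quadratic_trend_test,
    quasipoisson_fit,
)
from .synth import CohortSpec, GroundTruth, generate_cohort

log = logging.getLogger(__name__)


@dataclass
class ParticipantQC:
    participant_id: str
    keep: bool
    n_segments: int
    n_kept: int
    bad_sensors: List[str]
    kept_per_category: Dict[str, int]

    def to_row(self) -> dict:
        row = {
            "participant_id": self.participant_id,
            "keep": int(self.keep),
            "segments_total": self.n_segments,
            "segments_kept": self.n_kept,
            "sensors_interpolated": ",".join(self.bad_sensors) or "-",
        }
        for cat in CATEGORIES:
            row[f"kept_{cat}"] = self.kept_per_category.get(cat, 0)
            row[f"possible_{cat}"] = POSSIBLE_TRIALS[cat]
        return row


def preprocess_epochs(
    epochs: EpochSet,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> EpochSet:
    """Filter, average-reference and baseline-correct one participant."""
    out = lowpass_filter(epochs, config.filter_cutoff_hz)
    out = average_reference(out)
    out = baseline_correct(out, config.baseline_ms)
    return out


def qc_participant(
    epochs: EpochSet,
    config: AnalysisConfig = DEFAULT_CONFIG,
    possible_counts: Optional[Mapping[str, int]] = None,
) -> Tuple[EpochSet, "ParticipantQC", np.ndarray]:
    """Artifact QC with bad-sensor interpolation.

    Flags are computed on the (already baseline-corrected) epochs; sensors
    flagged in more than half of the segments are interpolated and the flags
    recomputed before segment rejection and the retention decision.
    Returns the (possibly interpolated) epochs, the QC summary, and the
    per-segment keep vector.
    """
    flags, _ = flag_sensor_artifacts(epochs.data, config)
    bad = detect_bad_sensors(flags, epochs.montage, config.bad_sensor_fraction)
    if bad:
        epochs = interpolate_bad_sensors(epochs, bad, epochs.montage, config.interp_k)
    qc = compute_qc(epochs, config, possible_counts=possible_counts)
    cats = epochs.categories
    kept_counts = {
        c: int(np.sum(qc.segment_keep & (cats == c))) for c in sorted(set(cats))
    }
    summary = ParticipantQC(
        participant_id=epochs.participant_id,
        keep=qc.participant_keep,
        n_segments=epochs.n_trials,
        n_kept=int(qc.segment_keep.sum()),
        bad_sensors=bad,
        kept_per_category=kept_counts,
    )
    return epochs, summary, qc.segment_keep


@dataclass
class PipelineResult:
    """Everything the full pipeline produces for one cohort."""

    lpp_table: LPPTable
    solution: ClusterSolution
    diagnostics: KSelectionDiagnostics
    outcomes: OutcomeTable
    truth: Optional[GroundTruth]
    qc_report: pd.DataFrame
    stats: dict
    config: AnalysisConfig

    def labels_by_participant(self) -> Dict[str, str]:
        return {
            pid: self.solution.labels.get(int(c), "unlabelled")
            for pid, c in zip(self.lpp_table.participants, self.solution.assignments)
        }


def cluster_lpp_table(
    lpp_table: LPPTable,
    config: AnalysisConfig = DEFAULT_CONFIG,
    seed: Optional[int] = None,
) -> Tuple[ClusterSolution, KSelectionDiagnostics]:
    """k selection + final fit + profile labelling on ipsatized profiles."""
    Z = lpp_table.z_matrix
    seed = config.seed if seed is None else seed
    diagnostics = select_k(Z, config, seed=seed)
    solution = kmeans_fit(
        Z,
        diagnostics.chosen_k,
        config.kmeans_restarts,
        seed,
        participants=lpp_table.participants,
    )
    solution = label_profiles(solution)
    return solution, diagnostics


def compute_statistics(
    lpp_table: LPPTable,
    solution: ClusterSolution,
    outcomes: OutcomeTable,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> dict:
    """The validation and outcome statistics battery for a labelled cohort."""
    pids = lpp_table.participants
    labels = {
        pid: solution.labels.get(int(c), "unlabelled")
        for pid, c in zip(pids, solution.assignments)
    }
    lpp_df = lpp_table.table
    report: dict = {"groups": solution.member_counts()}

    by_label: Dict[str, list] = {}
    for pid, lab in labels.items():
        by_label.setdefault(lab, []).append(pid)

    if set(by_label) == {LABEL_CP, LABEL_PC}:
        report["quadratic_trend"] = {
            lab: quadratic_trend_test(lpp_df, members).to_dict()
            for lab, members in by_label.items()
        }
        groups = np.asarray([labels[p] for p in pids])
        manova = group_by_category_test(lpp_table.lpp_matrix, groups)
        report["manova"] = {k: v.to_dict() for k, v in manova.items()}
        report["pairwise_between"] = [
            r.to_dict()
            for r in pairwise_group_comparisons(lpp_df, labels, config.bonferroni_family)
        ]

        out_df = outcomes.table.loc[pids]
        cp, pc = by_label[LABEL_CP], by_label[LABEL_PC]
        x = out_df.loc[cp, "candies"].to_numpy()
        y = out_df.loc[pc, "candies"].to_numpy()
        mw = mann_whitney_u(x, y)
        report["candies"] = {
            "mean_cp": float(x.mean()),
            "mean_pc": float(y.mean()),
            "mann_whitney": {**mw.to_dict(), "u_x": mw.u_x, "u_y": mw.u_y,
                             "method": mw.method},
        }
        group_col = pd.Series(
            [1.0 if labels[p] == LABEL_CP else 0.0 for p in pids],
            index=pids, name="group_cp",
        )
        design_unadj = pd.DataFrame({"group_cp": group_col})
        counts = out_df["candies"].to_numpy()
        fit0 = quasipoisson_fit(counts, design_unadj)
        design_adj = design_unadj.join(out_df[list(config.glm_covariates)])
        fit1 = quasipoisson_fit(counts, design_adj)
        report["quasipoisson"] = {
            "unadjusted": fit0.wald_test("group_cp").to_dict()
            | {"dispersion": fit0.dispersion},
            "adjusted": fit1.wald_test("group_cp").to_dict()
            | {"dispersion": fit1.dispersion},
        }
        covars = out_df[["age", "gender", "bmi", "pre_hunger"]]
        report["covariate_balance"] = [
            r.to_dict() for r in covariate_balance(covars, labels)
        ]
    else:
        report["note"] = (
            "profile labels unavailable (k != 2 or centroid tie); "
            "group statistics skipped"
        )
    return report


def run_cohort_pipeline(
    spec: CohortSpec,
    config: AnalysisConfig = DEFAULT_CONFIG,
    montage: Optional[SensorMontage] = None,
    out_dir: Optional[Path] = None,
    seed: Optional[int] = None,
) -> PipelineResult:
    """Simulate a cohort and run every analysis stage on it.

    Participants are streamed through the EEG stages one at a time.
    ``seed`` overrides the clustering seed only; the cohort itself is fully
    determined by ``spec.seed``.
    """
    cohort = generate_cohort(spec, montage)
    qc_rows = []
    averages: Dict[str, dict] = {}
    time_axis = None
    for epochs, schedule, _log in cohort.epoch_sets():
        pre = preprocess_epochs(epochs, config)
        pre, summary, keep = qc_participant(pre, config, possible_counts=POSSIBLE_TRIALS)
        qc_rows.append(summary.to_row())
        if not summary.keep:
            log.info("participant %s excluded by the retention rule", pre.participant_id)
            continue
        averages[pre.participant_id] = average_by_category(pre, keep)
        time_axis = pre.time_axis

    if not averages:
        raise ValidationError("no participants survived QC")
    lpp_df = build_lpp_table(averages, cohort.montage, time_axis, config.lpp_window_ms)
    lpp_table = ipsatize_table(lpp_df)
    solution, diagnostics = cluster_lpp_table(lpp_table, config, seed=seed)
    stats = compute_statistics(lpp_table, solution, cohort.outcomes, config)
    qc_report = pd.DataFrame(qc_rows)

    result = PipelineResult(
        lpp_table=lpp_table,
        solution=solution,
        diagnostics=diagnostics,
        outcomes=cohort.outcomes,
        truth=cohort.truth,
        qc_report=qc_report,
        stats=stats,
        config=config,
    )
    if out_dir is not None:
        write_pipeline_artifacts(result, Path(out_dir))
    return result


def write_pipeline_artifacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_tables(
        out_dir,
        lpp_table=result.lpp_table,
        cluster_solution=result.solution,
        outcome_table=result.outcomes,
        stats_report=result.stats,
    )
    result.diagnostics.frame().to_csv(out_dir / "diagnostics.tsv", sep="\t", index=False)
    result.qc_report.to_csv(out_dir / "qc_report.tsv", sep="\t", index=False)
    if result.truth is not None:
        result.truth.frame.to_csv(out_dir / "ground_truth.tsv", sep="\t",
                                  index_label="participant_id")
    report = {
        "config": result.config.to_dict(),
        "participants_in": len(result.qc_report),
        "participants_kept": int(result.qc_report["keep"].sum())
        if len(result.qc_report) else 0,
        "cluster_sizes": result.solution.member_counts(),
        "chosen_k": int(result.solution.k),
        "k_silhouette": int(result.diagnostics.k_silhouette),
        "k_gap": int(result.diagnostics.k_gap),
    }
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=2))
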