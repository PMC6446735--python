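"""Ipsative standardization and endophenotype clustering.

Each participant's 8-category LPP vector is ipsatized (within-person
z-scored: subtract the person's mean, divide by the person's sample SD) to
remove individual differences in overall response amplitude, then k-means
partitions the cohort. The number of clusters is chosen data-driven with the
mean silhouette coefficient and the gap statistic, and for k = 2 the clusters
are labelled by the sign of the food-paired minus erotica centroid contrast:
C>P (cue above pleasant) vs P>C.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .config import CATEGORIES, DEFAULT_CONFIG, AnalysisConfig
from .data_model import LPPTable, ValidationError

log = logging.getLogger(__name__)

LABEL_CP = "C>P"
LABEL_PC = "P>C"
LABEL_NONE = "unlabelled"


# ---------------------------------------------------------------------------
# ipsatization
# ---------------------------------------------------------------------------

def ipsatize(values: np.ndarray, participant_id: str = "") -> np.ndarray:
    """Within-person z-score: (x − mean(x)) / sd(x), sample SD (n−1).

    Invariant under per-person affine rescaling: ipsatize(a·x + c) equals
    ipsatize(x) for any a > 0.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("ipsatization needs a vector of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError(
            f"cannot ipsatize participant '{participant_id}': all values equal"
        )
    return (x - x.mean()) / sd


def ipsatize_table(lpp_df: pd.DataFrame) -> LPPTable:
    """Add ipsatized ``z_<category>`` columns to a raw LPP table."""
    df = lpp_df.copy()
    lpp_cols = [f"lpp_{c}" for c in CATEGORIES]
    z = np.vstack(
        [ipsatize(row, pid) for pid, row in zip(df.index, df[lpp_cols].to_numpy())]
    ) if len(df) else np.empty((0, len(CATEGORIES)))
    for j, c in enumerate(CATEGORIES):
        df[f"z_{c}"] = z[:, j] if len(df) else []
    return LPPTable(df)


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

@dataclass
class ClusterSolution:
    """A k-means partition with profile labels."""

    k: int
    assignments: np.ndarray              # (n,) cluster index
    centroids: np.ndarray                # (k, p), member means
    inertia: float                       # within-cluster sum of squares
    participants: Sequence[str] = field(default_factory=list)
    labels: Dict[int, str] = field(default_factory=dict)

    def label_of(self, participant_index: int) -> str:
        return self.labels.get(int(self.assignments[participant_index]), LABEL_NONE)

    def member_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for c in range(self.k):
            out[self.labels.get(c, LABEL_NONE)] = int(np.sum(self.assignments == c))
        return out

    def assignments_frame(self) -> pd.DataFrame:
        pids = (
            list(self.participants)
            if len(self.participants)
            else list(range(len(self.assignments)))
        )
        return pd.DataFrame(
            {
                "participant_id": pids,
                "cluster": self.assignments.astype(int),
                "label": [
                    self.labels.get(int(c), LABEL_NONE) for c in self.assignments
                ],
            }
        )


def _recompute(X: np.ndarray, assign: np.ndarray, k: int):
    """Centroids as exact member means, and the resulting inertia."""
    centroids = np.vstack([X[assign == c].mean(axis=0) for c in range(k)])
    inertia = float(np.sum((X - centroids[assign]) ** 2))
    return centroids, inertia


_EXACT_N_LIMIT = 12


def _exact_two_partition(X: np.ndarray) -> np.ndarray:
    """Globally optimal 2-partition by enumeration of all 2^(n-1)-1 splits."""
    n = X.shape[0]
    best_assign, best_w = None, np.inf
    for code in range(1, 2 ** (n - 1)):
        mask = (code >> np.arange(n)) & 1 == 1
        a, b = X[mask], X[~mask]
        w = np.sum((a - a.mean(axis=0)) ** 2) + np.sum((b - b.mean(axis=0)) ** 2)
        if w < best_w:
            best_w, best_assign = w, mask.astype(int)
    return best_assign


def kmeans_fit(
    X: np.ndarray,
    k: int,
    n_restarts: int = DEFAULT_CONFIG.kmeans_restarts,
    seed: int = 0,
    participants: Sequence[str] = (),
) -> ClusterSolution:
    """Minimum within-cluster-SS partition into k clusters.

    Lloyd iterations with the best of ``n_restarts`` k-means++
    initializations; tiny two-cluster instances (n <= 12) are instead solved
    exactly by enumerating every split, since restarted Lloyd can sit in a
    local optimum there. Final centroids are recomputed as exact member
    means so the solution satisfies the fixed-point invariant to machine
    precision.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("feature matrix must be 2-D")
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValidationError(f"k must be in [1, {n}]")
    if k == 1:
        assign = np.zeros(n, dtype=int)
        centroids, inertia = _recompute(X, assign, 1)
        return ClusterSolution(1, assign, centroids, inertia, list(participants))
    if k == 2 and n <= _EXACT_N_LIMIT:
        assign = _exact_two_partition(X)
        centroids, inertia = _recompute(X, assign, 2)
        return ClusterSolution(2, assign, centroids, inertia, list(participants))
    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        random_state=int(seed) % (2 ** 32),
        algorithm="lloyd",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # duplicate-point convergence chatter
        assign = km.fit_predict(X)
    assign = np.asarray(assign, dtype=int)
    centroids, inertia = _recompute(X, assign, k)
    return ClusterSolution(k, assign, centroids, inertia, list(participants))


# ---------------------------------------------------------------------------
# partition quality: silhouette and gap statistic
# ---------------------------------------------------------------------------

def silhouette_score(X: np.ndarray, assignments: np.ndarray):
    """Mean silhouette and per-point values, Euclidean distances.

    s(i) = (b − a) / max(a, b); singleton clusters score 0 by convention.
    Undefined for k = 1. Degenerate case of all-identical points returns 0.
    """
    X = np.asarray(X, dtype=float)
    assign = np.asarray(assignments, dtype=int)
    ks = np.unique(assign)
    if ks.size < 2:
        raise ValidationError("silhouette is undefined for a single cluster")
    with np.errstate(invalid="ignore"):
        s = silhouette_samples(X, assign)
    s = np.nan_to_num(s, nan=0.0)
    return float(s.mean()), s


@dataclass
class KSelectionDiagnostics:
    """Silhouette and gap-statistic profiles over a k grid."""

    k_grid: np.ndarray
    silhouette: np.ndarray       # NaN at k = 1
    gap: np.ndarray
    gap_se: np.ndarray
    k_silhouette: int
    k_gap: int
    chosen_k: int
    criterion: str

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_grid,
                "silhouette": self.silhouette,
                "gap": self.gap,
                "gap_se": self.gap_se,
            }
        )


def _log_wk(X: np.ndarray, k: int, n_restarts: int, seed: int) -> float:
    sol = kmeans_fit(X, k, n_restarts=n_restarts, seed=seed)
    return float(np.log(max(sol.inertia, 1e-300)))


def gap_statistic(
    X: np.ndarray,
    k_grid: Sequence[int],
    n_reference: int = DEFAULT_CONFIG.gap_n_reference,
    seed: int = 0,
    n_restarts: int = DEFAULT_CONFIG.gap_restarts,
):
    """Gap statistic over a k grid.

    Gap(k) = mean_b log W*_kb − log W_k, with W the pooled within-cluster
    sum of squares and the B reference sets drawn uniformly over the
    feature-wise bounding box of the data. The standard error is
    s_k = sd_b(log W*_kb) · sqrt(1 + 1/B). The selected k is the smallest k
    in the grid with Gap(k) >= Gap(k+1) − s_{k+1}.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k_grid = np.asarray(sorted(k_grid), dtype=int)
    if k_grid.min() < 1 or k_grid.max() > max(n - 1, 1):
        raise ValidationError(f"k grid must lie within [1, {n - 1}]")
    if n_reference < 10:
        raise ValidationError("need at least 10 reference sets")

    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    log_w = np.array([_log_wk(X, k, n_restarts, seed) for k in k_grid])
    log_w_ref = np.empty((n_reference, k_grid.size))
    for b in range(n_reference):
        ref = rng.uniform(lo, hi, size=X.shape)
        for j, k in enumerate(k_grid):
            log_w_ref[b, j] = _log_wk(ref, k, n_restarts, seed + 1 + b)
    gap = log_w_ref.mean(axis=0) - log_w
    se = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_reference)

    k_gap = int(k_grid[-1])
    for j in range(k_grid.size - 1):
        if gap[j] >= gap[j + 1] - se[j + 1]:
            k_gap = int(k_grid[j])
            break
    return gap, se, k_gap


def select_k(
    X: np.ndarray,
    config: AnalysisConfig = DEFAULT_CONFIG,
    seed: Optional[int] = None,
) -> KSelectionDiagnostics:
    """Run both k-selection criteria over the configured grid."""
    seed = config.seed if seed is None else seed
    n = np.asarray(X).shape[0]
    k_grid = np.arange(config.k_min, min(config.k_max, n - 1) + 1)
    sil = np.full(k_grid.size, np.nan)
    for j, k in enumerate(k_grid):
        if k < 2:
            continue
        sol = kmeans_fit(X, int(k), config.kmeans_restarts, seed)
        sil[j], _ = silhouette_score(X, sol.assignments)
    k_sil = int(k_grid[np.nanargmax(sil)]) if np.any(~np.isnan(sil)) else 1
    gap, se, k_gap = gap_statistic(
        X, k_grid, config.gap_n_reference, seed, config.gap_restarts
    )
    chosen = k_gap if config.k_criterion == "gap" else k_sil
    if k_gap != k_sil:
        log.warning(
            "silhouette (k=%d) and gap (k=%d) disagree; using %s criterion (k=%d)",
            k_sil, k_gap, config.k_criterion, chosen,
        )
    return KSelectionDiagnostics(
        k_grid=k_grid,
        silhouette=sil,
        gap=gap,
        gap_se=se,
        k_silhouette=k_sil,
        k_gap=k_gap,
        chosen_k=chosen,
        criterion=config.k_criterion,
    )


# ---------------------------------------------------------------------------
# profile labels
# ---------------------------------------------------------------------------

def label_profiles(
    solution: ClusterSolution,
    category_order: Sequence[str] = CATEGORIES,
) -> ClusterSolution:
    """Label a two-cluster solution by its food-paired vs erotica centroids.

    The cluster whose centroid has food_paired > erotica becomes C>P, the
    other P>C. Exact ties, or k != 2, leave clusters unlabelled with a
    warning.
    """
    if solution.k != 2:
        log.warning("profile labelling requires k = 2; leaving clusters unlabelled")
        solution.labels = {c: LABEL_NONE for c in range(solution.k)}
        return solution
    i_fp = list(category_order).index("food_paired")
    i_er = list(category_order).index("erotica")
    contrast = solution.centroids[:, i_fp] - solution.centroids[:, i_er]
    if contrast[0] == contrast[1]:
        log.warning("food_paired − erotica centroid tie; leaving clusters unlabelled")
        solution.labels = {0: LABEL_NONE, 1: LABEL_NONE}
        return solution
    cp = int(np.argmax(contrast))
    solution.labels = {cp: LABEL_CP, 1 - cp: LABEL_PC}
    return solution
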