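"""Cross-cohort replication of the trajectory clustering.

A replication cohort's asymmetry trajectories are clustered over exactly
the vertex set retained in the discovery cohort (constrained clustering, at
the discovery K).  Spatial agreement is quantified by per-cluster Dice
coefficients after optimal label matching, and tested against a null of
random spatial assignment by permuting one map's vertex labels (preserving
label counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .clustering import Partition, compute_dissimilarity, pam_cluster
from .vertexwise import AsymmetryTrajectorySet


def constrained_cluster(
    replication_trajs: AsymmetryTrajectorySet,
    discovery_mask: np.ndarray,
    K: int,
) -> Partition:
    """Cluster replication trajectories over the discovery vertex set."""
    mask = np.asarray(discovery_mask, bool)
    if mask.shape[0] != replication_trajs.trajectories.shape[0]:
        raise ValueError("discovery mask does not match replication trajectories")
    missing = np.flatnonzero(
        mask & ~np.all(np.isfinite(replication_trajs.trajectories), axis=1)
    )
    if missing.size:
        raise ValueError(
            f"replication trajectories missing at vertices {missing.tolist()}"
        )
    D, ids = compute_dissimilarity(replication_trajs, mask)
    if K == len(ids):
        # trivial partition: every vertex its own cluster/medoid
        return Partition(labels=np.arange(1, K + 1),
                         medoids=np.arange(K), vertex_ids=ids, cost=0.0)
    return pam_cluster(D, K, vertex_ids=ids)


def _check_comparable(A: Partition, B: Partition) -> None:
    if not np.array_equal(A.vertex_ids, B.vertex_ids):
        raise ValueError("partitions cover different vertex sets")
    if A.K != B.K:
        raise ValueError("partitions have different K")


def match_labels(labels_a: np.ndarray, labels_b: np.ndarray
                 ) -> dict[int, int]:
    """Map B's labels onto A's by maximum-total-overlap assignment."""
    la = np.unique(labels_a)
    lb = np.unique(labels_b)
    overlap = np.zeros((len(la), len(lb)))
    dice = np.zeros((len(la), len(lb)))
    for i, a in enumerate(la):
        in_a = labels_a == a
        na = in_a.sum()
        for j, b in enumerate(lb):
            o = np.sum(in_a & (labels_b == b))
            overlap[i, j] = o
            nb = np.sum(labels_b == b)
            dice[i, j] = 2.0 * o / (na + nb) if na + nb else 0.0
    # overlaps are integers; the small Dice term (< 0.5 in total) breaks
    # assignment ties in a label-permutation-invariant way
    eps = 1.0 / (2.0 * max(len(la), len(lb)) + 2.0)
    rows, cols = linear_sum_assignment(-(overlap + eps * dice))
    return {int(lb[j]): int(la[i]) for i, j in zip(rows, cols)}


def mean_dice(A: Partition | np.ndarray, B: Partition | np.ndarray,
              match: bool = True) -> tuple[dict[int, float], float]:
    """Per-matched-label and mean Dice between two partitions.

    B's cluster labels are first matched to A's by maximum total overlap
    (optimal assignment), then Dice_l = 2|A_l n B_l| / (|A_l| + |B_l|) per
    matched label l, and the mean over labels is returned.  Invariant to
    relabeling of either partition.
    """
    labels_a = A.labels if isinstance(A, Partition) else np.asarray(A)
    labels_b = B.labels if isinstance(B, Partition) else np.asarray(B)
    if isinstance(A, Partition) and isinstance(B, Partition):
        _check_comparable(A, B)
    elif len(labels_a) != len(labels_b):
        raise ValueError("label vectors differ in length")
    if match:
        remap = match_labels(labels_a, labels_b)
        mapped_b = np.array([remap[l] for l in labels_b])
    else:
        mapped_b = labels_b
    dice = {}
    for lab in np.unique(labels_a):
        in_a = labels_a == lab
        in_b = mapped_b == lab
        denom = in_a.sum() + in_b.sum()
        dice[int(lab)] = 2.0 * float(np.sum(in_a & in_b)) / denom if denom else 0.0
    return dice, float(np.mean(list(dice.values())))


@dataclass
class DiceResult:
    """Dice agreement with a label-permutation null."""

    dice_per_label: dict[int, float]
    mean_dice: float
    pvalue: float
    null_mean: float
    null_quantiles: dict[str, float]
    n_permutations: int
    seed: int
    null_distribution: np.ndarray = field(repr=False, default=None)


def expected_dice_random(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Closed-form expected mean Dice under uniform permutation of B.

    For label l with n_Al members in A and n_Bl in B over N vertices, the
    expected overlap is n_Al*n_Bl/N, so E[Dice_l] ~ 2 n_Al n_Bl / (N (n_Al
    + n_Bl)); the mean over labels is returned (matching is ignored, i.e.
    labels are assumed already aligned — adequate for the identity-matched
    case this checks).
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    N = len(labels_a)
    vals = []
    for lab in np.unique(labels_a):
        na = np.sum(labels_a == lab)
        nb = np.sum(labels_b == lab)
        vals.append(2.0 * na * nb / (N * (na + nb)) if na + nb else 0.0)
    return float(np.mean(vals))


def dice_permutation_test(
    A: Partition, B: Partition, n_perm: int = 10_000, seed: int = 0,
    match: bool = True,
) -> DiceResult:
    """Permutation test of spatial agreement between two partitions.

    The null distribution is mean_dice(A, pi(B)) over uniform random
    permutations pi of B's vertex assignments (label counts preserved);
    p = (1 + #{null >= observed}) / (1 + n_perm).  ``match`` controls
    whether labels are re-matched for the observed and each permuted map
    (the default, matching the statistic to itself) — with ``match=False``
    the null mean has the closed form of :func:`expected_dice_random`.
    """
    _check_comparable(A, B)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    dice, observed = mean_dice(A, B, match=match)
    rng = np.random.default_rng(seed)
    labels_b = B.labels
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(labels_b)
        null[i] = mean_dice(A.labels, perm, match=match)[1]
    p = (1.0 + float(np.sum(null >= observed - 1e-12))) / (1.0 + n_perm)
    qs = {q: float(np.quantile(null, float(q)))
          for q in ("0.025", "0.5", "0.975")}
    return DiceResult(
        dice_per_label=dice, mean_dice=observed, pvalue=float(p),
        null_mean=float(null.mean()), null_quantiles=qs,
        n_permutations=n_perm, seed=seed, null_distribution=null,
    )
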