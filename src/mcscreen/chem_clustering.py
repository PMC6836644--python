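"""Tanimoto leader (sphere-exclusion) clustering and diversity statistics.

Predicted actives are clustered on their binary fingerprints with a cap on the
Tanimoto distance between cluster center and members; one top-relevance
representative is kept per cluster, giving a chemically diverse shortlist.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def tanimoto_similarity(a: Sequence[int], b: Sequence[int]) -> float:
    """Jaccard/Tanimoto similarity |a AND b| / |a OR b| on binary vectors.

    Two all-zero vectors are identical objects and score 1 by convention
    (empty fingerprints can occur in synthetic data).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(a, b).sum()) / union


def tanimoto_distance(a: Sequence[int], b: Sequence[int]) -> float:
    """1 - Tanimoto similarity."""
    return 1.0 - tanimoto_similarity(a, b)


@dataclass
class ChemCluster:
    """A leader cluster: center + members within the distance threshold."""

    center_id: str
    member_ids: list[str]
    threshold: float

    def __post_init__(self) -> None:
        if self.center_id not in self.member_ids:
            raise ValueError("cluster center must be among its members")


def leader_cluster(
    fps: Sequence[tuple[str, Sequence[int]]],
    max_center_distance: float,
    ordering: Sequence[str],
) -> list[ChemCluster]:
    """Single-pass sphere-exclusion clustering.

    Compounds are visited in ``ordering`` (by convention, descending global
    relevance, so centers are the most promising compounds). Each compound
    joins the first existing center within ``max_center_distance``, else opens
    a new cluster as its center. Every compound is assigned exactly once;
    distinct centers are pairwise farther apart than the threshold.
    """
    if not 0.0 <= max_center_distance <= 1.0:
        raise ValueError("max_center_distance must lie in [0, 1]")
    fp_by_id = {cid: np.asarray(v, dtype=bool) for cid, v in fps}
    if len(fp_by_id) != len(fps):
        raise ValueError("duplicate compound ids in fingerprint list")
    unknown = [cid for cid in ordering if cid not in fp_by_id]
    if unknown:
        raise ValueError(f"unknown id in ordering: {unknown[0]!r}")
    if set(ordering) != set(fp_by_id):
        missing = sorted(set(fp_by_id) - set(ordering))
        raise ValueError(f"ordering must cover all ids; missing {missing[:3]}")
    clusters: list[ChemCluster] = []
    centers: list[np.ndarray] = []
    for cid in ordering:
        fp = fp_by_id[cid]
        for cluster, center_fp in zip(clusters, centers):
            if 1.0 - tanimoto_similarity(center_fp, fp) <= max_center_distance:
                cluster.member_ids.append(cid)
                break
        else:
            clusters.append(
                ChemCluster(center_id=cid, member_ids=[cid], threshold=max_center_distance)
            )
            centers.append(fp)
    return clusters


def select_representatives(
    clusters: Sequence[ChemCluster], theta_by_id: Mapping[str, float]
) -> list[str]:
    """Keep the top-relevance member of each cluster (ties to the
    lexicographically smaller id); one id per cluster, cluster order."""
    reps = []
    for cluster in clusters:
        for cid in cluster.member_ids:
            if cid not in theta_by_id:
                raise ValueError(f"missing relevance for compound {cid!r}")
        reps.append(min(cluster.member_ids, key=lambda c: (-theta_by_id[c], c)))
    return reps


@dataclass(frozen=True)
class DiversityStats:
    """Mean/SD of pairwise distances within the selection and of each selected
    compound's distance to its nearest training compound (population SD)."""

    pairwise_mean: float
    pairwise_sd: float
    nearest_training_mean: float
    nearest_training_sd: float


def diversity_stats(
    selected: Sequence[Sequence[int]], training: Sequence[Sequence[int]]
) -> DiversityStats:
    """Diversity of a selection: internal pairwise Tanimoto distances (all
    unordered pairs) and the distance of each member to the training set."""
    selected = [np.asarray(v, dtype=bool) for v in selected]
    training = [np.asarray(v, dtype=bool) for v in training]
    if len(selected) < 2:
        raise ValueError("need >= 2 selected compounds for the pairwise statistic")
    if not training:
        raise ValueError("empty training set: nearest-training distance undefined")
    pair = [
        1.0 - tanimoto_similarity(selected[i], selected[j])
        for i in range(len(selected))
        for j in range(i + 1, len(selected))
    ]
    nearest = [
        min(1.0 - tanimoto_similarity(s, t) for t in training) for s in selected
    ]
    return DiversityStats(
        pairwise_mean=float(np.mean(pair)),
        pairwise_sd=float(np.std(pair)),
        nearest_training_mean=float(np.mean(nearest)),
        nearest_training_sd=float(np.std(nearest)),
    )


def write_cluster_report(
    clusters: Sequence[ChemCluster],
    theta_by_id: Mapping[str, float],
    path: str | Path,
) -> Path:
    """TSV: cluster index, center, member count, representative and its theta."""
    reps = select_representatives(clusters, theta_by_id)
    rows = [
        {
            "cluster": i + 1,
            "center_id": c.center_id,
            "n_members": len(c.member_ids),
            "representative_id": rep,
            "representative_theta": theta_by_id[rep],
        }
        for i, (c, rep) in enumerate(zip(clusters, reps))
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
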