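"""Fisher-score feature clustering (ensemble stage 1).

Feature columns are grouped into ``k`` feature-clusters so that one classifier
can be trained per cluster. Within each feature type (binary bits, discrete
descriptors, continuous descriptors) columns are ranked by Fisher score and
dealt round-robin, so every cluster receives a stratified mixture of strong
and weak features of every type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from mcscreen.core_data import ACTIVE, INACTIVE, CompoundTable

#: score assigned to a perfectly separating zero-variance column, so the
#: Fisher ordering stays total
DEFAULT_ZERO_VARIANCE_CAP = 1e6

#: dealing order of feature types
TYPE_ORDER = ("binary", "discrete", "continuous")


def fisher_score(
    values: Sequence[float],
    labels: Sequence[str],
    zero_variance_cap: float = DEFAULT_ZERO_VARIANCE_CAP,
) -> float:
    """Two-class Fisher score of one feature column.

    ``(mu_A - mu_I)^2 / (var_A + var_I)`` with population variances. Returns
    0.0 when the class means coincide; when both variances vanish but the
    means differ (a perfectly separating column) the score is capped at
    ``zero_variance_cap``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if values.shape[0] != labels.shape[0]:
        raise ValueError("values and labels must have equal length")
    a = values[labels == ACTIVE]
    i = values[labels == INACTIVE]
    if a.size == 0 or i.size == 0:
        raise ValueError("both classes must be present to compute a Fisher score")
    mean_diff = a.mean() - i.mean()
    if mean_diff == 0.0:
        return 0.0
    denom = a.var() + i.var()  # population variances (ddof=0)
    if denom == 0.0:
        return float(zero_variance_cap)
    return float(mean_diff**2 / denom)


@dataclass
class FeatureClustering:
    """Partition of feature columns into ``k`` clusters plus per-column scores."""

    k: int
    clusters: list[list[str]]
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k != len(self.clusters):
            raise ValueError("k must equal the number of clusters")
        flat = [c for cl in self.clusters for c in cl]
        if len(flat) != len(set(flat)):
            raise ValueError("clusters must be pairwise disjoint")

    @property
    def all_columns(self) -> list[str]:
        return [c for cl in self.clusters for c in cl]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "k": self.k,
            "clusters": {str(i + 1): cl for i, cl in enumerate(self.clusters)},
            "scores": self.scores,
        }
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FeatureClustering":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        k = int(payload["k"])
        clusters = [payload["clusters"][str(i + 1)] for i in range(k)]
        return cls(k=k, clusters=clusters, scores=dict(payload.get("scores", {})))


def cluster_features(
    table: CompoundTable,
    labels: Sequence[str] | None = None,
    k: int = 3,
    zero_variance_cap: float = DEFAULT_ZERO_VARIANCE_CAP,
) -> FeatureClustering:
    """Split the table's feature columns into ``k`` Fisher-balanced clusters.

    Within each feature type columns are sorted by Fisher score descending
    (ties by original column order) and dealt round-robin across clusters; the
    dealing pointer continues across types so no cluster is left empty while
    ``k`` does not exceed the total column count. Deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    columns = table.feature_names
    if k > len(columns):
        raise ValueError(f"k={k} exceeds the number of feature columns ({len(columns)})")
    labels = np.asarray(
        list(labels) if labels is not None else table.labels, dtype=object
    )
    types = table.feature_types()
    matrix = table.feature_matrix(columns)
    scores = {
        name: fisher_score(matrix[:, j], labels, zero_variance_cap)
        for j, name in enumerate(columns)
    }
    clusters: list[list[str]] = [[] for _ in range(k)]
    pointer = 0
    for ftype in TYPE_ORDER:
        typed = [c for c in columns if types[c] == ftype]
        typed.sort(key=lambda c: -scores[c])  # stable: ties keep column order
        for col in typed:
            clusters[pointer % k].append(col)
            pointer += 1
    return FeatureClustering(k=k, clusters=clusters, scores=scores)
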