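"""Probability-product candidate ranking (three stages).

Stage 1 compiles, for every compound given a final Active label, the vector of
inner-classifier Active probabilities. Stage 2 reduces each vector to a single
global relevance: the product of its elements, which separates candidates even
when their sums and means coincide. Stage 3 sorts descending by relevance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mcscreen.core_data import ACTIVE
from mcscreen.mcs_model import PredictionResult

THETA_ABS_TOL = 1e-12


@dataclass(frozen=True)
class RankedCandidate:
    """A predicted-active compound with its probability vector and relevance."""

    id: str
    probabilities: tuple[float, ...]
    theta: float

    def __post_init__(self) -> None:
        expected = global_relevance(self.probabilities)
        if not math.isclose(self.theta, expected, rel_tol=0.0, abs_tol=THETA_ABS_TOL):
            raise ValueError(
                f"theta {self.theta} inconsistent with product {expected} for {self.id!r}"
            )


def compile_probabilities(
    meta_prediction: PredictionResult,
) -> list[tuple[str, np.ndarray]]:
    """Stage 1: keep only compounds with final label Active, each paired with
    its fixed-order inner-probability vector."""
    out: list[tuple[str, np.ndarray]] = []
    for row, (cid, label) in enumerate(zip(meta_prediction.ids, meta_prediction.labels)):
        if label == ACTIVE:
            out.append((cid, meta_prediction.probabilities[row].copy()))
    return out


def global_relevance(probabilities: Sequence[float]) -> float:
    """Stage 2: the product of all inner-classifier Active probabilities.

    Every element must lie in (0, 1]; the product then lies in (0, 1] and is
    strictly increasing in each coordinate.
    """
    p = np.asarray(list(probabilities), dtype=float)
    if p.size == 0:
        raise ValueError("probability vector must be non-empty")
    if (p <= 0).any() or (p > 1).any():
        bad = p[(p <= 0) | (p > 1)][0]
        raise ValueError(f"probabilities must lie in (0, 1], got {bad}")
    return float(np.prod(p))


def comparison_aggregates(probabilities: Sequence[float]) -> tuple[float, float]:
    """Sum and arithmetic mean of the vector — the aggregates the product
    out-discriminates (two different vectors can share both)."""
    p = np.asarray(list(probabilities), dtype=float)
    if p.size == 0:
        raise ValueError("probability vector must be non-empty")
    return float(p.sum()), float(p.mean())


def truncate3(value: float) -> float:
    """Truncate toward zero at the third decimal (reporting convention)."""
    return math.trunc(value * 1000) / 1000


def make_candidates(
    meta_prediction: PredictionResult,
    restrict_to: slice | None = None,
    floor: float = 1e-9,
) -> list[RankedCandidate]:
    """Build candidates from a meta-prediction.

    By default the relevance product runs over all contributing inner
    classifiers (six for a k=3 meta-model); pass ``restrict_to`` (a column
    slice) to confine it to one constituent model's three probabilities.
    A dissenting inner classifier may emit an Active probability of exactly
    0.0, which is outside the relevance domain (0, 1]; such values are clamped
    up to ``floor`` so a voted-Active compound still ranks (dead last among
    comparable vectors).
    """
    candidates = []
    for cid, probs in compile_probabilities(meta_prediction):
        if restrict_to is not None:
            probs = probs[restrict_to]
        vec = tuple(max(float(v), floor) for v in probs)
        candidates.append(
            RankedCandidate(id=cid, probabilities=vec, theta=global_relevance(vec))
        )
    return candidates


def rank_candidates(candidates: Sequence[RankedCandidate]) -> list[RankedCandidate]:
    """Stage 3: descending global relevance, ties broken by ascending id."""
    return sorted(candidates, key=lambda c: (-c.theta, c.id))


def write_ranking(
    candidates: Sequence[RankedCandidate], path: str | Path, top: int | None = None
) -> Path:
    """TSV report: rank, id, theta (full + 3-decimal truncated), probabilities."""
    ranked = rank_candidates(candidates)
    if top is not None:
        ranked = ranked[:top]
    rows = []
    for rank, c in enumerate(ranked, start=1):
        row = {
            "rank": rank,
            "compound_id": c.id,
            "theta": c.theta,
            "theta_3dp": truncate3(c.theta),
        }
        row.update({f"p{i+1}": v for i, v in enumerate(c.probabilities)})
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
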