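"""Synthetic compound-table generator.

Emulates the real data's schema — binary substructure bits plus discrete and
continuous physicochemical descriptors and a binary activity class — with a
controllable class-conditional signal, so the whole pipeline is testable
without any download. Default widths are reduced (256 bits, 10 discrete, 8
continuous) for speed; ``SyntheticSpec.paper_shape()`` emits the full
2048/50/34 layout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import yaml

from mcscreen.core_data import ACTIVE, INACTIVE, UNKNOWN, CompoundTable


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for one synthetic table.

    Informative bits fire with rate ``p_active`` in Actives and ``p_inactive``
    in Inactives; the remaining bits fire at ``background_rate`` regardless of
    class. Discrete descriptors are Poisson with a class-shifted rate and
    continuous descriptors Gaussian with a class-shifted mean.
    """

    n_active: int = 500
    n_inactive: int = 500
    n_bits: int = 256
    n_informative_bits: int = 40
    p_active: float = 0.8
    p_inactive: float = 0.2
    background_rate: float = 0.3
    n_discrete: int = 10
    n_continuous: int = 8
    discrete_base_rate: float = 3.0
    discrete_shift: float = 1.0
    continuous_shift: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative_bits > self.n_bits:
            raise ValueError("n_informative_bits must not exceed n_bits")
        for name in ("p_active", "p_inactive", "background_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        for name in ("n_active", "n_inactive", "n_bits", "n_discrete", "n_continuous"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.discrete_base_rate < 0 or self.discrete_base_rate + self.discrete_shift < 0:
            raise ValueError("Poisson rates must be non-negative")

    @classmethod
    def paper_shape(cls, **overrides) -> "SyntheticSpec":
        """Full-width schema: 2048 bits, 50 discrete, 34 continuous."""
        base = cls(n_bits=2048, n_informative_bits=160, n_discrete=50, n_continuous=34)
        return replace(base, **overrides)

    @classmethod
    def null_signal(cls, **overrides) -> "SyntheticSpec":
        """No class-conditional signal anywhere (label-independent columns)."""
        base = cls(
            n_informative_bits=0,
            p_active=0.3,
            p_inactive=0.3,
            discrete_shift=0.0,
            continuous_shift=0.0,
        )
        return replace(base, **overrides)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _column_names(spec: SyntheticSpec) -> tuple[list[str], list[str], list[str]]:
    bits = [f"fp{j:04d}" for j in range(spec.n_bits)]
    disc = [f"dd{j:02d}" for j in range(spec.n_discrete)]
    cont = [f"cd{j:02d}" for j in range(spec.n_continuous)]
    return bits, disc, cont


def _sample(
    spec: SyntheticSpec, labels: Sequence[str], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = len(labels)
    is_active = np.asarray([l == ACTIVE for l in labels])
    bits = (rng.random((n, spec.n_bits)) < spec.background_rate).astype(np.uint8)
    if spec.n_informative_bits:
        rates = np.where(is_active, spec.p_active, spec.p_inactive)[:, None]
        bits[:, : spec.n_informative_bits] = (
            rng.random((n, spec.n_informative_bits)) < rates
        ).astype(np.uint8)
    disc_rate = spec.discrete_base_rate + np.where(is_active, spec.discrete_shift, 0.0)
    disc = rng.poisson(disc_rate[:, None], size=(n, spec.n_discrete)).astype(float)
    cont_mean = np.where(is_active, spec.continuous_shift, 0.0)
    cont = rng.normal(cont_mean[:, None], 1.0, size=(n, spec.n_continuous))
    return bits, np.hstack([disc, cont]) if (spec.n_discrete + spec.n_continuous) else np.zeros((n, 0))


def generate_dataset(spec: SyntheticSpec) -> tuple[CompoundTable, list[str]]:
    """Labeled table plus the ground-truth informative column names
    (informative bits, and all descriptors when their shift is non-zero).
    Byte-identical for identical spec (the seed is part of the spec)."""
    rng = np.random.default_rng(spec.seed)
    labels = np.array(
        [ACTIVE] * spec.n_active + [INACTIVE] * spec.n_inactive, dtype=object
    )
    rng.shuffle(labels)
    bits, desc = _sample(spec, labels, rng)
    bit_names, disc_names, cont_names = _column_names(spec)
    table = CompoundTable(
        ids=[f"SYN{r:07d}" for r in range(len(labels))],
        bits=bits,
        bit_names=bit_names,
        descriptors=desc,
        descriptor_names=disc_names + cont_names,
        descriptor_types=["discrete"] * spec.n_discrete
        + ["continuous"] * spec.n_continuous,
        labels=labels,
    )
    informative = bit_names[: spec.n_informative_bits]
    if spec.discrete_shift != 0.0:
        informative = informative + disc_names
    if spec.continuous_shift != 0.0:
        informative = informative + cont_names
    return table, list(informative)


def generate_screening_library(
    spec: SyntheticSpec,
    prevalence: float,
    n_total: int | None = None,
    fixed_count: bool = True,
) -> tuple[CompoundTable, np.ndarray]:
    """Unlabeled library drawn from the same generative model.

    Returns ``(table, hidden_labels)`` where the table's labels are all
    ``Unknown`` and the hidden truth is kept for evaluation. With
    ``fixed_count`` (default, deterministic tests) exactly
    ``round(prevalence * n)`` compounds are Active; otherwise the count is a
    Binomial draw.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    n = n_total if n_total is not None else spec.n_active + spec.n_inactive
    rng = np.random.default_rng(spec.seed + 1)
    if fixed_count:
        n_active = int(round(prevalence * n))
    else:
        n_active = int(rng.binomial(n, prevalence))
    hidden = np.array([ACTIVE] * n_active + [INACTIVE] * (n - n_active), dtype=object)
    rng.shuffle(hidden)
    bits, desc = _sample(spec, hidden, rng)
    bit_names, disc_names, cont_names = _column_names(spec)
    table = CompoundTable(
        ids=[f"LIB{r:07d}" for r in range(n)],
        bits=bits,
        bit_names=bit_names,
        descriptors=desc,
        descriptor_names=disc_names + cont_names,
        descriptor_types=["discrete"] * spec.n_discrete
        + ["continuous"] * spec.n_continuous,
        labels=np.array([UNKNOWN] * n, dtype=object),
    )
    return table, hidden
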