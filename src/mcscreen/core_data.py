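"""Compound-table data model, tab-delimited I/O, row partitioning and
frequency-based fingerprint-bit selection.

A :class:`CompoundTable` is the currency of the whole pipeline: an ordered set
of compounds, each carrying a fixed-length binary substructure fingerprint, a
vector of typed (discrete/continuous) physicochemical descriptors and an
optional activity label.

File dialect: UTF-8, tab-separated, header row, ``.`` decimal separator, class
encoded as the strings ``Active`` / ``Inactive``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

ACTIVE = "Active"
INACTIVE = "Inactive"
UNKNOWN = "Unknown"

DISCRETE = "discrete"
CONTINUOUS = "continuous"

#: default column-name prefixes used by the synthetic generator and schema
#: inference (bit columns, discrete descriptors, continuous descriptors).
DEFAULT_BIT_PREFIX = "fp"
DEFAULT_DISCRETE_PREFIX = "dd"
DEFAULT_CONTINUOUS_PREFIX = "cd"
DEFAULT_ID_CANDIDATES = ("compound_id", "inchikey", "id")
DEFAULT_CLASS_CANDIDATES = ("class", "activity", "label")


class CompoundTableError(ValueError):
    """Raised when a table violates a structural invariant."""


@dataclass
class Schema:
    """Column layout of a tab-delimited compound table.

    ``bit_columns`` / ``discrete_columns`` / ``continuous_columns`` may be
    explicit name lists or ``None``, in which case they are inferred from the
    header by prefix (``fp``, ``dd``, ``cd``).
    """

    id_column: str = "compound_id"
    class_column: str | None = "class"
    bit_columns: list[str] | None = None
    discrete_columns: list[str] | None = None
    continuous_columns: list[str] | None = None
    bit_prefix: str = DEFAULT_BIT_PREFIX
    discrete_prefix: str = DEFAULT_DISCRETE_PREFIX
    continuous_prefix: str = DEFAULT_CONTINUOUS_PREFIX

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Schema":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise CompoundTableError(f"unknown schema keys: {sorted(unknown)}")
        return cls(**raw)

    def resolve(self, header: Sequence[str]) -> "Schema":
        """Return a fully explicit schema for the given header."""
        cols = list(header)
        id_col = self.id_column
        if id_col not in cols:
            for cand in DEFAULT_ID_CANDIDATES:
                if cand in cols:
                    id_col = cand
                    break
            else:
                raise CompoundTableError(
                    f"id column {self.id_column!r} not found in header"
                )
        class_col = self.class_column
        if class_col is not None and class_col not in cols:
            class_col = next((c for c in DEFAULT_CLASS_CANDIDATES if c in cols), None)
        reserved = {id_col} | ({class_col} if class_col else set())
        feature_cols = [c for c in cols if c not in reserved]
        bits = self.bit_columns
        if bits is None:
            bits = [c for c in feature_cols if c.startswith(self.bit_prefix)]
        disc = self.discrete_columns
        if disc is None:
            disc = [c for c in feature_cols if c.startswith(self.discrete_prefix)]
        cont = self.continuous_columns
        if cont is None:
            cont = [
                c for c in feature_cols if c not in set(bits) and c not in set(disc)
            ]
        return Schema(
            id_column=id_col,
            class_column=class_col,
            bit_columns=list(bits),
            discrete_columns=list(disc),
            continuous_columns=list(cont),
        )


@dataclass
class CompoundTable:
    """In-memory compound table.

    Attributes
    ----------
    ids : list of str
        Unique compound identifiers (InChIKey or synthetic), row order.
    bits : (n, n_bits) uint8 array
        Binary substructure fingerprints.
    bit_names, descriptor_names : list of str
        Column names for ``bits`` / ``descriptors``.
    descriptor_types : list of str
        One of ``"discrete"`` / ``"continuous"`` per descriptor column.
    descriptors : (n, n_desc) float array
    labels : (n,) object array of ``Active`` / ``Inactive`` / ``Unknown``
    """

    ids: list[str]
    bits: np.ndarray
    bit_names: list[str]
    descriptors: np.ndarray
    descriptor_names: list[str]
    descriptor_types: list[str]
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.bits = np.asarray(self.bits, dtype=np.uint8).reshape(n, -1) if n else (
            np.asarray(self.bits, dtype=np.uint8).reshape(0, len(self.bit_names))
        )
        self.descriptors = np.asarray(self.descriptors, dtype=float).reshape(
            n, len(self.descriptor_names)
        )
        if self.labels is None:
            self.labels = np.array([UNKNOWN] * n, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        n = len(self.ids)
        if any(not i for i in self.ids):
            raise CompoundTableError("empty compound id")
        if len(set(self.ids)) != n:
            seen: set[str] = set()
            for i in self.ids:
                if i in seen:
                    raise CompoundTableError(f"duplicate compound id: {i!r}")
                seen.add(i)
        if self.bits.shape != (n, len(self.bit_names)):
            raise CompoundTableError("bit matrix shape does not match bit names")
        if self.bits.size and not np.isin(self.bits, (0, 1)).all():
            raise CompoundTableError("bit matrix contains non-binary values")
        if len(self.descriptor_types) != len(self.descriptor_names):
            raise CompoundTableError("descriptor type tags do not match names")
        bad = set(self.descriptor_types) - {DISCRETE, CONTINUOUS}
        if bad:
            raise CompoundTableError(f"unknown descriptor types: {sorted(bad)}")
        if self.descriptors.size and not np.isfinite(self.descriptors).all():
            raise CompoundTableError("missing/non-finite descriptor values")
        if self.labels.shape != (n,):
            raise CompoundTableError("label vector length mismatch")
        bad_labels = set(self.labels) - {ACTIVE, INACTIVE, UNKNOWN}
        if bad_labels:
            raise CompoundTableError(f"unknown labels: {sorted(bad_labels)}")

    # -- convenience -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_bits(self) -> int:
        return len(self.bit_names)

    @property
    def feature_names(self) -> list[str]:
        return list(self.bit_names) + list(self.descriptor_names)

    def feature_types(self) -> dict[str, str]:
        types = {name: "binary" for name in self.bit_names}
        types.update(zip(self.descriptor_names, self.descriptor_types))
        return types

    def feature_matrix(self, columns: Sequence[str] | None = None) -> np.ndarray:
        """Dense float matrix of the requested feature columns (row order)."""
        if columns is None:
            columns = self.feature_names
        bit_idx = {n: j for j, n in enumerate(self.bit_names)}
        desc_idx = {n: j for j, n in enumerate(self.descriptor_names)}
        out = np.empty((len(self), len(columns)), dtype=float)
        for j, name in enumerate(columns):
            if name in bit_idx:
                out[:, j] = self.bits[:, bit_idx[name]]
            elif name in desc_idx:
                out[:, j] = self.descriptors[:, desc_idx[name]]
            else:
                raise CompoundTableError(f"unknown feature column: {name!r}")
        return out

    def subset(self, row_indices: Iterable[int]) -> "CompoundTable":
        idx = np.asarray(list(row_indices), dtype=int)
        return CompoundTable(
            ids=[self.ids[i] for i in idx],
            bits=self.bits[idx],
            bit_names=list(self.bit_names),
            descriptors=self.descriptors[idx],
            descriptor_names=list(self.descriptor_names),
            descriptor_types=list(self.descriptor_types),
            labels=self.labels[idx].copy(),
        )

    def with_labels(self, labels: Sequence[str]) -> "CompoundTable":
        return CompoundTable(
            ids=list(self.ids),
            bits=self.bits.copy(),
            bit_names=list(self.bit_names),
            descriptors=self.descriptors.copy(),
            descriptor_names=list(self.descriptor_names),
            descriptor_types=list(self.descriptor_types),
            labels=np.asarray(list(labels), dtype=object),
        )

    def to_frame(self, include_class: bool | None = None) -> pd.DataFrame:
        """Assemble the canonical DataFrame representation.

        ``include_class=None`` writes the class column only when at least one
        label is known; ``True`` forces it (Unknown → empty string); ``False``
        omits it.
        """
        data: dict[str, object] = {"compound_id": list(self.ids)}
        for j, name in enumerate(self.bit_names):
            data[name] = self.bits[:, j].astype(int)
        for j, name in enumerate(self.descriptor_names):
            col = self.descriptors[:, j]
            if self.descriptor_types[j] == DISCRETE:
                data[name] = col.astype(int)
            else:
                data[name] = col
        if include_class is None:
            include_class = bool((self.labels != UNKNOWN).any())
        if include_class:
            data["class"] = ["" if l == UNKNOWN else l for l in self.labels]
        return pd.DataFrame(data)


def read_compound_table(path: str | Path, schema: Schema | None = None) -> CompoundTable:
    """Parse a tab-delimited compound table.

    Rejects duplicate ids (naming the offender), non-binary bit values (naming
    row and column) and missing descriptor values. A missing class column
    yields all-``Unknown`` labels.
    """
    schema = schema or Schema()
    df = pd.read_csv(
        path, sep="\t", dtype={0: str}, keep_default_na=False, na_values=[],
        float_precision="round_trip",
    )
    resolved = schema.resolve(df.columns)
    ids = [str(v) for v in df[resolved.id_column]]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise CompoundTableError(f"duplicate compound id: {i!r}")
        seen.add(i)

    bit_cols = resolved.bit_columns or []
    for col in bit_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~vals.isin((0, 1))
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise CompoundTableError(
                f"non-binary value {df[col].iloc[row]!r} in bit column {col!r}, row {row}"
            )
    bits = (
        df[bit_cols].apply(pd.to_numeric).to_numpy(dtype=np.uint8)
        if bit_cols
        else np.zeros((len(df), 0), dtype=np.uint8)
    )

    desc_cols = (resolved.discrete_columns or []) + (resolved.continuous_columns or [])
    desc_types = [DISCRETE] * len(resolved.discrete_columns or []) + [
        CONTINUOUS
    ] * len(resolved.continuous_columns or [])
    if desc_cols:
        desc = df[desc_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        if not np.isfinite(desc).all():
            r, c = map(int, np.argwhere(~np.isfinite(desc))[0])
            raise CompoundTableError(
                f"missing or non-numeric descriptor in column {desc_cols[c]!r}, row {r}"
            )
    else:
        desc = np.zeros((len(df), 0), dtype=float)

    if resolved.class_column and resolved.class_column in df.columns:
        raw = [str(v).strip() for v in df[resolved.class_column]]
        labels = []
        for r, v in enumerate(raw):
            if v == ACTIVE or v == INACTIVE:
                labels.append(v)
            elif v == "" or v == UNKNOWN:
                labels.append(UNKNOWN)
            else:
                raise CompoundTableError(f"unrecognized class value {v!r} in row {r}")
    else:
        labels = [UNKNOWN] * len(df)

    return CompoundTable(
        ids=ids,
        bits=bits,
        bit_names=list(bit_cols),
        descriptors=desc,
        descriptor_names=list(desc_cols),
        descriptor_types=desc_types,
        labels=np.array(labels, dtype=object),
    )


def write_compound_table(
    table: CompoundTable, path: str | Path, include_class: bool | None = None
) -> Path:
    """Write the table as TSV; round-trips exactly through
    :func:`read_compound_table` (values and column order)."""
    path = Path(path)
    df = table.to_frame(include_class=include_class)
    df.to_csv(path, sep="\t", index=False)
    return path


@dataclass(frozen=True)
class GroupAssignment:
    """Row partition into ``n_groups`` evenly sized groups (1-based index)."""

    assignment: dict[str, int]
    n_groups: int
    seed: int

    def group_ids(self, group: int) -> list[str]:
        return [i for i, g in self.assignment.items() if g == group]

    def group_indices(self, table: CompoundTable, group: int) -> list[int]:
        return [r for r, i in enumerate(table.ids) if self.assignment[i] == group]

    def sizes(self) -> dict[int, int]:
        out = {g: 0 for g in range(1, self.n_groups + 1)}
        for g in self.assignment.values():
            out[g] += 1
        return out


def partition_rows(
    table: CompoundTable, n_groups: int, seed: int, stratify: bool = True
) -> GroupAssignment:
    """Randomly divide rows into ``n_groups`` evenly sized groups.

    Group sizes differ by at most one. With ``stratify`` (default) the rows of
    each class are dealt separately so per-group class counts stay within one
    of proportionality. Deterministic for a fixed seed.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_groups > len(table):
        raise ValueError("n_groups exceeds the number of records")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    pointer = 0
    if stratify:
        strata: list[list[int]] = []
        for label in (ACTIVE, INACTIVE, UNKNOWN):
            rows = [r for r in range(len(table)) if table.labels[r] == label]
            if rows:
                strata.append(rows)
    else:
        strata = [list(range(len(table)))]
    # deal each (shuffled) stratum round-robin, continuing the pointer across
    # strata so global sizes stay within one of each other
    for rows in strata:
        order = rng.permutation(len(rows))
        for k in order:
            assignment[table.ids[rows[k]]] = pointer % n_groups + 1
            pointer += 1
    return GroupAssignment(assignment=assignment, n_groups=n_groups, seed=seed)


def select_bits_by_frequency(
    bit_matrix: np.ndarray, target_count: int, target_frequency: float = 0.5
) -> list[int]:
    """Pick the ``target_count`` columns whose occurrence frequency is closest
    to ``target_frequency`` (ties broken by ascending column index).

    The returned indices are ordered by closeness, then index, so the head of
    the list is always the best-balanced bit.
    """
    bit_matrix = np.asarray(bit_matrix)
    if bit_matrix.size == 0 or bit_matrix.ndim != 2:
        raise ValueError("bit matrix must be a non-empty 2-D array")
    n_cols = bit_matrix.shape[1]
    if not 1 <= target_count <= n_cols:
        raise ValueError("target_count must be in [1, n_columns]")
    freqs = bit_matrix.mean(axis=0)
    order = sorted(range(n_cols), key=lambda j: (abs(freqs[j] - target_frequency), j))
    return order[:target_count]


def compute_circular_fingerprints(
    smiles_list: Sequence[str], diameter: int = 6, n_bits: int = 2048
) -> tuple[np.ndarray, list[tuple[int, str, str]]]:
    """Optional RDKit adapter: pharmacophoric circular fingerprints.

    Returns ``(matrix, errors)`` where unparseable SMILES produce an all-zero
    row and an ``(index, smiles, message)`` error record instead of failing
    globally. Requires the ``rdkit`` extra.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("rdkit is required for fingerprint computation") from exc
    if diameter % 2 != 0 or diameter < 0:
        raise ValueError("diameter must be a non-negative even integer")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=diameter // 2,
        fpSize=n_bits,
        atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
    )
    out = np.zeros((len(smiles_list), n_bits), dtype=np.uint8)
    errors: list[tuple[int, str, str]] = []
    for r, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            errors.append((r, smi, "unparseable SMILES"))
            continue
        fp = gen.GetFingerprint(mol)
        out[r, list(fp.GetOnBits())] = 1
    return out, errors
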