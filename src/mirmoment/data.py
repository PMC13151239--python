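"""Core labeled data types for association lists and similarity matrices.

The association universe is bipartite: diseases on one side, miRNAs on the
other, with experimentally validated links between them.  Similarity matrices
(semantic, functional, interaction-profile kernels) are square, symmetric,
label-indexed and valued in [0, 1].  All file formats are plain TSV so that
every input and output is auditable with standard text tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AssociationTable",
    "SimilarityMatrix",
    "BinaryProfileMatrix",
    "read_associations",
    "write_associations",
    "read_similarity",
    "write_similarity",
    "to_profile_matrix",
]


class DataFormatError(ValueError):
    """Raised when an input file violates the expected format or contract."""


@dataclass(frozen=True)
class AssociationTable:
    """Deduplicated disease-miRNA association records.

    ``disease_ids`` and ``mirna_ids`` are ordered unique label lists (order =
    first appearance in the source); ``pairs`` holds (disease_index,
    mirna_index) integer pairs.
    """

    disease_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        n_d, n_m = len(self.disease_ids), len(self.mirna_ids)
        if len(set(self.disease_ids)) != n_d or len(set(self.mirna_ids)) != n_m:
            raise DataFormatError("duplicate labels in id lists")
        for i, j in self.pairs:
            if not (0 <= i < n_d and 0 <= j < n_m):
                raise DataFormatError(f"pair index out of range: ({i}, {j})")

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_array(self) -> np.ndarray:
        """Pairs as a (n_pairs, 2) int array in deterministic sorted order."""
        if not self.pairs:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(sorted(self.pairs), dtype=np.int64)


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity with labels; entries in [0, 1]."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataFormatError(f"similarity matrix must be square, got {v.shape}")
        if v.shape[0] != len(self.labels):
            raise DataFormatError("label count does not match matrix size")
        if len(set(self.labels)) != len(self.labels):
            raise DataFormatError("duplicate labels")
        self.values = v

    def validate(self, *, atol: float = 1e-9, unit_diagonal: bool = False) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=atol, rtol=0.0):
            raise DataFormatError("matrix is asymmetric beyond tolerance")
        if v.min() < -atol or v.max() > 1.0 + atol:
            i, j = np.unravel_index(
                np.argmax(np.abs(v - np.clip(v, 0.0, 1.0))), v.shape
            )
            raise DataFormatError(
                f"entry out of [0, 1] at ({self.labels[i]!r}, {self.labels[j]!r}): "
                f"{v[i, j]}"
            )
        if unit_diagonal and not np.allclose(np.diag(v), 1.0, atol=atol):
            raise DataFormatError("diagonal entries must equal 1")


@dataclass
class BinaryProfileMatrix:
    """0/1 interaction profiles; row i is the profile vector of entity i."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.row_labels = tuple(self.row_labels)
        self.col_labels = tuple(self.col_labels)
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (len(self.row_labels), len(self.col_labels)):
            raise DataFormatError("profile matrix shape does not match labels")
        if not np.isin(v, (0.0, 1.0)).all():
            raise DataFormatError("profile entries must be 0 or 1")
        self.values = v


def _clean(label: str) -> str:
    return label.strip()


def read_associations(path) -> AssociationTable:
    """Read a two-column TSV association list (disease<TAB>miRNA).

    Lines are deduplicated; id ordering is first-appearance order.  A header
    line is accepted and skipped when its first field is ``disease`` (case
    insensitive).  Labels are whitespace-trimmed but otherwise taken as-is.
    """
    diseases: dict[str, int] = {}
    mirnas: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise DataFormatError(
                    f"{path}: line {lineno}: expected 'disease<TAB>miRNA', got {line!r}"
                )
            d, m = _clean(fields[0]), _clean(fields[1])
            if lineno == 1 and d.lower() in {"disease", "disease_id", "disease_name"}:
                continue
            n_lines += 1
            di = diseases.setdefault(d, len(diseases))
            mi = mirnas.setdefault(m, len(mirnas))
            pairs.add((di, mi))
    if n_lines == 0:
        raise DataFormatError(f"{path}: no association records")
    return AssociationTable(
        disease_ids=tuple(diseases), mirna_ids=tuple(mirnas), pairs=frozenset(pairs)
    )


def write_associations(table: AssociationTable, path) -> None:
    """Write a canonical two-column TSV (sorted by indices, deterministic)."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in sorted(table.pairs):
            fh.write(f"{table.disease_ids[i]}\t{table.mirna_ids[j]}\n")


def read_similarity(path, expected_labels) -> SimilarityMatrix:
    """Read a dense labeled similarity TSV and align it to ``expected_labels``.

    The file must have a header row and an index column of labels.  Rows and
    columns are reordered to ``expected_labels``; labels missing from the file
    raise an error listing them.  Values outside [0, 1] by more than 1e-6 or
    asymmetry beyond 1e-6 are errors naming the offending cell.
    """
    expected = [str(x) for x in expected_labels]
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [_clean(str(x)) for x in df.index]
    df.columns = [_clean(str(x)) for x in df.columns]
    if df.shape[0] != df.shape[1]:
        raise DataFormatError(f"{path}: matrix is not square: {df.shape}")
    have = set(df.index)
    if set(df.columns) != have:
        raise DataFormatError(f"{path}: row and column labels differ")
    missing = [x for x in expected if x not in have]
    if missing:
        raise DataFormatError(f"{path}: missing labels: {missing}")
    df = df.loc[expected, expected]
    values = df.to_numpy(dtype=np.float64)
    sim = SimilarityMatrix(labels=tuple(expected), values=values)
    sim.validate(atol=1e-6)
    return sim


def write_similarity(sim: SimilarityMatrix, path) -> None:
    """Write a labeled dense TSV with deterministic row ordering."""
    df = pd.DataFrame(sim.values, index=list(sim.labels), columns=list(sim.labels))
    df.to_csv(path, sep="\t", float_format="%.10g")


def to_profile_matrix(assoc: AssociationTable, axis: str) -> BinaryProfileMatrix:
    """Binary interaction profiles of the association table.

    ``axis='disease'`` gives shape (n_diseases, n_mirnas) with a 1 exactly at
    known pairs; ``axis='mirna'`` gives the transpose.
    """
    mat = np.zeros((assoc.n_diseases, assoc.n_mirnas))
    for i, j in assoc.pairs:
        mat[i, j] = 1.0
    if axis == "disease":
        return BinaryProfileMatrix(assoc.disease_ids, assoc.mirna_ids, mat)
    if axis == "mirna":
        return BinaryProfileMatrix(assoc.mirna_ids, assoc.disease_ids, mat.T)
    raise ValueError(f"axis must be 'disease' or 'mirna', got {axis!r}")
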