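"""Readers and writers for the formats the pipeline exchanges.

Aligned multi-FASTA, PHYLIP square / lower-triangular distance matrices,
Newick trees with support-as-internal-label, and tab-separated tables with
declared schemas.  Every reader/writer pair round-trips to the printed
precision, and readers never reorder records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, FormatError, SchemaError

DNA = "DNA"
PROTEIN = "PROTEIN"

_GAP_CHARS = frozenset("-.")
# IUPAC nucleotide codes (U accepted for RNA-style 16S deposits).
_DNA_CHARS = frozenset("ACGTURYSWKMBDHVN")
# 20 amino acids plus the standard ambiguity codes.
_PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYXBZ")

#: number of decimals written in PHYLIP distance matrices
DIST_DECIMALS = 6


@dataclass(frozen=True)
class Alignment:
    """A labeled, equal-length, gapped multiple sequence alignment.

    Parameters
    ----------
    labels : tuple of str
        Unique record identifiers, in file order.
    rows : tuple of str
        Upper-case gapped sequences, one per label, all of equal length.
    alphabet : {"DNA", "PROTEIN"}
    """

    labels: tuple
    rows: tuple
    alphabet: str

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))
        if self.alphabet not in (DNA, PROTEIN):
            raise AlignmentError(f"unknown alphabet {self.alphabet!r}")
        if len(self.labels) != len(self.rows):
            raise AlignmentError("labels and rows differ in count")
        if len(set(self.labels)) != len(self.labels):
            seen, dup = set(), None
            for lab in self.labels:
                if lab in seen:
                    dup = lab
                    break
                seen.add(lab)
            raise FormatError(f"duplicate record label {dup!r}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError(
                f"rows have unequal lengths {sorted(lengths)}; input is not aligned"
            )
        allowed = (_DNA_CHARS if self.alphabet == DNA else _PROTEIN_CHARS) | _GAP_CHARS
        for lab, row in zip(self.labels, self.rows):
            for pos, ch in enumerate(row):
                if ch not in allowed:
                    raise FormatError(
                        f"illegal character {ch!r} in record {lab!r} at position {pos + 1}"
                    )

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def take_columns(self, idx: Sequence[int]) -> "Alignment":
        """Return a new alignment restricted to the given column indices."""
        rows = ["".join(r[i] for i in idx) for r in self.rows]
        return Alignment(self.labels, tuple(rows), self.alphabet)

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]


@dataclass(frozen=True)
class DistanceMatrix:
    """A symmetric, zero-diagonal, label-indexed dissimilarity matrix.

    ``saturated`` optionally flags pairs whose distance was capped because
    the underlying estimator diverged (e.g. Jukes-Cantor p >= 0.75).
    """

    labels: tuple
    values: np.ndarray
    saturated: np.ndarray | None = field(default=None)

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n = len(self.labels)
        if vals.shape != (n, n):
            raise FormatError(f"values shape {vals.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise FormatError("duplicate labels in distance matrix")
        if not np.allclose(vals, vals.T, atol=1e-6, equal_nan=True):
            raise FormatError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(vals)) > 1e-12):
            raise FormatError("distance matrix diagonal is not zero")
        if np.any(np.isnan(vals)):
            raise FormatError("distance matrix contains NaN")
        if np.any(vals < -1e-12):
            raise FormatError("distance matrix contains negative entries")
        if self.saturated is not None:
            sat = np.asarray(self.saturated, dtype=bool)
            if sat.shape != (n, n):
                raise FormatError("saturated mask shape mismatch")
            object.__setattr__(self, "saturated", sat)

    @property
    def n(self) -> int:
        return len(self.labels)

    def submatrix(self, labels: Iterable[str]) -> "DistanceMatrix":
        labels = list(labels)
        index = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise KeyError(f"labels not in matrix: {missing}")
        idx = np.array([index[lab] for lab in labels])
        sat = self.saturated[np.ix_(idx, idx)] if self.saturated is not None else None
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)], sat)

    def __getitem__(self, pair) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


# ---------------------------------------------------------------------------
# FASTA


def read_alignment(path, alphabet: str) -> Alignment:
    """Read an aligned multi-FASTA file.

    Raises :class:`AlignmentError` on unequal row lengths and
    :class:`FormatError` on duplicate labels or illegal characters.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise FormatError(f"{path}: need at least 2 FASTA records, found {len(records)}")
    labels = tuple(r.id for r in records)
    rows = tuple(str(r.seq) for r in records)
    return Alignment(labels, rows, alphabet)


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for lab, row in zip(aln.labels, aln.rows):
            fh.write(f">{lab}\n")
            for i in range(0, len(row), 70):
                fh.write(row[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# PHYLIP distance matrices


def write_distmat(D: DistanceMatrix, path, dialect: str = "square") -> None:
    """Write a relaxed-PHYLIP distance matrix (names of any length).

    ``dialect`` selects the full square layout or the lower-triangular one
    (row i holding the i distances to earlier taxa).
    """
    if dialect not in ("square", "lower"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write(f"{D.n}\n")
        for i, lab in enumerate(D.labels):
            row = D.values[i, :] if dialect == "square" else D.values[i, :i]
            cells = " ".join(f"{v:.{DIST_DECIMALS}f}" for v in row)
            fh.write(f"{lab}\t{cells}".rstrip() + "\n")


def read_distmat(path) -> DistanceMatrix:
    """Read a PHYLIP distance matrix, square or lower-triangular.

    Accepts relaxed names (whitespace-delimited) as well as classic
    space-padded 10-character names, since both tokenize identically.
    """
    with open(path) as fh:
        tokens_per_line = [line.split() for line in fh if line.strip()]
    if not tokens_per_line:
        raise FormatError(f"{path}: empty distance matrix file")
    try:
        n = int(tokens_per_line[0][0])
    except ValueError:
        raise FormatError(f"{path}: header is not a taxon count") from None
    body = tokens_per_line[1:]
    if len(body) != n:
        raise FormatError(f"{path}: expected {n} rows, found {len(body)}")
    labels = [row[0] for row in body]
    if len(set(labels)) != n:
        raise FormatError(f"{path}: duplicate taxon names")
    counts = [len(row) - 1 for row in body]
    if counts == [n] * n:
        vals = np.array([[float(x) for x in row[1:]] for row in body])
        if not np.allclose(vals, vals.T, atol=10 ** -(DIST_DECIMALS - 1)):
            raise FormatError(f"{path}: square matrix is not symmetric")
        vals = (vals + vals.T) / 2.0
    elif counts == list(range(n)):
        vals = np.zeros((n, n))
        for i, row in enumerate(body):
            for j, x in enumerate(row[1:]):
                vals[i, j] = vals[j, i] = float(x)
    else:
        raise FormatError(
            f"{path}: rows are neither square (n values each) nor lower-triangular"
        )
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(tuple(labels), vals)


# ---------------------------------------------------------------------------
# Newick


def read_newick(path_or_string, taxon_namespace=None) -> dendropy.Tree:
    """Parse a Newick tree; internal node labels are taken as supports."""
    src = str(path_or_string)
    kwargs = dict(
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    if taxon_namespace is not None:
        kwargs["taxon_namespace"] = taxon_namespace
    try:
        if "(" in src:  # a literal newick string rather than a path
            tree = dendropy.Tree.get(data=src, **kwargs)
        else:
            tree = dendropy.Tree.get(path=src, **kwargs)
    except Exception as exc:  # dendropy raises assorted parse errors
        raise FormatError(f"could not parse Newick input: {exc}") from exc
    for node in tree.internal_nodes():
        if node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                node.support = None
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=f".{DIST_DECIMALS}f",
    )
    with open(path, "w") as fh:
        fh.write(s)


def leaf_labels(tree: dendropy.Tree) -> list:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def bipartitions(tree: dendropy.Tree) -> set:
    """Non-trivial splits of an (unrooted) tree as frozensets of leaf labels.

    Each split is canonicalized as the side not containing the first leaf,
    so topologically identical trees yield identical sets regardless of
    rooting or rotation.
    """
    all_leaves = frozenset(leaf_labels(tree))
    first = min(all_leaves)
    splits = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = clade if first not in clade else all_leaves - clade
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(side)
    return splits


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Symmetric-difference (Robinson-Foulds) distance between topologies."""
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)


# ---------------------------------------------------------------------------
# TSV tables

#: required columns and primary key per declared table schema
TABLE_SCHEMAS = {
    "hit": {
        "columns": ("genome", "subject_id", "pct_identity", "pct_positives", "bitscore"),
        "key": ("genome", "subject_id"),
    },
    "neighborhood": {
        "columns": ("genome", "gene_id", "position_index", "product"),
        "key": ("genome", "position_index"),
    },
    "site": {
        "columns": ("strain", "site", "pH", "organic_matter"),
        "key": ("strain",),
    },
    "presence": {
        "columns": ("strain",),
        "key": ("strain",),
    },
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a TSV table and validate it against a declared schema."""
    if schema not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown table schema {schema!r}")
    schema_def = TABLE_SCHEMAS[schema]
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, cannot satisfy schema {schema!r}") from None
    missing = [c for c in schema_def["columns"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: schema {schema!r} missing required columns {missing}")
    key = list(schema_def["key"])
    if df.duplicated(subset=key).any():
        dups = df[df.duplicated(subset=key)][key].iloc[0].tolist()
        raise SchemaError(f"{path}: duplicate primary key {dups} for schema {schema!r}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
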