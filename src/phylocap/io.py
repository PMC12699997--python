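"""Shared domain types and readers/writers for FASTA, Newick and tabular files.

The types defined here are the currency of the whole toolkit:

* :class:`GeneAlignment` / :class:`GeneAlignmentSet` — per-gene multiple
  sequence alignments keyed by sample id, the unit of marker selection,
  saturation analysis and barcoding.
* :class:`DistanceMatrix` — a labelled symmetric matrix, used both for
  sequence distances and for tree-to-tree (nRF) distances.
* :class:`PhyloTree` — an unrooted phylogenetic tree with branch lengths and
  optional per-edge support values, backed by :mod:`dendropy`, with a
  canonical bipartition-set view used by all Robinson-Foulds machinery.
* :class:`SpeciesMap` — sample id to species name mapping for barcoding.

All sequence coordinates in the toolkit are 0-based, half-open.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
from Bio import SeqIO

__all__ = [
    "ParseError",
    "ValidationError",
    "read_fasta",
    "write_fasta",
    "GeneAlignment",
    "GeneAlignmentSet",
    "DistanceMatrix",
    "SpeciesMap",
    "PhyloTree",
    "read_newick",
    "parse_newick",
    "write_matrix_csv",
    "read_matrix_csv",
]


class ParseError(ValueError):
    """A file could not be parsed as its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` map.

    Ids are the header token up to the first whitespace.  Case is preserved
    (lowercase marks soft-masked repeats).  Duplicate ids and empty records
    are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise ValidationError(f"duplicate FASTA id {rec.id!r} in {path}")
            seq = str(rec.seq)
            if not seq:
                raise ValidationError(f"empty sequence for id {rec.id!r} in {path}")
            records[rec.id] = seq
    except ValueError as exc:  # Bio.SeqIO signals malformed records this way
        if isinstance(exc, (ValidationError, ParseError)):
            raise
        raise ParseError(f"malformed FASTA in {path}: {exc}") from exc
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    """Write an ``{id: sequence}`` map as multi-line FASTA (case preserved)."""
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

_IUPAC = set("ACGTURYSWKMBDHVN-")


@dataclass
class GeneAlignment:
    """A per-gene multiple sequence alignment keyed by sample id.

    All rows have equal length; sample ids are unique (enforced by the dict).
    Validation of the alphabet is permissive: IUPAC ambiguity codes are
    accepted on read, and downstream distance computations treat anything
    outside A/C/G/T as missing data.
    """

    gene_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError(f"alignment {self.gene_id!r} has no rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValidationError(
                f"alignment {self.gene_id!r} has unequal row lengths {sorted(lengths)}"
            )
        if lengths == {0}:
            raise ValidationError(f"alignment {self.gene_id!r} has zero columns")
        bad = set()
        for seq in self.rows.values():
            bad |= set(seq.upper()) - _IUPAC
        if bad:
            raise ValidationError(
                f"alignment {self.gene_id!r} contains non-IUPAC symbols {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rows)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def subset(self, sample_ids: Iterable[str]) -> "GeneAlignment":
        wanted = [s for s in sample_ids if s in self.rows]
        return GeneAlignment(self.gene_id, {s: self.rows[s] for s in wanted})

    def take_columns(self, columns: Sequence[int]) -> "GeneAlignment":
        cols = list(columns)
        return GeneAlignment(
            self.gene_id, {s: "".join(seq[c] for c in cols) for s, seq in self.rows.items()}
        )

    def to_byte_matrix(self) -> np.ndarray:
        """Rows as a (n_rows, length) uint8 matrix of ASCII codes (as written)."""
        return np.frombuffer(
            "".join(self.rows.values()).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_rows, self.length)

    @classmethod
    def from_fasta(cls, path: str | Path, gene_id: str | None = None) -> "GeneAlignment":
        path = Path(path)
        return cls(gene_id or path.stem, read_fasta(path))

    def write(self, path: str | Path) -> None:
        write_fasta(self.rows, path)


@dataclass
class GeneAlignmentSet:
    """A collection of per-gene alignments; a sample may be absent from some genes."""

    genes: dict[str, GeneAlignment]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("empty gene alignment set")
        for gid, aln in self.genes.items():
            if aln.gene_id != gid:
                raise ValidationError(f"gene key {gid!r} != alignment id {aln.gene_id!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes)

    @property
    def sample_universe(self) -> list[str]:
        seen: dict[str, None] = {}
        for aln in self.genes.values():
            for s in aln.rows:
                seen.setdefault(s)
        return list(seen)

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneAlignment:
        return self.genes[gene_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    @classmethod
    def from_dir(cls, path: str | Path, pattern: str = "*.fasta") -> "GeneAlignmentSet":
        path = Path(path)
        genes = {}
        for f in sorted(path.glob(pattern)):
            genes[f.stem] = GeneAlignment.from_fasta(f)
        if not genes:
            raise ParseError(f"no {pattern} files under {path}")
        return cls(genes)

    def write_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for gid, aln in self.genes.items():
            aln.write(path / f"{gid}.fasta")


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

class DistanceMatrix:
    """Symmetric, zero-diagonal, non-negative labelled distance matrix."""

    #: symmetry tolerance for validation
    SYM_TOL = 1e-12

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        labels = list(labels)
        values = np.asarray(values, dtype=float)
        if len(set(labels)) != len(labels):
            raise ValidationError("distance matrix labels are not unique")
        if values.shape != (len(labels), len(labels)):
            raise ValidationError(
                f"distance matrix shape {values.shape} does not match {len(labels)} labels"
            )
        if len(labels) == 0:
            raise ValidationError("empty distance matrix")
        if np.any(np.diag(values) != 0.0):
            raise ValidationError("distance matrix diagonal must be exactly zero")
        if np.max(np.abs(values - values.T), initial=0.0) > self.SYM_TOL:
            raise ValidationError("distance matrix is not symmetric")
        if np.any(values < 0):
            raise ValidationError("distance matrix has negative entries")
        self.labels = labels
        self.values = values
        self._index = {lab: i for i, lab in enumerate(labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[lab] for lab in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def write_csv(self, path: str | Path) -> None:
        write_matrix_csv(self, path)


# ---------------------------------------------------------------------------
# Species map
# ---------------------------------------------------------------------------

@dataclass
class SpeciesMap:
    """Mapping from sample id to (binomial) species name."""

    mapping: dict[str, str]

    def species_of(self, sample_id: str) -> str:
        try:
            return self.mapping[sample_id]
        except KeyError:
            raise ValidationError(f"sample {sample_id!r} has no species entry") from None

    def samples_of(self, species: str) -> list[str]:
        return [s for s, sp in self.mapping.items() if sp == species]

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for sp in self.mapping.values():
            seen.setdefault(sp)
        return list(seen)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SpeciesMap":
        mapping: dict[str, str] = {}
        with Path(path).open() as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ParseError(f"species map line lacks two columns: {line!r}")
                if parts[0] in mapping:
                    raise ValidationError(f"duplicate sample {parts[0]!r} in species map")
                mapping[parts[0]] = parts[1]
        return cls(mapping)

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for s, sp in self.mapping.items():
                fh.write(f"{s}\t{sp}\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class PhyloTree:
    """An unrooted phylogenetic tree with branch lengths and edge supports.

    Backed by a private :class:`dendropy.Tree`.  On construction a degree-2
    root is collapsed (any support label sitting on it is discarded), so the
    bipartition view is that of an unrooted tree.  Bipartitions are stored
    canonically as the frozenset of leaf labels on the side *not* containing
    the lexicographically smallest leaf; only nontrivial bipartitions (both
    sides with >= 2 leaves) are reported.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        root = tree.seed_node
        if root is not None and len(root.child_nodes()) == 2 and len(tree.leaf_nodes()) > 2:
            tree.deroot()
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if any(lab is None for lab in labels):
            raise ValidationError("tree has unlabelled leaves")
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate leaf labels {dups}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError(f"negative branch length {edge.length}")
        self._leaves = frozenset(labels)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            if "uplicate" in str(exc):
                raise ValidationError(f"duplicate leaf labels: {exc}") from exc
            raise ParseError(f"invalid Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def read(cls, path: str | Path) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text())

    # -- basic views -------------------------------------------------------

    @property
    def leaves(self) -> frozenset[str]:
        return self._leaves

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    def _canonical(self, clade: frozenset[str]) -> frozenset[str]:
        ref = min(self._leaves)
        return frozenset(self._leaves - clade) if ref in clade else clade

    def _internal_nodes(self):
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root or node.is_leaf():
                continue
            yield node

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Nontrivial bipartitions, canonically encoded."""
        n = self.n_leaves
        out = set()
        for node in self._internal_nodes():
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 2 <= len(clade) <= n - 2:
                out.add(self._canonical(clade))
        return frozenset(out)

    def bipartition_supports(self) -> dict[frozenset[str], float]:
        """Support value per nontrivial internal edge (numeric node labels)."""
        n = self.n_leaves
        out: dict[frozenset[str], float] = {}
        for node in self._internal_nodes():
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if not (2 <= len(clade) <= n - 2):
                continue
            if node.label is None:
                continue
            try:
                out[self._canonical(clade)] = float(node.label)
            except ValueError:
                continue
        return out

    def set_supports(self, supports: Mapping[frozenset[str], float], fmt: str = "{:g}") -> None:
        """Attach support values (keyed by canonical bipartition) to edges."""
        n = self.n_leaves
        for node in self._internal_nodes():
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if not (2 <= len(clade) <= n - 2):
                continue
            key = self._canonical(clade)
            if key in supports:
                node.label = fmt.format(supports[key])

    def mean_support(self) -> float:
        sup = self.bipartition_supports()
        if not sup:
            return float("nan")
        return float(np.mean(list(sup.values())))

    def pruned_to(self, labels: Iterable[str]) -> "PhyloTree":
        """Restrict to a leaf subset, suppressing degree-2 nodes."""
        labels = set(labels)
        missing = labels - self._leaves
        if missing:
            raise ValidationError(f"labels not in tree: {sorted(missing)}")
        sub = self._tree.extract_tree_with_taxa_labels(labels)
        return PhyloTree(sub)

    def patristic_distances(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length distances (missing branch lengths count 0)."""
        pdm = self._tree.phylogenetic_distance_matrix()
        labels = sorted(self._leaves)
        taxa = {t.label: t for t in self._tree.taxon_namespace}
        n = len(labels)
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
                vals[i, j] = vals[j, i] = d
        return DistanceMatrix(labels, vals)

    # -- output ------------------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick", unquoted_underscores=True, suppress_rooting=True
        )
        return s.strip() + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick())

    def clone(self) -> "PhyloTree":
        return PhyloTree.from_newick(self.to_newick())

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree n_leaves={self.n_leaves}>"


def parse_newick(newick: str) -> PhyloTree:
    return PhyloTree.from_newick(newick)


def read_newick(path: str | Path) -> PhyloTree:
    return PhyloTree.read(path)


# ---------------------------------------------------------------------------
# Matrix CSV
# ---------------------------------------------------------------------------

def write_matrix_csv(matrix, path: str | Path, index_name: str = "sample") -> None:
    """Write a labelled matrix as CSV with 4-decimal values.

    Accepts a :class:`DistanceMatrix` or any object exposing ``labels`` (or
    ``samples``/``genes``) plus a ``values`` array.
    """
    if hasattr(matrix, "labels"):
        row_labels = col_labels = matrix.labels
    else:  # completeness-style matrices
        row_labels, col_labels = matrix.samples, matrix.genes
    values = np.asarray(matrix.values, dtype=float)
    if values.size == 0 or len(row_labels) == 0:
        raise ValidationError("refusing to write an empty matrix")
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([index_name] + list(col_labels))
        for lab, row in zip(row_labels, values):
            writer.writerow([lab] + [f"{v:.4f}" for v in row])


def read_matrix_csv(path: str | Path) -> DistanceMatrix:
    """Read a square labelled CSV back into a :class:`DistanceMatrix`."""
    with Path(path).open(newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 2:
        raise ParseError(f"matrix CSV {path} has no data rows")
    labels = rows[0][1:]
    values = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
    return DistanceMatrix(labels, values)
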