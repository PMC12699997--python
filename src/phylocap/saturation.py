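"""Stepwise gene-addition saturation analysis.

How many markers are enough?  Genes are added to a concatenated matrix in
steps (default 20 at a time), either in a seeded random order or ordered by
a relative substitution-rate surrogate (mean pairwise p-distance per gene,
slow to fast).  At each step a tree is built with the internal NJ +
bootstrap engine and compared, by nRF, to a reference tree — by default the
tree from the full gene set built the same way, optionally a user-supplied
(e.g. published) phylogeny.  The curve of (n_genes, nRF, mean support)
shows where adding markers stops improving the topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .distances import UndefinedDistanceError, alignment_distance_matrix
from .io import GeneAlignment, GeneAlignmentSet, PhyloTree
from .trees import bootstrap_support, nj_tree, rf_pair

__all__ = [
    "concatenate",
    "gene_rates",
    "SaturationCurve",
    "saturation_analysis",
]


def concatenate(
    genes: GeneAlignmentSet,
    gene_ids: list[str] | None = None,
    pad: str = "gap",
) -> tuple[GeneAlignment, list[tuple[str, int, int]]]:
    """Concatenate gene alignments into one supermatrix.

    Missing sample-by-gene blocks are filled with the pad symbol (``gap`` or
    ``N``).  Returns the concatenated alignment plus a partition table of
    0-based half-open column intervals per gene.
    """
    if gene_ids is None:
        gene_ids = genes.gene_ids
    if not gene_ids:
        raise ValueError("empty gene list")
    missing = [g for g in gene_ids if g not in genes.genes]
    if missing:
        raise ValueError(f"unknown gene ids: {missing}")
    if pad not in ("gap", "N"):
        raise ValueError("pad must be 'gap' or 'N'")
    pad_char = "-" if pad == "gap" else "N"
    samples: dict[str, None] = {}
    for gid in gene_ids:
        for s in genes[gid].rows:
            samples.setdefault(s)
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {s: [] for s in samples}
    offset = 0
    for gid in gene_ids:
        aln = genes[gid]
        L = aln.length
        for s in samples:
            chunks[s].append(aln.rows.get(s, pad_char * L))
        parts.append((gid, offset, offset + L))
        offset += L
    rows = {s: "".join(cs) for s, cs in chunks.items()}
    return GeneAlignment("concat", rows), parts


def gene_rates(genes: GeneAlignmentSet) -> dict[str, float]:
    """Relative substitution-rate surrogate per gene: the mean pairwise
    p-distance of its alignment.  Only the ordering of genes matters for the
    saturation analysis, which this surrogate preserves.  Genes whose
    distances are all undefined are excluded.
    """
    rates: dict[str, float] = {}
    for gid in genes:
        aln = genes[gid]
        if aln.n_rows < 2:
            continue
        try:
            D = alignment_distance_matrix(aln, metric="p")
        except UndefinedDistanceError:
            continue
        iu = np.triu_indices(len(D), 1)
        rates[gid] = float(D.values[iu].mean())
    return rates


@dataclass
class SaturationCurve:
    ordering: str
    seed: int
    step: int
    gene_order: list[str]
    #: (n_genes, nrf_to_reference, mean_support) per step
    points: list[tuple[int, float, float]]

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("ordering\tseed\tn_genes\tnrf\tmean_support\n")
            for n, nrf, sup in self.points:
                fh.write(f"{self.ordering}\t{self.seed}\t{n}\t{nrf:.4f}\t{sup:.2f}\n")


def write_partition_table(parts: list[tuple[str, int, int]], path: str | Path) -> None:
    """RAxML-style partition export (1-based inclusive coordinates)."""
    with Path(path).open("w") as fh:
        fh.write("# coordinates below are 1-based inclusive\n")
        for gid, start, end in parts:
            fh.write(f"DNA, {gid} = {start + 1}-{end}\n")


def saturation_analysis(
    genes: GeneAlignmentSet,
    ordering: str = "random",
    step: int = 20,
    reference: PhyloTree | None = None,
    replicates: int = 100,
    seed: int = 0,
    pad: str = "gap",
) -> SaturationCurve:
    """Build the gene-addition saturation curve.

    ``ordering`` is ``random`` (seeded shuffle) or ``rate`` (ascending
    rate surrogate, ties by gene id).  Step sizes are n = step, 2*step, ...
    up to the full set (the final point always uses every gene, so its nRF
    to the default reference is 0 by construction).
    """
    gene_ids = genes.gene_ids
    if ordering == "random":
        rng = np.random.default_rng(seed)
        order = [gene_ids[i] for i in rng.permutation(len(gene_ids))]
    elif ordering == "rate":
        rates = gene_rates(genes)
        order = sorted((g for g in gene_ids if g in rates), key=lambda g: (rates[g], g))
    else:
        raise ValueError(f"unknown ordering {ordering!r}")
    counts = list(range(step, len(order), step)) + [len(order)]

    def build(ids: list[str], rep_seed: int) -> PhyloTree:
        concat, _ = concatenate(genes, ids, pad=pad)
        if replicates > 0 and concat.n_rows >= 4:
            return bootstrap_support(concat, "p", replicates, rep_seed)
        return nj_tree(alignment_distance_matrix(concat, "p"))

    full_tree = build(order, seed)
    ref = reference if reference is not None else full_tree
    points: list[tuple[int, float, float]] = []
    for i, n in enumerate(counts):
        tree = full_tree if n == len(order) else build(order[:n], seed + 1 + i)
        nrf = rf_pair(tree, ref).nrf
        points.append((n, nrf, tree.mean_support()))
    return SaturationCurve(ordering, seed, step, order, points)
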