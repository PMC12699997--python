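"""Multilocus barcoding by distance skim plus a local phylogeny.

A query sample's gene sequences are inserted into a prealigned per-gene
database (keeping the database column space fixed), the alignments are
block-filtered and concatenated, and a blastn-score distance from the query
to every database sample picks the nearest neighbors: 20 in total with at
most 4 per species.  The query plus neighbors are then re-extracted from
the original alignments, re-filtered and re-concatenated, and a small NJ +
bootstrap tree is built; the species composition of the smallest clade
containing the query states the sister relationship.

A loci-resampling analysis quantifies how discrimination between designated
species pairs (intra- vs inter-specific distance distributions) improves
with the number of sampled loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from .distances import UndefinedDistanceError, alignment_distance_matrix, blastn_distance
from .io import (
    GeneAlignment,
    GeneAlignmentSet,
    PhyloTree,
    SpeciesMap,
    ValidationError,
)
from .saturation import concatenate
from .trees import bootstrap_support, nj_tree

__all__ = [
    "BarcodeDB",
    "BarcodeConfig",
    "NeighborSet",
    "add_query_to_alignment",
    "block_filter",
    "skim_neighbors",
    "barcode_run",
    "BarcodeReport",
    "loci_resampling_analysis",
    "LociResamplingResult",
]


@dataclass
class BarcodeDB:
    """Prealigned per-gene database plus the sample-to-species map."""

    genes: GeneAlignmentSet
    species: SpeciesMap

    def __post_init__(self) -> None:
        for sample in self.genes.sample_universe:
            self.species.species_of(sample)  # raises if missing

    @classmethod
    def read(cls, path: str | Path) -> "BarcodeDB":
        path = Path(path)
        return cls(
            GeneAlignmentSet.from_dir(path / "genes"),
            SpeciesMap.read_tsv(path / "species_map.tsv"),
        )

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.genes.write_dir(path / "genes")
        self.species.write_tsv(path / "species_map.tsv")


@dataclass(frozen=True)
class BarcodeConfig:
    m_neighbors: int = 20
    per_species_cap: int = 4
    block_gap_max: float = 0.5   # columns gappier than this are dropped
    block_min_len: int = 3       # surviving column runs shorter than this too
    bootstrap_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_species_cap > self.m_neighbors:
            raise ValueError("per_species_cap must be <= m_neighbors")


@dataclass
class NeighborSet:
    """Nearest database neighbors of a query, capped per species."""

    query_id: str
    neighbors: list[tuple[str, str, float]]  # (sample_id, species, distance)

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _, _ in self.neighbors]


# ---------------------------------------------------------------------------
# Query insertion
# ---------------------------------------------------------------------------

def _consensus(aln: GeneAlignment) -> str:
    """Majority base per column among unambiguous A/C/G/T; 'N' if none."""
    mat = aln.to_byte_matrix()
    cols = []
    for j in range(aln.length):
        counts: dict[str, int] = {}
        for b in mat[:, j]:
            c = chr(b).upper()
            if c in "ACGT":
                counts[c] = counts.get(c, 0) + 1
        if counts:
            cols.append(max(sorted(counts), key=lambda c: counts[c]))
        else:
            cols.append("N")
    return "".join(cols)


def _profile_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -5
    a.extend_gap_score = -1
    return a


def add_query_to_alignment(query: str, gene_aln: GeneAlignment) -> str | None:
    """Align an unaligned query into the alignment's fixed column space.

    The query is globally aligned to the alignment's majority consensus;
    query insertions relative to the profile are dropped so database columns
    are preserved.  Returns the aligned row (length = gene_aln.length), or
    None when the normalized score (score / query length) is negative —
    i.e. no credible homology.
    """
    query = query.replace("-", "")
    if not query:
        raise ValueError("empty query sequence")
    guide = _consensus(gene_aln)
    aln = _profile_aligner().align(guide, query)[0]
    if aln.score / len(query) < 0:
        return None
    row = ["-"] * len(guide)
    for (gs, ge), (qs, qe) in zip(*aln.aligned):
        for off in range(ge - gs):
            row[gs + off] = query[qs + off].upper()
    return "".join(row)


# ---------------------------------------------------------------------------
# Block filter
# ---------------------------------------------------------------------------

def block_filter(
    aln: GeneAlignment,
    gap_max: float = 0.5,
    min_len: int = 3,
) -> tuple[GeneAlignment | None, list[int]]:
    """Drop gap-rich columns, then short surviving blocks.

    A column with gap fraction > ``gap_max`` is removed; runs of surviving
    columns (contiguous in the original coordinates) shorter than
    ``min_len`` are removed too.  Returns the filtered alignment (None when
    nothing survives) and the retained original column indices.
    """
    n = aln.n_rows
    mat = aln.to_byte_matrix()
    gap_frac = (mat == ord("-")).sum(axis=0) / n
    surviving = [j for j in range(aln.length) if gap_frac[j] <= gap_max]
    kept: list[int] = []
    run: list[int] = []
    for j in surviving:
        if run and j != run[-1] + 1:
            if len(run) >= min_len:
                kept.extend(run)
            run = []
        run.append(j)
    if len(run) >= min_len:
        kept.extend(run)
    if not kept:
        return None, []
    return aln.take_columns(kept), kept


# ---------------------------------------------------------------------------
# Neighbor skim
# ---------------------------------------------------------------------------

def skim_neighbors(
    query_id: str,
    concat: GeneAlignment,
    species: SpeciesMap,
    cfg: BarcodeConfig = BarcodeConfig(),
) -> NeighborSet:
    """Nearest neighbors of the query by blastn-score distance.

    Database rows are sorted by ascending distance (ties keep database
    order) and taken greedily, skipping rows that would exceed the
    per-species cap, until ``m_neighbors`` are selected or rows run out.
    """
    if query_id not in concat.rows:
        raise ValidationError(f"query {query_id!r} not in alignment")
    qrow = concat.rows[query_id]
    dists: list[tuple[float, int, str]] = []
    for order, (sid, row) in enumerate(concat.rows.items()):
        if sid == query_id:
            continue
        try:
            d = blastn_distance(qrow, row)
        except UndefinedDistanceError:
            continue
        dists.append((d, order, sid))
    dists.sort(key=lambda t: (t[0], t[1]))
    taken: list[tuple[str, str, float]] = []
    per_species: dict[str, int] = {}
    for d, _, sid in dists:
        sp = species.species_of(sid)
        if per_species.get(sp, 0) >= cfg.per_species_cap:
            continue
        taken.append((sid, sp, d))
        per_species[sp] = per_species.get(sp, 0) + 1
        if len(taken) >= cfg.m_neighbors:
            break
    return NeighborSet(query_id, taken)


# ---------------------------------------------------------------------------
# Full barcode run
# ---------------------------------------------------------------------------

@dataclass
class BarcodeReport:
    query_id: str
    neighbors: NeighborSet
    tree: PhyloTree | None
    sister_species: list[str]
    top_hit_species: str
    monophyletic_top_hit: bool
    unresolved_tie: bool
    genes_used: list[str]
    warnings: list[str] = field(default_factory=list)


def _sister_clade(tree: PhyloTree, query_id: str, outgroup: str) -> list[str]:
    """Leaf labels of the smallest clade containing the query after rooting
    at the most distant neighbor."""
    import dendropy

    t = dendropy.Tree.get(
        data=tree.to_newick(), schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    og = None
    for leaf in t.leaf_node_iter():
        if leaf.taxon.label == outgroup:
            og = leaf
    if og is not None and og.edge.tail_node is not None:
        t.reroot_at_edge(og.edge, update_bipartitions=False)
    qleaf = next(
        leaf for leaf in t.leaf_node_iter() if leaf.taxon.label == query_id
    )
    node = qleaf.parent_node
    while node is not None:
        labels = [lf.taxon.label for lf in node.leaf_iter()]
        others = [l for l in labels if l != query_id and l != outgroup]
        if others:
            return others
        node = node.parent_node
    return []


def barcode_run(
    query_genes: Mapping[str, str],
    db: BarcodeDB,
    cfg: BarcodeConfig = BarcodeConfig(),
    query_id: str = "QUERY",
) -> BarcodeReport:
    """Insert, skim, and build the local tree for one query sample.

    ``query_genes`` maps gene ids to the query's unaligned sequences.
    """
    warnings: list[str] = []
    augmented: dict[str, GeneAlignment] = {}
    for gid, seq in query_genes.items():
        if gid not in db.genes.genes:
            warnings.append(f"gene {gid!r} not in database; skipped")
            continue
        aln = db.genes[gid]
        row = add_query_to_alignment(seq, aln)
        if row is None:
            warnings.append(f"gene {gid!r}: no credible homology; skipped")
            continue
        augmented[gid] = GeneAlignment(gid, {**aln.rows, query_id: row})
    if not augmented:
        raise ValidationError("no recoverable genes for query")
    filtered: dict[str, GeneAlignment] = {}
    for gid, aln in augmented.items():
        f, _ = block_filter(aln, cfg.block_gap_max, cfg.block_min_len)
        if f is None:
            warnings.append(f"gene {gid!r}: block filter removed all columns")
            continue
        filtered[gid] = f
    if not filtered:
        raise ValidationError("block filtering removed every gene")
    concat, _ = concatenate(GeneAlignmentSet(filtered), pad="gap")
    neighbors = skim_neighbors(query_id, concat, db.species, cfg)
    if not neighbors.neighbors:
        raise ValidationError("no neighbors could be scored")
    top_species = neighbors.neighbors[0][1]
    top_d = neighbors.neighbors[0][2]
    tie_species = {sp for _, sp, d in neighbors.neighbors if d <= top_d + 1e-12}
    unresolved_tie = len(tie_species) > 1

    # realign: restrict the augmented alignments to query + neighbors
    keep = [query_id] + neighbors.sample_ids
    local: dict[str, GeneAlignment] = {}
    for gid, aln in augmented.items():
        sub = aln.subset(keep)
        f, _ = block_filter(sub, cfg.block_gap_max, cfg.block_min_len)
        if f is not None:
            local[gid] = f
    tree = None
    sister: list[str] = []
    monophyletic = False
    if local:
        local_concat, _ = concatenate(GeneAlignmentSet(local), pad="gap")
        if local_concat.n_rows >= 4:
            tree = bootstrap_support(
                local_concat, "blastn", cfg.bootstrap_replicates, cfg.seed
            )
        elif local_concat.n_rows >= 3:
            tree = nj_tree(alignment_distance_matrix(local_concat, "blastn"))
        if tree is not None:
            outgroup = neighbors.neighbors[-1][0]  # most distant selected
            sister = _sister_clade(tree, query_id, outgroup)
            sister_species = sorted({db.species.species_of(s) for s in sister})
            monophyletic = sister_species == [top_species]
        else:
            warnings.append("too few samples for a local tree")
            sister_species = []
    else:
        warnings.append("no gene survived the local block filter")
        sister_species = []
    return BarcodeReport(
        query_id=query_id,
        neighbors=neighbors,
        tree=tree,
        sister_species=sister_species if tree is not None else [],
        top_hit_species=top_species,
        monophyletic_top_hit=monophyletic,
        unresolved_tie=unresolved_tie,
        genes_used=sorted(filtered),
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Loci resampling (discrimination vs number of loci)
# ---------------------------------------------------------------------------

@dataclass
class LociResamplingResult:
    """Distance distributions per (n_loci, replicate) for species pairs."""

    #: rows: dict(n_loci, replicate, species_a, species_b, kind, distance)
    records: list[dict]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.records)


def loci_resampling_analysis(
    db: BarcodeDB,
    species_pairs: Sequence[tuple[str, str]],
    grid: Sequence[int] | None = None,
    replicates: int = 5,
    seed: int = 0,
) -> LociResamplingResult:
    """Intra- vs inter-specific distances under loci resampling.

    For each loci count n in the grid (default 3..150) and each replicate,
    n genes are drawn without replacement, concatenated, and blastn-score
    distances computed for every intra- and inter-specific sample pair of
    each designated species pair.  Counts above the number of available
    genes are clipped.
    """
    if grid is None:
        grid = [3, 5, 10, 25, 50, 100, 150]
    for a, b in species_pairs:
        for sp in (a, b):
            if len(db.species.samples_of(sp)) < 2:
                raise ValidationError(f"species {sp!r} has < 2 individuals")
    gene_ids = db.genes.gene_ids
    rng = np.random.default_rng(seed)
    records: list[dict] = []
    for n in grid:
        n_eff = min(n, len(gene_ids))
        for rep in range(replicates):
            chosen = [gene_ids[i] for i in rng.choice(len(gene_ids), n_eff, replace=False)]
            concat, _ = concatenate(db.genes, chosen, pad="gap")
            for sp_a, sp_b in species_pairs:
                sa = db.species.samples_of(sp_a)
                sb = db.species.samples_of(sp_b)
                pairs = (
                    [("intra", x, y) for i, x in enumerate(sa) for y in sa[i + 1 :]]
                    + [("intra", x, y) for i, x in enumerate(sb) for y in sb[i + 1 :]]
                    + [("inter", x, y) for x in sa for y in sb]
                )
                for kind, x, y in pairs:
                    if x not in concat.rows or y not in concat.rows:
                        continue
                    d = blastn_distance(concat.rows[x], concat.rows[y])
                    records.append(
                        {"n_loci": n_eff, "replicate": rep, "species_a": sp_a,
                         "species_b": sp_b, "kind": kind, "distance": d}
                    )
    return LociResamplingResult(records)
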