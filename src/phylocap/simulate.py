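"""Synthetic data generator: trees, alignments, copy tables, barcode DBs.

Everything the toolkit consumes can be generated here, deterministically
per seed, so the whole pipeline is testable without downloads.  The
generator emulates the statistical structure the analyses assume: a single
species tree, rate-heterogeneous loci evolving under Jukes-Cantor (JC69),
contaminant extra gene copies at lower coverage than the target copy, and
species complexes with intraspecific divergence smaller than interspecific
divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .capture import GeneCopy
from .barcode import BarcodeDB
from .distances import alignment_distance_matrix
from .io import GeneAlignment, GeneAlignmentSet, PhyloTree, SpeciesMap

__all__ = [
    "SimulationSpec",
    "SpeciesComplexSpec",
    "ContaminationSpec",
    "simulate_tree",
    "evolve_alignment",
    "simulate_gene_set",
    "make_copy_table",
    "make_barcode_db",
    "jc_expected_pdist",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SpeciesComplexSpec:
    n_species: int = 10
    individuals_per_species: int = 4
    intra_divergence: float = 0.005
    inter_divergence: float = 0.10


@dataclass(frozen=True)
class ContaminationSpec:
    fraction_multicopy: float = 0.31
    copies_per_gene: int = 3
    contaminant_divergence: float = 0.15
    target_coverage: float = 100.0
    contaminant_coverage: float = 5.0
    #: root-to-tip depth (expected substitutions/site) the sample tree is
    #: rescaled to; capture loci are conserved, so samples stay well below
    #: saturation and within bait range of their reference
    tree_depth: float = 0.15


@dataclass(frozen=True)
class SimulationSpec:
    n_taxa: int = 20
    tree_model: str = "yule"
    birth_rate: float = 1.0
    gene_count: int = 40
    gene_length: int = 800
    rate_multiplier_low: float = 0.5
    rate_multiplier_high: float = 2.0
    substitution_model: str = "JC69"
    seed: int = 0
    species_complex: SpeciesComplexSpec | None = None
    contamination: ContaminationSpec | None = None

    def __post_init__(self) -> None:
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        if self.tree_model != "yule":
            raise ValueError("only the Yule tree model is supported")
        if self.substitution_model != "JC69":
            raise ValueError("only JC69 is supported")


def jc_expected_pdist(t: float) -> float:
    """Expected p-distance after total branch length t under JC69."""
    return 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_tree(
    n_taxa: int, birth_rate: float = 1.0, seed: int = 0, prefix: str = "t"
) -> PhyloTree:
    """Pure-birth (Yule) tree via exponential waiting times.

    Starting from 2 lineages at the root, with k lineages the time to the
    next split is Exponential(k * birth_rate); a uniformly chosen lineage
    splits.  After the n-th lineage appears the tips are extended by one
    final Exponential(n * birth_rate) segment, so the expected root-to-tip
    depth is (H_n - 1) / birth_rate with H_n the n-th harmonic number.
    Leaves are labelled ``<prefix>01 ...`` in a seeded random order.
    """
    if n_taxa < 3:
        raise ValueError("need >= 3 taxa")
    rng = np.random.default_rng(seed)
    taxa_labels = [f"{prefix}{i + 1:02d}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(taxa_labels)
    root = dendropy.Node()
    tips = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = 0.0
        root.add_child(child)
        tips.append(child)
    k = 2
    while True:
        wait = rng.exponential(1.0 / (k * birth_rate))
        for tip in tips:
            tip.edge.length += wait
        if k == n_taxa:
            break
        idx = int(rng.integers(0, k))
        parent = tips.pop(idx)
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            parent.add_child(child)
            tips.append(child)
        k += 1
    order = rng.permutation(n_taxa)
    for tip, lab_idx in zip(tips, order):
        tip.taxon = ns.get_taxon(taxa_labels[int(lab_idx)])
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _mutate(codes: np.ndarray, p_change: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution with probability p_change; the new base is
    uniform over the three alternatives (JC69 conditional step)."""
    out = codes.copy()
    hit = rng.random(codes.shape[0]) < p_change
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def evolve_alignment(
    tree: PhyloTree,
    length: int,
    rate_multiplier: float = 1.0,
    seed: int = 0,
    gene_id: str = "gene",
) -> GeneAlignment:
    """Evolve a gap-free alignment along a tree under JC69.

    The root sequence is uniform over A/C/G/T; along a branch of length t
    each site substitutes with probability 3/4 (1 - e^(-4 r t / 3)) where r
    is the per-gene rate multiplier.
    """
    rng = np.random.default_rng(seed)
    dtree = tree._tree  # traversal order is deterministic
    root_codes = rng.integers(0, 4, size=length)
    seqs: dict[int, np.ndarray] = {id(dtree.seed_node): root_codes}
    rows: dict[str, str] = {}
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            codes = root_codes
        else:
            t = (node.edge.length or 0.0) * rate_multiplier
            p = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
            codes = _mutate(seqs[id(node.parent_node)], p, rng)
            seqs[id(node)] = codes
        if node.is_leaf():
            rows[node.taxon.label] = "".join(_BASES[c] for c in codes)
    # stable row order by label
    return GeneAlignment(gene_id, {k: rows[k] for k in sorted(rows)})


def simulate_gene_set(spec: SimulationSpec) -> tuple[GeneAlignmentSet, PhyloTree, dict[str, float]]:
    """Simulate a rate-heterogeneous gene set on one species tree.

    Per-gene rate multipliers are drawn log-uniformly between the spec's low
    and high bounds.  Returns (genes, true tree, gene -> multiplier).
    """
    rng = np.random.default_rng(spec.seed)
    tree = simulate_tree(spec.n_taxa, spec.birth_rate, spec.seed)
    genes: dict[str, GeneAlignment] = {}
    multipliers: dict[str, float] = {}
    lo, hi = spec.rate_multiplier_low, spec.rate_multiplier_high
    for i in range(spec.gene_count):
        gid = f"gene{i + 1:03d}"
        mult = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        genes[gid] = evolve_alignment(
            tree, spec.gene_length, mult, seed=int(rng.integers(0, 2**31)), gene_id=gid
        )
        multipliers[gid] = mult
    return GeneAlignmentSet(genes), tree, multipliers


# ---------------------------------------------------------------------------
# Copy tables (contamination)
# ---------------------------------------------------------------------------

def make_copy_table(
    spec: SimulationSpec,
) -> tuple[list[GeneCopy], dict[tuple[str, str], str], dict[str, str]]:
    """Simulate extracted gene copies with coverage, plus truth labels.

    Each sample x gene cell holds one target copy at the target coverage;
    with probability ``fraction_multicopy`` extra contaminant copies are
    added, diverged from the target by ``contaminant_divergence`` and at the
    contaminant coverage.  Coverage values are deterministic means so that
    filter decisions are exact.  Returns (copies, truth labels mapping each
    cell to the target copy id, per-gene reference sequences).
    """
    if spec.contamination is None:
        raise ValueError("spec has no contamination block")
    con = spec.contamination
    tree = simulate_tree(spec.n_taxa, spec.birth_rate, spec.seed)
    # rescale to a capture-realistic depth (see ContaminationSpec.tree_depth)
    depth = tree.patristic_distances().values.max() / 2
    scale = con.tree_depth / depth if depth > 0 else 1.0
    for edge in tree._tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    rng = np.random.default_rng(spec.seed + 1)
    genes_d: dict[str, GeneAlignment] = {}
    lo, hi = spec.rate_multiplier_low, spec.rate_multiplier_high
    for i in range(spec.gene_count):
        gid = f"gene{i + 1:03d}"
        mult = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        genes_d[gid] = evolve_alignment(
            tree, spec.gene_length, mult, seed=int(rng.integers(0, 2**31)), gene_id=gid
        )
    genes = GeneAlignmentSet(genes_d)
    copies: list[GeneCopy] = []
    truth: dict[tuple[str, str], str] = {}
    references: dict[str, str] = {}
    for gid in genes:
        aln = genes[gid]
        # reference = the gene's medoid row (min total p-distance)
        D = alignment_distance_matrix(aln, metric="p")
        references[gid] = aln.rows[D.labels[int(D.values.sum(axis=1).argmin())]]
        for sample, seq in aln.rows.items():
            copies.append(GeneCopy(sample, gid, "c1", seq, con.target_coverage))
            truth[(sample, gid)] = "c1"
            if rng.random() < con.fraction_multicopy:
                for extra in range(2, con.copies_per_gene + 1):
                    codes = np.array([_BASES.index(c) for c in seq])
                    mutated = _mutate(codes, con.contaminant_divergence, rng)
                    copies.append(
                        GeneCopy(
                            sample, gid, f"c{extra}",
                            "".join(_BASES[c] for c in mutated),
                            con.contaminant_coverage,
                        )
                    )
    return copies, truth, references


# ---------------------------------------------------------------------------
# Barcode databases (species complexes)
# ---------------------------------------------------------------------------

def make_barcode_db(
    spec: SimulationSpec,
) -> tuple[BarcodeDB, dict[str, dict[str, str]], dict[str, str]]:
    """Simulate a species-complex barcode database plus withheld queries.

    Species mean sequences are separated by ``inter_divergence`` (each
    species branch mutates sites with probability inter/2) and individuals
    scatter around their species mean by ``intra_divergence`` (each
    individual branch mutates with probability intra/2).  One individual per
    species is withheld as a query.  Returns (database, queries keyed by
    query sample id then gene id, query sample -> true species).
    """
    if spec.species_complex is None:
        raise ValueError("spec has no species-complex block")
    sc = spec.species_complex
    rng = np.random.default_rng(spec.seed)
    species_names = [f"Species_{i + 1:02d}" for i in range(sc.n_species)]
    genes: dict[str, GeneAlignment] = {}
    queries: dict[str, dict[str, str]] = {}
    mapping: dict[str, str] = {}
    query_truth: dict[str, str] = {}
    for i in range(spec.gene_count):
        gid = f"gene{i + 1:03d}"
        root = rng.integers(0, 4, size=spec.gene_length)
        rows: dict[str, str] = {}
        for sp in species_names:
            mean = _mutate(root, sc.inter_divergence / 2.0, rng)
            for ind in range(1, sc.individuals_per_species + 2):
                codes = _mutate(mean, sc.intra_divergence / 2.0, rng)
                seq = "".join(_BASES[c] for c in codes)
                sample = f"{sp}_ind{ind}"
                if ind == sc.individuals_per_species + 1:  # withheld query
                    queries.setdefault(sample, {})[gid] = seq
                    query_truth[sample] = sp
                else:
                    rows[sample] = seq
                    mapping[sample] = sp
        genes[gid] = GeneAlignment(gid, rows)
    db = BarcodeDB(GeneAlignmentSet(genes), SpeciesMap(mapping))
    return db, queries, query_truth
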