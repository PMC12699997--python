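"""Tree building and comparison machinery.

Contains the internal tree engine (neighbor-joining with nonparametric
bootstrap), Robinson-Foulds distances on unrooted bipartition sets, the
modified Thompson-tau outlier test used to discard aberrant gene-tree
topologies, topology-cluster detection (classical 2D multidimensional
scaling followed by DBSCAN), and a per-edge gene-tree/species-tree
concordance counter.

The NJ engine is a surrogate for external maximum-likelihood inference:
every operation that consumes a tree also accepts externally computed
Newick, so ML trees can be substituted wherever desired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats
from sklearn.cluster import DBSCAN

from .distances import alignment_distance_matrix, UndefinedDistanceError
from .io import DistanceMatrix, GeneAlignment, PhyloTree, ValidationError

__all__ = [
    "nj_tree",
    "bootstrap_support",
    "TreePairStats",
    "rf_pair",
    "treeset_distance_matrix",
    "TauConfig",
    "tau_outliers",
    "gene_tree_outlier_filter",
    "TopologyClusterReport",
    "topology_clusters",
    "concordance_counts",
]


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Standard neighbor joining (Saitou-Nei, Q criterion).

    Deterministic: Q ties are broken by the lexicographically smallest
    (label, label) pair, where a cluster is keyed by the smallest leaf label
    it contains.  Negative branch lengths are clamped to zero.  Consistent on
    additive matrices: recovers the generating topology and branch lengths.
    """
    n0 = len(D)
    if n0 < 3:
        raise ValueError("neighbor joining needs >= 3 labels")
    taxa = dendropy.TaxonNamespace(D.labels)
    nodes: list[dendropy.Node] = []
    keys: list[str] = []  # lexicographic sort key per active cluster
    for lab in D.labels:
        nd = dendropy.Node()
        nd.taxon = taxa.get_taxon(lab)
        nodes.append(nd)
        keys.append(lab)
    d = D.values.astype(float).copy()
    active = list(range(n0))

    def _join(i: int, j: int, li: float, lj: float) -> dendropy.Node:
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(0.0, li)
        nodes[j].edge.length = max(0.0, lj)
        return parent

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cands = np.argwhere(q <= qmin + 1e-12)
        best = None
        for a, b in cands:
            if a >= b:
                continue
            ka, kb = keys[active[a]], keys[active[b]]
            pair = (min(ka, kb), max(ka, kb))
            if best is None or pair < best[0]:
                best = (pair, int(a), int(b))
        assert best is not None
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        parent = _join(i, j, li, lj)
        # distances from the new node to every other active cluster
        new_idx = len(nodes)
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        for c in active:
            if c in (i, j):
                continue
            d[new_idx, c] = d[c, new_idx] = 0.5 * (d[i, c] + d[j, c] - dij)
        active = [c for c in active if c not in (i, j)] + [new_idx]

    i, j, k = sorted(active, key=lambda c: keys[c])
    root = dendropy.Node()
    for c in (i, j, k):
        root.add_child(nodes[c])
    nodes[i].edge.length = max(0.0, 0.5 * (d[i, j] + d[i, k] - d[j, k]))
    nodes[j].edge.length = max(0.0, 0.5 * (d[i, j] + d[j, k] - d[i, k]))
    nodes[k].edge.length = max(0.0, 0.5 * (d[i, k] + d[j, k] - d[i, j]))
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree)


def bootstrap_support(
    aln: GeneAlignment,
    metric: str = "p",
    replicates: int = 100,
    seed: int = 0,
) -> PhyloTree:
    """Point NJ tree with nonparametric bootstrap supports.

    Each replicate resamples alignment columns with replacement and rebuilds
    the NJ tree; an internal edge's support is the percentage of replicates
    whose tree contains its bipartition.  A replicate whose resampled matrix
    has an undefined pair is redrawn (at most 10 retries each).
    """
    if aln.n_rows < 4:
        raise ValueError("bootstrap needs >= 4 rows")
    point = nj_tree(alignment_distance_matrix(aln, metric=metric))
    if replicates <= 0:
        return point
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in point.bipartitions()}
    length = aln.length
    for _ in range(replicates):
        for attempt in range(10):
            cols = rng.integers(0, length, size=length)
            rep_aln = aln.take_columns(cols.tolist())
            try:
                rep_tree = nj_tree(alignment_distance_matrix(rep_aln, metric=metric))
            except UndefinedDistanceError:
                continue
            break
        else:
            raise UndefinedDistanceError(
                "bootstrap replicate kept producing undefined distances"
            )
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    supports = {bp: 100.0 * c / replicates for bp, c in counts.items()}
    point.set_supports(supports)
    return point


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreePairStats:
    """RF comparison of two trees after pruning to their shared leaves."""

    rf: int
    rf_max: int
    nrf: float
    shared_leaves: int


def rf_pair(t1: PhyloTree, t2: PhyloTree) -> TreePairStats:
    """Symmetric bipartition difference and its normalization.

    Both trees are pruned to the shared leaf set; ``rf`` is the symmetric
    difference of the nontrivial bipartition sets and ``rf_max`` the sum of
    the two set sizes (equals 2(n-3) for binary trees), so ``nrf`` is in
    [0, 1] and handles polytomies gracefully.
    """
    shared = t1.leaves & t2.leaves
    if len(shared) < 4:
        raise ValidationError(f"only {len(shared)} shared leaves; need >= 4")
    p1 = t1 if t1.leaves == shared else t1.pruned_to(shared)
    p2 = t2 if t2.leaves == shared else t2.pruned_to(shared)
    b1, b2 = p1.bipartitions(), p2.bipartitions()
    rf = len(b1 ^ b2)
    rf_max = len(b1) + len(b2)
    nrf = rf / rf_max if rf_max > 0 else 0.0
    return TreePairStats(rf=rf, rf_max=rf_max, nrf=nrf, shared_leaves=len(shared))


def treeset_distance_matrix(trees: Mapping[str, PhyloTree]) -> DistanceMatrix:
    """nRF distance matrix over a labelled set of trees."""
    ids = list(trees)
    if len(ids) < 2:
        raise ValueError("need >= 2 trees")
    n = len(ids)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                vals[i, j] = vals[j, i] = rf_pair(trees[ids[i]], trees[ids[j]]).nrf
            except ValidationError as exc:
                raise ValidationError(
                    f"tree pair ({ids[i]!r}, {ids[j]!r}): {exc}"
                ) from exc
    return DistanceMatrix(ids, vals)


# ---------------------------------------------------------------------------
# Thompson tau
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TauConfig:
    """Modified Thompson-tau parameters (two-sided alpha, minimum n)."""

    alpha: float = 0.05
    min_n: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def _tau_threshold(n: int, alpha: float) -> float:
    t = stats.t.ppf(1 - alpha / 2, n - 2)
    return t * (n - 1) / (np.sqrt(n) * np.sqrt(n - 2 + t * t))


def tau_outliers(
    values: Mapping[str, float], cfg: TauConfig = TauConfig()
) -> tuple[list[str], list[str], list[dict]]:
    """Iterative modified Thompson-tau outlier rejection.

    At each step the sample mean m and standard deviation s are recomputed;
    the point with the largest |x - m| is removed if that deviation exceeds
    tau * s, where tau = t (n-1) / (sqrt(n) sqrt(n-2+t^2)) and t is the
    two-sided Student critical value at ``alpha`` with n-2 df.  Ties go to
    the larger value.  Returns (kept ids, removed ids in removal order,
    trace of removals).
    """
    ids = list(values)
    if len(ids) < cfg.min_n:
        raise ValueError(f"need >= {cfg.min_n} values, got {len(ids)}")
    kept = list(ids)
    removed: list[str] = []
    trace: list[dict] = []
    while len(kept) >= max(cfg.min_n, 3):
        x = np.array([values[i] for i in kept])
        n = len(x)
        m = x.mean()
        s = x.std(ddof=1)
        if s == 0:
            break
        delta = np.abs(x - m)
        dmax = delta.max()
        # candidates at the max deviation; tie -> larger value removed
        cand = [i for i in range(n) if delta[i] >= dmax - 1e-15]
        worst = max(cand, key=lambda i: (x[i], kept[i]))
        tau_s = _tau_threshold(n, cfg.alpha) * s
        if dmax > tau_s:
            trace.append(
                {"removed": kept[worst], "value": float(x[worst]),
                 "delta": float(dmax), "threshold": float(tau_s), "n": n}
            )
            removed.append(kept[worst])
            kept.pop(worst)
        else:
            break
    return kept, removed, trace


def gene_tree_outlier_filter(
    gene_trees: Mapping[str, PhyloTree],
    species_tree: PhyloTree | None = None,
    cfg: TauConfig = TauConfig(),
) -> tuple[list[str], dict]:
    """Discard gene trees whose average nRF to the rest is a tau outlier.

    Each gene's score is its mean nRF distance to every other gene tree,
    plus — when provided — the species tree as one extra comparator.
    """
    ids = list(gene_trees)
    if len(ids) < cfg.min_n:
        raise ValueError(f"need >= {cfg.min_n} gene trees")
    scores: dict[str, float] = {}
    for gid in ids:
        ds = [rf_pair(gene_trees[gid], gene_trees[o]).nrf for o in ids if o != gid]
        if species_tree is not None:
            ds.append(rf_pair(gene_trees[gid], species_tree).nrf)
        scores[gid] = float(np.mean(ds))
    kept, removed, trace = tau_outliers(scores, cfg)
    report = {"scores": scores, "removed": removed, "trace": trace}
    return kept, report


# ---------------------------------------------------------------------------
# Topology clusters (MDS + DBSCAN)
# ---------------------------------------------------------------------------

@dataclass
class TopologyClusterReport:
    """2D embedding and density-cluster labels for a set of trees."""

    labels: list[str]
    coordinates: np.ndarray  # (n, 2)
    cluster_labels: np.ndarray  # int per tree, -1 = noise
    n_clusters: int
    dominant_cluster_fraction: float
    eps: float


def classical_mds(D: DistanceMatrix, n_components: int = 2) -> np.ndarray:
    """Torgerson metric MDS: double-centered eigendecomposition of -D^2/2.

    Negative eigenvalues (nRF need not be Euclidean) are truncated at zero.
    """
    d2 = D.values ** 2
    n = len(D)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:n_components]
    w = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(w)


def topology_clusters(
    D: DistanceMatrix, eps: float | None = None, min_pts: int = 4
) -> TopologyClusterReport:
    """Detect clusters of similar topologies in an nRF distance matrix.

    The matrix is embedded in 2D by classical MDS and clustered with DBSCAN;
    ``eps`` defaults to half the median pairwise embedded distance.  A
    degenerate all-zero matrix reports a single cluster.
    """
    n = len(D)
    if n < min_pts:
        raise ValueError(f"need >= {min_pts} trees")
    coords = classical_mds(D, 2)
    iu = np.triu_indices(n, 1)
    emb = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    med = float(np.median(emb[iu]))
    if eps is None:
        eps = 0.5 * med
    if eps <= 0:  # all trees coincide
        labels = np.zeros(n, dtype=int)
        return TopologyClusterReport(D.labels, coords, labels, 1, 1.0, eps)
    labels = DBSCAN(eps=eps, min_samples=min_pts, metric="euclidean").fit_predict(coords)
    clusters = [c for c in set(labels) if c != -1]
    if clusters:
        dominant = max(np.sum(labels == c) for c in clusters) / n
    else:
        dominant = 0.0
    return TopologyClusterReport(
        D.labels, coords, labels, len(clusters), float(dominant), float(eps)
    )


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def _compatible(a: frozenset, b: frozenset, universe: frozenset) -> bool:
    """Bipartitions A|A' and B|B' on the same leaf set are compatible iff one
    of the four pairwise intersections is empty."""
    a2, b2 = universe - a, universe - b
    return not (a & b) or not (a & b2) or not (a2 & b) or not (a2 & b2)


def concordance_counts(
    species_tree: PhyloTree, gene_trees: Mapping[str, PhyloTree] | Sequence[PhyloTree]
) -> list[dict]:
    """Per species-tree edge, count concordant / conflicting / uninformative
    gene trees (a simplified bipartition-based concordance summary).

    A gene tree is *concordant* with a species-tree bipartition B when,
    restricted to the shared leaves (both sides still >= 2), the gene tree
    contains B; *conflicting* when it contains a bipartition incompatible
    with B; otherwise *uninformative*.  The three counts sum to the number
    of gene trees at every edge.
    """
    if isinstance(gene_trees, Mapping):
        trees = list(gene_trees.values())
    else:
        trees = list(gene_trees)
    sp_leaves = species_tree.leaves
    out = []
    for edge_id, bip in enumerate(sorted(species_tree.bipartitions(),
                                         key=lambda b: sorted(b))):
        side_a = bip
        side_b = sp_leaves - bip
        # label each edge by its smaller side (ties: lexicographic)
        small = min(side_a, side_b, key=lambda s: (len(s), sorted(s)))
        conc = confl = uninf = 0
        for gt in trees:
            shared = gt.leaves & sp_leaves
            a = side_a & shared
            b = side_b & shared
            if len(a) < 2 or len(b) < 2:
                uninf += 1
                continue
            pruned = gt if gt.leaves == shared else gt.pruned_to(shared)
            gbips = pruned.bipartitions()
            target = a if min(shared) not in a else b
            if target in gbips:
                conc += 1
            elif any(not _compatible(g, a, shared) for g in gbips):
                confl += 1
            else:
                uninf += 1
        out.append(
            {"edge_id": edge_id, "bipartition": "|".join(sorted(small)),
             "concordant": conc, "conflicting": confl, "uninformative": uninf}
        )
    return out
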