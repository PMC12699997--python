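"""K-medoids selection of representative sequences per gene.

Target-capture baits tolerate only limited divergence between bait and
template, so a universal bait set needs a small number of representative
sequences per gene that keep every known sequence within hybridization
range.  This module finds, per gene, the smallest number of medoids k such
that at least a fraction ``f_conv`` (default 0.95) of the sequences in the
alignment lie within p-distance ``d_max`` (default 0.25) of their nearest
medoid.  k is searched ascending from 1 with multiple seeded PAM restarts
per k; a gene whose best solution at ``k_max`` still misses the criterion is
reported as non-convergent.  Genes with alignments shorter than a minimum
exon length (default 600 bp) are discarded before clustering.

All tie-breaks are by lexicographic sequence id so runs are reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .distances import alignment_distance_matrix
from .io import DistanceMatrix, GeneAlignment, GeneAlignmentSet, write_fasta

__all__ = [
    "MedoidConfig",
    "MedoidSolution",
    "kmedoids_once",
    "select_representatives",
    "select_gene_set",
    "GeneSelectionReport",
]


@dataclass(frozen=True)
class MedoidConfig:
    """Clustering parameters.

    d_max
        Maximum allowed distance of a sequence from its medoid (0.20, 0.25
        or 0.30 are typical choices; default 0.25).
    k_max
        Largest medoid count tried per gene (default 70).
    f_conv
        Fraction of sequences that must lie within ``d_max`` of a medoid for
        the gene to count as converged (default 0.95, inclusive).
    restarts
        Random PAM restarts per (gene, k) (default 100).
    """

    d_max: float = 0.25
    k_max: int = 70
    f_conv: float = 0.95
    restarts: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.d_max < 1):
            raise ValueError("d_max must be in (0, 1)")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if not (0 < self.f_conv <= 1):
            raise ValueError("f_conv must be in (0, 1]")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class MedoidSolution:
    """One clustering outcome for a gene."""

    gene_id: str
    k: int
    medoid_ids: list[str]
    assignment: dict[str, str]
    fraction_within: float
    converged: bool
    objective: float
    #: objective after each PAM iteration (monotone non-increasing)
    objective_trace: list[float] = field(default_factory=list)


def _rank(labels: list[str]) -> np.ndarray:
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    rank = np.empty(len(labels), dtype=int)
    for r, i in enumerate(order):
        rank[i] = r
    return rank


def kmedoids_once(
    D: DistanceMatrix, k: int, seed: int, d_max: float = 0.25, gene_id: str = ""
) -> MedoidSolution:
    """One seeded PAM run: random distinct initial medoids, then alternate
    nearest-medoid assignment and within-cluster medoid updates until the
    medoid set is stable.  Deterministic given (D, k, seed); assignment ties
    and medoid-update ties go to the lexicographically smallest id.
    """
    n = len(D)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    labels = D.labels
    vals = D.values
    rank = _rank(labels)
    rng = np.random.default_rng(seed)
    medoids = set(int(i) for i in rng.choice(n, size=k, replace=False))
    trace: list[float] = []
    while True:
        med = sorted(medoids, key=lambda i: labels[i])  # lexicographic columns
        cols = vals[:, med]
        nearest = np.argmin(cols, axis=1)  # first minimum -> smallest id
        assign = np.array([med[j] for j in nearest])
        trace.append(float(vals[np.arange(n), assign].sum()))
        new_medoids = set()
        for m in med:
            members = np.flatnonzero(assign == m)
            if members.size == 0:  # duplicate-sequence medoid lost its points
                new_medoids.add(m)
                continue
            # order members lexicographically so argmin ties pick smallest id
            members = members[np.argsort(rank[members], kind="stable")]
            sub = vals[np.ix_(members, members)]
            best = members[int(np.argmin(sub.sum(axis=1)))]
            new_medoids.add(int(best))
        if new_medoids == medoids:
            break
        medoids = new_medoids
    dist_to_medoid = vals[np.arange(n), assign]
    objective = float(dist_to_medoid.sum())
    fraction_within = float(np.mean(dist_to_medoid <= d_max))
    return MedoidSolution(
        gene_id=gene_id,
        k=k,
        medoid_ids=sorted(labels[i] for i in medoids),
        assignment={labels[i]: labels[assign[i]] for i in range(n)},
        fraction_within=fraction_within,
        converged=fraction_within >= 0.95,  # provisional; caller re-evaluates
        objective=objective,
        objective_trace=trace,
    )


def _restart_seed(base_seed: int, gene_id: str, k: int, restart: int) -> int:
    ss = np.random.SeedSequence(
        entropy=[int(base_seed), zlib.crc32(gene_id.encode()), int(k), int(restart)]
    )
    return int(ss.generate_state(1)[0])


def select_representatives(aln: GeneAlignment, cfg: MedoidConfig) -> MedoidSolution:
    """Smallest k whose best restart reaches the convergence fraction.

    For each k from 1 to ``min(k_max, n)``, runs ``cfg.restarts`` seeded PAM
    restarts and keeps the restart with the highest fraction-within (ties:
    lower objective, then lower restart index).  Returns the first convergent
    k; if none converges, the best solution at the largest k tried, flagged
    ``converged=False``.
    """
    if aln.n_rows < 2:
        raise ValueError(f"gene {aln.gene_id!r}: need >= 2 rows")
    D = alignment_distance_matrix(aln, metric="p")
    n = len(D)
    k_cap = min(cfg.k_max, n)
    best_overall: MedoidSolution | None = None
    for k in range(1, k_cap + 1):
        best: MedoidSolution | None = None
        for r in range(cfg.restarts):
            sol = kmedoids_once(
                D, k, _restart_seed(cfg.seed, aln.gene_id, k, r), cfg.d_max, aln.gene_id
            )
            if best is None or (
                (-sol.fraction_within, sol.objective) < (-best.fraction_within, best.objective)
            ):
                best = sol
            if best.fraction_within == 1.0 and best.objective == 0.0:
                break  # cannot be improved
        assert best is not None
        best.converged = best.fraction_within >= cfg.f_conv
        if best.converged:
            return best
        best_overall = best
    assert best_overall is not None
    best_overall.converged = False
    return best_overall


@dataclass
class GeneSelectionReport:
    """Outcome of marker selection over a gene set."""

    solutions: dict[str, MedoidSolution]
    retained: list[str]
    non_converged: list[str]
    dropped_short: list[str]
    min_exon_len: int

    def rows(self) -> list[dict]:
        out = []
        for gid in self.dropped_short:
            out.append(
                {"gene_id": gid, "n": "", "k": "", "fraction_within": "",
                 "converged": "", "dropped_reason": f"shorter_than_{self.min_exon_len}"}
            )
        for gid, sol in self.solutions.items():
            out.append(
                {"gene_id": gid, "n": len(sol.assignment), "k": sol.k,
                 "fraction_within": f"{sol.fraction_within:.4f}",
                 "converged": str(sol.converged).lower(),
                 "dropped_reason": "" if sol.converged else "non_convergent"}
            )
        return out

    def write_tsv(self, path: str | Path) -> None:
        rows = self.rows()
        with Path(path).open("w") as fh:
            cols = ["gene_id", "n", "k", "fraction_within", "converged", "dropped_reason"]
            fh.write("\t".join(cols) + "\n")
            for row in rows:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def select_gene_set(
    genes: GeneAlignmentSet, cfg: MedoidConfig, min_exon_len: int = 600
) -> GeneSelectionReport:
    """Run representative selection over a gene set.

    Genes with alignment length < ``min_exon_len`` are dropped before
    clustering; retained genes are those whose clustering converged.
    """
    dropped_short = [gid for gid in genes if genes[gid].length < min_exon_len]
    solutions: dict[str, MedoidSolution] = {}
    for gid in genes:
        if gid in set(dropped_short):
            continue
        solutions[gid] = select_representatives(genes[gid], cfg)
    retained = [gid for gid, sol in solutions.items() if sol.converged]
    non_converged = [gid for gid, sol in solutions.items() if not sol.converged]
    return GeneSelectionReport(solutions, retained, non_converged, dropped_short, min_exon_len)


def write_representatives_fasta(
    report: GeneSelectionReport, genes: GeneAlignmentSet, out_dir: str | Path
) -> None:
    """Per retained gene, write the medoid sequences (gaps stripped)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for gid in report.retained:
        sol = report.solutions[gid]
        aln = genes[gid]
        recs = {m: aln.rows[m].replace("-", "") for m in sol.medoid_ids}
        write_fasta(recs, out_dir / f"{gid}_representatives.fasta")
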