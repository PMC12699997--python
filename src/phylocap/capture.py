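"""Post-extraction QC: multiple-copy filtering and completeness.

Target capture with a universal bait set frequently pulls down homologous
sequence from contaminant organisms alongside the target, so a gene can be
recovered in several copies.  Coverage depth is the main signal separating
the target copy from contaminants: the filter retains the deepest copy when
it is at least ``r_min`` times (default 10, inclusive) deeper covered than
the next deepest.  In *strict* mode a gene failing that condition is
dropped; in *default* mode the copy most similar to the gene's reference
sequence is retained instead.

Completeness of the resolved genes is summarized as a samples x genes
matrix of extracted non-gap length over reference length (capped at 1 in
the matrix; the raw ratio is kept for the CSV export).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio import Align

from .io import ValidationError, read_fasta

__all__ = [
    "GeneCopy",
    "FilterConfig",
    "CompletenessMatrix",
    "reference_similarity",
    "resolve_copies",
    "resolve_table",
    "completeness_matrix",
    "filter_report",
    "read_copies_fasta",
    "read_copies_tsv",
]


@dataclass
class GeneCopy:
    sample_id: str
    gene_id: str
    copy_id: str
    sequence: str
    mean_coverage: float
    reference_similarity: float | None = None

    def __post_init__(self) -> None:
        if self.mean_coverage < 0:
            raise ValidationError("mean_coverage must be >= 0")


@dataclass(frozen=True)
class FilterConfig:
    """Coverage-ratio threshold (inclusive) and filter mode."""

    r_min: float = 10.0
    mode: str = "default"

    def __post_init__(self) -> None:
        if self.r_min <= 1:
            raise ValueError("r_min must be > 1")
        if self.mode not in ("default", "strict"):
            raise ValueError("mode must be 'default' or 'strict'")


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -5
    a.extend_gap_score = -1
    return a


def reference_similarity(seq: str, reference: str) -> float:
    """p-identity of a global pairwise alignment to the reference.

    Scores: match +1 / mismatch -1, affine gaps open 5 extend 1.  Identity is
    matches over aligned (both-non-gap) columns.
    """
    aln = _aligner().align(seq.upper().replace("-", ""),
                           reference.upper().replace("-", ""))[0]
    matches = 0
    columns = 0
    for (qs, qe), (rs, re_) in zip(*aln.aligned):
        columns += qe - qs
        matches += sum(
            1 for x, y in zip(aln.query[rs:re_], aln.target[qs:qe]) if x == y
        )
    if columns == 0:
        return 0.0
    return matches / columns


def resolve_copies(
    copies: list[GeneCopy],
    reference: str | None = None,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[GeneCopy | None, str]:
    """Pick at most one copy for a sample-by-gene cell.

    Returns (copy or None, decision code).  Codes: ``single``,
    ``depth_ratio`` (the deepest copy satisfied the coverage-ratio
    condition), ``best_similarity`` (default-mode fallback), and
    ``dropped_multicopy`` (strict mode, condition failed).
    """
    if not copies:
        raise ValueError("no copies given")
    if len(copies) == 1:
        return copies[0], "single"
    by_depth = sorted(
        copies, key=lambda c: (-c.mean_coverage, c.copy_id)
    )
    c1, c2 = by_depth[0], by_depth[1]
    if c1.mean_coverage >= cfg.r_min * c2.mean_coverage:
        return c1, "depth_ratio"
    if cfg.mode == "strict":
        return None, "dropped_multicopy"
    # default mode: fall back to reference similarity
    for c in copies:
        if c.reference_similarity is None:
            if reference is None:
                raise ValidationError(
                    f"{c.sample_id}/{c.gene_id}: reference needed for similarity fallback"
                )
            c.reference_similarity = reference_similarity(c.sequence, reference)
    best = sorted(
        copies,
        key=lambda c: (-c.reference_similarity, -c.mean_coverage, c.copy_id),
    )[0]
    return best, "best_similarity"


def resolve_table(
    copies: list[GeneCopy],
    references: Mapping[str, str] | None = None,
    cfg: FilterConfig = FilterConfig(),
) -> dict[tuple[str, str], tuple[GeneCopy | None, str]]:
    """Resolve every sample-by-gene cell of a copy table."""
    cells: dict[tuple[str, str], list[GeneCopy]] = {}
    for c in copies:
        cells.setdefault((c.sample_id, c.gene_id), []).append(c)
    out = {}
    for key, cell in cells.items():
        ref = references.get(key[1]) if references else None
        out[key] = resolve_copies(cell, ref, cfg)
    return out


@dataclass
class CompletenessMatrix:
    """Samples x genes completeness fractions (capped at 1; raw kept)."""

    samples: list[str]
    genes: list[str]
    values: np.ndarray  # capped at 1.0
    raw: np.ndarray     # uncapped ratios

    def write_csv(self, path: str | Path) -> None:
        """CSV export of the raw (uncapped) ratios, 4 decimals."""
        import csv

        if not self.samples or not self.genes:
            raise ValidationError("refusing to write an empty matrix")
        with Path(path).open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sample"] + self.genes)
            for s, row in zip(self.samples, self.raw):
                w.writerow([s] + [f"{v:.4f}" for v in row])

    def heatmap(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4, 0.25 * len(self.genes)), max(3, 0.3 * len(self.samples)))
        )
        im = ax.imshow(self.values, aspect="auto", cmap="viridis", vmin=0, vmax=1)
        ax.set_xticks(range(len(self.genes)), self.genes, rotation=90, fontsize=6)
        ax.set_yticks(range(len(self.samples)), self.samples, fontsize=6)
        fig.colorbar(im, ax=ax, label="completeness")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def completeness_matrix(
    resolved: Mapping[tuple[str, str], tuple[GeneCopy | None, str]],
    references: Mapping[str, str],
) -> CompletenessMatrix:
    """Fraction of each reference length recovered, per sample x gene.

    Absent or dropped cells are 0.  The matrix value is capped at 1; the raw
    ratio (which can exceed 1 for extractions longer than the reference) is
    kept alongside for the CSV export.
    """
    samples = sorted({s for s, _ in resolved})
    genes = sorted({g for _, g in resolved} | set(references))
    for g in genes:
        if g not in references:
            raise ValidationError(f"no reference for gene {g!r}")
        if len(references[g].replace("-", "")) == 0:
            raise ValidationError(f"reference for gene {g!r} has zero length")
    raw = np.zeros((len(samples), len(genes)))
    for (s, g), (copy, _code) in resolved.items():
        if copy is None:
            continue
        ref_len = len(references[g].replace("-", ""))
        extracted = len(copy.sequence.replace("-", ""))
        raw[samples.index(s), genes.index(g)] = extracted / ref_len
    return CompletenessMatrix(samples, genes, np.minimum(raw, 1.0), raw)


def filter_report(
    copies: list[GeneCopy],
    cfg: FilterConfig = FilterConfig(),
    references: Mapping[str, str] | None = None,
) -> dict[str, dict]:
    """Per-sample multiple-copy statistics and filter decisions.

    Reports, per sample: the fraction of its genes recovered in multiple
    copies, the mean copy number among those genes, and counts per decision
    code.
    """
    cells: dict[tuple[str, str], list[GeneCopy]] = {}
    for c in copies:
        cells.setdefault((c.sample_id, c.gene_id), []).append(c)
    samples = sorted({s for s, _ in cells})
    out: dict[str, dict] = {}
    for s in samples:
        genes = {g: cell for (ss, g), cell in cells.items() if ss == s}
        n_genes = len(genes)
        multi = {g: cell for g, cell in genes.items() if len(cell) > 1}
        codes: dict[str, int] = {}
        for g, cell in genes.items():
            ref = references.get(g) if references else None
            _, code = resolve_copies(cell, ref, cfg)
            codes[code] = codes.get(code, 0) + 1
        out[s] = {
            "n_genes": n_genes,
            "multicopy_fraction": len(multi) / n_genes if n_genes else 0.0,
            "mean_copies_multicopy": (
                float(np.mean([len(c) for c in multi.values()])) if multi else 0.0
            ),
            "decision_counts": codes,
        }
    if not samples:
        out["_warning"] = {"message": "no copies in table"}
    return out


# ---------------------------------------------------------------------------
# Input parsing
# ---------------------------------------------------------------------------

def read_copies_fasta(path: str | Path) -> list[GeneCopy]:
    """Copies FASTA with structured headers ``sample|gene|copy|cov=<float>``."""
    out = []
    for header, seq in read_fasta(path).items():
        parts = header.split("|")
        if len(parts) != 4 or not parts[3].startswith("cov="):
            raise ValidationError(
                f"header {header!r} is not sample|gene|copy|cov=<float>"
            )
        out.append(
            GeneCopy(parts[0], parts[1], parts[2], seq, float(parts[3][4:]))
        )
    return out


def read_copies_tsv(path: str | Path) -> list[GeneCopy]:
    """TSV with columns sample_id, gene_id, copy_id, mean_coverage, sequence."""
    out = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        want = ["sample_id", "gene_id", "copy_id", "mean_coverage", "sequence"]
        if header != want:
            raise ValidationError(f"expected columns {want}, got {header}")
        for line in fh:
            if not line.strip():
                continue
            s, g, c, cov, seq = line.rstrip("\n").split("\t")
            out.append(GeneCopy(s, g, c, seq, float(cov)))
    return out


def write_decisions_tsv(
    resolved: Mapping[tuple[str, str], tuple[GeneCopy | None, str]],
    path: str | Path,
) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tgene_id\tretained_copy\tdecision\n")
        for (s, g), (copy, code) in sorted(resolved.items()):
            fh.write(f"{s}\t{g}\t{copy.copy_id if copy else ''}\t{code}\n")
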