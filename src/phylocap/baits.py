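"""Tiled hybridization-bait design with QC filters.

Representative (medoid) sequences are gap-stripped, short runs of Ns are
rewritten to Ts, and 80 bp windows are emitted in a 2x tiling (step 40 bp,
plus one flush window at the 3' end when needed).  Each bait is then
annotated and flagged:

* ``LOW_GC`` / ``HIGH_GC`` — GC percent outside the open interval
  (gc_low, gc_high); the bounds themselves fail (default 25 < GC < 67).
* ``REPEAT`` / ``REGION_REPEAT`` — soft-masked (lowercase) fraction above
  ``repeat_max`` percent in the bait window, or in the window extended by
  ``region_flank`` bases each side.
* ``MULTI_HIT`` — two or more distinct loci found across the screening
  genomes by an internal seed-and-extend search (both strands).
* ``RESIDUAL_N`` — any N left after run rewriting (runs longer than
  ``n_run_max`` are not rewritten and are discarded here).

A bait passes iff no flag is set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = [
    "BaitConfig",
    "Bait",
    "BaitSet",
    "rewrite_n_runs",
    "tile",
    "qc_bait",
    "count_hits",
    "design_bait_set",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


@dataclass(frozen=True)
class BaitConfig:
    bait_len: int = 80
    tiling: int = 2
    gc_low: float = 25.0       # percent, exclusive lower bound for retention
    gc_high: float = 67.0      # percent, exclusive upper bound
    repeat_max: float = 35.0   # percent, exclusive upper bound
    n_run_max: int = 10
    region_flank: int = 80
    seed_len: int = 16
    hit_min_len: int = 60
    hit_min_ident: float = 0.90

    def __post_init__(self) -> None:
        if self.bait_len % self.tiling != 0:
            raise ValueError("bait_len must be divisible by tiling")
        if not (0 <= self.gc_low < self.gc_high <= 100):
            raise ValueError("require 0 <= gc_low < gc_high <= 100")

    @property
    def step(self) -> int:
        return self.bait_len // self.tiling


@dataclass
class Bait:
    """One tiled window with QC annotations; coordinates are 0-based
    half-open on the gap-stripped source."""

    source_id: str
    start: int
    end: int
    sequence: str
    gc_pct: float = 0.0
    repeat_pct: float = 0.0
    region_repeat_pct: float = 0.0
    hit_count: int = 0
    flags: set[str] = field(default_factory=set)
    passed: bool = True

    @property
    def bait_id(self) -> str:
        return f"{self.source_id}_{self.start}_{self.end}"


def rewrite_n_runs(sequence: str, n_run_max: int = 10) -> str:
    """Replace every maximal run of N/n of length 1..n_run_max with Ts;
    longer runs are left unchanged."""

    def repl(m: re.Match) -> str:
        run = m.group(0)
        return "T" * len(run) if len(run) <= n_run_max else run

    return re.sub(r"[Nn]+", repl, sequence)


def tile(source: str, cfg: BaitConfig, source_id: str = "") -> list[Bait]:
    """Emit tiled windows over a (gap-stripped) source sequence.

    Windows start at 0 with step ``bait_len / tiling``; if the last regular
    window stops short of the end, one flush window [L - bait_len, L) is
    appended.  Sources shorter than ``bait_len`` yield no windows.
    """
    L = len(source)
    if L < cfg.bait_len:
        return []
    starts = list(range(0, L - cfg.bait_len + 1, cfg.step))
    if starts[-1] + cfg.bait_len < L:
        starts.append(L - cfg.bait_len)
    return [
        Bait(source_id, s, s + cfg.bait_len, source[s : s + cfg.bait_len].upper())
        for s in starts
    ]


# ---------------------------------------------------------------------------
# Hit screening (seed-and-extend)
# ---------------------------------------------------------------------------

def _diagonal_hit(bait: str, genome: str, diag: int, cfg: BaitConfig) -> tuple[int, int] | None:
    """Best qualifying ungapped hit interval on one alignment diagonal.

    ``diag`` is the genome position aligned with bait position 0.  Returns
    the genome-coordinate interval of the longest contiguous stretch with
    identity >= hit_min_ident and length >= hit_min_len, or None.
    """
    b0 = max(0, -diag)
    b1 = min(len(bait), len(genome) - diag)
    if b1 - b0 < cfg.hit_min_len:
        return None
    window = genome[diag + b0 : diag + b1].upper()
    bw = bait[b0:b1].upper()
    match = [1 if x == y else 0 for x, y in zip(bw, window)]
    csum = [0]
    for m in match:
        csum.append(csum[-1] + m)
    n = len(match)
    best = None
    for length in range(n, cfg.hit_min_len - 1, -1):
        for s in range(0, n - length + 1):
            if csum[s + length] - csum[s] >= cfg.hit_min_ident * length:
                best = (diag + b0 + s, diag + b0 + s + length)
                break
        if best:
            break
    return best


def _strand_loci(bait: str, genome: str, cfg: BaitConfig) -> list[tuple[int, int]]:
    k = cfg.seed_len
    gu = genome.upper()
    bu = bait.upper()
    index: dict[str, list[int]] = {}
    for p in range(len(gu) - k + 1):
        index.setdefault(gu[p : p + k], []).append(p)
    diags: set[int] = set()
    for q in range(len(bu) - k + 1):
        for p in index.get(bu[q : q + k], ()):
            diags.add(p - q)
    loci = []
    for diag in sorted(diags):
        hit = _diagonal_hit(bu, gu, diag, cfg)
        if hit:
            loci.append(hit)
    # merge loci overlapping by more than one tiling step
    loci.sort()
    merged: list[list[int]] = []
    for s, e in loci:
        if merged and merged[-1][1] - s > cfg.step:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def count_hits(bait_seq: str, genomes: Mapping[str, str], cfg: BaitConfig) -> int:
    """Count distinct loci matching a bait across genomes, both strands."""
    total = 0
    for seq in genomes.values():
        total += len(_strand_loci(bait_seq, seq, cfg))
        total += len(_strand_loci(bait_seq, seq.translate(_COMPLEMENT)[::-1], cfg))
    return total


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def _lower_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return sum(1 for c in seq if c.islower()) / len(seq)


def qc_bait(
    bait: Bait,
    masked_source: str,
    genomes: Mapping[str, str],
    cfg: BaitConfig,
) -> Bait:
    """Annotate a bait with GC, repeat content and hit count, and set flags.

    ``masked_source`` is the gap-stripped source with soft-masking case
    preserved (the carrier of repeat annotation); ``bait.sequence`` is the
    N-rewritten uppercase window.
    """
    seq = bait.sequence
    bait.gc_pct = 100.0 * sum(1 for c in seq if c in "GC") / cfg.bait_len
    bait.repeat_pct = 100.0 * _lower_fraction(masked_source[bait.start : bait.end])
    r0 = max(0, bait.start - cfg.region_flank)
    r1 = min(len(masked_source), bait.end + cfg.region_flank)
    bait.region_repeat_pct = 100.0 * _lower_fraction(masked_source[r0:r1])
    bait.hit_count = count_hits(seq, genomes, cfg) if genomes else 0
    flags = set()
    if bait.gc_pct <= cfg.gc_low:
        flags.add("LOW_GC")
    if bait.gc_pct >= cfg.gc_high:
        flags.add("HIGH_GC")
    if bait.repeat_pct > cfg.repeat_max:
        flags.add("REPEAT")
    if bait.region_repeat_pct > cfg.repeat_max:
        flags.add("REGION_REPEAT")
    if bait.hit_count >= 2:
        flags.add("MULTI_HIT")
    if "N" in seq:
        flags.add("RESIDUAL_N")
    bait.flags = flags
    bait.passed = not flags
    return bait


# ---------------------------------------------------------------------------
# Whole-set design
# ---------------------------------------------------------------------------

@dataclass
class BaitSet:
    """Passing baits plus the full annotated list and a per-source report."""

    baits: list[Bait]                 # passing only
    all_baits: list[Bait]
    report: dict[str, dict]
    warnings: list[str] = field(default_factory=list)

    def write_fasta(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for b in self.baits:
                fh.write(f">{b.bait_id}\n{b.sequence}\n")

    def write_qc_tsv(self, path: str | Path) -> None:
        cols = ["bait_id", "source_id", "start", "end", "gc_pct", "repeat_pct",
                "region_repeat_pct", "hit_count", "flags", "passed"]
        with Path(path).open("w") as fh:
            fh.write("\t".join(cols) + "\n")
            for b in self.all_baits:
                fh.write(
                    f"{b.bait_id}\t{b.source_id}\t{b.start}\t{b.end}\t"
                    f"{b.gc_pct:.2f}\t{b.repeat_pct:.2f}\t{b.region_repeat_pct:.2f}\t"
                    f"{b.hit_count}\t{','.join(sorted(b.flags))}\t"
                    f"{str(b.passed).lower()}\n"
                )


def design_bait_set(
    representatives: Mapping[str, str],
    genomes: Mapping[str, str],
    cfg: BaitConfig = BaitConfig(),
) -> BaitSet:
    """Design and QC a bait set from representative sequences.

    Per representative: strip gaps, rewrite N runs, tile, QC each window.
    Soft-masking (lowercase) in the input is honored for repeat annotation.
    """
    if not representatives:
        raise ValueError("no representative sequences")
    warnings: list[str] = []
    if not genomes:
        warnings.append("no screening genomes supplied; multi-hit screening skipped")
    all_baits: list[Bait] = []
    report: dict[str, dict] = {}
    for source_id, raw in representatives.items():
        masked = raw.replace("-", "")
        rewritten = rewrite_n_runs(masked, cfg.n_run_max)
        entry = {"n_baits": 0, "n_passed": 0, "too_short": False, "flag_counts": {}}
        baits = tile(rewritten, cfg, source_id)
        if not baits:
            entry["too_short"] = True
            report[source_id] = entry
            continue
        for b in baits:
            qc_bait(b, masked, genomes, cfg)
            for f in b.flags:
                entry["flag_counts"][f] = entry["flag_counts"].get(f, 0) + 1
        entry["n_baits"] = len(baits)
        entry["n_passed"] = sum(1 for b in baits if b.passed)
        report[source_id] = entry
        all_baits.extend(baits)
    passing = [b for b in all_baits if b.passed]
    return BaitSet(passing, all_baits, report, warnings)
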