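import numpy as np
import pytest

from phylocap.io import GeneAlignment, GeneAlignmentSet


def make_alignment(gene_id, rows):
    """Build a GeneAlignment from {sample: sequence}."""
    return GeneAlignment(gene_id, dict(rows))


@pytest.fixture
def small_alignment():
    return make_alignment(
        "g1",
        {
            "s1": "ACGTACGTAC",
            "s2": "ACGTACGTAA",
            "s3": "ACGTTCGTAC",
            "s4": "AGGTACGTAC",
        },
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_alignment(n_rows, length, rng, gene_id="g"):
    bases = np.array(list("ACGT"))
    rows = {
        f"s{i:02d}": "".join(bases[rng.integers(0, 4, size=length)])
        for i in range(n_rows)
    }
    return GeneAlignment(gene_id, rows)


def planted_cluster_alignment(cluster_sizes, length, within, between, rng, gene_id="g"):
    """Alignment whose rows form clusters: members of a cluster differ from
    the cluster center in ~within*length sites; centers differ from each
    other in ~between*length sites (disjoint site blocks guarantee exact
    separations are respected approximately)."""
    bases = "ACGT"
    center = rng.integers(0, 4, size=length)
    rows = {}
    idx = 0
    for ci, size in enumerate(cluster_sizes):
        c_center = center.copy()
        # displace each cluster center in its own disjoint block of sites
        block = slice(ci * int(between * length), (ci + 1) * int(between * length))
        c_center[block] = (c_center[block] + 1) % 4
        for m in range(size):
            seq = c_center.copy()
            n_mut = int(within * length)
            if n_mut:
                sites = rng.choice(length, size=n_mut, replace=False)
                seq[sites] = (seq[sites] + rng.integers(1, 4, size=n_mut)) % 4
            rows[f"c{ci}_m{m}_{idx:02d}"] = "".join(bases[b] for b in seq)
            idx += 1
    return GeneAlignment(gene_id, rows)
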