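import numpy as np
import pandas as pd
import pytest

from pivarkit.genomic_io import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_alignments(rows):
    """rows: (read_id, sample_id, chrom, start, end, strand, n_hits)."""
    return pd.DataFrame(
        rows, columns=["read_id", "sample_id", "chrom", "start", "end", "strand", "n_hits"]
    )


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=500):
    out = []
    for i in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(
            GenomicInterval(
                str(rng.choice(chroms)), start, start + length, f"iv{i}",
                str(rng.choice(["+", "-"])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)


def brute_force_overlap(a, b, max_gap=0):
    """O(n*m) pairwise scan; the oracle for interval_overlap."""
    pairs = []
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if x.chrom != y.chrom:
                continue
            gap = max(0, max(x.start, y.start) - min(x.end, y.end))
            if gap <= max_gap:
                ov = max(0, min(x.end, y.end) - max(x.start, y.start))
                pairs.append((i, j, ov, gap))
    return pairs


def brute_force_bh(pvals):
    """Direct step-up definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for rank, i in enumerate(order, start=1):
        q[i] = min(min(p[order[j - 1]] * m / j for j in range(rank, m + 1)), 1.0)
    return q


def fisher_enumeration_p(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c1 - a) / denom
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = comb(r1, x) * comb(r2, c1 - x) / denom
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


def wilcoxon_enumeration_p(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    from itertools import combinations

    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    mean = ranks.sum() * n1 / len(pooled)
    dev = abs(obs - mean)
    hits = total = 0
    for comb_idx in combinations(range(len(pooled)), n1):
        s = ranks[list(comb_idx)].sum()
        total += 1
        if abs(s - mean) >= dev - 1e-9:
            hits += 1
    return hits / total


def kinship_recursive(ped_rows):
    """Exact additive relationships by recursive path counting.

    ped_rows: list of (id, sire, dam) sorted parents-first.
    Returns dict (i, j) -> A value.  Independent of the tabular method.
    """
    parents = {r[0]: (r[1], r[2]) for r in ped_rows}
    order = {r[0]: k for k, r in enumerate(ped_rows)}
    memo = {}

    def phi(i, j):
        # kinship coefficient
        if i is None or j is None:
            return 0.0
        key = (i, j) if order[i] <= order[j] else (j, i)
        if key in memo:
            return memo[key]
        a, b = key
        if a == b:
            s, d = parents[a]
            val = 0.5 * (1.0 + phi(s, d))
        else:
            # b is the later individual
            s, d = parents[b]
            val = 0.5 * (phi(a, s) + phi(a, d))
        memo[key] = val
        return val

    ids = [r[0] for r in ped_rows]
    return {(i, j): 2.0 * phi(i, j) for i in ids for j in ids}


def gene_drop_A(ped_rows, n_drops=100_000, seed=0):
    """Monte-Carlo additive relationships by allele dropping (vectorized)."""
    rng = np.random.default_rng(seed)
    ids = [r[0] for r in ped_rows]
    pos = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    alleles = np.zeros((n_drops, n, 2), dtype=np.int32)
    next_allele = 0
    for k, (ind, sire, dam) in enumerate(ped_rows):
        for slot, parent in enumerate((sire, dam)):
            if parent is None:
                alleles[:, k, slot] = next_allele
                next_allele += 1
            else:
                pick = rng.integers(0, 2, size=n_drops)
                alleles[:, k, slot] = alleles[np.arange(n_drops), pos[parent], pick]
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            # kinship = P(random allele of i IBD to random allele of j)
            eq = np.zeros(n_drops)
            for s in range(2):
                for t in range(2):
                    eq += alleles[:, i, s] == alleles[:, j, t]
            A[i, j] = A[j, i] = (eq / 4.0).mean() * 2.0
    return ids, A
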