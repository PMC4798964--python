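"""Independent brute-force oracles used to cross-check package operations.

These deliberately use naive algorithms (all-pairs scans, per-basepair masks,
explicit enumeration) so they share no code path with the implementations they
verify.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

from epiconcord.genomic import GenomicInterval, RegionSet


def random_regionset(
    rng: np.random.Generator, n: int, chroms=("chr1", "chr2"), max_pos=10_000,
    max_len=300, label=None,
) -> RegionSet:
    ivs = []
    for _ in range(n):
        c = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(0, max_pos))
        L = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(c, s, s + L))
    return RegionSet(ivs, label=label)


def brute_intersect_fraction(a: RegionSet, b: RegionSet, min_bp: int = 1) -> float:
    """O(n*m) all-pairs overlap with per-bp accumulation against union of b."""
    n_hit = 0
    for iv in a:
        covered = set()
        for jv in b:
            if jv.chrom != iv.chrom:
                continue
            lo, hi = max(iv.start, jv.start), min(iv.end, jv.end)
            covered.update(range(lo, hi))
        if len(covered) >= min_bp:
            n_hit += 1
    return n_hit / len(a) if len(a) else 0.0


def brute_jaccard(a: RegionSet, b: RegionSet, genome_len: int = 20_000) -> float:
    """Per-basepair boolean mask Jaccard."""
    chroms = sorted(a.chroms | b.chroms)
    inter = union = 0
    for c in chroms:
        ma = np.zeros(genome_len, dtype=bool)
        mb = np.zeros(genome_len, dtype=bool)
        for iv in a:
            if iv.chrom == c:
                ma[iv.start: iv.end] = True
        for iv in b:
            if iv.chrom == c:
                mb[iv.start: iv.end] = True
        inter += int((ma & mb).sum())
        union += int((ma | mb).sum())
    return inter / union if union else 0.0


def brute_auroc(scores, labels) -> float:
    """All-pairs positive-vs-negative comparison, ties counting one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_fisher_two_sided(table) -> float:
    """Two-sided Fisher p by hypergeometric enumeration (min-likelihood rule)."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    rv = stats.hypergeom(n, col1, row1)
    k_min = max(0, row1 + col1 - n)
    k_max = min(row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(k_min, k_max + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(1.0, total)


def brute_binom_two_sided(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p by pmf enumeration (min-likelihood rule)."""
    pmf = stats.binom.pmf(np.arange(n + 1), n, p)
    return float(min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-7)].sum()))


def brute_gapped_score(seq: str, weight_of, l: int, k: int, revcomp: bool) -> float:
    """Score a sequence by explicit window/pattern enumeration.

    ``weight_of`` maps a canonical (positions, bases) pattern to a weight.
    Canonicalization here re-derives the reverse complement from scratch.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def rc_pattern(positions, bases):
        pairs = sorted(
            (l - 1 - p, comp[b]) for p, b in zip(positions, bases)
        )
        return tuple(p for p, _ in pairs), tuple(b for _, b in pairs)

    total = 0.0
    for i in range(len(seq) - l + 1):
        win = seq[i: i + l]
        if "N" in win:
            continue
        for positions in combinations(range(l), k):
            pat = (positions, tuple(win[p] for p in positions))
            if revcomp:
                pat = min(pat, rc_pattern(*pat))
            total += weight_of(pat)
    return total


def pattern_to_feature_id(positions, bases, l: int, k: int) -> int:
    """Map a (positions, bases) pattern to the package's integer feature id,
    re-deriving the id formula independently."""
    combs = list(combinations(range(l), k))
    comb_idx = combs.index(tuple(positions))
    code = 0
    for b in bases:
        code = code * 4 + "ACGT".index(b)
    return comb_idx * (4 ** k) + code
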