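"""Methylome segmentation into hypo-methylated regions (UMR/LMR) and DMVs.

Candidate segments are maximal runs of CpGs whose running-mean-smoothed
methylation level falls below a cutoff; a minimum-CpG threshold is then chosen
so that, in coordinate-shuffled null methylomes, the surviving segment count
stays below the target false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genomic import GenomicInterval, RegionSet, overlap_flags
from .methylome import Methylome

__all__ = [
    "SegmentationParams",
    "HypoSegment",
    "DmvParams",
    "segment_hypomethylated",
    "filter_max_length",
    "call_dmv",
    "merge_dmv_union",
    "classify_dmv_chromatin",
    "segments_to_regionset",
    "write_segments_bed",
]


@dataclass
class SegmentationParams:
    m_cutoff: float = 0.5
    seg_fdr: float = 0.05
    smooth_k: int = 3
    umr_min_cpgs: int = 30
    n_null: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.m_cutoff < 1:
            raise ValueError("m_cutoff must be in (0, 1)")
        if not 0 < self.seg_fdr < 1:
            raise ValueError("seg_fdr must be in (0, 1)")
        if self.umr_min_cpgs < 2:
            raise ValueError("umr_min_cpgs must be >= 2")
        if self.smooth_k < 1:
            raise ValueError("smooth_k must be >= 1")


@dataclass(frozen=True)
class HypoSegment:
    interval: GenomicInterval
    n_cpg: int
    mean_meth: float
    klass: str  # "UMR" or "LMR"

    def __len__(self) -> int:
        return len(self.interval)


@dataclass
class DmvParams:
    min_len: int = 5000
    max_mean_meth: float = 0.15

    def __post_init__(self) -> None:
        if self.min_len <= 0:
            raise ValueError("min_len must be positive")
        if not 0 < self.max_mean_meth < 1:
            raise ValueError("max_mean_meth must be in (0, 1)")


def _smoothed_levels(levels: np.ndarray, k: int) -> np.ndarray:
    """Centered running mean over up to k consecutive sites, truncated at the
    chromosome ends (window [i - k//2, i + (k-1)//2])."""
    n = len(levels)
    half_lo = k // 2
    half_hi = (k - 1) // 2
    cs = np.concatenate([[0.0], np.cumsum(levels)])
    lo = np.clip(np.arange(n) - half_lo, 0, n)
    hi = np.clip(np.arange(n) + half_hi + 1, 0, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def _candidate_runs(
    pos: np.ndarray, mc: np.ndarray, cov: np.ndarray, cutoff: float, smooth_k: int
) -> list[tuple[int, int]]:
    """Index ranges [i, j) of maximal runs with smoothed level < cutoff."""
    with np.errstate(invalid="ignore", divide="ignore"):
        levels = mc / cov
    sm = _smoothed_levels(levels, smooth_k)
    below = sm < cutoff
    if not below.any():
        return []
    d = np.diff(below.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(len(below))
    return list(zip(starts, ends))


def _run_sizes(m_arrays, cutoff: float, smooth_k: int) -> np.ndarray:
    sizes = []
    for pos, mc, cov in m_arrays:
        for i, j in _candidate_runs(pos, mc, cov, cutoff, smooth_k):
            sizes.append(j - i)
    return np.asarray(sizes, dtype=np.int64)


def _fdr_min_cpgs(
    obs_sizes: np.ndarray,
    null_sizes: list[np.ndarray],
    seg_fdr: float,
) -> int:
    """Smallest CpG-count threshold n such that the mean null segment count at
    >= n is <= seg_fdr times the observed count at >= n."""
    if len(obs_sizes) == 0:
        return 1
    n_max = int(obs_sizes.max())
    for n in range(1, n_max + 1):
        obs = int((obs_sizes >= n).sum())
        if obs == 0:
            break
        null_mean = float(np.mean([(ns >= n).sum() for ns in null_sizes]))
        if null_mean <= seg_fdr * obs:
            return n
    return n_max + 1


def segment_hypomethylated(
    m: Methylome, p: SegmentationParams
) -> list[HypoSegment]:
    """Call UMR/LMR segments on the CG sites of one methylome.

    Returns disjoint, sorted segments whose pooled methylation is below
    ``p.m_cutoff``; segments with >= ``p.umr_min_cpgs`` covered CpGs are UMRs,
    the rest LMRs. The minimum segment size (in CpGs) is calibrated against
    ``p.n_null`` within-chromosome coordinate shuffles of the site values.
    """
    chrom_arrays: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []
    n_sites = 0
    for chrom in m.chroms:
        df = m.subset(chrom=chrom, context="CG")
        df = df[df["cov"] > 0]
        if len(df) == 0:
            continue
        chrom_arrays.append(
            (
                chrom,
                df["pos"].to_numpy(np.int64),
                df["mc"].to_numpy(np.int64),
                df["cov"].to_numpy(np.int64),
            )
        )
        n_sites += len(df)
    if n_sites < p.smooth_k:
        raise ValueError(
            f"methylome has {n_sites} covered CpGs, fewer than smooth_k={p.smooth_k}"
        )

    obs_sizes = _run_sizes(
        [(pos, mc, cov) for _, pos, mc, cov in chrom_arrays], p.m_cutoff, p.smooth_k
    )
    rng = np.random.default_rng(p.seed)
    null_sizes = []
    for _ in range(p.n_null):
        shuffled = []
        for _, pos, mc, cov in chrom_arrays:
            perm = rng.permutation(len(pos))
            shuffled.append((pos, mc[perm], cov[perm]))
        null_sizes.append(_run_sizes(shuffled, p.m_cutoff, p.smooth_k))
    min_cpgs = _fdr_min_cpgs(obs_sizes, null_sizes, p.seg_fdr)

    segments: list[HypoSegment] = []
    for chrom, pos, mc, cov in chrom_arrays:
        for i, j in _candidate_runs(pos, mc, cov, p.m_cutoff, p.smooth_k):
            n_cpg = j - i
            if n_cpg < min_cpgs:
                continue
            mean_meth = float(mc[i:j].sum() / cov[i:j].sum())
            if mean_meth >= p.m_cutoff:
                continue
            iv = GenomicInterval(chrom, int(pos[i]) - 1, int(pos[j - 1]))
            klass = "UMR" if n_cpg >= p.umr_min_cpgs else "LMR"
            segments.append(HypoSegment(iv, n_cpg, mean_meth, klass))
    return segments


def filter_max_length(
    segments: list[HypoSegment], max_len: int = 5000
) -> list[HypoSegment]:
    """Keep only segments shorter than ``max_len`` bp (the short-segment
    post-filter used for overlap analyses)."""
    return [s for s in segments if len(s) < max_len]


def call_dmv(segments: list[HypoSegment], p: DmvParams | None = None) -> RegionSet:
    """DMVs = UMR segments with length >= min_len and mean_meth <= max_mean_meth."""
    p = p or DmvParams()
    ivs = [
        GenomicInterval(
            s.interval.chrom, s.interval.start, s.interval.end,
            name="DMV", score=round(s.mean_meth * 1000, 3),
        )
        for s in segments
        if s.klass == "UMR" and len(s) >= p.min_len and s.mean_meth <= p.max_mean_meth
    ]
    return RegionSet(ivs, label="DMV")


def merge_dmv_union(dmv_sets: list[RegionSet]) -> RegionSet:
    """Union of DMV calls across samples, with overlapping or adjacent
    intervals merged."""
    if not dmv_sets:
        raise ValueError("need at least one DMV set")
    all_ivs = [iv for rs in dmv_sets for iv in rs]
    return RegionSet(all_ivs, label="DMV_union").merged(book_ended=True)


def classify_dmv_chromatin(
    dmvs: RegionSet, k27me3: RegionSet, k4me3: RegionSet
) -> list[str]:
    """Per-DMV chromatin class from >=1 bp peak overlap:
    polycomb (K27me3 only), active (K4me3 only), both, or neither."""
    has27 = (
        overlap_flags(dmvs, k27me3) if len(k27me3) else np.zeros(len(dmvs), dtype=bool)
    )
    has4 = (
        overlap_flags(dmvs, k4me3) if len(k4me3) else np.zeros(len(dmvs), dtype=bool)
    )
    out = []
    for a, b in zip(has27, has4):
        if a and b:
            out.append("both")
        elif a:
            out.append("polycomb")
        elif b:
            out.append("active")
        else:
            out.append("neither")
    return out


def segments_to_regionset(
    segments: list[HypoSegment], klass: str | None = None, label: str | None = None
) -> RegionSet:
    ivs = [
        GenomicInterval(
            s.interval.chrom, s.interval.start, s.interval.end,
            name=s.klass, score=round(s.mean_meth * 1000, 3),
        )
        for s in segments
        if klass is None or s.klass == klass
    ]
    return RegionSet(ivs, label=label or klass)


def write_segments_bed(segments: list[HypoSegment], path: str | Path) -> None:
    """BED6 with class in the name field and mean_meth x1000 in the score field."""
    rs = segments_to_regionset(segments)
    with open(path, "w") as fh:
        for iv in rs:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t.\n"
            )
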