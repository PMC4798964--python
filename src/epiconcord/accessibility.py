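"""Accessibility-side operations: fragment filtering, consensus peak building,
and differential peak classification with fold-change and FDR thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic import GenomicInterval, RegionSet, overlap_flags

__all__ = [
    "FragmentRecord",
    "AccessibilityParams",
    "PeakCounts",
    "filter_short_fragments",
    "consensus_peaks",
    "count_fragments_in_peaks",
    "differential_peaks",
    "read_fragments_bed",
    "write_fragments_bed",
    "fragments_to_intervals",
]


@dataclass(frozen=True)
class FragmentRecord:
    chrom: str
    start: int
    end: int
    sample: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("fragment end must be > start")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AccessibilityParams:
    frag_max_len: int = 100  # exclusive cap: keep fragments strictly shorter
    fpkm_floor: float = 0.1
    fold_thresh: float = 2.0
    peak_fdr: float = 0.01
    min_overlap_samples: int = 2

    def __post_init__(self) -> None:
        if min(self.frag_max_len, self.fpkm_floor, self.peak_fdr) <= 0:
            raise ValueError("parameters must be positive")
        if self.fold_thresh <= 1:
            raise ValueError("fold_thresh must be > 1")


@dataclass
class PeakCounts:
    """Raw fragment counts over consensus peaks, one column per sample."""

    peaks: RegionSet
    counts: pd.DataFrame  # rows align with peaks order, columns = sample names
    library_sizes: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.peaks):
            raise ValueError("counts rows must align with peaks")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def normalized(self) -> pd.DataFrame:
        """Counts scaled to the mean library size."""
        libs = np.array([self.library_sizes[c] for c in self.counts.columns], float)
        return self.counts * (libs.mean() / libs)

    def log2_normalized(self, pseudo: float = 1.0) -> pd.DataFrame:
        return np.log2(self.normalized() + pseudo)


def filter_short_fragments(
    frags: Iterable[FragmentRecord], p: AccessibilityParams | None = None
) -> list[FragmentRecord]:
    """Keep fragments with length strictly less than ``frag_max_len`` bp."""
    p = p or AccessibilityParams()
    return [f for f in frags if len(f) < p.frag_max_len]


def consensus_peaks(
    peak_sets: dict, p: AccessibilityParams | None = None
) -> RegionSet:
    """Merge all input peaks; keep merged intervals supported by overlapping
    peaks from >= ``min_overlap_samples`` distinct input sets."""
    p = p or AccessibilityParams()
    if len(peak_sets) < 2:
        raise ValueError("need at least two peak sets")
    union = RegionSet([iv for rs in peak_sets.values() for iv in rs]).merged()
    support = np.zeros(len(union), dtype=int)
    for rs in peak_sets.values():
        support += overlap_flags(union, rs).astype(int) if len(rs) else 0
    kept = [iv for iv, s in zip(union, support) if s >= p.min_overlap_samples]
    return RegionSet(kept, label="consensus")


def fragments_to_intervals(frags: Iterable[FragmentRecord]) -> list[GenomicInterval]:
    return [GenomicInterval(f.chrom, f.start, f.end) for f in frags]


def count_fragments_in_peaks(
    peaks: RegionSet,
    fragments_by_sample: dict[str, Sequence[FragmentRecord]],
    library_sizes: dict[str, int] | None = None,
) -> PeakCounts:
    """Tabulate per-sample fragment counts (>=1 bp overlap) over peaks."""
    cols = {}
    libs = {}
    for sample, frags in fragments_by_sample.items():
        starts: dict[str, list[int]] = {}
        ends: dict[str, list[int]] = {}
        for f in frags:
            starts.setdefault(f.chrom, []).append(f.start)
            ends.setdefault(f.chrom, []).append(f.end)
        s_sorted = {c: np.sort(np.asarray(v)) for c, v in starts.items()}
        e_sorted = {c: np.sort(np.asarray(v)) for c, v in ends.items()}
        vals = np.zeros(len(peaks), dtype=np.int64)
        for i, iv in enumerate(peaks):
            if iv.chrom not in s_sorted:
                continue
            vals[i] = int(
                np.searchsorted(s_sorted[iv.chrom], iv.end, side="left")
                - np.searchsorted(e_sorted[iv.chrom], iv.start, side="right")
            )
        cols[sample] = vals
        libs[sample] = len(frags)
    if library_sizes is not None:
        libs = dict(library_sizes)
    return PeakCounts(
        peaks=peaks, counts=pd.DataFrame(cols), library_sizes=libs
    )


def differential_peaks(
    counts: PeakCounts,
    group_a: list[str],
    group_b: list[str],
    p: AccessibilityParams | None = None,
) -> pd.DataFrame:
    """Classify each consensus peak as A-enriched, B-enriched, or shared.

    Fold change is the ratio of library-size-normalized group means;
    significance comes from a two-sided exact binomial test of pooled raw
    counts against the group library-size ratio, BH-corrected across peaks.
    Enriched calls require fold > fold_thresh (strict) and q < peak_fdr.
    """
    p = p or AccessibilityParams()
    if not group_a or not group_b:
        raise ValueError("need at least one sample per group")
    norm = counts.normalized()
    mean_a = norm[group_a].mean(axis=1).to_numpy()
    mean_b = norm[group_b].mean(axis=1).to_numpy()
    raw_a = counts.counts[group_a].sum(axis=1).to_numpy()
    raw_b = counts.counts[group_b].sum(axis=1).to_numpy()
    lib_a = sum(counts.library_sizes[s] for s in group_a)
    lib_b = sum(counts.library_sizes[s] for s in group_b)
    pi0 = lib_a / (lib_a + lib_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mean_a / mean_b
    pvals = np.ones(len(norm))
    for i in range(len(norm)):
        n = int(raw_a[i] + raw_b[i])
        if n > 0:
            pvals[i] = stats.binomtest(int(raw_a[i]), n, pi0).pvalue
    qvals = stats.false_discovery_control(pvals, method="bh")
    klass = np.full(len(norm), "shared", dtype=object)
    sig = qvals < p.peak_fdr
    klass[(fold > p.fold_thresh) & sig] = "A-enriched"
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_fold = mean_b / mean_a
    klass[(inv_fold > p.fold_thresh) & sig] = "B-enriched"
    flagged_zero = (raw_a + raw_b) == 0
    klass[flagged_zero] = "shared"
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in counts.peaks],
            "start": [iv.start for iv in counts.peaks],
            "end": [iv.end for iv in counts.peaks],
            "fold": fold,
            "p_value": pvals,
            "q_value": qvals,
            "class": klass,
            "zero_counts": flagged_zero,
        }
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fragments_bed(
    path: str | Path, sample: str = "", replicate: int = 0
) -> list[FragmentRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append(FragmentRecord(f[0], int(f[1]), int(f[2]), sample, replicate))
    return out


def write_fragments_bed(frags: Sequence[FragmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in sorted(frags, key=lambda f: (f.chrom, f.start, f.end)):
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")
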