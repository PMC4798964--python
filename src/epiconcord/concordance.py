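"""Hypo-methylation vs chromatin-accessibility concordance: per-region signal
report, bootstrap Kolmogorov-Smirnov testing, and TSS-anchored density
matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .accessibility import AccessibilityParams, FragmentRecord, filter_short_fragments, fragments_to_intervals
from .diffmeth import DmrRecord
from .genomic import RegionSet, TssAnnotation, overlap_flags, region_fpkm

__all__ = [
    "ConcordanceReport",
    "KsParams",
    "TssProfileParams",
    "concordance_report",
    "bootstrap_ks",
    "ks_statistic",
    "dmr_tss_density",
]


@dataclass
class KsParams:
    nboot: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nboot < 100:
            raise ValueError("nboot must be >= 100")


@dataclass
class TssProfileParams:
    window: int = 100_000
    bin_size: int = 1000
    smooth_rows: int = 50

    def __post_init__(self) -> None:
        if self.window % self.bin_size != 0:
            raise ValueError("window must be divisible by bin_size")
        if self.smooth_rows < 1:
            raise ValueError("smooth_rows must be >= 1")


@dataclass
class ConcordanceReport:
    label: str
    n_regions: int
    n_overlapping: int
    fraction_overlapping: float
    n_inaccessible: int
    fraction_inaccessible: float
    fpkm: np.ndarray = field(repr=False)
    overlaps_peak: np.ndarray = field(repr=False)
    inaccessible: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_regions": self.n_regions,
            "n_overlapping": self.n_overlapping,
            "fraction_overlapping": self.fraction_overlapping,
            "n_inaccessible": self.n_inaccessible,
            "fraction_inaccessible": self.fraction_inaccessible,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def write_tsv(self, regions: RegionSet, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tfpkm\toverlaps_peak\tinaccessible\n")
            for iv, v, o, i in zip(regions, self.fpkm, self.overlaps_peak, self.inaccessible):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:.6g}\t{int(o)}\t{int(i)}\n")


def concordance_report(
    regions: RegionSet,
    peaks: RegionSet,
    fragments: Sequence[FragmentRecord],
    library_size: int,
    p: AccessibilityParams | None = None,
) -> ConcordanceReport:
    """Per-region accessibility signal and concordance aggregates.

    FPKM is computed from sub-``frag_max_len`` fragments only; a region is
    inaccessible when its FPKM is strictly below ``fpkm_floor``; overlap with
    peaks requires >= 1 bp.
    """
    p = p or AccessibilityParams()
    short = filter_short_fragments(fragments, p)
    fpkm = region_fpkm(fragments_to_intervals(short), regions, library_size)
    ov = (
        overlap_flags(regions, peaks)
        if len(peaks)
        else np.zeros(len(regions), dtype=bool)
    )
    inacc = fpkm < p.fpkm_floor
    n = len(regions)
    return ConcordanceReport(
        label=regions.label or "",
        n_regions=n,
        n_overlapping=int(ov.sum()),
        fraction_overlapping=float(ov.sum() / n) if n else 0.0,
        n_inaccessible=int(inacc.sum()),
        fraction_inaccessible=float(inacc.sum() / n) if n else 0.0,
        fpkm=fpkm,
        overlaps_peak=ov,
        inaccessible=inacc,
    )


def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS D with ties handled by evaluating the ECDF difference at
    distinct pooled values."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    grid = np.concatenate([a, b])
    grid.sort(kind="mergesort")
    fa = np.searchsorted(a, grid, side="right") / len(a)
    fb = np.searchsorted(b, grid, side="right") / len(b)
    return float(np.max(np.abs(fa - fb)))


def _ks_batch(a_mat: np.ndarray, b_mat: np.ndarray) -> np.ndarray:
    """Row-wise two-sample KS D for matrices of resamples (ties handled)."""
    nboot, na = a_mat.shape
    nb = b_mat.shape[1]
    pooled = np.concatenate([a_mat, b_mat], axis=1)
    order = np.argsort(pooled, axis=1, kind="mergesort")
    is_a = (order < na).astype(np.float64)
    cdf_diff = np.cumsum(is_a / na - (1 - is_a) / nb, axis=1)
    vals = np.take_along_axis(pooled, order, axis=1)
    # only positions that close a tie group contribute valid ECDF evaluations
    last_of_value = np.ones_like(vals, dtype=bool)
    last_of_value[:, :-1] = vals[:, :-1] != vals[:, 1:]
    masked = np.where(last_of_value, np.abs(cdf_diff), 0.0)
    return masked.max(axis=1)


def bootstrap_ks(
    values_a: Sequence[float], values_b: Sequence[float], p: KsParams | None = None
) -> tuple[float, float]:
    """Two-sample KS test with a bootstrap p-value under the pooled null.

    Resamples both groups (with replacement, original sizes) from the pooled
    data ``nboot`` times; p = (1 + #{D* >= D_obs}) / (1 + nboot).
    """
    p = p or KsParams()
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("each sample must have at least 5 values")
    d_obs = ks_statistic(a, b)
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(p.seed)
    idx_a = rng.integers(0, len(pooled), size=(p.nboot, len(a)))
    idx_b = rng.integers(0, len(pooled), size=(p.nboot, len(b)))
    d_boot = _ks_batch(pooled[idx_a], pooled[idx_b])
    pval = (1 + int((d_boot >= d_obs - 1e-12).sum())) / (1 + p.nboot)
    return d_obs, float(pval)


def dmr_tss_density(
    dmrs: Sequence[DmrRecord],
    tss: Sequence[TssAnnotation],
    p: TssProfileParams | None = None,
    order: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Indicator matrix of DMR positions in signed 1-kb bins around the nearest
    TSS, with mass-preserving vertical smoothing.

    Returns (unsmoothed matrix, smoothed matrix, n_excluded). Rows follow
    ``order`` (indices into ``dmrs``) when given, else input order; DMRs
    farther than ``window`` from every TSS are excluded and counted. Each row
    of the smoothed matrix redistributes its unit mass over up to
    ``smooth_rows`` neighboring rows (truncated, renormalized at the edges), so
    column totals are preserved exactly.
    """
    p = p or TssProfileParams()
    n_half = p.window // p.bin_size
    n_bins = 2 * n_half
    pos_by_chrom: dict[str, tuple[np.ndarray, list[TssAnnotation]]] = {}
    tmp: dict[str, list[TssAnnotation]] = {}
    for t in tss:
        tmp.setdefault(t.chrom, []).append(t)
    for c, v in tmp.items():
        pos_by_chrom[c] = (np.array([t.position for t in v]), v)
    ordered = [dmrs[i] for i in order] if order is not None else list(dmrs)
    rows = []
    n_excluded = 0
    for d in ordered:
        entry = pos_by_chrom.get(d.interval.chrom)
        if entry is None:
            n_excluded += 1
            continue
        positions, annots = entry
        mid = d.interval.midpoint
        k = int(np.argmin(np.abs(positions - mid)))
        t = annots[k]
        offset = mid - t.position if t.strand == "+" else t.position - mid
        b = offset // p.bin_size + n_half
        if not 0 <= b < n_bins:
            n_excluded += 1
            continue
        row = np.zeros(n_bins)
        row[b] = 1.0
        rows.append(row)
    mat = np.array(rows) if rows else np.zeros((0, n_bins))
    if len(mat) == 0:
        return mat, mat.copy(), n_excluded
    # each row j spreads 1/|W(j)| to rows in its (truncated) window
    n = len(mat)
    h_lo = p.smooth_rows // 2
    h_hi = (p.smooth_rows - 1) // 2
    lo = np.clip(np.arange(n) - h_lo, 0, n)
    hi = np.clip(np.arange(n) + h_hi + 1, 0, n)
    wsize = (hi - lo).astype(float)
    contrib = mat / wsize[:, None]
    cs = np.concatenate([np.zeros((1, n_bins)), np.cumsum(contrib, axis=0)], axis=0)
    smoothed = np.empty_like(mat)
    for i in range(n):
        a = max(0, i - h_hi)
        b_ = min(n, i + h_lo + 1)
        smoothed[i] = cs[b_] - cs[a]
    return mat, smoothed, n_excluded
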