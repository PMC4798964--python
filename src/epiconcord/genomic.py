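"""Core genomic interval types, arithmetic, standard-format I/O and null-model shuffling.

All in-memory coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "GenomeSpec",
    "SignalTrack",
    "TssAnnotation",
    "ShuffleParams",
    "OverlapResult",
    "TssDistance",
    "intersect_fraction",
    "overlap_flags",
    "jaccard",
    "shuffle_matched",
    "region_fpkm",
    "tss_distance_classify",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bedgraph",
    "read_tss",
    "write_tss",
]

BUCKET_PROXIMAL = "<10kb"
BUCKET_MID = "10-100kb"
BUCKET_FAR = ">100kb"


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must be > start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of +,-,. got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class RegionSet:
    """Sorted collection of :class:`GenomicInterval` with a sample/feature label.

    Intervals are sorted by (chrom, start, end) at construction; iteration and
    positional indexing follow that order.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], label: str | None = None):
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self.label = label
        self._by_chrom_cache: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.intervals == other.intervals

    @property
    def chroms(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, sorted by start."""
        if self._by_chrom_cache is None:
            out: dict[str, list[list[int]]] = {}
            for iv in self.intervals:
                out.setdefault(iv.chrom, [[], []])
                out[iv.chrom][0].append(iv.start)
                out[iv.chrom][1].append(iv.end)
            self._by_chrom_cache = {
                c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
                for c, (s, e) in out.items()
            }
        return self._by_chrom_cache

    def merged(self, book_ended: bool = True) -> "RegionSet":
        """Merge overlapping (and, by default, book-ended) intervals."""
        merged: list[GenomicInterval] = []
        cur: list | None = None
        for iv in self.intervals:
            if cur is not None and iv.chrom == cur[0] and (
                iv.start < cur[2] or (book_ended and iv.start == cur[2])
            ):
                cur[2] = max(cur[2], iv.end)
            else:
                if cur is not None:
                    merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
                cur = [iv.chrom, iv.start, iv.end]
        if cur is not None:
            merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
        return RegionSet(merged, label=self.label)

    @property
    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.merged())

    @classmethod
    def from_tuples(
        cls, tuples: Iterable[tuple], label: str | None = None
    ) -> "RegionSet":
        return cls((GenomicInterval(*t) for t in tuples), label=label)


@dataclass
class GenomeSpec:
    """Chromosome lengths plus excluded (gap/unmappable) intervals."""

    chrom_lengths: dict[str, int]
    gaps: RegionSet = field(default_factory=lambda: RegionSet([]))

    def __post_init__(self) -> None:
        for iv in self.gaps:
            L = self.chrom_lengths.get(iv.chrom)
            if L is None or iv.end > L:
                raise ValueError(f"gap {iv} outside genome bounds")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def contains(self, iv: GenomicInterval) -> bool:
        L = self.chrom_lengths.get(iv.chrom)
        return L is not None and iv.end <= L


@dataclass
class SignalTrack:
    """Binned per-chromosome signal density; NaN marks missing bins."""

    bin_size: int
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for c, arr in self.values.items():
            finite = arr[np.isfinite(arr)]
            if np.any(finite < 0):
                raise ValueError(f"negative signal values on {c}")


@dataclass(frozen=True)
class TssAnnotation:
    gene: str
    chrom: str
    position: int  # 0-based TSS coordinate
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("TSS position must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("TSS strand must be + or -")


@dataclass
class ShuffleParams:
    n_repeats: int = 10
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


class OverlapResult(NamedTuple):
    n_total: int
    n_overlapping: int
    fraction: float


class TssDistance(NamedTuple):
    distance: int | None
    bucket: str | None
    flagged: bool  # True when no TSS exists on the region's chromosome


def _check_namespaces(a: RegionSet, b: RegionSet) -> None:
    if len(a) and len(b) and not (a.chroms & b.chroms):
        raise ValueError(
            f"mismatched chromosome namespaces: {sorted(a.chroms)[:3]} vs "
            f"{sorted(b.chroms)[:3]}"
        )


def overlap_flags(a: RegionSet, b: RegionSet, min_bp: int = 1) -> np.ndarray:
    """Boolean array (aligned with ``a``'s order): interval has >= min_bp
    overlap with the merged union of ``b``."""
    _check_namespaces(a, b)
    bm = b.merged().by_chrom()
    flags = np.zeros(len(a), dtype=bool)
    for i, iv in enumerate(a):
        if iv.chrom not in bm:
            continue
        starts, ends = bm[iv.chrom]
        # merged intervals overlapping [iv.start, iv.end)
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        if hi <= lo:
            continue
        ov = np.minimum(ends[lo:hi], iv.end) - np.maximum(starts[lo:hi], iv.start)
        flags[i] = int(ov.sum()) >= min_bp
    return flags


def intersect_fraction(a: RegionSet, b: RegionSet, min_bp: int = 1) -> OverlapResult:
    """Count and fraction of ``a``'s intervals with >= min_bp overlap with ``b``."""
    flags = overlap_flags(a, b, min_bp=min_bp)
    n = len(a)
    k = int(flags.sum())
    return OverlapResult(n, k, k / n if n else 0.0)


def jaccard(a: RegionSet, b: RegionSet) -> float:
    """Base-pair Jaccard index: intersection bp / union bp (0 for two empty sets)."""
    am, bm = a.merged(), b.merged()
    inter = 0
    for chrom, (astarts, aends) in am.by_chrom().items():
        if chrom not in bm.by_chrom():
            continue
        bstarts, bends = bm.by_chrom()[chrom]
        i = j = 0
        while i < len(astarts) and j < len(bstarts):
            lo = max(astarts[i], bstarts[j])
            hi = min(aends[i], bends[j])
            if hi > lo:
                inter += int(hi - lo)
            if aends[i] < bends[j]:
                i += 1
            else:
                j += 1
    a_bp, b_bp = am.total_bp, bm.total_bp
    union = a_bp + b_bp - inter
    return inter / union if union > 0 else 0.0


def shuffle_matched(
    a: RegionSet, genome: GenomeSpec, params: ShuffleParams
) -> list[RegionSet]:
    """Size-matched random placement of ``a``'s intervals, ``n_repeats`` times.

    Each repeat preserves the multiset of interval lengths; placed intervals
    are mutually non-overlapping and avoid genome gaps. Deterministic per seed.
    """
    lengths = sorted((len(iv) for iv in a), reverse=True)
    chroms = sorted(genome.chrom_lengths)
    weights = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    gaps_by_chrom = genome.gaps.merged().by_chrom()
    out: list[RegionSet] = []
    for rep in range(params.n_repeats):
        rng = np.random.default_rng([params.seed, rep])
        # occupied[chrom] is a sorted list of (start, end), gaps pre-seeded
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
        for c, (gs, ge) in gaps_by_chrom.items():
            occupied[c] = [(int(s), int(e)) for s, e in zip(gs, ge)]
        placed: list[GenomicInterval] = []
        for L in lengths:
            ok = False
            for _ in range(params.max_retries):
                c = chroms[int(rng.choice(len(chroms), p=weights))]
                limit = genome.chrom_lengths[c] - L
                if limit < 0:
                    continue
                s = int(rng.integers(0, limit + 1))
                occ = occupied[c]
                k = bisect.bisect_right(occ, (s, s + L))
                if k > 0 and occ[k - 1][1] > s:
                    continue
                if k < len(occ) and occ[k][0] < s + L:
                    continue
                occ.insert(k, (s, s + L))
                placed.append(GenomicInterval(c, s, s + L))
                ok = True
                break
            if not ok:
                raise RuntimeError(
                    f"shuffle repeat {rep}: could not place interval of length {L} "
                    f"after {params.max_retries} retries"
                )
        out.append(RegionSet(placed, label=f"shuffle_{rep}"))
    return out


def region_fpkm(
    fragments: Sequence[GenomicInterval], regions: RegionSet, library_size: int
) -> np.ndarray:
    """Per-region fragments-per-kilobase-per-million values.

    value = (# fragments overlapping the region by >= 1 bp) * 1e9 /
            (region length in bp * library_size)
    Output aligns with ``regions``' iteration order.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    starts_by_chrom: dict[str, np.ndarray] = {}
    ends_by_chrom: dict[str, np.ndarray] = {}
    tmp: dict[str, list[list[int]]] = {}
    for f in fragments:
        tmp.setdefault(f.chrom, [[], []])
        tmp[f.chrom][0].append(f.start)
        tmp[f.chrom][1].append(f.end)
    for c, (s, e) in tmp.items():
        starts_by_chrom[c] = np.sort(np.asarray(s, dtype=np.int64))
        ends_by_chrom[c] = np.sort(np.asarray(e, dtype=np.int64))
    vals = np.zeros(len(regions), dtype=float)
    for i, iv in enumerate(regions):
        if iv.chrom in starts_by_chrom:
            s_arr = starts_by_chrom[iv.chrom]
            e_arr = ends_by_chrom[iv.chrom]
            n = len(s_arr)
            # fragments with start < iv.end and end > iv.start
            cnt = (
                int(np.searchsorted(s_arr, iv.end, side="left"))
                - int(np.searchsorted(e_arr, iv.start, side="right"))
            )
            cnt = max(0, min(cnt, n))
        else:
            cnt = 0
        vals[i] = cnt * 1e9 / (len(iv) * library_size)
    return vals


def tss_distance_classify(
    regions: RegionSet, tss: Sequence[TssAnnotation]
) -> list[TssDistance]:
    """Unsigned distance from each region's midpoint to the nearest TSS, with
    proximal/distal bucket labels. Regions on chromosomes lacking any TSS are
    flagged and excluded from bucket tallies by the caller."""
    pos_by_chrom: dict[str, np.ndarray] = {}
    for t in tss:
        pos_by_chrom.setdefault(t.chrom, [])
    for t in tss:
        pos_by_chrom[t.chrom].append(t.position)
    pos_by_chrom = {c: np.sort(np.asarray(v)) for c, v in pos_by_chrom.items()}
    out: list[TssDistance] = []
    for iv in regions:
        arr = pos_by_chrom.get(iv.chrom)
        if arr is None or len(arr) == 0:
            out.append(TssDistance(None, None, True))
            continue
        mid = iv.midpoint
        j = int(np.searchsorted(arr, mid))
        cands = arr[max(0, j - 1): j + 1]
        d = int(np.min(np.abs(cands - mid)))
        if d < 10_000:
            bucket = BUCKET_PROXIMAL
        elif d <= 100_000:
            bucket = BUCKET_MID
        else:
            bucket = BUCKET_FAR
        out.append(TssDistance(d, bucket, False))
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, label: str | None = None) -> RegionSet:
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 and f[3] != "." else None
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            strand = f[5] if len(f) > 5 else "."
            ivs.append(GenomicInterval(f[0], int(f[1]), int(f[2]), name, score, strand))
    return RegionSet(ivs, label=label)


def write_bed(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in regions:  # RegionSet is already sorted
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields += [
                    iv.name if iv.name is not None else ".",
                    f"{iv.score:g}" if iv.score is not None else "0",
                    iv.strand,
                ]
            fh.write("\t".join(fields) + "\n")


def read_narrowpeak(path: str | Path, label: str | None = None) -> RegionSet:
    """narrowPeak (BED6+4); signalValue lands in ``score``."""
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            ivs.append(
                GenomicInterval(
                    f[0], int(f[1]), int(f[2]),
                    name=f[3] if len(f) > 3 else None,
                    score=float(f[6]) if len(f) > 6 else None,
                    strand=f[5] if len(f) > 5 else ".",
                )
            )
    return RegionSet(ivs, label=label)


def write_narrowpeak(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(regions):
            sig = iv.score if iv.score is not None else 0.0
            fh.write(
                "\t".join(
                    [
                        iv.chrom, str(iv.start), str(iv.end),
                        iv.name or f"peak_{i}", "0", iv.strand,
                        f"{sig:g}", "-1", "-1", str(len(iv) // 2),
                    ]
                )
                + "\n"
            )


def read_bedgraph(path: str | Path, bin_size: int, genome: GenomeSpec) -> SignalTrack:
    values = {
        c: np.full(int(np.ceil(L / bin_size)), np.nan)
        for c, L in genome.chrom_lengths.items()
    }
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")[:4]
            if chrom not in values:
                continue
            b0, b1 = int(s) // bin_size, (int(e) - 1) // bin_size + 1
            values[chrom][b0:b1] = float(v)
    return SignalTrack(bin_size=bin_size, values=values)


def read_tss(path: str | Path) -> list[TssAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, chrom, pos, strand = line.split("\t")[:4]
            out.append(TssAnnotation(gene, chrom, int(pos), strand))
    return out


def write_tss(tss: Sequence[TssAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in sorted(tss, key=lambda t: (t.chrom, t.position)):
            fh.write(f"{t.gene}\t{t.chrom}\t{t.position}\t{t.strand}\n")
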