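"""Per-cytosine methylation data model, levels, binning, and allc-style I/O.

Cytosine positions are 1-based in memory and on disk (allc convention);
conversion to the 0-based interval world happens inside region queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .genomic import GenomeSpec, GenomicInterval

__all__ = [
    "CytosineRecord",
    "Methylome",
    "BinnedMeth",
    "GlobalLevels",
    "region_meth_level",
    "global_levels",
    "bin_meth_levels",
    "adjust_nonconversion",
    "read_allc",
    "write_allc",
    "pool_methylomes",
]

_COLUMNS = ["chrom", "pos", "strand", "context", "mc", "cov"]


@dataclass(frozen=True)
class CytosineRecord:
    chrom: str
    pos: int  # 1-based
    strand: str
    context: str  # "CG" or "CH"
    mc: int
    cov: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")
        if self.context not in ("CG", "CH"):
            raise ValueError("context must be CG or CH")
        if not (0 <= self.mc <= self.cov):
            raise ValueError(f"require 0 <= mc <= cov, got mc={self.mc} cov={self.cov}")


class Methylome:
    """Sorted per-cytosine methylation counts for one sample.

    Backed by a DataFrame with columns chrom, pos, strand, context, mc, cov,
    sorted by (chrom, pos). ``lambda_nc`` is the bisulfite non-conversion rate.
    """

    def __init__(
        self,
        records: pd.DataFrame | Iterable[CytosineRecord],
        sample_label: str = "",
        lambda_nc: float = 0.0,
    ):
        if not isinstance(records, pd.DataFrame):
            records = pd.DataFrame(
                [(r.chrom, r.pos, r.strand, r.context, r.mc, r.cov) for r in records],
                columns=_COLUMNS,
            )
        df = records[_COLUMNS].copy()
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if ((df["mc"] > df["cov"]) | (df["mc"] < 0)).any():
            raise ValueError("require 0 <= mc <= cov for every record")
        dup = df.duplicated(subset=["chrom", "pos", "strand"])
        if dup.any():
            raise ValueError("positions must be strictly increasing per (chrom, strand)")
        if not 0.0 <= lambda_nc < 1.0:
            raise ValueError("lambda_nc must be in [0, 1)")
        self.df = df
        self.sample_label = sample_label
        self.lambda_nc = float(lambda_nc)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def subset(self, chrom: str | None = None, context: str | None = None) -> pd.DataFrame:
        df = self.df
        if chrom is not None:
            df = df[df["chrom"] == chrom]
        if context is not None:
            df = df[df["context"] == context]
        return df


@dataclass
class BinnedMeth:
    """Pooled methylation counts in fixed-size genomic bins; NaN level = no data."""

    bin_size: int
    mc: dict[str, np.ndarray]
    cov: dict[str, np.ndarray]

    def level(self, chrom: str) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = self.mc[chrom] / self.cov[chrom]
        return np.where(self.cov[chrom] > 0, lv, np.nan)

    def flat_level(self, chrom_order: list[str] | None = None) -> np.ndarray:
        order = chrom_order if chrom_order is not None else sorted(self.mc)
        return np.concatenate([self.level(c) for c in order])


@dataclass(frozen=True)
class GlobalLevels:
    mcg: float
    mch: float
    mc_all: float
    frac_mc_in_ch: float


def adjust_nonconversion(p_hat: float, lambda_nc: float) -> float:
    """Linear non-conversion correction, clipped at zero:
    p_adj = max(0, (p_hat - lambda) / (1 - lambda))."""
    if not 0.0 <= lambda_nc < 1.0:
        raise ValueError("lambda_nc must be in [0, 1)")
    if np.isnan(p_hat):
        return float("nan")
    return max(0.0, (p_hat - lambda_nc) / (1.0 - lambda_nc))


def region_meth_level(
    m: Methylome, region: GenomicInterval, context: str = "CG"
) -> float:
    """Count-pooled methylation level (sum mc / sum cov) over covered sites of
    ``context`` within ``region``; NaN when no covered site exists."""
    df = m.subset(chrom=region.chrom, context=context)
    # 1-based pos p covers 0-based p-1: region [start, end) <-> pos in [start+1, end]
    sel = df[(df["pos"] >= region.start + 1) & (df["pos"] <= region.end) & (df["cov"] > 0)]
    cov = int(sel["cov"].sum())
    if cov == 0:
        return float("nan")
    return float(sel["mc"].sum() / cov)


def global_levels(m: Methylome) -> GlobalLevels:
    """Genome-wide mCG/CG, mCH/CH and total mC/C levels, non-conversion adjusted,
    plus the fraction of adjusted methylcytosine mass in the CH context."""
    lam = m.lambda_nc
    out: dict[str, float] = {}
    mass: dict[str, float] = {}
    for ctx in ("CG", "CH"):
        sel = m.df[(m.df["context"] == ctx) & (m.df["cov"] > 0)]
        cov = int(sel["cov"].sum())
        if cov == 0:
            out[ctx] = float("nan")
            mass[ctx] = float("nan")
        else:
            p = adjust_nonconversion(float(sel["mc"].sum() / cov), lam)
            out[ctx] = p
            mass[ctx] = p * cov
    covered = m.df[m.df["cov"] > 0]
    tot_cov = int(covered["cov"].sum())
    if tot_cov == 0:
        mc_all = float("nan")
    else:
        mc_all = adjust_nonconversion(float(covered["mc"].sum() / tot_cov), lam)
    tot_mass = np.nansum([mass["CG"], mass["CH"]])
    frac_ch = float(mass["CH"] / tot_mass) if tot_mass > 0 and not np.isnan(mass["CH"]) else float("nan")
    return GlobalLevels(mcg=out["CG"], mch=out["CH"], mc_all=mc_all, frac_mc_in_ch=frac_ch)


def bin_meth_levels(
    m: Methylome,
    bin_size: int = 500,
    context: str = "CG",
    genome: GenomeSpec | None = None,
) -> BinnedMeth:
    """Pooled (mc, cov) in bins tiling each chromosome from coordinate 0.

    A 1-based position p falls in bin (p-1) // bin_size. Bins with zero
    coverage carry NaN levels and are excluded downstream.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    mc_out: dict[str, np.ndarray] = {}
    cov_out: dict[str, np.ndarray] = {}
    chroms = (
        sorted(genome.chrom_lengths) if genome is not None else m.chroms
    )
    for chrom in chroms:
        df = m.subset(chrom=chrom, context=context)
        if genome is not None:
            n_bins = int(np.ceil(genome.chrom_lengths[chrom] / bin_size))
        else:
            n_bins = int((df["pos"].max() - 1) // bin_size) + 1 if len(df) else 0
        mc = np.zeros(n_bins, dtype=np.int64)
        cov = np.zeros(n_bins, dtype=np.int64)
        if len(df):
            idx = ((df["pos"].to_numpy() - 1) // bin_size).astype(np.int64)
            np.add.at(mc, idx, df["mc"].to_numpy())
            np.add.at(cov, idx, df["cov"].to_numpy())
        mc_out[chrom] = mc
        cov_out[chrom] = cov
    return BinnedMeth(bin_size=bin_size, mc=mc_out, cov=cov_out)


def pool_methylomes(methylomes: list[Methylome], sample_label: str = "") -> Methylome:
    """Sum counts across replicates at matching (chrom, pos, strand, context)."""
    if not methylomes:
        raise ValueError("need at least one methylome")
    df = pd.concat([m.df for m in methylomes], ignore_index=True)
    pooled = (
        df.groupby(["chrom", "pos", "strand", "context"], as_index=False)[["mc", "cov"]]
        .sum()
    )
    return Methylome(
        pooled, sample_label=sample_label or methylomes[0].sample_label,
        lambda_nc=methylomes[0].lambda_nc,
    )


# ---------------------------------------------------------------------------
# allc-style I/O
# ---------------------------------------------------------------------------

def _context_class(raw: pd.Series) -> pd.Series:
    return np.where(raw.str.startswith("CG"), "CG", "CH")


def read_allc(
    path: str | Path, sample_label: str = "", lambda_nc: float = 0.0
) -> Methylome:
    """Read an allc-style TSV: chrom, pos(1-based), strand, context, mc, cov
    [, call flag]. The flag column is optional and ignored; any tri-nucleotide
    context starting with CG maps to CG, everything else to CH."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"allc file {path} has {df.shape[1]} columns, expected >= 6")
    df = df.iloc[:, :6]
    df.columns = ["chrom", "pos", "strand", "context", "mc", "cov"]
    df = df.astype(
        {"chrom": str, "pos": np.int64, "strand": str, "context": str,
         "mc": np.int64, "cov": np.int64}
    )
    df["context"] = _context_class(df["context"].astype(str))
    return Methylome(df, sample_label=sample_label, lambda_nc=lambda_nc)


def write_allc(m: Methylome, path: str | Path) -> None:
    """Write allc TSV with a call flag column: 1 when a one-sided binomial test
    of mc out of cov against the non-conversion rate passes at 0.01."""
    df = m.df.copy()
    lam = max(m.lambda_nc, 1e-9)
    pvals = stats.binom.sf(df["mc"].to_numpy() - 1, df["cov"].to_numpy(), lam)
    df["flag"] = (pvals < 0.01).astype(int)
    df.to_csv(path, sep="\t", header=False, index=False)
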