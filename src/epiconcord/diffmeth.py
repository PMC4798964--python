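"""Differential methylation: per-site beta-binomial tests with replicates,
block-joining of sites into DMRs, group-specific hypo-DMR selection, per-DMV
Fisher tests, and the methylation-vs-expression correlation profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic import GenomicInterval, RegionSet, TssAnnotation
from .methylome import Methylome

__all__ = [
    "DmrParams",
    "DmsRecord",
    "DmrRecord",
    "DmsCallResult",
    "call_dms",
    "join_dms_to_dmr",
    "group_specific_hypo_dmr",
    "dmv_fisher_test",
    "meth_expr_correlation_profile",
    "CorrelationProfile",
    "dmrs_to_regionset",
]

# prior weight (pseudo-degrees-of-freedom) pulling per-site dispersion toward
# the genome-wide mean; few-replicate designs get heavy shrinkage
_DISPERSION_PRIOR_DF = 20.0


@dataclass
class DmrParams:
    site_fdr: float = 0.01
    max_gap: int = 250
    min_sites: int = 2

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_sites < 1:
            raise ValueError("min_sites must be >= 1")


@dataclass(frozen=True)
class DmsRecord:
    chrom: str
    pos: int  # 1-based CpG coordinate
    level_a: float
    level_b: float
    direction: str  # "A<B" or "A>B"
    p_value: float
    q_value: float
    significant: bool

    @property
    def delta(self) -> float:
        return self.level_a - self.level_b


@dataclass(frozen=True)
class DmrRecord:
    interval: GenomicInterval
    direction: str
    n_sites: int
    level_a: float
    level_b: float

    @property
    def delta(self) -> float:
        return self.level_a - self.level_b


class DmsCallResult(list):
    """List of DmsRecord with a counter of sites skipped for one-group-only
    coverage."""

    def __init__(self, records: Iterable[DmsRecord], n_skipped: int = 0):
        super().__init__(records)
        self.n_skipped = n_skipped


def _group_matrix(group: list[Methylome]) -> pd.DataFrame:
    """Wide per-site count matrix for one group: index (chrom, pos), columns
    mc_0, cov_0, mc_1, cov_1, ... (CG context, covered sites only)."""
    frames = []
    for j, m in enumerate(group):
        df = m.df[(m.df["context"] == "CG") & (m.df["cov"] > 0)]
        frames.append(
            df.set_index(["chrom", "pos"])[["mc", "cov"]].rename(
                columns={"mc": f"mc_{j}", "cov": f"cov_{j}"}
            )
        )
    out = frames[0]
    for f in frames[1:]:
        out = out.join(f, how="outer")
    return out


def _dispersion_mom(
    mc: np.ndarray, cov: np.ndarray, p_hat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site method-of-moments intraclass correlation from replicate
    residuals around the pooled group level. Returns (rho_numerator_stat,
    denominator) so estimates from the two groups can be pooled."""
    valid = cov > 0
    J = valid.sum(axis=1)
    var = p_hat * (1 - p_hat)
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = (mc - cov * p_hat[:, None]) ** 2 / (cov * var[:, None])
    resid = np.where(valid & (var[:, None] > 0), resid, 0.0)
    X = resid.sum(axis=1)
    df = np.where(var > 0, np.maximum(J - 1, 0), 0)
    mean_cov = np.where(J > 0, np.where(valid, cov, 0).sum(axis=1) / np.maximum(J, 1), 0)
    denom = df * np.maximum(mean_cov - 1, 0)
    return X - df, denom


def call_dms(
    group_a: list[Methylome],
    group_b: list[Methylome],
    p: DmrParams | None = None,
) -> DmsCallResult:
    """Per-CpG two-group beta-binomial Wald test (arcsine link).

    Sites must have pooled coverage in both groups; per-site dispersion is a
    method-of-moments estimate shrunk toward the genome-wide mean. P-values are
    BH-corrected genome-wide; records with q < site_fdr are flagged significant
    and carry the direction given by the sign of the level difference.
    """
    p = p or DmrParams()
    if not group_a or not group_b:
        raise ValueError("need at least one replicate per group")
    wa = _group_matrix(group_a)
    wb = _group_matrix(group_b)
    joined = wa.join(wb.rename(columns=lambda c: "B" + c), how="outer")
    ja, jb = len(group_a), len(group_b)
    mc_a = joined[[f"mc_{j}" for j in range(ja)]].to_numpy(float)
    cov_a = joined[[f"cov_{j}" for j in range(ja)]].to_numpy(float)
    mc_b = joined[[f"Bmc_{j}" for j in range(jb)]].to_numpy(float)
    cov_b = joined[[f"Bcov_{j}" for j in range(jb)]].to_numpy(float)
    mc_a, cov_a = np.nan_to_num(mc_a), np.nan_to_num(cov_a)
    mc_b, cov_b = np.nan_to_num(mc_b), np.nan_to_num(cov_b)

    tot_cov_a = cov_a.sum(axis=1)
    tot_cov_b = cov_b.sum(axis=1)
    keep = (tot_cov_a > 0) & (tot_cov_b > 0)
    n_skipped = int((~keep).sum())
    idx = joined.index[keep]
    mc_a, cov_a, mc_b, cov_b = mc_a[keep], cov_a[keep], mc_b[keep], cov_b[keep]
    tot_cov_a, tot_cov_b = tot_cov_a[keep], tot_cov_b[keep]
    if len(idx) == 0:
        return DmsCallResult([], n_skipped)

    p_a = mc_a.sum(axis=1) / tot_cov_a
    p_b = mc_b.sum(axis=1) / tot_cov_b

    num_a, den_a = _dispersion_mom(mc_a, cov_a, p_a)
    num_b, den_b = _dispersion_mom(mc_b, cov_b, p_b)
    num, den = num_a + num_b, den_a + den_b
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_site = np.clip(num / den, 0.0, 0.99)
    est = den > 0
    rho_bar = float(np.average(rho_site[est], weights=den[est])) if est.any() else 0.0
    df_site = np.where(est, den, 0.0)
    rho = np.where(
        est,
        (_DISPERSION_PRIOR_DF * rho_bar + df_site * np.nan_to_num(rho_site))
        / (_DISPERSION_PRIOR_DF + df_site),
        rho_bar,
    )

    def _arcsine_var(cov: np.ndarray, tot: np.ndarray, rho: np.ndarray) -> np.ndarray:
        infl = (cov * (1 + np.maximum(cov - 1, 0) * rho[:, None])).sum(axis=1)
        return infl / (4.0 * tot**2)

    theta = np.arcsin(np.sqrt(p_a)) - np.arcsin(np.sqrt(p_b))
    se = np.sqrt(_arcsine_var(cov_a, tot_cov_a, rho) + _arcsine_var(cov_b, tot_cov_b, rho))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(theta == 0.0, 0.0, theta / se)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    qvals = stats.false_discovery_control(pvals, method="bh")
    sig = qvals < p.site_fdr

    records = [
        DmsRecord(
            chrom=chrom,
            pos=int(pos),
            level_a=float(p_a[i]),
            level_b=float(p_b[i]),
            direction="A<B" if p_a[i] < p_b[i] else "A>B",
            p_value=float(pvals[i]),
            q_value=float(qvals[i]),
            significant=bool(sig[i] and p_a[i] != p_b[i]),
        )
        for i, (chrom, pos) in enumerate(idx)
    ]
    return DmsCallResult(records, n_skipped)


def join_dms_to_dmr(
    dms: Iterable[DmsRecord], p: DmrParams | None = None
) -> list[DmrRecord]:
    """Join significant same-direction sites within ``max_gap`` bp into blocks,
    drop blocks spanning any significant opposite-direction site, and keep
    blocks with >= ``min_sites`` members."""
    p = p or DmrParams()
    sig = sorted(
        (r for r in dms if r.significant), key=lambda r: (r.chrom, r.pos)
    )
    out: list[DmrRecord] = []
    by_chrom: dict[str, list[DmsRecord]] = {}
    for r in sig:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, recs in by_chrom.items():
        opp_pos = {
            d: np.array([r.pos for r in recs if r.direction != d], dtype=np.int64)
            for d in ("A<B", "A>B")
        }
        for direction in ("A<B", "A>B"):
            members = [r for r in recs if r.direction == direction]
            if not members:
                continue
            blocks: list[list[DmsRecord]] = [[members[0]]]
            for r in members[1:]:
                if r.pos - blocks[-1][-1].pos <= p.max_gap:
                    blocks[-1].append(r)
                else:
                    blocks.append([r])
            for block in blocks:
                first, last = block[0].pos, block[-1].pos
                opp = opp_pos[direction]
                if len(opp) and bool(np.any((opp >= first) & (opp <= last))):
                    continue
                if len(block) < p.min_sites:
                    continue
                out.append(
                    DmrRecord(
                        interval=GenomicInterval(chrom, first - 1, last),
                        direction=direction,
                        n_sites=len(block),
                        level_a=float(np.mean([r.level_a for r in block])),
                        level_b=float(np.mean([r.level_b for r in block])),
                    )
                )
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return out


def group_specific_hypo_dmr(
    candidates: RegionSet,
    hypo_calls: dict[str, Sequence[bool]],
    in_group: list[str],
    out_group: list[str],
) -> RegionSet:
    """Candidates hypo-methylated in every in-group sample and in no out-group
    sample. ``hypo_calls`` maps sample name to per-candidate booleans aligned
    with the candidate order."""
    for s in list(in_group) + list(out_group):
        if s not in hypo_calls:
            raise KeyError(f"sample {s!r} missing from hypo_calls")
        if len(hypo_calls[s]) != len(candidates):
            raise ValueError(f"hypo_calls[{s!r}] length != number of candidates")
    kept = []
    for i, iv in enumerate(candidates):
        if all(hypo_calls[s][i] for s in in_group) and not any(
            hypo_calls[s][i] for s in out_group
        ):
            kept.append(iv)
    return RegionSet(kept, label="group_specific_hypo")


def _region_counts(m: Methylome, iv: GenomicInterval, context: str = "CG") -> tuple[int, int]:
    df = m.subset(chrom=iv.chrom, context=context)
    sel = df[(df["pos"] >= iv.start + 1) & (df["pos"] <= iv.end)]
    return int(sel["mc"].sum()), int(sel["cov"].sum())


def dmv_fisher_test(
    dmvs: RegionSet,
    samples: list[Methylome],
    alpha_fdr: float = 1e-10,
) -> pd.DataFrame:
    """Pairwise Fisher's exact tests of pooled (mc, cov - mc) per DMV, with BH
    correction across all DMV x pair tests. Zero-coverage entries are skipped
    and flagged."""
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    labels = [m.sample_label or f"sample_{i}" for i, m in enumerate(samples)]
    counts = [
        [_region_counts(m, iv) for m in samples] for iv in dmvs
    ]
    rows = []
    for di, per_sample in enumerate(counts):
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                (mi, ci), (mj, cj) = per_sample[i], per_sample[j]
                skipped = ci == 0 or cj == 0
                if skipped:
                    pv = np.nan
                else:
                    _, pv = stats.fisher_exact(
                        [[mi, ci - mi], [mj, cj - mj]], alternative="two-sided"
                    )
                rows.append((di, labels[i], labels[j], pv, skipped))
    df = pd.DataFrame(
        rows, columns=["dmv_index", "sample_a", "sample_b", "p_value", "skipped"]
    )
    tested = ~df["skipped"]
    q = np.full(len(df), np.nan)
    if tested.any():
        q[tested.to_numpy()] = stats.false_discovery_control(
            df.loc[tested, "p_value"].to_numpy(), method="bh"
        )
    df["q_value"] = q
    df["significant"] = (df["q_value"] < alpha_fdr).fillna(False)
    return df


@dataclass
class CorrelationProfile:
    """Per-bin Pearson correlation of DMR methylation difference with the
    assigned gene's expression log-ratio, by signed TSS offset."""

    bin_offsets: np.ndarray  # signed bp of each bin's lower edge
    r: np.ndarray  # NaN where < min_dmrs
    n: np.ndarray
    n_dropped: int = 0  # DMRs with no expression entry or out of window


def meth_expr_correlation_profile(
    dmrs: Sequence[DmrRecord],
    tss: Sequence[TssAnnotation],
    expr_log2fc: dict[str, float],
    window: int = 100_000,
    bin_size: int = 1000,
    min_dmrs: int = 3,
) -> CorrelationProfile:
    """Each DMR is assigned to its nearest TSS; its signed, strand-oriented
    midpoint offset (downstream positive) selects a bin in +/- window."""
    if window % bin_size != 0:
        raise ValueError("window must be divisible by bin_size")
    n_bins_half = window // bin_size
    n_bins = 2 * n_bins_half
    by_chrom: dict[str, list[TssAnnotation]] = {}
    for t in tss:
        by_chrom.setdefault(t.chrom, []).append(t)
    pos_by_chrom = {
        c: (np.array([t.position for t in v]), v) for c, v in by_chrom.items()
    }
    deltas: dict[int, list[float]] = {b: [] for b in range(n_bins)}
    exprs: dict[int, list[float]] = {b: [] for b in range(n_bins)}
    n_dropped = 0
    for d in dmrs:
        entry = pos_by_chrom.get(d.interval.chrom)
        if entry is None:
            n_dropped += 1
            continue
        positions, annots = entry
        mid = d.interval.midpoint
        k = int(np.argmin(np.abs(positions - mid)))
        t = annots[k]
        offset = mid - t.position if t.strand == "+" else t.position - mid
        b = offset // bin_size + n_bins_half
        if not 0 <= b < n_bins:
            n_dropped += 1
            continue
        if t.gene not in expr_log2fc:
            n_dropped += 1
            continue
        deltas[b].append(d.delta)
        exprs[b].append(expr_log2fc[t.gene])
    r = np.full(n_bins, np.nan)
    n = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        n[b] = len(deltas[b])
        if n[b] >= min_dmrs and np.std(deltas[b]) > 0 and np.std(exprs[b]) > 0:
            r[b] = float(np.corrcoef(deltas[b], exprs[b])[0, 1])
    offsets = (np.arange(n_bins) - n_bins_half) * bin_size
    return CorrelationProfile(bin_offsets=offsets, r=r, n=n, n_dropped=n_dropped)


def dmrs_to_regionset(
    dmrs: Sequence[DmrRecord], direction: str | None = None, label: str | None = None
) -> RegionSet:
    ivs = [
        GenomicInterval(
            d.interval.chrom, d.interval.start, d.interval.end,
            name=d.direction, score=round(d.delta, 4),
        )
        for d in dmrs
        if direction is None or d.direction == direction
    ]
    return RegionSet(ivs, label=label)
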