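"""Synthetic epigenome generator.

Plants known regulatory-region classes (promoter UMRs, active enhancers,
vestigial enhancers, DMV-bearing TF loci, background controls) on a small
genome and emits, per cell-type profile and replicate: per-cytosine
methylation counts with beta-binomial noise and bisulfite non-conversion,
accessibility fragments and peaks, expression tables, and motif-planted
sequences — together with a ground-truth table for parameter-recovery tests.

Cell types: rodlike and conelike parents, a 50/50 hybrid intermediate, a
fetal_like state in which vestigial enhancers are still hypo-methylated and
accessible, and a cortexlike outgroup.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .accessibility import FragmentRecord
from .genomic import GenomeSpec, GenomicInterval, RegionSet, TssAnnotation
from .methylome import Methylome

__all__ = [
    "RegionClass",
    "CellTypeProfile",
    "SimulationConfig",
    "TruthTable",
    "default_profiles",
    "default_pwm",
    "build_truth",
    "simulate_methylome",
    "simulate_accessibility",
    "simulate_sequences",
    "simulate_expression",
    "emit_all",
    "PROFILE_NAMES",
]


class RegionClass:
    PROMOTER_UMR = "PROMOTER_UMR"
    ACTIVE_ENHANCER = "ACTIVE_ENHANCER"
    VESTIGIAL_ENHANCER = "VESTIGIAL_ENHANCER"
    DMV_TF_LOCUS = "DMV_TF_LOCUS"
    BACKGROUND = "BACKGROUND"

    ALL = (PROMOTER_UMR, ACTIVE_ENHANCER, VESTIGIAL_ENHANCER, DMV_TF_LOCUS, BACKGROUND)


PROFILE_NAMES = ("rodlike", "conelike", "hybrid", "fetal_like", "cortexlike")
_PROFILE_ID = {name: i for i, name in enumerate(PROFILE_NAMES)}

# sub-seeds separating the generator's independent random streams
_S_PLACE, _S_CPG, _S_CH, _S_METH, _S_ATAC, _S_SEQ, _S_EXPR = range(101, 108)


@dataclass
class CellTypeProfile:
    name: str
    mch_rate: float = 0.0
    mixing: float | None = None  # hybrid only: weight on the rodlike parent

    def __post_init__(self) -> None:
        if not 0 <= self.mch_rate < 1:
            raise ValueError("mch_rate must be in [0, 1)")
        if self.mixing is not None and not 0 <= self.mixing <= 1:
            raise ValueError("mixing must be in [0, 1]")


def default_profiles() -> dict[str, CellTypeProfile]:
    return {
        "rodlike": CellTypeProfile("rodlike", mch_rate=0.01),
        "conelike": CellTypeProfile("conelike", mch_rate=0.012),
        "hybrid": CellTypeProfile("hybrid", mch_rate=0.011, mixing=0.5),
        "fetal_like": CellTypeProfile("fetal_like", mch_rate=0.002),
        "cortexlike": CellTypeProfile("cortexlike", mch_rate=0.04),
    }


def default_pwm(seed: int = 0) -> np.ndarray:
    """Strong 8-bp position weight matrix (rows = positions, columns ACGT)."""
    consensus = "TGACGTCA"
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    pwm = np.full((len(consensus), 4), 0.03)
    for i, b in enumerate(consensus):
        pwm[i, base_idx[b]] = 0.91
    return pwm


@dataclass
class SimulationConfig:
    seed: int
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    # planted region counts and lengths
    n_promoter_umr: int = 60
    n_enhancer_rodlike: int = 150
    n_enhancer_conelike: int = 150
    vestigial_frac_rodlike: float = 0.30
    vestigial_frac_conelike: float = 0.05
    n_dmv_tf: int = 12
    n_background_regions: int = 50
    promoter_len: int = 2000
    enhancer_len: int = 700
    dmv_len: int = 6000
    background_len: int = 700
    min_region_gap: int = 3000
    # CpG landscape
    cpg_spacing_min: int = 25
    cpg_spacing_max: int = 75
    ch_spacing: int = 200
    # methylation levels
    level_umr: float = 0.06   # printed UMR median
    level_lmr: float = 0.24   # printed LMR median
    level_background: float = 0.80
    dmv_level_low: float = 0.08
    dmv_level_high: float = 0.40
    # sequencing noise
    coverage: float = 10.0
    n_replicates: int = 2
    dispersion: float = 0.01  # beta-binomial intraclass correlation
    lambda_nc: float = 0.005
    # accessibility
    accessibility_strength: float = 0.05  # expected fragments per bp
    bg_frag_rate: float = 2e-6
    sub100_frac: float = 0.85
    peak_jitter: int = 50
    # expression
    expr_fold: float = 5.0
    tpm_floor: float = 30.0
    # k-mer sequences
    n_kmer_pos: int = 500
    kmer_seq_len: int = 500
    kmer_gc: float = 0.45
    motifs_per_pos: int = 2  # planted motif instances per positive (>= 1)
    pwm: np.ndarray = field(default_factory=default_pwm)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "n_promoter_umr", "n_enhancer_rodlike", "n_enhancer_conelike",
            "n_dmv_tf", "n_background_regions",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def genome(self) -> GenomeSpec:
        return GenomeSpec(chrom_lengths=dict(self.chrom_lengths))

    def to_json(self) -> str:
        d = asdict(self)
        d["pwm"] = np.asarray(self.pwm).tolist()
        return json.dumps(d, indent=2)


class TruthTable:
    """Planted regions with per-profile true methylation levels and
    accessibility strengths.

    Columns: region_id, chrom, start, end, klass, owner, gene, plus
    level_<profile> and access_<profile> (relative accessibility strength,
    0 = closed) for every profile.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df.sort_values(["chrom", "start"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def regions(
        self, klass: str | None = None, owner: str | None = None,
        label: str | None = None,
    ) -> RegionSet:
        df = self.df
        if klass is not None:
            df = df[df["klass"] == klass]
        if owner is not None:
            df = df[df["owner"] == owner]
        return RegionSet(
            [
                GenomicInterval(r.chrom, int(r.start), int(r.end), name=r.region_id)
                for r in df.itertuples()
            ],
            label=label or klass,
        )

    def hypo_regions(self, profile: str, level_cut: float = 0.5) -> RegionSet:
        df = self.df[self.df[f"level_{profile}"] < level_cut]
        return RegionSet(
            [
                GenomicInterval(r.chrom, int(r.start), int(r.end), name=r.region_id)
                for r in df.itertuples()
            ],
            label=f"{profile}_hypo",
        )

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t"))


def _place_regions(
    config: SimulationConfig, rng: np.random.Generator, specs: list[tuple[str, str, int]]
) -> list[tuple[str, str, str, int, int]]:
    """Place (klass, owner, length) specs without overlap, longest first.
    Returns (region_id, klass, owner, chrom start, end) tuples in placement
    order; ids number regions within each class."""
    chroms = sorted(config.chrom_lengths)
    weights = np.array([config.chrom_lengths[c] for c in chroms], float)
    weights /= weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    placed = []
    order = sorted(range(len(specs)), key=lambda i: -specs[i][2])
    import bisect

    for idx in order:
        klass, owner, L = specs[idx]
        ok = False
        for _ in range(2000):
            c = chroms[int(rng.choice(len(chroms), p=weights))]
            limit = config.chrom_lengths[c] - L - config.min_region_gap
            if limit <= config.min_region_gap:
                continue
            s = int(rng.integers(config.min_region_gap, limit))
            occ = occupied[c]
            k = bisect.bisect_right(occ, (s, s + L))
            pad = config.min_region_gap
            if k > 0 and occ[k - 1][1] + pad > s:
                continue
            if k < len(occ) and occ[k][0] < s + L + pad:
                continue
            occ.insert(k, (s, s + L))
            placed.append((idx, klass, owner, c, s, s + L))
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place region of class {klass} length {L} without overlap"
            )
    placed.sort(key=lambda t: t[0])
    counters: dict[str, int] = {}
    out = []
    for _, klass, owner, c, s, e in placed:
        counters[klass] = counters.get(klass, 0) + 1
        out.append((f"{klass.lower()}_{counters[klass]:04d}", klass, owner, c, s, e))
    return out


def build_truth(
    config: SimulationConfig,
) -> tuple[GenomeSpec, TruthTable, list[TssAnnotation]]:
    """Plant all region classes and derive per-profile true states.

    Level anchors: promoter UMRs at ``level_umr`` (0.06), enhancer LMR-type
    regions at ``level_lmr`` (0.24) in the cell type where active, background
    at ``level_background``. Vestigial enhancers are hypo-methylated yet
    closed in their owner cell type and fully methylated in the other parent;
    the fetal_like profile keeps them hypo-methylated and open. Deterministic
    per seed.
    """
    rng = np.random.default_rng([config.seed, _S_PLACE])
    specs: list[tuple[str, str, int]] = []
    specs += [(RegionClass.PROMOTER_UMR, "", config.promoter_len)] * config.n_promoter_umr
    n_vest_rod = int(round(config.n_enhancer_rodlike * config.vestigial_frac_rodlike))
    n_vest_cone = int(round(config.n_enhancer_conelike * config.vestigial_frac_conelike))
    specs += [
        (RegionClass.ACTIVE_ENHANCER, "rodlike", config.enhancer_len)
    ] * (config.n_enhancer_rodlike - n_vest_rod)
    specs += [(RegionClass.VESTIGIAL_ENHANCER, "rodlike", config.enhancer_len)] * n_vest_rod
    specs += [
        (RegionClass.ACTIVE_ENHANCER, "conelike", config.enhancer_len)
    ] * (config.n_enhancer_conelike - n_vest_cone)
    specs += [(RegionClass.VESTIGIAL_ENHANCER, "conelike", config.enhancer_len)] * n_vest_cone
    specs += [(RegionClass.DMV_TF_LOCUS, "", config.dmv_len)] * config.n_dmv_tf
    specs += [(RegionClass.BACKGROUND, "", config.background_len)] * config.n_background_regions
    placed = _place_regions(config, rng, specs)

    profiles = default_profiles()
    bg = config.level_background
    rows = []
    tss: list[TssAnnotation] = []
    n_dmv_seen = 0
    for region_id, klass, owner, chrom, start, end in placed:
        level: dict[str, float] = {}
        access: dict[str, float] = {}
        gene = ""
        if klass == RegionClass.PROMOTER_UMR:
            for name in PROFILE_NAMES:
                level[name] = config.level_umr
                access[name] = 1.0
            gene = f"gene_{region_id}"
            strand = "+" if rng.random() < 0.5 else "-"
            tss.append(TssAnnotation(gene, chrom, (start + end) // 2, strand))
        elif klass in (RegionClass.ACTIVE_ENHANCER, RegionClass.VESTIGIAL_ENHANCER):
            other = "conelike" if owner == "rodlike" else "rodlike"
            level[owner] = config.level_lmr
            level[other] = bg
            level["fetal_like"] = config.level_lmr
            level["cortexlike"] = bg
            open_in_owner = 1.0 if klass == RegionClass.ACTIVE_ENHANCER else 0.0
            access[owner] = open_in_owner
            access[other] = 0.0
            access["fetal_like"] = 1.0
            access["cortexlike"] = 0.0
            gene = f"gene_{region_id}"
            side = 1 if rng.random() < 0.5 else -1
            dist = int(rng.integers(2000, 30_000))
            pos = min(
                max(0, (start + end) // 2 + side * dist),
                config.chrom_lengths[chrom] - 1,
            )
            strand = "+" if rng.random() < 0.5 else "-"
            tss.append(TssAnnotation(gene, chrom, pos, strand))
        elif klass == RegionClass.DMV_TF_LOCUS:
            n_dmv_seen += 1
            differential = n_dmv_seen % 2 == 0
            level["rodlike"] = config.dmv_level_low
            level["conelike"] = config.dmv_level_high if differential else config.dmv_level_low
            level["fetal_like"] = config.dmv_level_low
            level["cortexlike"] = config.dmv_level_low
            for name in PROFILE_NAMES:
                access.setdefault(name, 1.0)
            gene = f"gene_{region_id}"
            tss.append(TssAnnotation(gene, chrom, (start + end) // 2, "+"))
        else:  # BACKGROUND
            for name in PROFILE_NAMES:
                level[name] = bg
                access[name] = 0.0
        mix = profiles["hybrid"].mixing or 0.5
        level["hybrid"] = mix * level["rodlike"] + (1 - mix) * level["conelike"]
        access["hybrid"] = mix * access["rodlike"] + (1 - mix) * access["conelike"]
        row = {
            "region_id": region_id, "chrom": chrom, "start": start, "end": end,
            "klass": klass, "owner": owner, "gene": gene,
        }
        for name in PROFILE_NAMES:
            row[f"level_{name}"] = level[name]
            row[f"access_{name}"] = access[name]
        rows.append(row)
    truth = TruthTable(pd.DataFrame(rows))
    return config.genome(), truth, tss


def _cpg_positions(config: SimulationConfig) -> dict[str, np.ndarray]:
    """1-based CpG coordinates shared by all samples (seeded by config only)."""
    rng = np.random.default_rng([config.seed, _S_CPG])
    out = {}
    for chrom in sorted(config.chrom_lengths):
        L = config.chrom_lengths[chrom]
        n_max = L // config.cpg_spacing_min + 2
        gaps = rng.integers(config.cpg_spacing_min, config.cpg_spacing_max + 1, n_max)
        pos = np.cumsum(gaps)
        out[chrom] = pos[pos <= L - 2].astype(np.int64)
    return out


def _ch_positions(config: SimulationConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng([config.seed, _S_CH])
    out = {}
    for chrom in sorted(config.chrom_lengths):
        L = config.chrom_lengths[chrom]
        n = max(1, L // config.ch_spacing)
        pos = np.sort(rng.choice(L - 2, size=n, replace=False)) + 1
        out[chrom] = pos.astype(np.int64)
    return out


def _site_levels(
    truth: TruthTable, profile_name: str, chrom: str, pos: np.ndarray, bg: float
) -> np.ndarray:
    df = truth.df[truth.df["chrom"] == chrom]
    starts = df["start"].to_numpy(np.int64)
    ends = df["end"].to_numpy(np.int64)
    levels = df[f"level_{profile_name}"].to_numpy(float)
    out = np.full(len(pos), bg, dtype=float)
    # 1-based pos p lies in [start, end) iff start < p <= end
    idx = np.searchsorted(starts, pos - 1, side="right") - 1
    ok = (idx >= 0) & (pos - 1 < ends[np.clip(idx, 0, None)])
    out[ok] = levels[idx[ok]]
    return out


def _betabinom_draw(
    rng: np.random.Generator, cov: np.ndarray, p: np.ndarray, rho: float
) -> np.ndarray:
    mc = np.zeros(len(cov), dtype=np.int64)
    has = cov > 0
    if rho < 1e-9:
        mc[has] = rng.binomial(cov[has], p[has])
        return mc
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    pp = np.zeros(len(cov))
    mid = (a > 0) & (b > 0)
    pp[mid] = rng.beta(a[mid], b[mid])
    pp[(a > 0) & (b <= 0)] = 1.0
    mc[has] = rng.binomial(cov[has], pp[has])
    return mc


def simulate_methylome(
    truth: TruthTable,
    profile: CellTypeProfile | str,
    config: SimulationConfig,
    replicate: int = 0,
) -> Methylome:
    """One replicate methylome: per-CpG Poisson coverage, beta-binomial counts
    around the region's true level inflated by bisulfite non-conversion, plus
    CH-context sites at the profile's mCH rate."""
    if isinstance(profile, str):
        profile = default_profiles()[profile]
    pid = _PROFILE_ID[profile.name]
    rng = np.random.default_rng([config.seed, _S_METH, pid, replicate])
    lam = config.lambda_nc
    frames = []
    cpg = _cpg_positions(config)
    ch = _ch_positions(config)
    for chrom in sorted(config.chrom_lengths):
        pos = cpg[chrom]
        lvl = _site_levels(truth, profile.name, chrom, pos, config.level_background)
        p_obs = lvl + (1 - lvl) * lam
        cov = rng.poisson(config.coverage, len(pos))
        mc = _betabinom_draw(rng, cov, p_obs, config.dispersion)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom, "pos": pos,
                    "strand": np.where(pos % 2 == 0, "+", "-"),
                    "context": "CG", "mc": mc, "cov": cov,
                }
            )
        )
        cpos = ch[chrom]
        p_ch = profile.mch_rate + (1 - profile.mch_rate) * lam
        ccov = rng.poisson(config.coverage, len(cpos))
        cmc = rng.binomial(ccov, p_ch)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom, "pos": cpos,
                    "strand": np.where(cpos % 2 == 0, "+", "-"),
                    "context": "CH", "mc": cmc, "cov": ccov,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    # CpG and CH streams may collide at a coordinate; keep the CpG record
    df = df.drop_duplicates(subset=["chrom", "pos", "strand"], keep="first")
    return Methylome(
        df, sample_label=f"{profile.name}_r{replicate}", lambda_nc=lam
    )


def simulate_accessibility(
    truth: TruthTable,
    profile: CellTypeProfile | str,
    config: SimulationConfig,
    replicate: int = 0,
) -> tuple[list[FragmentRecord], RegionSet]:
    """Fragments (Poisson counts proportional to strength x length, mixed
    sub-100-bp and longer lengths) plus the emitted peak set for open regions.
    Background fragments fall uniformly at a low rate."""
    if isinstance(profile, str):
        profile = default_profiles()[profile]
    pid = _PROFILE_ID[profile.name]
    rng = np.random.default_rng([config.seed, _S_ATAC, pid, replicate])
    frags: list[FragmentRecord] = []
    peaks: list[GenomicInterval] = []
    sample = f"{profile.name}_r{replicate}"
    for r in truth.df.itertuples():
        strength = getattr(r, f"access_{profile.name}") * config.accessibility_strength
        L = int(r.end - r.start)
        if strength > 0:
            n = rng.poisson(strength * L)
            for _ in range(n):
                if rng.random() < config.sub100_frac:
                    flen = int(rng.integers(40, 100))
                else:
                    flen = int(rng.integers(120, 181))
                s = int(rng.integers(r.start, max(r.start + 1, r.end - flen)))
                frags.append(FragmentRecord(r.chrom, s, s + flen, sample, replicate))
            if getattr(r, f"access_{profile.name}") >= 0.4:
                j1 = int(rng.integers(-config.peak_jitter, config.peak_jitter + 1))
                j2 = int(rng.integers(-config.peak_jitter, config.peak_jitter + 1))
                peaks.append(
                    GenomicInterval(
                        r.chrom, max(0, int(r.start) + j1), int(r.end) + j2,
                        name=r.region_id,
                    )
                )
    for chrom in sorted(config.chrom_lengths):
        L = config.chrom_lengths[chrom]
        n_bg = rng.poisson(config.bg_frag_rate * L)
        for _ in range(n_bg):
            flen = int(rng.integers(40, 100))
            s = int(rng.integers(0, L - flen))
            frags.append(FragmentRecord(chrom, s, s + flen, sample, replicate))
    frags.sort(key=lambda f: (f.chrom, f.start, f.end))
    return frags, RegionSet(peaks, label=sample)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


_COMP = str.maketrans("ACGT", "TGCA")


def _sample_motif(rng: np.random.Generator, pwm: np.ndarray) -> str:
    return "".join("ACGT"[rng.choice(4, p=row / row.sum())] for row in pwm)


def simulate_sequences(
    truth: TruthTable, config: SimulationConfig
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Motif-planted positive sequences and GC-matched negatives.

    Every positive carries at least one PWM-sampled motif instance (random
    position and strand); each negative matches its paired positive's length
    and observed GC content.
    """
    rng = np.random.default_rng([config.seed, _S_SEQ])
    pwm = np.asarray(config.pwm)
    w = pwm.shape[0]
    pos_out, neg_out = [], []
    for i in range(config.n_kmer_pos):
        seq = _random_seq(rng, config.kmer_seq_len, config.kmer_gc)
        for _ in range(max(1, config.motifs_per_pos)):
            motif = _sample_motif(rng, pwm)
            if rng.random() < 0.5:
                motif = motif.translate(_COMP)[::-1]
            at = int(rng.integers(0, config.kmer_seq_len - w + 1))
            seq = seq[:at] + motif + seq[at + w:]
        pos_out.append((f"pos_{i:05d}", seq))
        gc_obs = (seq.count("G") + seq.count("C")) / len(seq)
        neg_out.append((f"neg_{i:05d}", _random_seq(rng, len(seq), gc_obs)))
    return pos_out, neg_out


def simulate_expression(
    truth: TruthTable,
    profiles: dict[str, CellTypeProfile] | None = None,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """TPM table (genes x profiles). Genes owned by a cell type get at least
    ``expr_fold``-fold higher TPM there (with the expressed side >=
    ``tpm_floor``); genes near promoter UMRs or DMV loci are expressed in all
    profiles with |log2 ratio| < 0.5 jitter. Couples expression to planted
    hypo-methylation so the methylation-expression anti-correlation exists by
    construction."""
    assert config is not None, "config is required"
    profiles = profiles or default_profiles()
    rng = np.random.default_rng([config.seed, _S_EXPR])
    rows = {}
    for r in truth.df.itertuples():
        if not r.gene:
            continue
        if r.klass in (RegionClass.ACTIVE_ENHANCER, RegionClass.VESTIGIAL_ENHANCER):
            high = float(rng.uniform(4 * config.tpm_floor, 10 * config.tpm_floor))
            fold = float(rng.uniform(config.expr_fold + 1, 2.5 * config.expr_fold))
            low = high / fold
            other = "conelike" if r.owner == "rodlike" else "rodlike"
            tpm = {r.owner: high, other: low}
            tpm["hybrid"] = float(np.sqrt(high * low))
            tpm["fetal_like"] = float(np.sqrt(high * low))
            tpm["cortexlike"] = low
        else:  # promoter or DMV gene: broadly expressed, near-unit ratios
            base = float(rng.uniform(config.tpm_floor, 6 * config.tpm_floor))
            tpm = {
                name: base * 2 ** float(rng.uniform(-0.4, 0.4))
                for name in PROFILE_NAMES
            }
        rows[r.gene] = tpm
    return pd.DataFrame.from_dict(rows, orient="index").loc[
        :, list(PROFILE_NAMES)
    ].sort_index()


def log2_ratio(expr: pd.DataFrame, a: str, b: str) -> dict[str, float]:
    return dict(np.log2(expr[a] / expr[b]))


def emit_all(
    config: SimulationConfig,
    outdir: str | Path,
    profiles: Sequence[str] = ("rodlike", "conelike", "hybrid"),
) -> dict:
    """Generate and write every dataset for the requested profiles.

    Emits allc TSVs, fragment BEDs and peak narrowPeaks per (profile,
    replicate), truth and TSS tables, the expression table, FASTA sequence
    sets, and an echo of the configuration. Returns a manifest of paths.
    """
    from .accessibility import write_fragments_bed
    from .genomic import write_narrowpeak, write_tss
    from .methylome import write_allc

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth, tss = build_truth(config)
    manifest: dict = {"outdir": str(outdir), "samples": {}}
    truth.write_tsv(outdir / "truth.tsv")
    write_tss(tss, outdir / "tss.tsv")
    with open(outdir / "genome.tsv", "w") as fh:
        for c, L in sorted(genome.chrom_lengths.items()):
            fh.write(f"{c}\t{L}\n")
    all_profiles = default_profiles()
    for name in profiles:
        prof = all_profiles[name]
        for rep in range(config.n_replicates):
            m = simulate_methylome(truth, prof, config, rep)
            frags, peaks = simulate_accessibility(truth, prof, config, rep)
            tag = f"{name}_r{rep}"
            write_allc(m, outdir / f"allc_{tag}.tsv")
            write_fragments_bed(frags, outdir / f"fragments_{tag}.bed")
            write_narrowpeak(peaks, outdir / f"peaks_{tag}.narrowPeak")
            manifest["samples"][tag] = {
                "allc": f"allc_{tag}.tsv",
                "fragments": f"fragments_{tag}.bed",
                "peaks": f"peaks_{tag}.narrowPeak",
            }
    expr = simulate_expression(truth, all_profiles, config)
    expr.to_csv(outdir / "expression.tsv", sep="\t")
    pos, neg = simulate_sequences(truth, config)
    for fname, records in (("sequences_pos.fa", pos), ("sequences_neg.fa", neg)):
        with open(outdir / fname, "w") as fh:
            for name_, seq in records:
                fh.write(f">{name_}\n{seq}\n")
    with open(outdir / "config.json", "w") as fh:
        fh.write(config.to_json())
    manifest.update(
        truth="truth.tsv", tss="tss.tsv", expression="expression.tsv",
        sequences_pos="sequences_pos.fa", sequences_neg="sequences_neg.fa",
        config="config.json", genome="genome.tsv",
    )
    return manifest
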