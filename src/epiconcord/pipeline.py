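"""Config-driven orchestration: simulate -> segment -> dmr -> atac ->
concordance -> cluster -> kmer, with a JSON summary report.

Every random draw derives from the global seed through fixed per-stage
sub-seed offsets, so a re-run with the same config overwrites its outputs
deterministically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import accessibility as acc
from . import concordance as conc
from . import diffmeth, distance, kmer, segmentation, simulate
from .genomic import write_bed
from .methylome import pool_methylomes

log = logging.getLogger("epiconcord")

ALL_STAGES = ("simulate", "segment", "dmr", "atac", "concord", "cluster", "kmer")

# per-stage seed offsets layered on the global seed
_STAGE_SEED = {name: 1000 + i for i, name in enumerate(ALL_STAGES)}


@dataclass
class PipelineConfig:
    outdir: str = "epiconcord_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    profiles: tuple[str, ...] = ("rodlike", "conelike", "hybrid")
    sim: simulate.SimulationConfig | None = None
    seg_params: segmentation.SegmentationParams | None = None
    dmr_params: diffmeth.DmrParams | None = None
    acc_params: acc.AccessibilityParams | None = None
    ks_params: conc.KsParams | None = None
    cluster_params: distance.ClusterParams | None = None
    kmer_params: kmer.KmerParams | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.sim is None:
            self.sim = simulate.SimulationConfig(seed=self.seed)
        self.seg_params = self.seg_params or segmentation.SegmentationParams(
            seed=self.seed + _STAGE_SEED["segment"]
        )
        self.dmr_params = self.dmr_params or diffmeth.DmrParams()
        self.acc_params = self.acc_params or acc.AccessibilityParams()
        self.ks_params = self.ks_params or conc.KsParams(
            seed=self.seed + _STAGE_SEED["concord"]
        )
        self.cluster_params = self.cluster_params or distance.ClusterParams()
        self.kmer_params = self.kmer_params or kmer.KmerParams()


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order and return the report
    (also written to <outdir>/report.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": list(config.stages)}
    sim = config.sim

    # --- simulate (always needed as the data source) -----------------------
    log.info("simulate: seed=%d profiles=%s", config.seed, config.profiles)
    genome, truth, tss = simulate.build_truth(sim)
    profiles = simulate.default_profiles()
    methylomes: dict[str, list] = {}
    fragments: dict[str, list] = {}
    peaks: dict[str, object] = {}
    for name in config.profiles:
        methylomes[name] = [
            simulate.simulate_methylome(truth, profiles[name], sim, rep)
            for rep in range(sim.n_replicates)
        ]
        per_rep = [
            simulate.simulate_accessibility(truth, profiles[name], sim, rep)
            for rep in range(sim.n_replicates)
        ]
        fragments[name] = [f for f, _ in per_rep]
        peaks[name] = [p for _, p in per_rep]
    if "simulate" in config.stages:
        simulate.emit_all(sim, outdir / "simulated", profiles=config.profiles)
        report["simulate"] = {
            "n_planted_regions": len(truth),
            "n_cpg_sites": int(sum(len(v) for v in simulate._cpg_positions(sim).values())),
        }

    # --- segmentation ------------------------------------------------------
    segments: dict[str, list] = {}
    if {"segment", "dmr", "concord"} & set(config.stages):
        seg_report = {}
        for name in config.profiles:
            pooled = pool_methylomes(methylomes[name], sample_label=name)
            segs = segmentation.segment_hypomethylated(pooled, config.seg_params)
            segments[name] = segs
            dmvs = segmentation.call_dmv(segs)
            seg_report[name] = {
                "n_segments": len(segs),
                "n_umr": sum(1 for s in segs if s.klass == "UMR"),
                "n_lmr": sum(1 for s in segs if s.klass == "LMR"),
                "n_dmv": len(dmvs),
            }
            if "segment" in config.stages:
                segmentation.write_segments_bed(segs, outdir / f"segments_{name}.bed")
                write_bed(dmvs, outdir / f"dmv_{name}.bed")
            log.info("segment[%s]: %s", name, seg_report[name])
        if "segment" in config.stages:
            report["segment"] = seg_report

    # --- differential methylation -----------------------------------------
    if "dmr" in config.stages and len(config.profiles) >= 2:
        a_name, b_name = config.profiles[0], config.profiles[1]
        dms = diffmeth.call_dms(methylomes[a_name], methylomes[b_name], config.dmr_params)
        dmrs = diffmeth.join_dms_to_dmr(dms, config.dmr_params)
        n_hypo_a = sum(1 for d in dmrs if d.direction == "A<B")
        n_hypo_b = sum(1 for d in dmrs if d.direction == "A>B")
        report["dmr"] = {
            "comparison": f"{a_name}_vs_{b_name}",
            "n_sites_tested": len(dms),
            "n_sites_skipped": dms.n_skipped,
            "n_dms_significant": sum(1 for r in dms if r.significant),
            "n_dmr": len(dmrs),
            f"n_hypo_{a_name}": n_hypo_a,
            f"n_hypo_{b_name}": n_hypo_b,
        }
        write_bed(diffmeth.dmrs_to_regionset(dmrs), outdir / "dmrs.bed")
        log.info("dmr: %s", report["dmr"])

    # --- accessibility -----------------------------------------------------
    if "atac" in config.stages and len(config.profiles) >= 2:
        a_name, b_name = config.profiles[0], config.profiles[1]
        peak_sets = {
            (name, rep): peaks[name][rep]
            for name in (a_name, b_name)
            for rep in range(sim.n_replicates)
        }
        consensus = acc.consensus_peaks(peak_sets, config.acc_params)
        frags_by_sample = {}
        for name in (a_name, b_name):
            for rep in range(sim.n_replicates):
                frags_by_sample[f"{name}_r{rep}"] = acc.filter_short_fragments(
                    fragments[name][rep], config.acc_params
                )
        pc = acc.count_fragments_in_peaks(consensus, frags_by_sample)
        diff = acc.differential_peaks(
            pc,
            [f"{a_name}_r{r}" for r in range(sim.n_replicates)],
            [f"{b_name}_r{r}" for r in range(sim.n_replicates)],
            config.acc_params,
        )
        diff.to_csv(outdir / "differential_peaks.tsv", sep="\t", index=False)
        report["atac"] = {
            "n_consensus_peaks": len(consensus),
            "class_counts": diff["class"].value_counts().to_dict(),
        }
        log.info("atac: %s", report["atac"])

    # --- concordance -------------------------------------------------------
    if "concord" in config.stages:
        section = {}
        signals = {}
        for name in config.profiles:
            lmrs = segmentation.segments_to_regionset(
                segmentation.filter_max_length(segments[name]), label=name
            )
            frags = [f for rep in fragments[name] for f in rep]
            merged_peaks = acc.consensus_peaks(
                {(name, rep): peaks[name][rep] for rep in range(sim.n_replicates)},
                config.acc_params,
            )
            rep_ = conc.concordance_report(
                lmrs, merged_peaks, frags, max(1, len(frags)), config.acc_params
            )
            section[name] = rep_.to_dict()
            signals[name] = rep_.fpkm
            rep_.write_tsv(lmrs, outdir / f"concordance_{name}.tsv")
        if len(config.profiles) >= 2:
            a_name, b_name = config.profiles[0], config.profiles[1]
            d, pval = conc.bootstrap_ks(
                signals[a_name], signals[b_name], config.ks_params
            )
            section["ks"] = {"comparison": f"{a_name}_vs_{b_name}", "D": d, "p": pval}
        report["concord"] = section
        log.info("concord: %s", {k: v for k, v in section.items() if k == "ks"})

    # --- clustering --------------------------------------------------------
    if "cluster" in config.stages:
        flat_meth = [m for name in config.profiles for m in methylomes[name]]
        dm = distance.pearson_distance_matrix(flat_meth, config.cluster_params)
        cl = distance.hierarchical_cluster(dm, config.cluster_params)
        dm.write_tsv(outdir / "distance_pearson.tsv")
        flat_peaks = [p for name in config.profiles for p in peaks[name]]
        dj = distance.jaccard_distance_matrix(flat_peaks)
        cj = distance.hierarchical_cluster(dj, config.cluster_params)
        dj.write_tsv(outdir / "distance_jaccard.tsv")
        with open(outdir / "dendrograms.nwk", "w") as fh:
            fh.write(cl.newick + "\n" + cj.newick + "\n")
        report["cluster"] = {
            "pearson_leaf_order": cl.leaf_order,
            "jaccard_leaf_order": cj.leaf_order,
        }
        log.info("cluster: %s", report["cluster"])

    # --- k-mer model -------------------------------------------------------
    if "kmer" in config.stages:
        pos, neg = simulate.simulate_sequences(None, sim)
        n_test = max(10, len(pos) // 5)
        model = kmer.train(
            [s for _, s in pos[n_test:]],
            [s for _, s in neg[n_test:]],
            config.kmer_params,
            seed=config.seed + _STAGE_SEED["kmer"],
        )
        test_seqs = [s for _, s in pos[:n_test]] + [s for _, s in neg[:n_test]]
        labels = [True] * n_test + [False] * n_test
        scores = kmer.score_many(model, test_seqs)
        auc = kmer.auroc(scores, labels)
        model.save(outdir / "kmer_model.tsv")
        report["kmer"] = {
            "n_train_pos": model.n_pos,
            "n_train_neg": model.n_neg,
            "held_out_auroc": auc,
        }
        log.info("kmer: auROC=%.3f", auc)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
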