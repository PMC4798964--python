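# epiconcord

Toolkit for joint analysis of DNA methylation and chromatin accessibility in
contrasting cell types, built around the regulatory signatures of rod- and
cone-like photoreceptor epigenomes:

- **methylome segmentation** into un-methylated regions (UMRs), low-methylated
  regions (LMRs) and DNA methylation valleys (DMVs ≥ 5 kb, mean mCG ≤ 15%),
  with an FDR calibrated against coordinate-shuffled nulls (m = 0.5, 5% FDR);
- **differential methylation**: replicate-aware beta-binomial site tests
  (FDR < 0.01), block-joining of same-direction sites within 250 bp into DMRs
  (≥ 2 sites, opposite-direction blocks removed), group-specific hypo-DMR
  selection, per-DMV Fisher exact tests, and a methylation-vs-expression
  correlation profile in 1-kb bins around the TSS;
- **accessibility**: sub-100-bp fragment filtering, consensus peaks
  (minOverlap = 2), differential peaks (fold > 2, FDR < 0.01), per-region FPKM
  with an inaccessibility floor of 0.1 — the "vestigial enhancer" signature of
  hypo-methylated yet closed chromatin;
- **concordance statistics**: region/peak overlap fractions, bootstrap
  Kolmogorov–Smirnov tests (nboot = 1000), TSS-anchored DMR density matrices
  with window-50 vertical smoothing;
- **epigenomic distances**: 1 − Pearson r over 500-bp methylation bins and
  1 − Jaccard over peak sets, with deterministic hierarchical clustering and
  Newick export;
- **gapped k-mer sequence model** (l = 10, k = 6): explicit-feature linear
  scorer (score = Σ wᵢxᵢ), auROC, replicate-count expression discretization
  and top-decile enrichment;
- a **synthetic epigenome generator** that plants promoter UMRs, active and
  vestigial enhancers, DMV-bearing TF loci and background controls across
  rodlike/conelike parents, a 50/50 hybrid intermediate, a fetal-like state
  and a cortex-like outgroup — with beta-binomial count noise, bisulfite
  non-conversion, and a ground-truth table so every stage is verifiable by
  parameter recovery.

## Run the tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle equivalence
against brute-force implementations, segmentation/vestigial-fraction/DMR
recovery on seeded synthetic data, test calibration, clustering determinism,
k-mer model performance).

## CLI

One subcommand per stage, plus an end-to-end driver:

```bash
# full simulated pipeline with a summary report
epiconcord run-all --outdir out/ --seed 1

# emit a synthetic epigenome (allc TSVs, fragment BEDs, narrowPeaks, FASTA,
# expression table, ground truth)
epiconcord simulate --outdir sim/ --seed 1

# individual stages on files
epiconcord segment --allc sim/allc_rodlike_r0.tsv --allc sim/allc_rodlike_r1.tsv --out segs.bed
epiconcord dmr --group-a sim/allc_rodlike_r0.tsv --group-a sim/allc_rodlike_r1.tsv \
               --group-b sim/allc_conelike_r0.tsv --group-b sim/allc_conelike_r1.tsv --out dmrs.bed
epiconcord concord --regions segs.bed --peaks sim/peaks_rodlike_r0.narrowPeak \
                   --fragments sim/fragments_rodlike_r0.bed --out report.json
epiconcord cluster --allc rod=sim/allc_rodlike_r0.tsv --allc cone=sim/allc_conelike_r0.tsv --out dist.tsv
epiconcord kmer --pos sim/sequences_pos.fa --neg sim/sequences_neg.fa --model-out model.tsv
```

## Layout

```
src/epiconcord/
  genomic.py        intervals, BED/narrowPeak I/O, shuffling, FPKM, TSS distance
  methylome.py      per-cytosine model, allc I/O, levels, binning, non-conversion
  segmentation.py   UMR/LMR calling, DMVs, chromatin classification
  diffmeth.py       DMS tests, DMR joining, Fisher tests, expression correlation
  accessibility.py  fragments, consensus peaks, differential peaks
  concordance.py    overlap/inaccessibility reports, bootstrap KS, TSS density
  distance.py       1-r / 1-Jaccard matrices, hierarchical clustering
  kmer.py           gapped k-mer featurizer, linear model, auROC, enrichment
  simulate.py       synthetic epigenome generator + ground truth
  pipeline.py       stage orchestration and reporting
  cli.py            click CLI
```

## Conventions

Interval coordinates are 0-based half-open (BED); cytosine positions are
1-based (allc) and converted at the I/O boundary. All randomness flows from
explicit seeds; identical configs reproduce byte-identical outputs.
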