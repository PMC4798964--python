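import numpy as np
import pandas as pd
import pytest

from epiconcord import simulate
from epiconcord.genomic import GenomicInterval
from epiconcord.methylome import global_levels, pool_methylomes, region_meth_level
from epiconcord.simulate import (
    RegionClass,
    SimulationConfig,
    build_truth,
    default_profiles,
    simulate_accessibility,
    simulate_expression,
    simulate_methylome,
    simulate_sequences,
)


def small_config(seed=3, **kw):
    defaults = dict(
        chrom_lengths={"chr1": 600_000, "chr2": 600_000},
        n_promoter_umr=8,
        n_enhancer_rodlike=20,
        n_enhancer_conelike=20,
        n_dmv_tf=2,
        n_background_regions=6,
        n_kmer_pos=40,
        kmer_seq_len=120,
    )
    defaults.update(kw)
    return SimulationConfig(seed=seed, **defaults)


class TestBuildTruth:
    def test_determinism(self):
        _, t1, tss1 = build_truth(small_config())
        _, t2, tss2 = build_truth(small_config())
        pd.testing.assert_frame_equal(t1.df, t2.df)
        assert tss1 == tss2

    def test_requested_counts_exact(self):
        cfg = small_config(vestigial_frac_rodlike=0.30)
        _, truth, _ = build_truth(cfg)
        vest_rod = truth.df[
            (truth.df["klass"] == RegionClass.VESTIGIAL_ENHANCER)
            & (truth.df["owner"] == "rodlike")
        ]
        assert len(vest_rod) == round(20 * 0.30)
        assert (truth.df["klass"] == RegionClass.PROMOTER_UMR).sum() == 8

    def test_planted_regions_disjoint(self):
        _, truth, _ = build_truth(small_config())
        df = truth.df.sort_values(["chrom", "start"])
        for c, sub in df.groupby("chrom"):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            assert np.all(starts[1:] >= ends[:-1])

    def test_level_anchors(self):
        _, truth, _ = build_truth(small_config())
        prom = truth.df[truth.df["klass"] == RegionClass.PROMOTER_UMR].iloc[0]
        assert prom["level_rodlike"] == pytest.approx(0.06)
        enh = truth.df[
            (truth.df["klass"] == RegionClass.ACTIVE_ENHANCER)
            & (truth.df["owner"] == "rodlike")
        ].iloc[0]
        assert enh["level_rodlike"] == pytest.approx(0.24)
        assert enh["level_conelike"] == pytest.approx(0.80)

    def test_vestigial_state_contract(self):
        _, truth, _ = build_truth(small_config(vestigial_frac_rodlike=0.5))
        vest = truth.df[
            (truth.df["klass"] == RegionClass.VESTIGIAL_ENHANCER)
            & (truth.df["owner"] == "rodlike")
        ]
        # hypo-methylated yet closed in the owner; methylated in the other parent
        assert (vest["level_rodlike"] < 0.5).all()
        assert (vest["access_rodlike"] == 0).all()
        assert (vest["level_conelike"] > 0.5).all()
        # fetal-like state keeps them hypo-methylated and open
        assert (vest["level_fetal_like"] < 0.5).all()
        assert (vest["access_fetal_like"] == 1).all()

    def test_hybrid_is_convex_combination(self):
        _, truth, _ = build_truth(small_config())
        lv = truth.df[["level_rodlike", "level_conelike", "level_hybrid"]].to_numpy()
        assert np.allclose(lv[:, 2], 0.5 * lv[:, 0] + 0.5 * lv[:, 1])


class TestSimulateMethylome:
    def test_reproducible_per_seed(self):
        cfg = small_config()
        _, truth, _ = build_truth(cfg)
        m1 = simulate_methylome(truth, "rodlike", cfg, 0)
        m2 = simulate_methylome(truth, "rodlike", cfg, 0)
        pd.testing.assert_frame_equal(m1.df, m2.df)

    def test_replicates_differ_same_expectation(self):
        cfg = small_config(coverage=20)
        _, truth, _ = build_truth(cfg)
        m0 = simulate_methylome(truth, "rodlike", cfg, 0)
        m1 = simulate_methylome(truth, "rodlike", cfg, 1)
        assert not m0.df["mc"].equals(m1.df["mc"])
        g0, g1 = global_levels(m0), global_levels(m1)
        assert abs(g0.mcg - g1.mcg) < 0.01

    def test_level_recovery_high_depth(self):
        # depth high enough that 3 SE < 0.01 even for ~14-CpG regions
        cfg = small_config(coverage=1000, dispersion=1e-8, lambda_nc=0.0)
        _, truth, _ = build_truth(cfg)
        m = simulate_methylome(truth, "rodlike", cfg, 0)
        for r in truth.df.head(8).itertuples():
            iv = GenomicInterval(r.chrom, int(r.start), int(r.end))
            est = region_meth_level(m, iv)
            assert abs(est - getattr(r, "level_rodlike")) < 0.01

    def test_mch_rate_zero_leaves_lambda_only(self):
        cfg = small_config(lambda_nc=0.004)
        _, truth, _ = build_truth(cfg)
        profiles = default_profiles()
        profiles["rodlike"].mch_rate = 0.0
        m = simulate_methylome(truth, profiles["rodlike"], cfg, 0)
        ch = m.df[m.df["context"] == "CH"]
        raw = ch["mc"].sum() / ch["cov"].sum()
        assert abs(raw - 0.004) < 0.002
        assert global_levels(m).mch < 0.002  # ~0 after adjustment


class TestSimulateAccessibility:
    def test_vestigial_low_fpkm(self):
        cfg = small_config(vestigial_frac_rodlike=0.5)
        _, truth, _ = build_truth(cfg)
        frags, peaks = simulate_accessibility(truth, "rodlike", cfg, 0)
        from epiconcord.concordance import concordance_report

        vest = truth.regions(RegionClass.VESTIGIAL_ENHANCER, owner="rodlike")
        rep = concordance_report(vest, peaks, frags, max(1, len(frags)))
        assert rep.fraction_inaccessible >= 0.9

    def test_zero_strength_only_background(self):
        cfg = small_config(accessibility_strength=0.0, bg_frag_rate=0.0)
        _, truth, _ = build_truth(cfg)
        frags, peaks = simulate_accessibility(truth, "rodlike", cfg, 0)
        assert frags == []

    def test_strength_scaling(self):
        cfg1 = small_config(bg_frag_rate=0.0)
        cfg2 = small_config(bg_frag_rate=0.0, accessibility_strength=0.1)
        _, truth1, _ = build_truth(cfg1)
        _, truth2, _ = build_truth(cfg2)
        f1, _ = simulate_accessibility(truth1, "rodlike", cfg1, 0)
        f2, _ = simulate_accessibility(truth2, "rodlike", cfg2, 0)
        assert len(f2) / len(f1) == pytest.approx(2.0, rel=0.2)


class TestSimulateSequences:
    def test_fixed_motif_always_present(self):
        pwm = np.zeros((8, 4))
        consensus = "TGACGTCA"
        for i, b in enumerate(consensus):
            pwm[i, "ACGT".index(b)] = 1.0
        cfg = small_config(pwm=pwm, motifs_per_pos=1)
        _, truth, _ = build_truth(cfg)
        pos, neg = simulate_sequences(truth, cfg)
        rc = consensus.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert all(consensus in s or rc in s for _, s in pos)

    def test_gc_matched(self):
        cfg = small_config()
        _, truth, _ = build_truth(cfg)
        pos, neg = simulate_sequences(truth, cfg)

        def gc(s):
            return (s.count("G") + s.count("C")) / len(s)

        mean_pos = np.mean([gc(s) for _, s in pos])
        mean_neg = np.mean([gc(s) for _, s in neg])
        assert abs(mean_pos - mean_neg) < 0.02

    def test_pwm_scan_oracle(self):
        cfg = small_config(n_kmer_pos=200, kmer_seq_len=300)
        _, truth, _ = build_truth(cfg)
        pos, _ = simulate_sequences(truth, cfg)
        pwm = np.asarray(cfg.pwm)
        logodds = np.log(pwm / 0.25)
        rc_logodds = logodds[::-1, ::-1]
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}

        def best(seq):
            enc = np.array([idx[c] for c in seq])
            w = pwm.shape[0]
            m = -np.inf
            for i in range(len(enc) - w + 1):
                win = enc[i: i + w]
                m = max(
                    m,
                    float(logodds[np.arange(w), win].sum()),
                    float(rc_logodds[np.arange(w), win].sum()),
                )
            return m

        hits = sum(best(s) > 3.0 for _, s in pos)
        assert hits / len(pos) >= 0.99


class TestSimulateExpression:
    def test_owner_fold_and_floor(self):
        cfg = small_config()
        _, truth, _ = build_truth(cfg)
        expr = simulate_expression(truth, config=cfg)
        enh = truth.df[truth.df["klass"] == RegionClass.ACTIVE_ENHANCER]
        for r in enh.itertuples():
            other = "conelike" if r.owner == "rodlike" else "rodlike"
            assert expr.loc[r.gene, r.owner] / expr.loc[r.gene, other] >= 5.0
            assert expr.loc[r.gene, r.owner] >= 30.0

    def test_unflagged_near_unity(self):
        cfg = small_config()
        _, truth, _ = build_truth(cfg)
        expr = simulate_expression(truth, config=cfg)
        prom = truth.df[truth.df["klass"] == RegionClass.PROMOTER_UMR]
        for r in prom.itertuples():
            ratio = np.log2(expr.loc[r.gene, "rodlike"] / expr.loc[r.gene, "conelike"])
            assert abs(ratio) < 0.81

    def test_non_negative(self):
        cfg = small_config()
        _, truth, _ = build_truth(cfg)
        expr = simulate_expression(truth, config=cfg)
        assert (expr.to_numpy() >= 0).all()


class TestEmitAll:
    def test_byte_identical_re_emission(self, tmp_path):
        cfg = small_config(n_replicates=1)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate.emit_all(cfg, d1, profiles=("rodlike",))
        simulate.emit_all(cfg, d2, profiles=("rodlike",))
        for f in sorted(d1.iterdir()):
            assert (d2 / f.name).read_bytes() == f.read_bytes(), f.name

    def test_manifest_files_exist(self, tmp_path):
        cfg = small_config(n_replicates=1)
        manifest = simulate.emit_all(cfg, tmp_path / "out", profiles=("rodlike",))
        for key in ("truth", "tss", "expression", "config"):
            assert (tmp_path / "out" / manifest[key]).exists()
        for sample in manifest["samples"].values():
            for f in sample.values():
                assert (tmp_path / "out" / f).exists()
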