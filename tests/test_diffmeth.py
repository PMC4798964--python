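import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_methylome
from epiconcord.diffmeth import (
    DmrParams,
    DmrRecord,
    DmsRecord,
    call_dms,
    dmv_fisher_test,
    group_specific_hypo_dmr,
    join_dms_to_dmr,
    meth_expr_correlation_profile,
)
from epiconcord.genomic import GenomicInterval, RegionSet, TssAnnotation
from oracle_utils import brute_fisher_two_sided


def _dms(pos, direction, significant=True, chrom="chr1", la=None, lb=None):
    if la is None:
        la, lb = (0.1, 0.9) if direction == "A<B" else (0.9, 0.1)
    return DmsRecord(chrom, pos, la, lb, direction, 1e-6, 1e-4, significant)


class TestCallDms:
    def test_identical_counts_p_one(self):
        pos = np.arange(1, 500, 10)
        a = make_methylome(pos, np.full(len(pos), 0.5), cov=20, exact=True)
        res = call_dms([a], [a])
        assert all(r.p_value == 1.0 for r in res)
        assert not any(r.significant for r in res)

    def test_one_group_coverage_skipped(self):
        a = make_methylome([10, 20], [0.5, 0.5], cov=10, exact=True)
        b = make_methylome([10, 30], [0.5, 0.5], cov=10, exact=True)
        res = call_dms([a], [b])
        assert len(res) == 1
        assert res.n_skipped == 2

    def test_null_calibration_small(self):
        n = 3000
        pos = np.arange(1, n * 10, 10)
        groups = []
        for g in range(2):
            reps = [
                make_methylome(pos, np.full(n, 0.5), cov=20, seed=100 + 10 * g + r)
                for r in range(2)
            ]
            groups.append(reps)
        res = call_dms(groups[0], groups[1])
        frac = np.mean([r.significant for r in res])
        assert frac <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / n)

    def test_power_and_direction(self):
        n = 1000
        pos = np.arange(1, n * 10, 10)
        a = [make_methylome(pos, np.full(n, 0.8), cov=30, seed=s) for s in (1, 2)]
        b = [make_methylome(pos, np.full(n, 0.2), cov=30, seed=s) for s in (3, 4)]
        res = call_dms(a, b)
        hits = [r for r in res if r.significant]
        assert len(hits) / n >= 0.9
        assert all(r.direction == "A>B" for r in hits)

    def test_needs_replicates(self):
        with pytest.raises(ValueError):
            call_dms([], [make_methylome([10], [0.5], exact=True)])


class TestJoinDmsToDmr:
    def test_gap_rule_hand_trace(self):
        dms = [_dms(100, "A<B"), _dms(200, "A<B"), _dms(600, "A<B")]
        dmrs = join_dms_to_dmr(dms, DmrParams(max_gap=250, min_sites=2))
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.interval.start, d.interval.end) == (99, 200)
        assert d.n_sites == 2 and d.direction == "A<B"

    def test_opposite_direction_removal(self):
        dms = [_dms(100, "A<B"), _dms(150, "A>B"), _dms(200, "A<B")]
        assert join_dms_to_dmr(dms, DmrParams()) == []

    def test_single_site_insufficient(self):
        assert join_dms_to_dmr([_dms(100, "A<B")], DmrParams()) == []

    def test_gap_boundary_inclusive(self):
        dms = [_dms(100, "A<B"), _dms(350, "A<B")]
        assert len(join_dms_to_dmr(dms, DmrParams(max_gap=250))) == 1
        dms = [_dms(100, "A<B"), _dms(351, "A<B")]
        assert len(join_dms_to_dmr(dms, DmrParams(max_gap=250))) == 0

    def test_insignificant_sites_ignored(self):
        dms = [
            _dms(100, "A<B"), _dms(150, "A>B", significant=False), _dms(200, "A<B")
        ]
        assert len(join_dms_to_dmr(dms, DmrParams())) == 1

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        dms = [
            _dms(int(p), "A<B" if rng.random() < 0.7 else "A>B")
            for p in rng.choice(100_000, 200, replace=False)
        ]
        ref = join_dms_to_dmr(dms, DmrParams())
        shuffled = list(dms)
        rng.shuffle(shuffled)
        assert join_dms_to_dmr(shuffled, DmrParams()) == ref

    def test_no_opposite_site_inside_and_disjoint(self):
        rng = np.random.default_rng(5)
        dms = [
            _dms(int(p), "A<B" if rng.random() < 0.5 else "A>B")
            for p in np.sort(rng.choice(50_000, 300, replace=False))
        ]
        dmrs = join_dms_to_dmr(dms, DmrParams())
        for d in dmrs:
            for r in dms:
                if r.significant and r.direction != d.direction:
                    inside = d.interval.start < r.pos <= d.interval.end
                    assert not inside
        for direction in ("A<B", "A>B"):
            ivs = [d.interval for d in dmrs if d.direction == direction]
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start


class TestGroupSpecific:
    candidates = RegionSet.from_tuples([("chr1", 0, 100), ("chr1", 200, 300),
                                        ("chr1", 400, 500)])

    def test_paper_selection_logic(self):
        calls = {
            "rod": [True, True, True],
            "cone": [True, True, False],
            "ctx1": [False, True, False],
            "ctx2": [False, True, False],
        }
        out = group_specific_hypo_dmr(
            self.candidates, calls, ["rod", "cone"], ["ctx1", "ctx2"]
        )
        assert [(iv.start, iv.end) for iv in out] == [(0, 100)]

    def test_hypo_everywhere_excluded(self):
        calls = {s: [True, True, True] for s in ("rod", "cone", "ctx")}
        out = group_specific_hypo_dmr(self.candidates, calls, ["rod", "cone"], ["ctx"])
        assert len(out) == 0

    def test_missing_sample_errors(self):
        with pytest.raises(KeyError):
            group_specific_hypo_dmr(self.candidates, {"rod": [True] * 3}, ["rod"], ["cone"])


class TestDmvFisher:
    def test_identical_tables_not_significant(self):
        dmvs = RegionSet.from_tuples([("chr1", 0, 1000)])
        m = make_methylome([100, 200], [0.5, 0.5], cov=50, exact=True, label="a")
        m2 = make_methylome([100, 200], [0.5, 0.5], cov=50, exact=True, label="b")
        df = dmv_fisher_test(dmvs, [m, m2])
        assert df["p_value"].iloc[0] == pytest.approx(1.0)
        assert not df["significant"].iloc[0]

    def test_extreme_difference_significant_vs_oracle(self):
        p_pkg = stats.fisher_exact([[10, 90], [90, 10]])[1]
        p_oracle = brute_fisher_two_sided([[10, 90], [90, 10]])
        assert p_pkg == pytest.approx(p_oracle, rel=1e-8)
        assert p_pkg < 1e-10

        dmvs = RegionSet.from_tuples([("chr1", 0, 1000)])
        a = make_methylome([100], [0.1], cov=100, exact=True, label="a")
        b = make_methylome([100], [0.9], cov=100, exact=True, label="b")
        df = dmv_fisher_test(dmvs, [a, b])
        assert df["significant"].iloc[0]

    def test_doubling_counts_never_increases_p(self):
        for mc_a, mc_b in [(10, 30), (5, 20), (40, 60)]:
            p1 = stats.fisher_exact([[mc_a, 100 - mc_a], [mc_b, 100 - mc_b]])[1]
            p2 = stats.fisher_exact(
                [[2 * mc_a, 200 - 2 * mc_a], [2 * mc_b, 200 - 2 * mc_b]]
            )[1]
            assert p2 <= p1 + 1e-12

    def test_zero_coverage_skipped(self):
        dmvs = RegionSet.from_tuples([("chr1", 0, 50), ("chr1", 90, 300)])
        a = make_methylome([100], [0.5], cov=10, exact=True, label="a")
        b = make_methylome([100], [0.5], cov=10, exact=True, label="b")
        df = dmv_fisher_test(dmvs, [a, b])
        skipped = df[df["dmv_index"] == 0]
        assert skipped["skipped"].all()


class TestMethExprProfile:
    def _dmr(self, chrom, start, end, delta):
        la = 0.5 + delta / 2
        lb = 0.5 - delta / 2
        return DmrRecord(GenomicInterval(chrom, start, end), "A>B" if delta > 0 else "A<B", 3, la, lb)

    def test_perfect_anticorrelation(self):
        rng = np.random.default_rng(1)
        dmrs, expr = [], {}
        genes = []
        for i in range(30):
            g = f"g{i}"
            pos = 500_000 + i * 250_000
            genes.append(TssAnnotation(g, "chr1", pos, "+"))
            delta = float(rng.uniform(-0.6, 0.6))
            start = pos + 3500
            dmrs.append(self._dmr("chr1", start, start + 60, delta))
            expr[g] = -delta
        prof = meth_expr_correlation_profile(dmrs, genes, expr)
        populated = ~np.isnan(prof.r)
        assert populated.any()
        assert np.allclose(prof.r[populated], -1.0)

    def test_bin_occupancy_minimum(self):
        tss = [TssAnnotation("g", "chr1", 100_000, "+")]
        dmrs = [self._dmr("chr1", 103_000, 103_100, 0.2),
                self._dmr("chr1", 103_200, 103_300, -0.1)]
        prof = meth_expr_correlation_profile(dmrs, tss, {"g": 1.0})
        assert np.isnan(prof.r).all()  # never >= 3 DMRs per bin

    def test_missing_gene_dropped(self):
        tss = [TssAnnotation("g", "chr1", 100_000, "+")]
        dmrs = [self._dmr("chr1", 103_000, 103_100, 0.2)]
        prof = meth_expr_correlation_profile(dmrs, tss, {})
        assert prof.n_dropped == 1

    def test_permutation_null(self):
        rng = np.random.default_rng(2)
        genes, dmrs, expr = [], [], {}
        for i in range(200):
            g = f"g{i}"
            pos = 200_000 + i * 40_000
            genes.append(TssAnnotation(g, "chr1", pos, "+"))
            start = pos + int(rng.integers(-20_000, 20_000))
            dmrs.append(self._dmr("chr1", start, start + 80, float(rng.uniform(-0.5, 0.5))))
            expr[g] = float(rng.normal())
        vals = list(expr.values())
        mean_abs = []
        for _ in range(100):
            rng.shuffle(vals)
            perm = dict(zip(expr.keys(), vals))
            prof = meth_expr_correlation_profile(dmrs, genes, perm)
            ok = ~np.isnan(prof.r)
            if ok.any():
                mean_abs.append(np.nanmean(np.abs(prof.r[ok])))
        # weak correlations in expectation under permutation
        assert np.mean(mean_abs) < 0.45

    def test_strand_orientation(self):
        # DMR 4 kb 3' of a minus-strand TSS has positive (downstream) offset
        tss = [TssAnnotation("g", "chr1", 100_000, "-")]
        dmrs = [self._dmr("chr1", 95_950, 96_050, 0.1)] * 3
        prof = meth_expr_correlation_profile(dmrs, tss, {"g": 1.0})
        bin_idx = np.flatnonzero(prof.n)
        assert len(bin_idx) == 1
        assert prof.bin_offsets[bin_idx[0]] == 4000
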