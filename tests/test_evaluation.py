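import dataclasses

import numpy as np
import pytest
from conftest import naive_fdr, naive_recall
from hypothesis import given, settings
from hypothesis import strategies as st

from cnasim import (CallRecord, LrrModel, SampleConfig, SampleTruth,
                    SignalTrack, TruthRegion, build_pattern_detailed,
                    estimate_contraction, fdr_matrix, recall_table,
                    region_recalled)


def region(start_bp, end_bp, cn=3, loh="none", chrom="chr1",
           cns=None, fractions=(1.0,)):
    cns = cns if cns is not None else (cn,)
    n_snps = (end_bp - start_bp) // 5000
    return TruthRegion(chrom=chrom, snp_start=start_bp // 5000,
                       snp_end=end_bp // 5000, start_bp=start_bp,
                       end_bp=end_bp, cns=cns, fractions=fractions,
                       loh_status=loh, n_snps=n_snps)


class TestRegionRecalled:
    def test_sixty_percent_overlap(self):
        t = region(100_000, 200_000, cn=3)
        call = CallRecord("chr1", 140_000, 260_000, 3)
        assert region_recalled(t, [call])

    def test_copy_number_mismatch(self):
        t = region(100_000, 200_000, cn=3)
        call = CallRecord("chr1", 140_000, 260_000, 4)
        assert not region_recalled(t, [call])

    def test_no_pooling_of_partial_calls(self):
        t = region(100_000, 200_000, cn=3)
        calls = [CallRecord("chr1", 100_000, 140_000, 3),   # 40%
                 CallRecord("chr1", 160_000, 190_000, 3)]   # 30%
        assert not region_recalled(t, calls)

    def test_exact_half_counts(self):
        t = region(0, 100_000, cn=3)
        call = CallRecord("chr1", 50_000, 200_000, 3)
        assert region_recalled(t, [call])

    def test_chromosome_must_match(self):
        t = region(0, 100_000, cn=3, chrom="chr2")
        assert not region_recalled(t, [CallRecord("chr1", 0, 100_000, 3)])

    def test_loh_matching_ignores_germline_vs_somatic(self):
        t = region(0, 100_000, cn=2, loh="germline")
        call = CallRecord("chr1", 0, 100_000, 2, loh="somatic")
        assert region_recalled(t, [call], require_loh=True)
        bare = CallRecord("chr1", 0, 100_000, 2, loh="none")
        assert not region_recalled(t, [bare], require_loh=True)

    def test_major_subclone_cn_used_for_complex(self):
        t = region(0, 100_000, cns=(0, 3, 4), fractions=(0.25, 0.5, 0.25))
        assert region_recalled(t, [CallRecord("chr1", 0, 100_000, 3)])
        assert not region_recalled(t, [CallRecord("chr1", 0, 100_000, 4)])

    def test_monotone_in_min_overlap(self):
        t = region(0, 100_000, cn=3)
        call = CallRecord("chr1", 30_000, 100_000, 3)  # 70% overlap
        assert region_recalled(t, [call], min_overlap=0.5)
        assert region_recalled(t, [call], min_overlap=0.7)
        assert not region_recalled(t, [call], min_overlap=0.8)


def truth_of(regions):
    n = sum(r.n_snps for r in regions)
    return SampleTruth(regions=regions, dna_index=1.0, shift=0.0,
                       contamination=0.25, n_snps=n)


def tiling(specs):
    """specs: list of (n_snps, cn, loh); returns tiled chr1 regions."""
    out, pos = [], 0
    for n, cn, loh in specs:
        out.append(region(pos * 5000, (pos + n) * 5000, cn=cn, loh=loh))
        pos += n
    return out


class TestRecallTable:
    def test_perfect_calls(self):
        regions = tiling([(20, 3, "none"), (30, 1, "somatic"),
                          (10, 2, "none"), (40, 4, "none")])
        calls = [CallRecord(r.chrom, r.start_bp, r.end_bp, r.cns[0],
                            r.loh_status) for r in regions]
        tbl = recall_table([truth_of(regions)], [calls],
                           group_by=("copy_number",))
        assert np.all(tbl["recall"] == 1.0)
        # diploid-het truth is excluded entirely
        assert 2 not in set(tbl["copy_number"])
        assert tbl["n_truth"].sum() == 3

    def test_no_calls(self):
        regions = tiling([(20, 3, "none"), (30, 1, "somatic")])
        tbl = recall_table([truth_of(regions)], [[]],
                           group_by=("copy_number",))
        assert np.all(tbl["recall"] == 0.0)
        assert tbl["n_truth"].sum() == 2

    def test_seven_of_ten(self):
        regions = tiling([(20, 3, "none")] * 10)
        calls = [CallRecord("chr1", r.start_bp, r.end_bp, 3)
                 for r in regions[:7]]
        tbl = recall_table([truth_of(regions)], [calls],
                           group_by=("copy_number",))
        assert tbl.loc[0, "recall"] == pytest.approx(0.7)

    def test_diploid_calls_excluded(self):
        # a CN2 no-LOH call overlapping a CN2-LOH truth region must not count
        regions = tiling([(20, 2, "somatic")])
        calls = [CallRecord("chr1", 0, 100_000, 2, "none")]
        tbl = recall_table([truth_of(regions)], [calls],
                           group_by=("copy_number",))
        assert tbl.loc[0, "recall"] == 0.0

    def test_grouping_by_length_and_loh(self):
        regions = tiling([(10, 3, "none"), (160, 3, "somatic")])
        calls = [CallRecord("chr1", r.start_bp, r.end_bp, 3) for r in regions]
        tbl = recall_table([truth_of(regions)], [calls],
                           group_by=("length_bin", "loh"))
        assert set(tbl["length_bin"]) == {10, 160}
        assert set(tbl["loh"]) == {True, False}

    def test_empty_cells_absent_not_zero(self):
        regions = tiling([(20, 3, "none")])
        tbl = recall_table([truth_of(regions)], [[]], group_by=("copy_number",))
        assert list(tbl["copy_number"]) == [3]


class TestFdrMatrix:
    def test_all_correct(self):
        regions = tiling([(20, 3, "none"), (30, 4, "none")])
        calls = [CallRecord("chr1", r.start_bp, r.end_bp, r.cns[0])
                 for r in regions]
        fdr = fdr_matrix(truth_of(regions), calls)
        assert fdr.total_fdr == 0.0
        assert fdr.n_calls == 2

    def test_one_in_four_wrong(self):
        regions = tiling([(20, 3, "none")] * 4)
        calls = [CallRecord("chr1", r.start_bp, r.end_bp, 3) for r in regions]
        calls[0] = dataclasses.replace(calls[0], copy_number=4)
        fdr = fdr_matrix(truth_of(regions), calls)
        assert fdr.total_fdr == pytest.approx(0.25)
        assert fdr.matrix.loc[4, 3] == pytest.approx(0.25)

    def test_superdiagonal_bias(self):
        # a caller reporting CN+1 everywhere puts all mass one off-diagonal
        # (no CN1 truth here: its CN2 call would be dropped as diploid)
        regions = tiling([(20, 3, "none"), (20, 4, "none")])
        calls = [CallRecord("chr1", r.start_bp, r.end_bp, r.cns[0] + 1)
                 for r in regions]
        fdr = fdr_matrix(truth_of(regions), calls)
        assert fdr.total_fdr == 1.0
        for r in regions:
            assert fdr.matrix.loc[r.cns[0] + 1, r.cns[0]] > 0

    def test_orphan_call_counted_wrong(self):
        regions = tiling([(20, 3, "none")])
        calls = [CallRecord("chr2", 0, 1000, 3)]
        fdr = fdr_matrix(truth_of(regions), calls)
        assert fdr.total_fdr == 1.0
        assert fdr.matrix.loc[3, -1] == 1.0

    def test_total_is_offdiagonal_sum(self):
        rng = np.random.default_rng(0)
        regions = tiling([(20, int(cn), "none")
                          for cn in rng.integers(1, 6, size=12)])
        calls = [CallRecord("chr1", r.start_bp, r.end_bp,
                            int(rng.integers(1, 6))) for r in regions]
        fdr = fdr_matrix(truth_of(regions), calls)
        off = sum(float(fdr.matrix.loc[i, j])
                  for i in fdr.matrix.index for j in fdr.matrix.columns
                  if i != j)
        assert fdr.total_fdr == pytest.approx(off)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_random_fixtures_match_naive(self, seed):
        rng = np.random.default_rng(seed)
        n_reg = int(rng.integers(3, 20))
        specs = [(int(rng.choice([10, 20, 40])),
                  int(rng.integers(1, 6)),
                  str(rng.choice(["none", "somatic", "germline"])))
                 for _ in range(n_reg)]
        regions = tiling(specs)
        calls = []
        for r in regions:
            if rng.random() < 0.75:
                jitter = int(rng.integers(0, r.end_bp - r.start_bp))
                calls.append(CallRecord(
                    "chr1", r.start_bp + jitter - 20_000,
                    max(r.end_bp - jitter, r.start_bp + jitter - 10_000),
                    int(rng.integers(1, 6)),
                    str(rng.choice(["none", "somatic", "unspecified"]))))
        calls = [c for c in calls if c.end > c.start and c.start >= 0]
        truth = truth_of(regions)

        tbl = recall_table([truth], [calls], group_by=())
        got = (int(tbl["n_recalled"].sum()), int(tbl["n_truth"].sum())) \
            if len(tbl) else (0, 0)
        exp = naive_recall(regions, calls)
        if exp[1] == 0:
            assert got == (0, 0) or len(tbl) == 0
        else:
            assert got == exp

        fdr = fdr_matrix(truth, calls)
        exp_fdr, exp_n = naive_fdr(regions, calls)
        assert fdr.n_calls == exp_n
        assert fdr.total_fdr == pytest.approx(exp_fdr)


@settings(max_examples=40, deadline=None)
@given(st.integers(min_value=0, max_value=10_000),
       st.floats(min_value=0.1, max_value=0.5),
       st.floats(min_value=0.5, max_value=1.0))
def test_recall_monotone_in_min_overlap(seed, lo, hi):
    rng = np.random.default_rng(seed)
    t = region(0, 100_000, cn=3)
    calls = [CallRecord("chr1", int(rng.integers(0, 90_000)),
                        int(rng.integers(95_000, 200_000)), 3)
             for _ in range(3)]
    if region_recalled(t, calls, min_overlap=hi):
        assert region_recalled(t, calls, min_overlap=lo)


class TestEstimateContraction:
    @staticmethod
    def sweep(contaminations, seed=0):
        cfg = SampleConfig().zero_noise()
        out = []
        for w1 in contaminations:
            res = build_pattern_detailed("near_triploid", w1, seed=seed,
                                         config=cfg)
            out.append((res.truth, res.track, w1))
        return out, cfg.lrr

    def test_pure_sample_q_is_one(self):
        samples, model = self.sweep([0.0, 0.5])
        fit = estimate_contraction(samples, model)
        assert fit.q[0] == pytest.approx(1.0, abs=1e-9)

    def test_half_contamination_q_half(self):
        samples, model = self.sweep([0.0, 0.5])
        fit = estimate_contraction(samples, model)
        assert fit.q[1] == pytest.approx(0.5, abs=1e-9)

    def test_sweep_slope_and_r2(self):
        samples, model = self.sweep([0.0, 0.25, 0.5, 0.75])
        fit = estimate_contraction(samples, model)
        assert fit.slope == pytest.approx(1.0, abs=1e-6)
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)
        assert fit.r_squared > 0.99

    def test_degenerate_regression_rejected(self):
        regions = tiling([(20, 2, "none"), (30, 2, "none")])
        truth = truth_of(regions)
        track = SignalTrack(lrr=np.zeros(50), baf=np.full(50, 0.5))
        with pytest.raises(ValueError, match="degenerate|distinct"):
            estimate_contraction([(truth, track, 0.0), (truth, track, 0.5)],
                                 LrrModel())
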