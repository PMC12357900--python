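"""Tests for MFI normalisation, fingerprints, N:C summaries, TSS windows
and ROUT outlier removal."""

import numpy as np
import pandas as pd
import pytest

from nfkb_crosstalk import (FlowSample, PeakRecord, TssRecord,
                            ValidationError, mfi_fold_change,
                            nc_ratio_summary, normalize_mfi, rout_outliers,
                            tss_window_scores, zscore_fingerprint)
from nfkb_crosstalk.synth import FlowSpec, gen_flow_sample, gen_nc_ratios


def flow(values, marker="RelA", sample_id="s"):
    return FlowSample(sample_id=sample_id, marker=marker,
                      values=np.asarray(values, dtype=float))


class TestNormalizeMfi:
    def test_identical_samples_give_one(self):
        s = flow([10, 20, 30])
        assert normalize_mfi(s, s) == 1.0

    def test_direct_arithmetic(self):
        stained = flow(np.full(101, 5000.0))
        unstained = flow(np.full(101, 250.0))
        assert normalize_mfi(stained, unstained) == 20.0

    def test_marker_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            normalize_mfi(flow([1], marker="RelA"), flow([1], marker="RelB"))

    def test_nonpositive_values_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            flow([0.0, 1.0])


class TestFingerprint:
    def make_pair(self, n=2000, seed=0, shift=1.0):
        rng = np.random.default_rng(seed)
        x = 10 ** rng.normal(3.0, 0.3, n) * shift
        y = 10 ** rng.normal(2.5, 0.3, n)
        return (flow(x, "RelA"), flow(y, "RelB"))

    def test_self_reference_standardises_to_unit_moments(self):
        pair = self.make_pair()
        fp = zscore_fingerprint([pair])
        for col in ("z_x", "z_y"):
            assert fp.z[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert fp.z[col].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_density_integrates_to_one(self):
        fp = zscore_fingerprint([self.make_pair()])
        cell = (fp.x_grid[0, 1] - fp.x_grid[0, 0]) ** 2
        assert fp.density.sum() * cell == pytest.approx(1.0, abs=1e-6)
        assert np.all(fp.density >= 0)

    def test_scaling_one_marker_shifts_only_its_z(self):
        pair = self.make_pair(seed=1)
        ref = (pair[0].values, pair[1].values)
        base = zscore_fingerprint([pair], reference=ref)
        shifted_pair = (flow(pair[0].values * 10, "RelA"), pair[1])
        shifted = zscore_fingerprint([shifted_pair], reference=ref)
        sd_ref = np.log10(pair[0].values).std(ddof=0)
        dx = (shifted.sample_medians["s"][0] - base.sample_medians["s"][0])
        assert dx == pytest.approx(1.0 / sd_ref, rel=1e-9)
        assert shifted.sample_medians["s"][1] == pytest.approx(
            base.sample_medians["s"][1])

    def test_common_positive_scale_is_invariant(self):
        pair = self.make_pair(seed=2)
        fp1 = zscore_fingerprint([pair])
        scaled = (flow(pair[0].values * 7.3, "RelA"),
                  flow(pair[1].values * 7.3, "RelB"))
        fp2 = zscore_fingerprint([scaled])
        assert np.allclose(fp1.z[["z_x", "z_y"]], fp2.z[["z_x", "z_y"]],
                           atol=1e-9)

    def test_planted_relb_ordering_recovered(self):
        lo_a, _, _ = gen_flow_sample(FlowSpec(marker="RelA", n=3000, seed=3,
                                              sample_id="lineLo"))
        lo_b, _, _ = gen_flow_sample(FlowSpec(
            marker="RelB", log10_medians=(2.5,), n=3000, seed=4,
            sample_id="lineLo"))
        hi_a, _, _ = gen_flow_sample(FlowSpec(marker="RelA", n=3000, seed=5,
                                              sample_id="lineHi"))
        hi_b, _, _ = gen_flow_sample(FlowSpec(
            marker="RelB", log10_medians=(3.5,), n=3000, seed=6,
            sample_id="lineHi"))
        fp = zscore_fingerprint([(lo_a, lo_b), (hi_a, hi_b)])
        assert fp.sample_medians["lineHi"][1] > fp.sample_medians["lineLo"][1]

    def test_zero_variance_reference_rejected(self):
        pair = (flow([100.0] * 5, "RelA"), flow([1, 2, 3, 4, 5], "RelB"))
        with pytest.raises(ValidationError):
            zscore_fingerprint([pair])


class TestMfiFoldChange:
    def test_identity_is_one(self):
        s = flow([5, 6, 7])
        assert mfi_fold_change(s, s) == 1.0

    def test_planted_lognormal_shift_recovered(self):
        rng = np.random.default_rng(10)
        control = flow(10 ** rng.normal(3.0, 0.25, 5000))
        condition = flow(10 ** (rng.normal(3.0, 0.25, 5000)
                                + np.log10(2.5)))
        assert 2.4 <= mfi_fold_change(condition, control) <= 2.6

    def test_empty_condition_rejected(self):
        with pytest.raises(ValidationError):
            flow([])


class TestNcRatioSummary:
    def test_single_cell(self):
        df = pd.DataFrame({"sample": ["a"], "nc_ratio": [1.0]})
        out = nc_ratio_summary(df)
        assert out.loc[0, "mean"] == 1.0 and out.loc[0, "sd"] == 0.0

    def test_planted_medians_recovered(self):
        table, truth = gen_nc_ratios(
            {"mono": (0.8, 0.2), "cocx": (0.8, 0.2, 2.0)}, n=2000, seed=8)
        out = nc_ratio_summary(table).set_index("sample")
        for name, med in truth["medians"].items():
            assert out.loc[name, "median"] == pytest.approx(med, rel=0.05)

    def test_nonpositive_rows_dropped_with_log(self, caplog):
        df = pd.DataFrame({"sample": ["a"] * 4,
                           "nc_ratio": [1.0, 2.0, -1.0, 0.0]})
        with caplog.at_level("WARNING", logger="nfkb_crosstalk"):
            out = nc_ratio_summary(df)
        assert out.loc[0, "n"] == 2
        assert any("non-positive" in r.message for r in caplog.records)

    def test_all_nonpositive_rejected(self):
        df = pd.DataFrame({"sample": ["a"], "nc_ratio": [-1.0]})
        with pytest.raises(ValidationError):
            nc_ratio_summary(df)


class TestTssWindow:
    TSS = TssRecord(gene="MCL1", chrom="chr1", position=10_000)

    def peak(self, start, end, chrom="chr1", subunit="cRel"):
        return PeakRecord(chrom, start, end, 1.0, subunit=subunit)

    def test_peak_at_tss_included(self):
        got = tss_window_scores([self.peak(10_000, 10_001)], self.TSS)
        assert got == {"cRel": [1.0]}

    def test_right_boundary_convention(self):
        # window is [pos-1000, pos+1000]: a peak starting at pos+1001 is out,
        # one starting at pos+1000 is in
        out = tss_window_scores([self.peak(11_001, 11_100)], self.TSS)
        assert out == {}
        edge = tss_window_scores([self.peak(11_000, 11_100)], self.TSS)
        assert edge == {"cRel": [1.0]}

    def test_left_boundary_convention(self):
        assert tss_window_scores([self.peak(8_900, 9_000)], self.TSS) == {}
        got = tss_window_scores([self.peak(8_900, 9_001)], self.TSS)
        assert got == {"cRel": [1.0]}

    def test_other_chromosome_excluded(self):
        assert tss_window_scores([self.peak(10_000, 10_001, chrom="chr2")],
                                 self.TSS) == {}

    def test_agrees_with_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(99)
        chroms = [f"chr{i}" for i in range(1, 6)]
        peaks = []
        for _ in range(1000):
            start = int(rng.integers(0, 200_000))
            peaks.append(PeakRecord(
                chrom=str(rng.choice(chroms)), start=start,
                end=start + int(rng.integers(1, 2000)),
                score=float(rng.random()),
                subunit=str(rng.choice(["RelA", "RelB", "cRel"]))))
        for _ in range(50):
            tss = TssRecord(gene="g", chrom=str(rng.choice(chroms)),
                            position=int(rng.integers(0, 200_000)))
            got = tss_window_scores(peaks, tss)
            lo, hi = tss.position - 1000, tss.position + 1000 + 1
            expected: dict[str, list[float]] = {}
            for pk in peaks:  # O(n*m) brute-force overlap scan
                if pk.chrom == tss.chrom and max(pk.start, lo) < min(pk.end, hi):
                    expected.setdefault(pk.subunit, []).append(pk.score)
            assert got == expected


class TestRout:
    def test_gross_outlier_removed(self):
        kept, out = rout_outliers(np.array([1.0, 1.0, 1.0, 1.0, 100.0]))
        assert list(out) == [100.0]
        assert list(kept) == [1.0] * 4

    def test_all_identical_returns_no_outliers(self):
        vals = np.full(10, 3.14)
        kept, out = rout_outliers(vals)
        assert np.array_equal(kept, vals) and out.size == 0

    def test_false_positive_rate_bounded_on_clean_gaussian(self):
        # mean removed fraction on null data stays below 2q (ROUT's design
        # goal); 200 seeds x n=1000 as a Monte-Carlo bound
        q = 0.01
        fractions = []
        for seed in range(200):
            vals = np.random.default_rng(seed).normal(0, 1, 1000)
            _, out = rout_outliers(vals, q=q)
            fractions.append(out.size / vals.size)
        assert np.mean(fractions) <= 2 * q

    def test_planted_6sd_contaminants_recovered(self):
        # 10% contamination at >= 6 robust SD, n=100, 500 seeded trials
        hits = 0
        for seed in range(500):
            rng = np.random.default_rng(10_000 + seed)
            clean = rng.normal(0, 1, 90)
            planted = 6.0 + rng.exponential(1.0, 10)
            vals = np.concatenate([clean, planted])
            _, out = rout_outliers(vals, q=0.01)
            if np.all(np.isin(planted, out)):
                hits += 1
        assert hits / 500 >= 0.99

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            rout_outliers([1.0, 2.0])
        with pytest.raises(ValidationError):
            rout_outliers([1.0, 2.0, 3.0], q=0.5)
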