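"""Binning, GC correction, reference normalization and karyotype calling."""

import numpy as np
import pandas as pd
import pytest

import secmdecon as sd
from secmdecon.errors import LowQualityError, ParameterError

from conftest import make_readset


def flat_bins(genome, n_bins=500, chrom="chr1", width=1000, gc=None, seed=0):
    """A single-chromosome bin scheme with controllable GC."""
    starts = np.arange(n_bins) * width
    if gc is None:
        rng = np.random.default_rng(seed)
        gc = np.clip(rng.uniform(0.3, 0.6, n_bins), 0, 1)
    table = pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + width,
                          "gc": gc, "blacklist": False})
    return sd.BinScheme(table=table, genome=genome)


class TestBinCounts:
    def test_all_reads_in_one_bin(self, genome, bins):
        rows = [(f"r{i}", "chr1", 65_000 + i, 65_100 + i, 0, 0) for i in range(10)]
        rs = make_readset(rows, genome=genome)
        counts = sd.bin_counts(rs, bins)
        idx = np.flatnonzero(counts)
        assert len(idx) == 1 and counts[idx[0]] == 10
        assert bins.table.loc[idx[0], "start"] == 60_000

    def test_boundary_read_goes_to_right_bin(self, genome, bins):
        rs = make_readset([("r", "chr1", 20_000, 20_100, 0, 0)], genome=genome)
        counts = sd.bin_counts(rs, bins)
        i = int(np.flatnonzero(counts)[0])
        assert bins.table.loc[i, "start"] == 20_000

    def test_chromosome_mismatch_errors(self, bins):
        rs = make_readset([("r", "chrZ", 0, 100, 0, 0)])
        with pytest.raises(ParameterError):
            sd.bin_counts(rs, bins)

    def test_blacklisted_bins_get_no_count(self, genome):
        b = flat_bins(genome, n_bins=30)
        b.table.loc[0, "blacklist"] = True
        rs = make_readset([("r", "chr1", 10, 110, 0, 0)], genome=genome)
        assert sd.bin_counts(rs, b).sum() == 0

    def test_uniform_euploid_counts_proportional_to_length(self, genome, bins, signatures):
        rs = sd.generate_reads(signatures["blastocyst"], sd.Karyotype.reference_diploid(),
                               1_000_000, genome, seed=17)
        counts = sd.bin_counts(rs, bins)
        p = bins.lengths / bins.lengths.sum()
        expected = 1_000_000 * p
        se = np.sqrt(1_000_000 * p * (1 - p))
        assert (np.abs(counts - expected) <= 3 * se).mean() > 0.99


class TestGcCorrect:
    def test_constant_counts_unchanged(self, genome):
        b = flat_bins(genome, 200)
        counts = np.full(200, 50.0)
        corrected, usable = sd.gc_correct(counts, b)
        assert usable.all()
        np.testing.assert_allclose(corrected, counts, rtol=1e-6)

    def test_mean_preserved(self, genome):
        b = flat_bins(genome, 300, seed=5)
        rng = np.random.default_rng(6)
        counts = rng.poisson(100, 300).astype(float)
        corrected, usable = sd.gc_correct(counts, b)
        assert corrected[usable].mean() == pytest.approx(counts[usable].mean(), rel=1e-9)

    def test_injected_linear_bias_removed(self, genome):
        """Regression oracle: after correction, count~GC correlation vanishes."""
        b = flat_bins(genome, 500, seed=7)
        rng = np.random.default_rng(8)
        clean = rng.poisson(500, 500).astype(float)
        biased = sd.inject_gc_bias(clean, b, slope=1.5)
        gc = b.table["gc"].to_numpy()
        assert abs(np.corrcoef(biased, gc)[0, 1]) > 0.5  # bias went in
        corrected, usable = sd.gc_correct(biased, b)
        r = np.corrcoef(corrected[usable], gc[usable])[0, 1]
        assert abs(r) < 0.05

    def test_too_few_bins_rejected(self, genome):
        b = flat_bins(genome, 10)
        with pytest.raises(LowQualityError):
            sd.gc_correct(np.ones(10), b)


class TestNormalize:
    def test_sample_equal_reference_gives_cn2(self, genome):
        b = flat_bins(genome, 100)
        counts = np.full(100, 40.0)
        prof = sd.normalize_to_reference(counts, counts, b)
        np.testing.assert_allclose(prof.cn, 2.0)

    def test_scaled_chromosome_reads_cn3(self, genome, bins):
        ref = np.full(len(bins), 100.0)
        sample = ref.copy()
        mask = np.asarray([str(c) == "chr21" for c in bins.chroms])
        sample[mask] *= 1.5
        prof = sd.normalize_to_reference(sample, ref, bins)
        summ = sd.chromosome_summary(prof)
        # normalization mass includes the gained chromosome, slightly deflating all
        assert summ["chr21"] == pytest.approx(3.0, abs=0.05)
        assert summ["chr1"] == pytest.approx(2.0, abs=0.05)

    def test_zero_reference_bin_flagged_not_divided(self, genome):
        b = flat_bins(genome, 50)
        ref = np.full(50, 10.0)
        ref[7] = 0.0
        prof = sd.normalize_to_reference(np.full(50, 10.0), ref, b)
        assert np.isnan(prof.cn[7])
        assert np.isfinite(prof.cn[np.arange(50) != 7]).all()

    def test_scale_invariance(self, genome, bins):
        rng = np.random.default_rng(9)
        ref = rng.poisson(200, len(bins)).astype(float) + 1
        sample = rng.poisson(200, len(bins)).astype(float)
        p1 = sd.normalize_to_reference(sample, ref, bins)
        p2 = sd.normalize_to_reference(sample * 7.3, ref, bins)
        np.testing.assert_allclose(p1.cn, p2.cn, rtol=1e-9)

    def test_trisomy22_half_diluted_reads_near_2p5(self, genome, bins, signatures):
        """A +22 embryo mixed 50/50 with euploid cumulus reads ~2.5 on chr22."""
        embryo = sd.generate_reads(signatures["blastocyst"],
                                   sd.Karyotype.from_string("+22,XX"),
                                   400_000, genome, seed=31)
        contam = sd.generate_reads(signatures["cumulus"], sd.Karyotype.euploid("XX"),
                                   400_000, genome, seed=32)
        mix = sd.mix_samples(embryo, contam, 0.5, 800_000, seed=33)
        ref = sd.make_reference(genome, bins, 800_000, seed=34)
        prof = sd.cnv_pipeline(mix, bins, ref)
        assert sd.chromosome_summary(prof)["chr22"] == pytest.approx(2.5, abs=0.1)


class TestChromosomeSummary:
    def _profile(self, genome, values, chrom="chr1"):
        b = flat_bins(genome, len(values), chrom=chrom)
        return sd.CNVProfile(bins=b, cn=np.asarray(values, dtype=float), n_reads_used=100)

    def test_median(self, genome):
        prof = self._profile(genome, [2, 2, 2, 3, 2])
        assert sd.chromosome_summary(prof)["chr1"] == 2.0
        prof = self._profile(genome, [3, 3, 3, 2, 3])
        assert sd.chromosome_summary(prof)["chr1"] == 3.0

    def test_below_min_bins_is_nan(self, genome):
        prof = self._profile(genome, [2.0, 2.0, np.nan, np.nan, np.nan])
        assert np.isnan(sd.chromosome_summary(prof, min_bins=3)["chr1"])


class TestThresholdsAndCalling:
    def test_threshold_pair_validation(self):
        with pytest.raises(ParameterError):
            sd.ThresholdPair(2.5, 1.5)

    @pytest.mark.parametrize("cn,loss,gain,state", [
        (2.4, 1.5, 2.5, "neutral"),
        (2.4, 1.6, 2.4, "gain"),     # sweep: tighter pair flips the call
        (1.5, 1.5, 2.5, "loss"),     # inclusive boundary
        (2.5, 1.5, 2.5, "gain"),
    ])
    def test_threshold_states(self, cn, loss, gain, state):
        assert sd.ThresholdPair(loss, gain).state(cn) == state

    def _uniform_profile(self, genome, bins, per_chrom):
        cn = np.empty(len(bins))
        for chrom, v in per_chrom.items():
            cn[np.asarray([str(c) == chrom for c in bins.chroms])] = v
        return sd.CNVProfile(bins=bins, cn=cn, n_reads_used=10 ** 6)

    def test_euploid_xx(self, genome, bins):
        per = {c: 2.0 for c in genome.autosomes}
        per.update({"chrX": 2.0, "chrY": 0.0})
        call = sd.call_karyotype(self._uniform_profile(genome, bins, per),
                                 sd.ThresholdPair(1.5, 2.5))
        assert call.ploidy == "euploid" and call.sex == "XX"

    def test_trisomy22_gain_called(self, genome, bins):
        per = {c: 2.0 for c in genome.autosomes}
        per.update({"chr22": 3.0, "chrX": 2.0, "chrY": 0.0})
        call = sd.call_karyotype(self._uniform_profile(genome, bins, per),
                                 sd.ThresholdPair(1.5, 2.5))
        assert call.states["chr22"] == "gain"
        assert call.ploidy == "aneuploid"

    def test_xy_sex_call(self, genome, bins):
        per = {c: 2.0 for c in genome.autosomes}
        per.update({"chrX": 1.0, "chrY": 1.0})
        call = sd.call_karyotype(self._uniform_profile(genome, bins, per),
                                 sd.ThresholdPair(1.5, 2.5))
        assert call.sex == "XY" and call.ploidy == "euploid"

    def test_sex_dosage_anomaly_is_aneuploid(self, genome, bins):
        per = {c: 2.0 for c in genome.autosomes}
        per.update({"chrX": 2.0, "chrY": 1.0})  # XXY-like dosage
        call = sd.call_karyotype(self._uniform_profile(genome, bins, per),
                                 sd.ThresholdPair(1.5, 2.5))
        assert call.sex == "undetermined" and call.ploidy == "aneuploid"

    def test_too_few_callable_autosomes(self, genome, bins):
        cn = np.full(len(bins), np.nan)
        prof = sd.CNVProfile(bins=bins, cn=cn, n_reads_used=0)
        with pytest.raises(LowQualityError):
            sd.call_karyotype(prof, sd.ThresholdPair(1.5, 2.5))


class TestPipelineProperties:
    def test_pure_sample_parameter_recovery(self, genome, bins, signatures):
        """Autosomal summaries of a pure aneuploid sample track the truth."""
        kt = sd.Karyotype.from_string("-16,+18,XY")
        rs = sd.generate_reads(signatures["blastocyst"], kt, 1_000_000, genome, seed=41)
        ref = sd.make_reference(genome, bins, 1_000_000, seed=42)
        prof = sd.cnv_pipeline(rs, bins, ref)
        summ = sd.chromosome_summary(prof)
        # dilution: the aneuploid genome's total mass differs slightly from 2A
        mad = np.mean([abs(summ[c] - kt.copy_number(c)) for c in genome.autosomes])
        assert mad < 0.15
        call = sd.call_karyotype(prof, sd.ThresholdPair(1.5, 2.5))
        assert call.states["chr16"] == "loss" and call.states["chr18"] == "gain"
        assert call.sex == "XY"

    def test_gc_correct_noop_commutes_on_unbiased_constant_counts(self, genome):
        b = flat_bins(genome, 120)
        counts = np.full(120, 80.0)
        ref = np.full(120, 60.0)
        direct = sd.normalize_to_reference(counts, ref, b)
        corrected, usable = sd.gc_correct(counts, b)
        via_gc = sd.normalize_to_reference(corrected, ref, b, usable=usable)
        np.testing.assert_allclose(direct.cn, via_gc.cn, rtol=1e-6)


class TestBinSchemeIO:
    def test_bed_round_trip(self, genome, bins, tmp_path):
        p = tmp_path / "bins.bed"
        bins.to_bed(p)
        back = sd.BinScheme.from_bed(p, genome)
        assert len(back) == len(bins)
        np.testing.assert_allclose(back.table["gc"], bins.table["gc"], atol=1e-12)

    def test_overlapping_bins_rejected(self, genome):
        t = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 500],
                          "end": [1000, 1500], "gc": [0.4, 0.4]})
        with pytest.raises(ParameterError):
            sd.BinScheme(table=t, genome=genome)
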