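"""ChIP normalization, z-scoring, gene summaries and metagene profiles."""

import numpy as np
import pytest

from endosign.chip_signal import (
    BinTrack,
    CoverageTrack,
    bin_log_ratio,
    gene_zscore,
    metagene_profile,
    zscore_track,
)
from endosign.errors import ConfigurationError, InputError
from endosign.genes import GeneAnnotation

from conftest import make_bintrack, make_coverage


class TestBinLogRatio:
    def test_exact_arithmetic_with_pseudocount(self):
        track = bin_log_ratio(make_coverage([5.0]), make_coverage([3.0]), bin_width=1)
        assert track.values["Chr1"][0] == pytest.approx(np.log2(6 / 4), abs=1e-12)
        assert round(track.values["Chr1"][0], 3) == 0.585

    def test_identity_ratio_is_zero(self):
        track = bin_log_ratio(make_coverage([4.0, 7.0]), make_coverage([4.0, 7.0]), bin_width=1)
        np.testing.assert_allclose(track.values["Chr1"], 0.0)

    def test_doubling_approaches_one(self):
        track = bin_log_ratio(make_coverage([2000.0]), make_coverage([1000.0]), bin_width=1)
        assert track.values["Chr1"][0] == pytest.approx(1.0, abs=2e-3)

    def test_double_zero_bin_is_missing_not_zero(self):
        track = bin_log_ratio(make_coverage([0.0, 3.0]), make_coverage([0.0, 3.0]), bin_width=1)
        assert np.isnan(track.values["Chr1"][0])
        assert track.values["Chr1"][1] == 0.0

    def test_mismatched_chromosomes_listed_in_error(self):
        chip = CoverageTrack(step=1, values={"Chr1": np.ones(3), "Chr2": np.ones(3)})
        ctrl = CoverageTrack(step=1, values={"Chr1": np.ones(3)})
        with pytest.raises(InputError, match="Chr2"):
            bin_log_ratio(chip, ctrl, bin_width=1)

    def test_bins_aggregate_steps(self):
        # 3 steps of 1 bp per 3-bp bin: read-equivalents are summed
        chip = make_coverage([1.0, 2.0, 3.0])
        ctrl = make_coverage([2.0, 2.0, 2.0])
        track = bin_log_ratio(chip, ctrl, bin_width=3)
        assert track.values["Chr1"][0] == pytest.approx(np.log2((6 + 1) / (6 + 1)))


class TestZscore:
    def test_population_sd_convention(self):
        z = zscore_track(make_bintrack([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z.values["Chr1"], [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_constant_track_warns_and_zeros(self):
        with pytest.warns(RuntimeWarning):
            z = zscore_track(make_bintrack([5.0, 5.0, 5.0]))
        np.testing.assert_array_equal(z.values["Chr1"], 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        z1 = zscore_track(make_bintrack(rng.normal(3, 2, 500)))
        z2 = zscore_track(z1)
        np.testing.assert_allclose(z2.values["Chr1"], z1.values["Chr1"], atol=1e-12)

    def test_missing_stays_missing_and_moments(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 5, 1000)
        vals[::17] = np.nan
        z = zscore_track(make_bintrack(vals))
        out = z.values["Chr1"]
        assert np.isnan(out[::17]).all()
        finite = out[np.isfinite(out)]
        assert abs(finite.mean()) < 1e-9
        assert abs(finite.std(ddof=0) - 1.0) < 1e-9

    def test_too_few_finite_bins(self):
        with pytest.raises(InputError):
            zscore_track(make_bintrack([1.0, np.nan]))


class TestGeneZscore:
    def test_mean_of_body_bins(self):
        track = make_bintrack([1.0, 3.0], bin_width=100)
        gene = GeneAnnotation("g", "Chr1", 0, 200, "+")
        assert gene_zscore(track, gene).z == pytest.approx(2.0)

    def test_alternating_seven_bins(self):
        track = make_bintrack([1, -1, 1, -1, 1, -1, 1], bin_width=10)
        gene = GeneAnnotation("g", "Chr1", 0, 70, "+")
        assert gene_zscore(track, gene).z == pytest.approx(1 / 7)

    def test_all_missing_not_scorable(self):
        track = make_bintrack([np.nan, np.nan], bin_width=100)
        gene = GeneAnnotation("g", "Chr1", 0, 200, "+")
        res = gene_zscore(track, gene)
        assert res.not_scorable and res.n_bins == 0

    def test_partial_overlap_bins_count_whole(self):
        track = make_bintrack([10.0, 20.0, 30.0], bin_width=100)
        gene = GeneAnnotation("g", "Chr1", 150, 250, "+")  # touches bins 1 and 2
        assert gene_zscore(track, gene).z == pytest.approx(25.0)

    def test_agrees_with_bruteforce_on_random_genomes(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 40))
            w = int(rng.choice([10, 50, 150]))
            vals = rng.normal(size=n)
            vals[rng.random(n) < 0.2] = np.nan
            track = make_bintrack(vals, bin_width=w)
            start = int(rng.integers(0, n * w - 1))
            end = int(rng.integers(start + 1, n * w + 1))
            gene = GeneAnnotation("g", "Chr1", start, end, "+")
            # independent overlap enumeration
            overlap = [
                vals[i]
                for i in range(n)
                if i * w < end and (i + 1) * w > start and np.isfinite(vals[i])
            ]
            res = gene_zscore(track, gene)
            if overlap:
                assert res.z == pytest.approx(np.mean(overlap))
                assert res.n_bins == len(overlap)
            else:
                assert res.not_scorable


class TestMetagene:
    def test_default_geometry_is_80_positions(self):
        track = make_bintrack(np.ones(1000), bin_width=150)
        genes = [GeneAnnotation("g", "Chr1", 50_000, 54_000, "+")]
        prof = metagene_profile(track, genes)
        assert prof.n_positions == 80
        assert len(prof.mean_value) == 80

    def test_constant_field_gives_flat_profile(self):
        track = make_bintrack(np.full(1000, 2.5), bin_width=150)
        genes = [
            GeneAnnotation("a", "Chr1", 30_000, 33_000, "+"),
            GeneAnnotation("b", "Chr1", 60_000, 62_000, "-"),
        ]
        prof = metagene_profile(track, genes)
        np.testing.assert_allclose(prof.mean_value, 2.5)
        assert (prof.n_genes == 2).all()

    def test_strand_flip_symmetry_exact(self, rng):
        L = 10_000
        w = 100
        vals = rng.normal(size=L // w)
        fwd = make_bintrack(vals, bin_width=w)
        rev = make_bintrack(vals[::-1].copy(), bin_width=w)
        gene_fwd = GeneAnnotation("f", "Chr1", 3000, 5000, "+")
        gene_rev = GeneAnnotation("r", "Chr1", L - 5000, L - 3000, "-")
        p_fwd = metagene_profile(fwd, [gene_fwd], flank_bp=2000, flank_bin_bp=100, body_bins=40)
        p_rev = metagene_profile(rev, [gene_rev], flank_bp=2000, flank_bin_bp=100, body_bins=40)
        np.testing.assert_allclose(p_fwd.mean_value, p_rev.mean_value, atol=1e-12)

    def test_body_positions_reproduce_ramp_means(self):
        # gene of 200 bp over a 10-bp-bin linear ramp; oracle = explicit
        # overlap-weighted average per 5-bp body slice
        w = 10
        vals = np.arange(100, dtype=float)
        track = make_bintrack(vals, bin_width=w)
        gene = GeneAnnotation("g", "Chr1", 100, 300, "+")
        prof = metagene_profile(track, [gene], flank_bp=100, flank_bin_bp=50, body_bins=40)
        body = prof.mean_value[2:42]
        slice_len = 200 / 40
        expected = []
        for j in range(40):
            a = 100 + j * slice_len
            b = a + slice_len
            wsum = wtot = 0.0
            for i in range(len(vals)):
                ov = min(b, (i + 1) * w) - max(a, i * w)
                if ov > 0:
                    wsum += vals[i] * ov
                    wtot += ov
            expected.append(wsum / wtot)
        np.testing.assert_allclose(body, expected, atol=1e-12)

    def test_short_gene_skipped(self):
        track = make_bintrack(np.ones(100), bin_width=150)
        genes = [GeneAnnotation("tiny", "Chr1", 10, 30, "+")]
        prof = metagene_profile(track, genes, body_bins=40)
        assert (prof.n_genes == 0).all()

    def test_flank_not_divisible_raises(self):
        track = make_bintrack(np.ones(10), bin_width=150)
        genes = [GeneAnnotation("g", "Chr1", 0, 1000, "+")]
        with pytest.raises(ConfigurationError):
            metagene_profile(track, genes, flank_bp=2000, flank_bin_bp=300)
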