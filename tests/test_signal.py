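"""Coverage binning, RPM, Hann smoothing and co-oriented averaging.

The smoothing and averaging operations are checked against naive
loop-based oracles (direct weighted sums, per-hotspot python loops) to
1e-9 relative, per the pipeline's equivalence contracts.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsbend import (AnalysisConfig, EndMap, GenomeSpec, bin_coverage,
                    cooriented_average, hann_smooth,
                    normalize_to_resection_peak, rpm_normalize,
                    simulate_hotspots, smooth_profile)
from dsbend.genome import BOTTOM, TOP, HotspotSet
from dsbend.signal import CoorientedProfile, StrandTrack, hann_window


def endmap(records):
    chroms, poss, strands = zip(*records)
    return EndMap(np.array(chroms, dtype=object), np.array(poss),
                  np.array(strands, dtype=np.uint8))


class TestBinCoverage:
    def test_empty_endmap_gives_zero_track(self, tiny_genome):
        track = bin_coverage(EndMap.empty(), tiny_genome, 40)
        assert track.total() == 0

    def test_read_lands_in_floor_bin(self, tiny_genome):
        track = bin_coverage(endmap([("chr1", 1000, TOP)]), tiny_genome, 40)
        assert track.top["chr1"][25] == 1
        assert track.total() == 1

    @given(n=st.integers(0, 300), bin_size=st.sampled_from([1, 7, 40]),
           seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_total_mass_equals_record_count(self, n, bin_size, seed):
        genome = GenomeSpec(chroms={"c1": 5000, "c2": 3000})
        rng = np.random.default_rng(seed)
        chroms = np.array(rng.choice(["c1", "c2"], n), dtype=object)
        lens = np.where(chroms == "c1", 5000, 3000)
        pos = (rng.random(n) * lens).astype(np.int64)
        strand = rng.integers(0, 2, n).astype(np.uint8)
        track = bin_coverage(EndMap(chroms, pos, strand), genome, bin_size)
        assert track.total() == n
        assert track.n_mapped == n


class TestRpmNormalize:
    def test_bins_sum_to_one_million(self, tiny_genome):
        reads = [("chr1", i * 100, TOP if i % 2 else BOTTOM) for i in range(10)]
        track = rpm_normalize(bin_coverage(endmap(reads), tiny_genome, 10))
        assert track.total() == pytest.approx(1e6)

    def test_single_read_value(self, tiny_genome):
        reads = [("chr1", 50, TOP)] + [("chr2", i, BOTTOM) for i in range(9)]
        track = rpm_normalize(bin_coverage(endmap(reads), tiny_genome, 1))
        assert track.top["chr1"][50] == pytest.approx(1e5)

    def test_scale_invariance(self, tiny_genome):
        reads = [("chr1", 500, TOP), ("chr2", 700, BOTTOM)]
        single = rpm_normalize(bin_coverage(endmap(reads), tiny_genome, 10))
        double = rpm_normalize(bin_coverage(endmap(reads * 2), tiny_genome, 10))
        for c in tiny_genome.chroms:
            np.testing.assert_allclose(single.top[c], double.top[c])

    def test_double_normalization_rejected(self, tiny_genome):
        track = rpm_normalize(bin_coverage(
            endmap([("chr1", 5, TOP)]), tiny_genome, 10))
        with pytest.raises(ValueError, match="already"):
            rpm_normalize(track)

    def test_empty_library_rejected(self, tiny_genome):
        with pytest.raises(ValueError, match="n_mapped"):
            rpm_normalize(bin_coverage(EndMap.empty(), tiny_genome, 10))


def hann_smooth_oracle(values, window_bins):
    """Direct weighted sum with reflected indexing (O(n*m))."""
    w = hann_window(window_bins)
    half = window_bins // 2
    n = len(values)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for k in range(-half, half + 1):
            j = i + k
            if j < 0:
                j = -j
            elif j >= n:
                j = 2 * (n - 1) - j
            acc += w[k + half] * values[j]
        out[i] = acc
    return out


class TestHannSmooth:
    def test_window_one_is_identity(self):
        x = np.array([1.0, 4.0, 2.0, 8.0])
        np.testing.assert_array_equal(hann_smooth(x, 1), x)

    def test_constant_vector_preserved(self):
        x = np.full(50, 3.7)
        np.testing.assert_allclose(hann_smooth(x, 21), x, rtol=1e-12)

    def test_impulse_reproduces_unit_sum_weights(self):
        x = np.zeros(11)
        x[5] = 1.0
        out = hann_smooth(x, 5)
        np.testing.assert_allclose(out[3:8], hann_window(5), rtol=1e-12)

    @given(n=st.integers(5, 60), window=st.sampled_from([3, 5, 7, 9]),
           seed=st.integers(0, 2**16))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_bruteforce_oracle(self, n, window, seed):
        if window > n:
            return
        x = np.random.default_rng(seed).random(n) * 10
        np.testing.assert_allclose(hann_smooth(x, window),
                                   hann_smooth_oracle(x, window), rtol=1e-9)

    def test_sum_preserved_away_from_edges(self):
        rng = np.random.default_rng(0)
        x = np.zeros(2000)
        x[500:1500] = rng.random(1000)  # <1% of mass near edges
        assert hann_smooth(x, 151).sum() == pytest.approx(x.sum(), rel=1e-3)

    @pytest.mark.parametrize("window", [2, 4, 1001])
    def test_even_or_oversized_window_rejected(self, window):
        with pytest.raises(ValueError):
            hann_smooth(np.ones(100), window)


def cooriented_oracle(track, hotspots, flank):
    """Per-hotspot python-loop aggregation (the O(n*m) reference)."""
    tops, bots = [], []
    for i in range(len(hotspots)):
        c = int(hotspots.center[i])
        chrom = hotspots.chrom[i]
        if c - flank < 0 or c + flank >= len(track.top[chrom]):
            continue
        tops.append([track.top[chrom][c + d] for d in range(-flank, flank + 1)])
        bots.append([track.bottom[chrom][c - d] for d in range(-flank, flank + 1)])
    return np.mean(tops, axis=0), np.mean(bots, axis=0)


class TestCoorientedAverage:
    def small_cfg(self, flank=500):
        return AnalysisConfig(profile_flank_bp=flank, background_offset_bp=500,
                              core_exclusion_bp=100)

    def test_single_read_at_plus_500(self, tiny_genome):
        hs = HotspotSet(np.array(["chr1"], dtype=object), np.array([50_000]),
                        np.array([1.0]), np.array(["prdm9"], dtype=object))
        track = bin_coverage(endmap([("chr1", 50_500, TOP)]), tiny_genome, 1)
        prof = cooriented_average(track, hs, self.small_cfg(1000), combine=True)
        nz = prof.distances[prof.values > 0]
        assert list(nz) == [500]

    def test_strand_mirror_symmetry_exact(self, tiny_genome):
        hs = HotspotSet(np.array(["chr1"], dtype=object), np.array([50_000]),
                        np.array([1.0]), np.array(["prdm9"], dtype=object))
        rng = np.random.default_rng(3)
        offsets = rng.integers(-900, 900, 200)
        reads = [("chr1", 50_000 + o, TOP) for o in offsets]
        reads += [("chr1", 50_000 - o, BOTTOM) for o in offsets]
        track = bin_coverage(endmap(reads), tiny_genome, 1)
        prof = cooriented_average(track, hs, self.small_cfg(1000), combine=True)
        np.testing.assert_array_equal(prof.top, prof.bottom_flipped)

    def test_matches_bruteforce_oracle(self, tiny_genome):
        hs = simulate_hotspots(tiny_genome, 30, min_spacing=1500, seed=8)
        rng = np.random.default_rng(9)
        n = 3000
        chroms = np.array(rng.choice(list(tiny_genome.chroms), n), dtype=object)
        lens = np.array([tiny_genome.chroms[c] for c in chroms])
        pos = (rng.random(n) * lens).astype(np.int64)
        strand = rng.integers(0, 2, n).astype(np.uint8)
        track = rpm_normalize(bin_coverage(
            EndMap(chroms, pos, strand), tiny_genome, 1))
        cfg = self.small_cfg(500)
        prof = cooriented_average(track, hs, cfg, combine=True)
        o_top, o_bot = cooriented_oracle(track, hs, 500)
        np.testing.assert_allclose(prof.top, o_top, rtol=1e-9)
        np.testing.assert_allclose(prof.bottom_flipped, o_bot, rtol=1e-9)
        np.testing.assert_allclose(prof.values, o_top + o_bot, rtol=1e-9)

    def test_edge_hotspots_skipped_not_padded(self, tiny_genome):
        hs = HotspotSet(np.array(["chr1", "chr1"], dtype=object),
                        np.array([100, 50_000]), np.array([1.0, 1.0]),
                        np.array(["prdm9", "prdm9"], dtype=object))
        track = bin_coverage(endmap([("chr1", 50_200, TOP)]), tiny_genome, 1)
        prof = cooriented_average(track, hs, self.small_cfg(1000))
        assert prof.n_hotspots == 1

    def test_all_edge_hotspots_error(self, tiny_genome):
        hs = HotspotSet(np.array(["chr1"], dtype=object), np.array([10]),
                        np.array([1.0]), np.array(["prdm9"], dtype=object))
        track = bin_coverage(EndMap.empty(), tiny_genome, 1)
        with pytest.raises(ValueError, match="usable"):
            cooriented_average(track, hs, self.small_cfg(1000))


class TestNormalizeToResectionPeak:
    def make_profile(self, values, flank=3000):
        d = np.arange(-flank, flank + 1)
        return CoorientedProfile(distances=d, values=np.asarray(values, float),
                                 n_hotspots=10, combined=True)

    def test_constant_profile_is_error(self, cfg):
        prof = self.make_profile(np.full(6001, 2.0))
        with pytest.raises(ValueError, match="no resection signal"):
            normalize_to_resection_peak(prof, cfg)

    def test_triangular_profile_normalizes_to_peak(self, cfg):
        d = np.arange(-3000, 3001)
        values = np.clip(1.0 - np.abs(d - 800) / 1700, 0, None)
        prof = self.make_profile(values)
        out = normalize_to_resection_peak(prof, cfg)
        assert out.value_at(800) == pytest.approx(1.0)
        assert out.value_at(2500) == pytest.approx(0.0, abs=1e-12)
        window = (out.distances > 100) & (out.distances <= 2500)
        assert out.values[window].max() == pytest.approx(1.0)

    def test_simulated_peak_near_gamma_mode(self, wildtype_profile_inputs, cfg):
        # gamma(16, 50) mode = (16-1)*50 = 750 nt
        track, prdm9, _ = wildtype_profile_inputs
        prof = smooth_profile(cooriented_average(track, prdm9, cfg), 151)
        out = normalize_to_resection_peak(prof, cfg)
        window = (out.distances > 100) & (out.distances <= 2500)
        peak_d = out.distances[window][np.argmax(out.values[window])]
        assert 650 <= peak_d <= 850

    def test_uncombined_profile_rejected(self, cfg):
        prof = CoorientedProfile(distances=np.arange(-3000, 3001),
                                 values=np.ones(6001), n_hotspots=1,
                                 combined=False)
        with pytest.raises(ValueError, match="combined"):
            normalize_to_resection_peak(prof, cfg)
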