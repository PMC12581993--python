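import numpy as np
import pytest

from g4topo import (
    G4Hit,
    Interval,
    OriginSpec,
    SequenceRecord,
    SkewParams,
    bin_circular,
    bin_enrichment,
    circ_distance,
    gc_skew_binned,
    leading_fraction,
    linear_origin_profile,
    origins_with_hit_fraction,
    revcomp,
    signed_offset,
)
from g4topo.replication import gc_skew_windows


def _hit(s, e, strand="+", contig="chr1"):
    return G4Hit(contig, s, e, strand, "regex")


class TestCircularGeometry:
    @pytest.mark.parametrize("p,q,L,d", [(10, 90, 100, 20), (0, 50, 100, 50), (7, 7, 100, 0)])
    def test_circ_distance(self, p, q, L, d):
        assert circ_distance(p, q, L) == d
        assert circ_distance(q, p, L) == d

    def test_circ_distance_bound_and_range_check(self, rng):
        L = 1000
        for _ in range(200):
            p, q = int(rng.integers(L)), int(rng.integers(L))
            assert 0 <= circ_distance(p, q, L) <= L // 2
        with pytest.raises(ValueError):
            circ_distance(-1, 0, 100)

    @pytest.mark.parametrize("p,expected", [(60, 10), (40, -10), (0, 50)])
    def test_signed_offset(self, p, expected):
        assert signed_offset(p, OriginSpec("c", 50, 100)) == expected

    def test_signed_offset_magnitude_is_circ_distance(self, rng):
        ori = OriginSpec("c", 333, 1000)
        for p in rng.integers(0, 1000, size=200):
            assert abs(signed_offset(int(p), ori)) == circ_distance(int(p), 333, 1000)

    def test_linear_topology_rejected(self):
        with pytest.raises(ValueError):
            signed_offset(5, OriginSpec("c", 0, 10, topology="linear"))


class TestBinning:
    def test_hit_at_ori_hits_center_bin(self):
        ori = OriginSpec("c", 50_000, 100_000)
        prof = bin_circular([_hit(49_995, 50_005)], ori, n_bins=101)
        assert prof.counts_fwd[prof.center_bin] == 1

    def test_long_hit_counted_in_every_touched_bin(self):
        ori = OriginSpec("c", 500, 1000)
        # bin width ~ 1000/11 = 90.9; a 200-bp hit touches 3-4 bins
        prof = bin_circular([_hit(400, 600)], ori, n_bins=11)
        assert prof.counts_fwd.sum() >= 3
        assert prof.counts_fwd.max() == 1

    def test_strands_tallied_separately(self):
        ori = OriginSpec("c", 500, 1000)
        prof = bin_circular([_hit(100, 110, "+"), _hit(100, 110, "-")], ori, 11)
        assert prof.counts_fwd.sum() == prof.counts_rev.sum() == 1

    def test_uniform_hits_approximately_uniform_bins(self, rng):
        L, n = 1_000_000, 101
        ori = OriginSpec("c", 123_456, L)
        starts = rng.integers(0, L - 10, size=20_000)
        prof = bin_circular([_hit(int(s), int(s) + 5) for s in starts], ori, n)
        expected = 20_000 / n
        sd = np.sqrt(20_000 * (1 / n) * (1 - 1 / n))
        assert np.all(np.abs(prof.counts_fwd - expected) < 5 * sd)

    def test_rotation_invariance(self, rng):
        L = 10_000
        starts = rng.integers(0, L - 20, size=50)
        hits = [_hit(int(s), int(s) + 12) for s in starts]
        ori = OriginSpec("c", 4000, L)
        base = bin_circular(hits, ori, 101)
        shift = 2711
        rotated = [_hit((h.start + shift) % L, (h.start + shift) % L + 12)
                   for h in hits if (h.start + shift) % L + 12 <= L]
        kept = [h for h in hits if (h.start + shift) % L + 12 <= L]
        ori_rot = OriginSpec("c", (4000 + shift) % L, L)
        rot = bin_circular(rotated, ori_rot, 101)
        base_kept = bin_circular(kept, ori, 101)
        np.testing.assert_array_equal(rot.counts_fwd, base_kept.counts_fwd)


class TestEnrichmentAndSkew:
    def test_uniform_enrichment_one(self):
        ori = OriginSpec("c", 500, 1000)
        prof = bin_circular([_hit(i * 100, i * 100 + 4) for i in range(10)], ori, 5)
        prof = bin_enrichment(prof)
        assert prof.enrichment_fwd.mean() == pytest.approx(1.0, abs=1e-9)

    def test_single_loaded_bin(self):
        ori = OriginSpec("c", 50_000, 100_000)
        prof = bin_enrichment(bin_circular([_hit(49_999, 50_003)], ori, 1001))
        assert prof.enrichment_fwd[prof.center_bin] == pytest.approx(1001.0)

    def test_empty_strand_reported_missing(self):
        ori = OriginSpec("c", 500, 1000)
        prof = bin_enrichment(bin_circular([_hit(10, 20, "+")], ori, 11))
        assert prof.enrichment_rev is None
        assert prof.enrichment_fwd is not None

    def test_skew_formula_and_zero_gc_skip(self):
        mids, skews = gc_skew_windows("GGGGCC" + "AATTAA", window=6)
        assert skews.tolist() == [pytest.approx(1 / 3)]
        assert mids.tolist() == [3]

    def test_binned_skew_sign_reverses_at_origin(self):
        # forward strand G-rich on the positive replichore, C-rich on the other
        L = 20_000
        half = L // 2
        seq = ("GA" * (half // 2)) + ("CA" * (half // 2))
        rec = SequenceRecord("c", seq, "circular")
        ori = OriginSpec("c", 0, L)  # positive offsets = first half
        skew = gc_skew_binned(rec, ori, SkewParams(25), n_bins=101)
        c = 50
        assert np.nanmean(skew[c + 2 :]) > 0.9
        assert np.nanmean(skew[2 : c - 1]) < -0.9

    def test_revcomp_swaps_strand_counts_and_negates_skew(self, rng):
        # bin width chosen to divide L exactly so mirroring is bin-exact
        L, n_bins = 5050, 101
        seq = "".join(rng.choice(list("ACGT"), size=L))
        rec = SequenceRecord("c", seq, "circular")
        hits = []
        for _ in range(40):
            s = int(rng.integers(0, L - 30))
            hits.append(_hit(s, s + 20, str(rng.choice(["+", "-"]))))
        ori = OriginSpec("c", 0, L)
        fwd = bin_circular(hits, ori, n_bins)
        flip = lambda st: "+" if st == "-" else "-"
        hits_rc = [_hit(L - h.end, L - h.start, flip(h.strand)) for h in hits]
        # mirrored genome: origin maps back to position 0 -> offset negation
        rec_rc = SequenceRecord("c", revcomp(seq), "circular")
        rc = bin_circular(hits_rc, OriginSpec("c", 0, L), n_bins)
        np.testing.assert_array_equal(rc.counts_rev[::-1], fwd.counts_fwd)
        np.testing.assert_array_equal(rc.counts_fwd[::-1], fwd.counts_rev)
        skew_f = gc_skew_binned(rec, ori, n_bins=101)
        skew_r = gc_skew_binned(rec_rc, OriginSpec("c", 0, L), n_bins=101)
        assert np.nansum(skew_f) == pytest.approx(-np.nansum(skew_r), abs=1e-9)


class TestLeadingFraction:
    def test_definitions(self):
        ori = OriginSpec("c", 50, 100)
        assert leading_fraction([_hit(59, 61, "+")], ori) == 1.0
        assert leading_fraction([_hit(59, 61, "+"), _hit(59, 61, "-")], ori) == 0.5
        assert leading_fraction([_hit(59, 61, "+")], ori, invert=True) == 0.0

    def test_no_hits_errors(self):
        with pytest.raises(ValueError):
            leading_fraction([], OriginSpec("c", 50, 100))

    def test_unbiased_hits_near_half(self, rng):
        L = 100_000
        ori = OriginSpec("c", 40_000, L)
        hits = []
        for _ in range(2000):
            s = int(rng.integers(0, L - 10))
            hits.append(_hit(s, s + 6, str(rng.choice(["+", "-"]))))
        se = 0.5 / np.sqrt(2000)
        assert abs(leading_fraction(hits, ori) - 0.5) < 3 * se + 1e-9


class TestLinearOrigins:
    def test_single_origin_counts_and_enrichment(self):
        origins = [Interval("chr1", 1000, 1001)]
        prof = linear_origin_profile([_hit(995, 1005, "+")], origins, halfwin=50)
        nz = np.flatnonzero(prof.counts_fwd)
        assert prof.offsets[nz].tolist() == list(range(-5, 5))
        assert prof.enrichment_rev is None
        assert prof.enrichment_fwd[nz[0]] == pytest.approx(
            1 / prof.counts_fwd.mean()
        )

    def test_origins_with_hit_fraction(self):
        origins = [Interval("chr1", 100, 101), Interval("chr1", 10_000, 10_001)]
        assert origins_with_hit_fraction(origins, [_hit(95, 99)], halfwin=10) == 0.5
        assert origins_with_hit_fraction(origins, [], halfwin=10) == 0.0

    def test_halfwin_zero_degenerate(self):
        origins = [Interval("chr1", 100, 101)]
        assert origins_with_hit_fraction(origins, [_hit(100, 101)], halfwin=0) == 1.0
        assert origins_with_hit_fraction(origins, [_hit(101, 102)], halfwin=0) == 0.0

    def test_no_origins_errors(self):
        with pytest.raises(ValueError):
            origins_with_hit_fraction([], [_hit(0, 5)])
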