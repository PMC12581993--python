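import numpy as np
import pytest

from g4topo import (
    FeatureRecord,
    G4Hit,
    MCParams,
    Profile,
    collect_anchors,
    enrichment_profile,
    fold_enrichment_region,
    mc_confidence,
    occupancy_profile,
    pool_profiles,
)


def _gene(s, e, strand="+", gid="g1"):
    return FeatureRecord("chr1", s, e, strand, "gene", gid)


def _intron(s, e, strand="+", gid="g1"):
    return FeatureRecord("chr1", s, e, strand, "intron", gid)


def _hit(s, e, strand="+"):
    return G4Hit("chr1", s, e, strand, "regex")


def _profile_from_counts(counts, flank=None):
    counts = np.asarray(counts, dtype=np.int64)
    flank = flank or len(counts) // 2
    return Profile("TSS", flank, np.zeros_like(counts), counts, n_anchors=1)


class TestAnchors:
    def test_plus_gene_tss_tes(self):
        (tss,) = collect_anchors([_gene(100, 200, "+")], "TSS")
        (tes,) = collect_anchors([_gene(100, 200, "+")], "TES")
        assert (tss.position, tes.position) == (100, 199)

    def test_minus_gene_tss_tes(self):
        (tss,) = collect_anchors([_gene(100, 200, "-")], "TSS")
        (tes,) = collect_anchors([_gene(100, 200, "-")], "TES")
        assert (tss.position, tes.position) == (199, 100)

    def test_intron_splice_anchors(self):
        (ss5,) = collect_anchors([_intron(10, 20, "+")], "SS5")
        (ss3,) = collect_anchors([_intron(10, 20, "+")], "SS3")
        assert (ss5.position, ss3.position) == (10, 19)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            collect_anchors([_gene(0, 10)], "TTS")


class TestOccupancy:
    def test_plus_anchor_coverage(self):
        anchors = collect_anchors([_gene(1000, 2000, "+")], "TSS")
        p = occupancy_profile([_hit(995, 1005, "+")], anchors, flank=500)
        nz = np.flatnonzero(p.counts_nontemplate)
        assert p.offsets[nz].tolist() == list(range(-5, 5))
        assert p.counts_template.sum() == 0

    def test_minus_anchor_orientation_flip(self):
        anchors = collect_anchors([_gene(50, 101, "-")], "TSS")  # TSS at 100
        p = occupancy_profile([_hit(103, 108, "+")], anchors, flank=500)
        nz = np.flatnonzero(p.counts_template)
        assert p.offsets[nz].tolist() == list(range(-7, -2))
        assert p.counts_nontemplate.sum() == 0

    def test_no_hits_all_zero(self):
        anchors = collect_anchors([_gene(1000, 2000)], "TSS")
        p = occupancy_profile([], anchors, flank=100)
        assert p.counts_total.sum() == 0

    def test_counts_conservation(self, rng):
        # total counts equal hit-bp falling inside windows (single anchor)
        anchors = collect_anchors([_gene(5000, 6000, "+")], "TSS")
        hits = []
        for _ in range(50):
            s = int(rng.integers(4000, 6000))
            hits.append(_hit(s, s + int(rng.integers(1, 40)), str(rng.choice(["+", "-"]))))
        p = occupancy_profile(hits, anchors, flank=500)
        expected = sum(
            max(0, min(h.end, 5500) - max(h.start, 4500)) for h in hits
        )
        assert int(p.counts_total.sum()) == expected

    def test_edge_windows_truncated_not_wrapped(self):
        anchors = collect_anchors([_gene(10, 100, "+")], "TSS")  # TSS at 10
        p = occupancy_profile([_hit(0, 5)], anchors, flank=500)
        assert int(p.counts_total.sum()) == 5

    def test_start_mode_counts_once(self):
        anchors = collect_anchors([_gene(1000, 2000, "+")], "TSS")
        p = occupancy_profile([_hit(995, 1005)], anchors, flank=500,
                              count_mode="start")
        assert int(p.counts_total.sum()) == 1
        assert p.counts_nontemplate[p.offsets.tolist().index(-5)] == 1

    def test_orientation_reflection_invariance(self, rng):
        # mirroring genome and strands leaves the profile unchanged
        L = 10_000
        genes = [_gene(4000, 6000, "+")]
        hits = []
        for _ in range(30):
            s = int(rng.integers(3000, 7000))
            hits.append(_hit(s, s + int(rng.integers(2, 30)), str(rng.choice(["+", "-"]))))
        p1 = occupancy_profile(hits, collect_anchors(genes, "TSS"), flank=500)
        flip = lambda st: "+" if st == "-" else "-"
        genes_m = [FeatureRecord("chr1", L - 6000, L - 4000, "-", "gene", "g1")]
        hits_m = [G4Hit("chr1", L - h.end, L - h.start, flip(h.strand), "regex")
                  for h in hits]
        p2 = occupancy_profile(hits_m, collect_anchors(genes_m, "TSS"), flank=500)
        np.testing.assert_array_equal(p1.counts_template, p2.counts_template)
        np.testing.assert_array_equal(p1.counts_nontemplate, p2.counts_nontemplate)


class TestEnrichment:
    def test_uniform_counts_enrichment_one(self):
        p = enrichment_profile(_profile_from_counts([3] * 10))
        np.testing.assert_allclose(p.enrichment, 1.0)

    def test_half_and_half(self):
        p = enrichment_profile(_profile_from_counts([2] * 5 + [0] * 5))
        assert p.enrichment[:5].tolist() == [2.0] * 5
        assert p.enrichment[5:].tolist() == [0.0] * 5

    def test_mean_identity(self, rng):
        counts = rng.poisson(4, size=1000)
        counts[0] += 1  # ensure nonzero
        p = enrichment_profile(_profile_from_counts(counts))
        assert abs(p.enrichment.mean() - 1.0) < 1e-9

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="empty profile"):
            enrichment_profile(_profile_from_counts([0] * 10))


class TestMonteCarlo:
    def test_singleton_bands_collapse_to_point(self, rng):
        p = _profile_from_counts(rng.poisson(5, size=100) + 1)
        out = mc_confidence([p], MCParams(n_reps=100, seed=1))
        np.testing.assert_array_equal(out.ci_low, out.enrichment)
        np.testing.assert_array_equal(out.ci_high, out.enrichment)

    def test_identical_profiles_zero_width(self, rng):
        counts = rng.poisson(5, size=100) + 1
        profiles = [_profile_from_counts(counts.copy()) for _ in range(10)]
        out = mc_confidence(profiles, MCParams(n_reps=200, seed=2))
        np.testing.assert_allclose(out.ci_high - out.ci_low, 0.0, atol=1e-12)

    def test_reproducible_given_seed(self, rng):
        profiles = [_profile_from_counts(rng.poisson(5, size=50) + 1)
                    for _ in range(8)]
        a = mc_confidence(profiles, MCParams(n_reps=100, seed=7))
        b = mc_confidence(profiles, MCParams(n_reps=100, seed=7))
        np.testing.assert_array_equal(a.ci_low, b.ci_low)
        np.testing.assert_array_equal(a.ci_high, b.ci_high)

    def test_bands_shrink_with_more_species(self, rng):
        def cohort(n):
            return [_profile_from_counts(rng.poisson(10, size=50) + 1)
                    for _ in range(n)]

        small = mc_confidence(cohort(5), MCParams(n_reps=300, seed=3))
        large = mc_confidence(cohort(50), MCParams(n_reps=300, seed=3))
        assert (large.ci_high - large.ci_low).mean() < (small.ci_high - small.ci_low).mean()


class TestFoldEnrichment:
    def test_uniform_is_one(self):
        p = enrichment_profile(_profile_from_counts([4] * 20, flank=10))
        assert fold_enrichment_region(p, (-10, 10)) == pytest.approx(1.0)

    def test_enriched_region_value(self):
        p = enrichment_profile(_profile_from_counts([2] * 10 + [0] * 10, flank=10))
        assert fold_enrichment_region(p, (-10, 0)) == pytest.approx(2.0)

    def test_empty_range_errors(self):
        p = enrichment_profile(_profile_from_counts([1] * 20, flank=10))
        with pytest.raises(ValueError):
            fold_enrichment_region(p, (5, 5))


def test_pool_profiles_requires_matching_shape():
    a = _profile_from_counts([1] * 10, flank=5)
    b = _profile_from_counts([1] * 20, flank=10)
    with pytest.raises(ValueError):
        pool_profiles([a, b])
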