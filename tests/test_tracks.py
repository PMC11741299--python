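import numpy as np
import pytest
from scipy.stats import binom, ks_2samp

from cleavenet import tracks as trk
from cleavenet.tracks import (CutSite, GenomeSequence, Interval, RegionSet,
                              build_coverage, enumerate_candidate_bins,
                              filter_training_peaks, gc_content,
                              gc_match_negatives, shift_cut_site,
                              strand_pwm_alignment_check, subsample_track,
                              unshift_cut_site)


@pytest.mark.parametrize("strand,pos,assay,expected", [
    ("+", 100, "ATAC", 104),
    ("-", 100, "ATAC", 96),
    ("+", 100, "DNASE", 100),
    ("-", 100, "DNASE", 101),
])
def test_assay_shifts(strand, pos, assay, expected):
    shifted = shift_cut_site(CutSite("chr1", pos, strand), assay)
    assert shifted.pos == expected
    assert shifted.strand == strand
    # round trip restores the original position exactly
    assert unshift_cut_site(shifted, assay).pos == pos


def test_shift_rejects_unknown_assay():
    with pytest.raises(ValueError, match="assay"):
        shift_cut_site(CutSite("chr1", 5, "+"), "CHIP")


def test_build_coverage_pools_strands():
    genome = GenomeSequence({"chr1": "A" * 50})
    sites = [CutSite("chr1", 10, "+"), CutSite("chr1", 10, "+"),
             CutSite("chr1", 18, "-")]
    track = build_coverage(sites, genome, "ATAC")
    assert track.counts["chr1"][14] == 3
    assert track.total() == 3


def test_build_coverage_empty_and_unknown_chrom():
    genome = GenomeSequence({"chr1": "A" * 50})
    assert build_coverage([], genome, "ATAC").total() == 0
    with pytest.raises(KeyError, match="chrX"):
        build_coverage([CutSite("chrX", 1, "+")], genome, "ATAC")


def test_coverage_conservation(small_world):
    """Total coverage equals the number of sites minus dropped ones."""
    _, _, _, _, sites, track = small_world
    assert track.total() == len(sites) - track.n_dropped


def test_coverage_drops_out_of_bounds():
    genome = GenomeSequence({"chr1": "A" * 20})
    sites = [CutSite("chr1", 18, "+"), CutSite("chr1", 2, "-")]
    with pytest.warns(UserWarning, match="dropped"):
        track = build_coverage(sites, genome, "ATAC")
    assert track.n_dropped == 2
    assert track.total() == 0


def test_bedgraph_roundtrip(tmp_path, small_world):
    _, genome, _, _, _, track = small_world
    path = tmp_path / "cov.bedgraph"
    track.write_bedgraph(path)
    back = trk.CoverageTrack.from_bedgraph(path, genome)
    for c in genome.chrom_names:
        assert np.array_equal(track.counts[c], back.counts[c])


def test_bigwig_roundtrip(tmp_path):
    genome = GenomeSequence({"chr1": "ACGT" * 300})
    rng = np.random.default_rng(0)
    track = trk.CoverageTrack(
        {"chr1": rng.integers(0, 5, size=1200).astype(np.int64)})
    path = tmp_path / "cov.bw"
    track.write_bigwig(str(path))
    back = trk.CoverageTrack.from_bigwig(str(path), genome)
    assert np.array_equal(track.counts["chr1"], back.counts["chr1"])


@pytest.mark.parametrize("length,expected_starts", [
    (4114, [0, 1000, 2000]),
    (2114, [0]),
    (2113, []),
])
def test_enumerate_candidate_bins(length, expected_starts):
    genome = GenomeSequence({"chr1": "A" * length})
    bins = enumerate_candidate_bins(genome, window=2114, stride=1000)
    assert [iv.start for iv in bins] == expected_starts


def test_enumerate_bins_matches_brute_force():
    rng = np.random.default_rng(3)
    for _ in range(5):
        L = int(rng.integers(500, 10_000))
        w = int(rng.integers(100, 400))
        s = int(rng.integers(50, 300))
        genome = GenomeSequence({"c": "A" * L})
        got = [iv.start for iv in enumerate_candidate_bins(genome, w, s)]
        brute = [x for x in range(0, L) if x % s == 0 and x + w <= L]
        assert got == brute


def _random_genome(rng, length, gc=0.45):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def test_gc_match_negatives_count_and_disjointness():
    rng = np.random.default_rng(0)
    genome = GenomeSequence({"chr1": _random_genome(rng, 300_000)})
    cands = enumerate_candidate_bins(genome, 1000, 500)
    peaks = RegionSet([Interval("chr1", s, s + 1000)
                       for s in range(0, 100_000, 10_000)])
    blacklist = RegionSet([Interval("chr1", 150_000, 152_000)])
    negs = gc_match_negatives(cands, peaks, blacklist, genome,
                              multiplier=2.0, seed=1)
    assert len(negs) == 2 * len(peaks)
    pk = peaks.by_chrom()
    bl = blacklist.by_chrom()
    for iv in negs:
        assert not trk.overlaps_any(iv, pk)
        assert not trk.overlaps_any(iv, bl)


def test_gc_match_negatives_matches_gc_distribution():
    rng = np.random.default_rng(7)
    # two GC strata so matching is non-trivial
    lo = _random_genome(rng, 200_000, gc=0.35)
    hi = _random_genome(rng, 200_000, gc=0.55)
    genome = GenomeSequence({"chr1": lo + hi})
    cands = enumerate_candidate_bins(genome, 1000, 250)
    peak_starts = list(range(5_000, 60_000, 5_000)) + \
        list(range(205_000, 260_000, 5_000))
    peaks = RegionSet([Interval("chr1", s, s + 1000) for s in peak_starts])
    negs = gc_match_negatives(cands, peaks, RegionSet(), genome,
                              multiplier=3.0, seed=2)
    peak_gc = [gc_content(genome.fetch(iv.chrom, iv.start, iv.end))
               for iv in peaks]
    neg_gc = [gc_content(genome.fetch(iv.chrom, iv.start, iv.end))
              for iv in negs]
    ks = ks_2samp(peak_gc, neg_gc).statistic
    assert ks < 0.2, f"GC distributions diverge (KS={ks:.3f})"


def test_filter_training_peaks_quantile_edges_blacklist():
    L = 120_000
    genome = GenomeSequence({"chr1": "A" * L})
    counts = np.zeros(L, dtype=np.int64)
    peaks = []
    # 100 interior peaks with totals 1..100
    for i in range(100):
        c = 3_000 + i * 1_000
        counts[c] = i + 1
        peaks.append(Interval("chr1", c - 400, c + 400, summit=400,
                              name=f"p{i}"))
    # an edge peak whose 2114 bp window cannot be built
    peaks.append(Interval("chr1", 100, 900, summit=400, name="edge"))
    # a blacklisted peak
    peaks.append(Interval("chr1", 110_000, 110_800, summit=400, name="bl"))
    track = trk.CoverageTrack({"chr1": counts})
    blacklist = RegionSet([Interval("chr1", 110_300, 110_500)])
    kept = filter_training_peaks(RegionSet(peaks), track, blacklist, genome,
                                 window=2114)
    names = {iv.name for iv in kept}
    assert "edge" not in names and "bl" not in names
    # 0.99 linear-interpolation quantile of (1..100, 0, 0) keeps totals <= q
    totals = np.array([i + 1 for i in range(100)] + [0, 0], dtype=float)
    q = np.quantile(totals, 0.99)
    assert names == {f"p{i}" for i in range(100) if i + 1 <= q}


def test_subsample_track_extremes_and_binomial_bounds():
    sites = [CutSite("chr1", i, "+") for i in range(10_000)]
    assert subsample_track(sites, 1.0, seed=1) == sites
    assert subsample_track(sites, 0.0, seed=1) == []
    kept = len(subsample_track(sites, 0.5, seed=1234))
    lo, hi = binom.ppf([0.005, 0.995], 10_000, 0.5)
    assert lo <= kept <= hi
    # reproducible by seed
    again = subsample_track(sites, 0.5, seed=1234)
    assert len(again) == kept


def test_strand_pwm_alignment_detects_misalignment(small_world):
    """The check distinguishes shift pairs by their net cross-strand offset:
    for +4/-4-consistent ATAC reads, the 1-bp-misaligned +4/-5 pair scores
    clearly lower than the aligned pairs (the published diagnosis), while
    pairs with the same net offset are equivalent."""
    _, genome, _, _, sites, _ = small_world
    table, best = strand_pwm_alignment_check(
        sites[:20_000], genome, k=24,
        shift_candidates=[(0, 1), (4, -4), (4, -5)])
    t = table.set_index(["plus_shift", "minus_shift"])["agreement"]
    assert t[(4, -4)] > t[(4, -5)] + 0.1, "1-bp misalignment not detected"
    assert t[(4, -4)] > t[(0, 1)] + 0.1
    assert best == (4, -4)


def test_strand_pwm_alignment_dnase_shift(small_world):
    """DNase-convention reads (0/+1) are identified against 0/0 and +4/-4."""
    spec, genome, _, rates, _, _ = small_world
    from cleavenet import simulate as sim
    dnase_sites = sim.sample_cut_sites(rates, 30_000, seed=4, assay="DNASE")
    table, best = strand_pwm_alignment_check(
        dnase_sites, genome, k=24,
        shift_candidates=[(0, 0), (0, 1), (4, -4)])
    assert best == (0, 1)


def test_strand_pwm_alignment_needs_sites():
    genome = GenomeSequence({"chr1": "ACGT" * 100})
    with pytest.raises(ValueError, match="per strand"):
        strand_pwm_alignment_check([CutSite("chr1", 50, "+")], genome)


def test_interval_validation():
    with pytest.raises(ValueError):
        Interval("chr1", 10, 10)
    with pytest.raises(ValueError):
        Interval("chr1", 0, 10, summit=10)
    with pytest.raises(ValueError):
        GenomeSequence({"c": "ACGT"}).fetch("c", 2, 6)


def test_region_set_bed_roundtrip(tmp_path):
    rs = RegionSet([Interval("chr2", 5, 900, summit=30, name="a"),
                    Interval("chr1", 0, 100, summit=50, name="b")])
    path = tmp_path / "r.narrowPeak"
    rs.to_bed(path, narrowpeak=True)
    back = RegionSet.from_bed(path)
    # deterministically sorted by (chrom, start)
    assert [iv.chrom for iv in back] == ["chr1", "chr2"]
    assert back[0].summit == 50 and back[1].summit == 30
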