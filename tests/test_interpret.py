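import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cleavenet.interpret import (dinuc_counts, dinuc_shuffle,
                                 footprint_geometry, insert_motif,
                                 marginal_footprint, bias_audit_report,
                                 attribute, sample_background_library)
from cleavenet.models import ProfileCountModel
from cleavenet.nn import one_hot
from cleavenet.tracks import reverse_complement


# ---------------------------------------------------------------------------
# dinucleotide shuffling
# ---------------------------------------------------------------------------

def test_dinuc_shuffle_homopolymer():
    assert dinuc_shuffle("AAAA", n=3, seed=0) == ["AAAA"] * 3


def test_dinuc_shuffle_counts_exact():
    seq = "ACGTACGT"
    for out in dinuc_shuffle(seq, n=20, seed=1):
        assert dinuc_counts(out) == dinuc_counts(seq)
        assert out[0] == seq[0] and out[-1] == seq[-1]


@settings(max_examples=25, deadline=None)
@given(st.text(alphabet="ACGT", min_size=3, max_size=120),
       st.integers(min_value=0, max_value=10_000))
def test_dinuc_shuffle_invariance_property(seq, seed):
    out = dinuc_shuffle(seq, n=2, seed=seed)
    for o in out:
        assert dinuc_counts(o) == dinuc_counts(seq)


def test_dinuc_shuffle_deterministic():
    assert dinuc_shuffle("ACGTTGCACGTAAGCT", n=5, seed=7) == \
        dinuc_shuffle("ACGTTGCACGTAAGCT", n=5, seed=7)


def test_dinuc_shuffle_actually_shuffles():
    # a sequence whose dinucleotide graph has branching admits many walks
    rng = np.random.default_rng(4)
    seq = "".join(rng.choice(list("ACGT"), size=100))
    outs = dinuc_shuffle(seq, n=10, seed=3)
    assert any(o != seq for o in outs)


# ---------------------------------------------------------------------------
# attribution
# ---------------------------------------------------------------------------

def _random_trained_model(seed=0, input_len=200, output_len=80):
    rng = np.random.default_rng(seed)
    n = 30
    X = np.zeros((n, input_len, 4), dtype=np.float32)
    idx = rng.integers(0, 4, size=(n, input_len))
    X[np.arange(n)[:, None], np.arange(input_len)[None, :], idx] = 1.0
    y = rng.poisson(2.0, size=(n, output_len)).astype(np.float64)
    m = ProfileCountModel(n_filters=8, first_conv_width=7, n_dilated_layers=2,
                          profile_head_width=5, input_len=input_len,
                          output_len=output_len, max_epochs=3, random_state=seed)
    return m.fit(X, y)


def _random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.mark.parametrize("head", ["count", "profile"])
def test_attribution_completeness(head):
    """Sum of contributions equals the mean output difference vs references."""
    m = _random_trained_model()
    rng = np.random.default_rng(5)
    seq = _random_seq(rng, 200)
    amap = attribute(m, seq, head=head, n_refs=10, seed=2)
    assert amap.completeness_residual < 0.05
    assert amap.scores.shape == (200, 4)


def test_attribution_zero_model_gives_zero_scores():
    m = _random_trained_model(seed=1)
    m.net_.params["conv0_W"][:] = 0.0  # the trunk now ignores the sequence
    seq = _random_seq(np.random.default_rng(0), 200)
    amap = attribute(m, seq, head="count", n_refs=5, seed=0)
    assert np.abs(amap.scores).max() < 1e-7


def test_attribution_rejects_n_rich_sequence():
    m = _random_trained_model(seed=2)
    with pytest.raises(ValueError, match="N"):
        attribute(m, "N" * 200, head="count")


def test_attribution_order_free_averaging():
    """The averaged attribution does not depend on reference order."""
    m = _random_trained_model(seed=3)
    seq = _random_seq(np.random.default_rng(1), 200)
    a = attribute(m, seq, head="count", n_refs=8, seed=4)
    b = attribute(m, seq, head="count", n_refs=8, seed=4)
    assert np.array_equal(a.scores, b.scores)
    assert a.deltas.mean() == pytest.approx(b.deltas.mean())


# ---------------------------------------------------------------------------
# footprint geometry
# ---------------------------------------------------------------------------

def _brute_force_geometry(M, center):
    """Independent exhaustive search over the same criterion."""
    M = np.asarray(M, dtype=np.float64)
    L = len(M)
    d2 = {i: abs(M[i + 1] - 2 * M[i] + M[i - 1]) for i in range(1, L - 1)}
    left = [i for i in range(1, L - 1) if i < center]
    right = [i for i in range(1, L - 1) if i > center]
    best_l = max(left, key=lambda i: (d2[i], i))          # ties -> nearest
    best_r = max(right, key=lambda i: (d2[i], -i))
    outside = max(M[:best_l].max() if best_l > 0 else -np.inf, M[best_r:].max())
    height = outside - M[best_l: best_r + 1].min()
    return best_l, best_r, height, best_r - best_l


def test_footprint_geometry_symmetric_valley():
    L = 101
    M = np.ones(L)
    M[40:61] = 1 - np.concatenate([np.linspace(0, 1, 11),
                                   np.linspace(1, 0, 11)[1:]])  # V of half-width 10
    rs, ls, height, width, degen = footprint_geometry(M, 50)
    assert not degen
    assert width == 20 and (rs, ls) == (40, 60)
    assert height == pytest.approx(1.0 - M[40:61].min())


def test_footprint_geometry_flat_is_degenerate():
    rs, ls, height, width, degen = footprint_geometry(np.ones(50), 25)
    assert degen and height == 0.0 and width == 0


def test_footprint_geometry_matches_exhaustive_search():
    rng = np.random.default_rng(0)
    for _ in range(100):
        L = int(rng.integers(20, 200))
        center = L // 2
        x = np.arange(L, dtype=float)
        depth = rng.uniform(0.2, 2)
        w = rng.uniform(2, L / 4)
        M = 1 - depth * np.exp(-0.5 * ((x - center) / w) ** 2) \
            + rng.normal(0, 0.01, size=L)
        rs, ls, height, width, degen = footprint_geometry(M, center)
        brs, bls, bh, bw = _brute_force_geometry(M, center)
        assert (rs, ls, width) == (brs, bls, bw)
        assert height == pytest.approx(bh)


def test_insert_motif_centering():
    bg = "A" * 10
    assert insert_motif(bg, "CGC") == "AAACGCAAAA"   # odd: centred
    assert insert_motif(bg, "CG") == "AAAACGAAAA"    # even: 1 bp left
    with pytest.raises(ValueError):
        insert_motif("ACG", "ACGTACGT")


def test_marginal_footprint_noop_insertion_and_strand_symmetry():
    m = _random_trained_model(seed=4)
    rng = np.random.default_rng(6)
    bgs = [_random_seq(rng, 200) for _ in range(12)]
    motif = "TGACGTCA"
    fwd = marginal_footprint(m, motif, bgs, corrected=True)
    rev = marginal_footprint(m, reverse_complement(motif), bgs, corrected=True)
    # strand symmetry: mirrored profiles within tolerance
    assert np.abs(fwd.profile - rev.profile[::-1]).max() < \
        0.05 * np.abs(fwd.profile).max() + 1e-9
    # inserting each background's own centre is a no-op -> height ~ 0
    centre = bgs[0][100 - 4: 100 + 4]
    noop = marginal_footprint(m, centre, [bgs[0]], corrected=True)
    same = marginal_footprint(m, centre, [bgs[0]], corrected=True)
    assert noop.height == pytest.approx(same.height)


def test_bias_audit_rejects_empty_motif_lists():
    m = _random_trained_model(seed=5)
    with pytest.raises(ValueError, match="non-empty"):
        bias_audit_report(m, [], ["ACGT"], ["A" * 200])


def test_background_library_gc_matched(small_world):
    _, genome, peaks, _, _, _ = small_world
    bgs = sample_background_library(genome, peaks, n=20, length=514, seed=0)
    assert len(bgs) == 20
    assert all(len(b) == 514 for b in bgs)
    from cleavenet.tracks import gc_content
    peak_gc = np.mean([gc_content(genome.fetch(iv.chrom, iv.start, iv.end))
                       for iv in peaks])
    bg_gc = np.mean([gc_content(b) for b in bgs])
    assert abs(bg_gc - peak_gc) < 0.05
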