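"""Attributions, marginal footprinting and the bias-correction audit.

Attribution uses the DeepLIFT rescale rule against dinucleotide-shuffled
reference sequences (20 by default); for this package's ReLU/linear nets the
rule satisfies summation-to-delta exactly, so the sum of per-base scores
equals the mean difference between the model output on the sequence and on
the references. Profile-head attributions aggregate per-output-position
scores weighted by the predicted probabilities.

Marginal footprints insert a motif at the centre of GC-matched background
sequences, average predicted profiles over the library and both strands, and
measure the protection valley's height and width from the positions of
maximum gradient change on either side of the insertion point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .models import BiasFactorizedModel, ProfileCountModel
from .nn import one_hot, softmax
from .tracks import reverse_complement


# ---------------------------------------------------------------------------
# dinucleotide shuffling (Altschul–Erickson Euler-path shuffle)
# ---------------------------------------------------------------------------

def dinuc_shuffle(sequence: str, n: int = 1, seed: int = 0) -> List[str]:
    """Shuffles preserving the exact dinucleotide count multiset.

    Implements the Eulerian-path shuffle: the sequence is a walk on the graph
    whose vertices are symbols and whose edges are its dinucleotides; a
    uniform random new walk with the same edge multiset is produced by fixing
    a random in-tree to the terminal vertex for the last exit of every other
    vertex and permuting the remaining edge orders.
    """
    rng = np.random.default_rng(seed)
    s = sequence.upper()
    if len(s) < 3 or len(set(s)) == 1:
        return [s] * n
    out = []
    symbols = sorted(set(s))
    sym_idx = {c: i for i, c in enumerate(symbols)}
    edges = {c: [] for c in symbols}
    for a, b in zip(s[:-1], s[1:]):
        edges[a].append(b)
    last = s[-1]
    for _ in range(n):
        while True:
            # choose a candidate last-exit edge for every non-terminal vertex
            last_edge = {}
            for v in symbols:
                if v == last or not edges[v]:
                    continue
                last_edge[v] = edges[v][rng.integers(len(edges[v]))]
            # check the last-exit edges form paths that all reach `last`
            ok = True
            for v in last_edge:
                seen = {v}
                cur = v
                while cur != last:
                    cur = last_edge.get(cur)
                    if cur is None or cur in seen:
                        ok = False
                        break
                    seen.add(cur)
                if not ok:
                    break
            if ok:
                break
        shuffled = {}
        for v in symbols:
            pool = list(edges[v])
            if v in last_edge:
                pool.remove(last_edge[v])
            rng.shuffle(pool)
            if v in last_edge:
                pool.append(last_edge[v])
            shuffled[v] = pool
        ptr = {v: 0 for v in symbols}
        walk = [s[0]]
        cur = s[0]
        for _ in range(len(s) - 1):
            nxt = shuffled[cur][ptr[cur]]
            ptr[cur] += 1
            walk.append(nxt)
            cur = nxt
        out.append("".join(walk))
    return out


def dinuc_counts(sequence: str) -> dict:
    counts = {}
    for a, b in zip(sequence[:-1], sequence[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# attribution
# ---------------------------------------------------------------------------

@dataclass
class AttributionMap:
    scores: np.ndarray       # (L, 4) mean contribution per base and position
    projected: np.ndarray    # (L,) scores at the observed bases
    head: str
    reference_count: int
    deltas: np.ndarray       # per-reference f(x) - f(ref)

    @property
    def completeness_residual(self) -> float:
        """|sum(scores) - mean delta| / |mean delta|."""
        mean_delta = float(self.deltas.mean())
        return abs(float(self.scores.sum()) - mean_delta) / max(abs(mean_delta),
                                                                1e-12)


def _model_nets(model, corrected: bool):
    """(net, count weight, logit weight) triples whose outputs add up to the
    requested prediction: combined logits are a plain sum while combined
    log-counts weight the bias head by gamma."""
    if isinstance(model, BiasFactorizedModel):
        if corrected:
            return [(model.net_, 1.0, 1.0)]
        if model.count_combine != "add":
            raise ValueError("combined attribution requires count_combine='add'")
        return [(model.net_, 1.0, 1.0),
                (model.bias_model.net_, model.gamma_, 1.0)]
    return [(model.net_, 1.0, 1.0)]


def attribute(model: Union[ProfileCountModel, BiasFactorizedModel],
              sequence: str, head: str = "count", n_refs: int = 20,
              seed: int = 0, corrected: bool = True) -> AttributionMap:
    """DeepLIFT contributions of each input base against shuffled references.

    ``head`` selects the scalar being explained: the count head output, or
    the profile logits aggregated with the predicted probabilities as fixed
    weights. For a factorized model, ``corrected=True`` attributes the
    residual submodel alone.
    """
    if head not in ("count", "profile"):
        raise ValueError("head must be 'count' or 'profile'")
    seq = sequence.upper()
    n_frac = seq.count("N") / max(len(seq), 1)
    if n_frac > 0.2:
        raise ValueError(f"sequence is {n_frac:.0%} N; attribution meaningless")
    nets = _model_nets(model, corrected)
    input_len = nets[0][0].cfg.input_len
    if len(seq) != input_len:
        raise ValueError(f"sequence must be {input_len} bp")
    refs = dinuc_shuffle(seq, n=n_refs, seed=seed)
    x1 = one_hot(seq)[None]
    X = np.repeat(x1, n_refs, axis=0)
    R = np.stack([one_hot(r) for r in refs])

    total = None
    fx = 0.0
    frefs = np.zeros(n_refs)
    profile_w = None
    if head == "profile":
        # profile weights are the model's own combined/corrected
        # probabilities on the observed sequence, held fixed
        if isinstance(model, BiasFactorizedModel):
            profile_w = model.predict_profile(x1, corrected=corrected)[0]
        else:
            profile_w = model.predict_profile(x1)[0]
        profile_w = profile_w.astype(np.float64)
    for net, count_w, logit_w in nets:
        logits_x, counts_x = net.forward(x1)
        logits_r, counts_r = net.forward(R)
        if head == "count":
            dlogits = np.zeros((n_refs, net.cfg.output_len), dtype=net.dtype)
            dcounts = np.full(n_refs, count_w, dtype=net.dtype)
            fx += count_w * float(counts_x[0])
            frefs += count_w * counts_r
        else:
            dlogits = np.repeat(profile_w[None] * logit_w, n_refs,
                                axis=0).astype(net.dtype)
            dcounts = np.zeros(n_refs, dtype=net.dtype)
            fx += logit_w * float(profile_w @ logits_x[0])
            frefs += logit_w * (logits_r @ profile_w)
        contrib = net.deeplift(X, R, dlogits, dcounts)
        total = contrib if total is None else total + contrib
    scores = total.mean(axis=0).astype(np.float64)
    projected = (scores * x1[0]).sum(axis=1)
    return AttributionMap(scores=scores, projected=projected, head=head,
                          reference_count=n_refs, deltas=fx - frefs)


# ---------------------------------------------------------------------------
# marginal footprinting
# ---------------------------------------------------------------------------

@dataclass
class MarginalFootprint:
    profile: np.ndarray      # smoothed, scaled footprint M
    rs: int                  # left valley boundary
    ls: int                  # right valley boundary
    height: float
    width: int
    log_fc: float            # log total-count fold change vs controls
    degenerate: bool = False


def insert_motif(background: str, motif: str) -> str:
    """Replace bases at the centre of the background with the motif
    (even-length motifs sit 1 bp left of centre)."""
    if len(motif) > len(background):
        raise ValueError("motif longer than background sequence")
    start = len(background) // 2 - (len(motif) + 1) // 2
    return background[:start] + motif + background[start + len(motif):]


def _predict_profile_counts(model, X, corrected: bool):
    """(probabilities, total counts) for a batch."""
    if isinstance(model, BiasFactorizedModel):
        fp = model.predict_factorized(X)
        part = fp.tf_part if corrected else fp.combined
    else:
        part = model.predict_prediction(X)
    return part.probabilities, np.maximum(part.total_counts, 1e-9)


def _mean_response_profile(model, seqs: Sequence[str], corrected: bool,
                           batch: int = 64) -> np.ndarray:
    """Average of softmax(f)*exp(S), strand-averaged, over a library."""
    fwd = np.stack([one_hot(s) for s in seqs])
    rev = np.stack([one_hot(reverse_complement(s)) for s in seqs])
    acc = None
    for X, flip in ((fwd, False), (rev, True)):
        p, n = _predict_profile_counts(model, X, corrected)
        prof = p * n[:, None]
        if flip:
            prof = prof[:, ::-1]
        acc = prof if acc is None else acc + prof
    return (acc / 2).mean(axis=0)


def marginal_footprint(model, motif: str, backgrounds: Sequence[str],
                       corrected: bool = True,
                       smooth_width: int = 5) -> MarginalFootprint:
    """Marginal footprint of a motif over a background-sequence library.

    Steps: insert the motif at each background's centre; predict profiles for
    each sequence and its reverse complement (flipping the latter); convert to
    response profiles softmax(f)*exp(S); average over strands and the library.
    Controls come from the uninserted backgrounds. The reported footprint M is
    the probability-normalized inserted profile scaled by exp(log fold change
    of totals vs control), smoothed with a width-5 moving average.
    """
    if not backgrounds:
        raise ValueError("background library is empty")
    inserted = [insert_motif(b, motif) for b in backgrounds]
    fp_with = _mean_response_profile(model, inserted, corrected)
    fp_ctrl = _mean_response_profile(model, list(backgrounds), corrected)
    log_fc = float(np.log(fp_with.sum() / fp_ctrl.sum()))
    prob = fp_with / fp_with.sum()
    scaled = prob * np.exp(log_fc)
    kernel = np.ones(smooth_width) / smooth_width
    M = np.convolve(scaled, kernel, mode="same")
    center = len(M) // 2
    rs, ls, height, width, degenerate = footprint_geometry(M, center)
    return MarginalFootprint(profile=M, rs=rs, ls=ls, height=height,
                             width=width, log_fc=log_fc, degenerate=degenerate)


def footprint_geometry(M: np.ndarray, center: int, eps: float = 1e-12):
    """Valley geometry from maximum gradient change.

    The boundary on each side of ``center`` is the position of maximum
    second-difference magnitude (ties broken toward the centre). Height is
    max(M[:rs], M[ls:]) - min(M[rs:ls+1]); width is ls - rs. A flat profile
    is reported as degenerate with zero height and width.

    Returns (rs, ls, height, width, degenerate).
    """
    M = np.asarray(M, dtype=np.float64)
    L = len(M)
    if not 0 < center < L - 1:
        raise ValueError("center must be interior to the profile")
    d2 = np.abs(M[2:] - 2 * M[1:-1] + M[:-2])  # |second difference| at 1..L-2
    if d2.max() < eps:
        return center, center, 0.0, 0, True
    left_idx = np.arange(1, L - 1)[np.arange(1, L - 1) < center]
    right_idx = np.arange(1, L - 1)[np.arange(1, L - 1) > center]
    dl = d2[left_idx - 1]
    rs = int(left_idx[::-1][np.argmax(dl[::-1])])   # ties -> nearest centre
    dr = d2[right_idx - 1]
    ls = int(right_idx[np.argmax(dr)])              # ties -> nearest centre
    outside = []
    if rs > 0:
        outside.append(M[:rs].max())
    if ls < L:
        outside.append(M[ls:].max())
    height = float(max(outside) - M[rs: ls + 1].min())
    return rs, ls, height, int(ls - rs), False


# ---------------------------------------------------------------------------
# background libraries and the audit report
# ---------------------------------------------------------------------------

def sample_background_library(genome, peaks, n: int = 100,
                              length: Optional[int] = None, seed: int = 0,
                              model=None) -> List[str]:
    """Random genomic sequences GC-matched to the peak set, for footprinting.

    Draws windows away from peaks whose GC content falls within the central
    80% of the peak GC distribution.
    """
    from .tracks import gc_content, overlaps_any
    rng = np.random.default_rng(seed)
    if length is None:
        if model is None:
            raise ValueError("need either length or a model")
        length = model.input_len
    peak_gc = [gc_content(genome.fetch(iv.chrom, iv.start, iv.end))
               for iv in peaks]
    lo, hi = np.quantile(peak_gc, [0.1, 0.9])
    by_chrom = peaks.by_chrom()
    from .tracks import Interval
    out = []
    tries = 0
    while len(out) < n and tries < 200 * n:
        tries += 1
        c = genome.chrom_names[rng.integers(len(genome.chrom_names))]
        if genome.chrom_lengths[c] <= length:
            continue
        start = int(rng.integers(0, genome.chrom_lengths[c] - length))
        iv = Interval(c, start, start + length)
        if overlaps_any(iv, by_chrom):
            continue
        seq = genome.fetch(c, start, start + length)
        if "N" in seq:
            continue
        if lo <= gc_content(seq) <= hi:
            out.append(seq)
    if len(out) < n:
        raise RuntimeError(f"could only sample {len(out)}/{n} GC-matched "
                           "background sequences")
    return out


def bias_audit_report(model: BiasFactorizedModel, bias_kmers: Sequence[str],
                      tf_motifs: Sequence[str], backgrounds: Sequence[str],
                      bias_ratio_max: float = 0.2,
                      tf_ratio_range=(0.8, 1.2)) -> pd.DataFrame:
    """Verify bias correction by marginal footprinting.

    For every bias k-mer and TF motif, measures the footprint height with the
    full (uncorrected) prediction and with the bias-corrected prediction.
    PASS requires every bias k-mer's corrected/uncorrected height ratio below
    ``bias_ratio_max`` and every TF motif's ratio within ``tf_ratio_range``.
    The returned table carries a ``passed`` attribute in ``df.attrs``.
    """
    if not bias_kmers or not tf_motifs:
        raise ValueError("bias_kmers and tf_motifs must both be non-empty")
    rows = []
    ok = True
    for kind, motifs in (("bias", bias_kmers), ("tf", tf_motifs)):
        for m in motifs:
            unc = marginal_footprint(model, m, backgrounds, corrected=False)
            cor = marginal_footprint(model, m, backgrounds, corrected=True)
            ratio = cor.height / unc.height if unc.height > 0 else np.nan
            if kind == "bias":
                passed = bool(ratio < bias_ratio_max)
            else:
                passed = bool(tf_ratio_range[0] <= ratio <= tf_ratio_range[1])
            ok &= passed
            rows.append({"kind": kind, "motif": m,
                         "uncorrected_height": unc.height,
                         "corrected_height": cor.height,
                         "ratio": ratio, "passed": passed})
    df = pd.DataFrame(rows)
    df.attrs["passed"] = bool(ok)
    return df
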