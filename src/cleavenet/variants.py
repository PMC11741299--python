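"""Allele-substitution effect scoring across cross-validation folds.

For a SNV with alleles a1 (ref) and a2 (alt), each fold's model scores the
pair of sequences S1, S2 built by substituting the alleles at the centre of
the input window:

* ``logFC = log f(S2) - log f(S1)`` where f is the predicted total count;
* ``JSD`` between the two predicted probability profiles (Kullback-Leibler
  with natural log, no square root), signed by sign(logFC);
* ``AAQ`` (active allele quantile): the larger allele's empirical percentile
  of predicted log counts within the fold's peak-count distribution.

Aggregates over folds: ``IES = mean(logFC) * mean(signed JSD)`` and
``IPS = mean(|logFC|) * mean(|JSD|) * mean(AAQ)`` (non-negative by
construction). Empirical p-values compare the observed IPS with IPS scores of
dinucleotide-shuffled windows carrying the same alleles.

Scores use bias-corrected predictions by default; ``corrected=False`` exposes
the uncorrected ablation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .interpret import dinuc_shuffle
from .models import BiasFactorizedModel, ProfileCountModel
from .nn import one_hot
from .tracks import GenomeSequence, reverse_complement


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str

    def __post_init__(self):
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only SNVs are supported")


def read_variants(path: str) -> List[Variant]:
    """Read SNVs from a TSV (chrom, pos, ref, alt; 1-based) or a VCF."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        out = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.split("\t")
                for alt in f[4].split(","):
                    if len(f[3]) == 1 and len(alt) == 1:
                        out.append(Variant(f[0], int(f[1]), f[3], alt))
        return out
    df = pd.read_csv(path, sep="\t")
    return [Variant(r["chrom"], int(r["pos"]), r["ref"], r["alt"])
            for _, r in df.iterrows()]


def jsd_natural(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence with natural log (in [0, ln 2])."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)
    return float(0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum())


def _predict_pair(model, X, corrected: bool):
    """(probabilities, log predicted counts) for a batch of windows."""
    if isinstance(model, BiasFactorizedModel):
        fp = model.predict_factorized(X)
        part = fp.tf_part if corrected else fp.combined
    else:
        part = model.predict_prediction(X)
    counts = np.maximum(part.total_counts, 1e-9)
    return part.probabilities, np.log(counts)


def _allele_windows(genome: GenomeSequence, variant: Variant, input_len: int):
    pos0 = variant.pos - 1
    lo = pos0 - input_len // 2
    hi = lo + input_len
    if lo < 0 or hi > genome.chrom_lengths[variant.chrom]:
        raise ValueError(f"variant {variant} too close to chromosome edge")
    seq = genome.fetch(variant.chrom, lo, hi)
    centre = pos0 - lo
    if seq[centre] != variant.ref.upper():
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: genome has "
            f"{seq[centre]}, variant says {variant.ref}")
    s1 = seq
    s2 = seq[:centre] + variant.alt.upper() + seq[centre + 1:]
    return s1, s2


@dataclass
class VariantScoreRecord:
    variant: Variant
    logfc: np.ndarray       # per fold
    jsd: np.ndarray         # per fold, signed
    aaq: np.ndarray         # per fold, in [0, 1]
    ies: float
    ips: float
    pvalue: Optional[float] = None

    def to_row(self) -> dict:
        row = {"chrom": self.variant.chrom, "pos": self.variant.pos,
               "ref": self.variant.ref, "alt": self.variant.alt}
        for i, (l, j, a) in enumerate(zip(self.logfc, self.jsd, self.aaq)):
            row.update({f"logfc_{i}": l, f"jsd_{i}": j, f"aaq_{i}": a})
        row.update({"mean_logfc": float(self.logfc.mean()),
                    "mean_jsd": float(self.jsd.mean()),
                    "ies": self.ies, "ips": self.ips})
        if self.pvalue is not None:
            row["pvalue"] = self.pvalue
        return row


def _scores_from_windows(models: Sequence, s1: str, s2: str,
                         peak_log_counts: Sequence[np.ndarray],
                         corrected: bool):
    logfc, jsd, aaq = [], [], []
    X = np.stack([one_hot(s1), one_hot(s2)])
    for model, peaks_lc in zip(models, peak_log_counts):
        probs, logc = _predict_pair(model, X, corrected)
        lfc = float(logc[1] - logc[0])
        d = jsd_natural(probs[0], probs[1])
        sign = 1.0 if lfc > 0 else (-1.0 if lfc < 0 else 0.0)
        pl = np.asarray(peaks_lc, dtype=np.float64)
        pct = [float((pl <= c).mean()) for c in logc]
        logfc.append(lfc)
        jsd.append(sign * d)
        aaq.append(max(pct))
    logfc = np.array(logfc)
    jsd = np.array(jsd)
    aaq = np.array(aaq)
    ies = float(logfc.mean() * jsd.mean())
    ips = float(np.abs(logfc).mean() * np.abs(jsd).mean() * aaq.mean())
    return logfc, jsd, aaq, ies, ips


def score_variant(models: Sequence, genome: GenomeSequence, variant: Variant,
                  peak_log_counts: Sequence[np.ndarray],
                  corrected: bool = True) -> VariantScoreRecord:
    """Score one SNV across fold models.

    ``peak_log_counts`` holds, per fold, the predicted log counts over that
    fold's peak set (the AAQ reference distribution).
    """
    input_len = models[0].input_len
    s1, s2 = _allele_windows(genome, variant, input_len)
    logfc, jsd, aaq, ies, ips = _scores_from_windows(
        models, s1, s2, peak_log_counts, corrected)
    return VariantScoreRecord(variant=variant, logfc=logfc, jsd=jsd, aaq=aaq,
                              ies=ies, ips=ips)


def empirical_pvalue(variant: Variant, models: Sequence,
                     genome: GenomeSequence,
                     peak_log_counts: Sequence[np.ndarray],
                     n_null: int = 10_000, seed: int = 0,
                     corrected: bool = True) -> float:
    """Empirical p of the variant's IPS against a dinucleotide-shuffled null.

    Null windows are dinucleotide shuffles of the reference window with the
    ref/alt alleles reintroduced at the centre. Uses the add-one pseudocount:
    p = (1 + #{null IPS >= observed}) / (1 + n_null).
    """
    input_len = models[0].input_len
    s1, s2 = _allele_windows(genome, variant, input_len)
    _, _, _, _, obs_ips = _scores_from_windows(models, s1, s2,
                                               peak_log_counts, corrected)
    centre = input_len // 2
    shuffles = dinuc_shuffle(s1, n=n_null, seed=seed)
    ge = 0
    for shuf in shuffles:
        n1 = shuf[:centre] + variant.ref.upper() + shuf[centre + 1:]
        n2 = shuf[:centre] + variant.alt.upper() + shuf[centre + 1:]
        _, _, _, _, null_ips = _scores_from_windows(models, n1, n2,
                                                    peak_log_counts, corrected)
        if null_ips >= obs_ips:
            ge += 1
    return (1 + ge) / (1 + n_null)


def score_variants_table(models: Sequence, genome: GenomeSequence,
                         variants: Sequence[Variant],
                         peak_log_counts: Sequence[np.ndarray],
                         corrected: bool = True) -> pd.DataFrame:
    records = [score_variant(models, genome, v, peak_log_counts, corrected)
               for v in variants]
    return pd.DataFrame([r.to_row() for r in records])


def enrichment_curve(scores: np.ndarray, pips: np.ndarray,
                     score_thresholds: Sequence[float],
                     pip_thresholds: Sequence[float],
                     control_pip_max: float = 0.0) -> pd.DataFrame:
    """Fine-mapped-overlap enrichment over a threshold grid.

    Observed(t, p) = #{variants with PIP > p and score > t}. Expected(t, p) =
    (rate of score > t among control variants with PIP <= control_pip_max)
    * #{PIP > p}. Enrichment = Observed / Expected.
    """
    scores = np.asarray(scores, dtype=np.float64)
    pips = np.asarray(pips, dtype=np.float64)
    controls = pips <= control_pip_max
    if controls.sum() == 0:
        raise ValueError("no control variants at the control PIP threshold")
    rows = []
    for t in score_thresholds:
        bg_rate = float((scores[controls] > t).mean())
        for p in pip_thresholds:
            fine = pips > p
            observed = int((fine & (scores > t)).sum())
            expected = bg_rate * int(fine.sum())
            rows.append({"score_threshold": t, "pip_threshold": p,
                         "observed": observed, "expected": expected,
                         "enrichment": observed / expected if expected > 0
                         else np.nan})
    return pd.DataFrame(rows)
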