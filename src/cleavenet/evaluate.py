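"""Model evaluation: count correlation, profile JSD with reference baselines,
and genome-wide classification with positive/ambiguous/negative bin labels.

Note on the two JSD conventions in this package: evaluation uses base-2 logs
(so the divergence lies in [0, 1]); variant scoring uses natural logs. Both
are divergences, not square-root distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import rel_entr
from scipy.stats import pearsonr
from sklearn.metrics import average_precision_score, roc_auc_score

from .nn import one_hot
from .tracks import CoverageTrack, GenomeSequence, Interval, RegionSet


def count_metric(obs_totals, pred_log_counts) -> float:
    """Pearson r between observed log(1+total) and predicted log counts."""
    obs = np.log1p(np.asarray(obs_totals, dtype=np.float64))
    pred = np.asarray(pred_log_counts, dtype=np.float64)
    return float(pearsonr(obs, pred)[0])


def profile_jsd(p, q) -> float:
    """Jensen-Shannon divergence with base-2 logs; symmetric, in [0, 1]."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("profiles must have positive mass")
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)
    ln2 = np.log(2.0)
    return float((0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum()) / ln2)


def jsd_baselines(profiles: np.ndarray, seed: int = 0) -> Dict[str, np.ndarray]:
    """Reference JSD distributions for a set of observed count profiles.

    * ``pseudorep``: JSD between two random 50/50 read splits of each profile
      (the concordance upper bound — approaches 0 with depth);
    * ``mean``: JSD of each profile against the region-set average profile;
    * ``shuffled``: JSD of each profile against a within-region permutation.
    """
    rng = np.random.default_rng(seed)
    profiles = np.asarray(profiles, dtype=np.float64)
    keep = profiles.sum(axis=1) > 0
    profiles = profiles[keep]
    mean_profile = profiles.sum(axis=0)
    out = {"pseudorep": [], "mean": [], "shuffled": []}
    for k in profiles:
        a = rng.binomial(k.astype(np.int64), 0.5)
        b = k - a
        if a.sum() > 0 and b.sum() > 0:
            out["pseudorep"].append(profile_jsd(a, b))
        out["mean"].append(profile_jsd(k, mean_profile))
        out["shuffled"].append(profile_jsd(k, rng.permutation(k)))
    return {k: np.array(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# genome-wide bin labeling
# ---------------------------------------------------------------------------

@dataclass
class BinLabelSet:
    """Per-bin labels with reason codes; ambiguous bins are excluded from
    AUROC/AUPRC."""

    table: pd.DataFrame  # chrom, start, end, label, reason

    def to_bed(self, path: str) -> None:
        t = self.table.sort_values(["chrom", "start"])
        with open(path, "w") as fh:
            for _, r in t.iterrows():
                name = r["label"] if r["reason"] == "" else \
                    f"{r['label']}:{r['reason']}"
                fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{name}\n")


def _coverage_fraction(bins_start, bins_end, regions: RegionSet, chrom: str,
                       L: int) -> np.ndarray:
    """Fraction of each bin covered by the union of regions on one chrom."""
    mask = np.zeros(L, dtype=bool)
    for iv in regions:
        if iv.chrom == chrom:
            mask[max(0, iv.start): min(L, iv.end)] = True
    cum = np.concatenate([[0], np.cumsum(mask)])
    return (cum[bins_end] - cum[bins_start]) / (bins_end - bins_start)


def label_bins(genome: GenomeSequence, idr_peaks: RegionSet,
               overlap_peaks: RegionSet, blacklist: RegionSet,
               mappability: Optional[RegionSet] = None,
               bin_size: int = 100, summit_flank: int = 100) -> BinLabelSet:
    """Positive / ambiguous / negative labels over genome-wide bins.

    Positive regions are IDR summits extended by ``summit_flank`` on both
    sides; a bin is positive when fully covered by them. Ambiguous bins are:
    partial (<100%) IDR-region overlap; any overlap-peak overlap without being
    positive; any blacklist overlap; or <50% uniquely-mappable positions (when
    a mappability set is supplied — otherwise that rule is skipped with a
    warning). Everything else is negative.
    """
    if mappability is None:
        warnings.warn("no mappability intervals supplied; mappability rule skipped")
    pos_regions = RegionSet([
        Interval(iv.chrom, max(0, iv.summit_pos - summit_flank),
                 iv.summit_pos + summit_flank)
        for iv in idr_peaks])
    rows = []
    for chrom in genome.chrom_names:
        L = genome.chrom_lengths[chrom]
        starts = np.arange(0, L - bin_size + 1, bin_size)
        ends = starts + bin_size
        f_pos = _coverage_fraction(starts, ends, pos_regions, chrom, L)
        f_ovl = _coverage_fraction(starts, ends, overlap_peaks, chrom, L)
        f_bl = _coverage_fraction(starts, ends, blacklist, chrom, L)
        f_map = (np.ones(len(starts)) if mappability is None else
                 _coverage_fraction(starts, ends, mappability, chrom, L))
        for s, e, fp, fo, fb, fm in zip(starts, ends, f_pos, f_ovl, f_bl, f_map):
            if fp >= 1.0:
                label, reason = "positive", ""
            elif fp > 0:
                label, reason = "ambiguous", "partial_idr"
            elif fo > 0:
                label, reason = "ambiguous", "overlap_peak"
            elif fb > 0:
                label, reason = "ambiguous", "blacklist"
            elif fm < 0.5:
                label, reason = "ambiguous", "low_mappability"
            else:
                label, reason = "negative", ""
            # blacklist overrides everything except positivity per printed rules
            if label != "positive" and fb > 0:
                label, reason = "ambiguous", reason or "blacklist"
            rows.append({"chrom": chrom, "start": int(s), "end": int(e),
                         "label": label, "reason": reason})
    return BinLabelSet(pd.DataFrame(rows))


def genomewide_classification(model, genome: GenomeSequence,
                              labels: BinLabelSet, window: int = 1000,
                              stride: int = 250, aggregate: str = "max",
                              batch: int = 64) -> Dict[str, float]:
    """AUROC/AUPRC of per-bin predicted log counts vs bin labels.

    Predictions are made on windows tiling each chromosome with the given
    stride; each labeled bin's score aggregates (max by default, mean by flag)
    the predicted log counts of all windows covering it.
    """
    input_len = model.input_len
    scores_by_chrom: Dict[str, tuple] = {}
    for chrom in genome.chrom_names:
        L = genome.chrom_lengths[chrom]
        centers = np.arange(window // 2, L - window // 2 + 1, stride)
        centers = centers[(centers - input_len // 2 >= 0)
                          & (centers + input_len // 2 <= L)]
        if len(centers) == 0:
            continue
        preds = []
        for i in range(0, len(centers), batch):
            X = np.stack([
                one_hot(genome.fetch(chrom, int(c) - input_len // 2,
                                     int(c) + input_len // 2))
                for c in centers[i: i + batch]])
            preds.append(np.asarray(model.predict(X)))
        scores_by_chrom[chrom] = (centers, np.concatenate(preds))
    t = labels.table
    bin_scores, bin_labels = [], []
    for _, r in t[t["label"] != "ambiguous"].iterrows():
        entry = scores_by_chrom.get(r["chrom"])
        if entry is None:
            continue
        centers, preds = entry
        covering = (centers - window // 2 < r["end"]) & \
                   (centers + window // 2 > r["start"])
        if not covering.any():
            continue
        vals = preds[covering]
        bin_scores.append(vals.max() if aggregate == "max" else vals.mean())
        bin_labels.append(1 if r["label"] == "positive" else 0)
    y = np.array(bin_labels)
    s = np.array(bin_scores)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need both positive and negative bins")
    return {"auroc": float(roc_auc_score(y, s)),
            "auprc": float(average_precision_score(y, s)),
            "prevalence": float(y.mean()), "n_bins": int(len(y))}
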