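"""Genomes, intervals and base-resolution cut-site coverage.

Coordinates are 0-based half-open (BED convention) everywhere; peak summits
are stored as offsets from the interval start. Cut sites are the 5' ends of
aligned reads; assay-specific shifts recentre them on the enzyme's point of
action (+4/-4 for Tn5 transposition in ATAC, 0/+1 for DNase-I cleavage).
Coverage tracks pool both strands after shifting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

log = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# (plus-strand shift, minus-strand shift) applied to 5' read-end positions
ASSAY_SHIFTS = {"ATAC": (4, -4), "DNASE": (0, 1)}


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class GenomeSequence:
    """In-memory genome with bounds-checked, uppercase sequence access."""

    def __init__(self, chroms: Dict[str, str]):
        self._seqs = {c: s.upper() for c, s in chroms.items()}
        self.chrom_names = list(self._seqs)
        self.chrom_lengths = {c: len(s) for c, s in self._seqs.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeSequence":
        from pyfaidx import Fasta
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= self.chrom_lengths[chrom]):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds "
                f"(length {self.chrom_lengths[chrom]})")
        return self._seqs[chrom][start:end]

    def write_fasta(self, path: str, width: int = 80) -> None:
        with open(path, "w") as fh:
            for c in self.chrom_names:
                fh.write(f">{c}\n")
                s = self._seqs[c]
                for i in range(0, len(s), width):
                    fh.write(s[i: i + width] + "\n")


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    summit: Optional[int] = None  # offset from start
    name: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")
        if self.summit is not None and not (0 <= self.summit < self.end - self.start):
            raise ValueError("summit offset outside interval")

    @property
    def summit_pos(self) -> int:
        off = self.summit if self.summit is not None else (self.end - self.start) // 2
        return self.start + off

    def overlaps(self, other: "Interval") -> bool:
        return (self.chrom == other.chrom and self.start < other.end
                and other.start < self.end)


class RegionSet:
    """Ordered set of genomic intervals with BED/narrowPeak round-trip."""

    def __init__(self, intervals: Iterable[Interval] = ()):
        self.intervals: List[Interval] = list(intervals)

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def sorted(self) -> "RegionSet":
        return RegionSet(sorted(self.intervals,
                                key=lambda iv: (iv.chrom, iv.start, iv.end)))

    @classmethod
    def from_bed(cls, path: str) -> "RegionSet":
        out = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                summit = None
                if len(f) >= 10 and f[9] not in (".", "-1"):
                    summit = int(f[9])
                name = f[3] if len(f) >= 4 else "."
                out.append(Interval(f[0], int(f[1]), int(f[2]),
                                    summit=summit, name=name))
        return cls(out)

    def to_bed(self, path: str, narrowpeak: bool = False) -> None:
        with open(path, "w") as fh:
            for iv in self.sorted():
                if narrowpeak:
                    summit = iv.summit if iv.summit is not None else -1
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}"
                             f"\t0\t.\t0\t-1\t-1\t{summit}\n")
                else:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")

    def by_chrom(self) -> Dict[str, np.ndarray]:
        """chrom -> (n, 2) sorted start/end arrays, for overlap queries."""
        grouped: Dict[str, list] = {}
        for iv in self.intervals:
            grouped.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {c: np.array(sorted(v), dtype=np.int64).reshape(-1, 2)
                for c, v in grouped.items()}


def overlaps_any(iv: Interval, by_chrom: Dict[str, np.ndarray]) -> bool:
    arr = by_chrom.get(iv.chrom)
    if arr is None or arr.shape[0] == 0:
        return False
    i = np.searchsorted(arr[:, 0], iv.end)
    return bool(np.any(arr[:i, 1] > iv.start))


@dataclass(frozen=True)
class CutSite:
    chrom: str
    pos: int  # 5' read end, 0-based
    strand: str  # '+' or '-'


class CoverageTrack:
    """Per-chromosome unstranded integer cut-count vectors."""

    def __init__(self, counts: Dict[str, np.ndarray]):
        self.counts = {c: np.asarray(v, dtype=np.int64) for c, v in counts.items()}
        self.n_dropped = 0

    @classmethod
    def zeros(cls, genome: GenomeSequence) -> "CoverageTrack":
        return cls({c: np.zeros(genome.chrom_lengths[c], dtype=np.int64)
                    for c in genome.chrom_names})

    def total(self) -> int:
        return int(sum(v.sum() for v in self.counts.values()))

    def region_counts(self, chrom: str, start: int, end: int) -> np.ndarray:
        arr = self.counts[chrom]
        start = max(start, 0)
        end = min(end, len(arr))
        return arr[start:end]

    def region_total(self, chrom: str, start: int, end: int) -> int:
        return int(self.region_counts(chrom, start, end).sum())

    # -- bedGraph (canonical on-disk format) --------------------------------
    def write_bedgraph(self, path: str) -> None:
        with open(path, "w") as fh:
            for c in sorted(self.counts):
                arr = self.counts[c]
                nz = np.flatnonzero(np.diff(arr) != 0) + 1
                bounds = np.concatenate([[0], nz, [len(arr)]])
                for s, e in zip(bounds[:-1], bounds[1:]):
                    v = arr[s]
                    if v != 0:
                        fh.write(f"{c}\t{s}\t{e}\t{v}\n")

    @classmethod
    def from_bedgraph(cls, path: str, genome: GenomeSequence) -> "CoverageTrack":
        track = cls.zeros(genome)
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                c, s, e, v = line.split()[:4]
                track.counts[c][int(s):int(e)] += int(float(v))
        return track

    # -- bigWig (optional) ---------------------------------------------------
    def write_bigwig(self, path: str) -> None:
        import pyBigWig
        bw = pyBigWig.open(str(path), "w")
        bw.addHeader([(c, len(self.counts[c])) for c in sorted(self.counts)])
        for c in sorted(self.counts):
            arr = self.counts[c].astype(np.float64)
            bw.addEntries(c, 0, values=arr, span=1, step=1)
        bw.close()

    @classmethod
    def from_bigwig(cls, path: str, genome: GenomeSequence) -> "CoverageTrack":
        import pyBigWig
        bw = pyBigWig.open(str(path))
        counts = {}
        for c in genome.chrom_names:
            vals = np.nan_to_num(np.array(
                bw.values(c, 0, genome.chrom_lengths[c]), dtype=np.float64))
            counts[c] = np.rint(vals).astype(np.int64)
        bw.close()
        return cls(counts)


# ---------------------------------------------------------------------------
# cut-site BED6 IO
# ---------------------------------------------------------------------------

def write_cut_sites(sites: Sequence[CutSite], path: str) -> None:
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda s: (s.chrom, s.pos, s.strand)):
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t.\t0\t{s.strand}\n")


def read_cut_sites(path: str) -> List[CutSite]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(CutSite(f[0], int(f[1]), f[5] if len(f) > 5 else "+"))
    return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def shift_cut_site(site: CutSite, assay: str) -> CutSite:
    """Recentre a 5' read end on the enzyme's point of action.

    ATAC: +4 bp on the plus strand, -4 bp on the minus strand (the +4/-4
    convention that aligns the Tn5 dimer centre across strands). DNase: plus
    strand unshifted, minus strand +1 bp.
    """
    try:
        splus, sminus = ASSAY_SHIFTS[assay.upper()]
    except KeyError:
        raise ValueError(f"assay must be one of {sorted(ASSAY_SHIFTS)}, got {assay!r}")
    delta = splus if site.strand == "+" else sminus
    return replace(site, pos=site.pos + delta)


def unshift_cut_site(site: CutSite, assay: str) -> CutSite:
    splus, sminus = ASSAY_SHIFTS[assay.upper()]
    delta = splus if site.strand == "+" else sminus
    return replace(site, pos=site.pos - delta)


def build_coverage(sites: Sequence[CutSite], genome: GenomeSequence,
                   assay: str) -> CoverageTrack:
    """Unstranded per-base counts of assay-shifted cut sites.

    Sites whose shifted position falls outside the chromosome are dropped and
    counted on ``track.n_dropped`` (with one summary warning). Unknown
    chromosomes are an error.
    """
    track = CoverageTrack.zeros(genome)
    dropped = 0
    for site in sites:
        if site.chrom not in track.counts:
            raise KeyError(f"unknown chromosome {site.chrom!r} in cut sites")
        s = shift_cut_site(site, assay)
        if 0 <= s.pos < len(track.counts[s.chrom]):
            track.counts[s.chrom][s.pos] += 1
        else:
            dropped += 1
    track.n_dropped = dropped
    if dropped:
        warnings.warn(f"dropped {dropped} cut sites shifted outside chromosome bounds")
    return track


def strand_pwm_alignment_check(sites: Sequence[CutSite], genome: GenomeSequence,
                               k: int = 24,
                               shift_candidates: Sequence[Tuple[int, int]] = (
                                   (0, 0), (0, 1), (4, -4), (4, -5)),
                               min_sites_per_strand: int = 50):
    """Score candidate (plus, minus) strand shifts by cross-strand PWM agreement.

    For each candidate, builds a k-mer PWM from sequence flanking shifted plus
    reads and another from reverse-complemented flanks of shifted minus reads;
    the recommended shift maximizes the Pearson correlation between the two
    PWMs. Returns (DataFrame, recommended (plus, minus) shift or None on tie).
    """
    import pandas as pd
    from .nn import one_hot
    if k % 2:
        raise ValueError("k must be even")
    plus = [s for s in sites if s.strand == "+"]
    minus = [s for s in sites if s.strand == "-"]
    if len(plus) < min_sites_per_strand or len(minus) < min_sites_per_strand:
        raise ValueError(
            f"need >= {min_sites_per_strand} sites per strand, have "
            f"{len(plus)}+/{len(minus)}-")
    rows = []
    half = k // 2
    for splus, sminus in shift_candidates:
        pwm = {}
        for strand_sites, delta, rc in ((plus, splus, False), (minus, sminus, True)):
            counts = np.zeros((k, 4), dtype=np.float64)
            n = 0
            for s in strand_sites:
                p = s.pos + delta
                lo, hi = p - half, p + half
                if lo < 0 or hi > genome.chrom_lengths[s.chrom]:
                    continue
                seq = genome.fetch(s.chrom, lo, hi)
                if rc:
                    seq = reverse_complement(seq)
                counts += one_hot(seq, dtype=np.float64)
                n += 1
            counts += 0.25  # pseudocount
            pwm["-" if rc else "+"] = counts / counts.sum(axis=1, keepdims=True)
        agreement = float(np.corrcoef(pwm["+"].ravel(), pwm["-"].ravel())[0, 1])
        rows.append({"plus_shift": splus, "minus_shift": sminus,
                     "agreement": agreement, "plus_pwm": pwm["+"],
                     "minus_pwm": pwm["-"]})
    table = pd.DataFrame(rows)
    best = table["agreement"].max()
    winners = table[np.isclose(table["agreement"], best, atol=1e-9)]
    if len(winners) > 1:
        log.warning("strand-shift check: %d candidates tie at agreement %.4f",
                    len(winners), best)
        return table, None
    row = winners.iloc[0]
    return table, (int(row["plus_shift"]), int(row["minus_shift"]))


def enumerate_candidate_bins(genome: GenomeSequence, window: int,
                             stride: int) -> RegionSet:
    """All fully-contained bins starting at 0, stride, 2*stride, ..."""
    out = []
    for c in genome.chrom_names:
        L = genome.chrom_lengths[c]
        for start in range(0, L - window + 1, stride):
            out.append(Interval(c, start, start + window))
    return RegionSet(out)


def gc_content(seq: str) -> float:
    """G+C fraction of the full interval; N counts as neither."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def gc_match_negatives(candidates: RegionSet, peaks: RegionSet,
                       blacklist: RegionSet, genome: GenomeSequence,
                       multiplier: float = 2.0, bin_width: float = 0.01,
                       max_n_fraction: float = 0.05,
                       seed: int = 0) -> RegionSet:
    """Sample background regions whose GC distribution matches the peaks.

    Candidates overlapping any peak or blacklist interval by >= 1 bp, or with
    more than ``max_n_fraction`` N bases, are excluded. The target size is
    ``multiplier * len(peaks)``, allocated across 0.01-wide GC bins in
    proportion to the peak GC histogram; empty bins borrow from the nearest
    non-empty bin (logged).
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    rng = np.random.default_rng(seed)
    excl_peaks = peaks.by_chrom()
    excl_bl = blacklist.by_chrom()
    nbins = int(round(1.0 / bin_width)) + 1

    def gc_bin(iv: Interval) -> Optional[int]:
        seq = genome.fetch(iv.chrom, iv.start, iv.end)
        if seq.count("N") > max_n_fraction * len(seq):
            return None
        return min(int(gc_content(seq) / bin_width), nbins - 1)

    pool: Dict[int, list] = {}
    for iv in candidates:
        if overlaps_any(iv, excl_peaks) or overlaps_any(iv, excl_bl):
            continue
        b = gc_bin(iv)
        if b is not None:
            pool.setdefault(b, []).append(iv)

    peak_bins = [b for b in (gc_bin(iv) for iv in peaks) if b is not None]
    if not peak_bins:
        raise ValueError("no usable peaks for GC matching")
    want_total = int(round(multiplier * len(peaks)))
    hist = np.bincount(peak_bins, minlength=nbins).astype(np.float64)
    target = hist / hist.sum() * want_total
    # largest-remainder rounding to hit want_total exactly
    floor = np.floor(target).astype(int)
    rem = want_total - floor.sum()
    order = np.argsort(-(target - floor))
    floor[order[:rem]] += 1

    chosen: List[Interval] = []
    for b in range(nbins):
        need = floor[b]
        if need == 0:
            continue
        avail = pool.get(b, [])
        take = min(need, len(avail))
        if take:
            idx = rng.choice(len(avail), size=take, replace=False)
            chosen.extend(avail[i] for i in sorted(idx))
            pool[b] = [v for i, v in enumerate(avail) if i not in set(idx)]
        short = need - take
        if short:
            # borrow from nearest non-empty bins
            for dist in range(1, nbins):
                for nb in (b - dist, b + dist):
                    if short == 0:
                        break
                    if 0 <= nb < nbins and pool.get(nb):
                        avail = pool[nb]
                        t = min(short, len(avail))
                        idx = rng.choice(len(avail), size=t, replace=False)
                        chosen.extend(avail[i] for i in sorted(idx))
                        pool[nb] = [v for i, v in enumerate(avail)
                                    if i not in set(idx)]
                        short -= t
                        log.info("GC bin %d short; borrowed %d from bin %d",
                                 b, t, nb)
                if short == 0:
                    break
    if len(chosen) < want_total:
        warnings.warn(
            f"only {len(chosen)} GC-matched negatives available "
            f"(wanted {want_total})")
    return RegionSet(chosen).sorted()


def filter_training_peaks(peaks: RegionSet, track: CoverageTrack,
                          blacklist: RegionSet, genome: GenomeSequence,
                          window: int = 2114, count_window: int = 1000,
                          count_quantile: float = 0.99) -> RegionSet:
    """Drop outlier-count peaks, edge peaks and blacklist overlappers.

    A peak is removed when its total counts in ``count_window`` bp around the
    summit exceed the ``count_quantile`` (linear-interpolation) quantile over
    all peaks, when the ``window`` bp input window around the summit does not
    fit inside the chromosome, or when it overlaps the blacklist by >= 1 bp.
    """
    excl_bl = blacklist.by_chrom()
    totals = np.array([
        track.region_total(iv.chrom, iv.summit_pos - count_window // 2,
                           iv.summit_pos + count_window // 2)
        for iv in peaks], dtype=np.float64)
    if len(totals) == 0:
        return RegionSet()
    thresh = np.quantile(totals, count_quantile)
    kept = []
    for iv, tot in zip(peaks, totals):
        if tot > thresh:
            continue
        s = iv.summit_pos
        if s - window // 2 < 0 or s + window // 2 > genome.chrom_lengths[iv.chrom]:
            continue
        if overlaps_any(iv, excl_bl):
            continue
        kept.append(iv)
    return RegionSet(kept)


def subsample_track(sites: Sequence[CutSite], fraction: float,
                    seed: int = 1234) -> List[CutSite]:
    """Bernoulli thinning of cut sites at the given rate, seeded."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if fraction == 1.0:
        return list(sites)
    if fraction == 0.0:
        return []
    rng = np.random.default_rng(seed)
    keep = rng.random(len(sites)) < fraction
    return [s for s, k in zip(sites, keep) if k]
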