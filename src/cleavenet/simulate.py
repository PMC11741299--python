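"""Synthetic cleavage-profile generator with known ground truth.

The generator emulates the structure of an ATAC/DNase experiment at desk
scale: a random genome at a target GC content, accessible "peak" regions
whose accessibility is a smooth bump boosted by planted TF motif instances,
a k-mer enzyme sequence preference that multiplies the per-base cut rate
(shaping profiles without changing regional totals much), per-motif
protection footprints, and multinomially sampled stranded cut sites at a
configurable read depth. Because the per-base rate field is a deterministic
function of the sequence, variant effects have exact ground truth: mutate the
base, rebuild the field, compare window totals.

What it does not emulate: paired-end fragment structure, nucleosome
positioning, mappability artifacts or single-cell sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .nn import one_hot
from .tracks import CutSite, GenomeSequence, Interval, RegionSet, reverse_complement

BASES = "ACGT"


# ---------------------------------------------------------------------------
# ground-truth components
# ---------------------------------------------------------------------------

@dataclass
class BiasTruth:
    """Additive-log k-mer enzyme preference.

    ``weights`` is a (k, 4) matrix; the log preference of a k-mer is the sum
    of per-position weights. Each row is zero-centred so the mean log
    preference over all 4^k k-mers is exactly 0 (identifiability).
    """

    weights: np.ndarray
    assay: str = "ATAC"

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        self.weights = w - w.mean(axis=1, keepdims=True)
        self.k = self.weights.shape[0]

    @classmethod
    def tn5_like(cls, k: int = 6, scale: float = 1.0, assay: str = "ATAC") -> "BiasTruth":
        """A hand-set, roughly palindromic Tn5-flavoured 6-mer preference,
        strong enough to dominate profile shape at base resolution."""
        if k != 6:
            raise ValueError("the built-in preference is defined for k=6")
        #                A      C      G      T
        w = np.array([[-0.3,  0.5,  0.4, -0.6],
                      [-0.5,  0.3,  0.9, -0.7],
                      [ 0.8, -0.4, -0.2, -0.2],
                      [-0.2, -0.2, -0.4,  0.8],
                      [-0.7,  0.9,  0.3, -0.5],
                      [-0.6,  0.4,  0.5, -0.3]]) * scale
        return cls(weights=w, assay=assay)

    @property
    def top_kmer(self) -> str:
        """Most-preferred k-mer (per-position argmax; preference is additive)."""
        return "".join(BASES[i] for i in self.weights.argmax(axis=1))

    def log_preference(self, kmer: str) -> float:
        oh = one_hot(kmer, dtype=np.float64)
        return float((oh * self.weights).sum())

    def log_preference_field(self, seq: str) -> np.ndarray:
        """Per-position log preference of the k-mer centred at each position
        (k-mer spans [pos - k//2, pos - k//2 + k)); edge positions with a
        truncated k-mer get the contribution of in-range columns only."""
        oh = one_hot(seq, dtype=np.float64)
        L = len(seq)
        out = np.zeros(L, dtype=np.float64)
        per_pos = oh @ self.weights.T  # (L, k): column j = weight if base at
        # that position sat at k-mer offset j
        half = self.k // 2
        for j in range(self.k):
            shift = j - half  # k-mer offset j sits at pos + shift... invert
            src = per_pos[:, j]
            if shift <= 0:
                out[-shift:] += src[: L + shift] if shift else src
            else:
                out[: L - shift] += src[shift:]
        return out


@dataclass
class MotifTruth:
    """A planted TF motif: PWM, accessibility gain and protection footprint."""

    name: str
    pwm: np.ndarray  # (len, 4) position probability matrix
    access_effect: float = 4.0  # multiplicative accessibility gain per match
    protection: float = 0.5  # multiplicative cut suppression inside the motif
    match_threshold: float = 0.8  # fraction of max log-odds required for a hit

    def __post_init__(self):
        self.pwm = np.asarray(self.pwm, dtype=np.float64)
        if not np.allclose(self.pwm.sum(axis=1), 1.0):
            raise ValueError("pwm rows must sum to 1")
        if self.access_effect <= 0 or not (0 < self.protection <= 1):
            raise ValueError("access_effect > 0 and protection in (0, 1] required")

    @property
    def length(self) -> int:
        return self.pwm.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log(np.maximum(self.pwm, 1e-6) / 0.25)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmax(axis=1))

    def scan(self, seq: str) -> List[Tuple[int, float, str]]:
        """(start, score, strand) of matches >= threshold, both strands."""
        lo = self.log_odds
        thr = self.match_threshold * self.max_score
        hits = []
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            oh = one_hot(s, dtype=np.float64)
            L = len(s) - self.length + 1
            if L <= 0:
                continue
            scores = np.zeros(L)
            for j in range(self.length):
                scores += oh[j: j + L] @ lo[j]
            for i in np.flatnonzero(scores >= thr):
                start = i if strand == "+" else len(seq) - self.length - i
                hits.append((int(start), float(scores[i]), strand))
        return sorted(hits)

    def sample_instance(self, rng: np.random.Generator) -> str:
        idx = [rng.choice(4, p=row) for row in self.pwm]
        return "".join(BASES[i] for i in idx)


def default_motifs() -> List[MotifTruth]:
    """Three planted motifs with deep, moderate and shallow footprints."""

    def sharp_pwm(consensus: str, p: float = 0.95) -> np.ndarray:
        pwm = np.full((len(consensus), 4), (1 - p) / 3)
        for i, b in enumerate(consensus):
            pwm[i, BASES.index(b)] = p
        return pwm

    return [
        MotifTruth("deepTF", sharp_pwm("TGACGTCATC"), access_effect=6.0,
                   protection=0.15),
        MotifTruth("midTF", sharp_pwm("GGATTACCAG"), access_effect=4.0,
                   protection=0.45),
        MotifTruth("shallowTF", sharp_pwm("CACCTGTTGC"), access_effect=3.0,
                   protection=0.80),
    ]


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic experiment."""

    n_chroms: int = 4
    chrom_length: int = 500_000
    gc: float = 0.41
    peak_width: int = 800
    peak_spacing: int = 3_000
    edge_margin: int = 2_000
    weak_instance_fraction: float = 0.25  # peaks planted with a broken motif
    background_access: float = 0.02
    depth: int = 2_000_000
    seed: int = 0
    bias: Optional[BiasTruth] = None
    motifs: List[MotifTruth] = dc_field(default_factory=default_motifs)

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.bias is None:
            self.bias = BiasTruth.tn5_like()

    @property
    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-operation substream of the master seed."""
        import zlib
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stream.encode())])
        return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def generate_genome(spec: SimulationSpec) -> Tuple[GenomeSequence, RegionSet]:
    """Random genome at target GC with motif instances planted inside peaks.

    Peaks are evenly spaced (with small random offsets) and each receives one
    planted instance of a motif (cycled through the motif list) at its centre;
    a ``weak_instance_fraction`` of peaks instead receive the instance broken
    at its highest-information column, leaving room for motif-creating
    variants. Peak summits sit at planted-motif centres.
    """
    rng = np.random.default_rng(spec.seed)
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    peaks: List[Interval] = []
    chroms: Dict[str, str] = {}
    k = 0
    for c in spec.chrom_names:
        seq = rng.choice(list(BASES), size=spec.chrom_length, p=p)
        centers = np.arange(spec.edge_margin + spec.peak_width // 2,
                            spec.chrom_length - spec.edge_margin
                            - spec.peak_width // 2, spec.peak_spacing)
        centers = centers + rng.integers(-spec.peak_spacing // 4,
                                         spec.peak_spacing // 4 + 1,
                                         size=len(centers))
        for center in centers:
            motif = spec.motifs[k % len(spec.motifs)] if spec.motifs else None
            weak = False
            if motif is not None:
                # sample an instance from the PWM, resampling until it scores
                # above the match threshold (falls back to the consensus)
                inst = motif.consensus
                thr = motif.match_threshold * motif.max_score
                for _ in range(20):
                    cand = motif.sample_instance(rng)
                    score = sum(motif.log_odds[j, BASES.index(b)]
                                for j, b in enumerate(cand))
                    if score >= thr:
                        inst = cand
                        break
                if rng.random() < spec.weak_instance_fraction:
                    weak = True
                    col = int(motif.log_odds.max(axis=1).argmax())
                    worst = BASES[int(motif.pwm[col].argmin())]
                    inst = inst[:col] + worst + inst[col + 1:]
                start = int(center) - motif.length // 2
                seq[start: start + motif.length] = list(inst)
            s = int(center) - spec.peak_width // 2
            name = f"peak_{len(peaks)}" + ("_weak" if weak else "")
            peaks.append(Interval(c, s, s + spec.peak_width,
                                  summit=spec.peak_width // 2, name=name))
            k += 1
        chroms[c] = "".join(seq)
    return GenomeSequence(chroms), RegionSet(peaks)


# ---------------------------------------------------------------------------
# the true cut-rate field
# ---------------------------------------------------------------------------

def _accessibility(seq: str, peaks: Sequence[Interval], spec: SimulationSpec,
                   chrom: str) -> Tuple[np.ndarray, np.ndarray]:
    """(accessibility, protection) fields for one chromosome.

    accessibility = background + sum over peaks of a Gaussian bump
    (sigma = peak_width / 6) whose amplitude is 1 plus the summed access
    gains of PWM matches found *in the actual sequence* of the peak window;
    protection multiplies the rate down across every matched motif span.
    """
    L = len(seq)
    access = np.full(L, spec.background_access, dtype=np.float64)
    protect = np.ones(L, dtype=np.float64)
    sigma = spec.peak_width / 6.0
    pos = np.arange(L, dtype=np.float64)
    for iv in peaks:
        if iv.chrom != chrom:
            continue
        window = seq[iv.start: iv.end]
        gain = 0.0
        for motif in spec.motifs:
            for start, _score, _strand in motif.scan(window):
                gain += motif.access_effect
                lo = iv.start + start
                protect[lo: lo + motif.length] *= motif.protection
        center = iv.summit_pos
        lo, hi = max(0, center - 4 * int(sigma)), min(L, center + 4 * int(sigma))
        bump = np.exp(-0.5 * ((pos[lo:hi] - center) / sigma) ** 2)
        access[lo:hi] += (1.0 + gain) * bump
    return access, protect


def true_cut_rate(genome: GenomeSequence, spec: SimulationSpec,
                  peaks: RegionSet) -> Dict[str, np.ndarray]:
    """Per-base expected cut rate: accessibility x exp(bias) x protection."""
    rates = {}
    for c in genome.chrom_names:
        seq = genome.fetch(c, 0, genome.chrom_lengths[c])
        access, protect = _accessibility(seq, peaks, spec, c)
        bias = np.exp(spec.bias.log_preference_field(seq))
        rates[c] = access * bias * protect
    return rates


def sample_cut_sites(rates: Dict[str, np.ndarray], depth: int,
                     seed: int, assay: str = "ATAC") -> List[CutSite]:
    """Multinomial sample of ``depth`` cut events, with strands assigned so
    that the assay's read shift re-aligns both strands onto the cut centre
    (ATAC: + read at c-4 or - read at c+4; DNase: + at c or - at c-1)."""
    rng = np.random.default_rng(seed)
    if depth == 0:
        return []
    chroms = sorted(rates)
    mass = np.array([rates[c].sum() for c in chroms])
    per_chrom = rng.multinomial(depth, mass / mass.sum())
    plus_d, minus_d = {"ATAC": (-4, 4), "DNASE": (0, -1)}[assay.upper()]
    sites: List[CutSite] = []
    for c, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        r = rates[c]
        counts = rng.multinomial(n, r / r.sum())
        positions = np.repeat(np.flatnonzero(counts), counts[counts > 0])
        strands = rng.random(len(positions)) < 0.5
        L = len(r)
        for posn, is_plus in zip(positions, strands):
            if is_plus:
                read = int(posn) + plus_d
            else:
                read = int(posn) + minus_d
            read = min(max(read, 0), L - 1)
            sites.append(CutSite(c, read, "+" if is_plus else "-"))
    return sites


# ---------------------------------------------------------------------------
# variant sets with exact ground truth
# ---------------------------------------------------------------------------

def _window_total(rate: np.ndarray, center: int, width: int = 1000) -> float:
    lo = max(0, center - width // 2)
    return float(rate[lo: center + width // 2].sum())


def _chrom_rate(genome_seq: str, peaks: Sequence[Interval],
                spec: SimulationSpec, chrom: str) -> np.ndarray:
    access, protect = _accessibility(genome_seq, peaks, spec, chrom)
    bias = np.exp(spec.bias.log_preference_field(genome_seq))
    return access * bias * protect


def make_variant_set(genome: GenomeSequence, peaks: RegionSet,
                     spec: SimulationSpec, n_per_class: int = 100,
                     seed: int = 0) -> pd.DataFrame:
    """SNVs with exact ground-truth regional log fold changes.

    Three classes: ``decrease`` (break the highest-information column of a
    planted consensus instance), ``increase`` (restore the broken column of a
    planted weak instance), ``null`` (random background substitution far from
    any peak). ``true_logfc`` is the log ratio of total true cut rate in the
    1 kb window around the variant, alt over ref, recomputed from the rate
    field. Positions are 1-based (VCF convention).
    """
    rng = np.random.default_rng(seed)
    strong = [iv for iv in peaks if not iv.name.endswith("_weak")]
    weak = [iv for iv in peaks if iv.name.endswith("_weak")]
    rng.shuffle(strong)
    rng.shuffle(weak)
    motif_by_idx = {iv.name: spec.motifs[int(iv.name.split("_")[1]) % len(spec.motifs)]
                    for iv in peaks} if spec.motifs else {}
    rows = []
    _ref_rate_cache: Dict[str, np.ndarray] = {}

    def add_variant(chrom: str, pos0: int, alt: str, label: str):
        seq = genome.fetch(chrom, 0, genome.chrom_lengths[chrom])
        ref = seq[pos0]
        if ref == alt:
            return False
        chrom_peaks = [iv for iv in peaks if iv.chrom == chrom]
        if chrom not in _ref_rate_cache:
            _ref_rate_cache[chrom] = _chrom_rate(seq, chrom_peaks, spec, chrom)
        r_ref = _ref_rate_cache[chrom]
        alt_seq = seq[:pos0] + alt + seq[pos0 + 1:]
        r_alt = _chrom_rate(alt_seq, chrom_peaks, spec, chrom)
        lfc = np.log(_window_total(r_alt, pos0) / _window_total(r_ref, pos0))
        rows.append({"chrom": chrom, "pos": pos0 + 1, "ref": ref, "alt": alt,
                     "true_logfc": lfc, "label": label})
        return True

    for iv in strong:
        if sum(r["label"] == "decrease" for r in rows) >= n_per_class:
            break
        motif = motif_by_idx.get(iv.name)
        if motif is None:
            continue
        col = int(motif.log_odds.max(axis=1).argmax())
        pos0 = iv.summit_pos - motif.length // 2 + col
        worst = BASES[int(motif.pwm[col].argmin())]
        add_variant(iv.chrom, pos0, worst, "decrease")

    for iv in weak:
        if sum(r["label"] == "increase" for r in rows) >= n_per_class:
            break
        motif = motif_by_idx.get(iv.name)
        if motif is None:
            continue
        col = int(motif.log_odds.max(axis=1).argmax())
        pos0 = iv.summit_pos - motif.length // 2 + col
        add_variant(iv.chrom, pos0, motif.consensus[col], "increase")

    peak_arr = peaks.by_chrom()
    n_null = 0
    tries = 0
    while n_null < n_per_class and tries < 50 * n_per_class:
        tries += 1
        c = spec.chrom_names[rng.integers(len(spec.chrom_names))]
        pos0 = int(rng.integers(spec.edge_margin,
                                genome.chrom_lengths[c] - spec.edge_margin))
        probe = Interval(c, max(0, pos0 - 1500), pos0 + 1500)
        if tracks_overlap(probe, peak_arr):
            continue
        ref = genome.fetch(c, pos0, pos0 + 1)
        alt = BASES[(BASES.index(ref) + 1 + rng.integers(3)) % 4] \
            if ref in BASES else "A"
        if ref not in BASES:
            continue
        if add_variant(c, pos0, alt, "null"):
            n_null += 1
    return pd.DataFrame(rows)


def tracks_overlap(iv: Interval, by_chrom) -> bool:
    from .tracks import overlaps_any
    return overlaps_any(iv, by_chrom)


def write_variants_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_variants_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
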