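"""Branch point sequence prediction.

One branch point is predicted per intron by scanning candidate positions
up to 250 bp upstream of the 3' splice site and scoring each candidate
heptamer (branch point at position 6) with an additive log2 mixture of

* a 7-position position weight matrix (PWM) log-odds term, and
* a log-odds weight for the octanucleotide covering the heptamer plus one
  downstream base, trained by contrasting octamer frequencies in the
  polypyrimidine tract region (3-16 bp upstream of the 3' splice site)
  against a background region (187-200 bp upstream) of long introns.

Distances are counted so the last intronic base (second base of the
acceptor AG) has distance 1 from the 3' splice site; the predicted branch
point typically sits 14-145 bases upstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome_io import Intron

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: heptamer positions relative to the branch point (position 6 of 7)
HEPTAMER_LEN = 7
BP_POS_IN_HEPTAMER = 6  # 1-based

# octamer training regions, as distances from the intron 3' end
PPT_REGION = (3, 16)        # polypyrimidine tract, 14-mer
BACKGROUND_REGION = (187, 200)
MIN_TRAINING_INTRON = 301   # introns longer than 300 bp


def _octamer_index(octamer: str) -> int:
    idx = 0
    for ch in octamer:
        idx = idx * 4 + _BASE_INDEX[ch]
    return idx


class OctamerWeightTable:
    """Log2-odds weights over all 65,536 octanucleotides.

    weight(o) = log2 p_ppt(o) - log2 p_bg(o), with each probability
    pseudocount-smoothed over the full octamer space.
    """

    def __init__(self, pt_counts: np.ndarray, bg_counts: np.ndarray,
                 pseudocount: float = 1.0):
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        self.pt_counts = pt_counts
        self.bg_counts = bg_counts
        self.pseudocount = pseudocount
        n = 4 ** 8
        pt_total = pt_counts.sum() + pseudocount * n
        bg_total = bg_counts.sum() + pseudocount * n
        self._weights = (np.log2((pt_counts + pseudocount) / pt_total)
                         - np.log2((bg_counts + pseudocount) / bg_total))

    @classmethod
    def zeros(cls) -> "OctamerWeightTable":
        """A neutral table (weight 0 everywhere): pure-PWM prediction."""
        return cls(np.zeros(4 ** 8), np.zeros(4 ** 8))

    def weight(self, octamer: str) -> float:
        if len(octamer) != 8:
            raise ValueError("octamer must have length 8")
        if any(b not in _BASE_INDEX for b in octamer):
            raise ValueError(f"octamer {octamer!r} contains non-ACGT bases")
        return float(self._weights[_octamer_index(octamer)])

    def pt_count(self, octamer: str) -> int:
        return int(self.pt_counts[_octamer_index(octamer)])

    def bg_count(self, octamer: str) -> int:
        return int(self.bg_counts[_octamer_index(octamer)])


def _region_14mer(seq: str, region: tuple[int, int]) -> str | None:
    """The 14-mer whose bases lie at distances region[0]..region[1] from
    the intron 3' end (distance 1 = last base)."""
    lo, hi = region
    L = len(seq)
    start = L - hi       # 0-based index of the most 5' base
    end = L - lo + 1
    if start < 0:
        return None
    return seq[start:end]


def train_octamer_weights(introns: Iterable[Intron],
                          pseudocount: float = 1.0) -> OctamerWeightTable:
    """Accumulate octamer counts from long introns and build the table.

    Each qualifying intron (> 300 bp) contributes the 7 sliding octamers of
    its polypyrimidine-tract 14-mer and of its background 14-mer; windows
    containing N are skipped.
    """
    pt = np.zeros(4 ** 8)
    bg = np.zeros(4 ** 8)
    n_used = 0
    skipped_n = 0
    for intron in introns:
        if intron.length < MIN_TRAINING_INTRON:
            continue
        n_used += 1
        for region, counts in ((PPT_REGION, pt), (BACKGROUND_REGION, bg)):
            mer = _region_14mer(intron.sequence, region)
            if mer is None:
                continue
            for i in range(len(mer) - 7):
                oct_ = mer[i:i + 8]
                if "N" in oct_:
                    skipped_n += 1
                    continue
                counts[_octamer_index(oct_)] += 1
    if n_used == 0:
        raise ValueError("no introns longer than 300 bp; cannot train weights")
    if skipped_n:
        logger.info("train_octamer_weights skipped %d windows containing N",
                    skipped_n)
    return OctamerWeightTable(pt, bg, pseudocount)


class HeptamerPWM:
    """7 x 4 position probabilities with a background composition."""

    def __init__(self, probs: np.ndarray,
                 background: Sequence[float] = (0.25, 0.25, 0.25, 0.25)):
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (7, 4):
            raise ValueError(f"PWM must be 7x4, got {probs.shape}")
        if (probs <= 0).any():
            raise ValueError("all PWM entries must be positive")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        self.probs = probs
        self.background = np.asarray(background, dtype=float)
        if self.background.shape != (4,) or (self.background <= 0).any():
            raise ValueError("background must be 4 positive frequencies")

    @classmethod
    def from_file(cls, path) -> "HeptamerPWM":
        """Load a tab-separated 7-row x 4-column (A C G T) probability file."""
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if fields[0].upper() in ("A", "C", "G", "T") and len(fields) > 4:
                    fields = fields[1:]
                rows.append([float(x) for x in fields[:4]])
        return cls(np.array(rows))

    @classmethod
    def from_heptamers(cls, heptamers: Sequence[str],
                       pseudocount: float = 0.5) -> "HeptamerPWM":
        """Estimate the PWM from aligned heptamers with a per-cell pseudocount."""
        counts = np.full((7, 4), pseudocount, dtype=float)
        for h in heptamers:
            if len(h) != 7:
                raise ValueError(f"heptamer {h!r} does not have length 7")
            for i, b in enumerate(h):
                if b in _BASE_INDEX:
                    counts[i, _BASE_INDEX[b]] += 1
        return cls(counts / counts.sum(axis=1, keepdims=True))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# A\tC\tG\tT\n")
            for row in self.probs:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")

    def log_odds(self, heptamer: str) -> float:
        if len(heptamer) != 7:
            raise ValueError("heptamer must have length 7")
        total = 0.0
        for i, b in enumerate(heptamer):
            if b not in _BASE_INDEX:
                raise ValueError(f"non-ACGT base {b!r} in heptamer")
            j = _BASE_INDEX[b]
            total += math.log2(self.probs[i, j] / self.background[j])
        return total


def score_candidate(intron_sequence: str, bp_offset: int, pwm: HeptamerPWM,
                    weights: OctamerWeightTable) -> float:
    """Mixture score of the candidate branch point at oriented index
    ``bp_offset`` (1-based along the intron sequence).

    The heptamer spans indices bp_offset-5 .. bp_offset+1 and the scored
    octamer extends one further base downstream.
    """
    L = len(intron_sequence)
    start = bp_offset - BP_POS_IN_HEPTAMER + 1  # heptamer position 1
    end = bp_offset + 2                          # octamer last base
    if start < 1 or end > L:
        raise ValueError(
            f"candidate at {bp_offset} does not fit inside intron of length {L}")
    octamer = intron_sequence[start - 1:end]
    heptamer = octamer[:7]
    return pwm.log_odds(heptamer) + weights.weight(octamer)


@dataclass(frozen=True)
class BranchPointPrediction:
    """The single highest-scoring branch point of one intron."""

    intron_id: str
    chrom: str
    strand: str
    bp_distance: int         # bases from BP to the intron 3' end (last base = 1)
    heptamer: str
    score: float
    heptamer_start: int      # genomic, 1-based inclusive
    heptamer_end: int
    bp_pos: int              # genomic position of the branch point base
    splice_class: str = "GT-AG"

    @property
    def bp_base(self) -> str:
        return self.heptamer[BP_POS_IN_HEPTAMER - 1]

    @property
    def motif_class(self) -> str:
        return classify_motif(self.heptamer)


def classify_motif(heptamer: str) -> str:
    """TNA / CNA / other from heptamer positions 4 and 6."""
    if len(heptamer) != 7:
        raise ValueError("heptamer must have length 7")
    if heptamer[5] == "A":
        if heptamer[3] == "T":
            return "TNA"
        if heptamer[3] == "C":
            return "CNA"
    return "other"


def predict_branch_point(intron: Intron, pwm: HeptamerPWM,
                         weights: OctamerWeightTable, search_bp: int = 250,
                         min_len: int = 20,
                         min_distance: int = 9) -> BranchPointPrediction | None:
    """Argmax-scored branch point of one intron, or None.

    Candidates are every distance d in [min_distance, search_bp] whose
    heptamer and covering octamer fit inside the intron; ties break toward
    the smallest d (the candidate closest to the 3' splice site).  Windows
    containing N are not candidates.  Introns shorter than ``min_len``
    return None.
    """
    L = intron.length
    if L < min_len:
        return None
    seq = intron.sequence
    best: tuple[float, int] | None = None
    # oriented index of the BP at distance d is L - d + 1; the octamer needs
    # indices L-d-4 .. L-d+3 inside [1, L], i.e. 3 <= d <= L-5
    lo = max(min_distance, 3)
    hi = min(search_bp, L - 5)
    for d in range(lo, hi + 1):
        bp_idx = L - d + 1
        octamer = seq[bp_idx - 6:bp_idx + 2]
        if "N" in octamer:
            continue
        s = pwm.log_odds(octamer[:7]) + weights.weight(octamer)
        if best is None or s > best[0]:
            best = (s, d)
    if best is None:
        return None
    score, d = best
    bp_idx = L - d + 1
    hept_idx = (bp_idx - 5, bp_idx + 1)  # oriented, 1-based inclusive
    g1 = intron.oriented_position(hept_idx[0])
    g2 = intron.oriented_position(hept_idx[1])
    return BranchPointPrediction(
        intron_id=intron.intron_id, chrom=intron.chrom, strand=intron.strand,
        bp_distance=d, heptamer=seq[hept_idx[0] - 1:hept_idx[1]], score=score,
        heptamer_start=min(g1, g2), heptamer_end=max(g1, g2),
        bp_pos=intron.oriented_position(bp_idx),
        splice_class=intron.splice_class)


def predict_all(introns: Iterable[Intron], pwm: HeptamerPWM,
                weights: OctamerWeightTable,
                **kwargs) -> list[BranchPointPrediction]:
    out = []
    for intron in introns:
        pred = predict_branch_point(intron, pwm, weights, **kwargs)
        if pred is not None:
            out.append(pred)
    return out


def compare_predictions(set_a: Sequence[BranchPointPrediction],
                        set_b: Sequence[BranchPointPrediction]) -> dict:
    """Overlap of two prediction sets keyed by intron_id.

    The match fraction is over introns predicted in both sets and compares
    the genomic branch-point coordinate; it is None when no introns are
    shared.
    """
    a = {p.intron_id: p for p in set_a}
    b = {p.intron_id: p for p in set_b}
    shared = sorted(set(a) & set(b))
    matches = sum(1 for i in shared if a[i].bp_pos == b[i].bp_pos)
    return {
        "n_a": len(a), "n_b": len(b), "shared_introns": len(shared),
        "exact_matches": matches,
        "match_fraction": matches / len(shared) if shared else None,
    }


def summarize_predictions(predictions: Sequence[BranchPointPrediction]) -> dict:
    """Distance statistics, motif-class and branch-point base composition.

    Distances are summarized overall and stratified by motif class and by
    splice-site class; heptamer base composition is per position.
    """
    preds = list(predictions)
    if not preds:
        raise ValueError("no predictions to summarize")

    def dist_stats(ps):
        d = np.array([p.bp_distance for p in ps], dtype=float)
        return {"n": len(ps), "min": float(d.min()), "max": float(d.max()),
                "mean": float(d.mean()),
                "sd": float(d.std(ddof=1)) if len(ps) > 1 else 0.0}

    by_motif: dict[str, list] = {}
    by_splice: dict[str, list] = {}
    for p in preds:
        by_motif.setdefault(p.motif_class, []).append(p)
        by_splice.setdefault(p.splice_class, []).append(p)

    n = len(preds)
    comp = np.zeros((7, 4))
    for p in preds:
        for i, bch in enumerate(p.heptamer):
            if bch in _BASE_INDEX:
                comp[i, _BASE_INDEX[bch]] += 1
    bp_fraction = {bch: sum(1 for p in preds if p.bp_base == bch) / n
                   for bch in BASES}
    return {
        "distance": dist_stats(preds),
        "distance_by_motif": {k: dist_stats(v) for k, v in sorted(by_motif.items())},
        "distance_by_splice_class": {k: dist_stats(v)
                                     for k, v in sorted(by_splice.items())},
        "motif_class_counts": {k: len(v) for k, v in sorted(by_motif.items())},
        "motif_class_fractions": {k: len(v) / n for k, v in sorted(by_motif.items())},
        "heptamer_base_composition": comp / n,
        "bp_base_fraction": bp_fraction,
    }
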