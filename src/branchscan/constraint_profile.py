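"""Constraint statistics from variant density.

The elementary statistic is 100*m/n variants per 100 bp, where m counts
variable *sites* (a multiallelic record is one site) overlapping a set of
n target bases.  It is applied at feature level, per codon position, and
at single-nucleotide resolution around oriented anchors (splice sites,
branch points).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._stats import FisherResult, fisher_2x2
from .feature_map import EXCLUDED, FeatureClass, FeatureMap
from .genome_io import TranscriptModel, VariantSite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariabilityEstimate:
    """m variable sites over n target bases."""

    m: int
    n: int

    def __post_init__(self):
        if not 0 <= self.m <= self.n:
            raise ValueError(f"need 0 <= m <= n, got m={self.m}, n={self.n}")

    @property
    def rate(self) -> float:
        """Variants per 100 bp."""
        return 100.0 * self.m / self.n if self.n else float("nan")


def index_variants(variants: Iterable[VariantSite],
                   ) -> dict[str, dict[int, VariantSite]]:
    """chrom -> pos -> site lookup (streams are materialized once here)."""
    idx: dict[str, dict[int, VariantSite]] = {}
    for v in variants:
        idx.setdefault(v.chrom, {})[v.pos] = v
    return idx


def _as_index(variants) -> dict[str, dict[int, VariantSite]]:
    if isinstance(variants, dict):
        return variants
    return index_variants(variants)


def feature_variability(fmap: FeatureMap, variants,
                        ) -> dict[str | FeatureClass, VariabilityEstimate]:
    """Per-feature-class and genome-wide variants per 100 bp.

    Each variant site increments m of exactly the one class of its base.
    Variants on chromosomes absent from the map are skipped with a log
    message; variants on lncRNA-excluded bases are tracked under the key
    ``"excluded"`` and do not contribute to any of the nine classes.
    """
    vidx = _as_index(variants)
    m = {cls: 0 for cls in FeatureClass}
    m_excluded = 0
    total_sites = 0
    for chrom, sites in vidx.items():
        if chrom not in fmap.labels:
            logger.warning("skipping %d variants on unknown chromosome %s",
                           len(sites), chrom)
            continue
        labels = fmap.labels[chrom]
        for pos in sites:
            total_sites += 1
            cls = labels[pos - 1]
            if cls == EXCLUDED:
                m_excluded += 1
            else:
                m[FeatureClass(cls)] += 1
    out: dict[str | FeatureClass, VariabilityEstimate] = {
        cls: VariabilityEstimate(m[cls], fmap.feature_length(cls))
        for cls in FeatureClass}
    out["excluded"] = VariabilityEstimate(m_excluded, fmap.excluded_bases)
    out["genome_wide"] = VariabilityEstimate(total_sites, fmap.genome_length)
    return out


@dataclass(frozen=True)
class Anchor:
    """An oriented genomic position with optional parent bounds.

    Offset o maps to genomic position pos + o on the plus strand and
    pos - o on the minus strand.  Nonnegative offsets must stay inside
    ``parent_nonneg`` and negative offsets inside ``parent_neg`` (genomic
    closed intervals); a None parent leaves that side unconstrained.
    """

    chrom: str
    pos: int
    strand: str
    parent_nonneg: tuple[int, int] | None = None
    parent_neg: tuple[int, int] | None = None

    def offset_position(self, offset: int) -> int | None:
        """Genomic position of an offset, or None when it leaves its parent."""
        g = self.pos + offset if self.strand == "+" else self.pos - offset
        parent = self.parent_nonneg if offset >= 0 else self.parent_neg
        if parent is not None and not parent[0] <= g <= parent[1]:
            return None
        return g


@dataclass
class PositionalProfile:
    """Per-offset variability around a set of oriented anchors."""

    anchor_description: str
    offsets: list[int]
    estimates: dict[int, VariabilityEstimate] = field(default_factory=dict)

    def rate(self, offset: int) -> float:
        return self.estimates[offset].rate


def positional_profile(anchors: Sequence[Anchor], window: int, variants,
                       offsets: Sequence[int] | None = None,
                       description: str = "anchors") -> PositionalProfile:
    """Count variable sites at each offset around oriented anchors.

    Offsets run in transcript orientation.  Anchors whose offset position
    falls outside the appropriate parent interval drop out of that offset's
    denominator.
    """
    if not anchors:
        raise ValueError("empty anchor set")
    vidx = _as_index(variants)
    if offsets is None:
        offsets = list(range(-window, window + 1))
    prof = PositionalProfile(description, list(offsets))
    for off in offsets:
        n = m = 0
        for a in anchors:
            g = a.offset_position(off)
            if g is None:
                continue
            n += 1
            if g in vidx.get(a.chrom, ()):
                m += 1
        prof.estimates[off] = VariabilityEstimate(m, n)
    return prof


def splice_site_anchors(transcripts: Iterable[TranscriptModel],
                        ) -> tuple[list[Anchor], list[Anchor]]:
    """5' and 3' splice-site anchors for the unique introns of transcripts.

    Offset 0 is the first intronic base at the 5' site and the last
    intronic base at the 3' site; the exonic side (negative offsets at the
    5' site, positive at the 3' site) is bounded by the flanking exon of
    the first transcript carrying the intron.
    """
    five: dict[tuple, Anchor] = {}
    three: dict[tuple, Anchor] = {}
    for tx in transcripts:
        exons = tx.exons_genomic()
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            istart, iend = e1 + 1, s2 - 1
            if istart > iend:
                continue
            key = (tx.chrom, istart, iend, tx.strand)
            if key in five:
                continue
            intron = (istart, iend)
            if tx.strand == "+":
                five[key] = Anchor(tx.chrom, istart, "+", intron, (s1, e1))
                three[key] = Anchor(tx.chrom, iend, "+", (s2, e2), intron)
            else:
                five[key] = Anchor(tx.chrom, iend, "-", intron, (s2, e2))
                three[key] = Anchor(tx.chrom, istart, "-", (s1, e1), intron)
    return list(five.values()), list(three.values())


def _parse_intron_id(intron_id: str) -> tuple[str, int, int, str]:
    chrom, span, strand = intron_id.rsplit(":", 2)
    s, e = span.split("-")
    return chrom, int(s), int(e), strand


def heptamer_profile(predictions: Sequence, window: int, variants,
                     ) -> dict[str, PositionalProfile]:
    """Variability across the predicted heptamer and +/- window intronic bases.

    Offsets are relative to the branch point (offset 0); heptamer positions
    1-7 sit at offsets -5..+1.  Both sides are bounded by the intron.  A
    profile restricted to the canonical TNA subset is returned alongside.
    """
    if not predictions:
        raise ValueError("no predictions supplied")
    offsets = list(range(-(5 + window), (1 + window) + 1))

    def anchors_of(preds):
        out = []
        for p in preds:
            chrom, s, e, strand = _parse_intron_id(p.intron_id)
            out.append(Anchor(chrom, p.bp_pos, strand, (s, e), (s, e)))
        return out

    vidx = _as_index(variants)
    full = positional_profile(anchors_of(predictions), window, vidx,
                              offsets=offsets, description="branch point")
    result = {"all": full}
    tna = [p for p in predictions if p.motif_class == "TNA"]
    if tna:
        result["TNA"] = positional_profile(
            anchors_of(tna), window, vidx, offsets=offsets,
            description="branch point (TNA)")
    return result


def heptamer_offset_of_position(position: int) -> int:
    """Branch-point offset of a 1-based heptamer position (6 -> 0)."""
    if not 1 <= position <= 7:
        raise ValueError("heptamer position must be 1..7")
    return position - 6


def codon_position_variability(transcripts: Iterable[TranscriptModel],
                               variants, mode: str = "union",
                               ) -> dict[int, VariabilityEstimate]:
    """Variability at codon positions 1/2/3 of CDS bases.

    Codon positions derive from each CDS interval's frame in transcript
    orientation.  Under ``union`` (default) a base contributes once per
    distinct codon position claimed by any transcript; under ``first`` the
    first transcript claiming a base wins.
    """
    if mode not in ("union", "first"):
        raise ValueError(f"unknown mode {mode!r}")
    vidx = _as_index(variants)
    claims: dict[int, set] = {1: set(), 2: set(), 3: set()}
    claimed_any: set = set()
    for tx in transcripts:
        if not tx.cds:
            continue
        total = sum(e - s + 1 for s, e, _ in tx.cds)
        if total % 3 != 0:
            logger.warning("transcript %s: CDS length %d not divisible by 3; "
                           "skipped from codon-position analysis",
                           tx.transcript_id, total)
            continue
        for s, e, frame in tx.cds:
            span = range(s, e + 1) if tx.strand == "+" else range(e, s - 1, -1)
            for i, g in enumerate(span):
                cp = ((i - frame) % 3) + 1
                key = (tx.chrom, g)
                if mode == "first" and key in claimed_any:
                    continue
                claims[cp].add(key)
                claimed_any.add(key)
    out = {}
    for cp in (1, 2, 3):
        n = len(claims[cp])
        m = sum(1 for chrom, pos in claims[cp] if pos in vidx.get(chrom, ()))
        out[cp] = VariabilityEstimate(m, n)
    return out


DEFAULT_MAF_BINS = (0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class AFSHistogram:
    """Minor-allele-frequency spectrum per feature class."""

    bin_edges: tuple[float, ...]
    counts: dict
    fractions: dict


def afs_by_feature(fmap: FeatureMap, variants,
                   bin_edges: Sequence[float] = DEFAULT_MAF_BINS,
                   ) -> AFSHistogram:
    """Histogram of folded MAF per feature; bins are (e_i, e_{i+1}]."""
    edges = tuple(bin_edges)
    if edges[0] != 0.0 or edges[-1] != 0.5 or list(edges) != sorted(set(edges)):
        raise ValueError("bin edges must increase from 0 to 0.5")
    nbins = len(edges) - 1
    vidx = _as_index(variants)
    counts = {cls: np.zeros(nbins, dtype=int) for cls in FeatureClass}
    inner = np.array(edges[1:-1])
    for chrom, sites in vidx.items():
        if chrom not in fmap.labels:
            continue
        labels = fmap.labels[chrom]
        for pos, site in sites.items():
            if not 0.0 <= site.maf <= 0.5:
                raise ValueError(f"MAF {site.maf} outside [0, 0.5]")
            cls = labels[pos - 1]
            if cls == EXCLUDED:
                continue
            b = int(np.searchsorted(inner, site.maf, side="left"))
            counts[FeatureClass(cls)][b] += 1
    fractions = {}
    for cls, c in counts.items():
        tot = c.sum()
        fractions[cls] = c / tot if tot else np.zeros(nbins)
    return AFSHistogram(edges, counts, fractions)


@dataclass
class ConsensusMatrix:
    """Per-position base probabilities and information content (bits)."""

    probs: np.ndarray           # L x 4, columns A C G T
    information: np.ndarray     # L


def consensus_matrix(sequences: Sequence[str]) -> ConsensusMatrix:
    """Position probability matrix of equal-length uppercase sequences.

    Information content per position is 2 + sum_b p_b log2 p_b (0 log 0 = 0),
    between 0 and 2 bits.  N and other non-ACGT characters are ignored in
    the per-position normalization.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("at least one sequence is required")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must all have the same length")
    base_idx = {b: i for i, b in enumerate("ACGT")}
    counts = np.zeros((L, 4))
    for s in seqs:
        for i, b in enumerate(s):
            j = base_idx.get(b)
            if j is not None:
                counts[i, j] += 1
    col_tot = counts.sum(axis=1, keepdims=True)
    if (col_tot == 0).any():
        raise ValueError("a position has no ACGT observations")
    probs = counts / col_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    return ConsensusMatrix(probs=probs, information=np.clip(info, 0.0, 2.0))


def compare_variability(est_a: VariabilityEstimate,
                        est_b: VariabilityEstimate) -> FisherResult:
    """Two-sided Fisher test of [[m_a, n_a-m_a], [m_b, n_b-m_b]]."""
    if est_a.n < 1 or est_b.n < 1:
        raise ValueError("both estimates need n >= 1")
    return fisher_2x2(est_a.m, est_a.n - est_a.m, est_b.m, est_b.n - est_b.m)
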