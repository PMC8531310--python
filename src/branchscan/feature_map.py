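"""Per-base partition of the genome into nine feature classes.

Every base receives exactly one label, resolved by a fixed priority:
stop codon > start codon > 5' splice site > 3' splice site > 3' UTR >
5' UTR > exon > intron > intergenic.  Splice sites are the two intronic
bases at each intron end (the GT / AG dinucleotides in transcript
orientation).  Bases that overlap a lncRNA gene but no other feature are
excluded from the intergenic denominator.
"""

from __future__ import annotations

import os
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

from .genome_io import GenomeSequence, TranscriptModel


class FeatureClass(IntEnum):
    """Feature labels; smaller value = higher assignment priority."""

    STOP_CODON = 0
    START_CODON = 1
    SPLICE5 = 2
    SPLICE3 = 3
    UTR3 = 4
    UTR5 = 5
    EXON = 6
    INTRON = 7
    INTERGENIC = 8


#: sentinel for lncRNA-overlapping bases outside every other feature
EXCLUDED = 9

_PLUS, _MINUS = 0, 1


class FeatureMap:
    """Dense per-base feature labels plus the painting strand."""

    def __init__(self, labels: dict[str, np.ndarray],
                 strands: dict[str, np.ndarray]):
        self.labels = labels
        self.strands = strands

    @property
    def chrom_names(self) -> list[str]:
        return list(self.labels)

    def class_of(self, chrom: str, pos: int) -> int:
        return int(self.labels[chrom][pos - 1])

    def strand_of(self, chrom: str, pos: int) -> str:
        return "-" if self.strands[chrom][pos - 1] == _MINUS else "+"

    def feature_length(self, cls: int) -> int:
        return sum(int((arr == cls).sum()) for arr in self.labels.values())

    @property
    def excluded_bases(self) -> int:
        return self.feature_length(EXCLUDED)

    @property
    def assigned_total(self) -> int:
        return sum(arr.size for arr in self.labels.values()) - self.excluded_bases

    @property
    def genome_length(self) -> int:
        return sum(arr.size for arr in self.labels.values())

    def positions_of(self, chrom: str, cls: int) -> np.ndarray:
        """1-based positions of a class on one chromosome."""
        return np.nonzero(self.labels[chrom] == cls)[0] + 1

    def write_class_bed(self, cls: int, path: str | os.PathLike) -> None:
        """Export the class partition as sorted BED intervals."""
        with open(path, "w") as fh:
            for chrom in sorted(self.labels):
                mask = self.labels[chrom] == cls
                if not mask.any():
                    continue
                edges = np.flatnonzero(np.diff(np.r_[0, mask.view(np.int8), 0]))
                for s, e in zip(edges[::2], edges[1::2]):
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def _paint(labels, strands, chrom_arrs, intervals, code):
    for chrom, start, end, strand in intervals:
        arr = chrom_arrs.get(chrom)
        if arr is None:
            raise KeyError(f"annotation on unknown chromosome {chrom!r}")
        if start < 1 or end > arr.size:
            raise ValueError(
                f"feature [{start}, {end}] beyond chromosome {chrom} "
                f"(length {arr.size})")
        labels[chrom][start - 1:end] = code
        strands[chrom][start - 1:end] = _MINUS if strand == "-" else _PLUS


def build_feature_map(transcripts: Iterable[TranscriptModel],
                      lncrna_intervals: Sequence[tuple[str, int, int]],
                      genome: GenomeSequence) -> FeatureMap:
    """Label every genome base with its single highest-priority feature.

    The priority rule operates on the union of all transcripts' features,
    so a base exonic in one isoform and intronic in another is exonic.
    """
    labels = {c: np.full(genome.length(c), FeatureClass.INTERGENIC, np.uint8)
              for c in genome.chrom_names}
    strands = {c: np.zeros(genome.length(c), np.uint8)
               for c in genome.chrom_names}

    by_class: dict[int, list] = {cls: [] for cls in FeatureClass
                                 if cls != FeatureClass.INTERGENIC}
    for tx in transcripts:
        exons = tx.exons_genomic()
        for s, e in exons:
            by_class[FeatureClass.EXON].append((tx.chrom, s, e, tx.strand))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            istart, iend = e1 + 1, s2 - 1
            if istart > iend:
                continue
            by_class[FeatureClass.INTRON].append((tx.chrom, istart, iend, tx.strand))
            ilen = iend - istart + 1
            if tx.strand == "+":
                donor = (istart, min(istart + 1, iend))
                acceptor = (max(iend - 1, istart), iend)
            else:
                donor = (max(iend - 1, istart), iend)
                acceptor = (istart, min(istart + 1, iend))
            by_class[FeatureClass.SPLICE5].append(
                (tx.chrom, donor[0], donor[1], tx.strand))
            if ilen > 2:  # tiny introns: the donor dinucleotide wins
                by_class[FeatureClass.SPLICE3].append(
                    (tx.chrom, acceptor[0], acceptor[1], tx.strand))
        for s, e in tx.utr5:
            by_class[FeatureClass.UTR5].append((tx.chrom, s, e, tx.strand))
        for s, e in tx.utr3:
            by_class[FeatureClass.UTR3].append((tx.chrom, s, e, tx.strand))
        for s, e in tx.start_codon:
            by_class[FeatureClass.START_CODON].append((tx.chrom, s, e, tx.strand))
        for s, e in tx.stop_codon:
            by_class[FeatureClass.STOP_CODON].append((tx.chrom, s, e, tx.strand))

    # lowest priority first; later paints overwrite earlier ones
    for cls in sorted(by_class, reverse=True):
        _paint(labels, strands, labels, by_class[cls], cls)

    for chrom, start, end in lncrna_intervals:
        arr = labels.get(chrom)
        if arr is None:
            raise KeyError(f"lncRNA on unknown chromosome {chrom!r}")
        seg = arr[start - 1:end]
        seg[seg == FeatureClass.INTERGENIC] = EXCLUDED

    return FeatureMap(labels, strands)


def feature_lengths(fmap: FeatureMap) -> dict[FeatureClass, int]:
    """Base counts of the nine classes (lncRNA-excluded bases not included)."""
    return {cls: fmap.feature_length(cls) for cls in FeatureClass}
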