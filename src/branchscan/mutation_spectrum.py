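"""Substitution-type spectra (Ti/Tv) at selected residue sets.

Counting here is allele-level: every ALT allele at a targeted position is
one substitution event (a multiallelic site contributes one event per ALT),
unlike the site-level counting used for variability.  Substitutions at
minus-strand features are complemented into feature orientation; intergenic
residues are taken on the plus strand, where no orientation exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._stats import FisherResult, fisher_2x2
from .constraint_profile import _as_index
from .feature_map import FeatureClass, FeatureMap
from .genome_io import GenomeSequence, Intron

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(ref: str, alt: str) -> bool:
    return (ref, alt) in TRANSITIONS


@dataclass
class SubstitutionSpectrum:
    """Counts of the three possible substitutions of one reference base."""

    ref_base: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        alts = [b for b in "ACGT" if b != self.ref_base]
        self.counts = {a: int(self.counts.get(a, 0)) for a in alts}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def ti(self) -> int:
        return sum(c for a, c in self.counts.items()
                   if is_transition(self.ref_base, a))

    @property
    def tv(self) -> int:
        return sum(c for a, c in self.counts.items()
                   if not is_transition(self.ref_base, a))

    @property
    def titv(self) -> float | None:
        return titv_ratio(self)


def titv_ratio(spectrum: SubstitutionSpectrum) -> float | None:
    """ti/tv, or None when no transversions were observed."""
    return spectrum.ti / spectrum.tv if spectrum.tv > 0 else None


def substitution_spectrum(target_positions: Sequence[tuple[str, int, str]],
                          reference_base: str, variants,
                          ) -> SubstitutionSpectrum:
    """Tally ALT alleles at oriented targets sharing one reference base.

    ``target_positions`` are (chrom, genomic pos, strand) triples; on the
    minus strand both the reference check and the ALT alleles are
    complemented into feature orientation.  Targets whose oriented
    reference base does not match are excluded with a log message.
    """
    if reference_base not in "ACGT":
        raise ValueError(f"invalid reference base {reference_base!r}")
    vidx = _as_index(variants)
    spec = SubstitutionSpectrum(ref_base=reference_base)
    mismatched = 0
    for chrom, pos, strand in target_positions:
        site = vidx.get(chrom, {}).get(pos)
        if site is None:
            continue
        ref = site.ref if strand == "+" else _COMP[site.ref]
        if ref != reference_base:
            mismatched += 1
            continue
        for alt in site.alts:
            oriented = alt if strand == "+" else _COMP[alt]
            if oriented in spec.counts:
                spec.counts[oriented] += 1
    if mismatched:
        logger.warning("%d targets had an oriented reference base other than "
                       "%s and were excluded", mismatched, reference_base)
    return spec


def compare_titv(spec_a: SubstitutionSpectrum,
                 spec_b: SubstitutionSpectrum) -> FisherResult:
    """Two-sided Fisher test of [[ti_a, tv_a], [ti_b, tv_b]]."""
    if spec_a.ti + spec_a.tv < 1 or spec_b.ti + spec_b.tv < 1:
        raise ValueError("both spectra need at least one substitution")
    return fisher_2x2(spec_a.ti, spec_a.tv, spec_b.ti, spec_b.tv)


def _splice_site_targets(introns: Iterable[Intron], cls: FeatureClass,
                         base: str) -> list[tuple[str, int, str]]:
    """Positions of ``base`` inside canonical splice-site dinucleotides.

    The tally at splice sites is limited to sites whose canonical motif
    (GT at the donor, AG at the acceptor) contains the studied residue.
    """
    targets = []
    for intron in introns:
        if cls == FeatureClass.SPLICE5:
            if intron.donor_dinucleotide != "GT":
                continue
            motif_idx = {"G": 1, "T": 2}
        else:
            if intron.acceptor_dinucleotide != "AG":
                continue
            motif_idx = {"A": intron.length - 1, "G": intron.length}
        idx = motif_idx.get(base)
        if idx is None:
            continue
        targets.append((intron.chrom, intron.oriented_position(idx),
                        intron.strand))
    return targets


def feature_residue_spectra(fmap: FeatureMap, genome: GenomeSequence,
                            variants, bases: Sequence[str] = ("A", "T"),
                            introns: Iterable[Intron] | None = None,
                            ) -> dict[tuple[FeatureClass, str],
                                      SubstitutionSpectrum]:
    """Substitution spectra of selected residues within each feature class.

    For the two splice-site classes the residues are restricted to
    canonical GT / AG dinucleotides when ``introns`` are supplied (classes
    are skipped otherwise).  Orientation follows the strand recorded in
    the feature map.
    """
    vidx = _as_index(variants)
    intron_list = list(introns) if introns is not None else None
    out: dict[tuple[FeatureClass, str], SubstitutionSpectrum] = {}
    seqs = {c: genome.sequence(c, 1, genome.length(c))
            for c in fmap.chrom_names}
    for cls in FeatureClass:
        for base in bases:
            if cls in (FeatureClass.SPLICE5, FeatureClass.SPLICE3):
                if intron_list is None:
                    continue
                targets = _splice_site_targets(intron_list, cls, base)
            else:
                targets = []
                for chrom in fmap.chrom_names:
                    seq = seqs[chrom]
                    strands = fmap.strands[chrom]
                    for pos in fmap.positions_of(chrom, cls):
                        strand = "-" if (cls != FeatureClass.INTERGENIC
                                         and strands[pos - 1] == 1) else "+"
                        b = seq[pos - 1]
                        if strand == "-":
                            b = _COMP[b]
                        if b == base:
                            targets.append((chrom, int(pos), strand))
            out[(cls, base)] = substitution_spectrum(targets, base, vidx)
    return out
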