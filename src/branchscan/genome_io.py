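"""Reading and validation of FASTA/GTF/VCF inputs and BED output.

Coordinates are 1-based inclusive throughout the package (the GTF and VCF
convention); only BED output converts to 0-based half-open, at the boundary.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import gffutils
import pyfaidx
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")
# any IUPAC ambiguity code (or stray character) collapses to N
_TO_N = str.maketrans({c: "N" for c in
                       "BDEFHIJKLMOPQRSUVWXYZbdefhijklmopqrsuvwxyz"})


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _clean(seq: str) -> str:
    seq = seq.upper().translate(_TO_N)
    return seq


class GenomeSequence:
    """Random-access view of an indexed FASTA file.

    Lookups are 1-based inclusive.  Bases are folded to uppercase and any
    character outside {A, C, G, T, N} is read back as N.
    """

    def __init__(self, path: str | os.PathLike):
        try:
            self._fasta = pyfaidx.Fasta(str(path), sequence_always_upper=True)
        except (ValueError, pyfaidx.FastaIndexingError) as exc:
            raise ValueError(f"invalid FASTA {path}: {exc}") from exc
        if len(self._fasta.keys()) == 0:
            raise ValueError(f"FASTA {path} contains no records")

    @property
    def chrom_names(self) -> list[str]:
        return list(self._fasta.keys())

    def length(self, chrom: str) -> int:
        if chrom not in self._fasta:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return len(self._fasta[chrom])

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """Uppercase DNA for the closed interval [start, end]."""
        n = self.length(chrom)
        if not (1 <= start <= end <= n):
            raise ValueError(
                f"interval [{start}, {end}] outside [1, {n}] on {chrom}")
        return _clean(self._fasta[chrom][start - 1:end].seq)

    def base(self, chrom: str, pos: int) -> str:
        return self.sequence(chrom, pos, pos)


def read_fasta(path: str | os.PathLike) -> GenomeSequence:
    """Open and index a FASTA file (duplicate record names are rejected)."""
    return GenomeSequence(path)


@dataclass
class TranscriptModel:
    """One protein-coding transcript with its genomic sub-features.

    ``exons`` and ``cds`` are ordered 5'->3' in transcript orientation, so
    on the minus strand the genomically last interval comes first.  All
    intervals are 1-based inclusive; CDS intervals carry the GTF frame
    (bases to skip to reach the first base of a codon).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    start_codon: list[tuple[int, int]] = field(default_factory=list)
    stop_codon: list[tuple[int, int]] = field(default_factory=list)

    def exons_genomic(self) -> list[tuple[int, int]]:
        return sorted(self.exons)


def _biotype(attrs) -> str | None:
    for key in ("gene_biotype", "transcript_biotype", "gene_type"):
        if key in attrs:
            return attrs[key][0]
    return None


def read_gtf(path: str | os.PathLike) -> list[TranscriptModel]:
    """Parse an Ensembl-dialect GTF into transcript models.

    Only protein-coding transcripts are returned.  A transcript whose CDS
    falls outside its exons is rejected with a logged warning; a feature
    line without a transcript_id attribute is a hard error.
    """
    db = gffutils.create_db(
        str(path), ":memory:",
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique", keep_order=True)
    wanted = {"exon", "CDS", "five_prime_utr", "three_prime_utr",
              "start_codon", "stop_codon"}
    per_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in wanted:
            continue
        attrs = feat.attributes
        if "transcript_id" not in attrs:
            raise ValueError(
                f"{feat.featuretype} feature at {feat.seqid}:{feat.start} "
                "lacks a transcript_id attribute")
        if _biotype(attrs) not in (None, "protein_coding"):
            continue
        tid = attrs["transcript_id"][0]
        rec = per_tx.setdefault(tid, {
            "gene_id": attrs.get("gene_id", ["?"])[0],
            "chrom": feat.seqid, "strand": feat.strand,
            "exon": [], "CDS": [], "five_prime_utr": [],
            "three_prime_utr": [], "start_codon": [], "stop_codon": []})
        if feat.featuretype == "CDS":
            frame = int(feat.frame) if feat.frame in ("0", "1", "2") else 0
            rec["CDS"].append((feat.start, feat.end, frame))
        else:
            rec[feat.featuretype].append((feat.start, feat.end))

    models: list[TranscriptModel] = []
    for tid, rec in per_tx.items():
        if not rec["exon"]:
            logger.warning("transcript %s has no exons; skipped", tid)
            continue
        rev = rec["strand"] == "-"
        exons = sorted(rec["exon"], reverse=rev)
        cds = sorted(rec["CDS"], reverse=rev)
        ok = all(any(es <= cs and ce <= ee for es, ee in exons)
                 for cs, ce, _ in cds)
        if not ok:
            logger.warning("transcript %s: CDS outside exons; rejected", tid)
            continue
        models.append(TranscriptModel(
            transcript_id=tid, gene_id=rec["gene_id"], chrom=rec["chrom"],
            strand=rec["strand"], exons=exons, cds=cds,
            utr5=sorted(rec["five_prime_utr"], reverse=rev),
            utr3=sorted(rec["three_prime_utr"], reverse=rev),
            start_codon=sorted(rec["start_codon"], reverse=rev),
            stop_codon=sorted(rec["stop_codon"], reverse=rev)))
    models.sort(key=lambda m: (m.chrom, min(s for s, _ in m.exons), m.transcript_id))
    return models


def read_lncrna_intervals(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    """Genomic spans of lncRNA genes from a GTF (for intergenic exclusion)."""
    db = gffutils.create_db(
        str(path), ":memory:",
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique", keep_order=True)
    out = []
    for feat in db.features_of_type("gene"):
        if _biotype(feat.attributes) == "lncRNA":
            out.append((feat.seqid, feat.start, feat.end))
    return sorted(out)


@dataclass(frozen=True)
class Intron:
    """A unique intron, oriented 5'->3' along its transcript.

    ``sequence`` is reverse-complemented for minus-strand introns, so it
    always starts at the donor site and ends at the acceptor site.
    """

    chrom: str
    strand: str
    start: int
    end: int
    sequence: str

    @property
    def intron_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def donor_dinucleotide(self) -> str:
        return self.sequence[:2]

    @property
    def acceptor_dinucleotide(self) -> str:
        return self.sequence[-2:]

    @property
    def splice_class(self) -> str:
        pair = (self.donor_dinucleotide, self.acceptor_dinucleotide)
        if pair == ("GT", "AG"):
            return "GT-AG"
        if pair == ("GC", "AG"):
            return "GC-AG"
        if pair == ("AT", "AC"):
            return "AT-AC"
        return "other"

    def oriented_position(self, index: int) -> int:
        """Genomic coordinate of the 1-based oriented sequence index."""
        if not 1 <= index <= self.length:
            raise ValueError(f"index {index} outside intron of length {self.length}")
        if self.strand == "+":
            return self.start + index - 1
        return self.end - index + 1


def extract_introns(transcripts: Iterable[TranscriptModel],
                    genome: GenomeSequence) -> list[Intron]:
    """Unique introns (gaps between consecutive exons) across transcripts.

    Deduplicated by (chrom, start, end, strand); identical coordinates on
    opposite strands remain distinct because orientation determines the
    branch point search.
    """
    seen: dict[tuple, Intron] = {}
    for tx in transcripts:
        exons = tx.exons_genomic()
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            istart, iend = e1 + 1, s2 - 1
            if istart > iend:
                continue
            key = (tx.chrom, istart, iend, tx.strand)
            if key in seen:
                continue
            if iend > genome.length(tx.chrom) or istart < 1:
                raise ValueError(
                    f"intron [{istart}, {iend}] outside chromosome {tx.chrom}")
            seq = genome.sequence(tx.chrom, istart, iend)
            if tx.strand == "-":
                seq = reverse_complement(seq)
            seen[key] = Intron(chrom=tx.chrom, strand=tx.strand,
                               start=istart, end=iend, sequence=seq)
    return sorted(seen.values(), key=lambda i: (i.chrom, i.start, i.end, i.strand))


@dataclass(frozen=True)
class VariantSite:
    """One polymorphic SNP site (possibly multiallelic) with folded MAF."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    maf: float

    def __post_init__(self):
        if self.ref in self.alts:
            raise ValueError(f"REF {self.ref} appears in ALTs {self.alts}")
        if not self.alts:
            raise ValueError("at least one ALT is required")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"MAF {self.maf} outside [0, 0.5]")

    @property
    def multiallelic(self) -> bool:
        return len(self.alts) > 1


def read_vcf(path: str | os.PathLike) -> Iterator[VariantSite]:
    """Stream SNP sites from a VCF, skipping indels and non-PASS records.

    MAF is folded to [0, 0.5] from INFO/AF (the ALT with the highest
    frequency at multiallelic sites) or, when AF is absent, from genotypes.
    A record carrying neither is a hard error.
    """
    skipped_indel = skipped_filter = skipped_bad = 0
    vcf = VCF(str(path))
    for rec in vcf:
        if rec.FILTER is not None:  # None covers PASS and '.'
            skipped_filter += 1
            continue
        if not rec.is_snp or len(rec.REF) != 1 or \
                any(len(a) != 1 for a in rec.ALT):
            skipped_indel += 1
            continue
        af = rec.INFO.get("AF")
        if af is not None:
            afs = af if isinstance(af, (tuple, list)) else (af,)
            top = max(float(a) for a in afs)
        else:
            gts = rec.genotypes
            if not gts:
                raise ValueError(
                    f"record at {rec.CHROM}:{rec.POS} has neither AF nor genotypes")
            alleles = [a for row in gts for a in row[:-1] if a >= 0]
            if not alleles:
                skipped_bad += 1
                continue
            counts: dict[int, int] = {}
            for a in alleles:
                counts[a] = counts.get(a, 0) + 1
            alt_counts = [counts.get(i + 1, 0) for i in range(len(rec.ALT))]
            top = max(alt_counts) / len(alleles)
        try:
            yield VariantSite(chrom=rec.CHROM, pos=rec.POS, ref=rec.REF,
                              alts=tuple(rec.ALT), maf=min(top, 1.0 - top))
        except ValueError as exc:
            skipped_bad += 1
            logger.warning("skipping malformed record %s:%d: %s",
                           rec.CHROM, rec.POS, exc)
    if skipped_indel or skipped_filter or skipped_bad:
        logger.info("read_vcf skipped %d indel/non-SNP, %d filtered, "
                    "%d malformed records",
                    skipped_indel, skipped_filter, skipped_bad)


def write_bed(predictions: Sequence, path: str | os.PathLike) -> None:
    """Write branch point predictions as BED with thick branch-point base.

    Columns: chrom, heptamer start (0-based), heptamer end, name
    (intron_id|motif_class), score (mixture score x100, truncated, clamped
    to [0, 1000]), strand, thickStart, thickEnd (the single branch-point
    base).
    """
    preds = list(predictions)
    if not preds:
        raise ValueError("refusing to write an empty prediction set")
    with open(path, "w") as fh:
        for p in preds:
            score = max(0, min(1000, int(p.score * 100)))
            fh.write("\t".join(map(str, (
                p.chrom, p.heptamer_start - 1, p.heptamer_end,
                f"{p.intron_id}|{p.motif_class}", score, p.strand,
                p.bp_pos - 1, p.bp_pos))) + "\n")


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    heptamer_start: int  # 1-based inclusive
    heptamer_end: int
    name: str
    score: int
    strand: str
    bp_pos: int  # 1-based

    @property
    def intron_id(self) -> str:
        return self.name.rsplit("|", 1)[0]

    @property
    def motif_class(self) -> str:
        return self.name.rsplit("|", 1)[1]


def read_bed(path: str | os.PathLike) -> list[BedRecord]:
    """Read back a prediction BED written by :func:`write_bed`."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, s, e, name, score, strand, ts, te = line.rstrip("\n").split("\t")
            out.append(BedRecord(chrom=c, heptamer_start=int(s) + 1,
                                 heptamer_end=int(e), name=name,
                                 score=int(score), strand=strand,
                                 bp_pos=int(ts) + 1))
    return out
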