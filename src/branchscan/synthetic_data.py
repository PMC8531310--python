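"""Seeded simulation of genome, annotation and variant catalogue.

The generator emits a FASTA genome, an Ensembl-dialect GTF and a VCF with
the statistical structure the analysis assumes: protein-coding genes with
UTRs, start/stop codons and canonical GT..AG introns; one branch point
heptamer planted per intron at a truncated-normal distance from the 3'
splice site (mean 29, sd 11, bounds 14-145 bases) followed by a
polypyrimidine tract; and SNPs drawn per feature class at configurable
densities (variants per 100 bp) and transition/transversion ratios, with
Beta-distributed folded minor allele frequencies.  A machine-readable
truth set records every planted branch point, feature label and variant.

The same seed yields byte-identical output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as _sps

from .feature_map import EXCLUDED, FeatureClass
from .genome_io import reverse_complement

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def default_bps_pwm() -> np.ndarray:
    """A degenerate nnyTrAy-style heptamer PWM (rows 1-7, columns A C G T).

    Position 4 is predominantly T, position 6 predominantly A; positions
    3, 5 and 7 lean pyrimidine/purine/pyrimidine; 1-2 are unconstrained.
    """
    return np.array([
        [0.25, 0.25, 0.25, 0.25],
        [0.25, 0.25, 0.25, 0.25],
        [0.10, 0.30, 0.10, 0.50],
        [0.02, 0.05, 0.02, 0.91],
        [0.45, 0.15, 0.25, 0.15],
        [0.96, 0.02, 0.01, 0.01],
        [0.10, 0.35, 0.10, 0.45],
    ])


def consensus_pwm(consensus: str = "TACTAAC", p: float = 0.97) -> np.ndarray:
    """A sharp PWM concentrated on one heptamer (for recovery experiments)."""
    if len(consensus) != 7:
        raise ValueError("consensus must have length 7")
    idx = {b: i for i, b in enumerate("ACGT")}
    pwm = np.full((7, 4), (1.0 - p) / 3.0)
    for i, b in enumerate(consensus):
        pwm[i, idx[b]] = p
    return pwm


DEFAULT_DENSITIES = {
    FeatureClass.STOP_CODON: 0.5,
    FeatureClass.START_CODON: 0.5,
    FeatureClass.SPLICE5: 0.18,
    FeatureClass.SPLICE3: 0.13,
    FeatureClass.UTR3: 1.0,
    FeatureClass.UTR5: 0.9,
    FeatureClass.EXON: 0.8,
    FeatureClass.INTRON: 1.1,
    FeatureClass.INTERGENIC: 1.5,
}

DEFAULT_TITV = {
    FeatureClass.STOP_CODON: 2.4,
    FeatureClass.START_CODON: 2.4,
    FeatureClass.SPLICE5: 1.5,
    FeatureClass.SPLICE3: 1.5,
    FeatureClass.UTR3: 2.2,
    FeatureClass.UTR5: 2.2,
    FeatureClass.EXON: 2.5,
    FeatureClass.INTRON: 2.1,
    FeatureClass.INTERGENIC: 2.2,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 400_000
    n_genes: int = 60
    n_lncrnas: int = 4
    exons_per_gene: tuple[int, int] = (3, 7)
    exon_length: tuple[int, int] = (60, 240)
    intron_length: tuple[int, int] = (200, 1500)
    utr_length: tuple[int, int] = (20, 60)
    intergenic_gap: tuple[int, int] = (1500, 5000)
    bp_pwm: np.ndarray = field(default_factory=default_bps_pwm)
    bp_distance_mean: float = 29.0
    bp_distance_sd: float = 11.0
    bp_distance_bounds: tuple[int, int] = (14, 145)
    ppt_length: int = 10
    ppt_pyrimidine_fraction: float = 0.85
    base_composition: tuple[float, ...] = (0.3, 0.2, 0.2, 0.3)
    densities: dict = field(default_factory=lambda: dict(DEFAULT_DENSITIES))
    titv: dict = field(default_factory=lambda: dict(DEFAULT_TITV))
    maf_beta: tuple[float, float] = (0.5, 3.0)
    multiallelic_fraction: float = 0.005
    agez_suppression: float = 0.0   # drop prob. for AG-creating SNPs in the AGEZ
    fixed_counts: bool = False      # expected counts instead of binomial draws

    def validate(self) -> None:
        if self.intron_length[0] < self.bp_distance_bounds[1] + 10:
            raise ValueError(
                "minimum intron length must exceed the branch point distance "
                f"bound plus heptamer/donor room "
                f"({self.bp_distance_bounds[1] + 10}); got {self.intron_length[0]}")
        for cls, d in self.densities.items():
            if d < 0 or d > 100:
                raise ValueError(f"density for {cls} outside [0, 100]: {d}")
        if not 0.0 <= self.agez_suppression <= 1.0:
            raise ValueError("agez_suppression must lie in [0, 1]")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")


@dataclass(frozen=True)
class TruthBranchPoint:
    intron_id: str
    chrom: str
    strand: str
    intron_start: int
    intron_end: int
    bp_pos: int          # genomic position of the planted branch point
    bp_distance: int     # distance from the intron 3' end (last base = 1)
    heptamer: str


@dataclass(frozen=True)
class TruthVariant:
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    maf: float
    feature: int         # FeatureClass value or EXCLUDED
    transition: bool     # of the first ALT


@dataclass
class TruthSet:
    labels: dict[str, np.ndarray]
    strands: dict[str, np.ndarray]
    feature_intervals: dict
    branch_points: list[TruthBranchPoint]
    variants: list[TruthVariant] = field(default_factory=list)


def _random_seq(rng, n, comp) -> np.ndarray:
    return rng.choice(_BASES, size=n, p=np.asarray(comp))


def _sample_heptamer(rng, pwm: np.ndarray) -> str:
    return "".join(rng.choice(_BASES, p=row / row.sum()) for row in pwm)


def _build_gene_local(rng, cfg: SimulationConfig):
    """One gene in transcript-local coordinates (1-based, 5'->3')."""
    n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exon_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1,
                             size=n_ex)
    intron_lens = rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1,
                               size=n_ex - 1)
    u5 = int(min(rng.integers(*cfg.utr_length), exon_lens[0] - 10))
    u3 = int(min(rng.integers(*cfg.utr_length), exon_lens[-1] - 13))

    # coding length must be a multiple of 3; spare bases extend the 3' UTR
    cds_total = int(exon_lens.sum()) - u5 - u3 - 3  # minus the stop codon
    u3 += cds_total % 3
    cds_total -= cds_total % 3

    seq = []
    pos = 0
    exons, introns = [], []
    for i, el in enumerate(exon_lens):
        exons.append((pos + 1, pos + int(el)))
        seq.append(_random_seq(rng, int(el), cfg.base_composition))
        pos += int(el)
        if i < n_ex - 1:
            introns.append((pos + 1, pos + int(intron_lens[i])))
            seq.append(_random_seq(rng, int(intron_lens[i]),
                                   cfg.base_composition))
            pos += int(intron_lens[i])
    arr = np.concatenate(seq)
    glen = arr.size

    # carve CDS/UTR structure out of the exon chain; the start codon is part
    # of the CDS (Ensembl convention) and the stop codon is not
    cds_intervals = []
    remaining = cds_total
    tx_cds_start = u5 + 1
    for (es, ee) in exons:
        local_start = max(es, tx_cds_start)
        if remaining <= 0 or local_start > ee:
            continue
        take = min(remaining, ee - local_start + 1)
        cds_intervals.append((local_start, local_start + take - 1))
        remaining -= take
    # stop codon: the 3 bases after the CDS end, inside the last exon
    cds_end = cds_intervals[-1][1]
    stop = (cds_end + 1, cds_end + 3)
    start = (u5 + 1, u5 + 3)
    utr5 = [(exons[0][0], u5)] if u5 > 0 else []
    utr3 = [(stop[1] + 1, exons[-1][1])] if stop[1] < exons[-1][1] else []

    arr[start[0] - 1:start[1]] = list("ATG")
    arr[stop[0] - 1:stop[1]] = list("TAA")

    # frames in transcript order
    frames = []
    cum = 0
    for s, e in cds_intervals:
        frames.append((3 - cum % 3) % 3)
        cum += e - s + 1

    # plant intron signals: donor GTAAG, acceptor AG, heptamer, PPT
    bp_local = []
    a, b = cfg.bp_distance_bounds
    lo = (a - cfg.bp_distance_mean) / cfg.bp_distance_sd
    hi = (b - cfg.bp_distance_mean) / cfg.bp_distance_sd
    pyr = np.array([0.0, 0.5, 0.0, 0.5])
    pur = np.array([0.5, 0.0, 0.5, 0.0])
    ppt_p = (cfg.ppt_pyrimidine_fraction * pyr
             + (1 - cfg.ppt_pyrimidine_fraction) * pur)
    for (is_, ie) in introns:
        L = ie - is_ + 1
        arr[is_ - 1:is_ + 4] = list("GTAAG")
        arr[ie - 2:ie] = list("AG")
        ppt = _BASES[np.searchsorted(np.cumsum(ppt_p),
                                     rng.random(cfg.ppt_length),
                                     side="right")]
        arr[ie - 2 - cfg.ppt_length:ie - 2] = ppt
        d = int(round(float(_sps.truncnorm.rvs(lo, hi, loc=cfg.bp_distance_mean,
                                               scale=cfg.bp_distance_sd,
                                               random_state=rng))))
        d = max(a, min(d, b, L - 10))
        hept = _sample_heptamer(rng, cfg.bp_pwm)
        bp_idx = L - d + 1                      # intron-local, 1-based
        arr[is_ - 1 + bp_idx - 6:is_ - 1 + bp_idx + 1] = list(hept)
        bp_local.append((is_, ie, bp_idx, d, hept))

    return {
        "seq": arr, "length": glen, "exons": exons, "introns": introns,
        "cds": list(zip((s for s, _ in cds_intervals),
                        (e for _, e in cds_intervals), frames)),
        "utr5": utr5, "utr3": utr3, "start": [start], "stop": [stop],
        "bps": bp_local,
    }


def _flip(interval, glen):
    a, b = interval
    return (glen - b + 1, glen - a + 1)


_PAINT_ORDER = [FeatureClass.INTRON, FeatureClass.EXON, FeatureClass.UTR5,
                FeatureClass.UTR3, FeatureClass.SPLICE3, FeatureClass.SPLICE5,
                FeatureClass.START_CODON, FeatureClass.STOP_CODON]


def simulate_genome(config: SimulationConfig, out_dir: str | os.PathLike,
                    ) -> tuple[Path, Path, TruthSet]:
    """Emit genome.fa and annotation.gtf; return their paths and the truth.

    Deterministic under ``config.seed``: the same configuration produces
    byte-identical files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    seqs = {c: _random_seq(rng, config.chromosome_length,
                           config.base_composition) for c in chroms}
    labels = {c: np.full(config.chromosome_length, FeatureClass.INTERGENIC,
                         np.uint8) for c in chroms}
    strands = {c: np.zeros(config.chromosome_length, np.uint8) for c in chroms}
    intervals: dict = {cls: [] for cls in FeatureClass}
    intervals[EXCLUDED] = []
    gtf_lines: list[tuple] = []
    truth_bps: list[TruthBranchPoint] = []

    cursors = {c: 0 for c in chroms}
    gene_no = 0

    def paint(chrom, cls, s, e, strand):
        labels[chrom][s - 1:e] = cls
        strands[chrom][s - 1:e] = 1 if strand == "-" else 0
        intervals[cls].append((chrom, s, e))

    for g in range(config.n_genes + config.n_lncrnas):
        is_lnc = g >= config.n_genes
        chrom = chroms[g % len(chroms)]
        gap = int(rng.integers(*config.intergenic_gap))
        strand = "+" if rng.random() < 0.5 else "-"
        if is_lnc:
            glen = int(rng.integers(500, 2000))
            offset = cursors[chrom] + gap
            if offset + glen > config.chromosome_length:
                continue
            gs, ge = offset + 1, offset + glen
            gid = f"LNC{g + 1:04d}"
            attrs = f'gene_id "{gid}"; gene_biotype "lncRNA";'
            gtf_lines.append((chrom, gs, "gene", gs, ge, strand, ".", attrs))
            tattrs = (f'gene_id "{gid}"; transcript_id "{gid}.1"; '
                      f'gene_biotype "lncRNA";')
            gtf_lines.append((chrom, gs, "transcript", gs, ge, strand, ".", tattrs))
            gtf_lines.append((chrom, gs, "exon", gs, ge, strand, ".", tattrs))
            seg = labels[chrom][gs - 1:ge]
            seg[seg == FeatureClass.INTERGENIC] = EXCLUDED
            intervals[EXCLUDED].append((chrom, gs, ge))
            cursors[chrom] = ge
            continue

        gene = _build_gene_local(rng, config)
        glen = gene["length"]
        offset = cursors[chrom] + gap
        if offset + glen > config.chromosome_length:
            continue
        gene_no += 1
        gs, ge = offset + 1, offset + glen
        local = gene["seq"]
        if strand == "+":
            seqs[chrom][gs - 1:ge] = local
            tolocal = lambda iv: (offset + iv[0], offset + iv[1])
        else:
            seqs[chrom][gs - 1:ge] = np.array(
                list(reverse_complement("".join(local))))
            tolocal = lambda iv: (offset + _flip(iv, glen)[0],
                                  offset + _flip(iv, glen)[1])

        gid = f"GENE{gene_no:04d}"
        tid = f"{gid}.1"
        attrs = f'gene_id "{gid}"; gene_biotype "protein_coding";'
        tattrs = (f'gene_id "{gid}"; transcript_id "{tid}"; '
                  f'gene_biotype "protein_coding";')
        gtf_lines.append((chrom, gs, "gene", gs, ge, strand, ".", attrs))
        gtf_lines.append((chrom, gs, "transcript", gs, ge, strand, ".", tattrs))

        feature_of = {"exons": ("exon", FeatureClass.EXON),
                      "utr5": ("five_prime_utr", FeatureClass.UTR5),
                      "utr3": ("three_prime_utr", FeatureClass.UTR3),
                      "start": ("start_codon", FeatureClass.START_CODON),
                      "stop": ("stop_codon", FeatureClass.STOP_CODON)}
        # paint in priority order, lowest first; GTF rows carry all features
        for (is_, ie, bp_idx, d, hept) in gene["bps"]:
            s, e = tolocal((is_, ie))
            paint(chrom, FeatureClass.INTRON, s, e, strand)
        for s_, e_ in gene["exons"]:
            s, e = tolocal((s_, e_))
            paint(chrom, FeatureClass.EXON, s, e, strand)
        for key in ("utr5", "utr3"):
            for s_, e_ in gene[key]:
                s, e = tolocal((s_, e_))
                paint(chrom, feature_of[key][1], s, e, strand)
        for (is_, ie, bp_idx, d, hept) in gene["bps"]:
            # splice sites: first/last 2 intronic bases in transcript sense
            for cls, a_, b_ in ((FeatureClass.SPLICE3, ie - 1, ie),
                                (FeatureClass.SPLICE5, is_, is_ + 1)):
                s, e = tolocal((a_, b_))
                paint(chrom, cls, s, e, strand)
        for key in ("start", "stop"):
            for s_, e_ in gene[key]:
                s, e = tolocal((s_, e_))
                paint(chrom, feature_of[key][1], s, e, strand)

        for key in ("exons", "utr5", "utr3", "start", "stop"):
            ftype = feature_of[key][0]
            for s_, e_ in gene[key]:
                s, e = tolocal((s_, e_))
                gtf_lines.append((chrom, s, ftype, s, e, strand, ".", tattrs))
        for (cs, ce, frame) in gene["cds"]:
            s, e = tolocal((cs, ce))
            gtf_lines.append((chrom, s, "CDS", s, e, strand, str(frame), tattrs))

        for (is_, ie, bp_idx, d, hept) in gene["bps"]:
            s, e = tolocal((is_, ie))
            if strand == "+":
                bp_pos = s + bp_idx - 1
            else:
                bp_pos = e - bp_idx + 1
            truth_bps.append(TruthBranchPoint(
                intron_id=f"{chrom}:{s}-{e}:{strand}", chrom=chrom,
                strand=strand, intron_start=s, intron_end=e,
                bp_pos=bp_pos, bp_distance=d, heptamer=hept))
        cursors[chrom] = ge

    fasta_path = out / "genome.fa"
    with open(fasta_path, "w") as fh:
        for chrom in chroms:
            fh.write(f">{chrom}\n")
            s = "".join(seqs[chrom])
            for i in range(0, len(s), 80):
                fh.write(s[i:i + 80] + "\n")

    gtf_path = out / "annotation.gtf"
    order = {"gene": 0, "transcript": 1, "exon": 2, "CDS": 3,
             "five_prime_utr": 4, "three_prime_utr": 5, "start_codon": 6,
             "stop_codon": 7}
    gtf_lines.sort(key=lambda r: (r[0], r[1], order[r[2]], r[3], r[4]))
    with open(gtf_path, "w") as fh:
        fh.write("#!genome-build synthetic\n")
        for chrom, _, ftype, s, e, strand, frame, attrs in gtf_lines:
            fh.write(f"{chrom}\tbranchscan_sim\t{ftype}\t{s}\t{e}\t.\t"
                     f"{strand}\t{frame}\t{attrs}\n")

    truth = TruthSet(labels=labels, strands=strands,
                     feature_intervals=intervals, branch_points=truth_bps)
    truth._seqs = seqs  # noqa: SLF001 - reused by simulate_variants
    return fasta_path, gtf_path, truth


def _agez_genomic_positions(truth: TruthSet) -> dict[str, set[int]]:
    """Genomic positions inside the truth AGEZ (BP+1 .. acceptor AG-1)."""
    zones: dict[str, set[int]] = {}
    for bp in truth.branch_points:
        L = bp.intron_end - bp.intron_start + 1
        bp_idx = L - bp.bp_distance + 1
        for idx in range(bp_idx + 1, L - 2 + 1):
            if bp.strand == "+":
                g = bp.intron_start + idx - 1
            else:
                g = bp.intron_end - idx + 1
            zones.setdefault(bp.chrom, set()).add(g)
    return zones


def simulate_variants(config: SimulationConfig, truth: TruthSet,
                      out_dir: str | os.PathLike) -> Path:
    """Draw SNPs per feature at the planted densities and write variants.vcf.

    Site counts per class are binomial in the class size (or fixed to the
    rounded expectation with ``fixed_counts``); ALT alleles realize the
    planted Ti/Tv ratio; folded MAFs follow the configured Beta law.  With
    ``agez_suppression`` > 0, variants that would create an AG dinucleotide
    inside a truth AGEZ are dropped with that probability.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seqs = truth._seqs
    agez = _agez_genomic_positions(truth) if config.agez_suppression > 0 else {}

    records = []
    truth.variants = []
    for chrom in sorted(truth.labels):
        lab = truth.labels[chrom]
        seq = seqs[chrom]
        chosen: dict[int, int] = {}
        for cls in list(FeatureClass) + [EXCLUDED]:
            density = config.densities.get(
                cls, config.densities[FeatureClass.INTERGENIC])
            if density <= 0:
                continue
            positions = np.nonzero(lab == cls)[0]
            if positions.size == 0:
                continue
            p = density / 100.0
            n_sites = (int(round(positions.size * p)) if config.fixed_counts
                       else int(rng.binomial(positions.size, p)))
            n_sites = min(n_sites, positions.size)
            if n_sites == 0:
                continue
            picked = rng.choice(positions, size=n_sites, replace=False)
            titv = config.titv.get(cls, 2.1)
            p_ti = titv / (titv + 1.0)
            for pos0 in sorted(int(x) for x in picked):
                ref = seq[pos0]
                if ref not in _TRANSITION:
                    continue
                if rng.random() < p_ti:
                    alt = _TRANSITION[ref]
                    transition = True
                else:
                    choices = [b for b in "ACGT"
                               if b != ref and b != _TRANSITION[ref]]
                    alt = choices[int(rng.integers(2))]
                    transition = False
                alts = [alt]
                if rng.random() < config.multiallelic_fraction:
                    extra = [b for b in "ACGT" if b != ref and b != alt]
                    alts.append(extra[int(rng.integers(len(extra)))])
                pos = pos0 + 1
                if config.agez_suppression > 0 and \
                        pos in agez.get(chrom, ()):  # oriented AG creation
                    # strand of the intron equals the painting strand here
                    strand = "-" if truth.strands[chrom][pos0] == 1 else "+"
                    if _creates_ag(seq, pos0, alts, strand) and \
                            rng.random() < config.agez_suppression:
                        continue
                if pos in chosen:
                    continue
                chosen[pos] = 1
                maf = float(0.5 * rng.beta(*config.maf_beta))
                maf = min(max(maf, 1e-4), 0.5)
                records.append((chrom, pos, ref, alts, maf))
                truth.variants.append(TruthVariant(
                    chrom=chrom, pos=pos, ref=ref, alts=tuple(alts), maf=maf,
                    feature=int(cls), transition=transition))

    records.sort(key=lambda r: (r[0], r[1]))
    truth.variants.sort(key=lambda v: (v.chrom, v.pos))
    vcf_path = out / "variants.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,'
                 'Description="Alternate allele frequency">\n')
        for chrom in sorted(truth.labels):
            fh.write(f"##contig=<ID={chrom},length={truth.labels[chrom].size}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alts, maf in records:
            afs = [maf] + [round(maf * 0.3, 6) for _ in alts[1:]]
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t"
                     f"AF={','.join(f'{a:.6f}' for a in afs)}\n")
    return vcf_path


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _creates_ag(seq: np.ndarray, pos0: int, alts: Sequence[str],
                strand: str) -> bool:
    """Would any ALT at 0-based genomic pos0 create a new oriented AG?"""
    for alt in alts:
        a = alt
        before = after = 0
        if strand == "+":
            left = seq[pos0 - 1] if pos0 > 0 else "N"
            right = seq[pos0 + 1] if pos0 + 1 < seq.size else "N"
            before += (left == "A" and seq[pos0] == "G") + \
                      (seq[pos0] == "A" and right == "G")
            after += (left == "A" and a == "G") + (a == "A" and right == "G")
        else:
            # oriented sequence is the reverse complement; an oriented AG is
            # a genomic CT read rightwards
            left = seq[pos0 - 1] if pos0 > 0 else "N"
            right = seq[pos0 + 1] if pos0 + 1 < seq.size else "N"
            before += (seq[pos0] == "C" and right == "T") + \
                      (left == "C" and seq[pos0] == "T")
            after += (a == "C" and right == "T") + (left == "C" and a == "T")
        if after > before:
            return True
    return False


def truth_report(truth: TruthSet, out_dir: str | os.PathLike) -> list[Path]:
    """Write truth/*.tsv tables keyed to the emitted files."""
    out = Path(out_dir) / "truth"
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    p = out / "branch_points.tsv"
    with open(p, "w") as fh:
        fh.write("intron_id\tchrom\tstrand\tintron_start\tintron_end\t"
                 "bp_pos\tbp_distance\theptamer\n")
        for bp in truth.branch_points:
            fh.write(f"{bp.intron_id}\t{bp.chrom}\t{bp.strand}\t"
                     f"{bp.intron_start}\t{bp.intron_end}\t{bp.bp_pos}\t"
                     f"{bp.bp_distance}\t{bp.heptamer}\n")
    paths.append(p)

    p = out / "variants.tsv"
    with open(p, "w") as fh:
        fh.write("chrom\tpos\tref\talts\tmaf\tfeature\ttransition\n")
        for v in truth.variants:
            name = ("excluded" if v.feature == EXCLUDED
                    else FeatureClass(v.feature).name.lower())
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{','.join(v.alts)}\t"
                     f"{v.maf:.6f}\t{name}\t{int(v.transition)}\n")
    paths.append(p)

    p = out / "feature_lengths.tsv"
    with open(p, "w") as fh:
        fh.write("feature\tbases\n")
        for cls in FeatureClass:
            n = sum(int((arr == cls).sum()) for arr in truth.labels.values())
            fh.write(f"{cls.name.lower()}\t{n}\n")
        n = sum(int((arr == EXCLUDED).sum()) for arr in truth.labels.values())
        fh.write(f"excluded\t{n}\n")
    paths.append(p)
    return paths


def simulate_all(config: SimulationConfig, out_dir: str | os.PathLike,
                 ) -> dict:
    """Genome + annotation + variants + truth tables in one call."""
    fasta, gtf, truth = simulate_genome(config, out_dir)
    vcf = simulate_variants(config, truth, out_dir)
    reports = truth_report(truth, out_dir)
    return {"fasta": fasta, "gtf": gtf, "vcf": vcf, "truth": truth,
            "truth_tables": reports}
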