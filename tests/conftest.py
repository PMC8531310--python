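"""Shared fixtures: hand-built toy inputs and seeded simulations."""

from __future__ import annotations

import textwrap

import pytest

import branchscan.genome_io as gio
from branchscan.bps_predict import (HeptamerPWM, OctamerWeightTable,
                                    predict_all, train_octamer_weights)
from branchscan.constraint_profile import index_variants
from branchscan.feature_map import build_feature_map
from branchscan.synthetic_data import (SimulationConfig, consensus_pwm,
                                       default_bps_pwm, simulate_all)


def write_fasta(path, seqs: dict[str, str]):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    return path


def write_text(path, text: str):
    path.write_text(textwrap.dedent(text).lstrip("\n"))
    return path


def write_vcf(path, records, contigs=(("chr1", 100000),)):
    """records: (chrom, pos, ref, alt_string, info) tuples."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="AF">\n')
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, info in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")
    return path


def make_site(chrom, pos, ref, alts, maf=0.1):
    return gio.VariantSite(chrom=chrom, pos=pos, ref=ref,
                           alts=tuple(alts), maf=maf)


class SimBundle:
    """A simulation plus everything the pipeline derives from it."""

    def __init__(self, config, out_dir, pwm=None, weights="train"):
        self.config = config
        self.sim = simulate_all(config, out_dir)
        self.truth = self.sim["truth"]
        self.genome = gio.read_fasta(self.sim["fasta"])
        self.transcripts = gio.read_gtf(self.sim["gtf"])
        self.lncrnas = gio.read_lncrna_intervals(self.sim["gtf"])
        self.introns = gio.extract_introns(self.transcripts, self.genome)
        self.variants = index_variants(gio.read_vcf(self.sim["vcf"]))
        self.fmap = build_feature_map(self.transcripts, self.lncrnas,
                                      self.genome)
        self.pwm = pwm or HeptamerPWM(config.bp_pwm)
        if weights == "train":
            self.weights = train_octamer_weights(self.introns)
        else:
            self.weights = OctamerWeightTable.zeros()
        self.predictions = predict_all(self.introns, self.pwm, self.weights)
        self.truth_bp = {b.intron_id: b for b in self.truth.branch_points}


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory) -> SimBundle:
    """Default study conditions: degenerate nnyTrAy PWM, trained octamers."""
    out = tmp_path_factory.mktemp("sim_default")
    return SimBundle(SimulationConfig(seed=11), out)


@pytest.fixture(scope="session")
def sharp_sim(tmp_path_factory) -> SimBundle:
    """Sharp planted PWM on uniform background, scored with the planted
    PWM alone (octamer weights zero): the recovery regime."""
    out = tmp_path_factory.mktemp("sim_sharp")
    cfg = SimulationConfig(seed=7, bp_pwm=consensus_pwm(),
                           base_composition=(0.25, 0.25, 0.25, 0.25))
    return SimBundle(cfg, out, weights="zeros")


@pytest.fixture(scope="session")
def toy_gene_gtf(tmp_path_factory):
    """One plus-strand 2-exon gene on a 200-bp chromosome.

    exon1 [11,40] (UTR5 [11,20], start codon [21,23], CDS [21,40]),
    intron [41,140] (GT..AG), exon2 [141,190]
    (CDS [141,167], stop codon [168,170], UTR3 [171,190]).
    """
    d = tmp_path_factory.mktemp("toy")
    gtf = d / "toy.gtf"
    write_text(gtf, """
    chr1\tsrc\tgene\t11\t190\t.\t+\t.\tgene_id "G1"; gene_biotype "protein_coding";
    chr1\tsrc\ttranscript\t11\t190\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; gene_biotype "protein_coding";
    chr1\tsrc\texon\t11\t40\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
    chr1\tsrc\texon\t141\t190\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
    chr1\tsrc\tCDS\t21\t40\t.\t+\t0\tgene_id "G1"; transcript_id "T1";
    chr1\tsrc\tCDS\t141\t167\t.\t+\t1\tgene_id "G1"; transcript_id "T1";
    chr1\tsrc\tfive_prime_utr\t11\t20\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
    chr1\tsrc\tthree_prime_utr\t171\t190\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
    chr1\tsrc\tstart_codon\t21\t23\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
    chr1\tsrc\tstop_codon\t168\t170\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
    """)
    seq = (["A"] * 10 + ["C"] * 10 + list("ATG") + ["C"] * 17
           + list("GT") + ["T"] * 96 + list("AG")
           + ["G"] * 27 + list("TAA") + ["G"] * 20 + ["A"] * 10)
    fasta = write_fasta(d / "toy.fa", {"chr1": "".join(seq)})
    return {"gtf": gtf, "fasta": fasta, "dir": d}
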