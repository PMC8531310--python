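"""End-to-end orchestration: ingest -> map -> predict -> profile -> spectrum -> agez.

Produces tab-separated report tables mirroring the analysis' headline
shapes: per-feature variability, splice-site positional profiles, branch
point summary, heptamer profiles, Ti/Tv spectra and the AGEZ depletion
report.  Every printed rate carries the m and n it derives from.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np

from . import agez as agez_mod
from . import bps_predict as bps
from . import constraint_profile as cp
from . import genome_io as gio
from . import mutation_spectrum as ms
from .feature_map import FeatureClass, build_feature_map, feature_lengths

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    fasta: str
    gtf: str
    vcf: str
    out_dir: str
    pwm_file: str | None = None
    window: int = 21                 # profile halfwidth around anchors
    search_bp: int = 250             # branch point search bound
    min_intron_len: int = 20
    octamer_pseudocount: float = 1.0
    maf_bins: Sequence[float] = cp.DEFAULT_MAF_BINS
    seed: int = 0


@dataclass
class RunReport:
    config: RunConfig
    feature_variability: dict = field(default_factory=dict)
    splice_profiles: dict = field(default_factory=dict)
    predictions: list = field(default_factory=list)
    prediction_summary: dict = field(default_factory=dict)
    splice_class_counts: dict = field(default_factory=dict)
    heptamer_profiles: dict = field(default_factory=dict)
    codon_variability: dict = field(default_factory=dict)
    spectra: dict = field(default_factory=dict)
    bps_spectra: dict = field(default_factory=dict)
    agez: object = None
    afs: object = None
    paths: dict = field(default_factory=dict)


def percentage(count: int, total: int) -> float | None:
    """100*count/total rounded half-up to 2 decimals; None for zero totals."""
    if total == 0:
        return None
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _write_tsv(path: Path, header: Sequence[str], rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def run_all(config: RunConfig) -> RunReport:
    """Run every stage and write the report bundle under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config)

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        stage("ingest")
        genome = gio.read_fasta(config.fasta)
        transcripts = gio.read_gtf(config.gtf)
        lnc = gio.read_lncrna_intervals(config.gtf)
        introns = gio.extract_introns(transcripts, genome)
        variants = cp.index_variants(gio.read_vcf(config.vcf))
    except Exception as exc:  # noqa: BLE001
        raise StageError("ingest", exc) from exc

    try:
        stage("feature_map")
        fmap = build_feature_map(transcripts, lnc, genome)
        fv = cp.feature_variability(fmap, variants)
        report.feature_variability = fv
        _write_tsv(out / "feature_variability.tsv",
                   ("feature", "m", "n", "rate_per_100bp"),
                   [(k.name.lower() if isinstance(k, FeatureClass) else k,
                     v.m, v.n, _fmt(v.rate)) for k, v in fv.items()])
        report.afs = cp.afs_by_feature(fmap, variants, config.maf_bins)
        rows = []
        for cls, counts in report.afs.counts.items():
            for b, c in enumerate(counts):
                rows.append((cls.name.lower(),
                             f"({report.afs.bin_edges[b]},"
                             f"{report.afs.bin_edges[b + 1]}]",
                             c, _fmt(float(report.afs.fractions[cls][b]))))
        _write_tsv(out / "afs_by_feature.tsv",
                   ("feature", "maf_bin", "count", "fraction"), rows)
    except Exception as exc:  # noqa: BLE001
        raise StageError("feature_map", exc) from exc

    try:
        stage("profiles")
        five, three = cp.splice_site_anchors(transcripts)
        p5 = cp.positional_profile(five, config.window, variants,
                                   description="5' splice site")
        p3 = cp.positional_profile(three, config.window, variants,
                                   description="3' splice site")
        report.splice_profiles = {"splice5": p5, "splice3": p3}
        rows = []
        for name, prof in report.splice_profiles.items():
            for off in prof.offsets:
                e = prof.estimates[off]
                rows.append((name, off, e.m, e.n, _fmt(e.rate)))
        _write_tsv(out / "splice_site_profiles.tsv",
                   ("site", "offset", "m", "n", "rate_per_100bp"), rows)
        report.codon_variability = cp.codon_position_variability(
            transcripts, variants)
        _write_tsv(out / "codon_position_variability.tsv",
                   ("codon_position", "m", "n", "rate_per_100bp"),
                   [(k, v.m, v.n, _fmt(v.rate))
                    for k, v in report.codon_variability.items()])
    except Exception as exc:  # noqa: BLE001
        raise StageError("profiles", exc) from exc

    try:
        stage("predict")
        weights = bps.train_octamer_weights(introns, config.octamer_pseudocount)
        if config.pwm_file:
            pwm = bps.HeptamerPWM.from_file(config.pwm_file)
        else:
            from .synthetic_data import default_bps_pwm
            pwm = bps.HeptamerPWM(default_bps_pwm())
        preds = bps.predict_all(introns, pwm, weights,
                                search_bp=config.search_bp,
                                min_len=config.min_intron_len)
        if not preds:
            raise ValueError("no branch points predicted")
        report.predictions = preds
        report.prediction_summary = bps.summarize_predictions(preds)
        report.splice_class_counts = {}
        for intron in introns:
            report.splice_class_counts[intron.splice_class] = \
                report.splice_class_counts.get(intron.splice_class, 0) + 1
        gio.write_bed(preds, out / "branch_points.bed")
        s = report.prediction_summary
        rows = [("n_predictions", len(preds)),
                ("distance_min", _fmt(s["distance"]["min"])),
                ("distance_max", _fmt(s["distance"]["max"])),
                ("distance_mean", _fmt(s["distance"]["mean"])),
                ("distance_sd", _fmt(s["distance"]["sd"]))]
        rows += [(f"splice_class_{k}", v)
                 for k, v in sorted(report.splice_class_counts.items())]
        rows += [(f"motif_{k}", v)
                 for k, v in s["motif_class_counts"].items()]
        rows += [(f"bp_base_{k}", _fmt(v))
                 for k, v in s["bp_base_fraction"].items()]
        _write_tsv(out / "bps_summary.tsv", ("statistic", "value"), rows)
        cm = cp.consensus_matrix([p.heptamer for p in preds])
        _write_tsv(out / "bps_consensus.tsv",
                   ("position", "A", "C", "G", "T", "information_bits"),
                   [(i + 1, *(_fmt(float(x)) for x in cm.probs[i]),
                     _fmt(float(cm.information[i])))
                    for i in range(cm.probs.shape[0])])
    except Exception as exc:  # noqa: BLE001
        raise StageError("predict", exc) from exc

    try:
        stage("heptamer_profile")
        hp = cp.heptamer_profile(preds, config.window, variants)
        report.heptamer_profiles = hp
        rows = []
        for name, prof in hp.items():
            for off in prof.offsets:
                e = prof.estimates[off]
                rows.append((name, off, e.m, e.n, _fmt(e.rate)))
        _write_tsv(out / "heptamer_profiles.tsv",
                   ("subset", "bp_offset", "m", "n", "rate_per_100bp"), rows)
    except Exception as exc:  # noqa: BLE001
        raise StageError("heptamer_profile", exc) from exc

    try:
        stage("spectrum")
        spectra = ms.feature_residue_spectra(fmap, genome, variants,
                                             introns=introns)
        report.spectra = spectra
        tna = [p for p in preds if p.motif_class == "TNA"]
        bps_targets = {"T4": [], "A6": []}
        for p in tna:
            chrom, s, e, strand = cp._parse_intron_id(p.intron_id)
            L = e - s + 1
            bp_idx = L - p.bp_distance + 1
            # oriented intron indices of heptamer positions 4 and 6
            for key, hidx in (("T4", bp_idx - 2), ("A6", bp_idx)):
                g = s + hidx - 1 if strand == "+" else e - hidx + 1
                bps_targets[key].append((chrom, g, strand))
        report.bps_spectra = {
            "T4": ms.substitution_spectrum(bps_targets["T4"], "T", variants),
            "A6": ms.substitution_spectrum(bps_targets["A6"], "A", variants),
        }
        rows = []

        def spec_row(label, base, spec, ref_spec):
            p = None
            if spec.ti + spec.tv >= 1 and ref_spec is not None and \
                    ref_spec.ti + ref_spec.tv >= 1 and spec is not ref_spec:
                p = ms.compare_titv(spec, ref_spec).p_value
            return (label, base, *(spec.counts[a] for a in spec.counts),
                    spec.ti, spec.tv, _fmt(spec.titv), _fmt(p))

        intron_specs = {b: spectra[(FeatureClass.INTRON, b)] for b in "AT"
                        if (FeatureClass.INTRON, b) in spectra}
        rows.append(spec_row("bps_position4", "T", report.bps_spectra["T4"],
                             intron_specs.get("T")))
        rows.append(spec_row("bps_position6", "A", report.bps_spectra["A6"],
                             intron_specs.get("A")))
        for (cls, base), spec in spectra.items():
            rows.append(spec_row(cls.name.lower(), base, spec,
                                 intron_specs.get(base)))
        _write_tsv(out / "titv_spectra.tsv",
                   ("feature", "ref_base", "alt1", "alt2", "alt3",
                    "ti", "tv", "titv", "p_vs_intron"), rows)
    except Exception as exc:  # noqa: BLE001
        raise StageError("spectrum", exc) from exc

    try:
        stage("agez")
        rep = agez_mod.agez_depletion_test(introns, preds, variants)
        report.agez = rep
        _write_tsv(out / "agez_report.tsv",
                   ("region", "opportunities", "observed", "rate"),
                   [("agez", rep.agez_opportunities, rep.agez_observed,
                     _fmt(rep.agez_rate)),
                    ("other_intronic", rep.rest_opportunities,
                     rep.rest_observed, _fmt(rep.rest_rate)),
                    ("ratio", "", "", _fmt(rep.rate_ratio)),
                    ("fisher_p", "", "", _fmt(rep.p_value))])
    except Exception as exc:  # noqa: BLE001
        raise StageError("agez", exc) from exc

    summary = summarize_counts(report)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    report.paths = {p.name: p for p in out.iterdir()}
    return report


def summarize_counts(report: RunReport) -> dict:
    """Headline percentages (half-up, 2 decimals) from a populated report.

    Covers splice-site class frequencies, branch-point base composition,
    motif classes, and heptamer position-4 thymine conservation.
    """
    out: dict = {}
    total_introns = sum(report.splice_class_counts.values())
    for k, v in sorted(report.splice_class_counts.items()):
        out[f"pct_splice_{k}"] = percentage(v, total_introns)
    preds = report.predictions
    n = len(preds)
    for base in "ACGT":
        cnt = sum(1 for p in preds if p.bp_base == base)
        out[f"pct_bp_{base}"] = percentage(cnt, n)
    for k, v in report.prediction_summary.get("motif_class_counts", {}).items():
        out[f"pct_motif_{k}"] = percentage(v, n)
    t4 = sum(1 for p in preds if p.heptamer[3] == "T")
    out["pct_heptamer_position4_T"] = percentage(t4, n)
    out["n_introns"] = total_introns
    out["n_predictions"] = n
    return out
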