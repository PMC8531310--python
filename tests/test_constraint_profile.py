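"""Variability statistics: rates, profiles, spectra, Fisher engine."""

import math
import random

import numpy as np
import pytest

from branchscan._stats import fisher_2x2
from branchscan.constraint_profile import (Anchor, VariabilityEstimate,
                                           afs_by_feature,
                                           codon_position_variability,
                                           compare_variability,
                                           consensus_matrix,
                                           feature_variability,
                                           heptamer_profile,
                                           positional_profile,
                                           splice_site_anchors)
from branchscan.feature_map import FeatureClass, build_feature_map
from branchscan.genome_io import TranscriptModel
from conftest import make_site, write_fasta

import branchscan.genome_io as gio


def fisher_oracle(a, b, c, d):
    """Exhaustive two-sided Fisher p by hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    p_obs = math.comb(r1, a) * math.comb(r2, c) / denom
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = math.comb(r1, x) * math.comb(r2, c1 - x) / denom
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


class TestVariabilityEstimate:
    def test_rate_definition(self):
        assert VariabilityEstimate(2, 100).rate == 2.0

    def test_site_count_cannot_exceed_bases(self):
        with pytest.raises(ValueError):
            VariabilityEstimate(5, 3)

    def test_published_genome_wide_rate_arithmetic(self):
        """29,418,150 sites over 2,489,368,272 bases is 1.18 per 100 bp,
        one variable site every ~85 bp."""
        est = VariabilityEstimate(29_227_950 + 190_200, 2_489_368_272)
        assert round(est.rate, 2) == 1.18
        assert round(est.n / est.m) == 85


class TestFeatureVariability:
    def test_two_variants_in_100bp_feature(self, tmp_path):
        genome = gio.read_fasta(write_fasta(tmp_path / "g.fa",
                                            {"chr1": "A" * 100}))
        tx = TranscriptModel("T", "G", "chr1", "+", exons=[(1, 100)])
        fmap = build_feature_map([tx], [], genome)
        variants = [make_site("chr1", 10, "A", "G"),
                    make_site("chr1", 90, "A", "C")]
        fv = feature_variability(fmap, variants)
        assert fv[FeatureClass.EXON].rate == 2.0

    def test_matches_brute_force_per_variant_lookup(self, default_sim):
        fv = feature_variability(default_sim.fmap, default_sim.variants)
        counts = {cls: 0 for cls in FeatureClass}
        for chrom, sites in default_sim.variants.items():
            for pos in sites:
                cls = default_sim.fmap.labels[chrom][pos - 1]
                if cls in counts:
                    counts[FeatureClass(cls)] += 1
        for cls in FeatureClass:
            assert fv[cls].m == counts[cls]

    def test_class_sums_account_for_every_site(self, default_sim):
        fv = feature_variability(default_sim.fmap, default_sim.variants)
        total = sum(fv[cls].m for cls in FeatureClass) + fv["excluded"].m
        assert total == fv["genome_wide"].m
        assert fv["genome_wide"].m == sum(
            len(s) for s in default_sim.variants.values())

    def test_planted_density_recovery_within_3se(self, default_sim):
        """Each per-feature rate falls within 3 binomial standard errors
        of the planted density."""
        fv = feature_variability(default_sim.fmap, default_sim.variants)
        planted = default_sim.config.densities
        for cls in FeatureClass:
            est = fv[cls]
            p = planted[cls] / 100.0
            se = 100.0 * math.sqrt(p * (1 - p) / est.n)
            assert abs(est.rate - planted[cls]) <= 3 * se, cls


class TestPositionalProfile:
    def test_single_anchor_single_variant(self):
        a = Anchor("chr1", 100, "+")
        prof = positional_profile([a], 1, [make_site("chr1", 100, "A", "G")])
        assert prof.rate(0) == 100.0
        assert prof.rate(-1) == 0.0 and prof.rate(1) == 0.0

    def test_minus_strand_orientation(self):
        """A variant genomically left of a minus-strand anchor appears at
        a positive (downstream) offset."""
        a = Anchor("chr1", 100, "-")
        prof = positional_profile([a], 2, [make_site("chr1", 98, "A", "G")])
        assert prof.rate(2) == 100.0
        assert prof.rate(-2) == 0.0

    def test_parent_bounds_drop_truncated_anchors(self):
        a = Anchor("chr1", 100, "+", parent_nonneg=(100, 102),
                   parent_neg=(95, 99))
        prof = positional_profile([a], 6, [])
        assert prof.estimates[2].n == 1
        assert prof.estimates[3].n == 0   # beyond nonneg parent
        assert prof.estimates[-5].n == 1
        assert prof.estimates[-6].n == 0  # beyond neg parent

    def test_matches_brute_force_counting(self):
        rng = random.Random(9)
        anchors = []
        for k in range(30):
            strand = rng.choice("+-")
            pos = rng.randint(200, 5000)
            anchors.append(Anchor("chr1", pos, strand,
                                  parent_nonneg=(pos - 15, pos + 15)
                                  if strand == "+" else (pos - 15, pos + 15),
                                  parent_neg=None))
        variants = [make_site("chr1", rng.randint(150, 5100), "A", "G")
                    for _ in range(300)]
        vset = {v.pos for v in variants}
        uniq = {v.pos: v for v in variants}
        prof = positional_profile(anchors, 20, list(uniq.values()))
        for off in prof.offsets:
            m = n = 0
            for a in anchors:
                g = a.pos + off if a.strand == "+" else a.pos - off
                if off >= 0 and not (a.parent_nonneg[0] <= g
                                     <= a.parent_nonneg[1]):
                    continue
                n += 1
                m += g in vset
            assert prof.estimates[off].n == n
            assert prof.estimates[off].m == m

    def test_empty_anchor_set_is_error(self):
        with pytest.raises(ValueError):
            positional_profile([], 5, [])

    def test_splice_anchor_offsets_stay_in_parents(self, default_sim):
        five, three = splice_site_anchors(default_sim.transcripts)
        assert len(five) == len(default_sim.introns)
        prof = positional_profile(five, 21, default_sim.variants)
        # intron side: every intron is >= 200 bp so nothing truncates
        assert prof.estimates[21].n == len(five)
        # exon side: some flanking exons are shorter than 21 bp is false
        # here (exons >= 60), so the exonic side is full too
        assert prof.estimates[-21].n == len(five)


class TestHeptamerProfile:
    def test_variants_outside_heptamers_score_zero_inside(self, sharp_sim):
        far = [make_site("chr1", 1, "A", "G")]
        prof = heptamer_profile(sharp_sim.predictions, 2, far)
        for off in range(-5, 2):
            assert prof["all"].estimates[off].m == 0

    def test_tna_subset_arithmetic(self):
        from branchscan.bps_predict import BranchPointPrediction
        preds = []
        for i, hept in enumerate(["TACTAAC", "GGCGGGC"] * 4):
            start = 1000 * (i + 1)
            preds.append(BranchPointPrediction(
                intron_id=f"chr1:{start}-{start + 400}:+", chrom="chr1",
                strand="+", bp_distance=30, heptamer=hept, score=1.0,
                heptamer_start=start + 365, heptamer_end=start + 371,
                bp_pos=start + 370))
        prof = heptamer_profile(preds, 3, [])
        for off in prof["all"].offsets:
            assert prof["TNA"].estimates[off].n * 2 == \
                prof["all"].estimates[off].n

    def test_matches_brute_force(self, sharp_sim):
        prof = heptamer_profile(sharp_sim.predictions, 10,
                                sharp_sim.variants)
        for off in (-15, -5, -2, 0, 1, 11):
            m = n = 0
            for p in sharp_sim.predictions:
                chrom, span, strand = p.intron_id.rsplit(":", 2)
                s, e = map(int, span.split("-"))
                g = p.bp_pos + off if strand == "+" else p.bp_pos - off
                if not s <= g <= e:
                    continue
                n += 1
                m += g in sharp_sim.variants.get(chrom, {})
            assert prof["all"].estimates[off].n == n
            assert prof["all"].estimates[off].m == m


class TestCodonPositionVariability:
    def test_single_cds_frame_zero(self):
        tx = TranscriptModel("T", "G", "chr1", "+", exons=[(1, 6)],
                             cds=[(1, 6, 0)])
        out = codon_position_variability([tx],
                                         [make_site("chr1", 3, "A", "G")])
        assert out[3].m == 1 and out[1].m == 0 and out[2].m == 0
        assert out[1].n == out[2].n == out[3].n == 2

    def test_minus_strand_last_genomic_base_is_position_one(self):
        tx = TranscriptModel("T", "G", "chr1", "-", exons=[(1, 6)],
                             cds=[(1, 6, 0)])
        out = codon_position_variability([tx],
                                         [make_site("chr1", 6, "A", "G")])
        assert out[1].m == 1

    def test_multi_isoform_union_matches_brute_force(self, default_sim):
        out = codon_position_variability(default_sim.transcripts,
                                         default_sim.variants)
        claims = {1: set(), 2: set(), 3: set()}
        for tx in default_sim.transcripts:
            if sum(e - s + 1 for s, e, _ in tx.cds) % 3:
                continue
            for s, e, frame in tx.cds:
                rng_ = range(s, e + 1) if tx.strand == "+" else \
                    range(e, s - 1, -1)
                for i, g in enumerate(rng_):
                    claims[((i - frame) % 3) + 1].add((tx.chrom, g))
        for cp in (1, 2, 3):
            assert out[cp].n == len(claims[cp])
            m = sum(1 for c, g in claims[cp]
                    if g in default_sim.variants.get(c, {}))
            assert out[cp].m == m


class TestAfs:
    def test_all_low_maf_in_lowest_bin(self, tmp_path):
        genome = gio.read_fasta(write_fasta(tmp_path / "g.fa",
                                            {"chr1": "A" * 100}))
        fmap = build_feature_map([], [], genome)
        variants = [make_site("chr1", i, "A", "G", maf=0.005)
                    for i in range(1, 20)]
        hist = afs_by_feature(fmap, variants)
        assert hist.counts[FeatureClass.INTERGENIC][0] == 19
        assert hist.counts[FeatureClass.INTERGENIC][1:].sum() == 0

    def test_fractions_sum_to_one_per_nonempty_feature(self, default_sim):
        hist = afs_by_feature(default_sim.fmap, default_sim.variants)
        for cls, frac in hist.fractions.items():
            if hist.counts[cls].sum():
                assert frac.sum() == pytest.approx(1.0)

    def test_histogram_matches_hand_count(self, tmp_path):
        genome = gio.read_fasta(write_fasta(tmp_path / "g.fa",
                                            {"chr1": "A" * 100}))
        fmap = build_feature_map([], [], genome)
        mafs = [0.005, 0.01, 0.02, 0.05, 0.07, 0.3, 0.45, 0.5]
        variants = [make_site("chr1", i + 1, "A", "G", maf=m)
                    for i, m in enumerate(mafs)]
        hist = afs_by_feature(fmap, variants)
        # bins (0,.01] (.01,.05] (.05,.1] (.1,.2] (.2,.3] (.3,.4] (.4,.5]
        assert list(hist.counts[FeatureClass.INTERGENIC]) == \
            [2, 2, 1, 0, 1, 0, 2]


class TestConsensusMatrix:
    def test_unanimous_sequences_have_full_information(self):
        cm = consensus_matrix(["TACTAAC"] * 5)
        assert np.allclose(cm.probs.sum(axis=1), 1.0)
        assert np.allclose(cm.information, 2.0)

    def test_uniform_position_has_zero_information(self):
        cm = consensus_matrix(["A", "C", "G", "T"])
        assert cm.information[0] == pytest.approx(0.0)

    def test_hand_computed_matrix(self):
        seqs = ["AAC", "AAC", "ACC", "AGC", "ATC", "AAC", "CAC", "GAC"]
        cm = consensus_matrix(seqs)
        assert cm.probs[0, 0] == pytest.approx(6 / 8)   # A at position 1
        assert cm.probs[1, 0] == pytest.approx(5 / 8)
        assert cm.probs[2, 1] == pytest.approx(1.0)
        expected_ic0 = 2 + (6 / 8) * math.log2(6 / 8) \
            + 2 * (1 / 8) * math.log2(1 / 8)
        assert cm.information[0] == pytest.approx(expected_ic0)

    def test_ragged_lengths_are_error(self):
        with pytest.raises(ValueError):
            consensus_matrix(["AAC", "AACA"])


class TestFisherEngine:
    def test_identical_estimates_give_p_one(self):
        e = VariabilityEstimate(10, 100)
        assert compare_variability(e, e).p_value == pytest.approx(1.0)

    def test_small_table_against_enumeration(self):
        res = fisher_2x2(1, 9, 9, 1)
        assert res.exact
        assert res.p_value == pytest.approx(fisher_oracle(1, 9, 9, 1),
                                            abs=1e-9)
        assert res.p_value == pytest.approx(0.0011, abs=1e-4)

    def test_200_random_tables_agree_with_oracle(self):
        rng = random.Random(17)
        for _ in range(200):
            a, b, c, d = (rng.randint(0, 40) for _ in range(4))
            if min(a + b, c + d) == 0:
                continue
            res = fisher_2x2(a, b, c, d)
            assert res.p_value == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-9), (a, b, c, d)

    def test_large_table_uses_flagged_approximation(self):
        res = fisher_2x2(500_000, 1_500_000, 600_000, 1_400_000)
        assert not res.exact
        assert 0.0 < res.p_value < 1e-10  # grossly unequal rates, p stays >0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2(-1, 2, 3, 4)


def test_profile_consistency_with_feature_rate(default_sim):
    """Mean per-offset intronic rate approximates the intron feature rate
    under uniform intronic variant density."""
    fv = feature_variability(default_sim.fmap, default_sim.variants)
    five, _ = splice_site_anchors(default_sim.transcripts)
    prof = positional_profile(five, 21, default_sim.variants)
    intron_offsets = [o for o in prof.offsets if o >= 2]  # skip GT dinuc
    mean_rate = np.mean([prof.estimates[o].rate for o in intron_offsets])
    intron_rate = fv[FeatureClass.INTRON].rate
    assert abs(mean_rate - intron_rate) < 0.5  # both ~1.1 per 100 bp
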