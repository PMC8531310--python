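"""AG-exclusion-zone (AGEZ) depletion analysis.

The first AG dinucleotide downstream of the branch point is favored as the
3' splice site, so the stretch between the branch point and the acceptor
AG must stay AG-free.  Point mutations that would create a new AG
dinucleotide are therefore expected to be depleted inside the AGEZ
relative to the rest of the intron.  An AG-creating opportunity is a
(position, alternate base) pair whose substitution strictly increases the
number of AG dinucleotides in the sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._stats import FisherResult, fisher_2x2
from .bps_predict import BranchPointPrediction
from .constraint_profile import _as_index
from .genome_io import Intron

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class AGCreationSite:
    """One oriented intron position where a point mutation creates an AG."""

    position: int            # 1-based index in the oriented intron sequence
    required_alt: str        # the base the mutation must introduce (A or G)
    rationale: str           # "pre-G" (x->A before G) or "post-A" (x->G after A)


def define_agez(intron: Intron,
                prediction: BranchPointPrediction,
                from_heptamer_end: bool = False) -> tuple[int, int] | None:
    """Oriented AGEZ interval of an intron with a predicted branch point.

    Spans from the base immediately 3' of the branch point (or of the
    heptamer when ``from_heptamer_end``) to the base immediately 5' of the
    acceptor AG; both bounds are 1-based indices into the oriented intron
    sequence.  None is returned for an empty zone.  Introns without a
    canonical AG acceptor are rejected.
    """
    if intron.acceptor_dinucleotide != "AG":
        raise ValueError(
            f"intron {intron.intron_id} lacks a canonical AG acceptor")
    L = intron.length
    bp_idx = L - prediction.bp_distance + 1
    start = bp_idx + 2 if from_heptamer_end else bp_idx + 1
    end = L - 2
    if start > end:
        return None
    return (start, end)


def _ag_delta(seq: str, i: int, alt: str) -> int:
    """Change in AG-dinucleotide count when position i (0-based) becomes alt.

    Only the pairs (i-1, i) and (i, i+1) can change, so the local delta
    equals the global mutate-and-count difference.
    """
    def is_ag(a: str, b: str) -> bool:
        return a == "A" and b == "G"

    before = after = 0
    if i > 0:
        before += is_ag(seq[i - 1], seq[i])
        after += is_ag(seq[i - 1], alt)
    if i < len(seq) - 1:
        before += is_ag(seq[i], seq[i + 1])
        after += is_ag(alt, seq[i + 1])
    return after - before


def enumerate_ag_creating_sites(sequence: str,
                                interval: tuple[int, int] | None,
                                ) -> list[AGCreationSite]:
    """All AG-creating (position, alternate) pairs inside an interval.

    A pair qualifies only if the substitution strictly increases the AG
    count; mutations that simultaneously destroy an existing AG (e.g. the
    G of "AGG" to A) do not.  Neighboring context outside the interval
    still participates in the delta.
    """
    if interval is None:
        return []
    lo, hi = interval
    if lo < 1 or hi > len(sequence):
        raise ValueError(f"interval {interval} outside sequence of length "
                         f"{len(sequence)}")
    sites = []
    for pos in range(lo, hi + 1):
        i = pos - 1
        base = sequence[i]
        for alt, rationale in (("A", "pre-G"), ("G", "post-A")):
            if base == alt:
                continue
            if _ag_delta(sequence, i, alt) > 0:
                sites.append(AGCreationSite(position=pos, required_alt=alt,
                                            rationale=rationale))
    return sites


@dataclass
class AgezReport:
    """Opportunity and observed AG-creating mutation counts by region."""

    agez_opportunities: int
    agez_observed: int
    rest_opportunities: int
    rest_observed: int
    p_value: float | None = None

    @property
    def agez_rate(self) -> float:
        return (self.agez_observed / self.agez_opportunities
                if self.agez_opportunities else float("nan"))

    @property
    def rest_rate(self) -> float:
        return (self.rest_observed / self.rest_opportunities
                if self.rest_opportunities else float("nan"))

    @property
    def rate_ratio(self) -> float:
        r = self.rest_rate
        return self.agez_rate / r if r and r > 0 else float("nan")


def agez_depletion_test(introns: Sequence[Intron],
                        predictions: Sequence[BranchPointPrediction],
                        variants,
                        from_heptamer_end: bool = False) -> AgezReport:
    """Test whether AG-creating mutations are depleted inside the AGEZ.

    Opportunities are pooled over the AGEZ versus the remainder of each
    intron (terminal splice-site dinucleotides excluded); an opportunity is
    observed when a variant at that position carries the required oriented
    ALT allele.  Introns without a prediction or without a canonical AG
    acceptor are excluded entirely.
    """
    vidx = _as_index(variants)
    pred_by_id = {p.intron_id: p for p in predictions}
    agez_opp = agez_obs = rest_opp = rest_obs = 0
    n_used = n_skipped = 0
    for intron in introns:
        pred = pred_by_id.get(intron.intron_id)
        if pred is None:
            continue
        if intron.acceptor_dinucleotide != "AG":
            n_skipped += 1
            continue
        n_used += 1
        zone = define_agez(intron, pred, from_heptamer_end=from_heptamer_end)
        interior = (3, intron.length - 2)
        sites = enumerate_ag_creating_sites(intron.sequence, interior) \
            if interior[0] <= interior[1] else []
        chrom_sites = vidx.get(intron.chrom, {})
        for site in sites:
            in_agez = zone is not None and zone[0] <= site.position <= zone[1]
            g = intron.oriented_position(site.position)
            v = chrom_sites.get(g)
            hit = False
            if v is not None:
                for alt in v.alts:
                    oriented = alt if intron.strand == "+" else _COMP[alt]
                    if oriented == site.required_alt:
                        hit = True
            if in_agez:
                agez_opp += 1
                agez_obs += hit
            else:
                rest_opp += 1
                rest_obs += hit
    if n_used == 0:
        raise ValueError("no intron had both a prediction and an AG acceptor")
    if n_skipped:
        logger.info("agez_depletion_test excluded %d non-AG-acceptor introns",
                    n_skipped)
    report = AgezReport(agez_opportunities=agez_opp, agez_observed=agez_obs,
                        rest_opportunities=rest_opp, rest_observed=rest_obs)
    if agez_opp == 0 or rest_opp == 0:
        logger.warning("zero opportunities in one region; no test performed")
        return report
    res: FisherResult = fisher_2x2(agez_obs, agez_opp - agez_obs,
                                   rest_obs, rest_opp - rest_obs)
    report.p_value = res.p_value
    return report
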