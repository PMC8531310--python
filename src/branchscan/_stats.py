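"""Two-sided Fisher's exact test for 2x2 tables of feature counts.

Genome-scale contingency tables (hundreds of millions of bases) make the
exact hypergeometric summation numerically pointless and slow, so tables
whose grand total exceeds a threshold fall back to a chi-square test with
continuity correction, computed in log space via the survival function.
The fallback is flagged in the returned result.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats as _sps

#: above this grand total the chi-square approximation is used
EXACT_TOTAL_LIMIT = 1_000_000


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float | None
    exact: bool

    def __float__(self) -> float:  # allows use where a bare p is expected
        return self.p_value


def fisher_2x2(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided test of association for the table [[a, b], [c, d]].

    Exact (conditional hypergeometric, summing all tables with probability
    not exceeding the observed one) when a+b+c+d <= EXACT_TOTAL_LIMIT,
    otherwise a continuity-corrected chi-square approximation.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError(f"cell counts must be nonnegative integers, got {(a, b, c, d)}")
    total = a + b + c + d
    if total == 0:
        raise ValueError("empty contingency table")
    odds: float | None
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = float("inf")
    else:
        odds = None
    if total <= EXACT_TOTAL_LIMIT:
        _, p = _sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        return FisherResult(p_value=min(1.0, float(p)), odds_ratio=odds, exact=True)
    # Degenerate margins carry no information; match the exact test's p = 1.
    if min(a + b, c + d, a + c, b + d) == 0:
        return FisherResult(p_value=1.0, odds_ratio=odds, exact=False)
    chi2, p, _, _ = _sps.chi2_contingency([[a, b], [c, d]], correction=True)
    # extreme tables underflow the survival function; keep p in (0, 1]
    p = max(float(p), 5e-324)
    return FisherResult(p_value=p, odds_ratio=odds, exact=False)
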