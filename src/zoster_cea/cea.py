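"""Cost-effectiveness arithmetic: ICERs, dominance, NMB, averted burden, frontier.

Conventions: the *reference* is the cheaper/less effective baseline (here
usually no vaccination) and the *comparator* the strategy being judged.
``delta`` quantities are comparator minus reference.  The incremental
cost-effectiveness ratio (ICER) = dCost/dQALY is reported only in the standard
quadrant; strict dominance in either direction is reported as a marker instead
of a number.  Net monetary benefit NMB = WTP x dQALY - dCost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence, Union

from .cohort import StrategyResult

# Dominance / degenerate markers returned by compute_icer
COMPARATOR_DOMINANT = "comparator_dominant"    # cheaper and more effective
COMPARATOR_DOMINATED = "comparator_dominated"  # costlier and less effective
ICER_UNDEFINED = "undefined"                   # zero QALY difference

IcerValue = Union[float, str]


def compute_icer(delta_cost: float, delta_qaly: float) -> IcerValue:
    """ICER or a dominance marker for one pairwise comparison.

    Scale-invariant: per-person and per-1000 increments give the same answer.
    """
    if delta_qaly == 0:
        return ICER_UNDEFINED
    if delta_qaly > 0 and delta_cost < 0:
        return COMPARATOR_DOMINANT
    if delta_qaly < 0 and delta_cost > 0:
        return COMPARATOR_DOMINATED
    # standard quadrant, or the south-west quadrant where the ratio is still
    # informative (comparator cheaper and less effective)
    return delta_cost / delta_qaly


def nmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    return wtp * delta_qaly - delta_cost


@dataclass(frozen=True)
class CEAComparison:
    """One pairwise comparison at a willingness-to-pay threshold."""

    reference: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: IcerValue
    nmb_at_wtp: float
    cost_effective_at_wtp: bool


def compare(reference: StrategyResult, comparator: StrategyResult, wtp: float) -> CEAComparison:
    """Pairwise comparison of two StrategyResults (per-1000 scale)."""
    dc = comparator.total_cost_per_1000 - reference.total_cost_per_1000
    dq = comparator.total_qalys_per_1000 - reference.total_qalys_per_1000
    benefit = nmb(dc, dq, wtp)
    return CEAComparison(
        reference=str(getattr(reference.strategy, "value", reference.strategy)),
        comparator=str(getattr(comparator.strategy, "value", comparator.strategy)),
        delta_cost=dc,
        delta_qaly=dq,
        icer=compute_icer(dc, dq),
        nmb_at_wtp=benefit,
        cost_effective_at_wtp=benefit > 0,
    )


def decide_at_wtp(comparison: CEAComparison, wtp: float) -> bool:
    """True iff the comparator is cost-effective at the threshold (NMB > 0)."""
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be > 0")
    return nmb(comparison.delta_cost, comparison.delta_qaly, wtp) > 0


def round_half_away(x: float) -> int:
    """Round to nearest integer with ties away from zero (report formatting)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


class AvertedPct(NamedTuple):
    """Percentage of burden averted; raw value plus report rounding."""

    value: float
    rounded: int


def averted_pct(cases_reference: float, cases_comparator: float) -> AvertedPct:
    """Percent of the reference arm's burden averted by the comparator.

    Returns the unrounded percentage together with the nearest-integer value
    used in reporting.  A zero reference burden leaves the percentage undefined.
    """
    if cases_reference == 0:
        raise ZeroDivisionError("averted percentage undefined for zero reference burden")
    pct = 100.0 * (cases_reference - cases_comparator) / cases_reference
    return AvertedPct(pct, round_half_away(pct))


@dataclass
class FrontierEntry:
    result: StrategyResult
    dominated: bool = False
    extended_dominated: bool = False
    icer_vs_previous: IcerValue = None  # sequential ICER along the frontier
    on_frontier: bool = False


def frontier(results: Sequence[StrategyResult], wtp: float) -> list[FrontierEntry]:
    """Incremental analysis over the cost-effectiveness frontier.

    Strategies are sorted by cost (stable: ties keep input order and the later
    duplicate is flagged dominated); strictly dominated options (>= cost,
    <= QALYs than another) are removed, then extended dominance prunes any
    strategy whose sequential ICER exceeds that of the next one up, and
    sequential ICERs are recomputed on the survivors.  The surviving set is
    independent of input order.
    """
    if len(results) < 2:
        raise ValueError("frontier needs at least 2 strategies")
    entries = [FrontierEntry(r) for r in results]
    entries.sort(key=lambda e: (e.result.total_cost_per_1000, -e.result.total_qalys_per_1000))

    # strict dominance (ties: the equally-good later entry is dominated)
    for i, e in enumerate(entries):
        for j, other in enumerate(entries):
            if i == j or other.dominated:
                continue
            oc, oq = other.result.total_cost_per_1000, other.result.total_qalys_per_1000
            ec, eq = e.result.total_cost_per_1000, e.result.total_qalys_per_1000
            if (oc <= ec and oq > eq) or (oc < ec and oq >= eq) or (oc == ec and oq == eq and j < i):
                e.dominated = True
                break

    def live():
        return [e for e in entries if not e.dominated and not e.extended_dominated]

    # extended dominance: prune until sequential ICERs are increasing
    changed = True
    while changed:
        changed = False
        alive = live()
        for k in range(1, len(alive) - 1):
            lo, mid, hi = alive[k - 1], alive[k], alive[k + 1]
            icer_mid = compute_icer(
                mid.result.total_cost_per_1000 - lo.result.total_cost_per_1000,
                mid.result.total_qalys_per_1000 - lo.result.total_qalys_per_1000,
            )
            icer_hi = compute_icer(
                hi.result.total_cost_per_1000 - mid.result.total_cost_per_1000,
                hi.result.total_qalys_per_1000 - mid.result.total_qalys_per_1000,
            )
            if (
                isinstance(icer_mid, float)
                and isinstance(icer_hi, float)
                and icer_mid > icer_hi
            ):
                mid.extended_dominated = True
                changed = True
                break

    prev = None
    for e in live():
        e.on_frontier = True
        if prev is not None:
            e.icer_vs_previous = compute_icer(
                e.result.total_cost_per_1000 - prev.result.total_cost_per_1000,
                e.result.total_qalys_per_1000 - prev.result.total_qalys_per_1000,
            )
        prev = e
    return entries
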