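"""Pairwise cost-effectiveness comparison.

The incremental cost-effectiveness ratio (ICER) is the incremental cost
per QALY gained of an intervention over a comparator; it is compared
against a willingness-to-pay (WTP) threshold (baseline: US$ 23 050/QALY,
three times 2014 Chinese GDP per capita).  Net monetary benefit (NMB) is
WTP x incremental effect - incremental cost.  All arithmetic uses the
full-precision model outputs; rounding happens only in report formatting.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import CohortResult


@dataclass(frozen=True)
class CeComparison:
    intervention: str
    comparator: str
    incremental_cost: float
    incremental_qaly: float
    icer: float | None          # None when incremental_qaly == 0
    nmb: float
    wtp: float
    dominance: str              # 'dominant' | 'dominated' | 'trade-off' | 'equivalent'
    cost_effective: bool


def compare(intervention: CohortResult, comparator: CohortResult,
            wtp: float) -> CeComparison:
    """Compare two cohort runs produced under identical parameters.

    Dominance: the intervention is dominant when it is no more costly and
    no less effective (at least one strictly); dominated in the mirror
    case.  For trade-offs, cost-effectiveness is equivalent to a positive
    net monetary benefit at the given threshold.
    """
    d_cost = intervention.discounted_cost - comparator.discounted_cost
    d_qaly = intervention.discounted_qaly - comparator.discounted_qaly
    icer = d_cost / d_qaly if d_qaly != 0.0 else None
    nmb = wtp * d_qaly - d_cost

    if d_cost == 0.0 and d_qaly == 0.0:
        dominance = "equivalent"
        cost_effective = True
    elif d_cost <= 0.0 and d_qaly >= 0.0:
        dominance = "dominant"
        cost_effective = True
    elif d_cost >= 0.0 and d_qaly <= 0.0:
        dominance = "dominated"
        cost_effective = False
    else:
        dominance = "trade-off"
        cost_effective = nmb > 0.0

    return CeComparison(
        intervention=intervention.strategy,
        comparator=comparator.strategy,
        incremental_cost=d_cost,
        incremental_qaly=d_qaly,
        icer=icer,
        nmb=nmb,
        wtp=wtp,
        dominance=dominance,
        cost_effective=cost_effective,
    )
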