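"""Base-case results table: per-1000 outcomes and pairwise ICERs by age.

One row per (starting age x strategy) with lifetime herpes zoster cases, PHN
cases, discounted total cost and QALYs per 1000 people, plus incremental
cost/QALYs and the ICER of each vaccination strategy against no vaccination
(the primary pairwise design; the full frontier is available from
:func:`zoster_cea.cea.frontier`).
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .cea import compare, round_half_away
from .cohort import STRATEGY_ORDER, Strategy, evaluate_all
from .params import ParameterSet

BASECASE_COLUMNS = [
    "start_age",
    "strategy",
    "cases_per_1000",
    "phn_per_1000",
    "cost_per_1000",
    "qalys_per_1000",
    "incremental_cost",
    "incremental_qalys",
    "icer",
]


def basecase_table(params: ParameterSet, ages: Sequence[int] = (50, 60, 70, 80)) -> pd.DataFrame:
    """Unrounded base-case results, strategies ordered none / ZVL / RZV."""
    records = []
    for age in ages:
        results = evaluate_all(params, age)
        ref = results[Strategy.NONE]
        for strat in STRATEGY_ORDER:
            res = results[strat]
            row = {
                "start_age": age,
                "strategy": strat.value,
                "cases_per_1000": res.cases_per_1000,
                "phn_per_1000": res.phn_per_1000,
                "cost_per_1000": res.total_cost_per_1000,
                "qalys_per_1000": res.total_qalys_per_1000,
                "incremental_cost": None,
                "incremental_qalys": None,
                "icer": None,
            }
            if strat is not Strategy.NONE:
                cmp_ = compare(ref, res, params.economics.wtp)
                row["incremental_cost"] = cmp_.delta_cost
                row["incremental_qalys"] = cmp_.delta_qaly
                row["icer"] = cmp_.icer
            records.append(row)
    return pd.DataFrame.from_records(records, columns=BASECASE_COLUMNS)


def format_basecase_table(table: pd.DataFrame) -> pd.DataFrame:
    """Report formatting: costs and ICERs to whole USD (ties away from zero),
    QALYs to 2 decimals, case counts to whole persons."""
    out = table.copy()

    def money(x):
        if x is None or isinstance(x, str) or (isinstance(x, float) and math.isnan(x)):
            return None if not isinstance(x, str) else x
        return round_half_away(float(x))

    for col in ("cases_per_1000", "phn_per_1000", "cost_per_1000", "incremental_cost"):
        out[col] = [money(x) for x in out[col]]
    out["icer"] = [x if isinstance(x, str) or x is None else money(x) for x in out["icer"]]
    for col in ("qalys_per_1000", "incremental_qalys"):
        out[col] = [None if x is None else round(float(x), 2) for x in out[col]]
    return out
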