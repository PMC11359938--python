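"""Sensitivity and scenario analyses around the base-case model.

Four analyses, mirroring how published vaccine CEAs probe uncertainty:

* **one_way_tornado** — each parameter in ``owsa_spec`` is swung to its low
  and high bound with everything else at base, and the vaccination-vs-none
  ICER is recorded; bars sorted by width give the tornado diagram data.
* **run_psa** — Monte-Carlo resampling of every parameter in ``psa_spec``;
  each draw is evaluated for all three strategies (common draw across
  strategies, so contrasts share Monte-Carlo noise), yielding per-draw
  (cost, QALY) pairs and a cost-effectiveness acceptability curve (CEAC):
  the share of draws in which each strategy has the highest net monetary
  benefit on a willingness-to-pay grid.
* **compliance_scenario** — the two-dose completion rate of the recombinant
  vaccine is swept (dose costs follow compliance; partial completers keep
  the scaled one-dose protection) and the RZV-vs-none ICER recomputed.
* **zvl_price_threshold** — the live attenuated vaccine's per-dose price at
  which its net monetary benefit equals the recombinant vaccine's.  NMB is
  affine in the price (one dose charged at cycle 0), so the root follows in
  closed form from two evaluations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bands import band_of
from .cea import compute_icer
from .cohort import STRATEGY_ORDER, Strategy, evaluate_all, evaluate_strategy
from .errors import ConfigurationError
from .params import ParameterSet, get_path, set_path
from .synthetic import sample_psa_draw

DEFAULT_START_AGES = (50, 60, 70, 80)


# ---------------------------------------------------------------------------
# one-way (tornado) sensitivity


@dataclass(frozen=True)
class TornadoEntry:
    parameter_path: str
    low_value: float
    high_value: float
    icer_at_low: float
    icer_at_high: float

    @property
    def bar_width(self) -> float:
        if math.isnan(self.icer_at_low) or math.isnan(self.icer_at_high):
            return float("nan")
        return abs(self.icer_at_high - self.icer_at_low)


def _icer_vs_none(params: ParameterSet, strategy: Strategy, start_age: int) -> float:
    ref = evaluate_strategy(params, Strategy.NONE, start_age)
    cmp_ = evaluate_strategy(params, strategy, start_age)
    icer = compute_icer(
        cmp_.total_cost_per_1000 - ref.total_cost_per_1000,
        cmp_.total_qalys_per_1000 - ref.total_qalys_per_1000,
    )
    return icer if isinstance(icer, float) else float("nan")


def one_way_tornado(
    params: ParameterSet,
    strategy: Strategy = Strategy.RZV,
    start_age: int = 60,
    top_n: Optional[int] = 6,
) -> list[TornadoEntry]:
    """One-at-a-time parameter swings; entries sorted by bar width, widest first.

    ``top_n`` limits the report to the most influential parameters (the
    published tornado diagrams show six); pass ``None`` for all.
    """
    if not params.owsa_spec:
        raise ConfigurationError("owsa_spec is empty; nothing to vary")
    entries = []
    for path, (low, high) in params.owsa_spec.items():
        icers = []
        for bound in (low, high):
            varied = params.copy()
            set_path(varied, path, bound)
            icers.append(_icer_vs_none(varied, strategy, start_age))
        entries.append(
            TornadoEntry(
                parameter_path=path,
                low_value=low,
                high_value=high,
                icer_at_low=icers[0],
                icer_at_high=icers[1],
            )
        )
    entries.sort(key=lambda e: -(0.0 if math.isnan(e.bar_width) else e.bar_width))
    return entries if top_n is None else entries[:top_n]


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter_path for e in entries],
            "low_value": [e.low_value for e in entries],
            "high_value": [e.high_value for e in entries],
            "icer_at_low": [e.icer_at_low for e in entries],
            "icer_at_high": [e.icer_at_high for e in entries],
            "bar_width": [e.bar_width for e in entries],
        }
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PsaOutput:
    """Per-draw strategy outcomes and the acceptability curve of one PSA run."""

    n_draws: int
    seed: Optional[int]
    start_age: int
    draws: pd.DataFrame  # columns: draw, strategy, cost, qaly (per 1000)
    ceac: pd.DataFrame   # columns: wtp, strategy, probability
    wtp_grid: np.ndarray = field(repr=False, default=None)


def default_wtp_grid(params: ParameterSet, n: int = 101) -> np.ndarray:
    """0 to 3x the configured willingness-to-pay threshold, inclusive."""
    return np.linspace(0.0, 3.0 * params.economics.wtp, n)


def preferred_strategy_shares(
    draws: pd.DataFrame, wtp_grid: np.ndarray
) -> pd.DataFrame:
    """CEAC: share of draws in which each strategy has maximal NMB per WTP.

    Ties resolve to the first strategy in the fixed order (no vaccination,
    live attenuated, recombinant), so probabilities always sum to one.
    """
    wide_c = draws.pivot(index="draw", columns="strategy", values="cost")
    wide_q = draws.pivot(index="draw", columns="strategy", values="qaly")
    order = [s.value for s in STRATEGY_ORDER]
    costs = wide_c[order].to_numpy()
    qalys = wide_q[order].to_numpy()
    records = []
    for wtp in np.asarray(wtp_grid, dtype=float):
        nmb = wtp * qalys - costs
        best = np.argmax(nmb, axis=1)  # argmax takes the first maximum: fixed tie order
        for k, name in enumerate(order):
            records.append(
                {"wtp": wtp, "strategy": name, "probability": float(np.mean(best == k))}
            )
    return pd.DataFrame.from_records(records)


def run_psa(
    params: ParameterSet,
    n_draws: int = 10000,
    seed: Optional[int] = None,
    wtp_grid: Optional[np.ndarray] = None,
    start_age: int = 60,
) -> PsaOutput:
    """Monte-Carlo PSA: ``n_draws`` parameter draws, all strategies per draw.

    A single seeded random stream drives every draw; the same seed reproduces
    the output bit for bit.
    """
    if not params.psa_spec:
        raise ConfigurationError("psa_spec is empty; cannot run PSA")
    rng = np.random.default_rng(seed)
    grid = default_wtp_grid(params) if wtp_grid is None else np.asarray(wtp_grid, float)
    records = []
    for i in range(n_draws):
        draw_params = sample_psa_draw(params, rng)
        results = evaluate_all(draw_params, start_age)
        for strat in STRATEGY_ORDER:
            res = results[strat]
            records.append(
                {
                    "draw": i,
                    "strategy": strat.value,
                    "cost": res.total_cost_per_1000,
                    "qaly": res.total_qalys_per_1000,
                }
            )
    draws = pd.DataFrame.from_records(records)
    ceac = preferred_strategy_shares(draws, grid)
    return PsaOutput(
        n_draws=n_draws, seed=seed, start_age=start_age, draws=draws, ceac=ceac, wtp_grid=grid
    )


# ---------------------------------------------------------------------------
# compliance scenario sweep


def compliance_scenario(
    params: ParameterSet,
    rates: Sequence[float],
    start_ages: Sequence[int] = DEFAULT_START_AGES,
) -> pd.DataFrame:
    """RZV-vs-none ICER under varying two-dose completion rates.

    Dose costs follow compliance (completers pay two doses, the rest one);
    partial completers keep single-dose protection as configured by
    ``model.rzv_one_dose_factor``.
    """
    records = []
    for age in start_ages:
        for rate in rates:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"compliance rate {rate} outside [0, 1]")
            scenario = params.copy()
            scenario.economics.compliance_two_dose = float(rate)
            records.append(
                {
                    "start_age": age,
                    "compliance_two_dose": rate,
                    "icer_vs_none": _icer_vs_none(scenario, Strategy.RZV, age),
                }
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# ZVL price threshold


@dataclass(frozen=True)
class ThresholdResult:
    """Price at which the live attenuated vaccine matches the recombinant one.

    ``threshold_price`` is the equalizing per-dose price when it falls inside
    [0, base price]; otherwise it is NaN, ``achievable`` is False, and
    ``unconstrained_price`` still reports the affine solution (which may be
    negative or above the base price) for diagnostic use.
    """

    age_band: str
    base_price: float
    threshold_price: float
    pct_reduction_from_base: float
    achievable: bool
    unconstrained_price: float
    note: str = ""


def _nmb_at(params: ParameterSet, strategy: Strategy, start_age: int) -> float:
    ref = evaluate_strategy(params, Strategy.NONE, start_age)
    res = evaluate_strategy(params, strategy, start_age)
    wtp = params.economics.wtp
    return wtp * (res.total_qalys_per_1000 - ref.total_qalys_per_1000) - (
        res.total_cost_per_1000 - ref.total_cost_per_1000
    )


def zvl_price_threshold(params: ParameterSet, start_age: int) -> ThresholdResult:
    """Per-dose ZVL price equalizing its net monetary benefit with RZV's.

    NMB(ZVL) is affine in the dose price, so two evaluations (price 0 and the
    base price) determine the crossing exactly.
    """
    base_price = params.costs.price_zvl_dose
    nmb_rzv = _nmb_at(params, Strategy.RZV, start_age)

    def nmb_zvl(price: float) -> float:
        p = params.copy()
        p.costs.price_zvl_dose = price
        return _nmb_at(p, Strategy.ZVL, start_age)

    n0, n1 = nmb_zvl(0.0), nmb_zvl(base_price)
    slope = (n1 - n0) / base_price if base_price > 0 else 0.0
    if slope == 0.0:
        p_star = float("nan")
    else:
        p_star = (nmb_rzv - n0) / slope

    band = band_of(start_age).label
    achievable = math.isfinite(p_star) and 0.0 <= p_star <= base_price
    if achievable:
        return ThresholdResult(
            age_band=band,
            base_price=base_price,
            threshold_price=p_star,
            pct_reduction_from_base=100.0 * (base_price - p_star) / base_price,
            achievable=True,
            unconstrained_price=p_star,
        )
    return ThresholdResult(
        age_band=band,
        base_price=base_price,
        threshold_price=float("nan"),
        pct_reduction_from_base=float("nan"),
        achievable=False,
        unconstrained_price=p_star,
        note="not achievable by price alone",
    )


def threshold_table(
    params: ParameterSet, start_ages: Sequence[int] = DEFAULT_START_AGES
) -> pd.DataFrame:
    rows = [zvl_price_threshold(params, age) for age in start_ages]
    return pd.DataFrame(
        {
            "age_band": [r.age_band for r in rows],
            "base_price": [r.base_price for r in rows],
            "threshold_price": [r.threshold_price for r in rows],
            "pct_reduction_from_base": [r.pct_reduction_from_base for r in rows],
            "achievable": [r.achievable for r in rows],
            "unconstrained_price": [r.unconstrained_price for r in rows],
        }
    )
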