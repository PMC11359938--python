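"""Annual-cycle Markov cohort engine.

A closed cohort enters the model healthy at its vaccination age (50, 60, 70,
or 80) and is cycled annually over a 40-year horizon through six states:

    Healthy -> AcuteHZ -> {PHN, OtherComplication, HZResolved, Dead}
    HZResolved -> AcuteHZ (recurrence)      Dead is absorbing.

Each cycle, all-cause mortality at the attained age is applied first; disease
transitions occur among survivors (multiplicative competing-risk composition).
Zoster-attributable death applies only during the acute episode via the
per-episode case fatality.  Vaccine protection multiplies ``(1 - VE(t))`` onto
both the first-episode incidence and the recurrence probability, where the
waning curve is indexed by the band at vaccination and ``t`` is years since
vaccination (cycle index).

Costs: both RZV doses (weighted by two-dose compliance) or the single ZVL
dose, plus administration, are charged at cycle 0.  Acute-episode costs
(direct medical, non-medical, productivity loss) attach to each cycle spent in
AcuteHZ — one cycle per episode, so totals equal episodes x unit cost — while
PHN and other-complication costs attach to each occupied cycle, which
generalizes correctly when those states are configured to last more than one
cycle.  QALYs accrue per cycle as occupancy-weighted state utilities, with
disease-state utilities capped at the background utility of the attained age.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import band_of
from .efficacy import build_curves, effective_rzv_efficacy, efficacy_at, scale_curve
from .errors import ZosterCeaError
from .params import ParameterSet, mortality_at


class HealthState(enum.IntEnum):
    HEALTHY = 0
    ACUTE_HZ = 1
    PHN = 2
    OTHER_COMP = 3
    HZ_RESOLVED = 4
    DEAD = 5


N_STATES = len(HealthState)


class Strategy(str, enum.Enum):
    NONE = "no_vaccination"
    ZVL = "zvl"
    RZV = "rzv"


STRATEGY_ORDER = (Strategy.NONE, Strategy.ZVL, Strategy.RZV)

COST_CATEGORIES = ("vaccine", "admin", "direct_medical", "nonmedical", "indirect")


@dataclass
class CohortTrace:
    """Cycle-by-cycle record of one strategy run on a unit cohort.

    ``occupancy`` has ``horizon + 1`` rows (states at the start of each cycle,
    plus the endpoint); event and value streams have ``horizon`` entries, one
    per lived cycle, all undiscounted and per person.
    """

    strategy: Strategy
    start_age: int
    occupancy: np.ndarray
    new_hz_episodes: np.ndarray
    new_phn_cases: np.ndarray
    new_comp_cases: np.ndarray
    cost_streams: dict[str, np.ndarray]
    qaly_stream: np.ndarray

    @property
    def cost_stream(self) -> np.ndarray:
        """Total undiscounted cost per cycle, summed over categories."""
        return sum(self.cost_streams.values())

    def to_dataframe(self) -> pd.DataFrame:
        """One row per cycle: occupancies, new events, costs, QALYs."""
        h = len(self.qaly_stream)
        df = pd.DataFrame({"cycle": np.arange(h), "age": self.start_age + np.arange(h)})
        for s in HealthState:
            df[f"occ_{s.name.lower()}"] = self.occupancy[:h, s]
        df["new_hz_episodes"] = self.new_hz_episodes
        df["new_phn_cases"] = self.new_phn_cases
        df["new_comp_cases"] = self.new_comp_cases
        for cat in COST_CATEGORIES:
            df[f"cost_{cat}"] = self.cost_streams[cat]
        df["qalys"] = self.qaly_stream
        return df


@dataclass(frozen=True)
class StrategyResult:
    """Lifetime per-1000 outcomes of one strategy (discounted cost/QALYs)."""

    strategy: Strategy
    start_age: int
    cases_per_1000: float
    phn_per_1000: float
    total_cost_per_1000: float
    total_qalys_per_1000: float


def _vaccine_efficacy(params: ParameterSet, strategy: Strategy, start_band_label: str,
                      curves, t: float) -> float:
    if strategy is Strategy.NONE:
        return 0.0
    if strategy is Strategy.ZVL:
        return efficacy_at(curves[("ZVL", start_band_label)], t)
    two = curves[("RZV", start_band_label)]
    one = scale_curve(two, params.model.rzv_one_dose_factor)
    return effective_rzv_efficacy(two, one, params.economics.compliance_two_dose, t)


def build_transition_matrix(
    params: ParameterSet, strategy: Strategy, start_age: int, cycle: int, curves=None
) -> np.ndarray:
    """Per-cycle transition matrix for one strategy at one cycle index.

    Rows sum to 1 exactly by construction; a defensive renormalization keeps
    them within 1e-12 against floating-point drift.
    """
    if not 0 <= cycle < params.economics.horizon:
        raise ValueError(f"cycle {cycle} outside [0, horizon)")
    if curves is None:
        curves = build_curves(params)
    age = start_age + cycle
    band = band_of(age)
    start_band = band_of(start_age)
    epi = params.epidemiology

    q = mortality_at(params, age)
    ve = _vaccine_efficacy(params, strategy, start_band.label, curves, cycle)
    inc = epi.hz_incidence[band.label] * (1.0 - ve)
    rec = epi.p_recurrence * (1.0 - ve)
    f = epi.hz_case_fatality[band.label]
    p_phn = epi.p_phn_given_hz[band.label]
    if strategy is not Strategy.NONE:
        mult = params.model.phn_breakthrough_multiplier.get(
            "ZVL" if strategy is Strategy.ZVL else "RZV", 1.0
        )
        p_phn = min(1.0, p_phn * mult)
    p_comp = epi.p_other_comp_given_hz[band.label]
    if p_phn + p_comp > 1.0:
        raise ZosterCeaError(
            f"AcuteHZ row at age {age}: conditional PHN+complication probability "
            f"{p_phn + p_comp:.4f} exceeds 1"
        )

    s = 1.0 - q  # survivors of all-cause mortality this cycle
    M = np.zeros((N_STATES, N_STATES))
    H, HZ, P, C, R, D = HealthState

    M[H, HZ] = s * inc
    M[H, H] = s * (1.0 - inc)
    M[H, D] = q

    surv_hz = s * (1.0 - f)
    M[HZ, P] = surv_hz * p_phn
    M[HZ, C] = surv_hz * p_comp
    M[HZ, R] = surv_hz * (1.0 - p_phn - p_comp)
    M[HZ, D] = q + s * f

    e_p = params.model.phn_exit_prob
    M[P, R] = s * e_p
    M[P, P] = s * (1.0 - e_p)
    M[P, D] = q

    e_c = params.model.comp_exit_prob
    M[C, R] = s * e_c
    M[C, C] = s * (1.0 - e_c)
    M[C, D] = q

    M[R, HZ] = s * rec
    M[R, R] = s * (1.0 - rec)
    M[R, D] = q

    M[D, D] = 1.0

    M /= M.sum(axis=1, keepdims=True)
    return M


def _doses(params: ParameterSet, strategy: Strategy) -> float:
    """Expected number of doses administered per person at cycle 0."""
    if strategy is Strategy.NONE:
        return 0.0
    if strategy is Strategy.ZVL:
        return 1.0
    c = params.economics.compliance_two_dose
    return 2.0 * c + 1.0 * (1.0 - c)


def _state_utilities(params: ParameterSet, age: int) -> np.ndarray:
    uh = params.utilities.u_healthy[band_of(age).label]
    u = np.array([
        uh,
        min(params.utilities.u_hz, uh),
        min(params.utilities.u_phn, uh),
        min(params.utilities.u_other_comp, uh),
        uh,
        0.0,
    ])
    return u


def run_cohort(params: ParameterSet, strategy: Strategy, start_age: int) -> CohortTrace:
    """Simulate a unit cohort from ``start_age`` over the configured horizon."""
    strategy = Strategy(strategy)
    if start_age < 50:
        raise ValueError("cohorts start at age 50 or older")
    h = params.economics.horizon
    curves = build_curves(params)

    occ = np.zeros((h + 1, N_STATES))
    occ[0, HealthState.HEALTHY] = 1.0
    new_hz = np.zeros(h)
    new_phn = np.zeros(h)
    new_comp = np.zeros(h)
    costs = {cat: np.zeros(h) for cat in COST_CATEGORIES}
    qalys = np.zeros(h)

    doses = _doses(params, strategy)
    price = {
        Strategy.NONE: 0.0,
        Strategy.ZVL: params.costs.price_zvl_dose,
        Strategy.RZV: params.costs.price_rzv_dose,
    }[strategy]
    costs["vaccine"][0] = doses * price
    costs["admin"][0] = doses * params.costs.cost_admin_dose
    if strategy is not Strategy.NONE:
        vac_key = "ZVL" if strategy is Strategy.ZVL else "RZV"
        costs["direct_medical"][0] += params.model.adverse_event_cost.get(vac_key, 0.0)

    H, HZ, P, C = (HealthState.HEALTHY, HealthState.ACUTE_HZ,
                   HealthState.PHN, HealthState.OTHER_COMP)
    R = HealthState.HZ_RESOLVED
    hcc = params.model.half_cycle_correction

    for t in range(h):
        M = build_transition_matrix(params, strategy, start_age, t, curves=curves)
        occ[t + 1] = occ[t] @ M
        new_hz[t] = occ[t, H] * M[H, HZ] + occ[t, R] * M[R, HZ]
        new_phn[t] = occ[t, HZ] * M[HZ, P]
        new_comp[t] = occ[t, HZ] * M[HZ, C]

        # state membership during cycle t (trapezoidal under half-cycle correction)
        state = 0.5 * (occ[t] + occ[t + 1]) if hcc else occ[t]
        costs["direct_medical"][t] += (
            state[HZ] * params.costs.cost_hz_episode
            + state[P] * params.costs.cost_phn
            + state[C] * params.costs.cost_other_comp
        )
        costs["nonmedical"][t] += state[HZ] * params.costs.cost_nonmedical
        costs["indirect"][t] += state[HZ] * params.costs.cost_indirect
        qalys[t] = float(state @ _state_utilities(params, start_age + t))

    if strategy is not Strategy.NONE:
        vac_key = "ZVL" if strategy is Strategy.ZVL else "RZV"
        qalys[0] -= params.model.adverse_event_disutility.get(vac_key, 0.0)

    return CohortTrace(
        strategy=strategy,
        start_age=start_age,
        occupancy=occ,
        new_hz_episodes=new_hz,
        new_phn_cases=new_phn,
        new_comp_cases=new_comp,
        cost_streams=costs,
        qaly_stream=qalys,
    )


def discounted_total(stream: np.ndarray, rate: float) -> float:
    """Present value of a per-cycle stream at an annual discount rate."""
    t = np.arange(len(stream))
    return float(np.sum(stream / (1.0 + rate) ** t))


def summarize(trace: CohortTrace, params: ParameterSet) -> StrategyResult:
    """Lifetime per-1000 totals: discounted costs/QALYs, undiscounted counts."""
    r = params.economics.discount_rate
    return StrategyResult(
        strategy=trace.strategy,
        start_age=trace.start_age,
        cases_per_1000=float(trace.new_hz_episodes.sum()) * 1000.0,
        phn_per_1000=float(trace.new_phn_cases.sum()) * 1000.0,
        total_cost_per_1000=discounted_total(trace.cost_stream, r) * 1000.0,
        total_qalys_per_1000=discounted_total(trace.qaly_stream, r) * 1000.0,
    )


def evaluate_strategy(params: ParameterSet, strategy: Strategy, start_age: int) -> StrategyResult:
    return summarize(run_cohort(params, strategy, start_age), params)


def evaluate_all(params: ParameterSet, start_age: int) -> dict[Strategy, StrategyResult]:
    """Run all three strategies from one starting age."""
    return {s: evaluate_strategy(params, s, start_age) for s in STRATEGY_ORDER}
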