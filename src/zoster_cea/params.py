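"""Model parameterization: types, loading, validation, serialization.

A :class:`ParameterSet` holds every input of one analysis run: age-banded
herpes zoster epidemiology, a single-year-of-age life table, costs (2023 USD,
societal perspective), health-state utilities, economic settings, vaccine
efficacy anchors, and the specifications used by the probabilistic (PSA) and
one-way (OWSA) sensitivity analyses.

Configs are YAML (JSON, being a YAML subset, is accepted too).  The packaged
default ``basecase.yaml`` carries the values printed in the source study's
main text; inputs the study keeps in its appendix ship as clearly labelled
literature-plausible placeholders that a user can overwrite.
"""

from __future__ import annotations

import copy
import csv
import importlib.resources
import math
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional

import yaml

from .bands import BAND_LABELS, canonical_label
from .errors import ConfigurationError, ParameterValidationError

VACCINES = ("RZV", "ZVL")

# ParameterSet fields holding monetary amounts; converted once at load when the
# config declares `currency: CNY`.
_COST_FIELDS = (
    "cost_hz_episode",
    "cost_phn",
    "cost_other_comp",
    "cost_nonmedical",
    "cost_indirect",
    "price_rzv_dose",
    "price_zvl_dose",
    "cost_admin_dose",
)


@dataclass
class EpidemiologyParams:
    """Annual probabilities describing herpes zoster natural history.

    ``hz_incidence``, ``p_phn_given_hz``, ``p_other_comp_given_hz`` and
    ``hz_case_fatality`` are keyed by attained-age band; ``all_cause_mortality``
    is a life table keyed by single year of age (held flat beyond its last
    entry).  ``p_recurrence`` is the annual probability that a person who has
    recovered from an episode develops a new one.
    """

    hz_incidence: dict[str, float]
    p_phn_given_hz: dict[str, float]
    p_other_comp_given_hz: dict[str, float]
    hz_case_fatality: dict[str, float]
    p_recurrence: float
    all_cause_mortality: dict[int, float]


@dataclass
class CostParams:
    """Per-event disease costs and per-dose vaccine prices (2023 USD).

    ``cost_hz_episode`` is the direct medical cost of one acute episode;
    ``cost_phn``/``cost_other_comp`` attach to each year spent in the
    corresponding state; ``cost_nonmedical`` and ``cost_indirect``
    (productivity loss) attach to the acute episode, completing the societal
    perspective.
    """

    cost_hz_episode: float
    cost_phn: float
    cost_other_comp: float
    cost_nonmedical: float
    cost_indirect: float
    price_rzv_dose: float = 453.55
    price_zvl_dose: float = 194.28
    cost_admin_dose: float = 4.24
    cny_per_usd: float = 7.0467


@dataclass
class UtilityParams:
    """Health-state utility weights on [0, 1]; death is 0 implicitly.

    Background utility is banded by attained age.  Disease-state utilities are
    applied as ``min(state utility, background utility at that age)`` so an
    acute episode never scores above the age norm.
    """

    u_healthy: dict[str, float]
    u_hz: float
    u_phn: float
    u_other_comp: float = 0.80


@dataclass
class EconomicSettings:
    discount_rate: float = 0.05
    horizon: int = 40
    wtp: float = 12681.0
    coverage: float = 0.30
    compliance_two_dose: float = 1.0


@dataclass
class ModelSettings:
    """Structural knobs of the cohort engine.

    ``phn_exit_prob`` / ``comp_exit_prob`` encode mean state dwell time as a
    per-cycle exit probability (1.0 = the state lasts one annual cycle).
    ``rzv_one_dose_factor`` scales the two-dose efficacy curve to describe
    recipients who never return for the second dose — an assumption, since
    no single-dose trial anchor is available; override it when modelling
    compliance scenarios if better data exist.  ``phn_breakthrough_multiplier``
    optionally rescales the PHN risk of breakthrough cases per vaccine, and the
    adverse-event hooks charge a one-off cost/disutility at vaccination
    (all default to neutral values).
    """

    phn_exit_prob: float = 1.0
    comp_exit_prob: float = 1.0
    half_cycle_correction: bool = False
    rzv_one_dose_factor: float = 0.9
    phn_breakthrough_multiplier: dict[str, float] = field(
        default_factory=lambda: {"RZV": 1.0, "ZVL": 1.0}
    )
    adverse_event_cost: dict[str, float] = field(
        default_factory=lambda: {"RZV": 0.0, "ZVL": 0.0}
    )
    adverse_event_disutility: dict[str, float] = field(
        default_factory=lambda: {"RZV": 0.0, "ZVL": 0.0}
    )


@dataclass
class ParameterSet:
    """Every input of one model run.

    ``efficacy_anchors`` maps vaccine -> band -> list of
    ``[years_since_vaccination, efficacy]`` pairs used to fit linear waning
    curves.  ``psa_spec`` maps a dotted parameter path to a distribution spec
    (see :mod:`zoster_cea.synthetic`); ``owsa_spec`` maps a dotted path to
    ``[low, high]`` bounds for the tornado analysis.
    """

    epidemiology: EpidemiologyParams
    costs: CostParams
    utilities: UtilityParams
    economics: EconomicSettings
    model: ModelSettings
    efficacy_anchors: dict[str, dict[str, list[list[float]]]]
    psa_spec: dict[str, dict] = field(default_factory=dict)
    owsa_spec: dict[str, list] = field(default_factory=dict)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


@dataclass(frozen=True)
class Violation:
    """One invariant violation: which field, the offending value, the rule."""

    field: str
    value: Any
    rule: str

    def __str__(self) -> str:
        return f"{self.field}={self.value!r} violates: {self.rule}"


# ---------------------------------------------------------------------------
# dotted-path access


def get_path(params: ParameterSet, path: str) -> Any:
    """Resolve a dotted path like ``costs.cost_phn`` or
    ``efficacy_anchors.ZVL.50-59.0.1`` (list segments are integer indices)."""
    obj: Any = params
    for seg in str(path).split("."):
        if is_dataclass(obj) and not isinstance(obj, type):
            if not hasattr(obj, seg):
                raise ConfigurationError(f"path {path!r}: no field {seg!r}")
            obj = getattr(obj, seg)
        elif isinstance(obj, Mapping):
            if seg in obj:
                obj = obj[seg]
            elif seg.lstrip("-").isdigit() and int(seg) in obj:
                obj = obj[int(seg)]
            else:
                raise ConfigurationError(f"path {path!r}: no key {seg!r}")
        elif isinstance(obj, (list, tuple)):
            try:
                obj = obj[int(seg)]
            except (ValueError, IndexError):
                raise ConfigurationError(f"path {path!r}: bad index {seg!r}") from None
        else:
            raise ConfigurationError(f"path {path!r}: cannot descend into {type(obj).__name__}")
    return obj


def set_path(params: ParameterSet, path: str, value: Any) -> None:
    """Set the scalar at a dotted path in place."""
    segs = str(path).split(".")
    parent = get_path(params, ".".join(segs[:-1])) if len(segs) > 1 else params
    leaf = segs[-1]
    if is_dataclass(parent) and not isinstance(parent, type):
        if not hasattr(parent, leaf):
            raise ConfigurationError(f"path {path!r}: no field {leaf!r}")
        setattr(parent, leaf, value)
    elif isinstance(parent, dict):
        if leaf in parent:
            parent[leaf] = value
        elif leaf.lstrip("-").isdigit() and int(leaf) in parent:
            parent[int(leaf)] = value
        else:
            raise ConfigurationError(f"path {path!r}: no key {leaf!r}")
    elif isinstance(parent, list):
        try:
            parent[int(leaf)] = value
        except (ValueError, IndexError):
            raise ConfigurationError(f"path {path!r}: bad index {leaf!r}") from None
    else:
        raise ConfigurationError(f"path {path!r}: cannot assign into {type(parent).__name__}")


# ---------------------------------------------------------------------------
# validation


def _check_prob(out: list, name: str, value: Any) -> None:
    if not isinstance(value, (int, float)) or math.isnan(value) or not 0.0 <= value <= 1.0:
        out.append(Violation(name, value, "must be a probability in [0, 1]"))


def _check_banded_probs(out: list, name: str, mapping: Any) -> None:
    if not isinstance(mapping, Mapping):
        out.append(Violation(name, mapping, "must be a mapping keyed by age band"))
        return
    for label in BAND_LABELS:
        if label not in mapping:
            out.append(Violation(f"{name}.{label}", None, "band missing"))
        else:
            _check_prob(out, f"{name}.{label}", mapping[label])


def validate(params: ParameterSet) -> list[Violation]:
    """Check every structural invariant; return violations instead of raising.

    An empty list means the set is internally consistent.  Validation never
    mutates its input and is idempotent.
    """
    v: list[Violation] = []
    epi, costs, util, econ, model = (
        params.epidemiology,
        params.costs,
        params.utilities,
        params.economics,
        params.model,
    )

    for name in ("hz_incidence", "p_phn_given_hz", "p_other_comp_given_hz", "hz_case_fatality"):
        _check_banded_probs(v, f"epidemiology.{name}", getattr(epi, name))
    _check_prob(v, "epidemiology.p_recurrence", epi.p_recurrence)

    if not isinstance(epi.all_cause_mortality, Mapping) or not epi.all_cause_mortality:
        v.append(Violation("epidemiology.all_cause_mortality", epi.all_cause_mortality,
                           "life table must be a non-empty mapping age -> probability"))
    else:
        if min(epi.all_cause_mortality) > 50:
            v.append(Violation("epidemiology.all_cause_mortality", min(epi.all_cause_mortality),
                               "life table must start at or below age 50"))
        for age, q in epi.all_cause_mortality.items():
            _check_prob(v, f"epidemiology.all_cause_mortality.{age}", q)

    # PHN and other-complication splits are conditional on an episode and must
    # leave non-negative mass for uncomplicated resolution.
    if isinstance(epi.p_phn_given_hz, Mapping) and isinstance(epi.p_other_comp_given_hz, Mapping):
        for label in BAND_LABELS:
            p = epi.p_phn_given_hz.get(label, 0)
            c = epi.p_other_comp_given_hz.get(label, 0)
            if isinstance(p, (int, float)) and isinstance(c, (int, float)) and p + c > 1.0:
                v.append(Violation(f"epidemiology.(p_phn+p_other_comp).{label}", p + c,
                                   "conditional splits of an episode must sum to <= 1"))

    for f_ in fields(CostParams):
        val = getattr(costs, f_.name)
        if not isinstance(val, (int, float)) or math.isnan(val) or val < 0:
            v.append(Violation(f"costs.{f_.name}", val, "must be a non-negative number"))

    _check_banded_probs(v, "utilities.u_healthy", util.u_healthy)
    for name in ("u_hz", "u_phn", "u_other_comp"):
        _check_prob(v, f"utilities.{name}", getattr(util, name))
    if isinstance(util.u_healthy, Mapping) and util.u_healthy:
        vals = [x for x in util.u_healthy.values() if isinstance(x, (int, float))]
        if vals and isinstance(util.u_hz, (int, float)) and isinstance(util.u_phn, (int, float)):
            if not (util.u_phn <= util.u_hz <= max(vals)):
                v.append(Violation("utilities", (util.u_phn, util.u_hz),
                                   "ordering u_phn <= u_hz <= max(u_healthy) required"))

    if not isinstance(econ.discount_rate, (int, float)) or econ.discount_rate < 0:
        v.append(Violation("economics.discount_rate", econ.discount_rate, "must be >= 0"))
    if not isinstance(econ.horizon, int) or econ.horizon < 1:
        v.append(Violation("economics.horizon", econ.horizon, "must be an integer >= 1"))
    if not isinstance(econ.wtp, (int, float)) or econ.wtp <= 0:
        v.append(Violation("economics.wtp", econ.wtp, "must be > 0"))
    _check_prob(v, "economics.coverage", econ.coverage)
    _check_prob(v, "economics.compliance_two_dose", econ.compliance_two_dose)

    _check_prob(v, "model.phn_exit_prob", model.phn_exit_prob)
    _check_prob(v, "model.comp_exit_prob", model.comp_exit_prob)
    if not isinstance(model.rzv_one_dose_factor, (int, float)) or not 0 <= model.rzv_one_dose_factor <= 1:
        v.append(Violation("model.rzv_one_dose_factor", model.rzv_one_dose_factor,
                           "must be in [0, 1]"))

    for vac in VACCINES:
        curves = params.efficacy_anchors.get(vac)
        if not isinstance(curves, Mapping):
            v.append(Violation(f"efficacy_anchors.{vac}", curves, "vaccine block missing"))
            continue
        for label in BAND_LABELS:
            anchors = curves.get(label)
            name = f"efficacy_anchors.{vac}.{label}"
            if not isinstance(anchors, (list, tuple)) or len(anchors) < 2:
                v.append(Violation(name, anchors, "at least 2 (years, efficacy) anchors required"))
                continue
            years = set()
            for pair in anchors:
                if not isinstance(pair, (list, tuple)) or len(pair) != 2:
                    v.append(Violation(name, pair, "anchor must be a [years, efficacy] pair"))
                    continue
                t, e = pair
                if not isinstance(t, (int, float)) or t < 0:
                    v.append(Violation(name, t, "anchor years must be >= 0"))
                else:
                    years.add(float(t))
                _check_prob(v, name, e)
            if len(years) < 2:
                v.append(Violation(name, anchors, "anchors need >= 2 distinct time points"))

    for spec_name in ("psa_spec", "owsa_spec"):
        for path in getattr(params, spec_name):
            try:
                val = get_path(params, path)
            except ConfigurationError:
                v.append(Violation(f"{spec_name}.{path}", None,
                                   "path does not resolve into the parameter set"))
                continue
            if not isinstance(val, (int, float)):
                v.append(Violation(f"{spec_name}.{path}", val, "path must point at a scalar"))
    for path, bounds in params.owsa_spec.items():
        if not (isinstance(bounds, (list, tuple)) and len(bounds) == 2 and bounds[0] <= bounds[1]):
            v.append(Violation(f"owsa_spec.{path}", bounds, "bounds must be [low, high] with low <= high"))

    return v


# ---------------------------------------------------------------------------
# (de)serialization


_SECTION_TYPES = {
    "epidemiology": EpidemiologyParams,
    "costs": CostParams,
    "utilities": UtilityParams,
    "economics": EconomicSettings,
    "model": ModelSettings,
}
_TOP_KEYS = set(_SECTION_TYPES) | {"efficacy_anchors", "psa_spec", "owsa_spec", "currency"}


def _canonical_band_dict(d: Mapping, where: str) -> dict:
    try:
        return {canonical_label(k): v for k, v in d.items()}
    except KeyError as e:
        raise ConfigurationError(f"{where}: {e.args[0]}") from None


def from_dict(raw: Mapping) -> ParameterSet:
    """Build a ParameterSet from a plain config mapping; unknown keys rejected."""
    if not isinstance(raw, Mapping):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown top-level config keys: {sorted(unknown)}")

    sections = {}
    for name, cls in _SECTION_TYPES.items():
        block = raw.get(name)
        if block is None:
            if name == "model":
                sections[name] = ModelSettings()
                continue
            raise ParameterValidationError([Violation(name, None, "required section missing")])
        if not isinstance(block, Mapping):
            raise ConfigurationError(f"section {name!r} must be a mapping")
        allowed = {f_.name for f_ in fields(cls)}
        bad = set(block) - allowed
        if bad:
            raise ConfigurationError(f"unknown keys in section {name!r}: {sorted(bad)}")
        missing = [
            f_.name for f_ in fields(cls)
            if f_.name not in block
            and f_.default is dataclass_missing and f_.default_factory is dataclass_missing  # type: ignore[misc]
        ]
        if missing:
            raise ParameterValidationError(
                [Violation(f"{name}.{m}", None, "required field missing") for m in missing]
            )
        kwargs = dict(block)
        # canonicalize band-keyed mappings
        for key, val in list(kwargs.items()):
            if key in ("all_cause_mortality",):
                kwargs[key] = {int(a): float(q) for a, q in val.items()}
            elif isinstance(val, Mapping) and any(str(k)[:1].isdigit() for k in val):
                kwargs[key] = _canonical_band_dict(val, f"{name}.{key}")
        sections[name] = cls(**kwargs)

    anchors_raw = raw.get("efficacy_anchors")
    if not isinstance(anchors_raw, Mapping):
        raise ParameterValidationError([Violation("efficacy_anchors", None, "required section missing")])
    anchors: dict[str, dict[str, list[list[float]]]] = {}
    for vac, curves in anchors_raw.items():
        if vac not in VACCINES:
            raise ConfigurationError(f"unknown vaccine {vac!r} in efficacy_anchors")
        anchors[vac] = {
            band: [[float(t), float(e)] for t, e in pairs]
            for band, pairs in _canonical_band_dict(curves, f"efficacy_anchors.{vac}").items()
        }

    return ParameterSet(
        epidemiology=sections["epidemiology"],
        costs=sections["costs"],
        utilities=sections["utilities"],
        economics=sections["economics"],
        model=sections["model"],
        efficacy_anchors=anchors,
        psa_spec=dict(raw.get("psa_spec") or {}),
        owsa_spec={k: list(b) for k, b in (raw.get("owsa_spec") or {}).items()},
    )


# sentinel used by from_dict for "no default"
from dataclasses import MISSING as dataclass_missing  # noqa: E402


def to_dict(params: ParameterSet) -> dict:
    """Plain-dict form of a ParameterSet, suitable for YAML round-tripping."""
    out: dict[str, Any] = {}
    for name, cls in _SECTION_TYPES.items():
        obj = getattr(params, name)
        out[name] = {f_.name: copy.deepcopy(getattr(obj, f_.name)) for f_ in fields(cls)}
    out["efficacy_anchors"] = copy.deepcopy(params.efficacy_anchors)
    out["psa_spec"] = copy.deepcopy(params.psa_spec)
    out["owsa_spec"] = copy.deepcopy(params.owsa_spec)
    return out


def save_parameters(params: ParameterSet, path) -> None:
    Path(path).write_text(yaml.safe_dump(to_dict(params), sort_keys=False), encoding="utf-8")


def _coerce_override(value):
    if isinstance(value, str):
        return yaml.safe_load(value)
    return value


def load_parameters(path=None, overrides: Optional[Mapping[str, Any]] = None) -> ParameterSet:
    """Load and validate a ParameterSet from YAML/JSON.

    ``path=None`` loads the packaged base case.  ``overrides`` is a flat
    mapping of dotted paths to values applied after the file, e.g.
    ``{"economics.discount_rate": 0}``; string values are YAML-parsed.
    Costs given in CNY (``currency: CNY``) are converted to USD once at load.
    Raises :class:`ParameterValidationError` on any invariant violation.
    """
    if path is None:
        text = (importlib.resources.files("zoster_cea") / "data" / "basecase.yaml").read_text(
            encoding="utf-8"
        )
    else:
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {p}")
        text = p.read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ConfigurationError(f"config does not parse as YAML/JSON: {e}") from e

    params = from_dict(raw)

    currency = str(raw.get("currency", "USD")).upper()
    if currency == "CNY":
        rate = params.costs.cny_per_usd
        for name in _COST_FIELDS:
            setattr(params.costs, name, getattr(params.costs, name) / rate)
        params.economics.wtp = params.economics.wtp / rate
    elif currency != "USD":
        raise ConfigurationError(f"unsupported currency {currency!r} (use USD or CNY)")

    for key, value in (overrides or {}).items():
        set_path(params, key, _coerce_override(value))

    violations = validate(params)
    if violations:
        raise ParameterValidationError(violations)
    return params


def default_parameters() -> ParameterSet:
    """The packaged base-case ParameterSet."""
    return load_parameters(None)


# ---------------------------------------------------------------------------
# CSV import helpers


def life_table_from_csv(path) -> dict[int, float]:
    """Read a life table CSV with header ``age,value`` into {age: probability}."""
    out: dict[int, float] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out[int(row["age"])] = float(row["value"])
    if not out:
        raise ConfigurationError(f"life table CSV {path} is empty")
    return out


def band_values_from_csv(path) -> dict[str, float]:
    """Read a per-band CSV with header ``band_label,value`` into {band: value}."""
    out: dict[str, float] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out[canonical_label(row["band_label"])] = float(row["value"])
    if not out:
        raise ConfigurationError(f"band CSV {path} is empty")
    return out


def mortality_at(params: ParameterSet, age: float) -> float:
    """Annual all-cause death probability at an attained age.

    The life table is held flat beyond its oldest entry and looked up at the
    integer part of the age.
    """
    table = params.epidemiology.all_cause_mortality
    a = int(age)
    if a in table:
        return table[a]
    lo, hi = min(table), max(table)
    return table[hi] if a > hi else table[lo]
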