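"""Synthetic parameter sets and probabilistic sensitivity (PSA) draws.

``make_synthetic_parameters`` produces random but structurally valid
:class:`~zoster_cea.params.ParameterSet` objects so every downstream stage can
be exercised without any external data: incidence and PHN risk rise with age,
costs are positive and right-skewed, utilities sit on [0, 1] with the
PHN <= acute-zoster <= background ordering intact.

``sample_psa_draw`` implements one Monte-Carlo parameter draw.  Distribution
families follow standard health-economics practice: beta for probabilities,
utilities and efficacy anchors; gamma (or lognormal) for costs; uniform
between one-way bounds when nothing better is known; ``point`` for fixed
values.  When a spec gives only a (low, high) range, hyperparameters come from
method of moments with the base value as the mean and ``(high - low) / 3.92``
as the standard error (the range read as a 95% interval).  Draws that break a
cross-parameter invariant are rejected and redrawn rather than clipped, so no
probability mass piles up on the bounds; the draw order is fixed by sorting
target paths, making a seeded PSA run bit-reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from .bands import BAND_LABELS
from .errors import ConfigurationError
from .params import ParameterSet, from_dict, get_path, set_path, validate

_MAX_TRIES = 1000

FAMILIES = ("beta", "gamma", "lognormal", "uniform", "point")


# ---------------------------------------------------------------------------
# distribution machinery


def _moments(spec: dict, base: float) -> tuple[float, float]:
    """(mean, sd) for a spec given as a range around the base value."""
    mean = float(spec.get("mean", base))
    if "sd" in spec:
        return mean, float(spec["sd"])
    low, high = float(spec["low"]), float(spec["high"])
    if low > high:
        raise ConfigurationError(f"low > high in distribution spec {spec}")
    return mean, (high - low) / (2.0 * 1.96)


def beta_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments beta(alpha, beta) hyperparameters."""
    if not 0.0 < mean < 1.0:
        raise ConfigurationError(f"beta mean {mean} must lie strictly inside (0, 1)")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ConfigurationError(
            f"beta variance {var:.4g} too large for mean {mean:.4g}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments gamma (shape, scale)."""
    if mean <= 0 or sd <= 0:
        raise ConfigurationError("gamma requires positive mean and sd")
    return (mean / sd) ** 2, sd * sd / mean


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments lognormal (mu, sigma) on the log scale."""
    if mean <= 0 or sd <= 0:
        raise ConfigurationError("lognormal requires positive mean and sd")
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def draw_one(spec: dict, base: float, rng: np.random.Generator) -> float:
    """One draw from a distribution spec targeted at a scalar with value ``base``."""
    family = spec.get("family", "point")
    if family not in FAMILIES:
        raise ConfigurationError(f"unknown distribution family {family!r}")
    if family == "point":
        return base
    if family == "uniform":
        low, high = float(spec["low"]), float(spec["high"])
        if low > high:
            raise ConfigurationError(f"uniform low > high in {spec}")
        return float(rng.uniform(low, high))
    if family == "beta":
        if not 0.0 <= base <= 1.0:
            raise ConfigurationError(
                f"beta distribution targeted at value {base} outside [0, 1]"
            )
        if "alpha" in spec and "beta" in spec:
            a, b = float(spec["alpha"]), float(spec["beta"])
        else:
            a, b = beta_params_from_moments(*_moments(spec, base))
        return float(rng.beta(a, b))
    if family == "gamma":
        if base < 0:
            raise ConfigurationError(f"gamma distribution targeted at negative value {base}")
        if "shape" in spec and "scale" in spec:
            k, theta = float(spec["shape"]), float(spec["scale"])
        else:
            k, theta = gamma_params_from_moments(*_moments(spec, base))
        return float(rng.gamma(k, theta))
    # lognormal
    if base < 0:
        raise ConfigurationError(f"lognormal distribution targeted at negative value {base}")
    if "mu" in spec and "sigma" in spec:
        mu, sigma = float(spec["mu"]), float(spec["sigma"])
    else:
        mu, sigma = lognormal_params_from_moments(*_moments(spec, base))
    return float(rng.lognormal(mu, sigma))


def sample_psa_draw(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One PSA parameter draw: a new ParameterSet with psa_spec targets replaced.

    Non-targeted fields are untouched.  The whole draw is rejected and redrawn
    if it violates any parameter-set invariant (at most 1000 attempts).
    """
    if not params.psa_spec:
        raise ConfigurationError("psa_spec is empty; nothing to draw")
    paths = sorted(params.psa_spec)
    bases = {p: float(get_path(params, p)) for p in paths}
    for _ in range(_MAX_TRIES):
        draw = params.copy()
        for path in paths:
            set_path(draw, path, draw_one(params.psa_spec[path], bases[path], rng))
        if not validate(draw):
            return draw
    raise ConfigurationError(
        "PSA rejection sampling failed to produce a valid draw after "
        f"{_MAX_TRIES} attempts; check psa_spec ranges against invariants"
    )


# ---------------------------------------------------------------------------
# synthetic parameter sets


def _rel_range(value: float, rel: float, cap: float | None = None) -> list[float]:
    lo, hi = value * (1 - rel), value * (1 + rel)
    if cap is not None:
        hi = min(hi, cap)
    return [lo, hi]


def make_synthetic_parameters(seed: int, difficulty: str = "realistic") -> ParameterSet:
    """A random, fully valid ParameterSet.

    ``difficulty='realistic'`` draws magnitudes bracketing the published
    anchors with substantial noise; ``'easy'`` stays close to round central
    values.  Age gradients (incidence, PHN risk, case fatality rising; background
    utility falling) are enforced by construction, and the same seed always
    yields the same set.
    """
    if difficulty not in ("easy", "realistic"):
        raise ValueError("difficulty must be 'easy' or 'realistic'")
    rng = np.random.default_rng(seed)
    noise = 0.05 if difficulty == "easy" else 0.20

    def jitter(x):
        return x * rng.lognormal(0.0, noise)

    inc = np.sort([jitter(x) for x in (0.006, 0.008, 0.010, 0.012)])
    p_phn = np.sort(np.clip([jitter(x) for x in (0.13, 0.18, 0.25, 0.33)], 0.01, 0.6))
    p_comp = np.clip([jitter(x) for x in (0.08, 0.10, 0.12, 0.14)], 0.01, 0.35)
    cfr = np.sort(np.clip([jitter(x) for x in (2e-4, 5e-4, 1.5e-3, 4e-3)], 1e-5, 0.05))

    gomp_b = 2.0e-5 * rng.lognormal(0.0, noise / 2)
    gomp_c = 0.10 * rng.lognormal(0.0, noise / 4)
    life = {a: round(min(0.7, gomp_b * math.exp(gomp_c * a)), 6) for a in range(50, 101)}

    u_healthy = np.clip(np.sort([jitter(x) for x in (0.91, 0.88, 0.84, 0.78)])[::-1], 0.5, 0.99)
    u_hz = float(np.clip(jitter(0.85), 0.70, u_healthy.max()))
    u_phn = float(np.clip(jitter(0.74), 0.40, u_hz))
    u_comp = float(np.clip(jitter(0.80), u_phn, u_hz))

    # right-skewed costs via lognormal jitter of plausible Chinese magnitudes
    costs = {
        "cost_hz_episode": jitter(385.0),
        "cost_phn": jitter(1650.0),
        "cost_other_comp": jitter(820.0),
        "cost_nonmedical": jitter(75.0),
        "cost_indirect": jitter(310.0),
    }

    rzv0 = np.clip([jitter(x) for x in (0.966, 0.974, 0.913, 0.913)], 0.6, 0.995)
    rzv10 = np.clip(rzv0 * rng.uniform(0.6, 0.9, size=4), 0.1, rzv0)
    zvl0 = np.clip([jitter(x) for x in (0.627, 0.644, 0.186, 0.186)], 0.05, 0.9)
    zvl_end = rng.uniform(0.0, 0.1, size=4) * zvl0

    def anchor_block(e0, e_end, t_end):
        return {
            label: [[0, round(float(e0[i]), 4)], [t_end, round(float(e_end[i]), 4)]]
            for i, label in enumerate(BAND_LABELS)
        }

    raw = {
        "epidemiology": {
            "hz_incidence": dict(zip(BAND_LABELS, map(float, inc))),
            "p_phn_given_hz": dict(zip(BAND_LABELS, map(float, p_phn))),
            "p_other_comp_given_hz": dict(zip(BAND_LABELS, map(float, p_comp))),
            "hz_case_fatality": dict(zip(BAND_LABELS, map(float, cfr))),
            "p_recurrence": float(np.clip(jitter(0.005), 1e-4, 0.05)),
            "all_cause_mortality": life,
        },
        "costs": {k: float(v) for k, v in costs.items()},
        "utilities": {
            "u_healthy": dict(zip(BAND_LABELS, map(float, u_healthy))),
            "u_hz": u_hz,
            "u_phn": u_phn,
            "u_other_comp": u_comp,
        },
        "economics": {
            "discount_rate": 0.05,
            "horizon": 40,
            "wtp": 12681.0,
            "coverage": 0.30,
            "compliance_two_dose": 1.0,
        },
        "model": {},
        "efficacy_anchors": {
            "RZV": anchor_block(rzv0, rzv10, 10),
            "ZVL": anchor_block(zvl0, zvl_end, 11),
        },
    }
    params = from_dict(raw)

    # PSA/OWSA specs mirroring the packaged defaults, re-centred on the drawn base
    psa: dict[str, dict] = {}
    owsa: dict[str, list] = {}
    for label in BAND_LABELS:
        path = f"epidemiology.hz_incidence.{label}"
        lo, hi = _rel_range(get_path(params, path), 0.25)
        psa[path] = {"family": "beta", "low": lo, "high": hi}
        owsa[path] = [lo, hi]
        phn_path = f"epidemiology.p_phn_given_hz.{label}"
        lo, hi = _rel_range(get_path(params, phn_path), 0.25, cap=0.95)
        psa[phn_path] = {"family": "beta", "low": lo, "high": hi}
    for name in costs:
        path = f"costs.{name}"
        lo, hi = _rel_range(get_path(params, path), 0.20)
        psa[path] = {"family": "gamma", "low": lo, "high": hi}
        owsa[path] = [lo, hi]
    psa["utilities.u_hz"] = {"family": "beta", **dict(zip(("low", "high"), _rel_range(u_hz, 0.05, cap=0.999)))}
    psa["utilities.u_phn"] = {"family": "beta", **dict(zip(("low", "high"), _rel_range(u_phn, 0.05, cap=0.999)))}
    for vac, t_end in (("RZV", 10), ("ZVL", 11)):
        for label in BAND_LABELS:
            path = f"efficacy_anchors.{vac}.{label}.0.1"
            lo, hi = _rel_range(get_path(params, path), 0.10, cap=0.999)
            psa[path] = {"family": "beta", "low": lo, "high": hi}
    owsa["economics.discount_rate"] = [0.0, 0.08]
    owsa["utilities.u_phn"] = _rel_range(u_phn, 0.05, cap=0.999)
    owsa["costs.price_rzv_dose"] = _rel_range(params.costs.price_rzv_dose, 0.20)
    owsa["costs.price_zvl_dose"] = _rel_range(params.costs.price_zvl_dose, 0.20)
    owsa["efficacy_anchors.RZV.60-69.0.1"] = _rel_range(float(rzv0[1]), 0.05, cap=0.999)
    owsa["efficacy_anchors.ZVL.60-69.0.1"] = _rel_range(float(zvl0[1]), 0.15, cap=0.999)
    params.psa_spec = psa
    params.owsa_spec = owsa

    violations = validate(params)
    if violations:  # pragma: no cover - generator is constructed to be valid
        raise AssertionError(f"synthetic generator produced invalid set: {violations}")
    return params
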