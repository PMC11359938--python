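"""Vaccine efficacy as linear waning in years since vaccination.

Protection against a herpes zoster episode is modelled, per vaccine and per
vaccination-age band, as an ordinary least-squares line through trial
follow-up anchors ``(years since vaccination, efficacy)``.  Evaluation clamps
to [0, 1]: beyond the fitted follow-up the line is extrapolated until it
reaches zero and held there (no rebound), the conservative floor when no
long-term datum exists.

The recombinant subunit vaccine (RZV) is a two-dose schedule.  Recipients who
never complete the second dose are assigned the two-dose curve scaled by a
configurable factor (``model.rzv_one_dose_factor``); cohort-level protection
is the compliance-weighted mixture of the two curves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bands import AgeBand, band_of
from .errors import FittingError

__all__ = [
    "EfficacyCurve",
    "fit_linear_waning",
    "efficacy_at",
    "effective_rzv_efficacy",
    "build_curves",
]


@dataclass(frozen=True)
class EfficacyCurve:
    """A fitted linear waning curve for one vaccine and vaccination-age band."""

    vaccine: str
    band: AgeBand
    intercept: float
    slope: float
    max_followup: float

    def __call__(self, years: float) -> float:
        return efficacy_at(self, years)


def fit_linear_waning(anchors, vaccine: str = "", band: AgeBand | None = None) -> EfficacyCurve:
    """Ordinary least-squares line through (years, efficacy) anchors.

    Requires at least two anchors at distinct non-negative times with efficacy
    on [0, 1].
    """
    pts = [(float(t), float(e)) for t, e in anchors]
    if len(pts) < 2:
        raise FittingError("need at least 2 efficacy anchors")
    t = np.array([p[0] for p in pts])
    e = np.array([p[1] for p in pts])
    if np.any(t < 0):
        raise FittingError("anchor years must be non-negative")
    if np.any((e < 0) | (e > 1)):
        raise FittingError("anchor efficacies must be in [0, 1]")
    if np.unique(t).size < 2:
        raise FittingError("anchors need >= 2 distinct time points")
    if len(pts) == 2:
        # exact two-point line; polyfit would add harmless but avoidable
        # floating-point noise at the endpoints
        slope = (e[1] - e[0]) / (t[1] - t[0])
        intercept = e[0] - slope * t[0]
    else:
        slope, intercept = np.polyfit(t, e, 1)
    return EfficacyCurve(
        vaccine=vaccine,
        band=band,
        intercept=float(intercept),
        slope=float(slope),
        max_followup=float(t.max()),
    )


def efficacy_at(curve: EfficacyCurve, years_since_vaccination: float) -> float:
    """Protective efficacy at a time since vaccination, clamped to [0, 1].

    The returned fraction multiplies ``(1 - VE)`` onto the unvaccinated
    incidence in the cohort engine.
    """
    if years_since_vaccination < 0:
        raise ValueError("years since vaccination must be >= 0")
    raw = curve.intercept + curve.slope * years_since_vaccination
    return float(min(1.0, max(0.0, raw)))


def effective_rzv_efficacy(
    curve_two_dose: EfficacyCurve,
    curve_one_dose: EfficacyCurve,
    compliance_two_dose: float,
    t: float,
) -> float:
    """Cohort-level RZV efficacy under partial two-dose compliance.

    A fraction ``compliance_two_dose`` of recipients completes both doses and
    follows the two-dose curve; the remainder follows the one-dose curve.
    """
    if not 0.0 <= compliance_two_dose <= 1.0:
        raise ValueError("compliance must be in [0, 1]")
    return compliance_two_dose * efficacy_at(curve_two_dose, t) + (
        1.0 - compliance_two_dose
    ) * efficacy_at(curve_one_dose, t)


def scale_curve(curve: EfficacyCurve, factor: float) -> EfficacyCurve:
    """Scale a curve's efficacy uniformly (used for the one-dose RZV assumption)."""
    return replace(curve, intercept=curve.intercept * factor, slope=curve.slope * factor)


def build_curves(params) -> dict[tuple[str, str], EfficacyCurve]:
    """Fit all (vaccine, band) curves declared in a ParameterSet's anchors."""
    curves: dict[tuple[str, str], EfficacyCurve] = {}
    for vaccine, by_band in params.efficacy_anchors.items():
        for label, anchors in by_band.items():
            band = band_of(int(label[:2]))
            curves[(vaccine, label)] = fit_linear_waning(anchors, vaccine=vaccine, band=band)
    return curves
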