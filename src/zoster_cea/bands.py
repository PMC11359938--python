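"""Age bands used throughout the model.

All herpes zoster epidemiology, utilities, and vaccine efficacy inputs are
stratified into four attained-age bands: 50-59, 60-69, 70-79, and 80+.
All-cause mortality is resolved by single year of age instead (see
:mod:`zoster_cea.params`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class AgeBand:
    """A half-open attained-age interval [lower_age, upper_age).

    The last band is open-ended (``upper_age is None``), covering everyone
    aged 80 and over.
    """

    label: str
    lower_age: int
    upper_age: Optional[int]

    def contains(self, age: float) -> bool:
        if age < self.lower_age:
            return False
        return self.upper_age is None or age < self.upper_age


BANDS: tuple[AgeBand, ...] = (
    AgeBand("50-59", 50, 60),
    AgeBand("60-69", 60, 70),
    AgeBand("70-79", 70, 80),
    AgeBand("80+", 80, None),
)

BAND_LABELS: tuple[str, ...] = tuple(b.label for b in BANDS)

# Unicode / alternate spellings accepted in config files.
_LABEL_ALIASES = {
    "50-59": "50-59",
    "50–59": "50-59",
    "60-69": "60-69",
    "60–69": "60-69",
    "70-79": "70-79",
    "70–79": "70-79",
    "80+": "80+",
    ">=80": "80+",
    "≥80": "80+",
}


def canonical_label(label: str) -> str:
    """Map an age-band spelling to its canonical form, e.g. '≥80' -> '80+'."""
    key = str(label).strip()
    try:
        return _LABEL_ALIASES[key]
    except KeyError:
        raise KeyError(f"unknown age band label: {label!r}") from None


def band_of(age: float) -> AgeBand:
    """Return the unique band containing an attained age.

    Ages of 80 and above all map to the open-ended last band.  The model is
    defined only for adults aged 50 or older, so younger ages are rejected.
    """
    if age < 50:
        raise ValueError(f"age {age} is below the modelled population (>= 50 years)")
    for band in BANDS:
        if band.contains(age):
            return band
    # unreachable: the last band is open-ended
    raise AssertionError("age bands failed to cover input")
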