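"""Concentration-time projection from a single animal species to humans.

Eight preset methods share one multiplicative form: predicted human
concentration at time t equals the animal concentration at t times

    (D_h / D_a)^dose_exponent x (W_a / W_h)^b(t)

where D are total doses in mg, W body weights in kg, and b(t) the volume
exponent, possibly switching from an early to a late value at a fixed day.
Time points are never rescaled: the animal's sampling times are carried
over to the predicted human profile unchanged.

Presets
-------
=======  ===========  =============  =========  ======
method   b (early)    b (late)       dose exp   switch
=======  ===========  =============  =========  ======
I        1.0          --             1.0        --
II       0.9          --             1.0        --
III      0.8          --             1.0        --
IV       1.0          --             0.85       --
V        0.9          --             0.85       --
VI       0.8          --             0.85       --
VII      1.0          0.8            1.0        day 14
VIII     0.9          0.8            1.0        day 14
=======  ===========  =============  =========  ======

The switch is inclusive: at t >= switch_time the late exponent applies.
Doses enter as total amounts; per-kg doses are converted via body weight
before the ratio is formed (the only convention under which equal mg/kg
doses with b = 1 leave the concentration unchanged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from .errors import DomainError, ValidationError
from .profiles_io import ConcProfile

__all__ = [
    "ScalingMethodSpec",
    "PredictedProfile",
    "METHOD_PRESETS",
    "METHOD_MNEMONICS",
    "get_method",
    "select_exponent",
    "scaling_factor",
    "predict_profile",
]


@dataclass(frozen=True)
class ScalingMethodSpec:
    """A named projection method with its exponents and optional switch."""

    method_id: str
    volume_exponent_early: float
    volume_exponent_late: Optional[float] = None
    dose_exponent: float = 1.0
    switch_time: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 < self.volume_exponent_early <= 1.5:
            raise ValidationError(
                f"volume_exponent_early must be in (0, 1.5], "
                f"got {self.volume_exponent_early}"
            )
        if (self.volume_exponent_late is None) != (self.switch_time is None):
            raise ValidationError(
                "volume_exponent_late and switch_time must be given together"
            )
        if self.volume_exponent_late is not None:
            if not 0 < self.volume_exponent_late <= 1.5:
                raise ValidationError(
                    f"volume_exponent_late must be in (0, 1.5], "
                    f"got {self.volume_exponent_late}"
                )
            if self.switch_time < 0:
                raise ValidationError(
                    f"switch_time must be >= 0, got {self.switch_time}"
                )


METHOD_PRESETS = {
    "I": ScalingMethodSpec("I", 1.0),
    "II": ScalingMethodSpec("II", 0.9),
    "III": ScalingMethodSpec("III", 0.8),
    "IV": ScalingMethodSpec("IV", 1.0, dose_exponent=0.85),
    "V": ScalingMethodSpec("V", 0.9, dose_exponent=0.85),
    "VI": ScalingMethodSpec("VI", 0.8, dose_exponent=0.85),
    "VII": ScalingMethodSpec("VII", 1.0, volume_exponent_late=0.8, switch_time=14.0),
    "VIII": ScalingMethodSpec("VIII", 0.9, volume_exponent_late=0.8, switch_time=14.0),
}

#: Alternative names accepted anywhere a method is selected.
METHOD_MNEMONICS = {
    "v1.0": "I",
    "v0.9": "II",
    "v0.8": "III",
    "cl0.85-v1.0": "IV",
    "cl0.85-v0.9": "V",
    "cl0.85-v0.8": "VI",
    "v1.0+0.8": "VII",
    "v0.9+0.8": "VIII",
}


def get_method(name: str) -> ScalingMethodSpec:
    """Resolve a preset by roman numeral (case-insensitive) or mnemonic."""
    key = name.strip()
    if key.upper() in METHOD_PRESETS:
        return METHOD_PRESETS[key.upper()]
    if key.lower() in METHOD_MNEMONICS:
        return METHOD_PRESETS[METHOD_MNEMONICS[key.lower()]]
    valid = ", ".join(list(METHOD_PRESETS) + list(METHOD_MNEMONICS))
    raise ValidationError(f"unknown method {name!r}; valid presets: {valid}")


@dataclass(frozen=True)
class PredictedProfile:
    """A projected human profile plus the provenance of the projection."""

    base: ConcProfile
    method: ScalingMethodSpec
    source_species: str


def select_exponent(method: ScalingMethodSpec, t: float) -> float:
    """Volume exponent in force at time ``t`` (days).

    Methods with a switch use the late exponent from ``switch_time``
    onwards (inclusive); all other methods are time-invariant.
    """
    if method.switch_time is not None and t >= method.switch_time:
        return method.volume_exponent_late
    return method.volume_exponent_early


def scaling_factor(
    method: ScalingMethodSpec,
    animal_dose_total: float,
    human_dose_total: float,
    animal_weight: float,
    human_weight: float,
    t: float = 0.0,
) -> float:
    """Multiplier taking an animal concentration at ``t`` to a human one.

    Evaluated in log space: exp(de*ln(D_h/D_a) + b(t)*ln(W_a/W_h)).
    """
    for name, value in (
        ("animal_dose_total", animal_dose_total),
        ("human_dose_total", human_dose_total),
        ("animal_weight", animal_weight),
        ("human_weight", human_weight),
    ):
        if not value > 0:
            raise DomainError(f"{name} must be > 0, got {value}")
    b = select_exponent(method, t)
    return math.exp(
        method.dose_exponent * math.log(human_dose_total / animal_dose_total)
        + b * math.log(animal_weight / human_weight)
    )


def predict_profile(
    animal: ConcProfile,
    human_dose_per_kg: float,
    method: ScalingMethodSpec,
    human_weight: float = 70.0,
) -> PredictedProfile:
    """Project an animal profile to a predicted human profile.

    Every point (t, C_a) maps to (t, C_a x factor(t)); the time grid is
    carried over unchanged and the point count is preserved.
    """
    if not human_dose_per_kg > 0:
        raise DomainError(f"human_dose_per_kg must be > 0, got {human_dose_per_kg}")
    if not human_weight > 0:
        raise DomainError(f"human_weight must be > 0, got {human_weight}")
    human_dose_total = human_dose_per_kg * human_weight
    concs = tuple(
        c
        * scaling_factor(
            method,
            animal.dose_total,
            human_dose_total,
            animal.body_weight,
            human_weight,
            t,
        )
        for t, c in animal.points
    )
    base = replace(
        animal,
        species_label="human-predicted",
        body_weight=human_weight,
        dose_per_kg=human_dose_per_kg,
        dose_total=human_dose_total,
        concentrations=concs,
        lloq=None,
    )
    return PredictedProfile(base=base, method=method, source_species=animal.species_label)
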