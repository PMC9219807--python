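"""Fixed-exponent single-species scaling of clearance and half-life.

Human clearance is predicted as CL_animal x (W_h/W_a)^0.85 and human
half-life as t1/2_animal x (W_h/W_a)^0.15, with 0.15 = 1 - 0.85.  Both
exponents are user-adjustable; clearance is always scaled in absolute
units (L/day), never per-kg.

Also provides the equivalent-time diagnostic
(W_h/W_a)^(v_exponent - cl_exponent): how many human days correspond to
one animal day if time were rescaled.  The prediction pipeline itself
never rescales time; the factor is informational only.  With exponents
CL = 0.79 and V = 1.0 it evaluates to 1.876 for monkey (3.5 kg) -> human
(70 kg) and 3.265 for rat (0.25 kg) -> human, commonly quoted rounded to
2 and 3 days (some sources print 1.85 and 3.25 for the unrounded values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

__all__ = [
    "PKScalingSpec",
    "predict_human_clearance",
    "predict_human_half_life",
    "equivalent_time_factor",
]


@dataclass(frozen=True)
class PKScalingSpec:
    """Exponents and target weight for fixed-exponent PK scaling.

    The defaults satisfy ``halflife_exponent == 1 - cl_exponent``; the
    half-life exponent is stored independently so it can be varied to
    probe the sensitivity of the half-life prediction.
    """

    cl_exponent: float = 0.85
    halflife_exponent: float = 0.15
    human_weight: float = 70.0


_DEFAULT = PKScalingSpec()


def _weight_ratio(animal_weight: float, spec: PKScalingSpec) -> float:
    if not animal_weight > 0:
        raise DomainError(f"animal_weight must be > 0, got {animal_weight}")
    if not spec.human_weight > 0:
        raise DomainError(f"human_weight must be > 0, got {spec.human_weight}")
    return spec.human_weight / animal_weight


def predict_human_clearance(
    cl_animal: float, animal_weight: float, spec: PKScalingSpec = _DEFAULT
) -> float:
    """Predicted human clearance, L/day: CL_a x (W_h/W_a)^cl_exponent."""
    if not cl_animal > 0:
        raise DomainError(f"cl_animal must be > 0, got {cl_animal}")
    ratio = _weight_ratio(animal_weight, spec)
    return cl_animal * math.exp(spec.cl_exponent * math.log(ratio))


def predict_human_half_life(
    thalf_animal: float, animal_weight: float, spec: PKScalingSpec = _DEFAULT
) -> float:
    """Predicted human half-life, days: t1/2_a x (W_h/W_a)^halflife_exponent."""
    if not thalf_animal > 0:
        raise DomainError(f"thalf_animal must be > 0, got {thalf_animal}")
    ratio = _weight_ratio(animal_weight, spec)
    return thalf_animal * math.exp(spec.halflife_exponent * math.log(ratio))


def equivalent_time_factor(
    animal_weight: float,
    human_weight: float = 70.0,
    cl_exponent: float = 0.79,
    v_exponent: float = 1.0,
) -> float:
    """Human days equivalent to one animal day: (W_h/W_a)^(e_V - e_CL).

    Diagnostic only -- no operation in this package rescales time.
    """
    if not animal_weight > 0:
        raise DomainError(f"animal_weight must be > 0, got {animal_weight}")
    if not human_weight > 0:
        raise DomainError(f"human_weight must be > 0, got {human_weight}")
    return math.exp((v_exponent - cl_exponent) * math.log(human_weight / animal_weight))
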