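"""Ground-truth generator: paired animal/human two-compartment profiles.

The animal is parameterised directly (CL, V1, Q, V2); the human is
derived by allometry with configurable exponents — clearances (CL and
the inter-compartmental flow Q) scale with weight^e_cl, volumes (V1 and
V2) with weight^e_v.  IV-bolus concentrations follow the bi-exponential
closed form C(t) = A exp(-alpha t) + B exp(-beta t); optional
multiplicative lognormal noise and LLOQ censoring make the output look
like reported mean data.

Because the human is constructed from the animal by exact power laws,
every projection method has a knowable truth: with e_cl == e_v == b and
no noise, the method with volume exponent b reproduces the human profile
identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import SimulationError, ValidationError
from .profiles_io import ConcProfile

__all__ = [
    "MacroConstants",
    "SimScenario",
    "DEFAULT_SAMPLING",
    "macro_constants",
    "concentrations",
    "simulate_pair",
    "load_scenario",
]

#: Default sampling design (days), typical of reported ADC mean profiles.
DEFAULT_SAMPLING = (0.25, 1.0, 3.0, 7.0, 10.0, 14.0, 21.0, 28.0, 35.0, 42.0)


@dataclass(frozen=True)
class MacroConstants:
    """Bi-exponential macro constants: C(t) = A e^(-alpha t) + B e^(-beta t)."""

    A: float  # ug/mL
    B: float  # ug/mL
    alpha: float  # 1/day, fast phase
    beta: float  # 1/day, slow (terminal) phase

    @property
    def c0(self) -> float:
        return self.A + self.B


def macro_constants(
    cl: float, v1: float, q: float, v2: float, dose_total: float
) -> MacroConstants:
    """Closed-form macro constants of the two-compartment IV-bolus model.

    With k10 = CL/V1, k12 = Q/V1, k21 = Q/V2, alpha and beta are the
    roots of s^2 - (k10+k12+k21) s + k10 k21, and
    A = C0 (alpha - k21)/(alpha - beta), B = C0 (k21 - beta)/(alpha - beta)
    with C0 = dose/V1.  ``q == 0`` degenerates to the mono-exponential
    limit (B = 0, alpha = k10, beta = 0) and is returned without error.
    """
    for name, value in (("cl", cl), ("v1", v1), ("v2", v2), ("dose_total", dose_total)):
        if not value > 0:
            raise ValidationError(f"{name} must be > 0, got {value}")
    if q < 0:
        raise ValidationError(f"q must be >= 0, got {q}")
    c0 = dose_total / v1
    k10 = cl / v1
    if q == 0:
        return MacroConstants(A=c0, B=0.0, alpha=k10, beta=0.0)
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = math.sqrt(s * s - 4.0 * k10 * k21)
    alpha = (s + disc) / 2.0
    beta = (s - disc) / 2.0
    a = c0 * (alpha - k21) / (alpha - beta)
    b = c0 * (k21 - beta) / (alpha - beta)
    return MacroConstants(A=a, B=b, alpha=alpha, beta=beta)


def concentrations(mc: MacroConstants, times: Sequence[float]) -> np.ndarray:
    """Evaluate the bi-exponential curve at the given times."""
    t = np.asarray(times, dtype=float)
    return mc.A * np.exp(-mc.alpha * t) + mc.B * np.exp(-mc.beta * t)


@dataclass(frozen=True)
class SimScenario:
    """Everything needed to simulate one animal/human profile pair."""

    ref_weight: float  # kg, animal
    cl_ref: float  # L/day
    v1_ref: float  # L
    q_ref: float  # L/day
    v2_ref: float  # L
    dose_animal_per_kg: float  # mg/kg
    dose_human_per_kg: float  # mg/kg
    target_weight: float = 70.0  # kg, human
    e_cl: float = 0.85  # exponent for CL and Q
    e_v: float = 0.9  # exponent for V1 and V2
    sampling_times: tuple = DEFAULT_SAMPLING
    noise_cv: float = 0.0
    lloq: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sampling_times", tuple(float(t) for t in self.sampling_times))
        for name in ("ref_weight", "target_weight", "cl_ref", "v1_ref", "v2_ref",
                     "dose_animal_per_kg", "dose_human_per_kg"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.q_ref < 0:
            raise ValidationError(f"q_ref must be >= 0, got {self.q_ref}")
        for name in ("e_cl", "e_v"):
            if not 0 < getattr(self, name) <= 1.5:
                raise ValidationError(
                    f"{name} must be in (0, 1.5], got {getattr(self, name)}"
                )
        if self.noise_cv < 0:
            raise ValidationError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.lloq is not None and not self.lloq > 0:
            raise ValidationError(f"lloq must be > 0, got {self.lloq}")
        times = self.sampling_times
        if len(times) == 0:
            raise ValidationError("sampling_times must be non-empty")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("sampling_times must be strictly increasing")


def _noisy_censored(
    clean: np.ndarray,
    times: Sequence[float],
    cv: float,
    lloq: Optional[float],
    rng: np.random.Generator,
    label: str,
) -> tuple:
    conc = clean.copy()
    if cv > 0:
        sigma = math.sqrt(math.log1p(cv * cv))
        conc = conc * np.exp(rng.normal(0.0, sigma, size=len(conc)))
    if lloq is not None:
        keep = conc >= lloq
    else:
        keep = np.ones(len(conc), dtype=bool)
    if not keep.any():
        raise SimulationError(f"all {label} points censored below LLOQ {lloq}")
    t = np.asarray(times, dtype=float)
    return tuple(t[keep]), tuple(conc[keep])


def simulate_pair(scenario: SimScenario) -> tuple:
    """Simulate matched animal and human profiles plus the ground truth.

    Returns ``(animal, human, truth)`` where ``truth`` maps parameter
    names ("cl_human", "v1_human", "thalf_terminal_human", ...) to their
    exact values before noise.  The same seed always yields identical
    profiles; animal noise is drawn before human noise from one stream.
    """
    r = scenario.target_weight / scenario.ref_weight
    f_cl = math.exp(scenario.e_cl * math.log(r))
    f_v = math.exp(scenario.e_v * math.log(r))
    cl_h = scenario.cl_ref * f_cl
    q_h = scenario.q_ref * f_cl
    v1_h = scenario.v1_ref * f_v
    v2_h = scenario.v2_ref * f_v

    dose_a = scenario.dose_animal_per_kg * scenario.ref_weight
    dose_h = scenario.dose_human_per_kg * scenario.target_weight

    mc_a = macro_constants(scenario.cl_ref, scenario.v1_ref, scenario.q_ref,
                           scenario.v2_ref, dose_a)
    mc_h = macro_constants(cl_h, v1_h, q_h, v2_h, dose_h)

    rng = np.random.default_rng(scenario.seed)
    times = scenario.sampling_times
    t_a, c_a = _noisy_censored(concentrations(mc_a, times), times,
                               scenario.noise_cv, scenario.lloq, rng, "animal")
    t_h, c_h = _noisy_censored(concentrations(mc_h, times), times,
                               scenario.noise_cv, scenario.lloq, rng, "human")

    animal = ConcProfile(
        species_label="animal",
        body_weight=scenario.ref_weight,
        times=t_a,
        concentrations=c_a,
        dose_per_kg=scenario.dose_animal_per_kg,
        analyte="total",
        lloq=scenario.lloq,
    )
    human = ConcProfile(
        species_label="human",
        body_weight=scenario.target_weight,
        times=t_h,
        concentrations=c_h,
        dose_per_kg=scenario.dose_human_per_kg,
        analyte="total",
        lloq=scenario.lloq,
    )

    def _thalf(mc: MacroConstants) -> float:
        rate = mc.beta if mc.beta > 0 else mc.alpha
        return math.log(2.0) / rate

    truth = {
        "weight_ratio": r,
        "cl_animal": scenario.cl_ref,
        "v1_animal": scenario.v1_ref,
        "q_animal": scenario.q_ref,
        "v2_animal": scenario.v2_ref,
        "vss_animal": scenario.v1_ref + scenario.v2_ref,
        "dose_animal_mg": dose_a,
        "alpha_animal": mc_a.alpha,
        "beta_animal": mc_a.beta,
        "thalf_terminal_animal": _thalf(mc_a),
        "cl_human": cl_h,
        "v1_human": v1_h,
        "q_human": q_h,
        "v2_human": v2_h,
        "vss_human": v1_h + v2_h,
        "dose_human_mg": dose_h,
        "alpha_human": mc_h.alpha,
        "beta_human": mc_h.beta,
        "thalf_terminal_human": _thalf(mc_h),
    }
    return animal, human, truth


def load_scenario(path) -> SimScenario:
    """Load a scenario from a flat key-value YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: scenario file must be a key-value mapping")
    valid = set(SimScenario.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValidationError(
            f"{path}: unknown scenario key(s): {', '.join(sorted(unknown))}"
        )
    return SimScenario(**raw)
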