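"""Concentration-time profile data model and lossless CSV I/O.

A :class:`ConcProfile` is the package's universal currency: one analyte's
mean concentration-time series in one species, together with the dose and
body-weight metadata every scaling operation needs.

Units are fixed throughout the package: time in days, concentration in
ug/mL (numerically identical to mg/L), body weight in kg, dose in mg
(per-kg doses in mg/kg), clearance in L/day.

The on-disk format is a UTF-8 CSV with a leading ``#key=value`` metadata
block followed by a ``time_days,conc_ug_ml`` header::

    #species=monkey
    #body_weight_kg=3.5
    #dose=1 mg/kg
    #analyte=total
    time_days,conc_ug_ml
    1,100
    7,50
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError

log = logging.getLogger(__name__)

ANALYTES = ("total", "conjugated", "unconjugated", "payload")

#: Fixed body weights (kg) used for the three species presets.
SPECIES_WEIGHTS = {"rat": 0.25, "monkey": 3.5, "human": 70.0}

_REL_TOL = 1e-9


@dataclass(frozen=True)
class SpeciesPreset:
    """A named species with its fixed default body weight in kg."""

    name: str
    default_weight: float


SPECIES_PRESETS = {
    name: SpeciesPreset(name, weight) for name, weight in SPECIES_WEIGHTS.items()
}


@dataclass
class ConcProfile:
    """One analyte's concentration-time series in one species.

    Parameters
    ----------
    species_label:
        Free-form species identifier ("monkey", "human-predicted", ...).
    body_weight:
        Body weight in kg, > 0.
    times:
        Strictly increasing sampling times in days, all >= 0.
    concentrations:
        Concentrations in ug/mL, all > 0 (below-LLOQ values must be
        excluded before construction, never stored as zero).
    dose_per_kg, dose_total:
        Dose in mg/kg and mg.  At least one must be given; the missing
        one is derived through ``body_weight``.  When both are given they
        must agree to 1e-9 relative.
    analyte:
        One of ``total``, ``conjugated``, ``unconjugated``, ``payload``.
    lloq:
        Optional lower limit of quantification in ug/mL.
    matrix:
        Free-text matrix tag (serum/plasma); carried without semantics.
    """

    species_label: str
    body_weight: float
    times: tuple
    concentrations: tuple
    dose_per_kg: Optional[float] = None
    dose_total: Optional[float] = None
    analyte: str = "total"
    lloq: Optional[float] = None
    matrix: Optional[str] = None

    def __post_init__(self) -> None:
        self.times = tuple(float(t) for t in self.times)
        self.concentrations = tuple(float(c) for c in self.concentrations)
        if len(self.times) != len(self.concentrations):
            raise ValidationError(
                f"times and concentrations differ in length "
                f"({len(self.times)} vs {len(self.concentrations)})"
            )
        if len(self.times) == 0:
            raise ValidationError("profile has no data points")
        if not (self.body_weight > 0) or not math.isfinite(self.body_weight):
            raise ValidationError(f"body_weight must be > 0, got {self.body_weight}")
        for i, t in enumerate(self.times):
            if t < 0 or not math.isfinite(t):
                raise ValidationError(f"time at row {i} must be >= 0, got {t}")
            if i > 0 and t <= self.times[i - 1]:
                raise ValidationError(
                    f"times must be strictly increasing; row {i} has "
                    f"t={t} after t={self.times[i - 1]}"
                )
        for i, c in enumerate(self.concentrations):
            if c <= 0 or not math.isfinite(c):
                raise ValidationError(
                    f"concentration at row {i} must be > 0, got {c}"
                )
        if self.analyte not in ANALYTES:
            raise ValidationError(
                f"analyte must be one of {ANALYTES}, got {self.analyte!r}"
            )
        if self.lloq is not None and not self.lloq > 0:
            raise ValidationError(f"lloq must be > 0, got {self.lloq}")

        if self.dose_per_kg is None and self.dose_total is None:
            raise ConfigurationError("a dose is required: dose_per_kg or dose_total")
        if self.dose_per_kg is not None and not self.dose_per_kg > 0:
            raise ValidationError(f"dose_per_kg must be > 0, got {self.dose_per_kg}")
        if self.dose_total is not None and not self.dose_total > 0:
            raise ValidationError(f"dose_total must be > 0, got {self.dose_total}")
        if self.dose_total is None:
            self.dose_total = self.dose_per_kg * self.body_weight
        elif self.dose_per_kg is None:
            self.dose_per_kg = self.dose_total / self.body_weight
        else:
            expected = self.dose_per_kg * self.body_weight
            if abs(self.dose_total - expected) > _REL_TOL * max(
                abs(self.dose_total), abs(expected)
            ):
                raise ValidationError(
                    f"dose_total {self.dose_total} mg inconsistent with "
                    f"dose_per_kg {self.dose_per_kg} mg/kg x "
                    f"body_weight {self.body_weight} kg = {expected} mg"
                )

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def points(self) -> list:
        """Ordered (time, concentration) pairs."""
        return list(zip(self.times, self.concentrations))

    def with_points(self, times: Sequence[float], concentrations: Sequence[float]) -> "ConcProfile":
        """Copy of this profile with a replaced data section."""
        return replace(self, times=tuple(times), concentrations=tuple(concentrations))


def _parse_dose(raw: str) -> tuple:
    """Parse a dose string with unit suffix -> (dose_per_kg, dose_total)."""
    s = raw.strip().lower()
    if s.endswith("mg/kg"):
        return float(s[: -len("mg/kg")].strip()), None
    if s.endswith("mg"):
        return None, float(s[: -len("mg")].strip())
    raise ConfigurationError(
        f"dose {raw!r} must carry a unit suffix: 'mg/kg' or 'mg'"
    )


def _parse_metadata(path: Path) -> dict:
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped.startswith("#"):
                break
            body = stripped.lstrip("#").strip()
            if "=" not in body:
                continue
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def read_profile(
    path, overrides: Optional[Mapping[str, str]] = None
) -> ConcProfile:
    """Read a profile CSV, validate it, and return a :class:`ConcProfile`.

    Metadata comes from the leading ``#key=value`` block; entries in
    ``overrides`` win over the file.  Recognised keys: ``species``,
    ``body_weight_kg``, ``dose`` (with ``mg/kg`` or ``mg`` suffix),
    ``analyte``, ``lloq_ug_ml``, ``matrix``.  When ``body_weight_kg`` is
    absent the species must be one of the presets (rat 0.25 kg,
    monkey 3.5 kg, human 70 kg).

    Rows with concentration strictly below the LLOQ are dropped; the
    dropped count is reported via logging.
    """
    path = Path(path)
    meta = _parse_metadata(path)
    if overrides:
        meta = {**meta, **{k: str(v) for k, v in overrides.items()}}

    if "species" not in meta:
        raise ConfigurationError(f"{path}: missing required metadata key 'species'")
    species = meta["species"]

    if "body_weight_kg" in meta:
        body_weight = float(meta["body_weight_kg"])
    elif species in SPECIES_WEIGHTS:
        body_weight = SPECIES_WEIGHTS[species]
    else:
        raise ConfigurationError(
            f"{path}: missing required metadata key 'body_weight_kg' "
            f"(species {species!r} is not a preset)"
        )

    if "dose" not in meta:
        raise ConfigurationError(f"{path}: missing required metadata key 'dose'")
    dose_per_kg, dose_total = _parse_dose(meta["dose"])
    if "dose_total_mg" in meta:
        dose_total = float(meta["dose_total_mg"])

    if "analyte" not in meta:
        raise ConfigurationError(f"{path}: missing required metadata key 'analyte'")

    lloq = float(meta["lloq_ug_ml"]) if "lloq_ug_ml" in meta else None

    try:
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty data section") from None
    for col in ("time_days", "conc_ug_ml"):
        if col not in frame.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if len(frame) == 0:
        raise ValidationError(f"{path}: empty data section")

    times = frame["time_days"].astype(float).tolist()
    concs = frame["conc_ug_ml"].astype(float).tolist()

    if lloq is not None:
        kept = [(t, c) for t, c in zip(times, concs) if c >= lloq]
        dropped = len(times) - len(kept)
        if dropped:
            log.info("%s: dropped %d row(s) below LLOQ %g ug/mL", path, dropped, lloq)
        if not kept:
            raise ValidationError(f"{path}: all rows below LLOQ {lloq} ug/mL")
        times = [t for t, _ in kept]
        concs = [c for _, c in kept]

    return ConcProfile(
        species_label=species,
        body_weight=body_weight,
        times=tuple(times),
        concentrations=tuple(concs),
        dose_per_kg=dose_per_kg,
        dose_total=dose_total,
        analyte=meta["analyte"],
        lloq=lloq,
        matrix=meta.get("matrix"),
    )


def write_profile(profile: ConcProfile, path) -> None:
    """Serialize a profile so that re-reading it reproduces every field.

    Floats are written with :func:`repr`, i.e. the shortest decimal string
    that round-trips exactly (always >= the required 10 significant
    digits of fidelity).  Both dose fields are populated on output.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"#species={profile.species_label}\n")
    buf.write(f"#body_weight_kg={profile.body_weight!r}\n")
    buf.write(f"#dose={profile.dose_per_kg!r} mg/kg\n")
    buf.write(f"#dose_total_mg={profile.dose_total!r}\n")
    buf.write(f"#analyte={profile.analyte}\n")
    if profile.lloq is not None:
        buf.write(f"#lloq_ug_ml={profile.lloq!r}\n")
    if profile.matrix is not None:
        buf.write(f"#matrix={profile.matrix}\n")
    buf.write("time_days,conc_ug_ml\n")
    for t, c in profile.points:
        buf.write(f"{t!r},{c!r}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
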