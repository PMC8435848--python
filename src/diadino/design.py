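"""Factorial experimental design and semi-continuous renewal arithmetic.

The experiment crosses three temperatures (12, 18, 24 degC) with three
nutrient-concentration levels (low / normal / high) and three N:P molar
supply ratios (10:1, 24:1, 63:1), in triplicate.  Nitrate and phosphate
concentrations for each cell of the design are fixed constants of the
medium recipe; silicate is supplied at the same concentration everywhere
so that it never limits the diatom.

Semi-continuous culturing replaces a fixed fraction of the culture volume
with fresh medium once per renewal interval ``t`` (1 d).  The daily renewal
fraction is tied to the target gross growth rate ``mu`` by

    D = 1 - exp(-mu * t)

so that a population growing at per-capita rate ``mu`` is exactly offset by
the daily dilution loss and the net growth rate ``r = mu - D`` is ~0 at
steady state.  ``mu`` itself is set to 20 % of the maximal growth rate
observed in batch culture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidArgumentError

TEMPERATURES_C: tuple[int, ...] = (12, 18, 24)
NUTRIENT_LEVELS: tuple[str, ...] = ("low", "normal", "high")
NP_LABELS: tuple[str, ...] = ("10:1", "24:1", "63:1")

#: Nitrate / phosphate concentrations (umol L^-1) per (level, N:P label),
#: stored exactly as printed in the medium recipe.
NITRATE_UMOL_L: dict[tuple[str, str], float] = {
    ("low", "10:1"): 35.2,
    ("low", "24:1"): 88.0,
    ("low", "63:1"): 88.0,
    ("normal", "10:1"): 352.0,
    ("normal", "24:1"): 880.0,
    ("normal", "63:1"): 880.0,
    ("high", "10:1"): 1760.0,
    ("high", "24:1"): 4400.0,
    ("high", "63:1"): 4400.0,
}

PHOSPHATE_UMOL_L: dict[tuple[str, str], float] = {
    ("low", "10:1"): 3.6,
    ("low", "24:1"): 3.6,
    ("low", "63:1"): 1.4,
    ("normal", "10:1"): 36.0,
    ("normal", "24:1"): 36.0,
    ("normal", "63:1"): 14.0,
    ("high", "10:1"): 180.0,
    ("high", "24:1"): 180.0,
    ("high", "63:1"): 70.0,
}

#: Silicate (umol L^-1), identical in all treatments.
SILICATE_UMOL_L: float = 880.0

#: Default culture volume (mL) and renewal interval (d).
CULTURE_VOLUME_ML: float = 200.0
RENEWAL_INTERVAL_D: float = 1.0

#: Gross growth rate in semi-continuous phase as a fraction of mu_max.
MU_FRACTION: float = 0.2


def np_label_value(np_label: str) -> float:
    """Numeric molar ratio for an N:P label such as ``"24:1"``."""
    try:
        num, den = np_label.split(":")
        return float(num) / float(den)
    except (ValueError, ZeroDivisionError) as exc:
        raise InvalidArgumentError(f"malformed N:P label {np_label!r}") from exc


@dataclass(frozen=True)
class Treatment:
    """One cell of the 3 x 3 x 3 factorial design."""

    id: str
    temperature: int
    nutrient_level: str
    np_label: str
    nitrate: float
    phosphate: float
    silicate: float = SILICATE_UMOL_L

    def __post_init__(self) -> None:
        if self.temperature not in TEMPERATURES_C:
            raise InvalidArgumentError(f"unknown temperature {self.temperature}")
        if self.nutrient_level not in NUTRIENT_LEVELS:
            raise InvalidArgumentError(f"unknown level {self.nutrient_level!r}")
        if self.np_label not in NP_LABELS:
            raise InvalidArgumentError(f"unknown N:P label {self.np_label!r}")
        if min(self.nitrate, self.phosphate, self.silicate) <= 0:
            raise InvalidArgumentError("concentrations must be positive")
        labeled = np_label_value(self.np_label)
        if abs(self.nitrate / self.phosphate / labeled - 1.0) >= 0.05:
            raise InvalidArgumentError(
                f"N:P = {self.nitrate / self.phosphate:.3f} deviates >5% "
                f"from label {self.np_label}"
            )

    @property
    def np_molar_ratio(self) -> float:
        return self.nitrate / self.phosphate


@dataclass(frozen=True)
class CultureSpec:
    """A single culture unit (flask) within a treatment."""

    treatment: Treatment
    culture_type: str  # mono_diatom | mono_dino | biculture
    replicate: int
    volume: float = CULTURE_VOLUME_ML
    renewal_interval_t: float = RENEWAL_INTERVAL_D

    def __post_init__(self) -> None:
        if self.culture_type not in ("mono_diatom", "mono_dino", "biculture"):
            raise InvalidArgumentError(f"unknown culture type {self.culture_type!r}")
        if self.replicate not in (1, 2, 3):
            raise InvalidArgumentError("replicate must be 1, 2 or 3")
        if self.volume <= 0 or self.renewal_interval_t <= 0:
            raise InvalidArgumentError("volume and renewal interval must be > 0")

    @property
    def culture_id(self) -> str:
        short = {"mono_diatom": "Md", "mono_dino": "Mo", "biculture": "Bi"}
        return f"{self.treatment.id}_{short[self.culture_type]}_{self.replicate}"


@dataclass(frozen=True)
class DilutionSchedule:
    """Daily renewal derived from the target gross growth rate."""

    mu_target: float
    renewal_interval_t: float = RENEWAL_INTERVAL_D
    volume: float = CULTURE_VOLUME_ML
    renewal_fraction_D: float = field(init=False)
    renewal_volume: float = field(init=False)

    def __post_init__(self) -> None:
        D = renewal_rate(self.mu_target, self.renewal_interval_t)
        object.__setattr__(self, "renewal_fraction_D", D)
        object.__setattr__(self, "renewal_volume", renewal_volume(D, self.volume))


def build_design() -> list[Treatment]:
    """Full factorial design: 27 treatments with the recipe concentrations.

    Deterministic; treatment ids are ``T{temp}_L{level}_R{ratio}`` and act
    as stable join keys across output tables.
    """
    out = []
    for temp in TEMPERATURES_C:
        for level in NUTRIENT_LEVELS:
            for label in NP_LABELS:
                out.append(
                    Treatment(
                        id=f"T{temp}_L{level}_R{label}",
                        temperature=temp,
                        nutrient_level=level,
                        np_label=label,
                        nitrate=NITRATE_UMOL_L[(level, label)],
                        phosphate=PHOSPHATE_UMOL_L[(level, label)],
                    )
                )
    return out


def design_frame(design: list[Treatment] | None = None) -> pd.DataFrame:
    """Design as a tidy table (schema of ``design.csv``)."""
    design = build_design() if design is None else design
    return pd.DataFrame(
        {
            "id": [t.id for t in design],
            "temperature_C": [t.temperature for t in design],
            "nutrient_level": [t.nutrient_level for t in design],
            "np_label": [t.np_label for t in design],
            "nitrate_umol_L": [t.nitrate for t in design],
            "phosphate_umol_L": [t.phosphate for t in design],
            "silicate_umol_L": [t.silicate for t in design],
        }
    )


def renewal_rate(mu: float, t: float = RENEWAL_INTERVAL_D) -> float:
    """Renewal fraction ``D = 1 - exp(-mu * t)`` per renewal interval.

    Parameters
    ----------
    mu : gross growth rate (d^-1), >= 0.
    t : renewal interval (d), > 0.
    """
    if mu < 0:
        raise InvalidArgumentError("mu must be >= 0")
    if t <= 0:
        raise InvalidArgumentError("t must be > 0")
    return 1.0 - math.exp(-mu * t)


def renewal_volume(D: float, volume: float = CULTURE_VOLUME_ML) -> float:
    """Volume of medium replaced per renewal: ``D * volume`` (mL)."""
    if not 0.0 <= D < 1.0:
        raise InvalidArgumentError("D must be in [0, 1)")
    if volume <= 0:
        raise InvalidArgumentError("volume must be > 0")
    return D * volume


def gross_growth_target(mu_max: float) -> float:
    """Target gross growth rate: 20 % of the batch maximal growth rate."""
    if mu_max < 0:
        raise InvalidArgumentError("mu_max must be >= 0")
    return MU_FRACTION * mu_max


def net_growth_rate(mu: float, D: float) -> float:
    """Net growth rate ``r = mu - D``; zero at steady state."""
    if mu < 0 or D < 0:
        raise InvalidArgumentError("mu and D must be >= 0")
    return mu - D
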