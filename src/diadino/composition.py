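"""Elemental stoichiometry and lipid biomarker indices.

Bulk chemical composition of a mixed diatom-dinoflagellate culture carries
a community signal: diatoms have a lower cellular N:P quota and are
enriched in 16:1n-7, EPA (20:5n-3) and brassicasterol/epi-brassicasterol,
whereas dinoflagellates are enriched in DHA (22:6n-3) and dinosterol.  The
indices computed here -- molar POC/PON and PON/POP, the fatty-acid ratios
16:1/16:0 and EPA/DHA, and the sterol fraction B/(B+D) -- therefore track
the relative contribution of the two groups to the particulate pool.

Undefined ratios (zero denominators) raise ``UndefinedRatioError``; the
batch helper ``compute_indices`` converts them to NaN so that a sample with
one missing index is retained rather than dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidArgumentError, UndefinedRatioError

#: Atomic weights (g mol^-1) used for mass <-> mole conversion.
ATOMIC_WEIGHT: dict[str, float] = {"C": 12.011, "N": 14.007, "P": 30.974}

#: Canonical names of the 22 fatty acids resolved by the GC method; the
#: first seven are the components that typically dominate total FAs.
FATTY_ACIDS: tuple[str, ...] = (
    "14:0",
    "16:0",
    "16:1n-7",
    "18:1n-9c",
    "18:2n-6c",
    "20:5n-3",
    "22:6n-3",
    "12:0",
    "15:0",
    "16:1n-9",
    "16:2n-4",
    "16:3n-4",
    "17:0",
    "18:0",
    "18:1n-7",
    "18:3n-3",
    "18:4n-3",
    "20:0",
    "20:4n-6",
    "22:0",
    "22:5n-3",
    "24:0",
)

EPA = "20:5n-3"
DHA = "22:6n-3"

_ALIASES = {"epa": EPA, "dha": DHA}


def canonical_fa(name: str) -> str:
    """Normalise a fatty-acid name to its canonical form."""
    key = name.strip().lower().replace(" ", "")
    if key in _ALIASES:
        return _ALIASES[key]
    for fa in FATTY_ACIDS:
        if key == fa.lower():
            return fa
    raise InvalidArgumentError(f"unknown fatty acid {name!r}")


@dataclass(frozen=True)
class ElementalSample:
    """Particulate organic C/N/P of one culture (umol per L of culture)."""

    poc: float
    pon: float
    pop: float
    filtered_volume: float = 20.0  # mL, metadata only
    culture_id: str = ""

    def __post_init__(self) -> None:
        if min(self.poc, self.pon, self.pop) < 0:
            raise InvalidArgumentError("elemental pools must be >= 0")
        if self.filtered_volume <= 0:
            raise InvalidArgumentError("filtered volume must be > 0")


@dataclass(frozen=True)
class LipidProfile:
    """Fatty-acid and sterol concentrations of one culture (ug L^-1)."""

    fa: dict[str, float]
    brassicasterol_epi: float
    dinosterol: float
    culture_id: str = ""

    def __post_init__(self) -> None:
        canon = {canonical_fa(k): float(v) for k, v in self.fa.items()}
        if any(v < 0 for v in canon.values()):
            raise InvalidArgumentError("FA concentrations must be >= 0")
        if self.brassicasterol_epi < 0 or self.dinosterol < 0:
            raise InvalidArgumentError("sterol concentrations must be >= 0")
        object.__setattr__(self, "fa", canon)

    def total_fa(self) -> float:
        return sum(self.fa.values())


@dataclass
class CompositionIndices:
    """Derived indices; NaN marks an undefined (flagged-missing) ratio."""

    poc_pon: float
    pon_pop: float
    r_16_1_16_0: float
    epa_dha: float
    b_over_bd: float
    carbon_normalized: dict[str, float] = field(default_factory=dict)


def to_molar(mass_ug: float, element: str) -> float:
    """Convert a mass in ug of C, N or P to umol."""
    if element not in ATOMIC_WEIGHT:
        raise InvalidArgumentError(f"unknown element {element!r}")
    if mass_ug < 0:
        raise InvalidArgumentError("mass must be >= 0")
    return mass_ug / ATOMIC_WEIGHT[element]


def elemental_ratios(sample: ElementalSample) -> tuple[float, float]:
    """Molar POC/PON and PON/POP of a sample."""
    if sample.pon <= 0:
        raise UndefinedRatioError("PON is zero; POC/PON undefined")
    poc_pon = sample.poc / sample.pon
    if sample.pop <= 0:
        raise UndefinedRatioError("POP is zero; PON/POP undefined")
    return poc_pon, sample.pon / sample.pop


def fa_indices(profile: LipidProfile) -> tuple[float, float]:
    """Diatom-indicator fatty-acid ratios 16:1n-7/16:0 and EPA/DHA."""
    p160 = profile.fa.get("16:0", 0.0)
    if p160 <= 0:
        raise UndefinedRatioError("16:0 is zero; 16:1/16:0 undefined")
    r1 = profile.fa.get("16:1n-7", 0.0) / p160
    dha = profile.fa.get(DHA, 0.0)
    if dha <= 0:
        raise UndefinedRatioError("DHA is zero; EPA/DHA undefined")
    return r1, profile.fa.get(EPA, 0.0) / dha


def sterol_index(brassicasterol_epi: float, dinosterol: float) -> float:
    """Sterol fraction B/(B+D), a proxy for the diatom share in [0, 1]."""
    if brassicasterol_epi < 0 or dinosterol < 0:
        raise InvalidArgumentError("sterol concentrations must be >= 0")
    total = brassicasterol_epi + dinosterol
    if total <= 0:
        raise UndefinedRatioError("both sterols zero; B/(B+D) undefined")
    return brassicasterol_epi / total


def major_components(profile: LipidProfile, threshold_pct: float = 5.0) -> set[str]:
    """Fatty acids whose share of total FAs strictly exceeds the threshold."""
    total = profile.total_fa()
    if total <= 0:
        raise InvalidArgumentError("empty fatty-acid profile")
    return {
        name for name, conc in profile.fa.items() if 100.0 * conc / total > threshold_pct
    }


def carbon_normalize(conc_ug_l: float, poc_umol_l: float) -> float:
    """Concentration per unit biomass carbon: ug (mg C)^-1."""
    if poc_umol_l <= 0:
        raise UndefinedRatioError("POC must be > 0 for carbon normalisation")
    if conc_ug_l < 0:
        raise InvalidArgumentError("concentration must be >= 0")
    mg_c_per_l = poc_umol_l * ATOMIC_WEIGHT["C"] * 1e-3
    return conc_ug_l / mg_c_per_l


def compute_indices(
    sample: ElementalSample, profile: LipidProfile
) -> CompositionIndices:
    """All indices for one sample; undefined ratios become NaN flags.

    ``carbon_normalized`` maps each lipid analyte (sterols and FAs) to
    ug (mg C)^-1 when POC is positive, else is empty.
    """
    nan = float("nan")
    try:
        poc_pon, pon_pop = elemental_ratios(sample)
    except UndefinedRatioError:
        poc_pon = sample.poc / sample.pon if sample.pon > 0 else nan
        pon_pop = nan
    try:
        r_16, epa_dha = fa_indices(profile)
    except UndefinedRatioError:
        p160 = profile.fa.get("16:0", 0.0)
        r_16 = profile.fa.get("16:1n-7", 0.0) / p160 if p160 > 0 else nan
        epa_dha = nan
    try:
        b_bd = sterol_index(profile.brassicasterol_epi, profile.dinosterol)
    except UndefinedRatioError:
        b_bd = nan
    cnorm: dict[str, float] = {}
    if sample.poc > 0:
        cnorm = {
            name: carbon_normalize(conc, sample.poc)
            for name, conc in profile.fa.items()
        }
        cnorm["brassicasterol_epi"] = carbon_normalize(
            profile.brassicasterol_epi, sample.poc
        )
        cnorm["dinosterol"] = carbon_normalize(profile.dinosterol, sample.poc)
    return CompositionIndices(
        poc_pon=poc_pon,
        pon_pop=pon_pop,
        r_16_1_16_0=r_16,
        epa_dha=epa_dha,
        b_over_bd=b_bd,
        carbon_normalized=cnorm,
    )
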