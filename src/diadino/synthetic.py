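"""Synthetic experiments with the statistical structure the analysis assumes.

The generator emulates the full factorial competition experiment: for every
treatment it simulates a diatom monoculture, a dinoflagellate monoculture
and a biculture, first in batch and then semi-continuously with a daily
renewal tied to 20 % of the diatom's batch growth rate, and finally samples
chemical composition at steady state.  Observation noise mimics
hemocytometer counting (Poisson counts over a fixed counting volume, with
optional multiplicative day-to-day process variation) and analytical
chemistry error (multiplicative lognormal per analyte).

All ground-truth constants live in this module (``default_ground_truth``):
growth rates and carrying capacities per temperature and nutrient level in
realistic culture ranges (mu_max ~ 0.25-1.05 d^-1, K ~ 16-280 x10^4 cells
mL^-1), an interaction surface alpha(T, nitrate) that is positive (dino
superiority) at low nutrient levels, negative (diatom superiority) at high
levels for 12/18 degC, and curves back to positive at 24 degC and the very
highest nitrate, with a response amplitude that shrinks as temperature
rises, and species chemical signatures that give diatoms the lower N:P
quota and the 16:1n-7 / EPA / brassicasterol enrichment.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import FATTY_ACIDS, ElementalSample, LipidProfile
from .design import Treatment, build_design, design_frame, gross_growth_target, renewal_rate
from .dynamics import (
    BATCH,
    DEFAULT_STEP,
    DETECTION_FLOOR,
    SEMICONTINUOUS,
    CommunityParams,
    Trajectory,
    advance,
    detect_steady_state,
)
from .errors import InvalidArgumentError
from .inference import estimate_mu_max

CULTURE_TYPES = ("mono_diatom", "mono_dino", "biculture")

#: First day with daily log-growth below this rate counts as early
#: stationary phase and triggers the switch to semi-continuous mode.
STATIONARY_LOG_GROWTH: float = 0.05

#: Default phase lengths (d).
BATCH_MAX_DAYS: int = 25
SEMICONTINUOUS_DAYS: int = 25

#: Inoculation densities (10^4 cells mL^-1).
N0_DIATOM: float = 0.5
N0_DINO: float = 0.5


# ---------------------------------------------------------------------------
# ground truth


@dataclass(frozen=True)
class SpeciesSignature:
    """Per-cell chemical signature of one species.

    Quotas in fmol cell^-1; lipids in ug per 10^6 cells.
    """

    c_quota: float
    n_quota: float
    p_quota: float
    fa: dict[str, float]
    brassicasterol_epi: float
    dinosterol: float


# invented, biologically plausible per-cell signatures ----------------------
# P. tricornutum is a small diatom (~0.7 pmol C per cell) with a low N:P
# quota; P. minimum is a much larger dinoflagellate with a high N:P quota.
_DIATOM_FA = {
    "14:0": 0.12, "16:0": 0.35, "16:1n-7": 0.60, "18:1n-9c": 0.08,
    "18:2n-6c": 0.06, "20:5n-3": 0.45, "22:6n-3": 0.05,
    "12:0": 0.01, "15:0": 0.01, "16:1n-9": 0.02, "16:2n-4": 0.03,
    "16:3n-4": 0.04, "17:0": 0.01, "18:0": 0.03, "18:1n-7": 0.02,
    "18:3n-3": 0.02, "18:4n-3": 0.02, "20:0": 0.01, "20:4n-6": 0.02,
    "22:0": 0.01, "22:5n-3": 0.01, "24:0": 0.01,
}
_DINO_FA = {
    "14:0": 0.50, "16:0": 1.60, "16:1n-7": 0.15, "18:1n-9c": 0.90,
    "18:2n-6c": 0.55, "20:5n-3": 0.50, "22:6n-3": 1.40,
    "12:0": 0.03, "15:0": 0.03, "16:1n-9": 0.04, "16:2n-4": 0.02,
    "16:3n-4": 0.02, "17:0": 0.03, "18:0": 0.25, "18:1n-7": 0.08,
    "18:3n-3": 0.06, "18:4n-3": 0.10, "20:0": 0.03, "20:4n-6": 0.06,
    "22:0": 0.03, "22:5n-3": 0.08, "24:0": 0.03,
}

DIATOM_SIGNATURE = SpeciesSignature(
    c_quota=700.0, n_quota=90.0, p_quota=8.0,
    fa=_DIATOM_FA, brassicasterol_epi=0.25, dinosterol=0.0,
)
DINO_SIGNATURE = SpeciesSignature(
    c_quota=2600.0, n_quota=330.0, p_quota=16.0,
    fa=_DINO_FA, brassicasterol_epi=0.0, dinosterol=1.00,
)

#: alpha(T, x) = a0 - a1 log10(x) + a2 max(0, log10(x) - c)^2, a2 > 0 only
#: at 24 degC (the warm-end upturn at very high nitrate).
_ALPHA_COEF: dict[int, tuple[float, float, float, float]] = {
    12: (3.12, 1.20, 0.0, 3.2),
    18: (2.08, 0.80, 0.0, 3.2),
    24: (1.30, 0.50, 3.5, 3.2),
}

_R_DIATOM_BASE = {12: 0.55, 18: 0.85, 24: 0.70}
_R_DINO_BASE = {12: 0.32, 18: 0.42, 24: 0.52}
_R_LEVEL_FACTOR = {"low": 0.85, "normal": 1.0, "high": 1.1}
_K_DIATOM = {"low": 45.0, "normal": 130.0, "high": 280.0}
_K_DINO = {"low": 16.0, "normal": 45.0, "high": 90.0}

#: multiplicative modifiers on the cellular N and P quotas: the N quota
#: rises with nutrient level (POC/PON falls as nutrients rise) and, at the
#: two lower levels only, tracks the supply N:P ratio; the P quota rises
#: faster still at high nutrients (luxury P uptake), so cellular N:P falls
#: as the nutrient level rises.
_N_LEVEL_FACTOR = {"low": 0.85, "normal": 1.0, "high": 1.1}
_N_SUPPLY_RATIO_FACTOR = {"10:1": 0.90, "24:1": 1.0, "63:1": 1.15}
_P_LEVEL_FACTOR = {"low": 0.80, "normal": 1.0, "high": 1.35}

#: temperature effect on the diatom EPA quota (EPA/DHA rises with T).
_EPA_TEMP_SLOPE = 0.03


@dataclass(frozen=True)
class GroundTruth:
    """All generator constants in one place; see module docstring."""

    diatom: SpeciesSignature = DIATOM_SIGNATURE
    dino: SpeciesSignature = DINO_SIGNATURE
    alpha_coef: dict[int, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(_ALPHA_COEF)
    )
    beta_base: float = 0.30
    beta_temp_slope: float = 0.01

    def alpha(self, temperature: int, nitrate: float) -> float:
        return alpha_surface(temperature, nitrate, self.alpha_coef)

    def beta(self, temperature: int, nitrate: float) -> float:
        return self.beta_base + self.beta_temp_slope * (temperature - 18.0)

    def params_for(self, treatment: Treatment) -> CommunityParams:
        t, lev = treatment.temperature, treatment.nutrient_level
        return CommunityParams(
            r_diatom=_R_DIATOM_BASE[t] * _R_LEVEL_FACTOR[lev],
            r_dino=_R_DINO_BASE[t] * _R_LEVEL_FACTOR[lev],
            K_diatom=_K_DIATOM[lev],
            K_dino=_K_DINO[lev],
            alpha=self.alpha(t, treatment.nitrate),
            beta=self.beta(t, treatment.nitrate),
        )

    def n_quota_modifier(self, treatment: Treatment) -> float:
        mod = _N_LEVEL_FACTOR[treatment.nutrient_level]
        if treatment.nutrient_level in ("low", "normal"):
            mod *= _N_SUPPLY_RATIO_FACTOR[treatment.np_label]
        return mod

    def p_quota_modifier(self, treatment: Treatment) -> float:
        return _P_LEVEL_FACTOR[treatment.nutrient_level]

    def epa_modifier(self, treatment: Treatment) -> float:
        return 1.0 + _EPA_TEMP_SLOPE * (treatment.temperature - 18.0)

    def to_jsonable(self) -> dict:
        return {
            "diatom": asdict(self.diatom),
            "dino": asdict(self.dino),
            "alpha_coef": {str(k): list(v) for k, v in self.alpha_coef.items()},
            "beta_base": self.beta_base,
            "beta_temp_slope": self.beta_temp_slope,
        }


def default_ground_truth() -> GroundTruth:
    """The study-condition ground truth used by all defaults."""
    return GroundTruth()


def alpha_surface(
    temperature: int,
    nitrate: float,
    coef: dict[int, tuple[float, float, float, float]] | None = None,
) -> float:
    """True interaction surface alpha(T, nitrate); see module docstring."""
    coef = _ALPHA_COEF if coef is None else coef
    if temperature not in coef:
        raise InvalidArgumentError(f"unknown temperature {temperature}")
    if nitrate <= 0:
        raise InvalidArgumentError("nitrate must be > 0")
    a0, a1, a2, c = coef[temperature]
    u = math.log10(nitrate)
    return a0 - a1 * u + a2 * max(0.0, u - c) ** 2


# ---------------------------------------------------------------------------
# noise


@dataclass(frozen=True)
class NoiseConfig:
    """Observation-noise settings.

    ``counting_volume``: hemocytometer volume counted per sample, in uL; a
    density of N x10^4 cells mL^-1 yields an expected count of
    ``10 N counting_volume`` cells.  ``process_cv``: multiplicative
    lognormal day-to-day variability of the sampled culture.
    ``chemistry_cv``: multiplicative lognormal analytical error per analyte.
    """

    counting_volume: float = 2.0
    process_cv: float = 0.05
    chemistry_cv: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.counting_volume <= 0:
            raise InvalidArgumentError("counting_volume must be > 0")
        if self.process_cv < 0 or self.chemistry_cv < 0:
            raise InvalidArgumentError("noise CVs must be >= 0")


def _lognormal_factor(cv: float, rng: np.random.Generator, size=None):
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_counts(true_density, cfg: NoiseConfig, rng: np.random.Generator):
    """Hemocytometer observation of a latent density (vectorised).

    Counted cells ~ Poisson(latent x counting volume); the observed density
    is count / volume.  Process noise perturbs the latent density first.
    """
    dens = np.asarray(true_density, dtype=float)
    if np.any(dens < 0):
        raise InvalidArgumentError("density must be >= 0")
    latent = dens * _lognormal_factor(cfg.process_cv, rng, size=dens.shape or None)
    cells_per_count = 10.0 * cfg.counting_volume  # cells per (10^4 mL^-1) unit
    counts = rng.poisson(latent * cells_per_count)
    return counts / cells_per_count


def generate_composition(
    n_diatom: float,
    n_dino: float,
    treatment: Treatment,
    truth: GroundTruth,
    rng: np.random.Generator,
    chemistry_cv: float = 0.0,
) -> tuple[ElementalSample, LipidProfile]:
    """Bulk composition of a mixture of the two species.

    Pools are sums of density x per-cell signature x treatment modifier;
    each analyte then receives independent multiplicative lognormal error.
    A density of N x10^4 cells mL^-1 equals 10 N x10^6 cells L^-1, and a
    quota of q fmol cell^-1 contributes 0.01 N q umol L^-1.
    """
    if n_diatom < 0 or n_dino < 0:
        raise InvalidArgumentError("densities must be >= 0")
    if n_diatom == 0 and n_dino == 0:
        raise InvalidArgumentError("at least one species must be present")
    nmod = truth.n_quota_modifier(treatment)
    pmod = truth.p_quota_modifier(treatment)
    emod = truth.epa_modifier(treatment)
    d, o = truth.diatom, truth.dino

    def noisy(v: float) -> float:
        return float(v * _lognormal_factor(chemistry_cv, rng))

    poc = 1e-2 * (n_diatom * d.c_quota + n_dino * o.c_quota)
    pon = 1e-2 * (n_diatom * d.n_quota + n_dino * o.n_quota) * nmod
    pop = 1e-2 * (n_diatom * d.p_quota + n_dino * o.p_quota) * pmod
    cells_diatom = 10.0 * n_diatom  # 10^6 cells L^-1
    cells_dino = 10.0 * n_dino
    fa = {}
    for name in FATTY_ACIDS:
        per_d = d.fa.get(name, 0.0) * (emod if name == "20:5n-3" else 1.0)
        fa[name] = noisy(cells_diatom * per_d + cells_dino * o.fa.get(name, 0.0))
    brass = noisy(
        cells_diatom * d.brassicasterol_epi + cells_dino * o.brassicasterol_epi
    )
    dino_sterol = noisy(cells_diatom * d.dinosterol + cells_dino * o.dinosterol)
    filtered = float(rng.uniform(15.0, 30.0))
    sample = ElementalSample(
        poc=noisy(poc), pon=noisy(pon), pop=noisy(pop), filtered_volume=filtered
    )
    profile = LipidProfile(
        fa=fa, brassicasterol_epi=brass, dinosterol=dino_sterol
    )
    return sample, profile


# ---------------------------------------------------------------------------
# latent experiment (noise-free dynamics, shared by all replicates)


@dataclass
class LatentUnit:
    """Noise-free trajectory and protocol constants of one culture."""

    treatment: Treatment
    culture_type: str
    trajectory: Trajectory
    mu_max: float
    mu: float
    D: float
    switch_day: int
    steady_day: int
    washout: bool


@dataclass
class LatentExperiment:
    design: list[Treatment]
    units: dict[tuple[str, str], LatentUnit]  # key: (treatment id, type)
    step: float


def simulate_latent(
    truth: GroundTruth,
    design: list[Treatment] | None = None,
    batch_max_days: int = BATCH_MAX_DAYS,
    semicontinuous_days: int = SEMICONTINUOUS_DAYS,
    step: float = DEFAULT_STEP,
) -> LatentExperiment:
    """Deterministic latent dynamics for every treatment and culture type.

    All cultures are integrated in one vectorised sweep.  The batch phase
    runs until the diatom (or, in the dinoflagellate monoculture, the dino)
    reaches early stationary phase; mu_max is then estimated from the
    latent batch curve, the renewal fraction is set to
    ``D = 1 - exp(-0.2 mu_max)`` -- using the diatom's mu_max in bicultures
    -- and the semi-continuous phase runs for ``semicontinuous_days``.
    """
    design = build_design() if design is None else design
    n_tr = len(design)
    types = list(CULTURE_TYPES)
    m = n_tr * len(types)
    r1 = np.empty(m)
    r2 = np.empty(m)
    K1 = np.empty(m)
    K2 = np.empty(m)
    al = np.empty(m)
    be = np.empty(m)
    n1 = np.empty(m)
    n2 = np.empty(m)
    meta = []
    for i, tr in enumerate(design):
        p = truth.params_for(tr)
        for j, ct in enumerate(types):
            k = i * len(types) + j
            r1[k], r2[k] = p.r_diatom, p.r_dino
            K1[k], K2[k] = p.K_diatom, p.K_dino
            al[k], be[k] = p.alpha, p.beta
            n1[k] = 0.0 if ct == "mono_dino" else N0_DIATOM
            n2[k] = 0.0 if ct == "mono_diatom" else N0_DINO
            meta.append((tr, ct))

    # batch phase: daily snapshots for all cultures at once
    batch = np.empty((batch_max_days + 1, m, 2))
    batch[0, :, 0] = n1
    batch[0, :, 1] = n2
    c1, c2 = n1.copy(), n2.copy()
    for d in range(1, batch_max_days + 1):
        c1, c2 = advance(c1, c2, r1, r2, K1, K2, al, be, duration=1.0, step=step)
        batch[d, :, 0] = c1
        batch[d, :, 1] = c2

    # per-culture switch day: first day the trigger species' daily
    # log-growth falls below the stationary threshold
    trigger = np.array([0 if ct != "mono_dino" else 1 for _, ct in meta])
    dens = batch[:, np.arange(m), trigger]
    with np.errstate(divide="ignore", invalid="ignore"):
        lg = np.diff(np.log(np.maximum(dens, 1e-300)), axis=0)
    switch = np.full(m, batch_max_days, dtype=int)
    for k in range(m):
        hit = np.nonzero(lg[:, k] < STATIONARY_LOG_GROWTH)[0]
        if len(hit):
            switch[k] = hit[0] + 1

    # mu_max from the latent batch curve, per culture
    mu_max = np.empty(m)
    for k, (tr, ct) in enumerate(meta):
        df = pd.DataFrame(
            {
                "day": np.arange(switch[k] + 1, dtype=float),
                "n_diatom": batch[: switch[k] + 1, k, 0],
                "n_dino": batch[: switch[k] + 1, k, 1],
                "phase": BATCH,
                "post_dilution": False,
            }
        )
        species = "dino" if ct == "mono_dino" else "diatom"
        try:
            mu_max[k] = estimate_mu_max(Trajectory(df), species=species).mu_max
        except Exception:
            mu_max[k] = float("nan")
    mu = np.array([gross_growth_target(v) if np.isfinite(v) else np.nan for v in mu_max])
    D = np.array([renewal_rate(v) if np.isfinite(v) else 0.0 for v in mu])

    # semi-continuous phase, vectorised with per-culture D
    sc_pre = np.empty((semicontinuous_days, m, 2))
    sc_post = np.empty((semicontinuous_days, m, 2))
    s1 = batch[switch, np.arange(m), 0].copy()
    s2 = batch[switch, np.arange(m), 1].copy()
    start1, start2 = s1.copy(), s2.copy()
    for d in range(semicontinuous_days):
        s1, s2 = advance(s1, s2, r1, r2, K1, K2, al, be, duration=1.0, step=step)
        sc_pre[d, :, 0] = s1
        sc_pre[d, :, 1] = s2
        s1 = s1 * (1.0 - D)
        s2 = s2 * (1.0 - D)
        sc_post[d, :, 0] = s1
        sc_post[d, :, 1] = s2

    units: dict[tuple[str, str], LatentUnit] = {}
    for k, (tr, ct) in enumerate(meta):
        sw = int(switch[k])
        rows = []
        for d in range(sw + 1):
            rows.append((float(d), BATCH, False, batch[d, k, 0], batch[d, k, 1]))
        rows.append((float(sw), SEMICONTINUOUS, True, start1[k], start2[k]))
        for d in range(semicontinuous_days):
            day = float(sw + d + 1)
            rows.append((day, SEMICONTINUOUS, False, sc_pre[d, k, 0], sc_pre[d, k, 1]))
            rows.append((day, SEMICONTINUOUS, True, sc_post[d, k, 0], sc_post[d, k, 1]))
        traj = Trajectory(
            pd.DataFrame(
                rows,
                columns=["day", "phase", "post_dilution", "n_diatom", "n_dino"],
            ),
            D=float(D[k]),
        )
        steady = detect_steady_state(traj, window=5, cv_tol=0.05)
        last_day = sw + semicontinuous_days
        present = (n1[k] > 0 and sc_post[-1, k, 0] > DETECTION_FLOOR) or (
            n2[k] > 0 and sc_post[-1, k, 1] > DETECTION_FLOOR
        )
        units[(tr.id, ct)] = LatentUnit(
            treatment=tr,
            culture_type=ct,
            trajectory=traj,
            mu_max=float(mu_max[k]),
            mu=float(mu[k]),
            D=float(D[k]),
            switch_day=sw,
            steady_day=int(steady) if steady is not None else last_day,
            washout=not present,
        )
    return LatentExperiment(design=design, units=units, step=step)


# ---------------------------------------------------------------------------
# observed experiment


@dataclass
class SyntheticExperiment:
    """A complete observed experiment: trajectories per culture unit plus a
    steady-state composition table and the generating ground truth."""

    design: list[Treatment]
    units: pd.DataFrame  # culture_id, treatment_id, culture_type, replicate,
    #                      mu_max, mu, D, switch_day, steady_day, washout
    trajectories: dict[str, Trajectory]
    composition: pd.DataFrame
    truth: GroundTruth
    noise: NoiseConfig
    seed: int
    replicates: int = 3

    @property
    def manifest(self) -> dict:
        cfg = asdict(self.noise)
        payload = json.dumps(
            {"noise": cfg, "seed": self.seed, "replicates": self.replicates},
            sort_keys=True,
        )
        return {
            "seed": self.seed,
            "replicates": self.replicates,
            "noise": cfg,
            "config_hash": hashlib.sha256(payload.encode()).hexdigest(),
            "version": 1,
        }


def _unit_rng(seed: int, t_idx: int, ct_idx: int, rep: int) -> np.random.Generator:
    """Deterministic hierarchical stream per (treatment, culture, replicate)."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(t_idx, ct_idx, rep))
    return np.random.default_rng(ss)


def observe(
    latent: LatentExperiment,
    truth: GroundTruth,
    cfg: NoiseConfig,
    seed: int,
    replicates: int = 3,
    noiseless: bool = False,
) -> SyntheticExperiment:
    """Apply the observation model to a latent experiment.

    Each replicate of each culture gets its own RNG stream; daily counts
    perturb the pre-dilution densities (post-dilution densities follow
    volumetrically), and the steady-state composition sample receives
    analytical noise.  ``noiseless`` bypasses every noise source while
    keeping the data layout identical.
    """
    short = {"mono_diatom": "Md", "mono_dino": "Mo", "biculture": "Bi"}
    unit_rows = []
    trajectories: dict[str, Trajectory] = {}
    comp_rows = []
    for t_idx, tr in enumerate(latent.design):
        for ct_idx, ct in enumerate(CULTURE_TYPES):
            lu = latent.units[(tr.id, ct)]
            ldf = lu.trajectory.df
            for rep in (1, 2, 3)[:replicates]:
                rng = _unit_rng(seed, t_idx, ct_idx, rep)
                cid = f"{tr.id}_{short[ct]}_{rep}"
                df = ldf.copy()
                if not noiseless:
                    day = df["day"].to_numpy()
                    post = df["post_dilution"].to_numpy()
                    n1 = df["n_diatom"].to_numpy(dtype=float).copy()
                    n2 = df["n_dino"].to_numpy(dtype=float).copy()
                    obs_ix = np.nonzero(~post)[0]  # what the counter sees
                    if ct != "mono_dino":
                        n1[obs_ix] = generate_counts(n1[obs_ix], cfg, rng)
                    if ct != "mono_diatom":
                        n2[obs_ix] = generate_counts(n2[obs_ix], cfg, rng)
                    # post-dilution densities follow volumetrically from the
                    # daily count: the same water is diluted by 1 - D
                    by_day = {day[i]: i for i in obs_ix}
                    for i in np.nonzero(post)[0]:
                        j = by_day.get(day[i])
                        if j is not None:
                            # the phase-entry record (day == switch) is the
                            # undiluted batch state; later post records are
                            # the daily count after renewal
                            f = 1.0 if day[i] == lu.switch_day else 1.0 - lu.D
                            n1[i] = n1[j] * f
                            n2[i] = n2[j] * f
                    df["n_diatom"] = n1
                    df["n_dino"] = n2
                trajectories[cid] = Trajectory(df, D=lu.D)
                unit_rows.append(
                    {
                        "culture_id": cid,
                        "treatment_id": tr.id,
                        "culture_type": ct,
                        "replicate": rep,
                        "mu_max": lu.mu_max,
                        "mu": lu.mu,
                        "D": lu.D,
                        "switch_day": lu.switch_day,
                        "steady_day": lu.steady_day,
                        "washout": lu.washout,
                    }
                )
                # steady-state composition sample from the latent densities
                lrow = ldf[
                    (ldf["day"] == lu.steady_day)
                    & (ldf["phase"] == SEMICONTINUOUS)
                    & (~ldf["post_dilution"])
                ]
                if len(lrow) == 0:
                    continue
                lat1 = float(lrow["n_diatom"].iloc[0])
                lat2 = float(lrow["n_dino"].iloc[0])
                if lat1 <= 0 and lat2 <= 0:
                    continue
                ccv = 0.0 if noiseless else cfg.chemistry_cv
                sample, profile = generate_composition(
                    lat1, lat2, tr, truth, rng, chemistry_cv=ccv
                )
                orow = trajectories[cid].df
                orow = orow[
                    (orow["day"] == lu.steady_day)
                    & (orow["phase"] == SEMICONTINUOUS)
                    & (~orow["post_dilution"])
                ]
                rec = {
                    "culture_id": cid,
                    "treatment_id": tr.id,
                    "culture_type": ct,
                    "replicate": rep,
                    "day": lu.steady_day,
                    "n_diatom_obs": float(orow["n_diatom"].iloc[0]),
                    "n_dino_obs": float(orow["n_dino"].iloc[0]),
                    "poc_umol_L": sample.poc,
                    "pon_umol_L": sample.pon,
                    "pop_umol_L": sample.pop,
                    "filtered_volume_mL": sample.filtered_volume,
                    "brassicasterol_ug_L": profile.brassicasterol_epi,
                    "dinosterol_ug_L": profile.dinosterol,
                }
                for name in FATTY_ACIDS:
                    rec[f"fa_{name}_ug_L"] = profile.fa[name]
                comp_rows.append(rec)
    return SyntheticExperiment(
        design=latent.design,
        units=pd.DataFrame(unit_rows),
        trajectories=trajectories,
        composition=pd.DataFrame(comp_rows),
        truth=truth,
        noise=cfg,
        seed=seed,
        replicates=replicates,
    )


def generate_experiment(
    truth: GroundTruth | None = None,
    cfg: NoiseConfig | None = None,
    seed: int = 0,
    replicates: int = 3,
    noiseless: bool = False,
    design: list[Treatment] | None = None,
    semicontinuous_days: int = SEMICONTINUOUS_DAYS,
) -> SyntheticExperiment:
    """Generate a complete synthetic experiment (latent sweep + observation).

    Deterministic given (truth, cfg, seed): two calls with identical
    arguments produce bit-identical tables.
    """
    truth = default_ground_truth() if truth is None else truth
    cfg = NoiseConfig() if cfg is None else cfg
    latent = simulate_latent(
        truth, design=design, semicontinuous_days=semicontinuous_days
    )
    return observe(
        latent, truth, cfg, seed=seed, replicates=replicates, noiseless=noiseless
    )


# ---------------------------------------------------------------------------
# fixture I/O


def trajectory_frame(exp: SyntheticExperiment) -> pd.DataFrame:
    """All trajectories in one tidy table (schema of ``trajectory.csv``)."""
    parts = []
    for cid, traj in exp.trajectories.items():
        df = traj.df.copy()
        df.insert(0, "culture_id", cid)
        df = df.rename(
            columns={
                "n_diatom": "n_diatom_1e4_per_ml",
                "n_dino": "n_dino_1e4_per_ml",
            }
        )
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


def write_fixture(exp: SyntheticExperiment, directory: str | Path) -> list[Path]:
    """Write design.csv, units.csv, trajectory.csv, composition.csv,
    ground_truth.json and manifest.json; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(name: str, df: pd.DataFrame) -> None:
        path = directory / name
        df.to_csv(path, index=False)
        written.append(path)

    _csv("design.csv", design_frame(exp.design))
    _csv("units.csv", exp.units)
    _csv("trajectory.csv", trajectory_frame(exp))
    _csv("composition.csv", exp.composition)
    gt_path = directory / "ground_truth.json"
    gt_path.write_text(json.dumps(exp.truth.to_jsonable(), indent=2, sort_keys=True))
    written.append(gt_path)
    man_path = directory / "manifest.json"
    man_path.write_text(json.dumps(exp.manifest, indent=2, sort_keys=True))
    written.append(man_path)
    return written
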