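"""End-to-end orchestration: generate (or load) -> fit -> analyze -> report.

The pipeline mirrors the structure of the study's results: a per-unit
interaction table (alpha, beta per biculture with superiority calls),
AICc-selected GLMs per response, per-temperature additive-model summaries
of the nitrate effect on alpha, and composition-vs-community regressions.
Reports are plain JSON + CSV so that reruns under a fixed seed are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition as comp_mod
from .design import build_design, np_label_value
from .dynamics import SEMICONTINUOUS, Trajectory
from .errors import DiadinoError, SchemaError
from .glms import (
    GAMFit,
    ModelSpec,
    fit_gam_1d,
    fit_glm,
    ols_regression,
    response_amplitude,
    select_model,
)
from .inference import (
    classify_superiority,
    estimate_interaction,
    fit_logistic_mono,
    per_capita_rates,
)
from .synthetic import (
    NoiseConfig,
    SyntheticExperiment,
    default_ground_truth,
    generate_experiment,
)

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "mode",
    "input_dir",
    "seed",
    "noiseless",
    "replicates",
    "counting_volume",
    "process_cv",
    "chemistry_cv",
    "dilution_corrected",
    "family_per_response",
    "basis_size",
    "out_dir",
}

_RESPONSES = ("alpha", "poc_pon", "pon_pop", "r_16_1_16_0", "epa_dha", "b_over_bd")


@dataclass
class PipelineConfig:
    """Validated run configuration; unknown keys are rejected."""

    mode: str = "synthetic"  # synthetic | csv
    input_dir: str | None = None
    seed: int = 0
    noiseless: bool = False
    replicates: int = 3
    counting_volume: float = 2.0
    process_cv: float = 0.05
    chemistry_cv: float = 0.08
    dilution_corrected: bool = True
    family_per_response: dict[str, str] = field(default_factory=dict)
    basis_size: int = 10
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "csv"):
            raise SchemaError(f"unknown mode {self.mode!r}")
        if self.mode == "csv" and not self.input_dir:
            raise SchemaError("mode 'csv' requires input_dir")
        for resp, fam in self.family_per_response.items():
            if fam not in ("gaussian_identity", "gamma_log"):
                raise SchemaError(f"unknown family {fam!r} for response {resp!r}")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise SchemaError("config must be a mapping")
        return cls.from_dict(raw)

    def noise(self) -> NoiseConfig:
        return NoiseConfig(
            counting_volume=self.counting_volume,
            process_cv=self.process_cv,
            chemistry_cv=self.chemistry_cv,
            seed=self.seed,
        )


@dataclass
class ReportBundle:
    interaction: pd.DataFrame
    indices: pd.DataFrame
    glm_report: dict
    gam_report: dict
    regressions: dict
    exclusions: list[dict]
    manifest: dict

    def to_json(self) -> str:
        payload = {
            "manifest": self.manifest,
            "glm": self.glm_report,
            "gam": self.gam_report,
            "regressions": self.regressions,
            "exclusions": self.exclusions,
            "interaction": _records(self.interaction),
            "indices": _records(self.indices),
        }
        return json.dumps(payload, sort_keys=True, indent=1, allow_nan=False,
                          default=_jsonable)

    def write(self, out_dir: str | Path) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        p = out / "interaction.csv"
        self.interaction.to_csv(p, index=False)
        paths.append(p)
        p = out / "indices.csv"
        self.indices.to_csv(p, index=False)
        paths.append(p)
        p = out / "stats_report.json"
        p.write_text(self.to_json())
        paths.append(p)
        return paths


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        v = obj.item()
        if isinstance(v, float) and not np.isfinite(v):
            return None
        return v
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _records(df: pd.DataFrame) -> list[dict]:
    """DataFrame rows as JSON-safe dicts (non-finite floats -> None)."""
    out = []
    for rec in df.to_dict(orient="records"):
        out.append(
            {
                k: (None if isinstance(v, float) and not np.isfinite(v) else v)
                for k, v in rec.items()
            }
        )
    return out


def _clean_float(x: float) -> float | None:
    x = float(x)
    return x if np.isfinite(x) else None


# ---------------------------------------------------------------------------
# loading external CSV fixtures

_TRAJ_COLS = {
    "culture_id",
    "day",
    "phase",
    "post_dilution",
    "n_diatom_1e4_per_ml",
    "n_dino_1e4_per_ml",
}
_UNIT_COLS = {"culture_id", "treatment_id", "culture_type", "replicate", "D"}


def load_cultures(directory: str | Path):
    """Load a fixture directory written by ``write_fixture``.

    Returns (units table, {culture_id: Trajectory}, composition table).
    Densities are asserted non-negative (with row references) and unknown
    columns produce a warning, not a failure.
    """
    directory = Path(directory)
    traj_path = directory / "trajectory.csv"
    units_path = directory / "units.csv"
    comp_path = directory / "composition.csv"
    for p in (traj_path, units_path, comp_path):
        if not p.exists():
            raise SchemaError(f"missing required file {p.name} in {directory}")
    traj = pd.read_csv(traj_path)
    units = pd.read_csv(units_path)
    comp = pd.read_csv(comp_path)
    missing = _TRAJ_COLS - set(traj.columns)
    if missing:
        raise SchemaError(f"trajectory.csv missing columns: {sorted(missing)}")
    missing = _UNIT_COLS - set(units.columns)
    if missing:
        raise SchemaError(f"units.csv missing columns: {sorted(missing)}")
    extra = set(traj.columns) - _TRAJ_COLS
    if extra:
        logger.warning("trajectory.csv: ignoring unknown columns %s", sorted(extra))
    for col in ("n_diatom_1e4_per_ml", "n_dino_1e4_per_ml"):
        bad = traj.index[traj[col] < 0]
        if len(bad):
            raise SchemaError(
                f"trajectory.csv: negative density in column {col} at rows "
                f"{bad[:5].tolist()}"
            )
    d_map = units.set_index("culture_id")["D"].to_dict()
    trajectories = {}
    for cid, g in traj.groupby("culture_id", sort=True):
        df = g.rename(
            columns={
                "n_diatom_1e4_per_ml": "n_diatom",
                "n_dino_1e4_per_ml": "n_dino",
            }
        )[["day", "phase", "post_dilution", "n_diatom", "n_dino"]].reset_index(
            drop=True
        )
        trajectories[cid] = Trajectory(df, D=d_map.get(cid))
    return units, trajectories, comp


# ---------------------------------------------------------------------------
# stages


def interaction_table(
    units: pd.DataFrame,
    trajectories: dict[str, Trajectory],
    dilution_corrected: bool = True,
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-biculture interaction estimates with monoculture (r, K) fixed.

    Each biculture replicate uses the logistic fits of its own replicate's
    monocultures.  Units whose estimate fails are reported with NaN and an
    explicit exclusion record, never silently dropped.
    """
    rows, exclusions = [], []
    units_ix = units.set_index("culture_id")
    by_key = {
        (r.treatment_id, r.culture_type, r.replicate): cid
        for cid, r in units_ix.iterrows()
    }
    bicultures = units[units["culture_type"] == "biculture"]
    for _, u in bicultures.iterrows():
        cid = u["culture_id"]
        rec = {
            "treatment_id": u["treatment_id"],
            "replicate": int(u["replicate"]),
            "culture_id": cid,
            "alpha": np.nan,
            "alpha_se": np.nan,
            "beta": np.nan,
            "beta_se": np.nan,
            "n_points": 0,
            "superiority": "",
        }
        try:
            md_id = by_key[(u["treatment_id"], "mono_diatom", u["replicate"])]
            mo_id = by_key[(u["treatment_id"], "mono_dino", u["replicate"])]
            d_fit = fit_logistic_mono(trajectories[md_id], species="diatom")
            o_fit = fit_logistic_mono(trajectories[mo_id], species="dino")
            series = per_capita_rates(
                trajectories[cid],
                D=float(u["D"]),
                dilution_corrected=dilution_corrected,
            )
            est = estimate_interaction(series, d_fit, o_fit)
            rec.update(
                alpha=est.alpha,
                alpha_se=est.alpha_se,
                beta=est.beta,
                beta_se=est.beta_se,
                n_points=est.n_points,
                superiority=classify_superiority(est.alpha),
            )
            if series.excluded_days:
                exclusions.append(
                    {
                        "culture_id": cid,
                        "stage": "per_capita_rates",
                        "reason": "density at/below detection floor",
                        "days": series.excluded_days,
                    }
                )
        except (DiadinoError, KeyError) as exc:
            exclusions.append(
                {"culture_id": cid, "stage": "interaction", "reason": str(exc)}
            )
        rows.append(rec)
    return pd.DataFrame(rows), exclusions


def indices_table(composition: pd.DataFrame) -> pd.DataFrame:
    """Composition indices per sampled culture (biculture and mono)."""
    out = []
    for _, row in composition.iterrows():
        sample = comp_mod.ElementalSample(
            poc=row["poc_umol_L"],
            pon=row["pon_umol_L"],
            pop=row["pop_umol_L"],
            filtered_volume=row.get("filtered_volume_mL", 20.0),
            culture_id=row["culture_id"],
        )
        fa = {
            c[len("fa_") : -len("_ug_L")]: row[c]
            for c in composition.columns
            if c.startswith("fa_") and c.endswith("_ug_L")
        }
        profile = comp_mod.LipidProfile(
            fa=fa,
            brassicasterol_epi=row["brassicasterol_ug_L"],
            dinosterol=row["dinosterol_ug_L"],
            culture_id=row["culture_id"],
        )
        idx = comp_mod.compute_indices(sample, profile)
        n1, n2 = float(row["n_diatom_obs"]), float(row["n_dino_obs"])
        out.append(
            {
                "culture_id": row["culture_id"],
                "treatment_id": row["treatment_id"],
                "culture_type": row["culture_type"],
                "replicate": int(row["replicate"]),
                "n_diatom_obs": n1,
                "n_dino_obs": n2,
                "diatom_dino_ratio": n1 / n2 if n2 > 0 else np.nan,
                "diatom_fraction": n1 / (n1 + n2) if n1 + n2 > 0 else np.nan,
                "poc_pon": idx.poc_pon,
                "pon_pop": idx.pon_pop,
                "r_16_1_16_0": idx.r_16_1_16_0,
                "epa_dha": idx.epa_dha,
                "b_over_bd": idx.b_over_bd,
                "dinosterol_ug_mgC": idx.carbon_normalized.get("dinosterol", np.nan),
                "brassicasterol_ug_mgC": idx.carbon_normalized.get(
                    "brassicasterol_epi", np.nan
                ),
            }
        )
    return pd.DataFrame(out)


def _response_table(
    interaction: pd.DataFrame, indices: pd.DataFrame, design_df: pd.DataFrame
) -> pd.DataFrame:
    """Biculture-level table joining responses with numeric factors."""
    meta = design_df.set_index("id")
    bic = indices[indices["culture_type"] == "biculture"]
    merged = interaction.merge(
        bic[
            [
                "culture_id",
                "poc_pon",
                "pon_pop",
                "r_16_1_16_0",
                "epa_dha",
                "b_over_bd",
                "diatom_dino_ratio",
                "diatom_fraction",
            ]
        ],
        on="culture_id",
        how="left",
    )
    merged["temperature"] = [
        float(meta.loc[t, "temperature_C"]) for t in merged["treatment_id"]
    ]
    merged["nitrate"] = [
        float(meta.loc[t, "nitrate_umol_L"]) for t in merged["treatment_id"]
    ]
    merged["np_ratio"] = [
        np_label_value(meta.loc[t, "np_label"]) for t in merged["treatment_id"]
    ]
    return merged


def _glm_stage(table: pd.DataFrame, family_per_response: dict[str, str]) -> dict:
    report = {}
    for resp in _RESPONSES:
        if resp not in table.columns:
            continue
        fam = family_per_response.get(resp, "gaussian_identity")
        fits = []
        for order in (1, 2, 3):
            spec = ModelSpec(response=resp, order=order, family_link=fam)
            try:
                fits.append(fit_glm(table, spec))
            except DiadinoError as exc:
                logger.warning("GLM %s order %d failed: %s", resp, order, exc)
        if not fits:
            report[resp] = {"error": "no candidate converged"}
            continue
        chosen = select_model(fits)
        report[resp] = {
            "candidates": [
                {"order": f.spec.order, "k": f.k, "aicc": _clean_float(f.aicc)}
                for f in fits
            ],
            "chosen_order": chosen.spec.order,
            "n": chosen.n,
            "coefficients": {
                term: {
                    "coef": _clean_float(r["coef"]),
                    "se": _clean_float(r["se"]),
                    "t": _clean_float(r["t"]),
                    "p": _clean_float(r["p"]),
                }
                for term, r in chosen.coefficients.iterrows()
            },
        }
    return report


def _gam_summary(fit: GAMFit) -> dict:
    return {
        "intercept": _clean_float(fit.intercept),
        "intercept_se": _clean_float(fit.intercept_se),
        "edf": _clean_float(fit.edf),
        "p": _clean_float(fit.p_smooth),
        "gcv": _clean_float(fit.gcv),
        "r2_adj": _clean_float(fit.r2_adj),
        "deviance_explained_pct": _clean_float(100.0 * fit.deviance_explained),
        "response_amplitude": _clean_float(response_amplitude(fit)),
        "n": fit.n,
    }


def _gam_stage(table: pd.DataFrame, basis_size: int) -> dict:
    """Per-temperature and joined smooth of alpha on nitrate concentration."""
    report = {}
    ok = table.dropna(subset=["alpha", "nitrate"])
    for temp, sub in ok.groupby("temperature"):
        try:
            fit = fit_gam_1d(
                sub["nitrate"].to_numpy(),
                sub["alpha"].to_numpy(),
                basis_size=min(basis_size, len(sub) - 1),
            )
            report[f"{int(temp)}C"] = _gam_summary(fit)
        except DiadinoError as exc:
            report[f"{int(temp)}C"] = {"error": str(exc)}
    try:
        fit = fit_gam_1d(
            ok["nitrate"].to_numpy(), ok["alpha"].to_numpy(), basis_size=basis_size
        )
        report["joined"] = _gam_summary(fit)
    except DiadinoError as exc:
        report["joined"] = {"error": str(exc)}
    return report


def _regression_stage(table: pd.DataFrame) -> dict:
    """Composition-vs-community regressions (community-proxy couplings)."""
    pairs = [
        ("pon_pop", "diatom_dino_ratio"),
        ("r_16_1_16_0", "diatom_dino_ratio"),
        ("epa_dha", "diatom_dino_ratio"),
        ("b_over_bd", "diatom_fraction"),
    ]
    out = {}
    for resp, xcol in pairs:
        sub = table.dropna(subset=[resp, xcol])
        try:
            fit = ols_regression(sub[xcol], sub[resp])
            out[f"{resp}~{xcol}"] = {
                "slope": _clean_float(fit.slope),
                "intercept": _clean_float(fit.intercept),
                "r2": _clean_float(fit.r2),
                "p": _clean_float(fit.p),
                "n": fit.n,
            }
        except DiadinoError as exc:
            out[f"{resp}~{xcol}"] = {"error": str(exc)}
    return out


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage and assemble the report bundle.

    Per-unit failures are recorded as exclusions; only a global failure
    (unreadable input, invalid config) raises.
    """
    from .design import design_frame

    if config.mode == "synthetic":
        exp = generate_experiment(
            truth=default_ground_truth(),
            cfg=config.noise(),
            seed=config.seed,
            replicates=config.replicates,
            noiseless=config.noiseless,
        )
        units, trajectories, comp = exp.units, exp.trajectories, exp.composition
        design_df = design_frame(exp.design)
        manifest = exp.manifest
    else:
        units, trajectories, comp = load_cultures(config.input_dir)
        design_df = pd.read_csv(Path(config.input_dir) / "design.csv")
        manifest = {"seed": config.seed, "input_dir": str(config.input_dir)}
    interaction, exclusions = interaction_table(
        units, trajectories, dilution_corrected=config.dilution_corrected
    )
    indices = indices_table(comp)
    table = _response_table(interaction, indices, design_df)
    glm_report = _glm_stage(table, config.family_per_response)
    gam_report = _gam_stage(table, config.basis_size)
    regressions = _regression_stage(
        indices[indices["culture_type"] == "biculture"]
    )
    bundle = ReportBundle(
        interaction=interaction,
        indices=indices,
        glm_report=glm_report,
        gam_report=gam_report,
        regressions=regressions,
        exclusions=exclusions,
        manifest={**manifest, "config": dataclasses.asdict(config)},
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle
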