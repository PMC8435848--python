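import json

import numpy as np
import pandas as pd
import pytest

from diadino.composition import compute_indices
from diadino.design import build_design
from diadino.errors import InvalidArgumentError
from diadino.inference import estimate_interaction, per_capita_rates, GrowthFit
from diadino.pipeline import load_cultures
from diadino.synthetic import (
    NoiseConfig,
    alpha_surface,
    default_ground_truth,
    generate_composition,
    generate_counts,
    generate_experiment,
    observe,
    write_fixture,
)

DESIGN_NITRATES = sorted({t.nitrate for t in build_design()})


class TestAlphaSurface:
    def test_dino_superiority_at_low_nutrients(self):
        for nitrate in (35.2, 88.0):
            for temp in (12, 18, 24):
                assert alpha_surface(temp, nitrate) > 0

    def test_diatom_superiority_at_high_nutrients_cool(self):
        for nitrate in (1760.0, 4400.0):
            for temp in (12, 18):
                assert alpha_surface(temp, nitrate) < 0

    def test_warm_upturn_at_highest_nitrate(self):
        assert alpha_surface(24, 4400.0) > 0

    def test_amplitude_decreases_with_temperature(self):
        grid = np.geomspace(min(DESIGN_NITRATES), max(DESIGN_NITRATES), 200)
        amps = {
            t: np.ptp([alpha_surface(t, x) for x in grid]) for t in (12, 18, 24)
        }
        assert amps[12] > amps[18] > amps[24]

    def test_warm_curve_has_interior_minimum(self):
        grid = np.geomspace(min(DESIGN_NITRATES), max(DESIGN_NITRATES), 400)
        vals = [alpha_surface(24, x) for x in grid]
        i = int(np.argmin(vals))
        assert 0 < i < len(grid) - 1

    def test_unknown_temperature_rejected(self):
        with pytest.raises(InvalidArgumentError):
            alpha_surface(15, 100.0)


class TestCountingNoise:
    def test_zero_density_always_zero(self, rng):
        cfg = NoiseConfig(process_cv=0.0)
        assert generate_counts(0.0, cfg, rng) == 0.0

    def test_poisson_cv_at_400_expected_cells(self, rng):
        cfg = NoiseConfig(counting_volume=4.0, process_cv=0.0)
        draws = generate_counts(np.full(10_000, 10.0), cfg, rng)  # 400 cells
        cv = draws.std() / draws.mean()
        assert cv == pytest.approx(1 / np.sqrt(400.0), rel=0.2)

    def test_large_volume_recovers_truth(self, rng):
        cfg = NoiseConfig(counting_volume=1e5, process_cv=0.0)  # 10^7 cells
        obs = generate_counts(np.full(100, 10.0), cfg, rng)
        assert np.abs(obs / 10.0 - 1).max() < 0.01

    def test_negative_density_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            generate_counts(-1.0, NoiseConfig(), rng)


class TestCompositionGeneration:
    def _indices(self, n_diatom, n_dino, truth, rng):
        tr = build_design()[0]
        sample, profile = generate_composition(n_diatom, n_dino, tr, truth, rng)
        return compute_indices(sample, profile)

    def test_pure_diatom_sterol_end_member(self, truth, rng):
        assert self._indices(50.0, 0.0, truth, rng).b_over_bd == 1.0

    def test_pure_dino_sterol_end_member(self, truth, rng):
        assert self._indices(0.0, 50.0, truth, rng).b_over_bd == 0.0

    def test_noiseless_mixtures_monotone_in_diatom_fraction(self, truth, rng):
        fracs = np.linspace(0.1, 0.9, 9)
        pon_pop, epa_dha, b_bd = [], [], []
        for f in fracs:
            idx = self._indices(100.0 * f, 100.0 * (1 - f), truth, rng)
            pon_pop.append(idx.pon_pop)
            epa_dha.append(idx.epa_dha)
            b_bd.append(idx.b_over_bd)
        assert (np.diff(pon_pop) < 0).all()
        assert (np.diff(epa_dha) > 0).all()
        assert (np.diff(b_bd) > 0).all()

    def test_both_species_absent_rejected(self, truth, rng):
        with pytest.raises(InvalidArgumentError):
            generate_composition(0.0, 0.0, build_design()[0], truth, rng)

    def test_quota_invariants(self, truth):
        assert truth.diatom.n_quota / truth.diatom.p_quota < (
            truth.dino.n_quota / truth.dino.p_quota
        )
        assert truth.diatom.brassicasterol_epi > 0
        assert truth.diatom.dinosterol == 0.0
        assert truth.dino.dinosterol > 0


class TestExperimentGeneration:
    def test_design_arithmetic(self, noisy_experiment):
        units = noisy_experiment.units
        assert len(units) == 243
        assert (units["culture_type"] == "biculture").sum() == 81
        assert units["culture_type"].str.startswith("mono").sum() == 162
        # every biculture has both monocultures in the same replicate
        key = units.set_index(["treatment_id", "culture_type", "replicate"]).index
        for tid in units["treatment_id"].unique():
            for rep in (1, 2, 3):
                assert (tid, "mono_diatom", rep) in key
                assert (tid, "mono_dino", rep) in key

    def test_deterministic_given_seed(self, truth, latent):
        a = observe(latent, truth, NoiseConfig(), seed=5, replicates=1)
        b = observe(latent, truth, NoiseConfig(), seed=5, replicates=1)
        pd.testing.assert_frame_equal(a.units, b.units)
        pd.testing.assert_frame_equal(a.composition, b.composition)
        cid = a.units["culture_id"].iloc[0]
        pd.testing.assert_frame_equal(a.trajectories[cid].df, b.trajectories[cid].df)

    def test_seed_changes_observations(self, truth, latent):
        a = observe(latent, truth, NoiseConfig(), seed=5, replicates=1)
        b = observe(latent, truth, NoiseConfig(), seed=6, replicates=1)
        assert not a.composition.equals(b.composition)

    def test_noiseless_alpha_recovery_against_surface(
        self, truth, noiseless_experiment
    ):
        exp = noiseless_experiment
        units = exp.units.set_index("culture_id")
        design = {t.id: t for t in exp.design}
        checked = 0
        for cid, u in units[units["culture_type"] == "biculture"].iterrows():
            tr = design[u["treatment_id"]]
            p = truth.params_for(tr)
            series = per_capita_rates(exp.trajectories[cid], D=float(u["D"]))
            est = estimate_interaction(
                series,
                GrowthFit(mu_max=0, window=(0, 0), r=p.r_diatom, K=p.K_diatom),
                GrowthFit(mu_max=0, window=(0, 0), r=p.r_dino, K=p.K_dino),
            )
            assert abs(est.alpha - p.alpha) <= 0.02, cid
            checked += 1
        assert checked == 27

    def test_dominant_fatty_acids_in_typical_biculture(self, truth, rng):
        from diadino.composition import major_components, LipidProfile

        tr = next(t for t in build_design() if t.nutrient_level == "normal")
        _, profile = generate_composition(60.0, 30.0, tr, truth, rng)
        majors = major_components(profile)
        assert {"16:0", "16:1n-7", "20:5n-3", "22:6n-3"} <= majors


class TestFixtureIO:
    def test_round_trip(self, tmp_path, truth, latent):
        exp = observe(latent, truth, NoiseConfig(), seed=3, replicates=1)
        write_fixture(exp, tmp_path)
        units, trajectories, comp = load_cultures(tmp_path)
        assert len(units) == len(exp.units)
        cid = exp.units["culture_id"].iloc[5]
        got = trajectories[cid].df.reset_index(drop=True)
        want = exp.trajectories[cid].df.reset_index(drop=True)
        pd.testing.assert_frame_equal(got, want, check_dtype=False)
        assert len(comp) == len(exp.composition)

    def test_manifest_hash_tracks_seed_and_config(self, truth, latent):
        a = observe(latent, truth, NoiseConfig(), seed=1, replicates=1)
        b = observe(latent, truth, NoiseConfig(), seed=2, replicates=1)
        c = observe(
            latent, truth, NoiseConfig(counting_volume=4.0), seed=1, replicates=1
        )
        assert a.manifest["config_hash"] != b.manifest["config_hash"]
        assert a.manifest["config_hash"] != c.manifest["config_hash"]
        a2 = observe(latent, truth, NoiseConfig(), seed=1, replicates=1)
        assert a.manifest["config_hash"] == a2.manifest["config_hash"]

    def test_fixture_small_on_disk(self, tmp_path, truth, latent):
        exp = observe(latent, truth, NoiseConfig(), seed=3)
        paths = write_fixture(exp, tmp_path)
        total = sum(p.stat().st_size for p in paths)
        assert total < 10 * 1024 * 1024

    def test_ground_truth_json_readable(self, tmp_path, truth, latent):
        exp = observe(latent, truth, NoiseConfig(), seed=3, replicates=1)
        write_fixture(exp, tmp_path)
        gt = json.loads((tmp_path / "ground_truth.json").read_text())
        assert gt["diatom"]["dinosterol"] == 0.0
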