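"""Synthetic CBMN generator: determinism, distributions, recovery."""

import numpy as np
import pytest

from cbmn_screen import (
    SyntheticConfig,
    cbpi,
    cbpi_quality_flag,
    magnitude_of_protection,
    records_to_frame,
    simulate_calibration_dataset,
    simulate_cbpi_tallies,
    simulate_screening_experiment,
    write_scoring_table,
)
from cbmn_screen.errors import ValidationError
from cbmn_screen.simulate import default_effects


def small_config(**kw):
    base = dict(seed=1, n_donors=2, n_experiments=3, include_cbpi=False,
                effects={"rosmarinic_acid": {"pre": 0.58}}, solvents={})
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfig:
    def test_defaults_match_study_design(self):
        cfg = SyntheticConfig()
        assert cfg.n_donors == 6 and cfg.n_experiments == 5
        assert len(cfg.calibration_doses) == 20
        assert cfg.calibration_doses[0] == 0.0
        assert cfg.calibration_doses[-1] == 16362.0
        assert cfg.baseline_freq == 10.0  # 0.02 MN/BC scaled to 500 BC
        assert cfg.irradiated_control_mean == 26.0
        assert cfg.slope == pytest.approx(1 / 64.37)
        assert len(default_effects()) == 29

    @pytest.mark.parametrize(
        "kw",
        [
            dict(dispersion=-0.1),
            dict(cbpi_target=0.9),
            dict(effects={"x": {"before": 0.5}}),
            dict(effects={"x": {"pre": 1.2}}),
            dict(n_donors=0),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValidationError):
            SyntheticConfig(**kw)

    def test_dmso_offset_can_push_mean_negative(self):
        cfg = SyntheticConfig(
            effects={"x": {"pre": 0.95}}, solvents={"x": "dmso"}, dmso_offset=0.10,
            include_cbpi=False,
        )
        with pytest.raises(ValidationError, match="negative mean"):
            simulate_screening_experiment(cfg)

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = small_config(dispersion=0.3)
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.truth()))
        assert SyntheticConfig.from_file(path) == cfg


class TestDeterminism:
    def test_same_seed_identical_tables(self, tmp_path):
        cfg = SyntheticConfig(seed=7)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_scoring_table(simulate_screening_experiment(cfg), a)
        write_scoring_table(simulate_screening_experiment(SyntheticConfig(seed=7)), b)
        assert a.read_bytes() == b.read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_calibration_dataset(small_config(seed=1))
        b = simulate_calibration_dataset(small_config(seed=2))
        assert [r.mn_count for r in a] != [r.mn_count for r in b]


class TestCalibrationDataset:
    def test_degenerate_flat_schedule_recovers_baseline(self):
        cfg = SyntheticConfig(
            seed=5, slope=0.0, donor_sd=0.0, include_cbpi=False,
            calibration_doses=(0.0, 100.0, 200.0), effects={}, solvents={},
        )
        counts = np.array([r.mn_count for r in simulate_calibration_dataset(cfg)])
        se = np.sqrt(cfg.baseline_freq / len(counts))
        assert abs(counts.mean() - cfg.baseline_freq) < 3 * se

    def test_poisson_variance_to_mean_near_one(self):
        cfg = SyntheticConfig(
            seed=11, donor_sd=0.0, dispersion=0.0, include_cbpi=False,
            calibration_doses=(2000.0,), n_donors=1, n_experiments=400,
            effects={}, solvents={},
        )
        counts = np.array([r.mn_count for r in simulate_calibration_dataset(cfg)])
        ratio = counts.var(ddof=1) / counts.mean()
        # var/mean of Poisson has SE ~ sqrt(2/(n-1))
        assert abs(ratio - 1.0) < 3 * np.sqrt(2 / (len(counts) - 1))

    def test_overdispersion_raises_variance(self):
        base = dict(seed=11, donor_sd=0.0, include_cbpi=False, n_donors=1,
                    n_experiments=600, calibration_doses=(2000.0,), effects={}, solvents={})
        poisson = simulate_calibration_dataset(SyntheticConfig(dispersion=0.0, **base))
        nb = simulate_calibration_dataset(SyntheticConfig(dispersion=2.0, **base))
        v_p = np.var([r.mn_count for r in poisson], ddof=1)
        v_nb = np.var([r.mn_count for r in nb], ddof=1)
        assert v_nb > 1.5 * v_p

    def test_schedule_and_labels(self):
        cfg = small_config()
        recs = simulate_calibration_dataset(cfg)
        assert len(recs) == len(cfg.calibration_doses) * 2 * 3
        assert {r.substance for r in recs} == {"control"}
        assert {r.timing for r in recs} == {"none"}
        assert sorted({r.dose_mGy for r in recs}) == sorted(cfg.calibration_doses)


class TestScreeningExperiment:
    def test_empty_effects_emit_only_control_arms(self):
        cfg = SyntheticConfig(seed=1, effects={}, solvents={}, dmso_offset=0.0,
                              include_cbpi=False)
        recs = simulate_screening_experiment(cfg)
        assert {(r.substance, r.timing) for r in recs} == {("control", "none")}
        assert sorted({r.dose_mGy for r in recs}) == [0.0, 2000.0]

    def test_null_effect_arm_matches_control_distribution(self):
        cfg = SyntheticConfig(
            seed=3, donor_sd=0.0, include_cbpi=False, n_experiments=60,
            effects={"inert": {"pre": 0.0}}, solvents={}, dmso_offset=0.0,
        )
        df = records_to_frame(simulate_screening_experiment(cfg))
        irr = df[(df.substance == "control") & (df.dose_mGy == 2000.0)]["mn_count"]
        arm = df[df.substance == "inert"]["mn_count"]
        se = np.sqrt(26.0 / len(arm) + 26.0 / len(irr))
        assert abs(arm.mean() - irr.mean()) < 3 * se

    def test_dmso_offset_applies_pre_only(self):
        cfg = SyntheticConfig(
            seed=4, donor_sd=0.0, include_cbpi=False, n_experiments=80,
            effects={"lipo": {"pre": 0.3, "post": 0.3}}, solvents={"lipo": "dmso"},
            dmso_offset=0.10,
        )
        df = records_to_frame(simulate_screening_experiment(cfg))
        pre = df[(df.substance == "lipo") & (df.timing == "pre")]["mn_count"].mean()
        post = df[(df.substance == "lipo") & (df.timing == "post")]["mn_count"].mean()
        # pre mean 26*(1-0.4)=15.6; post mean 26*(1-0.3)=18.2
        n = 6 * 80
        assert abs(pre - 15.6) < 3 * np.sqrt(15.6 / n)
        assert abs(post - 18.2) < 3 * np.sqrt(18.2 / n)

    def test_protection_recovered_by_pipeline(self):
        """Mean MP over seeded replicates is close to the configured truth."""
        mps = []
        for seed in range(40):
            cfg = SyntheticConfig(seed=seed, include_cbpi=False,
                                  effects={"rosmarinic_acid": {"pre": 0.58}}, solvents={})
            df = records_to_frame(simulate_screening_experiment(cfg))
            ctrl = df[(df.substance == "control") & (df.dose_mGy == 2000.0)]["freq_per_500"].mean()
            treat = df[df.substance == "rosmarinic_acid"]["freq_per_500"].mean()
            mps.append(magnitude_of_protection(ctrl, treat))
        mean = np.mean(mps)
        se = np.std(mps, ddof=1) / np.sqrt(len(mps))
        assert abs(mean - 58.0) < 3 * se

    def test_radiosensitizer_effect_raises_frequency(self):
        cfg = SyntheticConfig(seed=6, include_cbpi=False, donor_sd=0.0,
                              effects={"zoledronic_acid": {"pre": -0.35}}, solvents={})
        df = records_to_frame(simulate_screening_experiment(cfg))
        arm = df[df.substance == "zoledronic_acid"]["freq_per_500"]
        n = len(arm)
        assert abs(arm.mean() - 35.1) < 3 * np.sqrt(35.1 / n)


class TestCbpiTallies:
    def test_target_one_all_mononucleate(self):
        cfg = SyntheticConfig(cbpi_target=1.0)
        mono, bi, multi = simulate_cbpi_tallies(cfg, 1000, np.random.default_rng(0))
        assert (mono, bi, multi) == (1000, 0, 0)

    def test_large_draw_near_target(self):
        cfg = SyntheticConfig(cbpi_target=1.65)
        mono, bi, multi = simulate_cbpi_tallies(cfg, 100_000, np.random.default_rng(1))
        assert abs(cbpi(mono, bi, multi) - 1.65) < 0.05

    def test_default_target_passes_quality_gate(self):
        cfg = SyntheticConfig()
        mono, bi, multi = simulate_cbpi_tallies(cfg, 1000, np.random.default_rng(2))
        assert cbpi_quality_flag(cbpi(mono, bi, multi)) == "pass"

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            simulate_cbpi_tallies(SyntheticConfig(), 0)
        with pytest.raises(ValidationError):
            SyntheticConfig(cbpi_target=3.2)
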