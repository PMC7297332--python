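"""Synthetic dose-log generator: moment matching, determinism, coupling."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from cathlar import (
    CouplingError,
    GeneratorConfig,
    Role,
    calibrate_lognormal,
    generate,
    generate_frame,
    write_dose_log,
)


class TestCalibrateLognormal:
    def test_back_transform_reproduces_requested_moments(self):
        mu, sigma = calibrate_lognormal(59.33, 95.03)
        mean = math.exp(mu + sigma**2 / 2)
        var = mean**2 * (math.exp(sigma**2) - 1)
        assert mean == pytest.approx(59.33, abs=1e-9)
        assert math.sqrt(var) == pytest.approx(95.03, abs=1e-9)

    def test_unit_cv_gives_log_variance_ln2(self):
        # mean = sd -> sigma^2 = ln(1 + 1) = ln 2
        _, sigma = calibrate_lognormal(4.0, 4.0)
        assert sigma**2 == pytest.approx(math.log(2.0))

    def test_zero_sd_degenerates_to_point_mass(self):
        mu, sigma = calibrate_lognormal(4.0, 0.0)
        assert sigma == 0.0 and math.exp(mu) == pytest.approx(4.0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            calibrate_lognormal(0.0, 1.0)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        mean=st.floats(0.5, 1e4),
        cv=st.floats(0.0, 5.0),
    )
    def test_moment_identity_property(self, mean, cv):
        mu, sigma = calibrate_lognormal(mean, cv * mean)
        back_mean = math.exp(mu + sigma**2 / 2)
        back_sd = back_mean * math.sqrt(math.expm1(sigma**2))
        assert back_mean == pytest.approx(mean, rel=1e-9)
        assert back_sd == pytest.approx(cv * mean, rel=1e-6, abs=1e-12)


class TestGenerate:
    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(n_procedures=50, seed=123)
        a, b = generate(cfg), generate(cfg)
        assert a == b
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_dose_log(a, pa)
        write_dose_log(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ(self):
        assert generate(GeneratorConfig(n_procedures=20, seed=1)) != generate(
            GeneratorConfig(n_procedures=20, seed=2)
        )

    def test_all_quantities_nonnegative(self):
        frame = generate_frame(GeneratorConfig(n_procedures=2000, seed=5))
        cols = [
            "fluoro_time_min", "fluoro_kv", "fluoro_ma", "acq_kv", "acq_ma",
            "acq_time_s", "dap_gycm2", "epd_dose_usv",
        ]
        assert (frame[cols].to_numpy(float) >= 0).all()
        assert (frame["dap_gycm2"] > 0).all()

    def test_type_frequencies_match_configured_probabilities(self):
        cfg = GeneratorConfig(n_procedures=20_000, seed=11)
        frame = generate_frame(cfg)
        counts = (
            frame.drop_duplicates("procedure_id")["procedure_type"]
            .value_counts()
            .reindex(["CA_PCI", "CA", "OTHERS"])
            .to_numpy(float)
        )
        expected = np.asarray(cfg.type_probabilities) * counts.sum()
        assert chisquare(counts, expected).pvalue > 0.01

    def test_marginal_mean_and_sd_track_configured_cell(self):
        # CA-with-PCI primary-dose cell; tight bands are the acceptance suite's job
        cfg = GeneratorConfig(
            n_procedures=20_000, seed=3, type_probabilities=(1.0, 0.0, 0.0)
        )
        doses = generate_frame(cfg).query("role == 'PRIMARY'")["epd_dose_usv"]
        assert doses.mean() == pytest.approx(59.33, rel=0.05)
        assert doses.std(ddof=1) == pytest.approx(95.03, rel=0.15)

    def test_invalid_type_probabilities_rejected(self):
        cfg = GeneratorConfig(type_probabilities=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="sum to 1"):
            cfg.validate()

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = GeneratorConfig(n_procedures=17, seed=9)
        cfg.coupling_r2[Role.PRIMARY] = 0.2
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = GeneratorConfig.from_yaml(path)
        assert back == cfg
        assert generate(back) == generate(cfg)


class TestCoupling:
    def test_zero_target_gives_independence(self):
        cfg = GeneratorConfig(n_procedures=50_000, seed=21)
        cfg.coupling_r2 = {Role.PRIMARY: 0.0, Role.ASSISTANT: 0.0}
        frame = generate_frame(cfg)
        sub = frame[frame.role == "PRIMARY"]
        r = np.corrcoef(sub["dap_gycm2"], sub["epd_dose_usv"])[0, 1]
        assert r**2 < 0.01

    def test_infeasible_target_raises_naming_role(self):
        cfg = GeneratorConfig(n_procedures=10, seed=0)
        cfg.coupling_r2 = {Role.PRIMARY: 0.99, Role.ASSISTANT: 0.46}
        with pytest.raises(CouplingError, match="PRIMARY"):
            generate_frame(cfg)

    def test_fitted_r2_near_target_on_average(self):
        # light version of the calibration study (full version in acceptance)
        from cathlar.association import regress_dose_on_dap

        vals = []
        for seed in range(25):
            frame = generate_frame(GeneratorConfig(n_procedures=5_000, seed=seed))
            vals.append(regress_dose_on_dap(frame, Role.ASSISTANT).r_squared)
        assert np.mean(vals) == pytest.approx(0.46, abs=0.05)
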