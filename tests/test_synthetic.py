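import dataclasses

import numpy as np
import pytest
from scipy import stats

from diastolab.cohort import Cohort
from diastolab.synthetic import (
    BASE_VARIABLES,
    CalibrationError,
    DependenceSpec,
    GeneratorConfig,
    MarginalSpec,
    MissingnessSpec,
    _solve_truncnorm,
    _solve_trunclognormal,
    apply_missingness,
    generate_cohort,
    marginal_exceedance,
    nearest_valid_correlation,
    validate_synthetic,
)


class TestCorrelationRepair:
    def test_identity_is_fixed_point(self):
        eye = np.eye(4)
        assert np.array_equal(nearest_valid_correlation(eye), eye)

    def test_valid_matrix_returned_unchanged(self):
        m = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
        assert np.array_equal(nearest_valid_correlation(m), m)

    def test_infeasible_triangle_repaired(self):
        m = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        out = nearest_valid_correlation(m)
        w, v = np.linalg.eigh(m)
        assert np.linalg.eigvalsh(out).min() >= -1e-10
        assert np.allclose(np.diag(out), 1.0)
        assert np.allclose(out, out.T)
        # eigen-clipping oracle: reconstruction before renormalization
        recon = (v * np.clip(w, 0, None)) @ v.T
        d = np.sqrt(np.diag(recon))
        assert np.allclose(out, recon / np.outer(d, d))

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            nearest_valid_correlation(np.array([[1.0, 0.5], [0.4, 1.0]]))

    def test_out_of_range_entry_rejected(self):
        with pytest.raises(ValueError):
            nearest_valid_correlation(np.array([[1.0, 1.5], [1.5, 1.0]]))


class TestMomentMatching:
    @pytest.mark.parametrize(
        "mean,sd,lo,hi", [(11, 5, 2, 40), (30, 14, 8, 100), (6.6, 2.6, 2, 20)]
    )
    def test_truncated_normal_hits_target_moments(self, mean, sd, lo, hi):
        loc, scale = _solve_truncnorm(mean, sd, lo, hi)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        assert m == pytest.approx(mean, rel=1e-8)
        assert np.sqrt(v) == pytest.approx(sd, rel=1e-8)

    def test_truncated_lognormal_hits_target_moments(self):
        # verified against direct quadrature-free large-sample simulation
        mu, sig = _solve_trunclognormal(11.0, 5.0, 2.0, 40.0)
        rng = np.random.default_rng(0)
        z = rng.standard_normal(400_000)
        la, lb = (np.log(2) - mu) / sig, (np.log(40) - mu) / sig
        x = np.exp(stats.truncnorm.ppf(stats.norm.cdf(z), la, lb, loc=mu, scale=sig))
        assert x.mean() == pytest.approx(11.0, rel=0.01)
        assert x.std(ddof=1) == pytest.approx(5.0, rel=0.03)

    def test_wedge_pressure_marginal_matches_printed_prevalence(self):
        # the 11 +/- 5 mmHg marginal should put ~21% of patients at >= 15
        prev = marginal_exceedance(GeneratorConfig().marginal("pcwp"), 15.0)
        assert prev == pytest.approx(0.21, abs=0.02)


class TestGenerateCohort:
    def test_zero_n_gives_empty_cohort(self):
        cohort = generate_cohort(dataclasses.replace(GeneratorConfig(), n=0))
        assert len(cohort) == 0

    def test_same_config_same_cohort(self):
        cfg = dataclasses.replace(GeneratorConfig(), n=100, seed=42)
        a = generate_cohort(cfg).to_dataframe()
        b = generate_cohort(cfg).to_dataframe()
        assert a.equals(b)

    def test_different_seeds_differ(self):
        a = generate_cohort(dataclasses.replace(GeneratorConfig(), n=100, seed=1))
        b = generate_cohort(dataclasses.replace(GeneratorConfig(), n=100, seed=2))
        assert not a.to_dataframe().equals(b.to_dataframe())

    def test_provenance_carries_config_hash(self):
        cfg = dataclasses.replace(GeneratorConfig(), n=5)
        assert cfg.config_hash() in generate_cohort(cfg).provenance

    def test_values_respect_truncation_bounds(self):
        cohort = generate_cohort(dataclasses.replace(GeneratorConfig(), n=5000, seed=3))
        df = cohort.to_dataframe()
        assert df.pcwp_mmhg.between(2, 40).all()
        assert df.lvef_pct.dropna().between(50, 80).all()

    def test_ratios_available_exactly_when_components_are(self):
        cohort = generate_cohort(dataclasses.replace(GeneratorConfig(), n=2000, seed=4))
        for rec in cohort:
            e = rec.echo
            assert (e.e_a_ratio is not None) == (
                e.mitral_e_vel is not None and e.mitral_a_vel is not None
            )
            assert (e.e_over_e_prime_mean is not None) == (
                None not in (e.mitral_e_vel, e.septal_e_prime, e.lateral_e_prime)
            )

    def test_infeasible_dependence_raises_calibration_error(self):
        k = len(BASE_VARIABLES)
        m = np.eye(k)
        m[0, 1] = m[1, 0] = 0.95
        m[0, 2] = m[2, 0] = 0.95
        m[1, 2] = m[2, 1] = -0.95
        dep = DependenceSpec(full_matrix=tuple(tuple(row) for row in m))
        cfg = dataclasses.replace(GeneratorConfig(), n=10, dependence=dep)
        with pytest.raises(CalibrationError, match="repair moved"):
            generate_cohort(cfg)

    def test_sample_correlations_near_latent_targets(self):
        cfg = dataclasses.replace(GeneratorConfig(), n=20_000, seed=12)
        df = generate_cohort(cfg).to_dataframe()
        ok = df.mitral_e_vel_cm_s.notna()
        r_e = np.corrcoef(df.mitral_e_vel_cm_s[ok], df.pcwp_mmhg[ok])[0, 1]
        ok = df.las_r_pct.notna()
        r_las = np.corrcoef(df.las_r_pct[ok], df.pcwp_mmhg[ok])[0, 1]
        assert r_e == pytest.approx(0.50, abs=0.03)
        assert r_las == pytest.approx(-0.37, abs=0.04)


class TestApplyMissingness:
    def test_zero_probability_is_identity(self, complete_cohort_300):
        spec = MissingnessSpec(tuple((v, 0.0) for v in BASE_VARIABLES if v != "pcwp"))
        out = apply_missingness(complete_cohort_300, spec, seed=1)
        assert out.to_dataframe().equals(complete_cohort_300.to_dataframe())

    def test_probability_one_blanks_everything(self, complete_cohort_300):
        spec = MissingnessSpec(tuple((v, 1.0) for v in BASE_VARIABLES if v != "pcwp"))
        out = apply_missingness(complete_cohort_300, spec, seed=1)
        df = out.to_dataframe()
        assert df.tr_peak_vel_m_s.isna().all()
        assert df.las_r_pct.isna().all()

    def test_input_cohort_unmodified(self, complete_cohort_300):
        before = complete_cohort_300.to_dataframe().copy()
        apply_missingness(
            complete_cohort_300, MissingnessSpec((("tr_peak_vel", 0.5),)), seed=1
        )
        assert complete_cohort_300.to_dataframe().equals(before)

    def test_deterministic_for_fixed_seed(self, complete_cohort_300):
        spec = MissingnessSpec((("tr_peak_vel", 0.3), ("las_r", 0.2)))
        a = apply_missingness(complete_cohort_300, spec, seed=9).to_dataframe()
        b = apply_missingness(complete_cohort_300, spec, seed=9).to_dataframe()
        assert a.equals(b)

    def test_binomial_rate_recovery(self):
        cfg = dataclasses.replace(
            GeneratorConfig(), n=20_000, seed=6, missingness=MissingnessSpec(()),
        )
        cohort = generate_cohort(cfg)
        out = apply_missingness(cohort, MissingnessSpec((("tr_peak_vel", 0.11),)), seed=2)
        observed = out.to_dataframe().tr_peak_vel_m_s.notna().mean()
        assert observed == pytest.approx(0.89, abs=0.01)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            MissingnessSpec((("tr_peak_vel", 1.5),))


class TestValidateSynthetic:
    def test_forced_dependence_mismatch_fails_correlation_check(self):
        zeroed = DependenceSpec(
            corr_with_pcwp=tuple((v, 0.0) for v, _ in DependenceSpec().corr_with_pcwp),
            inter_echo=(),
        )
        cfg = dataclasses.replace(GeneratorConfig(), n=5000, seed=7, dependence=zeroed)
        cohort = generate_cohort(cfg)
        target_cfg = dataclasses.replace(cfg, dependence=DependenceSpec())
        report = validate_synthetic(cohort, target_cfg)
        failing = {c.name for c in report.checks if not c.passed}
        assert "corr[las_r,pcwp]" in failing
        assert not report.passed

    def test_empty_cohort_flags_insufficient_n(self):
        report = validate_synthetic(Cohort([]), GeneratorConfig())
        assert not report.passed
        assert report.checks[0].note == "insufficient n"

    def test_stratum_contrasts_hold_across_seeds(self):
        # elevated-pressure stratum: higher E, E/A, E/e', LAVi; lower strain
        for seed in range(5):
            cfg = dataclasses.replace(GeneratorConfig(), n=2000, seed=seed)
            df = generate_cohort(cfg).to_dataframe()
            hi = df.pcwp_mmhg >= 15
            for col in ("mitral_e_vel_cm_s", "e_a_ratio", "e_over_e_prime_mean",
                        "la_volume_index_ml_m2"):
                assert df.loc[hi, col].mean() > df.loc[~hi, col].mean()
            assert df.loc[hi, "las_r_pct"].mean() < df.loc[~hi, "las_r_pct"].mean()


class TestConfigSerialization:
    def test_json_round_trip(self):
        cfg = dataclasses.replace(GeneratorConfig(), n=123, seed=9)
        back = GeneratorConfig.from_json(cfg.to_json())
        assert back == cfg
        assert back.config_hash() == cfg.config_hash()

    def test_marginal_validation(self):
        with pytest.raises(ValueError):
            MarginalSpec("x", "normal", 1.0, -1.0, 0.0, 10.0)
        with pytest.raises(ValueError):
            MarginalSpec("x", "weird", 1.0, 1.0, 0.0, 10.0)
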