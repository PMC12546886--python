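import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from emseed.phenotype import (
    DEFAULT_SVI_WEIGHTS,
    EconModel,
    FeatureNormalizer,
    GerminationKinetics,
    SVIWeights,
    VarietyProfile,
    benefit_cost_ratio,
    composite_svi,
    denormalize_feature,
    dose_response,
    effective_dose,
    germination_curve,
    normalize_feature,
    simulate_batch,
    simulate_seed_records,
    vigor_index,
)
from emseed.physics import TreatmentProtocol


@pytest.fixture
def kin():
    return GerminationKinetics(G_max=95.0, k=0.5, t50=5.0)


@pytest.fixture
def profile(mech):
    return VarietyProfile(
        name="test",
        control_germination_pct=80.0,
        control_vigor_index=70.0,
        delta_g_max=12.0,
        delta_vi_max=10.0,
        d_opt=5e-5,
        gamma=1.5,
        f_n=300.0,
        zeta=0.05,
        dispersion=1.0,
    )


class TestGerminationCurve:
    def test_midpoint(self, kin):
        assert germination_curve(kin, 5.0) == pytest.approx(47.5)

    def test_saturation(self, kin):
        t = kin.t50 + 30.0 / kin.k
        assert germination_curve(kin, t) == pytest.approx(95.0, abs=1e-6 * 95)

    def test_point_value(self, kin):
        # 95 / (1 + e^-1)
        assert germination_curve(kin, 7.0) == pytest.approx(95.0 / (1 + math.exp(-1)), rel=1e-12)

    def test_monotone(self, kin):
        t = np.linspace(0, 14, 200)
        assert np.all(np.diff(germination_curve(kin, t)) >= 0)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            GerminationKinetics(G_max=105.0, k=0.5, t50=5.0)
        with pytest.raises(ValueError):
            GerminationKinetics(G_max=90.0, k=-1.0, t50=5.0)


class TestVigorIndex:
    def test_trivials(self):
        assert vigor_index(100.0, 10.0) == pytest.approx(10.0)
        assert vigor_index(0.0, 55.0) == 0.0

    def test_arithmetic(self):
        assert vigor_index(82.4, 9.25) == pytest.approx(7.622, abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            vigor_index(-1.0, 5.0)


class TestCompositeSvi:
    def test_extremes(self):
        w = SVIWeights(weights=(0.5, 0.5), x_min=(0.0, 0.0), x_max=(10.0, 20.0))
        assert composite_svi([10.0, 20.0], w) == pytest.approx(1.0)
        assert composite_svi([0.0, 0.0], w) == pytest.approx(0.0)

    def test_weighted_positions(self):
        w = SVIWeights(weights=(0.5, 0.5), x_min=(0.0, 0.0), x_max=(1.0, 1.0))
        assert composite_svi([1.0, 0.5], w) == pytest.approx(0.75)

    def test_range_error_without_clipping(self):
        w = SVIWeights(weights=(1.0,), x_min=(0.0,), x_max=(1.0,))
        with pytest.raises(ValueError):
            composite_svi([1.5], w, clip=False)
        assert composite_svi([1.5], w, clip=True) == pytest.approx(1.0)


class TestFeatureNormalizer:
    def test_at_mean_gives_bias(self):
        n = FeatureNormalizer(mu=3.0, sigma=2.0, w=1.5, b=0.7)
        assert normalize_feature(3.0, n) == pytest.approx(0.7)

    def test_plain_zscore(self):
        n = FeatureNormalizer(mu=10.0, sigma=4.0)
        assert normalize_feature(18.0, n) == pytest.approx(2.0)

    @given(st.floats(-1e6, 1e6), st.floats(0.1, 100), st.floats(-10, 10), st.floats(0.1, 5), st.floats(-5, 5))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, x, sigma, mu, w, b):
        n = FeatureNormalizer(mu=mu, sigma=sigma, w=w, b=b)
        assert denormalize_feature(normalize_feature(x, n), n) == pytest.approx(x, rel=1e-9, abs=1e-6)


class TestEffectiveDose:
    def test_resonant_equals_energy(self, profile, mech):
        from emseed.physics import total_energy

        p = TreatmentProtocol(3.5, profile.f_n, 180.0, 27.5, 5.0, 50.0)
        res = mech.with_resonance(profile.f_n, profile.zeta)
        assert effective_dose(p, profile, mech) == pytest.approx(
            total_energy(p, res), rel=1e-12
        )

    def test_control_is_zero(self, profile, mech):
        assert effective_dose(None, profile, mech) == 0.0

    def test_increasing_in_duration(self, profile, mech):
        doses = [
            effective_dose(TreatmentProtocol(2.5, 200.0, d, 25.0, 5.0, 50.0), profile, mech)
            for d in np.linspace(30, 300, 12)
        ]
        assert np.all(np.diff(doses) > 0)

    def test_off_resonance_reduces_dose(self, profile, mech):
        on = effective_dose(TreatmentProtocol(2.5, profile.f_n, 120.0, 25.0, 5.0, 50.0), profile, mech)
        off = effective_dose(TreatmentProtocol(2.5, 900.0, 120.0, 25.0, 5.0, 50.0), profile, mech)
        assert off < 0.2 * on


class TestDoseResponse:
    def test_peak_at_d_opt(self, profile):
        dg, dvi = dose_response(profile.d_opt, profile)
        assert dg == pytest.approx(profile.delta_g_max)
        assert dvi == pytest.approx(profile.delta_vi_max)

    def test_zero_dose(self, profile):
        assert dose_response(0.0, profile) == (0.0, 0.0)

    def test_gamma_one_double_dose(self, profile):
        from dataclasses import replace

        p1 = replace(profile, gamma=1.0)
        dg, _ = dose_response(2 * p1.d_opt, p1)
        assert dg == pytest.approx(p1.delta_g_max * 2 * math.exp(-1), rel=1e-12)

    def test_unimodal_single_sign_change(self, profiles):
        for profile in profiles:
            d = np.linspace(1e-9, 10 * profile.d_opt, 5000)
            g = np.array([dose_response(x, profile)[0] for x in d])
            changes = np.sum(np.diff(np.sign(np.diff(g))) != 0)
            assert changes == 1

    def test_negative_dose_rejected(self, profile):
        with pytest.raises(ValueError):
            dose_response(-1.0, profile)


class TestSimulateBatch:
    def test_control_mean_converges(self, mech):
        profile = VarietyProfile(
            name="nodisp",
            control_germination_pct=80.0,
            control_vigor_index=70.0,
            delta_g_max=10.0,
            delta_vi_max=8.0,
            d_opt=5e-5,
            dispersion=0.0,
        )
        out = simulate_batch(profile, None, 4000, 3, 7, mech)
        mean_g = np.mean([o.germination_pct for o in out])
        se = 100 * math.sqrt(0.8 * 0.2 / (3 * 4000))
        assert abs(mean_g - 80.0) < 3 * se

    def test_null_treatment_indistinguishable(self, mech):
        profile = VarietyProfile(
            name="null",
            control_germination_pct=75.0,
            control_vigor_index=65.0,
            delta_g_max=0.0,
            delta_vi_max=0.0,
            d_opt=5e-5,
            dispersion=0.0,
        )
        proto = TreatmentProtocol(3.5, 300.0, 180.0, 27.5, 5.0, 50.0)
        rng = np.random.default_rng(3)
        treated = simulate_seed_records(profile, proto, 100, 3, rng, mech)
        control = simulate_seed_records(profile, None, 100, 3, rng, mech)
        res = stats.ttest_ind(treated["germinated"], control["germinated"])
        assert res.pvalue > 0.01

    def test_determinism(self, profile, mech, mid_protocol):
        a = simulate_batch(profile, mid_protocol, 200, 3, 99, mech)
        b = simulate_batch(profile, mid_protocol, 200, 3, 99, mech)
        assert [o.germination_pct for o in a] == [o.germination_pct for o in b]
        assert [o.vigor_index for o in a] == [o.vigor_index for o in b]

    def test_empty_batch_error(self, profile, mech):
        with pytest.raises(ValueError):
            simulate_batch(profile, None, 0, 3, 1, mech)

    def test_germination_day_ecdf_matches_logistic(self, mech):
        # empirical germination-day distribution follows the truncated
        # logistic CDF (KS distance < 0.05 at n = 5000)
        profile = VarietyProfile(
            name="kinetics",
            control_germination_pct=99.0,
            control_vigor_index=90.0,
            delta_g_max=0.0,
            delta_vi_max=0.0,
            d_opt=5e-5,
            dispersion=0.0,
            k=0.9,
            t50=5.0,
        )
        rng = np.random.default_rng(11)
        recs = simulate_seed_records(profile, None, 5000, 1, rng, mech)
        days = recs.loc[recs["germinated"] == 1, "germination_day"].to_numpy()
        f14 = 1.0 / (1.0 + math.exp(-0.9 * (14.0 - 5.0)))

        def cdf(t):
            return (1.0 / (1.0 + np.exp(-0.9 * (np.asarray(t) - 5.0)))) / f14

        res = stats.ks_1samp(days, cdf)
        assert res.statistic < 0.05

    def test_replicate_dispersion_matches_parameter(self, mech):
        profile = VarietyProfile(
            name="disp",
            control_germination_pct=80.0,
            control_vigor_index=70.0,
            delta_g_max=0.0,
            delta_vi_max=0.0,
            d_opt=5e-5,
            dispersion=2.0,
        )
        rng = np.random.default_rng(5)
        recs = simulate_seed_records(profile, None, 4000, 60, rng, mech)
        rep_means = 100 * recs.groupby("replicate")["germinated"].mean()
        # replicate SD should reflect the configured overdispersion
        assert 1.2 < rep_means.std() < 2.8

    def test_vigor_consistent_with_definition(self, profile, mech):
        out = simulate_batch(profile, None, 1000, 3, 21, mech)
        for o in out:
            assert o.vigor_index == pytest.approx(
                o.germination_pct * o.mean_seedling_length_cm / 100.0, rel=1e-9
            )


class TestBenefitCostRatio:
    def test_equal_flows(self):
        assert benefit_cost_ratio(
            EconModel(benefits=(100.0, 100.0), costs=(100.0, 100.0), discount_rate=0.07)
        ) == pytest.approx(1.0)

    def test_zero_rate(self):
        assert benefit_cost_ratio(
            EconModel(benefits=(300.0,), costs=(100.0,), discount_rate=0.0)
        ) == pytest.approx(3.0)

    def test_discounted_oracle(self):
        # independent spreadsheet-style oracle
        b = [110.0, 121.0]
        c = [100.0, 100.0]
        r = 0.05
        num = sum(bi / (1 + r) ** i for i, bi in enumerate(b, start=1))
        den = sum(ci / (1 + r) ** i for i, ci in enumerate(c, start=1))
        got = benefit_cost_ratio(EconModel(benefits=tuple(b), costs=tuple(c), discount_rate=r))
        assert got == pytest.approx(num / den, rel=1e-12)

    def test_zero_cost_error(self):
        with pytest.raises(ZeroDivisionError):
            benefit_cost_ratio(EconModel(benefits=(1.0,), costs=(0.0,), discount_rate=0.0))


class TestCalibrationProfiles:
    def test_shipped_profiles_valid(self, profiles):
        assert len(profiles) == 3
        for p in profiles:
            assert p.control_germination_pct + p.delta_g_max <= 100.0
            assert p.d_opt > 0

    def test_d_opt_consistent_with_reference_protocol(self, run_config, profiles, mech):
        from emseed.config import reference_protocol

        for p, vc in zip(profiles, run_config.varieties):
            assert effective_dose(reference_protocol(vc), p, mech) == pytest.approx(
                p.d_opt, rel=1e-9
            )
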