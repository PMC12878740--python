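import math

import numpy as np
import pytest

from mgpbpk import (
    ImplantConfig,
    ParameterError,
    PhysiologyParams,
    approx_trajectory,
    default_time_grid,
    min_implants_hyper,
    min_serum_normalized,
    rho_for_target,
    scale_implants,
    sigma_hyp,
    simulate,
    steady_state,
    t_hyp,
    time_scales,
)


class TestTimeScales:
    def test_local_buildup_time_rounds_to_six_days(self, params, screw):
        # Printed as "about 6 days": formula value 6.07, integer precision.
        T1 = time_scales(params, screw).T1
        assert T1 == pytest.approx((1 - 1e-4) * 52.7 * 4 / 34.7, rel=1e-12)
        assert round(T1) == 6

    def test_systemic_buildup_time(self, params, screw):
        assert time_scales(params, screw).TMg == pytest.approx(104, rel=0.01)

    def test_tissue_and_bone_dominate_the_buildup_time(self, params, screw):
        shares = time_scales(params, screw).shares
        serum, rbc, bone, tissue = shares
        assert tissue == pytest.approx(0.74, rel=0.01)
        assert round(100 * bone) == 25  # printed as "about 25%"
        assert math.fsum(shares) == pytest.approx(1.0, abs=1e-12)

    def test_buildup_time_inverse_in_excretion_rate(self, params, screw):
        doubled = params.replace(gamma=2 * params.gamma)
        assert time_scales(doubled, screw).TMg == pytest.approx(
            time_scales(params, screw).TMg / 2, rel=1e-12)


class TestSigmaHyp:
    def test_reference_critical_rate(self, params, screw):
        assert sigma_hyp(params, screw) == pytest.approx(1.41, rel=0.01)

    def test_vanishing_zone_fraction_limit(self, params):
        tiny = ImplantConfig.from_totals(sigma=0.05, VI=1e-9, params=params)
        assert sigma_hyp(params, tiny) == pytest.approx(
            params.phiD * (1.05 / 0.85 - 1), rel=1e-6)

    def test_linear_in_intake_rate(self, params, screw):
        halved = params.replace(phiD=params.phiD / 2)
        assert sigma_hyp(halved, screw) == pytest.approx(
            sigma_hyp(params, screw) / 2, rel=1e-12)


class TestOnsetTime:
    def test_double_critical_rate_gives_ln2_times_buildup(self, params, screw):
        s_hyp = sigma_hyp(params, screw)
        TMg = time_scales(params, screw).TMg
        onset = t_hyp(params, screw, sigma=2 * s_hyp)
        assert onset == pytest.approx(TMg * math.log(2), rel=1e-12)
        assert onset == pytest.approx(72, rel=0.01)

    def test_below_critical_rate_never_reaches_threshold(self, params, screw):
        assert t_hyp(params, screw) is None  # single screw: 0.05 << 1.41
        assert t_hyp(params, screw, sigma=sigma_hyp(params, screw)) is None

    def test_monotone_decreasing_in_release_rate(self, params, screw):
        rates = np.linspace(1.5, 50.0, 40)
        onsets = [t_hyp(params, screw, sigma=s) for s in rates]
        assert all(a > b for a, b in zip(onsets, onsets[1:]))
        assert onsets[-1] < 5  # very large release: onset approaches zero


class TestExponentialApproximation:
    def test_starts_at_homeostasis(self, params, screw):
        traj = approx_trajectory(params, screw, t_grid=np.array([0.0, 1.0]))
        assert np.allclose(traj.normalized[0], 1.0, atol=1e-12)

    def test_one_buildup_time_reaches_632_percent(self, params, screw):
        ts = time_scales(params, screw)
        traj = approx_trajectory(params, screw,
                                 t_grid=np.array([0.0, ts.TMg]))
        gain = screw.sigma / ((1 - screw.xi) * params.phiD)
        assert traj.normalized[1, 0] == pytest.approx(
            1 + (1 - math.exp(-1)) * gain, rel=1e-12)

    @pytest.mark.parametrize("n", [1, 10])
    def test_within_one_percent_of_ode_for_small_zone_fraction(self, params, n):
        implant = scale_implants(0.05, 0.00527, n, params)
        grid = default_time_grid(1095.0)
        ode = simulate(params, implant, t_grid=grid)
        approx = approx_trajectory(params, implant, t_grid=grid)
        for col in (0, 2):  # serum and tissue
            rel = np.abs(approx.normalized[:, col] - ode.normalized[:, col]
                         ) / ode.normalized[:, col]
            assert rel.max() < 0.01

    def test_two_year_serum_within_half_percent(self, params, screw):
        grid = np.array([0.0, 730.0])
        ode = simulate(params, screw, t_grid=grid)
        approx = approx_trajectory(params, screw, t_grid=grid)
        assert approx.normalized[-1, 0] == pytest.approx(
            ode.normalized[-1, 0], rel=5e-3)

    def test_converges_to_steady_state_within_zone_fraction(self, params, screw):
        far = approx_trajectory(params, screw,
                                t_grid=np.array([0.0, 1e6]))
        ss = steady_state(params, screw)
        assert far.normalized[-1, 0] == pytest.approx(ss.Cs, rel=2 * screw.xi)

    def test_large_zone_fraction_warns(self, params):
        big = ImplantConfig.from_totals(sigma=10.0, VI=5.0, params=params)
        with pytest.warns(UserWarning, match="xi"):
            approx_trajectory(params, big, t_grid=np.array([0.0, 1.0]))

    def test_buildup_time_independent_of_release_rate(self, params):
        """The numeric 63.2%-rise time must not move with sigma."""
        rise_times = []
        grid = np.concatenate([[0.0], np.geomspace(0.1, 1095, 600)])
        for sigma in (0.05, 0.5, 1.45):
            implant = ImplantConfig.from_totals(
                sigma=sigma, VI=sigma / 0.05 * 0.00527, params=params)
            traj = simulate(params, implant, t_grid=grid)
            ss = steady_state(params, implant).Cs
            target = 1 + (1 - math.exp(-1)) * (ss - 1)
            rise_times.append(np.interp(target, traj.normalized[:, 0], traj.t))
        TMg = time_scales(params, scale_implants(0.05, 0.00527, 1, params)).TMg
        for t63 in rise_times:
            assert t63 == pytest.approx(TMg, rel=0.05)


class TestMinimumSerum:
    def test_normal_intake_leaves_serum_unchanged(self, params):
        assert min_serum_normalized(params, 1.0) == 1.0

    def test_zero_intake_drop_is_about_eight_percent(self, params):
        level = min_serum_normalized(params, 0.0)
        assert level == pytest.approx(1 - 10.9 / 138, rel=1e-12)
        assert level == pytest.approx(0.92, abs=0.005)
        assert level > 0.76  # stays above the hypomagnesemia band

    def test_out_of_range_intake_rejected(self, params):
        with pytest.raises(ParameterError):
            min_serum_normalized(params, 1.5)


class TestIntakeRecommendation:
    def test_no_release_needs_no_restriction(self, params, inert_implant):
        rec = rho_for_target(params, inert_implant, "homeostasis")
        assert rec.rho == 1.0 and rec.feasible

    def test_twenty_screws_homeostasis_factor(self, params):
        implant = scale_implants(0.05, 0.00527, 20, params)
        rec = rho_for_target(params, implant, "homeostasis")
        assert rec.raw == pytest.approx(1 - 1 / 6, rel=1e-12)

    def test_avoid_hyper_allows_larger_intake(self, params):
        implant = scale_implants(0.05, 0.00527, 20, params)
        avoid = rho_for_target(params, implant, "avoid_hyper")
        keep = rho_for_target(params, implant, "homeostasis")
        assert avoid.raw == pytest.approx(1.05 / 0.85 - 1 / 6, rel=1e-12)
        assert avoid.raw > keep.raw

    def test_overwhelming_release_flagged_infeasible(self, params):
        implant = ImplantConfig.from_totals(
            sigma=2 * params.phiD, VI=0.1, params=params)
        rec = rho_for_target(params, implant, "homeostasis")
        assert rec.raw == pytest.approx(-1.0)
        assert not rec.feasible
        assert rec.rho == 0.0


class TestMinimumImplantCount:
    def test_reference_count_is_29(self, params):
        assert min_implants_hyper(params) == 29

    def test_count_brackets_the_threshold(self, params):
        chyp_star = params.C_hyp / params.C_hom
        below = steady_state(params, scale_implants(0.05, 0.00527, 28, params))
        above = steady_state(params, scale_implants(0.05, 0.00527, 29, params))
        assert below.Cs == pytest.approx(1.2333, abs=1e-4)
        assert above.Cs == pytest.approx(1.2417, abs=1e-4)
        assert below.Cs < chyp_star <= above.Cs

    def test_single_implant_at_critical_rate(self, params):
        # one implant releasing just above the xi->0 critical rate
        critical = params.phiD * (params.C_hyp / params.C_hom - 1)
        assert min_implants_hyper(params, sigma0=1.001 * critical) == 1

    def test_monotone_nonincreasing_in_release_rate(self, params):
        counts = [min_implants_hyper(params, sigma0=s)
                  for s in (0.05, 0.1, 0.5, 1.45)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_nonpositive_rate_rejected(self, params):
        with pytest.raises(ParameterError):
            min_implants_hyper(params, sigma0=0.0)
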