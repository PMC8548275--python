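import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gonad.doublet import (
    DoubletParams,
    bifurcation_along_gonad,
    bifurcation_point,
    delta_P,
    dnu_dt,
    effective_potential,
    find_fixed_points,
    integrate_doublet,
    lambda_basal,
    linear_growth_rate,
)

STABLE = DoubletParams(S=1.0, Pc_minus_Pr=0.5, T=0.5)
UNSTABLE = DoubletParams(S=0.0, Pc_minus_Pr=-0.2, T=1.0)


class TestLambda:
    def test_symmetry_values(self):
        assert lambda_basal(0.0) == 0.0
        assert lambda_basal(1.0) == 1.0
        assert lambda_basal(-1.0) == -1.0

    def test_slope_at_origin_equals_exponent(self):
        for p in (0.5, 2 / 3, 1.0):
            eps = 1e-7
            num = (lambda_basal(eps, p) - lambda_basal(-eps, p)) / (2 * eps)
            assert num == pytest.approx(p, rel=1e-5)

    def test_odd(self):
        nu = np.linspace(-1, 1, 21)
        np.testing.assert_allclose(lambda_basal(-nu), -lambda_basal(nu), atol=1e-14)


class TestDeltaP:
    def test_zero_at_symmetric(self):
        assert delta_P(0.0, STABLE) == 0.0

    def test_odd(self):
        assert delta_P(-0.3, STABLE) == -delta_P(0.3, STABLE)

    def test_direct_arithmetic(self):
        p = DoubletParams(T=1.0, R=10.0)
        assert delta_P(0.5, p) == pytest.approx(0.05)


class TestVectorField:
    def test_symmetric_state_is_fixed_point(self):
        for p in (STABLE, UNSTABLE, DoubletParams(S=-2.0, T=3.0)):
            assert dnu_dt(0.0, p) == 0.0

    def test_balloon_term_alone_destabilises(self):
        p = DoubletParams(S=0.0, Pc_minus_Pr=0.0, T=1.0)
        assert dnu_dt(0.1, p) > 0
        # term-by-term: matches alpha0 * T nu / (8 R A_c) * (1 + 6 nu^2 + nu^4)
        nu = 0.1
        expected = p.alpha0 * p.T * nu / p.R / (8 * p.A_c) * (1 + 6 * nu**2 + nu**4)
        assert dnu_dt(nu, p) == pytest.approx(expected, rel=1e-12)

    def test_large_uptake_stabilises(self):
        p = DoubletParams(S=10.0, Pc_minus_Pr=0.0, T=0.0)
        for nu in (-0.5, -0.1, 0.1, 0.5):
            assert np.sign(dnu_dt(nu, p)) == -np.sign(nu)

    @settings(max_examples=40, deadline=None)
    @given(
        st.floats(-0.99, 0.99),
        st.floats(-5, 5),
        st.floats(-2, 2),
        st.floats(0, 5),
    )
    def test_odd_symmetry(self, nu, S, dP, T):
        p = DoubletParams(S=S, Pc_minus_Pr=dP, T=T)
        assert dnu_dt(-nu, p) == pytest.approx(-float(dnu_dt(nu, p)), rel=1e-9, abs=1e-15)


class TestGrowthRate:
    def test_matches_numerical_derivative(self):
        for p in (STABLE, UNSTABLE, DoubletParams(S=0.3, Pc_minus_Pr=-0.7, T=2.5, R=7.0)):
            h = 1e-6
            num = (dnu_dt(h, p) - dnu_dt(-h, p)) / (2 * h)
            assert linear_growth_rate(p) == pytest.approx(float(num), rel=1e-8)

    def test_stabilisers_give_negative_sigma(self):
        assert linear_growth_rate(DoubletParams(S=1.0, Pc_minus_Pr=0.5, T=0.0)) < 0

    def test_tension_alone_gives_positive_sigma(self):
        assert linear_growth_rate(DoubletParams(S=0.0, Pc_minus_Pr=0.0, T=1.0)) > 0


class TestPotential:
    def test_stable_regime_single_minimum_at_zero(self):
        W = effective_potential(STABLE)
        i0 = np.argmin(np.abs(W["nu"].to_numpy()))
        assert np.argmin(W["W"].to_numpy()) == i0

    def test_unstable_regime_maximum_at_zero_minima_at_edges(self):
        W = effective_potential(UNSTABLE)
        w = W["W"].to_numpy()
        nu = W["nu"].to_numpy()
        i0 = np.argmin(np.abs(nu))
        assert w[i0] >= w.max() - 1e-12
        assert w[0] == w.min() or w[-1] == w.min()

    def test_even_in_nu(self):
        W = effective_potential(UNSTABLE, np.linspace(-1, 1, 41))
        np.testing.assert_allclose(W["W"].to_numpy(), W["W"].to_numpy()[::-1], atol=1e-12)

    def test_gradient_roundtrip_reconstructs_flow(self):
        # central differences of W at +-h recover dnu/dt to 1e-6
        h = 1e-4
        for p in (STABLE, UNSTABLE):
            for nu in (-0.7, -0.2, 0.3, 0.8):
                W = effective_potential(p, np.array([nu - h, nu + h]))
                dW = (W["W"].iloc[1] - W["W"].iloc[0]) / (2 * h)
                assert -dW == pytest.approx(float(dnu_dt(nu, p)), abs=1e-6)

    def test_normalisation_preserves_shape(self):
        W = effective_potential(UNSTABLE)
        ratio = W["W"] / W["W_norm"]
        finite = np.isfinite(ratio)
        assert np.allclose(ratio[finite], ratio[finite].iloc[0])


class TestIntegration:
    def test_symmetric_state_stays_fixed(self):
        traj = integrate_doublet(0.0, UNSTABLE, (0, 1000))
        np.testing.assert_allclose(traj["nu"], 0.0, atol=1e-12)

    def test_unstable_coarsens_to_sign_of_seed(self):
        up = integrate_doublet(1e-3, UNSTABLE, (0, 1e5))
        dn = integrate_doublet(-1e-3, UNSTABLE, (0, 1e5))
        assert up.attrs["coarsened"] and up.attrs["end_state"] > 0.99
        assert dn.attrs["coarsened"] and dn.attrs["end_state"] < -0.99

    def test_stable_returns_to_zero_monotonically(self):
        traj = integrate_doublet(0.2, STABLE, (0, 1e4))
        nu = traj["nu"].to_numpy()
        assert abs(nu[-1]) < 1e-4
        assert (np.diff(nu) <= 1e-9).all()
        assert not traj.attrs["coarsened"]

    def test_trajectory_symmetry(self):
        up = integrate_doublet(0.05, UNSTABLE, (0, 5e4), max_step=100.0)
        dn = integrate_doublet(-0.05, UNSTABLE, (0, 5e4), max_step=100.0)
        t = np.linspace(0, min(up["t"].iloc[-1], dn["t"].iloc[-1]), 50)
        nu_up = np.interp(t, up["t"], up["nu"])
        nu_dn = np.interp(t, dn["t"], dn["nu"])
        np.testing.assert_allclose(nu_up, -nu_dn, atol=1e-6)

    def test_invalid_start(self):
        with pytest.raises(ValueError):
            integrate_doublet(1.5, STABLE, (0, 10))


class TestFixedPoints:
    def test_stable_regime(self):
        fps = find_fixed_points(STABLE)
        assert len(fps) == 1
        assert fps["nu"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert fps["stable"].iloc[0]

    def test_unstable_regime(self):
        fps = find_fixed_points(UNSTABLE)
        nus = fps["nu"].to_numpy()
        assert set(np.round(nus, 6)) == {-1.0, 0.0, 1.0}
        assert not fps.loc[np.isclose(nus, 0.0), "stable"].iloc[0]
        assert fps.loc[np.isclose(nus, 1.0), "stable"].iloc[0]

    def test_bracketing_matches_fine_scan(self, rng):
        # oracle: brute-force sign scan at delta nu = 1e-4
        for _ in range(20):
            p = DoubletParams(
                S=rng.uniform(-2, 2),
                Pc_minus_Pr=rng.uniform(-1, 1),
                T=rng.uniform(0, 3),
                R=rng.uniform(5, 15),
            )
            fps = find_fixed_points(p)
            interior = fps[np.abs(fps["nu"]) < 1.0 - 1e-9]["nu"].to_numpy()
            grid = np.linspace(-1 + 1e-9, 1 - 1e-9, 20001)
            f = dnu_dt(grid, p)
            brute = [float(g) for g in grid[f == 0.0]]
            for i in np.nonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0)[0]:
                brute.append(0.5 * (grid[i] + grid[i + 1]))
            assert len(interior) == len(brute)
            for a, b in zip(np.sort(interior), np.sort(brute)):
                assert a == pytest.approx(b, abs=2e-4)


class TestBifurcationSweep:
    @pytest.fixture(scope="class")
    def solution(self):
        from gonad.hydromodel import ModelParams, solve_steady_state

        x = np.linspace(0, 1, 41)
        s = np.where(x < 0.65, 40 * np.sin(np.pi * x / 0.65),
                     -24 * np.sin(np.pi * (x - 0.65) / 0.35))
        import pandas as pd

        params = ModelParams(alpha=50.0, kappa_r=1.0, gamma_c=1.0, rhoV=np.exp(-1.5 * x))
        return solve_steady_state(pd.DataFrame({"x": x, "S": s}), params)

    def _branches(self, solution):
        s_amp = float(np.abs(solution.profile["S"]).max())
        dp_amp = float(np.abs(solution.profile["Pc"] - solution.profile["Pr"]).max())
        template = DoubletParams(A_c=100.0, alpha0=1.0, T=0.02 * s_amp * 8 * 12.0, R=12.0)
        return bifurcation_along_gonad(solution, template, pressure_scale=s_amp / dp_amp)

    def test_distal_single_stable_branch(self, solution):
        br = self._branches(solution)
        # exclude the distal tip itself, where S(0) = 0 is marginal
        distal = br[(br["x"] > 0.04) & (br["x"] < 0.3)]
        assert (distal.groupby("x")["nu"].count() == 1).all()
        assert distal["stable"].all()
        np.testing.assert_allclose(distal["nu"], 0.0, atol=1e-9)

    def test_proximal_bistable_branches(self, solution):
        br = self._branches(solution)
        prox = br[br["x"] > 0.9]
        for _, grp in prox.groupby("x"):
            nus = np.round(grp["nu"].to_numpy(), 6)
            assert {-1.0, 1.0} <= set(nus)
            assert not grp.loc[np.isclose(grp["nu"], 0.0), "stable"].any()
            assert grp.loc[np.isclose(np.abs(grp["nu"]), 1.0), "stable"].all()

    def test_bifurcation_at_sigma_crossing(self, solution):
        br = self._branches(solution)
        xb = bifurcation_point(br)
        # consistency: the symmetric branch loses stability where sigma
        # crosses zero (same object), and that is near the uptake zero
        per_x = br.drop_duplicates("x")
        last_stable = per_x[per_x["sigma"] < 0]["x"].max()
        first_unstable = per_x[per_x["sigma"] > 0]["x"].min()
        assert last_stable <= xb <= first_unstable
        assert xb == pytest.approx(0.65, abs=0.05)
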