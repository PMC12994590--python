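"""Core ODE model: right-hand side, solver, and analytic limits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mitrapk as mp
from mitrapk.model import InvalidParameterError, system_matrix


def bateman(t, dose, ka, cl, vc):
    """One-compartment oral closed form (ng/mL)."""
    ke = cl / vc
    return 1000.0 * dose * ka / (vc * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))


class TestRhs:
    def test_zero_state_is_equilibrium(self, median_params):
        assert np.all(mp.pk_rhs(np.zeros(5), median_params) == 0.0)

    def test_hand_substitution_oracle(self, median_params):
        """Derivative at state (1,1,1,1,1) agrees with direct arithmetic."""
        p = median_params
        d = mp.pk_rhs(np.ones(5), p)
        expected = np.array(
            [
                -p.ka * 1.0,
                p.ka * 1.0
                - (p.CL_app / p.Vc_app) * 1.0
                - (p.Q_app / p.Vc_app) * 1.0
                + (p.Q_app / p.Vp_app) * 1.0,
                (p.Q_app / p.Vc_app) * 1.0 - (p.Q_app / p.Vp_app) * 1.0,
                p.F_met * (p.CL_app / p.Vc_app) * 1.0
                - (p.CL_met_app / p.Vc_met_app) * 1.0
                - (p.Q_met_app / p.Vc_met_app) * 1.0
                + (p.Q_met_app / p.Vp_met_app) * 1.0,
                (p.Q_met_app / p.Vc_met_app) * 1.0 - (p.Q_met_app / p.Vp_met_app) * 1.0,
            ]
        )
        np.testing.assert_allclose(d, expected, rtol=0, atol=1e-12)

    def test_no_formation_keeps_metabolite_zero(self, median_params):
        p = median_params.replace(F_met=0.0)
        d = mp.pk_rhs(np.array([10.0, 5.0, 2.0, 0.0, 0.0]), p)
        assert d[3] == 0.0 and d[4] == 0.0

    def test_nonfinite_inputs_rejected(self, median_params):
        with pytest.raises(InvalidParameterError):
            mp.pk_rhs(np.array([1.0, np.nan, 0, 0, 0]), median_params)
        with pytest.raises(InvalidParameterError):
            mp.PKParameters(**{**median_params.to_dict(), "CL_app": np.inf})

    def test_parameter_invariants_enforced(self, median_params):
        with pytest.raises(InvalidParameterError):
            median_params.replace(Vc_app=-1.0)
        with pytest.raises(InvalidParameterError):
            median_params.replace(F_met=1.2)


class TestSolveProfile:
    def test_zero_dose_gives_zero_profile(self, median_params, fine_grid):
        prof = mp.solve_profile(median_params, mp.DoseRegimen(0.0), fine_grid)
        assert np.all(prof.conc_parent == 0.0)
        assert np.all(prof.conc_metabolite == 0.0)

    def test_concentration_zero_at_time_zero(self, median_params, fine_grid):
        prof = mp.solve_profile(median_params, mp.DoseRegimen(25.0), fine_grid)
        assert prof.conc_parent[0] == 0.0
        assert prof.conc_metabolite[0] == 0.0
        assert np.all(prof.conc_parent >= 0.0)

    @pytest.mark.parametrize("method", ["exact", "rk45"])
    def test_bateman_limit(self, method, fine_grid):
        """With no peripheral exchange and no formation, the parent profile
        collapses to the one-compartment closed form."""
        p = mp.PKParameters(
            ka=2.0, CL_app=18.0, Vc_app=120.0, Q_app=1e-9, Vp_app=100.0,
            F_met=0.0, CL_met_app=50.0, Vc_met_app=40.0, Q_met_app=5.0,
            Vp_met_app=60.0,
        )
        prof = mp.solve_profile(p, mp.DoseRegimen(25.0), fine_grid, method=method)
        expected = bateman(fine_grid, 25.0, 2.0, 18.0, 120.0)
        np.testing.assert_allclose(prof.conc_parent[1:], expected[1:], rtol=1e-5)

    def test_exact_and_rk45_agree(self, median_params):
        grid = np.arange(0.0, 72.0001, 0.5)
        reg = mp.DoseRegimen(25.0, 24.0, 3)
        a = mp.solve_profile(median_params, reg, grid, method="exact")
        b = mp.solve_profile(median_params, reg, grid, method="rk45")
        np.testing.assert_allclose(a.conc_parent, b.conc_parent, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(
            a.conc_metabolite, b.conc_metabolite, rtol=1e-6, atol=1e-8
        )

    def test_dose_linearity(self, median_params, fine_grid):
        reg1 = mp.DoseRegimen(25.0)
        reg2 = mp.DoseRegimen(50.0)
        p1 = mp.solve_profile(median_params, reg1, fine_grid)
        p2 = mp.solve_profile(median_params, reg2, fine_grid)
        np.testing.assert_allclose(2 * p1.conc_parent, p2.conc_parent, rtol=1e-9)
        np.testing.assert_allclose(
            2 * p1.conc_metabolite, p2.conc_metabolite, rtol=1e-9
        )

    def test_multidose_superposition(self, median_params):
        """Three repeated doses equal the sum of three shifted single doses."""
        grid = np.arange(0.0, 96.0001, 0.5)
        multi = mp.solve_profile(
            median_params, mp.DoseRegimen(25.0, 24.0, 3), grid
        )
        single = mp.solve_profile(median_params, mp.DoseRegimen(25.0), grid)
        total = np.zeros_like(grid)
        for k in range(3):
            shifted = np.where(
                grid >= 24.0 * k,
                np.interp(grid - 24.0 * k, grid, single.conc_parent),
                0.0,
            )
            total += shifted
        np.testing.assert_allclose(
            multi.conc_parent, total, rtol=1e-6, atol=1e-9
        )

    def test_parent_mass_nonincreasing_after_last_dose(self, median_params):
        grid = np.arange(0.0, 48.0001, 0.5)
        prof = mp.solve_profile(
            median_params, mp.DoseRegimen(25.0), grid, keep_amounts=True
        )
        parent_total = prof.amounts[:, :3].sum(axis=1)
        assert np.all(np.diff(parent_total) <= 1e-9)

    def test_grid_validation(self, median_params):
        with pytest.raises(ValueError):
            mp.solve_profile(median_params, mp.DoseRegimen(25.0), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            mp.solve_profile(median_params, mp.DoseRegimen(25.0), np.array([-1.0, 2.0]))

    @given(scale=st.floats(0.3, 1.5))
    def test_metabolite_scaling_ridge(self, scale):
        """Jointly rescaling all metabolite-side parameters (keeping
        F_met <= 1) leaves both concentration profiles unchanged — the
        model's structural non-identifiability."""
        base = mp.REFERENCE_MEDIAN_PARAMS
        scaled = base.replace(
            F_met=base.F_met * scale,
            CL_met_app=base.CL_met_app * scale,
            Vc_met_app=base.Vc_met_app * scale,
            Q_met_app=base.Q_met_app * scale,
            Vp_met_app=base.Vp_met_app * scale,
        )
        grid = np.array([0.5, 1.0, 2.0, 6.0, 24.0, 48.0])
        a = mp.solve_profile(base, mp.DoseRegimen(25.0), grid)
        b = mp.solve_profile(scaled, mp.DoseRegimen(25.0), grid)
        np.testing.assert_allclose(a.conc_parent, b.conc_parent, rtol=1e-9)
        np.testing.assert_allclose(a.conc_metabolite, b.conc_metabolite, rtol=1e-9)


class TestMassBalance:
    def test_exposure_identity_arithmetic(self, median_params):
        assert mp.metabolite_exposure_identity(median_params.replace(F_met=0.0), 25.0) == 0.0
        p = median_params.replace(F_met=0.65, CL_met_app=106.29)
        expected = 25e6 * 0.65 / 106290.0
        assert mp.metabolite_exposure_identity(p, 25.0) == pytest.approx(expected)

    def test_numeric_auc_converges_to_identity(self, median_params):
        grid = np.arange(0.0, 2000.0001, 0.5)
        prof = mp.solve_profile(median_params, mp.DoseRegimen(25.0), grid)
        auc = np.trapezoid(prof.conc_metabolite, grid)
        assert auc == pytest.approx(
            mp.metabolite_exposure_identity(median_params, 25.0), rel=1e-3
        )

    def test_parent_elimination_accounts_for_dose(self, median_params):
        """Dose minus remaining parent amounts equals the integral of the
        elimination flux (CL/Vc * CENTER)."""
        grid = np.arange(0.0, 500.0001, 0.02)
        prof = mp.solve_profile(
            median_params, mp.DoseRegimen(25.0), grid, keep_amounts=True
        )
        eliminated = np.trapezoid(
            (median_params.CL_app / median_params.Vc_app) * prof.amounts[:, 1], grid
        )
        remaining = prof.amounts[-1, :3].sum()
        assert 25.0 - remaining == pytest.approx(eliminated, rel=1e-4)
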