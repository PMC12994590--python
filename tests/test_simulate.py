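"""Repeated-dose simulation, metric extraction, and summaries."""

import numpy as np
import pandas as pd
import pytest

import mitrapk as mp
from mitrapk.bayes import FULL_PARAM_NAMES
from mitrapk.model import SimulatedProfile


@pytest.fixture(scope="module")
def posterior_like():
    """Synthetic posterior container with mild log-normal scatter."""
    rng = np.random.default_rng(12)
    base = np.concatenate([mp.REFERENCE_MEDIAN_PARAMS.to_array(), [0.14, 0.11]])
    vals = base * np.exp(0.05 * rng.standard_normal((4, 250, len(base))))
    f = mp.PARAM_NAMES.index("F_met")
    vals[:, :, f] = np.clip(vals[:, :, f], None, 1.0)
    return mp.PosteriorDraws(values=vals)


@pytest.fixture(scope="module")
def regimen():
    return mp.DoseRegimen(dose=25.0, interval=24.0, n_doses=7)


class TestSampling:
    def test_seed_reproducibility(self, posterior_like):
        a = mp.sample_parameter_sets(posterior_like, n=50, seed=5)
        b = mp.sample_parameter_sets(posterior_like, n=50, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_without_replacement_distinct(self, posterior_like):
        sets = mp.sample_parameter_sets(posterior_like, n=200, seed=0)
        assert len(sets[["chain", "draw"]].drop_duplicates()) == 200

    def test_full_take_is_permutation(self, posterior_like):
        total = posterior_like.n_chains * posterior_like.n_draws
        sets = mp.sample_parameter_sets(posterior_like, n=total, seed=1)
        assert len(sets[["chain", "draw"]].drop_duplicates()) == total

    def test_oversampling_without_replacement_rejected(self, posterior_like):
        total = posterior_like.n_chains * posterior_like.n_draws
        with pytest.raises(ValueError):
            mp.sample_parameter_sets(posterior_like, n=total + 1, seed=0)

    def test_summary_marginals_match_reference_medians(self):
        sets = mp.sample_sets_from_summary(n=4000, seed=2)
        assert (sets["F_met"] <= 1.0).all()
        for name in ("CL_app", "Vc_app"):
            med = float(sets[name].median())
            ref = float(mp.REFERENCE_POSTERIOR.loc[name, "median"])
            assert med == pytest.approx(ref, rel=0.05)


class TestExtractMetrics:
    def test_constant_profile(self):
        times = np.arange(0.0, 24.0001, 0.5)
        prof = SimulatedProfile(times, np.full_like(times, 7.0), np.full_like(times, 7.0))
        m = mp.extract_metrics(prof, mp.DoseRegimen(25.0, 24.0, 1))
        row = m.per_dose[m.per_dose["analyte"] == "parent"].iloc[0]
        assert row["cmax"] == 7.0
        assert row["cmin"] == 7.0
        assert row["auc"] == pytest.approx(7.0 * 24.0)

    def test_linear_ramp_auc_exact(self):
        times = np.arange(0.0, 24.0001, 0.5)
        ramp = 10.0 * times / 24.0
        prof = SimulatedProfile(times, ramp, ramp)
        m = mp.extract_metrics(prof, mp.DoseRegimen(25.0, 24.0, 1))
        row = m.per_dose[m.per_dose["analyte"] == "parent"].iloc[0]
        assert row["auc"] == pytest.approx(10.0 * 24.0 / 2.0)
        assert row["tmax"] == 23.5  # last point inside the half-open interval

    def test_first_dose_trough_is_zero(self, median_params, regimen):
        grid = np.arange(0.0, 200.0001, 0.5)
        prof = mp.solve_profile(median_params, regimen, grid)
        m = mp.extract_metrics(prof, regimen)
        parent = m.per_dose[m.per_dose["analyte"] == "parent"]
        assert parent.iloc[0]["cmin"] == 0.0
        # later troughs are the pre-dose concentrations, strictly rising
        cmins = parent["cmin"].to_numpy()
        assert np.all(np.diff(cmins) > 0)

    def test_tmax_invariant_to_dose(self, median_params):
        grid = np.arange(0.0, 48.0001, 0.5)
        m1 = mp.extract_metrics(
            mp.solve_profile(median_params, mp.DoseRegimen(25.0), grid),
            mp.DoseRegimen(25.0),
        )
        m2 = mp.extract_metrics(
            mp.solve_profile(median_params, mp.DoseRegimen(250.0), grid),
            mp.DoseRegimen(250.0),
        )
        pd.testing.assert_series_equal(m1.per_dose["tmax"], m2.per_dose["tmax"])

    def test_misaligned_grid_rejected(self, median_params, regimen):
        grid = np.arange(0.0, 200.0001, 0.7)
        prof = mp.solve_profile(median_params, regimen, grid)
        with pytest.raises(ValueError, match="grid"):
            mp.extract_metrics(prof, regimen)

    def test_grid_refinement_stable_auc(self, median_params, regimen):
        coarse = np.arange(0.0, 168.0001, 0.25)
        fine = np.arange(0.0, 168.0001, 0.125)
        mc = mp.extract_metrics(mp.solve_profile(median_params, regimen, coarse), regimen)
        mf = mp.extract_metrics(mp.solve_profile(median_params, regimen, fine), regimen)
        ac = mc.per_dose.set_index(["dose_event", "analyte"])["auc"]
        af = mf.per_dose.set_index(["dose_event", "analyte"])["auc"]
        assert np.all(np.abs(ac / af - 1.0) < 0.005)


class TestSteadyState:
    def test_parent_auc_monotone_to_clearance_limit(self, median_params, regimen):
        grid = np.arange(0.0, 200.0001, 0.5)
        prof = mp.solve_profile(median_params, regimen, grid)
        m = mp.extract_metrics(prof, regimen)
        parent = m.per_dose[m.per_dose["analyte"] == "parent"]
        aucs = parent["auc"].to_numpy()
        assert np.all(np.diff(aucs) > 0)
        limit = 25.0 * 1e6 / (median_params.CL_app * 1000.0)
        assert aucs[-1] == pytest.approx(limit, rel=0.05)

    def test_metabolite_auc_approaches_exposure_identity(self, median_params, regimen):
        grid = np.arange(0.0, 200.0001, 0.5)
        prof = mp.solve_profile(median_params, regimen, grid)
        m = mp.extract_metrics(prof, regimen)
        met_auc = m.per_dose[m.per_dose["analyte"] == "metabolite"]["auc"].to_numpy()[-1]
        assert met_auc == pytest.approx(
            mp.metabolite_exposure_identity(median_params, 25.0), rel=0.05
        )

    def test_accumulation_factor_at_least_one(self, median_params, regimen):
        grid = np.arange(0.0, 200.0001, 0.5)
        prof = mp.solve_profile(median_params, regimen, grid)
        m = mp.extract_metrics(prof, regimen)
        assert m.accumulation_factor["parent"] >= 1.0
        assert m.accumulation_factor["metabolite"] >= 1.0


class TestEnsemble:
    def test_single_set_bands_coincide_with_profile(self, median_params, regimen):
        sets = pd.DataFrame([median_params.to_dict()])
        ens = mp.simulate_ensemble(sets, regimen)
        parent = ens.bands[ens.bands["analyte"] == "parent"]
        np.testing.assert_allclose(parent["median"], parent["lower"], rtol=1e-12)
        np.testing.assert_allclose(parent["median"], parent["upper"], rtol=1e-12)

    def test_median_within_min_max(self, posterior_like, regimen):
        sets = mp.sample_parameter_sets(posterior_like, n=25, seed=3)
        ens = mp.simulate_ensemble(sets, regimen)
        lo = ens.profiles.min(axis=0)
        hi = ens.profiles.max(axis=0)
        med = np.median(ens.profiles, axis=0)
        assert np.all(med >= lo - 1e-12) and np.all(med <= hi + 1e-12)

    def test_one_draw_summary_collapses(self, median_params, regimen):
        sets = pd.DataFrame([median_params.to_dict()])
        ens = mp.simulate_ensemble(sets, regimen)
        summ = mp.summarize_metrics(ens)
        np.testing.assert_allclose(summ["median"], summ["min"], rtol=1e-12)
        np.testing.assert_allclose(summ["median"], summ["max"], rtol=1e-12)

    def test_metrics_increase_toward_plateau(self, posterior_like, regimen):
        sets = mp.sample_parameter_sets(posterior_like, n=40, seed=4)
        ens = mp.simulate_ensemble(sets, regimen)
        summ = mp.summarize_metrics(ens)
        for analyte in ("parent", "metabolite"):
            for metric in ("cmax", "auc"):
                med = (
                    summ[(summ["analyte"] == analyte) & (summ["metric"] == metric)]
                    .sort_values("dose_event")["median"]
                    .to_numpy()
                )
                assert np.all(np.diff(med) > 0)
                # plateau: later gains much smaller than the first one
                assert (med[-1] - med[-2]) < 0.25 * (med[1] - med[0])
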