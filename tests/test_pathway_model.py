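"""Kinetic branch-point model and the two regression models."""

import numpy as np
import pytest

from hopflow import (
    GENES,
    KineticParameterSet,
    NoSteadyStateError,
    ProteinProfile,
    StrainDataset,
    MonoterpeneMeasurement,
    loglinear_fit,
    predict_titers,
    predict_titers_batch,
    smooth_regressor_fit,
    steady_state_gpp,
)
from hopflow.pathway_model import FitError, _consumption, _enzymes, _supply


def profile(h=1.0, f=1.0, l=1.0, g=1.0, sid="s"):
    return ProteinProfile(sid, {"tHMGR": h, "FPPS_star": f, "LIS": l, "GES": g})


def random_params(rng) -> KineticParameterSet:
    """Random valid parameter draw spanning the nominal order-of-magnitude ranges."""
    rho_wt = rng.uniform(0.01, 0.2)
    return KineticParameterSet(
        v_H=rng.uniform(1, 50),
        rho_wt=rho_wt,
        rho_star=rng.uniform(rho_wt + 0.05, 0.9),
        kcat_L=rng.uniform(1, 50),
        kcat_G=rng.uniform(1, 50),
        kcat_F2=rng.uniform(1, 20),
        K_L=rng.uniform(10, 100),
        K_G=rng.uniform(10, 100),
        K_F=rng.uniform(10, 100),
        k_d=rng.uniform(0.01, 1.0),
        alpha_H=rng.uniform(0.2, 5),
        alpha_F=rng.uniform(0.2, 5),
        alpha_L=rng.uniform(0.2, 5),
        alpha_G=rng.uniform(0.2, 5),
        beta=rng.uniform(0, 3),
        yield_T=rng.uniform(0.1, 5),
    )


def grid_bisect_oracle(params, prof, n_grid=2000, n_bisect=200):
    """Independent root finder: scan a dense G grid for the sign change of
    supply − consumption, then bisect the bracketing cell."""
    E_H, E_F, E_L, E_G = _enzymes(params, prof)
    supply = _supply(params, E_H, E_F)
    if supply == 0:
        return 0.0
    hi = supply / params.k_d + (
        params.kcat_L * E_L + params.kcat_G * E_G + params.kcat_F2 * (1 + params.beta) * E_F
    ) / params.k_d
    f = lambda G: supply - _consumption(params, E_F, E_L, E_G, G)
    grid = np.linspace(0.0, hi, n_grid)
    vals = np.array([f(g) for g in grid])
    idx = int(np.flatnonzero(vals >= 0)[-1])  # f decreasing: last non-negative cell
    lo, up = grid[idx], grid[min(idx + 1, n_grid - 1)]
    for _ in range(n_bisect):
        mid = 0.5 * (lo + up)
        if f(mid) >= 0:
            lo = mid
        else:
            up = mid
    return 0.5 * (lo + up)


class TestSteadyState:
    def test_zero_supply_gives_zero_everything(self):
        params = KineticParameterSet()
        pred = predict_titers(params, profile(h=0.0))
        assert pred.gpp_ss == 0.0
        assert pred.linalool == 0.0 and pred.geraniol == 0.0

    def test_leak_only_closed_form(self):
        """With all enzymatic consumption off, G* = v_H·E_H·θ / k_d exactly."""
        params = KineticParameterSet(kcat_L=0.0, kcat_G=0.0, kcat_F2=0.0, k_d=0.2)
        prof = profile(h=2.0, f=1.5)
        theta = (params.rho_star + params.rho_wt * params.beta) / (1 + params.beta)
        expected = params.v_H * params.alpha_H * 2.0 * theta / params.k_d
        assert steady_state_gpp(params, prof) == pytest.approx(expected, rel=1e-10)

    def test_no_steady_state_when_nothing_consumes(self):
        params = KineticParameterSet(kcat_L=0.0, kcat_G=0.0, kcat_F2=0.0, k_d=0.0)
        with pytest.raises(NoSteadyStateError):
            steady_state_gpp(params, profile())

    def test_agrees_with_grid_bisection_oracle(self):
        """100 seeded random parameter/profile draws vs an independent dense-grid
        + bisection root finder, to 1e-6 relative."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            params = random_params(rng)
            prof = profile(*rng.uniform(0.05, 2.0, size=4))
            got = steady_state_gpp(params, prof)
            want = grid_bisect_oracle(params, prof)
            assert got == pytest.approx(want, rel=1e-6, abs=1e-12)

    def test_flux_balance_at_root(self):
        """|supply − consumption| / supply <= 1e-8 at the returned root."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            params = random_params(rng)
            prof = profile(*rng.uniform(0.05, 2.0, size=4))
            E_H, E_F, E_L, E_G = _enzymes(params, prof)
            supply = _supply(params, E_H, E_F)
            G = steady_state_gpp(params, prof)
            assert abs(supply - _consumption(params, E_F, E_L, E_G, G)) <= 1e-8 * supply

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(3)
        params = random_params(rng)
        A = rng.uniform(0.05, 2.0, size=(20, 4))
        lin, ger = predict_titers_batch(params, A)
        for i, row in enumerate(A):
            pred = predict_titers(params, ProteinProfile("x", dict(zip(GENES, row))))
            assert lin[i] == pytest.approx(pred.linalool, rel=1e-9)
            assert ger[i] == pytest.approx(pred.geraniol, rel=1e-9)


class TestMechanism:
    def test_synthase_absent_means_no_product(self):
        params = KineticParameterSet()
        assert predict_titers(params, profile(l=0.0)).linalool == 0.0

    def test_symmetric_branches_give_equal_titers(self):
        params = KineticParameterSet(kcat_L=15.0, kcat_G=15.0, K_L=40.0, K_G=40.0)
        pred = predict_titers(params, profile(l=0.8, g=0.8))
        assert pred.linalool == pred.geraniol

    def test_doubling_ges_raises_geraniol_fraction(self):
        """Across 100 random draws, doubling GES abundance strictly raises the
        geraniol share of total monoterpenes (the branch competition the
        GES/LIS-ratio correlation reflects)."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            params = random_params(rng)
            h, f, l, g = rng.uniform(0.05, 2.0, size=4)
            p1 = predict_titers(params, profile(h, f, l, g))
            p2 = predict_titers(params, profile(h, f, l, 2 * g))
            frac1 = p1.geraniol / (p1.linalool + p1.geraniol)
            frac2 = p2.geraniol / (p2.linalool + p2.geraniol)
            assert frac2 > frac1

    def test_total_production_monotone_in_thmgr(self):
        params = KineticParameterSet()
        totals = []
        for h in np.linspace(0.05, 2.0, 8):
            pred = predict_titers(params, profile(h=h))
            totals.append(pred.linalool + pred.geraniol)
        assert np.all(np.diff(totals) > 0)

    def test_total_production_monotone_in_rho_star_at_beta_zero(self):
        totals = []
        for rho in np.linspace(0.1, 0.9, 6):
            params = KineticParameterSet(rho_star=rho, beta=0.0)
            pred = predict_titers(params, profile())
            totals.append(pred.linalool + pred.geraniol)
        assert np.all(np.diff(totals) > 0)

    def test_alpha_rescaling_degeneracy(self):
        """Scaling all alphas by c while dividing v_H and the kcats by c leaves
        predictions unchanged (relative→absolute conversion is unidentifiable)."""
        c = 3.7
        base = KineticParameterSet()
        scaled = base.with_updates(
            alpha_H=base.alpha_H * c,
            alpha_F=base.alpha_F * c,
            alpha_L=base.alpha_L * c,
            alpha_G=base.alpha_G * c,
            v_H=base.v_H / c,
            kcat_L=base.kcat_L / c,
            kcat_G=base.kcat_G / c,
            kcat_F2=base.kcat_F2 / c,
        )
        prof = profile(0.7, 1.3, 0.4, 0.9)
        p1, p2 = predict_titers(base, prof), predict_titers(scaled, prof)
        assert p2.linalool == pytest.approx(p1.linalool, rel=1e-9)
        assert p2.geraniol == pytest.approx(p1.geraniol, rel=1e-9)

    def test_rho_star_must_exceed_rho_wt(self):
        with pytest.raises(ValueError):
            KineticParameterSet(rho_star=0.05, rho_wt=0.5)


def _loglinear_dataset(coef, n=10, seed=0, floor=0.01):
    """Dataset whose titers follow an exact log-linear law in the abundances."""
    rng = np.random.default_rng(seed)
    profiles, titers = [], []
    for i in range(n):
        # keep abundances near 1 so every titer stays above the log floor
        a = rng.uniform(0.5, 2.0, size=4)
        x = np.concatenate([[1.0], np.log10(a + 1e-3)])
        logt = coef @ x
        t = np.maximum(10.0 ** logt - floor, 0.0)
        profiles.append(ProteinProfile(f"s{i}", dict(zip(GENES, a))))
        titers.append(MonoterpeneMeasurement(f"s{i}", 1, float(t[0]), float(t[1])))
    return StrainDataset(profiles=profiles, titers=titers)


class TestLogLinear:
    coef = np.array([[-0.5, 0.8, 0.3, 0.9, -0.2], [-0.3, 0.6, 0.4, -0.3, 1.1]])

    def test_exact_family_recovery(self):
        ds = _loglinear_dataset(self.coef, n=12, seed=1)
        model = loglinear_fit(ds)
        assert np.allclose(model.coef, self.coef, atol=1e-8)

    def test_constant_titers_give_zero_slopes(self):
        rng = np.random.default_rng(2)
        profiles = [
            ProteinProfile(f"s{i}", dict(zip(GENES, rng.uniform(0.1, 2, 4)))) for i in range(8)
        ]
        titers = [MonoterpeneMeasurement(f"s{i}", 1, 0.5, 0.5) for i in range(8)]
        model = loglinear_fit(StrainDataset(profiles=profiles, titers=titers))
        assert np.allclose(model.coef[:, 1:], 0.0, atol=1e-10)
        assert np.allclose(model.coef[:, 0], np.log10(0.5 + model.titer_floor), atol=1e-10)

    def test_saturated_noiseless_fit_interpolates(self):
        ds = _loglinear_dataset(self.coef, n=5, seed=3)  # n == p
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = loglinear_fit(ds)
        ids, rows = ds.abundance_matrix()
        lin, ger = model.predict(np.array(rows))
        means = ds.mean_titers()
        obs = np.array([means[s] for s in ids])
        assert np.allclose(lin, obs[:, 0], rtol=1e-6, atol=1e-10)
        assert np.allclose(ger, obs[:, 1], rtol=1e-6, atol=1e-10)

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(4)
        profiles, titers = [], []
        for i in range(9):
            h = rng.uniform(0.1, 2.0)
            # LIS locked to tHMGR -> collinear in log space
            a = {"tHMGR": h, "FPPS_star": rng.uniform(0.1, 2.0), "LIS": h, "GES": rng.uniform(0.1, 2.0)}
            profiles.append(ProteinProfile(f"s{i}", a))
            titers.append(MonoterpeneMeasurement(f"s{i}", 1, 0.1 * (i + 1), 0.1))
        with pytest.raises(FitError, match="tHMGR|LIS"):
            loglinear_fit(StrainDataset(profiles=profiles, titers=titers))


class TestSmoothRegressor:
    def test_interpolates_training_points(self, truth, noiseless_dataset):
        model = smooth_regressor_fit(noiseless_dataset, kernel_scale=1.0)
        ids, rows = noiseless_dataset.abundance_matrix()
        lin, ger = model.predict(np.array(rows))
        means = noiseless_dataset.mean_titers()
        obs = np.array([means[s] for s in ids])
        assert np.allclose(lin, obs[:, 0], rtol=1e-4, atol=1e-8)
        assert np.allclose(ger, obs[:, 1], rtol=1e-4, atol=1e-8)

    def test_far_from_data_reverts_to_prior_mean(self, noiseless_dataset):
        model = smooth_regressor_fit(noiseless_dataset, kernel_scale=0.5)
        far = np.array([[1e6, 1e6, 1e6, 1e6]])
        lin, ger = model.predict(far)
        means = noiseless_dataset.mean_titers()
        obs = np.array(list(means.values()))
        prior_lin = 10 ** np.mean(np.log10(obs[:, 0] + model.titer_floor)) - model.titer_floor
        assert lin[0] == pytest.approx(prior_lin, rel=1e-6)

    def test_nonpositive_kernel_scale_rejected(self, noiseless_dataset):
        with pytest.raises(ValueError):
            smooth_regressor_fit(noiseless_dataset, kernel_scale=0.0)

    def test_beats_mean_predictor_out_of_sample(self, truth):
        """Held-out RMSE of the smooth regressor on kinetic-model data is no
        worse than predicting the training mean."""
        from hopflow import NoiseModel, generate_dataset, initial_designs
        from hopflow.fitting import loo_cv

        designs = initial_designs(truth.catalog, n=14, seed=9)
        ds = generate_dataset(designs, truth, NoiseModel.noiseless(), replicates=1, seed=9)
        res = loo_cv(ds, model_kind="smooth", kernel_scale=1.0)
        obs = np.array(list(ds.mean_titers().values()))
        rmse_mean = np.sqrt(np.mean((obs[:, 0] - obs[:, 0].mean()) ** 2))
        assert res.rmse_linalool <= rmse_mean
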