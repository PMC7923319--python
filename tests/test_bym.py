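"""BYM disease-mapping model: adjacency, CAR, sampler, DIC, summaries."""

import copy
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from afmap.bym import (
    McmcSettings,
    ModelSpec,
    build_adjacency,
    car_full_conditional,
    car_prior_logratio,
    dic,
    fit_bym,
    fit_iid_only,
    posterior_predictive_totals,
    residual_irr_table,
    sensitivity_analysis,
    spatial_fraction,
)
from afmap.geography import Geography, generate_lattice_geography
from afmap.synthetic import SimulationParams, simulate_region_counts

FAST = McmcSettings(n_iter=1500, n_burnin=750, thin=2, n_chains=2, seed=0)


def region_exposures(geography, py=2000.0, with_sex=True):
    rows = []
    for rid in geography.region_ids:
        if with_sex:
            for sex in ("female", "male"):
                rows.append({"region_id": rid, "sex": sex, "person_years": py})
        else:
            rows.append({"region_id": rid, "person_years": py})
    return pd.DataFrame(rows)


class TestAdjacency:
    def test_square_lattice_degrees(self):
        g = generate_lattice_geography(2, 2, 10.0)
        adj = build_adjacency(g)
        assert (adj.degrees == 2).all()

    def test_island_with_extra_edge(self):
        g = Geography(
            ("a", "b", "c"),
            {"a": (0, 0), "b": (1, 0), "c": (9, 9)},
            adjacency={("a", "b")},
            extra_edges={("b", "c")},
        )
        adj = build_adjacency(g)
        assert adj.degrees[2] == 1
        assert g.is_connected()

    def test_isolated_region_rejected(self):
        g = Geography(
            ("a", "b", "c"),
            {"a": (0, 0), "b": (1, 0), "c": (9, 9)},
            adjacency={("a", "b")},
        )
        with pytest.raises(ValueError):
            build_adjacency(g)

    def test_matrix_symmetric_on_random_lattices(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            rows, cols = rng.integers(2, 7, 2)
            adj = build_adjacency(generate_lattice_geography(int(rows), int(cols), 5.0))
            m = adj.matrix()
            assert np.array_equal(m, m.T)
            assert np.trace(m) == 0

    def test_color_classes_are_independent_sets(self, lattice98):
        adj = build_adjacency(lattice98)
        edge_set = {tuple(e) for e in adj.edges}
        for block in adj.color_classes():
            s = set(block.tolist())
            for i, j in edge_set:
                assert not (i in s and j in s)
        assert sum(len(b) for b in adj.color_classes()) == adj.n


class TestCarConditional:
    def test_closed_form_mean_and_precision(self, lattice98):
        adj = build_adjacency(lattice98)
        rng = np.random.default_rng(1)
        v = rng.normal(size=adj.n)
        tau = 7.5
        for i in (0, 13, 97):
            mean, prec = car_full_conditional(v, i, adj, tau)
            nb = adj.neighbors[i]
            assert mean == pytest.approx(v[nb].mean())
            assert prec == pytest.approx(tau * len(nb))

    def test_sampler_logratio_matches_full_conditional_density(self, lattice98):
        """The Metropolis prior term equals the log-density ratio of the
        closed-form N(neighbour mean, 1/(tau*m)) full conditional."""
        adj = build_adjacency(lattice98)
        rng = np.random.default_rng(2)
        v = rng.normal(size=adj.n)
        tau = 3.0
        for i in (5, 50, 90):
            mean, prec = car_full_conditional(v, i, adj, tau)
            cur, prop = v[i], v[i] + rng.normal()
            direct = stats.norm.logpdf(prop, mean, 1 / math.sqrt(prec)) - stats.norm.logpdf(
                cur, mean, 1 / math.sqrt(prec)
            )
            nb_sum = v[adj.neighbors[i]].sum()
            sampler = car_prior_logratio(prop, cur, nb_sum, len(adj.neighbors[i]), tau)
            assert sampler == pytest.approx(direct, abs=1e-10)


class TestFitBym:
    def test_deterministic_under_seed(self, lattice98, sex_exposures):
        sim = simulate_region_counts(SimulationParams(seed=5), lattice98, sex_exposures)
        spec = ModelSpec(geography=lattice98, fixed_effects=("sex",))
        mc = McmcSettings(n_iter=400, n_burnin=200, thin=2, n_chains=2, seed=3)
        a = fit_bym(sim.cells, spec, mc)
        b = fit_bym(sim.cells, spec, mc)
        for key in ("beta", "u", "v", "tau_u", "tau_v"):
            assert np.array_equal(a.draws[key], b.draws[key])

    def test_sum_to_zero_every_saved_draw(self, lattice98, sex_exposures):
        sim = simulate_region_counts(SimulationParams(seed=6), lattice98, sex_exposures)
        fit = fit_bym(sim.cells, ModelSpec(geography=lattice98, fixed_effects=("sex",)), FAST)
        assert np.abs(fit.draws["v"].sum(axis=1)).max() < 1e-8

    def test_null_recovery_flags_few_regions(self, lattice98, sex_exposures):
        """Data with u = v = 0: residual IRR intervals cover 1 in nearly all
        regions (nominal 5% false-flag rate)."""
        params = SimulationParams(seed=7, tau_u=1e9, tau_v=1e9)
        sim = simulate_region_counts(params, lattice98, sex_exposures)
        fit = fit_bym(sim.cells, ModelSpec(geography=lattice98, fixed_effects=("sex",)), FAST)
        irr = residual_irr_table(fit)
        assert irr["significant"].mean() <= 0.12
        assert np.allclose(irr["irr_mean"], 1.0, atol=0.15)

    def test_beta_recovery_and_interval(self, lattice98, sex_exposures):
        truth = math.log(1.25)
        params = SimulationParams(seed=8, beta={"sex[male]": truth},
                                  baseline_log_rate=math.log(0.005))
        sim = simulate_region_counts(params, lattice98, sex_exposures)
        fit = fit_bym(sim.cells, ModelSpec(geography=lattice98, fixed_effects=("sex",)), FAST)
        summ = fit.beta_summary().loc["sex[male]"]
        assert summ["ci_low"] <= summ["mean"] <= summ["ci_high"]
        assert abs(summ["mean"] - truth) < 0.12

    def test_posterior_predictive_conservation(self, lattice98, sex_exposures):
        sim = simulate_region_counts(SimulationParams(seed=9), lattice98, sex_exposures)
        fit = fit_bym(sim.cells, ModelSpec(geography=lattice98, fixed_effects=("sex",)), FAST)
        totals = posterior_predictive_totals(fit, n_draws=200, seed=1)
        observed = sim.cells["cases"].sum()
        se = totals.std()
        assert abs(totals.mean() - observed) < 3 * se

    def test_empty_cells_rejected(self, lattice98):
        with pytest.raises(ValueError):
            fit_bym(pd.DataFrame(), ModelSpec(geography=lattice98), FAST)

    def test_cases_without_person_years_rejected(self, lattice98):
        cells = pd.DataFrame(
            {"region_id": [lattice98.region_ids[0]], "person_years": [0.0], "cases": [3],
             "sex": ["male"]}
        )
        with pytest.raises(ValueError):
            fit_bym(cells, ModelSpec(geography=lattice98, fixed_effects=("sex",)), FAST)


class TestBetaPosteriorOracle:
    def test_matches_dense_grid_posterior(self):
        """3-region toy, intercept-only, random effects off: the MCMC
        posterior for beta0 matches numeric grid integration to 2 decimals."""
        g = generate_lattice_geography(1, 3, 10.0)
        cells = pd.DataFrame(
            {"region_id": g.region_ids, "person_years": [100.0, 150.0, 80.0],
             "cases": [12, 18, 9]}
        )
        spec = ModelSpec(geography=g, fixed_effects=(), include_structured=False,
                         include_iid=False)
        mc = McmcSettings(n_iter=22_000, n_burnin=2_000, thin=2, n_chains=2, seed=4)
        fit = fit_bym(cells, spec, mc)
        draws = fit.draws["beta"][:, 0]

        grid = np.linspace(-4, 0, 8001)
        y, E = cells["cases"].to_numpy(), cells["person_years"].to_numpy()
        loglik = (y.sum() * grid)[None].T - np.outer(np.exp(grid), E).sum(axis=1)[None].T
        logpost = loglik.ravel() + stats.norm.logpdf(grid, 0, 1 / math.sqrt(0.001))
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        mean_grid = (grid * w).sum()
        sd_grid = math.sqrt(((grid - mean_grid) ** 2 * w).sum())
        assert draws.mean() == pytest.approx(mean_grid, abs=0.01)
        assert draws.std() == pytest.approx(sd_grid, abs=0.01)


class TestDic:
    @staticmethod
    def glm_fit(cells, g, mc=None):
        spec = ModelSpec(geography=g, fixed_effects=(), include_structured=False,
                         include_iid=False)
        return fit_bym(cells, spec, mc or McmcSettings(
            n_iter=6000, n_burnin=1000, thin=2, n_chains=2, seed=2))

    def test_degenerate_posterior_has_zero_pd(self):
        g = generate_lattice_geography(1, 2, 10.0)
        cells = pd.DataFrame(
            {"region_id": g.region_ids, "person_years": [100.0, 100.0], "cases": [10, 12]}
        )
        fit = self.glm_fit(cells, g)
        # freeze the posterior at its mean: p_d collapses to 0
        frozen = copy.deepcopy(fit)
        eta_bar = fit.mean_eta
        mu = np.exp(eta_bar)
        y = fit.data.y
        from scipy.special import gammaln

        ll = float(np.sum(y * eta_bar - mu - gammaln(y + 1)))
        frozen.draws["loglik"] = np.full_like(fit.draws["loglik"], ll)
        d, p_d = dic(frozen)
        assert p_d == pytest.approx(0.0, abs=1e-9)
        assert d == pytest.approx(-2 * ll, abs=1e-9)

    def test_matches_quadrature_oracle_single_cell(self):
        """Single Poisson cell, intercept only: DIC from deterministic
        inverse-CDF 'draws' of the grid posterior matches quadrature."""
        g = generate_lattice_geography(1, 2, 10.0)
        cells = pd.DataFrame(
            {"region_id": g.region_ids, "person_years": [50.0, 1e-9], "cases": [20, 0]}
        )
        y, E = 20.0, 50.0
        grid = np.linspace(-3, 1, 200_001)
        from scipy.special import gammaln

        loglik = y * (grid + math.log(E)) - E * np.exp(grid) - gammaln(y + 1)
        logpost = loglik + stats.norm.logpdf(grid, 0, 1 / math.sqrt(0.001))
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        d_bar_quad = float((-2 * loglik * w).sum())
        eta_bar_quad = float((grid * w).sum()) + math.log(E)
        d_hat_quad = -2 * (y * eta_bar_quad - E * math.exp(eta_bar_quad - math.log(E) + math.log(1.0)) * 1.0 - float(gammaln(y + 1)))
        # mu at eta_bar: exp(eta_bar) with offset already inside
        d_hat_quad = -2 * (y * eta_bar_quad - math.exp(eta_bar_quad) - float(gammaln(y + 1)))
        dic_quad = d_bar_quad + (d_bar_quad - d_hat_quad)

        fit = self.glm_fit(cells, g)
        # replace MCMC draws by deterministic stratified draws from the grid posterior
        cdf = np.cumsum(w)
        probs = (np.arange(100_000) + 0.5) / 100_000
        beta_draws = grid[np.searchsorted(cdf, probs)]
        cell = int(np.nonzero(fit.data.exposure > 1e-6)[0][0])
        ll_draws = y * (beta_draws + math.log(E)) - E * np.exp(beta_draws) - float(gammaln(y + 1))
        other = fit.data.y[1 - cell] if len(fit.data.y) > 1 else None
        frozen = copy.deepcopy(fit)
        # restrict the data to the single informative cell for the oracle
        frozen.data.y = np.array([y])
        frozen.data.exposure = np.array([E])
        frozen.mean_eta = np.array([beta_draws.mean() + math.log(E)])
        frozen.draws["loglik"] = ll_draws
        d, p_d = dic(frozen)
        assert d == pytest.approx(dic_quad, abs=1e-3)

    def test_noise_covariate_increases_pd(self, small_lattice):
        """Adding an uninformative covariate raises the effective parameter
        count in the clear majority of replicates."""
        exposures = region_exposures(small_lattice, py=500.0)
        mc = McmcSettings(n_iter=1200, n_burnin=600, thin=2, n_chains=2, seed=5)
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            params = SimulationParams(seed=100 + seed, beta={}, tau_u=1e9, tau_v=1e9,
                                      baseline_log_rate=math.log(0.01))
            sim = simulate_region_counts(params, small_lattice, exposures)
            base = fit_bym(
                sim.cells,
                ModelSpec(geography=small_lattice, fixed_effects=(),
                          include_structured=False, include_iid=False),
                mc,
            )
            with_noise = fit_bym(
                sim.cells,
                ModelSpec(geography=small_lattice, fixed_effects=("sex",),
                          include_structured=False, include_iid=False),
                mc,
            )
            wins += with_noise.p_d > base.p_d
        assert wins >= int(0.7 * n_rep)


class TestSpatialFraction:
    def test_iid_only_fit_returns_zero(self, small_lattice):
        exposures = region_exposures(small_lattice)
        sim = simulate_region_counts(SimulationParams(seed=3), small_lattice, exposures)
        spec = ModelSpec(geography=small_lattice, fixed_effects=("sex",))
        fit = fit_iid_only(sim.cells, spec, FAST)
        assert spatial_fraction(fit) == 0.0
        assert np.all(fit.draws["v"] == 0)

    def test_pure_components_give_extremes(self, small_lattice, sex_exposures):
        sim = simulate_region_counts(SimulationParams(seed=4), small_lattice,
                                     region_exposures(small_lattice))
        fit = fit_bym(sim.cells, ModelSpec(geography=small_lattice, fixed_effects=("sex",)),
                      McmcSettings(n_iter=400, n_burnin=200, thin=2, n_chains=2, seed=1))
        crafted = copy.deepcopy(fit)
        crafted.draws["u"] = np.zeros_like(fit.draws["u"])
        assert spatial_fraction(crafted) == pytest.approx(1.0)
        crafted.draws["v"] = np.zeros_like(fit.draws["v"])
        crafted.draws["u"] = np.abs(np.random.default_rng(0).normal(size=fit.draws["u"].shape))
        assert spatial_fraction(crafted) == pytest.approx(0.0)

    def test_strong_spatial_signal_dominates(self, lattice98, sex_exposures):
        """tau_v << tau_u: most random-effect variation is structured."""
        params = SimulationParams(seed=10, tau_u=4000.0, tau_v=2.0,
                                  baseline_log_rate=math.log(0.01))
        sim = simulate_region_counts(params, lattice98, sex_exposures)
        fit = fit_bym(sim.cells, ModelSpec(geography=lattice98, fixed_effects=("sex",)), FAST)
        assert fit.spatial_fraction > 0.5


class TestResidualIrr:
    def test_planted_region_effect_recovered(self, lattice98):
        """One region with log-effect 0.30 and ample data: residual IRR near
        1.35 and flagged significant."""
        u = np.random.default_rng(11).normal(0, 0.15, 98)
        u[42] = 0.30
        exposures = region_exposures(lattice98, py=60_000.0)
        params = SimulationParams(seed=11, baseline_log_rate=math.log(0.006))
        sim = simulate_region_counts(params, lattice98, exposures,
                                     region_effects=(u, np.zeros(98)))
        fit = fit_bym(sim.cells, ModelSpec(geography=lattice98, fixed_effects=("sex",)), FAST)
        irr = residual_irr_table(fit)
        row = irr.iloc[42]
        assert row["irr_mean"] == pytest.approx(math.exp(0.30), abs=0.08)
        assert row["significant"]

    def test_adjustment_contrast_on_confounded_data(self, lattice98):
        """When low income concentrates in specific regions and carries real
        risk, adjusting for income shifts those regions' residual IRRs."""
        rng = np.random.default_rng(12)
        xs = lattice98.coord_array()[:, 0]
        low_share = 0.2 + 0.6 * (xs - xs.min()) / (xs.max() - xs.min())
        rows = []
        for i, rid in enumerate(lattice98.region_ids):
            rows.append({"region_id": rid, "income": 1, "person_years": 4000 * low_share[i]})
            rows.append({"region_id": rid, "income": 5, "person_years": 4000 * (1 - low_share[i])})
        exposures = pd.DataFrame(rows)
        params = SimulationParams(seed=13, beta={"income[1]": math.log(1.6)},
                                  baseline_log_rate=math.log(0.006))
        sim = simulate_region_counts(params, lattice98, exposures,
                                     region_effects=(np.zeros(98), np.zeros(98)))
        cells = sim.cells.rename(columns={"income": "income_q"})
        semi = fit_bym(cells, ModelSpec(geography=lattice98, fixed_effects=()), FAST)
        full = fit_bym(cells, ModelSpec(geography=lattice98, fixed_effects=("income",)), FAST)
        irr_semi = residual_irr_table(semi)["irr_mean"].to_numpy()
        irr_full = residual_irr_table(full)["irr_mean"].to_numpy()
        # unadjusted residuals track the income composition; adjusted ones do not
        corr_semi = np.corrcoef(irr_semi, low_share)[0, 1]
        corr_full = np.corrcoef(irr_full, low_share)[0, 1]
        assert corr_semi > 0.5
        assert abs(corr_full) < corr_semi - 0.2


class TestSensitivity:
    def test_default_only_gives_zero_change(self, small_lattice):
        sim = simulate_region_counts(SimulationParams(seed=14), small_lattice,
                                     region_exposures(small_lattice))
        spec = ModelSpec(geography=small_lattice, fixed_effects=("sex",))
        mc = McmcSettings(n_iter=500, n_burnin=250, thin=2, n_chains=2, seed=2)
        table = sensitivity_analysis(sim.cells, spec, mc, [(1.0, 0.0005)])
        assert table["max_abs_irr_change"].iloc[0] == pytest.approx(0.0)

    def test_well_identified_data_insensitive_to_hyperprior(self, small_lattice):
        """Many cases per region: the three hyperpriors agree within 0.05."""
        params = SimulationParams(seed=15, baseline_log_rate=math.log(0.01))
        sim = simulate_region_counts(params, small_lattice,
                                     region_exposures(small_lattice, py=50_000.0))
        spec = ModelSpec(geography=small_lattice, fixed_effects=("sex",))
        mc = McmcSettings(n_iter=1500, n_burnin=750, thin=2, n_chains=2, seed=3)
        table = sensitivity_analysis(sim.cells, spec, mc)
        assert table["max_abs_irr_change"].max() < 0.05

    def test_missing_default_rejected(self, small_lattice):
        spec = ModelSpec(geography=small_lattice)
        with pytest.raises(ValueError):
            sensitivity_analysis(pd.DataFrame(), spec, FAST, [(1.0, 0.05)])
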