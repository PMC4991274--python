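import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cwm_phylo import (
    FIXED_TERMS,
    McmcSchedule,
    SimulationParams,
    SpeciesRecord,
    SubplotRecord,
    VariancePrior,
    build_design,
    effective_sample_size,
    gibbs_sampler,
    pmcmc,
    sensitivity_scan,
    simulate_dataset,
    summarize,
)
from cwm_phylo.records import BiomassTable


def _p_only_params(seed, **kw):
    beta = {t: 0.0 for t in FIXED_TERMS}
    beta["P"] = 0.9
    kw.setdefault("n_species", 30)
    kw.setdefault("n_plots", 8)
    kw.setdefault("subplots_per_plot", 4)
    return SimulationParams(
        beta=beta,
        sigma2_plot=0.1,
        sigma2_species=0.1,
        sigma2_phylo=0.1,
        sigma2_resid=0.3,
        occupancy=0.6,
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="module")
def fixture_design():
    ds = simulate_dataset(_p_only_params(seed=17))
    return build_design(ds.biomass, ds.species, ds.design, ds.tree)


@pytest.fixture(scope="module")
def fixture_chains(fixture_design):
    sched = McmcSchedule(iterations=36_000, burn_in=4_000, thinning=4)
    return gibbs_sampler(fixture_design, VariancePrior(1.0, 0.5), sched, seed=101)


class TestBuildDesign:
    def test_single_row_seventeen_columns(self):
        species = [SpeciesRecord("sp1", 2.0, "diploid", (1.0, 0.0, 0.0))]
        design = [SubplotRecord("p1", "s1", 0.0, 0.0, False, ph=5.0)]
        bio = BiomassTable(pd.DataFrame({"s1": [3.0]}, index=["sp1"]))
        import dendropy

        tree = dendropy.Tree.get(data="(sp1:1,dummy:1);", schema="newick")
        tree.is_rooted = True
        d = build_design(bio, species, design, tree)
        assert d.X.shape == (1, 17)
        assert d.y[0] == pytest.approx(np.log(3.0))

    def test_log_response_unit_biomass(self):
        species = [SpeciesRecord("sp1", 2.0, "diploid", (1.0, 0.0, 0.0))]
        design = [SubplotRecord("p1", "s1", 0.0, 0.0, False, ph=5.0)]
        bio = BiomassTable(pd.DataFrame({"s1": [1.0]}, index=["sp1"]))
        import dendropy

        tree = dendropy.Tree.get(data="(sp1:1,x:1);", schema="newick")
        tree.is_rooted = True
        d = build_design(bio, species, design, tree)
        assert d.y[0] == 0.0

    def test_column_order_snapshot(self, fixture_design):
        assert fixture_design.term_names == [
            "intercept", "GS", "N", "P", "ploidy", "pH",
            "GS:N", "GS:P", "N:P", "GS:ploidy", "N:ploidy", "P:ploidy",
            "GS:N:P", "GS:N:ploidy", "GS:P:ploidy", "N:P:ploidy",
            "GS:N:P:ploidy",
        ]

    def test_zero_rows_excluded(self, fixture_design):
        ds = simulate_dataset(_p_only_params(seed=17))
        n_occupied = int((ds.biomass.data.to_numpy() > 0).sum())
        assert fixture_design.n_obs == n_occupied


class TestGibbsSampler:
    def test_same_seed_identical_chains(self, fixture_design):
        sched = McmcSchedule(iterations=1500, burn_in=500, thinning=2)
        c1 = gibbs_sampler(fixture_design, VariancePrior(1.0, 0.5), sched, seed=7)
        c2 = gibbs_sampler(fixture_design, VariancePrior(1.0, 0.5), sched, seed=7)
        pd.testing.assert_frame_equal(c1, c2)

    def test_prior_recovery_without_data(self):
        """With no data every variance full conditional is the prior, so the
        sampled marginal must match scaled-inv-chi2(nu, V)."""
        pr = VariancePrior(1.0, 0.5)
        sched = McmcSchedule(iterations=5100, burn_in=100, thinning=1)
        chains = gibbs_sampler(None, pr, sched, seed=11)
        ref = stats.invgamma(a=pr.nu / 2, scale=pr.nu * pr.v / 2)
        for comp in chains.columns:
            ks = stats.kstest(chains[comp], ref.cdf)
            assert ks.pvalue > 0.01

    def test_flat_prior_no_data_rejected(self):
        with pytest.raises(ValueError, match="improper|nu"):
            gibbs_sampler(None, VariancePrior(1.0, 0.0), McmcSchedule(200, 10, 1), seed=0)

    def test_degenerate_random_variances_reduce_to_ols(self, fixture_design):
        """Pinning the three G-side variances near zero leaves a fixed-effect
        model whose posterior mean must match ordinary least squares."""
        tiny = VariancePrior(v=1e-10, nu=1e8)
        priors = {
            "var_plot": tiny,
            "var_species": tiny,
            "var_phylo": tiny,
            "var_residual": VariancePrior(1.0, 0.5),
        }
        sched = McmcSchedule(iterations=6000, burn_in=1000, thinning=5)
        chains = gibbs_sampler(fixture_design, priors, sched, seed=13)
        ols = np.linalg.lstsq(fixture_design.X, fixture_design.y, rcond=None)[0]
        post = chains[list(fixture_design.term_names)].mean().to_numpy()
        assert np.max(np.abs(post - ols)) < 0.02

    def test_split_chain_stationarity(self, fixture_chains, fixture_design):
        half = len(fixture_chains) // 2
        for term in ("intercept", "GS", "P", "var_residual"):
            x = fixture_chains[term].to_numpy()
            d = abs(x[:half].mean() - x[half:].mean())
            assert d < 0.1 * x.std()

    def test_recovers_p_effect_on_fixture(self, fixture_chains):
        assert fixture_chains["P"].mean() == pytest.approx(0.9, abs=0.25)

    def test_credible_interval_calibration(self):
        """95% CIs cover the generating coefficients at nominal rate over
        replicate synthetic datasets (binomial tolerance)."""
        sched = McmcSchedule(iterations=4000, burn_in=1000, thinning=3)
        covered = total = 0
        for rep in range(25):
            params = _p_only_params(seed=3000 + rep, n_species=20, n_plots=8,
                                    subplots_per_plot=2)
            ds = simulate_dataset(params)
            d = build_design(ds.biomass, ds.species, ds.design, ds.tree)
            chains = gibbs_sampler(d, VariancePrior(1.0, 0.5), sched, seed=rep)
            for term in ("GS", "N", "P", "ploidy", "pH"):
                lo, hi = np.percentile(chains[term], [2.5, 97.5])
                truth = params.beta[term]
                covered += lo <= truth <= hi
                total += 1
        assert covered / total >= 0.85


class TestSummaries:
    def test_constant_chain_collapsed_ci_and_flagged_ess(self):
        chains = pd.DataFrame({"theta": np.full(100, 2.5)})
        out = summarize(chains).iloc[0]
        assert out.ci_lower == out.ci_upper == 2.5
        assert np.isnan(out.ess)

    def test_standard_normal_chain(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20_000)
        out = summarize(pd.DataFrame({"z": x})).iloc[0]
        assert out.pmcmc == pytest.approx(1.0, abs=0.05)
        assert out.ci_lower == pytest.approx(-1.96, abs=0.06)
        assert out.ci_upper == pytest.approx(1.96, abs=0.06)

    def test_all_positive_chain_pmcmc_floor(self):
        x = np.abs(np.random.default_rng(1).normal(size=10_000)) + 0.01
        val, label = pmcmc(x)
        assert val == pytest.approx(1e-4)
        assert label == "< 0.0001"


class TestEffectiveSampleSize:
    def test_iid_chain_near_m(self):
        x = np.random.default_rng(2).normal(size=10_000)
        assert 9000 <= effective_sample_size(x) <= 11_000

    def test_ar1_closed_form(self):
        """AR(1) with rho = 0.5 has ESS = M (1 - rho) / (1 + rho) = M/3."""
        rng = np.random.default_rng(3)
        rho, m = 0.5, 10_000
        x = np.empty(m)
        x[0] = rng.normal()
        for i in range(1, m):
            x[i] = rho * x[i - 1] + rng.normal() * np.sqrt(1 - rho**2)
        ess = effective_sample_size(x)
        assert ess == pytest.approx(m / 3, rel=0.2)

    def test_constant_chain_flagged(self):
        assert np.isnan(effective_sample_size(np.ones(100)))

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.arange(5.0))

    def test_capped_at_m(self, fixture_chains):
        for col in fixture_chains.columns:
            ess = effective_sample_size(fixture_chains[col])
            assert np.isnan(ess) or ess <= len(fixture_chains)


class TestSensitivity:
    def test_identical_priors_zero_change(self, fixture_design):
        sched = McmcSchedule(iterations=1200, burn_in=200, thinning=2)
        out = sensitivity_scan(
            fixture_design, [VariancePrior(1.0, 0.5), VariancePrior(1.0, 0.5)],
            schedule=sched, seed=5,
        )
        assert out.max_abs_change.iloc[1] == pytest.approx(0.0, abs=1e-12)

    def test_weak_to_moderate_priors_stable(self, fixture_design):
        """On a well-identified dataset the fixed-effect posteriors barely
        move across flat-ish to informative variance priors."""
        sched = McmcSchedule(iterations=4000, burn_in=1000, thinning=3)
        out = sensitivity_scan(
            fixture_design,
            [VariancePrior(1.0, 0.002), VariancePrior(1.0, 0.5), VariancePrior(1.0, 2.0)],
            schedule=sched, seed=6,
        )
        assert out.max_abs_change.max() < 0.05

    def test_tiny_data_more_sensitive_than_full_data(self, fixture_design):
        """With a handful of rows the prior leaks into the posterior, so the
        scan must report larger shifts than on the full fixture."""
        ds = simulate_dataset(_p_only_params(seed=23, n_species=4, n_plots=4,
                                             subplots_per_plot=1))
        # keep only a few occupied cells
        small = build_design(ds.biomass, ds.species, ds.design, ds.tree)
        sched = McmcSchedule(iterations=4000, burn_in=1000, thinning=3)
        priors = [VariancePrior(0.1, 2.0), VariancePrior(10.0, 2.0)]
        out_small = sensitivity_scan(small, priors, schedule=sched, seed=7)
        out_big = sensitivity_scan(fixture_design, priors, schedule=sched, seed=7)
        assert out_small.max_abs_change.max() > out_big.max_abs_change.max()
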