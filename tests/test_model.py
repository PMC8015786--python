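import numpy as np
import pytest
from scipy.stats import cauchy, norm, poisson

from guildgrowth import (
    MCMCConfig,
    ModelInputs,
    ModelParameters,
    UnconstrainedPosterior,
    fit,
    joint_log_posterior,
    latent_states,
    log_prior,
    observation_log_density,
    process_log_density,
)
from guildgrowth.model import growth_means


# ---------------------------------------------------------------------------
# direct fixture construction for density unit tests
# ---------------------------------------------------------------------------


def make_inputs(count, species_idx, year_idx, gamma_idx, gamma_species,
                group_idx, regime, x, n_species=None, years=None,
                gamma_site=None):
    S = n_species or int(np.max(species_idx)) + 1
    T = len(regime) + 1
    G = int(np.max(gamma_idx)) + 1
    return ModelInputs(
        count=np.asarray(count, int),
        species_idx=np.asarray(species_idx, int),
        year_idx=np.asarray(year_idx, int),
        gamma_idx=np.asarray(gamma_idx, int),
        gamma_species=np.asarray(gamma_species, int),
        gamma_site=gamma_site or [f"S{i}" for i in range(G)],
        species=[f"sp{i}" for i in range(S)],
        group_labels=[f"g{i}" for i in range(int(np.max(group_idx)) + 1)],
        group_idx=np.asarray(group_idx, int),
        years=np.asarray(years if years is not None
                         else np.arange(2000, 2000 + T)),
        regime=np.asarray(regime, int),
        x=np.asarray(x, float),
        covariate_mean=0.0,
        covariate_sd=1.0,
    )


def one_species_inputs(regime=(2,), x=(0.5,), counts=(0,)):
    N = len(counts)
    return make_inputs(
        count=counts, species_idx=[0] * N, year_idx=[0] * N,
        gamma_idx=[0] * N, gamma_species=[0], group_idx=[0],
        regime=regime, x=x,
    )


def params_for(inputs, **overrides):
    S, F, T = inputs.n_species, inputs.n_groups, inputs.n_years
    base = dict(
        lambda_bar=np.zeros(F), alpha=np.zeros(F), beta=np.zeros(F),
        n1=np.zeros(S), lam=np.zeros((S, T - 1)),
        gamma=np.zeros(inputs.n_site_effects), eps=np.zeros(inputs.n_obs),
        sigma_lam=np.ones(F), sigma_gamma=np.ones(S), sigma_eps=np.ones(S),
    )
    base.update({k: np.asarray(v, float) for k, v in overrides.items()})
    return ModelParameters(**base)


def random_params(inputs, rng):
    S, F, T = inputs.n_species, inputs.n_groups, inputs.n_years
    return ModelParameters(
        lambda_bar=rng.normal(0, 1, F), alpha=rng.normal(0, 1, F),
        beta=rng.normal(0, 1, F), n1=rng.normal(0, 1, S),
        lam=rng.normal(0, 0.5, (S, T - 1)),
        gamma=rng.normal(0, 0.5, inputs.n_site_effects),
        eps=rng.normal(0, 0.5, inputs.n_obs),
        sigma_lam=rng.uniform(0.2, 2, F), sigma_gamma=rng.uniform(0.2, 2, S),
        sigma_eps=rng.uniform(0.2, 2, S),
    )


# ---------------------------------------------------------------------------
# prior
# ---------------------------------------------------------------------------


class TestLogPrior:
    def test_closed_form_oracle_at_half_cauchy_median(self, two_year_inputs):
        """All locations 0, every σ at the half-Cauchy(0,2) median (= 2):
        value equals the independent sum of textbook log pdfs."""
        ins = two_year_inputs
        p = params_for(ins, sigma_lam=np.full(ins.n_groups, 2.0),
                       sigma_gamma=np.full(ins.n_species, 2.0),
                       sigma_eps=np.full(ins.n_species, 2.0))
        n_loc = 3 * ins.n_groups + ins.n_species
        n_sig = ins.n_groups + 2 * ins.n_species
        expected = (
            n_loc * norm.logpdf(0.0, 0.0, 2.0)
            + n_sig * (np.log(2.0) + cauchy.logpdf(2.0, 0.0, 2.0))
            + ins.n_site_effects * norm.logpdf(0.0, 0.0, 2.0)
            + ins.n_obs * norm.logpdf(0.0, 0.0, 2.0)
        )
        assert log_prior(p, ins) == pytest.approx(expected, abs=1e-10)

    def test_single_normal_contribution_value(self, two_year_inputs):
        """Moving one Normal(0,2) location off its mode changes the prior by
        the closed-form difference; the at-mode term is −log(2√(2π))."""
        ins = two_year_inputs
        base = params_for(ins)
        moved = params_for(ins, beta=[1.0, 0.0, 0.0])
        delta = log_prior(moved, ins) - log_prior(base, ins)
        assert delta == pytest.approx(-1.0 / 8.0)
        assert norm.logpdf(0.0, 0.0, 2.0) == pytest.approx(-1.6120857, abs=1e-6)

    def test_nonpositive_sigma_gives_neg_inf_not_exception(self, two_year_inputs):
        p = params_for(two_year_inputs,
                       sigma_lam=[-1.0, 1.0, 1.0])
        assert log_prior(p, two_year_inputs) == -np.inf
        p0 = params_for(two_year_inputs, sigma_eps=[0.0, 1.0, 1.0])
        assert log_prior(p0, two_year_inputs) == -np.inf


# ---------------------------------------------------------------------------
# process density
# ---------------------------------------------------------------------------


class TestProcessDensity:
    def test_standard_normal_at_mode_regime1(self):
        ins = one_species_inputs(regime=(1,), x=(0.0,))
        p = params_for(ins)  # λ = λ̄ = 0, σ_λ = 1
        assert process_log_density(p, ins) == pytest.approx(
            -0.5 * np.log(2 * np.pi))

    def test_regime2_zero_deviation_hand_arithmetic(self):
        # α = 0, β = 1, X = 0.5, λ = 0.5, σ = 1 → standard normal at its mean
        ins = one_species_inputs(regime=(2,), x=(0.5,))
        p = params_for(ins, beta=[1.0], lam=[[0.5]])
        assert process_log_density(p, ins) == pytest.approx(-0.9189385, abs=1e-6)

    def test_matches_brute_force_loop(self, tiny_inputs, rng):
        p = random_params(tiny_inputs, rng)
        total = 0.0
        for s in range(tiny_inputs.n_species):
            f = tiny_inputs.group_idx[s]
            for t in range(tiny_inputs.n_years - 1):
                if tiny_inputs.regime[t] == 1:
                    mean = p.lambda_bar[f]
                else:
                    mean = p.alpha[f] + p.beta[f] * tiny_inputs.x[t]
                total += norm.logpdf(p.lam[s, t], mean, p.sigma_lam[f])
        assert process_log_density(p, tiny_inputs) == pytest.approx(total,
                                                                    abs=1e-10)

    def test_zero_sigma_gives_neg_inf(self, tiny_inputs):
        p = params_for(tiny_inputs, sigma_lam=np.zeros(tiny_inputs.n_groups))
        assert process_log_density(p, tiny_inputs) == -np.inf


# ---------------------------------------------------------------------------
# observation density
# ---------------------------------------------------------------------------


class TestObservationDensity:
    def test_poisson_one_at_zero(self):
        ins = one_species_inputs(counts=(0,))
        p = params_for(ins)
        assert observation_log_density(p, ins) == pytest.approx(-1.0)

    def test_count_two_mean_two(self):
        ins = one_species_inputs(counts=(2,))
        p = params_for(ins, n1=[np.log(2.0)])
        expected = 2 * np.log(2) - 2 - np.log(2)
        assert observation_log_density(p, ins) == pytest.approx(expected)
        assert expected == pytest.approx(-1.3068528, abs=1e-6)

    def test_matches_per_row_oracle(self, tiny_inputs, rng):
        ins = tiny_inputs
        p = random_params(ins, rng)
        n = latent_states(p)
        total = 0.0
        for i in range(ins.n_obs):
            mu = np.exp(n[ins.species_idx[i], ins.year_idx[i]]
                        + p.gamma[ins.gamma_idx[i]] + p.eps[i])
            total += poisson.logpmf(ins.count[i], mu)
        assert observation_log_density(p, ins) == pytest.approx(total,
                                                                abs=1e-8)


# ---------------------------------------------------------------------------
# joint posterior
# ---------------------------------------------------------------------------


class TestJointPosterior:
    def test_decomposition_identity_random_points(self, tiny_inputs):
        """joint = prior + process + observation on 100 random fixtures."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = random_params(tiny_inputs, rng)
            expected = (log_prior(p, tiny_inputs)
                        + process_log_density(p, tiny_inputs)
                        + observation_log_density(p, tiny_inputs))
            assert joint_log_posterior(p, tiny_inputs) == pytest.approx(
                expected, abs=1e-8)

    def test_invariant_to_observation_row_order(self, tiny_inputs, rng):
        ins = tiny_inputs
        p = random_params(ins, rng)
        perm = rng.permutation(ins.n_obs)
        shuffled = ModelInputs(
            count=ins.count[perm], species_idx=ins.species_idx[perm],
            year_idx=ins.year_idx[perm], gamma_idx=ins.gamma_idx[perm],
            gamma_species=ins.gamma_species, gamma_site=ins.gamma_site,
            species=ins.species, group_labels=ins.group_labels,
            group_idx=ins.group_idx, years=ins.years, regime=ins.regime,
            x=ins.x, covariate_mean=ins.covariate_mean,
            covariate_sd=ins.covariate_sd,
        )
        p_perm = ModelParameters(**{**p.__dict__, "eps": p.eps[perm]})
        assert joint_log_posterior(p, ins) == pytest.approx(
            joint_log_posterior(p_perm, shuffled), abs=1e-8)

    def test_monolithic_oracle_two_species_three_years(self, rng):
        """Independently coded single-pass oracle agrees to 1e-8."""
        ins = make_inputs(
            count=[3, 0, 5, 1, 2, 0], species_idx=[0, 1, 0, 1, 0, 1],
            year_idx=[0, 0, 1, 1, 2, 2], gamma_idx=[0, 1, 0, 1, 0, 1],
            gamma_species=[0, 1], group_idx=[0, 0], regime=[1, 2],
            x=[0.0, -0.3],
        )
        p = random_params(ins, rng)
        lp = joint_log_posterior(p, ins)

        # --- oracle: every term written out longhand -----------------------
        total = 0.0
        for v in [*p.lambda_bar, *p.alpha, *p.beta, *p.n1]:
            total += norm.logpdf(v, 0, 2)
        for s in [*p.sigma_lam, *p.sigma_gamma, *p.sigma_eps]:
            total += np.log(2) + cauchy.logpdf(s, 0, 2)
        for j in range(2):
            total += norm.logpdf(p.gamma[j], 0, p.sigma_gamma[ins.gamma_species[j]])
        for i in range(6):
            total += norm.logpdf(p.eps[i], 0, p.sigma_eps[ins.species_idx[i]])
        n = {(s, 0): p.n1[s] for s in range(2)}
        for s in range(2):
            for t in range(2):
                n[(s, t + 1)] = n[(s, t)] + p.lam[s, t]
                f = ins.group_idx[s]
                mean = (p.lambda_bar[f] if ins.regime[t] == 1
                        else p.alpha[f] + p.beta[f] * ins.x[t])
                total += norm.logpdf(p.lam[s, t], mean, p.sigma_lam[f])
        for i in range(6):
            mu = np.exp(n[(ins.species_idx[i], ins.year_idx[i])]
                        + p.gamma[ins.gamma_idx[i]] + p.eps[i])
            total += poisson.logpmf(ins.count[i], mu)
        assert lp == pytest.approx(total, abs=1e-8)

    def test_species_relabeling_within_group_is_exchangeable(self, rng):
        """Swapping two same-group species together with their data leaves
        the joint density unchanged."""
        ins = make_inputs(
            count=[3, 0, 5, 1], species_idx=[0, 1, 0, 1],
            year_idx=[0, 0, 1, 1], gamma_idx=[0, 1, 0, 1],
            gamma_species=[0, 1], group_idx=[0, 0], regime=[1], x=[0.0],
        )
        p = random_params(ins, rng)
        lp = joint_log_posterior(p, ins)
        swap = [1, 0]
        p_sw = ModelParameters(
            lambda_bar=p.lambda_bar, alpha=p.alpha, beta=p.beta,
            n1=p.n1[swap], lam=p.lam[swap], gamma=p.gamma[swap],
            eps=p.eps, sigma_lam=p.sigma_lam, sigma_gamma=p.sigma_gamma[swap],
            sigma_eps=p.sigma_eps[swap],
        )
        # relabel: old species 0 becomes 1 and vice versa; site-effect slot j
        # now belongs to new species j and holds the relabeled effect
        ins_sw = make_inputs(
            count=[3, 0, 5, 1], species_idx=[1, 0, 1, 0],
            year_idx=[0, 0, 1, 1], gamma_idx=[1, 0, 1, 0],
            gamma_species=[0, 1], group_idx=[0, 0], regime=[1], x=[0.0],
        )
        assert joint_log_posterior(p_sw, ins_sw) == pytest.approx(lp, abs=1e-9)


# ---------------------------------------------------------------------------
# unconstrained target (sampler side)
# ---------------------------------------------------------------------------


class TestUnconstrainedPosterior:
    @pytest.mark.parametrize("fixed_case", ["none", "lam", "sigma_lam",
                                            "gamma_eps"])
    def test_gradient_matches_finite_differences(self, tiny_inputs, rng,
                                                 fixed_case):
        ins = tiny_inputs
        fixed = {
            "none": None,
            "lam": {"lam": rng.normal(0, 0.2, (ins.n_species,
                                               ins.n_years - 1))},
            "sigma_lam": {"sigma_lam": np.full(ins.n_groups, 0.5)},
            "gamma_eps": {"gamma": np.zeros(ins.n_site_effects),
                          "sigma_gamma": np.zeros(1),
                          "eps": np.zeros(ins.n_obs),
                          "sigma_eps": np.zeros(1)},
        }[fixed_case]
        post = UnconstrainedPosterior(ins, fixed=fixed)
        theta = rng.normal(0, 0.3, post.dim)
        _, grad = post.logp_and_grad(theta)
        h = 1e-6
        for i in range(0, post.dim, max(1, post.dim // 40)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fd = (post.logp_and_grad(tp)[0] - post.logp_and_grad(tm)[0]) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)

    def test_density_equals_centered_joint_plus_jacobian(self, tiny_inputs):
        """The sampled parameterization implies exactly the centered joint
        density (state map is unit-Jacobian; log-σ and non-centered γ/ε
        contribute the usual change-of-variable terms)."""
        rng = np.random.default_rng(3)
        post = UnconstrainedPosterior(tiny_inputs)
        for _ in range(100):
            theta = rng.normal(0, 0.4, post.dim)
            lp, _ = post.logp_and_grad(theta)
            params = post.transform(theta)
            expected = (joint_log_posterior(params, tiny_inputs)
                        + post.log_jacobian(theta))
            assert lp == pytest.approx(expected, abs=1e-8)

    def test_shared_sigma_variant_reduces_dimension(self, tiny_inputs):
        per = UnconstrainedPosterior(tiny_inputs)
        shared = UnconstrainedPosterior(tiny_inputs, shared_obs_sigmas=True)
        assert per.dim - shared.dim == 2 * (tiny_inputs.n_species - 1)

    def test_sigma_zero_requires_fixed_effects(self, tiny_inputs):
        with pytest.raises(ValueError, match="fixed at 0"):
            UnconstrainedPosterior(tiny_inputs,
                                   fixed={"sigma_eps": np.zeros(1)})


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class TestFit:
    def test_conjugate_posterior_mean_recovered(self, conjugate_setup):
        ins, fixed, post_mean, post_sd = conjugate_setup
        draws = fit(ins, MCMCConfig(chains=3, iterations=1000, warmup=400),
                    seed=11, fixed=fixed)
        lb = draws.draws["lambda_bar"].ravel()
        mc_se = post_sd / np.sqrt(200.0)  # conservative effective sample size
        assert abs(lb.mean() - post_mean) < 3 * mc_se
        assert lb.std() == pytest.approx(post_sd, rel=0.15)

    def test_seed_reproducibility(self, tiny_inputs):
        cfg = MCMCConfig(chains=2, iterations=120, warmup=60)
        a = fit(tiny_inputs, cfg, seed=5)
        b = fit(tiny_inputs, cfg, seed=5)
        c = fit(tiny_inputs, cfg, seed=6)
        np.testing.assert_array_equal(a.draws["lambda_bar"],
                                      b.draws["lambda_bar"])
        assert not np.array_equal(a.draws["lambda_bar"],
                                  c.draws["lambda_bar"])

    def test_chain_bookkeeping_shapes(self, tiny_inputs):
        cfg = MCMCConfig(chains=2, iterations=150, warmup=70)
        draws = fit(tiny_inputs, cfg, seed=1)
        assert draws.n_chains == 2
        assert draws.n_draws == 80
        assert draws.total_saved == 160
        S, F, T = (tiny_inputs.n_species, tiny_inputs.n_groups,
                   tiny_inputs.n_years)
        assert draws.draws["lam"].shape == (2, 80, S, T - 1)
        assert draws.draws["sigma_lam"].shape == (2, 80, F)
        assert "eps" not in draws.draws  # per-event effects not stored

    def test_latent_state_draws_consistent_with_growth_draws(self, tiny_inputs):
        draws = fit(tiny_inputs, MCMCConfig(chains=2, iterations=120,
                                            warmup=60), seed=2)
        p0 = ModelParameters(
            **{k: draws.draws[k][0, 0] for k in
               ("lambda_bar", "alpha", "beta", "n1", "lam", "gamma",
                "sigma_lam", "sigma_gamma", "sigma_eps")},
            eps=np.zeros(tiny_inputs.n_obs),
        )
        states = latent_states(p0)
        np.testing.assert_allclose(np.diff(states, axis=1),
                                   draws.draws["lam"][0, 0], atol=1e-10)

    def test_save_load_round_trip(self, tiny_inputs, tmp_path):
        from guildgrowth import PosteriorDraws

        draws = fit(tiny_inputs, MCMCConfig(chains=2, iterations=120,
                                            warmup=60), seed=3)
        draws.save(tmp_path / "d")
        back = PosteriorDraws.load(tmp_path / "d")
        for k, arr in draws.draws.items():
            np.testing.assert_allclose(back.draws[k], arr, rtol=1e-12)
        assert back.species == draws.species
        assert back.group_labels == draws.group_labels

    def test_mcmc_config_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(iterations=100, warmup=100)
        with pytest.raises(ValueError):
            MCMCConfig(chains=0)


class TestGrowthMeans:
    def test_regime_switch_in_mean_matrix(self, tiny_inputs, rng):
        p = random_params(tiny_inputs, rng)
        m = growth_means(p, tiny_inputs)
        reg1 = tiny_inputs.regime == 1
        for s in range(tiny_inputs.n_species):
            f = tiny_inputs.group_idx[s]
            np.testing.assert_allclose(m[s, reg1], p.lambda_bar[f])
            np.testing.assert_allclose(
                m[s, ~reg1],
                p.alpha[f] + p.beta[f] * tiny_inputs.x[~reg1])
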