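"""The hierarchical state-space model and its MCMC fit.

Process model (annual, on the log scale): each species' log abundance
follows n_{s,t+1} = n_{s,t} + λ_{s,t}, with the log-growth increments
partially pooled within functional feeding groups.  Transitions before the
covariate record draw λ_{s,t} ~ Normal(λ̄_f, σ_λ,f) (regime 1); transitions
during it draw λ_{s,t} ~ Normal(α_f + β_f·X_t, σ_λ,f) (regime 2), with X_t
the z-scored annual zooplankton biomass of the origin year.

Observation model (Poisson-lognormal): event counts y_i ~ Poisson(μ_i) with
log μ_i = n_{s,t} + γ_{s,site} + ε_i, a species-site random effect γ and a
per-event overdispersion effect ε.

Priors: Normal(0, 2) on λ̄_f, α_f, β_f and the initial log abundances
n_{s,1}; half-Cauchy(0, 2) on every standard deviation; γ ~ Normal(0,
σ_γ,s) and ε ~ Normal(0, σ_ε,s) per species (optionally shared across
species).

Sampling uses Hamiltonian Monte Carlo with analytic gradients on an
unconstrained parameterization: log transforms for the standard deviations
and a non-centered parameterization for λ, γ and ε.  The implied joint
density equals the centered form up to the usual change-of-variable
Jacobians, which is asserted by the test suite.
"""

from __future__ import annotations

import logging
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import cauchy, norm, poisson

from ._hmc import HMCOptions, run_hmc
from ._kernels import HAVE_NUMBA, logp_grad_allfree
from .data_io import ModelInputs

logger = logging.getLogger("guildgrowth")

LOG_2PI = float(np.log(2.0 * np.pi))
_LOGMU_MAX = 600.0  # beyond this exp() overflows; the state is rejected

BACKEND_ID = "guildgrowth-hmc"

#: parameter blocks, in canonical packing order
BLOCK_NAMES = (
    "lambda_bar", "alpha", "beta", "n1", "lam", "gamma", "eps",
    "sigma_lam", "sigma_gamma", "sigma_eps",
)


class FitError(RuntimeError):
    """Sampler failure; carries whatever diagnostics were collected."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


# ---------------------------------------------------------------------------
# parameters and densities (centered form)
# ---------------------------------------------------------------------------


@dataclass
class ModelParameters:
    """Every model unknown, in its natural (centered) parameterization.

    Shapes: group-level blocks have length F, species-level length S, the
    growth draws are (S, T−1), site effects length G (one per species-site
    pair with data) and overdispersion effects length N (one per event row).
    """

    lambda_bar: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    n1: np.ndarray
    lam: np.ndarray
    gamma: np.ndarray
    eps: np.ndarray
    sigma_lam: np.ndarray
    sigma_gamma: np.ndarray
    sigma_eps: np.ndarray

    def validate_shapes(self, inputs: ModelInputs) -> None:
        S, F, T = inputs.n_species, inputs.n_groups, inputs.n_years
        expect = {
            "lambda_bar": (F,), "alpha": (F,), "beta": (F,), "n1": (S,),
            "lam": (S, T - 1), "gamma": (inputs.n_site_effects,),
            "eps": (inputs.n_obs,),
        }
        for name, shape in expect.items():
            got = np.shape(getattr(self, name))
            if got != shape:
                raise ValueError(f"{name} has shape {got}, expected {shape}")
        for name in ("sigma_lam", "sigma_gamma", "sigma_eps"):
            n = np.shape(getattr(self, name))[0]
            full = {"sigma_lam": F, "sigma_gamma": S, "sigma_eps": S}[name]
            if n not in (1, full):
                raise ValueError(f"{name} must have length 1 or {full}, got {n}")


def latent_states(params: ModelParameters) -> np.ndarray:
    """Log-abundance trajectories: n_{s,1} plus the cumulated growth draws."""
    lam = np.atleast_2d(params.lam)
    inc = np.concatenate(
        [np.zeros((lam.shape[0], 1)), np.cumsum(lam, axis=1)], axis=1
    )
    return np.asarray(params.n1)[:, None] + inc


def _sigma_slot(sigma: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Per-unit SD, supporting both per-species and shared (scalar) variants."""
    sigma = np.asarray(sigma, dtype=float)
    return np.broadcast_to(sigma, (1,))[np.zeros_like(idx)] if sigma.size == 1 \
        else sigma[idx]


def growth_means(params: ModelParameters, inputs: ModelInputs) -> np.ndarray:
    """(S, T−1) regime-appropriate mean of each growth draw."""
    g = inputs.group_idx
    reg2 = (inputs.regime == 2)
    m1 = np.asarray(params.lambda_bar)[g][:, None]
    m2 = np.asarray(params.alpha)[g][:, None] + \
        np.asarray(params.beta)[g][:, None] * inputs.x[None, :]
    return np.where(reg2[None, :], m2, m1)


def log_prior(params: ModelParameters, inputs: ModelInputs) -> float:
    """Sum of the independent prior log densities (Table-of-priors form).

    Normal(0, 2) on the location blocks, half-Cauchy(0, 2) on the SDs, and
    the random-effect densities γ ~ N(0, σ_γ,s), ε ~ N(0, σ_ε,s).  Any
    non-positive SD yields −inf rather than an exception.
    """
    sigmas = np.concatenate([
        np.atleast_1d(params.sigma_lam),
        np.atleast_1d(params.sigma_gamma),
        np.atleast_1d(params.sigma_eps),
    ]).astype(float)
    if np.any(sigmas <= 0.0):
        return -np.inf
    total = 0.0
    for block in (params.lambda_bar, params.alpha, params.beta, params.n1):
        total += float(np.sum(norm.logpdf(np.asarray(block), 0.0, 2.0)))
    # half-Cauchy(0, 2): the positive half of Cauchy(0, 2), density 2·f(σ)
    total += float(np.sum(np.log(2.0) + cauchy.logpdf(sigmas, 0.0, 2.0)))
    sg = _sigma_slot(params.sigma_gamma, inputs.gamma_species)
    total += float(np.sum(norm.logpdf(np.asarray(params.gamma), 0.0, sg)))
    se = _sigma_slot(params.sigma_eps, inputs.species_idx)
    total += float(np.sum(norm.logpdf(np.asarray(params.eps), 0.0, se)))
    return total


def process_log_density(params: ModelParameters, inputs: ModelInputs) -> float:
    """Log density of the growth draws at their regime-appropriate means."""
    sl = np.asarray(params.sigma_lam, dtype=float)
    if np.any(sl <= 0.0):
        return -np.inf
    m = growth_means(params, inputs)
    scale = (sl if sl.size > 1 else np.repeat(sl, inputs.n_groups))[
        inputs.group_idx][:, None]
    return float(np.sum(norm.logpdf(np.asarray(params.lam), m, scale)))


def observation_log_density(
    params: ModelParameters, inputs: ModelInputs,
    states: np.ndarray | None = None,
) -> float:
    """Poisson log-pmf of every event count at its exp-link mean.

    Log-factorial terms are included so the value matches independent
    textbook oracles exactly.
    """
    n = latent_states(params) if states is None else states
    log_mu = (
        n[inputs.species_idx, inputs.year_idx]
        + np.asarray(params.gamma)[inputs.gamma_idx]
        + np.asarray(params.eps)
    )
    if np.max(log_mu, initial=-np.inf) > _LOGMU_MAX:
        return -np.inf
    return float(np.sum(poisson.logpmf(inputs.count, np.exp(log_mu))))


def joint_log_posterior(params: ModelParameters, inputs: ModelInputs) -> float:
    """log p(params | data) up to the normalizing constant.

    Exactly ``log_prior + process_log_density + observation_log_density``,
    with the latent states reconstructed deterministically from n_{s,1} and
    the growth draws.
    """
    lp = log_prior(params, inputs)
    if not np.isfinite(lp):
        return -np.inf
    lproc = process_log_density(params, inputs)
    if not np.isfinite(lproc):
        return -np.inf
    return lp + lproc + observation_log_density(params, inputs)


# ---------------------------------------------------------------------------
# unconstrained posterior (sampler target)
# ---------------------------------------------------------------------------


def _halfcauchy2_logpdf(sigma: np.ndarray) -> np.ndarray:
    return -np.log(np.pi) - np.log1p(sigma * sigma / 4.0)


def _halfcauchy2_dlogsigma(sigma: np.ndarray) -> np.ndarray:
    # d/d(log σ) of the half-Cauchy(0,2) log pdf
    s2 = sigma * sigma
    return -2.0 * s2 / (4.0 + s2)


class UnconstrainedPosterior:
    """Joint posterior on an unconstrained parameterization.

    Free standard deviations are sampled on the log scale (with Jacobian).
    The latent trajectory is sampled as the states n_{s,t} themselves (the
    map (n₁, λ) ↔ n is unit-Jacobian, so the implied joint density equals
    the centered form); the weakly identified γ and ε blocks are
    non-centered.  Any block may instead be held fixed at supplied values —
    fixing γ, ε and the SDs reduces the model to analytically tractable
    special cases used by the oracle tests.

    Special conventions:

    * ``sigma_lam`` fixed at 0 makes the growth draws deterministic
      (λ ≡ regime mean), the point-mass convention.
    * ``sigma_gamma``/``sigma_eps`` fixed at 0 require the matching effect
      block fixed at 0; both then drop from the density.
    """

    def __init__(
        self,
        inputs: ModelInputs,
        fixed: dict[str, np.ndarray] | None = None,
        shared_obs_sigmas: bool = False,
    ):
        inputs.validate()
        self.inputs = inputs
        self.shared_obs_sigmas = shared_obs_sigmas
        self.fixed = {k: np.asarray(v, dtype=float) for k, v in (fixed or {}).items()}
        unknown = set(self.fixed) - set(BLOCK_NAMES)
        if unknown:
            raise ValueError(f"unknown fixed block(s): {sorted(unknown)}")

        S, F, T = inputs.n_species, inputs.n_groups, inputs.n_years
        G, N = inputs.n_site_effects, inputs.n_obs
        n_sig = 1 if shared_obs_sigmas else S
        self._shapes = {
            "lambda_bar": (F,), "alpha": (F,), "beta": (F,), "n1": (S,),
            "lam": (S, T - 1), "gamma": (G,), "eps": (N,),
            "sigma_lam": (F,), "sigma_gamma": (n_sig,), "sigma_eps": (n_sig,),
        }
        for name, val in self.fixed.items():
            want = self._shapes[name]
            if name.startswith("sigma"):
                # scalar/short SD specs broadcast to the full per-unit shape
                self.fixed[name] = np.broadcast_to(
                    np.atleast_1d(val), want if val.size in (1, want[0])
                    else val.shape
                ).astype(float)
                val = self.fixed[name]
            if val.shape != want:
                raise ValueError(
                    f"fixed block {name} has shape {val.shape}, expected {want}"
                )
        for sig, eff in (("sigma_gamma", "gamma"), ("sigma_eps", "eps")):
            if sig in self.fixed and np.any(self.fixed[sig] == 0.0):
                if eff not in self.fixed or np.any(self.fixed[eff] != 0.0):
                    raise ValueError(f"{sig} fixed at 0 requires {eff} fixed at 0")

        sl_fixed = self.fixed.get("sigma_lam")
        if sl_fixed is not None and np.any(sl_fixed == 0.0):
            if not np.all(sl_fixed == 0.0):
                raise ValueError(
                    "sigma_lam fixed with mixed zero/positive entries is not "
                    "supported; fix all groups at 0 or none"
                )
            if "lam" in self.fixed:
                raise ValueError(
                    "sigma_lam fixed at 0 makes lam deterministic; do not "
                    "also fix lam"
                )
            self.lam_mode = "deterministic"
        elif "lam" in self.fixed:
            self.lam_mode = "fixed"
        else:
            self.lam_mode = "states"
        self._n1_free = "n1" not in self.fixed
        if self.lam_mode == "states":
            self._shapes["nstate"] = (S, T) if self._n1_free else (S, T - 1)

        free = [b for b in ("lambda_bar", "alpha", "beta") if b not in self.fixed]
        if self.lam_mode == "states":
            free.append("nstate")
        elif self._n1_free:
            free.append("n1")
        for b in ("gamma", "eps", "sigma_lam", "sigma_gamma", "sigma_eps"):
            if b not in self.fixed:
                free.append(b)
        self.free = free
        self._slices: dict[str, slice] = {}
        off = 0
        for b in self.free:
            size = int(np.prod(self._shapes[b]))
            self._slices[b] = slice(off, off + size)
            off += size
        self.dim = off

        # cached index arrays
        self._reg2 = inputs.regime == 2
        self._x = inputs.x
        self._gi = inputs.group_idx
        self._sig_idx_species = (np.zeros(S, dtype=int) if shared_obs_sigmas
                                 else np.arange(S))
        self._sig_of_gamma = self._sig_idx_species[inputs.gamma_species]
        self._sig_of_obs = self._sig_idx_species[inputs.species_idx]
        self._lgamma_y = gammaln(inputs.count + 1.0)

        # compiled fast path for the standard (no fixed blocks) posterior;
        # the numpy implementation below is the reference and covers every
        # fixed-block variant
        self._use_kernel = HAVE_NUMBA and not self.fixed
        if self._use_kernel:
            self._kernel_args = (
                inputs.count.astype(np.float64),
                self._lgamma_y.astype(np.float64),
                (inputs.species_idx * T + inputs.year_idx).astype(np.int64),
                inputs.gamma_idx.astype(np.int64),
                self._sig_of_obs.astype(np.int64),
                self._gi.astype(np.int64),
                self._reg2.astype(np.int64),
                self._x.astype(np.float64),
                self._sig_of_gamma.astype(np.int64),
                F, S, T, G, N, n_sig,
                self._slices["lambda_bar"].start,
                self._slices["alpha"].start,
                self._slices["beta"].start,
                self._slices["nstate"].start,
                self._slices["gamma"].start,
                self._slices["eps"].start,
                self._slices["sigma_lam"].start,
                self._slices["sigma_gamma"].start,
                self._slices["sigma_eps"].start,
            )

    # -- packing helpers ----------------------------------------------------

    def _get(self, theta: np.ndarray, name: str) -> np.ndarray:
        return theta[self._slices[name]].reshape(self._shapes[name])

    def pack(self, blocks: dict[str, np.ndarray]) -> np.ndarray:
        theta = np.empty(self.dim)
        for b in self.free:
            theta[self._slices[b]] = np.asarray(blocks[b], dtype=float).ravel()
        return theta

    def _resolve_sigma(self, theta, name):
        if name in self.fixed:
            return self.fixed[name], False
        return np.exp(self._get(theta, name)), True

    def _growth_means(self, loc) -> np.ndarray:
        return np.where(
            self._reg2[None, :],
            loc["alpha"][self._gi][:, None]
            + loc["beta"][self._gi][:, None] * self._x[None, :],
            loc["lambda_bar"][self._gi][:, None],
        )

    def _trajectory(self, theta, loc, m):
        """(n, lam, n1) under the active trajectory mode."""
        S = self.inputs.n_species
        if self.lam_mode == "states":
            block = self._get(theta, "nstate")
            n = (block if self._n1_free
                 else np.concatenate([self.fixed["n1"][:, None], block], axis=1))
            return n, np.diff(n, axis=1), n[:, 0]
        n1 = self.fixed["n1"] if not self._n1_free else self._get(theta, "n1")
        lam = m if self.lam_mode == "deterministic" else self.fixed["lam"]
        n = n1[:, None] + np.concatenate(
            [np.zeros((S, 1)), np.cumsum(lam, axis=1)], axis=1
        )
        return n, lam, n1

    # -- transform to centered parameters -----------------------------------

    def transform(self, theta: np.ndarray) -> ModelParameters:
        """Centered ModelParameters implied by one unconstrained point."""
        sl, _ = self._resolve_sigma(theta, "sigma_lam")
        sg, _ = self._resolve_sigma(theta, "sigma_gamma")
        se, _ = self._resolve_sigma(theta, "sigma_eps")
        loc = {
            b: (self.fixed[b] if b in self.fixed else self._get(theta, b))
            for b in ("lambda_bar", "alpha", "beta")
        }
        m = self._growth_means(loc)
        _, lam, n1 = self._trajectory(theta, loc, m)
        gamma = (self.fixed["gamma"] if "gamma" in self.fixed
                 else sg[self._sig_of_gamma] * self._get(theta, "gamma"))
        eps = (self.fixed["eps"] if "eps" in self.fixed
               else se[self._sig_of_obs] * self._get(theta, "eps"))
        return ModelParameters(
            lambda_bar=loc["lambda_bar"], alpha=loc["alpha"], beta=loc["beta"],
            n1=n1, lam=lam, gamma=gamma, eps=eps,
            sigma_lam=sl, sigma_gamma=sg, sigma_eps=se,
        )

    def log_jacobian(self, theta: np.ndarray) -> float:
        """log |d(centered)/d(unconstrained)| of the free-block transform.

        The state map (n₁, λ) ↔ n is triangular with unit diagonal, so only
        the log-σ transforms and the non-centered γ/ε scalings contribute.
        """
        total = 0.0
        for name in ("sigma_lam", "sigma_gamma", "sigma_eps"):
            if name in self.free:
                total += float(np.sum(self._get(theta, name)))
        sg, _ = self._resolve_sigma(theta, "sigma_gamma")
        se, _ = self._resolve_sigma(theta, "sigma_eps")
        if "gamma" in self.free:
            total += float(np.sum(np.log(sg[self._sig_of_gamma])))
        if "eps" in self.free:
            total += float(np.sum(np.log(se[self._sig_of_obs])))
        return total

    # -- density and gradient ------------------------------------------------

    def logp_and_grad(self, theta: np.ndarray):
        # transient overflow during leapfrog exploration is handled by the
        # finiteness guards below, not worth a warning each time
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            if self._use_kernel:
                return logp_grad_allfree(
                    np.ascontiguousarray(theta, dtype=np.float64),
                    *self._kernel_args,
                )
            return self._logp_and_grad(theta)

    def _logp_and_grad(self, theta: np.ndarray):
        ins = self.inputs
        S, F, T = ins.n_species, ins.n_groups, ins.n_years
        neg_inf = (-np.inf, np.zeros(self.dim))

        sl, sl_free = self._resolve_sigma(theta, "sigma_lam")
        sg, sg_free = self._resolve_sigma(theta, "sigma_gamma")
        se, se_free = self._resolve_sigma(theta, "sigma_eps")
        loc = {
            b: (self.fixed[b] if b in self.fixed else self._get(theta, b))
            for b in ("lambda_bar", "alpha", "beta")
        }
        reg2 = self._reg2
        x = self._x
        gi = self._gi
        m = self._growth_means(loc)
        n, lam, n1 = self._trajectory(theta, loc, m)

        gamma_free = "gamma" in self.free
        if gamma_free:
            z_gam = self._get(theta, "gamma")
            gamma = sg[self._sig_of_gamma] * z_gam
        else:
            gamma = self.fixed["gamma"]
        eps_free = "eps" in self.free
        if eps_free:
            z_eps = self._get(theta, "eps")
            eps = se[self._sig_of_obs] * z_eps
        else:
            eps = self.fixed["eps"]

        log_mu = n[ins.species_idx, ins.year_idx] + gamma[ins.gamma_idx] + eps
        if not np.all(np.isfinite(log_mu)) or np.max(log_mu, initial=0.0) > _LOGMU_MAX:
            return neg_inf
        mu = np.exp(log_mu)
        y = ins.count
        logp = float(np.sum(y * log_mu - mu) - np.sum(self._lgamma_y))
        g_obs = (y - mu).astype(float)

        grad = np.zeros(self.dim)

        # observation gradient accumulated onto the latent states
        A = np.zeros((S, T))
        np.add.at(A, (ins.species_idx, ins.year_idx), g_obs)

        # process density and D[s,t] = dlogp/d(mean m[s,t])
        slg = sl[gi][:, None]
        if self.lam_mode == "deterministic":
            # λ ≡ m: the trajectory depends on the group-level means directly
            C = np.flip(np.cumsum(np.flip(A, axis=1), axis=1), axis=1)
            D = C[:, 1:]
        else:
            r = (lam - m) / slg
            logp += float(
                -0.5 * np.sum(r * r) - lam.shape[1] * np.sum(np.log(sl[gi]))
                - 0.5 * lam.size * LOG_2PI
            )
            D = r / slg
        if self.lam_mode == "states":
            dn = A.copy()
            dn[:, 1:] -= D      # d/dn_{t+1} of −½((n_{t+1}−n_t−m)/σ)²
            dn[:, :-1] += D
            if self._n1_free:
                dn[:, 0] -= n1 / 4.0
                grad[self._slices["nstate"]] = dn.ravel()
            else:
                grad[self._slices["nstate"]] = dn[:, 1:].ravel()
        elif self._n1_free:
            grad[self._slices["n1"]] = np.sum(A, axis=1) - n1 / 4.0

        # group-level locations
        Ds1 = np.sum(D * ~reg2[None, :], axis=1)   # per species, regime 1
        Ds2 = np.sum(D * reg2[None, :], axis=1)
        Dsx = np.sum(D * (reg2 * x)[None, :], axis=1)
        if "lambda_bar" in self.free:
            grad[self._slices["lambda_bar"]] = (
                np.bincount(gi, weights=Ds1, minlength=F)
                - loc["lambda_bar"] / 4.0
            )
        if "alpha" in self.free:
            grad[self._slices["alpha"]] = (
                np.bincount(gi, weights=Ds2, minlength=F) - loc["alpha"] / 4.0
            )
        if "beta" in self.free:
            grad[self._slices["beta"]] = (
                np.bincount(gi, weights=Dsx, minlength=F) - loc["beta"] / 4.0
            )
        for v in (loc["lambda_bar"], loc["alpha"], loc["beta"], n1):
            logp += float(-np.sum(v * v) / 8.0
                          - v.size * (np.log(2.0) + 0.5 * LOG_2PI))

        # site effects
        Gg = np.bincount(ins.gamma_idx, weights=g_obs,
                         minlength=ins.n_site_effects)
        if gamma_free:
            logp += float(-0.5 * np.sum(z_gam * z_gam)
                          - 0.5 * z_gam.size * LOG_2PI)
            grad[self._slices["gamma"]] = Gg * sg[self._sig_of_gamma] - z_gam
        else:
            sgf = sg[self._sig_of_gamma]
            pos = sgf > 0
            logp += float(-0.5 * np.sum((gamma[pos] / sgf[pos]) ** 2)
                          - np.sum(np.log(sgf[pos]))
                          - 0.5 * np.sum(pos) * LOG_2PI)

        # overdispersion effects
        if eps_free:
            logp += float(-0.5 * np.sum(z_eps * z_eps)
                          - 0.5 * z_eps.size * LOG_2PI)
            grad[self._slices["eps"]] = g_obs * se[self._sig_of_obs] - z_eps
        else:
            sef = se[self._sig_of_obs]
            pos = sef > 0
            logp += float(-0.5 * np.sum((eps[pos] / sef[pos]) ** 2)
                          - np.sum(np.log(sef[pos]))
                          - 0.5 * np.sum(pos) * LOG_2PI)

        # standard deviations: half-Cauchy(0, 2) prior (+ log Jacobian if free)
        for name, sig, isfree in (("sigma_lam", sl, sl_free),
                                  ("sigma_gamma", sg, sg_free),
                                  ("sigma_eps", se, se_free)):
            pos = sig > 0.0  # σ=0 entries follow the point-mass convention
            logp += float(np.sum(_halfcauchy2_logpdf(sig[pos])))
            if isfree:  # free σ = exp(·) is never 0
                logp += float(np.sum(np.log(sig)))  # Jacobian of σ = exp(·)

        if sl_free:
            r = (lam - m) / slg
            per_sp = np.sum(r * r - 1.0, axis=1)
            grad[self._slices["sigma_lam"]] = (
                _halfcauchy2_dlogsigma(sl) + 1.0
                + np.bincount(gi, weights=per_sp, minlength=F)
            )

        if sg_free:
            dls = _halfcauchy2_dlogsigma(sg) + 1.0
            if gamma_free:
                w = Gg * z_gam
                dls += sg * np.bincount(self._sig_of_gamma, weights=w,
                                        minlength=sg.size)
            else:
                w = (gamma / sg[self._sig_of_gamma]) ** 2 - 1.0
                dls += np.bincount(self._sig_of_gamma, weights=w,
                                   minlength=sg.size)
            grad[self._slices["sigma_gamma"]] = dls

        if se_free:
            dls = _halfcauchy2_dlogsigma(se) + 1.0
            if eps_free:
                w = g_obs * z_eps
                dls += se * np.bincount(self._sig_of_obs, weights=w,
                                        minlength=se.size)
            else:
                w = (eps / se[self._sig_of_obs]) ** 2 - 1.0
                dls += np.bincount(self._sig_of_obs, weights=w,
                                   minlength=se.size)
            grad[self._slices["sigma_eps"]] = dls

        if not np.isfinite(logp):
            return neg_inf
        return logp, grad

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        """Data-informed start: latent states near per-year log mean counts."""
        ins = self.inputs
        theta = np.zeros(self.dim)
        tot = np.zeros((ins.n_species, ins.n_years))
        cnt = np.zeros((ins.n_species, ins.n_years))
        np.add.at(tot, (ins.species_idx, ins.year_idx), ins.count.astype(float))
        np.add.at(cnt, (ins.species_idx, ins.year_idx), 1.0)
        n_init = np.log(tot / np.maximum(cnt, 1.0) + 0.5)
        if "nstate" in self._slices:
            block = n_init if self._n1_free else n_init[:, 1:]
            theta[self._slices["nstate"]] = block.ravel()
        elif "n1" in self._slices:
            theta[self._slices["n1"]] = n_init[:, 0]
        for name, s0 in (("sigma_lam", 0.3), ("sigma_gamma", 0.3),
                         ("sigma_eps", 0.5)):
            if name in self._slices:
                theta[self._slices[name]] = np.log(s0)
        theta += 0.05 * rng.standard_normal(self.dim)
        return theta

# ---------------------------------------------------------------------------
# posterior draws container
# ---------------------------------------------------------------------------


@dataclass
class MCMCConfig:
    """Sampler protocol.  Defaults follow the survey analysis protocol:
    3 chains of 5,000 iterations each, the first 2,000 discarded, for 9,000
    saved draws total."""

    chains: int = 3
    iterations: int = 5000
    warmup: int = 2000
    target_accept: float = 0.9
    max_leapfrog: int = 96
    int_time: float = 1.2
    save_eps: bool = False

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        if self.chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_keep(self) -> int:
        return self.iterations - self.warmup


@dataclass
class PosteriorDraws:
    """Saved MCMC draws with the chain structure preserved.

    ``draws`` maps block name → array of shape (chains, draws, *block shape).
    Label metadata (species codes, guild labels, transition origin years)
    lets summaries name every scalar parameter.
    """

    draws: dict[str, np.ndarray]
    species: list[str]
    group_labels: list[str]
    group_idx: np.ndarray
    years: np.ndarray
    regime: np.ndarray
    x: np.ndarray
    gamma_species: np.ndarray
    gamma_site: list[str]
    covariate_mean: float
    covariate_sd: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    @property
    def total_saved(self) -> int:
        return self.n_chains * self.n_draws

    def _labels(self, block: str) -> list[str]:
        shape = self.draws[block].shape[2:]
        if block in ("lambda_bar", "alpha", "beta", "sigma_lam"):
            keys = self.group_labels
        elif block in ("n1",):
            keys = self.species
        elif block in ("sigma_gamma", "sigma_eps"):
            keys = self.species if shape[0] > 1 else ["shared"]
        elif block == "lam":
            origins = self.years[:-1]
            return [f"lam[{s},{y}]" for s in self.species for y in origins]
        elif block == "gamma":
            return [
                f"gamma[{self.species[sp]},{site}]"
                for sp, site in zip(self.gamma_species, self.gamma_site)
            ]
        elif block == "eps":
            return [f"eps[{i}]" for i in range(shape[0])]
        else:
            raise KeyError(block)
        return [f"{block}[{k}]" for k in keys]

    def parameter_names(self, blocks: list[str] | None = None) -> list[str]:
        names = []
        for b in blocks or self.draws:
            names.extend(self._labels(b))
        return names

    def parameter_array(self, blocks: list[str] | None = None) -> np.ndarray:
        """(chains, draws, P) matrix of the requested blocks, flattened."""
        mats = [
            self.draws[b].reshape(self.n_chains, self.n_draws, -1)
            for b in (blocks or self.draws)
        ]
        return np.concatenate(mats, axis=2)

    def to_frame(self, blocks: list[str] | None = None) -> pd.DataFrame:
        """Tidy wide table: one row per saved draw, chain/iteration columns."""
        arr = self.parameter_array(blocks)
        names = self.parameter_names(blocks)
        C, D, P = arr.shape
        df = pd.DataFrame(arr.reshape(C * D, P), columns=names)
        df.insert(0, "iteration", np.tile(np.arange(D), C))
        df.insert(0, "chain", np.repeat(np.arange(C), D))
        return df

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "draws.csv", index=False)
        meta = {
            "species": self.species,
            "group_labels": self.group_labels,
            "group_idx": self.group_idx.tolist(),
            "years": self.years.tolist(),
            "regime": self.regime.tolist(),
            "x": self.x.tolist(),
            "gamma_species": self.gamma_species.tolist(),
            "gamma_site": self.gamma_site,
            "covariate_mean": self.covariate_mean,
            "covariate_sd": self.covariate_sd,
            "diagnostics": _jsonable(self.diagnostics),
        }
        (out / "draws_meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, out_dir) -> "PosteriorDraws":
        from pathlib import Path

        out = Path(out_dir)
        meta = json.loads((out / "draws_meta.json").read_text())
        df = pd.read_csv(out / "draws.csv")
        chains = int(df["chain"].max()) + 1
        ndraws = int(df["iteration"].max()) + 1
        species = meta["species"]
        groups = meta["group_labels"]
        years = np.array(meta["years"])
        S, F, T = len(species), len(groups), years.size
        G = len(meta["gamma_site"])
        stub = cls(
            draws={}, species=species, group_labels=groups,
            group_idx=np.array(meta["group_idx"]), years=years,
            regime=np.array(meta["regime"]), x=np.array(meta["x"]),
            gamma_species=np.array(meta["gamma_species"]),
            gamma_site=meta["gamma_site"],
            covariate_mean=meta["covariate_mean"],
            covariate_sd=meta["covariate_sd"],
            diagnostics=meta.get("diagnostics", {}),
        )
        shapes = {
            "lambda_bar": (F,), "alpha": (F,), "beta": (F,), "n1": (S,),
            "lam": (S, T - 1), "gamma": (G,),
        }
        n_sig = sum(c.startswith("sigma_eps[") for c in df.columns)
        shapes["sigma_lam"] = (F,)
        shapes["sigma_gamma"] = (n_sig,)
        shapes["sigma_eps"] = (n_sig,)
        for block, shape in shapes.items():
            stub.draws[block] = np.empty((chains, ndraws) + shape)
        n_eps = sum(c.startswith("eps[") for c in df.columns)
        if n_eps:
            stub.draws["eps"] = np.empty((chains, ndraws, n_eps))
        cols = stub.parameter_names()
        arr = df[cols].to_numpy().reshape(chains, ndraws, len(cols))
        off = 0
        for block in stub.draws:
            size = int(np.prod(stub.draws[block].shape[2:]))
            stub.draws[block] = arr[:, :, off:off + size].reshape(
                stub.draws[block].shape
            )
            off += size
        return stub


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit(
    inputs: ModelInputs,
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
    fixed: dict[str, np.ndarray] | None = None,
    shared_obs_sigmas: bool = False,
) -> PosteriorDraws:
    """Fit the model by HMC and return the saved draws.

    Chains run independently from jittered data-informed starting points;
    ``seed`` determines every random draw, so identical calls produce
    identical output.  Raises :class:`FitError` with attached diagnostics if
    the sampler cannot proceed.
    """
    mcmc = mcmc or MCMCConfig()
    post = UnconstrainedPosterior(inputs, fixed=fixed,
                                  shared_obs_sigmas=shared_obs_sigmas)
    options = HMCOptions(
        target_accept=mcmc.target_accept, max_leapfrog=mcmc.max_leapfrog,
        int_time=mcmc.int_time,
    )
    seeds = np.random.SeedSequence(seed).spawn(mcmc.chains)
    chain_draws, chain_stats = [], []
    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        x0 = post.initial_point(rng)
        try:
            draws, stats = run_hmc(
                post.logp_and_grad, x0, mcmc.warmup, mcmc.n_keep, rng, options
            )
        except FloatingPointError as exc:
            raise FitError(
                f"chain {c} failed: {exc}",
                diagnostics={"chain": c, "stats": [
                    _jsonable({k: v for k, v in s.items() if k != "inv_mass"})
                    for s in chain_stats]},
            ) from exc
        logger.info(
            "chain %d: step %.3g, accept %.2f, %d divergences",
            c, stats["step_size"], stats["mean_accept"], stats["divergences"],
        )
        chain_draws.append(draws)
        chain_stats.append(stats)

    div_total = sum(s["divergences"] for s in chain_stats)
    if div_total > 0:
        logger.warning("%d divergent transitions across %d saved draws",
                       div_total, mcmc.chains * mcmc.n_keep)
    if div_total > 0.3 * mcmc.chains * mcmc.n_keep:
        raise FitError(
            f"{div_total} divergent transitions "
            f"({div_total / (mcmc.chains * mcmc.n_keep):.0%} of saved draws)",
            diagnostics={"stats": [
                _jsonable({k: v for k, v in s.items() if k != "inv_mass"})
                for s in chain_stats]},
        )

    # vectorized transform of every saved draw to centered parameters
    blocks: dict[str, list[np.ndarray]] = {b: [] for b in BLOCK_NAMES}
    for draws in chain_draws:
        centred = _transform_batch(post, draws)
        for b in BLOCK_NAMES:
            blocks[b].append(centred[b])
    out_blocks = ("lambda_bar", "alpha", "beta", "n1", "lam", "gamma",
                  "sigma_lam", "sigma_gamma", "sigma_eps") + (
                      ("eps",) if mcmc.save_eps else ())
    ins = inputs
    return PosteriorDraws(
        draws={b: np.stack(blocks[b]) for b in out_blocks},
        species=ins.species, group_labels=ins.group_labels,
        group_idx=ins.group_idx, years=ins.years,
        regime=ins.regime, x=ins.x, gamma_species=ins.gamma_species,
        gamma_site=ins.gamma_site, covariate_mean=ins.covariate_mean,
        covariate_sd=ins.covariate_sd,
        diagnostics={
            "backend": BACKEND_ID,
            "chains": mcmc.chains,
            "iterations": mcmc.iterations,
            "warmup": mcmc.warmup,
            "seed": seed,
            "step_size": [s["step_size"] for s in chain_stats],
            "mean_accept": [s["mean_accept"] for s in chain_stats],
            "divergences": [s["divergences"] for s in chain_stats],
        },
    )


def _transform_batch(post: UnconstrainedPosterior,
                     draws: np.ndarray) -> dict[str, np.ndarray]:
    """Transform (D, dim) unconstrained draws to centered blocks at once."""
    ins = post.inputs
    D = draws.shape[0]
    gi = ins.group_idx
    reg2 = post._reg2

    def col(name, fallback_shape):
        if name in post.fixed:
            return np.broadcast_to(post.fixed[name], (D,) + fallback_shape).copy()
        return draws[:, post._slices[name]].reshape((D,) + post._shapes[name])

    out: dict[str, np.ndarray] = {}
    for name in ("sigma_lam", "sigma_gamma", "sigma_eps"):
        if name in post.fixed:
            out[name] = np.broadcast_to(
                post.fixed[name], (D,) + post.fixed[name].shape).copy()
        else:
            out[name] = np.exp(draws[:, post._slices[name]])
    for name in ("lambda_bar", "alpha", "beta"):
        out[name] = col(name, post._shapes[name])
    m = np.where(
        reg2[None, None, :],
        out["alpha"][:, gi][:, :, None]
        + out["beta"][:, gi][:, :, None] * post._x[None, None, :],
        out["lambda_bar"][:, gi][:, :, None],
    )
    if post.lam_mode == "states":
        shape = post._shapes["nstate"]
        block = draws[:, post._slices["nstate"]].reshape((D,) + shape)
        if post._n1_free:
            n = block
        else:
            first = np.broadcast_to(post.fixed["n1"][None, :, None],
                                    (D, shape[0], 1))
            n = np.concatenate([first, block], axis=2)
        out["lam"] = np.diff(n, axis=2)
        out["n1"] = n[:, :, 0]
    elif post.lam_mode == "deterministic":
        out["lam"] = m
        out["n1"] = col("n1", post._shapes["n1"])
    else:
        out["lam"] = np.broadcast_to(post.fixed["lam"],
                                     (D,) + post._shapes["lam"]).copy()
        out["n1"] = col("n1", post._shapes["n1"])
    if "gamma" in post.fixed:
        out["gamma"] = np.broadcast_to(post.fixed["gamma"],
                                       (D,) + post._shapes["gamma"]).copy()
    else:
        z = draws[:, post._slices["gamma"]]
        out["gamma"] = out["sigma_gamma"][:, post._sig_of_gamma] * z
    if "eps" in post.fixed:
        out["eps"] = np.broadcast_to(post.fixed["eps"],
                                     (D,) + post._shapes["eps"]).copy()
    else:
        z = draws[:, post._slices["eps"]]
        out["eps"] = out["sigma_eps"][:, post._sig_of_obs] * z
    return out
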