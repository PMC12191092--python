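"""Generic gradient-based samplers used by all model families.

``hmc_sample`` is a static-trajectory Hamiltonian Monte Carlo sampler with
dual-averaging step-size adaptation and diagonal mass-matrix estimation
during warmup (randomized trajectory lengths guard against resonance).
``fit_vi`` is a mean-field Gaussian variational optimizer (single-sample
reparameterization gradients with Adam).  Both consume an arbitrary
``value_and_grad(theta) -> (logp, dlogp/dtheta)`` callable, so every model
supplies only its joint log-density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

ValueAndGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class HmcDiagnostics:
    accept_rate: float
    divergences: int
    step_size: list[float]
    rhat_max: Optional[float] = None
    ess_min: Optional[float] = None
    converged: bool = True


@dataclass
class HmcResult:
    samples: np.ndarray  # (chains, draws, dim)
    diagnostics: HmcDiagnostics

    def flat(self) -> np.ndarray:
        c, d, k = self.samples.shape
        return self.samples.reshape(c * d, k)


def find_map(
    value_and_grad: ValueAndGrad,
    init: np.ndarray,
    maxiter: int = 500,
    frozen: Optional[np.ndarray] = None,
) -> np.ndarray:
    """L-BFGS maximum a posteriori point, used to initialize chains.

    ``frozen`` indices (typically log-scale hyperparameters, whose joint MAP
    is degenerate at the hierarchical funnel) are held at their initial
    values by zeroing their gradient components.
    """
    from scipy.optimize import minimize

    frozen_idx = np.asarray(frozen, dtype=int) if frozen is not None else None

    def neg(theta):
        v, g = value_and_grad(theta)
        g = -g
        if frozen_idx is not None and len(frozen_idx):
            g[frozen_idx] = 0.0
        return -v, g

    res = minimize(neg, init, jac=True, method="L-BFGS-B", options={"maxiter": maxiter})
    x = res.x
    if frozen_idx is not None and len(frozen_idx):
        x[frozen_idx] = init[frozen_idx]
    return x


def _leapfrog(value_and_grad, theta, p, eps, n_steps, inv_mass):
    v, g = value_and_grad(theta)
    p = p + 0.5 * eps * g
    for step in range(n_steps):
        theta = theta + eps * inv_mass * p
        v, g = value_and_grad(theta)
        if not np.isfinite(v):
            return theta, p, v, g
        p = p + (eps if step < n_steps - 1 else 0.5 * eps) * g
    return theta, p, v, g


def _find_initial_step(value_and_grad, theta, inv_mass, rng) -> float:
    """Double/halve until the one-step acceptance probability crosses 0.5."""
    eps = 0.1
    dim = len(theta)
    p0 = rng.normal(size=dim) / np.sqrt(inv_mass)
    v0, _ = value_and_grad(theta)
    h0 = v0 - 0.5 * np.sum(inv_mass * p0**2)
    theta1, p1, v1, _ = _leapfrog(value_and_grad, theta, p0, eps, 1, inv_mass)
    h1 = v1 - 0.5 * np.sum(inv_mass * p1**2) if np.isfinite(v1) else -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps = eps * (2.0**direction)
        theta1, p1, v1, _ = _leapfrog(value_and_grad, theta, p0, eps, 1, inv_mass)
        h1 = v1 - 0.5 * np.sum(inv_mass * p1**2) if np.isfinite(v1) else -np.inf
        crossed = (h1 - h0) > np.log(0.5)
        if (direction == 1.0 and not crossed) or (direction == -1.0 and crossed):
            break
    return float(min(max(eps, 1e-6), 1.0))


def hmc_sample(
    value_and_grad: ValueAndGrad,
    init: np.ndarray,
    *,
    draws: int = 500,
    warmup: int = 500,
    chains: int = 4,
    seed: int = 0,
    max_leapfrog: int = 20,
    target_accept: float = 0.8,
    init_jitter: float = 0.1,
) -> HmcResult:
    """Sample with randomized-length static HMC.

    Warmup schedule: dual averaging of the step size throughout; a diagonal
    mass matrix is estimated from the middle warmup window (30%-80%) and the
    step-size adaptation restarts on the re-scaled space.
    """
    dim = len(init)
    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(chains)
    all_samples = np.empty((chains, draws, dim))
    accepts, divergences, step_sizes = [], 0, []

    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        theta = init + init_jitter * rng.normal(size=dim)
        inv_mass = np.ones(dim)
        eps = _find_initial_step(value_and_grad, theta, inv_mass, rng)
        # dual averaging state (da_m restarts when the mass matrix updates)
        mu = np.log(10 * eps)
        log_eps_bar, h_bar, da_m = 0.0, 0.0, 0
        gamma, t0, kappa = 0.05, 10.0, 0.75
        window = []
        mass_end = int(0.8 * warmup)
        mass_start = int(0.3 * warmup)
        n_accept = 0

        v_cur, _ = value_and_grad(theta)
        for it in range(warmup + draws):
            adapting = it < warmup
            p0 = rng.normal(size=dim) / np.sqrt(inv_mass)
            h0 = v_cur - 0.5 * np.sum(inv_mass * p0**2)
            n_steps = int(rng.integers(1, max_leapfrog + 1))
            theta_prop, p1, v_prop, _ = _leapfrog(
                value_and_grad, theta, p0, eps, n_steps, inv_mass
            )
            if np.isfinite(v_prop):
                h1 = v_prop - 0.5 * np.sum(inv_mass * p1**2)
                log_ratio = h1 - h0
            else:
                log_ratio = -np.inf
            accept_prob = min(1.0, np.exp(min(log_ratio, 0.0)))
            if log_ratio < -1000:
                if not adapting:
                    divergences += 1
            if rng.uniform() < accept_prob:
                theta, v_cur = theta_prop, v_prop
                if not adapting:
                    n_accept += 1
            if adapting:
                # dual averaging toward target acceptance
                da_m += 1
                h_bar = (1 - 1 / (da_m + t0)) * h_bar + (
                    target_accept - accept_prob
                ) / (da_m + t0)
                log_eps = mu - np.sqrt(da_m) / gamma * h_bar
                w = da_m ** (-kappa)
                log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
                eps = float(np.exp(log_eps))
                if mass_start <= it < mass_end:
                    window.append(theta.copy())
                if it == mass_end - 1 and len(window) > 10:
                    var = np.var(np.asarray(window), axis=0) + 1e-8
                    inv_mass = var / np.mean(var)  # normalized diagonal mass
                    eps = _find_initial_step(value_and_grad, theta, inv_mass, rng)
                    mu = np.log(10 * eps)
                    log_eps_bar, h_bar, da_m = 0.0, 0.0, 0
                if it == warmup - 1:
                    eps = float(np.exp(log_eps_bar))
            else:
                all_samples[c, it - warmup] = theta
        accepts.append(n_accept / draws)
        step_sizes.append(eps)

    diag = HmcDiagnostics(
        accept_rate=float(np.mean(accepts)),
        divergences=divergences,
        step_size=step_sizes,
    )
    if chains >= 2 and draws >= 4:
        try:
            import arviz as az

            rhats = az.rhat(az.convert_to_dataset(all_samples))["x"].values
            ess = az.ess(az.convert_to_dataset(all_samples))["x"].values
            diag.rhat_max = float(np.nanmax(rhats))
            diag.ess_min = float(np.nanmin(ess))
            diag.converged = bool(diag.rhat_max < 1.1)
        except Exception:  # pragma: no cover - diagnostics are best-effort
            pass
    if diag.accept_rate < 0.5:
        diag.converged = False
    return HmcResult(samples=all_samples, diagnostics=diag)


@dataclass
class ViResult:
    mean: np.ndarray
    log_sd: np.ndarray
    elbo: float
    elbo_trace: np.ndarray

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        sd = np.exp(self.log_sd)
        return self.mean[None, :] + sd[None, :] * rng.normal(size=(n, len(self.mean)))


def fit_vi(
    value_and_grad: ValueAndGrad,
    init: np.ndarray,
    *,
    steps: int = 3000,
    learning_rate: float = 0.02,
    seed: int = 0,
    init_log_sd: float = -2.0,
    restarts: int = 1,
    init_jitter: float = 0.0,
) -> ViResult:
    """Mean-field Gaussian VI by single-sample reparameterization + Adam.

    Maximizes ELBO(m, s) = E_q[logp(m + s*eps)] + sum(log s) + const.  With
    ``restarts`` > 1, the fit with the best trailing-average ELBO wins
    (guards against mode collapse in multimodal posteriors).
    """
    dim = len(init)
    root = np.random.SeedSequence(seed)
    best: Optional[ViResult] = None
    for r, ss in enumerate(root.spawn(max(restarts, 1))):
        rng = np.random.default_rng(ss)
        m = init + (init_jitter * rng.normal(size=dim) if r > 0 or init_jitter else 0.0)
        log_s = np.full(dim, init_log_sd)
        adam_m = np.zeros(2 * dim)
        adam_v = np.zeros(2 * dim)
        b1, b2, eps_adam = 0.9, 0.999, 1e-8
        trace = np.empty(steps)
        for t in range(steps):
            epsn = rng.normal(size=dim)
            s = np.exp(log_s)
            theta = m + s * epsn
            v, g = value_and_grad(theta)
            if not np.isfinite(v):
                g = np.zeros(dim)
                v = -1e10
            grad_m = g
            grad_log_s = g * epsn * s + 1.0  # +1 from the entropy term
            grad = np.concatenate([grad_m, grad_log_s])
            adam_m = b1 * adam_m + (1 - b1) * grad
            adam_v = b2 * adam_v + (1 - b2) * grad**2
            mhat = adam_m / (1 - b1 ** (t + 1))
            vhat = adam_v / (1 - b2 ** (t + 1))
            update = learning_rate * mhat / (np.sqrt(vhat) + eps_adam)
            m = m + update[:dim]
            log_s = np.clip(log_s + update[dim:], -12.0, 4.0)
            trace[t] = v + np.sum(log_s)
        tail = float(np.mean(trace[-max(steps // 20, 10) :]))
        cand = ViResult(mean=m, log_sd=log_s, elbo=tail, elbo_trace=trace)
        if best is None or cand.elbo > best.elbo:
            best = cand
    return best
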