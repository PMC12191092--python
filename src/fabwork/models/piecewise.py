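"""Piecewise-linear Bayesian GLM via additive coefficient decomposition.

The covariate space is partitioned by one or more partitioning covariates
(quantile bins for continuous columns, natural {0,1} split for binaries).
Each cell c of the resulting product partition carries an effective
intercept/coefficient vector built additively:

    beta_c = beta_global + sum_d delta_{d, level_d(c)}

with zero-mean hierarchical shrinkage priors delta ~ Normal(0, s_d) on every
per-dimension deviation (random intercepts and random slopes).  No
sum-to-zero constraint is imposed; identification comes from the shrinkage.
With the deviation scale fixed at zero, or a single-cell partition, the
model reduces structurally to the plain logistic regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from ..prep import DesignMatrix
from .hmc import find_map, fit_vi, hmc_sample
from .likelihood import bernoulli_gh, half_normal_logpdf_via_log
from .logistic import (
    LogisticModelSpec,
    OddsRatioSummary,
    Posterior,
    _GlmDensity,
    _MarginalizedResults,
    summarize_odds_ratios,
)


class PartitionSpec(BaseModel):
    """Which covariates define the local regions and where the knots sit."""

    model_config = ConfigDict(frozen=True)

    covariates: tuple[str, ...]
    knot_quantiles: tuple[float, ...] = (1.0 / 3.0, 2.0 / 3.0)
    min_level_rows: int = Field(default=2, ge=1)


class PiecewiseModelSpec(LogisticModelSpec):
    """Logistic spec plus deviation-prior settings.

    ``deviation_scale`` fixes the prior scale of the per-level deviations;
    None learns it (half-normal hyperprior); exactly 0 removes the deviations
    (degenerate limit == plain logistic).
    """

    deviation_scale: Optional[float] = None
    deviation_prior_scale: float = Field(default=0.5, gt=0)


@dataclass
class _Dimension:
    column: str
    col_idx: int
    kind: str  # "binary" or "quantile"
    edges: np.ndarray  # bin edges for quantile dims, empty for binary
    n_levels: int
    level_map: np.ndarray  # raw bin -> merged level


def _assign_dimension(design: DesignMatrix, column: str, part: PartitionSpec) -> tuple[_Dimension, np.ndarray]:
    j = design.column_index(column)
    if not design.mask[:, j].all():
        raise ValueError(
            f"partition covariate {column!r} has masked cells; partition "
            "covariates must be fully observed"
        )
    values = design.Z[:, j]
    uniq = np.unique(values)
    if len(uniq) <= 2:
        kind, edges = "binary", np.array([])
        raw = np.searchsorted(uniq, values)
        n_raw = len(uniq)
    else:
        kind = "quantile"
        edges = np.unique(np.quantile(values, list(part.knot_quantiles)))
        raw = np.digitize(values, edges)
        n_raw = len(edges) + 1
    # merge levels with too few rows into a neighbor
    counts = np.bincount(raw, minlength=n_raw)
    level_map = np.arange(n_raw)
    while True:
        merged_counts = np.bincount(level_map[raw])
        small = np.flatnonzero(merged_counts < part.min_level_rows)
        if len(small) == 0 or len(np.unique(level_map)) == 1:
            break
        lvl = small[0]
        target = lvl - 1 if lvl > 0 else lvl + 1
        warnings.warn(
            f"partition level {lvl} of {column!r} has fewer than "
            f"{part.min_level_rows} rows; merging with a neighbor"
        )
        uniq_lvls = np.unique(level_map)
        level_map = np.where(level_map == uniq_lvls[lvl], uniq_lvls[target], level_map)
        # relabel to consecutive
        _, level_map = np.unique(level_map, return_inverse=True)
    levels = level_map[raw]
    dim = _Dimension(
        column=column,
        col_idx=j,
        kind=kind,
        edges=edges,
        n_levels=int(levels.max()) + 1,
        level_map=level_map,
    )
    return dim, levels


class _PiecewiseDensity(_GlmDensity):
    def __init__(self, design: DesignMatrix, part: PartitionSpec, spec: PiecewiseModelSpec):
        super().__init__(design, spec)
        self.part = part
        self.pw_spec = spec
        self.dims: list[_Dimension] = []
        self.levels: list[np.ndarray] = []
        zero_dev = spec.deviation_scale is not None and spec.deviation_scale == 0.0
        for column in part.covariates:
            dim, lv = _assign_dimension(design, column, part)
            if dim.n_levels >= 2 and not zero_dev:
                self.dims.append(dim)
                self.levels.append(lv)
        self.learn_dev = spec.deviation_scale is None and bool(self.dims)
        for d, dim in enumerate(self.dims):
            self.layout.add(f"delta_{d}", dim.n_levels * (self.p + 1))
            if self.learn_dev:
                self.layout.add(f"log_dev_{d}", 1)
        # cell bookkeeping
        if self.dims:
            key = np.zeros(self.N, dtype=np.int64)
            mult = 1
            for lv, dim in zip(self.levels, self.dims):
                key += lv * mult
                mult *= dim.n_levels
            self.cell_key = key
            self.cells = np.unique(key)
            self.cell_levels = []
            for c in self.cells:
                rest, lv_c = int(c), []
                for dim in self.dims:
                    lv_c.append(rest % dim.n_levels)
                    rest //= dim.n_levels
                self.cell_levels.append(tuple(lv_c))
            self.cell_rows = [np.flatnonzero(key == c) for c in self.cells]
        else:
            self.cell_key = np.zeros(self.N, dtype=np.int64)
            self.cells = np.array([0])
            self.cell_levels = [()]
            self.cell_rows = [np.arange(self.N)]

    def initial_point(self) -> np.ndarray:
        theta = super().initial_point()
        for d in range(len(self.dims)):
            if self.learn_dev:
                theta[self.layout.slices[f"log_dev_{d}"]] = np.log(0.2)
        return theta

    def dev_scale(self, theta: np.ndarray, d: int) -> float:
        if self.learn_dev:
            return float(np.exp(self.layout.get(theta, f"log_dev_{d}")[0]))
        return float(self.pw_spec.deviation_scale)

    def deltas(self, theta: np.ndarray) -> list[np.ndarray]:
        """Deviations on the data scale (delta = s_d * delta_raw)."""
        return [
            self.dev_scale(theta, d)
            * self.layout.get(theta, f"delta_{d}").reshape(dim.n_levels, self.p + 1)
            for d, dim in enumerate(self.dims)
        ]

    def __call__(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        # non-centered as in the base GLM: beta = lam*beta_raw, u = tau*u_raw,
        # delta_d = s_d * delta_raw_d, standard-normal priors on raw scales
        if not self.dims:
            return super().__call__(theta)
        if not np.all(np.isfinite(theta)) or np.abs(theta).max() > 100.0:
            return -np.inf, np.zeros_like(theta)  # diverged trajectory
        lay, spec = self.layout, self.pw_spec
        grad = np.zeros_like(theta)
        alpha = lay.get(theta, "alpha")[0]
        beta_raw = lay.get(theta, "beta")
        lam = self._lam(theta)
        beta = lam * beta_raw
        dev_scales = [self.dev_scale(theta, d) for d in range(len(self.dims))]
        deltas_raw = [
            lay.get(theta, f"delta_{d}").reshape(dim.n_levels, self.p + 1)
            for d, dim in enumerate(self.dims)
        ]
        deltas = [s * dr for s, dr in zip(dev_scales, deltas_raw)]
        mu, sig = self.mu_sigma(theta)

        if spec.year_intercepts:
            u_raw = lay.get(theta, "u")
            tau = float(np.exp(lay.get(theta, "log_tau")[0]))
            u = tau * u_raw
        else:
            u = None

        logp = 0.0
        G1_full = np.zeros(self.N)
        g_alpha = 0.0
        g_beta = np.zeros(self.p)
        g_deltas = [np.zeros_like(d) for d in deltas]
        g_mu = np.zeros(self.M)
        g_sig = np.zeros(self.M)

        for c_idx, rows in enumerate(self.cell_rows):
            lv = self.cell_levels[c_idx]
            alpha_c = alpha + sum(deltas[d][lv[d], 0] for d in range(len(self.dims)))
            beta_c = beta + sum(deltas[d][lv[d], 1:] for d in range(len(self.dims)))
            Zc = self.Z0[rows]
            eta = alpha_c + Zc @ beta_c
            if u is not None:
                eta = eta + u[self.year_idx[rows]]
            beta_imp = beta_c[self.imp_cols]
            if self.M:
                miss_c = self.miss_r[rows]
                m = miss_c @ (beta_imp * mu)
                v = miss_c @ (beta_imp**2 * sig**2)
            else:
                m = np.zeros(len(rows))
                v = np.zeros(len(rows))
            ll, G1, G2 = bernoulli_gh(self.y[rows], eta, m, v, self.gh_x, self.gh_w)
            logp += float(ll.sum())
            G1_full[rows] = G1
            s1 = float(G1.sum())
            g_alpha += s1
            gb = Zc.T @ G1
            if self.M:
                mtG1 = miss_c.T @ G1
                mtG2 = miss_c.T @ G2
                gb[self.imp_cols] += mu * mtG1 + 2.0 * beta_imp * sig**2 * mtG2
                g_mu += beta_imp * mtG1
                g_sig += 2.0 * beta_imp**2 * sig * mtG2
            g_beta += gb
            for d in range(len(self.dims)):
                g_deltas[d][lv[d], 0] += s1
                g_deltas[d][lv[d], 1:] += gb

        grad[lay.slices["alpha"]] = g_alpha

        # priors: intercept; raw-coefficient prior + shrinkage hyperprior
        logp += -(alpha**2) / (2 * spec.intercept_scale**2)
        grad[lay.slices["alpha"]] += -alpha / spec.intercept_scale**2
        logp += -float(beta_raw @ beta_raw) / 2.0
        grad[lay.slices["beta"]] = lam * g_beta - beta_raw
        if "log_lam" in lay:
            lp, g = half_normal_logpdf_via_log(
                lay.get(theta, "log_lam")[0], spec.shrinkage_scale
            )
            logp += lp
            grad[lay.slices["log_lam"]] = g + float(g_beta @ beta)

        # deviation priors (raw standard-normal; hyperprior on each scale)
        for d, dim in enumerate(self.dims):
            s_d = dev_scales[d]
            logp += -float((deltas_raw[d] ** 2).sum()) / 2.0
            grad[lay.slices[f"delta_{d}"]] = (
                s_d * g_deltas[d] - deltas_raw[d]
            ).reshape(-1)
            if self.learn_dev:
                lp, g = half_normal_logpdf_via_log(
                    lay.get(theta, f"log_dev_{d}")[0], spec.deviation_prior_scale
                )
                logp += lp
                grad[lay.slices[f"log_dev_{d}"]] = g + float(
                    (g_deltas[d] * deltas[d]).sum()
                )

        if spec.year_intercepts:
            g_u = np.bincount(self.year_idx, weights=G1_full, minlength=self.T)
            logp += -float(u_raw @ u_raw) / 2.0
            grad[lay.slices["u"]] = tau * g_u - u_raw
            lp, g = half_normal_logpdf_via_log(lay.get(theta, "log_tau")[0], spec.tau_scale)
            logp += lp
            grad[lay.slices["log_tau"]] = g + float(g_u @ u)

        if self.learn_imputation:
            quad = self.obs_ssq - 2 * mu * self.obs_sum + self.obs_n * mu**2
            logp += float(np.sum(-self.obs_n * np.log(sig) - quad / (2 * sig**2)))
            g_mu = g_mu + (self.obs_sum - self.obs_n * mu) / sig**2
            g_sig = g_sig + (-self.obs_n / sig + quad / sig**3)
            logp += float(np.sum(-(mu**2) / (2 * spec.mu_prior_scale**2)))
            g_mu = g_mu - mu / spec.mu_prior_scale**2
            log_sig_v = lay.get(theta, "log_sig")
            lp, g = half_normal_logpdf_via_log(log_sig_v, spec.sigma_prior_scale)
            logp += float(np.sum(lp))
            grad[lay.slices["mu"]] = g_mu
            grad[lay.slices["log_sig"]] = g_sig * sig + g
        return logp, grad


class PiecewiseResults(_MarginalizedResults):
    """Results for the piecewise GLM; prediction applies each row's cell
    coefficients."""

    def __init__(self, model: "PiecewiseLogistic", posterior: Posterior):
        self.model = model
        self.design = model.design
        self.spec = model.spec
        self.posterior = posterior

    @property
    def converged(self) -> bool:
        return self.posterior.diagnostics.get("converged", True)

    def _levels_for(self, design: DesignMatrix) -> list[np.ndarray]:
        dens = self.model._density
        out = []
        for dim in dens.dims:
            values = design.Z[:, dim.col_idx]
            if dim.kind == "binary":
                uniq = np.unique(self.design.Z[:, dim.col_idx])
                raw = np.searchsorted(uniq, values)
            else:
                raw = np.digitize(values, dim.edges)
            out.append(dim.level_map[np.clip(raw, 0, len(dim.level_map) - 1)])
        return out

    def _eta_m_v(self, design: DesignMatrix):
        dens = self.model._density
        post = self.posterior.draws
        S = self.posterior.n_draws
        N = design.n_rows
        Z0 = np.where(design.mask, design.Z, 0.0)
        levels = self._levels_for(design)
        eta = np.tile(post["alpha"][:, None], (1, N))
        if "u" in post:
            year_idx = np.searchsorted(dens.years, design.year)
            eta = eta + post["u"][:, year_idx]
        m = np.zeros((S, N))
        v = np.zeros((S, N))
        miss = ~design.mask
        deltas = [
            post[f"delta_{d}"] for d in range(len(dens.dims))
        ]  # each (S, L_d, p+1)
        # group rows by cell
        if dens.dims:
            key = np.zeros(N, dtype=np.int64)
            mult = 1
            for lv, dim in zip(levels, dens.dims):
                key += lv * mult
                mult *= dim.n_levels
        else:
            key = np.zeros(N, dtype=np.int64)
        for c in np.unique(key):
            rows = np.flatnonzero(key == c)
            lv = []
            rest = int(c)
            for dim in dens.dims:
                lv.append(rest % dim.n_levels)
                rest //= dim.n_levels
            alpha_c = np.zeros(S)
            beta_c = post["beta"].copy()
            for d in range(len(dens.dims)):
                alpha_c += deltas[d][:, lv[d], 0]
                beta_c = beta_c + deltas[d][:, lv[d], 1:]
            eta[:, rows] += alpha_c[:, None] + beta_c @ Z0[rows].T
            if dens.M:
                miss_c = miss[rows][:, dens.imp_cols].astype(float)
                beta_imp = beta_c[:, dens.imp_cols]
                m[:, rows] = (beta_imp * post["mu"]) @ miss_c.T
                v[:, rows] = (beta_imp**2 * post["sigma"] ** 2) @ miss_c.T
        return eta, m, v

    def odds_ratios(self) -> OddsRatioSummary:
        """Global (cell-averaged prior) coefficients."""
        return summarize_odds_ratios(self.posterior.draws["beta"], self.design.columns)

    def effective_coefficients(self) -> dict[tuple, OddsRatioSummary]:
        return effective_coefficients(self)


class PiecewiseLogistic:
    """Piecewise-linear Bayesian logistic regression (additive decomposition)."""

    def __init__(
        self,
        design: DesignMatrix,
        partition: PartitionSpec,
        spec: Optional[PiecewiseModelSpec] = None,
    ):
        if design.n_rows == 0:
            raise ValueError("empty design")
        self.design = design
        self.partition = partition
        self.spec = spec or PiecewiseModelSpec()
        self._density = _PiecewiseDensity(design, partition, self.spec)

    def fit(self, seed: int = 0) -> PiecewiseResults:
        dens = self._density
        spec = self.spec
        theta0 = find_map(
            dens, dens.initial_point(), frozen=dens.frozen_map_indices()
        )
        if spec.algorithm == "hmc":
            res = hmc_sample(
                dens,
                theta0,
                draws=spec.draws,
                warmup=spec.warmup,
                chains=spec.chains,
                seed=seed,
                max_leapfrog=spec.max_leapfrog,
                target_accept=spec.target_accept,
            )
            flat = res.flat()
            diagnostics = {
                "algorithm": "hmc",
                "accept_rate": res.diagnostics.accept_rate,
                "divergences": res.diagnostics.divergences,
                "rhat_max": res.diagnostics.rhat_max,
                "converged": res.diagnostics.converged,
            }
            if not res.diagnostics.converged:
                warnings.warn("piecewise GLM fit flagged by convergence diagnostics")
            chains = spec.chains
        else:
            vi = fit_vi(dens, theta0, steps=spec.vi_steps, seed=seed)
            rng = np.random.default_rng(seed + 1)
            flat = vi.sample(spec.draws * spec.chains, rng)
            diagnostics = {"algorithm": "vi", "elbo": vi.elbo, "converged": True}
            chains = 1

        lay = dens.layout
        if spec.fixed_shrinkage is None:
            lam = np.exp(flat[:, lay.slices["log_lam"]][:, 0])
        else:
            lam = np.full(flat.shape[0], spec.fixed_shrinkage)
        draws: dict[str, np.ndarray] = {
            "alpha": flat[:, lay.slices["alpha"]][:, 0],
            "beta": lam[:, None] * flat[:, lay.slices["beta"]],
        }
        if spec.year_intercepts:
            tau = np.exp(flat[:, lay.slices["log_tau"]][:, 0])
            draws["u"] = tau[:, None] * flat[:, lay.slices["u"]]
            draws["tau"] = tau
        if spec.fixed_shrinkage is None:
            draws["lam"] = lam
        for d, dim in enumerate(dens.dims):
            if dens.learn_dev:
                s_d = np.exp(flat[:, lay.slices[f"log_dev_{d}"]][:, 0])
                draws[f"dev_scale_{d}"] = s_d
            else:
                s_d = np.full(flat.shape[0], spec.deviation_scale)
            draws[f"delta_{d}"] = s_d[:, None, None] * flat[
                :, lay.slices[f"delta_{d}"]
            ].reshape(flat.shape[0], dim.n_levels, dens.p + 1)
        if dens.M:
            if dens.learn_imputation:
                draws["mu"] = flat[:, lay.slices["mu"]]
                draws["sigma"] = np.exp(flat[:, lay.slices["log_sig"]])
            else:
                S = flat.shape[0]
                mu0, sig0 = spec.fixed_imputation
                draws["mu"] = np.full((S, dens.M), mu0)
                draws["sigma"] = np.full((S, dens.M), sig0)

        posterior = Posterior(
            draws=draws,
            chains=chains,
            seed=seed,
            diagnostics=diagnostics,
            column_names=self.design.column_names,
            imp_col_names=[self.design.columns[j].name for j in dens.imp_cols],
        )
        return PiecewiseResults(self, posterior)


def fit_piecewise_glm(
    design: DesignMatrix,
    partition: PartitionSpec,
    spec: Optional[PiecewiseModelSpec] = None,
    seed: int = 0,
) -> PiecewiseResults:
    return PiecewiseLogistic(design, partition, spec).fit(seed=seed)


def effective_coefficients(results: PiecewiseResults) -> dict[tuple, OddsRatioSummary]:
    """Per-cell odds-ratio summaries of exp(beta_global + sum_d delta)."""
    dens = results.model._density
    post = results.posterior.draws
    out: dict[tuple, OddsRatioSummary] = {}
    for lv in dens.cell_levels:
        beta_c = post["beta"].copy()
        for d, level in enumerate(lv):
            beta_c = beta_c + post[f"delta_{d}"][:, level, 1:]
        out[lv] = summarize_odds_ratios(beta_c, results.design.columns)
    return out
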