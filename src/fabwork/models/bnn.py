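"""Shallow Bayesian neural network for the steady-work outcome.

A single hidden layer (default width 12, tanh activation):

    y_i ~ Bernoulli(logit^-1(w2' tanh(W1 z_i + b1) + b2))

with Normal(0, weight_scale) priors on all weights and biases.  Missing
standardized covariate cells are per-cell latents with standard-normal
priors on the standardized scale, fitted jointly with the weights.  The
latents enter the first layer nonlinearly, so no quadrature collapse is
available; inference is mean-field Gaussian variational with random
restarts (hand-derived reparameterization gradients, Adam).

``width_scan`` refits across hidden widths and ranks them by PSIS-LOO elpd
with a one-standard-error preference for smaller widths.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy.special import expit

from ..prep import DesignMatrix
from .hmc import find_map, fit_vi
from .likelihood import log_sigmoid
from .logistic import Posterior, _Layout

logger = logging.getLogger(__name__)


class BnnSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    hidden: int = Field(default=12, ge=1)
    scan_range: tuple[int, int] = (2, 20)
    weight_scale: float = Field(default=1.0, gt=0)
    activation: str = "tanh"
    draws: int = Field(default=500, ge=100)
    vi_steps: int = Field(default=4000, ge=100)
    restarts: int = Field(default=5, ge=1)
    learning_rate: float = Field(default=0.02, gt=0)

    @property
    def scan_widths(self) -> list[int]:
        lo, hi = self.scan_range
        if lo > hi:
            raise ValueError("empty width-scan range")
        return list(range(lo, hi + 1))


class _BnnDensity:
    def __init__(self, design: DesignMatrix, spec: BnnSpec):
        if spec.activation != "tanh":
            raise ValueError("only the tanh activation is supported")
        self.spec = spec
        self.y = design.y.astype(float)
        self.s = 2.0 * self.y - 1.0
        self.Z0 = np.where(design.mask, design.Z, 0.0)
        self.N, self.p = self.Z0.shape
        miss = np.argwhere(~design.mask)
        self.miss_rows = miss[:, 0]
        self.miss_cols = miss[:, 1]
        self.n_miss = len(miss)
        H = spec.hidden
        lay = _Layout()
        lay.add("W1", H * self.p)
        lay.add("b1", H)
        lay.add("w2", H)
        lay.add("b2", 1)
        if self.n_miss:
            lay.add("z", self.n_miss)
        self.layout = lay
        self.H = H

    def fill_design(self, z: Optional[np.ndarray]) -> np.ndarray:
        Z = self.Z0
        if self.n_miss and z is not None:
            Z = Z.copy()
            Z[self.miss_rows, self.miss_cols] = z
        return Z

    def __call__(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        if not np.all(np.isfinite(theta)) or np.abs(theta).max() > 100.0:
            return -np.inf, np.zeros_like(theta)  # diverged trajectory
        lay, spec = self.layout, self.spec
        W1 = lay.get(theta, "W1").reshape(self.H, self.p)
        b1 = lay.get(theta, "b1")
        w2 = lay.get(theta, "w2")
        b2 = lay.get(theta, "b2")[0]
        z = lay.get(theta, "z") if self.n_miss else None
        Z = self.fill_design(z)

        A = np.tanh(Z @ W1.T + b1)  # (N, H)
        f = A @ w2 + b2
        a = self.s * f
        logp = float(log_sigmoid(a).sum())
        gf = self.s * expit(-a)  # (N,)

        grad = np.zeros_like(theta)
        grad[lay.slices["w2"]] = A.T @ gf
        grad[lay.slices["b2"]] = gf.sum()
        gA = gf[:, None] * w2[None, :]
        gH = gA * (1.0 - A**2)
        grad[lay.slices["W1"]] = (gH.T @ Z).reshape(-1)
        grad[lay.slices["b1"]] = gH.sum(axis=0)
        if self.n_miss:
            gZ = gH @ W1  # (N, p)
            grad[lay.slices["z"]] = gZ[self.miss_rows, self.miss_cols]

        ws2 = spec.weight_scale**2
        for key in ("W1", "b1", "w2", "b2"):
            vals = lay.get(theta, key)
            logp += float(-(vals**2).sum() / (2 * ws2))
            grad[lay.slices[key]] += -vals / ws2
        if self.n_miss:
            logp += float(-(z**2).sum() / 2.0)  # standard-normal latent prior
            grad[lay.slices["z"]] += -z
        return logp, grad


class BnnResults:
    """Posterior draws and predictions for the Bayesian neural network.

    Exposes the same pointwise_loglik / predictive_draws / predict_prob /
    loo contract as the GLM results, so evaluation is model-agnostic.
    """

    def __init__(self, model: "BayesianNeuralNet", posterior: Posterior):
        self.model = model
        self.design = model.design
        self.spec = model.spec
        self.posterior = posterior

    @property
    def converged(self) -> bool:
        return self.posterior.diagnostics.get("converged", True)

    def _f_draws(self, design: Optional[DesignMatrix] = None) -> np.ndarray:
        """(S, N) draws of the pre-sigmoid output."""
        dens = self.model._density
        post = self.posterior.draws
        S = self.posterior.n_draws
        own = design is None or design is self.design
        target = self.design if own else design
        if not own and target.column_names != self.design.column_names:
            raise ValueError("design columns do not match the fitted design")
        Zbase = np.where(target.mask, target.Z, 0.0)
        miss = np.argwhere(~target.mask)
        rng = np.random.default_rng(self.posterior.seed + 777_003)
        out = np.empty((S, target.n_rows))
        for s in range(S):
            Z = Zbase
            if len(miss):
                Z = Zbase.copy()
                if own and dens.n_miss:
                    Z[dens.miss_rows, dens.miss_cols] = post["z"][s]
                else:
                    Z[miss[:, 0], miss[:, 1]] = rng.normal(size=len(miss))
            A = np.tanh(Z @ post["W1"][s].T + post["b1"][s])
            out[s] = A @ post["w2"][s] + post["b2"][s]
        return out

    def pointwise_loglik(self, design: Optional[DesignMatrix] = None) -> np.ndarray:
        target = self.design if design is None else design
        f = self._f_draws(design)
        return log_sigmoid((2.0 * target.y[None, :] - 1.0) * f)

    def predictive_draws(self, design: Optional[DesignMatrix] = None) -> np.ndarray:
        return expit(self._f_draws(design))

    def predict_prob(self, design: Optional[DesignMatrix] = None) -> np.ndarray:
        return self.predictive_draws(design).mean(axis=0)

    def loo(self, thin_to: Optional[int] = None):
        from ..evaluation import loo_predictive

        loglik = self.pointwise_loglik()
        pred = self.predictive_draws()
        if thin_to is not None and thin_to < loglik.shape[0]:
            idx = np.linspace(0, loglik.shape[0] - 1, thin_to).astype(int)
            loglik, pred = loglik[idx], pred[idx]
        return loo_predictive(loglik, pred)


class BayesianNeuralNet:
    """Shallow BNN classifier fitted by mean-field variational inference."""

    def __init__(self, design: DesignMatrix, spec: Optional[BnnSpec] = None):
        if design.n_rows == 0:
            raise ValueError("empty design")
        self.design = design
        self.spec = spec or BnnSpec()
        self._density = _BnnDensity(design, self.spec)

    def fit(self, seed: int = 0) -> BnnResults:
        dens = self._density
        spec = self.spec
        root = np.random.SeedSequence(seed)
        vi = None
        # restarts: random init -> L-BFGS mode -> mean-field VI around it;
        # the best trailing-average ELBO wins (guards against mode collapse)
        for ss in root.spawn(spec.restarts):
            rng = np.random.default_rng(ss)
            init = np.zeros(dens.layout.dim)
            init[dens.layout.slices["W1"]] = rng.normal(
                0.0, 1.0 / np.sqrt(dens.p), size=dens.H * dens.p
            )
            init[dens.layout.slices["b1"]] = rng.normal(0.0, 0.3, size=dens.H)
            init[dens.layout.slices["w2"]] = rng.normal(0.0, 0.5, size=dens.H)
            mode = find_map(dens, init, maxiter=300)
            cand = fit_vi(
                dens,
                mode,
                steps=spec.vi_steps,
                learning_rate=spec.learning_rate,
                seed=int(rng.integers(2**31)),
                init_log_sd=-3.0,
            )
            if vi is None or cand.elbo > vi.elbo:
                vi = cand
        converged = bool(np.isfinite(vi.elbo))
        if not converged:
            warnings.warn("BNN variational fit did not converge")
        flat = vi.sample(spec.draws, np.random.default_rng(seed + 1))
        lay = dens.layout
        S = flat.shape[0]
        draws = {
            "W1": flat[:, lay.slices["W1"]].reshape(S, dens.H, dens.p),
            "b1": flat[:, lay.slices["b1"]],
            "w2": flat[:, lay.slices["w2"]],
            "b2": flat[:, lay.slices["b2"]][:, 0],
            # alpha key kept for the shared Posterior container draw count
            "alpha": flat[:, lay.slices["b2"]][:, 0],
        }
        if dens.n_miss:
            draws["z"] = flat[:, lay.slices["z"]]
        posterior = Posterior(
            draws=draws,
            chains=1,
            seed=seed,
            diagnostics={
                "algorithm": "vi",
                "elbo": vi.elbo,
                "converged": converged,
                "hidden": dens.H,
                "activation": spec.activation,
            },
            column_names=self.design.column_names,
            imp_col_names=[
                self.design.columns[j].name for j in np.unique(dens.miss_cols)
            ]
            if dens.n_miss
            else [],
        )
        return BnnResults(self, posterior)


def fit_bnn(
    design: DesignMatrix, spec: Optional[BnnSpec] = None, seed: int = 0
) -> BnnResults:
    return BayesianNeuralNet(design, spec).fit(seed=seed)


def width_scan(
    design: DesignMatrix,
    spec: Optional[BnnSpec] = None,
    seed: int = 0,
    widths: Optional[list[int]] = None,
    thin_to: Optional[int] = 500,
) -> pd.DataFrame:
    """Fit the BNN across hidden widths; rank by PSIS-LOO elpd.

    Returns a table sorted by width with the chosen width (argmax elpd with
    one-SE tie-breaking toward smaller widths) in ``df.attrs["selected"]``.
    Failed widths are logged and excluded.
    """
    spec = spec or BnnSpec()
    widths = widths if widths is not None else spec.scan_widths
    rows = []
    for h in widths:
        sub = spec.model_copy(update={"hidden": h})
        try:
            res = BayesianNeuralNet(design, sub).fit(seed=seed)
            loo = res.loo(thin_to=thin_to)
            rows.append(
                {
                    "hidden": h,
                    "elpd_loo": loo.elpd_loo,
                    "elpd_se": loo.se,
                    "n_high_khat": loo.n_high_khat,
                }
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("width %d failed: %s", h, exc)
    df = pd.DataFrame(rows).sort_values("hidden").reset_index(drop=True)
    if len(df):
        best = df.loc[df["elpd_loo"].idxmax()]
        ok = df[df["elpd_loo"] >= best["elpd_loo"] - best["elpd_se"]]
        df.attrs["selected"] = int(ok["hidden"].min())
    return df
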