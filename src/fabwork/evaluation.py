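"""Model evaluation: PSIS-LOO, and LOO-cross-validated ROC / PR curves.

Leave-one-out predictive quantities are estimated by Pareto-smoothed
importance sampling (PSIS): for observation i the raw importance weights are
1 / p(y_i | theta^(s)); the largest M = min(ceil(0.2 S), ceil(3 sqrt(S)))
weights are replaced by expected order statistics of a generalized Pareto
distribution fitted to the weight tail, truncated at the raw maximum, and
normalized.  The fitted shape k-hat diagnoses reliability (k-hat > 0.7 is
flagged).  The smoothed weights give the LOO predictive probability of each
observation, from which leave-one-out ROC and precision-recall curves and
their areas are computed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

KHAT_WARN = 0.7


# ---------------------------------------------------------------------------
# generalized Pareto tail fit
# ---------------------------------------------------------------------------


def fit_gpd_tail(exceedances: np.ndarray) -> tuple[float, float]:
    """Fit a generalized Pareto distribution to positive exceedances.

    Profile-posterior point estimate (quadrature over the transformed scale
    parameter with a weakly informative regularization of the shape toward
    0.5).  Returns (k_hat, sigma_hat); (nan, nan) with fewer than 5 values.
    """
    x = np.sort(np.asarray(exceedances, dtype=float))
    n = len(x)
    if n < 5 or x[-1] <= 0:
        return float("nan"), float("nan")
    if x[0] == x[-1]:  # constant exceedances: degenerate boundary case
        return -1.0, 0.0
    prior_bs, prior_k = 3.0, 10.0
    m_grid = 30 + int(np.sqrt(n))
    jj = np.arange(1, m_grid + 1, dtype=float)
    xstar = x[int(n / 4.0 + 0.5) - 1]
    b = 1.0 / x[-1] + (1.0 - np.sqrt(m_grid / (jj - 0.5))) / (prior_bs * xstar)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.log1p(-b[:, None] * x[None, :]).mean(axis=1)
        log_lik = n * (np.log(-b / k) - k - 1.0)
    log_lik = np.where(np.isfinite(log_lik), log_lik, -np.inf)
    # posterior weight of each grid point: exp(L_i) / sum_j exp(L_j)
    with np.errstate(over="ignore"):
        w = 1.0 / np.exp(log_lik[None, :] - log_lik[:, None]).sum(axis=1)
    w = np.where(np.isfinite(w), w, 0.0)
    if w.sum() <= 0:
        return float("nan"), float("nan")
    b_post = float(np.sum(b * w) / w.sum())
    k_post = float(np.log1p(-b_post * x).mean())
    sigma = -k_post / b_post
    k_post = (n * k_post + prior_k * 0.5) / (n + prior_k)
    return k_post, float(sigma)


def _gpd_quantile(p: np.ndarray, k: float, sigma: float) -> np.ndarray:
    if abs(k) < 1e-12:
        return -sigma * np.log1p(-p)
    return sigma * np.expm1(-k * np.log1p(-p)) / k


def psis_smooth(log_weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Pareto-smooth raw log importance weights.

    Returns (normalized weights summing to 1, k_hat).  With S < 25 draws the
    smoothing is skipped in favor of plain truncated importance sampling
    (truncation at sqrt(S) times the mean weight), and k_hat is NaN.
    """
    lw = np.asarray(log_weights, dtype=float)
    if not np.isfinite(lw).all():
        raise ValueError("non-finite log-weights")
    S = len(lw)
    lw = lw - lw.max()
    if S < 25:
        warnings.warn("fewer than 25 draws: falling back to truncated IS")
        w = np.exp(lw)
        w = np.minimum(w, np.sqrt(S) * w.mean())
        return w / w.sum(), float("nan")

    M = int(min(np.ceil(0.2 * S), np.ceil(3.0 * np.sqrt(S))))
    order = np.argsort(lw)
    tail_ids = order[S - M :]
    cutoff_lw = lw[order[S - M - 1]]
    raw_max = np.exp(lw.max())  # == 1 after shift

    w = np.exp(lw)
    exceed = w[tail_ids] - np.exp(cutoff_lw)
    khat, sigma = fit_gpd_tail(exceed)
    if np.isfinite(khat) and len(np.unique(exceed)) >= 5 and sigma > 0:
        probs = (np.arange(1, M + 1) - 0.5) / M
        smoothed = np.exp(cutoff_lw) + _gpd_quantile(probs, khat, sigma)
        # assign expected order statistics in rank order of the raw tail
        rank = np.argsort(w[tail_ids])
        new_tail = np.empty(M)
        new_tail[rank] = smoothed
        w[tail_ids] = np.minimum(new_tail, raw_max)
    return w / w.sum(), khat


# ---------------------------------------------------------------------------
# LOO predictive quantities
# ---------------------------------------------------------------------------


@dataclass
class LooResult:
    """Per-observation PSIS-LOO quantities and totals."""

    elpd_i: np.ndarray
    p_hat: np.ndarray
    khat: np.ndarray
    elpd_loo: float
    se: float
    n_high_khat: int

    @property
    def n_obs(self) -> int:
        return len(self.elpd_i)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"elpd_loo_i": self.elpd_i, "p_loo": self.p_hat, "khat": self.khat}
        )


def loo_predictive(loglik: np.ndarray, pred_draws: np.ndarray) -> LooResult:
    """PSIS-LOO from an (S, N) pointwise log-likelihood matrix and matched
    (S, N) per-draw event probabilities."""
    loglik = np.asarray(loglik, dtype=float)
    pred_draws = np.asarray(pred_draws, dtype=float)
    if loglik.shape != pred_draws.shape:
        raise ValueError("loglik and pred_draws shapes differ")
    bad = ~np.isfinite(loglik)
    if bad.any():
        raise ValueError(f"non-finite log-likelihood entries at {np.argwhere(bad)[:5]}")
    S, N = loglik.shape
    elpd = np.empty(N)
    p_hat = np.empty(N)
    khat = np.empty(N)
    if S == 1:
        return LooResult(
            elpd_i=loglik[0].copy(),
            p_hat=pred_draws[0].copy(),
            khat=np.full(N, np.nan),
            elpd_loo=float(loglik.sum()),
            se=float(np.sqrt(N) * loglik[0].std(ddof=1)) if N > 1 else 0.0,
            n_high_khat=0,
        )
    for i in range(N):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w, k = psis_smooth(-loglik[:, i])
        elpd[i] = logsumexp(loglik[:, i], b=w)
        p_hat[i] = float(w @ pred_draws[:, i])
        khat[i] = k
    se = float(np.sqrt(N) * elpd.std(ddof=1)) if N > 1 else 0.0
    return LooResult(
        elpd_i=elpd,
        p_hat=p_hat,
        khat=khat,
        elpd_loo=float(elpd.sum()),
        se=se,
        n_high_khat=int(np.nansum(khat > KHAT_WARN)),
    )


# ---------------------------------------------------------------------------
# ROC and precision-recall curves
# ---------------------------------------------------------------------------


@dataclass
class CurveResult:
    """Operating points of a classification curve plus its area."""

    kind: str  # "roc" or "prc"
    points: np.ndarray  # (k, 2): (FPR, TPR) or (recall, precision)
    thresholds: np.ndarray
    auc: float
    baseline: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        x, y = ("fpr", "tpr") if self.kind == "roc" else ("recall", "precision")
        df = pd.DataFrame(self.points, columns=[x, y])
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _grouped_counts(scores: np.ndarray, y: np.ndarray):
    """Cumulative TP/FP at each unique threshold, descending; tied scores
    cross the threshold together."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = y[order]
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    idx = np.flatnonzero(distinct)
    tp = np.cumsum(y_sorted)[idx]
    fp = np.cumsum(1 - y_sorted)[idx]
    return s_sorted[idx], tp.astype(float), fp.astype(float)


def roc_curve(p_hat: np.ndarray, y: np.ndarray) -> CurveResult:
    """Receiver operating characteristic with trapezoidal AUROC."""
    y = np.asarray(y).astype(int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_curve requires both classes present")
    thresholds, tp, fp = _grouped_counts(p_hat, y)
    tpr = np.r_[0.0, tp / n1]
    fpr = np.r_[0.0, fp / n0]
    auc = float(np.trapezoid(tpr, fpr))
    return CurveResult(
        kind="roc",
        points=np.column_stack([fpr, tpr]),
        thresholds=thresholds,
        auc=auc,
    )


def pr_curve(p_hat: np.ndarray, y: np.ndarray) -> CurveResult:
    """Precision-recall curve; AUPRC by step-wise (right-continuous)
    interpolation, which is unbiased for PR curves where the linear
    trapezoid is not."""
    y = np.asarray(y).astype(int)
    n1 = int(y.sum())
    if n1 == 0:
        raise ValueError("pr_curve requires at least one positive")
    thresholds, tp, fp = _grouped_counts(p_hat, y)
    recall = tp / n1
    precision = tp / (tp + fp)
    auc = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return CurveResult(
        kind="prc",
        points=np.column_stack([recall, precision]),
        thresholds=thresholds,
        auc=auc,
        baseline=n1 / len(y),
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


@dataclass
class ModelEvaluation:
    """One model's LOO-CV evaluation bundle."""

    name: str
    covariate_set: str
    loo: LooResult
    roc: CurveResult
    prc: CurveResult
    y: np.ndarray

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.roc.to_csv(directory / "roc.csv")
        self.prc.to_csv(directory / "prc.csv")
        self.loo.to_frame().to_csv(directory / "loo_pointwise.csv", index=False)
        summary = {
            "name": self.name,
            "covariate_set": self.covariate_set,
            "elpd_loo": self.loo.elpd_loo,
            "elpd_se": self.loo.se,
            "auroc": self.roc.auc,
            "auprc": self.prc.auc,
            "prevalence": self.prc.baseline,
            "n_high_khat": self.loo.n_high_khat,
        }
        (directory / "summary.json").write_text(json.dumps(summary, indent=2))


def evaluate_model(results, name: str, thin_to: Optional[int] = 1000) -> ModelEvaluation:
    """PSIS-LOO + LOO-CV curves for any fitted results object exposing the
    pointwise_loglik / predictive_draws contract."""
    loglik = results.pointwise_loglik()
    pred = results.predictive_draws()
    if thin_to is not None and thin_to < loglik.shape[0]:
        idx = np.linspace(0, loglik.shape[0] - 1, thin_to).astype(int)
        loglik, pred = loglik[idx], pred[idx]
    loo = loo_predictive(loglik, pred)
    y = results.design.y
    return ModelEvaluation(
        name=name,
        covariate_set=results.design.covariate_set,
        loo=loo,
        roc=roc_curve(loo.p_hat, y),
        prc=pr_curve(loo.p_hat, y),
        y=y,
    )


def compare_models(evaluations: Sequence[ModelEvaluation]) -> pd.DataFrame:
    """Ranked comparison table; models must share the observation set."""
    if not evaluations:
        raise ValueError("no evaluations to compare")
    y0 = evaluations[0].y
    for ev in evaluations[1:]:
        if len(ev.y) != len(y0) or not np.array_equal(ev.y, y0):
            raise ValueError(
                f"evaluation {ev.name!r} uses a different observation set; "
                "comparison invalid"
            )
    rows = [
        {
            "model": ev.name,
            "covariate_set": ev.covariate_set,
            "elpd_loo": ev.loo.elpd_loo,
            "elpd_se": ev.loo.se,
            "auroc": ev.roc.auc,
            "auprc": ev.prc.auc,
            "n_high_khat": ev.loo.n_high_khat,
        }
        for ev in evaluations
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["auroc", "elpd_loo"], ascending=False)
        .reset_index(drop=True)
    )
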