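"""Bayesian model sampling (BMS) over two-way fixed-effects linear models.

Candidate covariates are screened by computing posterior inclusion
probabilities (PIPs) over the 2^K space of linear FE models.  The panel is
first demeaned (regional FE) and carries year dummies; the dummies plus
any user-designated always-included regressors form the *fixed* block and
are partialled out of the outcome and the candidates before each model's
marginal likelihood is evaluated under a Zellner g-prior on the candidate
block with a flat prior on the fixed block and p(sigma2) ~ 1/sigma2:

    log m(M) = -(k_M / 2) log(1 + g)
               - ((n - q) / 2) log( y'y - g/(1+g) * y' P_M y )

(all quantities on the residualized data; q = rank of the fixed block,
k_M = candidates included in M, P_M the projection on them).  Defaults are
the conventional unit-information prior g = n and a uniform model prior.

Model space exploration is exact enumeration for small K, or an MC3
(Markov chain Monte Carlo model composition) Metropolis chain with
add/drop/swap moves; marginal likelihoods are cached per visited model,
so chains on enumerable spaces are cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .panel_prep import PanelDataset

__all__ = ["BmsConfig", "BmsResult", "run_bms", "select_covariates"]

logger = logging.getLogger(__name__)

MAX_ENUM = 2**20


@dataclass
class BmsConfig:
    """Configuration of one BMS run.

    ``fixed_columns`` are always included (the panel's year dummies are
    added to them automatically); ``candidate_columns`` are sampled over.
    """

    candidate_columns: list[str]
    fixed_columns: list[str] = field(default_factory=list)
    g_prior: Literal["unit_information", "fixed_g"] = "unit_information"
    g: float | None = None
    model_prior: Literal["uniform", "binomial"] = "uniform"
    prior_inclusion_prob: float = 0.5
    sampler: Literal["enumerate", "mc3"] = "enumerate"
    n_draws: int = 50_000
    burn_in: int = 2_000
    seed: int = 20080101

    def __post_init__(self) -> None:
        overlap = set(self.candidate_columns) & set(self.fixed_columns)
        if overlap:
            raise ValueError(f"columns both candidate and fixed: {sorted(overlap)}")
        if not self.candidate_columns:
            raise ValueError("need at least one candidate column")
        if self.sampler == "enumerate" and 2 ** len(self.candidate_columns) > MAX_ENUM:
            raise ValueError(
                f"2^{len(self.candidate_columns)} models is too many to enumerate; "
                "use sampler='mc3'"
            )
        if not 0 < self.prior_inclusion_prob < 1:
            raise ValueError("prior_inclusion_prob must be in (0, 1)")


@dataclass
class BmsResult:
    """Posterior inclusion probabilities and model posterior masses."""

    pip: pd.Series
    top_models: list[tuple[tuple[int, ...], float]]
    marginal_logliks: dict[tuple[int, ...], float]
    fixed_columns: list[str]
    sampler: str
    n_models_visited: int
    total_mass: float = 1.0


class _MarginalLikelihood:
    """Cached g-prior marginal log-likelihoods on residualized data."""

    def __init__(self, y_r: np.ndarray, Z_r: np.ndarray, n_eff: int, g: float):
        self.n_eff = n_eff
        self.g = g
        self.yy = float(y_r @ y_r)
        self.G = Z_r.T @ Z_r
        self.v = Z_r.T @ y_r
        self.shrink = g / (1.0 + g)
        self._cache: dict[tuple[int, ...], float] = {}

    def __call__(self, mask: tuple[int, ...]) -> float:
        val = self._cache.get(mask)
        if val is not None:
            return val
        k = sum(mask)
        if k == 0:
            val = -0.5 * self.n_eff * np.log(self.yy)
        else:
            idx = np.flatnonzero(mask)
            G = self.G[np.ix_(idx, idx)]
            try:
                L = np.linalg.cholesky(G)
            except np.linalg.LinAlgError:
                logger.warning("rank-deficient candidate block %s: zero mass", mask)
                self._cache[mask] = -np.inf
                return -np.inf
            w = np.linalg.solve(L, self.v[idx])
            ssr = self.yy - self.shrink * float(w @ w)
            if ssr <= 0:
                ssr = np.finfo(float).tiny
            val = -0.5 * k * np.log(1.0 + self.g) - 0.5 * self.n_eff * np.log(ssr)
        self._cache[mask] = float(val)
        return float(val)


def _residualize(y: np.ndarray, Z: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Project the fixed block out of y and the candidates."""
    if F.shape[1] == 0:
        return y, Z, 0
    Q, R = np.linalg.qr(F)
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R).max())))
    y_r = y - Q @ (Q.T @ y)
    Z_r = Z - Q @ (Q.T @ Z)
    return y_r, Z_r, rank


def _log_model_prior(mask: tuple[int, ...], config: BmsConfig) -> float:
    if config.model_prior == "uniform":
        return 0.0
    k, K = sum(mask), len(mask)
    pi = config.prior_inclusion_prob
    return k * np.log(pi) + (K - k) * np.log1p(-pi)


def run_bms(panel: PanelDataset, config: BmsConfig) -> BmsResult:
    """Run Bayesian model sampling on a demeaned panel with year dummies.

    Returns PIPs for the candidates (fixed columns have PIP 1 by
    construction) and the visited models with their posterior mass —
    exact under enumeration, Monte-Carlo frequencies under MC3.
    """
    if not panel.demeaned:
        raise ValueError("panel must be within-transformed before BMS")
    if not panel.year_dummies:
        logger.warning("panel has no year dummies; BMS runs without time FE")

    cand = list(config.candidate_columns)
    fixed = list(dict.fromkeys(config.fixed_columns + panel.year_dummies))
    missing = (set(cand) | set(fixed)) - set(panel.data.columns)
    if missing:
        raise ValueError(f"unknown columns {sorted(missing)}")

    y = panel.y()
    Z = panel.data[cand].to_numpy(float)
    F = panel.data[fixed].to_numpy(float) if fixed else np.empty((len(y), 0))
    n = len(y)
    y_r, Z_r, q = _residualize(y, Z, F)
    g = float(n) if config.g_prior == "unit_information" else float(config.g or n)
    lnm = _MarginalLikelihood(y_r, Z_r, n - q, g)
    K = len(cand)

    if config.sampler == "enumerate":
        masks = [tuple((m >> j) & 1 for j in range(K)) for m in range(2**K)]
        logpost = np.array([lnm(mk) + _log_model_prior(mk, config) for mk in masks])
        lz = logsumexp(logpost)
        mass = np.exp(logpost - lz)
        pip_vals = np.zeros(K)
        for mk, ms in zip(masks, mass):
            pip_vals += ms * np.array(mk)
        order = np.argsort(mass)[::-1]
        top = [(masks[i], float(mass[i])) for i in order[:25]]
        result_mass = {mk: float(m) for mk, m in zip(masks, mass)}
        pip = pd.Series(pip_vals, index=cand)
        return BmsResult(
            pip=pip,
            top_models=top,
            marginal_logliks={mk: lnm(mk) for mk in masks},
            fixed_columns=fixed,
            sampler="enumerate",
            n_models_visited=len(masks),
            total_mass=float(sum(result_mass.values())),
        )

    # ---- MC3 -------------------------------------------------------------
    rng = np.random.default_rng(config.seed)
    mask = tuple(rng.integers(0, 2, size=K).tolist())
    cur = lnm(mask) + _log_model_prior(mask, config)
    incl = np.zeros(K)
    visits: dict[tuple[int, ...], int] = {}
    kept = 0
    for it in range(config.n_draws + config.burn_in):
        prop = list(mask)
        if K >= 2 and rng.random() < 0.25:
            ones = [j for j in range(K) if mask[j]]
            zeros = [j for j in range(K) if not mask[j]]
            if ones and zeros:  # swap move keeps model size
                prop[ones[rng.integers(len(ones))]] = 0
                prop[zeros[rng.integers(len(zeros))]] = 1
            else:
                j = int(rng.integers(K))
                prop[j] = 1 - prop[j]
        else:
            j = int(rng.integers(K))
            prop[j] = 1 - prop[j]
        prop_t = tuple(prop)
        cand_post = lnm(prop_t) + _log_model_prior(prop_t, config)
        if np.log(rng.random()) < cand_post - cur:
            mask, cur = prop_t, cand_post
        if it >= config.burn_in:
            kept += 1
            incl += np.array(mask)
            visits[mask] = visits.get(mask, 0) + 1

    pip = pd.Series(incl / kept, index=cand)
    top = sorted(visits.items(), key=lambda kv: kv[1], reverse=True)[:25]
    top_models = [(mk, c / kept) for mk, c in top]
    return BmsResult(
        pip=pip,
        top_models=top_models,
        marginal_logliks=dict(lnm._cache),
        fixed_columns=fixed,
        sampler="mc3",
        n_models_visited=len(visits),
        total_mass=1.0,
    )


def select_covariates(
    result: BmsResult, threshold: float = 0.5
) -> list[str]:
    """Candidates with PIP >= threshold, plus all fixed columns.

    The 0.5 default is the median-probability model rule.  Ordering is
    deterministic: candidates in their original order, then fixed columns.
    """
    chosen = [c for c in result.pip.index if result.pip[c] >= threshold]
    return chosen + [c for c in result.fixed_columns if c not in chosen]
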