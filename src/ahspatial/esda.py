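"""Exploratory spatial data analysis: global Moran's I.

Moran's I measures global spatial autocorrelation of a district-level
variable x under a weights matrix W:

    I = (N / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with S0 the sum of all weights.  Under the null of no spatial structure
E[I] = -1/(N-1).  Inference is available under the normality and
randomization (permutation-moment) analytic nulls, and by seeded Monte
Carlo permutation of x (the default: the null the analytic formulas
approximate, without their assumptions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .weights import SpatialWeights

__all__ = ["MoranResult", "morans_i", "moran_by_year", "moran_pooled"]

logger = logging.getLogger(__name__)

Inference = Literal["normal", "randomization", "permutation"]


@dataclass
class MoranResult:
    """Moran's I with its null moments and a p-value.

    ``p_value`` is one-sided toward the observed side of E[I] for
    permutation inference, and two-sided for the analytic nulls.
    ``sim`` holds the permutation replicates (permutation inference only).
    """

    I: float
    expected_I: float
    variance_I: float
    z_score: float
    p_value: float
    inference: Inference
    n_used: int
    sim: np.ndarray | None = None


def _moments(w: np.ndarray, x: np.ndarray, inference: Inference) -> tuple[float, float]:
    n = len(x)
    s0 = w.sum()
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    e_i = -1.0 / (n - 1)
    if inference == "normal":
        var = (n * n * s1 - n * s2 + 3 * s0 * s0) / ((n * n - 1) * s0 * s0) - e_i**2
    else:  # randomization
        z = x - x.mean()
        m2 = (z**2).sum() / n
        m4 = (z**4).sum() / n
        b2 = m4 / m2**2
        num = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0) - b2 * (
            (n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0
        )
        var = num / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - e_i**2
    return e_i, float(var)


def morans_i(
    x: np.ndarray,
    W: SpatialWeights,
    inference: Inference = "permutation",
    n_perm: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I of ``x`` (ordered like ``W.district_ids``).

    Island districts (zero weight rows) are excluded from the statistic
    with a warning; ``n_used`` reports the remaining count.  Constant x or
    fewer than 3 usable districts raise ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    if len(x) != W.n:
        raise ValueError(f"x has length {len(x)}, weights have {W.n} districts")
    if not np.isfinite(x).all():
        raise ValueError("x contains non-finite values")

    w = W.dense()
    keep = np.asarray(w.sum(axis=1)).ravel() > 0
    if not keep.all():
        dropped = [d for d, k in zip(W.district_ids, keep) if not k]
        logger.warning("excluding %d island district(s) from Moran's I: %s",
                       len(dropped), ", ".join(dropped[:10]))
        w = w[np.ix_(keep, keep)]
        x = x[keep]
    n = len(x)
    if n < 3:
        raise ValueError("Moran's I needs at least 3 non-island districts")
    if np.ptp(x) == 0:
        raise ValueError("Moran's I is undefined for a constant variable")

    s0 = w.sum()
    z = x - x.mean()
    denom = (z**2).sum()

    def stat(zv: np.ndarray) -> float:
        return float(n / s0 * (zv @ w @ zv) / (zv**2).sum())

    i_obs = float(n / s0 * (z @ w @ z) / denom)
    e_i = -1.0 / (n - 1)

    if inference == "permutation":
        rng = np.random.default_rng(seed)
        sim = np.empty(n_perm)
        for b in range(n_perm):
            zp = rng.permutation(z)
            sim[b] = stat(zp)
        var = float(sim.var(ddof=1))
        zsc = (i_obs - sim.mean()) / np.sqrt(var) if var > 0 else np.nan
        if i_obs >= e_i:
            p = (1 + np.sum(sim >= i_obs)) / (n_perm + 1)
        else:
            p = (1 + np.sum(sim <= i_obs)) / (n_perm + 1)
        return MoranResult(i_obs, e_i, var, float(zsc), float(p),
                           "permutation", n, sim=sim)

    e_i, var = _moments(w, x, inference)
    zsc = (i_obs - e_i) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(zsc))
    return MoranResult(i_obs, e_i, var, float(zsc), float(p), inference, n)


def moran_by_year(
    panel_df, column: str, W: SpatialWeights, year: int | None = None, **kwargs
) -> dict[int, MoranResult]:
    """Moran's I of one panel column per year (or a single year).

    The panel frame needs ``district_id`` and ``year`` columns; district
    order is aligned to ``W.district_ids``.
    """
    years = [year] if year is not None else sorted(panel_df["year"].unique())
    out: dict[int, MoranResult] = {}
    for yr in years:
        sub = panel_df[panel_df["year"] == yr].set_index("district_id")
        x = sub.loc[W.district_ids, column].to_numpy(float)
        out[int(yr)] = morans_i(x, W, **kwargs)
    return out


def moran_pooled(panel_df, column: str, W: SpatialWeights, **kwargs) -> MoranResult:
    """Moran's I on within-year-demeaned pooled values, averaged over years.

    Each year's cross-section is demeaned and the yearly statistics are
    combined by averaging I (the expected value and variance scale
    accordingly); a single representative result is returned with the
    pooled z-score from the per-year permutation distributions.
    """
    per_year = moran_by_year(panel_df, column, W, **kwargs)
    i_mean = float(np.mean([r.I for r in per_year.values()]))
    e = next(iter(per_year.values())).expected_I
    var = float(np.mean([r.variance_I for r in per_year.values()]) / len(per_year))
    zsc = (i_mean - e) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(zsc))
    r0 = next(iter(per_year.values()))
    return MoranResult(i_mean, e, var, float(zsc), float(p), r0.inference,
                       r0.n_used)
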