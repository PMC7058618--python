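"""Maximum-likelihood fixed-effects spatial error models (SEM / SDEM).

Model
-----
For the demeaned balanced panel with year dummies, the spatial error model
(SEM) is

    y_t = X_t beta + u_t,      u_t = rho W u_t + eps_t,   eps_t ~ N(0, sigma2 I_N)

for each year t, with one time-constant row-standardized weights matrix W.
Writing B(rho) = I_N - rho W, the log-likelihood concentrates over beta and
sigma2: beta_hat(rho) is OLS on the spatially filtered data (B y_t, B X_t),
sigma2_hat(rho) the mean squared filtered residual, and

    ll(rho) = -(n/2) (log(2 pi sigma2_hat(rho)) + 1) + c log|B(rho)|

with n the number of observations entering the Gaussian kernel and c the
number of periods carrying the Jacobian.

Year fixed effects interact with a row-standardized W: the dummies (plus
the intercept that is added automatically alongside them) absorb every
year's cross-district mean, which is exactly the unit-eigenvector
component of W (W 1 = 1) — the most spatially amplified direction of u.
The likelihood of the remaining data therefore drops that eigenvalue:
n = (N-1)*T and log|B| is replaced by log|B| - log(1 - rho).  This is the
exact marginal likelihood of the projected model, not an approximation;
without it rho_hat is biased downward by O(1/N) however long the panel.
The optional ``bias_correction`` flag additionally replaces T by the T-1
effective periods left after regional demeaning (Lee-Yu style); it rescales
sigma2 and the likelihood level but provably leaves the rho argmax
unchanged, and is off by default.

log|B(rho)| is computed from the (complex) eigenvalues of W, so each
likelihood evaluation is O(N K^2) after a one-off O(N^3) eigendecomposition.
rho is searched on (1/min_real_eig(W), 1) by a coarse grid warm start
followed by bounded scalar minimization (xatol 1e-8).

The spatial Durbin error model (SDEM) augments X with spatially lagged
copies W x of the designated "Durbin" columns (local spillovers of
observables) and is estimated by the same machinery; the LR test of the
theta coefficients against the nested SEM decides between them, and the
BIC ranks fits across weight matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .panel_prep import PanelDataset
from .weights import SpatialWeights, rho_interval

__all__ = [
    "SpatialModelSpec",
    "SpatialFitResult",
    "LrTestResult",
    "fit_sem",
    "fit_sdem",
    "lr_test",
    "model_select",
    "significance_stars",
]

logger = logging.getLogger(__name__)


@dataclass
class SpatialModelSpec:
    """Which spatial model to fit on which weights."""

    model: Literal["sem", "sdem"] = "sem"
    durbin_columns: list[str] = field(default_factory=list)
    bias_correction: bool = False

    def __post_init__(self) -> None:
        if self.model == "sdem" and not self.durbin_columns:
            raise ValueError("SDEM requires nonempty durbin_columns")
        if self.model == "sem" and self.durbin_columns:
            raise ValueError("SEM does not take durbin_columns")


@dataclass
class SpatialFitResult:
    """ML estimates for one model / weights combination."""

    model: str
    weights_kind: str
    outcome: str
    beta: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    rho: float
    rho_se: float
    sigma2: float
    loglik: float
    bic: float
    vcov: pd.DataFrame
    n_obs: int
    k_params: int
    n_districts: int
    n_periods: int
    rho_bounds: tuple[float, float]
    converged: bool
    durbin_columns: list[str] = field(default_factory=list)
    profile_loglik: Callable[[float], float] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def rho_z(self) -> float:
        return self.rho / self.rho_se if self.rho_se > 0 else np.nan

    @property
    def rho_p(self) -> float:
        z = self.rho_z
        return float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan

    def coefficient_table(self) -> pd.DataFrame:
        """Tidy per-coefficient table including the spatial error term."""
        tab = pd.DataFrame(
            {"coef": self.beta, "se": self.se, "z": self.z, "p": self.p}
        )
        tab.loc["spatial_error_rho"] = [self.rho, self.rho_se, self.rho_z, self.rho_p]
        tab["stars"] = [significance_stars(p) for p in tab["p"]]
        return tab


@dataclass
class LrTestResult:
    """Likelihood-ratio test of a nested restriction."""

    stat: float
    df: int
    p_value: float


def significance_stars(p: float) -> str:
    """``***`` for p<0.01, ``**`` for p<0.05, empty otherwise."""
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    return ""


def _panel_arrays(
    panel: PanelDataset, x_cols: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """y as (N, T), X as (N, T, K), district-major year-minor."""
    N, T = panel.n_districts, panel.n_years
    y = panel.y().reshape(N, T)
    X = panel.X(x_cols).reshape(N, T, len(x_cols))
    return y, X, N, T


def _fit_filtered(
    y: np.ndarray, X: np.ndarray, Wy: np.ndarray, WX: np.ndarray, rho: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS on spatially filtered data; returns (beta, residuals, rss)."""
    yt = (y - rho * Wy).reshape(-1)
    K = X.shape[-1]
    Xt = (X - rho * WX).reshape(-1, K)
    beta, _, rank, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    # all-zero columns (e.g. a degenerate Durbin lag) cannot affect the fit;
    # lstsq gives them coefficient 0 — only genuine collinearity is an error
    n_effective = int(Xt.any(axis=0).sum())
    if rank < n_effective:
        raise np.linalg.LinAlgError("collinear filtered design matrix")
    resid = yt - Xt @ beta
    return beta, resid, float(resid @ resid)


def fit_sem(
    panel: PanelDataset,
    W: SpatialWeights,
    x_cols: Sequence[str] | None = None,
    rho_fixed: float | None = None,
    spec: SpatialModelSpec | None = None,
    _model_label: str = "sem",
    _durbin: Sequence[str] = (),
) -> SpatialFitResult:
    """Fit the fixed-effects SEM by concentrated maximum likelihood.

    Parameters
    ----------
    panel : PanelDataset
        Must be within-transformed (demeaned) with year dummies appended.
    W : SpatialWeights
        Row-standardized, held fixed over time; N must match the panel.
    x_cols : regressor columns; defaults to covariates + year dummies.
    rho_fixed : pin the spatial error parameter instead of estimating it
        (``rho_fixed=0`` reproduces two-way fixed-effects OLS exactly).
    spec : optional :class:`SpatialModelSpec` carrying ``bias_correction``.

    Raises on unbalanced/untransformed panels, mismatched N, non-row-
    standardized W, collinear regressors, and optimizer failure.
    """
    spec = spec or SpatialModelSpec(model="sem")
    if not panel.demeaned:
        raise ValueError("panel must be within-transformed before spatial estimation")
    if not W.row_standardized:
        raise ValueError("W must be row-standardized")
    if W.n != panel.n_districts:
        raise ValueError(
            f"W has {W.n} districts, panel has {panel.n_districts}"
        )
    if list(W.district_ids) != list(panel.districts):
        raise ValueError("W district order does not match the panel")

    x_cols = list(x_cols) if x_cols is not None else panel.covariates + panel.year_dummies
    has_dummies = bool(panel.year_dummies) and set(panel.year_dummies) <= set(x_cols)
    y, X, N, T = _panel_arrays(panel, x_cols)
    if has_dummies and "const" not in x_cols:
        # intercept + T-1 dummies spans all T per-year means; without it the
        # reference year's mean of the filtered residual stays unabsorbed
        X = np.concatenate([np.ones((N, T, 1)), X], axis=2)
        x_cols = ["const"] + x_cols
    K = X.shape[-1]

    Wd = W.dense()
    Wy = Wd @ y
    WX = np.einsum("ij,jtk->itk", Wd, X)
    eigs = np.linalg.eigvals(Wd)

    # Year dummies absorb each year's cross-district mean, i.e. the unit
    # eigenvector of a row-standardized W (W 1 = 1).  The exact likelihood
    # of the remaining data drops that eigenvalue: kernel dimension (N-1)
    # per period and log|B| - log(1 - rho) in the Jacobian.  Without it,
    # rho_hat is biased downward by O(1/N) regardless of T.
    rowsums = np.asarray(W.matrix.sum(axis=1)).ravel()
    drop_unit_eig = has_dummies and bool(np.allclose(rowsums, 1.0))
    if has_dummies and not drop_unit_eig:
        logger.warning(
            "W has island rows; unit-eigenvalue adjustment for year dummies skipped"
        )
    N_eff = N - 1 if drop_unit_eig else N

    # Lee-Yu style degrees-of-freedom correction for regional demeaning:
    # rescales sigma2 and the likelihood level, not the rho argmax.
    T_eff = T - 1 if (spec.bias_correction and panel.fe.region_fe) else T
    n_ll = N_eff * T_eff

    lo, hi = rho_interval(W)
    lo_s, hi_s = lo + 1e-6, hi - 1e-6

    def logdet(rho: float) -> float:
        ld = float(np.log(1.0 - rho * eigs).sum().real)
        if drop_unit_eig:
            ld -= float(np.log(1.0 - rho))
        return ld

    def profile_ll(rho: float) -> float:
        _, _, rss = _fit_filtered(y, X, Wy, WX, rho)
        sigma2 = rss / n_ll
        return -0.5 * n_ll * (np.log(2 * np.pi * sigma2) + 1.0) + T_eff * logdet(rho)

    converged = True
    if rho_fixed is not None:
        if not (lo < rho_fixed < hi):
            raise ValueError(f"rho_fixed={rho_fixed} outside admissible {lo, hi}")
        rho_hat = float(rho_fixed)
    else:
        grid = np.linspace(lo_s, hi_s, 25)
        ll_grid = np.array([profile_ll(r) for r in grid])
        j = int(np.argmax(ll_grid))
        bl = grid[max(j - 1, 0)]
        bu = grid[min(j + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda r: -profile_ll(r), bounds=(bl, bu), method="bounded",
            options={"xatol": 1e-8},
        )
        if not res.success:
            raise RuntimeError(f"rho optimization failed: {res}")
        rho_hat = float(res.x)
        converged = bool(res.success)
        if min(rho_hat - lo_s, hi_s - rho_hat) < 1e-4:
            logger.warning("rho estimate %.4f is at the boundary of %s", rho_hat, (lo, hi))

    try:
        beta, resid, rss = _fit_filtered(y, X, Wy, WX, rho_hat)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            f"singular filtered design; check collinearity among {x_cols}"
        ) from None
    sigma2 = rss / n_ll
    ll = float(profile_ll(rho_hat))

    # beta block: asymptotically orthogonal to (rho, sigma2) in the SEM
    Xt = (X - rho_hat * WX).reshape(-1, K)
    XtX_inv = np.linalg.pinv(Xt.T @ Xt)  # pinv: tolerates degenerate zero columns
    vcov_beta = sigma2 * XtX_inv
    se = np.sqrt(np.diag(vcov_beta))

    # rho: curvature of the profile likelihood (observed information)
    if rho_fixed is None:
        h = max(1e-5, 1e-5 * (hi_s - lo_s))
        r0 = np.clip(rho_hat, lo_s + h, hi_s - h)
        d2 = (profile_ll(r0 + h) - 2 * profile_ll(r0) + profile_ll(r0 - h)) / h**2
        rho_se = float(np.sqrt(-1.0 / d2)) if d2 < 0 else np.nan
    else:
        rho_se = np.nan

    k_params = K + 1 + (0 if rho_fixed is not None else 1)  # beta, sigma2[, rho]
    n_obs = N * T
    bic = -2.0 * ll + k_params * np.log(n_obs)

    names = list(x_cols)
    vcov = pd.DataFrame(vcov_beta, index=names, columns=names)
    z = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    return SpatialFitResult(
        model=_model_label,
        weights_kind=W.kind,
        outcome=panel.outcome,
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        z=pd.Series(z, index=names),
        p=pd.Series(p, index=names),
        rho=rho_hat,
        rho_se=rho_se,
        sigma2=float(sigma2),
        loglik=ll,
        bic=float(bic),
        vcov=vcov,
        n_obs=n_obs,
        k_params=k_params,
        n_districts=N,
        n_periods=T,
        rho_bounds=(lo, hi),
        converged=converged,
        durbin_columns=list(_durbin),
        profile_loglik=profile_ll,
    )


def fit_sdem(
    panel: PanelDataset,
    W: SpatialWeights,
    x_cols: Sequence[str] | None = None,
    durbin_columns: Sequence[str] | None = None,
    rho_fixed: float | None = None,
    spec: SpatialModelSpec | None = None,
) -> SpatialFitResult:
    """Fit the spatial Durbin error model: SEM plus W-lagged covariates.

    The designated Durbin columns (by default all substantive covariates)
    are spatially lagged year by year and appended as ``W_<col>`` regressors
    whose coefficients are the local-spillover thetas.  Year dummies are
    never lagged (W is row-standardized, so their lag is the dummy itself).
    """
    spec = spec or SpatialModelSpec(
        model="sdem",
        durbin_columns=list(durbin_columns or panel.covariates),
    )
    durbin = list(durbin_columns) if durbin_columns is not None else list(spec.durbin_columns)
    if not durbin:
        raise ValueError("SDEM requires at least one durbin column")
    unknown = set(durbin) - set(panel.data.columns)
    if unknown:
        raise ValueError(f"unknown durbin columns {sorted(unknown)}")

    aug = panel.copy()
    N, T = aug.n_districts, aug.n_years
    Wd = W.dense()
    lag_names = []
    for col in durbin:
        vals = aug.data[col].to_numpy(float).reshape(N, T)
        aug.data[f"W_{col}"] = (Wd @ vals).reshape(-1)
        lag_names.append(f"W_{col}")
    aug.covariates = aug.covariates + lag_names

    cols = (list(x_cols) + lag_names) if x_cols is not None else None
    sem_spec = SpatialModelSpec(model="sem", bias_correction=spec.bias_correction)
    return fit_sem(
        aug, W, x_cols=cols, rho_fixed=rho_fixed, spec=sem_spec,
        _model_label="sdem", _durbin=lag_names,
    )


def lr_test(
    full: SpatialFitResult,
    restricted: SpatialFitResult,
    df: int | None = None,
    tol: float = 1e-6,
) -> LrTestResult:
    """Likelihood-ratio test of the restricted model against the full one.

    ``stat = 2 (ll_full - ll_restricted)`` against chi-square with
    ``df = k_full - k_restricted`` (overridable; a mismatch with the
    declared restriction count raises).
    """
    if full.n_obs != restricted.n_obs or full.outcome != restricted.outcome:
        raise ValueError("LR test requires the same data and outcome in both fits")
    k_diff = full.k_params - restricted.k_params
    if k_diff <= 0:
        raise ValueError("full model must have more parameters than restricted")
    if df is not None and df != k_diff:
        raise ValueError(f"declared df={df} does not match parameter difference {k_diff}")
    stat = 2.0 * (full.loglik - restricted.loglik)
    if stat < -tol:
        raise ValueError(
            f"full log-likelihood {full.loglik:.6f} below restricted "
            f"{restricted.loglik:.6f}: models not nested or not converged"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, k_diff))
    return LrTestResult(float(stat), k_diff, p)


def model_select(
    fits: Sequence[SpatialFitResult], rule: Literal["bic"] = "bic"
) -> pd.DataFrame:
    """Rank fits by BIC (ascending); ties go to the smaller model.

    All fits must share the outcome and sample size, otherwise their BICs
    are not comparable.
    """
    if not fits:
        raise ValueError("no fits to rank")
    n0, out0 = fits[0].n_obs, fits[0].outcome
    for f in fits:
        if f.n_obs != n0 or f.outcome != out0:
            raise ValueError("fits differ in sample or outcome; BICs not comparable")
    tab = pd.DataFrame(
        {
            "model": [f.model for f in fits],
            "weights": [f.weights_kind for f in fits],
            "loglik": [f.loglik for f in fits],
            "k_params": [f.k_params for f in fits],
            "bic": [f.bic for f in fits],
            "rho": [f.rho for f in fits],
        }
    )
    tab = tab.sort_values(["bic", "k_params"], kind="mergesort").reset_index(drop=True)
    tab.index.name = "rank"
    return tab
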