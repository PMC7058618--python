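"""Synthetic district panels with a known spatial-error data-generating
process.

The real discharge data behind the analysis are administrative and not
publicly distributable, so every downstream stage is exercised on
synthetic data with known ground truth.  The generator emulates the study
design: a balanced panel of 117 districts over the 6 years 2008-2013,
an outcome share of avoidable hospitalisations around 11% of general
hospitalisations, and disturbances following the spatial error process

    u_t = (I - rho W)^{-1} eps_t,   eps_t ~ iid N(0, sigma_eps^2)

applied year by year, on top of district and year fixed effects and a
linear covariate signal y_it = alpha_i + tau_t + x_it' beta + u_it.

Geometry defaults to a lattice of square cells (queen contiguity is then
analytically checkable); ``random_points`` scatters centroids uniformly on
a 300 x 300 km square so a 50 km distance cut-off is non-degenerate.
Covariates are drawn jointly normal with a mild uniform cross-correlation.
The spatial solve uses a dense LU factorisation of (I - rho W): exact, and
cheap at a few hundred districts.

Everything is driven by one integer seed; the same seed reproduces
byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping

from . import acsc as acsc_mod
from .panel_prep import FixedEffectsSpec, PanelDataset
from .weights import SpatialWeights

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "Geometry",
    "generate_geometry",
    "generate_panel",
    "generate_discharges",
    "grid_shape",
]

DEFAULT_SEED = 20080101  # study start year; arbitrary but fixed


@dataclass
class SyntheticConfig:
    """Stated world of the generator.

    Defaults mirror the study design: 117 districts x 6 years starting
    2008, spatial error parameter 0.4, eight candidate covariates of which
    x1 and x3 are active, idiosyncratic noise on the share scale, and a
    baseline share of ~0.11 entering through the district effects.
    """

    n_districts: int = 117
    n_years: int = 6
    start_year: int = 2008
    layout: str = "grid"  # or "random_points"
    cell_size_km: float = 20.0
    rho_true: float = 0.4
    beta_true: tuple[float, ...] = (0.01, 0.0, 0.01, 0.0, 0.0, 0.0, 0.0, 0.0)
    sigma_eps: float = 0.02
    fe_sd_region: float = 0.02
    fe_sd_time: float = 0.005
    baseline_share: float = 0.11
    covariate_corr: float = 0.3
    covariate_sd: float = 1.0
    outcome_scale: str = "proportion"
    clip_share: bool = False
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_districts < 4:
            raise ValueError("n_districts must be at least 4")
        if self.n_years < 1:
            raise ValueError("n_years must be positive")
        if not abs(self.rho_true) < 1:
            raise ValueError(f"|rho_true| must be < 1, got {self.rho_true}")
        if self.sigma_eps < 0 or self.fe_sd_region < 0 or self.fe_sd_time < 0:
            raise ValueError("dispersion parameters must be nonnegative")
        if self.layout not in ("grid", "random_points"):
            raise ValueError(f"unknown layout {self.layout!r}")

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))

    @property
    def covariate_names(self) -> list[str]:
        return [f"x{j + 1}" for j in range(len(self.beta_true))]

    @property
    def active_covariates(self) -> list[str]:
        return [n for n, b in zip(self.covariate_names, self.beta_true) if b != 0]


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside every generated dataset."""

    config: SyntheticConfig
    region_effects: np.ndarray
    time_effects: np.ndarray
    active_covariates: list[str]
    covariate_corr_matrix: np.ndarray
    u: np.ndarray | None = None  # latent spatial disturbances, (N, T)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "region_effects": self.region_effects.tolist(),
            "time_effects": self.time_effects.tolist(),
            "active_covariates": self.active_covariates,
            "covariate_corr_matrix": self.covariate_corr_matrix.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class Geometry:
    """District ids with centroids (km) and optional square-cell polygons."""

    district_ids: list[str]
    centroids: np.ndarray  # (N, 2) in km
    polygons: list[Polygon] | None = None

    def centroid_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "district_id": self.district_ids,
                "x_km": self.centroids[:, 0],
                "y_km": self.centroids[:, 1],
            }
        )

    def to_geojson(self, path: str | Path) -> None:
        feats = []
        for i, did in enumerate(self.district_ids):
            geom = (
                mapping(self.polygons[i])
                if self.polygons is not None
                else {"type": "Point", "coordinates": list(self.centroids[i])}
            )
            feats.append(
                {"type": "Feature", "properties": {"district_id": did}, "geometry": geom}
            )
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": feats})
        )


def grid_shape(n: int) -> tuple[int, int]:
    """Rows x cols for a lattice of n cells: the divisor pair closest to
    square, rows >= cols (117 -> 13 x 9; primes degenerate to n x 1)."""
    best = (n, 1)
    for c in range(1, int(math.isqrt(n)) + 1):
        if n % c == 0:
            best = (n // c, c)
    return best


def _district_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"D{i + 1:0{width}d}" for i in range(n)]


def generate_geometry(config: SyntheticConfig) -> Geometry:
    """District geometries for the configured layout.

    ``grid``: a rows x cols lattice of square cells of ``cell_size_km``,
    ids assigned row-major.  ``random_points``: centroids uniform on a
    300 x 300 km square (polygons absent), seeded by ``config.seed``.
    """
    ids = _district_ids(config.n_districts)
    if config.layout == "grid":
        rows, cols = grid_shape(config.n_districts)
        s = config.cell_size_km
        cents, polys = [], []
        for i in range(config.n_districts):
            r, c = divmod(i, cols)
            x0, y0 = c * s, r * s
            polys.append(Polygon([(x0, y0), (x0 + s, y0), (x0 + s, y0 + s), (x0, y0 + s)]))
            cents.append((x0 + s / 2, y0 + s / 2))
        return Geometry(ids, np.array(cents), polys)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    cents = rng.uniform(0.0, 300.0, size=(config.n_districts, 2))
    return Geometry(ids, cents, None)


def _spatial_disturbances(
    config: SyntheticConfig, W: SpatialWeights, rng: np.random.Generator
) -> np.ndarray:
    """u_t = (I - rho W)^{-1} eps_t for every year, dense solve."""
    N, T = config.n_districts, config.n_years
    eps = rng.normal(0.0, config.sigma_eps, size=(N, T))
    if config.rho_true == 0:
        return eps
    B = np.eye(N) - config.rho_true * W.dense()
    try:
        return np.linalg.solve(B, eps)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by |rho|<1
        raise np.linalg.LinAlgError(
            f"(I - rho W) singular at rho={config.rho_true}: {exc}"
        ) from exc


def generate_panel(
    config: SyntheticConfig, W: SpatialWeights
) -> tuple[PanelDataset, SyntheticTruth]:
    """Generate the covariate panel and SEM outcome under ``W``.

    Covariates are iid over district-years, jointly normal with mean 0,
    sd ``covariate_sd`` and constant cross-correlation ``covariate_corr``
    (the realised correlation matrix is stored in the truth object).  The
    outcome is ``share_total = baseline + alpha_i + tau_t + x'beta + u``;
    with ``clip_share=True`` it is clipped to [0, 1] and the unclipped
    latent value is retained in column ``share_total_latent``.
    """
    if W.n != config.n_districts:
        raise ValueError(f"W has {W.n} districts, config wants {config.n_districts}")
    if not W.row_standardized:
        raise ValueError("generate_panel expects a row-standardized W")

    N, T, K = config.n_districts, config.n_years, len(config.beta_true)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    corr = np.full((K, K), config.covariate_corr)
    np.fill_diagonal(corr, 1.0)
    L = np.linalg.cholesky(corr)
    X = rng.standard_normal(size=(N * T, K)) @ L.T * config.covariate_sd

    alpha = rng.normal(0.0, config.fe_sd_region, size=N)
    tau = rng.normal(0.0, config.fe_sd_time, size=T)
    u = _spatial_disturbances(config, W, rng)

    beta = np.asarray(config.beta_true, dtype=float)
    signal = (X @ beta).reshape(N, T)
    y = config.baseline_share + alpha[:, None] + tau[None, :] + signal + u

    df = pd.DataFrame(
        {
            "district_id": np.repeat(W.district_ids, T),
            "year": np.tile(config.years, N),
        }
    )
    latent = y.reshape(-1)
    if config.clip_share:
        df["share_total"] = np.clip(latent, 0.0, 1.0)
        df["share_total_latent"] = latent
    else:
        df["share_total"] = latent
    for j, name in enumerate(config.covariate_names):
        df[name] = X[:, j]

    panel = PanelDataset(
        df,
        outcome="share_total",
        covariates=config.covariate_names,
        outcome_scale=config.outcome_scale,
        fe=FixedEffectsSpec(region_fe=True, time_fe=True, demeaned=False),
    )
    truth = SyntheticTruth(
        config=config,
        region_effects=alpha,
        time_effects=tau,
        active_covariates=config.active_covariates,
        covariate_corr_matrix=corr,
        u=u,
    )
    return panel, truth


# non-ACSC filler diagnoses for the discharge fixture
_FILLER_CODES = ("C50.9", "Z38.0", "S72.0", "M16.1", "O80", "K35.8")
_ACUTE_CODES = ("N30.0", "J18.1", "I20.9", "R02", "L03.1", "K25.0")
_CHRONIC_CODES = ("J45.0", "E10.3", "I50.1", "J44.9", "I10", "G40.9")


def generate_discharges(
    config: SyntheticConfig,
    table: Sequence[acsc_mod.AcscEntry] | None = None,
    shares: pd.DataFrame | None = None,
    general_mean: int = 2000,
    acute_fraction: float = 0.41,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a toy discharge file with exact per-district-year truth counts.

    Parameters
    ----------
    shares : optional DataFrame with ``district_id, year, share_total``;
        when given, each cell's ACSC count is ``round(share * general)``
        so that classifying the discharges approximately reproduces the
        panel outcome.  Without it, shares are drawn around the baseline.
    general_mean : Poisson mean of general hospitalisations per cell.
    acute_fraction : binomial share of ACSC admissions that are acute
        (0.41 mirrors the relative magnitude of acute vs chronic shares).

    Returns
    -------
    (records, truth) : DataFrames.  ``records`` has columns
        district_id, year, icd10, count (both ACSC and non-ACSC codes);
        ``truth`` the exact ah_total/ah_acute/ah_chronic/general_hosp.
    """
    if table is None:
        table = acsc_mod.load_acsc_table()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    ids = _district_ids(config.n_districts)

    share_map: dict[tuple[str, int], float] = {}
    if shares is not None:
        for r in shares.itertuples():
            share_map[(str(r.district_id), int(r.year))] = float(r.share_total)

    rec_rows, truth_rows = [], []
    for did in ids:
        for yr in config.years:
            general = int(rng.poisson(general_mean)) + 1
            share = share_map.get(
                (did, yr),
                float(np.clip(rng.normal(config.baseline_share, 0.02), 0.0, 0.9)),
            )
            ah_total = int(np.clip(round(share * general), 0, general))
            ah_acute = int(rng.binomial(ah_total, acute_fraction))
            ah_chronic = ah_total - ah_acute
            for codes, total in ((_ACUTE_CODES, ah_acute), (_CHRONIC_CODES, ah_chronic)):
                if total > 0:
                    split = rng.multinomial(total, np.full(len(codes), 1 / len(codes)))
                    for code, cnt in zip(codes, split):
                        if cnt > 0:
                            rec_rows.append((did, yr, code, int(cnt)))
            filler = general - ah_total
            if filler > 0:
                split = rng.multinomial(
                    filler, np.full(len(_FILLER_CODES), 1 / len(_FILLER_CODES))
                )
                for code, cnt in zip(_FILLER_CODES, split):
                    if cnt > 0:
                        rec_rows.append((did, yr, code, int(cnt)))
            truth_rows.append((did, yr, ah_total, ah_acute, ah_chronic, general))

    records = pd.DataFrame(rec_rows, columns=["district_id", "year", "icd10", "count"])
    truth = pd.DataFrame(
        truth_rows,
        columns=["district_id", "year", "ah_total", "ah_acute", "ah_chronic", "general_hosp"],
    )
    return records, truth
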