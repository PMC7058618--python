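"""Balanced panel container and fixed-effects preparation.

The estimation sample is a balanced district x year panel.  Regional fixed
effects are removed by demeaning every variable by its district average
(the within transformation), which also eliminates all time-invariant
variables; time fixed effects are implemented as T-1 year dummy columns
appended *after* demeaning (reference = first year).  Pooled standard
deviations of the raw covariates are kept for translating coefficients
into per-SD effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelDataset",
    "FixedEffectsSpec",
    "lag_covariates",
    "within_transform",
    "untransform",
    "column_sds",
    "read_panel_csv",
]

logger = logging.getLogger(__name__)

ID_COLS = ["district_id", "year"]


@dataclass
class FixedEffectsSpec:
    """Which fixed effects the model carries and how they were handled."""

    region_fe: bool = True
    time_fe: bool = True
    demeaned: bool = False


@dataclass
class PanelDataset:
    """A balanced district-major, year-minor panel.

    Attributes
    ----------
    data : DataFrame
        Columns ``district_id, year``, the outcome, covariates, and (after
        :func:`within_transform`) year dummies.
    outcome : str
        Name of the dependent-variable column (an AH share).
    covariates : list of str
        Substantive regressor columns (excludes year dummies).
    outcome_scale : {"proportion", "percent"}
        Scale of the outcome; reporting refuses to convert effects to
        percentage points without it.
    year_dummies : list of str
        Dummy columns present in ``data`` (empty before transformation).
    district_means : DataFrame or None
        Per-district means removed by the within transformation.
    """

    data: pd.DataFrame
    outcome: str
    covariates: list[str]
    outcome_scale: str = "proportion"
    fe: FixedEffectsSpec = field(default_factory=FixedEffectsSpec)
    year_dummies: list[str] = field(default_factory=list)
    district_means: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        df = self.data
        for col in ID_COLS + [self.outcome, *self.covariates]:
            if col not in df.columns:
                raise ValueError(f"panel is missing column {col!r}")
        if self.outcome_scale not in ("proportion", "percent"):
            raise ValueError("outcome_scale must be 'proportion' or 'percent'")
        if len(set(df.columns)) != len(df.columns):
            raise ValueError("duplicate column names in panel")
        value_cols = [self.outcome, *self.covariates]
        if df[value_cols].isna().any().any():
            raise ValueError("panel contains missing values; imputation is not supported")
        df = df.sort_values(ID_COLS, kind="mergesort").reset_index(drop=True)
        counts = df.groupby("district_id")["year"].apply(tuple)
        if counts.nunique() != 1:
            raise ValueError("panel is unbalanced: districts observed in different years")
        if df.duplicated(ID_COLS).any():
            raise ValueError("duplicate district-year rows")
        self.data = df

    # -- shapes -------------------------------------------------------------
    @property
    def districts(self) -> list[str]:
        return list(dict.fromkeys(self.data["district_id"]))

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    @property
    def n_districts(self) -> int:
        return len(self.districts)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def demeaned(self) -> bool:
        return self.fe.demeaned

    # -- arrays -------------------------------------------------------------
    def y(self) -> np.ndarray:
        return self.data[self.outcome].to_numpy(float)

    def X(self, columns: Sequence[str] | None = None) -> np.ndarray:
        cols = list(columns) if columns is not None else self.covariates + self.year_dummies
        return self.data[cols].to_numpy(float)

    def copy(self) -> "PanelDataset":
        return replace(self, data=self.data.copy(),
                       covariates=list(self.covariates),
                       year_dummies=list(self.year_dummies))

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def read_panel_csv(
    path: str | Path,
    outcome: str,
    covariates: Sequence[str],
    outcome_scale: str = "proportion",
) -> PanelDataset:
    """Load a panel CSV (district_id, year, value columns)."""
    df = pd.read_csv(path, dtype={"district_id": str})
    return PanelDataset(df, outcome, list(covariates), outcome_scale)


def lag_covariates(
    panel: PanelDataset, columns: Sequence[str], lag: int = 1
) -> PanelDataset:
    """Replace columns by their within-district lag, dropping the first years.

    The named columns (e.g. unemployment rates, to break reverse causality)
    are shifted by ``lag`` years within each district; the first ``lag``
    years are dropped for *all* districts so the panel stays balanced.
    """
    if lag < 1 or lag >= panel.n_years:
        raise ValueError(f"need 1 <= lag < T={panel.n_years}, got {lag}")
    missing = set(columns) - set(panel.data.columns)
    if missing:
        raise ValueError(f"cannot lag unknown columns {sorted(missing)}")
    df = panel.data.copy()
    for col in columns:
        df[col] = df.groupby("district_id")[col].shift(lag)
    keep_years = panel.years[lag:]
    df = df[df["year"].isin(keep_years)].reset_index(drop=True)
    return replace(panel, data=df)


def within_transform(
    panel: PanelDataset, spec: FixedEffectsSpec | None = None
) -> PanelDataset:
    """Demean by district and append year dummies.

    Every value column is replaced by its deviation from the district mean
    (eliminating regional fixed effects and any time-invariant variable);
    year dummies for all but the first year are then appended.  District
    means are stored for back-transformation.  Calling this on an already
    transformed panel returns an unchanged copy (idempotence).
    """
    spec = spec or FixedEffectsSpec()
    if panel.demeaned:
        return panel.copy()
    df = panel.data.copy()
    value_cols = [panel.outcome] + list(panel.covariates)
    means = None
    if spec.region_fe:
        means = df.groupby("district_id")[value_cols].mean()
        df[value_cols] = df[value_cols] - df.groupby("district_id")[value_cols].transform("mean")
    dummies: list[str] = []
    if spec.time_fe:
        for yr in panel.years[1:]:
            name = f"year_{yr}"
            df[name] = (df["year"] == yr).astype(float)
            dummies.append(name)
    out_spec = FixedEffectsSpec(spec.region_fe, spec.time_fe, demeaned=True)
    return replace(panel, data=df, fe=out_spec, year_dummies=dummies,
                   district_means=means)


def untransform(panel: PanelDataset) -> PanelDataset:
    """Add the stored district means back (drops year dummies)."""
    if not panel.demeaned or panel.district_means is None:
        return panel.copy()
    df = panel.data.copy()
    value_cols = [panel.outcome] + list(panel.covariates)
    for col in value_cols:
        df[col] = df[col] + df["district_id"].map(panel.district_means[col])
    df = df.drop(columns=panel.year_dummies)
    return replace(panel, data=df, fe=FixedEffectsSpec(panel.fe.region_fe,
                                                       panel.fe.time_fe, False),
                   year_dummies=[], district_means=None)


def column_sds(panel: PanelDataset, columns: Sequence[str] | None = None) -> pd.Series:
    """Sample SDs (ddof=1) over the pooled raw panel, for per-SD effects.

    Constant columns get sd 0 with a warning rather than an error.
    """
    cols = list(columns) if columns is not None else list(panel.covariates)
    missing = set(cols) - set(panel.data.columns)
    if missing:
        raise ValueError(f"unknown columns {sorted(missing)}")
    sds = panel.data[cols].std(ddof=1)
    for col, s in sds.items():
        if s == 0:
            logger.warning("column %r is constant; sd set to 0", col)
    return sds
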