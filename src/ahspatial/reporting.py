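"""Publication-style effect translation and tables.

Coefficients of the spatial models are translated into the percentage-
point change of the outcome share per one standard deviation of each
covariate (``pp = beta * sd``, rescaled to percentage points according to
the outcome scale), and into that change as a percent of the mean share.
Entries not significant at the 95% level are rendered ``n.s.``.

Two renderers mirror the usual presentation: a coefficient matrix with
significance stars, a spatial-error-term row and a BIC row (one column per
fitted outcome/weights combination), and a per-SD effect matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spatial_models import SpatialFitResult, significance_stars

__all__ = [
    "EffectReport",
    "effect_per_sd",
    "render_coefficient_table",
    "render_effect_table",
    "effects_to_csv",
    "read_effects_csv",
]


@dataclass
class EffectReport:
    """Per-SD standardized effects for one fit.

    ``table`` columns: beta, sd, pp_change, pct_of_mean, p, significant.
    ``mean_share_pct`` is the pooled mean outcome share in percent.
    """

    table: pd.DataFrame
    mean_share_pct: float
    outcome: str
    outcome_scale: str


def _pp_factor(outcome_scale: str) -> float:
    if outcome_scale == "proportion":
        return 100.0
    if outcome_scale == "percent":
        return 1.0
    raise ValueError(
        f"outcome_scale must be 'proportion' or 'percent', got {outcome_scale!r}; "
        "refusing to guess (a wrong guess is a 100x error)"
    )


def effect_per_sd(
    fit: SpatialFitResult,
    sds: pd.Series | Mapping[str, float],
    mean_share: float,
    outcome_scale: str | None = None,
    covariates: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> EffectReport:
    """Percentage-point change of the share per covariate SD.

    Parameters
    ----------
    fit : SpatialFitResult
    sds : per-covariate standard deviations on the raw (pooled) panel.
    mean_share : pooled mean of the outcome on its own scale (must be > 0).
    outcome_scale : {"proportion", "percent"} — required, no default.
    covariates : subset to report; defaults to every fitted coefficient
        that has an SD entry.
    alpha : significance level below which effects are displayed (0.05).
    """
    factor = _pp_factor(outcome_scale)  # raises if None/invalid
    if mean_share <= 0:
        raise ValueError("mean_share must be positive")
    sds = pd.Series(sds, dtype=float)
    cols = list(covariates) if covariates is not None else [
        c for c in fit.beta.index if c in sds.index
    ]
    missing = [c for c in cols if c not in sds.index]
    if missing:
        raise ValueError(f"no SD available for {missing}")

    mean_share_pct = mean_share * factor
    rows = []
    for c in cols:
        beta = float(fit.beta[c])
        pp = beta * float(sds[c]) * factor
        rows.append(
            {
                "covariate": c,
                "beta": beta,
                "sd": float(sds[c]),
                "pp_change": pp,
                "pct_of_mean": pp / mean_share_pct * 100.0,
                "p": float(fit.p[c]),
                "significant": bool(fit.p[c] < alpha),
            }
        )
    tab = pd.DataFrame(rows).set_index("covariate")
    return EffectReport(tab, float(mean_share_pct), fit.outcome, outcome_scale)


def render_coefficient_table(
    fits: Mapping[str, SpatialFitResult], digits: int = 3
) -> str:
    """Markdown coefficient matrix across fits with stars, rho and BIC rows."""
    labels = list(fits)
    all_coefs: list[str] = []
    for f in fits.values():
        for c in f.beta.index:
            if c not in all_coefs and not c.startswith("year_"):
                all_coefs.append(c)

    def cell(f: SpatialFitResult, c: str) -> str:
        if c not in f.beta.index:
            return ""
        return f"{f.beta[c]:.{digits}f}{significance_stars(f.p[c])}"

    lines = ["| | " + " | ".join(labels) + " |",
             "|---" * (len(labels) + 1) + "|"]
    for c in all_coefs:
        lines.append(f"| {c} | " + " | ".join(cell(f, c) for f in fits.values()) + " |")
    rho_cells = [
        f"{f.rho:.{digits}f}{significance_stars(f.rho_p)}" for f in fits.values()
    ]
    lines.append("| Spatial error term rho | " + " | ".join(rho_cells) + " |")
    lines.append(
        "| BIC | " + " | ".join(f"{f.bic:.2f}" for f in fits.values()) + " |"
    )
    lines.append("")
    lines.append("***p < 0.01, **p < 0.05")
    return "\n".join(lines)


def render_effect_table(
    effects: Mapping[str, EffectReport], digits: int = 2
) -> str:
    """Markdown per-SD effect matrix; non-significant entries become n.s."""
    labels = list(effects)
    covs: list[str] = []
    for rep in effects.values():
        for c in rep.table.index:
            if c not in covs:
                covs.append(c)

    def cell(rep: EffectReport, c: str) -> str:
        if c not in rep.table.index:
            return ""
        row = rep.table.loc[c]
        return f"{row.pp_change:.{digits}f}" if row.significant else "n.s."

    lines = ["| | " + " | ".join(labels) + " |",
             "|---" * (len(labels) + 1) + "|"]
    for c in covs:
        lines.append(
            f"| {c} | " + " | ".join(cell(r, c) for r in effects.values()) + " |"
        )
    means = " | ".join(f"{r.mean_share_pct:.{digits}f}" for r in effects.values())
    lines.append(f"| Mean share of AH on overall hospitalisations (in %) | {means} |")
    lines.append("")
    lines.append("n.s. = not significant at a 95%-level")
    return "\n".join(lines)


def effects_to_csv(report: EffectReport, path: str | Path) -> None:
    """Full-precision CSV of an effect report (round-trips exactly)."""
    out = report.table.copy()
    out["mean_share_pct"] = report.mean_share_pct
    out["outcome"] = report.outcome
    out["outcome_scale"] = report.outcome_scale
    out.to_csv(path, float_format="%.17g")


def read_effects_csv(path: str | Path) -> EffectReport:
    df = pd.read_csv(path, index_col="covariate", float_precision="round_trip")
    mean_pct = float(df["mean_share_pct"].iloc[0])
    outcome = str(df["outcome"].iloc[0])
    scale = str(df["outcome_scale"].iloc[0])
    tab = df.drop(columns=["mean_share_pct", "outcome", "outcome_scale"])
    tab["significant"] = tab["significant"].astype(bool)
    return EffectReport(tab, mean_pct, outcome, scale)
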