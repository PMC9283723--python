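"""Substrate-depletion kinetics: k, half-life, intrinsic clearance, and the
two-enzyme substrate classification.

Parent-compound disappearance is modelled as first order: a log-linear
ordinary least-squares fit of ln(% remaining) against time gives the rate
constant k = −slope, t1/2 = ln 2 / k, and CLint = k · V / amount (incubation
volume per amount of enzyme).  Fits are censored at the 120-min reporting
horizon: a fitted half-life beyond 120 min, or a slope that is not credibly
negative (one-sided p > 0.05), is reported as ">120" with CLint as an upper
bound.  Points below the limit of quantification (default 1 % remaining) are
excluded before fitting.

Substrate categories across the two enzymes: fast turnover in both
(t1/2 <= 30 min) = common; slow in both = weak; fast in exactly one =
preferred for that enzyme, upgraded to selective when the counterpart
half-life exceeds the 120-min horizon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import DepletionAssay, SubstrateThresholds

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

SUBSTRATE_CATEGORIES = (
    "CYP3A7_selective",
    "CYP3A7_preferred",
    "CYP3A4_selective",
    "CYP3A4_preferred",
    "common",
    "weak",
    "unclassified",
)


@dataclass
class DepletionSeries:
    compound_id: str
    enzyme: str
    time_min: np.ndarray
    pct_remaining: np.ndarray


@dataclass
class DepletionFit:
    k_per_min: float
    t_half_min: float          # inf-capable; censored fits carry the bound
    censored: bool
    slope_p: float             # one-sided p for a negative slope
    clint_ul_min_pmol: float | None = None
    quantified: bool = True

    def t_half_label(self, censor_min: float = 120.0) -> str:
        return f">{censor_min:g}" if self.censored else f"{self.t_half_min:g}"


def fit_depletion(
    series: DepletionSeries,
    thresholds: SubstrateThresholds = SubstrateThresholds(),
) -> DepletionFit:
    """Log-linear OLS depletion fit with LOQ filtering and censoring."""
    t = np.asarray(series.time_min, dtype=float)
    y = np.asarray(series.pct_remaining, dtype=float)
    keep = y >= thresholds.loq_pct
    t, y = t[keep], y[keep]
    if len(t) < 3 or 0.0 not in t:
        # mirrors compounds for which MS quantification failed
        return DepletionFit(np.nan, np.nan, False, np.nan, quantified=False)

    res = stats.linregress(t, np.log(y))
    slope = float(res.slope)
    # one-sided test for a genuinely negative slope
    if np.isnan(res.pvalue):  # zero-variance (perfectly flat) series
        slope_p = 1.0 if slope >= 0 else 0.0
    else:
        slope_p = res.pvalue / 2.0 if slope < 0 else 1.0 - res.pvalue / 2.0
    k = max(-slope, 0.0)
    t_half = LN2 / k if k > 0 else math.inf
    censored = (t_half > thresholds.censor_t_half_min) or (
        slope_p > thresholds.max_slope_p
    )
    if censored:
        t_half = math.inf
    return DepletionFit(k_per_min=k, t_half_min=t_half, censored=censored, slope_p=slope_p)


def compute_clint(
    fit: DepletionFit, assay: DepletionAssay = DepletionAssay()
) -> DepletionFit:
    """Scale the depletion rate to intrinsic clearance (µl/min/pmol).

    CLint = k · volume / CYP amount.  For censored fits the value is the
    upper bound implied by the censoring half-life.
    """
    if assay.volume_ul <= 0 or assay.cyp_amount_pmol <= 0:
        raise ValueError("volume and CYP amount must be positive")
    if not fit.quantified:
        return fit
    k = fit.k_per_min
    if fit.censored:
        # bound at the censor-horizon rate
        k = min(k, LN2 / 120.0) if np.isfinite(k) else LN2 / 120.0
    fit.clint_ul_min_pmol = k * assay.volume_ul / assay.cyp_amount_pmol
    return fit


def _is_fast(t_half: float, thresholds: SubstrateThresholds) -> bool:
    if thresholds.boundary_inclusive:
        return t_half <= thresholds.fast_t_half_min
    return t_half < thresholds.fast_t_half_min


def classify_substrate_pair(
    t_half_3a7: float | None,
    t_half_3a4: float | None,
    thresholds: SubstrateThresholds = SubstrateThresholds(),
) -> str:
    """Two-enzyme substrate category from the pair of half-lives.

    ``None``/NaN marks a missing result (no MS data for that enzyme);
    ``inf`` (or any value above the censor horizon) marks a censored ">120"
    half-life.
    """
    missing7 = t_half_3a7 is None or (isinstance(t_half_3a7, float) and np.isnan(t_half_3a7))
    missing4 = t_half_3a4 is None or (isinstance(t_half_3a4, float) and np.isnan(t_half_3a4))
    if missing7 or missing4:
        return "unclassified"
    fast7 = _is_fast(t_half_3a7, thresholds)
    fast4 = _is_fast(t_half_3a4, thresholds)
    if fast7 and fast4:
        return "common"
    if not fast7 and not fast4:
        return "weak"
    if fast7:
        return (
            "CYP3A7_selective"
            if t_half_3a4 > thresholds.censor_t_half_min
            else "CYP3A7_preferred"
        )
    return (
        "CYP3A4_selective"
        if t_half_3a7 > thresholds.censor_t_half_min
        else "CYP3A4_preferred"
    )


def fit_depletion_panel(
    panel: pd.DataFrame,
    thresholds: SubstrateThresholds = SubstrateThresholds(),
    assay: DepletionAssay = DepletionAssay(),
) -> pd.DataFrame:
    """Fit every compound-enzyme time course in a long-format panel.

    ``panel`` columns: compound_id, enzyme, time_min, pct_remaining.
    """
    rows = []
    for (cid, enzyme), grp in panel.groupby(["compound_id", "enzyme"], sort=True):
        s = DepletionSeries(
            compound_id=str(cid),
            enzyme=str(enzyme),
            time_min=grp["time_min"].to_numpy(dtype=float),
            pct_remaining=grp["pct_remaining"].to_numpy(dtype=float),
        )
        fit = compute_clint(fit_depletion(s, thresholds), assay)
        rows.append(
            {
                "compound_id": s.compound_id,
                "enzyme": s.enzyme,
                "k_per_min": fit.k_per_min,
                "t_half_min": fit.t_half_min,
                "t_half_label": fit.t_half_label(thresholds.censor_t_half_min)
                if fit.quantified
                else "no_data",
                "censored": fit.censored,
                "slope_p": fit.slope_p,
                "clint_ul_min_pmol": fit.clint_ul_min_pmol,
                "quantified": fit.quantified,
            }
        )
    return pd.DataFrame(rows)


def substrate_classification_table(
    kinetics: pd.DataFrame,
    thresholds: SubstrateThresholds = SubstrateThresholds(),
) -> pd.DataFrame:
    """Pivot per-enzyme kinetics into one categorized row per compound."""
    wide = kinetics.pivot(index="compound_id", columns="enzyme", values="t_half_min")
    quant = kinetics.pivot(index="compound_id", columns="enzyme", values="quantified")
    rows = []
    for cid in wide.index:
        t7 = wide.at[cid, "CYP3A7"] if "CYP3A7" in wide.columns else np.nan
        t4 = wide.at[cid, "CYP3A4"] if "CYP3A4" in wide.columns else np.nan
        if "CYP3A7" in quant.columns and quant.at[cid, "CYP3A7"] is False:
            t7 = np.nan
        if "CYP3A4" in quant.columns and quant.at[cid, "CYP3A4"] is False:
            t4 = np.nan
        rows.append(
            {
                "compound_id": cid,
                "t_half_3a7_min": t7,
                "t_half_3a4_min": t4,
                "category": classify_substrate_pair(
                    None if pd.isna(t7) else float(t7),
                    None if pd.isna(t4) else float(t4),
                    thresholds,
                ),
            }
        )
    return pd.DataFrame(rows)


def substrate_rate_percentages(
    n_measured: int, n_cyp3a7: int, n_cyp3a4: int, n_overlap: int
) -> dict[str, int]:
    """Headline substrate percentages from bookkeeping counts.

    Returns the CYP3A7 substrate rate (of measured compounds), the overlap
    rate (of CYP3A7 substrates) and the CYP3A4-only rate (of CYP3A4
    substrates), each rounded to the nearest integer percent.
    """
    if min(n_measured, n_cyp3a7, n_cyp3a4) <= 0:
        raise ValueError("counts must be positive")
    return {
        "pct_cyp3a7_substrates": round(100.0 * n_cyp3a7 / n_measured),
        "pct_overlap_of_cyp3a7": round(100.0 * n_overlap / n_cyp3a7),
        "pct_cyp3a4_only_of_cyp3a4": round(100.0 * (n_cyp3a4 - n_overlap) / n_cyp3a4),
    }


def summarize_substrate_table(
    classifications: pd.DataFrame,
    thresholds: SubstrateThresholds = SubstrateThresholds(),
) -> dict[str, float]:
    """Category counts plus the headline substrate rates.

    Percentages are rounded to the nearest integer; the denominator for the
    per-enzyme substrate rates is the number of compounds with data for that
    enzyme, and the overlap percentage is relative to the CYP3A7 substrate
    count (the published reporting convention).
    """
    if classifications.empty:
        return {}
    out: dict[str, float] = {}
    for cat in SUBSTRATE_CATEGORIES:
        out[f"n_{cat}"] = int((classifications["category"] == cat).sum())

    has7 = classifications["t_half_3a7_min"].notna()
    has4 = classifications["t_half_3a4_min"].notna()
    fast7 = has7 & classifications["t_half_3a7_min"].apply(
        lambda v: _is_fast(v, thresholds) if pd.notna(v) else False
    )
    fast4 = has4 & classifications["t_half_3a4_min"].apply(
        lambda v: _is_fast(v, thresholds) if pd.notna(v) else False
    )
    out["n_measured"] = int((has7 | has4).sum())
    out["n_cyp3a7_substrates"] = int(fast7.sum())
    out["n_cyp3a4_substrates"] = int(fast4.sum())
    out["n_overlap"] = int((fast7 & fast4).sum())
    if has7.sum():
        out["pct_cyp3a7_substrates"] = round(100.0 * fast7.sum() / has7.sum())
    if has4.sum():
        out["pct_cyp3a4_substrates"] = round(100.0 * fast4.sum() / has4.sum())
    if fast7.sum():
        out["pct_overlap_of_cyp3a7"] = round(100.0 * (fast7 & fast4).sum() / fast7.sum())
    if fast4.sum():
        n_3a4_only = int((fast4 & ~fast7).sum())
        out["n_cyp3a4_only"] = n_3a4_only
        out["pct_cyp3a4_only_of_cyp3a4"] = round(100.0 * n_3a4_only / fast4.sum())
    return out
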