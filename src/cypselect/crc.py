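"""Four-parameter Hill fitting, qHTS curve classification and hit calling.

The model is the standard four-parameter logistic in log10 concentration,

    a(x) = bottom + (top - bottom) / (1 + (AC50 / x)^h),

with ``bottom`` the low-concentration asymptote (baseline, expected 0 for a
control-normalized series), ``top`` the high-concentration asymptote, ``h``
the Hill slope (bounded positive), and signed efficacy = top - bottom
(negative = inhibition of the reporter signal, positive = activation).

Curve classes follow the qHTS triage taxonomy: 1.1/1.2 complete curves (both
asymptotes supported by data), 2.1/2.2 partial curves (only the baseline
plateau reached), 3 single-point or poorly supported activity, 4 inactive.
The x.1/x.2 split is at 80 % absolute efficacy.  Hit calling: classes 1.1,
1.2 and 2.1 are active; 2.2 is active only above 50 % absolute efficacy
(strict inequality); class 4 is inactive; everything else is inconclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .config import HitThresholds
from .plates import ConcentrationResponse

logger = logging.getLogger(__name__)

CURVE_CLASSES = ("1.1", "1.2", "2.1", "2.2", "3", "4")


@dataclass
class HillFit:
    ac50_um: float
    hill: float
    top: float
    bottom: float
    r2: float
    converged: bool
    beyond_range: bool
    n_points: int

    @property
    def efficacy_pct(self) -> float:
        """Signed fitted response extremum relative to the baseline asymptote."""
        return self.top - self.bottom

    def predict(self, conc_um) -> np.ndarray:
        x = np.asarray(conc_um, dtype=float)
        return hill_curve(x, self.bottom, self.top, np.log10(self.ac50_um), self.hill)


@dataclass(frozen=True)
class ActivityCall:
    value: str       # active | inactive | inconclusive
    direction: str   # inhibitor | activator | none


def hill_curve(conc_um, bottom, top, log_ac50, hill):
    """Evaluate the four-parameter Hill model at conc_um (µM)."""
    logx = np.log10(np.asarray(conc_um, dtype=float))
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ac50 - logx)))


def fit_hill(series: ConcentrationResponse, n_starts: int = 7) -> HillFit:
    """Least-squares Hill fit with multi-start initialization.

    Starts are spread over a log-spaced AC50 grid covering the tested range;
    AC50 is bounded to [min conc / 10, max conc * 10] and the Hill slope to
    [0.3, 8].  A best fit whose AC50 exceeds the highest tested concentration
    is retained but flagged ``beyond_range``.
    """
    x = series.concentrations_um
    y = series.activities_pct
    n = len(x)
    if not series.fittable or n < 4:
        return HillFit(np.nan, np.nan, 0.0, 0.0, 0.0, False, False, n)

    logx = np.log10(x)
    lo, hi = logx[0], logx[-1]
    bottom0 = float(np.mean(y[:2]))
    top0 = float(np.mean(y[-2:]))
    bounds = (
        np.array([-150.0, -150.0, lo - 1.0, 0.3]),
        np.array([150.0, 150.0, hi + 1.0, 8.0]),
    )

    def residuals(theta):
        bottom, top, log_ac50, h = theta
        return hill_curve(x, bottom, top, log_ac50, h) - y

    ln10 = np.log(10.0)

    def jacobian(theta):
        bottom, top, log_ac50, h = theta
        u = 10.0 ** (h * (log_ac50 - logx))
        f = 1.0 / (1.0 + u)
        g = u / (1.0 + u) ** 2  # -df/d(h*(la-lx)) / ln10 factor handled below
        J = np.empty((len(x), 4))
        J[:, 0] = 1.0 - f
        J[:, 1] = f
        J[:, 2] = -(top - bottom) * ln10 * h * g
        J[:, 3] = -(top - bottom) * ln10 * (log_ac50 - logx) * g
        return J

    best = None
    best_sse = np.inf
    for log_ac50_0 in np.linspace(lo, hi, n_starts):
        theta0 = np.clip(
            np.array([bottom0, top0, log_ac50_0, 1.2]), bounds[0] + 1e-9, bounds[1] - 1e-9
        )
        try:
            res = least_squares(residuals, theta0, jac=jacobian, bounds=bounds, method="trf")
        except Exception:  # pragma: no cover - scipy failure path
            continue
        if not res.success or not np.all(np.isfinite(res.x)):
            continue
        sse = float(np.sum(res.fun**2))
        if sse < best_sse:
            best_sse = sse
            best = res.x

    if best is None:
        return HillFit(np.nan, np.nan, 0.0, 0.0, 0.0, False, False, n)

    bottom, top, log_ac50, h = (float(v) for v in best)
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - best_sse / ss_tot if ss_tot > 0 else (1.0 if best_sse < 1e-12 else 0.0)
    ac50 = 10.0**log_ac50
    return HillFit(
        ac50_um=ac50,
        hill=h,
        top=top,
        bottom=bottom,
        r2=r2,
        converged=True,
        beyond_range=bool(ac50 > x[-1]),
        n_points=n,
    )


def classify_curve(
    fit: HillFit,
    series: ConcentrationResponse,
    config: HitThresholds = HitThresholds(),
    dmso_sd_pct: float | None = None,
) -> str:
    """Assign a qHTS curve class to a fitted series.

    Class 4 (inactive) when the fit failed, the fitted span is within the
    noise band, or the AC50 sits beyond the tested range.  Otherwise the
    class depends on which asymptotes the data actually reach: both plateaus
    supported -> 1.1/1.2; exactly one plateau, with r2 >= ``config.min_r2``
    -> 2.1/2.2; response confined to the single top concentration -> 3;
    residual poorly-supported fits also map to 3 (inconclusive downstream).
    """
    noise_band = config.noise_band_pct
    if dmso_sd_pct is not None:
        noise_band = max(noise_band, config.noise_band_sd_mult * dmso_sd_pct)

    eff = fit.efficacy_pct if fit.converged else 0.0
    if not fit.converged or abs(eff) < noise_band or fit.beyond_range:
        return "4"

    y = series.activities_pct
    # single-point activity takes precedence: a response confined to the top
    # concentration is class 3 no matter how well a steep Hill curve fits it
    exceed = np.abs(y) > noise_band
    if exceed.sum() == 1 and exceed[-1]:
        return "3"
    span = abs(fit.top - fit.bottom)
    tol = config.plateau_tol_frac * span
    baseline_supported = bool(np.any(np.abs(y - fit.bottom) <= tol))
    top_supported = bool(np.any(np.abs(y - fit.top) <= tol))

    full = abs(eff) >= config.full_efficacy_pct
    if baseline_supported and top_supported:
        return "1.1" if full else "1.2"
    # partial curve: exactly one asymptote reached (the baseline for ordinary
    # potencies, the response plateau for compounds saturating from the
    # lowest tested concentration)
    if (baseline_supported or top_supported) and fit.r2 >= config.min_r2:
        return "2.1" if full else "2.2"
    return "3"


def call_activity(
    curve_class: str, fit: HillFit, config: HitThresholds = HitThresholds()
) -> ActivityCall:
    """Hit call from curve class and fitted efficacy."""
    if curve_class == "4":
        return ActivityCall("inactive", "none")
    direction = "inhibitor" if fit.efficacy_pct < 0 else "activator"
    if curve_class in ("1.1", "1.2", "2.1"):
        return ActivityCall("active", direction)
    if curve_class == "2.2" and abs(fit.efficacy_pct) > config.efficacy_pct:
        return ActivityCall("active", direction)
    return ActivityCall("inconclusive", direction)


def analyze_series(
    series_list: list[ConcentrationResponse],
    config: HitThresholds = HitThresholds(),
    dmso_sd_pct: float | None = None,
) -> pd.DataFrame:
    """Fit, classify and call every series; one row per compound-enzyme."""
    rows = []
    for s in series_list:
        fit = fit_hill(s)
        cls = classify_curve(fit, s, config, dmso_sd_pct)
        call = call_activity(cls, fit, config)
        rows.append(
            {
                "compound_id": s.compound_id,
                "enzyme": s.enzyme,
                "ac50_um": fit.ac50_um,
                "hill": fit.hill,
                "top": fit.top,
                "bottom": fit.bottom,
                "efficacy_pct": fit.efficacy_pct,
                "r2": fit.r2,
                "converged": fit.converged,
                "beyond_range": fit.beyond_range,
                "curve_class": cls,
                "activity": call.value,
                "direction": call.direction,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        logger.info(
            "fitted %d series: %d active, %d inactive, %d inconclusive",
            len(df),
            int((df["activity"] == "active").sum()),
            int((df["activity"] == "inactive").sum()),
            int((df["activity"] == "inconclusive").sum()),
        )
    return df


def waterfall_export(
    series_list: list[ConcentrationResponse], results: pd.DataFrame
) -> pd.DataFrame:
    """Long-format export of every fitted curve for waterfall-style plotting."""
    calls = results.set_index(["compound_id", "enzyme"])["activity"]
    rows = []
    for s in series_list:
        call = calls.get((s.compound_id, s.enzyme), "inconclusive")
        for x, a in zip(s.concentrations_um, s.activities_pct):
            rows.append(
                {
                    "compound_id": s.compound_id,
                    "enzyme": s.enzyme,
                    "concentration_um": x,
                    "activity_pct": a,
                    "activity_call": call,
                }
            )
    return pd.DataFrame(rows)
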