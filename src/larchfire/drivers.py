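"""Driver analysis: combustion metrics, VPD, transforms, and AICc model ranking.

Six response metrics are analysed: absolute aboveground, belowground, and
total combustion (Ca, Cb, Ct, kg C m^-2) and their relative counterparts
(pCa, pCb, pCt, fractions of the corresponding pre-fire pool). Candidate
linear models encode hypotheses about plot attributes (M1: stand age,
pre-fire SOL, condensed moisture class), pre-fire stand composition (M2:
pre-fire tree biomass, larch proportion), and fire attributes (M3: FWI),
plus their unions and a null model, ranked by the small-sample corrected
Akaike information criterion

    AICc = -2 logL + 2K + 2K(K+1)/(n - K - 1)

where K counts the intercept, slope terms, factor dummy levels, and the
residual variance.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import CombustionMetrics, ValidationError

# Predictor sets per candidate model. "moisture_class" expands to a 3-level
# factor (two dummy columns); everything else is a numeric slope.
CANDIDATE_MODELS: dict[str, list[str]] = {
    "Null": [],
    "M1": ["stand_age", "prefire_sol", "moisture_class"],
    "M2": ["prefire_tree_biomass", "larch_proportion"],
    "M3": ["fwi"],
}
CANDIDATE_MODELS["M4"] = CANDIDATE_MODELS["M1"] + CANDIDATE_MODELS["M2"]
CANDIDATE_MODELS["M5"] = CANDIDATE_MODELS["M1"] + CANDIDATE_MODELS["M3"]
CANDIDATE_MODELS["M6"] = CANDIDATE_MODELS["M2"] + CANDIDATE_MODELS["M3"]
CANDIDATE_MODELS["Full"] = (
    CANDIDATE_MODELS["M1"] + CANDIDATE_MODELS["M2"] + CANDIDATE_MODELS["M3"]
)

FACTOR_PREDICTORS = {"moisture_class": 3}  # name -> number of levels

# Tukey power-ladder exponents applied to the aboveground metrics
TUKEY_LAMBDAS = {"ca": 0.35, "pca": 0.45}


def compute_vpd(temp_c: float, rh: float) -> float:
    """Vapor pressure deficit (kPa) from temperature (degC) and RH (%).

    SVP = 0.6107 * 10^(7.5 T / (T + 237.3)); VPD = (1 - RH/100) * SVP.
    """
    if not 0.0 <= rh <= 100.0:
        raise ValidationError("RH must lie in [0, 100]")
    svp = 0.6107 * 10.0 ** (7.5 * temp_c / (temp_c + 237.3))
    return (1.0 - rh / 100.0) * svp


def tukey_transform(x, lam: float):
    """Power-ladder transform x^lambda (log for lambda = 0); requires x > 0."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise ValidationError("power-ladder transform requires strictly positive values")
    out = np.log(arr) if lam == 0 else arr**lam
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def compute_metrics(
    plot_id: str,
    trees: float,
    fwd: float,
    cwd: float,
    belowground: float,
    prefire_above: float,
    prefire_below: float,
) -> CombustionMetrics:
    """Assemble the six response metrics from per-pool combustion and pools."""
    ca = trees + fwd + cwd
    cb = belowground
    ct = ca + cb

    def rel(comb: float, pool: float, label: str) -> float | None:
        if pool <= 0:
            if comb > 1e-9:
                raise ValidationError(f"{label}: combustion without a pre-fire pool")
            return None
        # tiny overshoots from floating point are tolerated, not hidden errors
        return min(comb / pool, 1.0) if comb <= pool * (1 + 1e-9) else comb / pool

    return CombustionMetrics(
        plot_id=plot_id,
        ca=ca,
        cb=cb,
        ct=ct,
        pca=rel(ca, prefire_above, "aboveground"),
        pcb=rel(cb, prefire_below, "belowground"),
        pct=rel(ct, prefire_above + prefire_below, "total"),
        pool_breakdown={"trees": trees, "fwd": fwd, "cwd": cwd, "belowground": belowground},
    )


def screen_collinearity(
    predictors: pd.DataFrame,
    response: pd.Series | None = None,
    alpha: float = 0.05,
) -> tuple[list[str], list[dict]]:
    """Drop one member of each significantly rank-correlated predictor pair.

    For each pair with Spearman p < alpha, the member with the weaker rank
    correlation to the response is dropped (without a response, the
    second-listed member is dropped). Constant predictors are dropped with a
    reason code. Returns (retained names, report rows).
    """
    report: list[dict] = []
    cols = list(predictors.columns)
    retained = []
    for c in cols:
        if predictors[c].nunique(dropna=True) <= 1:
            report.append({"pair": (c,), "rho": None, "p": None, "dropped": c, "reason": "constant"})
        else:
            retained.append(c)

    dropped: set[str] = set()
    for i, a in enumerate(retained):
        for b in retained[i + 1 :]:
            if a in dropped or b in dropped:
                continue
            rho, p = stats.spearmanr(predictors[a], predictors[b])
            if p < alpha:
                if response is not None:
                    ra = abs(stats.spearmanr(predictors[a], response)[0])
                    rb = abs(stats.spearmanr(predictors[b], response)[0])
                    loser = a if ra < rb else b
                else:
                    loser = b
                dropped.add(loser)
                report.append(
                    {"pair": (a, b), "rho": float(rho), "p": float(p), "dropped": loser,
                     "reason": "collinear"}
                )
    return [c for c in retained if c not in dropped], report


def count_parameters(predictors: list[str]) -> int:
    """K = intercept + numeric slopes + (levels - 1) dummies per factor + sigma^2."""
    k = 2  # intercept + residual variance
    for p in predictors:
        k += FACTOR_PREDICTORS[p] - 1 if p in FACTOR_PREDICTORS else 1
    return k


def aicc(loglik: float, k: int, n: int) -> float:
    if n <= k + 1:
        raise ValidationError(f"AICc undefined for n={n} <= K+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def design_matrix(df: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    """Intercept + numeric columns + factor dummies (first level dropped)."""
    parts = [pd.Series(1.0, index=df.index, name="const")]
    for p in predictors:
        if p in FACTOR_PREDICTORS:
            dummies = pd.get_dummies(df[p].astype("category"), prefix=p, drop_first=True)
            parts.append(dummies.astype(float))
        else:
            parts.append(df[p].astype(float))
    return pd.concat(parts, axis=1)


@dataclass
class ModelFitResult:
    name: str
    k: int
    loglik: float
    aicc: float
    delta_aicc: float
    weight: float
    r2: float
    skipped: bool = False
    reason: str | None = None


def fit_and_rank(
    df: pd.DataFrame,
    response: str,
    candidates: dict[str, list[str]] | None = None,
) -> list[ModelFitResult]:
    """OLS per candidate model and AICc ranking with Akaike weights.

    Candidates with n <= K + 1 are reported as skipped, never silently
    dropped. Weights are renormalised over the fitted candidates and the best
    model has delta AICc = 0.
    """
    if candidates is None:
        candidates = CANDIDATE_MODELS
    y = df[response].astype(float)
    n = len(df)
    fitted: list[ModelFitResult] = []
    for name, preds in candidates.items():
        k = count_parameters(preds)
        if n <= k + 1:
            fitted.append(
                ModelFitResult(name, k, math.nan, math.nan, math.nan, 0.0, math.nan,
                               skipped=True, reason=f"n={n} <= K+1={k + 1}")
            )
            continue
        X = design_matrix(df, preds)
        res = sm.OLS(y, X).fit()
        fitted.append(
            ModelFitResult(name, k, float(res.llf), aicc(float(res.llf), k, n),
                           math.nan, math.nan, float(res.rsquared))
        )
    usable = [f for f in fitted if not f.skipped]
    if not usable:
        raise ValidationError("no candidate model could be fitted")
    best = min(f.aicc for f in usable)
    for f in usable:
        f.delta_aicc = f.aicc - best
    total = sum(math.exp(-f.delta_aicc / 2.0) for f in usable)
    for f in usable:
        f.weight = math.exp(-f.delta_aicc / 2.0) / total
    fitted.sort(key=lambda f: (f.skipped, f.aicc if not f.skipped else math.inf))
    return fitted


def rank_table(results: list[ModelFitResult]) -> pd.DataFrame:
    """Tidy ranking table (model, K, AICc, dAICc, wi, logL, R2)."""
    return pd.DataFrame(
        {
            "model": [r.name for r in results],
            "K": [r.k for r in results],
            "AICc": [r.aicc for r in results],
            "dAICc": [r.delta_aicc for r in results],
            "wi": [r.weight for r in results],
            "logL": [r.loglik for r in results],
            "R2": [r.r2 for r in results],
            "skipped": [r.skipped for r in results],
        }
    )
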