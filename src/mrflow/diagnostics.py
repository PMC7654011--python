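"""Heterogeneity, pleiotropy, instrument-strength and influence diagnostics.

Covers Cochran's Q (IVW and Egger flavours), the Egger intercept test
for directional pleiotropy, leave-one-out influence analysis, the
instrument-strength F statistic ``F = R^2 (n - k - 1) / (k (1 - R^2))``,
the Steiger directionality test, and renderer-agnostic scatter/funnel
plot tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError
from .estimators import MREstimate, egger, ivw, ratio_estimates
from .harmonize import HarmonizedSet


@dataclass(frozen=True)
class HeterogeneityResult:
    method: str  # "ivw" or "egger"
    q: float
    df: int
    pval: float


@dataclass(frozen=True)
class InstrumentStrength:
    r2_total: float
    n: int
    k: int
    f_stat: float
    weak: bool  # True when F <= 10


@dataclass(frozen=True)
class SteigerResult:
    r2_exp: float
    r2_out: float
    direction: str  # "exposure_to_outcome" or "outcome_to_exposure"
    per_snp: pd.DataFrame = field(compare=False, default=None)


def cochran_q(hset: HarmonizedSet, method: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q heterogeneity statistic.

    ``ivw``: Q = sum w_j (r_j - beta_fixed)^2 over Wald ratios with
    w_j = 1/se_ratio_j^2, df = J-1.  ``egger``: weighted residual sum of
    squares around the Egger fit with weights 1/se_out^2, df = J-2.
    """
    j = len(hset)
    if method == "ivw":
        if j < 2:
            raise InsufficientDataError("Cochran Q (IVW) requires >= 2 SNPs")
        rs = ratio_estimates(hset)
        ratios = np.array([r.ratio for r in rs])
        weights = np.array([r.weight for r in rs])
        beta_fixed = (weights * ratios).sum() / weights.sum()
        q = float((weights * (ratios - beta_fixed) ** 2).sum())
        df = j - 1
    elif method == "egger":
        if j < 3:
            raise InsufficientDataError("Cochran Q (Egger) requires >= 3 SNPs")
        fit = egger(hset)
        q = float(fit.extras["cochran_q"])
        df = j - 2
    else:
        raise ValueError(f"unknown heterogeneity method {method!r}")
    pval = float(max(stats.chi2.sf(q, df), 5e-324))
    return HeterogeneityResult(method=method, q=q, df=df, pval=pval)


def egger_intercept_test(hset: HarmonizedSet) -> dict:
    """Egger intercept as a directional-pleiotropy indicator.

    Returns the intercept estimate, SE and p, plus
    ``pleiotropy_detected`` — True when the intercept p < 0.05.
    """
    fit = egger(hset)
    p = fit.extras["intercept_p"]
    return {
        "intercept": fit.extras["intercept"],
        "se": fit.extras["intercept_se"],
        "pval": p,
        "pleiotropy_detected": p < 0.05,
    }


def leave_one_out(
    hset: HarmonizedSet,
    method: str = "ivw",
    alpha: float = 0.05,
    flag_rule: str = "significance_flip",
) -> pd.DataFrame:
    """Leave-one-out estimates with influence flags.

    A SNP is "potentially influential" when the full-set estimate is
    significant at ``alpha`` but the estimate without that SNP is not
    (``significance_flip``, default), or — with
    ``flag_rule="outside_ci"`` — when the leave-one-out estimate falls
    outside the full-set 95% CI.
    """
    if method != "ivw":
        raise ValueError("leave-one-out supports the ivw method")
    if flag_rule not in ("significance_flip", "outside_ci"):
        raise ValueError(f"unknown flag_rule {flag_rule!r}")
    j = len(hset)
    if j < 3:
        raise InsufficientDataError("leave-one-out requires >= 3 SNPs")
    full = ivw(hset)
    rows = []
    for rec in hset.retained:
        sub = hset.without([rec.rsid])
        est = ivw(sub)
        if flag_rule == "significance_flip":
            influential = full.pval < alpha and est.pval >= alpha
        else:
            influential = not (full.ci95_low <= est.beta <= full.ci95_high)
        rows.append(
            {
                "excluded_rsid": rec.rsid, "beta": est.beta, "se": est.se,
                "pval": est.pval, "influential": influential,
            }
        )
    return pd.DataFrame(rows)


def f_statistic(r2_total: float, n: int, k: int) -> InstrumentStrength:
    """Instrument-strength F statistic, ``R^2 (n - k - 1) / (k (1 - R^2))``.

    ``r2_total`` is the variance of the exposure explained by the k
    instruments jointly and ``n`` the exposure GWAS sample size.  Values
    of F well above 10 indicate negligible weak-instrument bias.
    """
    if not (0.0 <= r2_total < 1.0):
        raise ConfigurationError(f"r2_total must lie in [0, 1), got {r2_total}")
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if n <= k + 1:
        raise ConfigurationError(f"need n > k + 1 (got n={n}, k={k})")
    f = r2_total * (n - k - 1) / (k * (1.0 - r2_total))
    return InstrumentStrength(r2_total=r2_total, n=n, k=k, f_stat=float(f), weak=f <= 10)


def snp_r2(beta: np.ndarray, se: np.ndarray, n: int) -> np.ndarray:
    """Per-SNP variance explained via the t-statistic: t^2 / (t^2 + n - 2)."""
    t2 = (np.asarray(beta) / np.asarray(se)) ** 2
    return t2 / (t2 + n - 2)


def steiger_direction(hset: HarmonizedSet, n_exp: int, n_out: int) -> SteigerResult:
    """Steiger directionality test: exposure→outcome iff the instruments
    explain more variance in the exposure than in the outcome."""
    if n_exp <= 2 or n_out <= 2:
        raise ConfigurationError("Steiger test requires sample sizes > 2")
    bx = np.array([r.beta_exp for r in hset.retained])
    sx = np.array([r.se_exp for r in hset.retained])
    by = np.array([r.beta_out for r in hset.retained])
    sy = np.array([r.se_out for r in hset.retained])
    r2x = snp_r2(bx, sx, n_exp)
    r2y = snp_r2(by, sy, n_out)
    per_snp = pd.DataFrame(
        {"rsid": hset.rsids(), "r2_exp": r2x, "r2_out": r2y}
    )
    r2_exp, r2_out = float(r2x.sum()), float(r2y.sum())
    direction = "exposure_to_outcome" if r2_exp > r2_out else "outcome_to_exposure"
    return SteigerResult(r2_exp=r2_exp, r2_out=r2_out, direction=direction, per_snp=per_snp)


def scatter_data(hset: HarmonizedSet, estimates: dict[str, MREstimate]) -> pd.DataFrame:
    """Plot-ready scatter table: per-SNP points plus one line per method.

    Point rows carry (beta_exp, beta_out) with SE error bars; line rows
    carry (slope, intercept) — the Egger line keeps its fitted intercept,
    all other methods pass through the origin.
    """
    rows = [
        {
            "kind": "point", "rsid": r.rsid,
            "beta_exp": r.beta_exp, "se_exp": r.se_exp,
            "beta_out": r.beta_out, "se_out": r.se_out,
            "method": "", "slope": np.nan, "intercept": np.nan,
        }
        for r in hset.retained
    ]
    for name, est in estimates.items():
        rows.append(
            {
                "kind": "line", "rsid": "",
                "beta_exp": np.nan, "se_exp": np.nan,
                "beta_out": np.nan, "se_out": np.nan,
                "method": name, "slope": est.beta,
                "intercept": est.extras.get("intercept", 0.0),
            }
        )
    return pd.DataFrame(rows)


def funnel_data(hset: HarmonizedSet, estimates: dict[str, MREstimate]) -> pd.DataFrame:
    """Plot-ready funnel table: per-SNP (ratio, 1/se_ratio) plus method verticals."""
    rows = [
        {"kind": "point", "rsid": r.rsid, "ratio": r.ratio,
         "precision": 1.0 / r.se_ratio, "method": ""}
        for r in ratio_estimates(hset)
    ]
    for name, est in estimates.items():
        rows.append(
            {"kind": "line", "rsid": "", "ratio": est.beta,
             "precision": np.nan, "method": name}
        )
    return pd.DataFrame(rows)
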