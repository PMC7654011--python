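"""Causal estimators for two-sample MR on harmonized summary statistics.

Per-SNP Wald ratios (outcome beta over exposure beta) are combined by
five estimators with different robustness profiles:

* ``ivw`` — inverse-variance-weighted meta-analysis of the ratios;
  fixed-effect, or multiplicative random-effect when Cochran's Q signals
  heterogeneity (the ``auto`` rule applies random effects iff Q's p < 0.05).
* ``egger`` — weighted regression of outcome on exposure betas with a free
  intercept; the slope is the causal estimate, the intercept measures
  directional pleiotropy.
* ``weighted_median`` — consistent when at least half the weight is on
  valid instruments.
* ``mode_based`` — the dominant cluster of ratio estimates, via a
  weighted Gaussian kernel density; consistent when the largest cluster
  is valid even if most instruments are not.
* ``raps`` — robust adjusted profile score: profile likelihood of the
  ratio model accounting for exposure-side noise, with optional
  overdispersion and a Huber-robustified score against idiosyncratic
  pleiotropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .errors import EstimationError, InsufficientDataError
from .harmonize import HarmonizedRecord, HarmonizedSet

Z95 = 1.959963984540054  # Phi^{-1}(0.975)

HUBER_C = 1.345  # 95%-efficiency tuning constant


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio with delta-method SE and inverse-variance weight."""

    rsid: str
    ratio: float
    se_ratio: float

    @property
    def weight(self) -> float:
        return 1.0 / self.se_ratio**2


@dataclass
class MREstimate:
    """One estimator's causal effect with normal/t 95% CI and p-value."""

    method: str
    beta: float
    se: float
    ci95_low: float
    ci95_high: float
    pval: float
    n_snp: int
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "method": self.method, "beta": self.beta, "se": self.se,
            "ci_low": self.ci95_low, "ci_high": self.ci95_high,
            "pval": self.pval, "n_snp": self.n_snp,
        }
        row.update({f"extra_{k}": v for k, v in self.extras.items()})
        return row


def wald_ratio(record: HarmonizedRecord, order: str = "first") -> RatioEstimate:
    """Wald ratio ``beta_out / beta_exp`` with first- or second-order SE.

    First order: ``se_out / |beta_exp|``.  Second order adds the
    exposure-noise term: ``se^2 = se_out^2/beta_exp^2 +
    beta_out^2 * se_exp^2 / beta_exp^4``.
    """
    if record.beta_exp == 0:
        raise EstimationError(f"{record.rsid}: degenerate instrument (beta_exp = 0)")
    ratio = record.beta_out / record.beta_exp
    if order == "first":
        se = record.se_out / abs(record.beta_exp)
    elif order == "second":
        se = np.sqrt(
            record.se_out**2 / record.beta_exp**2
            + record.beta_out**2 * record.se_exp**2 / record.beta_exp**4
        )
    else:
        raise ValueError(f"unknown SE order {order!r}")
    return RatioEstimate(record.rsid, ratio, float(se))


def ratio_estimates(hset: HarmonizedSet, order: str = "first") -> list[RatioEstimate]:
    return [wald_ratio(r, order) for r in hset.retained]


def _arrays(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    x = np.array([r.beta_exp for r in hset.retained], dtype=float)
    sx = np.array([r.se_exp for r in hset.retained], dtype=float)
    y = np.array([r.beta_out for r in hset.retained], dtype=float)
    sy = np.array([r.se_out for r in hset.retained], dtype=float)
    return x, sx, y, sy


def _two_sided_normal_p(z: float) -> float:
    # clamped into (0, 1] so downstream log transforms stay defined
    return float(min(1.0, max(2.0 * stats.norm.sf(abs(z)), 5e-324)))


def ivw_from_ratios(
    ratios: np.ndarray, weights: np.ndarray, model: str = "auto"
) -> tuple[float, float, float, int, str, float]:
    """Core IVW on precomputed ratios; returns (beta, se, p, J, model, Q)."""
    ratios = np.asarray(ratios, dtype=float)
    weights = np.asarray(weights, dtype=float)
    j = ratios.size
    if j == 0:
        raise EstimationError("IVW requires at least one SNP")
    wsum = weights.sum()
    beta = float((weights * ratios).sum() / wsum)
    se_fixed = float(wsum**-0.5)
    q = float((weights * (ratios - beta) ** 2).sum())
    if j > 1:
        q_p = float(stats.chi2.sf(q, j - 1))
        scale = max(1.0, np.sqrt(q / (j - 1)))
    else:
        q_p, scale = 1.0, 1.0
    if model == "fixed":
        chosen, se = "fixed", se_fixed
    elif model == "random":
        chosen, se = "random", se_fixed * scale
    elif model == "auto":
        if q_p < 0.05:
            chosen, se = "random", se_fixed * scale
        else:
            chosen, se = "fixed", se_fixed
    else:
        raise ValueError(f"unknown IVW model {model!r}")
    p = _two_sided_normal_p(beta / se)
    return beta, se, p, j, chosen, q


def ivw(hset: HarmonizedSet, model: str = "auto", se_order: str = "first") -> MREstimate:
    """Inverse-variance-weighted meta-analysis of per-SNP Wald ratios."""
    rs = ratio_estimates(hset, se_order)
    ratios = np.array([r.ratio for r in rs])
    weights = np.array([r.weight for r in rs])
    beta, se, p, j, chosen, q = ivw_from_ratios(ratios, weights, model)
    return MREstimate(
        method="ivw", beta=beta, se=se,
        ci95_low=beta - Z95 * se, ci95_high=beta + Z95 * se,
        pval=p, n_snp=j,
        extras={"model": chosen, "cochran_q": q, "se_order": se_order},
    )


def egger(hset: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted regression of outcome betas on exposure betas.

    Each SNP is first oriented so its exposure beta is positive (the
    regression is not invariant to allele orientation otherwise).
    Weights are 1/se_out^2; SEs carry a multiplicative overdispersion
    factor floored at 1, and p-values use t(J-2).
    """
    j = len(hset)
    if j < 3:
        raise InsufficientDataError(f"MR-Egger requires >= 3 SNPs, got {j}")
    x, _, y, sy = _arrays(hset)
    sign = np.where(x < 0, -1.0, 1.0)
    x, y = x * sign, y * sign
    if np.allclose(x, x[0]):
        raise EstimationError("degenerate design: no variance in exposure betas")
    w = 1.0 / sy**2
    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    # statsmodels' scale is Q_egger/(J-2); refloor it at 1 (multiplicative
    # overdispersion never shrinks SEs below the fixed-effect ones)
    q_egger = float(fit.scale * (j - 2))
    infl = max(1.0, fit.scale)
    cov = np.asarray(fit.normalized_cov_params) * infl
    slope, intercept = float(fit.params[1]), float(fit.params[0])
    se_slope = float(np.sqrt(cov[1, 1]))
    se_int = float(np.sqrt(cov[0, 0]))
    tdist = stats.t(df=j - 2)
    tcrit = float(tdist.ppf(0.975))
    p_slope = float(min(1.0, max(2.0 * tdist.sf(abs(slope / se_slope)), 5e-324)))
    p_int = float(min(1.0, max(2.0 * tdist.sf(abs(intercept / se_int)), 5e-324)))
    return MREstimate(
        method="egger", beta=slope, se=se_slope,
        ci95_low=slope - tcrit * se_slope, ci95_high=slope + tcrit * se_slope,
        pval=p_slope, n_snp=j,
        extras={
            "intercept": intercept, "intercept_se": se_int, "intercept_p": p_int,
            "cochran_q": q_egger, "df": j - 2,
        },
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by interpolating cumulative weight percentiles at 0.5."""
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w)
    p = s - w / 2.0
    return float(np.interp(0.5, p, r))


def _parametric_bootstrap_se(
    hset: HarmonizedSet,
    point_fn,
    n_boot: int,
    seed: int,
) -> float:
    """SD of the point estimate over parametric resamples of the betas."""
    x, sx, y, sy = _arrays(hset)
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        xb = rng.normal(x, sx)
        yb = rng.normal(y, sy)
        # guard against resampled exposure betas crossing zero
        xb = np.where(xb == 0, np.finfo(float).tiny, xb)
        ratios = yb / xb
        weights = (xb / sy) ** 2
        est[b] = point_fn(ratios, weights)
    return float(est.std(ddof=1)) if n_boot > 1 else float("nan")


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE."""
    j = len(hset)
    if j < 3:
        raise InsufficientDataError(f"weighted median requires >= 3 SNPs, got {j}")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rs = ratio_estimates(hset)
    ratios = np.array([r.ratio for r in rs])
    weights = np.array([r.weight for r in rs])
    beta = _weighted_median_point(ratios, weights)
    se = _parametric_bootstrap_se(hset, _weighted_median_point, n_boot, seed)
    p = _two_sided_normal_p(beta / se) if np.isfinite(se) and se > 0 else 1.0
    return MREstimate(
        method="weighted_median", beta=beta, se=se,
        ci95_low=beta - Z95 * se, ci95_high=beta + Z95 * se,
        pval=p, n_snp=j, extras={"n_boot": n_boot, "seed": seed},
    )


_MODE_GRID_SIZE = 512


def _mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """Argmax of the weighted Gaussian KDE of the ratios on a fixed grid."""
    j = ratios.size
    sd = ratios.std(ddof=1) if j > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    h = phi * 0.9 * spread * j ** (-1 / 5)
    if h <= 0:  # all ratios identical: the mode is their common value
        return float(ratios[0])
    grid = np.linspace(ratios.min(), ratios.max(), _MODE_GRID_SIZE)
    dens = (weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2)).sum(axis=0)
    return float(grid[int(np.argmax(dens))])


def mode_based(
    hset: HarmonizedSet,
    phi: float = 1.0,
    weighted: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode-based estimate: the dominant cluster of Wald ratios.

    The bandwidth is ``phi * 0.9 * min(sd, iqr/1.349) * J^(-1/5)`` on the
    ratio estimates; ``phi`` trades cluster resolution against stability
    and must be chosen (and is recorded) explicitly.
    """
    j = len(hset)
    if j < 3:
        raise InsufficientDataError(f"mode-based estimate requires >= 3 SNPs, got {j}")
    if phi <= 0:
        raise ValueError("phi must be positive")
    rs = ratio_estimates(hset)
    ratios = np.array([r.ratio for r in rs])
    weights = np.array([r.weight for r in rs]) if weighted else np.ones(j)

    def point(r: np.ndarray, w: np.ndarray) -> float:
        return _mode_point(r, w if weighted else np.ones(r.size), phi)

    beta = point(ratios, weights)
    se = _parametric_bootstrap_se(hset, point, n_boot, seed)
    p = _two_sided_normal_p(beta / se) if np.isfinite(se) and se > 0 else 1.0
    return MREstimate(
        method="mode_based", beta=beta, se=se,
        ci95_low=beta - Z95 * se, ci95_high=beta + Z95 * se,
        pval=p, n_snp=j,
        extras={"phi": phi, "weighted": weighted, "n_boot": n_boot, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Robust adjusted profile score (RAPS)
# ---------------------------------------------------------------------------

def _huber_rho(t: np.ndarray, c: float = HUBER_C) -> np.ndarray:
    a = np.abs(t)
    return np.where(a <= c, 0.5 * t**2, c * a - 0.5 * c**2)


def _huber_psi(t: np.ndarray, c: float = HUBER_C) -> np.ndarray:
    return np.clip(t, -c, c)


def _huber_delta(c: float = HUBER_C) -> float:
    """E[psi(Z) Z] under Z ~ N(0,1); equals 1 for the identity score."""
    return float(2 * (stats.norm.cdf(c) - 0.5) - 2 * c * stats.norm.pdf(c)
                 + 2 * c**2 * stats.norm.sf(c))


def _raps_tau2(beta: float, x, sx, y, sy, psi, delta: float) -> float:
    """Solve the overdispersion estimating equation for tau^2 >= 0 at fixed beta."""
    resid = y - beta * x

    def eq(tau2: float) -> float:
        var = sy**2 + beta**2 * sx**2 + tau2
        t = resid / np.sqrt(var)
        return float(((psi(t) * t - delta) / var).sum())

    if eq(0.0) <= 0:  # residuals already under-dispersed: boundary solution
        return 0.0
    hi = float(resid.var() + (sy**2 + beta**2 * sx**2).max()) + 1e-12
    while eq(hi) > 0:
        hi *= 4.0
        if hi > 1e12:
            raise EstimationError("overdispersion solve failed to bracket tau^2")
    return float(optimize.brentq(eq, 0.0, hi, xtol=1e-14, rtol=1e-12))


def raps(
    hset: HarmonizedSet,
    loss: str = "huber",
    overdispersion: bool = True,
) -> MREstimate:
    """Robust adjusted profile score estimator.

    Models ``beta_out_j ~ N(beta * beta_exp_j, se_out_j^2 +
    beta^2 * se_exp_j^2 + tau^2)`` with systematic-pleiotropy variance
    ``tau^2 >= 0`` (present iff ``overdispersion``), and maximizes the
    profile likelihood with the chosen loss applied to standardized
    residuals (``l2`` = Gaussian, ``huber`` = 95%-efficiency Huber).
    The SE comes from an M-estimator sandwich built on the numerically
    differentiated profile score.
    """
    j = len(hset)
    if j < 3:
        raise InsufficientDataError(f"RAPS requires >= 3 SNPs, got {j}")
    x, sx, y, sy = _arrays(hset)
    if loss == "l2":
        rho, psi, delta = lambda t: 0.5 * t**2, lambda t: t, 1.0
    elif loss == "huber":
        rho, psi, delta = _huber_rho, _huber_psi, _huber_delta()
    else:
        raise ValueError(f"unknown loss {loss!r}")

    def tau2_of(beta: float) -> float:
        if not overdispersion:
            return 0.0
        return _raps_tau2(beta, x, sx, y, sy, psi, delta)

    def negloglik(beta: float) -> float:
        var = sy**2 + beta**2 * sx**2 + tau2_of(beta)
        t = (y - beta * x) / np.sqrt(var)
        return float((rho(t) + 0.5 * np.log(var)).sum())

    # bracket the optimum around the IVW slope, then refine
    b0 = float((x * y / sy**2).sum() / (x**2 / sy**2).sum())
    span = 10.0 * max(abs(b0), (sy / np.abs(x)).mean()) + 1e-6
    grid = np.linspace(b0 - span, b0 + span, 41)
    vals = [negloglik(b) for b in grid]
    k = int(np.argmin(vals))
    lo = grid[max(0, k - 1)]
    hi = grid[min(len(grid) - 1, k + 1)]
    res = optimize.minimize_scalar(negloglik, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:
        raise EstimationError(f"RAPS profile optimization did not converge: {res.message}")
    beta_hat = float(res.x)
    tau2_hat = tau2_of(beta_hat)

    def score_contrib(beta: float) -> np.ndarray:
        """Per-SNP profile-score contributions d(-loglik_j)/d(beta)."""
        var = sy**2 + beta**2 * sx**2 + tau2_of(beta)
        s = np.sqrt(var)
        t = (y - beta * x) / s
        dvar = 2 * beta * sx**2
        dt = (-x * s - (y - beta * x) * dvar / (2 * s)) / var
        return psi(t) * dt + 0.5 * dvar / var

    h = 1e-5 * (abs(beta_hat) + 1.0)
    score_hi = score_contrib(beta_hat + h)
    score_lo = score_contrib(beta_hat - h)
    bread = float((score_hi - score_lo).sum() / (2 * h))
    meat = float((score_contrib(beta_hat) ** 2).sum())
    if bread <= 0:
        raise EstimationError("RAPS sandwich: non-positive curvature at optimum")
    se = float(np.sqrt(meat) / bread)
    p = _two_sided_normal_p(beta_hat / se)
    return MREstimate(
        method="raps", beta=beta_hat, se=se,
        ci95_low=beta_hat - Z95 * se, ci95_high=beta_hat + Z95 * se,
        pval=p, n_snp=j,
        extras={"loss": loss, "overdispersion": overdispersion, "tau2": tau2_hat},
    )


def all_estimates(
    hset: HarmonizedSet,
    *,
    ivw_model: str = "auto",
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    raps_loss: str = "huber",
    raps_overdispersion: bool = True,
) -> dict[str, MREstimate]:
    """The five estimators on one harmonized set, keyed by method name."""
    return {
        "ivw": ivw(hset, model=ivw_model),
        "mode_based": mode_based(hset, phi=phi, n_boot=n_boot, seed=seed + 1),
        "weighted_median": weighted_median(hset, n_boot=n_boot, seed=seed + 2),
        "egger": egger(hset),
        "raps": raps(hset, loss=raps_loss, overdispersion=raps_overdispersion),
    }


def estimates_table(estimates: dict[str, MREstimate]):
    import pandas as pd

    return pd.DataFrame([e.to_row() for e in estimates.values()])
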