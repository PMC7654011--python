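"""MR-PRESSO: pleiotropy residual sum and outlier tests.

Three Monte-Carlo tests built on leave-one-out IVW residuals:

* global test — is the observed weighted residual sum of squares (RSS)
  larger than expected under the no-pleiotropy null?
* outlier test — per-SNP residual p-values (Bonferroni-adjusted) flag
  individual pleiotropic variants;
* distortion test — does removing the flagged outliers shift the causal
  estimate more than removing as many random SNPs would?

The null distribution is simulated by redrawing both exposure and
outcome betas around their leave-one-out predictions; p-values use the
add-one convention ``(1 + #{exceedances}) / (1 + n_sim)`` so they are
never exactly zero.  Note the implied floor: the smallest attainable
Bonferroni-adjusted per-SNP p is ``J / (n_sim + 1)``, so ``n_sim`` must
comfortably exceed ``J / alpha`` for the outlier test to have any power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimationError, InsufficientDataError, StateError
from .harmonize import HarmonizedSet

DEFAULT_N_SIM = 1000
DEFAULT_OUTLIER_ALPHA = 0.05


@dataclass
class PressoResult:
    """Accumulates global, outlier and distortion test results."""

    rss_obs: float
    global_p: float
    n_sim: int
    seed: int
    per_snp_p: dict[str, float] = field(default_factory=dict)
    per_snp_p_adj: dict[str, float] = field(default_factory=dict)
    outliers: set[str] = field(default_factory=set)
    outlier_alpha: float | None = None
    outlier_criterion: str | None = None
    distortion_p: float | None = None
    distortion_coef: float | None = None
    beta_before: float | None = None
    beta_after: float | None = None
    # per-SNP observed and simulated residual sums, kept for the outlier test
    _rss_per_snp: np.ndarray | None = None
    _sim_rss_per_snp: np.ndarray | None = None
    _rsids: list[str] = field(default_factory=list)

    def per_snp_table(self) -> pd.DataFrame:
        rows = [
            {
                "rsid": rsid,
                "p_raw": self.per_snp_p.get(rsid),
                "p_adj": self.per_snp_p_adj.get(rsid),
                "outlier": rsid in self.outliers,
            }
            for rsid in self._rsids
        ]
        return pd.DataFrame(rows)


def _loo_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slopes, vectorized over SNPs.

    Works on 1-D arrays or on (n_sim, J) stacks (last axis = SNPs).
    """
    num = (w * x * y).sum(axis=-1, keepdims=True) - w * x * y
    den = (w * x * x).sum(axis=-1, keepdims=True) - w * x * x
    return num / den


def presso_global(
    hset: HarmonizedSet, n_sim: int = DEFAULT_N_SIM, seed: int = 0
) -> PressoResult:
    """MR-PRESSO global test of horizontal pleiotropy.

    Observed RSS_j = w_j (beta_out_j - b_loo(-j) * beta_exp_j)^2 with
    w_j = 1/se_out_j^2; the null redraws exposure betas around their
    observed values and outcome betas around the leave-one-out
    predictions, recomputing the RSS on each replicate.
    """
    j = len(hset)
    if j < 4:
        raise InsufficientDataError(f"MR-PRESSO requires >= 4 SNPs, got {j}")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    # canonical rsid order so results are invariant to input row order
    recs = sorted(hset.retained, key=lambda r: r.rsid)
    x = np.array([r.beta_exp for r in recs])
    sx = np.array([r.se_exp for r in recs])
    y = np.array([r.beta_out for r in recs])
    sy = np.array([r.se_out for r in recs])
    w = 1.0 / sy**2

    b_loo = _loo_slopes(x, y, w)
    rss_per_snp = w * (y - b_loo * x) ** 2
    rss_obs = float(rss_per_snp.sum())

    rng = np.random.default_rng(seed)
    xs = rng.normal(x, sx, size=(n_sim, j))
    ys = rng.normal(b_loo * x, sy, size=(n_sim, j))
    b_loo_sim = _loo_slopes(xs, ys, w)
    sim_rss_per_snp = w * (ys - b_loo_sim * xs) ** 2
    sim_rss = sim_rss_per_snp.sum(axis=1)

    global_p = float((1 + (sim_rss >= rss_obs).sum()) / (1 + n_sim))
    return PressoResult(
        rss_obs=rss_obs, global_p=global_p, n_sim=n_sim, seed=seed,
        _rss_per_snp=rss_per_snp, _sim_rss_per_snp=sim_rss_per_snp,
        _rsids=[r.rsid for r in recs],
    )


def presso_outlier(
    hset: HarmonizedSet,
    result: PressoResult,
    outlier_alpha: float = DEFAULT_OUTLIER_ALPHA,
    criterion: str = "adjusted",
) -> PressoResult:
    """Per-SNP outlier test on the stored simulated residuals.

    Raw p_j = (1 + #{RSS*_j >= RSS_j}) / (1 + n_sim); adjusted
    p_j = min(1, J * p_j) (Bonferroni).  Flagging compares the adjusted
    (default) or raw p against ``outlier_alpha``.
    """
    if result._sim_rss_per_snp is None or result._rss_per_snp is None:
        raise StateError("presso_outlier requires presso_global to have been run")
    if criterion not in ("adjusted", "raw"):
        raise ValueError(f"unknown outlier criterion {criterion!r}")
    j = len(result._rsids)
    exceed = (result._sim_rss_per_snp >= result._rss_per_snp[None, :]).sum(axis=0)
    p_raw = (1 + exceed) / (1 + result.n_sim)
    p_adj = np.minimum(1.0, j * p_raw)
    result.per_snp_p = dict(zip(result._rsids, p_raw.astype(float)))
    result.per_snp_p_adj = dict(zip(result._rsids, p_adj.astype(float)))
    flag_p = p_adj if criterion == "adjusted" else p_raw
    result.outliers = {
        rsid for rsid, p in zip(result._rsids, flag_p) if p < outlier_alpha
    }
    result.outlier_alpha = outlier_alpha
    result.outlier_criterion = criterion
    return result


def presso_distortion(
    hset: HarmonizedSet,
    result: PressoResult,
    n_sim: int = DEFAULT_N_SIM,
    seed: int | None = None,
) -> PressoResult:
    """Distortion test: does outlier removal shift the IVW estimate?

    D = (beta_before - beta_after) / |beta_after|; the null removes
    |outliers| SNPs drawn uniformly from the non-outlier pool and
    recomputes D, giving a two-sided empirical p.  With no flagged
    outliers, distortion_p = 1 by convention.
    """
    if result.outlier_criterion is None:
        raise StateError("presso_distortion requires presso_outlier to have been run")
    recs = sorted(hset.retained, key=lambda r: r.rsid)
    x = np.array([r.beta_exp for r in recs])
    y = np.array([r.beta_out for r in recs])
    sy = np.array([r.se_out for r in recs])
    w = (x / sy) ** 2
    ratios = y / x

    def ivw_fixed(mask: np.ndarray) -> float:
        return float((w[mask] * ratios[mask]).sum() / w[mask].sum())

    rsids = np.array([r.rsid for r in recs])
    is_out = np.isin(rsids, list(result.outliers))
    result.beta_before = ivw_fixed(np.ones(len(rsids), dtype=bool))
    if not result.outliers:
        result.distortion_p = 1.0
        result.distortion_coef = 0.0
        result.beta_after = result.beta_before
        return result
    if is_out.all():
        raise EstimationError("all SNPs flagged as outliers; distortion test undefined")
    result.beta_after = ivw_fixed(~is_out)
    d_obs = (result.beta_before - result.beta_after) / abs(result.beta_after)
    result.distortion_coef = float(d_obs)

    pool = np.flatnonzero(~is_out)
    k = int(is_out.sum())
    rng = np.random.default_rng(result.seed + 1 if seed is None else seed)
    # vectorized draws: the first k columns of a random argsort are a
    # uniform without-replacement sample from the pool for each replicate
    removed = np.argsort(rng.random((n_sim, pool.size)), axis=1)[:, :k]
    w_rm = w[pool][removed].sum(axis=1)
    wr_rm = (w * ratios)[pool][removed].sum(axis=1)
    b_sub = ((w * ratios).sum() - wr_rm) / (w.sum() - w_rm)
    d_null = (result.beta_before - b_sub) / np.abs(b_sub)
    result.distortion_p = float((1 + (np.abs(d_null) >= abs(d_obs)).sum()) / (1 + n_sim))
    return result


def run_presso(
    hset: HarmonizedSet,
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
    outlier_alpha: float = DEFAULT_OUTLIER_ALPHA,
    criterion: str = "adjusted",
) -> PressoResult:
    """Global, outlier and distortion tests in sequence."""
    result = presso_global(hset, n_sim=n_sim, seed=seed)
    presso_outlier(hset, result, outlier_alpha=outlier_alpha, criterion=criterion)
    presso_distortion(hset, result, n_sim=n_sim)
    return result
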