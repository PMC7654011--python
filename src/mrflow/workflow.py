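"""Staged MR analysis: full set → outlier-pruned → heterogeneity-pruned.

The analysis ladder re-runs every estimator and diagnostic after each
pruning stage:

* Step 1 — all selected, harmonized instruments;
* Step 2 — entered when the MR-PRESSO global test detects pleiotropy
  (p < 0.05) and outliers were flagged: the flagged SNPs are removed;
* Step 3 — entered when IVW heterogeneity is still significant after
  Step 2: every SNP whose (adjusted) MR-PRESSO outlier p fell below 1 in
  the full-set outlier test is removed.

The final stage carries the step code reported in the result tables; a
Bonferroni rule over the five methods (alpha/5 = 0.01 by default) turns
per-method p-values into an overall verdict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import RunConfig
from .diagnostics import (
    HeterogeneityResult,
    InstrumentStrength,
    cochran_q,
    f_statistic,
    leave_one_out,
    steiger_direction,
)
from .errors import InsufficientDataError
from .estimators import MREstimate, all_estimates
from .gwas_io import GwasSummary
from .harmonize import HarmonizedSet, harmonize
from .instruments import LDPanel, clump, filter_maf, filter_significant
from .presso import PressoResult, run_presso

logger = logging.getLogger(__name__)


@dataclass
class StagedResult:
    """Everything computed at one step of the analysis ladder."""

    step: int
    snps_used: list[str]
    estimates: dict[str, MREstimate]
    het_ivw: HeterogeneityResult
    het_egger: HeterogeneityResult
    egger_intercept: dict
    presso: PressoResult
    strength: InstrumentStrength
    steiger: object
    influential: list[str]
    conclusion: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def bonferroni_conclude(
    estimates: dict[str, MREstimate],
    alpha: float = 0.05,
    n_methods: int = 5,
    lead_method: str = "ivw",
    influential: list[str] | None = None,
) -> dict:
    """Per-method significance at alpha/n_methods plus an overall verdict.

    Verdict "causal" requires the lead method (IVW by default) to pass
    the Bonferroni threshold with no influential-SNP flag; "suggestive"
    when any method passes; otherwise "null".
    """
    if n_methods < 1:
        raise ValueError("n_methods must be >= 1")
    threshold = alpha / n_methods
    per_method = {name: est.pval < threshold for name, est in estimates.items()}
    influential = influential or []
    if per_method.get(lead_method, False) and not influential:
        verdict = "causal"
    elif any(per_method.values()):
        verdict = "suggestive"
    else:
        verdict = "null"
    return {
        "threshold": threshold,
        "per_method": per_method,
        "verdict": verdict,
        "influential": list(influential),
    }


def select_instruments(
    exposure: GwasSummary, panel: LDPanel, config: RunConfig
):
    """Significance filter → LD clumping → MAF filter, with provenance."""
    instruments = filter_significant(exposure, config.p_thresh)
    instruments = clump(instruments, panel, config.clump_r2, config.clump_window_kb)
    instruments = filter_maf(
        instruments, config.maf_min, strict_missing=config.maf_strict_missing
    )
    return instruments


def _analyse_stage(
    hset: HarmonizedSet,
    step: int,
    config: RunConfig,
    seed: int,
    n_exp: int,
    n_out: int,
) -> StagedResult:
    j = len(hset)
    if j < 4:
        raise InsufficientDataError(
            f"step {step}: only {j} harmonized SNPs remain (need >= 4)"
        )
    estimates = all_estimates(
        hset,
        ivw_model=config.ivw_model,
        phi=config.mbe_phi,
        n_boot=config.n_boot,
        seed=seed,
        raps_loss=config.raps_loss,
        raps_overdispersion=config.raps_overdispersion,
    )
    het_ivw = cochran_q(hset, "ivw")
    het_egger = cochran_q(hset, "egger")
    intercept = {
        "intercept": estimates["egger"].extras["intercept"],
        "se": estimates["egger"].extras["intercept_se"],
        "pval": estimates["egger"].extras["intercept_p"],
        "pleiotropy_detected": estimates["egger"].extras["intercept_p"] < 0.05,
    }
    presso = run_presso(
        hset,
        n_sim=config.presso_n_sim,
        seed=seed + 10_000,
        outlier_alpha=config.presso_outlier_alpha,
        criterion=config.presso_outlier_criterion,
    )
    steiger = steiger_direction(hset, n_exp=n_exp, n_out=n_out)
    strength = f_statistic(steiger.r2_exp, n=n_exp, k=j)
    loo = leave_one_out(hset)
    influential = list(loo.loc[loo["influential"], "excluded_rsid"])
    conclusion = bonferroni_conclude(
        estimates,
        alpha=config.bonferroni_alpha,
        n_methods=config.n_methods,
        lead_method=config.lead_method,
        influential=influential,
    )
    return StagedResult(
        step=step,
        snps_used=hset.rsids(),
        estimates=estimates,
        het_ivw=het_ivw,
        het_egger=het_egger,
        egger_intercept=intercept,
        presso=presso,
        strength=strength,
        steiger=steiger,
        influential=influential,
        conclusion=conclusion,
    )


def run_staged(
    exposure: GwasSummary,
    outcome: GwasSummary,
    panel: LDPanel,
    config: RunConfig | None = None,
    seed: int = 0,
) -> list[StagedResult]:
    """Run the full staged analysis; returns one StagedResult per step run.

    Escalation: Step 2 when the Step-1 PRESSO global p < 0.05 and
    outliers were flagged; Step 3 when Step-2 IVW heterogeneity p < 0.05
    and the "outlier p below 1" pruning removes strictly more SNPs than
    Step 2 did.
    """
    config = config or RunConfig()
    n_exp = exposure.n_total or (
        (exposure.n_cases or 0) + (exposure.n_controls or 0)
    )
    n_out = outcome.n_total or 0
    if n_exp <= 2 or n_out <= 2:
        raise InsufficientDataError(
            "exposure and outcome summaries must carry sample sizes"
        )

    instruments = select_instruments(exposure, panel, config)
    hset = harmonize(
        instruments,
        outcome,
        palindrome_mode=config.palindrome_mode,
        eaf_window=config.eaf_window,
        panel=panel,
        proxy_r2_min=config.proxy_r2_min,
        proxy_window_kb=config.proxy_window_kb,
    )

    results: list[StagedResult] = []
    step1 = _analyse_stage(hset, 1, config, seed, n_exp, n_out)
    results.append(step1)

    if step1.presso.global_p >= config.presso_alpha:
        return results
    if not step1.presso.outliers:
        step1.notes.append(
            "PRESSO global test significant but no outlier passed the "
            "per-SNP threshold; reporting step 1 results"
        )
        logger.warning(step1.notes[-1])
        return results

    hset2 = hset.without(step1.presso.outliers)
    step2 = _analyse_stage(hset2, 2, config, seed, n_exp, n_out)
    results.append(step2)

    if step2.het_ivw.pval >= config.heterogeneity_alpha:
        return results
    below = {
        rsid
        for rsid, p in (
            step1.presso.per_snp_p_adj
            if config.presso_outlier_criterion == "adjusted"
            else step1.presso.per_snp_p
        ).items()
        if p < config.step3_p_below
    }
    if below <= step1.presso.outliers:
        step2.notes.append(
            "heterogeneity persists but the outlier-p<1 pruning removes no "
            "additional SNP; reporting step 2 results"
        )
        logger.warning(step2.notes[-1])
        return results
    hset3 = hset.without(below)
    step3 = _analyse_stage(hset3, 3, config, seed, n_exp, n_out)
    results.append(step3)
    return results


_METHOD_LABELS = {
    "ivw": "IVW", "mode_based": "MBE", "weighted_median": "WMM",
    "egger": "MR-Egger", "raps": "MR.RAPS",
}


def render_report(
    staged: list[StagedResult],
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    all_steps: bool = False,
) -> pd.DataFrame:
    """Result-table rendering with the published column families.

    One row per reported step: SNP count, then per-method beta / 95% CI /
    p, Cochran Q (df) and p for IVW and Egger, and the Egger intercept
    (SE) and p.  By default only the final step is reported; with
    ``all_steps`` every step gets a row.
    """
    if not staged:
        raise ValueError("no staged results to report")
    chosen = staged if all_steps else [staged[-1]]
    rows = []
    for st in chosen:
        row: dict = {
            "exposure": exposure_name,
            "outcome": outcome_name,
            "step": st.step,
            "n_snp": len(st.snps_used),
        }
        for method, label in _METHOD_LABELS.items():
            est = st.estimates[method]
            row[f"{label}_beta"] = est.beta
            row[f"{label}_ci_low"] = est.ci95_low
            row[f"{label}_ci_high"] = est.ci95_high
            row[f"{label}_pval"] = est.pval
        row["IVW_Q"] = st.het_ivw.q
        row["IVW_Q_df"] = st.het_ivw.df
        row["IVW_Q_pval"] = st.het_ivw.pval
        row["Egger_Q"] = st.het_egger.q
        row["Egger_Q_df"] = st.het_egger.df
        row["Egger_Q_pval"] = st.het_egger.pval
        row["Egger_intercept"] = st.egger_intercept["intercept"]
        row["Egger_intercept_se"] = st.egger_intercept["se"]
        row["Egger_intercept_pval"] = st.egger_intercept["pval"]
        row["PRESSO_global_p"] = st.presso.global_p
        row["PRESSO_distortion_p"] = st.presso.distortion_p
        row["F_stat"] = st.strength.f_stat
        row["steiger_direction"] = st.steiger.direction
        row["verdict"] = st.conclusion["verdict"]
        rows.append(row)
    return pd.DataFrame(rows)


def report_to_text(report: pd.DataFrame) -> str:
    """Deterministic tab-delimited serialization of a report table."""
    return report.to_csv(sep="\t", index=False, float_format="%.10g")
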