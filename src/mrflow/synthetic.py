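"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the data structure of an IBD→BMD style analysis:
a case-control exposure GWAS (effects in logOR, SEs from the standard
case-control frequency approximation) and a continuous outcome GWAS
(effects in g/cm^2), linked by a linear causal effect and optional
horizontal pleiotropy.  For SNP j with effect-allele frequency p_j
(q_j = 1 - p_j):

    gamma_j ~ N(0, gamma_sd^2)                     true exposure effect
    se_exp_j = sqrt(1/(2 n_cases p_j q_j) + 1/(2 n_controls p_j q_j))
    beta_exp_j ~ N(gamma_j, se_exp_j^2)            observed
    alpha_j = 0 w.p. 1 - pi_pleio, else
        N(mu_alpha + inside_corr (sd_alpha/gamma_sd) gamma_j,
          (1 - inside_corr^2) sd_alpha^2)          direct (pleiotropic) effect
    Gamma_j = beta_true * gamma_j + alpha_j        true outcome effect
    se_out_j = 1/sqrt(2 n_out p_j q_j)
    beta_out_j ~ N(Gamma_j, se_out_j^2)            observed

Planted outliers get a directional direct effect of
``outlier_scale * se_out_j``.  A :class:`TruthLedger` records every true
quantity so estimator bias, coverage and outlier-detection power can be
scored without re-deriving the truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .gwas_io import GwasSummary, VariantAssociation
from .instruments import LDPanel
from .diagnostics import snp_r2

#: Allele pairs assigned to generated SNPs (non-palindromic by default so
#: harmonization keeps every SNP; palindromic_fraction injects A/T pairs).
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))
_PALINDROMIC_PAIR = ("A", "T")

#: z threshold equivalent to two-sided P < 5e-8 (genome-wide significance)
GWS_Z = float(stats.norm.isf(2.5e-8))


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative parameterization of one synthetic two-sample dataset."""

    j_snps: int = 100
    beta_true: float = -0.02          # outcome units (g/cm^2) per logOR
    gamma_sd: float = 0.15            # SD of true instrument-exposure effects
    n_cases: int = 12_882
    n_controls: int = 21_770
    n_out: int = 20_000
    eaf_range: tuple[float, float] = (0.10, 0.90)
    pi_pleio: float = 0.0             # proportion of pleiotropic SNPs
    mu_alpha: float = 0.0             # directional pleiotropy iff != 0
    sd_alpha: float = 0.0
    inside_corr: float = 0.0          # InSIDE violated iff != 0
    n_outliers: int = 0
    outlier_scale: float = 0.0        # direct effect in units of se_out
    palindromic_fraction: float = 0.0
    truncate_significant: bool = True  # emulate post-selection instruments
    ld_blocks: tuple[int, int, float] = (100, 1, 0.0)  # (n_blocks, block_size, rho)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi_pleio <= 1.0):
            raise ConfigurationError("pi_pleio must lie in [0, 1]")
        if abs(self.inside_corr) > 1.0:
            raise ConfigurationError("inside_corr must lie in [-1, 1]")
        if min(self.j_snps, self.n_cases, self.n_controls, self.n_out) <= 0:
            raise ConfigurationError("all sizes must be positive")
        if self.gamma_sd == 0 and self.beta_true != 0:
            raise ConfigurationError(
                "gamma_sd = 0 with beta_true != 0: causal effect unidentifiable"
            )
        if not (0 < self.eaf_range[0] <= self.eaf_range[1] < 1):
            raise ConfigurationError("eaf_range must satisfy 0 < lo <= hi < 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["eaf_range"] = list(self.eaf_range)
        d["ld_blocks"] = list(self.ld_blocks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
        if "eaf_range" in d:
            d["eaf_range"] = tuple(d["eaf_range"])
        if "ld_blocks" in d:
            d["ld_blocks"] = tuple(d["ld_blocks"])
        return cls(**d)


@dataclass
class TruthLedger:
    """Per-SNP and global ground truth of one simulated dataset."""

    per_snp: pd.DataFrame  # rsid, gamma, alpha, pleiotropic, outlier
    beta_true: float
    realized_inside_corr: float
    r2_total: float
    config: SimulationConfig = field(compare=False, default=None)


def _variant_layout(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic rsid/chrom/pos layout shared by summaries and LD panel.

    Variants are grouped into LD blocks; within a block positions are
    5 kb apart (inside any clumping window), blocks sit 50 Mb apart or on
    the next chromosome (outside a 10,000 kb window).
    """
    n_blocks, block_size, _ = config.ld_blocks
    rows = []
    idx = 0
    for b in range(n_blocks):
        chrom = str(b % 22 + 1)
        block_start = 1_000_000 + (b // 22) * 50_000_000
        for k in range(block_size):
            rows.append(
                {
                    "rsid": f"rs{idx + 1:06d}", "chrom": chrom,
                    "pos": block_start + k * 5_000, "block": b,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def simulate_ld_panel(config: SimulationConfig) -> LDPanel:
    """Block-diagonal LD panel: within-block r^2(i,j) = rho^(2|i-j|)."""
    layout = _variant_layout(config)
    _, block_size, rho = config.ld_blocks
    pairs: dict[tuple[str, str], float] = {}
    if rho > 0 and block_size > 1:
        for _, grp in layout.groupby("block"):
            rsids = list(grp["rsid"])
            for i in range(len(rsids)):
                for j in range(i + 1, len(rsids)):
                    pairs[(rsids[i], rsids[j])] = rho ** (2 * (j - i))
    return LDPanel(layout[["rsid", "chrom", "pos"]], pairs)


def simulate_two_sample(
    config: SimulationConfig,
) -> tuple[GwasSummary, GwasSummary, TruthLedger]:
    """Generate exposure and outcome summaries plus their truth ledger.

    Deterministic under ``config.seed``; independent sub-streams are
    spawned per component so partial re-runs stay reproducible.
    """
    j = config.j_snps
    ss = np.random.SeedSequence(config.seed)
    rng_eaf, rng_exp, rng_pleio, rng_out, rng_misc = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    layout = _variant_layout(config)
    if len(layout) < j:
        raise ConfigurationError(
            f"ld_blocks layout provides {len(layout)} variants < j_snps = {j}"
        )
    layout = layout.iloc[:j]

    eaf = rng_eaf.uniform(*config.eaf_range, size=j)
    pq = eaf * (1.0 - eaf)
    se_exp = np.sqrt(1.0 / (2 * config.n_cases * pq) + 1.0 / (2 * config.n_controls * pq))
    se_out = 1.0 / np.sqrt(2 * config.n_out * pq)

    gamma = rng_exp.normal(0.0, config.gamma_sd, size=j)
    beta_exp = rng_exp.normal(gamma, se_exp)
    if config.truncate_significant:
        # redraw until every observed exposure beta clears genome-wide
        # significance, emulating the post-selection instrument lists the
        # pipeline actually consumes
        for _ in range(10_000):
            weak = np.abs(beta_exp) / se_exp < GWS_Z
            if not weak.any():
                break
            gamma[weak] = rng_exp.normal(0.0, config.gamma_sd, size=int(weak.sum()))
            beta_exp[weak] = rng_exp.normal(gamma[weak], se_exp[weak])
        else:
            raise ConfigurationError(
                "significance truncation did not converge; gamma_sd too small "
                "relative to the exposure SEs"
            )

    pleio = rng_pleio.random(j) < config.pi_pleio
    alpha = np.zeros(j)
    if pleio.any() and (config.sd_alpha > 0 or config.mu_alpha != 0):
        rho = config.inside_corr
        slope = rho * (config.sd_alpha / config.gamma_sd) if config.gamma_sd > 0 else 0.0
        mean = config.mu_alpha + slope * gamma[pleio]
        sd = np.sqrt(max(0.0, 1.0 - rho**2)) * config.sd_alpha
        alpha[pleio] = rng_pleio.normal(mean, sd)

    outlier = np.zeros(j, dtype=bool)
    if config.n_outliers > 0:
        chosen = rng_misc.choice(j, size=min(config.n_outliers, j), replace=False)
        outlier[chosen] = True
        # direct effect aligned with the instrument's sign, so every planted
        # outlier displaces its Wald ratio in the same (positive) direction
        # and the set genuinely distorts the pooled causal estimate
        alpha[chosen] = config.outlier_scale * se_out[chosen] * np.sign(gamma[chosen])

    big_gamma = config.beta_true * gamma + alpha
    beta_out = rng_out.normal(big_gamma, se_out)

    p_exp = 2 * stats.norm.sf(np.abs(beta_exp) / se_exp)
    p_out = 2 * stats.norm.sf(np.abs(beta_out) / se_out)
    np.clip(p_exp, 5e-324, 1.0, out=p_exp)
    np.clip(p_out, 5e-324, 1.0, out=p_out)

    n_pal = int(round(config.palindromic_fraction * j))
    pal_idx = set(rng_misc.choice(j, size=n_pal, replace=False)) if n_pal else set()

    n_exp_total = config.n_cases + config.n_controls
    exposure = GwasSummary(
        trait_name="synthetic_exposure", unit="logOR",
        n_total=n_exp_total, n_cases=config.n_cases, n_controls=config.n_controls,
    )
    outcome = GwasSummary(
        trait_name="synthetic_outcome", unit="g/cm²", n_total=config.n_out
    )
    for i, row in enumerate(layout.itertuples(index=False)):
        ea, oa = (
            _PALINDROMIC_PAIR if i in pal_idx else _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        )
        common = dict(rsid=row.rsid, chrom=row.chrom, pos=int(row.pos),
                      effect_allele=ea, other_allele=oa, eaf=float(eaf[i]))
        exposure.add(
            VariantAssociation(
                beta=float(beta_exp[i]), se=float(se_exp[i]), pval=float(p_exp[i]),
                n=n_exp_total, **common,
            )
        )
        outcome.add(
            VariantAssociation(
                beta=float(beta_out[i]), se=float(se_out[i]), pval=float(p_out[i]),
                n=config.n_out, **common,
            )
        )

    if pleio.sum() >= 2 and np.std(alpha[pleio]) > 0 and np.std(gamma[pleio]) > 0:
        realized_corr = float(np.corrcoef(gamma[pleio], alpha[pleio])[0, 1])
    else:
        realized_corr = 0.0
    ledger = TruthLedger(
        per_snp=pd.DataFrame(
            {
                "rsid": layout["rsid"].to_numpy(), "gamma": gamma, "alpha": alpha,
                "pleiotropic": pleio, "outlier": outlier,
            }
        ),
        beta_true=config.beta_true,
        realized_inside_corr=realized_corr,
        r2_total=float(snp_r2(beta_exp, se_exp, n_exp_total).sum()),
        config=config,
    )
    return exposure, outcome, ledger


def random_harmonized_set(rng: np.random.Generator, j: int):
    """A random, well-conditioned harmonized set (for oracle cross-checks)."""
    from .harmonize import HarmonizedRecord, HarmonizedSet

    x = rng.uniform(0.05, 0.5, j) * rng.choice([-1.0, 1.0], j)
    sx = rng.uniform(0.005, 0.05, j)
    y = rng.normal(0.3 * x, 0.05)
    sy = rng.uniform(0.005, 0.05, j)
    recs = [
        HarmonizedRecord(
            rsid=f"rs{i + 1:04d}", effect_allele="A", other_allele="G",
            beta_exp=float(x[i]), se_exp=float(sx[i]),
            beta_out=float(y[i]), se_out=float(sy[i]),
        )
        for i in range(j)
    ]
    return HarmonizedSet(recs)


def scenario_presets() -> dict[str, SimulationConfig]:
    """Named generator configurations for the study's qualitative regimes.

    Scales are anchored on the IBD→BMD setting: a case-control exposure
    of ~13k cases / 22k controls, ~100 independent instruments, causal
    effects around -0.02 g/cm^2 per logOR.
    """
    base = SimulationConfig()
    return {
        "null": replace(base, beta_true=0.0, pi_pleio=0.0),
        "balanced_pleiotropy": replace(
            base, beta_true=0.0, pi_pleio=0.3, mu_alpha=0.0, sd_alpha=0.004
        ),
        "directional_inside": replace(
            base, beta_true=0.0, pi_pleio=0.3, mu_alpha=0.004, sd_alpha=0.002
        ),
        "inside_violated": replace(
            base, beta_true=0.0, pi_pleio=0.3, mu_alpha=0.004, sd_alpha=0.002,
            inside_corr=0.6,
        ),
        "outliers_planted": replace(
            base, beta_true=-0.02, n_outliers=5, outlier_scale=10.0
        ),
        "ibd_bmd_like": replace(
            base, beta_true=-0.02, j_snps=100, pi_pleio=0.3, mu_alpha=0.0,
            sd_alpha=0.002,
        ),
    }
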