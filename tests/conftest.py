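"""Shared fixtures: toy variant records, harmonized sets, and LD panels."""

from __future__ import annotations

import numpy as np
import pytest

from mrflow import (
    GwasSummary,
    HarmonizedRecord,
    HarmonizedSet,
    LDPanel,
    VariantAssociation,
)
import pandas as pd


def make_variant(rsid="rs1", chrom="1", pos=1000, ea="A", oa="G",
                 beta=0.1, se=0.02, pval=1e-9, eaf=0.3, n=10_000) -> VariantAssociation:
    return VariantAssociation(
        rsid=rsid, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        beta=beta, se=se, pval=pval, eaf=eaf, n=n,
    )


def make_summary(records, trait="trait", unit="logOR", **meta) -> GwasSummary:
    s = GwasSummary(trait_name=trait, unit=unit, **meta)
    for r in records:
        s.add(r)
    return s


def make_hrec(rsid, beta_exp, se_exp, beta_out, se_out, **kw) -> HarmonizedRecord:
    return HarmonizedRecord(
        rsid=rsid, effect_allele="A", other_allele="G",
        beta_exp=beta_exp, se_exp=se_exp, beta_out=beta_out, se_out=se_out, **kw
    )


def make_hset(beta_exp, se_exp, beta_out, se_out) -> HarmonizedSet:
    recs = [
        make_hrec(f"rs{i + 1:04d}", float(x), float(sx), float(y), float(sy))
        for i, (x, sx, y, sy) in enumerate(zip(beta_exp, se_exp, beta_out, se_out))
    ]
    return HarmonizedSet(recs)


def random_hset(rng: np.random.Generator, j: int) -> HarmonizedSet:
    """A random, well-conditioned harmonized set for oracle comparisons."""
    x = rng.uniform(0.05, 0.5, j) * rng.choice([-1.0, 1.0], j)
    sx = rng.uniform(0.005, 0.05, j)
    y = rng.normal(0.3 * x, 0.05)
    sy = rng.uniform(0.005, 0.05, j)
    return make_hset(x, sx, y, sy)


def make_panel(rows, r2_pairs=None) -> LDPanel:
    """rows: iterable of (rsid, chrom, pos); r2_pairs: {(a, b): r2}."""
    df = pd.DataFrame(rows, columns=["rsid", "chrom", "pos"])
    return LDPanel(df, r2_pairs or {})


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_hset(rng):
    return random_hset(rng, 8)
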