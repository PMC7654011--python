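"""Align exposure and outcome effects to a common effect allele.

For each instrument the outcome association is looked up (optionally via
an LD proxy), the two allele pairs are classified (same / swapped /
strand complement / complement+swapped / palindromic / incompatible),
and the outcome effect is re-expressed on the exposure's effect allele.
Palindromic SNPs (A/T or G/C), whose strand cannot be resolved from
allele labels, are either dropped outright or kept when both
effect-allele frequencies fall clearly on one side of 0.5 so the strand
can be inferred from frequency concordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .gwas_io import GwasSummary, VariantAssociation
from .instruments import (
    DEFAULT_PROXY_R2,
    DEFAULT_PROXY_WINDOW_KB,
    InstrumentSet,
    LDPanel,
    find_proxy,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))

DEFAULT_EAF_WINDOW = 0.08


def _is_palindromic(a: str, b: str) -> bool:
    return frozenset((a, b)) in _PALINDROMIC_PAIRS


def classify_alleles(exp: VariantAssociation, out: VariantAssociation) -> str:
    """Classify the outcome's allele pair relative to the exposure's.

    Returns one of ``same``, ``swapped``, ``strand_complement``,
    ``strand_complement_swapped``, ``palindromic``, ``incompatible``.
    A palindromic pair (A/T or G/C) on either record dominates, because
    for such SNPs identity and complement are indistinguishable.
    """
    e1, e2 = exp.effect_allele, exp.other_allele
    o1, o2 = out.effect_allele, out.other_allele
    if _is_palindromic(e1, e2) or _is_palindromic(o1, o2):
        return "palindromic" if {o1, o2} in ({e1, e2}, {_COMPLEMENT[e1], _COMPLEMENT[e2]}) else "incompatible"
    if (o1, o2) == (e1, e2):
        return "same"
    if (o1, o2) == (e2, e1):
        return "swapped"
    c1, c2 = _COMPLEMENT[e1], _COMPLEMENT[e2]
    if (o1, o2) == (c1, c2):
        return "strand_complement"
    if (o1, o2) == (c2, c1):
        return "strand_complement_swapped"
    return "incompatible"


@dataclass(frozen=True)
class HarmonizedRecord:
    """Exposure/outcome effects of one SNP on a common effect allele."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None
    action: str = "aligned"
    proxy_used: bool = False
    proxy_rsid: str | None = None

    def __post_init__(self) -> None:
        if not (self.se_exp > 0 and self.se_out > 0):
            raise ValueError(f"{self.rsid}: harmonized SEs must be positive")


@dataclass
class HarmonizedSet:
    """Retained harmonized records plus the dropped SNPs with reasons."""

    retained: list[HarmonizedRecord]
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (rsid, reason)
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.retained)

    def rsids(self) -> list[str]:
        return [r.rsid for r in self.retained]

    def subset(self, keep: set[str] | list[str]) -> "HarmonizedSet":
        keep = set(keep)
        kept = [r for r in self.retained if r.rsid in keep]
        return HarmonizedSet(kept, list(self.dropped), dict(self.counts))

    def without(self, drop: set[str] | list[str]) -> "HarmonizedSet":
        drop = set(drop)
        return self.subset([r.rsid for r in self.retained if r.rsid not in drop])

    def audit_table(self) -> pd.DataFrame:
        """One row per input SNP with its harmonization action."""
        rows = [
            {
                "rsid": r.rsid, "action": r.action,
                "effect_allele": r.effect_allele, "other_allele": r.other_allele,
                "beta_exp": r.beta_exp, "se_exp": r.se_exp,
                "beta_out": r.beta_out, "se_out": r.se_out,
                "eaf_exp": r.eaf_exp, "eaf_out": r.eaf_out,
                "proxy_used": r.proxy_used, "proxy_rsid": r.proxy_rsid or "",
            }
            for r in self.retained
        ]
        rows += [
            {"rsid": rsid, "action": reason} for rsid, reason in self.dropped
        ]
        return pd.DataFrame(rows)


def _bump(counts: dict[str, int], key: str) -> None:
    counts[key] = counts.get(key, 0) + 1


def harmonize(
    exposure: InstrumentSet,
    outcome: GwasSummary,
    palindrome_mode: str = "infer",
    eaf_window: float = DEFAULT_EAF_WINDOW,
    *,
    panel: LDPanel | None = None,
    proxy_r2_min: float = DEFAULT_PROXY_R2,
    proxy_window_kb: float = DEFAULT_PROXY_WINDOW_KB,
) -> HarmonizedSet:
    """Pair every instrument with its outcome effect on a common allele.

    Parameters
    ----------
    palindrome_mode
        ``"drop"`` removes every palindromic SNP; ``"infer"`` (default)
        keeps a palindromic SNP only when both EAFs are present and both
        lie outside ``[0.5 - eaf_window, 0.5 + eaf_window]``, aligning by
        frequency concordance (discordant sides imply the outcome effect
        refers to the opposite allele and its sign is flipped).
    panel
        Optional LD panel enabling proxy lookup for instruments missing
        from the outcome; without it such SNPs are dropped as missing.
    """
    if palindrome_mode not in ("infer", "drop"):
        raise ValueError(f"unknown palindrome_mode {palindrome_mode!r}")

    retained: list[HarmonizedRecord] = []
    dropped: list[tuple[str, str]] = []
    counts: dict[str, int] = {}

    for exp in exposure.records:
        proxy_used = False
        proxy_rsid = None
        if exp.rsid in outcome:
            out = outcome[exp.rsid]
        else:
            out = None
            if panel is not None and exp.rsid in panel:
                out = find_proxy(exp.rsid, outcome, panel, proxy_r2_min, proxy_window_kb)
            if out is None:
                dropped.append((exp.rsid, "dropped_missing"))
                _bump(counts, "dropped_missing")
                continue
            proxy_used = True
            proxy_rsid = out.rsid

        kind = classify_alleles(exp, out)
        if kind == "incompatible":
            dropped.append((exp.rsid, "dropped_incompatible"))
            _bump(counts, "dropped_incompatible")
            continue

        if kind == "palindromic":
            if palindrome_mode == "drop":
                dropped.append((exp.rsid, "dropped_palindromic"))
                _bump(counts, "dropped_palindromic")
                continue
            rec = _infer_palindrome(exp, out, eaf_window, proxy_used, proxy_rsid)
            if rec is None:
                dropped.append((exp.rsid, "dropped_palindromic"))
                _bump(counts, "dropped_palindromic")
                continue
            retained.append(rec)
            _bump(counts, rec.action)
            continue

        if kind in ("swapped", "strand_complement_swapped"):
            out = out.flipped()
            action = "sign_flipped"
        elif kind == "strand_complement":
            action = "strand_flipped"
        else:
            action = "aligned"

        retained.append(
            HarmonizedRecord(
                rsid=exp.rsid,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
                beta_exp=exp.beta, se_exp=exp.se,
                beta_out=out.beta, se_out=out.se,
                eaf_exp=exp.eaf, eaf_out=out.eaf,
                action=action, proxy_used=proxy_used, proxy_rsid=proxy_rsid,
            )
        )
        _bump(counts, action)

    counts["retained"] = len(retained)
    counts["input"] = len(exposure)
    logger.info("harmonization: %s", {k: v for k, v in sorted(counts.items())})
    return HarmonizedSet(retained, dropped, counts)


def _infer_palindrome(
    exp: VariantAssociation,
    out: VariantAssociation,
    eaf_window: float,
    proxy_used: bool,
    proxy_rsid: str | None,
) -> HarmonizedRecord | None:
    """Frequency-concordance alignment of a palindromic SNP; None → drop."""
    if exp.eaf is None or out.eaf is None:
        return None
    lo, hi = 0.5 - eaf_window, 0.5 + eaf_window
    if lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
        return None
    # express the outcome effect on the exposure's nominal effect allele
    if out.effect_allele == exp.effect_allele:
        beta_out, eaf_out, flipped = out.beta, out.eaf, False
    else:
        beta_out, eaf_out, flipped = -out.beta, 1.0 - out.eaf, True
    # discordant frequency sides: the outcome's labels sit on the other
    # strand, so the aligned-looking pairing is actually the opposite allele
    if (exp.eaf < 0.5) != (eaf_out < 0.5):
        beta_out, eaf_out, flipped = -beta_out, 1.0 - eaf_out, not flipped
    return HarmonizedRecord(
        rsid=exp.rsid,
        effect_allele=exp.effect_allele,
        other_allele=exp.other_allele,
        beta_exp=exp.beta, se_exp=exp.se,
        beta_out=beta_out, se_out=out.se,
        eaf_exp=exp.eaf, eaf_out=eaf_out,
        action="sign_flipped" if flipped else "aligned",
        proxy_used=proxy_used, proxy_rsid=proxy_rsid,
    )
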