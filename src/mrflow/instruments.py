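"""Instrument selection: significance filter, LD clumping, MAF filter, proxies.

The selection pipeline mirrors standard two-sample MR practice on
case-control exposure GWAS: keep genome-wide significant SNPs
(P < 5e-8), prune them to LD independence by greedy clumping against a
reference panel (r^2 < 0.001 within a 10,000 kb window, keeping the
lowest-P SNP of each clump), and drop rare variants (MAF < 0.01).
Every removal is counted in an :class:`InstrumentSet` provenance ledger
so that the SNP accounting of a run can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError, PanelLookupError
from .gwas_io import GwasSummary, VariantAssociation

logger = logging.getLogger(__name__)

DEFAULT_P_THRESH = 5e-8
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_WINDOW_KB = 10_000.0
DEFAULT_MAF_MIN = 0.01
DEFAULT_PROXY_R2 = 0.8
DEFAULT_PROXY_WINDOW_KB = 250.0


class LDPanel:
    """Pairwise r^2 between variants of a reference panel.

    Emulates an LD lookup against external reference genotypes (e.g.
    European 1000 Genomes samples): a variant table (rsid, chrom, pos)
    plus a sparse symmetric r^2 accessor.  Pairs not stored are taken as
    r^2 = 0; ``r2(a, a) = 1`` always.
    """

    def __init__(self, variants: pd.DataFrame, r2_pairs: dict[tuple[str, str], float]):
        variants = variants.reset_index(drop=True)
        if variants["rsid"].duplicated().any():
            raise DataError("LD panel variant table contains duplicate rsids")
        self.variants = variants
        self._pos = {
            r.rsid: (str(r.chrom), int(r.pos)) for r in variants.itertuples(index=False)
        }
        self._r2: dict[tuple[str, str], float] = {}
        for (a, b), v in r2_pairs.items():
            if not (0.0 <= v <= 1.0):
                raise DataError(f"r2({a},{b}) = {v} outside [0, 1]")
            self._r2[self._key(a, b)] = float(v)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._pos

    def __len__(self) -> int:
        return len(self._pos)

    def location(self, rsid: str) -> tuple[str, int]:
        try:
            return self._pos[rsid]
        except KeyError:
            raise PanelLookupError(f"variant {rsid!r} absent from LD panel") from None

    def r2(self, a: str, b: str) -> float:
        if a not in self._pos or b not in self._pos:
            raise PanelLookupError(f"variant pair ({a!r}, {b!r}) not fully in panel")
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    # -- on-disk long format: variant table + `rsid_a rsid_b r2` pair table --

    @classmethod
    def read(cls, variants_path, pairs_path) -> "LDPanel":
        variants = pd.read_csv(variants_path, sep="\t", dtype={"rsid": str, "chrom": str})
        pairs = pd.read_csv(pairs_path, sep="\t", dtype={"rsid_a": str, "rsid_b": str})
        r2_pairs = {
            (r.rsid_a, r.rsid_b): float(r.r2) for r in pairs.itertuples(index=False)
        }
        return cls(variants[["rsid", "chrom", "pos"]], r2_pairs)

    def write(self, variants_path, pairs_path) -> None:
        self.variants.to_csv(variants_path, sep="\t", index=False)
        rows = [
            {"rsid_a": a, "rsid_b": b, "r2": v}
            for (a, b), v in sorted(self._r2.items())
        ]
        pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2"]).to_csv(
            pairs_path, sep="\t", index=False
        )


@dataclass
class InstrumentSet:
    """Ordered instrument candidates with per-filter removal provenance."""

    records: list[VariantAssociation]
    provenance: dict[str, int] = field(default_factory=dict)
    flags: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def _child(self, kept: list[VariantAssociation], removed_key: str, n_removed: int,
               **extra_flags) -> "InstrumentSet":
        prov = dict(self.provenance)
        prov[removed_key] = prov.get(removed_key, 0) + n_removed
        flags = {k: list(v) for k, v in self.flags.items()}
        for k, v in extra_flags.items():
            flags.setdefault(k, []).extend(v)
        return InstrumentSet(kept, prov, flags)


def filter_significant(
    summary: GwasSummary, p_thresh: float = DEFAULT_P_THRESH
) -> InstrumentSet:
    """Keep SNPs with ``pval < p_thresh`` (strict), counting removals."""
    if not (0.0 < p_thresh < 1.0):
        raise DataError(f"p_thresh must lie in (0, 1), got {p_thresh}")
    kept = [r for r in summary.records.values() if r.pval < p_thresh]
    n_removed = len(summary) - len(kept)
    logger.info("significance filter (P < %g): kept %d / %d", p_thresh, len(kept), len(summary))
    return InstrumentSet(kept, {"input": len(summary), "not_significant": n_removed})


def filter_maf(
    instruments: InstrumentSet,
    maf_min: float = DEFAULT_MAF_MIN,
    *,
    strict_missing: bool = False,
) -> InstrumentSet:
    """Remove SNPs with minor-allele frequency strictly below ``maf_min``.

    MAF is ``min(eaf, 1 - eaf)``.  SNPs with missing EAF are retained and
    flagged by default; with ``strict_missing=True`` they are removed.
    """
    if not (0.0 <= maf_min < 0.5):
        raise DataError(f"maf_min must lie in [0, 0.5), got {maf_min}")
    kept: list[VariantAssociation] = []
    missing_flagged: list[str] = []
    for r in instruments.records:
        maf = r.maf
        if maf is None:
            if strict_missing:
                continue
            missing_flagged.append(r.rsid)
            kept.append(r)
        elif maf >= maf_min:
            kept.append(r)
    return instruments._child(
        kept, "low_maf", len(instruments) - len(kept), maf_missing=missing_flagged
    )


def clump(
    instruments: InstrumentSet,
    panel: LDPanel,
    r2_thresh: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_CLUMP_WINDOW_KB,
) -> InstrumentSet:
    """Greedy LD clumping: keep the lowest-P SNP of each LD neighbourhood.

    SNPs absent from the panel are removed first.  The survivors are
    sorted by ascending p-value (ties broken lexicographically by rsid);
    repeatedly the best unclaimed SNP becomes an index and every other
    unclaimed SNP on the same chromosome within ``window_kb`` whose r^2
    with the index exceeds ``r2_thresh`` is discarded.  The result is
    pairwise independent under (r2_thresh, window_kb) and invariant to
    input row order.
    """
    if not (0.0 < r2_thresh <= 1.0):
        raise DataError(f"r2_thresh must lie in (0, 1], got {r2_thresh}")
    if not window_kb > 0:
        raise DataError(f"window_kb must be positive, got {window_kb}")

    in_panel = [r for r in instruments.records if r.rsid in panel]
    n_absent = len(instruments) - len(in_panel)

    window_bp = window_kb * 1000.0
    ordered = sorted(in_panel, key=lambda r: (r.pval, r.rsid))
    kept: list[VariantAssociation] = []
    claimed: set[str] = set()
    for idx in ordered:
        if idx.rsid in claimed:
            continue
        kept.append(idx)
        claimed.add(idx.rsid)
        chrom_i, pos_i = panel.location(idx.rsid)
        for other in ordered:
            if other.rsid in claimed:
                continue
            chrom_j, pos_j = panel.location(other.rsid)
            if chrom_j != chrom_i or abs(pos_j - pos_i) > window_bp:
                continue
            if panel.r2(idx.rsid, other.rsid) > r2_thresh:
                claimed.add(other.rsid)

    child = instruments._child(kept, "absent_from_panel", n_absent)
    child.provenance["clumped_away"] = len(in_panel) - len(kept)
    logger.info(
        "clumping (r2 < %g, %g kb): %d absent from panel, %d clumped away, %d kept",
        r2_thresh, window_kb, n_absent, len(in_panel) - len(kept), len(kept),
    )
    return child


def find_proxy(
    target: str,
    outcome: GwasSummary,
    panel: LDPanel,
    r2_min: float = DEFAULT_PROXY_R2,
    window_kb: float = DEFAULT_PROXY_WINDOW_KB,
) -> VariantAssociation | None:
    """Best LD proxy for ``target`` among outcome SNPs, or None.

    Candidates are outcome SNPs present in the panel, on the target's
    chromosome within ``window_kb``, with panel r^2 >= ``r2_min``; the
    one with maximal r^2 wins (ties broken lexicographically by rsid).
    If the target itself is in the outcome it is its own proxy (r^2 = 1).
    """
    chrom_t, pos_t = panel.location(target)  # raises if target absent
    window_bp = window_kb * 1000.0
    best: tuple[float, str] | None = None
    for rsid, rec in outcome.records.items():
        if rsid not in panel:
            continue
        chrom_c, pos_c = panel.location(rsid)
        if chrom_c != chrom_t or abs(pos_c - pos_t) > window_bp:
            continue
        r2 = panel.r2(target, rsid)
        if r2 < r2_min:
            continue
        # maximise r2; break ties toward the lexicographically smaller rsid
        if best is None or (r2 > best[0]) or (r2 == best[0] and rsid < best[1]):
            best = (r2, rsid)
    if best is None:
        return None
    return outcome[best[1]]
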