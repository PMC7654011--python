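"""Reading, validating and writing GWAS summary-statistics tables.

The canonical on-disk dialect is tab-delimited with header
``rsid chrom pos effect_allele other_allele eaf beta se pval n``,
missing values as empty strings — the flat shape in which consortia
distribute their summary statistics.  All file-format handling for
association tables lives here; the rest of the package works with
:class:`VariantAssociation` / :class:`GwasSummary` objects.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: Canonical column order of the on-disk table.
CANONICAL_COLUMNS = (
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
)

_VALID_ALLELES = frozenset("ACGT")

#: Smallest positive double; p-values of exactly 0 are clamped here.
TINY_P = sys.float_info.min


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the additive effect per copy of ``effect_allele`` in the
    trait's unit (logOR for case-control traits, g/cm^2 or SD for
    continuous ones); ``eaf`` is the effect-allele frequency.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        object.__setattr__(self, "other_allele", self.other_allele.upper())
        if self.effect_allele not in _VALID_ALLELES or self.other_allele not in _VALID_ALLELES:
            raise DataError(
                f"{self.rsid}: alleles must be single bases in A/C/G/T "
                f"(got {self.effect_allele!r}/{self.other_allele!r}); indels are not supported"
            )
        if self.effect_allele == self.other_allele:
            raise DataError(f"{self.rsid}: effect and other allele are identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise DataError(f"{self.rsid}: standard error must be positive (got {self.se})")
        if not math.isfinite(self.beta):
            raise DataError(f"{self.rsid}: beta must be finite")
        if not (0 < self.pval <= 1):
            raise DataError(f"{self.rsid}: p-value must lie in (0, 1] (got {self.pval})")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise DataError(f"{self.rsid}: EAF must lie in [0, 1] (got {self.eaf})")

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)``; None if EAF missing."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.effect_allele, self.other_allele))

    def flipped(self) -> "VariantAssociation":
        """The same association expressed on the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass
class GwasSummary:
    """A full summary-statistics table for one trait, keyed by rsid."""

    trait_name: str
    unit: str = "SD"  # logOR for binary traits, g/cm^2 or SD for continuous
    n_total: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    ancestry: str = "European"
    records: dict[str, VariantAssociation] = field(default_factory=dict)

    def add(self, rec: VariantAssociation) -> None:
        if rec.rsid in self.records:
            raise DataError(f"duplicate rsid {rec.rsid!r} in {self.trait_name}")
        self.records[rec.rsid] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.records

    def __getitem__(self, rsid: str) -> VariantAssociation:
        return self.records[rsid]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rsid": r.rsid, "chrom": r.chrom, "pos": r.pos,
                "effect_allele": r.effect_allele, "other_allele": r.other_allele,
                "eaf": r.eaf, "beta": r.beta, "se": r.se, "pval": r.pval, "n": r.n,
            }
            for r in self.records.values()
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def read_gwas_table(
    path,
    column_map: dict[str, str] | None = None,
    *,
    trait_name: str = "trait",
    unit: str = "SD",
    delimiter: str = "\t",
    **meta,
) -> GwasSummary:
    """Read a summary-statistics table into a validated :class:`GwasSummary`.

    Parameters
    ----------
    path
        Tab-delimited file with a header row.
    column_map
        Mapping from canonical field name (see :data:`CANONICAL_COLUMNS`)
        to the source column name; fields left unmapped use the canonical
        name itself.  ``eaf`` and ``n`` may be absent from the source.

    Rows violating record invariants are rejected and logged with their
    1-based data row number; a duplicate rsid raises :class:`DataError`.
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)

    def src(canon: str) -> str:
        return column_map.get(canon, canon)

    required = ["rsid", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pval"]
    for canon in required:
        if src(canon) not in df.columns:
            raise ConfigurationError(
                f"{path}: mapped column {src(canon)!r} (for field {canon!r}) not in header"
            )
    has_eaf = src("eaf") in df.columns
    has_n = src("n") in df.columns

    summary = GwasSummary(trait_name=trait_name, unit=unit, **meta)
    n_rejected = 0
    n_clamped = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        try:
            pval = float(row[src("pval")])
            if pval == 0.0:
                pval = TINY_P
                n_clamped += 1
            eaf_raw = row[src("eaf")] if has_eaf else ""
            n_raw = row[src("n")] if has_n else ""
            rec = VariantAssociation(
                rsid=row[src("rsid")],
                chrom=str(row[src("chrom")]),
                pos=int(float(row[src("pos")])),
                effect_allele=row[src("effect_allele")],
                other_allele=row[src("other_allele")],
                eaf=None if eaf_raw == "" else float(eaf_raw),
                beta=float(row[src("beta")]),
                se=float(row[src("se")]),
                pval=pval,
                n=None if n_raw == "" else int(float(n_raw)),
            )
        except DataError as exc:
            n_rejected += 1
            logger.warning("%s: row %d rejected: %s", path, i, exc)
            continue
        except ValueError as exc:
            n_rejected += 1
            logger.warning("%s: row %d rejected (unparseable field): %s", path, i, exc)
            continue
        summary.add(rec)  # duplicate rsid propagates as DataError
    if n_clamped:
        logger.warning("%s: %d zero p-values clamped to %.3g", path, n_clamped, TINY_P)
    if n_rejected:
        logger.info("%s: %d of %d rows rejected", path, n_rejected, len(df))
    return summary


def write_gwas_table(summary: GwasSummary, path) -> None:
    """Write ``summary`` in the canonical tab-delimited dialect.

    Numeric fields use ``repr`` round-trip precision so that
    ``read_gwas_table(write_gwas_table(s))`` is field-identical to ``s``.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for r in summary.records.values():
            fh.write(
                "\t".join(
                    (
                        r.rsid, r.chrom, str(r.pos), r.effect_allele, r.other_allele,
                        "" if r.eaf is None else repr(float(r.eaf)),
                        repr(float(r.beta)), repr(float(r.se)), repr(float(r.pval)),
                        "" if r.n is None else str(int(r.n)),
                    )
                )
                + "\n"
            )
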