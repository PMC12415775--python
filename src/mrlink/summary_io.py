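"""Data model and I/O for GWAS summary-statistic tables.

A summary-statistic table holds one row per single-nucleotide polymorphism
(SNP): the per-effect-allele association estimate (log-odds for binary
traits), its standard error, p-value and, when available, the effect-allele
frequency and sample size.  Files are plain tab-separated text with a header;
column names can be remapped so that catalogs with arbitrary headers
(microbiome taxa, metabolites, immune traits, disease endpoints) all load
into the same in-memory representation.

Positions are 1-based.  Only biallelic SNPs with single-character A/C/G/T
alleles are retained; indels and multi-allelic rows are dropped and counted.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order used by :func:`write_summary_stats`.
CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "BETA", "SE", "P", "EAF", "N"]

#: Columns that must be present (directly or via ``column_map``).
MANDATORY_COLUMNS = ["SNP", "EA", "OA", "BETA", "SE", "P"]

VALID_ALLELES = frozenset("ACGT")

#: Smallest positive double; p-values of exactly 0 are clamped here so that
#: downstream -log10 transforms stay finite.
MIN_PVAL = float(np.nextafter(0.0, 1.0))

TRAIT_TYPES = ("continuous", "binary")


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP-trait association record."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: Optional[str] = None
    pos: Optional[int] = None
    eaf: Optional[float] = None
    n: Optional[int] = None

    def issues(self) -> list[str]:
        """Return human-readable invariant violations (empty when valid)."""
        out = []
        if self.effect_allele not in VALID_ALLELES:
            out.append(f"{self.snp_id}: effect allele {self.effect_allele!r} not in A/C/G/T")
        if self.other_allele not in VALID_ALLELES:
            out.append(f"{self.snp_id}: other allele {self.other_allele!r} not in A/C/G/T")
        if self.effect_allele == self.other_allele:
            out.append(f"{self.snp_id}: effect and other allele identical")
        if not np.isfinite(self.beta):
            out.append(f"{self.snp_id}: beta not finite")
        if not (np.isfinite(self.se) and self.se > 0):
            out.append(f"{self.snp_id}: se not positive")
        if not (np.isfinite(self.pval) and 0 < self.pval <= 1):
            out.append(f"{self.snp_id}: pval out of range (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            out.append(f"{self.snp_id}: eaf out of range (0, 1)")
        if self.n is not None and self.n <= 0:
            out.append(f"{self.snp_id}: n not positive")
        return out


@dataclass
class ParseReport:
    """Row accounting from :func:`read_summary_stats`."""

    n_rows: int = 0
    n_kept: int = 0
    dropped: Counter = field(default_factory=Counter)
    n_pval_clamped: int = 0
    n_eaf_cleared: int = 0

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


class SummaryStatsTable:
    """An ordered collection of SNP-trait associations for one trait.

    Parameters
    ----------
    trait_id:
        Identifier of the trait (taxon, metabolite, immune trait, disease).
    trait_type:
        ``"continuous"`` or ``"binary"``; binary-trait betas are log-odds.
    df:
        DataFrame with (a subset of) the canonical columns.  ``SNP``, ``EA``,
        ``OA``, ``BETA``, ``SE`` and ``P`` are required.
    """

    def __init__(
        self,
        trait_id: str,
        trait_type: str,
        df: pd.DataFrame,
        report: Optional[ParseReport] = None,
    ):
        if trait_type not in TRAIT_TYPES:
            raise ValueError(f"trait_type must be one of {TRAIT_TYPES}, got {trait_type!r}")
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing mandatory columns: {missing}")
        self.trait_id = trait_id
        self.trait_type = trait_type
        df = df.copy().reset_index(drop=True)
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        self.df = df[CANONICAL_COLUMNS]
        self.report = report

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"SummaryStatsTable({self.trait_id!r}, {self.trait_type}, {len(self)} SNPs)"

    @property
    def records(self) -> list[VariantAssociation]:
        out = []
        for row in self.df.itertuples(index=False):
            out.append(
                VariantAssociation(
                    snp_id=str(row.SNP),
                    chrom=None if pd.isna(row.CHR) else str(row.CHR),
                    pos=None if pd.isna(row.POS) else int(row.POS),
                    effect_allele=str(row.EA),
                    other_allele=str(row.OA),
                    beta=float(row.BETA),
                    se=float(row.SE),
                    pval=float(row.P),
                    eaf=None if pd.isna(row.EAF) else float(row.EAF),
                    n=None if pd.isna(row.N) else int(row.N),
                )
            )
        return out

    @classmethod
    def from_records(
        cls, trait_id: str, trait_type: str, records: Sequence[VariantAssociation]
    ) -> "SummaryStatsTable":
        df = pd.DataFrame(
            {
                "SNP": [r.snp_id for r in records],
                "CHR": [r.chrom for r in records],
                "POS": [r.pos for r in records],
                "EA": [r.effect_allele for r in records],
                "OA": [r.other_allele for r in records],
                "BETA": [r.beta for r in records],
                "SE": [r.se for r in records],
                "P": [r.pval for r in records],
                "EAF": [r.eaf for r in records],
                "N": [r.n for r in records],
            }
        )
        return cls(trait_id, trait_type, df)

    def subset(self, mask) -> "SummaryStatsTable":
        """Row-subset preserving order; ``mask`` is boolean or an index."""
        return SummaryStatsTable(self.trait_id, self.trait_type, self.df[mask])


def read_summary_stats(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    trait_id: str = "trait",
    trait_type: str = "continuous",
    sep: str = "\t",
) -> SummaryStatsTable:
    """Read a delimited summary-statistics file into a validated table.

    ``column_map`` maps canonical names (``SNP``, ``CHR``, ``POS``, ``EA``,
    ``OA``, ``BETA``, ``SE``, ``P``, ``EAF``, ``N``) to the column names used
    in the file.  Rows violating record invariants (zero/negative SE,
    non-ACGT or identical alleles, out-of-range p) are dropped and counted in
    ``table.report``; a p-value of exactly 0 is clamped to the smallest
    positive double instead of being dropped.
    """
    raw = pd.read_csv(path, sep=sep, dtype={0: str})
    if column_map:
        rename = {src: canon for canon, src in column_map.items() if src in raw.columns}
        missing_src = [src for canon, src in column_map.items() if src not in raw.columns]
        if missing_src:
            raise ValueError(f"mapped columns absent from file header: {missing_src}")
        raw = raw.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")

    report = ParseReport(n_rows=len(raw))
    df = raw.copy()
    df["SNP"] = df["SNP"].astype(str)
    df["EA"] = df["EA"].astype(str).str.upper()
    df["OA"] = df["OA"].astype(str).str.upper()
    for col in ("BETA", "SE", "P", "EAF"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    for col in ("POS", "N"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")

    clamp = df["P"] == 0
    if clamp.any():
        report.n_pval_clamped = int(clamp.sum())
        logger.warning("%d p-values of exactly 0 clamped to %g", clamp.sum(), MIN_PVAL)
        df.loc[clamp, "P"] = MIN_PVAL
    if "EAF" in df.columns:
        bad_eaf = df["EAF"].notna() & ((df["EAF"] <= 0) | (df["EAF"] >= 1))
        if bad_eaf.any():
            report.n_eaf_cleared = int(bad_eaf.sum())
            logger.info("%d out-of-range EAF values cleared to missing", bad_eaf.sum())
            df.loc[bad_eaf, "EAF"] = np.nan

    rules = [
        ("allele_not_snp", ~df["EA"].isin(VALID_ALLELES) | ~df["OA"].isin(VALID_ALLELES)),
        ("identical_alleles", df["EA"] == df["OA"]),
        ("beta_invalid", df["BETA"].isna() | ~np.isfinite(df["BETA"].fillna(np.nan))),
        ("se_not_positive", df["SE"].isna() | (df["SE"] <= 0)),
        ("pval_out_of_range", df["P"].isna() | (df["P"] <= 0) | (df["P"] > 1)),
        ("duplicate_snp_id", df["SNP"].duplicated(keep="first")),
    ]
    bad_total = pd.Series(False, index=df.index)
    for reason, mask in rules:
        new = mask & ~bad_total  # count each row once, first matching rule
        if new.any():
            report.dropped[reason] += int(new.sum())
        bad_total |= mask
    d = df[~bad_total]

    report.n_kept = len(d)
    if report.n_dropped:
        logger.info("read %s: kept %d rows, dropped %s", path, report.n_kept, dict(report.dropped))
    return SummaryStatsTable(trait_id, trait_type, d, report=report)


def write_summary_stats(table: SummaryStatsTable, path) -> None:
    """Write a table as tab-separated text with the canonical header.

    Floats are serialized with Python's shortest round-trip representation,
    so ``read_summary_stats(write(t))`` reproduces every value exactly.
    """
    table.df.to_csv(path, sep="\t", index=False, na_rep="NA")


def validate_table(table: SummaryStatsTable) -> list[str]:
    """Return all invariant violations in a table (empty iff valid)."""
    issues: list[str] = []
    seen: Counter = Counter(table.df["SNP"])
    for snp, count in seen.items():
        if count > 1:
            issues.append(f"{snp}: duplicate snp_id ({count} rows)")
    for rec in table.records:
        issues.extend(rec.issues())
    return issues
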