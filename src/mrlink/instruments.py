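"""Instrument selection and exposure/outcome harmonization.

Instrumental variables for two-sample MR are SNPs passing a genome-wide
sub-threshold p-value screen (default p < 1e-5, chosen to retain enough
instruments for small-GWAS exposures such as microbiome taxa), pruned for
linkage disequilibrium by greedy clumping (default r² < 0.01 within a
10,000 kb window) and filtered for instrument strength (F ≥ 10, with
F approximated by the squared instrument z-score).

Linkage disequilibrium is supplied as an explicit pairwise r² lookup rather
than computed from genotypes: real-data use requires reference-panel r²
values from the caller (or an external clumping run), while synthetic
pipelines construct the lookup directly.

Harmonization aligns the outcome table onto the exposure's effect-allele
orientation: matching alleles are kept, swapped alleles flip the outcome
beta's sign (and complement the frequency), strand flips are resolved by
complementing, and palindromic A/T and G/C SNPs are oriented by allele
frequency when unambiguous and dropped otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .summary_io import SummaryStatsTable, VariantAssociation

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Harmonization actions recorded per SNP.
ACTIONS = (
    "kept",
    "flipped",
    "dropped_palindromic",
    "dropped_incompatible",
    "dropped_missing",
)


class LDLookup:
    """Symmetric pairwise r² lookup between SNP identifiers.

    Absent pairs are treated as r² = 0; the diagonal is always 1.
    """

    def __init__(self, pairs: Optional[Mapping[Tuple[str, str], float]] = None):
        self._r2: dict[Tuple[str, str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> Tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must lie in [0, 1], got {r2}")
        if a != b:
            self._r2[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_file(cls, path) -> "LDLookup":
        """Read a tab-separated (snp_a, snp_b, r2) file."""
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        out = cls()
        for row in df.itertuples(index=False):
            out.set(str(row.snp_a), str(row.snp_b), float(row.r2))
        return out

    def to_file(self, path) -> None:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedSet:
    """Exposure/outcome effects aligned onto a shared effect allele."""

    snp_ids: np.ndarray
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    exposure_id: str = "exposure"
    outcome_id: str = "outcome"
    actions: dict = field(default_factory=dict)
    #: Effect-allele frequencies after orientation (NaN when absent).
    eaf_exp: Optional[np.ndarray] = None
    eaf_out: Optional[np.ndarray] = None

    def __post_init__(self):
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        for name in ("beta_exp", "se_exp", "beta_out", "se_out"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        lengths = {len(self.snp_ids), len(self.beta_exp), len(self.se_exp),
                   len(self.beta_out), len(self.se_out)}
        if len(lengths) != 1:
            raise ValueError("harmonized arrays must have equal length")
        if self.n_snp < 1:
            raise ValueError("no shared instruments")
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise ValueError("standard errors must be strictly positive")
        for name in ("eaf_exp", "eaf_out"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, np.asarray(val, dtype=float))

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def subset(self, mask) -> "HarmonizedSet":
        mask = np.asarray(mask)
        return HarmonizedSet(
            self.snp_ids[mask], self.beta_exp[mask], self.se_exp[mask],
            self.beta_out[mask], self.se_out[mask],
            exposure_id=self.exposure_id, outcome_id=self.outcome_id,
            actions=self.actions,
            eaf_exp=None if self.eaf_exp is None else self.eaf_exp[mask],
            eaf_out=None if self.eaf_out is None else self.eaf_out[mask],
        )


def f_statistic(record_or_beta: Union[VariantAssociation, float], se: Optional[float] = None):
    """Instrument-strength F statistic, the squared z-score (beta/se)²."""
    if se is None:
        rec = record_or_beta
        beta, se = rec.beta, rec.se
    else:
        beta = record_or_beta
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def select_instruments(
    table: SummaryStatsTable, p_threshold: float = 1e-5, f_min: float = 10.0
) -> SummaryStatsTable:
    """Keep SNPs with p < ``p_threshold`` and F ≥ ``f_min``, preserving order."""
    if p_threshold <= 0:
        raise ValueError("p_threshold must be positive")
    df = table.df
    f = (df["BETA"] / df["SE"]) ** 2
    keep = (df["P"] < p_threshold) & (f >= f_min)
    return table.subset(keep.to_numpy(dtype=bool))


def ld_clump(
    table: SummaryStatsTable,
    ld: LDLookup,
    r2_threshold: float = 0.01,
    window_kb: float = 10_000.0,
) -> SummaryStatsTable:
    """Greedy LD clumping by ascending p-value.

    Repeatedly takes the lowest-p unclaimed SNP as an index and removes all
    unclaimed SNPs on the same chromosome at center-to-center distance
    strictly less than ``window_kb`` whose r² with the index is
    ≥ ``r2_threshold``.  Ties in p are broken by (chrom, pos, snp_id).
    The returned table holds the index SNPs in that ordering.
    """
    df = table.df
    if len(df) == 0:
        return table.subset(np.zeros(0, dtype=bool))
    if df["CHR"].isna().any() or df["POS"].isna().any():
        raise ValueError("ld_clump requires chromosome and position for every SNP")
    order = df.assign(_chr=df["CHR"].astype(str), _pos=df["POS"].astype(float))
    order = order.sort_values(["P", "_chr", "_pos", "SNP"], kind="mergesort")
    snp = order["SNP"].to_numpy(dtype=object)
    chrom = order["_chr"].to_numpy(dtype=object)
    pos = order["_pos"].to_numpy(dtype=float)

    claimed = np.zeros(len(order), dtype=bool)
    index_rows = []
    for i in range(len(order)):
        if claimed[i]:
            continue
        index_rows.append(order.index[i])
        claimed[i] = True
        same = (~claimed) & (chrom == chrom[i])
        near = same & (np.abs(pos - pos[i]) / 1000.0 < window_kb)
        for j in np.flatnonzero(near):
            if ld.r2(snp[i], snp[j]) >= r2_threshold:
                claimed[j] = True
    return SummaryStatsTable(table.trait_id, table.trait_type, table.df.loc[index_rows])


def _is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT.get(ea) == oa


def _ambiguous(eaf: Optional[float], band: float) -> bool:
    return eaf is None or (band <= eaf <= 1.0 - band)


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    palindrome_eaf_band: float = 0.42,
) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect-allele orientation.

    Palindromic SNPs (A/T or G/C) are dropped when either table's
    effect-allele frequency is missing or falls inside
    ``[palindrome_eaf_band, 1 - palindrome_eaf_band]``; otherwise they are
    oriented so the frequencies agree on the same side of 0.5.
    """
    exp = exposure.df.set_index("SNP")
    out = outcome.df.set_index("SNP")
    actions: dict[str, str] = {}
    rows = []

    for snp in exp.index:
        if snp not in out.index:
            actions[snp] = "dropped_missing"
            continue
        e = exp.loc[snp]
        o = out.loc[snp]
        ea_e, oa_e = str(e["EA"]), str(e["OA"])
        ea_o, oa_o = str(o["EA"]), str(o["OA"])
        beta_o = float(o["BETA"])
        eaf_e = None if pd.isna(e["EAF"]) else float(e["EAF"])
        eaf_o = None if pd.isna(o["EAF"]) else float(o["EAF"])

        if _is_palindromic(ea_e, oa_e):
            if {ea_o, oa_o} != {ea_e, oa_e}:
                actions[snp] = "dropped_incompatible"
                continue
            # Align the allele labels first (swapped labels negate the beta
            # and complement the frequency), then resolve the remaining
            # strand ambiguity by frequency agreement.
            if ea_o != ea_e:
                beta_al = -beta_o
                eaf_al = None if eaf_o is None else 1.0 - eaf_o
            else:
                beta_al, eaf_al = beta_o, eaf_o
            if _ambiguous(eaf_e, palindrome_eaf_band) or _ambiguous(eaf_al, palindrome_eaf_band):
                actions[snp] = "dropped_palindromic"
                continue
            if (eaf_e < 0.5) != (eaf_al < 0.5):  # frequencies disagree: strand flip
                beta_al, eaf_al = -beta_al, 1.0 - eaf_al
            actions[snp] = "kept" if beta_al == beta_o else "flipped"
            rows.append((snp, float(e["BETA"]), float(e["SE"]), beta_al, float(o["SE"]),
                         eaf_e, eaf_al))
            continue

        # Non-palindromic: try direct match, swap, then strand complement.
        if (ea_o, oa_o) == (ea_e, oa_e):
            action = "kept"
        elif (ea_o, oa_o) == (oa_e, ea_e):
            action = "flipped"
        elif (COMPLEMENT.get(ea_o), COMPLEMENT.get(oa_o)) == (ea_e, oa_e):
            action = "kept"
        elif (COMPLEMENT.get(ea_o), COMPLEMENT.get(oa_o)) == (oa_e, ea_e):
            action = "flipped"
        else:
            actions[snp] = "dropped_incompatible"
            continue
        actions[snp] = action
        eaf_o_aligned = eaf_o
        if action == "flipped":
            beta_o = -beta_o
            eaf_o_aligned = None if eaf_o is None else 1.0 - eaf_o
        rows.append((snp, float(e["BETA"]), float(e["SE"]), beta_o, float(o["SE"]),
                     eaf_e, eaf_o_aligned))

    if not any(a in ("kept", "flipped") for a in actions.values()):
        raise ValueError("no shared instruments")

    snp_ids, beta_exp, se_exp, beta_out, se_out, eaf_exp, eaf_out = zip(*rows)
    as_float = lambda vals: np.array([np.nan if v is None else v for v in vals], dtype=float)
    return HarmonizedSet(
        np.array(snp_ids, dtype=object),
        np.array(beta_exp), np.array(se_exp),
        np.array(beta_out), np.array(se_out),
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        actions=actions,
        eaf_exp=as_float(eaf_exp),
        eaf_out=as_float(eaf_out),
    )
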