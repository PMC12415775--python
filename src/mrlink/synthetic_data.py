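"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: GWAS summary
statistics under a linear causal model with configurable horizontal
pleiotropy and LD-block structure, mediation triplets, and a three-group
(healthy control / Parkinson's with normal cognition / Parkinson's disease
dementia) cohort of zero-inflated taxon relative abundances with MMSE
scores.

Generative model for a pair of GWAS tables
------------------------------------------
For SNP j: minor-allele frequency mafⱼ ~ U(maf_range); true instrument
effect γⱼ = |N(0, 0.05²)|, conditioned to instrument strength F > 10 at the
exposure sample size (instrument effects are oriented positive, which is
without loss of generality since allele coding is arbitrary); pleiotropic
direct effect αⱼ = 0 for valid instruments and N(pleio_mean, pleio_sd²) for
the invalid fraction; true outcome effect Γⱼ = β·γⱼ + αⱼ.  Observed effects
are drawn normal around the truth with GWAS standard errors
seⱼ = 1/sqrt(2·mafⱼ(1−mafⱼ)·n).  Summary statistics are simulated directly
— no individual-level genotypes — which keeps calibration studies of
thousands of replicates in seconds.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import HarmonizedSet, LDLookup
from .summary_io import MIN_PVAL, SummaryStatsTable

#: Standard deviation of true instrument effects before F-conditioning.
GAMMA_SD = 0.05

#: Non-palindromic effect/other allele pairs used for generated SNPs.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

GROUPS = ("HC", "PD-NC", "PDD")


@dataclass
class SimulationTruth:
    """Generative parameters for one exposure→outcome GWAS pair."""

    beta_causal: float = 0.0
    prop_invalid: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    j_snps: int = 100
    n_exp: int = 100_000
    n_out: int = 100_000
    seed: int = 0
    #: Correlation between pleiotropic effects and instrument strength;
    #: non-zero values violate the InSIDE assumption (stresses MR-Egger).
    inside_violation_rho: float = 0.0
    #: Fraction of instruments conditioned to F > 10.
    strong_fraction: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.prop_invalid <= 1.0):
            raise ValueError("prop_invalid must lie in [0, 1]")
        if self.j_snps < 1:
            raise ValueError("j_snps must be >= 1")
        if self.n_exp < 2 or self.n_out < 2:
            raise ValueError("sample sizes must be >= 2")


def snp_id(j: int) -> str:
    """Deterministic identifier of the j-th generated SNP."""
    return f"rs{j:06d}"


def _gwas_se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _draw_gamma(rng, se_exp: np.ndarray, strong: np.ndarray, f_min: float = 10.0,
                max_rounds: int = 100) -> np.ndarray:
    """Half-normal instrument effects, conditioned to F > f_min where strong."""
    j = len(se_exp)
    gamma = np.abs(rng.normal(0.0, GAMMA_SD, j))
    for _ in range(max_rounds):
        weak = strong & ((gamma / se_exp) ** 2 <= f_min)
        if not weak.any():
            break
        gamma[weak] = np.abs(rng.normal(0.0, GAMMA_SD, int(weak.sum())))
    else:
        weak = strong & ((gamma / se_exp) ** 2 <= f_min)
        gamma[weak] = np.sqrt(f_min * 1.1) * se_exp[weak]
    return gamma


def _draw_pair_effects(truth: SimulationTruth, rng, maf_range: Tuple[float, float]):
    """Core arrays for one exposure→outcome pair; returns a dict."""
    lo, hi = maf_range
    if not (0.0 < lo < hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low < high <= 0.5")
    j = truth.j_snps
    maf = rng.uniform(lo, hi, j)
    se_exp = _gwas_se(maf, truth.n_exp)
    se_out = _gwas_se(maf, truth.n_out)
    strong = rng.random(j) < truth.strong_fraction
    gamma = _draw_gamma(rng, se_exp, strong)
    # Plant exactly round(prop_invalid * J) pleiotropic instruments at
    # random positions, so the invalid fraction is the stated one in every
    # replicate rather than Bernoulli-distributed around it.
    k = int(round(truth.prop_invalid * j))
    invalid = np.zeros(j, dtype=bool)
    invalid[rng.permutation(j)[:k]] = True
    alpha = np.zeros(j)
    if k:
        alpha[invalid] = rng.normal(truth.pleio_mean, max(truth.pleio_sd, 0.0), k)
        if truth.inside_violation_rho != 0.0:
            g = gamma[invalid]
            gs = (g - g.mean()) / (g.std() if g.std() > 0 else 1.0)
            alpha[invalid] += truth.inside_violation_rho * truth.pleio_sd * gs
    big_gamma = truth.beta_causal * gamma + alpha
    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(big_gamma, se_out)
    return {
        "maf": maf, "se_exp": se_exp, "se_out": se_out,
        "gamma": gamma, "alpha": alpha, "invalid": invalid,
        "beta_exp": beta_exp, "beta_out": beta_out,
    }


def simulate_harmonized(
    truth: SimulationTruth, maf_range: Tuple[float, float] = (0.05, 0.5)
) -> Tuple[HarmonizedSet, dict]:
    """Draw one exposure→outcome pair directly as a :class:`HarmonizedSet`.

    Fast path for calibration studies: skips table construction and the
    (identity) harmonization the full tables would round-trip through.
    Returns the set and the ground-truth arrays (γ, α, validity mask).
    """
    rng = np.random.default_rng(truth.seed)
    d = _draw_pair_effects(truth, rng, maf_range)
    hset = HarmonizedSet(
        np.array([snp_id(i) for i in range(truth.j_snps)], dtype=object),
        d["beta_exp"], d["se_exp"], d["beta_out"], d["se_out"],
        exposure_id="sim_exposure", outcome_id="sim_outcome",
        eaf_exp=d["maf"], eaf_out=d["maf"],
    )
    return hset, d


@dataclass
class LDBlockSpec:
    """Consecutive-SNP LD blocks: r² = rho² within a block, 0 across."""

    block_size: int
    rho: float

    def __post_init__(self):
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


def ld_block_matrix(j_snps: int, block_size: int, rho: float) -> LDLookup:
    """Pairwise lookup with r² = rho² inside consecutive blocks, 0 across."""
    spec = LDBlockSpec(block_size, rho)
    ld = LDLookup()
    r2 = spec.rho**2
    if r2 > 0:
        for start in range(0, j_snps, block_size):
            block = range(start, min(start + block_size, j_snps))
            for a in block:
                for b in block:
                    if a < b:
                        ld.set(snp_id(a), snp_id(b), r2)
    return ld


def _positions(j: int, ld_blocks: Optional[LDBlockSpec]) -> Tuple[np.ndarray, np.ndarray]:
    """Chromosome/position layout for generated SNPs.

    Without LD blocks, SNPs are spread across chromosomes 1-22 at 20,000 kb
    spacing (outside the default clumping window).  With blocks, SNPs of a
    block sit 100 kb apart on one chromosome and blocks are 50,000 kb apart.
    """
    if ld_blocks is None:
        chrom = np.array([str((i % 22) + 1) for i in range(j)], dtype=object)
        pos = np.array([1_000_000 + (i // 22) * 20_000_000 for i in range(j)])
        return chrom, pos
    bs = ld_blocks.block_size
    block_idx = np.arange(j) // bs
    within = np.arange(j) % bs
    chrom = np.array([str((b % 22) + 1) for b in block_idx], dtype=object)
    pos = 1_000_000 + (block_idx // 22) * 50_000_000 + within * 100_000
    return chrom, pos.astype(int)


def _pair_table(trait_id, trait_type, ids, chrom, pos, ea, oa, beta, se, eaf, n):
    z = np.abs(beta / se)
    pvals = np.maximum(2 * stats.norm.sf(z), MIN_PVAL)
    df = pd.DataFrame({
        "SNP": ids, "CHR": chrom, "POS": pos, "EA": ea, "OA": oa,
        "BETA": beta, "SE": se, "P": pvals, "EAF": eaf,
        "N": np.full(len(ids), n, dtype=int),
    })
    return SummaryStatsTable(trait_id, trait_type, df)


def simulate_summary_stats(
    truth: SimulationTruth,
    maf_range: Tuple[float, float] = (0.05, 0.5),
    ld_blocks: Optional[LDBlockSpec] = None,
) -> Tuple[SummaryStatsTable, SummaryStatsTable, LDLookup]:
    """Generate an exposure table, an outcome table and their LD lookup.

    Both tables cover the same SNPs with identical (non-palindromic) allele
    orientation and carry the generative truth on the returned tables as
    ``table.truth`` / ``table.truth_arrays``.
    """
    rng = np.random.default_rng(truth.seed)
    d = _draw_pair_effects(truth, rng, maf_range)
    j = truth.j_snps
    ids = np.array([snp_id(i) for i in range(j)], dtype=object)
    chrom, pos = _positions(j, ld_blocks)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), j)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)

    exposure = _pair_table("sim_exposure", "continuous", ids, chrom, pos, ea, oa,
                           d["beta_exp"], d["se_exp"], d["maf"], truth.n_exp)
    outcome = _pair_table("sim_outcome", "binary", ids, chrom, pos, ea, oa,
                          d["beta_out"], d["se_out"], d["maf"], truth.n_out)
    ld = (ld_block_matrix(j, ld_blocks.block_size, ld_blocks.rho)
          if ld_blocks is not None else LDLookup())
    for t in (exposure, outcome):
        t.truth = truth
        t.truth_arrays = d
    return exposure, outcome, ld


def simulate_bidirectional(
    truth: SimulationTruth,
    j_reverse: Optional[int] = None,
) -> Tuple[SummaryStatsTable, SummaryStatsTable]:
    """Tables for a one-directional causal system a→b, testable both ways.

    Trait a has ``truth.j_snps`` genuine instruments (set A); trait b has
    ``j_reverse`` instruments of its own (set B) with no effect on a, as
    there is no b→a path.  Table a covers A∪B (B with true effect 0), table
    b covers A∪B (A with effect β·γ plus pleiotropy, B with its own γ).
    """
    if j_reverse is None:
        j_reverse = truth.j_snps
    rng = np.random.default_rng(truth.seed)
    d = _draw_pair_effects(truth, rng, (0.05, 0.5))
    ja = truth.j_snps

    maf_b = rng.uniform(0.05, 0.5, j_reverse)
    se_b_on_b = _gwas_se(maf_b, truth.n_out)
    se_b_on_a = _gwas_se(maf_b, truth.n_exp)
    gamma_b = _draw_gamma(rng, se_b_on_b, np.ones(j_reverse, dtype=bool))
    beta_b_on_b = rng.normal(gamma_b, se_b_on_b)
    beta_b_on_a = rng.normal(0.0, se_b_on_a)  # no reverse path

    ids_a = np.array([f"a{i:05d}" for i in range(ja)], dtype=object)
    ids_b = np.array([f"b{i:05d}" for i in range(j_reverse)], dtype=object)
    ids = np.concatenate([ids_a, ids_b])
    j = ja + j_reverse
    chrom, pos = _positions(j, None)
    ea = np.full(j, "A", dtype=object)
    oa = np.full(j, "G", dtype=object)
    maf = np.concatenate([d["maf"], maf_b])

    table_a = _pair_table(
        "trait_a", "continuous", ids, chrom, pos, ea, oa,
        np.concatenate([d["beta_exp"], beta_b_on_a]),
        np.concatenate([d["se_exp"], se_b_on_a]),
        maf, truth.n_exp)
    table_b = _pair_table(
        "trait_b", "binary", ids, chrom, pos, ea, oa,
        np.concatenate([d["beta_out"], beta_b_on_b]),
        np.concatenate([d["se_out"], se_b_on_b]),
        maf, truth.n_out)
    for t in (table_a, table_b):
        t.truth = truth
    return table_a, table_b


@dataclass
class MediationTruth:
    """Generative parameters of an exposure→mediator→outcome triplet."""

    beta1: float
    beta2: float
    direct: float
    j_snps: int = 100
    n: int = 100_000
    seed: int = 0

    @property
    def total(self) -> float:
        return self.beta1 * self.beta2 + self.direct

    @property
    def proportion(self) -> Optional[float]:
        """Implied proportion mediated; None when the total effect is zero."""
        if self.total == 0:
            return None
        return self.beta1 * self.beta2 / self.total


def _relation_arrays(rng, j, n_left, n_right, effect):
    """One instrumented relation: strong instruments for the left trait and
    their (noisy) effects on the right trait under a linear model."""
    maf = rng.uniform(0.05, 0.5, j)
    se_l = _gwas_se(maf, n_left)
    se_r = _gwas_se(maf, n_right)
    gamma = _draw_gamma(rng, se_l, np.ones(j, dtype=bool))
    return {
        "maf": maf, "gamma": gamma,
        "se_left": se_l, "se_right": se_r,
        "beta_left": rng.normal(gamma, se_l),
        "beta_right": rng.normal(effect * gamma, se_r),
    }


def simulate_mediation_harmonized(
    truth: MediationTruth,
) -> Tuple[HarmonizedSet, HarmonizedSet, HarmonizedSet]:
    """Three harmonized relations (exp→med, med→out, exp→out).

    Each relation uses its own independent instrument set of ``j_snps``
    SNPs: set A instruments the exposure (used for both the exposure→mediator
    and exposure→outcome relations, where the total effect β1·β2 + direct
    applies), set B instruments the mediator.
    """
    rng = np.random.default_rng(truth.seed)
    j, n = truth.j_snps, truth.n
    a = _relation_arrays(rng, j, n, n, truth.beta1)
    b = _relation_arrays(rng, j, n, n, truth.beta2)
    # exposure→outcome shares A's instruments; redraw outcome noise.
    beta_out_on_a = rng.normal(truth.total * a["gamma"], a["se_right"])

    ids_a = np.array([f"a{i:05d}" for i in range(j)], dtype=object)
    ids_b = np.array([f"b{i:05d}" for i in range(j)], dtype=object)
    h1 = HarmonizedSet(ids_a, a["beta_left"], a["se_left"], a["beta_right"], a["se_right"],
                       exposure_id="sim_exposure", outcome_id="sim_mediator")
    h2 = HarmonizedSet(ids_b, b["beta_left"], b["se_left"], b["beta_right"], b["se_right"],
                       exposure_id="sim_mediator", outcome_id="sim_outcome")
    h3 = HarmonizedSet(ids_a, a["beta_left"], a["se_left"], beta_out_on_a, a["se_right"],
                       exposure_id="sim_exposure", outcome_id="sim_outcome")
    return h1, h2, h3


def simulate_mediation_triplet(
    beta1: float, beta2: float, direct: float,
    j_snps: int = 100, n: int = 100_000, seed: int = 0,
) -> Tuple[SummaryStatsTable, SummaryStatsTable, SummaryStatsTable, MediationTruth]:
    """Exposure, mediator and outcome GWAS tables with known mediation truth.

    The exposure table holds instrument set A (plus set B at null effect);
    the mediator table holds A at effect β1·γ and its own instruments B; the
    outcome table holds A at the total effect (β1·β2 + direct)·γ and B at
    β2·γ.
    """
    truth = MediationTruth(beta1, beta2, direct, j_snps, n, seed)
    rng = np.random.default_rng(seed)
    j = j_snps
    a = _relation_arrays(rng, j, n, n, beta1)
    b = _relation_arrays(rng, j, n, n, beta2)
    beta_out_on_a = rng.normal(truth.total * a["gamma"], a["se_right"])
    beta_exp_on_b = rng.normal(0.0, b["se_left"])  # B does not touch the exposure
    beta_med_on_a = a["beta_right"]

    ids = np.concatenate([[f"a{i:05d}" for i in range(j)],
                          [f"b{i:05d}" for i in range(j)]]).astype(object)
    chrom, pos = _positions(2 * j, None)
    ea = np.full(2 * j, "A", dtype=object)
    oa = np.full(2 * j, "G", dtype=object)
    maf = np.concatenate([a["maf"], b["maf"]])

    exposure = _pair_table("sim_exposure", "continuous", ids, chrom, pos, ea, oa,
                           np.concatenate([a["beta_left"], beta_exp_on_b]),
                           np.concatenate([a["se_left"], b["se_left"]]), maf, n)
    mediator = _pair_table("sim_mediator", "continuous", ids, chrom, pos, ea, oa,
                           np.concatenate([beta_med_on_a, b["beta_left"]]),
                           np.concatenate([a["se_right"], b["se_left"]]), maf, n)
    outcome = _pair_table("sim_outcome", "binary", ids, chrom, pos, ea, oa,
                          np.concatenate([beta_out_on_a, b["beta_right"]]),
                          np.concatenate([a["se_right"], b["se_right"]]), maf, n)
    for t in (exposure, mediator, outcome):
        t.truth = truth
    return exposure, mediator, outcome, truth


# ---------------------------------------------------------------------------
# Case-control cohort
# ---------------------------------------------------------------------------

#: Default per-group median relative abundances of the five MR-implicated
#: genera (zero-inflated log-normal location parameters).
DEFAULT_TAXA_MEDIANS = {
    "Roseburia":       {"HC": 0.017804, "PD-NC": 0.008067, "PDD": 0.008942},
    "Hungatella":      {"HC": 0.000437, "PD-NC": 0.000437, "PDD": 0.000646},
    "Lachnospira":     {"HC": 0.010449, "PD-NC": 0.004669, "PDD": 0.003327},
    "Butyricimonas":   {"HC": 0.000964, "PD-NC": 0.002711, "PDD": 0.003960},
    "Subdoligranulum": {"HC": 0.000719, "PD-NC": 0.000972, "PDD": 0.001217},
}

#: Default per-group MMSE mean and SD (0-30 cognitive score).
DEFAULT_MMSE = {"HC": (29.18, 0.90), "PD-NC": (28.50, 1.15), "PDD": (19.30, 4.10)}


@dataclass
class TaxonSpec:
    """Zero-inflated log-normal abundance model for one taxon."""

    name: str
    group_medians: dict
    sigma_log: float = 1.0
    zero_prob: float = 0.1


@dataclass
class AbundanceCohort:
    """Per-subject taxon relative abundances with group labels and MMSE."""

    df: pd.DataFrame          # columns: subject_id, group, mmse, <taxa...>
    taxa: Sequence[str]
    truth: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AbundanceCohort":
        df = pd.read_csv(path, sep="\t")
        taxa = [c for c in df.columns if c not in ("subject_id", "group", "mmse")]
        return cls(df=df, taxa=taxa)


def default_taxa_specs(sigma_log: float = 1.0, zero_prob: float = 0.1) -> list[TaxonSpec]:
    return [TaxonSpec(name, medians, sigma_log, zero_prob)
            for name, medians in DEFAULT_TAXA_MEDIANS.items()]


def simulate_cohort(
    n_hc: int = 28,
    n_pdnc: int = 20,
    n_pdd: int = 27,
    taxa: Optional[Sequence[TaxonSpec]] = None,
    mmse_spec: Optional[dict] = None,
    corr_taxon: str = "Subdoligranulum",
    corr_target: float = -0.316,
    seed: int = 0,
) -> AbundanceCohort:
    """Generate a three-group case-control cohort of relative abundances.

    Abundances follow a zero-inflated log-normal per group (median given by
    the taxon spec).  MMSE scores are drawn per group, then linearly blended
    with the standardized abundance of ``corr_taxon`` so that the pooled
    sample correlation equals ``corr_target`` before integer rounding and
    clipping to 0-30; the achieved post-rounding correlation is recorded in
    ``cohort.truth["achieved_r"]``.
    """
    if abs(corr_target) >= 1:
        raise ValueError("corr_target must lie in (-1, 1)")
    taxa = list(taxa) if taxa is not None else default_taxa_specs()
    mmse_spec = mmse_spec or DEFAULT_MMSE
    rng = np.random.default_rng(seed)

    groups = np.array(["HC"] * n_hc + ["PD-NC"] * n_pdnc + ["PDD"] * n_pdd, dtype=object)
    n = len(groups)
    df = pd.DataFrame({
        "subject_id": [f"S{i + 1:03d}" for i in range(n)],
        "group": groups,
    })

    for spec in taxa:
        vals = np.zeros(n)
        for g in GROUPS:
            idx = np.flatnonzero(groups == g)
            if idx.size == 0:
                continue
            mu = np.log(spec.group_medians[g])
            draw = rng.lognormal(mu, spec.sigma_log, idx.size)
            zero = rng.random(idx.size) < spec.zero_prob
            draw[zero] = 0.0
            vals[idx] = draw
        df[spec.name] = np.minimum(vals, 1.0)

    # Per-group MMSE, then exact-correlation blend with the target taxon.
    mmse = np.zeros(n)
    for g in GROUPS:
        idx = np.flatnonzero(groups == g)
        mean, sd = mmse_spec[g]
        mmse[idx] = rng.normal(mean, sd, idx.size)

    achieved_r = np.nan
    if corr_taxon in df.columns:
        a = df[corr_taxon].to_numpy(dtype=float)
        if np.std(a) > 0 and np.std(mmse) > 0:
            a_std = (a - a.mean()) / a.std()
            m_mean, m_sd = mmse.mean(), mmse.std()
            m_std = (mmse - m_mean) / m_sd
            rho_hat = float(np.mean(a_std * m_std))
            resid = m_std - rho_hat * a_std
            denom = np.sqrt(max(1.0 - rho_hat**2, 1e-12))
            resid /= denom
            blended = corr_target * a_std + np.sqrt(1.0 - corr_target**2) * resid
            mmse = m_mean + m_sd * blended
    mmse = np.clip(np.rint(mmse), 0, 30).astype(int)
    df["mmse"] = mmse
    if corr_taxon in df.columns:
        a = df[corr_taxon].to_numpy(dtype=float)
        if np.std(a) > 0 and np.std(mmse.astype(float)) > 0:
            achieved_r = float(np.corrcoef(a, mmse.astype(float))[0, 1])

    cols = ["subject_id", "group", "mmse"] + [t.name for t in taxa]
    df = df[cols]
    return AbundanceCohort(
        df=df,
        taxa=[t.name for t in taxa],
        truth={
            "seed": seed, "n_hc": n_hc, "n_pdnc": n_pdnc, "n_pdd": n_pdd,
            "corr_taxon": corr_taxon, "corr_target": corr_target,
            "achieved_r": achieved_r,
        },
    )
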