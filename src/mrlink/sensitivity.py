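"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

Four complementary checks on a harmonized instrument set:

* Cochran's Q — weighted dispersion of the Wald ratios around the
  fixed-effect IVW estimate, referred to a chi-square with J−1 df.
* MR-Egger intercept test — a non-zero intercept indicates directional
  horizontal pleiotropy (numbers shared with :func:`mrlink.estimators.mr_egger`).
* MR-PRESSO — a parametric-simulation residual-sum-of-squares test: the
  global test compares the observed leave-one-out weighted RSS against its
  simulated null distribution; per-SNP outlier tests compare each SNP's RSS
  contribution, Bonferroni-adjusted; flagged outliers are removed and the
  IVW estimate recomputed, with a distortion test comparing the observed
  displacement against displacements from randomly removed subsets.
* leave-one-out — the IVW estimate recomputed with each SNP omitted in turn.

All Monte-Carlo p-values are floored at 1/(n_sim+1) so a simulation can
never report exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, _ivw_core, _ratios, ivw, mr_egger
from .instruments import HarmonizedSet


def cochran_q(hset: HarmonizedSet) -> Tuple[float, int, float]:
    """Cochran's Q over the Wald ratios: (Q, df, chi-square upper-tail p).

    Q = Σ wⱼ (rⱼ − β̂)² with wⱼ the inverse ratio variances and β̂ the
    fixed-effect IVW estimate; df = J − 1.
    """
    if hset.n_snp < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    r, rse = _ratios(hset)
    _, _, q = _ivw_core(r, rse)
    df = hset.n_snp - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def egger_intercept_test(hset: HarmonizedSet) -> Tuple[float, float, float]:
    """(intercept, se, p) from the MR-Egger fit — identical numbers."""
    if hset.n_snp < 3:
        raise ValueError("Egger intercept test requires at least 3 instruments")
    extra = mr_egger(hset).extra
    return extra["intercept"], extra["intercept_se"], extra["intercept_p"]


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion results."""

    global_p: float
    global_rss: float
    outlier_p: np.ndarray        # raw per-SNP Monte-Carlo p-values
    outlier_p_adjusted: np.ndarray  # Bonferroni-adjusted
    outlier_flags: np.ndarray    # boolean, flagged at outlier_alpha
    corrected: Optional[MREstimate]
    distortion_p: Optional[float]
    n_sim: int


def _loo_slopes(be: np.ndarray, bo: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out intercept-free WLS slopes of bo on be, one per SNP.

    Supports batched input with shape (..., J); sums run over the last axis.
    """
    swbb = np.sum(w * be * bo, axis=-1, keepdims=True)
    swb2 = np.sum(w * be * be, axis=-1, keepdims=True)
    return (swbb - w * be * bo) / (swb2 - w * be * be)


def mr_presso(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """Detect and correct pleiotropic outlier instruments.

    The observed statistic is RSSⱼ = wⱼ (Γ̂ⱼ − β̂₍₋ⱼ₎ γ̂ⱼ)² summed over
    SNPs, with β̂₍₋ⱼ₎ the leave-one-out IVW slope and wⱼ = 1/σ_yⱼ².  The
    null distribution is built from ``n_sim`` parametric draws
    γ̂* ~ N(γ̂, σ_x), Γ̂* ~ N(β̂₍₋ⱼ₎ γ̂ⱼ, σ_y), re-running the
    leave-one-out fit on each draw.  Per-SNP contributions give outlier
    p-values, Bonferroni-adjusted and flagged below ``outlier_alpha``.
    """
    j = hset.n_snp
    if j < 4:
        raise ValueError("insufficient instruments for MR-PRESSO")
    rng = np.random.default_rng(seed)
    be, se_e = hset.beta_exp, hset.se_exp
    bo, se_o = hset.beta_out, hset.se_out
    w = 1.0 / se_o**2

    beta_loo = _loo_slopes(be, bo, w)
    contrib_obs = w * (bo - beta_loo * be) ** 2
    rss_obs = float(np.sum(contrib_obs))

    be_s = rng.normal(be, se_e, size=(n_sim, j))
    bo_s = rng.normal(beta_loo * be, se_o, size=(n_sim, j))
    beta_loo_s = _loo_slopes(be_s, bo_s, w)
    contrib_s = w * (bo_s - beta_loo_s * be_s) ** 2
    rss_s = contrib_s.sum(axis=1)

    floor = 1.0 / (n_sim + 1)
    global_p = max(float(np.mean(rss_s >= rss_obs)), floor)
    outlier_p = np.maximum(np.mean(contrib_s >= contrib_obs, axis=0), floor)
    outlier_p_adj = np.minimum(1.0, outlier_p * j)
    flags = outlier_p_adj < outlier_alpha

    corrected = None
    distortion_p = None
    n_keep = int(np.sum(~flags))
    if flags.any() and n_keep >= 2:
        corrected = ivw(hset.subset(~flags))
        beta_all = ivw(hset).beta
        d_obs = beta_all - corrected.beta
        k = int(flags.sum())
        if j - k >= 2:
            d_sim = np.empty(n_sim)
            r, rse = _ratios(hset)
            wr = 1.0 / rse**2
            for s in range(n_sim):
                drop = rng.choice(j, size=k, replace=False)
                keep = np.ones(j, dtype=bool)
                keep[drop] = False
                d_sim[s] = beta_all - float(
                    np.sum(wr[keep] * r[keep]) / np.sum(wr[keep])
                )
            distortion_p = max(float(np.mean(np.abs(d_sim) >= abs(d_obs))), floor)
    elif not flags.any():
        corrected = None

    return PressoResult(
        global_p=global_p,
        global_rss=rss_obs,
        outlier_p=outlier_p,
        outlier_p_adjusted=outlier_p_adj,
        outlier_flags=flags,
        corrected=corrected,
        distortion_p=distortion_p,
        n_sim=n_sim,
    )


def leave_one_out(hset: HarmonizedSet, model: str = "multiplicative_random") -> pd.DataFrame:
    """IVW estimate with each SNP omitted in turn, plus the all-SNP row.

    Returns a DataFrame with columns (omitted_snp_id, beta, se, pval);
    the final row has ``omitted_snp_id == "none"``.
    """
    if hset.n_snp < 3:
        raise ValueError("leave-one-out requires at least 3 instruments")
    rows = []
    for i in range(hset.n_snp):
        mask = np.ones(hset.n_snp, dtype=bool)
        mask[i] = False
        est = ivw(hset.subset(mask), model=model)
        rows.append((hset.snp_ids[i], est.beta, est.se, est.pval))
    full = ivw(hset, model=model)
    rows.append(("none", full.beta, full.se, full.pval))
    return pd.DataFrame(rows, columns=["omitted_snp_id", "beta", "se", "pval"])


@dataclass
class SensitivityReport:
    """Combined four-part sensitivity output for one instrument set."""

    q: float
    q_df: int
    q_pval: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    presso: Optional[PressoResult]
    loo: Optional[pd.DataFrame]

    def to_frame(self) -> pd.DataFrame:
        """One-row summary table (leave-one-out reported separately)."""
        row = {
            "q": self.q, "q_df": self.q_df, "q_pval": self.q_pval,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_p": self.egger_intercept_p,
            "presso_global_p": self.presso.global_p if self.presso else np.nan,
            "presso_n_outliers": int(self.presso.outlier_flags.sum()) if self.presso else 0,
            "presso_distortion_p": (
                self.presso.distortion_p
                if self.presso and self.presso.distortion_p is not None else np.nan
            ),
        }
        return pd.DataFrame([row])


def sensitivity_report(
    hset: HarmonizedSet, seed: int = 0, n_sim: int = 1000
) -> SensitivityReport:
    """Run all applicable diagnostics (skipping those the J count forbids)."""
    q, q_df, q_p = cochran_q(hset)
    if hset.n_snp >= 3:
        intercept, int_se, int_p = egger_intercept_test(hset)
        loo = leave_one_out(hset)
    else:
        intercept = int_se = int_p = float("nan")
        loo = None
    presso = mr_presso(hset, n_sim=n_sim, seed=seed) if hset.n_snp >= 4 else None
    return SensitivityReport(q, q_df, q_p, intercept, int_se, int_p, presso, loo)
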