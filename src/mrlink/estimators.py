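"""Two-sample Mendelian randomization estimators.

Given a harmonized instrument set with exposure effects γ̂ⱼ (SE σ_xⱼ) and
outcome effects Γ̂ⱼ (SE σ_yⱼ), each SNP provides a Wald ratio
rⱼ = Γ̂ⱼ/γ̂ⱼ with first-order standard error σ_yⱼ/|γ̂ⱼ|.  The five
estimators combine the ratios under different robustness assumptions:

* inverse-variance weighting (IVW) — precision-weighted mean of the ratios;
  the primary method.  The multiplicative random-effects variant inflates
  the fixed-effect SE by max(1, sqrt(Q/(J−1))) and never deflates it.
* MR-Egger — weighted regression of Γ̂ on γ̂ with an unconstrained
  intercept; the slope is the causal estimate and a non-zero intercept
  indicates directional horizontal pleiotropy (requires the InSIDE
  assumption).
* weighted median — consistent when valid instruments carry more than half
  of the total inverse-variance weight.
* simple and weighted mode — kernel-density mode of the ratios; consistent
  when the largest group of instruments sharing a causal estimate is valid.

Binary-outcome effects are on the log-odds scale, so estimates are also
reported as odds ratios with normal 95% confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .instruments import HarmonizedSet

logger = logging.getLogger(__name__)

#: Canonical reporting order of the five estimators.
CANONICAL_METHODS = ("ivw", "mr_egger", "weighted_median", "simple_mode", "weighted_mode")

#: Normal multiplier for 95% confidence intervals.
CI_Z = 1.96

SignalClass = str  # {"significant_consistent", "significant_inconsistent", "null"}


@dataclass
class MREstimate:
    """One method's causal estimate on the log-odds scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.or_ = float(np.exp(self.beta))
        self.ci_low = float(np.exp(self.beta - CI_Z * self.se))
        self.ci_high = float(np.exp(self.beta + CI_Z * self.se))


def wald_ratio(beta_exp, se_exp, beta_out, se_out) -> Tuple:
    """Per-SNP causal estimate Γ̂/γ̂ with first-order SE σ_y/|γ̂|.

    ``se_exp`` does not enter the first-order SE; the argument is accepted
    for interface symmetry.  Accepts scalars or arrays.
    """
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    if np.any(beta_exp == 0):
        raise ValueError("null instrument: beta_exp = 0")
    ratio = beta_out / beta_exp
    ratio_se = se_out / np.abs(beta_exp)
    if ratio.ndim == 0:
        return float(ratio), float(ratio_se)
    return ratio, ratio_se


def _ratios(hset: HarmonizedSet) -> Tuple[np.ndarray, np.ndarray]:
    return wald_ratio(hset.beta_exp, hset.se_exp, hset.beta_out, hset.se_out)


def _ivw_core(ratios: np.ndarray, ratio_se: np.ndarray) -> Tuple[float, float, float]:
    """Return (beta, fixed-effect se, Cochran's Q)."""
    w = 1.0 / ratio_se**2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (ratios - beta) ** 2))
    return beta, se_fixed, q


def ivw(hset: HarmonizedSet, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate over the Wald ratios.

    ``model="fixed"`` uses the fixed-effect SE (Σw)^(−1/2);
    ``model="multiplicative_random"`` (default) multiplies it by
    max(1, sqrt(Q/(J−1))), where Q is Cochran's heterogeneity statistic.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    if hset.n_snp < 2:
        raise ValueError("IVW requires at least 2 instruments")
    r, rse = _ratios(hset)
    beta, se, q = _ivw_core(r, rse)
    j = hset.n_snp
    if model == "multiplicative_random":
        se *= max(1.0, np.sqrt(q / (j - 1)))
    pval = float(2 * stats.norm.sf(abs(beta / se)))
    return MREstimate("ivw", beta, se, pval, j,
                      extra={"model": model, "q": q, "q_df": j - 1})


def mr_egger(hset: HarmonizedSet) -> MREstimate:
    """MR-Egger regression slope with the pleiotropy intercept in ``extra``.

    Instruments are re-signed so every exposure effect is non-negative, then
    Γ̂ is regressed on γ̂ with weights 1/σ_y² and a free intercept.  Both
    standard errors carry the residual inflation factor
    max(1, sqrt(RSS/(J−2))); p-values use a t reference with J−2 df.
    """
    j = hset.n_snp
    if j < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    sign = np.where(hset.beta_exp < 0, -1.0, 1.0)
    x = hset.beta_exp * sign
    y = hset.beta_out * sign
    w = 1.0 / hset.se_out**2

    sw, sx, sy = np.sum(w), np.sum(w * x), np.sum(w * y)
    sxx, sxy = np.sum(w * x * x), np.sum(w * x * y)
    det = sw * sxx - sx**2
    if det <= 0:
        raise ValueError("degenerate Egger design: no variation in exposure effects")
    slope = (sw * sxy - sx * sy) / det
    intercept = (sxx * sy - sx * sxy) / det
    rss = float(np.sum(w * (y - intercept - slope * x) ** 2))
    infl = max(1.0, np.sqrt(rss / (j - 2)))
    se_slope = float(np.sqrt(sw / det) * infl)
    se_int = float(np.sqrt(sxx / det) * infl)
    p_slope = float(2 * stats.t.sf(abs(slope / se_slope), df=j - 2))
    p_int = float(2 * stats.t.sf(abs(intercept / se_int), df=j - 2))
    return MREstimate(
        "mr_egger", float(slope), se_slope, p_slope, j,
        extra={"intercept": float(intercept), "intercept_se": se_int,
               "intercept_p": p_int, "rss": rss},
    )


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of the cumulative weight.

    With sorted ratios and normalized weights wⱼ, the cumulative positions
    sⱼ = Σ_{i≤j} w_i − wⱼ/2 define a piecewise-linear quantile function;
    the estimate is its value at cumulative weight 0.5.  Equal weights
    reproduce the ordinary sample median.
    """
    order = np.argsort(ratios, kind="stable")
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / np.sum(w)
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, r))


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap standard error.

    Weights are the inverse ratio variances.  The bootstrap redraws each
    SNP's exposure and outcome effects from normal(beta, se), recomputes the
    ratios and takes the weighted median with the original weights; the SE
    is the standard deviation over ``n_boot`` replicates.
    """
    if hset.n_snp < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    r, rse = _ratios(hset)
    w = 1.0 / rse**2
    beta = weighted_median_point(r, w)
    boots = _bootstrap_estimates(hset, w, weighted_median_point, n_boot, seed)
    se = float(np.std(boots, ddof=1))
    pval = float(2 * stats.norm.sf(abs(beta / se)))
    return MREstimate("weighted_median", beta, se, pval, hset.n_snp,
                      extra={"n_boot": n_boot, "seed": seed})


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    """Modified Silverman rule: phi · 0.9 · min(sd, iqr/1.349) · J^(−1/5)."""
    j = len(ratios)
    sd = float(np.std(ratios, ddof=1))
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25]))) / 1.349
    spread = min(x for x in (sd, iqr) if x > 0) if (sd > 0 or iqr > 0) else 0.0
    return phi * 0.9 * spread * j ** (-1 / 5)


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, h: float, n_grid: int = 512) -> float:
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, n_grid)
    dens = np.zeros_like(grid)
    for rj, wj in zip(ratios, weights):
        dens += wj * np.exp(-0.5 * ((grid - rj) / h) ** 2)
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    hset: HarmonizedSet,
    weighted: bool = False,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Simple or weighted mode-based estimate.

    The estimate is the maximizer of a Gaussian kernel density over the Wald
    ratios (bandwidth by the modified Silverman rule scaled by ``phi``); the
    weighted variant weights each ratio by its normalized inverse variance.
    If all ratios coincide the common value is returned directly.  SE by the
    same parametric bootstrap as the weighted median.
    """
    if hset.n_snp < 3:
        raise ValueError("mode estimators require at least 3 instruments")
    r, rse = _ratios(hset)
    ivw_w = 1.0 / rse**2
    w = ivw_w / np.sum(ivw_w) if weighted else np.full(len(r), 1.0 / len(r))
    h = _mode_bandwidth(r, phi)

    if h == 0.0:
        beta = float(r[0])
        point = lambda ratios, weights: float(np.median(ratios))  # noqa: E731
    else:
        beta = _kde_mode(r, w, h)

        def point(ratios, _unused, w=w, h=h):
            return _kde_mode(np.asarray(ratios), w, h)

    boots = _bootstrap_estimates(hset, ivw_w, point, n_boot, seed)
    se = float(np.std(boots, ddof=1))
    pval = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else 1.0
    method = "weighted_mode" if weighted else "simple_mode"
    return MREstimate(method, beta, se, pval, hset.n_snp,
                      extra={"phi": phi, "bandwidth": h, "n_boot": n_boot, "seed": seed})


def _bootstrap_estimates(hset, weights, point_fn, n_boot: int, seed: int) -> np.ndarray:
    """Parametric bootstrap of a ratio-based point estimator.

    Redraws beta_exp* ~ N(beta_exp, se_exp) and beta_out* ~ N(beta_out,
    se_out) per replicate, recomputes ratios, and re-applies ``point_fn``
    with the original weights (bandwidths/weights held fixed, as in standard
    two-sample MR bootstraps).
    """
    rng = np.random.default_rng(seed)
    be = rng.normal(hset.beta_exp, hset.se_exp, size=(n_boot, hset.n_snp))
    bo = rng.normal(hset.beta_out, hset.se_out, size=(n_boot, hset.n_snp))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = bo / be
    out = np.empty(n_boot)
    for i in range(n_boot):
        out[i] = point_fn(ratios[i], weights)
    return out


def estimate_all(hset: HarmonizedSet, seed: int = 0, n_boot: int = 1000) -> list[MREstimate]:
    """All applicable estimates in canonical order, deterministic given seed.

    With ≥3 instruments all five methods are returned; with exactly 2 only
    IVW applies; with 1 the single Wald ratio is returned.
    """
    if hset.n_snp == 0:
        raise ValueError("no instruments")
    if hset.n_snp == 1:
        r, rse = _ratios(hset)
        pval = float(2 * stats.norm.sf(abs(r[0] / rse[0])))
        logger.info("single instrument: returning Wald ratio only")
        return [MREstimate("wald_ratio", float(r[0]), float(rse[0]), pval, 1)]
    if hset.n_snp == 2:
        logger.info("2 instruments: only IVW is applicable")
        return [ivw(hset)]
    seeds = np.random.SeedSequence(seed).generate_state(3)
    return [
        ivw(hset),
        mr_egger(hset),
        weighted_median(hset, n_boot=n_boot, seed=int(seeds[0])),
        mode_estimate(hset, weighted=False, n_boot=n_boot, seed=int(seeds[1])),
        mode_estimate(hset, weighted=True, n_boot=n_boot, seed=int(seeds[2])),
    ]


def classify_causal_signal(estimates: Sequence[MREstimate]) -> SignalClass:
    """Apply the IVW-primary significance rule.

    ``significant_consistent`` when the IVW p-value is below 0.05 and every
    returned method agrees in direction; ``significant_inconsistent`` when
    IVW is significant but a direction disagrees; ``null`` otherwise.
    """
    ivw_est = next((e for e in estimates if e.method == "ivw"), None)
    if ivw_est is None:
        raise ValueError("no IVW estimate in collection")
    if ivw_est.pval >= 0.05:
        return "null"
    signs = {np.sign(e.beta) for e in estimates}
    return "significant_consistent" if len(signs) == 1 else "significant_inconsistent"
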