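"""Pipeline orchestration: full MR runs, bidirectional MR and two-step mediation.

Two-step mediation decomposes a total exposure→outcome effect into the
product of the exposure→mediator effect (β1) and the mediator→outcome
effect (β2), both estimated by univariable IVW.  The indirect effect is
β1·β2, its standard error follows from the delta method,
sqrt(β1²·se2² + β2²·se1²), and the proportion mediated is the indirect
effect over the total effect.  The proportion's confidence interval
propagates the indirect-effect CI over the total effect treated as fixed —
a simplification that understates the interval when the total effect is
itself noisy (see the methods note).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .estimators import MREstimate, classify_causal_signal, estimate_all
from .instruments import LDLookup, harmonize, ld_clump, select_instruments
from .sensitivity import SensitivityReport, sensitivity_report
from .summary_io import SummaryStatsTable

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tuning knobs for a full select→clump→harmonize→estimate run."""

    p_threshold: float = 1e-5
    f_min: float = 10.0
    r2_threshold: float = 0.01
    window_kb: float = 10_000.0
    palindrome_eaf_band: float = 0.42
    presso_n_sim: int = 1000
    n_boot: int = 1000
    #: Display-only significance filter applied when reporting mediator
    #: screens (screening itself always uses p < 0.05 on IVW).
    report_p_filter: float = 0.05


@dataclass
class DirectionReport:
    """One direction of an MR analysis."""

    exposure_id: str
    outcome_id: str
    n_instruments: int
    estimates: list = field(default_factory=list)
    classification: str = "inconclusive"
    sensitivity: Optional[SensitivityReport] = None
    inconclusive_reason: Optional[str] = None

    @property
    def ivw(self) -> Optional[MREstimate]:
        return next((e for e in self.estimates if e.method == "ivw"), None)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "exposure": self.exposure_id, "outcome": self.outcome_id,
            "method": e.method, "n_snp": e.n_snp, "beta": e.beta, "se": e.se,
            "pval": e.pval, "OR": e.or_, "ci_low": e.ci_low, "ci_high": e.ci_high,
        } for e in self.estimates]
        return pd.DataFrame(rows)


def run_mr(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    config: Optional[PipelineConfig] = None,
    ld: Optional[LDLookup] = None,
    seed: int = 0,
    with_sensitivity: bool = True,
) -> DirectionReport:
    """Full single-direction MR: select → clump → harmonize → estimate.

    Failure to find instruments yields an inconclusive report rather than an
    exception, so screening loops can continue past underpowered traits.
    """
    cfg = config or PipelineConfig()
    report = DirectionReport(exposure.trait_id, outcome.trait_id, 0)
    selected = select_instruments(exposure, cfg.p_threshold, cfg.f_min)
    if len(selected) == 0:
        report.inconclusive_reason = "no instruments pass selection"
        return report
    has_coords = not (selected.df["CHR"].isna().any() or selected.df["POS"].isna().any())
    if has_coords:
        selected = ld_clump(selected, ld or LDLookup(), cfg.r2_threshold, cfg.window_kb)
    elif ld is not None and len(ld):
        logger.warning("LD lookup supplied but positions missing; clumping skipped")
    try:
        hset = harmonize(selected, outcome, cfg.palindrome_eaf_band)
    except ValueError as exc:
        report.inconclusive_reason = str(exc)
        return report
    report.n_instruments = hset.n_snp
    report.estimates = estimate_all(hset, seed=seed, n_boot=cfg.n_boot)
    try:
        report.classification = classify_causal_signal(report.estimates)
    except ValueError:
        report.classification = "inconclusive"
    if with_sensitivity and hset.n_snp >= 2:
        report.sensitivity = sensitivity_report(hset, seed=seed, n_sim=cfg.presso_n_sim)
    return report


def bidirectional_mr(
    table_a: SummaryStatsTable,
    table_b: SummaryStatsTable,
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
    ld_a: Optional[LDLookup] = None,
    ld_b: Optional[LDLookup] = None,
) -> Tuple[DirectionReport, DirectionReport]:
    """Run the full pipeline in both directions (a→b, then b→a)."""
    s1, s2 = np.random.SeedSequence(seed).generate_state(2)
    forward = run_mr(table_a, table_b, config, ld_a, seed=int(s1))
    reverse = run_mr(table_b, table_a, config, ld_b, seed=int(s2))
    return forward, reverse


@dataclass
class MediationResult:
    """Two-step mediation decomposition of one exposure→mediator→outcome path."""

    mediator_id: str
    beta_total: float
    beta1: float
    se1: float
    beta2: float
    se2: float
    indirect: float
    se_indirect: float
    proportion: float
    proportion_ci: Tuple[float, float]
    direction_ok: bool


def two_step_mediation(
    exp_to_med: MREstimate,
    med_to_out: MREstimate,
    exp_to_out: MREstimate,
    mediator_id: str = "mediator",
) -> MediationResult:
    """Combine three IVW estimates into a mediation decomposition.

    indirect = β1·β2; se by the delta method; proportion = indirect/total
    with a CI propagating the indirect-effect CI over the fixed total.
    """
    b1, s1 = exp_to_med.beta, exp_to_med.se
    b2, s2 = med_to_out.beta, med_to_out.se
    bt = exp_to_out.beta
    if bt == 0:
        raise ValueError("undefined proportion: total effect is zero")
    indirect = b1 * b2
    se_ind = float(np.sqrt(b1**2 * s2**2 + b2**2 * s1**2))
    proportion = indirect / bt
    lo, hi = sorted(((indirect - 1.96 * se_ind) / bt, (indirect + 1.96 * se_ind) / bt))
    return MediationResult(
        mediator_id=mediator_id,
        beta_total=bt, beta1=b1, se1=s1, beta2=b2, se2=s2,
        indirect=indirect, se_indirect=se_ind,
        proportion=proportion, proportion_ci=(lo, hi),
        direction_ok=bool(np.sign(indirect) == np.sign(bt)),
    )


def mediation_screen(
    exposure: SummaryStatsTable,
    mediators: Sequence[SummaryStatsTable],
    outcome: SummaryStatsTable,
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Screen candidate mediators of an exposure→outcome effect.

    For each mediator, estimates exposure→mediator (β1) and mediator→outcome
    (β2); mediators are retained when both steps classify as
    ``significant_consistent`` under the IVW-primary rule.  Rows are sorted
    by \\|proportion mediated\\| descending.
    """
    cfg = config or PipelineConfig()
    seeds = np.random.SeedSequence(seed).generate_state(2 * len(mediators) + 1)
    total_rep = run_mr(exposure, outcome, cfg, seed=int(seeds[-1]), with_sensitivity=False)
    if total_rep.ivw is None:
        raise ValueError("cannot estimate the total exposure→outcome effect")
    rows = []
    for i, med in enumerate(mediators):
        step1 = run_mr(exposure, med, cfg, seed=int(seeds[2 * i]), with_sensitivity=False)
        step2 = run_mr(med, outcome, cfg, seed=int(seeds[2 * i + 1]), with_sensitivity=False)
        if step1.ivw is None or step2.ivw is None:
            continue
        if step1.classification != "significant_consistent":
            continue
        if step2.classification != "significant_consistent":
            continue
        res = two_step_mediation(step1.ivw, step2.ivw, total_rep.ivw, mediator_id=med.trait_id)
        rows.append({
            "mediator": res.mediator_id,
            "beta1": res.beta1, "se1": res.se1,
            "beta2": res.beta2, "se2": res.se2,
            "beta_total": res.beta_total,
            "indirect": res.indirect, "se_indirect": res.se_indirect,
            "proportion": res.proportion,
            "proportion_ci_low": res.proportion_ci[0],
            "proportion_ci_high": res.proportion_ci[1],
            "direction_ok": res.direction_ok,
        })
    out = pd.DataFrame(rows, columns=[
        "mediator", "beta1", "se1", "beta2", "se2", "beta_total",
        "indirect", "se_indirect", "proportion",
        "proportion_ci_low", "proportion_ci_high", "direction_ok",
    ])
    if len(out):
        out = out.reindex(out["proportion"].abs().sort_values(ascending=False).index)
        out = out.reset_index(drop=True)
    return out
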