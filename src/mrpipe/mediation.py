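"""Two-step MR mediation via the product-of-coefficients method.

Step 1 estimates the exposure's effect on the mediator (alpha) with the
exposure's instruments.  Step 2 estimates the mediator's direct effect on
the outcome (beta_m), adjusted for the exposure, by multivariable MR on
the mediator's instruments.  The indirect effect is alpha·beta_m with a
first-order delta-method SE (zero covariance across non-overlapping
samples), and the mediated proportion is indirect / total.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .harmonization import harmonize
from .mr_core import Z95, ivw_random_effects
from .mvmr import assemble_mvmr_input, mvmr_ivw
from .summary_io import GENOME_WIDE_P, GwasDataset, select_instruments

logger = logging.getLogger(__name__)

#: |total| below this makes the mediated proportion numerically undefined
TOTAL_EFFECT_FLOOR = 1e-10


@dataclass(frozen=True)
class MediationResult:
    """Decomposition of an exposure -> outcome effect through one mediator.

    All effects are on the analysis (log-odds for binary outcomes) scale;
    the mediated proportion is in percent and is NOT clamped to [0, 100] —
    out-of-range values are flagged instead.
    """

    exposure: str
    mediator: str
    outcome: str
    total: float
    se_total: float
    alpha: float
    se_alpha: float
    beta_m: float
    se_beta_m: float
    indirect: float
    se_indirect: float
    proportion: float | None          # percent
    proportion_ci: tuple[float, float] | None
    out_of_range: bool = False


def indirect_se(alpha: float, se_alpha: float, beta_m: float, se_beta_m: float) -> float:
    """Delta-method SE of the product alpha·beta_m (independent estimates)."""
    if se_alpha < 0 or se_beta_m < 0:
        raise ValueError("SEs must be non-negative")
    return math.sqrt(alpha ** 2 * se_beta_m ** 2 + beta_m ** 2 * se_alpha ** 2)


def proportion_ci(indirect: float, se_ind: float, total: float,
                  se_total: float) -> tuple[float, tuple[float, float], bool]:
    """Mediated proportion (percent) with a delta-method 95% CI.

    First-order ratio delta method, numerator–denominator covariance
    ignored.  Returns (proportion, (low, high), out_of_range flag); the
    flag marks CIs straddling 0% or exceeding 100%.
    """
    if total == 0:
        raise ValueError("total effect is zero; proportion undefined")
    prop = indirect / total
    se_prop = math.sqrt(se_ind ** 2 / total ** 2
                        + indirect ** 2 * se_total ** 2 / total ** 4)
    low, high = prop - Z95 * se_prop, prop + Z95 * se_prop
    flag = low < 0.0 or high > 1.0
    return prop * 100.0, (low * 100.0, high * 100.0), flag


def mediate(
    exposure: GwasDataset,
    mediator: GwasDataset,
    outcome: GwasDataset,
    p_threshold: float = GENOME_WIDE_P,
    maf_threshold: float = 0.42,
    outcome_p_threshold: float | None = None,
) -> MediationResult:
    """Two-step MR mediation of exposure -> mediator -> outcome.

    Total effect and alpha come from random-effects IVW on the exposure's
    instruments; beta_m is the mediator's direct effect from MVMR of
    (mediator, exposure) on the outcome using the mediator's instruments.

    ``outcome_p_threshold`` drops instruments primarily associated with
    the downstream trait (default: same as ``p_threshold``).
    """
    out_p = p_threshold if outcome_p_threshold is None else outcome_p_threshold
    instruments = select_instruments(exposure, p_threshold)

    total_res, _ = ivw_random_effects(
        harmonize(instruments, outcome, outcome_p_threshold=out_p,
                  maf_threshold=maf_threshold).pairs)
    alpha_res, _ = ivw_random_effects(
        harmonize(instruments, mediator, outcome_p_threshold=out_p,
                  maf_threshold=maf_threshold).pairs)

    try:
        mv_in = assemble_mvmr_input([mediator, exposure], outcome,
                                    p_threshold=p_threshold,
                                    instrument_source="first")
        beta_m_res = mvmr_ivw(mv_in)[0]
    except ValueError:
        # mediator instruments carry no exposure signal (zero/collinear
        # column): the exposure adjustment is a no-op and the direct
        # mediator effect reduces to univariable IVW
        logger.warning("exposure adjustment degenerate; using univariable "
                       "IVW for the mediator's direct effect")
        med_instruments = select_instruments(mediator, p_threshold)
        beta_m_res, _ = ivw_random_effects(
            harmonize(med_instruments, outcome, outcome_p_threshold=out_p,
                      maf_threshold=maf_threshold).pairs)

    ind = alpha_res.beta * beta_m_res.beta
    se_ind = indirect_se(alpha_res.beta, alpha_res.se, beta_m_res.beta, beta_m_res.se)

    if abs(total_res.beta) < TOTAL_EFFECT_FLOOR:
        logger.warning("total effect ~ 0; mediated proportion undefined")
        prop, ci, flag = None, None, True
    else:
        prop, ci, flag = proportion_ci(ind, se_ind, total_res.beta, total_res.se)

    return MediationResult(
        exposure=exposure.trait_name, mediator=mediator.trait_name,
        outcome=outcome.trait_name,
        total=total_res.beta, se_total=total_res.se,
        alpha=alpha_res.beta, se_alpha=alpha_res.se,
        beta_m=beta_m_res.beta, se_beta_m=beta_m_res.se,
        indirect=ind, se_indirect=se_ind,
        proportion=prop, proportion_ci=ci, out_of_range=flag,
    )
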