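"""Multivariable MR: direct effects of several exposures on one outcome.

Each exposure's direct effect (conditional on the other exposures) is the
corresponding coefficient of a weighted multiple regression, without
intercept, of outcome betas on the matrix of exposure betas across the
pooled instrument set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from . import summary_io
from .harmonization import align_alleles
from .mr_core import MRResult, _result
from .summary_io import GENOME_WIDE_P, GwasDataset

logger = logging.getLogger(__name__)

#: refuse to fit exposure matrices more ill-conditioned than this
MAX_CONDITION = 1e8


@dataclass
class MVMRInput:
    """Instrument-by-exposure effect matrices plus outcome effects.

    All effects are harmonized to a common per-SNP effect allele; SNPs
    with any missing cell were dropped before construction.
    """

    snp_ids: list[str]
    exposure_names: list[str]
    beta_exp: np.ndarray   # (L, K)
    se_exp: np.ndarray     # (L, K)
    beta_out: np.ndarray   # (L,)
    se_out: np.ndarray     # (L,)

    def __post_init__(self) -> None:
        L, K = self.beta_exp.shape
        if L != len(self.snp_ids) or K != len(self.exposure_names):
            raise ValueError("matrix shape inconsistent with labels")
        if np.isnan(self.beta_exp).any() or np.isnan(self.beta_out).any():
            raise ValueError("MVMR input must be complete-case")
        if L <= K + 1:
            raise ValueError(f"need more SNPs ({L}) than exposures + 1 ({K + 1})")


def assemble_mvmr_input(
    exposures: list[GwasDataset],
    outcome: GwasDataset,
    p_threshold: float = GENOME_WIDE_P,
    instrument_source: str = "union",
) -> MVMRInput:
    """Build the MVMR design from per-exposure GWAS plus one outcome GWAS.

    The instrument set is the union of each exposure's genome-wide-
    significant SNPs (``instrument_source="first"`` restricts it to the
    first exposure's instruments, as in two-step mediation).  Every SNP is
    harmonized to the first exposure's allele orientation; SNPs absent
    from any dataset, or failing harmonization anywhere, are dropped and
    logged.
    """
    if len(exposures) < 2:
        raise ValueError("multivariable MR needs at least 2 exposures")
    if instrument_source == "union":
        snp_set: set[str] = set()
        for exp in exposures:
            snp_set |= set(summary_io.select_instruments(exp, p_threshold).snp_ids)
    elif instrument_source == "first":
        snp_set = set(summary_io.select_instruments(exposures[0], p_threshold).snp_ids)
    else:
        raise ValueError(f"unknown instrument_source {instrument_source!r}")

    snp_ids = sorted(snp_set)
    ref = exposures[0]
    rows_b, rows_s, out_b, out_s, kept = [], [], [], [], []
    n_dropped = 0
    for snp in snp_ids:
        if snp not in ref or snp not in outcome or any(snp not in e for e in exposures[1:]):
            n_dropped += 1
            continue
        ref_rec = ref.get(snp)
        betas = [ref_rec.beta]
        ses = [ref_rec.se]
        ok = True
        for exp in exposures[1:]:
            pair = align_alleles(ref_rec, exp.get(snp))
            if pair.excluded:
                ok = False
                break
            betas.append(pair.beta_out)
            ses.append(pair.se_out)
        if not ok:
            n_dropped += 1
            continue
        out_pair = align_alleles(ref_rec, outcome.get(snp))
        if out_pair.excluded:
            n_dropped += 1
            continue
        rows_b.append(betas)
        rows_s.append(ses)
        out_b.append(out_pair.beta_out)
        out_s.append(out_pair.se_out)
        kept.append(snp)
    if n_dropped:
        logger.info("MVMR assembly: dropped %d SNP(s) missing or unharmonizable", n_dropped)

    return MVMRInput(
        snp_ids=kept,
        exposure_names=[e.trait_name for e in exposures],
        beta_exp=np.asarray(rows_b, dtype=float),
        se_exp=np.asarray(rows_s, dtype=float),
        beta_out=np.asarray(out_b, dtype=float),
        se_out=np.asarray(out_s, dtype=float),
    )


def mvmr_ivw(mv_input: MVMRInput) -> list[MRResult]:
    """Per-exposure direct effects by inverse-variance-weighted regression.

    Weighted multiple regression of outcome betas on all exposure-beta
    columns without intercept, weights 1/se_out²; SEs carry multiplicative
    overdispersion floored at 1; two-sided normal p-values.
    """
    X, y = mv_input.beta_exp, mv_input.beta_out
    L, K = X.shape
    cond = np.linalg.cond(X)
    if not np.isfinite(cond) or cond > MAX_CONDITION:
        raise ValueError(f"exposure matrix rank-deficient (condition number {cond:.3g})")

    w = 1.0 / mv_input.se_out ** 2
    fit = sm.WLS(y, X, weights=w).fit()
    scale = float(fit.scale)  # weighted RSS / (L - K)
    se = np.sqrt(np.diag(fit.normalized_cov_params)) * np.sqrt(max(1.0, scale))
    return [
        _result(f"mvmr-ivw[{name}]", L, float(b), float(s))
        for name, b, s in zip(mv_input.exposure_names, fit.params, se)
    ]
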