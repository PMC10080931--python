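"""Univariable MR estimators and heterogeneity / pleiotropy diagnostics.

Estimators operate on harmonized SNP pairs.  The primary analysis is the
multiplicative random-effects inverse-variance-weighted (IVW) estimator;
the weighted median (consistent when >= 50% of the instrument weight is
valid) and MR-Egger regression (whose intercept tests for directional
pleiotropy) serve as sensitivity analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .harmonization import HarmonizedPair

logger = logging.getLogger(__name__)

Z95 = 1.96  # normal quantile used for all 95% intervals


@dataclass(frozen=True)
class MRResult:
    """A causal estimate on the per-unit-exposure scale.

    ``beta`` is log-odds per unit exposure when the outcome is binary;
    ``or_scale`` exponentiates it.
    """

    method: str
    n_snp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float

    @property
    def or_scale(self) -> tuple[float, float, float]:
        return to_odds_ratio(self.beta, self.se)


@dataclass(frozen=True)
class HetStats:
    """Cochran Q heterogeneity statistics with the I² qualitative band."""

    q: float
    df: int
    pval: float
    i2: float

    @property
    def band(self) -> str:
        if self.i2 <= 25.0:
            return "low"
        if self.i2 < 50.0:
            return "moderate"
        return "high"


def _het_stats(q: float, df: int) -> HetStats:
    q = float(max(q, 0.0))
    pval = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HetStats(q=q, df=df, pval=pval, i2=i2)


def _result(method: str, n_snp: int, beta: float, se: float,
            pval: float | None = None, t_df: int | None = None) -> MRResult:
    if pval is None:
        if t_df is not None:
            pval = 2.0 * float(stats.t.sf(abs(beta / se), t_df))
        else:
            pval = 2.0 * float(stats.norm.sf(abs(beta / se)))
    pval = min(max(pval, np.finfo(float).tiny), 1.0)
    return MRResult(method=method, n_snp=n_snp, beta=float(beta), se=float(se),
                    ci_low=float(beta - Z95 * se), ci_high=float(beta + Z95 * se),
                    pval=pval)


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """(OR, 95% CI low, 95% CI high) for a log-odds estimate."""
    if not se > 0:
        raise ValueError("se must be > 0")
    return (math.exp(beta), math.exp(beta - Z95 * se), math.exp(beta + Z95 * se))


def wald_ratio(pair: HarmonizedPair, second_order: bool = False) -> MRResult:
    """Single-SNP ratio estimate: SNP-outcome beta / SNP-exposure beta.

    SE is first-order delta method (se_out / |beta_exp|) by default; the
    second-order form adds the exposure-uncertainty term.
    """
    if pair.beta_exp == 0:
        raise ValueError(f"{pair.snp_id}: zero exposure beta, ratio undefined")
    beta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    if second_order:
        se = math.sqrt(pair.se_out ** 2 / pair.beta_exp ** 2
                       + pair.beta_out ** 2 * pair.se_exp ** 2 / pair.beta_exp ** 4)
    return _result("wald-ratio", 1, beta, se)


def _arrays(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, ...]:
    usable = [p for p in pairs if not p.excluded and p.beta_exp != 0]
    dropped = len(list(pairs)) - len(usable)
    if dropped:
        logger.warning("dropping %d pair(s) with zero exposure beta or exclusion", dropped)
    bx = np.array([p.beta_exp for p in usable])
    sx = np.array([p.se_exp for p in usable])
    by = np.array([p.beta_out for p in usable])
    sy = np.array([p.se_out for p in usable])
    return bx, sx, by, sy


def ivw_random_effects(pairs: Sequence[HarmonizedPair]) -> tuple[MRResult, HetStats]:
    """Multiplicative random-effects IVW estimate with Cochran Q / I².

    Weighted regression of outcome betas on exposure betas through the
    origin, weights 1/se_out²; the fixed-effect SE is inflated by
    sqrt(Q/df) when Q exceeds its degrees of freedom (never deflated).
    A single pair falls back to the Wald ratio.
    """
    bx, sx, by, sy = _arrays(pairs)
    L = bx.size
    if L < 1:
        raise ValueError("no valid pairs for IVW")
    if L == 1:
        res = wald_ratio([p for p in pairs if not p.excluded and p.beta_exp != 0][0])
        return _result("ivw-re", 1, res.beta, res.se), _het_stats(0.0, 0)

    w = 1.0 / sy ** 2
    theta = float(np.sum(w * bx * by) / np.sum(w * bx ** 2))
    se_fe = float(1.0 / np.sqrt(np.sum(w * bx ** 2)))
    q = float(np.sum(w * (by - theta * bx) ** 2))
    df = L - 1
    se_re = se_fe * math.sqrt(max(1.0, q / df))
    return _result("ivw-re", L, theta, se_re), _het_stats(q, df)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation at cumulative weight 0.5."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, p, v))


def weighted_median(pairs: Sequence[HarmonizedPair], n_boot: int = 1000,
                    seed: int | None = None) -> MRResult:
    """Weighted-median estimate over per-SNP Wald ratios.

    Weights are inverse-variance (first-order ratio SEs); the SE comes
    from a seeded parametric bootstrap resampling per-SNP exposure and
    outcome betas from their sampling distributions.
    """
    bx, sx, by, sy = _arrays(pairs)
    L = bx.size
    if L < 3:
        raise ValueError("weighted median needs at least 3 pairs")
    if n_boot < 100:
        logger.warning("n_boot=%d is small; bootstrap SE will be noisy", n_boot)
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed for reproducibility")

    ratios = by / bx
    w = (bx / sy) ** 2  # 1 / se_ratio²
    est = _weighted_median(ratios, w)

    rng = np.random.default_rng(seed)
    bx_d = rng.normal(bx, sx, size=(n_boot, L))
    by_d = rng.normal(by, sy, size=(n_boot, L))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        ok = bx_d[b] != 0
        r = by_d[b, ok] / bx_d[b, ok]
        ww = (bx_d[b, ok] / sy[ok]) ** 2
        boots[b] = _weighted_median(r, ww)
    se = float(np.std(boots, ddof=1))
    return _result("weighted-median", L, est, se)


def egger(pairs: Sequence[HarmonizedPair]) -> tuple[MRResult, MRResult, HetStats]:
    """MR-Egger regression: (slope, intercept, heterogeneity).

    Weighted regression of outcome betas on exposure betas with an
    intercept (weights 1/se_out²), exposure betas oriented non-negative
    first.  A non-zero intercept indicates directional pleiotropy.
    SEs carry multiplicative overdispersion floored at 1; p-values use
    t with L-2 degrees of freedom.
    """
    bx, sx, by, sy = _arrays(pairs)
    L = bx.size
    if L < 3:
        raise ValueError("MR-Egger needs at least 3 pairs")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.ptp(bx) == 0:
        raise ValueError("all exposure betas equal; Egger slope unidentifiable")

    w = 1.0 / sy ** 2
    fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
    # residual overdispersion (RSS_w / (L-2)) inflates SEs, floored at 1
    scale = float(fit.scale)
    se_unscaled = np.sqrt(np.diag(fit.normalized_cov_params))
    se_int, se_slope = se_unscaled * math.sqrt(max(1.0, scale))
    b_int, b_slope = fit.params
    q = scale * (L - 2)
    slope = _result("egger-slope", L, b_slope, se_slope, t_df=L - 2)
    intercept = _result("egger-intercept", L, b_int, se_int, t_df=L - 2)
    return slope, intercept, _het_stats(q, L - 2)
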