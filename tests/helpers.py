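"""Shared builders and independent numerical oracles for the test suite.

Oracles deliberately avoid the library's code paths: weighted least
squares goes through scaled ``np.linalg.lstsq`` normal systems, and the
weighted median through a linear scan of the interpolated cumulative
weight function.
"""

from __future__ import annotations

import numpy as np

from mrpipe.harmonization import HarmonizedPair
from mrpipe.summary_io import GwasRecord


def make_record(snp="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.01,
                pval=1e-10, n=100_000, n_case=None) -> GwasRecord:
    return GwasRecord(snp_id=snp, effect_allele=ea, other_allele=oa, eaf=eaf,
                      beta=beta, se=se, pval=pval, n=n, n_case=n_case)


def make_pairs(bx, by, sy, sx=None, pval_out=0.5) -> list[HarmonizedPair]:
    bx, by, sy = map(np.atleast_1d, (bx, by, sy))
    sx = np.full_like(bx, 1e-6, dtype=float) if sx is None else np.atleast_1d(sx)
    return [
        HarmonizedPair(
            snp_id=f"rs{i + 1:04d}", effect_allele="A", other_allele="G",
            beta_exp=float(x), se_exp=float(s_x), eaf_exp=0.3, n_exp=100_000,
            beta_out=float(y), se_out=float(s_y), eaf_out=0.3, n_out=100_000,
            pval_out=pval_out,
        )
        for i, (x, y, s_x, s_y) in enumerate(zip(bx, by, sx, sy))
    ]


# ---------------------------------------------------------------- oracles

def wls_origin_oracle(bx, by, w):
    """No-intercept weighted least squares via a scaled lstsq system.

    Returns (coef, unscaled se) — the fixed-effect solution.
    """
    sw = np.sqrt(np.asarray(w, dtype=float))
    X = (sw * np.asarray(bx, dtype=float))[:, None]
    y = sw * np.asarray(by, dtype=float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    cov = np.linalg.inv(X.T @ X)
    return float(coef[0]), float(np.sqrt(cov[0, 0]))


def wls_intercept_oracle(bx, by, w):
    """Weighted least squares with intercept; returns params, unscaled SEs,
    and the weighted residual sum of squares."""
    sw = np.sqrt(np.asarray(w, dtype=float))
    X = np.column_stack([sw, sw * np.asarray(bx, dtype=float)])
    y = sw * np.asarray(by, dtype=float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    cov = np.linalg.inv(X.T @ X)
    return coef, np.sqrt(np.diag(cov)), float(resid @ resid)


def wls_multi_oracle(X, y, w):
    """No-intercept multiple weighted least squares; params and unscaled SEs."""
    sw = np.sqrt(np.asarray(w, dtype=float))[:, None]
    Xs = sw * np.asarray(X, dtype=float)
    ys = (sw[:, 0]) * np.asarray(y, dtype=float)
    coef, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    cov = np.linalg.inv(Xs.T @ Xs)
    return coef, np.sqrt(np.diag(cov))


def weighted_median_oracle(values, weights):
    """Interpolated weighted median by linear scan of the cumulative-weight
    function, solving the crossing segment exactly."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    v, w = values[order], weights[order]
    total = w.sum()
    p = (np.cumsum(w) - 0.5 * w) / total
    if p[0] >= 0.5:
        return float(v[0])
    for i in range(len(v) - 1):
        if p[i] <= 0.5 <= p[i + 1]:
            if p[i + 1] == p[i]:
                return float(v[i])
            frac = (0.5 - p[i]) / (p[i + 1] - p[i])
            return float(v[i] + frac * (v[i + 1] - v[i]))
    return float(v[-1])
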