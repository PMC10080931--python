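"""Instrument-strength (R², F) and statistical-power diagnostics.

Per-SNP variance explained uses the standard summary-statistic formula

    R² = 2·EAF·(1−EAF)·beta² / (2·EAF·(1−EAF)·beta² + 2·EAF·(1−EAF)·N·se²)

which algebraically reduces to z²/(z²+N); instrument strength is
F = R²·(N−2)/(1−R²), with F ≥ 10 the conventional weak-instrument floor.
Power for a binary outcome uses a normal approximation on the log-odds
scale with non-centrality |ln OR|·sqrt(N·R²·K·(1−K)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .summary_io import GwasDataset, GwasRecord

logger = logging.getLogger(__name__)

#: conventional weak-instrument threshold
F_WEAK = 10.0


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for a binary-outcome power calculation.

    n_total: outcome GWAS size; case_fraction: cases / n_total;
    r2_exposure: variance in the exposure explained by the instruments;
    odds_ratio: detectable OR per unit exposure; alpha: two-sided level.
    """

    n_total: int
    case_fraction: float
    r2_exposure: float
    odds_ratio: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name, v in (("case_fraction", self.case_fraction),
                        ("r2_exposure", self.r2_exposure),
                        ("alpha", self.alpha)):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not self.odds_ratio > 0:
            raise ValueError("odds_ratio must be > 0")
        if not self.n_total > 0:
            raise ValueError("n_total must be positive")


def variance_explained(record: GwasRecord) -> float:
    """Per-SNP fraction of exposure variance explained."""
    if record.eaf is None:
        raise ValueError(f"{record.snp_id}: EAF missing, R² undefined")
    if not 0.0 < record.eaf < 1.0:
        raise ValueError(f"{record.snp_id}: EAF must be in (0, 1)")
    if record.n < 3:
        raise ValueError(f"{record.snp_id}: need n >= 3")
    het = 2.0 * record.eaf * (1.0 - record.eaf)
    num = het * record.beta ** 2
    return num / (num + het * record.n * record.se ** 2)


def f_statistic(r2: float, n: int) -> float:
    """Instrument-strength F statistic from variance explained."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError(f"r2 must be in [0, 1), got {r2}")
    if n < 3:
        raise ValueError("need n >= 3")
    return r2 * (n - 2) / (1.0 - r2)


def mr_power_binary(spec: PowerSpec) -> float:
    """Two-sided power to detect the given OR for a binary outcome.

    z = |ln OR|·sqrt(N·R²·K·(1−K)); power = Φ(z−z_c) + Φ(−z−z_c) with z_c
    the upper alpha/2 normal quantile.  At OR = 1 power equals alpha.
    """
    k = spec.case_fraction
    z = abs(math.log(spec.odds_ratio)) * math.sqrt(
        spec.n_total * spec.r2_exposure * k * (1.0 - k))
    z_c = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(z - z_c) + stats.norm.cdf(-z - z_c))


def qc_table(instruments: GwasDataset) -> pd.DataFrame:
    """Per-SNP R² and F table; SNPs with missing EAF are flagged and skipped."""
    rows = []
    n_missing = 0
    for rec in instruments.records():
        if rec.eaf is None or not 0.0 < rec.eaf < 1.0:
            n_missing += 1
            rows.append({"snp_id": rec.snp_id, "r2": np.nan, "f_stat": np.nan,
                         "weak": np.nan})
            continue
        r2 = variance_explained(rec)
        f = f_statistic(r2, rec.n)
        rows.append({"snp_id": rec.snp_id, "r2": r2, "f_stat": f,
                     "weak": f < F_WEAK})
    if n_missing:
        logger.warning("%s: %d SNP(s) missing EAF, skipped in R² aggregation",
                       instruments.trait_name, n_missing)
    return pd.DataFrame(rows, columns=["snp_id", "r2", "f_stat", "weak"])


def aggregate_r2(instruments: GwasDataset) -> float:
    """Total variance explained: sum of per-SNP R² (independent instruments)."""
    tab = qc_table(instruments)
    return float(tab["r2"].sum(skipna=True))


def mean_f(instruments: GwasDataset) -> float:
    tab = qc_table(instruments)
    return float(tab["f_stat"].mean(skipna=True))
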