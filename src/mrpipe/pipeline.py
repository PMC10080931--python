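"""Workflow orchestration: univariable MR over outcome panels, Bonferroni
significance classification, and report tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .harmonization import HarmonizationResult, ProxyRecord, harmonize
from .mr_core import egger, ivw_random_effects, to_odds_ratio, weighted_median
from .summary_io import GENOME_WIDE_P, GwasDataset, select_instruments

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "outcome", "method", "n_snp", "beta", "se", "or", "ci_low", "ci_high",
    "pval", "q", "q_df", "q_pval", "i2", "het_band", "significance",
]


@dataclass
class AnalysisConfig:
    """Thresholds and run settings; defaults follow the study design
    (instrument p < 5e-8, palindromic MAF > 0.42 excluded, proxy r² > 0.60,
    family-wise alpha 0.05 over 5 primary outcomes, 4 for stroke subtypes)."""

    instrument_p: float = GENOME_WIDE_P
    outcome_p: float = GENOME_WIDE_P
    palindromic_maf: float = 0.42
    proxy_r2: float = 0.60
    alpha: float = 0.05
    family_size: int = 5
    methods: tuple[str, ...] = ("ivw-re", "weighted-median", "egger")
    n_boot: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        if "methods" in known:
            known["methods"] = tuple(known["methods"])
        return cls(**known)

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.family_size


def classify_significance(pval: float, family_size: int, alpha: float = 0.05) -> str:
    """Bonferroni classification: ``significant`` below alpha/family_size,
    ``suggestive`` below alpha, otherwise ``null``.

    The family-size-4 threshold 0.0125 is conventionally reported rounded
    to 0.013 but compared at full precision.
    """
    if not 0.0 < pval <= 1.0:
        raise ValueError(f"invalid p-value {pval}")
    if pval < alpha / family_size:
        return "significant"
    if pval < alpha:
        return "suggestive"
    return "null"


def _rows_for_outcome(outcome_name: str, pairs, config: AnalysisConfig) -> list[dict]:
    rows = []

    def row(method, res, het=None):
        or_, lo, hi = res.or_scale
        rows.append({
            "outcome": outcome_name, "method": method, "n_snp": res.n_snp,
            "beta": res.beta, "se": res.se, "or": or_, "ci_low": lo,
            "ci_high": hi, "pval": res.pval,
            "q": het.q if het else np.nan, "q_df": het.df if het else np.nan,
            "q_pval": het.pval if het else np.nan,
            "i2": het.i2 if het else np.nan,
            "het_band": het.band if het else "",
            "significance": classify_significance(res.pval, config.family_size,
                                                  config.alpha),
        })

    if "ivw-re" in config.methods:
        res, het = ivw_random_effects(pairs)
        row("ivw-re", res, het)
    if "weighted-median" in config.methods:
        row("weighted-median",
            weighted_median(pairs, n_boot=config.n_boot, seed=config.seed))
    if "egger" in config.methods:
        slope, intercept, het = egger(pairs)
        row("egger-slope", slope, het)
        row("egger-intercept", intercept)
    return rows


def run_univariable(
    exposure: GwasDataset,
    outcomes: Sequence[GwasDataset],
    config: AnalysisConfig | None = None,
    proxies: Sequence[ProxyRecord] = (),
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Univariable MR of one exposure against a panel of outcomes.

    Returns (results table, per-SNP exclusion log, per-outcome errors).
    A fatal error in one outcome aborts that outcome only.
    """
    config = config or AnalysisConfig()
    instruments = select_instruments(exposure, config.instrument_p)

    all_rows: list[dict] = []
    log_rows: list[pd.DataFrame] = []
    errors: dict[str, str] = {}
    for outcome in outcomes:
        try:
            harm = harmonize(
                instruments, outcome, proxies=proxies,
                maf_threshold=config.palindromic_maf,
                outcome_p_threshold=config.outcome_p, r2_min=config.proxy_r2)
            lf = harm.log_frame()
            lf.insert(0, "outcome", outcome.trait_name)
            log_rows.append(lf)
            all_rows.extend(_rows_for_outcome(outcome.trait_name, harm.pairs, config))
        except Exception as exc:  # pragma: no cover - defensive per-outcome isolation
            logger.error("outcome %s failed: %s", outcome.trait_name, exc)
            errors[outcome.trait_name] = str(exc)

    results = pd.DataFrame(all_rows, columns=RESULT_COLUMNS)
    log = (pd.concat(log_rows, ignore_index=True) if log_rows
           else pd.DataFrame(columns=["outcome", "snp_id", "reason"]))
    return results, log, errors


def format_or_ci(beta: float, se: float) -> str:
    """Render a log-scale estimate as ``OR (CI_low–CI_high)`` to 3 decimals."""
    or_, lo, hi = to_odds_ratio(beta, se)
    return f"{or_:.3f} ({lo:.3f}–{hi:.3f})"


def run_report(results: pd.DataFrame, path: str | Path | None = None) -> pd.DataFrame:
    """Human-readable report table with deterministic column order.

    ORs and CIs to 3 decimals; p-values in scientific notation.
    """
    if results.empty:
        report = pd.DataFrame(columns=["outcome", "method", "n_snp", "or_ci",
                                       "pval", "q", "q_pval", "i2", "significance"])
    else:
        report = pd.DataFrame({
            "outcome": results["outcome"],
            "method": results["method"],
            "n_snp": results["n_snp"],
            "or_ci": [format_or_ci(b, s) for b, s in
                      zip(results["beta"], results["se"])],
            "pval": [f"{p:.2e}" for p in results["pval"]],
            "q": [("" if np.isnan(q) else f"{q:.2f}") for q in results["q"]],
            "q_pval": [("" if np.isnan(p) else f"{p:.3g}") for p in results["q_pval"]],
            "i2": [("" if np.isnan(i) else f"{i:.1f}") for i in results["i2"]],
            "significance": results["significance"],
        })
    if path is not None:
        report.to_csv(path, sep="\t", index=False)
    return report


def plot_forest(results: pd.DataFrame, path: str | Path,
                method: str = "ivw-re") -> None:
    """Forest plot of per-outcome ORs for one method."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = results[results["method"] == method].reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(6, 0.6 * max(2, len(sub)) + 1))
    y = np.arange(len(sub))[::-1]
    ax.errorbar(sub["or"], y,
                xerr=[sub["or"] - sub["ci_low"], sub["ci_high"] - sub["or"]],
                fmt="s", color="black", capsize=3)
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(sub["outcome"])
    ax.set_xlabel("Odds ratio per unit exposure (95% CI)")
    ax.set_title(method)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
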