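"""Synthetic two-sample GWAS summary statistics with known ground truth.

Emulates the statistical structure of the real inputs: per-SNP exposure
effects with sampling noise, outcome effects theta x (true exposure
effect) + pleiotropy + noise, standard errors scaled by sample size,
allele frequency and (for binary traits) case fraction, plus allele-
orientation corruption (reported-allele swaps, strand flips, palindromic
SNPs) so the harmonization stage can be tested against a known
orientation.

Traits are standardized (betas in SD units; binary outcomes on the
log-odds scale), giving the asymptotic standard errors
se = 1/sqrt(2 f (1-f) N) and, for binary outcomes, an extra K(1-K)
efficiency factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .summary_io import GwasDataset

PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
NON_PALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SynthConfig:
    """Study conditions for the generator.

    Defaults emulate a large exposure GWAS feeding a binary-outcome MR:
    100 instruments on a standardized exposure (per-SNP effects of a few
    hundredths of an SD, per-SNP F in the tens), exposure N 400k, outcome
    N 500k at 10% case fraction, causal log-OR -0.3 per SD.
    """

    n_snps: int = 100
    theta_true: float = -0.3
    gamma_mean: float = 0.02
    gamma_sd: float = 0.005
    pleio_frac: float = 0.0          # fraction of invalid instruments
    pleio_mean: float = 0.0          # directional pleiotropy
    pleio_sd: float = 0.0            # balanced pleiotropy
    n_exposure: int = 400_000
    n_outcome: int = 500_000
    outcome_type: str = "binary"     # binary | continuous
    case_fraction: float = 0.10
    maf_range: tuple[float, float] = (0.05, 0.5)
    swap_frac: float = 0.30          # effect/other allele order swapped in outcome file
    flip_frac: float = 0.10          # outcome file on the opposite strand
    palindromic_frac: float = 0.15   # A/T or C/G allele pairs
    sampling_noise: bool = True
    seed: int | None = None
    # mediation block
    alpha_true: float = 0.3          # exposure -> mediator
    beta_m_true: float = -0.27       # mediator -> outcome, direct
    direct_true: float = -0.28       # exposure -> outcome, not through mediator
    n_mediator: int = 300_000
    n_snps_mediator: int = 60

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SynthConfig requires an explicit seed")
        if self.n_snps < 3:
            raise ValueError("need at least 3 SNPs")
        lo, hi = self.maf_range
        if not 0.0 < lo < hi <= 0.5:
            raise ValueError(f"degenerate maf_range {self.maf_range}")
        for name in ("pleio_frac", "swap_frac", "flip_frac", "palindromic_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.outcome_type not in ("binary", "continuous"):
            raise ValueError("outcome_type must be binary|continuous")


@dataclass
class TwoSampleTruth:
    """Ground truth retained by the generator (uncorrupted orientation)."""

    theta: float
    snp_id: np.ndarray
    gamma: np.ndarray          # true SNP-exposure effects
    pleiotropy: np.ndarray     # direct SNP-outcome effects
    invalid: np.ndarray        # bool, pleiotropic instruments
    eaf: np.ndarray            # true effect-allele frequency (exposure orientation)
    palindromic: np.ndarray    # bool
    swapped: np.ndarray        # bool, outcome file lists alleles in reverse order
    flipped_strand: np.ndarray # bool, outcome file on opposite strand


@dataclass
class MediationTruth:
    alpha: float
    beta_m: float
    direct: float

    @property
    def indirect(self) -> float:
        return self.alpha * self.beta_m

    @property
    def total(self) -> float:
        return self.direct + self.indirect

    @property
    def proportion(self) -> float:
        """Mediated proportion in percent."""
        return 100.0 * self.indirect / self.total


def _standard_se(eaf: np.ndarray, n: int, case_fraction: float | None = None) -> np.ndarray:
    var = 2.0 * eaf * (1.0 - eaf) * n
    if case_fraction is not None:
        var = var * case_fraction * (1.0 - case_fraction)
    return 1.0 / np.sqrt(var)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _alleles(rng: np.random.Generator, n: int, palindromic_frac: float
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pal = rng.random(n) < palindromic_frac
    ea = np.empty(n, dtype="<U1")
    oa = np.empty(n, dtype="<U1")
    pick_pal = rng.integers(0, len(PALINDROMIC_PAIRS), size=n)
    pick_np = rng.integers(0, len(NON_PALINDROMIC_PAIRS), size=n)
    for i in range(n):
        pair = (PALINDROMIC_PAIRS[pick_pal[i]] if pal[i]
                else NON_PALINDROMIC_PAIRS[pick_np[i]])
        ea[i], oa[i] = pair
    return ea, oa, pal


def _dataset(trait: str, trait_type: str, snp_id, ea, oa, eaf, beta, se, n,
             n_case=None) -> GwasDataset:
    tab = pd.DataFrame({
        "snp_id": snp_id, "effect_allele": ea, "other_allele": oa,
        "eaf": eaf, "beta": beta, "se": se, "pval": _pvals(beta, se),
        "n": np.full(len(beta), n, dtype=np.int64),
        "n_case": np.nan if n_case is None else float(n_case),
    })
    return GwasDataset(trait, trait_type, tab)


def _corrupt(rng: np.random.Generator, ea, oa, eaf, beta, swap_frac, flip_frac,
             ) -> tuple[np.ndarray, ...]:
    """Re-express records with swapped allele order and/or strand flips.

    Both are pure representation changes; the implied association is
    unchanged, which is what harmonization must recover.
    """
    n = len(beta)
    swap = rng.random(n) < swap_frac
    flip = rng.random(n) < flip_frac
    ea, oa = ea.copy(), oa.copy()
    eaf, beta = eaf.copy(), beta.copy()
    # swap: list the other allele as the effect allele
    ea[swap], oa[swap] = oa[swap].copy(), ea[swap].copy()
    beta[swap] = -beta[swap]
    eaf[swap] = 1.0 - eaf[swap]
    # strand flip: complement both alleles, numbers unchanged
    for i in np.nonzero(flip)[0]:
        ea[i], oa[i] = COMPLEMENT[ea[i]], COMPLEMENT[oa[i]]
    return ea, oa, eaf, beta, swap, flip


def _observed_eaf(rng, eaf, n, noise: bool) -> np.ndarray:
    if not noise:
        return eaf.copy()
    sd = np.sqrt(eaf * (1.0 - eaf) / (2.0 * n))
    return np.clip(rng.normal(eaf, sd), 1e-3, 1.0 - 1e-3)


def simulate_two_sample(config: SynthConfig
                        ) -> tuple[GwasDataset, GwasDataset, TwoSampleTruth]:
    """Generate matched exposure and outcome summary statistics.

    Returns (exposure dataset, outcome dataset, truth record); the outcome
    file carries the configured allele-orientation corruption while the
    truth record keeps the exposure orientation.
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_snps
    snp_id = np.array([f"rs{i + 1:06d}" for i in range(L)])

    maf = rng.uniform(*config.maf_range, size=L)
    eaf = np.where(rng.random(L) < 0.5, maf, 1.0 - maf)
    ea, oa, pal = _alleles(rng, L, config.palindromic_frac)

    gamma = rng.normal(config.gamma_mean, config.gamma_sd, size=L)
    invalid = rng.random(L) < config.pleio_frac
    pleio = np.where(invalid, rng.normal(config.pleio_mean, config.pleio_sd, size=L), 0.0)

    se_x = _standard_se(eaf, config.n_exposure)
    k = config.case_fraction if config.outcome_type == "binary" else None
    se_y = _standard_se(eaf, config.n_outcome, k)
    if config.sampling_noise:
        bx = rng.normal(gamma, se_x)
        by = rng.normal(config.theta_true * gamma + pleio, se_y)
    else:
        bx = gamma.copy()
        by = config.theta_true * gamma + pleio

    eaf_x = _observed_eaf(rng, eaf, config.n_exposure, config.sampling_noise)
    eaf_y = _observed_eaf(rng, eaf, config.n_outcome, config.sampling_noise)

    exposure = _dataset("exposure", "continuous", snp_id, ea, oa, eaf_x, bx,
                        se_x, config.n_exposure)
    ea_y, oa_y, eaf_y, by, swap, flip = _corrupt(
        rng, ea, oa, eaf_y, by, config.swap_frac, config.flip_frac)
    n_case = (round(config.case_fraction * config.n_outcome)
              if config.outcome_type == "binary" else None)
    outcome = _dataset("outcome", config.outcome_type, snp_id, ea_y, oa_y,
                       eaf_y, by, se_y, config.n_outcome, n_case)

    truth = TwoSampleTruth(
        theta=config.theta_true, snp_id=snp_id, gamma=gamma, pleiotropy=pleio,
        invalid=invalid, eaf=eaf, palindromic=pal, swapped=swap,
        flipped_strand=flip,
    )
    return exposure, outcome, truth


def simulate_mediation_chain(config: SynthConfig
                             ) -> tuple[GwasDataset, GwasDataset, GwasDataset, MediationTruth]:
    """Generate exposure, mediator and outcome GWAS for a mediation chain.

    Exposure instruments affect the mediator through the exposure
    (alpha_true) and the outcome both directly (direct_true) and through
    the mediator (beta_m_true); a second block of SNPs affects the
    mediator only, providing step-2 instruments.  The three GWAS use
    independent samples, honoring the two-sample independence the
    delta-method SEs assume.
    """
    rng = np.random.default_rng(config.seed)
    L, M = config.n_snps, config.n_snps_mediator
    total = L + M
    snp_id = np.array([f"rs{i + 1:06d}" for i in range(total)])

    maf = rng.uniform(*config.maf_range, size=total)
    eaf = np.where(rng.random(total) < 0.5, maf, 1.0 - maf)
    ea, oa, _pal = _alleles(rng, total, config.palindromic_frac)

    gamma = np.zeros(total)
    gamma[:L] = rng.normal(config.gamma_mean, config.gamma_sd, size=L)
    gamma_m = config.alpha_true * gamma
    gamma_m[L:] = rng.normal(config.gamma_mean, config.gamma_sd, size=M)
    gamma_y = config.direct_true * gamma + config.beta_m_true * gamma_m

    se_x = _standard_se(eaf, config.n_exposure)
    se_m = _standard_se(eaf, config.n_mediator)
    k = config.case_fraction if config.outcome_type == "binary" else None
    se_y = _standard_se(eaf, config.n_outcome, k)

    if config.sampling_noise:
        bx = rng.normal(gamma, se_x)
        bm = rng.normal(gamma_m, se_m)
        by = rng.normal(gamma_y, se_y)
    else:
        bx, bm, by = gamma.copy(), gamma_m.copy(), gamma_y.copy()

    exposure = _dataset("exposure", "continuous", snp_id, ea, oa,
                        _observed_eaf(rng, eaf, config.n_exposure, config.sampling_noise),
                        bx, se_x, config.n_exposure)

    eaf_m = _observed_eaf(rng, eaf, config.n_mediator, config.sampling_noise)
    ea_m, oa_m, eaf_m, bm, _, _ = _corrupt(rng, ea, oa, eaf_m, bm,
                                           config.swap_frac, config.flip_frac)
    mediator = _dataset("mediator", "continuous", snp_id, ea_m, oa_m, eaf_m,
                        bm, se_m, config.n_mediator)

    eaf_y = _observed_eaf(rng, eaf, config.n_outcome, config.sampling_noise)
    ea_y, oa_y, eaf_y, by, _, _ = _corrupt(rng, ea, oa, eaf_y, by,
                                           config.swap_frac, config.flip_frac)
    n_case = (round(config.case_fraction * config.n_outcome)
              if config.outcome_type == "binary" else None)
    outcome = _dataset("outcome", config.outcome_type, snp_id, ea_y, oa_y,
                       eaf_y, by, se_y, config.n_outcome, n_case)

    truth = MediationTruth(alpha=config.alpha_true, beta_m=config.beta_m_true,
                           direct=config.direct_true)
    return exposure, mediator, outcome, truth


def write_truth(truth: TwoSampleTruth, path: str | Path) -> None:
    """Sidecar table with the generator's per-SNP ground truth."""
    pd.DataFrame({
        "snp_id": truth.snp_id, "gamma": truth.gamma,
        "pleiotropy": truth.pleiotropy, "invalid": truth.invalid,
        "eaf": truth.eaf, "palindromic": truth.palindromic,
        "swapped": truth.swapped, "flipped_strand": truth.flipped_strand,
        "theta": truth.theta,
    }).to_csv(path, sep="\t", index=False)
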