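"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR needs exposure and outcome effects expressed on the same
effect allele.  Source GWAS may report the opposite allele (swap), the
opposite strand (complement), or both; palindromic SNPs (A/T, C/G) cannot
be strand-resolved from alleles alone and are handled by effect-allele
frequency concordance, with ambiguous high-MAF palindromes excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .summary_io import GENOME_WIDE_P, GwasDataset, GwasRecord, VALID_BASES

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: palindromes whose minor-allele frequency exceeds this are ambiguous
PALINDROME_MAF_MAX = 0.42
#: minimum LD r-squared for an acceptable proxy (strict >)
PROXY_R2_MIN = 0.60

# exclusion reasons
PALINDROMIC_AMBIGUOUS = "palindromic-ambiguous"
ALLELE_MISMATCH = "allele-mismatch"
OUTCOME_ASSOCIATED = "outcome-associated"
MISSING_NO_PROXY = "missing-no-proxy"


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one SNP on a common effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    eaf_exp: float | None
    n_exp: int
    beta_out: float
    se_out: float
    eaf_out: float | None
    n_out: int
    pval_out: float
    status: str = "kept"            # kept | flipped | proxy-substituted
    exclusion_reason: str | None = None
    proxy_snp: str | None = None

    @property
    def excluded(self) -> bool:
        return self.exclusion_reason is not None

    def exclude(self, reason: str) -> "HarmonizedPair":
        return replace(self, exclusion_reason=reason)


@dataclass(frozen=True)
class ProxyRecord:
    """An LD proxy available when an instrument is absent from the outcome GWAS."""

    query_snp: str
    proxy_snp: str
    r2: float
    allele_map: dict[str, str]  # query allele -> proxy allele

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"proxy {self.proxy_snp}: r2 outside [0, 1]")
        if len(self.allele_map) != 2 or len(set(self.allele_map.values())) != 2:
            raise ValueError(f"proxy {self.proxy_snp}: allele_map must be a bijection on two alleles")


def is_palindromic(record: GwasRecord) -> bool:
    """True iff the allele pair is its own reverse complement ({A,T} or {C,G})."""
    return COMPLEMENT[record.effect_allele] == record.other_allele


def _pair(exp: GwasRecord, out: GwasRecord, beta_out: float, eaf_out: float | None,
          status: str) -> HarmonizedPair:
    return HarmonizedPair(
        snp_id=exp.snp_id,
        effect_allele=exp.effect_allele,
        other_allele=exp.other_allele,
        beta_exp=exp.beta, se_exp=exp.se, eaf_exp=exp.eaf, n_exp=exp.n,
        beta_out=beta_out, se_out=out.se, eaf_out=eaf_out, n_out=out.n,
        pval_out=out.pval, status=status,
    )


def align_alleles(exp: GwasRecord, out: GwasRecord) -> HarmonizedPair:
    """Express the outcome effect on the exposure's effect allele.

    Same orientation -> kept; swapped alleles -> outcome beta negated and
    EAF reflected; a strand-complemented non-palindromic pair is first
    complemented; palindromic SNPs are resolved by EAF concordance (same
    side of 0.5 -> kept, opposite -> flipped; missing or 0.5 EAF ->
    excluded as ambiguous).  Irreconcilable alleles are excluded.
    """
    if exp.snp_id != out.snp_id:
        raise ValueError(f"snp_id mismatch: {exp.snp_id} vs {out.snp_id}")

    ee, eo = exp.effect_allele, exp.other_allele
    oe, oo = out.effect_allele, out.other_allele

    if is_palindromic(exp):
        if {oe, oo} != {ee, eo}:
            return _pair(exp, out, out.beta, out.eaf, "kept").exclude(ALLELE_MISMATCH)
        # strand is unknowable from alleles; use EAF concordance
        if exp.eaf is None or out.eaf is None or exp.eaf == 0.5 or out.eaf == 0.5:
            return _pair(exp, out, out.beta, out.eaf, "kept").exclude(PALINDROMIC_AMBIGUOUS)
        # orient the reported outcome effect onto the exposure's effect allele
        beta, eaf = (out.beta, out.eaf) if oe == ee else (-out.beta, 1.0 - out.eaf)
        same_side = (exp.eaf - 0.5) * (eaf - 0.5) > 0
        if same_side:
            status = "kept" if oe == ee else "flipped"
            return _pair(exp, out, beta, eaf, status)
        status = "flipped" if oe == ee else "kept"
        return _pair(exp, out, -beta, 1.0 - eaf, status)

    if (oe, oo) == (ee, eo):
        return _pair(exp, out, out.beta, out.eaf, "kept")
    if (oe, oo) == (eo, ee):
        eaf = None if out.eaf is None else 1.0 - out.eaf
        return _pair(exp, out, -out.beta, eaf, "flipped")
    ce, co = COMPLEMENT[oe], COMPLEMENT[oo]
    if (ce, co) == (ee, eo):
        return _pair(exp, out, out.beta, out.eaf, "kept")
    if (ce, co) == (eo, ee):
        eaf = None if out.eaf is None else 1.0 - out.eaf
        return _pair(exp, out, -out.beta, eaf, "flipped")
    return _pair(exp, out, out.beta, out.eaf, "kept").exclude(ALLELE_MISMATCH)


def filter_palindromic(pairs: Iterable[HarmonizedPair],
                       maf_threshold: float = PALINDROME_MAF_MAX) -> list[HarmonizedPair]:
    """Exclude palindromic pairs whose exposure-side MAF is above the threshold.

    MAF exactly at the threshold is retained (exclusion requires MAF strictly
    above).  Non-palindromic pairs pass untouched.
    """
    out = []
    for p in pairs:
        if p.excluded:
            out.append(p)
            continue
        palindromic = COMPLEMENT[p.effect_allele] == p.other_allele
        if palindromic:
            if p.eaf_exp is None:
                out.append(p.exclude(PALINDROMIC_AMBIGUOUS))
                continue
            maf = min(p.eaf_exp, 1.0 - p.eaf_exp)
            if maf > maf_threshold:
                out.append(p.exclude(PALINDROMIC_AMBIGUOUS))
                continue
        out.append(p)
    return out


def exclude_outcome_associated(pairs: Iterable[HarmonizedPair],
                               p_threshold: float = GENOME_WIDE_P) -> list[HarmonizedPair]:
    """Exclude SNPs primarily associated with the outcome (outcome p < threshold)."""
    return [p if p.excluded or not p.pval_out < p_threshold
            else p.exclude(OUTCOME_ASSOCIATED)
            for p in pairs]


def read_proxy_table(path: str | Path, delimiter: str = "\t") -> list[ProxyRecord]:
    """Read a user-supplied proxy table.

    Columns: query_snp, proxy_snp, r2, query_a1, proxy_a1, query_a2, proxy_a2
    (query allele -> proxy allele correspondence).
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    needed = {"query_snp", "proxy_snp", "r2", "query_a1", "proxy_a1", "query_a2", "proxy_a2"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"proxy table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(ProxyRecord(
            query_snp=row.query_snp, proxy_snp=row.proxy_snp, r2=float(row.r2),
            allele_map={row.query_a1: row.proxy_a1, row.query_a2: row.proxy_a2},
        ))
    return out


def substitute_proxies(
    missing: Sequence[str],
    proxies: Sequence[ProxyRecord],
    outcome: GwasDataset,
    r2_min: float = PROXY_R2_MIN,
) -> tuple[dict[str, tuple[GwasRecord, str]], list[str]]:
    """Resolve instruments absent from the outcome GWAS through LD proxies.

    For each missing rsID the highest-r² proxy with r² strictly above
    ``r2_min`` and present in the outcome dataset is substituted (ties broken
    lexicographically by proxy rsID).  The proxy's outcome effect is remapped
    onto the query SNP's alleles via the proxy's allele correspondence.

    Returns (query rsID -> (remapped outcome record, proxy rsID), unresolved list).
    """
    by_query: dict[str, list[ProxyRecord]] = {}
    for pr in proxies:
        by_query.setdefault(pr.query_snp, []).append(pr)

    substitutions: dict[str, tuple[GwasRecord, str]] = {}
    unresolved: list[str] = []
    for snp in missing:
        candidates = [pr for pr in by_query.get(snp, ())
                      if pr.r2 > r2_min and pr.proxy_snp in outcome]
        candidates.sort(key=lambda pr: (-pr.r2, pr.proxy_snp))
        chosen = None
        for pr in candidates:
            rec = outcome.get(pr.proxy_snp)
            mapped = _remap_proxy(snp, pr, rec)
            if mapped is None:
                logger.warning("proxy %s for %s: allele_map inconsistent with record, skipped",
                               pr.proxy_snp, snp)
                continue
            chosen = (mapped, pr.proxy_snp)
            break
        if chosen is None:
            unresolved.append(snp)
        else:
            substitutions[snp] = chosen
    if unresolved:
        logger.info("proxy substitution: %d instrument(s) unresolved", len(unresolved))
    return substitutions, unresolved


def _remap_proxy(query_snp: str, pr: ProxyRecord, rec: GwasRecord) -> GwasRecord | None:
    """Express the proxy's outcome effect on the query SNP's alleles."""
    inverse = {v: k for k, v in pr.allele_map.items()}
    if set((rec.effect_allele, rec.other_allele)) != set(inverse):
        return None
    q_effect = inverse[rec.effect_allele]
    q_other = inverse[rec.other_allele]
    return GwasRecord(
        snp_id=query_snp, effect_allele=q_effect, other_allele=q_other,
        eaf=rec.eaf, beta=rec.beta, se=rec.se, pval=rec.pval,
        n=rec.n, n_case=rec.n_case,
    )


@dataclass
class HarmonizationResult:
    """Kept pairs plus the full exclusion log."""

    pairs: list[HarmonizedPair]
    excluded: list[HarmonizedPair]
    unresolved: list[str]

    @property
    def exclusion_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.excluded:
            counts[p.exclusion_reason] = counts.get(p.exclusion_reason, 0) + 1
        if self.unresolved:
            counts[MISSING_NO_PROXY] = len(self.unresolved)
        return counts

    def log_frame(self) -> pd.DataFrame:
        rows = [{"snp_id": p.snp_id, "reason": p.exclusion_reason} for p in self.excluded]
        rows += [{"snp_id": s, "reason": MISSING_NO_PROXY} for s in self.unresolved]
        return pd.DataFrame(rows, columns=["snp_id", "reason"])


def harmonize(
    instruments: GwasDataset,
    outcome: GwasDataset,
    proxies: Sequence[ProxyRecord] = (),
    maf_threshold: float = PALINDROME_MAF_MAX,
    outcome_p_threshold: float = GENOME_WIDE_P,
    r2_min: float = PROXY_R2_MIN,
) -> HarmonizationResult:
    """Full harmonization of an instrument set against one outcome GWAS.

    Pipeline order: proxy substitution for absent SNPs, allele alignment,
    outcome-association exclusion, palindromic-MAF exclusion.
    """
    missing = [s for s in instruments.snp_ids if s not in outcome]
    substitutions, unresolved = ({}, list(missing))
    if proxies and missing:
        substitutions, unresolved = substitute_proxies(missing, proxies, outcome, r2_min)

    raw: list[HarmonizedPair] = []
    for exp_rec in instruments.records():
        if exp_rec.snp_id in outcome:
            pair = align_alleles(exp_rec, outcome.get(exp_rec.snp_id))
        elif exp_rec.snp_id in substitutions:
            out_rec, proxy_id = substitutions[exp_rec.snp_id]
            pair = align_alleles(exp_rec, out_rec)
            if not pair.excluded:
                pair = replace(pair, status="proxy-substituted", proxy_snp=proxy_id)
        else:
            continue  # reported in unresolved
        raw.append(pair)

    processed = filter_palindromic(
        exclude_outcome_associated(raw, outcome_p_threshold), maf_threshold)
    kept = [p for p in processed if not p.excluded]
    excluded = [p for p in processed if p.excluded]
    logger.info("%s vs %s: %d kept, %d excluded %s, %d unresolved",
                instruments.trait_name, outcome.trait_name, len(kept),
                len(excluded),
                {k: v for k, v in
                 HarmonizationResult(kept, excluded, unresolved).exclusion_counts.items()},
                len(unresolved))
    return HarmonizationResult(pairs=kept, excluded=excluded, unresolved=unresolved)
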