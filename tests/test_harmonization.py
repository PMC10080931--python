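"""Allele alignment, palindrome rules, outcome-association and proxy handling."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import make_pairs, make_record
from mrpipe.harmonization import (
    ALLELE_MISMATCH,
    COMPLEMENT,
    OUTCOME_ASSOCIATED,
    PALINDROMIC_AMBIGUOUS,
    ProxyRecord,
    align_alleles,
    exclude_outcome_associated,
    filter_palindromic,
    harmonize,
    is_palindromic,
    substitute_proxies,
)
from mrpipe.mr_core import ivw_random_effects
from mrpipe.summary_io import GwasDataset, select_instruments
from mrpipe.synthetic_data import SynthConfig, simulate_two_sample


@pytest.mark.parametrize("ea,oa,expected", [
    ("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
    ("A", "G", False), ("A", "C", False), ("G", "T", False),
])
def test_is_palindromic(ea, oa, expected):
    assert is_palindromic(make_record(ea=ea, oa=oa)) is expected


class TestAlignAlleles:
    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = make_record(ea="A", oa="G", beta=0.10)
        out = make_record(ea="G", oa="A", beta=-0.05, eaf=0.70)
        pair = align_alleles(exp, out)
        assert pair.status == "flipped"
        assert pair.beta_out == pytest.approx(0.05)
        assert pair.eaf_out == pytest.approx(0.30)

    def test_strand_complement_same_orientation_kept(self):
        exp = make_record(ea="A", oa="G", beta=0.10)
        out = make_record(ea="T", oa="C", beta=0.04)
        pair = align_alleles(exp, out)
        assert pair.status == "kept"
        assert pair.beta_out == pytest.approx(0.04)

    def test_irreconcilable_alleles_excluded(self):
        pair = align_alleles(make_record(ea="A", oa="G"),
                             make_record(ea="A", oa="C"))
        assert pair.exclusion_reason == ALLELE_MISMATCH

    def test_snp_id_mismatch_fatal(self):
        with pytest.raises(ValueError, match="mismatch"):
            align_alleles(make_record(snp="rs1"), make_record(snp="rs2"))

    @pytest.mark.parametrize("ea,oa", [("A", "G"), ("C", "T"), ("G", "T"), ("A", "C")])
    def test_rule_table_all_nonpalindromic_representations(self, ea, oa):
        """Identity/swap/complement/both must all recover the generated effect."""
        exp = make_record(ea=ea, oa=oa, beta=0.12, eaf=0.25)
        true_beta_out, true_eaf_out = -0.07, 0.25
        reprs = {
            "identity": (ea, oa, true_beta_out, true_eaf_out, "kept"),
            "swap": (oa, ea, -true_beta_out, 1 - true_eaf_out, "flipped"),
            "complement": (COMPLEMENT[ea], COMPLEMENT[oa],
                           true_beta_out, true_eaf_out, "kept"),
            "both": (COMPLEMENT[oa], COMPLEMENT[ea],
                     -true_beta_out, 1 - true_eaf_out, "flipped"),
        }
        for name, (rea, roa, rbeta, reaf, status) in reprs.items():
            out = make_record(ea=rea, oa=roa, beta=rbeta, eaf=reaf)
            pair = align_alleles(exp, out)
            assert not pair.excluded, name
            assert pair.status == status, name
            assert pair.beta_out == pytest.approx(true_beta_out), name
            assert pair.eaf_out == pytest.approx(true_eaf_out), name

    @pytest.mark.parametrize("swapped", [False, True])
    def test_palindromic_resolved_by_eaf_concordance(self, swapped):
        exp = make_record(ea="A", oa="T", beta=0.1, eaf=0.2)
        if swapped:
            out = make_record(ea="T", oa="A", beta=0.05, eaf=0.78)
            pair = align_alleles(exp, out)
            assert pair.status == "flipped"
            assert pair.beta_out == pytest.approx(-0.05)
        else:
            out = make_record(ea="A", oa="T", beta=0.05, eaf=0.22)
            pair = align_alleles(exp, out)
            assert pair.status == "kept"
            assert pair.beta_out == pytest.approx(0.05)

    def test_palindromic_missing_eaf_is_ambiguous(self):
        exp = make_record(ea="A", oa="T", eaf=None)
        out = make_record(ea="A", oa="T", eaf=0.2)
        assert align_alleles(exp, out).exclusion_reason == PALINDROMIC_AMBIGUOUS

    def test_realignment_is_a_no_op(self):
        """Harmonizing an already-harmonized pair changes nothing."""
        exp = make_record(ea="A", oa="G", beta=0.1, eaf=0.3)
        out = make_record(ea="G", oa="A", beta=-0.05, eaf=0.7)
        pair = align_alleles(exp, out)
        re_out = make_record(ea=pair.effect_allele, oa=pair.other_allele,
                             beta=pair.beta_out, eaf=pair.eaf_out)
        again = align_alleles(exp, re_out)
        assert again.status == "kept"
        assert again.beta_out == pytest.approx(pair.beta_out)
        assert again.eaf_out == pytest.approx(pair.eaf_out)


class TestFilterPalindromic:
    def test_high_maf_palindrome_excluded(self):
        [pair] = filter_palindromic(
            [align_alleles(make_record(ea="A", oa="T", eaf=0.45),
                           make_record(ea="A", oa="T", eaf=0.45))])
        assert pair.exclusion_reason == PALINDROMIC_AMBIGUOUS

    def test_low_maf_palindrome_retained(self):
        [pair] = filter_palindromic(
            [align_alleles(make_record(ea="C", oa="G", eaf=0.10),
                           make_record(ea="C", oa="G", eaf=0.10))])
        assert not pair.excluded

    def test_maf_exactly_at_threshold_retained(self):
        [pair] = filter_palindromic(
            [align_alleles(make_record(ea="C", oa="G", eaf=0.42),
                           make_record(ea="C", oa="G", eaf=0.42))])
        assert not pair.excluded

    def test_nonpalindromic_unaffected(self):
        [pair] = filter_palindromic(
            [align_alleles(make_record(ea="A", oa="G", eaf=0.50),
                           make_record(ea="A", oa="G", eaf=0.50))])
        assert not pair.excluded


class TestOutcomeAssociated:
    def test_strongly_outcome_associated_excluded(self):
        [pair] = exclude_outcome_associated(make_pairs(0.1, 0.05, 0.01,
                                                       pval_out=1e-9))
        assert pair.exclusion_reason == OUTCOME_ASSOCIATED

    def test_weakly_associated_retained(self):
        [pair] = exclude_outcome_associated(make_pairs(0.1, 0.05, 0.01,
                                                       pval_out=1e-7))
        assert not pair.excluded

    def test_empty_input(self):
        assert exclude_outcome_associated([]) == []


def _outcome_dataset(records):
    import pandas as pd

    tab = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return GwasDataset("outcome", "continuous", tab)


class TestProxies:
    def _proxy(self, query="rs1", proxy="rsP", r2=0.9,
               amap=None):
        return ProxyRecord(query, proxy, r2, amap or {"A": "C", "G": "T"})

    def test_low_r2_rejected(self):
        outcome = _outcome_dataset([make_record(snp="rsP", ea="C", oa="T")])
        subs, unresolved = substitute_proxies(["rs1"], [self._proxy(r2=0.55)],
                                              outcome)
        assert subs == {} and unresolved == ["rs1"]

    def test_highest_r2_wins(self):
        outcome = _outcome_dataset([
            make_record(snp="rsP1", ea="C", oa="T", beta=0.1),
            make_record(snp="rsP2", ea="C", oa="T", beta=0.2),
        ])
        proxies = [self._proxy(proxy="rsP1", r2=0.65),
                   self._proxy(proxy="rsP2", r2=0.90)]
        subs, _ = substitute_proxies(["rs1"], proxies, outcome)
        assert subs["rs1"][1] == "rsP2"

    def test_r2_tie_broken_lexicographically(self):
        outcome = _outcome_dataset([
            make_record(snp="rsB", ea="C", oa="T"),
            make_record(snp="rsA", ea="C", oa="T"),
        ])
        proxies = [self._proxy(proxy="rsB", r2=0.8),
                   self._proxy(proxy="rsA", r2=0.8)]
        subs, _ = substitute_proxies(["rs1"], proxies, outcome)
        assert subs["rs1"][1] == "rsA"

    def test_alleles_remapped_through_correspondence(self):
        outcome = _outcome_dataset([
            make_record(snp="rsP", ea="T", oa="C", beta=0.3, eaf=0.7)])
        subs, _ = substitute_proxies(["rs1"], [self._proxy()], outcome)
        rec, _ = subs["rs1"]
        # proxy effect allele T corresponds to query allele G
        assert (rec.effect_allele, rec.other_allele) == ("G", "A")
        assert rec.beta == pytest.approx(0.3)

    def test_inconsistent_allele_map_skipped_with_warning(self, caplog):
        outcome = _outcome_dataset([make_record(snp="rsP", ea="A", oa="G")])
        with caplog.at_level("WARNING"):
            subs, unresolved = substitute_proxies(["rs1"], [self._proxy()],
                                                  outcome)
        assert unresolved == ["rs1"]
        assert any("inconsistent" in r.message for r in caplog.records)

    def test_unresolved_snp_reported_and_pipeline_continues(self):
        outcome = _outcome_dataset([make_record(snp="rsOther", ea="A", oa="G")])
        subs, unresolved = substitute_proxies(["rs1"], [], outcome)
        assert unresolved == ["rs1"]


@given(st.integers(0, 10_000))
def test_sign_flip_of_both_betas_preserves_estimates(seed):
    rng = np.random.default_rng(seed)
    L = 10
    bx = rng.normal(0.1, 0.03, L)
    by = rng.normal(0.05, 0.02, L)
    sy = rng.uniform(0.01, 0.05, L)
    pairs = make_pairs(bx, by, sy)
    flipped = make_pairs(-bx, -by, sy)
    res1, _ = ivw_random_effects(pairs)
    res2, _ = ivw_random_effects(flipped)
    assert res1.beta == pytest.approx(res2.beta, rel=1e-12)
    assert res1.se == pytest.approx(res2.se, rel=1e-12)


def test_full_orientation_recovery_on_corrupted_synthetic_data():
    """With injected swaps and strand flips, harmonization recovers the
    generated orientation for every non-palindromic SNP."""
    cfg = SynthConfig(seed=42, n_snps=300, swap_frac=0.4, flip_frac=0.25,
                      palindromic_frac=0.2)
    exposure, outcome, truth = simulate_two_sample(cfg)
    idx = {s: i for i, s in enumerate(truth.snp_id)}
    n_checked = 0
    for rec in exposure.records():
        i = idx[rec.snp_id]
        if truth.palindromic[i]:
            continue
        pair = align_alleles(rec, outcome.get(rec.snp_id))
        assert not pair.excluded
        reported = outcome.get(rec.snp_id).beta
        uncorrupted = -reported if truth.swapped[i] else reported
        assert pair.beta_out == pytest.approx(uncorrupted, rel=1e-12)
        n_checked += 1
    assert n_checked > 100


def test_harmonize_pipeline_counts_and_log():
    cfg = SynthConfig(seed=9, n_snps=200)
    exposure, outcome, _ = simulate_two_sample(cfg)
    instruments = select_instruments(exposure)
    result = harmonize(instruments, outcome)
    log = result.log_frame()
    # every instrument is either kept, excluded with one reason, or unresolved
    assert len(result.pairs) + len(log) == len(instruments)
    assert not log["snp_id"].duplicated().any()
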