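"""TPM normalisation, the binomial imbalance test, and ASEG classification."""

import math

import numpy as np
import pandas as pd
import pytest

from polyka.ase import (ase_tests, aseg_summary_counts, classify_asegs, tpm)
from polyka.models import AlleleLocus, ASERecord


def _design(stages=1, reps=1):
    rows = [(f"stage{s + 1}_rep{r + 1}", f"stage{s + 1}", r + 1)
            for s in range(stages) for r in range(reps)]
    return pd.DataFrame(rows, columns=["sample", "stage", "replicate"])


class TestTPM:
    def test_equal_counts_and_lengths_split_the_million(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
        lengths = pd.Series([500, 500], index=["g1", "g2"])
        out = tpm(counts, lengths)
        assert out["s1"].tolist() == [500_000.0, 500_000.0]

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 500, (20, 4)),
                              index=[f"g{i}" for i in range(20)],
                              columns=list("abcd"))
        lengths = pd.Series(rng.integers(300, 3000, 20), index=counts.index)
        out = tpm(counts, lengths)
        assert np.allclose(out.sum(axis=0), 1e6)

    def test_length_normalisation_hand_example(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
        lengths = pd.Series([1000, 2000], index=["g1", "g2"])
        out = tpm(counts, lengths)
        assert out.loc["g1", "s1"] == pytest.approx(666_666.67, abs=0.01)
        assert out.loc["g2", "s1"] == pytest.approx(333_333.33, abs=0.01)

    def test_all_zero_sample_warns_and_stays_zero(self, caplog):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["g1", "g2"])
        lengths = pd.Series([500, 500], index=["g1", "g2"])
        with caplog.at_level("WARNING"):
            out = tpm(counts, lengths)
        assert (out["s1"] == 0).all()
        assert any("all-zero" in r.message for r in caplog.records)


def _two_allele_setup(ci, cj, li=900, lj=900):
    counts = pd.DataFrame({"stage1_rep1": [ci, cj]}, index=["gA", "gB"])
    lengths = pd.Series([li, lj], index=["gA", "gB"])
    locus = AlleleLocus("L1", 1, "two", gene_a="gA", gene_b="gB")
    return [locus], counts, lengths, _design()


def _binom_two_sided_oracle(k, n, p):
    """Exact two-sided binomial P by summation of no-more-likely outcomes."""
    from scipy.stats import binom

    probs = binom.pmf(np.arange(n + 1), n, p)
    return float(probs[probs <= probs[k] * (1 + 1e-9)].sum())


class TestAseTest:
    def test_balanced_counts_not_significant(self):
        loci, counts, lengths, design = _two_allele_setup(100, 100)
        (rec,) = ase_tests(loci, counts, lengths, design)
        assert rec.p_value == pytest.approx(1.0, abs=0.1)
        assert not rec.significant

    def test_strong_imbalance_matches_exact_binomial_oracle(self):
        loci, counts, lengths, design = _two_allele_setup(160, 10)
        (rec,) = ase_tests(loci, counts, lengths, design)
        assert rec.p_value == pytest.approx(_binom_two_sided_oracle(160, 170, 0.5),
                                            rel=1e-9)
        assert rec.log2fc == pytest.approx(4.0, abs=1e-3)
        assert rec.significant
        assert rec.dominant_allele == "A"

    def test_fold_change_gate_blocks_sub_twofold_bias(self):
        # 1900 vs 1000 reads: P is tiny but log2FC = 0.93 < 1
        loci, counts, lengths, design = _two_allele_setup(1900, 1000)
        (rec,) = ase_tests(loci, counts, lengths, design)
        assert rec.p_value < 1e-6
        assert abs(rec.log2fc) < 1.0
        assert not rec.significant

    def test_length_adjusted_null_absorbs_length_bias(self):
        # counts 2:1 purely from a 2:1 length difference -> not significant
        loci, counts, lengths, design = _two_allele_setup(200, 100, li=2000, lj=1000)
        (rec,) = ase_tests(loci, counts, lengths, design)
        assert rec.p_value == pytest.approx(1.0, abs=0.15)
        assert abs(rec.log2fc) < 0.2  # TPM already length-normalised
        assert not rec.significant

    def test_allele_relabelling_mirrors_the_record(self):
        loci, counts, lengths, design = _two_allele_setup(160, 10)
        (fwd,) = ase_tests(loci, counts, lengths, design)
        swapped = [AlleleLocus("L1", 1, "two", gene_a="gB", gene_b="gA")]
        (rev,) = ase_tests(swapped, counts, lengths, design)
        assert rev.p_value == pytest.approx(fwd.p_value, rel=1e-12)
        assert rev.log2fc == pytest.approx(-fwd.log2fc, rel=1e-12)
        assert rev.significant == fwd.significant

    def test_single_allele_locus_skipped(self):
        counts = pd.DataFrame({"stage1_rep1": [5]}, index=["gA"])
        lengths = pd.Series([900], index=["gA"])
        loci = [AlleleLocus("L1", 1, "singleton", gene_a="gA")]
        assert ase_tests(loci, counts, lengths, _design()) == []


def _rec(locus, stage, sig, dom):
    return ASERecord(locus, stage, "A", "B", 10.0, 1.0, 3.3, 0.001, 0.01,
                     sig, dom)


class TestClassification:
    def test_always_significant_same_dominant_is_consistent(self):
        recs = [_rec("L1", f"stage{s}", True, "A") for s in range(1, 5)]
        classes, summary = classify_asegs(recs)
        assert classes[0].label == "consistent"
        assert summary["n_consistent"] == 1

    def test_dominance_switch_is_inconsistent(self):
        recs = [_rec("L1", "stage1", True, "A"), _rec("L1", "stage2", True, "A"),
                _rec("L1", "stage3", True, "C"), _rec("L1", "stage4", False, "A")]
        classes, _ = classify_asegs(recs)
        assert classes[0].label == "inconsistent"

    def test_never_significant_is_balanced(self):
        recs = [_rec("L1", f"stage{s}", False, "A") for s in range(1, 5)]
        classes, summary = classify_asegs(recs)
        assert classes[0].label == "balanced"
        assert summary["n_significant"] == 0

    def test_consistent_plus_inconsistent_equals_significant(self, default_run):
        s = default_run.ase_summary
        assert s["n_consistent"] + s["n_inconsistent"] == s["n_significant"]

    def test_summary_counts_validate(self):
        with pytest.raises(ValueError):
            aseg_summary_counts(10, 5, 6)
        with pytest.raises(ValueError):
            aseg_summary_counts(10, 11, 1)


def test_recovery_on_planted_truth(default_run, truth_loci_as_alleles):
    """Planted consistent ASE recovered; balanced false positives bounded."""
    from polyka.ase import ase_tests as run_tests

    truth = default_run.truth
    records = run_tests([l for l in truth_loci_as_alleles if l.n_alleles >= 2],
                        default_run.counts, default_run.lengths,
                        default_run.design)
    classes, _ = classify_asegs(records)
    label_of = {c.locus_id: c.label for c in classes}

    consistent_planted = [a for a in truth.ase if a.consistent]
    hits = sum(1 for a in consistent_planted
               if label_of.get(a.locus_id) == "consistent")
    assert hits / len(consistent_planted) >= 0.9

    planted_ids = {a.locus_id for a in truth.ase}
    balanced_records = [r for r in records if r.locus_id not in planted_ids]
    fp = sum(r.significant for r in balanced_records) / len(balanced_records)
    assert fp <= 1.5 * 0.05
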