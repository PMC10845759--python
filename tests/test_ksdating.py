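"""NG86 counting against an independent path-enumeration oracle, peaks, dating."""

import itertools
import math

import numpy as np
import pytest

from polyka.ksdating import (CodonAlignment, EmptyAlignmentError,
                             InsufficientDataError, SENSE_CODONS, STOP_CODONS,
                             codon_align, codon_difference_counts, detect_peaks,
                             jukes_cantor, ks_to_time, ng86)
from polyka.models import GeneModel
from polyka.formats_io import translate_cds
from polyka.simulate import evolve_codon_pair, random_cds

# --- independent oracle -----------------------------------------------------

_CODE = {}
for _c in SENSE_CODONS:
    _CODE[_c] = translate_cds(_c) if _c not in ("TAA", "TAG", "TGA") else "*"


def oracle_sites(codon):
    """Per-codon synonymous sites by direct mutation enumeration."""
    s = 0.0
    for pos in range(3):
        outcomes = []
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            outcomes.append(_CODE[alt] == _CODE[codon])
        s += sum(outcomes) / len(outcomes)
    return s


def oracle_differences(c1, c2):
    """Average syn/nonsyn steps over all unblocked minimal paths."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in itertools.permutations(positions):
        cur, steps, ok = c1, [], True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            steps.append(_CODE[cur] == _CODE[nxt])
            cur = nxt
        if ok:
            paths.append(steps)
    if not paths:
        return None
    syn = sum(sum(p) for p in paths) / len(paths)
    return syn, len(positions) - syn


def _gene(gid, cds):
    return GeneModel(gid, "A", "hapA_Chr01", 1, 0, len(cds), "+", cds,
                     translate_cds(cds, gid))


# --- tests ------------------------------------------------------------------

def test_identical_sequences_give_zero_rates():
    aln = CodonAlignment("x", "y", ["ATG", "GGC", "TAT"], ["ATG", "GGC", "TAT"])
    e = ng86(aln)
    assert (e.Sd, e.Nd) == (0.0, 0.0)
    assert (e.Ks, e.Ka) == (0.0, 0.0)
    assert e.defined
    assert e.S + e.N == pytest.approx(3 * e.n_codons)


def test_no_sense_codon_pair_is_fully_path_blocked():
    # under the universal code every sense pair keeps >= 1 unblocked path
    for c1 in SENSE_CODONS:
        for c2 in SENSE_CODONS:
            assert codon_difference_counts(c1, c2) is not None


def test_ng86_counts_match_path_enumeration_oracle():
    rng = np.random.default_rng(42)
    codons = list(SENSE_CODONS)
    for _ in range(2000):
        n = int(rng.integers(1, 4))
        c1 = [codons[i] for i in rng.integers(0, len(codons), n)]
        c2 = [codons[i] for i in rng.integers(0, len(codons), n)]
        e = ng86(CodonAlignment("a", "b", c1, c2))
        S = sum((oracle_sites(x) + oracle_sites(y)) / 2 for x, y in zip(c1, c2))
        diffs = [oracle_differences(x, y) for x, y in zip(c1, c2)]
        Sd = sum(d[0] for d in diffs)
        Nd = sum(d[1] for d in diffs)
        assert e.S == pytest.approx(S, abs=1e-12)
        assert e.N == pytest.approx(3 * n - S, abs=1e-12)
        assert e.Sd == pytest.approx(Sd, abs=1e-12)
        assert e.Nd == pytest.approx(Nd, abs=1e-12)


def test_ks_is_monotone_in_ps():
    ps = np.linspace(0.0, 0.74, 200)
    ks = [jukes_cantor(p) for p in ps]
    assert all(b >= a for a, b in zip(ks, ks[1:]))
    assert all(k >= p for k, p in zip(ks, ps))  # correction never shrinks


def test_undefined_when_ps_saturates():
    # AAA (Lys) vs GGG (Gly): every path step nonsynonymous; pN large but
    # use many such codons so pS stays 0 and pN crosses 3/4? pN = Nd/N with
    # Nd = 3 per codon, N ~ 2.78 -> pN > 1: defined must be False.
    aln = CodonAlignment("a", "b", ["AAA"] * 5, ["GGG"] * 5)
    e = ng86(aln)
    assert not e.defined and math.isnan(e.Ka)


class TestCodonAlign:
    def test_identical_cds_all_codons_retained(self):
        cds = random_cds(50, np.random.default_rng(0))
        aln = codon_align(_gene("a", cds), _gene("b", cds))
        assert aln.n_codons == 50

    def test_in_frame_insertion_gives_shorter_codon_count(self):
        cds = random_cds(40, np.random.default_rng(1))
        longer = cds[:60] + "GCTGCA" + cds[60:]
        aln = codon_align(_gene("a", cds), _gene("b", longer))
        assert aln.n_codons == 40

    def test_ambiguous_codon_column_dropped(self):
        cds = random_cds(30, np.random.default_rng(2))
        with_n = cds[:30] + "AN" + cds[32:]
        g2 = GeneModel("b", "A", "hapA_Chr01", 1, 0, len(cds), "+", with_n,
                       translate_cds(cds))  # protein from clean copy
        aln = codon_align(_gene("a", cds), g2)
        assert aln.n_codons == 29

    def test_empty_protein_rejected(self):
        g = _gene("a", random_cds(10, np.random.default_rng(3)))
        bad = GeneModel("b", "A", "hapA_Chr01", 1, 0, 3, "+", "ATG", "")
        with pytest.raises((ValueError, EmptyAlignmentError)):
            codon_align(g, bad)


def test_ng86_recovers_generator_target_within_three_bootstrap_ses():
    rng = np.random.default_rng(5)
    cds = random_cds(10_000, rng)
    mutated = evolve_codon_pair(cds, 0.1, 0.0, 6)
    aln = codon_align(_gene("a", cds), _gene("b", mutated))
    est = ng86(aln)
    # bootstrap over codon columns on the per-column NG86 contributions
    cols = list(zip(aln.codons_1, aln.codons_2))
    per_s = np.array([(oracle_sites(x) + oracle_sites(y)) / 2 for x, y in cols])
    per_sd = np.array([oracle_differences(x, y)[0] for x, y in cols])
    boots = []
    for _ in range(200):
        idx = rng.integers(0, len(cols), len(cols))
        ps = per_sd[idx].sum() / per_s[idx].sum()
        boots.append(jukes_cantor(ps))
    se = np.std(boots, ddof=1)
    assert abs(est.Ks - 0.1) < 3 * se
    assert est.Ka < 0.005


class TestDetectPeaks:
    def test_single_value_cluster_peaks_at_its_location(self):
        rng = np.random.default_rng(0)
        vals = 0.3 + rng.normal(0, 1e-6, 500)
        peaks = detect_peaks(vals)
        assert len(peaks) >= 1
        assert peaks[0].mode == pytest.approx(0.3, abs=2.0 / 2047)

    def test_bimodal_mixture_yields_both_modes(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.normal(0.1, 0.01, 2000),
                               rng.normal(0.5, 0.05, 2000)])
        peaks = detect_peaks(vals)
        modes = sorted(p.mode for p in peaks[:2])
        assert modes[0] == pytest.approx(0.1, abs=0.02)
        assert modes[1] == pytest.approx(0.5, abs=0.05)

    def test_zeros_and_out_of_range_values_excluded(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([np.zeros(500), 5.0 + rng.normal(0, 0.1, 500),
                               0.2 + rng.normal(0, 0.005, 100)])
        peaks = detect_peaks(vals)
        assert peaks[0].n_pairs == pytest.approx(100, abs=5)
        assert peaks[0].mode == pytest.approx(0.2, abs=0.01)

    def test_insufficient_data_raises(self):
        with pytest.raises(InsufficientDataError):
            detect_peaks([0.1] * 10)


class TestDating:
    def test_event_time_worked_examples(self):
        assert ks_to_time(0.007).mya == 1.03
        assert ks_to_time(0.015).mya == 2.21

    def test_zero_ks_dates_to_zero(self):
        assert ks_to_time(0.0).t_years == 0.0

    def test_linearity(self):
        t1 = ks_to_time(0.2).t_years
        t2 = ks_to_time(0.4).t_years
        assert t2 == pytest.approx(2 * t1)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ks_to_time(0.1, r=0.0)
        with pytest.raises(ValueError):
            ks_to_time(-0.1)
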