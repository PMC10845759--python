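"""Anchors, chaining optimality, allele table partition, singleton calls."""

import itertools

import numpy as np
import pytest

from polyka import synteny
from polyka.models import AnchorPair, GeneModel, GeneSet
from polyka.synteny import (allele_census, best_chain, build_allele_table,
                            chain_blocks, classify_singletons, pairwise_anchors,
                            percent_of, protein_identity)

BLOSUM = None


def _gotoh_score(a, b, open_=10.0, extend=1.0):
    """Independent affine-gap global alignment score (BLOSUM62)."""
    global BLOSUM
    if BLOSUM is None:
        from Bio.Align import substitution_matrices

        BLOSUM = substitution_matrices.load("BLOSUM62")
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -open_ - (i - 1) * extend
    for j in range(1, m + 1):
        Y[0][j] = -open_ - (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - open_, X[i - 1][j] - extend,
                          Y[i - 1][j] - open_)
            Y[i][j] = max(M[i][j - 1] - open_, Y[i][j - 1] - extend,
                          X[i][j - 1] - open_)
    return max(M[n][m], X[n][m], Y[n][m])


class TestProteinIdentity:
    def test_identical_proteins_are_100(self):
        assert protein_identity("MKVLAT" * 20, "MKVLAT" * 20) == 100.0

    def test_single_mismatch_over_four_columns(self):
        # W vs F mismatch in otherwise identical short proteins
        assert protein_identity("MWKL", "MFKL") == 75.0

    def test_alignment_score_matches_independent_gotoh_dp(self):
        from polyka.align import align_proteins

        rng = np.random.default_rng(3)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(3):
            a = "".join(rng.choice(list(aas), 120))
            b = list(a)
            for pos in rng.choice(len(b), 15, replace=False):
                b[pos] = aas[rng.integers(20)]
            b = "".join(b)[:100]  # also truncate to force terminal gaps
            _, _, score = align_proteins(a, b)
            assert score == pytest.approx(_gotoh_score(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            protein_identity("", "MKL")


def _gene(gid, hap, chrom, group, idx, protein, strand="+"):
    return GeneModel(gid, hap, chrom, group, idx * 1000, idx * 1000 + 300,
                     strand, "ATG" * 100, protein)


def _mk_set(hap, proteins):
    genes = [_gene(f"{hap}{i:02d}", hap, f"hap{hap}_Chr01", 1, i, p)
             for i, p in enumerate(proteins)]
    return GeneSet(haplotype=hap, genes=genes)


class TestPairwiseAnchors:
    def _proteins(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        return ["".join(rng.choice(list(aas), 60)) for _ in range(n)]

    def test_identical_sets_anchor_every_gene_at_100(self):
        prots = self._proteins()
        anchors = pairwise_anchors(_mk_set("A", prots), _mk_set("B", prots))
        assert len(anchors) == len(prots)
        assert all(a.identity == 100.0 for a in anchors)
        assert all(a.gene_a[1:] == a.gene_b[1:] for a in anchors)

    def test_symmetry_under_swap(self):
        prots = self._proteins(seed=1)
        a_set, b_set = _mk_set("A", prots), _mk_set("B", list(reversed(prots)))
        ab = pairwise_anchors(a_set, b_set)
        ba = pairwise_anchors(b_set, a_set)
        assert {(x.gene_a, x.gene_b) for x in ab} == {(y.gene_b, y.gene_a) for y in ba}

    def test_gene_without_counterpart_absent(self):
        prots = self._proteins(seed=2)
        rng = np.random.default_rng(9)
        lone = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
        anchors = pairwise_anchors(_mk_set("A", prots + [lone]), _mk_set("B", prots))
        assert all(a.gene_a != "A12" for a in anchors)

    def test_same_haplotype_rejected(self):
        s = _mk_set("A", self._proteins(4))
        with pytest.raises(ValueError):
            pairwise_anchors(s, s)


def _exhaustive_best_weight(items, orientation, max_gap):
    """Oracle: maximum chain size by enumeration over all subsets."""
    n = len(items)
    best = 0
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            seq = sorted(combo, key=lambda k: items[k][0])
            ok = True
            for p, q in zip(seq, seq[1:]):
                ia_m, ib_m = items[p]
                ia_k, ib_k = items[q]
                if not (ia_m < ia_k <= ia_m + max_gap + 1):
                    ok = False
                    break
                if orientation == "same":
                    if not (ib_m < ib_k <= ib_m + max_gap + 1):
                        ok = False
                        break
                elif not (ib_m > ib_k >= ib_m - max_gap - 1):
                    ok = False
                    break
            if ok:
                best = max(best, r)
    return best


class TestChaining:
    def test_collinear_run_is_one_same_block(self):
        prots = TestPairwiseAnchors()._proteins(10, seed=4)
        a_set, b_set = _mk_set("A", prots), _mk_set("B", prots)
        anchors = pairwise_anchors(a_set, b_set)
        blocks = chain_blocks(anchors, a_set, b_set)
        assert len(blocks) == 1
        assert blocks[0].orientation == "same"
        assert blocks[0].n_anchors == 10

    def test_off_diagonal_anchor_excluded(self):
        # 8 collinear anchors plus one anchor jumping far in genome B
        items = [(i, i) for i in range(8)] + [(4, 40)]
        chain = best_chain(items, "same", max_gap=10)
        chosen = {items[k] for k in chain}
        assert (4, 40) not in chosen
        assert len(chain) == 8

    def test_chain_weight_matches_exhaustive_search_on_random_sets(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            n = int(rng.integers(2, 13))
            items = [(int(rng.integers(0, 20)), int(rng.integers(0, 20)))
                     for _ in range(n)]
            # unique ia values (one anchor per gene)
            items = list({ia: (ia, ib) for ia, ib in items}.values())
            for orientation in ("same", "inverted"):
                got = len(best_chain(items, orientation, max_gap=3))
                want = _exhaustive_best_weight(items, orientation, max_gap=3)
                assert got == want

    def test_planted_inversion_recovered_as_inverted_block(self, default_run):
        inv = [r for r in default_run.truth.rearrangements if r.kind == "inversion"]
        blocks = default_run.blocks
        inverted_genes = {g for b in blocks if b.orientation == "inverted"
                          for g in (b.anchor_genes_a + "," + b.anchor_genes_b).split(",")}
        recovered = sum(
            1 for r in inv
            if len(set(r.gene_ids.split(",")) & inverted_genes) >= len(r.gene_ids.split(",")) / 2)
        assert recovered / len(inv) >= 0.90


class TestAlleleTable:
    def test_loss_free_genome_gives_only_four_allele_loci(self, tiny_sim):
        _, _, loci = synteny.run_synteny(tiny_sim.gene_sets)
        assert all(l.allele_class == "four" for l in loci)
        census = allele_census(loci)
        assert census.n_singleton == 0

    def test_partition_every_gene_in_exactly_one_locus(self, default_run):
        seen = {}
        for locus in default_run.loci:
            for gid in locus.members().values():
                assert gid not in seen, f"{gid} in two loci"
                seen[gid] = locus.locus_id
        total = sum(len(gs.genes) for gs in default_run.gene_sets.values())
        assert len(seen) == total

    def test_census_accounting_identity(self, default_run):
        census = allele_census(default_run.loci)
        total = sum(len(gs.genes) for gs in default_run.gene_sets.values())
        assert census.total_genes == total
        assert census.total_singletons == census.n_singleton
        assert census.total_shared == total - census.n_singleton

    def test_component_splitting_respects_one_gene_per_haplotype(self):
        # a triangle plus a second A-gene attached by a weaker edge
        prots = None
        anchors = {("A", "B"): [AnchorPair("a1", "b1", 99.0, block_id="x"),
                                AnchorPair("a2", "b1", 90.0, block_id="x")]}
        sets = {
            "A": GeneSet("A", [_gene("a1", "A", "hapA_Chr01", 1, 0, "M" * 50),
                               _gene("a2", "A", "hapA_Chr01", 1, 1, "M" * 50)]),
            "B": GeneSet("B", [_gene("b1", "B", "hapB_Chr01", 1, 0, "M" * 50)]),
        }
        loci = build_allele_table(anchors, sets)
        classes = sorted(l.allele_class for l in loci)
        assert classes == ["singleton", "two"]
        two = next(l for l in loci if l.allele_class == "two")
        assert two.gene_a == "a1"  # the weaker a2-b1 edge was dropped


class TestSingletons:
    def test_planted_copy_singletons_classified_by_origin(self, default_run):
        calls = {c.gene_id: c for c in default_run.singleton_calls}
        truth = default_run.truth
        tandem = [s for s in truth.singletons if s.origin == "tandem"]
        reloc = [s for s in truth.singletons if s.origin == "relocated"]
        assert tandem and reloc

        allelic = ("four", "three", "two")  # reconstructed class of the source locus

        def ok_tandem(s):
            c = calls.get(s.gene_id)
            return c is not None and c.homolog_class in allelic and c.same_group

        def ok_reloc(s):
            c = calls.get(s.gene_id)
            return c is not None and c.homolog_class in allelic and c.same_group is False

        assert sum(map(ok_tandem, tandem)) / len(tandem) >= 0.9
        assert sum(map(ok_reloc, reloc)) / len(reloc) >= 0.9

    def test_identity_threshold_gates_homolog_class(self):
        rng = np.random.default_rng(21)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        prots = ["".join(rng.choice(list(aas), 80)) for _ in range(3)]
        sets = {"A": _mk_set("A", prots)}
        loci = [synteny.AlleleLocus(f"L{i}", 1, "singleton",
                                    gene_a=f"A{i:02d}") for i in range(3)]
        calls = classify_singletons(loci, sets, blocks=[])
        assert all(c.homolog_class == "none" for c in calls)
        assert all(c.best_homolog is None for c in calls)


def test_integer_percentages_round_as_printed():
    assert percent_of(1, 6) == 17
    assert percent_of(47, 100) == 47
    assert percent_of(0, 0) == 0
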