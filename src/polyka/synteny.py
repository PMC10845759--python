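"""Synteny anchors, collinear block chaining, and the allele table.

Alleles are homologous genes occupying the same locus on homologous
chromosomes of different haplotypes. They are recovered in four steps:
reciprocal-best protein matches between each haplotype pair (anchors),
dynamic-programming chaining of anchors into collinear blocks per
chromosome pair, a gene graph whose edges are in-block anchors, and a
split of any connected component that would place two genes of the same
haplotype at one locus. Genes left without allelic partners are singletons
and are classified by their best remaining homolog (>80% identity),
homologous-group retention and strand orientation against local synteny.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .align import align_proteins, percent_identity
from .models import (AlleleLocus, AnchorPair, GeneModel, GeneSet, HAPLOTYPES,
                     SingletonCall, SyntenyBlock)

log = logging.getLogger(__name__)

N_CANDIDATES = 5  # k-mer prescreen width before reciprocal-best resolution
_KMER = 4


def protein_identity(protein_a: str, protein_b: str) -> float:
    """Global-alignment percent identity (matches / alignment columns)."""
    row_a, row_b, _ = align_proteins(protein_a, protein_b)
    return percent_identity(row_a, row_b)


def _kmers(protein: str) -> set[str]:
    return {protein[i:i + _KMER] for i in range(len(protein) - _KMER + 1)}


def _top_candidates(query_kmers: dict[str, set[str]],
                    target_kmers: dict[str, set[str]],
                    top: int = N_CANDIDATES) -> dict[str, list[str]]:
    """Per query gene, the ``top`` target genes by shared k-mer count."""
    index: dict[str, list[str]] = {}
    for tid, ks in target_kmers.items():
        for k in ks:
            index.setdefault(k, []).append(tid)
    out: dict[str, list[str]] = {}
    for qid, ks in query_kmers.items():
        scores: dict[str, int] = {}
        for k in ks:
            for tid in index.get(k, ()):
                scores[tid] = scores.get(tid, 0) + 1
        ranked = sorted(scores, key=lambda t: (-scores[t], t))
        out[qid] = ranked[:top]
    return out


def pairwise_anchors(gene_set_a: GeneSet, gene_set_b: GeneSet,
                     min_identity: float = 60.0) -> list[AnchorPair]:
    """Reciprocal-best-hit anchors between two haplotypes.

    Candidates are prescreened to the best :data:`N_CANDIDATES` partners per
    gene by shared protein 4-mers; identities are computed by global
    alignment only on the candidate union, which keeps the result symmetric
    in the two gene sets. Ties are broken by lexicographic gene id.
    """
    if gene_set_a.haplotype == gene_set_b.haplotype:
        raise ValueError("pairwise_anchors requires two distinct haplotypes")
    ka = {g.gene_id: _kmers(g.protein) for g in gene_set_a.genes}
    kb = {g.gene_id: _kmers(g.protein) for g in gene_set_b.genes}
    prot_a = {g.gene_id: g.protein for g in gene_set_a.genes}
    prot_b = {g.gene_id: g.protein for g in gene_set_b.genes}

    cand_ab = _top_candidates(ka, kb)
    cand_ba = _top_candidates(kb, ka)
    pairs = {(a, b) for a, bs in cand_ab.items() for b in bs}
    pairs |= {(a, b) for b, as_ in cand_ba.items() for a in as_}

    ident: dict[tuple[str, str], float] = {}
    partners_of_a: dict[str, list[str]] = {}
    partners_of_b: dict[str, list[str]] = {}
    for a, b in pairs:
        ident[(a, b)] = protein_identity(prot_a[a], prot_b[b])
        partners_of_a.setdefault(a, []).append(b)
        partners_of_b.setdefault(b, []).append(a)

    def best(partners: Iterable[tuple[str, float]]) -> Optional[str]:
        ranked = sorted(partners, key=lambda t: (-t[1], t[0]))
        return ranked[0][0] if ranked else None

    best_a = {a: best((b, ident[(a, b)]) for b in bs)
              for a, bs in partners_of_a.items()}
    best_b = {b: best((a, ident[(a, b)]) for a in as_)
              for b, as_ in partners_of_b.items()}

    anchors = []
    for a, b in sorted(best_a.items()):
        if best_b.get(b) == a and ident[(a, b)] >= min_identity:
            anchors.append(AnchorPair(gene_a=a, gene_b=b, identity=ident[(a, b)]))
    return anchors


# ---------------------------------------------------------------------------
# collinear chaining

@dataclass
class _IndexedAnchor:
    anchor: AnchorPair
    chrom_a: str
    chrom_b: str
    ia: int  # gene order index on chromosome A
    ib: int


def _gene_order(gene_set: GeneSet) -> dict[str, tuple[str, int]]:
    out = {}
    for chrom, genes in gene_set.by_chromosome().items():
        for i, g in enumerate(genes):
            out[g.gene_id] = (chrom, i)
    return out


def best_chain(items: Sequence[tuple[int, int]], orientation: str,
               max_gap: int) -> list[int]:
    """Maximum-weight collinear chain over (ia, ib) anchor indices.

    Weight is the anchor count. Consecutive anchors must advance in both
    genomes (increasing ib for ``same``, decreasing for ``inverted``) with
    at most ``max_gap`` intervening genes on either side. Returns indices
    into ``items`` of one maximum chain, deterministically (ties prefer the
    earlier predecessor).
    """
    n = len(items)
    order = sorted(range(n), key=lambda k: (items[k][0], items[k][1]))
    dp = [1] * n
    prev: list[Optional[int]] = [None] * n
    for pos, k in enumerate(order):
        ia_k, ib_k = items[k]
        for m in order[:pos]:
            ia_m, ib_m = items[m]
            if not (ia_m < ia_k <= ia_m + max_gap + 1):
                continue
            if orientation == "same":
                ok = ib_m < ib_k <= ib_m + max_gap + 1
            else:
                ok = ib_m > ib_k >= ib_m - max_gap - 1
            if ok and dp[m] + 1 > dp[k]:
                dp[k] = dp[m] + 1
                prev[k] = m
    if n == 0:
        return []
    end = max(range(n), key=lambda k: (dp[k], -items[k][0]))
    chain = []
    cur: Optional[int] = end
    while cur is not None:
        chain.append(cur)
        cur = prev[cur]
    chain.reverse()
    return chain


def chain_blocks(anchors: Sequence[AnchorPair], gene_set_a: GeneSet,
                 gene_set_b: GeneSet, max_gap: int = 10,
                 min_block: int = 4) -> list[SyntenyBlock]:
    """Chain anchors into collinear blocks, greedily best-chain-first.

    Per chromosome pair the best same- or inverted-orientation chain is
    extracted repeatedly until no chain reaches ``min_block`` anchors; each
    anchor joins at most one block and gets its ``block_id`` set.
    """
    order_a = _gene_order(gene_set_a)
    order_b = _gene_order(gene_set_b)
    by_chrom_pair: dict[tuple[str, str], list[_IndexedAnchor]] = {}
    for anc in anchors:
        ca, ia = order_a[anc.gene_a]
        cb, ib = order_b[anc.gene_b]
        by_chrom_pair.setdefault((ca, cb), []).append(
            _IndexedAnchor(anc, ca, cb, ia, ib))

    blocks: list[SyntenyBlock] = []
    counter = 0
    hap_a, hap_b = gene_set_a.haplotype, gene_set_b.haplotype
    for (ca, cb) in sorted(by_chrom_pair):
        pool = by_chrom_pair[(ca, cb)]
        while True:
            items = [(x.ia, x.ib) for x in pool]
            best = None
            for orientation in ("same", "inverted"):
                chain = best_chain(items, orientation, max_gap)
                if best is None or len(chain) > len(best[1]):
                    best = (orientation, chain)
            if best is None or len(best[1]) < min_block:
                break
            orientation, chain_idx = best
            members = [pool[k] for k in sorted(chain_idx, key=lambda k: items[k][0])]
            counter += 1
            bid = f"blk_{hap_a}{hap_b}_{counter:04d}"
            for x in members:
                x.anchor.block_id = bid
            blocks.append(SyntenyBlock(
                block_id=bid, haplotype_a=hap_a, haplotype_b=hap_b,
                chromosome_a=ca, chromosome_b=cb, orientation=orientation,
                n_anchors=len(members),
                anchor_genes_a=",".join(x.anchor.gene_a for x in members),
                anchor_genes_b=",".join(x.anchor.gene_b for x in members)))
            used = set(chain_idx)
            pool = [x for k, x in enumerate(pool) if k not in used]
    return blocks


# ---------------------------------------------------------------------------
# allele table

def build_allele_table(anchors_by_pair: dict[tuple[str, str], Sequence[AnchorPair]],
                       gene_sets: dict[str, GeneSet]) -> list[AlleleLocus]:
    """Connected components of in-block anchors, split to one gene per haplotype.

    Components violating the one-gene-per-haplotype constraint lose their
    lowest-identity edges (ties by gene-id pair) until it holds. Remaining
    genes become singleton loci; every gene lands in exactly one locus.
    """
    hap_of: dict[str, str] = {}
    group_of: dict[str, int] = {}
    for hap, gs in gene_sets.items():
        for g in gs.genes:
            hap_of[g.gene_id] = hap
            group_of[g.gene_id] = g.homologous_group

    graph = nx.Graph()
    graph.add_nodes_from(hap_of)
    for (ha, hb), anchors in anchors_by_pair.items():
        for anc in anchors:
            if anc.block_id is None:
                continue
            graph.add_edge(anc.gene_a, anc.gene_b, identity=anc.identity)

    final_components: list[set[str]] = []

    def resolve(nodes: set[str]) -> None:
        sub = graph.subgraph(nodes)
        counts: dict[str, int] = {}
        for n in nodes:
            counts[hap_of[n]] = counts.get(hap_of[n], 0) + 1
        if all(c <= 1 for c in counts.values()):
            final_components.append(set(nodes))
            return
        u, v, _ = min(sub.edges(data="identity"),
                      key=lambda e: (e[2], tuple(sorted((e[0], e[1])))))
        g2 = nx.Graph(sub)
        g2.remove_edge(u, v)
        graph.remove_edge(u, v)
        for comp in nx.connected_components(g2):
            resolve(set(comp))

    for comp in nx.connected_components(graph):
        resolve(set(comp))

    final_components.sort(key=lambda c: min(c))
    loci: list[AlleleLocus] = []
    for i, comp in enumerate(final_components, start=1):
        members = sorted(comp)
        groups = sorted(group_of[m] for m in members)
        group = max(set(groups), key=lambda g: (groups.count(g), -g))
        locus = AlleleLocus(
            locus_id=f"L{i:05d}", homologous_group=group,
            allele_class=AlleleLocus.class_for_count(len(members)))
        for m in members:
            setattr(locus, f"gene_{hap_of[m].lower()}", m)
        loci.append(locus)
    return loci


# ---------------------------------------------------------------------------
# census

@dataclass
class AlleleCensus:
    """Locus-class and per-haplotype gene accounting of an allele table."""

    n_four: int = 0
    n_three: int = 0
    n_two: int = 0
    n_singleton: int = 0
    singletons_per_haplotype: dict[str, int] = field(default_factory=dict)
    shared_per_haplotype: dict[str, int] = field(default_factory=dict)

    @property
    def total_singletons(self) -> int:
        return sum(self.singletons_per_haplotype.values())

    @property
    def total_shared(self) -> int:
        return sum(self.shared_per_haplotype.values())

    @property
    def total_genes(self) -> int:
        return 4 * self.n_four + 3 * self.n_three + 2 * self.n_two + self.n_singleton

    @property
    def four_allele_fraction(self) -> float:
        n_loci = self.n_four + self.n_three + self.n_two + self.n_singleton
        return self.n_four / n_loci if n_loci else 0.0


def allele_census(loci: Sequence[AlleleLocus]) -> AlleleCensus:
    census = AlleleCensus(
        singletons_per_haplotype={h: 0 for h in HAPLOTYPES},
        shared_per_haplotype={h: 0 for h in HAPLOTYPES})
    for locus in loci:
        members = locus.members()
        if locus.allele_class == "four":
            census.n_four += 1
        elif locus.allele_class == "three":
            census.n_three += 1
        elif locus.allele_class == "two":
            census.n_two += 1
        else:
            census.n_singleton += 1
        target = (census.singletons_per_haplotype if len(members) == 1
                  else census.shared_per_haplotype)
        for hap in members:
            target[hap] += 1
    return census


# ---------------------------------------------------------------------------
# singleton classification

def classify_singletons(loci: Sequence[AlleleLocus], gene_sets: dict[str, GeneSet],
                        blocks: Sequence[SyntenyBlock] = (),
                        min_identity: float = 80.0) -> list[SingletonCall]:
    """Best-homolog classification of singleton genes.

    The best homolog is the highest-identity gene among all other genes
    (k-mer prescreen, then global alignment). Calls with identity strictly
    above ``min_identity`` record the homolog locus's allele class,
    homologous-group retention, and an inversion flag derived from the
    singleton's strand against the consensus strand relation of the nearest
    syntenic block on its chromosome (within 50 genes, else False).
    """
    genes_by_id: dict[str, GeneModel] = {}
    for gs in gene_sets.values():
        genes_by_id.update(gs.by_id())
    locus_of: dict[str, AlleleLocus] = {}
    for locus in loci:
        for gid in locus.members().values():
            locus_of[gid] = locus

    singleton_ids = [locus.members().popitem()[1] for locus in loci
                     if locus.allele_class == "singleton"]
    all_kmers = {gid: _kmers(g.protein) for gid, g in genes_by_id.items()}
    index: dict[str, list[str]] = {}
    for gid, ks in all_kmers.items():
        for k in ks:
            index.setdefault(k, []).append(gid)

    # positional index per chromosome for the inversion consensus
    orders: dict[str, dict[str, tuple[str, int]]] = {
        hap: _gene_order(gs) for hap, gs in gene_sets.items()}
    block_positions = _block_position_index(blocks, orders, genes_by_id)

    calls: list[SingletonCall] = []
    for gid in sorted(singleton_ids):
        g = genes_by_id[gid]
        scores: dict[str, int] = {}
        for k in all_kmers[gid]:
            for other in index.get(k, ()):
                if other != gid:
                    scores[other] = scores.get(other, 0) + 1
        cands = sorted(scores, key=lambda t: (-scores[t], t))[:N_CANDIDATES]
        best_id, best_ident = None, -1.0
        for c in cands:
            ident = protein_identity(g.protein, genes_by_id[c].protein)
            if ident > best_ident or (ident == best_ident and (best_id is None or c < best_id)):
                best_id, best_ident = c, ident
        if best_id is None or best_ident <= min_identity:
            calls.append(SingletonCall(gene_id=gid, best_homolog=None, identity=0.0,
                                       homolog_class="none", origin_category="no-homolog"))
            continue
        hom = genes_by_id[best_id]
        hom_locus = locus_of[best_id]
        hom_class = ("singleton-paralog" if hom_locus.allele_class == "singleton"
                     else hom_locus.allele_class)
        same_group = g.homologous_group == hom_locus.homologous_group
        inversion = _singleton_inversion(g, hom, orders, block_positions)
        origin = f"{hom_class}:{'same-group' if same_group else 'cross-group'}"
        calls.append(SingletonCall(
            gene_id=gid, best_homolog=best_id, identity=best_ident,
            homolog_class=hom_class, same_group=same_group, inversion=inversion,
            origin_category=origin))
    return calls


def _block_position_index(blocks, orders, genes_by_id):
    """chromosome -> [(gene order index, strand relation of the block)]."""
    idx: dict[str, list[tuple[int, bool]]] = {}
    for blk in blocks:
        genes_a = blk.anchor_genes_a.split(",")
        genes_b = blk.anchor_genes_b.split(",")
        rels = [genes_by_id[a].strand == genes_by_id[b].strand
                for a, b in zip(genes_a, genes_b) if a in genes_by_id and b in genes_by_id]
        if not rels:
            continue
        consensus = sum(rels) >= len(rels) / 2
        for side, genes in (("a", genes_a), ("b", genes_b)):
            hap = blk.haplotype_a if side == "a" else blk.haplotype_b
            for gid in genes:
                if gid in orders.get(hap, {}):
                    chrom, pos = orders[hap][gid]
                    idx.setdefault(chrom, []).append((pos, consensus))
    for lst in idx.values():
        lst.sort()
    return idx


_INVERSION_WINDOW_GENES = 50


def _singleton_inversion(gene: GeneModel, homolog: GeneModel, orders,
                         block_positions) -> bool:
    chrom_positions = block_positions.get(gene.chromosome)
    if not chrom_positions:
        return False
    _, pos = orders[gene.haplotype][gene.gene_id]
    nearest = min(chrom_positions, key=lambda t: (abs(t[0] - pos), t[0]))
    if abs(nearest[0] - pos) > _INVERSION_WINDOW_GENES:
        return False
    consensus_rel = nearest[1]
    rel = gene.strand == homolog.strand
    return rel != consensus_rel


def percent_of(part: int, whole: int) -> int:
    """Integer percentage as printed in the singleton-origin summaries."""
    if whole == 0:
        return 0
    return int(round(100.0 * part / whole))


def summarize_singletons(calls: Sequence[SingletonCall]) -> dict:
    """Counts and integer percentages of singleton origin classes."""
    n = len(calls)
    by_class: dict[str, list[SingletonCall]] = {}
    for c in calls:
        by_class.setdefault(c.homolog_class, []).append(c)
    summary: dict = {"n_singletons": n, "classes": {}}
    for cls, members in sorted(by_class.items()):
        same = sum(1 for c in members if c.same_group)
        inv = sum(1 for c in members if c.inversion)
        summary["classes"][cls] = {
            "n": len(members),
            "percent_of_singletons": percent_of(len(members), n),
            "n_same_group": same,
            "percent_same_group": percent_of(same, len(members)),
            "n_inverted": inv,
            "percent_inverted": percent_of(inv, len(members)),
        }
    return summary


def run_synteny(gene_sets: dict[str, GeneSet], min_identity: float = 60.0,
                max_gap: int = 10, min_block: int = 4
                ) -> tuple[dict[tuple[str, str], list[AnchorPair]],
                           list[SyntenyBlock], list[AlleleLocus]]:
    """Anchors for all six haplotype pairs, blocks, and the allele table."""
    anchors_by_pair: dict[tuple[str, str], list[AnchorPair]] = {}
    all_blocks: list[SyntenyBlock] = []
    haps = sorted(gene_sets)
    for ha, hb in itertools.combinations(haps, 2):
        anchors = pairwise_anchors(gene_sets[ha], gene_sets[hb], min_identity)
        blocks = chain_blocks(anchors, gene_sets[ha], gene_sets[hb],
                              max_gap=max_gap, min_block=min_block)
        anchors_by_pair[(ha, hb)] = anchors
        all_blocks.extend(blocks)
        log.info("haplotypes %s-%s: %d anchors, %d blocks", ha, hb, len(anchors), len(blocks))
    loci = build_allele_table(anchors_by_pair, gene_sets)
    return anchors_by_pair, all_blocks, loci
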