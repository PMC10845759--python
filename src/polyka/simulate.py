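"""Synthetic autotetraploid generator with a ground-truth ledger.

The generator emulates the statistical structure of a recently
tetraploidized genome carrying four highly homogeneous haplotypes:

* ancestral gene complements per base chromosome, some genes carrying an
  older (beta) or younger (alpha) within-genome paralog partner;
* tetraploidization producing four allelic copies per locus at a small
  synonymous divergence (default pairwise dS 0.007);
* programmed allele losses creating 3-, 2-allele loci and loss singletons,
  plus planted tandem-copy and relocated-copy singletons;
* segmental inversions (strand flips + order reversal) and cross-chromosome
  translocations at low rates;
* negative-binomial expression counts over stages x replicates with planted
  allele-specific expression of configurable effect size; and
* chromosome sequences carrying terminal 7-bp telomere arrays
  (CCCTAAA at 5', TTTAGGG at 3') and one centromeric tandem array of a
  random 150-180 bp monomer.

Every emitted gene appears in exactly one truth record, so recovery of
allele tables, Ks peaks, ASE calls and chromosome landmarks can be scored
exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import formats_io
from .ksdating import CODON_TABLE, NUCLEOTIDES, SENSE_CODONS, STOP_CODONS, codon_site_counts
from .models import GeneModel, GeneSet, HAPLOTYPES

log = logging.getLogger(__name__)

TELOMERE_5P = "CCCTAAA"
TELOMERE_3P = "TTTAGGG"


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic tetraploid.

    Divergence defaults follow the three dated events: allelic pairs at
    dS 0.007 (tetraploidization, ~1.03 Mya at r = 3.39e-9), alpha paralogs
    at 0.127 (~18.7 Mya) and beta paralogs at 0.50 (~73.7 Mya). Loss rates
    0.10/0.12/0.20 leave 58% of loci with four alleles. The ASE fraction
    0.054 matches the observed share of significantly imbalanced
    four-allele loci.
    """

    n_chromosomes: int = 4
    genes_per_chromosome: int = 150
    codons_per_gene: int = 200
    ds_allelic: float = 0.007
    ds_alpha: float = 0.127
    ds_beta: float = 0.50
    omega: float = 0.15
    loss_rate_to_3: float = 0.10
    loss_rate_to_2: float = 0.12
    loss_rate_to_1: float = 0.20
    inversion_rate: float = 0.08
    translocation_rate: float = 0.02
    alpha_pair_fraction: float = 0.13
    beta_pair_fraction: float = 0.07
    tandem_singleton_rate: float = 0.03
    relocated_singleton_rate: float = 0.03
    singleton_copy_ds: float = 0.02
    ase_fraction: float = 0.054
    ase_effect: float = 2.0
    ase_consistent_fraction: float = 0.5
    nb_dispersion: float = 0.1
    mean_expression: float = 300.0
    expression_sigma: float = 1.0
    replicates: int = 3
    stages: int = 4
    inversion_segment: int = 6
    translocation_segment: int = 6
    telomere_copies: int = 80
    centromere_copies: int = 300
    centromere_monomer_min: int = 150
    centromere_monomer_max: int = 180
    intergenic_length: int = 400
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "loss_rate_to_3": self.loss_rate_to_3,
            "loss_rate_to_2": self.loss_rate_to_2,
            "loss_rate_to_1": self.loss_rate_to_1,
            "inversion_rate": self.inversion_rate,
            "translocation_rate": self.translocation_rate,
            "alpha_pair_fraction": self.alpha_pair_fraction,
            "beta_pair_fraction": self.beta_pair_fraction,
            "tandem_singleton_rate": self.tandem_singleton_rate,
            "relocated_singleton_rate": self.relocated_singleton_rate,
            "ase_fraction": self.ase_fraction,
            "ase_consistent_fraction": self.ase_consistent_fraction,
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.loss_rate_to_3 + self.loss_rate_to_2 + self.loss_rate_to_1 > 1.0:
            raise ValueError("loss rates sum above 1")
        for name in ("ds_allelic", "ds_alpha", "ds_beta", "omega", "nb_dispersion",
                     "singleton_copy_ds"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# --- truth records (flat, table-serialisable) ------------------------------

@dataclass
class TruthLocus:
    locus_id: str
    homologous_group: int
    n_alleles: int
    gene_a: Optional[str] = None
    gene_b: Optional[str] = None
    gene_c: Optional[str] = None
    gene_d: Optional[str] = None

    def members(self) -> dict[str, str]:
        return {h: g for h, g in zip(HAPLOTYPES,
                                     (self.gene_a, self.gene_b, self.gene_c, self.gene_d))
                if g}


@dataclass
class TruthPair:
    gene_1: str
    gene_2: str
    event: str  # allelic | alpha | beta | copy
    target_ds: float


@dataclass
class TruthSingleton:
    gene_id: str
    origin: str  # loss | tandem | relocated
    source_gene: str = ""
    source_locus: str = ""


@dataclass
class TruthRearrangement:
    kind: str  # inversion | translocation
    haplotype: str
    chromosome: str
    dest_chromosome: str
    gene_ids: str  # comma-joined


@dataclass
class TruthASE:
    locus_id: str
    consistent: bool
    effect: float
    dominant_by_stage: str  # comma-joined haplotype letters


@dataclass
class TruthFeature:
    chromosome: str
    kind: str  # telomere_5p | telomere_3p | centromere
    start: int
    end: int
    monomer: str


@dataclass
class SyntheticTruth:
    loci: list[TruthLocus] = field(default_factory=list)
    pairs: list[TruthPair] = field(default_factory=list)
    singletons: list[TruthSingleton] = field(default_factory=list)
    rearrangements: list[TruthRearrangement] = field(default_factory=list)
    ase: list[TruthASE] = field(default_factory=list)
    features: list[TruthFeature] = field(default_factory=list)

    def pairs_by_event(self, event: str) -> list[tuple[str, str]]:
        return [(p.gene_1, p.gene_2) for p in self.pairs if p.event == event]


# --- codon-level evolution -------------------------------------------------

_SYN_ALTERNATIVES: dict[str, list[str]] = {}
_NONSYN_ALTERNATIVES: dict[str, list[str]] = {}
for _codon in SENSE_CODONS:
    syn, non = [], []
    for _pos in range(3):
        for _nt in NUCLEOTIDES:
            if _nt == _codon[_pos]:
                continue
            _alt = _codon[:_pos] + _nt + _codon[_pos + 1:]
            if _alt in STOP_CODONS:
                continue
            (syn if CODON_TABLE[_alt] == CODON_TABLE[_codon] else non).append(_alt)
    _SYN_ALTERNATIVES[_codon] = syn
    _NONSYN_ALTERNATIVES[_codon] = non


def evolve_codon_pair(cds: str, target_ds: float, omega: float,
                      seed: int | np.random.Generator) -> str:
    """Mutate a CDS so its expected NG86 divergence from the input is
    (Ks ~ target_ds, Ka ~ omega * target_ds).

    Substitution events are drawn as Poisson counts scaled by the NG86
    synonymous/nonsynonymous site totals of the input, allocated to codons
    in proportion to their site counts, and applied sequentially as random
    synonymous (or nonsynonymous) single-nucleotide changes; changes that
    would create a stop codon are never proposed. Multiple hits at one
    codon are possible, which is what the Jukes-Cantor correction of the
    estimator expects.
    """
    if target_ds < 0:
        raise ValueError("target_ds must be non-negative")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for c in codons:
        if c in STOP_CODONS:
            raise ValueError("CDS contains an internal stop codon")

    site_s = np.array([codon_site_counts(c)[0] for c in codons])
    site_n = np.array([codon_site_counts(c)[1] for c in codons])
    S, N = site_s.sum(), site_n.sum()

    n_syn = rng.poisson(target_ds * S)
    n_non = rng.poisson(omega * target_ds * N)
    syn_alloc = rng.multinomial(n_syn, site_s / S) if S > 0 and n_syn else np.zeros(len(codons), int)
    non_alloc = rng.multinomial(n_non, site_n / N) if N > 0 and n_non else np.zeros(len(codons), int)

    for idx in np.nonzero(syn_alloc + non_alloc)[0]:
        for kind, n_events in (("syn", syn_alloc[idx]), ("non", non_alloc[idx])):
            table = _SYN_ALTERNATIVES if kind == "syn" else _NONSYN_ALTERNATIVES
            for _ in range(int(n_events)):
                options = table[codons[idx]]
                if not options:  # codon drifted to one with no such change (ATG/TGG)
                    continue
                codons[idx] = options[rng.integers(len(options))]
    return "".join(codons)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random sense-codon CDS starting with ATG (no stop appended)."""
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(NUCLEOTIDES))[rng.integers(0, 4, n)])


_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# --- genome simulation -----------------------------------------------------

@dataclass
class _SimGene:
    """Internal mutable gene during simulation (before layout)."""
    gene_id: str
    haplotype: str
    group: int  # current physical chromosome group
    order: float  # sort key within chromosome
    strand: str
    cds: str


def simulate_genome(config: SimulationConfig
                    ) -> tuple[dict[str, GeneSet], dict[str, str], SyntheticTruth]:
    """Build four haplotype gene sets, chromosome sequences and the truth ledger."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_genes, rng_struct, rng_chrom = (np.random.default_rng(c) for c in ss.spawn(3))
    truth = SyntheticTruth()

    n_chr = config.n_chromosomes
    n_genes = config.genes_per_chromosome
    branch_allelic = config.ds_allelic / 2.0
    # Paralog branches are planted so the *pairwise* divergence, after the
    # extra allelic drift of tetraploidization, lands on the configured dS.
    branch_alpha = max(config.ds_alpha - config.ds_allelic, 0.0)
    branch_beta = max(config.ds_beta - config.ds_allelic, 0.0)

    # 1. ancestral chromosomes with paralog pair structure
    ancestral: dict[int, list[str]] = {}  # group -> CDS per slot
    paralog_partner: dict[int, list[tuple[int, int, str]]] = {}  # (src, copy, event)
    for g in range(1, n_chr + 1):
        n_alpha = int(round(config.alpha_pair_fraction * n_genes))
        n_beta = int(round(config.beta_pair_fraction * n_genes))
        slots = [random_cds(config.codons_per_gene, rng_genes) for _ in range(n_genes)]
        perm = rng_struct.permutation(n_genes)
        pairs = []
        k = 0
        for event, count, branch in (("alpha", n_alpha, branch_alpha),
                                     ("beta", n_beta, branch_beta)):
            for _ in range(count):
                src, copy = int(perm[k]), int(perm[k + 1])
                k += 2
                slots[copy] = evolve_codon_pair(slots[src], branch, config.omega, rng_genes)
                pairs.append((src, copy, event))
        ancestral[g] = slots
        paralog_partner[g] = pairs

    # 2. tetraploidize + losses + singleton planting
    genes: dict[str, list[_SimGene]] = {h: [] for h in HAPLOTYPES}
    slot_gene_ids: dict[tuple[int, int], dict[str, str]] = {}
    locus_counter = 0
    for g in range(1, n_chr + 1):
        for slot in range(n_genes):
            locus_counter += 1
            locus_id = f"T{locus_counter:05d}"
            copies: dict[str, _SimGene] = {}
            for hap in HAPLOTYPES:
                gid = f"{hap}c{g:02d}s{slot:04d}"
                cds = evolve_codon_pair(ancestral[g][slot], branch_allelic,
                                        config.omega, rng_genes)
                copies[hap] = _SimGene(gid, hap, g, float(slot), "+", cds)

            # allele loss
            u = rng_struct.random()
            if u < config.loss_rate_to_3:
                n_lost = 1
            elif u < config.loss_rate_to_3 + config.loss_rate_to_2:
                n_lost = 2
            elif u < config.loss_rate_to_3 + config.loss_rate_to_2 + config.loss_rate_to_1:
                n_lost = 3
            else:
                n_lost = 0
            lost = set(rng_struct.choice(list(HAPLOTYPES), size=n_lost, replace=False))
            kept = {h: sg for h, sg in copies.items() if h not in lost}
            for h, sg in kept.items():
                genes[h].append(sg)
            slot_gene_ids[(g, slot)] = {h: sg.gene_id for h, sg in kept.items()}

            tl = TruthLocus(locus_id=locus_id, homologous_group=g, n_alleles=len(kept))
            for h, sg in kept.items():
                setattr(tl, f"gene_{h.lower()}", sg.gene_id)
            truth.loci.append(tl)
            if len(kept) == 1:
                only = next(iter(kept.values()))
                truth.singletons.append(
                    TruthSingleton(gene_id=only.gene_id, origin="loss", source_locus=locus_id))
            haps = sorted(kept)
            for i in range(len(haps)):
                for j in range(i + 1, len(haps)):
                    truth.pairs.append(TruthPair(kept[haps[i]].gene_id, kept[haps[j]].gene_id,
                                                 "allelic", config.ds_allelic))

            # planted extra singletons copied off four-allele loci
            if len(kept) == 4:
                if rng_struct.random() < config.tandem_singleton_rate:
                    hap = str(rng_struct.choice(list(HAPLOTYPES)))
                    src = copies[hap]
                    gid = f"{src.gene_id}t"
                    cds = evolve_codon_pair(src.cds, config.singleton_copy_ds,
                                            config.omega, rng_genes)
                    genes[hap].append(_SimGene(gid, hap, g, float(slot) + 0.5, "+", cds))
                    truth.singletons.append(TruthSingleton(gid, "tandem", src.gene_id, locus_id))
                    truth.pairs.append(TruthPair(src.gene_id, gid, "copy",
                                                 config.singleton_copy_ds))
                if rng_struct.random() < config.relocated_singleton_rate and n_chr > 1:
                    hap = str(rng_struct.choice(list(HAPLOTYPES)))
                    src = copies[hap]
                    dest_choices = [c for c in range(1, n_chr + 1) if c != g]
                    dest = int(rng_struct.choice(dest_choices))
                    gid = f"{src.gene_id}r"
                    cds = evolve_codon_pair(src.cds, config.singleton_copy_ds,
                                            config.omega, rng_genes)
                    pos = float(rng_struct.uniform(0, n_genes)) - 0.25
                    genes[hap].append(_SimGene(gid, hap, dest, pos, "+", cds))
                    truth.singletons.append(TruthSingleton(gid, "relocated",
                                                           src.gene_id, locus_id))
                    truth.pairs.append(TruthPair(src.gene_id, gid, "copy",
                                                 config.singleton_copy_ds))

    # within-haplotype paralog pairs (alpha / beta), where both copies survive
    for g in range(1, n_chr + 1):
        for src, copy, event in paralog_partner[g]:
            target = config.ds_alpha if event == "alpha" else config.ds_beta
            for hap in HAPLOTYPES:
                gid_s = slot_gene_ids[(g, src)].get(hap)
                gid_c = slot_gene_ids[(g, copy)].get(hap)
                if gid_s and gid_c:
                    truth.pairs.append(TruthPair(gid_s, gid_c, event, target))

    # 3. rearrangements on haplotypes B, C, D (hapA is the reference frame)
    n_inv = int(round(config.inversion_rate * n_genes / config.inversion_segment))
    n_trans = int(round(config.translocation_rate * n_genes / config.translocation_segment))
    for hap in ("B", "C", "D"):
        for g in range(1, n_chr + 1):
            chrom_genes = sorted((sg for sg in genes[hap] if sg.group == g),
                                 key=lambda s: s.order)
            usable = len(chrom_genes)
            starts: list[int] = []
            taken: set[int] = set()
            for _ in range(n_inv + n_trans):
                for _attempt in range(50):
                    s = int(rng_struct.integers(0, usable - config.inversion_segment))
                    span = set(range(s - 1, s + config.inversion_segment + 1))
                    if not span & taken:
                        taken |= span
                        starts.append(s)
                        break
            for ev_idx, s in enumerate(starts):
                if ev_idx < n_inv:
                    seg = chrom_genes[s:s + config.inversion_segment]
                    orders = [x.order for x in seg]
                    for sg, new_order in zip(seg, reversed(orders)):
                        sg.order = new_order
                        sg.strand = "-" if sg.strand == "+" else "+"
                    truth.rearrangements.append(TruthRearrangement(
                        "inversion", hap, f"hap{hap}_Chr{g:02d}", f"hap{hap}_Chr{g:02d}",
                        ",".join(x.gene_id for x in seg)))
                else:
                    seg = chrom_genes[s:s + config.translocation_segment]
                    dest_choices = [c for c in range(1, n_chr + 1) if c != g]
                    dest = int(rng_struct.choice(dest_choices))
                    base = float(rng_struct.uniform(0, n_genes))
                    for off, sg in enumerate(seg):
                        sg.group = dest
                        sg.order = base + off * 0.001
                    truth.rearrangements.append(TruthRearrangement(
                        "translocation", hap, f"hap{hap}_Chr{g:02d}", f"hap{hap}_Chr{dest:02d}",
                        ",".join(x.gene_id for x in seg)))

    # 4. layout + chromosome sequences
    gene_sets: dict[str, GeneSet] = {}
    chrom_seqs: dict[str, str] = {}
    for hap in HAPLOTYPES:
        models: list[GeneModel] = []
        for g in range(1, n_chr + 1):
            chrom = f"hap{hap}_Chr{g:02d}"
            chrom_genes = sorted((sg for sg in genes[hap] if sg.group == g),
                                 key=lambda s: (s.order, s.gene_id))
            pieces: list[str] = []
            pos = 0

            tel5 = TELOMERE_5P * config.telomere_copies
            pieces.append(tel5)
            truth.features.append(TruthFeature(chrom, "telomere_5p", 0, len(tel5), TELOMERE_5P))
            pos += len(tel5)

            monomer_len = int(rng_chrom.integers(config.centromere_monomer_min,
                                                 config.centromere_monomer_max + 1))
            monomer = _random_dna(monomer_len, rng_chrom)
            half = len(chrom_genes) // 2
            for i, sg in enumerate(chrom_genes):
                if i == half:
                    gap = _random_dna(config.intergenic_length, rng_chrom)
                    pieces.append(gap)
                    pos += len(gap)
                    cen = monomer * config.centromere_copies
                    pieces.append(cen)
                    truth.features.append(TruthFeature(chrom, "centromere", pos,
                                                       pos + len(cen), monomer))
                    pos += len(cen)
                gap = _random_dna(config.intergenic_length, rng_chrom)
                pieces.append(gap)
                pos += len(gap)
                embedded = sg.cds if sg.strand == "+" else revcomp(sg.cds)
                pieces.append(embedded)
                models.append(GeneModel(
                    gene_id=sg.gene_id, haplotype=hap, chromosome=chrom,
                    homologous_group=g, start=pos, end=pos + len(embedded),
                    strand=sg.strand, cds=sg.cds,
                    protein=formats_io.translate_cds(sg.cds, sg.gene_id)))
                pos += len(embedded)
            gap = _random_dna(config.intergenic_length, rng_chrom)
            pieces.append(gap)
            pos += len(gap)
            tel3 = TELOMERE_3P * config.telomere_copies
            pieces.append(tel3)
            truth.features.append(TruthFeature(chrom, "telomere_3p", pos,
                                               pos + len(tel3), TELOMERE_3P))
            chrom_seqs[chrom] = "".join(pieces)
        gs = GeneSet(haplotype=hap, genes=models)
        gs.sort()
        gene_sets[hap] = gs

    return gene_sets, chrom_seqs, truth


# --- expression simulation -------------------------------------------------

def simulate_counts(truth: SyntheticTruth, config: SimulationConfig,
                    gene_sets: dict[str, GeneSet]
                    ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Negative-binomial count matrix with planted allelic imbalance.

    Returns (counts genes x samples, gene lengths in bp, design table).
    Balanced loci share one expression program across their alleles; ASE
    loci multiply the dominant allele's mean by 2**effect, either with one
    dominant haplotype in every stage (consistent) or re-drawn per stage
    (inconsistent). The ledger is updated with the planted ASE records.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[3])
    all_genes = [g for gs in gene_sets.values() for g in gs.genes]
    lengths = pd.Series({g.gene_id: len(g.cds) for g in all_genes}, name="length")

    samples = [f"stage{s + 1}_rep{r + 1}"
               for s in range(config.stages) for r in range(config.replicates)]
    design = pd.DataFrame({
        "sample": samples,
        "stage": [f"stage{s + 1}" for s in range(config.stages) for _ in range(config.replicates)],
        "replicate": [r + 1 for _ in range(config.stages) for r in range(config.replicates)],
    })

    mean = pd.DataFrame(0.0, index=lengths.index,
                        columns=[f"stage{s + 1}" for s in range(config.stages)])
    locus_of_gene = {g: tl for tl in truth.loci for g in tl.members().values()}

    four_allele = [tl for tl in truth.loci if tl.n_alleles == 4]
    n_ase = int(round(config.ase_fraction * len(four_allele)))
    ase_idx = set(rng.choice(len(four_allele), size=n_ase, replace=False)) if n_ase else set()

    def base_program() -> np.ndarray:
        base = config.mean_expression * rng.lognormal(0.0, config.expression_sigma)
        stage_mult = rng.lognormal(0.0, 0.3, size=config.stages)
        return base * stage_mult

    seen: set[str] = set()
    for tl in truth.loci:
        members = tl.members()
        prog = base_program()
        for hap, gid in members.items():
            mean.loc[gid, :] = prog
            seen.add(gid)
    for i, tl in enumerate(four_allele):
        if i not in ase_idx:
            continue
        members = tl.members()
        consistent = rng.random() < config.ase_consistent_fraction
        haps = sorted(members)
        if consistent:
            dom = str(rng.choice(haps))
            dominants = [dom] * config.stages
        else:
            dominants = [str(rng.choice(haps)) for _ in range(config.stages)]
            while len(set(dominants)) == 1:  # a switch must actually occur
                dominants = [str(rng.choice(haps)) for _ in range(config.stages)]
        for s, dom in enumerate(dominants):
            mean.iloc[mean.index.get_loc(members[dom]), s] *= 2.0 ** config.ase_effect
        truth.ase.append(TruthASE(tl.locus_id, consistent, config.ase_effect,
                                  ",".join(dominants)))
    # genes outside any locus record (none by construction) and planted extra
    # singletons are not in truth.loci member maps; give them programs too
    for g in all_genes:
        if g.gene_id not in seen:
            mean.loc[g.gene_id, :] = base_program()

    disp = config.nb_dispersion
    counts = pd.DataFrame(0, index=lengths.index, columns=samples, dtype=int)
    for s in range(config.stages):
        mu = mean[f"stage{s + 1}"].to_numpy()
        for r in range(config.replicates):
            lam = rng.gamma(shape=1.0 / disp, scale=mu * disp) if disp > 0 else mu
            counts[f"stage{s + 1}_rep{r + 1}"] = rng.poisson(lam)
    return counts, lengths, design


# --- writing ----------------------------------------------------------------

def write_simulation(outdir: str | Path, gene_sets: dict[str, GeneSet],
                     chrom_seqs: dict[str, str], truth: SyntheticTruth,
                     counts: pd.DataFrame, lengths: pd.Series,
                     design: pd.DataFrame, config: SimulationConfig) -> None:
    """Write the full synthetic dataset + truth ledger + config echo."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for hap, gs in gene_sets.items():
        formats_io.write_gff3(gs.genes, out / f"hap{hap}.gff3")
        formats_io.write_fasta({g.gene_id: g.cds for g in gs.genes}, out / f"hap{hap}.cds.fa")
        formats_io.write_fasta({g.gene_id: g.protein for g in gs.genes},
                               out / f"hap{hap}.prot.fa")
    formats_io.write_fasta(chrom_seqs, out / "genome.fa")
    counts.rename_axis("gene_id").to_csv(out / "counts.tsv", sep="\t")
    lengths.rename_axis("gene_id").to_csv(out / "lengths.tsv", sep="\t")
    design.to_csv(out / "design.tsv", sep="\t", index=False)
    formats_io.write_tables(truth.loci, out / "truth_loci.tsv", TruthLocus)
    formats_io.write_tables(truth.pairs, out / "truth_pairs.tsv", TruthPair)
    formats_io.write_tables(truth.singletons, out / "truth_singletons.tsv", TruthSingleton)
    formats_io.write_tables(truth.rearrangements, out / "truth_rearrangements.tsv",
                            TruthRearrangement)
    formats_io.write_tables(truth.ase, out / "truth_ase.tsv", TruthASE)
    formats_io.write_tables(truth.features, out / "truth_features.tsv", TruthFeature)
    config.to_yaml(out / "config.yaml")
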