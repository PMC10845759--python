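"""Domain records shared across the pipeline.

All genomic intervals held in memory are 0-based half-open; conversion to
GFF3 (1-based inclusive) or BED happens only in :mod:`polyka.formats_io`.
Records are flat dataclasses so they can round-trip through the generic
TSV table writer without custom serialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

HAPLOTYPES = ("A", "B", "C", "D")


@dataclass
class GeneModel:
    """One gene on one haplotype.

    Coordinates are 0-based half-open on the haplotype's chromosome.
    ``homologous_group`` is the base-chromosome number shared by the four
    homologous chromosomes (one per haplotype) descending from it.
    """

    gene_id: str
    haplotype: str
    chromosome: str
    homologous_group: int
    start: int
    end: int
    strand: str
    cds: str = ""
    protein: str = ""

    def __post_init__(self) -> None:
        if self.haplotype not in HAPLOTYPES:
            raise ValueError(f"unknown haplotype {self.haplotype!r}")
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


@dataclass
class GeneSet:
    """All genes of one haplotype, ordered by start within each chromosome."""

    haplotype: str
    genes: list[GeneModel] = field(default_factory=list)

    def by_chromosome(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            out.setdefault(g.chromosome, []).append(g)
        for lst in out.values():
            lst.sort(key=lambda g: (g.start, g.gene_id))
        return out

    def by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def sort(self) -> None:
        self.genes.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))


@dataclass
class AnchorPair:
    """Reciprocal-best protein match between two haplotypes."""

    gene_a: str
    gene_b: str
    identity: float
    reciprocal_best: bool = True
    block_id: Optional[str] = None


@dataclass
class SyntenyBlock:
    """A collinear chain of anchors between one chromosome pair.

    ``orientation`` is ``same`` when gene order runs in the same direction
    in both genomes and ``inverted`` when it is reversed in the second.
    """

    block_id: str
    haplotype_a: str
    haplotype_b: str
    chromosome_a: str
    chromosome_b: str
    orientation: str
    n_anchors: int
    anchor_genes_a: str = ""  # comma-joined gene ids, genome-A order
    anchor_genes_b: str = ""


@dataclass
class AlleleLocus:
    """A locus grouping 1-4 allelic genes (at most one per haplotype)."""

    locus_id: str
    homologous_group: int
    allele_class: str  # four | three | two | singleton
    gene_a: Optional[str] = None
    gene_b: Optional[str] = None
    gene_c: Optional[str] = None
    gene_d: Optional[str] = None

    _SLOTS = {"A": "gene_a", "B": "gene_b", "C": "gene_c", "D": "gene_d"}

    def members(self) -> dict[str, str]:
        """Haplotype -> gene id, only for haplotypes present at the locus."""
        out = {}
        for hap, slot in self._SLOTS.items():
            gid = getattr(self, slot)
            if gid:
                out[hap] = gid
        return out

    @property
    def n_alleles(self) -> int:
        return len(self.members())

    @staticmethod
    def class_for_count(n: int) -> str:
        return {4: "four", 3: "three", 2: "two", 1: "singleton"}[n]


@dataclass
class SingletonCall:
    """Origin classification of a gene without alleles."""

    gene_id: str
    best_homolog: Optional[str]
    identity: float
    homolog_class: str  # four | three | two | singleton-paralog | none
    same_group: Optional[bool] = None
    inversion: Optional[bool] = None
    origin_category: str = ""


@dataclass
class KsEstimate:
    """Nei-Gojobori (1986) quantities for one aligned gene pair.

    S and N are synonymous / nonsynonymous site counts averaged over the two
    sequences; Sd and Nd the path-averaged difference counts; Ks and Ka the
    Jukes-Cantor corrected rates. ``defined`` is False when pS (pN) reaches
    the JC singularity at 3/4.
    """

    gene_1: str
    gene_2: str
    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    defined: bool
    method: str = "NG86"


@dataclass
class KsPeak:
    label: str  # allelic | paralog | ortholog
    mode: float
    n_pairs: int
    bandwidth: float
    height: float = 0.0


@dataclass
class DatingResult:
    """T = Ks / (2 r), with r in substitutions/site/year and T in years."""

    ks: float
    r: float
    t_years: float

    @property
    def mya(self) -> float:
        return round(self.t_years / 1e6, 2)


@dataclass
class ASERecord:
    """Allele-pair expression comparison for one locus at one stage."""

    locus_id: str
    stage: str
    allele_i: str
    allele_j: str
    tpm_i: float
    tpm_j: float
    log2fc: float
    p_value: float
    fdr: float
    significant: bool
    dominant_allele: str


@dataclass
class ASEGClassification:
    locus_id: str
    label: str  # consistent | inconsistent | balanced


@dataclass
class DomainAnnotation:
    """One Pfam-style domain hit; envelope coordinates are 1-based aa."""

    protein_id: str
    domain_name: str
    start: int
    end: int
    e_value: float = 0.0


@dataclass
class NLRCall:
    protein_id: str
    has_nbarc: bool
    has_tir: bool
    has_cc: bool
    has_lrr: bool
    nlr_class: str  # NBS | TIR-NBS | CC-NBS | NBS-LRR | CNL | TNL
    integrated_domains: str = ""  # comma-joined


@dataclass
class CBFCall:
    protein_id: str
    has_ap2: bool
    dsxwr_pos: Optional[int]
    long_sig_pos: Optional[int]
    long_sig_mismatches: Optional[int]
    is_cbf: bool


@dataclass
class TelomereCall:
    chromosome: str
    terminus: str  # 5p | 3p
    copies: int
    start: int
    end: int


@dataclass
class TandemArray:
    chromosome: str
    start: int
    end: int
    period: int
    copies: float
    monomer: str


@dataclass
class CentromereCall:
    chromosome: str
    start: int
    end: int
    repeat_fraction: float
    representative_monomer: str
    monomer_count: int
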