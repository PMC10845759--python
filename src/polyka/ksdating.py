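"""Synonymous-rate estimation and WGD dating.

Gene pairs are codon-aligned by global protein alignment and back-translation;
Ks and Ka come from the Nei-Gojobori (1986) counting method with Jukes-Cantor
correction; peaks of the Ks distribution are read off a Gaussian kernel
density estimate; and divergence times follow T = Ks / (2 r) with r the
neutral substitution rate per site per year.

NG86 in brief: each codon position contributes one "site" split between
synonymous and nonsynonymous in proportion to the fraction of its possible
single-nucleotide changes that preserve the encoded amino acid (changes to
stop codons are excluded from the fraction's denominator). Differences
between a codon pair are counted by enumerating every minimal mutational
path between them, discarding paths that pass through a stop codon, and
averaging the synonymous/nonsynonymous step counts over the surviving paths.
pS = Sd/S is then corrected for multiple hits with
Ks = -(3/4) ln(1 - (4/3) pS), and likewise Ka from pN.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from scipy.stats import gaussian_kde

from .align import align_proteins
from .models import DatingResult, GeneModel, KsEstimate, KsPeak

log = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
NEUTRAL_RATE = 3.39e-9  # substitutions / synonymous site / year

CODON_TABLE: dict[str, str] = {
    "".join(c): str(Seq("".join(c)).translate())
    for c in itertools.product(NUCLEOTIDES, repeat=3)
}
STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
SENSE_CODONS = tuple(c for c in CODON_TABLE if c not in STOP_CODONS)


class EmptyAlignmentError(ValueError):
    """No codon columns survive filtering."""


# ---------------------------------------------------------------------------
# NG86 site and difference counting

@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes exactly one site, split by the fraction of its
    non-stop single-nucleotide changes that are synonymous; S + N = 3.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if CODON_TABLE[alt] == aa:
                syn += 1
        s += syn / valid  # valid >= 1 for every sense codon position
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_difference_counts(codon_1: str, codon_2: str) -> Optional[tuple[float, float]]:
    """Path-averaged (synonymous, nonsynonymous) differences between two codons.

    Enumerates all orderings of the differing positions; a path is discarded
    if any intermediate codon is a stop. Returns None when every minimal
    path is blocked (the column should then be dropped).
    """
    diff_positions = [i for i in range(3) if codon_1[i] != codon_2[i]]
    if not diff_positions:
        return 0.0, 0.0
    syn_counts, nonsyn_counts = [], []
    for order in itertools.permutations(diff_positions):
        current = codon_1
        syn = nonsyn = 0
        blocked = False
        for step, pos in enumerate(order):
            nxt = current[:pos] + codon_2[pos] + current[pos + 1:]
            if nxt in STOP_CODONS and step < len(order) - 1:
                blocked = True
                break
            if nxt in STOP_CODONS:  # endpoint is a stop: caller filtered these
                blocked = True
                break
            if CODON_TABLE[current] == CODON_TABLE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if not blocked:
            syn_counts.append(syn)
            nonsyn_counts.append(nonsyn)
    if not syn_counts:
        return None
    return float(np.mean(syn_counts)), float(np.mean(nonsyn_counts))


@dataclass
class CodonAlignment:
    """Gap- and ambiguity-free codon columns of one aligned gene pair."""

    gene_1: str
    gene_2: str
    codons_1: list[str]
    codons_2: list[str]

    @property
    def n_codons(self) -> int:
        return len(self.codons_1)


def _codons(cds: str) -> list[str]:
    return [cds[i:i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]


def codon_align(gene_1: GeneModel, gene_2: GeneModel) -> CodonAlignment:
    """Protein-guided codon alignment of a gene pair.

    The proteins are globally aligned and the alignment back-translated onto
    the CDSs; columns containing a gap, a stop codon, or an ambiguous base
    are dropped.
    """
    row1, row2, _ = align_proteins(gene_1.protein, gene_2.protein)
    cods1, cods2 = _codons(gene_1.cds), _codons(gene_2.cds)
    i = j = 0
    keep1: list[str] = []
    keep2: list[str] = []
    for a, b in zip(row1, row2):
        c1 = cods1[i] if a != "-" else None
        c2 = cods2[j] if b != "-" else None
        if a != "-":
            i += 1
        if b != "-":
            j += 1
        if c1 is None or c2 is None:
            continue
        if any(nt not in NUCLEOTIDES for nt in c1 + c2):
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        keep1.append(c1)
        keep2.append(c2)
    if not keep1:
        raise EmptyAlignmentError(
            f"no codon columns retained for pair {gene_1.gene_id} / {gene_2.gene_id}"
        )
    return CodonAlignment(gene_1.gene_id, gene_2.gene_id, keep1, keep2)


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; caller guards p < 3/4."""
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86(alignment: CodonAlignment) -> KsEstimate:
    """NG86 Ks/Ka for one codon alignment.

    Codon columns whose minimal paths all pass through stops are dropped
    (logged); ``defined`` is False when pS (or pN) reaches 3/4.
    """
    if alignment.n_codons < 1:
        raise EmptyAlignmentError("alignment has no codons")
    S = N = Sd = Nd = 0.0
    used = 0
    for c1, c2 in zip(alignment.codons_1, alignment.codons_2):
        diffs = codon_difference_counts(c1, c2)
        if diffs is None:
            log.info("codon column %s/%s dropped: all substitution paths blocked", c1, c2)
            continue
        s1, _ = codon_site_counts(c1)
        s2, _ = codon_site_counts(c2)
        s_avg = (s1 + s2) / 2.0
        S += s_avg
        N += 3.0 - s_avg
        Sd += diffs[0]
        Nd += diffs[1]
        used += 1
    if used == 0:
        raise EmptyAlignmentError("all codon columns dropped")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    defined = pS < 0.75 and pN < 0.75
    ks = jukes_cantor(pS) if pS < 0.75 else float("nan")
    ka = jukes_cantor(pN) if pN < 0.75 else float("nan")
    return KsEstimate(
        gene_1=alignment.gene_1, gene_2=alignment.gene_2, n_codons=used,
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=ks, Ka=ka, defined=defined,
    )


def ks_for_pairs(genes_by_id: dict[str, GeneModel],
                 pairs: Iterable[tuple[str, str]]) -> list[KsEstimate]:
    """Codon-align and NG86-estimate every gene-id pair; unknown ids raise."""
    out = []
    for gid1, gid2 in pairs:
        aln = codon_align(genes_by_id[gid1], genes_by_id[gid2])
        out.append(ng86(aln))
    return out


# ---------------------------------------------------------------------------
# Peak detection and dating

GRID_POINTS = 2048
KS_MAX = 2.0


class InsufficientDataError(ValueError):
    pass


def detect_peaks(ks_values: Sequence[float], label: str = "",
                 log_scale: bool = False, min_n: int = 50,
                 ks_max: float = KS_MAX) -> list[KsPeak]:
    """KDE peaks of a Ks sample.

    Values are filtered to (0, ks_max]; exact zeros are identical-gene
    artifacts and excluded. The density uses a Gaussian kernel with
    Silverman's bandwidth on a fixed 2048-point grid over [0, ks_max]
    (or over the data range of log10 Ks when ``log_scale``). Peaks are
    local maxima reaching at least 10% of the global maximum, returned
    highest first, so the primary mode is first.
    """
    vals = np.asarray([v for v in ks_values if np.isfinite(v) and 0.0 < v <= ks_max])
    if vals.size < min_n:
        raise InsufficientDataError(
            f"{vals.size} usable Ks values < required minimum {min_n}"
        )
    if log_scale:
        data = np.log10(vals)
        grid = np.linspace(data.min(), data.max(), GRID_POINTS)
    else:
        data = vals
        grid = np.linspace(0.0, ks_max, GRID_POINTS)
    grid_step = float(grid[1] - grid[0]) if grid[-1] > grid[0] else 1e-9
    std = float(data.std(ddof=1)) if data.size > 1 else 0.0
    if std * (data.size * 3.0 / 4.0) ** (-0.2) < grid_step:
        # degenerate spread: floor the kernel at one grid step so a tight
        # cluster still registers as a peak on the fixed grid
        if std == 0.0:
            data = data + np.linspace(-grid_step / 10, grid_step / 10, data.size)
            std = float(data.std(ddof=1))
        kde = gaussian_kde(data, bw_method=grid_step / std)
    else:
        kde = gaussian_kde(data, bw_method="silverman")
    dens = kde(grid)
    bandwidth = float(kde.factor * std)
    peak_floor = 0.10 * dens.max()
    peaks = []
    for i in range(1, GRID_POINTS - 1):
        if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1] and dens[i] >= peak_floor:
            mode = 10 ** grid[i] if log_scale else grid[i]
            peaks.append(KsPeak(label=label, mode=float(mode), n_pairs=int(vals.size),
                                bandwidth=bandwidth, height=float(dens[i])))
    peaks.sort(key=lambda p: -p.height)
    return peaks


def ks_to_time(ks: float, r: float = NEUTRAL_RATE) -> DatingResult:
    """Divergence time T = Ks / (2 r) in years (``.mya`` rounds to 2 dp)."""
    if ks < 0:
        raise ValueError("ks must be non-negative")
    if r <= 0:
        raise ValueError("substitution rate r must be positive")
    return DatingResult(ks=ks, r=r, t_years=ks / (2.0 * r))
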