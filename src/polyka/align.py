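"""Shared global protein alignment (BLOSUM62, affine gaps open 10 / extend 1)."""

from __future__ import annotations

from Bio import Align
from Bio.Align import substitution_matrices


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = make_aligner()


def align_proteins(protein_a: str, protein_b: str) -> tuple[str, str, float]:
    """Return the gapped rows of one optimal global alignment and its score."""
    if not protein_a or not protein_b:
        raise ValueError("cannot align an empty protein sequence")
    aln = _ALIGNER.align(protein_a, protein_b)[0]
    return str(aln[0]), str(aln[1]), aln.score


def percent_identity(row_a: str, row_b: str) -> float:
    """Matches over alignment columns (gap columns counted), in [0, 100]."""
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    return 100.0 * matches / len(row_a)
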