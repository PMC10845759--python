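"""Rule-based gene family classification and promoter motif scanning.

NLR (NBS-LRR) immune receptors are classified from a Pfam-style domain
table plus an external coiled-coil flag into the six canonical
architecture classes; non-canonical domains inside an NLR are reported as
integrated domains. CBF/DREB1 candidates require an AP2 domain flanked by
the DSXWR motif (X = any residue) on the N-terminal side and the long
PKKPAGRKKFRETRHP signature (mismatch-tolerant) on the C-terminal side.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from .models import CBFCall, DomainAnnotation, NLRCall

log = logging.getLogger(__name__)

NBARC = "NB-ARC"
TIR = "TIR"
RPW8 = "RPW8"
LRR_PREFIX = "LRR"

DSXWR = "DSXWR"
LONG_SIGNATURE = "PKKPAGRKKFRETRHP"
MAX_MISMATCH_LONG = 5


def _is_lrr(domain: str) -> bool:
    return domain.upper().startswith(LRR_PREFIX)


def classify_nlr(domain_table: Sequence[DomainAnnotation],
                 cc_flags: dict[str, bool],
                 rpw8_as_cc: bool = True) -> list[NLRCall]:
    """Six-class NLR architecture calls.

    Candidates are proteins with at least one NB-ARC domain. Class by
    domain flags: NB-ARC alone -> NBS; +TIR -> TIR-NBS; +CC -> CC-NBS;
    +LRR -> NBS-LRR; +CC+LRR -> CNL; +TIR+LRR -> TNL. The coiled-coil flag
    is an external prediction; an RPW8 domain also confers CC status when
    ``rpw8_as_cc``. Proteins carrying both TIR and CC are resolved
    TIR-first (logged). Proteins named in ``cc_flags`` but absent from the
    table are skipped with a warning.
    """
    domains_of: dict[str, list[DomainAnnotation]] = {}
    for d in domain_table:
        domains_of.setdefault(d.protein_id, []).append(d)
    for pid in cc_flags:
        if pid not in domains_of:
            log.warning("protein %s has a coiled-coil flag but no domain rows; skipped", pid)

    calls = []
    for pid in sorted(domains_of):
        names = [d.domain_name for d in domains_of[pid]]
        has_nbarc = NBARC in names
        if not has_nbarc:
            continue
        has_tir = TIR in names
        has_lrr = any(_is_lrr(n) for n in names)
        has_cc = bool(cc_flags.get(pid, False))
        if rpw8_as_cc and RPW8 in names:
            has_cc = True
        if has_tir and has_cc:
            log.info("protein %s carries both TIR and CC; resolved TIR-first", pid)
            has_cc = False
        if has_tir:
            nlr_class = "TNL" if has_lrr else "TIR-NBS"
        elif has_cc:
            nlr_class = "CNL" if has_lrr else "CC-NBS"
        else:
            nlr_class = "NBS-LRR" if has_lrr else "NBS"
        canonical = {NBARC, TIR, RPW8}
        integrated = sorted({n for n in names if n not in canonical and not _is_lrr(n)})
        calls.append(NLRCall(protein_id=pid, has_nbarc=True, has_tir=has_tir,
                             has_cc=bool(cc_flags.get(pid, False)) or (rpw8_as_cc and RPW8 in names),
                             has_lrr=has_lrr, nlr_class=nlr_class,
                             integrated_domains=",".join(integrated)))
    return calls


def match_dsxwr(protein: str) -> Optional[int]:
    """Leftmost DSXWR hit (0-based), X matching any residue."""
    for i in range(len(protein) - 4):
        window = protein[i:i + 5]
        if window[0] == "D" and window[1] == "S" and window[3] == "W" and window[4] == "R":
            return i
    return None


def match_long_signature(protein: str, max_mismatch: int = MAX_MISMATCH_LONG
                         ) -> Optional[tuple[int, int]]:
    """Best (position, mismatches) hit of the long CBF signature.

    Sliding-window Hamming comparison (no indels); best by mismatch count,
    ties leftmost; None when every window exceeds ``max_mismatch``.
    """
    m = len(LONG_SIGNATURE)
    best: Optional[tuple[int, int]] = None
    for i in range(len(protein) - m + 1):
        mm = sum(1 for a, b in zip(protein[i:i + m], LONG_SIGNATURE) if a != b)
        if mm <= max_mismatch and (best is None or mm < best[1]):
            best = (i, mm)
    return best


def classify_cbf(proteins: dict[str, str],
                 domain_table: Sequence[DomainAnnotation],
                 max_mismatch_long: int = MAX_MISMATCH_LONG,
                 dsxwr_n_terminal: bool = True) -> list[CBFCall]:
    """CBF/DREB1 calls: AP2 domain with both flanking signature motifs.

    Sidedness follows canonical CBF architecture: DSXWR N-terminal of the
    AP2 envelope and the long signature C-terminal (flip with
    ``dsxwr_n_terminal=False``).
    """
    ap2_env: dict[str, tuple[int, int]] = {}
    for d in domain_table:
        if d.domain_name == "AP2" and d.protein_id not in ap2_env:
            ap2_env[d.protein_id] = (d.start, d.end)

    calls = []
    for pid in sorted(proteins):
        seq = proteins[pid]
        env = ap2_env.get(pid)
        if env is None:
            calls.append(CBFCall(protein_id=pid, has_ap2=False, dsxwr_pos=None,
                                 long_sig_pos=None, long_sig_mismatches=None,
                                 is_cbf=False))
            continue
        ap2_start0, ap2_end0 = env[0] - 1, env[1]  # 1-based inclusive -> half-open
        dsx = match_dsxwr(seq)
        long_hit = match_long_signature(seq, max_mismatch_long)
        is_cbf = False
        if dsx is not None and long_hit is not None:
            if dsxwr_n_terminal:
                is_cbf = dsx + 5 <= ap2_start0 and long_hit[0] >= ap2_end0
            else:
                is_cbf = long_hit[0] + len(LONG_SIGNATURE) <= ap2_start0 and dsx >= ap2_end0
        calls.append(CBFCall(
            protein_id=pid, has_ap2=True, dsxwr_pos=dsx,
            long_sig_pos=long_hit[0] if long_hit else None,
            long_sig_mismatches=long_hit[1] if long_hit else None,
            is_cbf=is_cbf))
    return calls


def scan_motif(sequence: str, motif: str = "GATAA",
               include_reverse_complement: bool = False) -> list[int]:
    """All exact motif occurrences (0-based) on the given strand.

    With ``include_reverse_complement`` the reverse-complement motif is
    scanned on the same strand as well (positions still on the input).
    """
    seq = sequence.upper()
    motifs = [motif.upper()]
    if include_reverse_complement:
        comp = str.maketrans("ACGT", "TGCA")
        motifs.append(motif.upper().translate(comp)[::-1])
    hits: set[int] = set()
    for m in motifs:
        start = seq.find(m)
        while start != -1:
            hits.add(start)
            start = seq.find(m, start + 1)
    return sorted(hits)


def promoter_sequence(chromosome_seq: str, gene_start: int, gene_end: int,
                      strand: str, upstream_bp: int = 3000) -> str:
    """Strand-aware promoter: ``upstream_bp`` before the gene start.

    For + genes, the slice upstream of ``gene_start``; for - genes, the
    reverse complement of the slice downstream of ``gene_end``.
    """
    comp = str.maketrans("ACGT", "TGCA")
    if strand == "+":
        return chromosome_seq[max(0, gene_start - upstream_bp):gene_start]
    seg = chromosome_seq[gene_end:gene_end + upstream_bp]
    return seg.translate(comp)[::-1]
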