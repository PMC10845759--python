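"""Telomere and centromere landmark detection on chromosome sequences.

Telomeres are maximal tandem runs of the plant 7-bp unit (CCCTAAA at the
5' terminus, TTTAGGG at the 3') within a terminal window, tolerating a
small per-run mismatch fraction. Centromere candidates are the densest
tandem-repeat-rich region of a chromosome: a lightweight period-scanning
detector finds maximal tandem arrays, sliding windows locate the
repeat-richest run, and the array monomer with the highest copy count in
that run becomes the representative centromeric monomer.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Optional, Sequence

import numpy as np

from .models import CentromereCall, TandemArray, TelomereCall

log = logging.getLogger(__name__)

TELOMERE_UNIT_5P = "CCCTAAA"
TELOMERE_UNIT_3P = "TTTAGGG"
UNIT_LEN = 7

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _rotations(unit: str) -> list[str]:
    return [unit[i:] + unit[:i] for i in range(len(unit))]


def _best_terminal_run(window_seq: str, unit: str, max_mismatch_frac: float
                       ) -> Optional[tuple[int, int, int]]:
    """Longest mismatch-tolerant tandem run of ``unit`` (any rotation).

    Returns (start, end, copies) within the window, or None. A run starts
    at an exact unit match and extends unit-by-unit while both the per-unit
    mismatch count (ceil of the fraction over one unit) and the cumulative
    per-base mismatch fraction stay within ``max_mismatch_frac`` — the
    per-unit cap stops the run at the array edge instead of letting a long
    clean array bankroll a walk into unrelated sequence.
    """
    import math

    best: Optional[tuple[int, int, int]] = None
    rotations = _rotations(unit)
    per_unit_max = math.ceil(max_mismatch_frac * UNIT_LEN)
    n = len(window_seq)
    taken_until = -1
    for start in range(n - UNIT_LEN + 1):
        if start <= taken_until:
            continue
        first = window_seq[start:start + UNIT_LEN]
        if first not in rotations:
            continue
        motif = first
        mismatches = 0
        copies = 0
        pos = start
        while pos + UNIT_LEN <= n:
            unit_here = window_seq[pos:pos + UNIT_LEN]
            mm = sum(1 for a, b in zip(unit_here, motif) if a != b)
            if mm > per_unit_max:
                break
            if (mismatches + mm) / ((copies + 1) * UNIT_LEN) > max_mismatch_frac:
                break
            mismatches += mm
            copies += 1
            pos += UNIT_LEN
        taken_until = pos - 1
        if best is None or copies > best[2]:
            best = (start, pos, copies)
    return best


def find_telomeres(chromosome: str, sequence: str, min_copies: int = 50,
                   window: int = 50_000,
                   max_mismatch_frac: float = 0.1) -> list[TelomereCall]:
    """Telomere calls at both termini of one chromosome.

    The 5' window is scanned for CCCTAAA-family runs and the 3' window for
    TTTAGGG-family runs; a call requires at least ``min_copies`` unit
    copies inside the terminal ``window`` bp. Sequences shorter than two
    windows are scanned whole (both termini may then overlap).
    """
    seq = sequence.upper()
    n = len(seq)
    w = min(window, n)
    calls: list[TelomereCall] = []

    run5 = _best_terminal_run(seq[:w], TELOMERE_UNIT_5P, max_mismatch_frac)
    if run5 and run5[2] >= min_copies:
        calls.append(TelomereCall(chromosome=chromosome, terminus="5p",
                                  copies=run5[2], start=run5[0], end=run5[1]))
    offset = n - w
    run3 = _best_terminal_run(seq[offset:], TELOMERE_UNIT_3P, max_mismatch_frac)
    if run3 and run3[2] >= min_copies:
        calls.append(TelomereCall(chromosome=chromosome, terminus="3p",
                                  copies=run3[2], start=offset + run3[0],
                                  end=offset + run3[1]))
    return calls


# ---------------------------------------------------------------------------
# tandem arrays and centromeres

def _match_runs(seq_arr: np.ndarray, period: int, min_identity: float,
                min_array: int) -> list[tuple[int, int]]:
    """Maximal intervals where seq[i] == seq[i+period] holds densely.

    Smooths the self-match profile with a window of one period so single
    mismatches inside a copy do not break a run, then extracts runs whose
    mean identity stays at or above ``min_identity`` and whose total
    length (including the trailing period) reaches ``min_array``.
    """
    m = seq_arr[:-period] == seq_arr[period:]
    if m.size < period:
        return []
    kernel = np.ones(period) / period
    density = np.convolve(m.astype(float), kernel, mode="same")
    above = density >= min_identity
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    bounds = np.concatenate(([0], edges + 1, [above.size]))
    runs = [(int(bounds[i]), int(bounds[i + 1]))
            for i in range(len(bounds) - 1) if above[bounds[i]]]
    out = []
    for s, e in runs:
        if (e - s) + period >= min_array and (e - s) >= period:
            out.append((s, e + period))
    return out


def find_tandem_arrays(chromosome: str, sequence: str, min_period: int = 2,
                       max_period: int = 200, min_array: int = 500,
                       min_identity: float = 0.8) -> list[TandemArray]:
    """Maximal tandem arrays with period in [min_period, max_period].

    The sequence is compared against itself at every candidate period;
    dense self-match runs become arrays. A region is reported once, at the
    smallest period that explains it; regions already explained by a period
    below ``min_period`` (homopolymers, dinucleotide wobble) are excluded
    by the period-1 prescan. The consensus monomer is the per-column
    majority over the full copies of the array.
    """
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    if arr.size < min_array:
        return []

    homopolymer = set()
    for s, e in _match_runs(arr, 1, min_identity, min_array):
        homopolymer.add((s, e))

    claimed: list[tuple[int, int]] = []

    def overlaps_claimed(s: int, e: int) -> bool:
        return any(not (e <= cs or s >= ce) for cs, ce in claimed)

    arrays: list[TandemArray] = []
    for period in range(max(min_period, 2), max_period + 1):
        if arr.size <= period:
            break
        for s, e in _match_runs(arr, period, min_identity, min_array):
            if overlaps_claimed(s, e):
                continue
            if any(not (e <= hs or s >= he) for hs, he in homopolymer):
                continue
            copies = (e - s) / period
            if copies < 2:
                continue
            monomer = _consensus_monomer(seq[s:e], period)
            arrays.append(TandemArray(chromosome=chromosome, start=s, end=e,
                                      period=period, copies=round(copies, 1),
                                      monomer=monomer))
            claimed.append((s, e))
    arrays.sort(key=lambda a: a.start)
    return arrays


def _consensus_monomer(array_seq: str, period: int) -> str:
    full = len(array_seq) // period
    cols = []
    for j in range(period):
        counter = Counter(array_seq[i * period + j] for i in range(full))
        cols.append(counter.most_common(1)[0][0])
    return "".join(cols)


def locate_centromere(chromosome: str, arrays: Sequence[TandemArray],
                      chrom_length: int, window: int = 100_000,
                      min_fraction: float = 0.3) -> Optional[CentromereCall]:
    """At most one centromere candidate per chromosome.

    Tandem-repeat coverage is measured in sliding windows (step =
    window/10); the maximal run of windows at or above ``min_fraction``
    defines the candidate, whose interval is clipped to the tandem arrays
    it contains. The representative monomer is the consensus monomer of
    the highest-copy-count array inside the interval.
    """
    if not arrays or chrom_length <= 0:
        return None
    step = max(1, window // 10)
    cov = np.zeros(chrom_length, dtype=bool)
    for a in arrays:
        cov[a.start:a.end] = True
    starts = list(range(0, max(1, chrom_length - window + 1), step))
    fractions = [cov[s:s + window].mean() for s in starts]

    best_run: Optional[tuple[int, int]] = None
    run_start = None
    for i, frac in enumerate(fractions + [0.0]):
        if frac >= min_fraction and run_start is None:
            run_start = i
        elif frac < min_fraction and run_start is not None:
            if best_run is None or (i - run_start) > (best_run[1] - best_run[0]):
                best_run = (run_start, i)
            run_start = None
    if best_run is None:
        return None
    ext_start = starts[best_run[0]]
    ext_end = min(chrom_length, starts[best_run[1] - 1] + window)

    inside = [a for a in arrays if a.start < ext_end and a.end > ext_start]
    if not inside:
        return None
    # clip to the densest cluster of arrays: distant unrelated arrays (e.g.
    # a telomere run caught by the same window) must not stretch the call
    inside.sort(key=lambda a: a.start)
    clusters: list[list[TandemArray]] = [[inside[0]]]
    for a in inside[1:]:
        if a.start - clusters[-1][-1].end <= step:
            clusters[-1].append(a)
        else:
            clusters.append([a])
    cluster = max(clusters, key=lambda c: sum(a.end - a.start for a in c))
    start = min(a.start for a in cluster)
    end = max(a.end for a in cluster)
    rep = max(cluster, key=lambda a: (a.copies, -a.start))
    fraction = float(cov[start:end].mean())
    return CentromereCall(chromosome=chromosome, start=start, end=end,
                          repeat_fraction=round(fraction, 3),
                          representative_monomer=rep.monomer,
                          monomer_count=int(rep.copies))
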