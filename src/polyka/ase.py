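"""Allele-specific expression over stages of a multi-allelic locus table.

Expression is TPM-normalised per sample. Within each stage the replicate
raw counts of each allele are pooled and every allele pair of a locus is
compared by an exact binomial test whose null proportion is the
length-adjusted expectation p0 = L_i / (L_i + L_j); the fold change is
computed on mean TPM with a 0.1 pseudo-TPM. A locus is significant at a
stage when its best pair (smallest P) passes all three gates:
|log2FC| > 1, P < 0.05 and Benjamini-Hochberg FDR < 0.05 (FDR pooled over
every locus x stage x pair test in the run). Loci significant in every
stage with one dominant allele are consistent ASEGs; significant anywhere
else, inconsistent; never significant, balanced.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .models import AlleleLocus, ASEGClassification, ASERecord

log = logging.getLogger(__name__)

PSEUDO_TPM = 0.1
LOG2FC_GATE = 1.0
P_GATE = 0.05
FDR_GATE = 0.05


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: rate_g = count_g / length_g, scaled to 1e6.

    All-zero samples yield an all-zero column with a warning.
    """
    if not counts.index.equals(lengths.reindex(counts.index).index):
        raise ValueError("counts and lengths indices do not agree")
    lens = lengths.reindex(counts.index)
    if (lens <= 0).any():
        raise ValueError("every gene needs a positive length")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    rate = counts.div(lens, axis=0)
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        log.warning("all-zero sample(s): %s", ", ".join(totals.index[zero]))
        totals = totals.replace(0, 1.0)
    return rate.div(totals, axis=1) * 1e6


@dataclass
class _PairTest:
    locus_id: str
    stage: str
    allele_i: str  # haplotype letter
    allele_j: str
    gene_i: str
    gene_j: str
    tpm_i: float
    tpm_j: float
    log2fc: float
    p_value: float


def ase_tests(loci: Sequence[AlleleLocus], counts: pd.DataFrame,
              lengths: pd.Series, design: pd.DataFrame) -> list[ASERecord]:
    """Per-locus, per-stage allelic imbalance records.

    ``design`` maps sample columns to stages; replicates are pooled within
    a stage for the binomial test while the fold change uses mean TPM.
    Loci with fewer than two alleles are skipped (logged); zero-vs-zero
    allele pairs are skipped.
    """
    tpm_mat = tpm(counts, lengths)
    stages = list(dict.fromkeys(design["stage"]))
    samples_of_stage = {s: design.loc[design["stage"] == s, "sample"].tolist()
                        for s in stages}

    tests: list[_PairTest] = []
    dominant: dict[tuple[str, str], str] = {}
    for locus in loci:
        members = locus.members()  # haplotype -> gene id
        if len(members) < 2:
            log.info("locus %s has < 2 alleles; skipped", locus.locus_id)
            continue
        haps = sorted(members)
        for stage in stages:
            cols = samples_of_stage[stage]
            pooled = {h: int(counts.loc[members[h], cols].sum()) for h in haps}
            mean_tpm = {h: float(tpm_mat.loc[members[h], cols].mean()) for h in haps}
            dominant[(locus.locus_id, stage)] = max(
                haps, key=lambda h: (mean_tpm[h], h))
            for x in range(len(haps)):
                for y in range(x + 1, len(haps)):
                    hi, hj = haps[x], haps[y]
                    ci, cj = pooled[hi], pooled[hj]
                    if ci + cj == 0:
                        continue
                    li = float(lengths[members[hi]])
                    lj = float(lengths[members[hj]])
                    p0 = li / (li + lj)
                    p = binomtest(ci, ci + cj, p0).pvalue
                    lfc = math.log2((mean_tpm[hi] + PSEUDO_TPM) /
                                    (mean_tpm[hj] + PSEUDO_TPM))
                    tests.append(_PairTest(locus.locus_id, stage, hi, hj,
                                           members[hi], members[hj],
                                           mean_tpm[hi], mean_tpm[hj], lfc, p))
    if not tests:
        return []
    fdr = multipletests([t.p_value for t in tests], method="fdr_bh")[1]

    best: dict[tuple[str, str], tuple[_PairTest, float]] = {}
    for t, q in zip(tests, fdr):
        key = (t.locus_id, t.stage)
        if key not in best or t.p_value < best[key][0].p_value:
            best[key] = (t, q)

    records = []
    for (locus_id, stage), (t, q) in sorted(best.items()):
        significant = (abs(t.log2fc) > LOG2FC_GATE and t.p_value < P_GATE
                       and q < FDR_GATE)
        records.append(ASERecord(
            locus_id=locus_id, stage=stage, allele_i=t.allele_i,
            allele_j=t.allele_j, tpm_i=t.tpm_i, tpm_j=t.tpm_j,
            log2fc=t.log2fc, p_value=t.p_value, fdr=float(q),
            significant=significant,
            dominant_allele=dominant[(locus_id, stage)]))
    return records


def aseg_summary_counts(n_loci: int, n_significant: int, n_consistent: int) -> dict:
    """Accounting identities of an ASEG run.

    percent_significant is reported to one decimal; inconsistent ASEGs are
    the significant loci that are not consistent.
    """
    if n_consistent > n_significant or n_significant > n_loci:
        raise ValueError("inconsistent ASEG counts")
    return {
        "n_loci": n_loci,
        "n_significant": n_significant,
        "n_consistent": n_consistent,
        "n_inconsistent": n_significant - n_consistent,
        "percent_significant": round(100.0 * n_significant / n_loci, 1) if n_loci else 0.0,
    }


def classify_asegs(records: Sequence[ASERecord]
                   ) -> tuple[list[ASEGClassification], dict]:
    """Label each locus consistent / inconsistent / balanced, with a summary.

    consistent: significant at every stage with the same dominant allele;
    inconsistent: significant at >= 1 stage but not consistent;
    balanced: never significant.
    """
    by_locus: dict[str, list[ASERecord]] = {}
    for r in records:
        by_locus.setdefault(r.locus_id, []).append(r)

    classes = []
    n_sig = n_cons = 0
    for locus_id in sorted(by_locus):
        recs = by_locus[locus_id]
        sig = [r for r in recs if r.significant]
        if not sig:
            label = "balanced"
        elif (len(sig) == len(recs)
              and len({r.dominant_allele for r in sig}) == 1):
            label = "consistent"
            n_cons += 1
            n_sig += 1
        else:
            label = "inconsistent"
            n_sig += 1
        classes.append(ASEGClassification(locus_id=locus_id, label=label))
    summary = aseg_summary_counts(len(by_locus), n_sig, n_cons)
    return classes, summary
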