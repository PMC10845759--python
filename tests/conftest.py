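"""Shared fixtures: a tiny clean tetraploid and one full default-condition run."""

from __future__ import annotations

from types import SimpleNamespace

import pytest

from polyka import ase as ase_mod
from polyka import synteny
from polyka.models import AlleleLocus
from polyka.simulate import SimulationConfig, simulate_counts, simulate_genome


@pytest.fixture(scope="session")
def tiny_sim():
    """Small loss-free, rearrangement-free tetraploid for unit tests."""
    cfg = SimulationConfig(
        n_chromosomes=2, genes_per_chromosome=30, codons_per_gene=100,
        loss_rate_to_3=0.0, loss_rate_to_2=0.0, loss_rate_to_1=0.0,
        inversion_rate=0.0, translocation_rate=0.0,
        tandem_singleton_rate=0.0, relocated_singleton_rate=0.0,
        telomere_copies=60, centromere_copies=100, seed=11)
    gene_sets, chrom_seqs, truth = simulate_genome(cfg)
    counts, lengths, design = simulate_counts(truth, cfg, gene_sets)
    return SimpleNamespace(cfg=cfg, gene_sets=gene_sets, chrom_seqs=chrom_seqs,
                           truth=truth, counts=counts, lengths=lengths,
                           design=design)


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default study conditions (fixed seed).

    Shared by the recovery tests; built once per session because the
    synteny stage dominates the cost.
    """
    cfg = SimulationConfig(seed=1)
    gene_sets, chrom_seqs, truth = simulate_genome(cfg)
    counts, lengths, design = simulate_counts(truth, cfg, gene_sets)
    anchors_by_pair, blocks, loci = synteny.run_synteny(gene_sets)
    singleton_calls = synteny.classify_singletons(loci, gene_sets, blocks)
    records = ase_mod.ase_tests(
        [l for l in loci if l.allele_class != "singleton"],
        counts, lengths, design)
    classes, ase_summary = ase_mod.classify_asegs(records)
    return SimpleNamespace(
        cfg=cfg, gene_sets=gene_sets, chrom_seqs=chrom_seqs, truth=truth,
        counts=counts, lengths=lengths, design=design,
        anchors_by_pair=anchors_by_pair, blocks=blocks, loci=loci,
        singleton_calls=singleton_calls, ase_records=records,
        ase_classes=classes, ase_summary=ase_summary)


@pytest.fixture()
def truth_loci_as_alleles(default_run):
    """Truth loci recast as AlleleLocus records (isolates downstream modules)."""
    return [AlleleLocus(l.locus_id, l.homologous_group,
                        AlleleLocus.class_for_count(l.n_alleles),
                        l.gene_a, l.gene_b, l.gene_c, l.gene_d)
            for l in default_run.truth.loci]
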