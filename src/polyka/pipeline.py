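"""End-to-end orchestration: simulate -> alleles -> ks -> ase -> chromfeat.

Each stage writes its tables under the run directory together with a hash
of the configuration block that produced them; a rerun with an unchanged
configuration loads the existing outputs instead of recomputing (delete
the directory or change the config to force recomputation). The run ends
with a machine-readable ``summary.json`` whose counts equal the row counts
of the corresponding tables.

The family-rules stage runs only when a domain table (and optional
coiled-coil flag file) is configured: domain annotation is an input, not
something the generator emulates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, ase, chromfeat, formats_io, ksdating, synteny
from .models import (AlleleLocus, AnchorPair, CentromereCall, DomainAnnotation,
                     GeneSet, HAPLOTYPES, KsEstimate, KsPeak, SingletonCall,
                     SyntenyBlock, TandemArray, TelomereCall)
from .simulate import (SimulationConfig, SyntheticTruth, TruthASE, TruthFeature,
                       TruthLocus, TruthPair, TruthRearrangement, TruthSingleton,
                       simulate_counts, simulate_genome, write_simulation)

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """One pipeline run: output directory, seed, and per-stage parameters."""

    outdir: str
    seed: int = 0
    r: float = ksdating.NEUTRAL_RATE
    sim: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    min_identity: float = 60.0
    max_gap: int = 10
    min_block: int = 4
    singleton_min_identity: float = 80.0
    ks_max: float = ksdating.KS_MAX
    peak_min_n: int = 50
    telomere_min_copies: int = 50
    telomere_window: int = 50_000
    centromere_window: int = 100_000
    centromere_min_fraction: float = 0.3
    domains_path: Optional[str] = None
    cc_flags_path: Optional[str] = None

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimulationConfig(**self.sim)
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def block_hash(self, *fields: str) -> str:
        payload = {f: getattr(self, f) for f in fields}
        payload["seed"] = self.seed
        payload = {k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
                   for k, v in payload.items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _stage_cached(out: Path, stage: str, digest: str, outputs: list[Path]) -> bool:
    hash_file = out / f"{stage}.hash"
    if hash_file.exists() and hash_file.read_text().strip() == digest \
            and all(p.exists() for p in outputs):
        log.info("stage %s: outputs up to date, skipped", stage)
        return True
    return False


def _mark_stage(out: Path, stage: str, digest: str) -> None:
    (out / f"{stage}.hash").write_text(digest + "\n")


def _load_truth(simdir: Path) -> SyntheticTruth:
    return SyntheticTruth(
        loci=formats_io.read_tables(simdir / "truth_loci.tsv", TruthLocus),
        pairs=formats_io.read_tables(simdir / "truth_pairs.tsv", TruthPair),
        singletons=formats_io.read_tables(simdir / "truth_singletons.tsv", TruthSingleton),
        rearrangements=formats_io.read_tables(simdir / "truth_rearrangements.tsv",
                                              TruthRearrangement),
        ase=formats_io.read_tables(simdir / "truth_ase.tsv", TruthASE),
        features=formats_io.read_tables(simdir / "truth_features.tsv", TruthFeature),
    )


def stage_simulate(config: RunConfig):
    out = Path(config.outdir)
    simdir = out / "sim"
    digest = config.block_hash("sim")
    outputs = [simdir / "genome.fa", simdir / "counts.tsv", simdir / "truth_loci.tsv"]
    if _stage_cached(out, "simulate", digest, outputs):
        gene_sets = {h: formats_io.read_gene_set(simdir / f"hap{h}.gff3",
                                                 simdir / f"hap{h}.cds.fa", haplotype=h)
                     for h in HAPLOTYPES}
        chrom_seqs = formats_io.read_fasta(simdir / "genome.fa")
        truth = _load_truth(simdir)
        counts = pd.read_csv(simdir / "counts.tsv", sep="\t", index_col=0)
        lengths = pd.read_csv(simdir / "lengths.tsv", sep="\t", index_col=0)["length"]
        design = pd.read_csv(simdir / "design.tsv", sep="\t")
        return gene_sets, chrom_seqs, truth, counts, lengths, design
    gene_sets, chrom_seqs, truth = simulate_genome(config.sim)
    counts, lengths, design = simulate_counts(truth, config.sim, gene_sets)
    write_simulation(simdir, gene_sets, chrom_seqs, truth, counts, lengths,
                     design, config.sim)
    _mark_stage(out, "simulate", digest)
    return gene_sets, chrom_seqs, truth, counts, lengths, design


def stage_alleles(config: RunConfig, gene_sets: dict[str, GeneSet]):
    out = Path(config.outdir)
    digest = config.block_hash("min_identity", "max_gap", "min_block",
                               "singleton_min_identity", "sim")
    paths = {name: out / f"{name}.tsv"
             for name in ("anchors", "blocks", "alleles", "singletons")}
    if _stage_cached(out, "alleles", digest, list(paths.values())):
        anchors = formats_io.read_tables(paths["anchors"], AnchorPair)
        blocks = formats_io.read_tables(paths["blocks"], SyntenyBlock)
        loci = formats_io.read_tables(paths["alleles"], AlleleLocus)
        singleton_calls = formats_io.read_tables(paths["singletons"], SingletonCall)
        return anchors, blocks, loci, singleton_calls
    anchors_by_pair, blocks, loci = synteny.run_synteny(
        gene_sets, min_identity=config.min_identity, max_gap=config.max_gap,
        min_block=config.min_block)
    singleton_calls = synteny.classify_singletons(
        loci, gene_sets, blocks, min_identity=config.singleton_min_identity)
    anchors = [a for pair in sorted(anchors_by_pair) for a in anchors_by_pair[pair]]
    formats_io.write_tables(anchors, paths["anchors"], AnchorPair)
    formats_io.write_tables(blocks, paths["blocks"], SyntenyBlock)
    formats_io.write_tables(loci, paths["alleles"], AlleleLocus)
    formats_io.write_tables(singleton_calls, paths["singletons"], SingletonCall)
    _mark_stage(out, "alleles", digest)
    return anchors, blocks, loci, singleton_calls


def stage_ks(config: RunConfig, gene_sets: dict[str, GeneSet],
             loci: list[AlleleLocus], truth: Optional[SyntheticTruth]):
    """Ks of allelic pairs (from the allele table) and of paralog pairs.

    Paralog pair lists are an input at desk scale; on synthetic runs they
    come from the generator's ledger.
    """
    out = Path(config.outdir)
    digest = config.block_hash("ks_max", "peak_min_n", "r", "sim", "min_identity")
    paths = {name: out / f"{name}.tsv"
             for name in ("ks_allelic", "ks_paralog", "peaks", "dating")}
    genes_by_id = {}
    for gs in gene_sets.values():
        genes_by_id.update(gs.by_id())

    if _stage_cached(out, "ks", digest, [paths["ks_allelic"], paths["peaks"]]):
        ks_allelic = formats_io.read_tables(paths["ks_allelic"], KsEstimate)
        ks_paralog = (formats_io.read_tables(paths["ks_paralog"], KsEstimate)
                      if paths["ks_paralog"].exists() else [])
        peaks = formats_io.read_tables(paths["peaks"], KsPeak)
        return ks_allelic, ks_paralog, peaks

    allelic_pairs = []
    for locus in loci:
        members = sorted(locus.members().values())
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                allelic_pairs.append((members[i], members[j]))
    ks_allelic = ksdating.ks_for_pairs(genes_by_id, allelic_pairs)

    ks_paralog: list[KsEstimate] = []
    if truth is not None:
        paralog_pairs = truth.pairs_by_event("alpha") + truth.pairs_by_event("beta")
        paralog_pairs = [(a, b) for a, b in paralog_pairs
                         if a in genes_by_id and b in genes_by_id]
        ks_paralog = ksdating.ks_for_pairs(genes_by_id, paralog_pairs)

    peaks: list[KsPeak] = []
    dating_rows = []
    for label, estimates in (("allelic", ks_allelic), ("paralog", ks_paralog)):
        values = [e.Ks for e in estimates if e.defined]
        if len(values) >= config.peak_min_n:
            found = ksdating.detect_peaks(values, label=label, min_n=config.peak_min_n,
                                          ks_max=config.ks_max)
            peaks.extend(found)
            for p in found:
                d = ksdating.ks_to_time(p.mode, config.r)
                dating_rows.append({"label": label, "ks": p.mode, "r": config.r,
                                    "t_years": d.t_years, "mya": d.mya})

    formats_io.write_tables(ks_allelic, paths["ks_allelic"], KsEstimate)
    formats_io.write_tables(ks_paralog, paths["ks_paralog"], KsEstimate)
    formats_io.write_tables(peaks, paths["peaks"], KsPeak)
    pd.DataFrame(dating_rows).to_csv(paths["dating"], sep="\t", index=False)
    _mark_stage(out, "ks", digest)
    return ks_allelic, ks_paralog, peaks


def stage_ase(config: RunConfig, loci: list[AlleleLocus], counts: pd.DataFrame,
              lengths: pd.Series, design: pd.DataFrame):
    out = Path(config.outdir)
    digest = config.block_hash("sim", "min_identity")
    rec_path, cls_path = out / "ase_records.tsv", out / "aseg_classes.tsv"
    if _stage_cached(out, "ase", digest, [rec_path, cls_path]):
        records = formats_io.read_tables(rec_path, ase.ASERecord)
        classes, summary = ase.classify_asegs(records)
        return records, classes, summary
    records = ase.ase_tests(loci, counts, lengths, design)
    classes, summary = ase.classify_asegs(records)
    formats_io.write_tables(records, rec_path, ase.ASERecord)
    formats_io.write_tables(classes, cls_path, ase.ASEGClassification)
    with open(out / "ase_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _mark_stage(out, "ase", digest)
    return records, classes, summary


def stage_chromfeat(config: RunConfig, chrom_seqs: dict[str, str]):
    out = Path(config.outdir)
    digest = config.block_hash("telomere_min_copies", "telomere_window",
                               "centromere_window", "centromere_min_fraction", "sim")
    tel_path, cen_path = out / "telomeres.bed", out / "centromeres.bed"
    mono_path = out / "monomers.fa"
    telomeres: list[TelomereCall] = []
    centromeres: list[CentromereCall] = []
    if _stage_cached(out, "chromfeat", digest, [tel_path, cen_path]):
        tel_df = pd.read_csv(tel_path, sep="\t",
                             names=["chrom", "start", "end", "name"])
        cen_df = pd.read_csv(cen_path, sep="\t",
                             names=["chrom", "start", "end", "name"])
        monomers = formats_io.read_fasta(mono_path) if mono_path.exists() else {}
        for _, row in tel_df.iterrows():
            terminus, copies = row["name"].split(":")
            telomeres.append(TelomereCall(row["chrom"], terminus, int(copies),
                                          int(row["start"]), int(row["end"])))
        for _, row in cen_df.iterrows():
            centromeres.append(CentromereCall(
                row["chrom"], int(row["start"]), int(row["end"]), 0.0,
                monomers.get(row["chrom"], ""), 0))
        return telomeres, centromeres
    for chrom in sorted(chrom_seqs):
        seq = chrom_seqs[chrom]
        telomeres.extend(chromfeat.find_telomeres(
            chrom, seq, min_copies=config.telomere_min_copies,
            window=config.telomere_window))
        arrays = chromfeat.find_tandem_arrays(chrom, seq)
        call = chromfeat.locate_centromere(chrom, arrays, len(seq),
                                           window=config.centromere_window,
                                           min_fraction=config.centromere_min_fraction)
        if call:
            centromeres.append(call)
    formats_io.write_bed([(t.chromosome, t.start, t.end, f"{t.terminus}:{t.copies}")
                          for t in telomeres], tel_path)
    formats_io.write_bed([(c.chromosome, c.start, c.end, "centromere")
                          for c in centromeres], cen_path)
    formats_io.write_fasta({c.chromosome: c.representative_monomer
                            for c in centromeres}, mono_path)
    _mark_stage(out, "chromfeat", digest)
    return telomeres, centromeres


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in dependency order and write ``summary.json``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)

    gene_sets, chrom_seqs, truth, counts, lengths, design = stage_simulate(config)
    anchors, blocks, loci, singleton_calls = stage_alleles(config, gene_sets)
    ks_allelic, ks_paralog, peaks = stage_ks(config, gene_sets, loci, truth)
    records, classes, ase_summary = stage_ase(config, loci, counts, lengths, design)
    telomeres, centromeres = stage_chromfeat(config, chrom_seqs)

    census = synteny.allele_census(loci)
    summary = {
        "version": __version__,
        "config_hash": config.block_hash("sim", "min_identity", "max_gap", "min_block"),
        "n_genes": sum(len(gs.genes) for gs in gene_sets.values()),
        "census": {
            "n_four": census.n_four, "n_three": census.n_three,
            "n_two": census.n_two, "n_singleton": census.n_singleton,
            "total_genes": census.total_genes,
            "singletons_per_haplotype": census.singletons_per_haplotype,
            "shared_per_haplotype": census.shared_per_haplotype,
        },
        "n_anchors": len(anchors),
        "n_blocks": len(blocks),
        "singleton_summary": synteny.summarize_singletons(singleton_calls),
        "ks_peaks": [dataclasses.asdict(p) for p in peaks],
        "dating_mya": {p.label: ksdating.ks_to_time(p.mode, config.r).mya
                       for p in _primary_peaks(peaks)},
        "ase": ase_summary,
        "n_telomeres": len(telomeres),
        "n_centromeres": len(centromeres),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _primary_peaks(peaks: list[KsPeak]) -> list[KsPeak]:
    primary: dict[str, KsPeak] = {}
    for p in peaks:
        if p.label not in primary or p.height > primary[p.label].height:
            primary[p.label] = p
    return [primary[k] for k in sorted(primary)]


def load_domain_table(path: str | Path) -> list[DomainAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [DomainAnnotation(protein_id=row["protein_id"],
                             domain_name=row["domain_name"],
                             start=int(row["start"]), end=int(row["end"]),
                             e_value=float(row.get("e_value", 0.0)))
            for _, row in df.iterrows()]
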