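"""Reading and writing the standard formats consumed by the pipeline.

GFF3 is 1-based inclusive on disk and converted to the internal 0-based
half-open convention on read (and back on write). Only ``gene`` features
with an ``ID`` attribute are consumed; parse failures report the offending
line number. FASTA goes through Biopython.
"""

from __future__ import annotations

import dataclasses
import logging
import re
import typing
from pathlib import Path
from typing import Optional, Sequence, Type, TypeVar

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, GeneSet

log = logging.getLogger(__name__)

T = TypeVar("T")

_CHROM_GROUP_RE = re.compile(r"Chr_?0*(\d+)$", re.IGNORECASE)


class Gff3ParseError(ValueError):
    """Malformed GFF3 input, carrying the 1-based line number."""


class ValidationError(ValueError):
    """A record violates a model invariant (names the offending gene)."""


def homologous_group_from_chromosome(chromosome: str,
                                     mapping: Optional[dict[str, int]] = None) -> int:
    """Base-chromosome group from a ``ChrNN`` name or an explicit mapping."""
    if mapping is not None:
        try:
            return mapping[chromosome]
        except KeyError:
            raise ValidationError(f"chromosome {chromosome!r} missing from group mapping")
    m = _CHROM_GROUP_RE.search(chromosome)
    if not m:
        raise ValidationError(
            f"chromosome {chromosome!r} does not follow the ChrNN convention and "
            "no group mapping was supplied"
        )
    return int(m.group(1))


def translate_cds(cds: str, gene_id: str = "?") -> str:
    """Translate under the universal code; strips one terminal stop.

    Internal stops or a length not divisible by three raise
    :class:`ValidationError` naming the gene.
    """
    if len(cds) % 3 != 0:
        raise ValidationError(f"gene {gene_id}: CDS length {len(cds)} not divisible by 3")
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValidationError(f"gene {gene_id}: internal stop codon in CDS")
    return prot


def _parse_gff3_attributes(attr_field: str) -> dict[str, str]:
    out = {}
    for part in attr_field.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_gff3_genes(gff3_path: str | Path,
                    group_mapping: Optional[dict[str, int]] = None) -> list[GeneModel]:
    """Parse gene features from a GFF3 file (without sequences).

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    """
    genes: list[GeneModel] = []
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise Gff3ParseError(
                    f"{gff3_path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise Gff3ParseError(f"{gff3_path}:{lineno}: non-integer coordinates")
            if strand not in ("+", "-"):
                raise Gff3ParseError(f"{gff3_path}:{lineno}: bad strand {strand!r}")
            attr = _parse_gff3_attributes(attrs)
            gid = attr.get("ID")
            if not gid:
                raise Gff3ParseError(f"{gff3_path}:{lineno}: gene feature lacks ID attribute")
            hap = attr.get("haplotype", "A")
            genes.append(
                GeneModel(
                    gene_id=gid,
                    haplotype=hap,
                    chromosome=seqid,
                    homologous_group=homologous_group_from_chromosome(seqid, group_mapping),
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                )
            )
    return genes


def read_gene_set(gff3_path: str | Path, cds_fasta_path: str | Path,
                  haplotype: Optional[str] = None,
                  group_mapping: Optional[dict[str, int]] = None) -> GeneSet:
    """Load one haplotype's gene set from GFF3 coordinates plus CDS FASTA.

    Genes without a CDS record are dropped with a warning; proteins are
    derived by translation. Duplicate gene ids raise a validation error.
    """
    genes = read_gff3_genes(gff3_path, group_mapping)
    cds_by_id = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(cds_fasta_path), "fasta")}

    kept: list[GeneModel] = []
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"gene {g.gene_id}: duplicate id within haplotype")
        seen.add(g.gene_id)
        cds = cds_by_id.get(g.gene_id)
        if cds is None:
            log.warning("gene %s has no CDS record in %s; dropped", g.gene_id, cds_fasta_path)
            continue
        g.cds = cds
        g.protein = translate_cds(cds, g.gene_id)
        kept.append(g)

    if haplotype is None:
        haplotype = kept[0].haplotype if kept else "A"
    for g in kept:
        g.haplotype = haplotype
    gs = GeneSet(haplotype=haplotype, genes=kept)
    gs.sort()
    return gs


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Emit gene features, converting back to 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            fh.write(
                f"{g.chromosome}\tpolyka\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};haplotype={g.haplotype}\n"
            )


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path), "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(intervals: Sequence[tuple[str, int, int, str]], path: str | Path) -> None:
    """BED4 (already 0-based half-open, no conversion needed)."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# Generic TSV tables for the flat dataclass records

def _sort_key_fields(cls: type) -> list[str]:
    names = [f.name for f in dataclasses.fields(cls)]
    # primary key = leading id-ish fields; fall back to full row
    return names


def write_tables(objects: Sequence, path: str | Path, cls: Optional[type] = None) -> None:
    """Write dataclass records as a deterministic TSV (header always present).

    Rows are sorted by the full field tuple so two runs over the same inputs
    produce byte-identical files.
    """
    if cls is None:
        if not objects:
            raise ValueError("empty object list requires an explicit cls for the header")
        cls = type(objects[0])
    cols = [f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")]
    rows = [[getattr(o, c) for c in cols] for o in objects]
    rows.sort(key=lambda r: tuple("" if v is None else str(v) for v in r))
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(_serialize(v) for v in row) + "\n")


def _serialize(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "True" if v else "False"
    if isinstance(v, float):  # incl. numpy scalars; plain repr round-trips
        return repr(float(v))
    return str(v)


def read_tables(path: str | Path, cls: Type[T]) -> list[T]:
    """Read a TSV written by :func:`write_tables` back into dataclasses."""
    hints = typing.get_type_hints(cls)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: list[T] = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in df.columns:
            kwargs[col] = _deserialize(row[col], hints[col])
        out.append(cls(**kwargs))
    return out


def _deserialize(raw: str, hint):
    origin = typing.get_origin(hint)
    if origin is typing.Union:
        args = [a for a in typing.get_args(hint) if a is not type(None)]
        if raw == "":
            return None
        hint = args[0]
    if hint is bool:
        return raw == "True"
    if hint is int:
        return int(raw)
    if hint is float:
        return float(raw)
    return raw
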