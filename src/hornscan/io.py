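"""Readers and writers for the standard file formats the pipeline consumes.

FASTA goes through Biopython, VCF reading through cyvcf2.  VCF and GFF3
output is plain-text emission (fixed column layout, deterministic for a given
input), so that fixture bundles round-trip bit-exactly and stay diffable.
All VCF coordinates are 1-based; GFF3 is 1-based inclusive on disk and
converted to 0-based half-open :class:`~hornscan.containers.GeneModel`
segments in memory.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .containers import MISSING, NO_ALLELE, GeneModel, VariantTable

# --------------------------------------------------------------------- FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ----------------------------------------------------------------------- VCF


def _format_gt(alleles: np.ndarray) -> str:
    a0, a1 = int(alleles[0]), int(alleles[1])
    if a1 == NO_ALLELE:  # hemizygous
        return "." if a0 == MISSING else str(a0)
    left = "." if a0 == MISSING else str(a0)
    right = "." if a1 == MISSING else str(a1)
    return f"{left}/{right}"


def write_vcf(table: VariantTable, path: str | Path) -> None:
    """Write a focal-population VCF 4.2 (GT-only, biallelic records)."""
    lines = ["##fileformat=VCFv4.2", "##source=hornscan"]
    for name, row in table.scaffolds.iterrows():
        lines.append(f"##contig=<ID={name},length={int(row['length'])}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(table.samples)
    )
    sites = table.sites
    for i in range(table.n_sites):
        row = sites.iloc[i]
        gts = "\t".join(_format_gt(table.gt[i, j]) for j in range(table.n_samples))
        lines.append(
            f"{row['scaffold']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}"
            f"\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _genotype_alleles(genotype: Sequence[int | bool]) -> list[int]:
    """Allele indices from a cyvcf2 per-sample genotype entry.

    cyvcf2 yields ``[a0, a1, phased]`` for diploid and ``[a0, phased]`` for
    haploid calls; the trailing element is the phase flag.
    """
    return [int(a) for a in genotype[:-1]]


def read_vcf(
    path: str | Path, meta: pd.DataFrame, scaffolds: pd.DataFrame
) -> VariantTable:
    """Read a GT-only biallelic VCF into a VariantTable.

    ``meta``/``scaffolds`` supply the population, sex and Z-linkage context
    that the VCF itself does not carry.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    recs = []
    gts = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {var.CHROM}:{var.POS}; focal VCFs "
                "are expected biallelic"
            )
        recs.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        row = np.full((len(samples), 2), NO_ALLELE, dtype=np.int8)
        for j, g in enumerate(var.genotypes):
            alleles = _genotype_alleles(g)
            for k, a in enumerate(alleles[:2]):
                row[j, k] = MISSING if a < 0 else a
        gts.append(row)
    sites = pd.DataFrame(recs, columns=["scaffold", "pos", "ref", "alt"])
    gt = (
        np.stack(gts)
        if gts
        else np.empty((0, len(samples), 2), dtype=np.int8)
    )
    return VariantTable(sites, gt, samples, meta, scaffolds)


@dataclasses.dataclass(frozen=True)
class OutgroupCall:
    """Observed outgroup alleles at one site.

    ``alts`` are the outgroup's ALT alleles in VCF order; ``observed`` is the
    set of bases actually present in its genotype call(s).
    """

    ref: str
    alts: tuple[str, ...]
    observed: frozenset[str]


def write_outgroup_vcf(
    calls: Mapping[tuple[str, int], OutgroupCall],
    scaffolds: pd.DataFrame,
    path: str | Path,
    sample: str = "outgroup",
) -> None:
    lines = ["##fileformat=VCFv4.2", "##source=hornscan"]
    for name, row in scaffolds.iterrows():
        lines.append(f"##contig=<ID={name},length={int(row['length'])}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}")
    order = {name: i for i, name in enumerate(scaffolds.index)}
    for (scaffold, pos), call in sorted(
        calls.items(), key=lambda kv: (order[kv[0][0]], kv[0][1])
    ):
        alleles = [call.ref, *call.alts]
        gt_idx = sorted(alleles.index(b) for b in call.observed)
        if len(gt_idx) == 1:
            gt_idx = gt_idx * 2
        gt = "/".join(str(i) for i in gt_idx)
        lines.append(
            f"{scaffold}\t{pos}\t.\t{call.ref}\t{','.join(call.alts)}"
            f"\t.\tPASS\t.\tGT\t{gt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_outgroup_vcf(path: str | Path) -> dict[tuple[str, int], OutgroupCall]:
    """Read outgroup variant calls keyed by (scaffold, 1-based position)."""
    out: dict[tuple[str, int], OutgroupCall] = {}
    vcf = VCF(str(path))
    for var in vcf:
        alleles = [var.REF, *var.ALT]
        observed: set[str] = set()
        for g in var.genotypes:
            for a in _genotype_alleles(g):
                if a >= 0:
                    observed.add(alleles[a])
        if not observed:
            observed = {var.REF}
        out[(var.CHROM, var.POS)] = OutgroupCall(
            ref=var.REF, alts=tuple(var.ALT), observed=frozenset(observed)
        )
    return out


# ---------------------------------------------------------------------- GFF3


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for gene in genes:
        start, end = gene.span
        lines.append(
            f"{gene.scaffold}\thornscan\tgene\t{start + 1}\t{end}\t.\t"
            f"{gene.strand}\t.\tID={gene.gene_id}"
        )
        lines.append(
            f"{gene.scaffold}\thornscan\tmRNA\t{start + 1}\t{end}\t.\t"
            f"{gene.strand}\t.\tID={gene.gene_id}.t1;Parent={gene.gene_id}"
        )
        exons = list(gene.exons)
        order = exons if gene.strand == "+" else exons[::-1]
        phases: dict[tuple[int, int], int] = {}
        cum = 0
        for seg in order:
            phases[seg] = (3 - cum % 3) % 3
            cum += seg[1] - seg[0]
        for k, (s, e) in enumerate(exons):
            lines.append(
                f"{gene.scaffold}\thornscan\tCDS\t{s + 1}\t{e}\t.\t{gene.strand}\t"
                f"{phases[(s, e)]}\tID={gene.gene_id}.cds{k};Parent={gene.gene_id}.t1"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _gff_attributes(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if part and "=" in part:
            key, value = part.split("=", 1)
            out[key] = value
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3 (CDS features grouped via Parent links)."""
    mrna_gene: dict[str, str] = {}
    cds: dict[str, list[tuple[str, str, int, int]]] = {}
    gene_order: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            continue
        scaffold, _, ftype, start, end, _, strand, _, attrs = fields
        attrs = _gff_attributes(attrs)
        if ftype == "gene":
            gene_order.append(attrs["ID"])
        elif ftype == "mRNA":
            mrna_gene[attrs["ID"]] = attrs.get("Parent", attrs["ID"])
        elif ftype == "CDS":
            parent = attrs.get("Parent", attrs.get("ID", ""))
            gene_id = mrna_gene.get(parent, parent)
            cds.setdefault(gene_id, []).append(
                (scaffold, strand, int(start) - 1, int(end))
            )
    genes = []
    for gene_id in gene_order or list(cds):
        segs = sorted(cds.get(gene_id, []), key=lambda t: t[2])
        if not segs:
            continue
        scaffold, strand = segs[0][0], segs[0][1]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                scaffold=scaffold,
                strand=strand,
                exons=tuple((s, e) for _, _, s, e in segs),
            )
        )
    return genes


# ----------------------------------------------------------------------- TSV


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
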