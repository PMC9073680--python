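"""Coding-site degeneracy, variant effects and population summary statistics.

Site classes follow the standard nuclear codon table: a CDS position is
4-fold degenerate when every substitution preserves the amino acid and
0-fold degenerate when none does.  These classes proxy neutral vs selected
variation for pi_0 / pi_4 and Tajima's D_0 / D_4, while per-gene pN and pS
scale nonsynonymous/synonymous SNP counts by the number of 0-fold/4-fold
positions in the gene.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .containers import GeneModel, VariantTable, revcomp
from .polarize import PolarizationDecision, derived_counts

ZERO_FOLD = "zero_fold"
FOUR_FOLD = "four_fold"
OTHER = "other"

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
STOP_GAIN = "stop_gain"
STOP_LOSS = "stop_loss"
NON_CODING = "non_coding"

_BASES = "ACGT"


def _codon_to_aa(table_id: int = 1) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    aa = dict(table.forward_table)
    for stop in table.stop_codons:
        aa[stop] = "*"
    return aa


def translate_codon(codon: str, table_id: int = 1) -> str:
    """One-letter amino acid, with '*' for stop codons."""
    return _codon_to_aa(table_id)[codon.upper()]


def codon_degeneracy(codon: str, position: int, table_id: int = 1) -> str:
    """Degeneracy class of one codon position (0-based within the codon)."""
    aa_map = _codon_to_aa(table_id)
    codon = codon.upper()
    ref_aa = aa_map[codon]
    changed = 0
    for base in _BASES:
        if base == codon[position]:
            continue
        mutant = codon[:position] + base + codon[position + 1 :]
        if aa_map[mutant] != ref_aa:
            changed += 1
    if changed == 0:
        return FOUR_FOLD
    if changed == 3:
        return ZERO_FOLD
    return OTHER


# ----------------------------------------------------------- degeneracy maps


def classify_degeneracy(
    genes: Iterable[GeneModel],
    reference: Mapping[str, str],
    table_id: int = 1,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-CDS-position degeneracy classes for a set of gene models.

    Returns a frame with one row per (gene, position) -- columns
    ``gene_id, scaffold, pos`` (1-based), ``strand, codon, codon_pos,
    degeneracy`` -- plus the list of genes flagged and excluded because
    their CDS is not a multiple of 3 or contains an internal stop.
    """
    aa_map = _codon_to_aa(table_id)
    rows = []
    flagged = []
    for gene in genes:
        cds = gene.cds_sequence(reference)
        if len(cds) % 3 != 0:
            flagged.append(gene.gene_id)
            continue
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if any(aa_map.get(c) == "*" for c in codons[:-1]):
            flagged.append(gene.gene_id)
            continue
        positions = gene.genomic_positions()
        for ci, codon in enumerate(codons):
            for cp in range(3):
                rows.append(
                    (
                        gene.gene_id,
                        gene.scaffold,
                        int(positions[3 * ci + cp]) + 1,
                        gene.strand,
                        codon,
                        cp,
                        codon_degeneracy(codon, cp, table_id),
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "scaffold", "pos", "strand", "codon", "codon_pos",
            "degeneracy",
        ],
    )
    return df, flagged


def degeneracy_map(per_gene: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-gene classes to one class per genomic position.

    Positions claimed by overlapping CDS frames with conflicting classes
    collapse to ``other`` (and so drop out of the 0-fold/4-fold statistics).
    """
    def _merge(classes: pd.Series) -> str:
        uniq = set(classes)
        return uniq.pop() if len(uniq) == 1 else OTHER

    out = (
        per_gene.groupby(["scaffold", "pos"], sort=True)["degeneracy"]
        .agg(_merge)
        .reset_index()
    )
    return out


# -------------------------------------------------------------- SNP effects


@dataclasses.dataclass(frozen=True)
class EffectAnnotation:
    """Predicted coding-sequence consequence of one SNP in one gene."""

    scaffold: str
    pos: int  # 1-based
    gene_id: str | None
    effect: str
    codon_ref: str | None = None
    codon_alt: str | None = None

    def __post_init__(self) -> None:
        if self.effect == STOP_LOSS:
            aa_map = _codon_to_aa()
            if aa_map[self.codon_ref] != "*" or aa_map[self.codon_alt] == "*":
                raise ValueError(
                    "stop_loss requires a canonical stop reference codon and "
                    "a non-stop alternate codon"
                )


def annotate_effect(
    scaffold: str,
    pos: int,
    ref: str,
    alt: str,
    genes: Sequence[GeneModel],
    reference: Mapping[str, str],
    table_id: int = 1,
) -> list[EffectAnnotation]:
    """Annotate one SNP against every overlapping gene model.

    Returns one annotation per containing gene, or a single ``non_coding``
    annotation when the SNP lies in no CDS.
    """
    if reference[scaffold][pos - 1].upper() != ref.upper():
        raise ValueError(
            f"reference base at {scaffold}:{pos} is "
            f"{reference[scaffold][pos - 1]!r}, expected {ref!r}"
        )
    aa_map = _codon_to_aa(table_id)
    pos0 = pos - 1
    out = []
    for gene in genes:
        if gene.scaffold != scaffold or not gene.contains(pos0):
            continue
        positions = gene.genomic_positions()
        idx = int(np.flatnonzero(positions == pos0)[0])
        ci, cp = divmod(idx, 3)
        codon_pos = positions[3 * ci : 3 * ci + 3]
        bases = [reference[scaffold][p] for p in codon_pos]
        alt_bases = list(bases)
        alt_bases[cp] = alt
        if gene.strand == "-":
            bases = [revcomp(b) for b in bases]
            alt_bases = [revcomp(b) for b in alt_bases]
        codon_ref = "".join(bases).upper()
        codon_alt = "".join(alt_bases).upper()
        aa_ref, aa_alt = aa_map[codon_ref], aa_map[codon_alt]
        if aa_ref == aa_alt:
            effect = SYNONYMOUS
        elif aa_alt == "*":
            effect = STOP_GAIN
        elif aa_ref == "*":
            effect = STOP_LOSS
        else:
            effect = MISSENSE
        out.append(EffectAnnotation(scaffold, pos, gene.gene_id, effect,
                                    codon_ref, codon_alt))
    if not out:
        out.append(EffectAnnotation(scaffold, pos, None, NON_CODING))
    return out


def annotate_table(
    table: VariantTable,
    genes: Sequence[GeneModel],
    reference: Mapping[str, str],
) -> pd.DataFrame:
    """Effect annotations for every site of a VariantTable (one row per
    site x containing gene)."""
    rows = []
    for row in table.sites.itertuples(index=False):
        for ann in annotate_effect(
            row.scaffold, row.pos, row.ref, row.alt, genes, reference
        ):
            rows.append(
                (ann.scaffold, ann.pos, ann.gene_id, ann.effect,
                 ann.codon_ref, ann.codon_alt)
            )
    return pd.DataFrame(
        rows,
        columns=["scaffold", "pos", "gene_id", "effect", "codon_ref", "codon_alt"],
    )


# --------------------------------------------------------------- pN, pS


NONSYNONYMOUS_EFFECTS = {MISSENSE, STOP_GAIN, STOP_LOSS}


def gene_polymorphism(
    effects: pd.DataFrame,
    per_gene_degeneracy: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene pN and pS.

    pN = nonsynonymous SNP count / number of 0-fold positions in the gene;
    pS = synonymous SNP count / number of 4-fold positions.  The pN/pS ratio
    is reported only where pS > 0 (NaN otherwise).
    """
    site_counts = (
        per_gene_degeneracy.groupby("gene_id")["degeneracy"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=[ZERO_FOLD, FOUR_FOLD, OTHER], fill_value=0)
    )
    coding = effects[effects["gene_id"].notna()]
    n_nonsyn = (
        coding[coding["effect"].isin(NONSYNONYMOUS_EFFECTS)]
        .groupby("gene_id")
        .size()
    )
    n_syn = coding[coding["effect"] == SYNONYMOUS].groupby("gene_id").size()
    out = pd.DataFrame(index=site_counts.index)
    out["n_nonsyn"] = n_nonsyn.reindex(out.index, fill_value=0).astype(int)
    out["n_syn"] = n_syn.reindex(out.index, fill_value=0).astype(int)
    out["n_zero_fold"] = site_counts[ZERO_FOLD]
    out["n_four_fold"] = site_counts[FOUR_FOLD]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["pN"] = np.where(
            out["n_zero_fold"] > 0, out["n_nonsyn"] / out["n_zero_fold"], 0.0
        )
        out["pS"] = np.where(
            out["n_four_fold"] > 0, out["n_syn"] / out["n_four_fold"], 0.0
        )
    out["pn_ps"] = np.where(out["pS"] > 0, out["pN"] / out["pS"], np.nan)
    return out.reset_index()


def polymorphism_medians(per_gene: pd.DataFrame) -> dict[str, float]:
    """Median pN, pS and pN/pS across genes (medians resist outlier skew)."""
    ratio = per_gene["pn_ps"].dropna()
    return {
        "pN": float(per_gene["pN"].median()),
        "pS": float(per_gene["pS"].median()),
        "pn_ps": float(ratio.median()) if len(ratio) else float("nan"),
    }


# ------------------------------------------------------- pi and Tajima's D


def tajima_constants(n: int) -> dict[str, float]:
    """Standard constants a1..e2 for n sampled chromosomes (Tajima 1989)."""
    if n < 4:
        raise ValueError("Tajima's D variance terms are unstable for n < 4")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def pi_and_tajimas_d(
    freqs: np.ndarray,
    n: int,
    n_sites: int | None = None,
) -> tuple[float, int, float]:
    """Nucleotide diversity, segregating-site count and Tajima's D.

    ``freqs`` are per-site allele frequencies for one site class (monomorphic
    sites may be included as 0 or 1 and contribute nothing); ``n`` is the
    fixed number of sampled chromosomes.  Per-site heterozygosity uses the
    unbiased factor n/(n-1):

        pi = (1 / n_sites) * sum_i 2 p_i (1 - p_i) n / (n - 1)

    D is the standard normalized difference (pi_total - S/a1) /
    sqrt(e1 S + e2 S (S-1)); with S = 0 the statistic is undefined and 0.0
    is reported.
    """
    freqs = np.asarray(freqs, dtype=float)
    consts = tajima_constants(n)
    het = 2.0 * freqs * (1.0 - freqs) * n / (n - 1)
    pi_total = float(het.sum())
    s = int(((freqs > 0) & (freqs < 1)).sum())
    denom_sites = n_sites if n_sites is not None else len(freqs)
    pi = pi_total / denom_sites if denom_sites else 0.0
    if s == 0:
        return pi, 0, 0.0
    var = consts["e1"] * s + consts["e2"] * s * (s - 1)
    d = (pi_total - s / consts["a1"]) / math.sqrt(var)
    return pi, s, d


# -------------------------------------------------- per-population summary


def population_summary(
    table: VariantTable,
    decisions: Sequence[PolarizationDecision],
    genes: Sequence[GeneModel],
    reference: Mapping[str, str],
    population: str,
    exclude_scaffolds: Iterable[str] = (),
) -> dict:
    """Assemble the per-population summary block.

    Reports median pN / pS / pN/pS across genes and pi / Tajima's D at
    0-fold and 4-fold sites, using complete-case sites (every sample called)
    so the chromosome total n is fixed within the population.
    """
    excluded = set(exclude_scaffolds)
    table = table.exclude_scaffolds(excluded)
    use_genes = [g for g in genes if g.scaffold not in excluded]
    per_gene_deg, _ = classify_degeneracy(use_genes, reference)
    site_map = degeneracy_map(per_gene_deg)
    # pN/pS count only sites segregating within this population
    alt, chroms = table.allele_counts(population)
    segregating = (alt > 0) & (alt < chroms)
    effects = annotate_table(table.subset_sites(segregating), use_genes, reference)
    per_gene = gene_polymorphism(effects, per_gene_deg)
    medians = polymorphism_medians(per_gene)

    aligned = decisions if len(decisions) == table.n_sites else None
    keep, derived, total = derived_counts(
        table, aligned if aligned is not None else list(decisions), population
    )
    n_full = int(total.max()) if len(total) else 0
    complete = keep & (total == n_full) & (n_full >= 4)
    snp_pos = table.sites[["scaffold", "pos"]].copy()
    snp_pos["freq"] = np.where(total > 0, derived / np.maximum(total, 1), 0.0)
    snp_pos = snp_pos[complete]
    merged = snp_pos.merge(site_map, on=["scaffold", "pos"], how="left")

    out: dict = {"population": population, **medians, "per_gene": per_gene}
    for cls, label in ((ZERO_FOLD, "0"), (FOUR_FOLD, "4")):
        n_class_sites = int((site_map["degeneracy"] == cls).sum())
        class_freqs = merged.loc[merged["degeneracy"] == cls, "freq"].to_numpy()
        if n_full >= 4 and n_class_sites > 0:
            pi, s, d = pi_and_tajimas_d(class_freqs, n_full, n_class_sites)
        else:
            pi, s, d = float("nan"), 0, float("nan")
        out[f"pi_{label}"] = pi
        out[f"S_{label}"] = s
        out[f"tajimas_d_{label}"] = d
    out["n_chromosomes"] = n_full
    return out
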