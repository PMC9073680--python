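"""Synthetic three-population resequencing dataset with known truth.

The generator emulates the sampling design the analysis assumes: three
populations of unequal size (12, 4 and 8 diploids), Balding-Nichols
background differentiation calibrated to target pairwise F_ST, a large
autosomal inversion segregating in one population at 11/16 chromosomes, a
smaller Z-linked inversion at 13/14 with female hemizygosity, and a
stop-loss pseudogene variant whose genotypes copy the autosomal inversion.

Background allele frequencies follow the Balding-Nichols construction: an
ancestral derived-allele frequency p ~ Uniform(0.05, 0.95) and per-population
draws Beta(p(1-F)/F, (1-p)(1-F)/F).  Independent draws for two populations
with drift parameters F1, F2 give Hudson F_ST ~= (F1 + F2)/2, so per-pair
targets are converted into per-population F by non-negative least squares.

Inside an inversion interval every sampled chromosome is either the intact
ancestral arrangement or the single shared inverted haplotype: marker SNPs
are fixed on the inverted haplotype, so within the carrier population they
all sit at exactly k/T where k chromosomes of T carry the inversion.
Non-marker SNPs inside the interval are partially linked to a latent local
haplotype group in every population (the carrier status where the inversion
segregates, a neutral frequency elsewhere), which reproduces the elevated
linkage disequilibrium seen inside such regions even in populations lacking
the inverted orientation.

Everything is seeded: one integer seed fans out into named per-component
streams, so adding a component never shifts another component's draws.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from . import io as hio
from .containers import (
    MISSING,
    NO_ALLELE,
    GeneModel,
    Scaffold,
    VariantTable,
    revcomp,
    scaffold_frame,
)
from .io import OutgroupCall
from .popstats import ZERO_FOLD, classify_degeneracy

_BASES = np.array(list("ACGT"))

# site kinds recorded in the truth table
BACKGROUND = "background"
MARKER = "marker"
PSEUDOGENE = "pseudogene"
STOP_LOSS_SITE = "stop_loss"


@dataclasses.dataclass(frozen=True)
class PopulationSpec:
    name: str
    n_diploids: int
    n_males: int
    n_females: int

    def __post_init__(self) -> None:
        if self.n_diploids < 1:
            raise ValueError("each population needs at least one diploid")
        if self.n_males + self.n_females != self.n_diploids:
            raise ValueError(
                f"{self.name}: males + females must equal n_diploids"
            )


@dataclasses.dataclass(frozen=True)
class CarrierCounts:
    """Inversion carrier genotype-class counts within one population.

    ``hom``/``het`` count diploid samples (ZZ males on the Z), ``hemi``
    counts hemizygous carrier females on Z scaffolds.
    """

    hom: int = 0
    het: int = 0
    hemi: int = 0

    @property
    def chromosomes(self) -> int:
        return 2 * self.hom + self.het + self.hemi


@dataclasses.dataclass(frozen=True)
class InversionSpec:
    inversion_id: str
    scaffold: str
    start: int  # 0-based half-open
    end: int
    carriers: Mapping[str, CarrierCounts]
    marker_density: float = 1.5  # marker SNPs per kb on the inverted haplotype

    @property
    def n_markers(self) -> int:
        return int(round(self.marker_density * (self.end - self.start) / 1000))


@dataclasses.dataclass(frozen=True)
class PseudogeneSpec:
    gene_id: str = "g12_pseudo"
    n_linked_snps: int = 61
    include_stop_loss: bool = True
    linked_inversion: str = "inv12"


@dataclasses.dataclass(frozen=True)
class GenePlacement:
    gene_id: str
    scaffold: str
    start: int  # 0-based CDS start
    strand: str
    n_codons: int  # including start and stop

    @property
    def end(self) -> int:
        return self.start + 3 * self.n_codons


@dataclasses.dataclass
class SimConfig:
    populations: list[PopulationSpec]
    scaffolds: list[Scaffold]
    background_fst: dict[tuple[str, str], float]
    n_snps_per_scaffold: int
    inversions: list[InversionSpec]
    genes: list[GenePlacement]
    pseudogene: PseudogeneSpec | None
    seed: int
    missing_rate: dict[str, float] = dataclasses.field(default_factory=dict)
    frac_alt_ancestral: float = 0.25
    frac_outgroup_het: float = 0.15  # of alt-ancestral sites, shown as het
    frac_masked: float = 0.02
    zero_fold_suppression: float = 0.25
    linkage_lambda: float = 0.8  # fraction of inside-interval SNPs linked
    linkage_eps: float = 0.1  # per-chromosome flip rate at linked SNPs
    stage_probs: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "larva": 0.2, "pupa": 0.1, "adult": 0.25, "unbiased": 0.45,
        }
    )
    tissue_probs: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "antenna": 0.08, "head": 0.08, "muscle": 0.08, "midgut": 0.08,
            "malpighian": 0.08, "fat": 0.1, "unbiased": 0.5,
        }
    )
    sex_probs: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"male": 0.35, "female": 0.25, "unbiased": 0.4}
    )
    #: sex-class mix for genes inside the Z inversion (excess of unbiased
    #: genes, the composition signal the enrichment test should detect)
    z_inversion_sex_probs: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"male": 0.075, "female": 0.075, "unbiased": 0.85}
    )
    specificity: float = 0.9  # weight share of the focal category
    expression_noise_sd: float = 0.1  # lognormal sd on condition values

    def validate(self) -> None:
        pops = {p.name: p for p in self.populations}
        scafs = {s.name: s for s in self.scaffolds}
        for (a, b), f in self.background_fst.items():
            if a not in pops or b not in pops:
                raise ValueError(f"F_ST target for unknown pair ({a}, {b})")
            if not 0 <= f < 1:
                raise ValueError("target F_ST must lie in [0, 1)")
        for inv in self.inversions:
            scaffold = scafs.get(inv.scaffold)
            if scaffold is None:
                raise ValueError(f"{inv.inversion_id}: unknown scaffold")
            if not (0 <= inv.start < inv.end <= scaffold.length):
                raise ValueError(
                    f"{inv.inversion_id}: interval outside scaffold bounds"
                )
            for pop_name, cc in inv.carriers.items():
                pop = pops[pop_name]
                if scaffold.is_z:
                    n_diploid, n_hemi = pop.n_males, pop.n_females
                else:
                    n_diploid, n_hemi = pop.n_diploids, 0
                total = 2 * n_diploid + n_hemi
                if cc.hom + cc.het > n_diploid or cc.hemi > n_hemi:
                    raise ValueError(
                        f"{inv.inversion_id}: carrier classes exceed sample "
                        f"counts in {pop_name}"
                    )
                if cc.chromosomes > total:
                    raise ValueError(
                        f"{inv.inversion_id}: {cc.chromosomes} carrier "
                        f"chromosomes exceed the {total} sampled in {pop_name}"
                    )
        for gene in self.genes:
            if gene.end > scafs[gene.scaffold].length:
                raise ValueError(f"{gene.gene_id}: CDS outside scaffold")
        if self.pseudogene is not None:
            ids = {g.gene_id for g in self.genes}
            if self.pseudogene.gene_id not in ids:
                raise ValueError("pseudogene gene_id not among placed genes")


def default_config(seed: int = 0) -> SimConfig:
    """The package's study-design defaults.

    Three populations sized 12/4/8 diploids with the observed sex make-up,
    neutral-site pairwise F_ST targets of 0.054/0.081/0.044, a chr12-analog
    inversion spanning half its scaffold at 11/16 chromosomes in the
    southwestern population, a Z-analog inversion at 13/14, and a 61-SNP
    pseudogene (one SNP a stop loss) riding on the autosomal inversion.
    Scaffolds are desk-scale: 1 Mb autosomes and a 500 kb Z.
    """
    genes: list[GenePlacement] = []
    for i in range(8):
        genes.append(
            GenePlacement(
                f"g5_{i + 1}", "chr5", 50_000 + 100_000 * i,
                "+" if i % 2 == 0 else "-", 300,
            )
        )
    genes.append(GenePlacement("g12_out1", "chr12", 50_000, "+", 300))
    genes.append(GenePlacement("g12_out2", "chr12", 850_000, "-", 300))
    for i in range(11):
        genes.append(
            GenePlacement(
                f"g12_in{i + 1}", "chr12", 260_000 + 40_000 * i,
                "+" if i % 2 == 0 else "-", 300,
            )
        )
    genes.append(GenePlacement("g12_pseudo", "chr12", 495_000, "+", 500))
    for i in range(20):
        genes.append(
            GenePlacement(
                f"gZ_in{i + 1}", "chrZ", 155_000 + 9_000 * i,
                "+" if i % 2 == 0 else "-", 300,
            )
        )
    for i, start in enumerate((20_000, 60_000, 100_000, 380_000, 420_000, 460_000)):
        genes.append(
            GenePlacement(
                f"gZ_out{i + 1}", "chrZ", start, "+" if i % 2 == 0 else "-", 300
            )
        )
    return SimConfig(
        populations=[
            PopulationSpec("NC", 12, 12, 0),
            PopulationSpec("KS", 4, 1, 3),
            PopulationSpec("AZ", 8, 6, 2),
        ],
        scaffolds=[
            Scaffold("chr5", 1_000_000, "5", False),
            Scaffold("chr12", 1_000_000, "12", False),
            Scaffold("chrZ", 500_000, "Z", True),
        ],
        background_fst={
            ("NC", "KS"): 0.054,
            ("NC", "AZ"): 0.081,
            ("KS", "AZ"): 0.044,
        },
        n_snps_per_scaffold=400,
        inversions=[
            InversionSpec(
                "inv12", "chr12", 250_000, 750_000,
                carriers={"AZ": CarrierCounts(hom=4, het=3)},
            ),
            InversionSpec(
                "invZ", "chrZ", 150_000, 350_000,
                carriers={"AZ": CarrierCounts(hom=5, het=1, hemi=2)},
            ),
        ],
        genes=genes,
        pseudogene=PseudogeneSpec(),
        seed=seed,
    )


def stream(seed: int, name: str) -> np.random.Generator:
    """Named random stream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),))
    )


def solve_population_f(
    populations: Sequence[str],
    targets: Mapping[tuple[str, str], float],
) -> dict[str, float]:
    """Per-population Balding-Nichols F from pairwise F_ST targets.

    Independent Beta draws give pairwise F_ST ~= (F_i + F_j)/2; the linear
    system is solved by non-negative least squares.
    """
    pops = list(populations)
    idx = {p: i for i, p in enumerate(pops)}
    rows = []
    rhs = []
    for (a, b), t in targets.items():
        row = np.zeros(len(pops))
        row[idx[a]] = 1.0
        row[idx[b]] = 1.0
        rows.append(row)
        rhs.append(2.0 * t)
    if not rows:
        return {p: 0.0 for p in pops}
    f, _ = nnls(np.asarray(rows), np.asarray(rhs))
    return {p: float(f[idx[p]]) for p in pops}


@dataclasses.dataclass
class TruthTable:
    """Ground truth recorded alongside the simulated observables."""

    sites: pd.DataFrame
    inversion_genotypes: pd.DataFrame
    gene_classes: pd.DataFrame
    population_f: dict[str, float]


@dataclasses.dataclass
class SimResult:
    table: VariantTable
    reference: dict[str, str]
    outgroup: dict[tuple[str, int], OutgroupCall]
    genes: list[GeneModel]
    meta: pd.DataFrame
    expression: pd.DataFrame
    design: pd.DataFrame
    truth: TruthTable
    config: SimConfig | None = None


class _PopChromosomes:
    """Chromosome-slot bookkeeping for one population on one scaffold."""

    def __init__(self, spec: PopulationSpec, is_z: bool, sample_names, sexes):
        self.sample_names = list(sample_names)
        self.ploidy = np.array(
            [1 if (is_z and s == "F") else 2 for s in sexes], dtype=np.int64
        )
        self.offsets = np.concatenate([[0], np.cumsum(self.ploidy)])[:-1]
        self.total = int(self.ploidy.sum())
        self.is_z = is_z
        self.sexes = list(sexes)

    def dosage(self, chrom_flags: np.ndarray) -> np.ndarray:
        return np.add.reduceat(chrom_flags.astype(np.int64), self.offsets)


def _carrier_flags(
    chroms: _PopChromosomes, counts: CarrierCounts
) -> tuple[np.ndarray, dict[str, str]]:
    """Assign carrier chromosomes to samples and record truth genotypes."""
    flags = np.zeros(chroms.total, dtype=bool)
    genotypes: dict[str, str] = {}
    hom_left, het_left, hemi_left = counts.hom, counts.het, counts.hemi
    for j, name in enumerate(chroms.sample_names):
        off = chroms.offsets[j]
        if chroms.ploidy[j] == 1:
            if hemi_left > 0:
                flags[off] = True
                genotypes[name] = "carrier"
                hemi_left -= 1
            else:
                genotypes[name] = "non_carrier"
        elif hom_left > 0:
            flags[off : off + 2] = True
            genotypes[name] = "hom_inverted"
            hom_left -= 1
        elif het_left > 0:
            flags[off] = True
            genotypes[name] = "het"
            het_left -= 1
        else:
            genotypes[name] = "hom_ancestral"
    return flags, genotypes


def _make_reference(config: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    """Random reference with valid ORFs written at each gene placement."""
    seqs: dict[str, np.ndarray] = {}
    for scaffold in config.scaffolds:
        seqs[scaffold.name] = rng.choice(_BASES, size=scaffold.length)
    sense_codons = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in {"TAA", "TAG", "TGA"}
    ]
    for gene in config.genes:
        codons = ["ATG"]
        codons += list(rng.choice(sense_codons, size=gene.n_codons - 2))
        codons.append("TAA")
        cds = "".join(codons)
        if gene.strand == "-":
            cds = revcomp(cds)
        seqs[gene.scaffold][gene.start : gene.end] = list(cds)
    return {name: "".join(arr) for name, arr in seqs.items()}


def _gene_models(config: SimConfig) -> list[GeneModel]:
    return [
        GeneModel(g.gene_id, g.scaffold, g.strand, ((g.start, g.end),))
        for g in config.genes
    ]


def _draw_positions(
    rng: np.random.Generator, low: int, high: int, n: int, used: set[int]
) -> list[int]:
    """Draw n distinct 1-based positions in (low, high], avoiding `used`."""
    out: list[int] = []
    while len(out) < n:
        cand = int(rng.integers(low + 1, high + 1))
        if cand not in used:
            used.add(cand)
            out.append(cand)
    return sorted(out)


def simulate_dataset(config: SimConfig) -> SimResult:
    """Generate the full observable set plus truth tables."""
    config.validate()
    seed = config.seed

    reference = _make_reference(config, stream(seed, "reference"))
    genes = _gene_models(config)
    deg_frame, _ = classify_degeneracy(genes, reference)
    zero_fold_pos = {
        (r.scaffold, r.pos)
        for r in deg_frame.itertuples(index=False)
        if r.degeneracy == ZERO_FOLD
    }

    # ---- samples ---------------------------------------------------------
    sample_rows = []
    for pop in config.populations:
        for i in range(pop.n_diploids):
            sex = "M" if i < pop.n_males else "F"
            sample_rows.append((f"{pop.name}{i + 1:02d}", pop.name, sex))
    meta = pd.DataFrame(
        sample_rows, columns=["sample", "population", "sex"]
    ).set_index("sample")
    samples = list(meta.index)
    scaffolds_df = scaffold_frame(config.scaffolds)
    pop_f = solve_population_f(
        [p.name for p in config.populations], config.background_fst
    )

    # ---- per-scaffold chromosome bookkeeping -----------------------------
    pop_specs = {p.name: p for p in config.populations}
    chrom_sets: dict[tuple[str, str], _PopChromosomes] = {}
    for scaffold in config.scaffolds:
        for pop in config.populations:
            names = [s for s in samples if meta.loc[s, "population"] == pop.name]
            sexes = [meta.loc[s, "sex"] for s in names]
            chrom_sets[(scaffold.name, pop.name)] = _PopChromosomes(
                pop_specs[pop.name], scaffold.is_z, names, sexes
            )

    inv_by_scaffold: dict[str, InversionSpec] = {
        inv.scaffold: inv for inv in config.inversions
    }
    carrier_flags: dict[tuple[str, str], np.ndarray] = {}
    latent_labels: dict[tuple[str, str], np.ndarray] = {}
    inversion_truth_rows = []
    rng_latent = stream(seed, "latent_haplotypes")
    for inv in config.inversions:
        for pop in config.populations:
            chroms = chrom_sets[(inv.scaffold, pop.name)]
            counts = inv.carriers.get(pop.name)
            if counts is not None and counts.chromosomes > 0:
                flags, genos = _carrier_flags(chroms, counts)
                latent = flags
            else:
                flags = np.zeros(chroms.total, dtype=bool)
                genos = {
                    name: ("non_carrier" if p == 1 else "hom_ancestral")
                    for name, p in zip(chroms.sample_names, chroms.ploidy)
                }
                q = rng_latent.uniform(0.2, 0.8)
                latent = rng_latent.random(chroms.total) < q
            carrier_flags[(inv.inversion_id, pop.name)] = flags
            latent_labels[(inv.inversion_id, pop.name)] = latent
            for name, g in genos.items():
                inversion_truth_rows.append((inv.inversion_id, pop.name, name, g))

    # ---- site catalogue --------------------------------------------------
    rng_pos = stream(seed, "positions")
    site_plan: list[tuple[str, int, str, str | None, str | None]] = []
    # tuples: (scaffold, pos, kind, inversion_id, gene_id)
    pseudo = config.pseudogene
    pseudo_gene = None
    if pseudo is not None:
        pseudo_gene = next(
            g for g in config.genes if g.gene_id == pseudo.gene_id
        )
    for scaffold in config.scaffolds:
        used: set[int] = set()
        inv = inv_by_scaffold.get(scaffold.name)
        if pseudo is not None and pseudo_gene.scaffold == scaffold.name:
            inv_id = pseudo.linked_inversion
            stop_mid = pseudo_gene.end - 1  # middle base of TAA, 1-based
            n_other = pseudo.n_linked_snps
            if pseudo.include_stop_loss:
                used.add(stop_mid)
                site_plan.append(
                    (scaffold.name, stop_mid, STOP_LOSS_SITE, inv_id,
                     pseudo.gene_id)
                )
                n_other -= 1
            # linked SNPs in the gene body, sparing start and stop codons
            for p in _draw_positions(
                rng_pos, pseudo_gene.start + 3, pseudo_gene.end - 3, n_other, used
            ):
                site_plan.append(
                    (scaffold.name, p, PSEUDOGENE, inv_id, pseudo.gene_id)
                )
        if inv is not None:
            for p in _draw_positions(
                rng_pos, inv.start, inv.end, inv.n_markers, used
            ):
                site_plan.append(
                    (scaffold.name, p, MARKER, inv.inversion_id, None)
                )
        for p in _draw_positions(
            rng_pos, 0, scaffold.length, config.n_snps_per_scaffold, used
        ):
            inv_id = None
            if inv is not None and inv.start < p <= inv.end:
                inv_id = inv.inversion_id
            site_plan.append((scaffold.name, p, BACKGROUND, inv_id, None))
    order = {s.name: i for i, s in enumerate(config.scaffolds)}
    site_plan.sort(key=lambda t: (order[t[0]], t[1]))

    # ---- per-site generation ---------------------------------------------
    rng_freq = stream(seed, "frequencies")
    rng_geno = stream(seed, "genotypes")
    rng_out = stream(seed, "outgroup")
    rng_anc = stream(seed, "ancestry")
    pop_names = [p.name for p in config.populations]
    n_samples = len(samples)
    col_of = {s: j for j, s in enumerate(samples)}

    site_rows = []
    truth_rows = []
    gt_rows = []
    outgroup: dict[tuple[str, int], OutgroupCall] = {}
    base_choices = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}

    for scaffold_name, pos, kind, inv_id, gene_id in site_plan:
        ref_base = reference[scaffold_name][pos - 1]
        is_marker_like = kind in (MARKER, PSEUDOGENE, STOP_LOSS_SITE)
        # ancestral labelling
        if is_marker_like:
            anc_mode = "ref"
        else:
            u = rng_anc.random()
            if u < config.frac_masked:
                anc_mode = "masked"
            elif u < config.frac_masked + config.frac_alt_ancestral:
                anc_mode = "alt"
            else:
                anc_mode = "ref"
        # derived-allele frequencies
        p0 = rng_freq.uniform(0.05, 0.95)
        if (scaffold_name, pos) in zero_fold_pos and not is_marker_like:
            p0 *= config.zero_fold_suppression
        linked = (
            inv_id is not None
            and not is_marker_like
            and rng_freq.random() < config.linkage_lambda
        )
        pop_p = {}
        for name in pop_names:
            f = pop_f[name]
            if f < 1e-9:
                pop_p[name] = p0
            else:
                a = p0 * (1 - f) / f
                b = (1 - p0) * (1 - f) / f
                pop_p[name] = float(rng_freq.beta(a, b))

        # per-chromosome derived alleles
        gt_row = np.full((n_samples, 2), NO_ALLELE, dtype=np.int8)
        for name in pop_names:
            chroms = chrom_sets[(scaffold_name, name)]
            if kind == MARKER or kind == PSEUDOGENE or kind == STOP_LOSS_SITE:
                derived = carrier_flags[(inv_id, name)].copy()
            elif inv_id is not None and linked:
                labels = latent_labels[(inv_id, name)]
                flips = rng_geno.random(chroms.total) < config.linkage_eps
                derived = labels ^ flips
            elif inv_id is not None and carrier_flags[(inv_id, name)].any():
                # unlinked SNP inside the inversion in the carrier population:
                # the inverted haplotype is a single shared haplotype, so new
                # variation segregates only on non-carrier chromosomes
                free = ~carrier_flags[(inv_id, name)]
                derived = np.zeros(chroms.total, dtype=bool)
                derived[free] = rng_geno.random(int(free.sum())) < pop_p[name]
            else:
                derived = rng_geno.random(chroms.total) < pop_p[name]
            derived_allele = 0 if anc_mode == "alt" else 1
            other_allele = 1 - derived_allele
            miss = config.missing_rate.get(name, 0.0)
            for j, sample in enumerate(chroms.sample_names):
                off = chroms.offsets[j]
                ploidy = int(chroms.ploidy[j])
                col = col_of[sample]
                if miss > 0 and rng_geno.random() < miss:
                    gt_row[col, :ploidy] = MISSING
                    continue
                alleles = sorted(
                    derived_allele if derived[off + k] else other_allele
                    for k in range(ploidy)
                )
                gt_row[col, :ploidy] = alleles

        # allele identities and outgroup
        if anc_mode == "alt":
            alt_base = rng_out.choice(base_choices[ref_base])
            ancestral = alt_base
            if rng_out.random() < config.frac_outgroup_het:
                third = rng_out.choice(
                    [b for b in "ACGT" if b not in (ref_base, alt_base)]
                )
                outgroup[(scaffold_name, pos)] = OutgroupCall(
                    ref=ref_base,
                    alts=(third, alt_base),
                    observed=frozenset({third, alt_base}),
                )
            else:
                outgroup[(scaffold_name, pos)] = OutgroupCall(
                    ref=ref_base, alts=(alt_base,), observed=frozenset({alt_base})
                )
        elif anc_mode == "masked":
            alt_base = rng_out.choice(base_choices[ref_base])
            ancestral = "N"
            third = rng_out.choice(
                [b for b in "ACGT" if b not in (ref_base, alt_base)]
            )
            outgroup[(scaffold_name, pos)] = OutgroupCall(
                ref=ref_base, alts=(third,), observed=frozenset({third})
            )
        else:
            if kind == STOP_LOSS_SITE:
                alt_base = "C"  # TAA -> TCA, a canonical stop loss
            else:
                alt_base = rng_out.choice(base_choices[ref_base])
            ancestral = ref_base
        site_rows.append((scaffold_name, pos, ref_base, alt_base))
        neutral = (
            kind == BACKGROUND
            and inv_id is None
            and (scaffold_name, pos) not in zero_fold_pos
        )
        truth_rows.append(
            (
                scaffold_name, pos, ref_base, alt_base, ancestral, kind,
                inv_id or "", gene_id or "", bool(linked), neutral,
            )
        )
        gt_rows.append(gt_row)

    sites = pd.DataFrame(site_rows, columns=["scaffold", "pos", "ref", "alt"])
    gt = np.stack(gt_rows) if gt_rows else np.empty((0, n_samples, 2), np.int8)
    table = VariantTable(sites, gt, samples, meta, scaffolds_df)

    truth_sites = pd.DataFrame(
        truth_rows,
        columns=[
            "scaffold", "pos", "ref", "alt", "ancestral", "kind",
            "inversion_id", "gene_id", "linked", "neutral",
        ],
    )
    inversion_truth = pd.DataFrame(
        inversion_truth_rows,
        columns=["inversion_id", "population", "sample", "genotype"],
    )

    expression, design, gene_classes = _simulate_expression(config)
    truth = TruthTable(truth_sites, inversion_truth, gene_classes, pop_f)
    return SimResult(
        table=table,
        reference=reference,
        outgroup=outgroup,
        genes=genes,
        meta=meta.copy(),
        expression=expression,
        design=design,
        truth=truth,
        config=config,
    )


# ------------------------------------------------------------- expression


def default_design() -> pd.DataFrame:
    """Default tissue x stage x sex availability of expression libraries.

    Head, midgut and fat bodies are sampled in all three stages (the basis
    of the stage dimension); gonads are sexed in pupae and adults, antennae
    sexed in adults; remaining adult somatic tissues are pooled-sex.
    """
    rows = [
        ("larva_antenna", "larva", "antenna", "pooled"),
        ("larva_head", "larva", "head", "pooled"),
        ("larva_midgut", "larva", "midgut", "pooled"),
        ("larva_fat", "larva", "fat", "pooled"),
        ("pupa_head", "pupa", "head", "pooled"),
        ("pupa_midgut", "pupa", "midgut", "pooled"),
        ("pupa_fat", "pupa", "fat", "pooled"),
        ("pupa_gonad_M", "pupa", "gonad", "M"),
        ("pupa_gonad_F", "pupa", "gonad", "F"),
        ("adult_antenna_M", "adult", "antenna", "M"),
        ("adult_antenna_F", "adult", "antenna", "F"),
        ("adult_head", "adult", "head", "pooled"),
        ("adult_muscle", "adult", "muscle", "pooled"),
        ("adult_midgut", "adult", "midgut", "pooled"),
        ("adult_malpighian", "adult", "malpighian", "pooled"),
        ("adult_fat", "adult", "fat", "pooled"),
        ("adult_gonad_M", "adult", "gonad", "M"),
        ("adult_gonad_F", "adult", "gonad", "F"),
    ]
    return pd.DataFrame(rows, columns=["condition", "stage", "tissue", "sex"])


def _pick(rng: np.random.Generator, probs: dict[str, float]) -> str:
    cats = list(probs)
    p = np.array([probs[c] for c in cats], dtype=float)
    return cats[int(rng.choice(len(cats), p=p / p.sum()))]


def _simulate_expression(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    rng = stream(config.seed, "expression")
    design = default_design()
    z_inversions = {
        inv.inversion_id: inv
        for inv in config.inversions
        if any(s.name == inv.scaffold and s.is_z for s in config.scaffolds)
    }
    gene_rows = []
    for gene in config.genes:
        inv_label = ""
        for inv in config.inversions:
            if inv.scaffold == gene.scaffold and inv.start <= gene.start < inv.end:
                inv_label = inv.inversion_id
        sex_probs = (
            config.z_inversion_sex_probs
            if inv_label in z_inversions
            else config.sex_probs
        )
        if config.pseudogene is not None and gene.gene_id == config.pseudogene.gene_id:
            stage_c, tissue_c, sex_c = "larva", "antenna", "unbiased"
        else:
            stage_c = _pick(rng, config.stage_probs)
            tissue_c = _pick(rng, config.tissue_probs)
            sex_c = _pick(rng, sex_probs)
        gene_rows.append(
            (gene.gene_id, gene.scaffold, gene.start, gene.end, gene.strand,
             inv_label, stage_c, tissue_c, sex_c)
        )
    gene_classes = pd.DataFrame(
        gene_rows,
        columns=[
            "gene_id", "scaffold", "start", "end", "strand", "inversion_id",
            "stage_class", "tissue_class", "sex_class",
        ],
    )

    from .expression import _tissue_category  # category convention shared

    stage_cats = ["larva", "pupa", "adult"]
    tissue_cats = [
        "antenna", "head", "muscle", "midgut", "malpighian", "fat",
        "testis", "ovary",
    ]
    spec_w = config.specificity
    values = np.zeros((len(gene_classes), len(design)))
    for i, g in enumerate(gene_classes.itertuples(index=False)):
        base = float(rng.lognormal(mean=3.0, sigma=0.5))
        for j, cond in enumerate(design.itertuples(index=False)):
            w = 1.0
            if g.stage_class != "unbiased":
                w *= (
                    spec_w
                    if cond.stage == g.stage_class
                    else (1 - spec_w) / (len(stage_cats) - 1)
                )
            else:
                w *= 1.0 / len(stage_cats)
            tcat = _tissue_category(cond.tissue, cond.sex)
            if g.tissue_class != "unbiased":
                w *= (
                    spec_w
                    if tcat == g.tissue_class
                    else (1 - spec_w) / (len(tissue_cats) - 1)
                )
            else:
                w *= 1.0 / len(tissue_cats)
            if cond.sex in ("M", "F"):
                if g.sex_class == "unbiased":
                    w *= 0.5
                else:
                    focal = "M" if g.sex_class == "male" else "F"
                    w *= spec_w if cond.sex == focal else 1 - spec_w
            else:
                w *= 0.5
            noise = float(rng.lognormal(0.0, config.expression_noise_sd))
            values[i, j] = base * w * noise
    expression = pd.DataFrame(
        np.round(values * 100, 6),
        index=gene_classes["gene_id"],
        columns=design["condition"],
    )
    expression.index.name = "gene_id"
    return expression, design, gene_classes


# ----------------------------------------------------------- fixture bundle

BUNDLE_FILES = {
    "reference": "reference.fasta",
    "focal_vcf": "focal.vcf",
    "outgroup_vcf": "outgroup.vcf",
    "gff": "genes.gff3",
    "samples": "samples.tsv",
    "scaffolds": "scaffolds.tsv",
    "expression": "expression.tsv",
    "design": "expression_design.tsv",
    "truth_sites": "truth_sites.tsv",
    "truth_inversions": "truth_inversions.tsv",
    "truth_genes": "truth_genes.tsv",
    "truth_params": "truth_params.json",
}


def write_fixture_bundle(result: SimResult, directory: str | Path) -> dict[str, Path]:
    """Write the full observable + truth file set; deterministic per seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in BUNDLE_FILES.items()}
    hio.write_fasta(result.reference, paths["reference"])
    hio.write_vcf(result.table, paths["focal_vcf"])
    hio.write_outgroup_vcf(
        result.outgroup, result.table.scaffolds, paths["outgroup_vcf"]
    )
    hio.write_gff3(result.genes, paths["gff"])
    hio.write_tsv(result.meta.reset_index(), paths["samples"])
    hio.write_tsv(result.table.scaffolds.reset_index(), paths["scaffolds"])
    expr = result.expression.reset_index()
    expr.to_csv(paths["expression"], sep="\t", index=False, float_format="%.6f")
    hio.write_tsv(result.design, paths["design"])
    hio.write_tsv(result.truth.sites, paths["truth_sites"])
    hio.write_tsv(result.truth.inversion_genotypes, paths["truth_inversions"])
    hio.write_tsv(result.truth.gene_classes, paths["truth_genes"])
    params = {
        "population_f": result.truth.population_f,
        "seed": result.config.seed if result.config else None,
    }
    paths["truth_params"].write_text(json.dumps(params, indent=2, sort_keys=True))
    return paths


def read_fixture_bundle(directory: str | Path) -> SimResult:
    """Re-read a fixture bundle into the in-memory objects."""
    directory = Path(directory)
    paths = {k: directory / v for k, v in BUNDLE_FILES.items()}
    meta = hio.read_tsv(paths["samples"]).set_index("sample")
    scaffolds = hio.read_tsv(paths["scaffolds"]).set_index("name")
    scaffolds["is_z"] = scaffolds["is_z"].astype(bool)
    table = hio.read_vcf(paths["focal_vcf"], meta, scaffolds)
    params = json.loads(paths["truth_params"].read_text())
    truth = TruthTable(
        sites=hio.read_tsv(
            paths["truth_sites"], keep_default_na=False,
            dtype={"inversion_id": str, "gene_id": str},
        ),
        inversion_genotypes=hio.read_tsv(paths["truth_inversions"]),
        gene_classes=hio.read_tsv(
            paths["truth_genes"], keep_default_na=False,
            dtype={"inversion_id": str},
        ),
        population_f=params["population_f"],
    )
    return SimResult(
        table=table,
        reference=hio.read_fasta(paths["reference"]),
        outgroup=hio.read_outgroup_vcf(paths["outgroup_vcf"]),
        genes=hio.read_gff3(paths["gff"]),
        meta=meta,
        expression=hio.read_tsv(paths["expression"]).set_index("gene_id"),
        design=hio.read_tsv(paths["design"]),
        truth=truth,
        config=None,
    )
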