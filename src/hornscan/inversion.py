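"""Inversion detection from modal allele-frequency tracts.

Loci inside a segregating inversion cannot recombine with the other
orientation, so in a population where k of T sampled chromosomes carry the
inverted haplotype, SNPs fixed on that haplotype all sit at the same lattice
frequency k/T.  A long run of SNPs sharing one non-trivial lattice frequency
is therefore the frequency-domain signature of the inversion; per-sample
genotypes then follow from the fraction of tract-defining derived alleles a
sample carries.  Z-linked inversions respect hemizygosity: a female
contributes a single Z chromosome, and her genotype is carrier/non-carrier
rather than a diploid class.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import VariantTable
from .polarize import PolarizationDecision, derived_dosage

HOM_INVERTED = "hom_inverted"
HET = "het"
HOM_ANCESTRAL = "hom_ancestral"
CARRIER = "carrier"
NON_CARRIER = "non_carrier"
UNKNOWN = "unknown"

#: carried-derived-allele fraction cutpoints for diploid genotype classes
HET_LOWER, HET_UPPER = 0.25, 0.75


def breakpoint_span(start: int, end: int) -> int:
    """Interval length as end - start on printed 1-based breakpoints.

    This matches the convention used when reporting structural-variant
    breakpoints from read-pair callers (e.g. 13,233,866 - 5,414,046 =
    7,819,820 bp, i.e. ~7.82 Mb).
    """
    if end < start:
        raise ValueError("end must be >= start")
    return end - start


@dataclasses.dataclass(frozen=True)
class FrequencyTract:
    """A run of SNPs sharing one modal lattice allele frequency."""

    scaffold: str
    start: int  # 0-based half-open
    end: int
    modal_count: int  # k derived copies ...
    total_chromosomes: int  # ... of T sampled chromosomes
    n_modal: int
    n_snps: int
    population: str
    modal_positions: tuple[int, ...]  # 1-based positions of modal SNPs

    @property
    def modal_frequency(self) -> float:
        return self.modal_count / self.total_chromosomes

    @property
    def modal_fraction(self) -> Fraction:
        return Fraction(self.modal_count, self.total_chromosomes)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True)
class InversionCall:
    """Per-sample inversion genotypes and the implied carrier frequency."""

    tract: FrequencyTract
    genotypes: dict[str, str]
    carrier_chromosomes: int
    total_chromosomes: int

    @property
    def frequency(self) -> float:
        return self.carrier_chromosomes / self.total_chromosomes

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.carrier_chromosomes, self.total_chromosomes)


@dataclasses.dataclass(frozen=True)
class PopulationSites:
    """Polarized per-sample derived dosages for one population + scaffold."""

    scaffold: str
    population: str
    pos: np.ndarray  # 1-based, sorted
    dosage: np.ndarray  # (n_sites, n_samples), NaN missing
    ploidy: np.ndarray  # (n_samples,)
    samples: tuple[str, ...]

    def derived_counts(self) -> tuple[np.ndarray, np.ndarray]:
        called = ~np.isnan(self.dosage)
        derived = np.where(called, self.dosage, 0.0).sum(axis=1)
        total = (called * self.ploidy[None, :]).sum(axis=1)
        return derived.astype(np.int64), total.astype(np.int64)


def population_sites(
    table: VariantTable,
    decisions: Sequence[PolarizationDecision],
    population: str,
    scaffold: str,
) -> PopulationSites:
    """Extract polarized dosages for one population on one scaffold."""
    keep, dosage = derived_dosage(table, decisions)
    on_scaffold = (table.sites["scaffold"] == scaffold).to_numpy()
    mask = keep & on_scaffold
    idx = table.sample_indices(population)
    pos = table.sites["pos"].to_numpy()[mask]
    order = np.argsort(pos, kind="stable")
    return PopulationSites(
        scaffold=scaffold,
        population=population,
        pos=pos[order],
        dosage=dosage[np.ix_(np.flatnonzero(mask), idx)][order],
        ploidy=table.ploidy(scaffold)[idx],
        samples=tuple(table.samples[j] for j in idx),
    )


def detect_tracts(
    sites: PopulationSites,
    min_span: int = 100_000,
    min_modal_fraction: float = 0.6,
    min_modal_snps: int = 10,
    max_gap_snps: int = 10,
) -> list[FrequencyTract]:
    """Find maximal runs dominated by one non-trivial lattice frequency.

    Sites must be complete-case within the population (the lattice is only
    defined for a fixed chromosome total T); sites with missing genotypes
    are dropped before scanning.  Runs at frequency 0 or 1 are ignored.  A
    run is a chain of SNPs at one lattice value in which consecutive modal
    SNPs are separated by at most ``max_gap_snps`` off-modal SNPs (keeping
    the run ends anchored at modal SNPs and stopping the chain where the
    modal value becomes rare); it qualifies as a tract when at least
    ``min_modal_fraction`` of its SNPs sit at the modal value, it contains
    ``min_modal_snps`` of them, and it spans at least ``min_span`` bp.
    """
    derived, total = sites.derived_counts()
    t_full = int((sites.ploidy).sum())
    if t_full < 4:
        raise ValueError(
            f"only {t_full} sampled chromosomes in {sites.population}; the "
            "frequency lattice is too coarse to be informative"
        )
    complete = total == t_full
    pos = sites.pos[complete]
    k = derived[complete]
    tracts: list[FrequencyTract] = []
    values, counts = np.unique(k, return_counts=True)
    for v, c in zip(values, counts):
        if v <= 0 or v >= t_full or c < min_modal_snps:
            continue
        tracts.extend(
            _scan_value(
                sites.scaffold, sites.population, pos, k, int(v), t_full,
                min_span, min_modal_fraction, min_modal_snps, max_gap_snps,
            )
        )
    tracts.sort(key=lambda t: (t.start, -t.n_modal))
    return tracts


def _scan_value(
    scaffold: str,
    population: str,
    pos: np.ndarray,
    k: np.ndarray,
    value: int,
    t_full: int,
    min_span: int,
    min_fraction: float,
    min_snps: int,
    max_gap: int,
) -> list[FrequencyTract]:
    """Gap-bounded chains of sites at one lattice value."""
    modal_idx = np.flatnonzero(k == value)
    segments: list[tuple[int, int, int]] = []  # (start_idx, end_idx, n_modal)
    seg_start = modal_idx[0]
    seg_end = modal_idx[0]
    n_modal = 1
    for j in modal_idx[1:]:
        if j - seg_end - 1 <= max_gap:
            seg_end, n_modal = j, n_modal + 1
        else:
            segments.append((seg_start, seg_end, n_modal))
            seg_start = seg_end = j
            n_modal = 1
    segments.append((seg_start, seg_end, n_modal))
    segments = [
        _trim_segment(s, e, k, value, min_fraction) for s, e, _ in segments
    ]
    segments = [
        (s, e, m) for s, e, m in segments if m / (e - s + 1) >= min_fraction
    ]
    out = []
    for s, e, m in segments:
        span = int(pos[e] - pos[s])
        if span >= min_span and m >= min_snps:
            modal_pos = pos[s : e + 1][k[s : e + 1] == value]
            out.append(
                FrequencyTract(
                    scaffold=scaffold,
                    start=int(pos[s]) - 1,
                    end=int(pos[e]),
                    modal_count=value,
                    total_chromosomes=t_full,
                    n_modal=m,
                    n_snps=int(e - s + 1),
                    population=population,
                    modal_positions=tuple(int(p) for p in modal_pos),
                )
            )
    return out


#: site-count window used when trimming low-density chain tails
_EDGE_WINDOW = 25


def _trim_segment(
    s: int, e: int, k: np.ndarray, value: int, min_fraction: float
) -> tuple[int, int, int]:
    """Retract segment ends while their local modal density is low.

    Chains can pick up sporadic off-tract SNPs that happen to sit at the
    modal value; trimming anchors the bounds where the modal value is
    actually dense.
    """
    modal = np.flatnonzero(k[s : e + 1] == value) + s
    lo, hi = 0, len(modal) - 1
    while hi > lo:
        end = modal[hi]
        win = min(_EDGE_WINDOW, end - s + 1)
        density = np.mean(k[end - win + 1 : end + 1] == value)
        if density >= min_fraction:
            break
        hi -= 1
    while lo < hi:
        start = modal[lo]
        win = min(_EDGE_WINDOW, modal[hi] - start + 1)
        density = np.mean(k[start : start + win] == value)
        if density >= min_fraction:
            break
        lo += 1
    return int(modal[lo]), int(modal[hi]), int(hi - lo + 1)


def genotype_samples(
    tract: FrequencyTract,
    sites: PopulationSites,
    max_missing: float = 0.5,
) -> InversionCall:
    """Genotype every sample for the inverted haplotype.

    A sample's carried-allele fraction over the tract's modal SNPs maps to
    diploid classes at 0.25/0.75, or carrier/non-carrier at 0.5 for
    hemizygous samples.  Samples missing more than ``max_missing`` of the
    tract SNPs are labelled unknown and excluded from the frequency.
    """
    sel = np.isin(sites.pos, np.asarray(tract.modal_positions))
    if not sel.any():
        raise ValueError("tract SNP set is empty for these sites")
    dos = sites.dosage[sel]
    genotypes: dict[str, str] = {}
    carriers = 0
    total = 0
    for j, sample in enumerate(sites.samples):
        column = dos[:, j]
        called = ~np.isnan(column)
        if called.mean() < 1.0 - max_missing:
            genotypes[sample] = UNKNOWN
            continue
        ploidy = int(sites.ploidy[j])
        frac = float(column[called].mean()) / ploidy
        if ploidy == 1:
            label = CARRIER if frac >= 0.5 else NON_CARRIER
            carried = 1 if label == CARRIER else 0
        elif frac > HET_UPPER:
            label, carried = HOM_INVERTED, 2
        elif frac >= HET_LOWER:
            label, carried = HET, 1
        else:
            label, carried = HOM_ANCESTRAL, 0
        genotypes[sample] = label
        carriers += carried
        total += ploidy
    if total == 0:
        raise ValueError("no sample could be genotyped for the tract")
    return InversionCall(tract, genotypes, carriers, total)


_DIPLOID_CLASS = {0: HOM_ANCESTRAL, 1: HET, 2: HOM_INVERTED}
_HAPLOID_CLASS = {0: NON_CARRIER, 1: CARRIER}


def dosage_to_class(dosage: int, ploidy: int) -> str:
    table = _HAPLOID_CLASS if ploidy == 1 else _DIPLOID_CLASS
    try:
        return table[int(dosage)]
    except KeyError:
        raise ValueError(f"dosage {dosage} invalid for ploidy {ploidy}") from None


def concordance(
    call: InversionCall,
    variant_classes: Mapping[str, str],
) -> float:
    """Fraction of samples whose variant genotype matches the inversion's.

    ``variant_classes`` maps sample name to a genotype class (use
    :func:`dosage_to_class` to convert dosages).  1.0 means perfect
    co-segregation of the variant with the inverted haplotype.
    """
    shared = [
        s
        for s, g in call.genotypes.items()
        if g != UNKNOWN and s in variant_classes
    ]
    if not shared:
        raise ValueError("no samples shared between inversion call and variant")
    matches = sum(call.genotypes[s] == variant_classes[s] for s in shared)
    return matches / len(shared)


def tract_ld_profile(
    sites: PopulationSites,
    window: int = 50,
) -> pd.DataFrame:
    """Mean pairwise genotype r^2 in nonoverlapping windows.

    r^2 is the squared Pearson correlation of derived-allele dosages across
    samples; monomorphic SNPs and pairs with undefined variance are skipped,
    and windows without at least one usable SNP pair report NaN.
    """
    pos0 = sites.pos - 1
    length = int(pos0.max()) + 1 if len(pos0) else 0
    rows = []
    for start in range(0, length, window):
        end = start + window
        sel = (pos0 >= start) & (pos0 < end)
        r2s: list[float] = []
        if sel.sum() >= 2:
            dos = sites.dosage[sel]
            for a in range(dos.shape[0]):
                for b in range(a + 1, dos.shape[0]):
                    r2 = _pair_r2(dos[a], dos[b])
                    if r2 is not None:
                        r2s.append(r2)
        rows.append(
            (
                sites.scaffold,
                start,
                end,
                len(r2s),
                float(np.mean(r2s)) if r2s else float("nan"),
            )
        )
    return pd.DataFrame(
        rows, columns=["scaffold", "start", "end", "n_pairs", "mean_r2"]
    )


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return None
    xv, yv = x[ok], y[ok]
    if xv.std() == 0 or yv.std() == 0:
        return None
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def mean_r2_in_interval(
    profile: pd.DataFrame, start: int, end: int, inside: bool = True
) -> float:
    """Average windowed r^2 inside (or outside) a genomic interval."""
    mid = (profile["start"] + profile["end"]) / 2
    mask = (mid >= start) & (mid < end)
    if not inside:
        mask = ~mask
    vals = profile.loc[mask, "mean_r2"].dropna()
    if vals.empty:
        return float("nan")
    return float(vals.mean())
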