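"""Core in-memory containers shared by every analysis stage.

The substrate of the whole pipeline is a :class:`VariantTable`: per-site,
per-sample allele calls together with the sample metadata (population, sex)
and scaffold metadata (length, chromosome label, Z-linkage) needed to resolve
ploidy.  In Lepidoptera males are ZZ and females ZW, so female samples are
hemizygous (single-copy) on Z-linked scaffolds; the genotype array encodes
that with a dedicated sentinel in the second allele slot.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: allele slot is missing (uncalled genotype)
MISSING = -1
#: allele slot does not exist (hemizygous sample on a Z scaffold)
NO_ALLELE = -2

SITE_COLUMNS = ["scaffold", "pos", "ref", "alt"]


@dataclasses.dataclass(frozen=True)
class Scaffold:
    """A reference scaffold with its chromosome assignment."""

    name: str
    length: int
    chromosome: str = ""
    is_z: bool = False


def scaffold_frame(scaffolds: Iterable[Scaffold]) -> pd.DataFrame:
    """Tabulate scaffolds into the DataFrame layout used by VariantTable."""
    rows = [(s.name, s.length, s.chromosome, s.is_z) for s in scaffolds]
    df = pd.DataFrame(rows, columns=["name", "length", "chromosome", "is_z"])
    return df.set_index("name")


class VariantTable:
    """Per-site, per-sample allele calls with population and ploidy labels.

    Parameters
    ----------
    sites:
        DataFrame with columns ``scaffold, pos, ref, alt``; ``pos`` is 1-based
        (VCF convention) and each record is biallelic.
    gt:
        int8 array of shape ``(n_sites, n_samples, 2)``; values are 0 (ref
        allele), 1 (alt allele), ``MISSING`` or ``NO_ALLELE``.
    samples:
        sample names, column order of ``gt``.
    meta:
        DataFrame indexed by sample with columns ``population`` and ``sex``
        ('M'/'F').
    scaffolds:
        DataFrame indexed by scaffold name with columns ``length``,
        ``chromosome`` and ``is_z`` (see :func:`scaffold_frame`).
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        gt: np.ndarray,
        samples: Sequence[str],
        meta: pd.DataFrame,
        scaffolds: pd.DataFrame,
    ) -> None:
        sites = sites.reset_index(drop=True)
        if list(sites.columns[:4]) != SITE_COLUMNS:
            raise ValueError(f"sites must start with columns {SITE_COLUMNS}")
        gt = np.asarray(gt, dtype=np.int8)
        if gt.shape != (len(sites), len(samples), 2):
            raise ValueError(
                f"gt shape {gt.shape} does not match "
                f"({len(sites)}, {len(samples)}, 2)"
            )
        missing_meta = set(samples) - set(meta.index)
        if missing_meta:
            raise ValueError(f"samples absent from metadata: {sorted(missing_meta)}")
        unknown = set(sites["scaffold"]) - set(scaffolds.index)
        if unknown:
            raise ValueError(f"sites on unknown scaffolds: {sorted(unknown)}")
        self.sites = sites
        self.gt = gt
        self.samples = list(samples)
        self.meta = meta.loc[self.samples]
        self.scaffolds = scaffolds

    # ------------------------------------------------------------------ basic
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.meta["population"]:
            seen.setdefault(p, None)
        return list(seen)

    def sample_indices(self, population: str | None = None) -> np.ndarray:
        if population is None:
            return np.arange(self.n_samples)
        mask = (self.meta["population"] == population).to_numpy()
        if not mask.any():
            raise KeyError(f"no samples in population {population!r}")
        return np.flatnonzero(mask)

    def ploidy(self, scaffold: str) -> np.ndarray:
        """Chromosome copies carried by each sample on ``scaffold``."""
        is_z = bool(self.scaffolds.loc[scaffold, "is_z"])
        sex = self.meta["sex"].to_numpy()
        if is_z:
            return np.where(sex == "F", 1, 2).astype(np.int64)
        return np.full(self.n_samples, 2, dtype=np.int64)

    def site_ploidy(self) -> np.ndarray:
        """Per-site, per-sample ploidy matrix (1 for hemizygous slots)."""
        out = np.full((self.n_sites, self.n_samples), 2, dtype=np.int64)
        is_z = self.sites["scaffold"].map(self.scaffolds["is_z"]).to_numpy(bool)
        female = (self.meta["sex"] == "F").to_numpy()
        out[np.ix_(is_z, female)] = 1
        return out

    # ------------------------------------------------------------- genotypes
    def called_mask(self) -> np.ndarray:
        """True where the sample's genotype is fully called at the site."""
        return ~(self.gt == MISSING).any(axis=2)

    def alt_dosage(self) -> np.ndarray:
        """Alt-allele count per genotype; NaN where missing.

        Hemizygous genotypes range over {0, 1}, diploid over {0, 1, 2}.
        """
        dos = (self.gt == 1).sum(axis=2).astype(float)
        dos[~self.called_mask()] = np.nan
        return dos

    def allele_counts(self, population: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site ``(alt_count, called_chromosomes)`` within a population."""
        idx = self.sample_indices(population)
        sub = self.gt[:, idx, :]
        called = ~(sub == MISSING).any(axis=2)
        alt = np.where(called[:, :, None], sub == 1, False).sum(axis=(1, 2))
        chroms = (np.where(called[:, :, None], sub >= 0, False)).sum(axis=(1, 2))
        return alt.astype(np.int64), chroms.astype(np.int64)

    # --------------------------------------------------------------- subsets
    def subset_sites(self, mask: np.ndarray) -> "VariantTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return VariantTable(
            self.sites.iloc[idx], self.gt[idx], self.samples, self.meta, self.scaffolds
        )

    def subset_scaffolds(self, names: Iterable[str]) -> "VariantTable":
        names = set(names)
        mask = self.sites["scaffold"].isin(names).to_numpy()
        return self.subset_sites(mask)

    def exclude_scaffolds(self, names: Iterable[str]) -> "VariantTable":
        names = set(names)
        mask = ~self.sites["scaffold"].isin(names).to_numpy()
        return self.subset_sites(mask)

    def z_scaffolds(self) -> list[str]:
        return list(self.scaffolds.index[self.scaffolds["is_z"]])

    # -------------------------------------------------------------- equality
    def equals(self, other: "VariantTable") -> bool:
        return (
            self.samples == other.samples
            and self.sites.equals(other.sites)
            and np.array_equal(self.gt, other.gt)
            and self.meta.equals(other.meta)
            and self.scaffolds.equals(other.scaffolds)
        )


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene as an ordered set of CDS segments.

    ``exons`` are CDS segments in genomic order as 0-based half-open
    ``(start, end)`` intervals; for minus-strand genes translation runs from
    the last segment's end backwards.
    """

    gene_id: str
    scaffold: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"empty CDS segment ({start}, {end})")

    @property
    def cds_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def genomic_positions(self) -> np.ndarray:
        """0-based genomic positions in translation (5'→3' mRNA) order."""
        parts = [np.arange(start, end) for start, end in self.exons]
        pos = np.concatenate(parts)
        if self.strand == "-":
            pos = pos[::-1]
        return pos

    def cds_sequence(self, reference: Mapping[str, str]) -> str:
        seq = "".join(
            reference[self.scaffold][start:end] for start, end in self.exons
        )
        if self.strand == "-":
            seq = revcomp(seq)
        return seq.upper()

    def contains(self, pos0: int) -> bool:
        return any(start <= pos0 < end for start, end in self.exons)


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
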