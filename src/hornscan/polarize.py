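"""Ancestral-allele polarization by outgroup parsimony.

For each focal polymorphic site the outgroup (a congener aligned to the same
reference) either shows the reference allele, shares the focal alternate
allele, shares exactly one allele while heterozygous, or conflicts outright.
Those four cases map to four deterministic verdicts:

1. outgroup not variant at the site        -> reference allele ancestral
2. outgroup alternate equals focal alt     -> alternate allele ancestral
3. heterozygous outgroup shares one allele -> that shared allele ancestral
4. no shared resolution                    -> site masked (ancestral = N)

Masked sites are written as ``N`` into the derived "ancestral" reference and
excluded from every downstream derived-allele-frequency statistic, because an
unpolarized frequency folds onto [0, 0.5] and loses information.

Indels are not polarized: the analysis is SNP-based, so indel records pass
through with the reference kept as-is.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import VariantTable
from .io import OutgroupCall

REFERENCE_ANCESTRAL = "reference_ancestral"
ALTERNATE_ANCESTRAL = "alternate_ancestral"
SHARED_ANCESTRAL = "shared_allele_ancestral"
MASKED = "masked"

VERDICTS = (REFERENCE_ANCESTRAL, ALTERNATE_ANCESTRAL, SHARED_ANCESTRAL, MASKED)


@dataclasses.dataclass(frozen=True)
class PolarizationDecision:
    """Per-site ancestral-allele verdict with rule provenance."""

    scaffold: str
    pos: int  # 1-based, VCF convention
    ref: str
    alts: tuple[str, ...]
    outgroup_alleles: frozenset[str] | None
    verdict: str
    ancestral: str  # base, or "N" when masked
    rule: str

    def __post_init__(self) -> None:
        if (self.verdict == MASKED) != (self.ancestral == "N"):
            raise ValueError("verdict 'masked' iff ancestral allele is N")
        if self.ancestral not in {self.ref, *self.alts, "N"}:
            raise ValueError(
                f"ancestral allele {self.ancestral!r} outside focal allele set"
            )


def _classify_biallelic(
    ref: str, alt: str, observed: frozenset[str] | None
) -> tuple[str, str, str]:
    """(verdict, ancestral, rule) for one focal ref/alt pair."""
    if observed is None or observed <= {ref}:
        return REFERENCE_ANCESTRAL, ref, "rule1_outgroup_invariant"
    if observed == {alt}:
        # homozygous shared alternate; folded into rule 2
        return ALTERNATE_ANCESTRAL, alt, "rule2_shared_alt"
    shared = observed & {ref, alt}
    if len(shared) == 1:
        allele = next(iter(shared))
        return SHARED_ANCESTRAL, allele, "rule3_het_shared_one"
    # either the outgroup carries both focal alleles (no parsimony winner)
    # or it carries none of them
    return MASKED, "N", "rule4_no_parsimony"


def classify_site(
    scaffold: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    outgroup: OutgroupCall | None,
) -> PolarizationDecision:
    """Classify one focal polymorphic site against the outgroup call.

    Multi-allelic focal records are decomposed into per-alt comparisons; if
    the alts disagree on the inferred ancestral allele the site is masked
    (conservative extension of rule 4).  Indel alleles are not polarized and
    pass through with the reference kept ancestral.
    """
    if outgroup is not None and outgroup.ref != ref:
        raise ValueError(
            f"outgroup reference allele {outgroup.ref!r} does not match focal "
            f"reference {ref!r} at {scaffold}:{pos}"
        )
    alts = tuple(alts)
    observed = outgroup.observed if outgroup is not None else None
    if len(ref) != 1 or any(len(a) != 1 for a in alts):
        return PolarizationDecision(
            scaffold, pos, ref, alts, observed,
            REFERENCE_ANCESTRAL, ref, "indel_passthrough",
        )
    results = [_classify_biallelic(ref, alt, observed) for alt in alts]
    ancestors = {anc for _, anc, _ in results}
    if any(v == MASKED for v, _, _ in results) or len(ancestors) != 1:
        rule = "rule4_no_parsimony" if len(alts) == 1 else "rule4_alt_disagreement"
        return PolarizationDecision(
            scaffold, pos, ref, alts, observed, MASKED, "N", rule
        )
    verdict, ancestral, rule = results[0]
    if len(alts) > 1:
        # all alts concur; keep the shared ancestral allele
        verdict = (
            REFERENCE_ANCESTRAL if ancestral == ref else SHARED_ANCESTRAL
        )
    return PolarizationDecision(
        scaffold, pos, ref, alts, observed, verdict, ancestral, rule
    )


def polarize_table(
    table: VariantTable,
    outgroup_calls: Mapping[tuple[str, int], OutgroupCall],
) -> list[PolarizationDecision]:
    """Classify every site of a focal VariantTable."""
    decisions = []
    for row in table.sites.itertuples(index=False):
        outgroup = outgroup_calls.get((row.scaffold, row.pos))
        decisions.append(
            classify_site(row.scaffold, row.pos, row.ref, (row.alt,), outgroup)
        )
    return decisions


def decisions_frame(decisions: Iterable[PolarizationDecision]) -> pd.DataFrame:
    """Flatten decisions for TSV output."""
    rows = [
        (d.scaffold, d.pos, d.ref, ",".join(d.alts), d.verdict, d.ancestral, d.rule)
        for d in decisions
    ]
    return pd.DataFrame(
        rows,
        columns=["scaffold", "pos", "ref", "alt", "verdict", "ancestral", "rule"],
    )


def decisions_from_frame(df: pd.DataFrame) -> list[PolarizationDecision]:
    """Rebuild decisions from the TSV layout of :func:`decisions_frame`."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PolarizationDecision(
                scaffold=row.scaffold,
                pos=int(row.pos),
                ref=row.ref,
                alts=tuple(str(row.alt).split(",")),
                outgroup_alleles=None,
                verdict=row.verdict,
                ancestral=row.ancestral,
                rule=row.rule,
            )
        )
    return out


def build_ancestral_reference(
    reference: Mapping[str, str],
    decisions: Iterable[PolarizationDecision],
) -> tuple[dict[str, str], dict[str, int]]:
    """Substitute inferred ancestral bases into the reference.

    Positions with an alternate/shared ancestral verdict get the ancestral
    base, masked positions become ``N``; everything else is untouched.
    Returns the new sequence set and counts ``{unchanged, updated, masked}``
    (summing to the number of decisions).
    """
    seqs = {name: bytearray(seq, "ascii") for name, seq in reference.items()}
    counts = {"unchanged": 0, "updated": 0, "masked": 0}
    for d in decisions:
        if d.scaffold not in seqs:
            raise KeyError(f"decision on unknown scaffold {d.scaffold!r}")
        if not (1 <= d.pos <= len(seqs[d.scaffold])):
            raise IndexError(
                f"decision position {d.scaffold}:{d.pos} outside reference"
            )
        if d.verdict == MASKED:
            seqs[d.scaffold][d.pos - 1] = ord("N")
            counts["masked"] += 1
        elif d.verdict in (ALTERNATE_ANCESTRAL, SHARED_ANCESTRAL) and d.ancestral != d.ref:
            seqs[d.scaffold][d.pos - 1] = ord(d.ancestral)
            counts["updated"] += 1
        else:
            counts["unchanged"] += 1
    return {name: seq.decode("ascii") for name, seq in seqs.items()}, counts


def polarized_frequency(
    alt_count: int, called_chromosomes: int, decision: PolarizationDecision
) -> float | None:
    """Derived (non-ancestral) allele frequency; None for masked sites."""
    if decision.verdict == MASKED:
        return None
    if called_chromosomes == 0:
        raise ValueError(
            f"no called chromosomes at {decision.scaffold}:{decision.pos}"
        )
    p_alt = alt_count / called_chromosomes
    return p_alt if decision.ancestral == decision.ref else 1.0 - p_alt


def derived_dosage(
    table: VariantTable, decisions: Sequence[PolarizationDecision]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-genotype derived-allele dosage under the polarization decisions.

    Returns ``(keep, dosage)`` where ``keep`` is a per-site boolean mask
    (False for masked sites) and ``dosage`` is a float (n_sites, n_samples)
    matrix of derived-allele copies with NaN for missing genotypes.  Sites
    without a matching decision are treated as reference-ancestral, which is
    exactly rule 1 (no outgroup record means no evidence against the
    reference).
    """
    if len(decisions) == table.n_sites:
        aligned = decisions
    else:
        by_site = {(d.scaffold, d.pos): d for d in decisions}
        aligned = [
            by_site.get((row.scaffold, row.pos))
            for row in table.sites.itertuples(index=False)
        ]
    keep = np.ones(table.n_sites, dtype=bool)
    flip = np.zeros(table.n_sites, dtype=bool)
    for i, d in enumerate(aligned):
        if d is None:
            continue
        if d.verdict == MASKED:
            keep[i] = False
        elif d.ancestral != d.ref:
            flip[i] = True
    dosage = table.alt_dosage()
    ploidy = table.site_ploidy().astype(float)
    dosage[flip] = ploidy[flip] - dosage[flip]
    return keep, dosage


def derived_counts(
    table: VariantTable,
    decisions: Sequence[PolarizationDecision],
    population: str | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site derived-allele count and called-chromosome total.

    Returns ``(keep, derived, total)`` with masked sites flagged out of
    ``keep``; counts are integers on the frequency lattice {0..total}.
    """
    keep, dosage = derived_dosage(table, decisions)
    idx = table.sample_indices(population)
    dos = dosage[:, idx]
    ploidy = table.site_ploidy()[:, idx]
    called = ~np.isnan(dos)
    derived = np.where(called, dos, 0.0).sum(axis=1).astype(np.int64)
    total = np.where(called, ploidy, 0).sum(axis=1).astype(np.int64)
    return keep, derived, total
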