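"""Pairwise F_ST: per-site Hudson components, sliding windows, outliers, PCA.

The estimator is the Hudson form with the Bhatia et al. finite-sample
correction, computed from called genotypes:

    numerator   = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    denominator = p1(1-p2) + p2(1-p1)

Aggregates (windows, genome-wide values) are ratios of sums: per-site
numerators and denominators are summed first and divided once, which is
robust where averaging per-site ratios is not.  Small negative window values
arise from the unbiasedness correction and are expected.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import VariantTable
from .polarize import PolarizationDecision, derived_counts

#: windows with fewer SNPs than this report a missing value
MIN_SNPS_PER_WINDOW = 5


def site_fst(
    p1: float | np.ndarray,
    n1: int | np.ndarray,
    p2: float | np.ndarray,
    n2: int | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Hudson/Bhatia per-site F_ST components (numerator, denominator).

    Requires at least 2 sampled chromosomes per population.  Values are only
    meaningful inside ratio-of-sums aggregates.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 <= 1) or np.any(n2 <= 1):
        raise ValueError("site_fst requires >= 2 chromosomes per population")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def pair_site_components(
    table: VariantTable,
    pop1: str,
    pop2: str,
    decisions: Sequence[PolarizationDecision] | None = None,
    min_chromosomes: int = 2,
) -> pd.DataFrame:
    """Per-site F_ST components for one population pair.

    Polarization does not change the components (they are symmetric in
    allele labelling) but, when decisions are given, masked sites are
    excluded.  Sites with fewer than ``min_chromosomes`` called chromosomes
    in either population are dropped with a warning.
    """
    if decisions is not None:
        keep, d1, t1 = derived_counts(table, decisions, pop1)
        _, d2, t2 = derived_counts(table, decisions, pop2)
    else:
        d1, t1 = table.allele_counts(pop1)
        d2, t2 = table.allele_counts(pop2)
        keep = np.ones(table.n_sites, dtype=bool)
    enough = (t1 >= min_chromosomes) & (t2 >= min_chromosomes)
    n_thin = int((keep & ~enough).sum())
    if n_thin:
        warnings.warn(
            f"excluding {n_thin} sites with < {min_chromosomes} called "
            "chromosomes in a population"
        )
    keep = keep & enough
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(keep, d1 / np.maximum(t1, 1), 0.0)
        p2 = np.where(keep, d2 / np.maximum(t2, 1), 0.0)
    num = np.zeros(table.n_sites)
    den = np.zeros(table.n_sites)
    if keep.any():
        num[keep], den[keep] = site_fst(p1[keep], t1[keep], p2[keep], t2[keep])
    out = table.sites[["scaffold", "pos"]].copy()
    out["p1"], out["n1"] = p1, t1
    out["p2"], out["n2"] = p2, t2
    out["num"], out["den"] = num, den
    return out[keep].reset_index(drop=True)


@dataclasses.dataclass(frozen=True)
class WindowStat:
    """F_ST of one genomic window (0-based half-open interval)."""

    scaffold: str
    start: int
    end: int
    n_snps: int
    fst: float  # NaN when below the SNP floor
    comparison: str = ""
    partial: bool = False


def windowed_fst(
    sites: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    window: int = 10_000,
    step: int = 5_000,
    comparison: str = "",
    min_snps: int = MIN_SNPS_PER_WINDOW,
) -> list[WindowStat]:
    """Sliding-window ratio-of-sums F_ST.

    ``sites`` is the output of :func:`pair_site_components`, sorted by
    (scaffold, pos).  Windows are anchored at position 0 of each scaffold;
    terminal partial windows are retained and flagged.
    """
    if step > window:
        warnings.warn("step larger than window leaves uncovered gaps")
    out: list[WindowStat] = []
    for scaffold, length in scaffold_lengths.items():
        sub = sites[sites["scaffold"] == scaffold]
        pos0 = sub["pos"].to_numpy() - 1
        if len(pos0) and np.any(np.diff(pos0) < 0):
            raise ValueError(f"sites on {scaffold} are not position-sorted")
        num = sub["num"].to_numpy()
        den = sub["den"].to_numpy()
        cnum = np.concatenate([[0.0], np.cumsum(num)])
        cden = np.concatenate([[0.0], np.cumsum(den)])
        start = 0
        while start < length:
            end = min(start + window, length)
            lo = np.searchsorted(pos0, start, side="left")
            hi = np.searchsorted(pos0, end, side="left")
            n_snps = hi - lo
            s_den = cden[hi] - cden[lo]
            if n_snps >= min_snps and s_den > 0:
                value = (cnum[hi] - cnum[lo]) / s_den
            else:
                value = float("nan")
            out.append(
                WindowStat(
                    scaffold, start, end, int(n_snps), value,
                    comparison, partial=(end - start) < window,
                )
            )
            start += step
    return out


def windows_frame(windows: Iterable[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(w) for w in windows])


@dataclasses.dataclass(frozen=True)
class OutlierRegion:
    """Maximal merge of overlapping/adjacent super-threshold windows."""

    scaffold: str
    start: int
    end: int
    peak_fst: float
    n_windows: int
    comparison: str = ""


def merge_outliers(
    windows: Sequence[WindowStat], threshold: float = 0.5, max_gap: int = 0
) -> list[OutlierRegion]:
    """Merge windows with F_ST above ``threshold`` into candidate regions.

    Overlapping or adjacent super-threshold windows merge; ``max_gap`` > 0
    additionally bridges short sub-threshold interruptions (e.g. one
    SNP-poor window) up to that many bp.
    """
    hot = sorted(
        (w for w in windows if np.isfinite(w.fst) and w.fst > threshold),
        key=lambda w: (w.scaffold, w.start),
    )
    regions: list[OutlierRegion] = []
    cur: list[WindowStat] = []
    for w in hot:
        if cur and w.scaffold == cur[-1].scaffold and w.start <= max(
            c.end for c in cur
        ) + max_gap:
            cur.append(w)
        else:
            if cur:
                regions.append(_close_region(cur))
            cur = [w]
    if cur:
        regions.append(_close_region(cur))
    return regions


def _close_region(members: list[WindowStat]) -> OutlierRegion:
    return OutlierRegion(
        scaffold=members[0].scaffold,
        start=members[0].start,
        end=max(w.end for w in members),
        peak_fst=max(w.fst for w in members),
        n_windows=len(members),
        comparison=members[0].comparison,
    )


def genome_wide_fst(
    sites: pd.DataFrame,
    exclude_scaffolds: Iterable[str] = (),
    site_mask: np.ndarray | None = None,
) -> float:
    """Ratio-of-sums F_ST over all retained sites.

    ``exclude_scaffolds`` drops whole scaffolds (Z excluded by convention for
    genome-wide values); ``site_mask`` optionally restricts to a site class
    (e.g. a degeneracy selection aligned with ``sites``).
    """
    keep = ~sites["scaffold"].isin(set(exclude_scaffolds)).to_numpy()
    if site_mask is not None:
        keep &= np.asarray(site_mask, dtype=bool)
    if not keep.any():
        raise ValueError("no sites retained for genome-wide F_ST")
    den = sites["den"].to_numpy()[keep].sum()
    if den == 0:
        raise ValueError("zero total denominator; no informative sites")
    return float(sites["num"].to_numpy()[keep].sum() / den)


def genotype_pca(
    dosage: np.ndarray,
    n_components: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of a samples x sites genotype-dosage matrix.

    Columns are mean-centred (missing values imputed with the column mean)
    and decomposed by SVD.  Component signs are fixed by forcing the
    largest-magnitude loading of each component positive, so coordinates are
    deterministic.  Returns ``(coordinates, explained_variance, loadings)``.
    """
    X = np.array(dosage, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 sites for PCA")
    col_mean = np.nanmean(X, axis=0)
    nan_at = np.isnan(X)
    X[nan_at] = np.take(col_mean, np.where(nan_at)[1])
    X = X - X.mean(axis=0)
    if not np.any(X):
        raise ValueError("constant genotype matrix; PCA undefined")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    loadings = vt[:k]
    for c in range(k):
        j = np.argmax(np.abs(loadings[c]))
        if loadings[c, j] < 0:
            loadings[c] *= -1
            coords[:, c] *= -1
    explained = s[:k] ** 2 / (X.shape[0] - 1)
    return coords, explained, loadings
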