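"""Windowed nucleotide diversity and Tajima's D from genotype matrices.

Genes are tiled into fixed-size non-overlapping windows from their
genomic start; a partial tail window is never emitted, so every window
statistic is computed over exactly ``window_size`` bases. Per-site
diversity is the unbiased mean pairwise difference 2j(m-j)/(m(m-1))
for derived-allele count j among m called haplotypes; the window
denominator is the full window length, treating unreported positions
as monomorphic (the convention of windowed VCF diversity scans).

Tajima's D follows the 1989 definitions: with a1 = sum_{i<n} 1/i,

    D = (pi_sum - S/a1) / sqrt(e1*S + e2*S*(S-1))

computed complete-case (sites with any missing haplotype in the breed
are dropped from both S and pi_sum). D is undefined (NaN) when S = 0
or fewer than 4 haplotypes are available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MISSING, GeneModel, GenotypeMatrix
from .errors import ValidationError
from .sex_bias import RankSumResult, rank_sum_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Window:
    """A fixed-size genomic tile anchored to the gene it was cut from."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    gene_id: str


@dataclass
class WindowStat:
    window: Window
    pi: float  # per-site nucleotide diversity
    S: int  # segregating sites
    n_hap: int  # haplotypes used


@dataclass
class TajimaComponents:
    """Tajima (1989) constants and the resulting D statistic."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    S: int
    pi_sum: float
    D: float
    flag: str = ""


def tile_gene_windows(gene: GeneModel, size: int = 10_000) -> list[Window]:
    """Tile a gene span into consecutive ``size``-bp windows from its start.

    The final partial window (the gene tail truncated by the tiling) is
    dropped, so a 25 kb gene yields exactly two 10 kb windows.
    """
    if size <= 0:
        raise ValidationError("window size must be positive")
    windows = []
    pos = gene.start
    while pos + size <= gene.end:
        windows.append(Window(gene.chrom, pos, pos + size, gene.gene_id))
        pos += size
    return windows


def per_site_pi(alt_count: int, allele_total: int) -> float:
    """Unbiased mean pairwise difference at one site: 2j(m-j)/(m(m-1))."""
    if allele_total < 2:
        raise ValidationError("need at least 2 called alleles at a site")
    j, m = alt_count, allele_total
    if not 0 <= j <= m:
        raise ValidationError("alt count outside [0, allele total]")
    return 2.0 * j * (m - j) / (m * (m - 1))


def _breed_site_counts(G: GenotypeMatrix, rows: np.ndarray, breed: str):
    """Per-site (alt count, called-allele total) for one breed's haplotypes."""
    cols = G.breed_columns(breed)
    hap = G.haplotypes[np.ix_(rows, cols)]
    called = hap != MISSING
    m = called.sum(axis=1)
    j = np.where(called, hap, 0).sum(axis=1)
    return j, m, hap


def window_pi(G: GenotypeMatrix, w: Window, breed: str) -> WindowStat:
    """Nucleotide diversity of one window for one breed.

    Sites with missing haplotypes use the reduced allele total at that
    site; sites with fewer than 2 called alleles are ignored. S counts
    sites segregating within the breed (0 < j < m).
    """
    pos = G.sites["pos"].to_numpy()
    rows = np.flatnonzero(
        (G.sites["chrom"].to_numpy() == w.chrom) & (pos - 1 >= w.start) & (pos - 1 < w.end)
    )
    n_hap = len(G.breed_columns(breed))
    if rows.size == 0:
        return WindowStat(w, 0.0, 0, n_hap)
    j, m, _ = _breed_site_counts(G, rows, breed)
    usable = m >= 2
    j, m = j[usable], m[usable]
    seg = (j > 0) & (j < m)
    pi_sum = float(np.sum(2.0 * j * (m - j) / (m * (m - 1.0))))
    return WindowStat(w, pi_sum / (w.end - w.start), int(seg.sum()), n_hap)


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima's D for n haplotypes."""
    if n < 2:
        raise ValidationError("Tajima constants need n >= 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_D(
    G: GenotypeMatrix,
    region: tuple[str, int, int] | Window,
    breed: str,
) -> TajimaComponents:
    """Tajima's D for one breed over a genomic region (0-based half-open).

    Sites with any missing haplotype in the breed are dropped from both
    S and the pairwise-diversity sum (complete-case). Returns D = NaN
    flagged ``monomorphic`` when no segregating site remains.
    """
    if isinstance(region, Window):
        chrom, start, end = region.chrom, region.start, region.end
    else:
        chrom, start, end = region
    cols = G.breed_columns(breed)
    n = len(cols)
    if n < 4:
        raise ValidationError(f"Tajima's D needs >= 4 haplotypes (breed {breed!r} has {n})")
    pos = G.sites["pos"].to_numpy()
    rows = np.flatnonzero(
        (G.sites["chrom"].to_numpy() == chrom) & (pos - 1 >= start) & (pos - 1 < end)
    )
    hap = G.haplotypes[np.ix_(rows, cols)]
    complete = ~(hap == MISSING).any(axis=1)
    j = hap[complete].sum(axis=1)
    seg = (j > 0) & (j < n)
    S = int(seg.sum())
    k = tajima_constants(n)
    pi_sum = float(np.sum(2.0 * j[seg] * (n - j[seg]) / (n * (n - 1.0))))
    if S == 0:
        D, flag = math.nan, "monomorphic"
    else:
        D = (pi_sum - S / k["a1"]) / math.sqrt(k["e1"] * S + k["e2"] * S * (S - 1))
        flag = ""
    return TajimaComponents(n=n, S=S, pi_sum=pi_sum, D=D, flag=flag, **k)


def windowed_stats(
    G: GenotypeMatrix,
    genes: list[GeneModel],
    breeds: list[str],
    window_size: int = 10_000,
    tajima: bool = True,
) -> pd.DataFrame:
    """π (and optionally D) for every full window of every gene x breed."""
    rows = []
    for gene in genes:
        for w in tile_gene_windows(gene, window_size):
            for breed in breeds:
                ws = window_pi(G, w, breed)
                rec = {
                    "chrom": w.chrom,
                    "start": w.start,
                    "end": w.end,
                    "gene_id": w.gene_id,
                    "breed": breed,
                    "pi": ws.pi,
                    "S": ws.S,
                    "n_hap": ws.n_hap,
                }
                if tajima:
                    rec["tajima_D"] = tajima_D(G, w, breed).D
                rows.append(rec)
    return pd.DataFrame(rows)


def aggregate_by_category(
    stats: pd.DataFrame, categories: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Mean window π per breed x bias category.

    ``categories`` maps gene_id to its bias class; every window must map
    to a categorised gene. Empty categories simply yield no row.
    """
    cat = pd.Series(dict(categories) if not isinstance(categories, pd.Series) else categories)
    missing = set(stats["gene_id"]) - set(cat.index)
    if missing:
        raise ValidationError(f"windows map to uncategorised genes: {sorted(missing)[:5]}")
    df = stats.assign(category=stats["gene_id"].map(cat))
    out = (
        df.groupby(["breed", "category"], as_index=False)
        .agg(mean_pi=("pi", "mean"), n_windows=("pi", "size"))
        .sort_values(["breed", "category"], ignore_index=True)
    )
    return out


def compare_diversity(groupA, groupB) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum between two sets of window π values."""
    a = np.asarray(groupA, float)
    b = np.asarray(groupB, float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both diversity groups must be non-empty")
    return rank_sum_test(a, b)
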