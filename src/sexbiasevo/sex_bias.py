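"""Sex-bias calling, cross-breed bias dynamics and bootstrap clustering.

A gene is called sex-biased in a breed x tissue when its male/female
fold change (after a pseudocount) is at least ``fc_threshold`` and the
Benjamini-Hochberg FDR of a Welch t-test on log2(FPKM + pseudocount)
is below ``fdr``. Biased genes are binned by fold change into
low [2, 4), medium [4, 10) and high [10, inf) magnitude classes.

Cross-breed dynamics compare one wild and two domesticated breeds:

* BLG (bias-lost): biased in the wild breed, unbiased in both domestics.
* BAG (bias-acquired): unbiased in the wild breed, biased in both domestics.
* BCG (bias-converted): biased in all three, with both domestics'
  direction opposite to the wild breed's.
* conserved: biased in the same direction in all three breeds.
* other: any remaining pattern, including genes missing a call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix
from .errors import ValidationError

FC_BIN_EDGES = (2.0, 4.0, 10.0)  # low / medium / high, closed on the left

BIAS_CALL_COLUMNS = ["gene_id", "breed", "tissue", "fc", "direction", "p", "q", "magnitude"]


def filter_expressed(E: ExpressionMatrix, tissue: str, min_fpkm: float = 0.5) -> ExpressionMatrix:
    """Keep genes with FPKM >= ``min_fpkm`` in at least one sample of ``tissue``.

    Filtering is per tissue, so gonad and liver retain different gene sets.
    """
    sub = E.subset(tissue=tissue)
    if sub.values.shape[1] == 0:
        raise ValidationError(f"no samples for tissue {tissue!r}")
    keep = (sub.values >= min_fpkm).any(axis=1)
    return ExpressionMatrix(sub.values.loc[keep], sub.samples)


def remove_excluded_genes(
    E: ExpressionMatrix,
    sex_chrom_genes: set[str] = frozenset(),
    immune_genes: set[str] = frozenset(),
) -> ExpressionMatrix:
    """Drop sex-chromosome and immune/MHC genes from the matrix.

    Ids absent from the matrix are ignored. The analysis is autosomal by
    construction and immune loci are removed as confounders independent
    of sexual conflict.
    """
    excluded = set(sex_chrom_genes) | set(immune_genes)
    keep = ~E.values.index.isin(excluded)
    return ExpressionMatrix(E.values.loc[keep], E.samples)


def magnitude_bin(fc: float, q: float, fc_threshold: float = 2.0, fdr: float = 0.05) -> str:
    """Magnitude class as a pure function of (fc, q). Bins closed on the left."""
    if fc < fc_threshold or q >= fdr or not np.isfinite(q):
        return "unbiased"
    low, medium, high = FC_BIN_EDGES
    if fc >= high:
        return "high"
    if fc >= medium:
        return "medium"
    return "low"


def _welch_log_p(log_m: np.ndarray, log_f: np.ndarray) -> np.ndarray:
    """Row-wise Welch t-test p-values with degenerate-variance handling."""
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-constant rows
        p = stats.ttest_ind(log_m, log_f, axis=1, equal_var=False).pvalue
    p = np.asarray(p, dtype=float)
    # zero variance in both groups: p = 1 for equal means, 0 otherwise
    degenerate = (log_m.var(axis=1) == 0) & (log_f.var(axis=1) == 0)
    equal = np.isclose(log_m.mean(axis=1), log_f.mean(axis=1))
    p[degenerate & equal] = 1.0
    p[degenerate & ~equal] = 0.0
    return p


def _mwu_log_p(log_m: np.ndarray, log_f: np.ndarray) -> np.ndarray:
    p = np.empty(log_m.shape[0])
    for i in range(log_m.shape[0]):
        if np.ptp(np.concatenate([log_m[i], log_f[i]])) == 0:
            p[i] = 1.0
        else:
            p[i] = stats.mannwhitneyu(log_m[i], log_f[i], alternative="two-sided").pvalue
    return p


def call_sex_bias(
    E: ExpressionMatrix,
    breed: str,
    tissue: str,
    fc_threshold: float = 2.0,
    fdr: float = 0.05,
    pseudocount: float = 0.5,
    test: str = "welch",
) -> pd.DataFrame:
    """Call per-gene sex bias for one breed x tissue.

    Returns a DataFrame with columns ``gene_id, breed, tissue, fc,
    direction, p, q, magnitude``. ``fc`` is the linear ratio of sex mean
    FPKM (pseudocount-adjusted), larger sex over smaller, so fc >= 1;
    ``direction`` names the larger sex for biased genes and is ``none``
    otherwise. q-values are Benjamini-Hochberg over all genes of this
    breed x tissue family.
    """
    males = E.subset(breed=breed, tissue=tissue, sex="M").values.to_numpy(float)
    females = E.subset(breed=breed, tissue=tissue, sex="F").values.to_numpy(float)
    if males.shape[1] < 2 or females.shape[1] < 2:
        raise ValidationError(
            f"{breed}/{tissue}: need >= 2 samples per sex "
            f"(got {males.shape[1]} M, {females.shape[1]} F)"
        )

    log_m = np.log2(males + pseudocount)
    log_f = np.log2(females + pseudocount)
    if test == "welch":
        p = _welch_log_p(log_m, log_f)
    elif test == "mwu":
        p = _mwu_log_p(log_m, log_f)
    else:
        raise ValidationError(f"unknown test {test!r}")
    q = multipletests(p, method="fdr_bh")[1]

    ratio = (males.mean(axis=1) + pseudocount) / (females.mean(axis=1) + pseudocount)
    fc = np.maximum(ratio, 1.0 / ratio)
    larger = np.where(ratio >= 1, "male", "female")

    magnitude = [magnitude_bin(f, qv, fc_threshold, fdr) for f, qv in zip(fc, q)]
    direction = [
        larger[i] if magnitude[i] != "unbiased" else "none" for i in range(len(fc))
    ]
    genes = E.subset(breed=breed, tissue=tissue).values.index
    return pd.DataFrame(
        {
            "gene_id": genes,
            "breed": breed,
            "tissue": tissue,
            "fc": fc,
            "direction": direction,
            "p": p,
            "q": q,
            "magnitude": magnitude,
        }
    )


def classify_dynamics(
    calls_wild: pd.DataFrame, calls_dom1: pd.DataFrame, calls_dom2: pd.DataFrame
) -> pd.DataFrame:
    """Label each gene's cross-breed bias pattern (BLG/BAG/BCG/conserved/other).

    All three call sets should cover the same gene universe; genes missing
    a call in any breed are labelled ``other``.
    """
    frames = [calls_wild, calls_dom1, calls_dom2]
    universes = [set(f["gene_id"]) for f in frames]
    common = universes[0] & universes[1] & universes[2]
    if not common:
        raise ValidationError("gene universes of the three breeds are disjoint")

    by_gene = [f.set_index("gene_id") for f in frames]
    labels = []
    for gene in sorted(universes[0] | universes[1] | universes[2]):
        if gene not in common:
            labels.append((gene, "other"))
            continue
        dir_w, dir_1, dir_2 = (bg.at[gene, "direction"] for bg in by_gene)
        biased_w, biased_1, biased_2 = (d != "none" for d in (dir_w, dir_1, dir_2))
        if biased_w and not biased_1 and not biased_2:
            label = "BLG"
        elif not biased_w and biased_1 and biased_2:
            label = "BAG"
        elif biased_w and biased_1 and biased_2:
            if dir_1 != dir_w and dir_2 != dir_w:
                label = "BCG"
            elif dir_1 == dir_w and dir_2 == dir_w:
                label = "conserved"
            else:
                label = "other"
        else:
            label = "other"
        labels.append((gene, label))
    return pd.DataFrame(labels, columns=["gene_id", "label"])


def compare_bias_magnitude(
    callsA: pd.DataFrame, callsB: pd.DataFrame, direction: str
):
    """Two-sided Mann-Whitney U on |log2 fc| of biased genes of one direction.

    Exact p-values for small tie-free samples, normal approximation with
    tie correction otherwise (scipy's automatic policy).
    """
    a = np.log2(callsA.loc[callsA["direction"] == direction, "fc"].to_numpy(float))
    b = np.log2(callsB.loc[callsB["direction"] == direction, "fc"].to_numpy(float))
    if a.size == 0 or b.size == 0:
        raise ValidationError(f"no {direction}-biased genes in one of the call sets")
    return rank_sum_test(a, b)


class RankSumResult(NamedTuple):
    statistic: float  # Mann-Whitney U of the first sample
    pvalue: float


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> RankSumResult:
    """Shared two-sided Mann-Whitney U / Wilcoxon rank-sum machinery."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if np.ptp(np.concatenate([a, b])) == 0:
        return RankSumResult(len(a) * len(b) / 2.0, 1.0)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return RankSumResult(float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# bootstrap hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Complete-linkage merge tree over samples with bootstrap support.

    ``linkage`` is a scipy linkage matrix over ``labels``; ``support[i]``
    is the fraction of gene-bootstrap replicates whose tree contains
    internal node i's exact sample set.
    """

    linkage: np.ndarray
    labels: list[str]
    support: np.ndarray
    n_boot: int

    def node_sets(self) -> list[frozenset[str]]:
        return _linkage_clusters(self.linkage, self.labels)


def _linkage_clusters(Z: np.ndarray, labels: list[str]) -> list[frozenset[str]]:
    """Sample set of every internal node of a linkage matrix, in merge order."""
    n = len(labels)
    sets: list[frozenset[str]] = [frozenset([lab]) for lab in labels]
    out = []
    for a, b in Z[:, :2].astype(int):
        merged = sets[a] | sets[b]
        sets.append(merged)
        out.append(merged)
    return out


def cluster_samples(
    E: ExpressionMatrix,
    B: int = 1000,
    seed: int | None = None,
    pseudocount: float = 0.5,
) -> Dendrogram:
    """Euclidean complete-linkage clustering of samples on log2 expression.

    Bootstrap support for each internal node is the ordinary bootstrap
    proportion: the fraction of ``B`` gene-resampled replicate trees that
    contain the node's exact sample set.
    """
    if E.values.shape[1] < 3:
        raise ValidationError("need at least 3 samples to cluster")
    X = np.log2(E.values.to_numpy(float) + pseudocount).T  # samples x genes
    labels = list(E.values.columns)
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    ref_sets = _linkage_clusters(Z, labels)

    rng = np.random.default_rng(seed)
    n_genes = X.shape[1]
    hits = np.zeros(len(ref_sets))
    for _ in range(B):
        cols = rng.integers(0, n_genes, size=n_genes)
        Zb = hierarchy.linkage(X[:, cols], method="complete", metric="euclidean")
        boot_sets = set(_linkage_clusters(Zb, labels))
        for i, s in enumerate(ref_sets):
            if s in boot_sets:
                hits[i] += 1
    return Dendrogram(linkage=Z, labels=labels, support=hits / B, n_boot=B)
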