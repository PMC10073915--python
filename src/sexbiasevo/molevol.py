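"""Per-individual coding-sequence reconstruction and NG86 dN/dS.

Each individual's CDS is deduced by substituting its VCF alleles into
the reference CDS (heterozygous sites resolved by a configurable
policy, ALT by default). Divergence against the outgroup ortholog is
then measured with the Nei-Gojobori (1986) method: expected synonymous
and nonsynonymous site counts per codon, pathway-averaged difference
counts per codon pair, proportions converted to rates with the
Jukes-Cantor correction d = -(3/4) ln(1 - (4/3) p), and omega = dN/dS.

Per gene and breed, dN, dS and omega are averaged over individuals.
Genes whose omega is an extreme outlier (outside Tukey fences with a
3 x IQR multiplier) in exactly one breed while ordinary in all others
are removed across all breeds, damping artefacts private to a single
population sample.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .core_io import MISSING, GeneModel, GenotypeMatrix
from .errors import ValidationError

logger = logging.getLogger(__name__)

_BASES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(standard_dna_table.forward_table))  # 61 codons
_AA = dict(standard_dna_table.forward_table)


def _translate(codon: str) -> str | None:
    """Amino acid of a codon, or None for a stop."""
    return _AA.get(codon)


@dataclass
class NG86Counts:
    s_sites: float
    n_sites: float
    sd: float
    nd: float


@dataclass
class DnDsRecord:
    gene_id: str
    breed: str
    dN: float
    dS: float
    omega: float  # NaN when dS == 0 or the JC correction is undefined
    n_individuals: int
    flag: str = ""


# ---------------------------------------------------------------------------
# sequence reconstruction
# ---------------------------------------------------------------------------

HET_POLICIES = ("alt", "ref", "random")


def reconstruct_sequence(
    G: GenotypeMatrix,
    gene: GeneModel,
    individual: str,
    het_policy: str = "alt",
    rng: np.random.Generator | None = None,
) -> str:
    """Deduce one individual's CDS by applying its variants to the reference.

    Substitution happens in genomic frame; minus-strand genes are then
    reverse-complemented back into coding orientation. Heterozygous
    sites take the ALT allele under the default policy (capturing the
    individual's derived variation in the single output sequence);
    ``ref`` and seeded ``random`` resolution are available.
    """
    if het_policy not in HET_POLICIES:
        raise ValidationError(f"het_policy must be one of {HET_POLICIES}")
    if het_policy == "random" and rng is None:
        rng = np.random.default_rng()

    genomic = gene.cds_seq if gene.strand == "+" else str(Seq(gene.cds_seq).reverse_complement())
    seq = list(genomic)
    idx = G.individual_index(individual)
    pos = G.sites["pos"].to_numpy()
    rows = np.flatnonzero(
        (G.sites["chrom"].to_numpy() == gene.chrom)
        & (pos - 1 >= gene.start)
        & (pos - 1 < gene.end)
    )
    for r in rows:
        site = G.sites.iloc[r]
        offset = int(site["pos"]) - 1 - gene.start
        if seq[offset] != site["ref"]:
            raise ValidationError(
                f"{gene.gene_id}: VCF REF {site['ref']} at {site['chrom']}:{site['pos']} "
                f"disagrees with reference base {seq[offset]}"
            )
        a, b = G.haplotypes[r, 2 * idx], G.haplotypes[r, 2 * idx + 1]
        if a == MISSING and b == MISSING:
            continue  # uncalled: keep reference
        alleles = {int(x) for x in (a, b) if x != MISSING}
        if alleles == {0}:
            continue
        if alleles == {1}:
            seq[offset] = site["alt"]
        else:  # heterozygous
            if het_policy == "alt" or (het_policy == "random" and rng.random() < 0.5):
                seq[offset] = site["alt"]
    out = "".join(seq)
    return out if gene.strand == "+" else str(Seq(out).reverse_complement())


# ---------------------------------------------------------------------------
# NG86 site and difference counting
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Expected synonymous/nonsynonymous site counts of a sense codon.

    Each of the nine one-step neighbours contributes 1/3 of a site;
    changes creating stop codons count as nonsynonymous. s + n == 3.
    """
    codon = codon.upper()
    aa = _translate(codon)
    if aa is None or len(codon) != 3 or set(codon) - set(_BASES):
        raise ValidationError(f"not a sense codon: {codon!r}")
    s = 0.0
    for i in range(3):
        syn = sum(
            1
            for base in _BASES
            if base != codon[i] and _translate(codon[:i] + base + codon[i + 1 :]) == aa
        )
        s += syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng86_diffs(codon1: str, codon2: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences per NG86.

    All orderings of the differing positions are enumerated; pathways
    passing through a stop codon are excluded unless every pathway is
    blocked, in which case all are used.
    """
    c1, c2 = codon1.upper(), codon2.upper()
    for c in (c1, c2):
        if _translate(c) is None:
            raise ValidationError(f"not a sense codon: {c!r}")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order):
        """(syn, nonsyn, blocked) step counts along one substitution order."""
        cur = c1
        syn = nonsyn = 0
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            aa_cur, aa_nxt = _translate(cur), _translate(nxt)
            if aa_nxt is None:
                return None  # pathway passes through a stop
            if aa_cur == aa_nxt:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        return syn, nonsyn

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    open_paths = [p for p in paths if p is not None]
    if not open_paths:
        # all orderings stop-blocked: fall back to counting through stops
        def walk_through(order):
            cur = c1
            syn = nonsyn = 0
            for i in order:
                nxt = cur[:i] + c2[i] + cur[i + 1 :]
                if _translate(cur) is not None and _translate(cur) == _translate(nxt):
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
            return syn, nonsyn

        open_paths = [walk_through(order) for order in itertools.permutations(diff_pos)]
    sd = sum(p[0] for p in open_paths) / len(open_paths)
    nd = sum(p[1] for p in open_paths) / len(open_paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 distance from a proportion of differing sites; NaN at saturation."""
    if p < 0:
        raise ValidationError("proportion must be non-negative")
    if p == 0:
        return 0.0
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def dnds_pair(seqA: str, seqB: str) -> DnDsRecord:
    """NG86 dN, dS and omega between two aligned in-frame CDS.

    Site counts are averaged between the two sequences; codons
    containing N or a stop in either sequence are excluded. omega is
    NaN (flagged) when dS is zero or a JC correction saturates.
    """
    a, b = seqA.upper(), seqB.upper()
    if len(a) != len(b):
        raise ValidationError("sequences must be equal length")
    if len(a) % 3:
        raise ValidationError("sequence length not divisible by 3")
    S_a = S_b = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if _translate(ca) is None or _translate(cb) is None:
            continue  # ambiguous or stop codon: excluded from both sites and diffs
        sa, _ = ng86_sites(ca)
        sb, _ = ng86_sites(cb)
        S_a += sa
        S_b += sb
        sd, nd = ng86_diffs(ca, cb)
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise ValidationError("no comparable codons")
    S_sites = (S_a + S_b) / 2.0
    N_sites = 3.0 * n_codons - S_sites
    pS = Sd / S_sites if S_sites else 0.0
    pN = Nd / N_sites if N_sites else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    flag = ""
    if math.isnan(dS) or math.isnan(dN):
        omega, flag = math.nan, "jc_saturated"
    elif dS == 0:
        omega, flag = math.nan, "no synonymous divergence"
    else:
        omega = dN / dS
    return DnDsRecord("", "", dN, dS, omega, 1, flag)


# ---------------------------------------------------------------------------
# breed-level aggregation
# ---------------------------------------------------------------------------


def breed_gene_dnds(
    G: GenotypeMatrix,
    gene: GeneModel,
    breed: str,
    outgroup_cds: dict[str, str],
    ortholog_map: dict[str, str],
    het_policy: str = "alt",
    rng: np.random.Generator | None = None,
) -> DnDsRecord | None:
    """Mean dN/dS of one gene in one breed against its outgroup ortholog.

    Each individual's reconstructed CDS is compared to the outgroup CDS;
    dN, dS and omega are averaged over individuals (NaN omegas excluded
    from the omega mean). Returns None (logged) when the ortholog is
    absent or its length does not match — codon-aware alignment of
    indel-divergent orthologs is out of scope.
    """
    og_id = ortholog_map.get(gene.gene_id)
    if og_id is None or og_id not in outgroup_cds:
        logger.info("%s: no outgroup ortholog, skipped", gene.gene_id)
        return None
    og = outgroup_cds[og_id]
    if len(og) != len(gene.cds_seq) or len(og) % 3:
        logger.info("%s: ortholog length mismatch, skipped", gene.gene_id)
        return None
    ids = G.individuals.loc[G.individuals["breed"] == breed, "id"]
    if ids.empty:
        raise ValidationError(f"no individuals for breed {breed!r}")
    dn, ds, omegas = [], [], []
    for ind in ids:
        seq = reconstruct_sequence(G, gene, ind, het_policy=het_policy, rng=rng)
        rec = dnds_pair(seq, og)
        dn.append(rec.dN)
        ds.append(rec.dS)
        if not math.isnan(rec.omega):
            omegas.append(rec.omega)
    omega = float(np.mean(omegas)) if omegas else math.nan
    return DnDsRecord(
        gene_id=gene.gene_id,
        breed=breed,
        dN=float(np.nanmean(dn)),
        dS=float(np.nanmean(ds)),
        omega=omega,
        n_individuals=len(ids),
        flag="" if omegas else "no omega estimates",
    )


def records_to_frame(records: list[DnDsRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "breed": r.breed,
                "dN": r.dN,
                "dS": r.dS,
                "omega": r.omega,
                "n_individuals": r.n_individuals,
                "flag": r.flag,
            }
            for r in records
        ]
    )


def remove_single_breed_outliers(records: pd.DataFrame, fence: float = 3.0) -> pd.DataFrame:
    """Drop genes whose omega is an outlier in exactly one breed.

    A gene is removed from all breeds when its omega lies outside
    [Q1 - fence*IQR, Q3 + fence*IQR] of exactly one breed's omega
    distribution while inside the fences of every other breed where it
    has a record. Genes observed in fewer than 2 breeds are kept.
    """
    fences = {}
    for breed, grp in records.groupby("breed"):
        vals = grp["omega"].dropna()
        q1, q3 = vals.quantile([0.25, 0.75])
        iqr = q3 - q1
        fences[breed] = (q1 - fence * iqr, q3 + fence * iqr)
    drop = set()
    for gene, grp in records.groupby("gene_id"):
        grp = grp.dropna(subset=["omega"])
        if len(grp) < 2:
            continue
        outside = [
            not (fences[r.breed][0] <= r.omega <= fences[r.breed][1])
            for r in grp.itertuples()
        ]
        if sum(outside) == 1:
            drop.add(gene)
    if drop:
        logger.info("removed %d single-breed outlier genes", len(drop))
    return records[~records["gene_id"].isin(drop)].reset_index(drop=True)


def average_dnds_by_category(
    records: pd.DataFrame, categories: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Mean omega per breed x bias category (NaN omegas excluded)."""
    cat = pd.Series(dict(categories) if not isinstance(categories, pd.Series) else categories)
    df = records.assign(category=records["gene_id"].map(cat)).dropna(subset=["category"])
    out = (
        df.dropna(subset=["omega"])
        .groupby(["breed", "category"], as_index=False)
        .agg(mean_omega=("omega", "mean"), n_genes=("omega", "size"))
        .sort_values(["breed", "category"], ignore_index=True)
    )
    return out
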