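"""Readers and writers for the standard formats the pipeline touches.

Conventions enforced here:

* VCF is the only variant dialect. Only biallelic SNPs enter analysis;
  indel and multi-allelic records are skipped and counted.
* BED intervals are 0-based half-open; VCF positions are 1-based.
* Genotypes are unphased; within an individual the two haplotype slots
  carry no ordering information, and no downstream statistic may depend
  on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from cyvcf2 import VCF
from pyfaidx import Fasta

from .errors import (
    BoundsError,
    LookupError_,
    ParseError,
    ReconciliationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

MISSING = -1  # haplotype code for an uncalled allele

SEXES = ("M", "F")
TISSUES = ("gonad", "liver")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """FPKM values (genes x samples) with per-sample metadata.

    ``values`` is indexed by gene id with one column per sample;
    ``samples`` is indexed by sample id with columns breed / sex / tissue.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValidationError("gene ids are not unique")
        if not self.values.columns.is_unique:
            raise ValidationError("sample ids are not unique")
        if set(self.values.columns) != set(self.samples.index):
            raise ReconciliationError(
                "expression columns and sample sheet disagree: "
                f"{sorted(set(self.values.columns) ^ set(self.samples.index))}"
            )
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative FPKM values present")
        # keep metadata in column order
        self.samples = self.samples.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def subset(self, *, breed=None, sex=None, tissue=None, genes=None) -> "ExpressionMatrix":
        """Return a view restricted to matching samples and/or genes."""
        mask = pd.Series(True, index=self.samples.index)
        if breed is not None:
            mask &= self.samples["breed"] == breed
        if sex is not None:
            mask &= self.samples["sex"] == sex
        if tissue is not None:
            mask &= self.samples["tissue"] == tissue
        cols = self.samples.index[mask]
        vals = self.values[cols]
        if genes is not None:
            vals = vals.loc[genes]
        return ExpressionMatrix(vals, self.samples.loc[cols])


@dataclass
class GeneModel:
    """A single-exon gene span with its coding sequence.

    ``start``/``end`` follow the BED convention (0-based half-open);
    ``cds_seq`` is in transcription orientation (reverse-complemented
    for minus-strand genes).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    cds_seq: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"{self.gene_id}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if set(self.cds_seq) - set("ACGTN"):
            raise ValidationError(f"{self.gene_id}: CDS contains non-ACGTN characters")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenotypeMatrix:
    """Biallelic SNP sites x haplotypes for a set of diploid individuals.

    ``sites`` has columns chrom / pos (1-based) / ref / alt, positions
    strictly increasing within each chromosome. ``haplotypes`` is an
    int8 array of shape (n_sites, 2 * n_individuals) with values in
    {0, 1, MISSING}; columns 2i and 2i+1 belong to individual i.
    ``individuals`` has columns id / breed.
    """

    sites: pd.DataFrame
    haplotypes: np.ndarray
    individuals: pd.DataFrame
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.haplotypes.shape != (len(self.sites), 2 * len(self.individuals)):
            raise ValidationError("haplotype array shape inconsistent with sites/individuals")
        for _, grp in self.sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValidationError("positions not strictly increasing within chromosome")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def breed_columns(self, breed: str) -> np.ndarray:
        """Haplotype column indices belonging to one breed."""
        idx = np.flatnonzero((self.individuals["breed"] == breed).to_numpy())
        if idx.size == 0:
            raise LookupError_(f"no individuals for breed {breed!r}")
        return np.repeat(idx * 2, 2) + np.tile([0, 1], idx.size)

    def individual_index(self, individual_id: str) -> int:
        hits = np.flatnonzero((self.individuals["id"] == individual_id).to_numpy())
        if hits.size != 1:
            raise LookupError_(f"individual {individual_id!r} not found")
        return int(hits[0])


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def parse_vcf(path: str | Path, breed_map: Mapping[str, str]) -> GenotypeMatrix:
    """Read a VCF v4.x into a :class:`GenotypeMatrix`.

    Only samples named in ``breed_map`` are retained; every mapped sample
    must be present in the file. Biallelic SNPs are converted to 0/1
    haplotype codes, ``./.`` to missing. Indels and multi-allelic records
    are skipped and counted in ``n_skipped``.
    """
    path = Path(path)
    try:
        vcf = VCF(str(path))
        vcf_samples = list(vcf.samples)
    except Exception as exc:  # cyvcf2 raises on malformed headers
        raise ParseError(f"{path}: not a parseable VCF ({exc})") from exc
    if not vcf_samples:
        raise ParseError(f"{path}: no samples in #CHROM header line")
    missing = [s for s in breed_map if s not in vcf_samples]
    if missing:
        raise LookupError_(f"samples in breed map absent from VCF: {missing}")

    keep = [s for s in vcf_samples if s in breed_map]
    col_of = {s: i for i, s in enumerate(vcf_samples)}
    take = [col_of[s] for s in keep]

    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        gts = np.asarray(rec.genotypes)  # (n_samples, ploidy+1); last col = phasing
        hap = gts[take, :2].astype(np.int8).reshape(-1)
        hap[hap < 0] = MISSING
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(hap)
    if n_skipped:
        logger.info("%s: skipped %d non-biallelic-SNP records", path.name, n_skipped)

    sites = pd.DataFrame({"chrom": chroms, "pos": positions, "ref": refs, "alt": alts})
    haplotypes = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, 2 * len(keep)), dtype=np.int8)
    )
    individuals = pd.DataFrame({"id": keep, "breed": [breed_map[s] for s in keep]})
    return GenotypeMatrix(sites, haplotypes, individuals, n_skipped=n_skipped)


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as an uncompressed diploid VCF v4.2."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chrom_col = G.sites["chrom"]
        for chrom in pd.unique(chrom_col):
            end = int(G.sites.loc[chrom_col == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={max(end, 2)}>\n")
        ids = "\t".join(G.individuals["id"])
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{ids}\n")
        code = {0: "0", 1: "1", MISSING: "."}
        for i, site in enumerate(G.sites.itertuples(index=False)):
            hap = G.haplotypes[i]
            gt = "\t".join(
                f"{code[int(hap[2 * j])]}/{code[int(hap[2 * j + 1])]}"
                for j in range(len(G.individuals))
            )
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t{gt}\n"
            )


# ---------------------------------------------------------------------------
# FASTA / BED
# ---------------------------------------------------------------------------


def load_gene_models(fasta_path: str | Path, bed_path: str | Path) -> list[GeneModel]:
    """Extract gene spans from a BED file against an indexed FASTA.

    BED intervals are 0-based half-open; minus-strand genes are
    reverse-complemented so ``cds_seq`` reads 5'->3' on the coding strand.
    """
    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "name": str, "strand": str},
    )
    models = []
    for row in bed.itertuples(index=False):
        if row.chrom not in fa:
            raise LookupError_(f"contig {row.chrom!r} not in FASTA")
        contig_len = len(fa[row.chrom])
        if row.end > contig_len or row.start < 0:
            raise BoundsError(
                f"{row.name}: interval [{row.start},{row.end}) exceeds "
                f"contig {row.chrom} of length {contig_len}"
            )
        seq = str(fa[row.chrom][row.start : row.end])
        if row.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        models.append(
            GeneModel(
                gene_id=row.name,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                cds_seq=seq,
            )
        )
    return models


def load_cds_fasta(path: str | Path) -> dict[str, str]:
    """Read a CDS FASTA keyed by record id (e.g. outgroup orthologs)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def load_expression(matrix_path: str | Path, sheet_path: str | Path) -> ExpressionMatrix:
    """Read an FPKM TSV (genes x samples) and its sample sheet.

    The sheet must list exactly the matrix's sample columns, with columns
    sample_id / breed / sex / tissue.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)
    required = {"sample_id", "breed", "sex", "tissue"}
    if not required.issubset(sheet.columns):
        raise ParseError(f"sample sheet lacks columns {sorted(required - set(sheet.columns))}")
    sheet = sheet.set_index("sample_id")
    return ExpressionMatrix(values, sheet)


def load_ortholog_map(path: str | Path) -> dict[str, str]:
    """TSV with columns gene_id / outgroup_gene_id -> mapping dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "outgroup_gene_id"}.issubset(df.columns):
        raise ParseError("ortholog map needs columns gene_id, outgroup_gene_id")
    return dict(zip(df["gene_id"], df["outgroup_gene_id"]))


def load_weights(path: str | Path) -> pd.DataFrame:
    """Body-weight TSV with columns breed / sex / weight_g (grams)."""
    df = pd.read_csv(path, sep="\t")
    if not {"breed", "sex", "weight_g"}.issubset(df.columns):
        raise ParseError("weights table needs columns breed, sex, weight_g")
    if (df["weight_g"] <= 0).any():
        raise ValidationError("non-positive body weights present")
    return df


def load_gene_list(path: str | Path) -> set[str]:
    """One gene id per line; blank lines and #-comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out
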