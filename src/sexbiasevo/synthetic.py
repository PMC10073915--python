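"""Ground-truth synthetic inputs emulating the study design.

The generators mirror a three-breed comparison of one wild and two
domesticated populations: RNA expression for 5 males + 5 females per
breed in two tissues (gonad, liver), whole-genome genotypes for 8
diploid individuals per breed, genes tiled into 10 kb windows, codon
alignments with a planted omega, and adult body weights per sex.
Every quantity a downstream stage estimates is planted explicitly and
returned as truth, so recovery can be asserted end to end.

All randomness flows from an explicit seed; identical seeds produce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, GeneModel, GenotypeMatrix
from .errors import ConfigError
from .molevol import SENSE_CODONS, STOP_CODONS, _translate
from .popgen import tajima_constants

BREEDS = ("wild", "dom_meat", "dom_egg")
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# expression with planted bias dynamics
# ---------------------------------------------------------------------------


@dataclass
class ExpressionConfig:
    """Planted sex-bias structure for one simulated experiment.

    ``class_fractions`` gives, per tissue, the fraction of genes planted
    in each cross-breed dynamics class; the remainder is unbiased
    everywhere. Defaults emulate an embryonic gonad (a few percent of
    genes in each of the conserved and bias-lost classes, rarer
    bias-acquired and bias-converted genes) and a far less dimorphic
    liver. ``bin_mix`` sets the low/medium/high share of planted fold
    changes; ``sigma`` is log2-scale expression noise.
    """

    n_genes: int = 1000
    breeds: tuple[str, ...] = BREEDS
    tissues: tuple[str, ...] = ("gonad", "liver")
    n_per_sex: int = 5
    sigma: float = 0.25
    male_fraction: float = 0.5
    bin_mix: tuple[float, float, float] = (0.5, 0.3, 0.2)
    class_fractions: dict = field(
        default_factory=lambda: {
            "gonad": {"conserved": 0.08, "BLG": 0.08, "BAG": 0.01, "BCG": 0.002},
            "liver": {"conserved": 0.01, "BLG": 0.03, "BAG": 0.002, "BCG": 0.0},
        }
    )
    base_log2_range: tuple[float, float] = (2.0, 8.0)

    def validate(self) -> None:
        for tissue, fracs in self.class_fractions.items():
            if any(not 0 <= f <= 1 for f in fracs.values()) or sum(fracs.values()) > 1:
                raise ConfigError(f"{tissue}: class fractions must be in [0,1] and sum <= 1")
        if self.sigma < 0 or not 0 <= self.male_fraction <= 1:
            raise ConfigError("sigma must be >= 0 and male_fraction in [0,1]")
        if abs(sum(self.bin_mix) - 1) > 1e-9:
            raise ConfigError("bin_mix must sum to 1")


_BIN_RANGES = {"low": (2.0, 4.0), "medium": (4.0, 10.0), "high": (10.0, 30.0)}


def _draw_fc(rng: np.random.Generator, bin_mix) -> float:
    name = rng.choice(["low", "medium", "high"], p=list(bin_mix))
    lo, hi = _BIN_RANGES[name]
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _breed_pattern(label: str, direction: str, breeds) -> dict[str, str]:
    """Per-breed planted direction ('none' = unbiased) for a dynamics class."""
    wild, dom1, dom2 = breeds
    other = "female" if direction == "male" else "male"
    if label == "conserved":
        return {wild: direction, dom1: direction, dom2: direction}
    if label == "BLG":
        return {wild: direction, dom1: "none", dom2: "none"}
    if label == "BAG":
        return {wild: "none", dom1: direction, dom2: direction}
    if label == "BCG":
        return {wild: direction, dom1: other, dom2: other}
    return {wild: "none", dom1: "none", dom2: "none"}


def simulate_expression(
    cfg: ExpressionConfig, seed: int | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate an FPKM matrix with planted cross-breed bias dynamics.

    FPKM values are log-normal: log2 FPKM ~ N(mu_g +/- log2(FC)/2, sigma)
    with the half-shift added to the biased sex. Returns the matrix and
    a truth table with one row per gene x tissue x breed carrying the
    planted direction, fold change and dynamics label.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]

    samples = []
    for breed in cfg.breeds:
        for tissue in cfg.tissues:
            for sex in ("M", "F"):
                for i in range(cfg.n_per_sex):
                    samples.append(
                        {
                            "sample_id": f"{breed}_{tissue}_{sex}{i + 1}",
                            "breed": breed,
                            "sex": sex,
                            "tissue": tissue,
                        }
                    )
    sheet = pd.DataFrame(samples).set_index("sample_id")

    base = rng.uniform(*cfg.base_log2_range, size=cfg.n_genes)
    truth_rows = []
    values = np.empty((cfg.n_genes, len(sheet)))
    col_meta = list(sheet.itertuples())

    for tissue in cfg.tissues:
        fracs = cfg.class_fractions.get(tissue, {})
        labels = np.array(["unbiased"] * cfg.n_genes, dtype=object)
        order = rng.permutation(cfg.n_genes)
        pos = 0
        for label, frac in fracs.items():
            k = int(round(frac * cfg.n_genes))
            labels[order[pos : pos + k]] = label
            pos += k
        for g in range(cfg.n_genes):
            label = labels[g]
            direction = "male" if rng.random() < cfg.male_fraction else "female"
            fc = _draw_fc(rng, cfg.bin_mix) if label != "unbiased" else 1.0
            pattern = _breed_pattern(label, direction, cfg.breeds)
            for breed in cfg.breeds:
                d = pattern[breed]
                truth_rows.append(
                    {
                        "gene_id": genes[g],
                        "tissue": tissue,
                        "breed": breed,
                        "true_direction": d,
                        "true_fc": fc if d != "none" else 1.0,
                        "true_label": label,
                    }
                )

    truth = pd.DataFrame(truth_rows)
    truth_idx = truth.set_index(["gene_id", "tissue", "breed"])
    half_shift = np.log2(truth_idx["true_fc"]).to_frame("h")

    for c, meta in enumerate(col_meta):
        shifts = np.zeros(cfg.n_genes)
        sub = truth_idx.xs((meta.tissue, meta.breed), level=("tissue", "breed"))
        h = np.log2(sub.loc[genes, "true_fc"].to_numpy())
        d = sub.loc[genes, "true_direction"].to_numpy()
        sex_name = "male" if meta.sex == "M" else "female"
        shifts = np.where(d == sex_name, h / 2, np.where(d == "none", 0.0, -h / 2))
        noise = rng.normal(0.0, cfg.sigma, size=cfg.n_genes) if cfg.sigma > 0 else 0.0
        values[:, c] = 2.0 ** (base + shifts + noise)

    E = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sheet.index), sheet)
    return E, truth


# ---------------------------------------------------------------------------
# neutral haplotypes under a site-frequency-spectrum model
# ---------------------------------------------------------------------------


def simulate_haplotypes(
    theta: float,
    n_hap: int,
    L: int = 10_000,
    n_windows: int = 1,
    seed: int | None = None,
    breed: str = "wild",
    chrom: str = "chr_sim",
    id_prefix: str | None = None,
) -> tuple[GenotypeMatrix, list[GeneModel]]:
    """Neutral genotypes with E[window pi] = theta and E[Tajima's D] ~ 0.

    Windows are laid consecutively on one chromosome. Per window the
    segregating-site count is Poisson(theta * L * a1(n_hap)) and each
    site's derived-allele count i in 1..n-1 is drawn with probability
    proportional to 1/i — the neutral site frequency spectrum — which
    makes the expected per-site pairwise diversity exactly theta.
    Genealogy-free by design: sites are unlinked, which matches the
    neutral expectations used here but carries no linkage structure.

    Returns the genotype matrix (n_hap/2 diploid individuals, one breed)
    and one single-exon gene model per window so the tiling and
    statistics machinery can run unchanged.
    """
    if theta < 0:
        raise ConfigError("theta must be >= 0")
    if n_hap < 4 or n_hap % 2:
        raise ConfigError("n_hap must be an even number >= 4")
    rng = np.random.default_rng(seed)
    a1 = tajima_constants(n_hap)["a1"]
    freqs = np.arange(1, n_hap)
    sfs_p = (1.0 / freqs) / np.sum(1.0 / freqs)

    positions, counts = [], []
    for w in range(n_windows):
        S = rng.poisson(theta * L * a1)
        S = min(S, L)  # cannot place more sites than bases
        pos = rng.choice(np.arange(L), size=S, replace=False) + w * L + 1
        positions.extend(sorted(int(p) for p in pos))
        counts.extend(int(i) for i in rng.choice(freqs, size=S, p=sfs_p))

    n_sites = len(positions)
    hap = np.zeros((n_sites, n_hap), dtype=np.int8)
    for s, i in enumerate(counts):
        carriers = rng.choice(n_hap, size=i, replace=False)
        hap[s, carriers] = 1
    refs = rng.choice(list(_BASES), size=n_sites)
    alts = [
        _BASES[(int(_BASES.index(r)) + int(rng.integers(1, 4))) % 4] for r in refs
    ]
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": refs, "alt": alts}
    )
    prefix = id_prefix or breed
    individuals = pd.DataFrame(
        {"id": [f"{prefix}_{i + 1}" for i in range(n_hap // 2)], "breed": breed}
    )
    G = GenotypeMatrix(sites, hap, individuals)
    genes = [
        GeneModel(
            gene_id=f"win{w:04d}",
            chrom=chrom,
            start=w * L,
            end=(w + 1) * L,
            strand="+",
            cds_seq="",
        )
        for w in range(n_windows)
    ]
    return G, genes


def simulate_multibreed_haplotypes(
    thetas: dict[str, float],
    n_hap: int = 16,
    L: int = 10_000,
    n_windows: int = 1,
    seed: int | None = None,
    chrom: str = "chr_sim",
) -> tuple[GenotypeMatrix, list[GeneModel]]:
    """Neutral genotypes for several breeds over one shared window grid.

    Each breed gets its own per-site theta and its own private variant
    sites (drawn independently, as in diverged populations); at a
    breed's private site every other breed is homozygous reference.
    Sites colliding across breeds (same position) keep the first
    breed's variant only. Returns one genotype matrix covering all
    breeds plus the shared per-window gene models.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for breed, theta in thetas.items():
        sub_seed = int(rng.integers(2**31 - 1))
        G, genes = simulate_haplotypes(
            theta, n_hap, L, n_windows, seed=sub_seed, breed=breed, chrom=chrom
        )
        parts.append(G)

    seen: dict[int, int] = {}  # pos -> owning part index
    for k, G in enumerate(parts):
        for p in G.sites["pos"]:
            seen.setdefault(int(p), k)
    all_pos = sorted(seen)
    n_ind_per = n_hap // 2
    hap = np.zeros((len(all_pos), 2 * n_ind_per * len(parts)), dtype=np.int8)
    refs, alts = [], []
    row_of = {p: i for i, p in enumerate(all_pos)}
    for k, G in enumerate(parts):
        cols = slice(2 * n_ind_per * k, 2 * n_ind_per * (k + 1))
        for s, site in enumerate(G.sites.itertuples(index=False)):
            if seen[int(site.pos)] != k:
                continue  # collision: another breed owns this position
            hap[row_of[int(site.pos)], cols] = G.haplotypes[s]
    owner_sites = {p: parts[k].sites for p, k in seen.items()}
    for p in all_pos:
        src = owner_sites[p]
        row = src[src["pos"] == p].iloc[0]
        refs.append(row["ref"])
        alts.append(row["alt"])
    sites = pd.DataFrame({"chrom": chrom, "pos": all_pos, "ref": refs, "alt": alts})
    individuals = pd.concat([G.individuals for G in parts], ignore_index=True)
    return GenotypeMatrix(sites, hap, individuals), genes


# ---------------------------------------------------------------------------
# codon evolution at a planted omega
# ---------------------------------------------------------------------------


def simulate_coding(
    omega: float,
    target_divergence: float,
    n_codons: int,
    seed: int | None = None,
) -> tuple[str, str, float]:
    """Evolve a derived CDS from a random ancestor at a planted dN/dS.

    Single-base changes are proposed uniformly over positions and
    alternative bases; synonymous proposals are always accepted,
    nonsynonymous ones with probability ``omega``, and stop-creating
    ones rejected outright. Substitution stops once the accepted count
    reaches ``target_divergence`` substitutions per site. Returns
    (ancestral CDS, derived CDS, planted omega).
    """
    if omega < 0:
        raise ConfigError("omega must be >= 0")
    if not 0 <= target_divergence < 0.75:
        raise ConfigError("target divergence must be in [0, 0.75) to stay below saturation")
    rng = np.random.default_rng(seed)
    codons = list(rng.choice(SENSE_CODONS, size=n_codons))
    ancestor = "".join(codons)
    seq = list(codons)

    target = int(round(target_divergence * 3 * n_codons))
    accepted = 0
    attempts = 0
    max_attempts = max(1000, 1000 * target)
    while accepted < target:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigError(
                "substitution target unreachable (omega too small for the sequence?)"
            )
        ci = int(rng.integers(n_codons))
        pos = int(rng.integers(3))
        codon = seq[ci]
        new_base = _BASES[int(rng.integers(4))]
        if new_base == codon[pos]:
            continue
        cand = codon[:pos] + new_base + codon[pos + 1 :]
        if cand in STOP_CODONS:
            continue
        synonymous = _translate(cand) == _translate(codon)
        if synonymous or rng.random() < omega:
            seq[ci] = cand
            accepted += 1
    return ancestor, "".join(seq), omega


def _propose_substitution(
    seq: list[str], omega: float, rng: np.random.Generator, max_attempts: int = 10_000
) -> tuple[int, str, str]:
    """One accepted codon-model substitution on ``seq`` (not applied).

    Returns (base position, ref base, alt base) under the same
    accept/reject rule as :func:`simulate_coding`.
    """
    n_codons = len(seq) // 3
    for _ in range(max_attempts):
        ci = int(rng.integers(n_codons))
        pos = int(rng.integers(3))
        codon = "".join(seq[3 * ci : 3 * ci + 3])
        new_base = _BASES[int(rng.integers(4))]
        if new_base == codon[pos]:
            continue
        cand = codon[:pos] + new_base + codon[pos + 1 :]
        if cand in STOP_CODONS:
            continue
        if _translate(cand) == _translate(codon) or rng.random() < omega:
            return 3 * ci + pos, codon[pos], new_base
    raise ConfigError("could not find an acceptable substitution")


def simulate_coding_panel(
    omegas: dict[str, float],
    n_codons: int = 300,
    divergence: float = 0.05,
    poly_sites: int = 4,
    n_hap: int = 16,
    breeds: tuple[str, ...] = BREEDS,
    seed: int | None = None,
    chrom: str = "chr_cds",
) -> dict:
    """A panel of coding genes with outgroup divergence and polymorphism.

    Per gene, an outgroup/reference pair is evolved at that gene's
    planted omega; per breed, ``poly_sites`` segregating sites are
    added inside the CDS under the same omega acceptance rule, with
    derived-allele counts drawn from the neutral SFS. Genes are laid
    head-to-tail on one chromosome, plus strand.

    Returns a dict with keys ``genome`` (chrom -> sequence),
    ``genes`` (GeneModel list), ``outgroup`` (id -> CDS),
    ``ortholog_map``, ``genotypes`` (GenotypeMatrix over all breeds)
    and ``truth_omega`` (gene_id -> planted omega).
    """
    rng = np.random.default_rng(seed)
    gene_len = 3 * n_codons
    genes, outgroup, ortholog_map, truth = [], {}, {}, {}
    ref_parts = []
    site_rows = []  # (pos, ref, alt, breed, derived_count)
    used_positions: set[int] = set()
    freqs = np.arange(1, n_hap)
    sfs_p = (1.0 / freqs) / np.sum(1.0 / freqs)

    for gi, (gene_id, omega) in enumerate(omegas.items()):
        sub_seed = int(rng.integers(2**31 - 1))
        anc, ref, _ = simulate_coding(omega, divergence, n_codons, seed=sub_seed)
        og_id = f"og_{gene_id}"
        outgroup[og_id] = anc
        ortholog_map[gene_id] = og_id
        truth[gene_id] = omega
        start = gi * gene_len
        genes.append(
            GeneModel(gene_id=gene_id, chrom=chrom, start=start, end=start + gene_len,
                      strand="+", cds_seq=ref)
        )
        ref_parts.append(ref)
        for breed in breeds:
            placed = 0
            while placed < poly_sites:
                off, ref_base, alt_base = _propose_substitution(list(ref), omega, rng)
                pos = start + off + 1  # 1-based
                if pos in used_positions:
                    continue
                used_positions.add(pos)
                count = int(rng.choice(freqs, p=sfs_p))
                site_rows.append((pos, ref_base, alt_base, breed, count))
                placed += 1

    n_ind = n_hap // 2
    individuals = pd.DataFrame(
        [
            {"id": f"{breed}_{i + 1}", "breed": breed}
            for breed in breeds
            for i in range(n_ind)
        ]
    )
    site_rows.sort()
    hap = np.zeros((len(site_rows), 2 * len(individuals)), dtype=np.int8)
    breed_cols = {
        b: np.flatnonzero((individuals["breed"] == b).to_numpy()) for b in breeds
    }
    for s, (_, _, _, breed, count) in enumerate(site_rows):
        cols = np.repeat(breed_cols[breed] * 2, 2) + np.tile([0, 1], n_ind)
        carriers = rng.choice(cols, size=count, replace=False)
        hap[s, carriers] = 1
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": [r[0] for r in site_rows],
            "ref": [r[1] for r in site_rows],
            "alt": [r[2] for r in site_rows],
        }
    )
    return {
        "genome": {chrom: "".join(ref_parts)},
        "genes": genes,
        "outgroup": outgroup,
        "ortholog_map": ortholog_map,
        "genotypes": GenotypeMatrix(sites, hap, individuals),
        "truth_omega": truth,
    }


def concat_genotypes(parts: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Stack genotype matrices over disjoint chromosomes, same individuals."""
    first = parts[0]
    for G in parts[1:]:
        if not first.individuals.equals(G.individuals):
            raise ConfigError("genotype matrices must share identical individuals")
    sites = pd.concat([G.sites for G in parts], ignore_index=True)
    hap = np.vstack([G.haplotypes for G in parts])
    return GenotypeMatrix(sites, hap, first.individuals.copy())


# ---------------------------------------------------------------------------
# body weights
# ---------------------------------------------------------------------------


@dataclass
class WeightConfig:
    """Per-breed body-weight distributions (grams).

    Defaults emulate adult ducks: a wild breed with strong male-skewed
    dimorphism (SSD ~ 53.2%), a heavy meat breed and an egg breed with
    weaker dimorphism (~51.7% and ~51.1%), 25 birds per sex, and
    coefficient of variation ~8%.
    """

    breeds: dict = field(
        default_factory=lambda: {
            "wild": {"mu_m": 1589.5, "mu_f": 1400.0, "sd_m": 127.0, "sd_f": 112.0},
            "dom_meat": {"mu_m": 3204.9, "mu_f": 3000.0, "sd_m": 256.0, "sd_f": 240.0},
            "dom_egg": {"mu_m": 1569.4, "mu_f": 1500.0, "sd_m": 126.0, "sd_f": 120.0},
        }
    )
    n_per_sex: int = 25

    def true_ssd(self, breed: str) -> float:
        b = self.breeds[breed]
        return 100.0 * b["mu_m"] / (b["mu_m"] + b["mu_f"])


def simulate_weights(cfg: WeightConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw per-individual weights, Normal per sex truncated at zero."""
    rng = np.random.default_rng(seed)
    rows = []
    for breed, b in cfg.breeds.items():
        if b["mu_m"] <= 0 or b["mu_f"] <= 0:
            raise ConfigError(f"{breed}: weight means must be positive")
        for sex, mu, sd in (("M", b["mu_m"], b["sd_m"]), ("F", b["mu_f"], b["sd_f"])):
            w = rng.normal(mu, sd, size=cfg.n_per_sex)
            while (w <= 0).any():  # truncate at zero by redrawing
                w[w <= 0] = rng.normal(mu, sd, size=int((w <= 0).sum()))
            rows.extend({"breed": breed, "sex": sex, "weight_g": x} for x in w)
    return pd.DataFrame(rows)
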