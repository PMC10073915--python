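import itertools
import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from sexbiasevo.core_io import GeneModel
from sexbiasevo.errors import ValidationError
from sexbiasevo.molevol import (
    SENSE_CODONS,
    average_dnds_by_category,
    breed_gene_dnds,
    dnds_pair,
    jukes_cantor,
    ng86_diffs,
    ng86_sites,
    reconstruct_sequence,
    records_to_frame,
    remove_single_breed_outliers,
)
from sexbiasevo.synthetic import simulate_coding, simulate_coding_panel

BASES = "ACGT"


def aa(codon: str) -> str:
    """Oracle translation via Biopython (stops become '*')."""
    return str(Seq(codon).translate())


def oracle_sites(codon: str) -> float:
    s = 0.0
    for i, b in itertools.product(range(3), BASES):
        if b == codon[i]:
            continue
        mutant = codon[:i] + b + codon[i + 1 :]
        if aa(mutant) == aa(codon) and aa(mutant) != "*":
            s += 1 / 3
    return s


def oracle_diffs(c1: str, c2: str):
    """Exhaustive pathway enumeration with stop exclusion."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur, steps, blocked = c1, [], False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if aa(nxt) == "*":
                blocked = True
                break
            steps.append(aa(cur) == aa(nxt))
            cur = nxt
        if not blocked:
            paths.append(steps)
    if not paths:
        return None  # all pathways stop-blocked
    sd = np.mean([sum(p) for p in paths])
    nd = np.mean([len(p) - sum(p) for p in paths])
    return sd, nd


class TestSites:
    def test_phe_codon_enumeration(self):
        s, n = ng86_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_met_is_fully_nonsynonymous(self):
        assert ng86_sites("ATG") == (0.0, 3.0)

    def test_all_sense_codons_match_oracle_and_sum_to_three(self):
        for codon in SENSE_CODONS:
            s, n = ng86_sites(codon)
            assert s == pytest.approx(oracle_sites(codon), abs=1e-12), codon
            assert s + n == pytest.approx(3.0)

    def test_stop_and_ambiguous_rejected(self):
        for bad in ("TAA", "TGA", "NNT", "AT"):
            with pytest.raises(ValidationError):
                ng86_sites(bad)


class TestDiffs:
    def test_identity(self):
        assert ng86_diffs("TTT", "TTT") == (0.0, 0.0)

    def test_single_synonymous(self):
        assert ng86_diffs("TTT", "TTC") == (1.0, 0.0)

    def test_exhaustive_pairs_match_pathway_oracle(self):
        """All 61 x 61 sense-codon pairs: pathway-averaged counts equal the
        oracle, and sd + nd equals the raw difference count whenever at
        least one pathway avoids stops."""
        for c1, c2 in itertools.product(SENSE_CODONS, repeat=2):
            sd, nd = ng86_diffs(c1, c2)
            n_diff = sum(a != b for a, b in zip(c1, c2))
            want = oracle_diffs(c1, c2)
            if want is not None:
                assert sd == pytest.approx(want[0], abs=1e-12), (c1, c2)
                assert nd == pytest.approx(want[1], abs=1e-12), (c1, c2)
                assert sd + nd == pytest.approx(n_diff)
            else:
                # blocked everywhere: still averages over all orderings
                assert sd + nd == pytest.approx(n_diff)


class TestDnDsPair:
    def test_identical_sequences_flagged(self):
        rec = dnds_pair("ATGAAA", "ATGAAA")
        assert rec.dN == 0 and rec.dS == 0
        assert math.isnan(rec.omega)
        assert rec.flag == "no synonymous divergence"

    def test_single_synonymous_difference(self):
        seq = "".join(np.random.default_rng(0).choice(SENSE_CODONS, 300))
        # TTT -> TTC is synonymous
        assert "TTT" not in (seq[:3],)  # guard against accidental overlap edit
        a = "TTT" + seq
        b = "TTC" + seq
        rec = dnds_pair(a, b)
        assert rec.dN == 0
        assert rec.dS > 0
        assert rec.omega == 0

    def test_symmetry(self):
        a, b, _ = simulate_coding(0.7, 0.08, 200, seed=4)
        r1, r2 = dnds_pair(a, b), dnds_pair(b, a)
        assert r1.dN == pytest.approx(r2.dN)
        assert r1.dS == pytest.approx(r2.dS)

    def test_length_validation(self):
        with pytest.raises(ValidationError):
            dnds_pair("ATGA", "ATGA")
        with pytest.raises(ValidationError):
            dnds_pair("ATG", "ATGATG")

    def test_jukes_cantor_saturation(self):
        assert math.isnan(jukes_cantor(0.76))
        assert jukes_cantor(0.0) == 0.0

    @pytest.mark.parametrize("omega,tol", [(0.2, 0.15), (1.0, 0.10)])
    def test_planted_omega_recovery(self, omega, tol):
        anc, der, _ = simulate_coding(omega, 0.05, 10_000, seed=int(omega * 10))
        rec = dnds_pair(anc, der)
        assert rec.omega == pytest.approx(omega, rel=tol)


class TestReconstruct:
    def _setup(self, strand="+"):
        # genomic sequence ATGAAA on 'c'; gene covers it all
        cds = "ATGAAA" if strand == "+" else str(Seq("ATGAAA").reverse_complement())
        gene = GeneModel("g1", "c", 0, 6, strand, cds)
        sites = pd.DataFrame({"chrom": ["c"], "pos": [4], "ref": ["A"], "alt": ["G"]})
        individuals = pd.DataFrame({"id": ["i1"], "breed": ["wild"]})
        return gene, sites, individuals

    def _G(self, sites, individuals, hap):
        from sexbiasevo.core_io import GenotypeMatrix

        return GenotypeMatrix(sites, np.array(hap, dtype=np.int8), individuals)

    def test_hom_alt_substitution(self):
        gene, sites, ind = self._setup()
        G = self._G(sites, ind, [[1, 1]])
        assert reconstruct_sequence(G, gene, "i1") == "ATGGAA"

    def test_no_variants_identity(self):
        gene, sites, ind = self._setup()
        G = self._G(sites, ind, [[0, 0]])
        assert reconstruct_sequence(G, gene, "i1") == "ATGAAA"

    def test_het_policies(self):
        gene, sites, ind = self._setup()
        G = self._G(sites, ind, [[0, 1]])
        assert reconstruct_sequence(G, gene, "i1", "alt") == "ATGGAA"
        assert reconstruct_sequence(G, gene, "i1", "ref") == "ATGAAA"
        rng = np.random.default_rng(0)
        out = {reconstruct_sequence(G, gene, "i1", "random", rng) for _ in range(20)}
        assert out == {"ATGGAA", "ATGAAA"}

    def test_minus_strand_substitution_in_genomic_frame(self):
        gene, sites, ind = self._setup(strand="-")
        G = self._G(sites, ind, [[1, 1]])
        # genomic ATGAAA with A->G at genomic pos 4 = ATGGAA; coding strand revcomp
        assert reconstruct_sequence(G, gene, "i1") == str(Seq("ATGGAA").reverse_complement())

    def test_ref_mismatch_is_error(self):
        gene, sites, ind = self._setup()
        sites = sites.assign(ref=["C"], alt=["G"])
        G = self._G(sites, ind, [[1, 1]])
        with pytest.raises(ValidationError):
            reconstruct_sequence(G, gene, "i1")

    def test_missing_genotype_keeps_reference(self):
        gene, sites, ind = self._setup()
        G = self._G(sites, ind, [[-1, -1]])
        assert reconstruct_sequence(G, gene, "i1") == "ATGAAA"


class TestBreedDnDs:
    def test_identity_individuals_equal_reference_pair(self):
        panel = simulate_coding_panel({"cdsA": 0.3}, n_codons=120, poly_sites=0, seed=8)
        gene = panel["genes"][0]
        rec = breed_gene_dnds(
            panel["genotypes"], gene, "wild", panel["outgroup"], panel["ortholog_map"]
        )
        ref_rec = dnds_pair(gene.cds_seq, panel["outgroup"][panel["ortholog_map"]["cdsA"]])
        assert rec.omega == pytest.approx(ref_rec.omega)
        assert rec.n_individuals == 8

    def test_extra_nonsynonymous_allele_raises_mean_dn(self):
        panel = simulate_coding_panel({"cdsA": 0.3}, n_codons=120, poly_sites=0, seed=8)
        gene = panel["genes"][0]
        G = panel["genotypes"]
        ref_rec = breed_gene_dnds(G, gene, "wild", panel["outgroup"], panel["ortholog_map"])
        # plant a hom-alt nonsynonymous variant in one individual: ATG pos...
        # find a codon where a first-position change is nonsynonymous
        seq = gene.cds_seq
        pos = next(
            i for i in range(0, len(seq), 3)
            if str(Seq(seq[i : i + 3]).translate())
            != str(Seq(("G" if seq[i] != "G" else "C") + seq[i + 1 : i + 3]).translate())
            and ("G" if seq[i] != "G" else "C") + seq[i + 1 : i + 3] not in ("TAA", "TAG", "TGA")
        )
        alt = "G" if seq[pos] != "G" else "C"
        new_sites = pd.DataFrame(
            {"chrom": [gene.chrom], "pos": [pos + 1], "ref": [seq[pos]], "alt": [alt]}
        )
        hap = np.zeros((1, G.haplotypes.shape[1]), dtype=np.int8)
        hap[0, :2] = 1  # first wild individual hom-alt
        from sexbiasevo.core_io import GenotypeMatrix

        G2 = GenotypeMatrix(new_sites, hap, G.individuals.copy())
        rec = breed_gene_dnds(G2, gene, "wild", panel["outgroup"], panel["ortholog_map"])
        assert rec.dN > ref_rec.dN

    def test_length_mismatched_ortholog_skipped(self):
        panel = simulate_coding_panel({"cdsA": 0.3}, n_codons=60, poly_sites=0, seed=9)
        gene = panel["genes"][0]
        short = {k: v[:-3] for k, v in panel["outgroup"].items()}
        assert breed_gene_dnds(panel["genotypes"], gene, "wild", short, panel["ortholog_map"]) is None

    def test_planted_omega_recovered_per_breed(self):
        panel = simulate_coding_panel(
            {f"g{i}": 0.2 for i in range(4)}, n_codons=2000, poly_sites=3, seed=10
        )
        omegas = [
            breed_gene_dnds(
                panel["genotypes"], gene, breed, panel["outgroup"], panel["ortholog_map"]
            ).omega
            for gene in panel["genes"]
            for breed in ("wild", "dom_meat", "dom_egg")
        ]
        assert np.nanmean(omegas) == pytest.approx(0.2, rel=0.15)


class TestOutliers:
    def _records(self, omegas_by_gene):
        rows = []
        for gene, per_breed in omegas_by_gene.items():
            for breed, om in per_breed.items():
                rows.append({"gene_id": gene, "breed": breed, "dN": 0.1, "dS": 0.1,
                             "omega": om, "n_individuals": 8, "flag": ""})
        return pd.DataFrame(rows)

    def _base(self, spike=None):
        rng = np.random.default_rng(11)
        data = {
            f"g{i}": {b: float(rng.uniform(0.1, 0.3)) for b in ("w", "d1", "d2")}
            for i in range(30)
        }
        if spike:
            data["gX"] = spike
        return self._records(data)

    def test_single_breed_outlier_dropped_everywhere(self):
        recs = self._base(spike={"w": 50.0, "d1": 0.2, "d2": 0.2})
        out = remove_single_breed_outliers(recs)
        assert "gX" not in set(out["gene_id"])

    def test_two_breed_outlier_retained(self):
        recs = self._base(spike={"w": 50.0, "d1": 50.0, "d2": 0.2})
        out = remove_single_breed_outliers(recs)
        assert "gX" in set(out["gene_id"])

    def test_no_outliers_identity(self):
        recs = self._base()
        out = remove_single_breed_outliers(recs)
        pd.testing.assert_frame_equal(out, recs)


class TestCategoryMeans:
    def test_single_gene_category_and_permutation_invariance(self):
        recs = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "breed": ["w"] * 3,
                "omega": [0.1, 0.5, 0.3],
            }
        )
        cats = {"a": "male_high", "b": "male_high", "c": "unbiased"}
        out = average_dnds_by_category(recs, cats).set_index("category")
        assert out.loc["unbiased", "mean_omega"] == pytest.approx(0.3)
        assert out.loc["male_high", "mean_omega"] == pytest.approx(0.3)
        out2 = average_dnds_by_category(recs.sample(frac=1, random_state=2), cats)
        pd.testing.assert_frame_equal(out.reset_index(), out2[out.reset_index().columns])

    def test_planted_category_order(self):
        """Categories simulated at increasing omega keep that order in means."""
        planted = {"unbiased": 0.1, "male_low": 0.3, "male_high": 0.8}
        rows, cats = [], {}
        for ci, (cat, om) in enumerate(planted.items()):
            for i in range(3):
                gene = f"{cat}_{i}"
                anc, der, _ = simulate_coding(om, 0.05, 600, seed=100 + 10 * ci + i)
                rec = dnds_pair(anc, der)
                rows.append({"gene_id": gene, "breed": "w", "omega": rec.omega})
                cats[gene] = cat
        out = average_dnds_by_category(pd.DataFrame(rows), cats).set_index("category")
        assert (
            out.loc["unbiased", "mean_omega"]
            < out.loc["male_low", "mean_omega"]
            < out.loc["male_high", "mean_omega"]
        )
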