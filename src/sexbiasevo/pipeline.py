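"""End-to-end orchestration: filter -> call -> dynamics -> pi/D -> dN/dS -> SSD.

A run is a pure function of (inputs, config, seed). Each stage writes
its TSV into the report directory as it completes; if a stage fails,
everything written so far is renamed with a ``.partial`` suffix and a
:class:`~sexbiasevo.errors.StageError` naming the stage is raised.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from . import core_io, dimorphism, molevol, popgen, sex_bias
from .errors import ConfigError, StageError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and breed roles for a full pipeline run.

    ``wild_breed`` names the ancestral population; ``domestic_breeds``
    the two domesticated ones. Analysis-stage inputs are optional:
    stages whose inputs are absent are skipped.
    """

    out_dir: str = "report"
    expression: str | None = None
    sample_sheet: str | None = None
    vcf: str | None = None
    reference_fasta: str | None = None
    gene_bed: str | None = None
    outgroup_fasta: str | None = None
    ortholog_map: str | None = None
    weights: str | None = None
    sex_chrom_genes: str | None = None
    immune_genes: str | None = None

    wild_breed: str = "wild"
    domestic_breeds: tuple[str, str] = ("dom_meat", "dom_egg")
    tissues: tuple[str, ...] = ("gonad", "liver")
    bias_tissue: str = "gonad"  # tissue used for popgen / dN/dS categories

    fc_threshold: float = 2.0
    fdr: float = 0.05
    pseudocount: float = 0.5
    min_fpkm: float = 0.5
    window_size: int = 10_000
    fence: float = 3.0
    het_policy: str = "alt"
    seed: int = 0

    @property
    def breeds(self) -> tuple[str, ...]:
        return (self.wild_breed, *self.domestic_breeds)

    def validate(self) -> None:
        """Threshold sanity. Input paths are checked by the stage that
        reads them, so a missing file aborts naming that stage."""
        for name in ("fc_threshold", "fdr", "pseudocount", "window_size", "fence"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "domestic_breeds" in raw:
            raw["domestic_breeds"] = tuple(raw["domestic_breeds"])
        if "tissues" in raw:
            raw["tissues"] = tuple(raw["tissues"])
        return cls(**raw)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (so 0.005 -> 0.01), as used in summary tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def proportion_percent(count: int, total: int, decimals: int = 2) -> float:
    """Percentage ``100 * count / total`` rounded half-up to ``decimals``."""
    if total <= 0:
        return 0.0
    return round_half_up(100.0 * count / total, decimals)


def share_percent(count: int, total: int) -> int:
    """Integer percentage, truncated — the precision used for phrases
    like 'x% of sex-biased genes'."""
    if total <= 0:
        return 0
    return int(100 * count // total)


def summarize_counts(calls: pd.DataFrame, expressed: dict[tuple[str, str], int]) -> pd.DataFrame:
    """Per tissue x breed: expressed / biased / male / female counts and %.

    ``expressed`` maps (tissue, breed) to the number of expressed genes
    tested in that family. The overall proportion is reported to two
    decimals (half-up); the male and female shares of biased genes as
    truncated integer percentages.
    """
    rows = []
    for (tissue, breed), grp in calls.groupby(["tissue", "breed"], sort=False):
        biased = grp[grp["direction"] != "none"]
        n_male = int((biased["direction"] == "male").sum())
        n_female = int((biased["direction"] == "female").sum())
        n_expr = expressed[(tissue, breed)]
        n_total = len(biased)
        rows.append(
            {
                "tissue": tissue,
                "breed": breed,
                "n_expressed": n_expr,
                "n_biased": n_total,
                "n_male_biased": n_male,
                "n_female_biased": n_female,
                "proportion_pct": proportion_percent(n_total, n_expr, 2),
                "male_share_pct": share_percent(n_male, n_total),
                "female_share_pct": share_percent(n_female, n_total),
            }
        )
    return pd.DataFrame(rows)


def bias_category(call_row) -> str:
    """Seven-way category: {male,female} x {low,medium,high} or unbiased."""
    if call_row["direction"] == "none":
        return "unbiased"
    return f"{call_row['direction']}_{call_row['magnitude']}"


def _write(df: pd.DataFrame, out_dir: Path, name: str, written: list[Path]) -> Path:
    path = out_dir / name
    df.to_csv(path, sep="\t", index=False)
    written.append(path)
    return path


def run_all(cfg: RunConfig) -> dict[str, Path]:
    """Execute every stage whose inputs are configured; return output paths.

    Stage order: expression filtering, bias calling, dynamics, summary
    counts, windowed diversity + Tajima's D, dN/dS, SSD. Any stage
    failure aborts with the stage name; outputs written so far are
    renamed ``*.partial``.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    outputs: dict[str, Path] = {}
    stage = "setup"

    def fail(exc: Exception):
        for p in written:
            p.rename(p.with_suffix(p.suffix + ".partial"))
        return StageError(stage, exc)

    try:
        calls_all = None
        gonad_calls: dict[str, pd.DataFrame] = {}
        if cfg.expression and cfg.sample_sheet:
            stage = "sex_bias"
            E = core_io.load_expression(cfg.expression, cfg.sample_sheet)
            sex_genes = core_io.load_gene_list(cfg.sex_chrom_genes) if cfg.sex_chrom_genes else set()
            immune = core_io.load_gene_list(cfg.immune_genes) if cfg.immune_genes else set()
            E = sex_bias.remove_excluded_genes(E, sex_genes, immune)
            frames, expressed = [], {}
            for tissue in cfg.tissues:
                Et = sex_bias.filter_expressed(E, tissue, cfg.min_fpkm)
                for breed in cfg.breeds:
                    calls = sex_bias.call_sex_bias(
                        Et, breed, tissue, cfg.fc_threshold, cfg.fdr, cfg.pseudocount
                    )
                    expressed[(tissue, breed)] = len(calls)
                    frames.append(calls)
                    if tissue == cfg.bias_tissue:
                        gonad_calls[breed] = calls
            calls_all = pd.concat(frames, ignore_index=True)
            outputs["bias_calls"] = _write(calls_all, out_dir, "bias_calls.tsv", written)
            outputs["summary_counts"] = _write(
                summarize_counts(calls_all, expressed), out_dir, "summary_counts.tsv", written
            )

            stage = "dynamics"
            dom1, dom2 = cfg.domestic_breeds
            dynamics = sex_bias.classify_dynamics(
                gonad_calls[cfg.wild_breed], gonad_calls[dom1], gonad_calls[dom2]
            )
            outputs["dynamics"] = _write(dynamics, out_dir, "dynamics.tsv", written)

        genotypes = genes = None
        if cfg.vcf and cfg.reference_fasta and cfg.gene_bed:
            stage = "popgen"
            breed_map = _breed_map_from_vcf(cfg)
            genotypes = core_io.parse_vcf(cfg.vcf, breed_map)
            genes = core_io.load_gene_models(cfg.reference_fasta, cfg.gene_bed)
            stats = popgen.windowed_stats(
                genotypes, genes, list(cfg.breeds), cfg.window_size, tajima=True
            )
            outputs["windowed_pi"] = _write(
                stats.drop(columns=["tajima_D"]), out_dir, "windowed_pi.tsv", written
            )
            outputs["tajima_d"] = _write(
                stats.drop(columns=["pi", "S"]), out_dir, "tajima_d.tsv", written
            )
            if gonad_calls:
                per_breed = []
                for breed in cfg.breeds:
                    cats = {
                        r["gene_id"]: bias_category(r)
                        for _, r in gonad_calls[breed].iterrows()
                    }
                    covered = stats[
                        (stats["breed"] == breed) & stats["gene_id"].isin(cats)
                    ]
                    if not covered.empty:
                        per_breed.append(popgen.aggregate_by_category(covered, cats))
                if per_breed:
                    outputs["pi_by_category"] = _write(
                        pd.concat(per_breed, ignore_index=True),
                        out_dir,
                        "pi_by_category.tsv",
                        written,
                    )

        if genotypes is not None and genes and cfg.outgroup_fasta and cfg.ortholog_map:
            stage = "molevol"
            outgroup = core_io.load_cds_fasta(cfg.outgroup_fasta)
            orthologs = core_io.load_ortholog_map(cfg.ortholog_map)
            recs = []
            for gene in genes:
                for breed in cfg.breeds:
                    rec = molevol.breed_gene_dnds(
                        genotypes, gene, breed, outgroup, orthologs, cfg.het_policy
                    )
                    if rec is not None:
                        recs.append(rec)
            dnds = molevol.remove_single_breed_outliers(
                molevol.records_to_frame(recs), cfg.fence
            )
            outputs["dnds"] = _write(dnds, out_dir, "dnds.tsv", written)
            if gonad_calls:
                frames = []
                for breed in cfg.breeds:
                    cats = {
                        r["gene_id"]: bias_category(r)
                        for _, r in gonad_calls[breed].iterrows()
                    }
                    sub = dnds[dnds["breed"] == breed]
                    if not sub.empty:
                        frames.append(molevol.average_dnds_by_category(sub, cats))
                if frames:
                    outputs["dnds_by_category"] = _write(
                        pd.concat(frames, ignore_index=True),
                        out_dir,
                        "dnds_by_category.tsv",
                        written,
                    )

        if cfg.weights:
            stage = "dimorphism"
            wt = core_io.load_weights(cfg.weights)
            outputs["ssd"] = _write(dimorphism.ssd_table(wt), out_dir, "ssd.tsv", written)
            outputs["ssd_tests"] = _write(
                dimorphism.pairwise_ssd_tests(wt), out_dir, "ssd_tests.tsv", written
            )

        stage = "report"
        outputs["run_log"] = _write_run_log(cfg, out_dir, outputs)
    except StageError:
        raise
    except Exception as exc:
        raise fail(exc) from exc
    return outputs


def _breed_map_from_vcf(cfg: RunConfig) -> dict[str, str]:
    """Infer sample -> breed from sample-name prefixes matching breed names."""
    from cyvcf2 import VCF

    samples = VCF(str(cfg.vcf)).samples
    breed_map = {}
    for s in samples:
        for breed in cfg.breeds:
            if s.startswith(breed):
                breed_map[s] = breed
                break
    if not breed_map:
        raise ConfigError("no VCF sample names match configured breed names")
    return breed_map


def _write_run_log(cfg: RunConfig, out_dir: Path, outputs: dict[str, Path]) -> Path:
    import numpy
    import scipy

    from . import __version__

    path = out_dir / "run_log.txt"
    lines = [
        f"sexbiasevo {__version__} (numpy {numpy.__version__}, "
        f"scipy {scipy.__version__}, pandas {pd.__version__})",
        f"seed: {cfg.seed}",
        "parameters:",
    ]
    for f in dataclasses.fields(cfg):
        lines.append(f"  {f.name}: {getattr(cfg, f.name)}")
    lines.append("outputs:")
    lines.extend(f"  {k}: {v.name}" for k, v in outputs.items())
    path.write_text("\n".join(lines) + "\n")
    return path
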