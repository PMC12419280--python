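"""Readers and writers for every interchange format, plus the end-to-end
pipeline driver.

Conventions: positions are 0-based half-open in memory and 1-based in files
(VCF, annotation TSV, HGMD TSV); empty strings in TSVs denote absent values;
every output directory gets a run manifest (seed, config hash, library
versions) so results are reproducible from config + seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from . import __version__
from .burden import (
    HET,
    HOM,
    MISSING,
    WILD,
    GenotypeMatrix,
    gene_burden_table,
    rank_genes,
)
from .cascade import FilterConfig, group_by_gene, run_cascade
from .cohort import baseline_frame, baseline_table, select_extremes
from .errors import ConfigurationError, DataError, FormatError
from .varclass import PREDICTORS, AnnotatedVariant

logger = logging.getLogger("extremoseq")

ANNOTATION_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "region",
    "func_class",
    *PREDICTORS,
    "freq_1kg",
    "freq_esp6500",
    "freq_selfctrl",
    "freq_tianhao",
    "hgmd_id",
    "site_qual",
    "qual_class",
    "homology",
)

_GT_STRING = {WILD: "0/0", HET: "0/1", HOM: "1/1", MISSING: "./."}


# ---------------------------------------------------------------------------
# Phenotypes

def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False, float_format="%.6g")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns or "TG" not in df.columns:
        raise FormatError("phenotype CSV requires sample_id and TG columns")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


# ---------------------------------------------------------------------------
# Annotation TSV

def write_annotation_table(variants: Sequence[AnnotatedVariant], path) -> None:
    """Write the documented 21-column annotation TSV (positions 1-based)."""
    rows = []
    for v in variants:
        row = {
            "chrom": v.chrom,
            "pos": v.pos + 1,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "region": v.region,
            "func_class": v.func_class,
            "hgmd_id": v.hgmd_id or "",
            "site_qual": f"{v.site_qual:.4g}",
            "qual_class": v.qual_class,
            "homology": v.homology,
        }
        for name in PREDICTORS:
            row[name] = v.predictions.get(name) or ""
        for name in ("freq_1kg", "freq_esp6500", "freq_selfctrl", "freq_tianhao"):
            value = getattr(v, name)
            row[name] = "" if value is None else repr(float(value))
        rows.append(row)
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_annotation_table(path) -> list[AnnotatedVariant]:
    """Read the annotation TSV back into typed variants.

    Raises :class:`FormatError` listing any missing required columns and
    :class:`DataError` for frequencies outside [0, 1].
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation TSV missing columns: {missing}")
    variants = []
    for _, row in df.iterrows():
        freqs = {}
        for name in ("freq_1kg", "freq_esp6500", "freq_selfctrl", "freq_tianhao"):
            raw = row[name].strip()
            freqs[name] = float(raw) if raw else None
        variants.append(
            AnnotatedVariant(
                chrom=row["chrom"],
                pos=int(row["pos"]) - 1,
                ref=row["ref"],
                alt=row["alt"],
                gene=row["gene"],
                region=row["region"],
                func_class=row["func_class"],
                predictions={
                    name: (row[name] or None) for name in PREDICTORS
                },
                hgmd_id=row["hgmd_id"] or None,
                site_qual=float(row["site_qual"]),
                qual_class=row["qual_class"],
                homology=int(row["homology"]),
                **freqs,
            )
        )
    return variants


# ---------------------------------------------------------------------------
# VCF

def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with a GT-only FORMAT."""
    contigs = list(dict.fromkeys(chrom for chrom, _, _, _ in matrix.sites))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=extremoseq {__version__}\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j, (chrom, pos, ref, alt) in enumerate(matrix.sites):
            gts = "\t".join(_GT_STRING[int(c)] for c in matrix.calls[:, j])
            fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n")


def read_vcf_genotypes(path, sample_subset: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF into a genotype matrix.

    Multi-allelic records are split into one biallelic site per alternate
    allele; for each split site a genotype is the count of that allele
    (0=wild, 1=het, 2=hom), and any missing allele makes the call missing.
    """
    vf = pysam.VariantFile(str(path))
    if "GT" not in vf.header.formats:
        raise FormatError(f"{path}: no GT in FORMAT header")
    header_samples = list(vf.header.samples)
    if sample_subset is None:
        samples = header_samples
    else:
        absent = [s for s in sample_subset if s not in header_samples]
        if absent:
            raise DataError(f"samples not in VCF header: {absent}")
        samples = list(sample_subset)
    sites: list[tuple[str, int, str, str]] = []
    rows: list[np.ndarray] = []
    for rec in vf:
        alts = rec.alts or ()
        for ai, alt in enumerate(alts, start=1):
            codes = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    codes[i] = MISSING
                else:
                    codes[i] = min(2, sum(1 for a in gt if a == ai))
            sites.append((rec.chrom, rec.pos - 1, rec.ref, alt))
            rows.append(codes)
    calls = (
        np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls)


# ---------------------------------------------------------------------------
# Per-call qualities, truth, auxiliary tables

def _site_label(key) -> str:
    chrom, pos, ref, alt = key
    return f"{chrom}:{pos + 1}:{ref}:{alt}"


def write_quals(matrix: GenotypeMatrix, path) -> None:
    if matrix.quals is None:
        raise DataError("matrix carries no quality values")
    df = pd.DataFrame(
        matrix.quals.T,
        index=[_site_label(k) for k in matrix.sites],
        columns=matrix.samples,
    )
    df.to_csv(path, sep="\t", index_label="site", float_format="%.3f")


def read_quals(path, matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Attach a quality TSV to a matrix read from VCF (order-aligned by site
    label and sample id)."""
    df = pd.read_csv(path, sep="\t", index_col="site")
    labels = [_site_label(k) for k in matrix.sites]
    try:
        quals = df.loc[labels, matrix.samples].to_numpy(float).T
    except KeyError as exc:
        raise DataError(f"quality TSV does not cover the matrix: {exc}")
    return GenotypeMatrix(
        samples=matrix.samples, sites=matrix.sites, calls=matrix.calls, quals=quals
    )


def read_hgmd_table(path) -> pd.DataFrame:
    """HGMD-style lookup TSV (chrom, pos 1-based, ref, alt) → 0-based frame."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise FormatError(f"HGMD table requires columns {sorted(required)}")
    df = df.copy()
    df["pos"] = df["pos"].astype(int) - 1
    return df


def read_gene_scores(path) -> dict[str, float]:
    """External gene-score TSV: a symbol column (gene / gene_name / name) and
    a score column (score / grade) with values in [0, 1]."""
    df = pd.read_csv(path, sep="\t")
    sym = next((c for c in ("gene", "gene_name", "name") if c in df.columns), None)
    score = next((c for c in ("score", "grade") if c in df.columns), None)
    if sym is None or score is None:
        raise FormatError("gene-score TSV needs a symbol and a score column")
    out = {}
    for _, row in df.iterrows():
        value = float(row[score])
        if not (0.0 <= value <= 1.0):
            raise DataError(f"gene score {value} outside [0, 1] for {row[sym]}")
        out[str(row[sym])] = value
    return out


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def write_cohort(cohort, out_dir) -> dict[str, Path]:
    """Write a synthetic cohort as phenotypes.csv / variants.tsv /
    genotypes.vcf / quals.tsv / truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": out / "phenotypes.csv",
        "annotation": out / "variants.tsv",
        "vcf": out / "genotypes.vcf",
        "quals": out / "quals.tsv",
        "truth": out / "truth.json",
    }
    write_phenotypes(cohort.phenotypes, paths["phenotypes"])
    write_annotation_table(cohort.variants, paths["annotation"])
    write_vcf(cohort.genotypes, paths["vcf"])
    write_quals(cohort.genotypes, paths["quals"])
    write_truth(cohort.truth, paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# Report writers

def write_gene_table(rows, path) -> None:
    """Ranked gene table in the standard burden layout."""
    records = []
    for r in rows:
        rate = str(r.rate) if isinstance(r.rate, int) else f"{r.rate:.3f}"
        records.append(
            {
                "gene": r.gene,
                "snv_number": r.snv_count,
                "mutation_samples": r.carrier_samples,
                "total_A": r.counts_total[0],
                "total_B": r.counts_total[1],
                "total_C": r.counts_total[2],
                "extreme_A": r.counts_extreme[0],
                "extreme_B": r.counts_extreme[1],
                "extreme_C": r.counts_extreme[2],
                "control_A": r.counts_control[0],
                "control_B": r.counts_control[1],
                "control_C": r.counts_control[2],
                "mutation_rate": rate,
                "p": f"{r.p:.5f}",
            }
        )
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pipeline

@dataclass
class PipelineConfig:
    """One document configuring an end-to-end run.

    Either ``simulate`` (a SimulationConfig, possibly given as a dict in
    YAML) or the input paths must be provided.  The pipeline seed overrides
    the simulation seed so one number reproduces the whole run.
    """

    out_dir: str = "extremoseq_out"
    seed: int = 0
    tg_threshold: float = 0.45
    n_extreme: int | None = None
    n_control: int | None = None
    matching: bool = True
    top_k: int = 10
    convention: str = "doubling"
    filters: FilterConfig = field(default_factory=FilterConfig)
    simulate: object | None = None
    phenotype_csv: str | None = None
    vcf: str | None = None
    annotation_tsv: str | None = None
    quals_tsv: str | None = None
    hgmd_tsv: str | None = None
    gene_scores_tsv: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        from .synthio import SimulationConfig  # local: avoids import cycle

        if isinstance(self.filters, dict):
            self.filters = FilterConfig(**self.filters)
        if isinstance(self.simulate, dict):
            self.simulate = SimulationConfig(**self.simulate)
        if self.simulate is None:
            needed = {"phenotype_csv": self.phenotype_csv, "vcf": self.vcf,
                      "annotation_tsv": self.annotation_tsv}
            missing = [k for k, v in needed.items() if v is None]
            if missing:
                raise ConfigurationError(
                    f"no simulation block and missing input paths: {missing}"
                )
            for name, p in {**needed, "quals_tsv": self.quals_tsv,
                            "hgmd_tsv": self.hgmd_tsv,
                            "gene_scores_tsv": self.gene_scores_tsv}.items():
                if p is not None and not Path(p).exists():
                    raise ConfigurationError(f"{name} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _config_hash(config: PipelineConfig) -> str:
    text = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute cohort selection → cascade → burden and write all reports.

    Returns a bundle with the design, baseline rows, cascade report, ranked
    rows and output paths.  Outputs: baseline.tsv, cascade_report.tsv,
    cascade_report.json, gene_burden.tsv, manifest.json.
    """
    from . import synthio  # local: avoids import cycle

    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    gene_scores = None
    hgmd = None
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        cohort_data = synthio.generate_cohort(sim)
        phenotypes = cohort_data.phenotypes
        variants = cohort_data.variants
        genotypes = cohort_data.genotypes
    else:
        phenotypes = read_phenotypes(config.phenotype_csv)
        variants = read_annotation_table(config.annotation_tsv)
        genotypes = read_vcf_genotypes(config.vcf)
        if config.quals_tsv:
            genotypes = read_quals(config.quals_tsv, genotypes)
        if config.hgmd_tsv:
            hgmd = read_hgmd_table(config.hgmd_tsv)
    if config.gene_scores_tsv:
        gene_scores = read_gene_scores(config.gene_scores_tsv)

    design = select_extremes(
        phenotypes,
        tg_threshold=config.tg_threshold,
        n_extreme=config.n_extreme,
        n_control=config.n_control,
        matching=config.matching,
    )
    logger.info("cohort: %d extreme / %d control", design.n_extreme, design.n_control)

    rows_baseline = baseline_table(phenotypes, design)
    baseline_frame(rows_baseline).to_csv(out / "baseline.tsv", sep="\t", index=False)

    report = run_cascade(variants, genotypes, config.filters, hgmd_table=hgmd)
    for stage, n_in, n_out in report.stages:
        logger.info("cascade %s: %d -> %d", stage, n_in, n_out)
    report.to_frame().to_csv(out / "cascade_report.tsv", sep="\t", index=False)
    with open(out / "cascade_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)

    gene_to_sites = group_by_gene(report.final)
    burden_rows = gene_burden_table(
        genotypes, design, gene_to_sites,
        gene_scores=gene_scores, convention=config.convention,
    )
    ranked = rank_genes(burden_rows, top_k=config.top_k, gene_scores=gene_scores)
    write_gene_table(ranked, out / "gene_burden.tsv")

    import scipy

    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "versions": {
            "extremoseq": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "n_variants_in": len(variants),
        "n_variants_final": len(report.final),
        "n_genes_tested": len(gene_to_sites),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {
        "design": design,
        "baseline": rows_baseline,
        "cascade_report": report,
        "burden_rows": burden_rows,
        "ranked": ranked,
        "paths": {
            "baseline": out / "baseline.tsv",
            "cascade_report": out / "cascade_report.tsv",
            "gene_burden": out / "gene_burden.tsv",
            "manifest": out / "manifest.json",
        },
    }
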