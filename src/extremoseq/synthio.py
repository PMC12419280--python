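"""Synthetic cohort generator.

Emulates the data consumed by the pipeline — a phenotype table with
group-specific lipid/biochemistry distributions, an annotated variant table
with configurable rare/deleterious proportions, and a genotype matrix with
gene-level carrier enrichment planted at stated per-group carrier
probabilities — so every downstream stage is testable without sequencing
data.

Defaults reproduce the study conditions: 111 extreme-low-TG and 102
normal-TG samples, Table-style group means/SDs for each trait, TG truncated
at the 0.45 mmol/L threshold per group, and three genes planted at carrier
probabilities (0.10 extreme, 0.005 control) among 100 genes over a uniform
background carrier probability of 0.01 identical in both groups.

Randomness: one root seed; child streams (phenotypes=0, variants=1,
genotypes=2) are spawned from it, so each generator is independently
reproducible and equal (seed, config) gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .burden import HET, HOM, MISSING, GenotypeMatrix
from .errors import ConfigurationError
from .varclass import PREDICTORS, AnnotatedVariant

#: Per-group (mean, SD) of each trait; units mmol/L except age (years),
#: creatinine (umol/L) and AST/ALT (U/L).
DEFAULT_LIPID_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"extreme": (20.76, 1.48), "control": (20.91, 1.36)},
    "TG": {"extreme": (0.40, 0.04), "control": (1.43, 0.13)},
    "TC": {"extreme": (3.59, 0.59), "control": (4.71, 0.38)},
    "HDL_C": {"extreme": (1.56, 0.26), "control": (1.28, 0.25)},
    "LDL_C": {"extreme": (1.79, 0.44), "control": (2.93, 0.23)},
    "glucose": {"extreme": (4.88, 0.50), "control": (4.95, 0.50)},
    "creatinine": {"extreme": (73.90, 13.44), "control": (75.11, 13.47)},
    "BUN": {"extreme": (4.64, 1.12), "control": (4.40, 1.05)},
    "AST": {"extreme": (18.69, 4.44), "control": (20.66, 11.08)},
    "ALT": {"extreme": (15.90, 9.17), "control": (26.27, 25.80)},
}

DEFAULT_PLANTED = (
    ("GENE001", 0.10, 0.005, 0.1),
    ("GENE002", 0.10, 0.005, 0.1),
    ("GENE003", 0.10, 0.005, 0.1),
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    ``planted_genes`` holds (gene, p_carrier_extreme, p_carrier_control,
    hom_fraction) tuples; every other gene receives carriers at
    ``background_carrier_p`` identically in both groups.
    """

    n_extreme: int = 111
    n_control: int = 102
    lipid_params: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_LIPID_PARAMS.items()
        }
    )
    male_fraction_extreme: float = 0.477
    male_fraction_control: float = 0.480
    tg_threshold: float = 0.45
    n_genes: int = 100
    sites_per_gene: int = 3
    planted_genes: list = field(default_factory=lambda: [list(t) for t in DEFAULT_PLANTED])
    background_carrier_p: float = 0.01
    background_hom_fraction: float = 0.0
    rare_fraction: float = 0.3
    deleterious_fraction: float = 0.5
    hgmd_fraction: float = 0.02
    lowqual_site_fraction: float = 0.0
    qual_L_fraction: float = 0.0
    homology_zero_fraction: float = 0.0
    missing_rate: float = 0.02
    multi_site_carriers: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_extreme <= 0 or self.n_control <= 0:
            raise ConfigurationError("group sizes must be positive")
        if self.n_genes <= 0 or self.sites_per_gene <= 0:
            raise ConfigurationError("n_genes and sites_per_gene must be positive")
        probs = [
            self.background_carrier_p,
            self.background_hom_fraction,
            self.rare_fraction,
            self.deleterious_fraction,
            self.hgmd_fraction,
            self.lowqual_site_fraction,
            self.qual_L_fraction,
            self.homology_zero_fraction,
            self.missing_rate,
            self.male_fraction_extreme,
            self.male_fraction_control,
        ]
        for gene, p_e, p_c, hom_f in self.planted_genes:
            probs += [p_e, p_c, hom_f]
            if gene not in set(self.gene_names):
                raise ConfigurationError(
                    f"planted gene {gene!r} not among generated genes"
                )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")
        for trait, groups in self.lipid_params.items():
            for group, (_, sd) in groups.items():
                if sd < 0:
                    raise ConfigurationError(f"{trait}/{group}: negative SD")

    @property
    def gene_names(self) -> list[str]:
        return [f"GENE{i + 1:03d}" for i in range(self.n_genes)]


@dataclass
class SyntheticCohort:
    """Bundle of generated tables plus the planted-enrichment truth record."""

    phenotypes: pd.DataFrame
    variants: list[AnnotatedVariant]
    genotypes: GenotypeMatrix
    truth: dict


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Child generator ``stream`` of the root seed (documented stream order:
    0=phenotypes, 1=variants, 2=genotypes)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_phenotypes(config: SimulationConfig) -> pd.DataFrame:
    """Phenotype table with group-specific truncated-normal traits.

    Extreme-group TG is truncated to (0, threshold]; control TG to
    (threshold, inf).  Other traits are truncated at zero.  Sex counts per
    group match the configured male fraction exactly (rounded), with the
    assignment order randomised.
    """
    rng = _rng(config.seed, 0)
    frames = []
    specs = [
        ("extreme", config.n_extreme, config.male_fraction_extreme, 0),
        ("control", config.n_control, config.male_fraction_control, config.n_extreme),
    ]
    for group, n, male_frac, offset in specs:
        data: dict = {
            "sample_id": [f"S{offset + i + 1:04d}" for i in range(n)],
            "group": group,
        }
        n_male = round(n * male_frac)
        sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
        data["sex"] = rng.permutation(sexes)
        for trait, groups in config.lipid_params.items():
            mean, sd = groups[group]
            if trait == "TG":
                lo, hi = (
                    (1e-9, config.tg_threshold)
                    if group == "extreme"
                    else (config.tg_threshold + 1e-9, np.inf)
                )
            else:
                lo, hi = 0.0, np.inf
            data[trait] = _trunc_normal(rng, mean, sd, lo, hi, n)
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


def generate_variants(config: SimulationConfig) -> list[AnnotatedVariant]:
    """Annotated SNV sites, ``sites_per_gene`` per gene on one contig.

    A site is drawn "qualifying-deleterious" with probability
    ``deleterious_fraction`` (exonic or splice region, at least one damaging
    predictor) and "rare" with probability ``rare_fraction`` (all four allele
    frequencies strictly below the cascade caps, some absent); otherwise all
    four frequencies fall in a common range above the caps.
    """
    rng = _rng(config.seed, 1)
    variants: list[AnnotatedVariant] = []
    idx = 0
    nonqualifying_regions = (
        "intronic", "UTR5", "UTR3", "intergenic", "ncRNA_exonic", "upstream",
    )
    for g, gene in enumerate(config.gene_names):
        for j in range(config.sites_per_gene):
            idx += 1
            pos = (g + 1) * 10_000 + j * 100  # 0-based
            ref = rng.choice(_BASES)
            alt = rng.choice([b for b in _BASES if b != ref])
            deleterious = rng.random() < config.deleterious_fraction
            rare = rng.random() < config.rare_fraction

            predictions = {name: "tolerated" for name in PREDICTORS}
            if deleterious:
                region = "exonic" if rng.random() < 0.9 else "splicing"
                n_damaging = 1 + rng.integers(0, 5)
                order = rng.permutation(5)  # dbscSNV excluded: splice-only
                for k in order[:n_damaging]:
                    predictions[PREDICTORS[k]] = "damaging"
                if region == "splicing":
                    predictions["dbscSNV"] = "damaging"
                func_class = "nonsynonymous" if rng.random() < 0.95 else "stopgain"
            else:
                if rng.random() < 0.5:
                    region = "exonic"
                    func_class = "synonymous"
                else:
                    region = str(rng.choice(nonqualifying_regions))
                    func_class = "unknown"

            if rare:
                freqs = {
                    "freq_1kg": rng.uniform(0, 0.001),
                    "freq_esp6500": rng.uniform(0, 0.01),
                    "freq_selfctrl": rng.uniform(0, 0.01),
                    "freq_tianhao": rng.uniform(0, 0.005),
                }
                for name in list(freqs):
                    if rng.random() < 0.2:
                        freqs[name] = None
            else:
                base = rng.uniform(0.05, 0.5)
                freqs = {
                    name: float(np.clip(base + rng.normal(0, 0.01), 0.02, 1.0))
                    for name in (
                        "freq_1kg", "freq_esp6500", "freq_selfctrl", "freq_tianhao"
                    )
                }

            variants.append(
                AnnotatedVariant(
                    chrom="1",
                    pos=int(pos),
                    ref=str(ref),
                    alt=str(alt),
                    gene=gene,
                    region=region,
                    func_class=func_class,
                    predictions=predictions,
                    hgmd_id=(
                        f"CM{idx:06d}" if rng.random() < config.hgmd_fraction else None
                    ),
                    site_qual=float(np.clip(rng.normal(60, 10), 1, None)),
                    qual_class=("L" if rng.random() < config.qual_L_fraction else "M"),
                    homology=(
                        0 if rng.random() < config.homology_zero_fraction else 1
                    ),
                    **freqs,
                )
            )
    return variants


def generate_genotypes(
    config: SimulationConfig,
    variants: Sequence[AnnotatedVariant],
    phenotypes: pd.DataFrame,
) -> GenotypeMatrix:
    """Genotype matrix with planted per-group carrier enrichment.

    For each planted gene a sample becomes a carrier with its group's
    probability; carriers are hom with the gene's ``hom_fraction``, else het,
    at one uniformly chosen site of the gene (or at extra sites when
    ``multi_site_carriers``).  Non-planted genes use the background carrier
    probability identically in both groups.  Missing calls are inserted
    independently at ``missing_rate``; per-call Phred qualities are drawn
    around 60 except at "low-quality" sites (fraction
    ``lowqual_site_fraction``), whose calls centre near Phred 10.
    """
    rng = _rng(config.seed, 2)
    planted = {g: (p_e, p_c, h) for g, p_e, p_c, h in config.planted_genes}
    for gene in planted:
        if not any(v.gene == gene for v in variants):
            raise ConfigurationError(f"planted gene {gene!r} absent from variants")

    samples = list(phenotypes["sample_id"])
    n_samples = len(samples)
    is_extreme = (phenotypes["group"] == "extreme").to_numpy()
    sites = [v.key for v in variants]
    calls = np.zeros((n_samples, len(sites)), dtype=np.int8)

    gene_cols: dict[str, list[int]] = {}
    for j, v in enumerate(variants):
        gene_cols.setdefault(v.gene, []).append(j)

    for gene, cols in gene_cols.items():
        cols_arr = np.array(cols)
        if gene in planted:
            p_e, p_c, hom_f = planted[gene]
        else:
            p_e = p_c = config.background_carrier_p
            hom_f = config.background_hom_fraction
        p = np.where(is_extreme, p_e, p_c)
        carrier = rng.random(n_samples) < p
        hom = rng.random(n_samples) < hom_f
        site_choice = rng.integers(0, len(cols_arr), size=n_samples)
        extra = (
            rng.random((n_samples, len(cols_arr))) < 0.2
            if config.multi_site_carriers
            else None
        )
        rows = np.nonzero(carrier)[0]
        code = np.where(hom[rows], HOM, HET).astype(np.int8)
        calls[rows, cols_arr[site_choice[rows]]] = code
        if extra is not None:
            for i, r in enumerate(rows):
                for k in np.nonzero(extra[r])[0]:
                    calls[r, cols_arr[k]] = max(calls[r, cols_arr[k]], code[i])

    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls[miss] = MISSING

    quals = rng.normal(60, 15, size=calls.shape).clip(min=0.0)
    if config.lowqual_site_fraction > 0:
        lowqual_sites = rng.random(len(sites)) < config.lowqual_site_fraction
        quals[:, lowqual_sites] = rng.normal(
            10, 3, size=(n_samples, int(lowqual_sites.sum()))
        ).clip(min=0.0)

    return GenotypeMatrix(samples=samples, sites=sites, calls=calls, quals=quals)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort (phenotypes, variants, genotypes)."""
    phenotypes = generate_phenotypes(config)
    variants = generate_variants(config)
    genotypes = generate_genotypes(config, variants, phenotypes)
    truth = {
        "seed": config.seed,
        "planted": {
            g: {
                "p_carrier_extreme": p_e,
                "p_carrier_control": p_c,
                "hom_fraction": h,
            }
            for g, p_e, p_c, h in config.planted_genes
        },
        "background_carrier_p": config.background_carrier_p,
        "n_extreme": config.n_extreme,
        "n_control": config.n_control,
    }
    return SyntheticCohort(
        phenotypes=phenotypes, variants=variants, genotypes=genotypes, truth=truth
    )
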