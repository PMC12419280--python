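"""The low-frequency functional-variant prioritization cascade.

Ordered gates applied to annotated variants:

1. **HGMD flag** — known/novel lookup against a disease-mutation table.
   Annotation only; membership never removes a variant.
2. **Deleteriousness** — keep exonic or splice-affecting variants with at
   least ``min_predictors_damaging`` of the six predictors (SIFT, PolyPhen2,
   MutationTaster, CADD, DANN, dbscSNV) calling damage; dbscSNV counts only
   for splice-affecting sites.
3. **Frequency** — keep variants *strictly* below every configured allele-
   frequency cap (1000 Genomes 0.001; ESP6500 0.01; self-controls 0.01;
   internal reference database 0.005).  An absent frequency passes iff
   ``treat_missing_freq_as_rare``.
4. **Quality** — keep sites where the fraction of samples with call quality
   below the Phred threshold is at most ``max_lowqual_sample_fraction``, the
   site's quality letter grade is not the excluded class, and the homology
   flag matches.

The caps select *rare* variants (below the thresholds): this is the only
reading consistent with a study of low-frequency variants, and the final
gene tables require it.  Gates are independent predicates, so the surviving
set does not depend on stage order; the per-stage attrition report does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .varclass import EXONIC_OR_SPLICE, AnnotatedVariant


@dataclass
class FilterConfig:
    """Every threshold of the prioritization cascade.

    A frequency cap of ``None`` disables that cap; ``qual_threshold=None``
    disables the quality gate; ``require_homology=None`` disables the
    homology check.
    """

    max_freq_1kg: float | None = 0.001
    max_freq_selfctrl: float | None = 0.01
    max_freq_esp6500: float | None = 0.01
    max_freq_tianhao: float | None = 0.005
    min_predictors_damaging: int = 1
    require_region: bool = True
    qual_threshold: float | None = 20.0
    max_lowqual_sample_fraction: float = 0.50
    exclude_qual_class: str | None = "L"
    require_homology: int | None = 1
    treat_missing_freq_as_rare: bool = True

    def __post_init__(self) -> None:
        for name in ("max_freq_1kg", "max_freq_selfctrl", "max_freq_esp6500",
                     "max_freq_tianhao"):
            cap = getattr(self, name)
            if cap is not None and not (0.0 <= cap <= 1.0):
                raise ConfigurationError(f"{name}={cap} outside [0, 1]")
        if not (0.0 <= self.max_lowqual_sample_fraction <= 1.0):
            raise ConfigurationError("max_lowqual_sample_fraction outside [0, 1]")
        if self.min_predictors_damaging < 0:
            raise ConfigurationError("min_predictors_damaging must be >= 0")

    @classmethod
    def disabled(cls) -> "FilterConfig":
        """A configuration with every gate switched off (identity cascade)."""
        return cls(
            max_freq_1kg=None,
            max_freq_selfctrl=None,
            max_freq_esp6500=None,
            max_freq_tianhao=None,
            min_predictors_damaging=0,
            require_region=False,
            qual_threshold=None,
            exclude_qual_class=None,
            require_homology=None,
        )


@dataclass
class CascadeReport:
    """Per-stage attrition plus the surviving and HGMD-known variant lists."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)
    final: list[AnnotatedVariant] = field(default_factory=list)
    hgmd_known: list[AnnotatedVariant] = field(default_factory=list)

    def record(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise DataError(f"stage {name}: out ({n_out}) exceeds in ({n_in})")
        self.stages.append((name, n_in, n_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"stage": s, "variants_in": i, "variants_out": o, "removed": i - o}
                for s, i, o in self.stages
            ]
        )

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"stage": s, "variants_in": i, "variants_out": o}
                for s, i, o in self.stages
            ],
            "n_final": len(self.final),
            "n_hgmd_known": len(self.hgmd_known),
        }


def _as_key_set(hgmd_table) -> tuple[set, int]:
    """Normalise an HGMD lookup to a set of (chrom, pos, ref, alt) keys."""
    keys: set = set()
    skipped = 0
    if hgmd_table is None:
        return keys, 0
    if isinstance(hgmd_table, pd.DataFrame):
        rows: Iterable = hgmd_table[["chrom", "pos", "ref", "alt"]].itertuples(
            index=False
        )
    else:
        rows = hgmd_table
    for row in rows:
        try:
            chrom, pos, ref, alt = row
            keys.add((str(chrom), int(pos), str(ref), str(alt)))
        except (ValueError, TypeError):
            skipped += 1
    return keys, skipped


def flag_hgmd(
    variants: Sequence[AnnotatedVariant], hgmd_table
) -> list[AnnotatedVariant]:
    """Flag variants present in the disease-mutation lookup as known.

    The flag is annotation only — no variant is removed.  Malformed lookup
    rows are skipped with a single warning carrying the count.
    """
    keys, skipped = _as_key_set(hgmd_table)
    if skipped:
        warnings.warn(f"flag_hgmd: skipped {skipped} malformed lookup rows")
    return [replace(v, hgmd_known=v.key in keys) for v in variants]


def deleteriousness_filter(
    variants: Sequence[AnnotatedVariant], config: FilterConfig
) -> list[AnnotatedVariant]:
    """Keep exonic/splice-affecting variants with enough damaging calls."""
    out = []
    for v in variants:
        if config.require_region and v.region not in EXONIC_OR_SPLICE:
            continue
        if v.damaging_count() < config.min_predictors_damaging:
            continue
        out.append(v)
    return out


def frequency_filter(
    variants: Sequence[AnnotatedVariant], config: FilterConfig
) -> list[AnnotatedVariant]:
    """Keep variants strictly below every configured allele-frequency cap."""
    caps = (
        ("freq_1kg", config.max_freq_1kg),
        ("freq_esp6500", config.max_freq_esp6500),
        ("freq_selfctrl", config.max_freq_selfctrl),
        ("freq_tianhao", config.max_freq_tianhao),
    )
    out = []
    for v in variants:
        keep = True
        for name, cap in caps:
            if cap is None:
                continue
            freq = getattr(v, name)
            if freq is None:
                if not config.treat_missing_freq_as_rare:
                    keep = False
                    break
                continue
            if not (0.0 <= freq <= 1.0):
                raise DataError(
                    f"{name}={freq} outside [0, 1] at {v.chrom}:{v.pos + 1}"
                )
            if freq >= cap:
                keep = False
                break
        if keep:
            out.append(v)
    return out


def quality_filter(
    variants: Sequence[AnnotatedVariant],
    genotype_quals,
    config: FilterConfig,
) -> list[AnnotatedVariant]:
    """Site-quality gate: low-quality sample fraction, letter grade, homology.

    ``genotype_quals`` maps (chrom, pos, ref, alt) to a per-sample quality
    array, or is a GenotypeMatrix carrying a ``quals`` matrix.
    """
    if config.qual_threshold is not None:
        if genotype_quals is None:
            raise ConfigurationError("quality gate enabled but no quality matrix")
        if hasattr(genotype_quals, "site_quals"):
            genotype_quals = genotype_quals.site_quals()
    out = []
    for v in variants:
        if config.qual_threshold is not None:
            quals = genotype_quals.get(v.key)
            if quals is None:
                raise ConfigurationError(
                    f"no per-sample qualities for site {v.key}"
                )
            frac_low = float(np.mean(np.asarray(quals) < config.qual_threshold))
            if frac_low > config.max_lowqual_sample_fraction:
                continue
        if config.exclude_qual_class is not None and (
            v.qual_class == config.exclude_qual_class
        ):
            continue
        if config.require_homology is not None and v.homology != config.require_homology:
            continue
        out.append(v)
    return out


def run_cascade(
    variants: Sequence[AnnotatedVariant],
    genotype_quals,
    config: FilterConfig,
    hgmd_table=None,
) -> CascadeReport:
    """Run the full ordered cascade and report per-stage attrition."""
    report = CascadeReport()
    flagged = flag_hgmd(variants, hgmd_table)
    report.record("hgmd_flag", len(variants), len(flagged))
    report.hgmd_known = [v for v in flagged if v.hgmd_known]

    current = deleteriousness_filter(flagged, config)
    report.record("deleteriousness", len(flagged), len(current))

    after_freq = frequency_filter(current, config)
    report.record("frequency", len(current), len(after_freq))

    final = quality_filter(after_freq, genotype_quals, config)
    report.record("quality", len(after_freq), len(final))

    report.final = final
    return report


def group_by_gene(
    variants: Sequence[AnnotatedVariant],
) -> Mapping[str, list[tuple[str, int, str, str]]]:
    """Surviving site keys grouped by gene symbol, in first-seen order."""
    out: dict[str, list] = {}
    for v in variants:
        out.setdefault(v.gene, []).append(v.key)
    return out
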