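"""Variant region and functional-class taxonomy.

Every annotated exome variant is placed into exactly one of fifteen region
categories — eleven single-gene labels (exonic, splicing, ncRNA_exonic,
ncRNA_splicing, UTR5, UTR3, intronic, ncRNA_intronic, upstream, downstream,
intergenic) plus four compound cross-gene labels (``UTR5/UTR3``,
``exonic/splicing``, ``splicing/ncRNA_exonic``, ``upstream/downstream``) that
arise when a site falls in two overlapping genes with those paired roles.
Exonic variants of protein-coding genes are further assigned one of nine
functional classes by their effect on the coding sequence, and InDels are
summarised into a signed length-distribution table.

Coordinates are 0-based half-open internally; VCF positions (1-based) are
converted at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .errors import ClassificationError, DataError

#: Predictor columns consumed (never computed) from upstream annotation.
PREDICTORS = ("SIFT", "PolyPhen2", "MutationTaster", "CADD", "DANN", "dbscSNV")

#: The four compound cross-gene categories, keyed by the unordered label pair.
COMPOUND_CATEGORIES = {
    frozenset({"UTR5", "UTR3"}): "UTR5/UTR3",
    frozenset({"exonic", "splicing"}): "exonic/splicing",
    frozenset({"splicing", "ncRNA_exonic"}): "splicing/ncRNA_exonic",
    frozenset({"upstream", "downstream"}): "upstream/downstream",
}

#: Severity precedence for resolving multi-gene conflicts that are not one of
#: the four compound categories (most severe first).  ncRNA_splicing is slotted
#: directly after ncRNA_exonic, mirroring the coding-gene ordering.
REGION_PRECEDENCE = (
    "exonic",
    "splicing",
    "ncRNA_exonic",
    "ncRNA_splicing",
    "UTR5",
    "UTR3",
    "intronic",
    "ncRNA_intronic",
    "upstream",
    "downstream",
)

REGION_CATEGORIES = REGION_PRECEDENCE + ("intergenic",) + tuple(
    COMPOUND_CATEGORIES.values()
)

#: Region labels that satisfy the "exonic or splice-affecting" gate of the
#: prioritization cascade.
EXONIC_OR_SPLICE = frozenset(
    {"exonic", "splicing", "exonic/splicing", "splicing/ncRNA_exonic"}
)

SPLICE_AFFECTING = frozenset(
    {"splicing", "ncRNA_splicing", "exonic/splicing", "splicing/ncRNA_exonic"}
)

FUNC_CLASSES = (
    "stoploss",
    "frameshift insertion",
    "nonframeshift insertion",
    "frameshift deletion",
    "stopgain",
    "nonframeshift deletion",
    "synonymous",
    "nonsynonymous",
    "unknown",
)

_FREQ_FIELDS = ("freq_1kg", "freq_esp6500", "freq_selfctrl", "freq_tianhao")


@dataclass
class AnnotatedVariant:
    """One annotated variant site.

    ``pos`` is the 0-based position of the first reference base.  Frequency
    fields are allele frequencies in [0, 1] or ``None`` when the database has
    no entry.  ``predictions`` maps each of the six predictor names to
    ``"damaging"``, ``"tolerated"`` or ``None`` (absent).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    region: str = "exonic"
    func_class: str = "unknown"
    predictions: dict = field(default_factory=dict)
    freq_1kg: float | None = None
    freq_esp6500: float | None = None
    freq_selfctrl: float | None = None
    freq_tianhao: float | None = None
    hgmd_id: str | None = None
    site_qual: float = 0.0
    qual_class: str = "M"
    homology: int = 1
    hgmd_known: bool = False

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise DataError(f"negative position for variant {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise DataError(
                f"ref == alt ({self.ref}) at {self.chrom}:{self.pos + 1}"
            )
        if self.region not in REGION_CATEGORIES:
            raise DataError(f"unknown region category {self.region!r}")
        for name in _FREQ_FIELDS:
            value = getattr(self, name)
            if value is not None and not (0.0 <= value <= 1.0):
                raise DataError(
                    f"{name}={value} outside [0, 1] at {self.chrom}:{self.pos + 1}"
                )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """(chrom, pos, ref, alt) identity used for genotype/quality lookup."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def indel_length(self) -> int:
        """Signed length: insertions positive, deletions negative, SNVs zero."""
        return len(self.alt) - len(self.ref)

    def damaging_count(self, splice_only_dbscsnv: bool = True) -> int:
        """Number of predictors calling this variant damaging.

        dbscSNV is a splice-site predictor; by default its call counts only
        for splice-affecting regions.
        """
        n = 0
        for name in PREDICTORS:
            if self.predictions.get(name) != "damaging":
                continue
            if (
                splice_only_dbscsnv
                and name == "dbscSNV"
                and self.region not in SPLICE_AFFECTING
            ):
                continue
            n += 1
        return n


@dataclass
class GeneModel:
    """Minimal transcript model: sorted non-overlapping exons, CDS within exons.

    Intervals are 0-based half-open on the forward genomic strand; ``strand``
    only affects which flank is upstream and the reading direction of the CDS.
    """

    name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    coding: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"gene {self.name}: strand must be '+' or '-'")
        if not self.exons:
            raise DataError(f"gene {self.name}: no exons")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s, e) in self.exons:
            if s >= e:
                raise DataError(f"gene {self.name}: empty exon interval {(s, e)}")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise DataError(f"gene {self.name}: overlapping exons")
        self.cds = sorted(tuple(c) for c in self.cds)
        for (s, e) in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise DataError(f"gene {self.name}: CDS interval {(s, e)} not in exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.cds)


def _pos_of(variant) -> tuple[str, int]:
    if hasattr(variant, "chrom"):
        return variant.chrom, variant.pos
    chrom, pos = variant
    return chrom, pos


def _single_gene_label(model: GeneModel, pos: int, splice_window: int, flank: int):
    """Region label of ``pos`` with respect to one gene, or None if out of range."""
    if pos < model.start:
        if pos < model.start - flank:
            return None
        return "upstream" if model.strand == "+" else "downstream"
    if pos >= model.end:
        if pos >= model.end + flank:
            return None
        return "downstream" if model.strand == "+" else "upstream"

    if model.in_exon(pos):
        if not model.coding:
            return "ncRNA_exonic"
        if model.in_cds(pos):
            return "exonic"
        if not model.cds:
            return "exonic"
        cds_start = model.cds[0][0]
        cds_end = model.cds[-1][1]
        if pos < cds_start:
            return "UTR5" if model.strand == "+" else "UTR3"
        if pos >= cds_end:
            return "UTR3" if model.strand == "+" else "UTR5"
        return "exonic"

    # Intronic side: splice region = within splice_window of an exon boundary.
    near_boundary = any(
        (0 < s - pos <= splice_window) or (0 < pos - (e - 1) <= splice_window)
        for s, e in model.exons
    )
    if near_boundary:
        return "splicing" if model.coding else "ncRNA_splicing"
    return "intronic" if model.coding else "ncRNA_intronic"


def classify_region(
    variant,
    gene_models: Sequence[GeneModel],
    splice_window: int = 2,
    flank: int = 1000,
) -> str:
    """Assign the region category of a variant against a set of gene models.

    Per overlapping gene the variant receives that gene's label; conflicting
    labels across genes resolve to one of the four compound categories when
    the label pair matches, otherwise to the most severe single label.  A
    position with no gene within ``flank`` bases is intergenic.

    Raises :class:`ClassificationError` for a chromosome absent from every
    gene model.
    """
    chrom, pos = _pos_of(variant)
    chrom_models = [m for m in gene_models if m.chrom == chrom]
    if not chrom_models:
        raise ClassificationError(f"unknown chromosome {chrom!r}: no gene models")
    labels = set()
    for model in chrom_models:
        label = _single_gene_label(model, pos, splice_window, flank)
        if label is not None:
            labels.add(label)
    if not labels:
        return "intergenic"
    if len(labels) == 2:
        compound = COMPOUND_CATEGORIES.get(frozenset(labels))
        if compound is not None:
            return compound
    for label in REGION_PRECEDENCE:
        if label in labels:
            return label
    raise ClassificationError(f"unresolvable labels {labels} at {chrom}:{pos}")


def _cds_offset(model: GeneModel, pos: int) -> int | None:
    """Offset of genomic ``pos`` within the spliced CDS, reading 5'→3'."""
    forward = 0
    found = False
    for s, e in model.cds:
        if s <= pos < e:
            forward += pos - s
            found = True
            break
        forward += e - s
    if not found:
        return None
    if model.strand == "+":
        return forward
    total = sum(e - s for s, e in model.cds)
    return total - 1 - forward


def _spliced_cds(model: GeneModel, chrom_seq: str) -> str:
    seq = "".join(chrom_seq[s:e] for s, e in model.cds)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def classify_function(
    variant,
    gene_models: Sequence[GeneModel] | GeneModel,
    chrom_seqs: Mapping[str, str] | None = None,
) -> str:
    """Functional class of an exonic variant of a protein-coding gene.

    Insertions and deletions are frameshift iff the signed length difference
    is not a multiple of three.  Single-base substitutions are translated in
    their codon context (standard genetic code) and classed synonymous /
    nonsynonymous / stopgain / stoploss.  Any context that cannot be
    translated — no CDS hit, no reference sequence, a truncated codon, or a
    multi-base substitution — yields ``"unknown"`` rather than an exception.
    """
    if isinstance(gene_models, GeneModel):
        gene_models = [gene_models]
    chrom, pos = _pos_of(variant)
    ref, alt = variant.ref, variant.alt

    diff = len(alt) - len(ref)
    if diff > 0:
        return "frameshift insertion" if diff % 3 else "nonframeshift insertion"
    if diff < 0:
        return "frameshift deletion" if (-diff) % 3 else "nonframeshift deletion"
    if len(ref) != 1:
        return "unknown"

    gene = getattr(variant, "gene", "")
    candidates = [
        m
        for m in gene_models
        if m.chrom == chrom and m.coding and m.in_cds(pos)
        and (not gene or m.name == gene)
    ]
    if not candidates or chrom_seqs is None or chrom not in chrom_seqs:
        return "unknown"
    model = candidates[0]
    chrom_seq = chrom_seqs[chrom]

    offset = _cds_offset(model, pos)
    if offset is None:
        return "unknown"
    cds = _spliced_cds(model, chrom_seq)
    base_ref, base_alt = ref, alt
    if model.strand == "-":
        base_ref = str(Seq(ref).reverse_complement())
        base_alt = str(Seq(alt).reverse_complement())
    if offset >= len(cds) or cds[offset].upper() != base_ref.upper():
        return "unknown"
    codon_idx = offset // 3
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    if len(codon) < 3:
        return "unknown"
    within = offset % 3
    alt_codon = codon[:within] + base_alt + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "stopgain"
    if aa_ref == "*":
        return "stoploss"
    return "nonsynonymous"


#: Table bins for the InDel length distribution, in report order.
INDEL_BINS = (
    ("1-5", 1, 5),
    ("6-10", 6, 10),
    ("11-15", 11, 15),
    ("16-20", 16, 20),
    (">20", 21, math.inf),
    ("-5 to -1", -5, -1),
    ("-10 to -6", -10, -6),
    ("-15 to -11", -15, -11),
    ("-20 to -16", -20, -16),
    ("<-20", -math.inf, -21),
)


def indel_length_table(variants: Iterable) -> pd.DataFrame:
    """Bin signed InDel lengths into the ten standard report bins.

    Accepts AnnotatedVariants or plain signed integer lengths.  Zero-length
    rows (SNVs) are excluded from the table and counted in
    ``df.attrs["n_snv_excluded"]``.  Percentages are reported to 2 decimals.
    """
    lengths = []
    n_snv = 0
    for v in variants:
        d = v.indel_length if hasattr(v, "indel_length") else int(v)
        if d == 0:
            n_snv += 1
        else:
            lengths.append(d)
    counts = {name: 0 for name, _, _ in INDEL_BINS}
    for d in lengths:
        for name, lo, hi in INDEL_BINS:
            if lo <= d <= hi:
                counts[name] += 1
                break
    total = len(lengths)
    df = pd.DataFrame(
        {
            "bin": [name for name, _, _ in INDEL_BINS],
            "count": [counts[name] for name, _, _ in INDEL_BINS],
        }
    )
    df["percent"] = (
        (100.0 * df["count"] / total).round(2) if total else 0.0
    )
    df.attrs["n_snv_excluded"] = n_snv
    return df
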