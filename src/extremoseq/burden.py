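"""Gene-level carrier collapsing, the carrier-rate-ratio statistic, and the
two-sided exact test.

Genotypes at the variants surviving prioritization are collapsed per gene
into per-group (A, B, C) triples — wild-type, heterozygous-carrier,
homozygous-carrier sample counts.  A *carrier* is a sample that is het or hom
at any surviving site of the gene; a sample whose calls are all missing for a
gene is excluded from that gene's table.  Genes are ranked by a two-sided
exact test on the 2x2 carrier table, with the carrier-rate ratio

    rate = (carriers_extreme / n_extreme) / (carriers_control / n_control)

reported alongside.  The ratio is truncated (not rounded) to three decimals;
when the control group has no carriers the extreme-group carrier count itself
is reported in its place (the zero-control convention of the source tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .errors import DataError

# Genotype call codes.
WILD, HET, HOM, MISSING = 0, 1, 2, -1

SiteKey = tuple[str, int, str, str]


@dataclass
class GenotypeMatrix:
    """Per-sample, per-site diploid calls.

    ``calls`` is an int8 array of shape (n_samples, n_sites) holding the
    codes WILD/HET/HOM/MISSING.  ``quals`` optionally carries per-call
    Phred-scaled qualities of the same shape.
    """

    samples: list[str]
    sites: list[SiteKey]
    calls: np.ndarray
    quals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise DataError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.sites)})"
            )
        if self.quals is not None:
            self.quals = np.asarray(self.quals, dtype=float)
            if self.quals.shape != self.calls.shape:
                raise DataError("quals shape differs from calls shape")
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._site_index = {k: j for j, k in enumerate(self.sites)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_rows(self, sample_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._sample_index[s] for s in sample_ids])
        except KeyError as exc:
            raise DataError(f"sample {exc.args[0]!r} absent from genotype matrix")

    def site_cols(self, keys: Sequence[SiteKey]) -> np.ndarray:
        try:
            return np.array([self._site_index[k] for k in keys])
        except KeyError as exc:
            raise DataError(f"site {exc.args[0]!r} absent from genotype matrix")

    def site_quals(self) -> dict[SiteKey, np.ndarray]:
        """Per-site arrays of per-sample qualities (for the quality gate)."""
        if self.quals is None:
            return {}
        return {k: self.quals[:, j] for k, j in self._site_index.items()}


@dataclass
class GeneBurdenRow:
    """One ranked-table row: per-gene counts, rate statistic, and p-value."""

    gene: str
    snv_count: int
    carrier_samples: int
    counts_total: tuple[int, int, int]
    counts_extreme: tuple[int, int, int]
    counts_control: tuple[int, int, int]
    rate: float
    p: float
    gene_score: float | None = None

    def __post_init__(self) -> None:
        for e, c, t in zip(self.counts_extreme, self.counts_control, self.counts_total):
            if e + c != t:
                raise DataError(
                    f"gene {self.gene}: group counts do not sum to totals"
                )
        if any(x < 0 for t in (self.counts_total,) for x in t):
            raise DataError(f"gene {self.gene}: negative counts")
        if not (0.0 <= self.p <= 1.0):
            raise DataError(f"gene {self.gene}: p={self.p} outside [0, 1]")


def _collapse_calls(sub: np.ndarray) -> tuple[int, int, int, int]:
    """Collapse an (n_samples, n_sites) call block to (A, B, C, n_excluded)."""
    any_hom = (sub == HOM).any(axis=1)
    any_het = (sub == HET).any(axis=1)
    all_missing = (sub == MISSING).all(axis=1)
    c = int((any_hom & ~all_missing).sum())
    b = int((any_het & ~any_hom & ~all_missing).sum())
    excluded = int(all_missing.sum())
    a = sub.shape[0] - b - c - excluded
    return a, b, c, excluded


def collapse_gene(
    genotypes: GenotypeMatrix,
    design,
    gene_sites: Sequence[SiteKey],
) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    """Per-group (A, B, C) triples for one gene.

    A sample is C if hom at any site, else B if het at any site, else A;
    samples missing at every site of the gene are excluded from its table.
    """
    if not gene_sites:
        raise DataError("collapse_gene requires at least one site")
    cols = genotypes.site_cols(gene_sites)
    out = []
    for ids in (design.extreme_ids, design.control_ids):
        rows = genotypes.sample_rows(ids)
        a, b, c, _ = _collapse_calls(genotypes.calls[np.ix_(rows, cols)])
        out.append((a, b, c))
    return out[0], out[1]


def carrier_rate_statistic(
    extreme: tuple[int, int, int], control: tuple[int, int, int]
) -> float | int:
    """Carrier-rate ratio between groups from (A, B, C) triples.

    Carriers are B + C per group.  With control carriers present the ratio of
    per-group carrier frequencies is truncated to three decimals (exact
    integer arithmetic, so e.g. 1111/216 reports 5.143, not 5.144).  With
    zero control carriers the extreme-group carrier count is returned.
    """
    n_e, n_c = sum(extreme), sum(control)
    if n_e <= 0 or n_c <= 0:
        raise DataError("carrier_rate_statistic: empty group")
    if any(x < 0 for x in extreme + control):
        raise DataError("carrier_rate_statistic: negative counts")
    carriers_e = extreme[1] + extreme[2]
    carriers_c = control[1] + control[2]
    if carriers_c == 0:
        return carriers_e
    return (1000 * carriers_e * n_c // (carriers_c * n_e)) / 1000


def fisher_two_sided(
    extreme: tuple[int, int],
    control: tuple[int, int],
    convention: str = "doubling",
) -> float:
    """Two-sided exact p-value for a 2x2 (carriers, non-carriers) table.

    Under the hypergeometric null the one-sided tail of the observed or more
    extreme carrier split is computed; the default ``"doubling"`` convention
    doubles the smaller tail and caps at 1.  ``"minlike"`` instead sums the
    probabilities of all outcomes no more likely than the observed one (the
    convention of most software defaults).
    """
    k1, m1 = extreme
    k2, m2 = control
    if min(k1, m1, k2, m2) < 0:
        raise DataError("fisher_two_sided: negative cell")
    n = k1 + m1  # extreme-group size (row margin)
    big_n = n + k2 + m2
    big_k = k1 + k2  # total carriers (column margin)
    if big_n == 0 or big_k == 0 or big_k == big_n or n == 0 or n == big_n:
        return 1.0
    dist = hypergeom(big_n, big_k, n)
    lower = float(dist.cdf(k1))
    upper = float(dist.sf(k1 - 1))
    if convention == "doubling":
        return min(1.0, 2.0 * min(lower, upper))
    if convention == "minlike":
        k_lo = max(0, n - (big_n - big_k))
        k_hi = min(n, big_k)
        ks = np.arange(k_lo, k_hi + 1)
        pmf = dist.pmf(ks)
        cutoff = dist.pmf(k1) * (1 + 1e-7)
        return float(min(1.0, pmf[pmf <= cutoff].sum()))
    raise ValueError(f"unknown convention {convention!r}")


def gene_burden_table(
    genotypes: GenotypeMatrix,
    design,
    gene_to_sites: Mapping[str, Sequence[SiteKey]],
    gene_scores: Mapping[str, float] | None = None,
    convention: str = "doubling",
) -> list[GeneBurdenRow]:
    """Collapse and test every gene; returns unranked rows."""
    rows = []
    for gene, sites in gene_to_sites.items():
        ext, ctl = collapse_gene(genotypes, design, sites)
        total = tuple(e + c for e, c in zip(ext, ctl))
        carriers_e, non_e = ext[1] + ext[2], ext[0]
        carriers_c, non_c = ctl[1] + ctl[2], ctl[0]
        rows.append(
            GeneBurdenRow(
                gene=gene,
                snv_count=len(sites),
                carrier_samples=total[1] + total[2],
                counts_total=total,
                counts_extreme=ext,
                counts_control=ctl,
                rate=carrier_rate_statistic(ext, ctl),
                p=fisher_two_sided(
                    (carriers_e, non_e), (carriers_c, non_c), convention
                ),
                gene_score=(gene_scores or {}).get(gene),
            )
        )
    return rows


def rank_genes(
    rows: Sequence[GeneBurdenRow],
    top_k: int = 10,
    gene_scores: Mapping[str, float] | None = None,
) -> list[GeneBurdenRow]:
    """Rank rows ascending by p, ties by descending rate, then descending
    external gene score, then gene symbol; return the top ``top_k``."""
    if top_k <= 0:
        raise ValueError(f"top_k must be positive, got {top_k}")
    scored = list(rows)
    if gene_scores:
        scored = [
            GeneBurdenRow(**{**r.__dict__, "gene_score": gene_scores.get(r.gene)})
            for r in scored
        ]

    def key(row: GeneBurdenRow):
        score = row.gene_score if row.gene_score is not None else -np.inf
        return (row.p, -float(row.rate), -score, row.gene)

    return sorted(scored, key=key)[:top_k]
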