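"""Gene collapsing, the carrier-rate ratio, and the exact test."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from extremoseq.burden import (
    HET,
    HOM,
    MISSING,
    WILD,
    carrier_rate_statistic,
    collapse_gene,
    fisher_two_sided,
    gene_burden_table,
    rank_genes,
)
from extremoseq.cascade import group_by_gene
from extremoseq.cohort import select_extremes
from extremoseq.errors import DataError
from extremoseq.synthio import SimulationConfig, generate_cohort

from conftest import make_matrix


# ---------------------------------------------------------------------------
# carrier_rate_statistic

@pytest.mark.parametrize(
    "extreme, control, expected",
    [
        ((97, 11, 0), (100, 1, 0), 10.287),  # 1111/108, truncated
        ((97, 11, 0), (99, 1, 1), 5.143),    # 1111/216 = 5.1435 -> truncation
        ((98, 10, 0), (100, 1, 0), 9.351),   # 1010/108 = 9.3519 -> truncation
        ((97, 10, 1), (100, 1, 0), 10.287),  # hom counts as one carrier
        ((98, 9, 1), (101, 0, 0), 10),       # zero-control convention
        ((100, 8, 0), (101, 0, 0), 8),
        ((108, 0, 0), (101, 0, 0), 0),
    ],
)
def test_carrier_rate_published_patterns(extreme, control, expected):
    assert carrier_rate_statistic(extreme, control) == expected


def test_carrier_rate_truncates_not_rounds():
    # 5.1435... must report 5.143; naive rounding would give 5.144
    assert carrier_rate_statistic((97, 11, 0), (99, 1, 1)) == 5.143


def test_carrier_rate_scale_invariance():
    # scaling both groups' triples by the same factor leaves the ratio fixed
    base = ((90, 8, 2), (95, 4, 1))
    expected = carrier_rate_statistic(*base)
    for k in (2, 3, 10):
        scaled = tuple(tuple(k * x for x in g) for g in base)
        assert carrier_rate_statistic(*scaled) == expected


def test_carrier_rate_errors():
    with pytest.raises(DataError):
        carrier_rate_statistic((0, 0, 0), (10, 1, 0))
    with pytest.raises(DataError):
        carrier_rate_statistic((10, -1, 0), (10, 1, 0))


# ---------------------------------------------------------------------------
# fisher_two_sided vs an exact enumeration oracle

def _enumeration_oracle(k1, m1, k2, m2, convention):
    """Exact two-sided p by full hypergeometric enumeration with Fractions."""
    n, big_n, big_k = k1 + m1, k1 + m1 + k2 + m2, k1 + k2
    if big_k in (0, big_n) or n in (0, big_n):
        return 1.0
    denom = math.comb(big_n, n)
    support = range(max(0, n - (big_n - big_k)), min(n, big_k) + 1)
    pmf = {
        k: Fraction(math.comb(big_k, k) * math.comb(big_n - big_k, n - k), denom)
        for k in support
    }
    lower = sum(p for k, p in pmf.items() if k <= k1)
    upper = sum(p for k, p in pmf.items() if k >= k1)
    if convention == "doubling":
        return float(min(1, 2 * min(lower, upper)))
    observed = pmf[k1]
    return float(min(1, sum(p for p in pmf.values() if p <= observed)))


def test_fisher_examples_match_enumeration():
    # 10 carriers vs 0 in groups of 108/101: doubled upper tail
    p = fisher_two_sided((10, 98), (0, 101))
    assert p == pytest.approx(_enumeration_oracle(10, 98, 0, 101, "doubling"))
    assert p == pytest.approx(0.00220, abs=5e-5)
    # two-point support: one-sided 0.5, doubled
    assert fisher_two_sided((1, 0), (0, 1)) == pytest.approx(1.0)
    # identical proportions in a balanced table
    assert fisher_two_sided((5, 45), (5, 45)) == pytest.approx(1.0)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    st.tuples(
        st.integers(0, 80), st.integers(0, 80), st.integers(0, 80), st.integers(0, 80)
    ).filter(lambda t: 0 < sum(t) <= 300)
)
def test_fisher_matches_enumeration_on_small_tables(cells):
    k1, m1, k2, m2 = cells
    for convention in ("doubling", "minlike"):
        expected = _enumeration_oracle(k1, m1, k2, m2, convention)
        assert fisher_two_sided((k1, m1), (k2, m2), convention) == pytest.approx(
            expected, abs=1e-9
        )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.tuples(
        st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)
    ).filter(lambda t: sum(t) > 0 and (t[0] + t[1]) > 0 and (t[2] + t[3]) > 0)
)
def test_minlike_convention_agrees_with_reference(cells):
    """The min-likelihood flag reproduces the standard library convention."""
    k1, m1, k2, m2 = cells
    _, expected = fisher_exact([[k1, m1], [k2, m2]])
    assert fisher_two_sided((k1, m1), (k2, m2), "minlike") == pytest.approx(
        expected, abs=1e-9
    )


# ---------------------------------------------------------------------------
# collapse_gene

def test_collapse_reproduces_het_hom_pattern():
    # 9 het + 1 hom extreme carriers, clean controls
    extreme = [HET] * 9 + [HOM] + [WILD] * 98
    control = [WILD] * 101
    matrix, design = make_matrix(extreme, control)
    ext, ctl = collapse_gene(matrix, design, matrix.sites)
    assert ext == (98, 9, 1)
    assert ctl == (101, 0, 0)
    assert carrier_rate_statistic(ext, ctl) == 10


def test_collapse_excludes_all_missing_sample():
    extreme = [(HET, HET), (MISSING, MISSING), (WILD, WILD)]
    control = [(WILD, WILD), (WILD, MISSING)]
    matrix, design = make_matrix(extreme, control, n_sites=2)
    ext, ctl = collapse_gene(matrix, design, matrix.sites)
    assert sum(ext) == 2  # one extreme sample dropped for this gene
    assert ext == (1, 1, 0)
    assert ctl == (2, 0, 0)  # a partially missing sample still counts


def test_collapse_counts_multisite_carrier_once():
    matrix, design = make_matrix([(HET, HET)], [(WILD, WILD)], n_sites=2)
    ext, _ = collapse_gene(matrix, design, matrix.sites)
    assert ext == (0, 1, 0)
    # hom at any site dominates het at another
    matrix, design = make_matrix([(HET, HOM)], [(WILD, WILD)], n_sites=2)
    ext, _ = collapse_gene(matrix, design, matrix.sites)
    assert ext == (0, 0, 1)


def test_collapse_unknown_sample_errors():
    matrix, design = make_matrix([HET], [WILD])
    design.extreme_ids.append("GHOST")
    with pytest.raises(DataError, match="GHOST"):
        collapse_gene(matrix, design, matrix.sites)


# ---------------------------------------------------------------------------
# ranking and table assembly

def _row(gene, p, rate, score=None):
    from extremoseq.burden import GeneBurdenRow

    return GeneBurdenRow(
        gene=gene,
        snv_count=1,
        carrier_samples=1,
        counts_total=(10, 1, 0),
        counts_extreme=(5, 1, 0),
        counts_control=(5, 0, 0),
        rate=rate,
        p=p,
        gene_score=score,
    )


def test_rank_genes_order_and_tiebreaks():
    rows = [_row("B", 0.01, 8), _row("A", 0.002, 5), _row("C", 0.002, 10.287)]
    ranked = rank_genes(rows, top_k=3)
    assert [r.gene for r in ranked] == ["C", "A", "B"]  # p first, then rate
    with pytest.raises(ValueError):
        rank_genes(rows, top_k=0)


def test_rank_genes_external_score_tiebreak():
    rows = [_row("X", 0.01, 5), _row("Y", 0.01, 5)]
    ranked = rank_genes(rows, top_k=2, gene_scores={"X": 0.2, "Y": 0.9})
    assert [r.gene for r in ranked] == ["Y", "X"]


def test_burden_table_additivity(small_cohort, small_config):
    design = select_extremes(
        small_cohort.phenotypes,
        n_extreme=small_config.n_extreme,
        n_control=small_config.n_control,
    )
    rows = gene_burden_table(
        small_cohort.genotypes, design, group_by_gene(small_cohort.variants)
    )
    assert len(rows) == small_config.n_genes
    for r in rows:
        for e, c, t in zip(r.counts_extreme, r.counts_control, r.counts_total):
            assert e + c == t
        assert r.carrier_samples == r.counts_total[1] + r.counts_total[2]
        assert 0.0 <= r.p <= 1.0


def test_planted_ratio_recovered_over_replicates():
    """Mean carrier-rate ratio tracks the planted probability ratio.

    One gene planted at carrier probabilities 0.4 vs 0.2 (ratio 2); over
    replicates the mean reported rate should sit within 15% of 2 (the ratio
    estimator carries a small upward Jensen bias at these counts).
    """
    rates = []
    for seed in range(500):
        cfg = SimulationConfig(
            n_extreme=108,
            n_control=101,
            n_genes=2,
            sites_per_gene=2,
            planted_genes=[["GENE001", 0.4, 0.2, 0.0]],
            missing_rate=0.0,
            seed=seed,
        )
        cohort_data = generate_cohort(cfg)
        design = select_extremes(
            cohort_data.phenotypes, n_extreme=108, n_control=101
        )
        ext, ctl = collapse_gene(
            cohort_data.genotypes,
            design,
            [v.key for v in cohort_data.variants if v.gene == "GENE001"],
        )
        rate = carrier_rate_statistic(ext, ctl)
        if ctl[1] + ctl[2] > 0:  # ratio defined
            rates.append(float(rate))
    assert len(rates) >= 490
    assert np.mean(rates) == pytest.approx(2.0, rel=0.15)
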