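"""The prioritization cascade: gates, attrition, and set-level properties."""

import itertools

import numpy as np
import pytest

from extremoseq.cascade import (
    FilterConfig,
    deleteriousness_filter,
    flag_hgmd,
    frequency_filter,
    group_by_gene,
    quality_filter,
    run_cascade,
)
from extremoseq.errors import ConfigurationError, DataError
from extremoseq.synthio import SimulationConfig, generate_cohort, generate_variants
from extremoseq.varclass import PREDICTORS, AnnotatedVariant


def _variant(pos=100, **kw):
    defaults = dict(
        chrom="1",
        pos=pos,
        ref="A",
        alt="T",
        gene="G1",
        region="exonic",
        predictions={"SIFT": "damaging"},
        freq_1kg=0.0001,
        freq_esp6500=0.001,
        freq_selfctrl=0.001,
        freq_tianhao=0.0001,
        site_qual=60.0,
        qual_class="M",
        homology=1,
    )
    defaults.update(kw)
    return AnnotatedVariant(**defaults)


# ---------------------------------------------------------------------------
# flag_hgmd

def test_hgmd_flag_is_annotation_only():
    variants = [_variant(pos=i) for i in range(10)]
    table = [("1", 1, "A", "T"), ("1", 4, "A", "T"), ("1", 7, "A", "T")]
    flagged = flag_hgmd(variants, table)
    assert len(flagged) == 10  # nothing removed
    assert sum(v.hgmd_known for v in flagged) == 3
    assert [v.hgmd_known for v in flagged[:2]] == [False, True]


def test_hgmd_empty_table_all_novel():
    flagged = flag_hgmd([_variant()], [])
    assert not flagged[0].hgmd_known


def test_hgmd_malformed_rows_skipped_with_warning():
    with pytest.warns(UserWarning, match="2 malformed"):
        flagged = flag_hgmd(
            [_variant(pos=100)],
            [("1", 100, "A", "T"), ("bad",), ("1", "x", "A", "T")],
        )
    assert flagged[0].hgmd_known


# ---------------------------------------------------------------------------
# individual gates

def test_deleteriousness_gate():
    cfg = FilterConfig()
    kept = deleteriousness_filter(
        [
            _variant(predictions={p: "damaging" for p in PREDICTORS}),
            _variant(predictions={}),
            _variant(region="intergenic", predictions={"CADD": "damaging"}),
            _variant(region="splicing", predictions={"dbscSNV": "damaging"}),
        ],
        cfg,
    )
    assert len(kept) == 2
    assert {v.region for v in kept} == {"exonic", "splicing"}


def test_dbscsnv_counts_only_for_splice_regions():
    cfg = FilterConfig(min_predictors_damaging=1)
    exonic_only_dbscsnv = _variant(predictions={"dbscSNV": "damaging"})
    assert deleteriousness_filter([exonic_only_dbscsnv], cfg) == []


def test_frequency_gate_strict_inequality():
    cfg = FilterConfig()
    assert frequency_filter([_variant()], cfg)  # all below caps
    at_cap = _variant(freq_1kg=0.001)
    assert frequency_filter([at_cap], cfg) == []
    missing = _variant(freq_1kg=None)
    assert frequency_filter([missing], cfg)
    cfg2 = FilterConfig(treat_missing_freq_as_rare=False)
    assert frequency_filter([missing], cfg2) == []


def test_quality_gate_boundaries():
    cfg = FilterConfig()
    n = 100
    sites = {
        ("1", 100, "A", "T"): np.full(n, 30.0),            # all high
        ("1", 101, "A", "T"): np.r_[np.full(50, 10.0), np.full(50, 30.0)],  # 50%
        ("1", 102, "A", "T"): np.r_[np.full(51, 10.0), np.full(49, 30.0)],  # 51%
    }
    variants = [_variant(pos=100), _variant(pos=101), _variant(pos=102)]
    kept = quality_filter(variants, sites, cfg)
    assert [v.pos for v in kept] == [100, 101]  # exactly-50% is kept


def test_quality_gate_class_and_homology():
    cfg = FilterConfig()
    sites = {("1", 100, "A", "T"): np.full(4, 30.0)}
    assert quality_filter([_variant(qual_class="L")], sites, cfg) == []
    assert quality_filter([_variant(homology=0)], sites, cfg) == []


def test_quality_gate_requires_matrix():
    with pytest.raises(ConfigurationError):
        quality_filter([_variant()], None, FilterConfig())


def test_frequency_out_of_range_raises():
    v = _variant()
    v.freq_1kg = 1.5  # bypass constructor validation to hit the gate's check
    with pytest.raises(DataError):
        frequency_filter([v], FilterConfig())


# ---------------------------------------------------------------------------
# run_cascade

def _quals_for(variants, value=60.0, n=6):
    return {v.key: np.full(n, value) for v in variants}


def test_disabled_cascade_is_identity():
    variants = [
        _variant(pos=i, region="intergenic", predictions={}, freq_1kg=0.9)
        for i in range(5)
    ]
    report = run_cascade(variants, None, FilterConfig.disabled())
    assert [v.key for v in report.final] == [v.key for v in variants]


def test_clean_synthetic_cohort_passes_untouched():
    cfg = SimulationConfig(
        n_extreme=10,
        n_control=10,
        n_genes=5,
        sites_per_gene=2,
        planted_genes=[],
        rare_fraction=1.0,
        deleterious_fraction=1.0,
        missing_rate=0.0,
        seed=3,
    )
    cohort_data = generate_cohort(cfg)
    report = run_cascade(cohort_data.variants, cohort_data.genotypes, FilterConfig())
    assert len(report.final) == len(cohort_data.variants)


def test_hand_built_fixture_attrition():
    """12 variants, 5 violating exactly one gate each -> 7 survive."""
    quals_n = 10
    clean = [_variant(pos=i) for i in range(7)]
    violators = [
        _variant(pos=100, region="intronic"),                  # region gate
        _variant(pos=101, predictions={}),                     # no damaging call
        _variant(pos=102, freq_tianhao=0.005),                 # at the cap
        _variant(pos=103, qual_class="L"),                     # excluded grade
        _variant(pos=104, homology=0),                         # homology flag
    ]
    variants = clean + violators
    report = run_cascade(variants, _quals_for(variants, n=quals_n), FilterConfig())
    assert len(report.final) == 7
    assert [s for s, _, _ in report.stages] == [
        "hgmd_flag",
        "deleteriousness",
        "frequency",
        "quality",
    ]
    for _, n_in, n_out in report.stages:
        assert n_out <= n_in


def test_rare_fraction_survivor_count_binomial():
    """Frequency-gate survivors ~ Binomial(n, rare_fraction)."""
    cfg = SimulationConfig(
        n_genes=200,
        sites_per_gene=5,
        planted_genes=[],
        rare_fraction=0.3,
        deleterious_fraction=1.0,
        seed=21,
    )
    variants = generate_variants(cfg)
    assert len(variants) == 1000
    survivors = frequency_filter(variants, FilterConfig())
    se = np.sqrt(1000 * 0.3 * 0.7)
    assert abs(len(survivors) - 300) <= 3 * se


def test_cascade_monotone_in_frequency_caps():
    """Lowering any frequency cap never adds survivors."""
    cfg = SimulationConfig(
        n_genes=50, sites_per_gene=4, planted_genes=[], rare_fraction=0.5, seed=9
    )
    variants = generate_variants(cfg)
    previous = None
    for cap in (0.02, 0.01, 0.005, 0.001, 0.0005):
        survivors = {
            v.key for v in frequency_filter(variants, FilterConfig(max_freq_1kg=cap))
        }
        if previous is not None:
            assert survivors <= previous
        previous = survivors


def test_cascade_final_set_is_order_insensitive():
    cfg = SimulationConfig(
        n_genes=30,
        sites_per_gene=3,
        planted_genes=[],
        rare_fraction=0.5,
        deleterious_fraction=0.5,
        qual_L_fraction=0.1,
        homology_zero_fraction=0.1,
        seed=13,
    )
    variants = generate_variants(cfg)
    quals = _quals_for(variants)
    fc = FilterConfig()
    gates = {
        "d": lambda vs: deleteriousness_filter(vs, fc),
        "f": lambda vs: frequency_filter(vs, fc),
        "q": lambda vs: quality_filter(vs, quals, fc),
    }
    results = set()
    for order in itertools.permutations("dfq"):
        vs = variants
        for g in order:
            vs = gates[g](vs)
        results.add(frozenset(v.key for v in vs))
    assert len(results) == 1


def test_cascade_idempotent():
    cfg = SimulationConfig(
        n_genes=30, sites_per_gene=3, planted_genes=[], rare_fraction=0.5, seed=17
    )
    variants = generate_variants(cfg)
    quals = _quals_for(variants)
    fc = FilterConfig()
    once = run_cascade(variants, quals, fc).final
    twice = run_cascade(once, quals, fc).final
    assert [v.key for v in once] == [v.key for v in twice]


def test_group_by_gene_preserves_order():
    variants = [_variant(pos=1, gene="B"), _variant(pos=2, gene="A"),
                _variant(pos=3, gene="B")]
    grouped = group_by_gene(variants)
    assert list(grouped) == ["B", "A"]
    assert len(grouped["B"]) == 2
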