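"""Extreme-phenotype cohort selection and baseline statistics.

The study design sequences the tails of the triglyceride (TG) distribution:
samples at or below a TG threshold (0.45 mmol/L by default) form the
extreme-low group, and a sex/age-matched set from the normal-TG stratum forms
the control group.  Baseline trait comparisons follow the usual clinical
reporting rules: Shapiro-Wilk normality per group, pooled-variance t-test
with mean (SD) summaries when both groups pass, Mann-Whitney rank-sum with
median (IQR) otherwise, and a chi-square test for sex.  Post hoc power of the
two-sample comparison is computed from the noncentral t distribution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, SelectionError

DEFAULT_TG_THRESHOLD = 0.45

#: Quantitative traits summarised in the baseline table, in report order.
BASELINE_TRAITS = (
    "age",
    "TG",
    "TC",
    "HDL_C",
    "LDL_C",
    "glucose",
    "creatinine",
    "BUN",
    "AST",
    "ALT",
)


@dataclass
class CohortDesign:
    """The two phenotype-defined groups."""

    tg_threshold: float
    extreme_ids: list[str]
    control_ids: list[str]
    matching: bool = True

    def __post_init__(self) -> None:
        overlap = set(self.extreme_ids) & set(self.control_ids)
        if overlap:
            raise SelectionError(f"groups overlap: {sorted(overlap)[:5]}")

    @property
    def n_extreme(self) -> int:
        return len(self.extreme_ids)

    @property
    def n_control(self) -> int:
        return len(self.control_ids)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "tg_threshold": self.tg_threshold,
                    "extreme_ids": list(self.extreme_ids),
                    "control_ids": list(self.control_ids),
                    "matching": self.matching,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "CohortDesign":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class PowerSpec:
    """Inputs of the two-sample t-test power computation."""

    effect_size_d: float
    n1: int
    n2: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError(f"alpha={self.alpha} outside (0, 1)")
        if self.effect_size_d < 0:
            raise ConfigurationError("effect size must be non-negative")
        if self.n1 < 2 or self.n2 < 2:
            raise ConfigurationError("group sizes must be at least 2")


@dataclass
class BaselineRow:
    """One baseline-table row: group and pooled summaries, test, p-value."""

    trait: str
    test: str
    p: float
    extreme: dict = field(default_factory=dict)
    control: dict = field(default_factory=dict)
    pooled: dict = field(default_factory=dict)

    def summary(self, which: str) -> str:
        d = getattr(self, which)
        if "mean" in d:
            return f"{d['mean']:.2f} ({d['sd']:.2f})"
        if "median" in d:
            return f"{d['median']:.2f} ({d['iqr']:.2f})"
        return f"{d.get('count', 0)} ({100 * d.get('fraction', 0.0):.1f})"


def select_extremes(
    phenotypes: pd.DataFrame,
    tg_threshold: float = DEFAULT_TG_THRESHOLD,
    n_extreme: int | None = None,
    n_control: int | None = None,
    matching: bool = True,
) -> CohortDesign:
    """Select the extreme-low and control groups from a phenotype table.

    The extreme group is the ``n_extreme`` lowest-TG samples at or below the
    threshold (all such samples when ``n_extreme`` is None).  Controls come
    from the TG > threshold stratum: with ``matching`` a greedy sex-stratified
    nearest-age matcher reproduces the extreme group's sex composition;
    without it the controls closest to the stratum's median TG are taken.
    """
    df = phenotypes.sort_values(["TG", "sample_id"], kind="mergesort")
    low = df[df["TG"] <= tg_threshold]
    if n_extreme is None:
        n_extreme = len(low)
    if n_extreme <= 0:
        raise SelectionError("n_extreme must be positive")
    if len(low) < n_extreme:
        raise SelectionError(
            f"need {n_extreme} samples with TG <= {tg_threshold}, only {len(low)}"
        )
    extreme = low.head(n_extreme)

    pool = df[df["TG"] > tg_threshold]
    if n_control is None:
        n_control = len(pool)
    if n_control <= 0 or len(pool) < n_control:
        raise SelectionError(
            f"need {n_control} controls with TG > {tg_threshold}, only {len(pool)}"
        )

    if matching and "sex" in df.columns and "age" in df.columns:
        male_frac = float((extreme["sex"] == "M").mean())
        target_m = round(n_control * male_frac)
        mean_age = float(extreme["age"].mean())
        chosen = []
        by_sex = {
            sex: pool[pool["sex"] == sex]
            .assign(_d=lambda g: (g["age"] - mean_age).abs())
            .sort_values(["_d", "sample_id"], kind="mergesort")
            for sex in ("M", "F")
        }
        take_m = min(target_m, len(by_sex["M"]))
        take_f = min(n_control - take_m, len(by_sex["F"]))
        chosen = list(by_sex["M"].head(take_m)["sample_id"]) + list(
            by_sex["F"].head(take_f)["sample_id"]
        )
        if len(chosen) < n_control:  # one sex exhausted; fill from the other
            remaining = pool[~pool["sample_id"].isin(chosen)]
            remaining = remaining.assign(
                _d=(remaining["age"] - mean_age).abs()
            ).sort_values(["_d", "sample_id"], kind="mergesort")
            chosen += list(remaining.head(n_control - len(chosen))["sample_id"])
        control_ids = chosen
    else:
        med = float(pool["TG"].median())
        ranked = pool.assign(_d=(pool["TG"] - med).abs()).sort_values(
            ["_d", "sample_id"], kind="mergesort"
        )
        control_ids = list(ranked.head(n_control)["sample_id"])

    return CohortDesign(
        tg_threshold=tg_threshold,
        extreme_ids=list(extreme["sample_id"]),
        control_ids=control_ids,
        matching=matching,
    )


def _numeric_row(
    trait: str,
    x: np.ndarray,
    y: np.ndarray,
    normality: str,
    alpha: float,
    welch: bool,
) -> BaselineRow:
    pooled = np.concatenate([x, y])
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        warnings.warn(f"trait {trait!r} has zero variance in both groups; p set to 1")
        p, test = 1.0, "t"
        normal = True
    else:
        normal = _both_normal(x, y, normality, alpha)
        if normal:
            test = "t"
            _, p = stats.ttest_ind(x, y, equal_var=not welch)
        else:
            test = "rank-sum"
            _, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        p = float(p)
    if normal:
        summarise = lambda v: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1))}
    else:
        summarise = lambda v: {
            "median": float(np.median(v)),
            "iqr": float(np.percentile(v, 75) - np.percentile(v, 25)),
        }
    return BaselineRow(
        trait=trait,
        test=test,
        p=p,
        extreme=summarise(x),
        control=summarise(y),
        pooled=summarise(pooled),
    )


def _both_normal(x, y, normality: str, alpha: float) -> bool:
    for v in (x, y):
        if len(v) < 3 or np.ptp(v) == 0:
            return False
        if normality == "shapiro":
            p = stats.shapiro(v).pvalue
        else:
            p = stats.kstest((v - np.mean(v)) / np.std(v, ddof=1), "norm").pvalue
        if p < alpha:
            return False
    return True


def baseline_table(
    phenotypes: pd.DataFrame,
    design: CohortDesign,
    traits=BASELINE_TRAITS,
    normality: str = "shapiro",
    normality_alpha: float = 0.05,
    welch: bool = False,
) -> list[BaselineRow]:
    """Baseline comparison of the two groups, one row per trait plus sex.

    Per quantitative trait both groups are Shapiro-Wilk tested (Kolmogorov-
    Smirnov by ``normality="ks"``); a pooled-variance t-test with mean (SD)
    summaries is used when both pass at ``normality_alpha``, else a
    Mann-Whitney rank-sum with median (IQR).  Sex is compared by the Pearson
    chi-square on the 2x2 table.
    """
    if design.n_extreme == 0 or design.n_control == 0:
        raise SelectionError("both groups must be non-empty")
    df = phenotypes.set_index("sample_id")
    ext = df.loc[design.extreme_ids]
    ctl = df.loc[design.control_ids]
    rows = []
    if "sex" in df.columns:
        table = np.array(
            [
                [(ext["sex"] == "M").sum(), (ext["sex"] == "F").sum()],
                [(ctl["sex"] == "M").sum(), (ctl["sex"] == "F").sum()],
            ]
        )
        if (table.sum(axis=0) == 0).any():
            warnings.warn("sex table has an empty margin; p set to 1")
            p = 1.0
        else:
            _, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append(
            BaselineRow(
                trait="sex",
                test="chi-square",
                p=float(p),
                extreme={"count": int(table[0, 0]), "fraction": table[0, 0] / len(ext)},
                control={"count": int(table[1, 0]), "fraction": table[1, 0] / len(ctl)},
                pooled={
                    "count": int(table[:, 0].sum()),
                    "fraction": table[:, 0].sum() / (len(ext) + len(ctl)),
                },
            )
        )
    for trait in traits:
        if trait not in df.columns:
            continue
        rows.append(
            _numeric_row(
                trait,
                ext[trait].to_numpy(float),
                ctl[trait].to_numpy(float),
                normality,
                normality_alpha,
                welch,
            )
        )
    return rows


def baseline_frame(rows: list[BaselineRow]) -> pd.DataFrame:
    """Report-ready DataFrame in the usual baseline-table layout."""
    return pd.DataFrame(
        {
            "trait": [r.trait for r in rows],
            "extreme": [r.summary("extreme") for r in rows],
            "control": [r.summary("control") for r in rows],
            "pooled": [r.summary("pooled") for r in rows],
            "test": [r.test for r in rows],
            "p": [r.p for r in rows],
        }
    )


def pooled_mean(group_means: list[tuple[float, int]]) -> float:
    """Size-weighted mean across groups, rounded to 2 decimals (half-even)
    for report tables."""
    if not group_means:
        raise ConfigurationError("pooled_mean: empty input")
    if any(n <= 0 for _, n in group_means):
        raise ConfigurationError("pooled_mean: group sizes must be positive")
    total = sum(n for _, n in group_means)
    return round(sum(m * n for m, n in group_means) / total, 2)


def cohens_d(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Cohen's d with pooled SD: |m1 - m2| / s_p,
    s_p = sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2))."""
    if sd1 < 0 or sd2 < 0:
        raise ConfigurationError("SDs must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("group sizes must be at least 2")
    if sd1 == 0 and sd2 == 0:
        raise ConfigurationError("Cohen's d undefined with both SDs zero")
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    return float(abs(mean1 - mean2) / sp)


def ttest_power(spec: PowerSpec) -> float:
    """Power of the two-sided two-sample t-test via the noncentral t.

    Noncentrality ncp = d * sqrt(n1*n2 / (n1+n2)), df = n1+n2-2; power is the
    probability that |T| exceeds the central-t critical value under the
    alternative.  At d = 0 this reduces to alpha.
    """
    df = spec.n1 + spec.n2 - 2
    ncp = spec.effect_size_d * np.sqrt(spec.n1 * spec.n2 / (spec.n1 + spec.n2))
    tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
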