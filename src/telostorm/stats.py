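"""Group-comparison statistics: unpaired t, ANOVA + Dunnett, ANOVA + Tukey.

Thin, unit-aware wrappers over the scipy implementations, matching the
study's reporting conventions: two-tailed unpaired t tests at the 95%
confidence level, one-way ANOVA with Dunnett's many-to-one adjustment for
treatment-vs-control panels, Tukey's HSD for all-pairs Rg comparisons, and
group means with the standard error of the mean (s.e.m. = s.d./√n).

The statistical unit is carried explicitly (per-telomere Rg, per-nucleus
percentage, per-replicate ratio) so values from different units are not
accidentally pooled.  Telomeres from the same nucleus are treated as
independent observations, matching the source convention; the caveat is
documented rather than re-decided here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean, sample s.d. (ddof=1) over √n."""
    v = np.asarray(values, float)
    if len(v) < 2:
        return float("nan")
    return float(np.std(v, ddof=1) / np.sqrt(len(v)))


@dataclass
class GroupSamples:
    """Labelled groups of one statistical unit.

    ``unit`` names what one value is (e.g. "telomere Rg (nm)",
    "% TIF per nucleus", "ChIP ratio per replicate").
    """

    samples: dict[str, np.ndarray]
    unit: str = "value"

    def __post_init__(self) -> None:
        self.samples = {k: np.asarray(v, float) for k, v in self.samples.items()}
        for k, v in self.samples.items():
            if v.ndim != 1 or len(v) == 0:
                raise ValueError(f"group {k!r} must be a non-empty 1D array")

    def require_min_n(self, n: int) -> None:
        for k, v in self.samples.items():
            if len(v) < n:
                raise ValueError(f"group {k!r} has {len(v)} values; needs >= {n}")

    @property
    def labels(self) -> list[str]:
        return list(self.samples)


@dataclass
class ComparisonResult:
    """Outcome of one testing procedure.

    ``pvalues`` maps a comparison label ("A vs B") to its (adjusted, where
    applicable) p-value; ``statistic`` is the test's headline statistic
    (t or F).  Group means and s.e.m. are always included for reporting.
    """

    test: str
    statistic: float
    pvalues: dict[str, float]
    group_means: dict[str, float]
    group_sems: dict[str, float]
    confidence: float = 0.95
    anova_p: float | None = None

    def __post_init__(self) -> None:
        for label, p in self.pvalues.items():
            if not (np.isnan(p) or 0.0 <= p <= 1.0):
                raise ValueError(f"p-value for {label!r} outside [0, 1]: {p}")

    def min_p(self) -> float:
        return min(self.pvalues.values())


def _descriptives(groups: Mapping[str, np.ndarray]):
    means = {k: float(np.mean(v)) for k, v in groups.items()}
    sems = {k: sem(v) for k, v in groups.items()}
    return means, sems


def ttest_two_tailed(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    equal_var: bool = True,
) -> ComparisonResult:
    """Two-tailed unpaired t test (equal-variance by default, Welch optional).

    Degenerate input with zero pooled variance and equal means returns
    t = 0, p = 1 by convention; zero variance with unequal means is an error
    (the t statistic is unbounded).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    groups = {labels[0]: a, labels[1]: b}
    means, sems = _descriptives(groups)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if means[labels[0]] == means[labels[1]]:
            return ComparisonResult(
                "t (unpaired, two-tailed)", 0.0,
                {f"{labels[0]} vs {labels[1]}": 1.0}, means, sems,
            )
        raise ValueError("zero variance in both samples with unequal means")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(
        "t (unpaired, two-tailed)" + ("" if equal_var else " [Welch]"),
        float(res.statistic),
        {f"{labels[0]} vs {labels[1]}": float(res.pvalue)},
        means,
        sems,
    )


def anova_dunnett(
    groups: GroupSamples, control: str, rng: int | np.random.Generator | None = 0
) -> ComparisonResult:
    """One-way ANOVA plus Dunnett's many-to-one comparisons against a control.

    Each treatment group is compared with ``control``; p-values are adjusted
    for the family of treatment-vs-control tests.  ``rng`` seeds the
    multivariate-t quadrature so results are reproducible.
    """
    if control not in groups.samples:
        raise ValueError(f"control group {control!r} not present")
    groups.require_min_n(2)
    if len(groups.samples) < 2:
        raise ValueError("need the control plus at least one treatment group")
    treatment_labels = [k for k in groups.labels if k != control]
    treatments = [groups.samples[k] for k in treatment_labels]
    f_res = sps.f_oneway(*groups.samples.values())
    d_res = sps.dunnett(*treatments, control=groups.samples[control], rng=rng)
    means, sems = _descriptives(groups.samples)
    pvals = {
        f"{lab} vs {control}": float(p) for lab, p in zip(treatment_labels, d_res.pvalue)
    }
    return ComparisonResult(
        "one-way ANOVA + Dunnett", float(f_res.statistic), pvals, means, sems,
        anova_p=float(f_res.pvalue),
    )


def anova_tukey(groups: GroupSamples) -> ComparisonResult:
    """One-way ANOVA plus Tukey's HSD over all pairwise comparisons."""
    if len(groups.samples) < 2:
        raise ValueError("need at least 2 groups")
    groups.require_min_n(2)
    labels = groups.labels
    arrays = [groups.samples[k] for k in labels]
    f_res = sps.f_oneway(*arrays)
    t_res = sps.tukey_hsd(*arrays)
    means, sems = _descriptives(groups.samples)
    pvals = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pvals[f"{labels[i]} vs {labels[j]}"] = float(t_res.pvalue[i, j])
    return ComparisonResult(
        "one-way ANOVA + Tukey HSD", float(f_res.statistic), pvals, means, sems,
        anova_p=float(f_res.pvalue),
    )


def comparisons_frame(results: Sequence[ComparisonResult]):
    """Flatten ComparisonResults into a tidy frame: test, comparison, estimate, p_adj."""
    import pandas as pd

    rows = []
    for r in results:
        for comp, p in r.pvalues.items():
            parts = comp.split(" vs ")
            est = (
                r.group_means.get(parts[0], np.nan) - r.group_means.get(parts[1], np.nan)
                if len(parts) == 2
                else np.nan
            )
            rows.append({"test": r.test, "comparison": comp, "estimate": est, "p_adj": p})
    return pd.DataFrame(rows)
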