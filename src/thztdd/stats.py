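"""Group comparison statistics for the imaging experiment.

Per-group normality is screened with the Shapiro-Wilk test (Royston
approximation), group means are compared with one-way ANOVA, and pairwise
differences with the Tukey-Kramer honestly-significant-difference procedure.
For a balanced design the Tukey comparison reduces to the minimal significant
difference

    MSD = q_{alpha, k, df_w} * sqrt(MS_within / n)

with q the studentized-range critical value; a pair differs significantly iff
its mean difference exceeds the (Tukey-Kramer) threshold, equivalently iff
intervals of half-width threshold/2 around the two means do not overlap.

The ANOVA decomposition and the Tukey-Kramer table are computed here from
sums of squares; the studentized-range quantile comes from numerical
integration of the range distribution (scipy.stats.studentized_range), and
Shapiro-Wilk from scipy's Royston implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "PairComparison",
    "TukeyResult",
    "StatReport",
    "shapiro_wilk",
    "anova_oneway",
    "tukey_kramer",
    "run_group_comparison",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-replicate scalar summaries (central-ROI mean |M|_norm) for one
    treatment group."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("each group needs at least 2 finite values")
        if not np.all(np.isfinite(values)):
            raise ValueError("group values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    ms_within: float


@dataclass(frozen=True)
class PairComparison:
    group_a: str
    group_b: str
    mean_difference: float
    threshold: float  # minimal significant difference for this pair
    significant: bool


@dataclass(frozen=True)
class TukeyResult:
    pairs: tuple[PairComparison, ...]
    q_critical: float
    alpha: float
    msd: float | None  # common MSD when the design is balanced
    ms_within: float
    df_within: int

    def pair(self, a: str, b: str) -> PairComparison:
        for p in self.pairs:
            if {p.group_a, p.group_b} == {a, b}:
                return p
        raise KeyError(f"no comparison for ({a}, {b})")


@dataclass(frozen=True)
class StatReport:
    """Full battery: per-group Shapiro-Wilk, one-way ANOVA, Tukey-Kramer."""

    shapiro: dict[str, tuple[float, float]]
    anova: AnovaResult
    tukey: TukeyResult
    alpha_tukey: float = 0.05
    normality_warning: tuple[str, ...] = field(default_factory=tuple)

    def isolated_groups(self) -> tuple[str, ...]:
        """Groups whose Tukey interval overlaps no other group, i.e. that
        differ significantly from every other group."""
        labels = sorted(
            {p.group_a for p in self.tukey.pairs}
            | {p.group_b for p in self.tukey.pairs}
        )
        out = []
        for g in labels:
            others = [
                p
                for p in self.tukey.pairs
                if g in (p.group_a, p.group_b)
            ]
            if others and all(p.significant for p in others):
                out.append(g)
        return tuple(out)

    def to_dict(self) -> dict:
        return {
            "shapiro": {
                g: {"W": w, "p": p} for g, (w, p) in self.shapiro.items()
            },
            "anova": {
                "F": self.anova.F,
                "df_between": self.anova.df_between,
                "df_within": self.anova.df_within,
                "p": self.anova.p_value,
                "ms_within": self.anova.ms_within,
            },
            "tukey": {
                "alpha": self.tukey.alpha,
                "q_critical": self.tukey.q_critical,
                "msd": self.tukey.msd,
                "pairs": [
                    {
                        "a": p.group_a,
                        "b": p.group_b,
                        "difference": p.mean_difference,
                        "threshold": p.threshold,
                        "significant": p.significant,
                    }
                    for p in self.tukey.pairs
                ],
            },
            "normality_warning": list(self.normality_warning),
            "isolated_groups": list(self.isolated_groups()),
        }


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (Royston approximation).

    Valid for sample sizes 3 <= n <= 50; a zero-variance sample has no
    defined W.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or not 3 <= values.size <= 50:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 50")
    if np.ptp(values) == 0:
        raise ValueError("W is undefined for a zero-variance sample")
    res = sps.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def _group_arrays(groups: Sequence[GroupSummary]):
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be unique")
    return labels, [g.values for g in groups]


def anova_oneway(groups: Sequence[GroupSummary]) -> AnovaResult:
    """One-way fixed-effects ANOVA from the standard sums-of-squares
    decomposition; p-value from the upper tail of the F distribution."""
    _, arrays = _group_arrays(groups)
    k = len(arrays)
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = float(np.concatenate(arrays).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((a - m) ** 2) for a, m in zip(arrays, means)))
    df_b = k - 1
    df_w = int(ns.sum()) - k
    if df_w < 1 or ss_within <= 0:
        raise ValueError("pooled within-group variance must be positive")
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    f_stat = ms_b / ms_w
    p = float(sps.f.sf(f_stat, df_b, df_w))
    return AnovaResult(
        F=f_stat, df_between=df_b, df_within=df_w, p_value=p, ms_within=ms_w
    )


@lru_cache(maxsize=128)
def _studentized_range_critical(alpha: float, k: int, df: int) -> float:
    """Upper-alpha quantile of the studentized range of k means with df
    within-group degrees of freedom (numerical integration; cached because
    the same (alpha, k, df) recurs across replicated designs)."""
    return float(sps.studentized_range.ppf(1.0 - alpha, k, df))


def tukey_kramer(
    groups: Sequence[GroupSummary], alpha: float = 0.05
) -> TukeyResult:
    """Tukey-Kramer pairwise comparison of all group means.

    Pair (i, j) is significant iff |mean_i - mean_j| exceeds
    q * sqrt(MS_w/2 * (1/n_i + 1/n_j)); for a balanced design the common
    threshold is the minimal significant difference q * sqrt(MS_w / n).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    labels, arrays = _group_arrays(groups)
    anova = anova_oneway(groups)
    k = len(arrays)
    q_crit = _studentized_range_critical(alpha, k, anova.df_within)
    means = {lab: float(a.mean()) for lab, a in zip(labels, arrays)}
    ns = {lab: a.size for lab, a in zip(labels, arrays)}
    pairs = []
    for a, b in combinations(labels, 2):
        diff = means[a] - means[b]
        thr = q_crit * np.sqrt(
            anova.ms_within / 2.0 * (1.0 / ns[a] + 1.0 / ns[b])
        )
        pairs.append(
            PairComparison(a, b, diff, float(thr), bool(abs(diff) > thr))
        )
    n_common = {a.size for a in arrays}
    msd = (
        float(q_crit * np.sqrt(anova.ms_within / n_common.pop()))
        if len(n_common) == 1
        else None
    )
    return TukeyResult(
        pairs=tuple(pairs),
        q_critical=q_crit,
        alpha=alpha,
        msd=msd,
        ms_within=anova.ms_within,
        df_within=anova.df_within,
    )


def run_group_comparison(
    summaries: Sequence[GroupSummary], alpha: float = 0.05
) -> StatReport:
    """Assemble the full battery for the treatment groups.

    Normality failures (Shapiro-Wilk p < alpha) are reported as warnings and
    the parametric comparison proceeds regardless.  Groups too small for the
    test (n < 3) are omitted from the normality screen.
    """
    shapiro = {
        g.label: shapiro_wilk(g.values)
        for g in summaries
        if 3 <= g.n <= 50
    }
    warn = tuple(g for g, (_, p) in shapiro.items() if p < alpha)
    anova = anova_oneway(summaries)
    tukey = tukey_kramer(summaries, alpha=alpha)
    return StatReport(
        shapiro=shapiro,
        anova=anova,
        tukey=tukey,
        alpha_tukey=alpha,
        normality_warning=warn,
    )
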