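"""One-way ANOVA, Tukey multiple comparisons and eclosion rate.

Two entry points produce identical results: :func:`anova_oneway` on
replicate-level samples and :func:`anova_from_summary` on published
(mean, SD, n) triplets — the fixed-effects sums of squares depend on the
raw data only through those summaries, so rearing studies that publish
only mean +/- SD can still be re-analysed exactly.

The "R2" these studies print next to F is eta-squared,
SS_between / SS_total — the fraction of duration variance explained by
the temperature treatment.

Tukey's HSD uses the studentized range distribution
(:data:`scipy.stats.studentized_range`), with the Tukey–Kramer correction
for unbalanced groups, and summarises all pairwise tests as a compact
letter display (groups sharing a letter are not significantly different).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from string import ascii_lowercase

import numpy as np
from scipy import stats

from .datatypes import GroupSummary
from .exceptions import ValidationError

__all__ = [
    "AnovaResult",
    "TukeyResult",
    "anova_oneway",
    "anova_from_summary",
    "tukey_hsd",
    "compact_letter_display",
    "eclosion_rate",
]


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way fixed-effects ANOVA decomposition.

    ``r_squared`` is eta-squared: SS_between / (SS_between + SS_within).
    ``F`` is ``inf`` when SS_within = 0 with unequal means, and 0 (p = 1)
    when every observation is identical.
    """

    F: float
    p: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    r_squared: float

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within

    def summary(self) -> str:
        return (
            "One-way ANOVA\n"
            f"  F({self.df_between}, {self.df_within}) = {self.F:.4f}, "
            f"p = {self.p:.4g}\n"
            f"  SS_between = {self.ss_between:.4f}, SS_within = {self.ss_within:.4f}\n"
            f"  R2 (eta-squared) = {self.r_squared:.4f}"
        )


@dataclass(frozen=True)
class TukeyResult:
    """All pairwise Tukey(-Kramer) comparisons plus a compact letter display."""

    alpha: float
    comparisons: tuple[tuple[str, str, float, float], ...]  # (i, j, diff, p_adj)
    letters: dict[str, str] = field(default_factory=dict)

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, _, p in self.comparisons if p < self.alpha]

    def summary(self) -> str:
        lines = [f"Tukey HSD (alpha = {self.alpha:g})"]
        for a, b, d, p in self.comparisons:
            mark = "*" if p < self.alpha else " "
            lines.append(f"  {a} - {b}: diff = {d:+.4f}, p = {p:.4f} {mark}")
        lines.append("  letters: " + ", ".join(
            f"{g}: {l}" for g, l in self.letters.items()))
        return "\n".join(lines)


def _summaries_from_raw(groups, labels=None) -> list[GroupSummary]:
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    out = []
    for label, g in zip(labels, groups):
        g = np.asarray(g, dtype=float)
        if g.ndim != 1 or len(g) < 2:
            raise ValidationError(
                f"group {label!r}: need at least 2 observations, got {g.size}")
        out.append(GroupSummary(label=label, mean=float(g.mean()),
                                sd=float(g.std(ddof=1)), n=int(len(g))))
    return out


def anova_from_summary(summaries: list[GroupSummary]) -> AnovaResult:
    """One-way ANOVA from (mean, SD, n) group summaries.

    SS_between = sum n_i (mean_i - grand_mean)^2 with the grand mean
    weighted by n_i; SS_within = sum (n_i - 1) sd_i^2. Equals
    :func:`anova_oneway` on any raw data with these summaries.
    """
    if len(summaries) < 2:
        raise ValidationError("need at least 2 groups")
    n = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    grand = float(np.sum(n * means) / np.sum(n))
    ssb = float(np.sum(n * (means - grand) ** 2))
    ssw = float(np.sum((n - 1) * sds ** 2))
    dfb = len(summaries) - 1
    dfw = int(np.sum(n)) - len(summaries)
    if ssw == 0.0:
        if ssb == 0.0:
            F, p = 0.0, 1.0
        else:
            F, p = math.inf, 0.0
    else:
        F = (ssb / dfb) / (ssw / dfw)
        p = float(stats.f.sf(F, dfb, dfw))
    sst = ssb + ssw
    r2 = ssb / sst if sst > 0 else 0.0
    return AnovaResult(F=float(F), p=float(p), df_between=dfb, df_within=dfw,
                       ss_between=ssb, ss_within=ssw, r_squared=float(r2))


def anova_oneway(groups: list, labels: list[str] | None = None) -> AnovaResult:
    """One-way fixed-effects ANOVA on replicate-level samples."""
    return anova_from_summary(_summaries_from_raw(groups, labels))


def _pooled_variance(summaries: list[GroupSummary]) -> tuple[float, int]:
    n = np.array([s.n for s in summaries], dtype=float)
    sds = np.array([s.sd for s in summaries])
    dfw = int(np.sum(n)) - len(summaries)
    s2 = float(np.sum((n - 1) * sds ** 2) / dfw)
    return s2, dfw


def tukey_hsd(groups=None, alpha: float = 0.05, labels=None, *,
              summaries: list[GroupSummary] | None = None) -> TukeyResult:
    """Tukey(-Kramer) all-pairs comparisons with a compact letter display.

    Accepts raw samples or published (mean, SD, n) summaries. Adjusted
    p-values come from the studentized range distribution with k groups
    and the within-group df. With zero pooled variance, pairs with
    distinct means are flagged significant (p = 0) and ties get p = 1.
    """
    if summaries is None:
        if groups is None:
            raise ValidationError("provide raw groups or summaries")
        summaries = _summaries_from_raw(groups, labels)
    if len(summaries) < 2:
        raise ValidationError("need at least 2 groups")
    k = len(summaries)
    s2, dfw = _pooled_variance(summaries)
    comps = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = summaries[i], summaries[j]
            diff = a.mean - b.mean
            if s2 == 0.0:
                p = 1.0 if diff == 0.0 else 0.0
            else:
                # Tukey-Kramer standard error; q = |diff| / SE with
                # SE = sqrt(s2/2 * (1/na + 1/nb))
                se = math.sqrt(s2 / 2.0 * (1.0 / a.n + 1.0 / b.n))
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, k, dfw))
            comps.append((a.label, b.label, float(diff), min(max(p, 0.0), 1.0)))
    sig = {(a, b) for a, b, _, p in comps if p < alpha}
    order = [s.label for s in sorted(summaries, key=lambda s: -s.mean)]
    letters = compact_letter_display(order, sig)
    return TukeyResult(alpha=alpha, comparisons=tuple(comps), letters=letters)


def compact_letter_display(groups_by_rank: list[str],
                           significant_pairs: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``groups_by_rank`` orders groups (by descending mean, conventionally)
    so the first-ranked group receives 'a'. Groups sharing any letter are
    not significantly different; every group gets at least one letter.
    """
    sig = {frozenset(p) for p in significant_pairs}
    columns: list[set[str]] = [set(groups_by_rank)]
    for pair in sig:
        a, b = tuple(pair)
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop any column contained in another
        columns = []
        for col in new_columns:
            if any(col < other for other in new_columns) or col in columns:
                continue
            columns.append(col)
    # order columns by the rank of their best (earliest-ranked) member
    rank = {g: i for i, g in enumerate(groups_by_rank)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    letters: dict[str, list[str]] = {g: [] for g in groups_by_rank}
    for letter, col in zip(ascii_lowercase, columns):
        for g in col:
            letters[g].append(letter)
    return {g: "".join(sorted(ls)) for g, ls in letters.items()}


def eclosion_rate(n_emerged: int, n_started: int) -> float:
    """Percentage of individuals completing eclosion."""
    if n_started <= 0:
        raise ValidationError("n_started must be > 0")
    if not 0 <= n_emerged <= n_started:
        raise ValidationError("need 0 <= n_emerged <= n_started")
    return 100.0 * n_emerged / n_started
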