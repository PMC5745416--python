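"""Combining per-dataset results across clades.

Fisher's combined probability treats the per-dataset p-values of one
test as independent evidence: ``X² = -2 Σ ln p_i`` follows a
chi-squared distribution with ``2k`` degrees of freedom under the
global null.  Clade-level families of combined tests are compared
against a Bonferroni-corrected threshold ``alpha / k``.  Differences in
molecular consistency across clades are assessed with a one-way ANOVA
of per-dataset mean retention indices, and the clade dependence of the
hard-soft contrast with the difference-score reduction of the
two-level repeated-measures design: a one-way ANOVA of
``d = RI_hard - RI_soft`` across clades (exactly the clade x partition
interaction when the within factor has two levels), plus a paired
t-test of mean ``d`` against zero for the within-partition main effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class FisherResult:
    x2: float
    df: int
    p: float


@dataclass(frozen=True)
class BonferroniResult:
    alpha: float
    k: int
    threshold: float
    rendered: str


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int

    @property
    def available(self) -> bool:
        return not math.isnan(self.F)


@dataclass(frozen=True)
class MixedAnovaResult:
    """Clade effect on within-dataset RI differences + paired main effect."""

    clade_F: float
    clade_p: float
    within_t: float
    within_p: float
    mean_difference: float


def fishers_combined(pvals: Sequence[float]) -> FisherResult:
    """Fisher's combined probability over independent p-values."""
    ps = [float(p) for p in pvals]
    if not ps:
        raise ValidationError("no p-values to combine")
    for p in ps:
        if not (0.0 < p <= 1.0):
            raise ValidationError(f"p-value {p} outside (0, 1]")
    x2 = -2.0 * sum(math.log(p) for p in ps)
    df = 2 * len(ps)
    return FisherResult(x2=x2, df=df, p=float(stats.chi2.sf(x2, df)))


def bonferroni_alpha(alpha: float, k: int) -> BonferroniResult:
    """Family-wise threshold ``alpha / k`` with a 2-significant-figure
    rendering for reporting."""
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must be in (0, 1)")
    if k < 1:
        raise ValidationError("k must be >= 1")
    t = alpha / k
    return BonferroniResult(alpha=alpha, k=k, threshold=t, rendered=f"{t:.2g}")


def _check_groups(values, groups):
    values = [float(v) for v in values]
    groups = list(groups)
    if len(values) != len(groups):
        raise ValidationError("values and groups must align")
    by = {}
    for v, g in zip(values, groups):
        by.setdefault(g, []).append(v)
    return by


def anova_between(values: Sequence[float], groups: Sequence[str]) -> AnovaResult:
    """One-way fixed-effects ANOVA of values across groups.

    Returns NaN fields when F is undefined (all values identical).
    """
    by = _check_groups(values, groups)
    if len(by) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    if not any(len(v) >= 2 for v in by.values()):
        raise ValidationError("ANOVA needs a group with >= 2 values")
    samples = list(by.values())
    n = sum(len(s) for s in samples)
    dfb = len(samples) - 1
    dfw = n - len(samples)
    allv = np.concatenate([np.asarray(s) for s in samples])
    if np.allclose(allv, allv[0]):
        return AnovaResult(math.nan, math.nan, dfb, dfw)
    res = stats.f_oneway(*samples)
    return AnovaResult(float(res.statistic), float(res.pvalue), dfb, dfw)


def anova_mixed(
    ri_hard: Sequence[float],
    ri_soft: Sequence[float],
    groups: Sequence[str],
) -> MixedAnovaResult:
    """Clade effect on the hard-soft RI contrast (difference scores).

    Each dataset contributes one ``(RI_hard, RI_soft)`` pair; the clade
    effect is a one-way ANOVA of ``d = RI_hard - RI_soft`` across
    clades, and the within-factor main effect is a one-sample t-test of
    mean ``d`` against zero.  All-zero differences give ``p = 1`` for
    the within effect and an undefined (NaN) clade effect.
    """
    h = np.asarray(ri_hard, dtype=float)
    s = np.asarray(ri_soft, dtype=float)
    if h.shape != s.shape:
        raise ValidationError("ri_hard and ri_soft must pair up")
    d = h - s
    if d.size == 0:
        raise ValidationError("anova_mixed needs at least one dataset")
    by = _check_groups(d, groups)
    if np.allclose(d, d[0]):
        # zero variance: the paired test degenerates
        within_t, within_p = (0.0, 1.0) if np.allclose(d, 0.0) else (
            math.inf, 0.0
        )
    else:
        tr = stats.ttest_1samp(d, 0.0)
        within_t, within_p = float(tr.statistic), float(tr.pvalue)
    if len(by) >= 2 and any(len(v) >= 2 for v in by.values()):
        clade = anova_between(d, groups)
        clade_F, clade_p = clade.F, clade.p
    else:
        clade_F = clade_p = math.nan
    return MixedAnovaResult(
        clade_F=clade_F,
        clade_p=clade_p,
        within_t=within_t,
        within_p=within_p,
        mean_difference=float(d.mean()),
    )
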