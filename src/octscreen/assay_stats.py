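"""Screening-assay quality statistics.

Implements the standard plate-screening QC toolkit on control groups of one
readout: the Z'-factor, Z' = 1 - 3(sigma_p + sigma_n)/|mu_p - mu_n|, whose
value in [0.5, 1] is conventionally 'excellent'; the strictly standardized
mean difference, beta = (mu_p - mu_n)/sqrt(sigma_p^2 + sigma_n^2), for which
|beta| > 2 is excellent at small control group sizes; pooled-SD
repeatability (within-sample, across repeated acquisitions) and
reproducibility (across samples under one condition); percent change
between timepoints; and a two-sided Welch t-test for group comparison.

Sample standard deviations use the n-1 denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError, UndefinedStatisticError


@dataclass
class GroupStats:
    """Mean/SD/count of one readout for the positive and negative controls."""

    mu_positive: float
    sigma_positive: float
    n_positive: int
    mu_negative: float
    sigma_negative: float
    n_negative: int

    def __post_init__(self) -> None:
        if self.sigma_positive < 0 or self.sigma_negative < 0:
            raise ParameterError("standard deviations must be non-negative")

    @classmethod
    def from_samples(cls, positive: Sequence[float],
                     negative: Sequence[float]) -> "GroupStats":
        pos = np.asarray(positive, dtype=np.float64)
        neg = np.asarray(negative, dtype=np.float64)
        if pos.size < 2 or neg.size < 2:
            raise ParameterError("each control group needs >= 2 values")
        return cls(
            mu_positive=float(pos.mean()),
            sigma_positive=float(pos.std(ddof=1)),
            n_positive=int(pos.size),
            mu_negative=float(neg.mean()),
            sigma_negative=float(neg.std(ddof=1)),
            n_negative=int(neg.size),
        )


@dataclass
class AssayQuality:
    """Z' and SSMD for one readout, with qualitative flags."""

    readout: str
    zprime: float
    ssmd: float
    flags: dict = field(default_factory=dict)


def zprime(g: GroupStats) -> float:
    """Z'-factor: 1 - 3(sigma_p + sigma_n)/|mu_p - mu_n|. Always <= 1."""
    delta = g.mu_positive - g.mu_negative
    if delta == 0:
        raise UndefinedStatisticError("Z' undefined when group means coincide")
    return 1.0 - 3.0 * (g.sigma_positive + g.sigma_negative) / abs(delta)


def ssmd(g: GroupStats) -> float:
    """SSMD (beta): (mu_p - mu_n)/sqrt(sigma_p^2 + sigma_n^2)."""
    var = g.sigma_positive ** 2 + g.sigma_negative ** 2
    if var == 0:
        raise UndefinedStatisticError("SSMD undefined with zero variance in "
                                      "both groups")
    return (g.mu_positive - g.mu_negative) / float(np.sqrt(var))


def pooled_sd(groups: Iterable[Sequence[float]]) -> float:
    """Pooled standard deviation over replicate sets.

    sqrt( sum_i (n_i - 1) s_i^2 / sum_i (n_i - 1) ), with s_i the ddof=1
    sample SD of set i. Every set must hold at least two values.
    """
    num = 0.0
    dof = 0
    n_sets = 0
    for g in groups:
        arr = np.asarray(g, dtype=np.float64)
        if arr.size < 2:
            raise ParameterError("each replicate set needs >= 2 values")
        num += (arr.size - 1) * float(arr.var(ddof=1))
        dof += arr.size - 1
        n_sets += 1
    if n_sets == 0:
        raise ParameterError("no replicate sets given")
    return float(np.sqrt(num / dof))


def repeatability(table, readout: str) -> float:
    """Within-sample pooled SD of ``readout`` across repeated acquisitions.

    ``table`` is a screen DataFrame with sample_id / timepoint / repetition
    columns; repetitions of one sample at one timepoint form one replicate
    set, and the sets are pooled over all samples and timepoints.
    """
    keys = [k for k in ("sample_id", "timepoint") if k in table.columns]
    sets = [grp[readout].to_numpy() for _, grp in table.groupby(keys)]
    return pooled_sd(sets)


def reproducibility(table, condition, readout: str,
                    condition_cols: Sequence[str] = ("group", "timepoint")
                    ) -> float:
    """Between-sample SD of ``readout`` under one condition.

    Repetitions are first averaged per sample so acquisition noise does not
    inflate the between-sample spread; the SD is then taken across the
    per-sample means of all samples matching ``condition`` (a value or tuple
    aligned with ``condition_cols``).
    """
    if isinstance(condition, str):
        condition = (condition,)
    sub = table
    for col, val in zip(condition_cols, condition):
        sub = sub[sub[col] == val]
    means = sub.groupby("sample_id")[readout].mean().to_numpy()
    if means.size < 2:
        raise ParameterError("need >= 2 samples under the condition")
    return float(np.std(means, ddof=1))


def percent_change(baseline: float, followup: float) -> float:
    """Signed percent change from baseline: 100 (followup - baseline)/baseline."""
    if baseline == 0:
        raise ParameterError("baseline must be nonzero")
    return 100.0 * (followup - baseline) / baseline


def quality_flag(q: AssayQuality, n_per_group: int | None = None) -> dict:
    """Qualitative flags: Z' in [0.5, 1] and |beta| > 2 rate 'excellent'."""
    return {
        "zprime": "excellent" if 0.5 <= q.zprime <= 1.0 else "below-threshold",
        "ssmd": "excellent" if abs(q.ssmd) > 2.0 else "below-threshold",
    }


def assess(positive: Sequence[float], negative: Sequence[float],
           readout: str = "") -> AssayQuality:
    """Z', SSMD and flags for one readout from raw control-group values."""
    g = GroupStats.from_samples(positive, negative)
    q = AssayQuality(readout=readout, zprime=zprime(g), ssmd=ssmd(g))
    q.flags = quality_flag(q, n_per_group=min(g.n_positive, g.n_negative))
    return q


def group_compare(values_a: Sequence[float],
                  values_b: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value between two groups of readouts."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs >= 2 values")
    if a.var(ddof=1) + b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 1.0
        raise UndefinedStatisticError("zero variance with different means")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
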