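"""Group comparisons from summary statistics, and oxygen penetration depth.

One-way ANOVA and Tukey's HSD simultaneous confidence intervals can be
computed exactly from per-group (mean, SD, n) triples — the moments are
sufficient — which lets published comparisons (e.g. surface-water CH4
concentrations inside versus outside a macroalgae stand) be reproduced
from printed summaries without the raw data.  The studentized-range
quantile comes from scipy.

Also implements the standard microprofile rule for oxygen penetration
depth: the shallowest sediment depth where O2 drops below 1 uM, with a
persistence window so single noisy dips are not mistaken for the oxic
boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import InvalidInputError

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "TukeyResult",
    "summarize",
    "anova_from_summaries",
    "tukey_hsd_from_summaries",
    "oxygen_penetration_depth",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group: mean, sample SD and size."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidInputError(f"group {self.label!r}: n must be >= 2")
        if self.sd < 0:
            raise InvalidInputError(f"group {self.label!r}: sd must be >= 0")


@dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effects ANOVA computed from group summaries."""

    F: float
    df_between: int
    df_within: int
    msb: float
    mse: float
    p_value: float
    degenerate: bool = False  # True when MSE = 0 with nonzero MSB (F infinite)


@dataclass(frozen=True)
class TukeyResult:
    """One pairwise simultaneous comparison.

    ``difference = mean_b - mean_a`` for the declared pair order
    ``(label_a, label_b)``; the interval is symmetric about it.
    """

    pair: tuple[str, str]
    difference: float
    ci_low: float
    ci_high: float
    alpha: float
    df_within: int
    q_critical: float
    p_value: float


def summarize(label: str, values) -> GroupSummary:
    """Build a GroupSummary from raw observations (sample SD, ddof=1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InvalidInputError(f"group {label!r}: need at least 2 observations")
    return GroupSummary(label, float(arr.mean()), float(arr.std(ddof=1)), int(arr.size))


def _pooled(groups: Sequence[GroupSummary]):
    if len(groups) < 2:
        raise InvalidInputError("need at least 2 groups")
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise InvalidInputError("group labels must be unique")
    n_total = sum(g.n for g in groups)
    k = len(groups)
    grand = sum(g.n * g.mean for g in groups) / n_total
    ssb = sum(g.n * (g.mean - grand) ** 2 for g in groups)
    ssw = sum((g.n - 1) * g.sd**2 for g in groups)
    return n_total, k, ssb / (k - 1), ssw / (n_total - k)


def anova_from_summaries(groups: Sequence[GroupSummary]) -> AnovaResult:
    """One-way ANOVA from (mean, SD, n) triples.

    Identical to the raw-data ANOVA on any dataset with these exact
    moments: the between-group sum of squares needs only the means and
    sizes, the within-group sum only the SDs.  A zero MSE with nonzero
    MSB (identical values within groups, distinct between) yields an
    infinite F, flagged ``degenerate``.
    """
    n_total, k, msb, mse = _pooled(groups)
    df_b, df_w = k - 1, n_total - k
    if mse == 0:
        if msb == 0:
            return AnovaResult(0.0, df_b, df_w, msb, mse, 1.0)
        return AnovaResult(float("inf"), df_b, df_w, msb, mse, 0.0, degenerate=True)
    f = msb / mse
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, float(msb), float(mse), p)


def tukey_hsd_from_summaries(
    groups: Sequence[GroupSummary], alpha: float = 0.05
) -> list[TukeyResult]:
    """Tukey HSD simultaneous confidence intervals from group summaries.

    For each pair (a, b) in input order the interval is
    ``(mean_b - mean_a) +/- q_{1-alpha}(k, N-k) * sqrt(MSE/2 * (1/n_a + 1/n_b))``
    with q the studentized-range quantile (the Tukey-Kramer form for
    unequal group sizes).  The sign convention follows the declared pair
    order.
    """
    if not 0 < alpha < 1:
        raise InvalidInputError("alpha must be in (0, 1)")
    n_total, k, _, mse = _pooled(groups)
    df_w = n_total - k
    q_crit = float(stats.studentized_range.ppf(1 - alpha, k, df_w))
    out = []
    for a, b in combinations(groups, 2):
        diff = b.mean - a.mean
        se = math.sqrt(mse / 2.0 * (1.0 / a.n + 1.0 / b.n))
        half = q_crit * se
        if se > 0:
            p = float(stats.studentized_range.sf(abs(diff) / se, k, df_w))
        else:
            p = 1.0 if diff == 0 else 0.0
        out.append(
            TukeyResult(
                (a.label, b.label), diff, diff - half, diff + half,
                alpha, df_w, q_crit, p,
            )
        )
    return out


def oxygen_penetration_depth(
    depths,
    concentrations,
    threshold: float = 1.0,
    persistence: int = 3,
) -> float | None:
    """Oxygen penetration depth of a sediment microprofile.

    ``depths`` (um, positive downward from the sediment-water interface,
    strictly increasing) and ``concentrations`` (uM, NaN allowed for
    missing points).  Returns the shallowest depth >= 0 at which O2 is
    below ``threshold`` and stays below it for ``persistence``
    consecutive measured points (or to the end of the profile), so a
    single noisy sub-threshold dip does not count.  Returns ``None``
    when the threshold is never durably reached ("not reached").
    """
    depths = np.asarray(depths, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if depths.shape != conc.shape or depths.ndim != 1:
        raise InvalidInputError("depths and concentrations must be 1-D and equal length")
    if np.all(np.isnan(conc)):
        raise InvalidInputError("profile has no measured concentrations")
    if np.any(np.diff(depths) <= 0):
        raise InvalidInputError("depths must be strictly increasing")
    if persistence < 1:
        raise InvalidInputError("persistence must be >= 1")
    if (conc[~np.isnan(conc)] < 0).any():
        raise InvalidInputError("concentrations must be >= 0")

    # only the sediment side of the interface counts
    sel = depths >= 0
    d = depths[sel]
    c = conc[sel]
    measured = ~np.isnan(c)
    d, c = d[measured], c[measured]
    below = c < threshold
    for i in range(len(d)):
        window = below[i : i + persistence]
        if window.size and window.all():
            return float(d[i])
    return None
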