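"""Trial-design and summary statistics for the noninferiority pilot.

This module implements the design computations of a two-arm noninferiority
trial with a continuous endpoint (change in Fugl-Meyer motor score over three
weeks) and the summary-level analyses used in its report:

* **Sample size** for noninferiority of two means with common SD sigma and
  margin delta = ``margin_fraction`` x sigma:

      n = ceil( (z_{alpha/2} + z_beta)^2 * 2*sigma^2 / (|mu1 - mu2| + delta)^2 )

  With the pilot's design values (one-sided alpha = .025 so z = 1.96,
  beta = .2 so z = 0.84, mu1 = 11.0, mu2 = 10.0, sigma = 5.5, margin 40% of
  sigma giving delta = 2.2) this yields 47 per group, inflated to 59 under a
  20% dropout allowance.

* **Group confidence intervals** recomputed from printed (n, mean, SD)
  triplets using the Student-t quantile with n-1 degrees of freedom.

* **Two-sample t tests from summary statistics** (Welch by default, pooled
  optional) and **2x2 proportion comparisons** (Pearson chi-square without
  continuity correction, matching the SAS default used for the report, plus
  Fisher's exact test for sparse tables).

* **Stratified permuted-block randomization**: within each stratum (study
  center) consecutive blocks of fixed even length each contain equal numbers
  of both arms in seeded-random order, keeping every complete block exactly
  1:1.

* The **FMA data model**: 50 items scored 0/1/2, partitioned into 33
  upper-extremity items (subtotal <= 66) and 17 lower-extremity items
  (subtotal <= 34), total <= 100.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ARM_LABELS = ("experimental", "control")

N_UPPER_ITEMS = 33
N_LOWER_ITEMS = 17
MAX_ITEM_SCORE = 2


@dataclass(frozen=True)
class SampleSizeParams:
    """Design symbols for the noninferiority sample-size formula."""

    z_alpha_half: float = 1.96  # one-sided alpha = .025
    z_beta: float = 0.84  # beta = .2, power 80%
    mu1: float = 11.0  # expected change, experimental arm
    mu2: float = 10.0  # expected change, control arm
    sigma: float = 5.5  # common SD of the change
    margin_fraction: float = 0.40  # delta as a fraction of sigma

    def validate(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.margin_fraction <= 0:
            raise ValueError("margin_fraction must be positive")
        if self.z_alpha_half <= 0 or self.z_beta <= 0:
            raise ValueError("z quantiles must be positive")

    @property
    def margin(self) -> float:
        """The noninferiority margin delta = margin_fraction * sigma."""
        return self.margin_fraction * self.sigma


def noninferiority_sample_size(p: SampleSizeParams) -> int:
    """Per-group sample size for the noninferiority comparison of two means."""
    p.validate()
    denom = abs(p.mu1 - p.mu2) + p.margin
    if denom == 0:
        raise ZeroDivisionError("mu1 - mu2 and the margin cannot both be zero")
    n = (p.z_alpha_half + p.z_beta) ** 2 * 2 * p.sigma**2 / denom**2
    return math.ceil(n)


def inflate_for_dropout(n: int, rate: float) -> int:
    """Enrollment per group needed so that n complete after a dropout fraction."""
    if not 0 <= rate < 1:
        raise ValueError(f"dropout rate must lie in [0, 1), got {rate}")
    return math.ceil(n / (1.0 - rate))


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics (n, mean, SD) for one group."""

    n: int
    mean: float
    sd: float

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


def group_ci(g: GroupSummary, level: float = 0.95) -> tuple[float, float]:
    """Two-sided Student-t confidence interval for the group mean.

    mean +/- t_{1-(1-level)/2, n-1} * sd / sqrt(n), full precision; callers
    that reproduce report tables round each limit to 2 decimals.
    """
    g.validate()
    t = stats.t.ppf(1 - (1 - level) / 2, g.n - 1)
    half = t * g.sd / math.sqrt(g.n)
    return (g.mean - half, g.mean + half)


def two_sample_test(
    g1: GroupSummary, g2: GroupSummary, equal_var: bool = False
) -> tuple[float, float, float]:
    """Two-sample t test from summary statistics: (t, df, two-sided p).

    Welch's unequal-variance form by default; ``equal_var=True`` gives the
    pooled-variance test.
    """
    g1.validate()
    g2.validate()
    res = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=equal_var
    )
    if equal_var:
        df = g1.n + g2.n - 2
    else:
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def incidence(k: int, n: int) -> float:
    """Event incidence as a percentage, rounded to 2 decimals (report convention)."""
    if n == 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return round(100.0 * k / n, 2)


def compare_proportions(
    k1: int, n1: int, k2: int, n2: int
) -> tuple[float, float, tuple[float, float]]:
    """Compare two binomial proportions via a 2x2 table.

    Returns (Pearson chi-square p, Fisher exact p, (incidence1 %, incidence2 %)).
    The chi-square statistic is computed without the Yates continuity
    correction (the SAS default); Fisher's exact test is the recommended
    substitute whenever any expected cell count is below 5.
    """
    inc = (incidence(k1, n1), incidence(k2, n2))
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        # degenerate margin: chi-square undefined, Fisher still works
        chi_p = float("nan")
    else:
        chi_p = float(stats.chi2_contingency(table, correction=False).pvalue)
    fisher_p = float(stats.fisher_exact(table).pvalue)
    return chi_p, fisher_p, inc


@dataclass
class AllocationList:
    """Stratified block-randomized arm assignments."""

    assignments: dict[str, list[str]]  # stratum id -> ordered arm labels
    block_length: int
    seed: int

    def flatten(self) -> pd.DataFrame:
        """One row per randomization number: stratum, sequence index, arm."""
        rows = []
        num = 1
        for stratum in self.assignments:
            for i, arm in enumerate(self.assignments[stratum]):
                rows.append(
                    {"randomization_number": num, "stratum": stratum, "index_in_stratum": i, "arm": arm}
                )
                num += 1
        return pd.DataFrame(rows, columns=["randomization_number", "stratum", "index_in_stratum", "arm"])


def block_randomize(
    n_per_stratum: Mapping[str, int] | Sequence[int] | int,
    block_length: int = 4,
    seed: int = 0,
    arms: tuple[str, str] = ARM_LABELS,
) -> AllocationList:
    """Generate a 1:1 stratified permuted-block allocation list.

    Within each stratum, consecutive blocks of ``block_length`` contain each
    arm exactly ``block_length / 2`` times in seeded-random order; a final
    partial block is truncated.  Deterministic for a fixed seed.
    """
    if block_length < 2 or block_length % 2 != 0:
        raise ValueError(f"block_length must be even and >= 2, got {block_length}")
    if isinstance(n_per_stratum, int):
        n_per_stratum = {"stratum_1": n_per_stratum}
    elif not isinstance(n_per_stratum, Mapping):
        n_per_stratum = {
            f"stratum_{i + 1}": n for i, n in enumerate(n_per_stratum)
        }
    rng = np.random.default_rng(seed)
    half = block_length // 2
    assignments: dict[str, list[str]] = {}
    for stratum, n in n_per_stratum.items():
        if n < 0:
            raise ValueError(f"stratum size must be >= 0, got {n}")
        seq: list[str] = []
        while len(seq) < n:
            block = [arms[0]] * half + [arms[1]] * half
            rng.shuffle(block)
            seq.extend(block)
        assignments[stratum] = seq[:n]
    return AllocationList(assignments=assignments, block_length=block_length, seed=seed)


@dataclass(frozen=True)
class FmaAssessment:
    """One Fugl-Meyer motor assessment: 33 upper + 17 lower items scored 0/1/2."""

    upper_items: tuple[int, ...]
    lower_items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.upper_items) != N_UPPER_ITEMS:
            raise ValueError(
                f"expected {N_UPPER_ITEMS} upper-extremity items, got {len(self.upper_items)}"
            )
        if len(self.lower_items) != N_LOWER_ITEMS:
            raise ValueError(
                f"expected {N_LOWER_ITEMS} lower-extremity items, got {len(self.lower_items)}"
            )
        for v in (*self.upper_items, *self.lower_items):
            if v not in (0, 1, 2):
                raise ValueError(f"item scores must be 0, 1 or 2, got {v}")


def fma_totals(a: FmaAssessment) -> tuple[int, int, int]:
    """(upper subtotal, lower subtotal, total); maxima are 66, 34 and 100."""
    upper = sum(a.upper_items)
    lower = sum(a.lower_items)
    return upper, lower, upper + lower
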