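"""Count-derived proportion summaries.

Small-n cytological counts (e.g. how many pachytene cells with paired sex
chromosomes are in early/mid pachynema) are reported as integer percents
with an exact 95% binomial confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class ProportionSummary:
    """k successes of n trials, as a rounded percent with an exact CI."""

    k: int
    n: int
    percent: int
    ci: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not (0 <= self.k <= self.n):
            raise ValueError("need 0 <= k <= n")
        if not (0 <= self.percent <= 100):
            raise ValueError("percent out of range")
        lo, hi = self.ci
        if not (lo <= self.k / self.n <= hi):
            raise ValueError("CI must cover the point estimate")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial confidence interval for k/n."""
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def proportion_from_counts(k: int, n: int) -> ProportionSummary:
    """Percent (rounded half away from zero) plus exact 95% CI for k of n.

    Examples: 8 of 9 -> 89%; 32 of 59 -> 54%; 27 of 59 -> 46%.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    percent = _round_half_away(100.0 * k / n)
    return ProportionSummary(k=k, n=n, percent=percent, ci=clopper_pearson(k, n))
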