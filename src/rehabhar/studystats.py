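"""Study-design arithmetic: drop-out rates and the power-analysis
sample size.

The sample-size search assumes a paired (one-sample) t test on
pre–post change: for candidate size n, power is computed exactly from
the noncentral-t distribution with df = n - 1 and noncentrality
d * sqrt(n), and the smallest n reaching the target power is inflated
for anticipated loss as ceil(n / (1 - loss_rate)).
"""

from __future__ import annotations

import dataclasses
import math

from scipy import stats


@dataclasses.dataclass
class EnrollmentCount:
    enrolled: int
    dropped: int

    def __post_init__(self) -> None:
        if self.enrolled <= 0:
            raise ValueError("enrolled must be > 0")
        if not (0 <= self.dropped <= self.enrolled):
            raise ValueError("dropped must be within [0, enrolled]")


def dropout_rate(e: EnrollmentCount) -> float:
    """Drop-out percentage at full precision (100 * dropped / enrolled)."""
    return 100.0 * e.dropped / e.enrolled


def display_dropout(e: EnrollmentCount) -> int:
    """Integer display rounding, half away from zero."""
    return int(math.floor(dropout_rate(e) + 0.5))


@dataclasses.dataclass
class PowerSpec:
    """Inputs of the sample-size calculation.

    effect_size_d : Cohen's d of the paired change (mean / SD)
    alpha         : two-tailed type-I error level
    power         : target power (1 - beta)
    loss_rate     : anticipated attrition fraction
    """

    effect_size_d: float
    alpha: float = 0.05
    power: float = 0.80
    loss_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.power < 1):
            raise ValueError("power must be in (0, 1)")
        if not (0 <= self.loss_rate < 1):
            raise ValueError("loss rate must be in [0, 1)")
        if self.effect_size_d <= 0:
            raise ValueError("effect size must be positive")


def cohens_d_from_change(mean_change: float, sd_change: float) -> float:
    """Paired-change effect size d = mean change / SD of change."""
    if sd_change <= 0:
        raise ValueError("SD of change must be positive")
    return mean_change / sd_change


def paired_t_power(d: float, n: int, alpha: float = 0.05) -> float:
    """Exact power of a two-tailed paired t test at size n.

    Under the alternative the t statistic is noncentral t with
    df = n - 1 and noncentrality d * sqrt(n); power is the probability
    of exceeding the two-tailed critical value.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    df = n - 1
    nc = d * math.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(
        1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    )


def required_sample_size(spec: PowerSpec, n_max: int = 10**6) -> int:
    """Smallest n whose paired-t power reaches the target, inflated
    for anticipated loss (ceil(n / (1 - loss_rate)))."""
    for n in range(2, n_max + 1):
        if paired_t_power(spec.effect_size_d, n, spec.alpha) >= spec.power:
            return math.ceil(n / (1.0 - spec.loss_rate))
    raise ValueError(f"target power not attainable within n <= {n_max}")
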