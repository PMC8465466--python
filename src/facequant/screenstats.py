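"""Screening statistics: confusion-matrix metrics, 2x2 chi-square tests,
prevalence-based validation-set sizing and scenario expansion.

Diagnostic metrics follow the usual screening definitions with the case
class as positive:

    ACC = (TP + TN) / (TP + FN + FP + TN)
    SEN = TP / (TP + FN)          (recall on cases)
    SPE = TN / (TN + FP)          (recall on controls)

all reported as percentages rounded half-up to two decimals; the exact
rational values are kept internally.

Validation-set sizing uses the Buderer-type precision formula: the
minimum number of cases needed to estimate sensitivity within a
half-width ``margin`` at confidence 1 - alpha is

    n_case = ceil( z^2 * sens * (1 - sens) / margin^2 ),

with z the standard-normal quantile at 1 - alpha/2, and the control
count follows from the screened population's prevalence,
``n_control = ceil(n_case * (1 - prevalence) / prevalence)``.  Scenario
expansion scales a base design by a list of factors with half-up
rounding, modelling progressively larger realistic screening sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats


class UndefinedMetricError(ZeroDivisionError):
    def __init__(self, metric: str):
        self.metric = metric
        super().__init__(f"metric '{metric}' is undefined (zero denominator)")


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FN/FP/TN counts for one evaluation dataset (positive = case)."""

    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self):
        for f in ("TP", "FN", "FP", "TN"):
            v = getattr(self, f)
            if v < 0 or v != int(v):
                raise ValueError(f"{f} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN

    @property
    def n_case(self) -> int:
        return self.TP + self.FN

    @property
    def n_control(self) -> int:
        return self.FP + self.TN


def _pct(num: int, den: int) -> float:
    """Exact percentage num/den rounded half-up to two decimals."""
    return float((Decimal(100 * num) / Decimal(den)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float


def confusion_metrics(cm: ConfusionMatrix) -> Metrics:
    """ACC/SEN/SPE in percent, rounded half-up to two decimals.

    Raises :class:`UndefinedMetricError` naming the first metric whose
    denominator is zero.
    """
    if cm.total == 0:
        raise UndefinedMetricError("accuracy")
    if cm.n_case == 0:
        raise UndefinedMetricError("sensitivity")
    if cm.n_control == 0:
        raise UndefinedMetricError("specificity")
    return Metrics(
        accuracy=_pct(cm.TP + cm.TN, cm.total),
        sensitivity=_pct(cm.TP, cm.n_case),
        specificity=_pct(cm.TN, cm.n_control),
    )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    direction: str  # "case-higher" | "control-higher" | "equal"


def chi_square_2x2(a: int, b: int, c: int, d: int, correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]].

    Row 1 is the case group (a hits, b misses), row 2 the control group.
    Yates continuity correction is off by default; the table cell counts
    this test is meant for are large enough that it is immaterial.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0:
        raise ValueError("both row totals must be positive")
    table = np.array([[a, b], [c, d]], dtype=float)
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        # degenerate column: no association measurable
        stat, p = 0.0, 1.0
    else:
        stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    p_case = a / (a + b)
    p_control = c / (c + d)
    if p_case > p_control:
        direction = "case-higher"
    elif p_case < p_control:
        direction = "control-higher"
    else:
        direction = "equal"
    return ChiSquareResult(statistic=float(stat), df=1, p_value=float(p), direction=direction)


@dataclass(frozen=True)
class ValidationDesign:
    """Inputs for prevalence-based validation-set sizing.

    ``power`` is carried for record-keeping; the Buderer-type precision
    formula used here is driven by ``alpha`` and ``margin`` alone.
    """

    prevalence: float
    sensitivity: float
    specificity: float = 0.9
    margin: float = 0.1
    alpha: float = 0.05
    power: float = 0.90
    expansion_factors: tuple = (1.5, 2.0, 2.5, 3.0, 5.0)

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie strictly between 0 and 1")
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if not 0 < self.sensitivity < 1:
            raise ValueError("sensitivity must lie strictly between 0 and 1")
        if any(f < 1 for f in self.expansion_factors):
            raise ValueError("expansion factors must be >= 1")


def min_validation_sample(design: ValidationDesign) -> tuple[int, int]:
    """Minimum (n_case, n_control) for the design, both rounded up."""
    z = stats.norm.ppf(1 - design.alpha / 2)
    n_case = math.ceil(z**2 * design.sensitivity * (1 - design.sensitivity) / design.margin**2)
    n_case = max(n_case, 1)
    n_control = math.ceil(n_case * (1 - design.prevalence) / design.prevalence)
    return n_case, n_control


def _round_half_up(x: Decimal) -> int:
    return int(x.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def scenario_expand(base: tuple[int, int], factors) -> list[tuple[int, int]]:
    """Base design followed by each factor-scaled design (half-up rounding)."""
    n_case, n_control = base
    out = [(int(n_case), int(n_control))]
    for f in factors:
        if f < 1:
            raise ValueError("expansion factors must be >= 1")
        fd = Decimal(str(f))
        out.append((_round_half_up(fd * n_case), _round_half_up(fd * n_control)))
    return out


def sample_validation_set(pool, scenario: tuple[int, int], seed: int, label_col: str = "label"):
    """Draw a validation manifest: ``scenario`` = (n_case, n_control) rows
    sampled uniformly without replacement per class from ``pool``."""
    n_case, n_control = scenario
    rng = np.random.default_rng(seed)
    parts = []
    for label, n in (("case", n_case), ("control", n_control)):
        sub = pool[pool[label_col] == label]
        if len(sub) < n:
            raise ValueError(
                f"pool has only {len(sub)} {label} rows, {n} requested")
        take = rng.choice(len(sub), size=n, replace=False)
        parts.append(sub.iloc[np.sort(take)])
    import pandas as pd

    return pd.concat(parts, ignore_index=True)
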