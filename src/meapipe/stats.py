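"""Effect sizes, multiplicity correction and distribution-shape helpers.

Only the formulas the study protocol states explicitly live here; standard
tests (Mann-Whitney, Wilcoxon, Kolmogorov-Smirnov, Welch, mixed models) are
delegated to scipy/statsmodels by the pipeline.

Effect sizes are expressed on the correlation scale r in [0, 1] with the
usual benchmarks: r < 0.3 small, 0.3-0.5 moderate, > 0.5 strong.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "EffectSize",
    "r_from_t",
    "r_wendt",
    "r_from_d",
    "sidak_adjust",
    "sample_skewness",
    "benchmark_label",
]


def benchmark_label(r: float) -> str:
    if r < 0.3:
        return "small"
    if r <= 0.5:
        return "moderate"
    return "strong"


@dataclass(frozen=True)
class EffectSize:
    r: float
    source: str  # t_test | mann_whitney_wendt | cohens_d

    @property
    def benchmark(self) -> str:
        return benchmark_label(self.r)


def r_from_t(t: float, df: float) -> EffectSize:
    """r = sqrt(t^2 / (t^2 + df)) for an unpaired t statistic."""
    if df <= 0:
        raise ValueError("df must be positive")
    return EffectSize(math.sqrt(t * t / (t * t + df)), "t_test")


def r_wendt(u: float, n1: int, n2: int) -> EffectSize:
    """Wendt's rank-biserial effect size magnitude: r = |1 - 2U/(n1*n2)|."""
    if not 0 <= u <= n1 * n2:
        raise ValueError("U must lie in [0, n1*n2]")
    return EffectSize(abs(1.0 - 2.0 * u / (n1 * n2)), "mann_whitney_wendt")


def r_from_d(d: float) -> EffectSize:
    """Cohen's d converted to r (equal-group convention): r = |d|/sqrt(d^2+4)."""
    return EffectSize(abs(d) / math.sqrt(d * d + 4.0), "cohens_d")


def sidak_adjust(p: float, m: int) -> float:
    """Sidak multiplicity correction: p_adj = 1 - (1-p)^m, capped at 1."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, 1.0 - (1.0 - p) ** m)


def sample_skewness(values: Sequence[float] | np.ndarray) -> float:
    """Adjusted Fisher-Pearson standardized third moment (bias-corrected G1).

    Returns NaN for n < 3; returns 0.0 for zero-variance samples (the
    flagged degenerate convention used by the STTC summary).
    """
    x = np.asarray(values, float)
    if x.size < 3:
        return math.nan
    if np.all(x == x[0]):
        return 0.0
    return float(sps.skew(x, bias=False))
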