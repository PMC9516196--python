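"""Chi-square goodness-of-fit tests for Mendelian segregation ratios.

For a 2-class test (e.g. 29 mutant : 91 non-mutant against 1:3) the Yates
continuity correction is applied by default: with one degree of freedom and
small counts the uncorrected statistic is anticonservative, and the corrected
form chi2 = sum (max(|O - E| - 0.5, 0))^2 / E is the standard convention for
hand-scored F2 phenotype classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class SegregationCounts:
    """Observed phenotype-class counts and the expected integer ratio."""

    observed: tuple[int, ...]
    expected_ratio: tuple[int, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        obs = tuple(int(o) for o in self.observed)
        ratio = tuple(int(r) for r in self.expected_ratio)
        if len(obs) != len(ratio):
            raise ValueError("observed and expected_ratio must have the same length")
        if len(obs) < 2:
            raise ValueError("need at least two phenotype classes")
        if any(o < 0 for o in obs):
            raise ValueError("observed counts must be >= 0")
        if any(r <= 0 for r in ratio):
            raise ValueError("ratio entries must be > 0")
        if self.labels is not None and len(self.labels) != len(obs):
            raise ValueError("labels length mismatch")
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "expected_ratio", ratio)


@dataclass(frozen=True)
class SegregationTestResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float
    expected: tuple[float, ...]
    yates: bool


def chi_square_segregation(
    counts: SegregationCounts, yates: bool | None = None
) -> SegregationTestResult:
    """Goodness-of-fit chi-square of observed counts against an integer ratio.

    ``yates=None`` applies the continuity correction for 2-class tests and no
    correction otherwise.  The corrected deviation |O - E| - 0.5 is clamped at
    zero so near-perfect fits cannot contribute negatively.
    """
    obs = np.asarray(counts.observed, dtype=float)
    total = obs.sum()
    if total <= 0:
        raise ValueError("total observed count must be > 0")
    ratio = np.asarray(counts.expected_ratio, dtype=float)
    expected = total * ratio / ratio.sum()
    if np.any(expected == 0):
        raise ValueError("expected count of zero")
    if np.any(expected < 5):
        warnings.warn(
            "expected count below 5; chi-square approximation may be poor",
            stacklevel=2,
        )
    if yates is None:
        yates = len(obs) == 2
    c = 0.5 if yates else 0.0
    dev = np.maximum(np.abs(obs - expected) - c, 0.0)
    statistic = float(np.sum(dev**2 / expected))
    df = len(obs) - 1
    p = float(stats.chi2.sf(statistic, df))
    return SegregationTestResult(
        statistic=statistic,
        degrees_of_freedom=df,
        p_value=p,
        expected=tuple(expected),
        yates=bool(yates),
    )
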