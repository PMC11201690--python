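"""Group summaries, significance annotation, and concentration trends.

Experimental conditions are compared as mean ± sample SD per group, with
pairwise Welch (unequal-variance) t-tests annotated in the conventional
star style: NS (p >= 0.05), * (p < 0.05), ** (p < 0.01), *** (p < 0.001).
No multiple-testing correction is applied — the annotation mirrors the
pairwise figure style it reproduces.

The microparticle dilution series is summarized by an ordinary
least-squares fit of speckle size on an explicit concentration encoding
(dilution index or volume-percent); the encoding is an argument and is
echoed in the result rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "LinearFit",
    "summarize_groups",
    "compare_groups",
    "star_label",
    "fit_concentration_trend",
]

#: Significance thresholds, ordered most to least stringent.
STAR_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± sample SD of one experimental group."""

    label: str
    n: int
    mean: float
    sd: Optional[float]  # None when n < 2 (undefined)
    units: str = ""


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line with its predictor encoding recorded."""

    slope: float
    intercept: float
    encoding: str
    r_value: float


def summarize_groups(
    groups: Mapping[str, Sequence[float]],
    units: str = "",
) -> list[GroupSummary]:
    """Mean and sample (n-1) SD per group, in input order.

    Groups with a single value get ``sd=None`` (undefined), never 0.
    """
    out = []
    for label, values in groups.items():
        arr = np.asarray(values, float)
        if arr.size == 0:
            raise ValueError(f"group {label!r} is empty")
        sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
        out.append(GroupSummary(label=label, n=int(arr.size),
                                mean=float(arr.mean()), sd=sd, units=units))
    return out


def star_label(p_value: float) -> str:
    """Map a p-value to NS/*/**/*** at the conventional cut-offs.

    Thresholds are strict: p exactly at a cut-off gets the weaker label
    (p = 0.05 is NS, p = 0.049 is *).
    """
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p-value out of range: {p_value}")
    for threshold, label in STAR_THRESHOLDS:
        if p_value < threshold:
            return label
    return "NS"


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
) -> tuple[float, str]:
    """Welch two-sample t-test between two groups with a star label.

    Returns ``(p_value, label)``.  Two zero-variance groups with equal
    means are reported as NS (p = 1) rather than raising.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        return p, star_label(p) if p > 0 else "***"
    _, p = sps.ttest_ind(a, b, equal_var=False)
    p = float(p)
    return p, star_label(p)


def fit_concentration_trend(
    concentrations: Sequence[float],
    sizes: Sequence[float],
    encoding: str = "dilution-index",
) -> LinearFit:
    """OLS fit of speckle size on a concentration predictor.

    ``encoding`` documents what the x values mean (e.g. "dilution-index"
    for 1/2/3, "volume-percent" for 10/30/50); it is echoed in the result
    because the physical encoding behind any single slope is otherwise
    ambiguous.

    Raises
    ------
    ValueError
        If fewer than 2 distinct concentration levels are given.
    """
    x = np.asarray(concentrations, float)
    y = np.asarray(sizes, float)
    if x.shape != y.shape:
        raise ValueError("concentrations and sizes must align")
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct concentration levels")
    res = sps.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        encoding=encoding,
        r_value=float(res.rvalue),
    )
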