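"""Per-strain record assembly and the regression/hypothesis-test layer.

Joins fitness, divergence, EF-Tu abundance, synthesis rate, viability and
codon-adaptation values into strain records, then provides ordinary
least-squares fits (with R² and slope p-value) and the unpaired two-tailed
t-test used to compare fitness groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CorrelateError",
    "StrainRecord",
    "RegressionResult",
    "TTestResult",
    "linear_fit",
    "compare_groups",
    "fit_records",
]


class CorrelateError(ValueError):
    """Raised for degenerate or insufficient regression input."""


@dataclass
class StrainRecord:
    strain_id: str
    tuf_source: str = ""
    fitness: float | None = None              # relative to the native-tuf strain
    divergence: float | None = None           # normalized to [0, 1]
    ef_tu_abundance: float | None = None      # fraction of total protein
    synthesis_rate: float | None = None       # amino acids / second
    viable: bool | None = None
    tufB_amplified: bool = False
    cai: float | None = None
    ancestral: bool = False                   # reconstructed-ancestor source

    def __post_init__(self) -> None:
        if self.fitness is not None and self.fitness <= 0:
            raise CorrelateError(f"strain {self.strain_id}: fitness must be > 0")
        if self.divergence is not None and not (0 <= self.divergence <= 1):
            raise CorrelateError(f"strain {self.strain_id}: divergence must lie in [0, 1]")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    p_value: float


@dataclass
class TTestResult:
    t_statistic: float
    p_value: float
    df: float


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with R² and two-sided slope p-value.

    A constant y is a defined degenerate case (slope 0, R² 0, p 1); a
    constant x cannot identify a slope and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise CorrelateError("x and y must have equal length")
    if x.size < 3:
        raise CorrelateError(f"insufficient data: n={x.size} < 3")
    if np.ptp(x) == 0:
        raise CorrelateError("x is constant; slope is unidentifiable")
    if np.ptp(y) == 0:
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                                n=int(x.size), p_value=1.0)
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n=int(x.size),
        p_value=float(res.pvalue),
    )


def fit_records(
    records: list[StrainRecord],
    x_field: str,
    y_field: str,
    exclude_ancestral: bool = False,
) -> RegressionResult:
    """Regress one strain-record field on another, dropping incomplete records.

    ``exclude_ancestral=True`` restricts the fit to extant-source strains,
    the convention used when relating fitness to abundance or divergence
    (reconstructed ancestors can be outliers on those axes).
    """
    xs, ys = [], []
    for rec in records:
        if exclude_ancestral and rec.ancestral:
            continue
        xv = getattr(rec, x_field)
        yv = getattr(rec, y_field)
        if xv is None or yv is None:
            continue
        xs.append(float(xv))
        ys.append(float(yv))
    return linear_fit(xs, ys)


def compare_groups(a, b, equal_var: bool = True) -> TTestResult:
    """Unpaired two-tailed t-test between two groups.

    Pooled-variance (Student) by default; ``equal_var=False`` switches to
    Welch.  Degrees of freedom are reported exactly (n1+n2-2 for pooled,
    Welch-Satterthwaite otherwise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise CorrelateError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = float(a.size + b.size - 2)
    else:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = float((va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1)))
    t = float(res.statistic)
    p = 1.0 if math.isnan(res.pvalue) else float(res.pvalue)
    if math.isnan(t):  # identical zero-variance groups
        t = 0.0
    return TTestResult(t_statistic=t, p_value=p, df=df)
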