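"""Test–retest agreement: bias, limits of agreement, and ICC(2,1).

Scan–rescan reliability of the derived measurements is summarised by the
Bland–Altman-style bias (mean and SD of paired differences, with 95% limits
of agreement bias ± 1.96 SD) and by the single-measure intraclass
correlation coefficient from the two-way random-effects model for absolute
agreement, ICC(2,1):

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

where MS_R, MS_C and MS_E are the rows (subjects), columns (occasions) and
error mean squares of the two-way ANOVA over an n-subject × k-occasion
table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["AgreementResult", "bias_loa", "icc_two_way_random_absolute", "pointwise_icc"]


@dataclass
class AgreementResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    icc: float | None = None

    def to_dict(self) -> dict:
        d = {
            "bias": self.bias,
            "sd": self.sd,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
        }
        if self.icc is not None:
            d["icc"] = self.icc
        return d


def bias_loa(m1: np.ndarray, m2: np.ndarray) -> AgreementResult:
    """Bias (mean, SD of paired differences) and 95% limits of agreement."""
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape:
        raise ValueError("paired measurements must have equal length")
    d = m1 - m2
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return AgreementResult(bias=bias, sd=sd, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)


def icc_two_way_random_absolute(table: np.ndarray) -> float:
    """Single-measure ICC(2,1), two-way random effects, absolute agreement.

    ``table`` is subjects × occasions with no missing cells.  Zero
    between-subject variance returns 0 by convention (flagged).
    """
    X = np.asarray(table, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 occasions")
    if not np.isfinite(X).all():
        raise ValueError("missing cells are not supported")
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if ms_r <= ms_e or denom <= 0:
        warnings.warn("no between-subject variance; ICC set to 0", stacklevel=2)
        return 0.0
    return float((ms_r - ms_e) / denom)


def pointwise_icc(excursion_1: np.ndarray, excursion_2: np.ndarray) -> float:
    """Cohort reliability of pointwise excursion.

    ICC(2,1) is computed per vertex from the two scan occasions and
    summarised by the mean over vertices (one number is reported for the
    whole surface; the mean is the aggregation used here).
    """
    a = np.asarray(excursion_1, dtype=float)
    b = np.asarray(excursion_2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("excursion matrices must have equal shape")
    iccs = np.empty(a.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for v in range(a.shape[1]):
            iccs[v] = icc_two_way_random_absolute(np.column_stack([a[:, v], b[:, v]]))
    return float(iccs.mean())
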