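"""Validation statistics for comparing motion traces.

Implements the comparison toolkit used to validate manual, registration-
derived and GP-predicted landmark traces against each other: absolute
point-wise deviations (PWD) per axis and in-plane 2D, root-mean-square
deviation (RMSD), the two-sided Wilcoxon signed-rank test, and the
1.5 x IQR outlier rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import ComparisonReport, MotionTrace
from .errors import ContractError, InsufficientDataError

__all__ = [
    "pwd",
    "rmsd",
    "wilcoxon_two_sided",
    "WilcoxonResult",
    "flag_outliers",
    "compare_traces",
]


def pwd(a: MotionTrace, b: MotionTrace):
    """Absolute point-wise deviations between two frame-aligned traces.

    Returns ``(per_axis, pwd_2d)``: a dict of |a - b| series per shared
    axis, and the per-frame Euclidean norm over the first two shared
    (in-plane) axes.
    """
    if len(a) != len(b):
        raise ContractError(f"trace lengths differ: {len(a)} vs {len(b)}")
    shared = [ax for ax in a.axes if ax in b.axes]
    if not shared:
        raise ContractError("traces share no axis")
    per_axis = {ax: np.abs(a.axis(ax) - b.axis(ax)) for ax in shared}
    inplane = shared[:2]
    pwd_2d = np.sqrt(sum((a.axis(ax) - b.axis(ax)) ** 2 for ax in inplane))
    return per_axis, pwd_2d


def rmsd(series: np.ndarray) -> float:
    """Root-mean-square of a deviation series."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise InsufficientDataError("empty deviation series")
    return float(np.sqrt(np.mean(series**2)))


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n: int  # non-zero differences used
    significant: bool
    all_zero: bool = False


def _exact_signed_rank_p(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p for differences without zeros.

    Mid-ranks handle ties; the null distribution of W+ is built by
    convolving the characteristic polynomial of the doubled ranks
    (doubling keeps tie mid-ranks integral).
    """
    ranks = stats.rankdata(np.abs(d))
    r2 = np.round(2.0 * ranks).astype(int)
    w_plus = int(round(float(np.sum(r2[d > 0]))))
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    p_low = float(dist[: w_plus + 1].sum())
    p_high = float(dist[w_plus:].sum())
    p = min(1.0, 2.0 * min(p_low, p_high))
    return float(np.sum(ranks[d > 0])), p


def wilcoxon_two_sided(
    x: np.ndarray,
    y: np.ndarray | None = None,
    alpha: float = 0.05,
    zero_method: str = "wilcox",
    exact_max_n: int = 25,
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are excluded (``zero_method="wilcox"``; ``"pratt"``
    keeps them in the ranking); ties get mid-ranks.  The null
    distribution is exact for up to ``exact_max_n`` non-zero
    differences and a tie-corrected normal approximation above.  If all
    differences are zero the test is vacuous: p = 1, flagged.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if d.size < 5:
        raise InsufficientDataError("need at least 5 paired samples")
    if np.all(d == 0):
        return WilcoxonResult(0.0, 1.0, 0, False, all_zero=True)
    if zero_method == "pratt":
        res = stats.wilcoxon(d, zero_method="pratt", alternative="two-sided",
                             method="approx")
        return WilcoxonResult(float(res.statistic), float(res.pvalue),
                              int(np.count_nonzero(d)), res.pvalue <= alpha)
    d = d[d != 0]
    if d.size <= exact_max_n:
        w, p = _exact_signed_rank_p(d)
    else:
        res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                             method="approx", correction=False)
        w, p = float(res.statistic), float(res.pvalue)
    return WilcoxonResult(w, p, int(d.size), p <= alpha)


def flag_outliers(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Flag values outside ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]``.

    Quartiles use linear interpolation.  Returns (flags, fraction).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise InsufficientDataError("need at least 4 values")
    q1, q3 = np.percentile(values, [25.0, 75.0])
    iqr = q3 - q1
    flags = (values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)
    return flags, float(np.mean(flags))


def compare_traces(a: MotionTrace, b: MotionTrace, alpha: float = 0.05) -> ComparisonReport:
    """Full comparison report between two frame-aligned traces.

    The Wilcoxon test pools the signed per-axis differences across the
    shared axes; the outlier fraction applies the 1.5 x IQR rule to the
    in-plane PWD series.
    """
    per_axis, pwd_2d = pwd(a, b)
    shared = tuple(per_axis)
    signed = np.concatenate([a.axis(ax) - b.axis(ax) for ax in shared])
    wres = wilcoxon_two_sided(signed, alpha=alpha)
    flags, frac = flag_outliers(pwd_2d)
    return ComparisonReport(
        axes=shared,
        pwd_per_axis=per_axis,
        pwd_2d=pwd_2d,
        rmsd_per_axis={ax: rmsd(v) for ax, v in per_axis.items()},
        rmsd_2d=rmsd(pwd_2d),
        wilcoxon_p=wres.p_value,
        outlier_fraction=frac,
        n=len(a),
    )
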