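"""Two-group statistics for neuron cohorts.

Thin, explicitly-contracted wrappers over scipy.stats matching the tests
reported for recorded dopaminergic cohorts: a pooled-variance unpaired
Student's t on firing rate, a Mann-Whitney U (reported as min(U_a, U_b), with
midrank tie handling) on CVisi, and a Pearson chi-square (no continuity
correction) on the group x pattern contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = ["StatError", "students_t", "mann_whitney_u", "chi_square", "sem"]


class StatError(ValueError):
    """Raised for degenerate statistical inputs."""


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean with the sample (n-1) SD."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise StatError("SEM requires at least 2 values")
    return float(np.std(v, ddof=1) / np.sqrt(v.size))


def students_t(
    group_a: Sequence[float], group_b: Sequence[float]
) -> Tuple[float, int, float]:
    """Pooled-variance unpaired two-sided Student's t-test.

    Returns
    -------
    (t, df, p) with ``df = n_a + n_b - 2``.

    Raises
    ------
    StatError
        If either group has fewer than 2 values or the pooled variance is 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatError("each group needs at least 2 values for a t-test")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and np.mean(a) == np.mean(b):
        return 0.0, int(a.size + b.size - 2), 1.0
    res = sps.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    if not np.isfinite(res.statistic):
        raise StatError("zero pooled variance with unequal means")
    return float(res.statistic), int(df), float(res.pvalue)


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> Tuple[float, float]:
    """Mann-Whitney U with midrank ties, reported as ``min(U_a, U_b)``.

    The p-value uses exact enumeration for small tie-free samples
    (n <= 20 per group) and the tie-corrected normal approximation otherwise,
    following common reporting practice.

    Returns
    -------
    (U, p)

    Raises
    ------
    StatError
        If either group is empty.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatError("both groups must be non-empty for Mann-Whitney U")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    u_a = float(res.statistic)
    u_b = a.size * b.size - u_a
    return min(u_a, u_b), float(res.pvalue)


def chi_square(table: np.ndarray) -> Tuple[float, int, float]:
    """Pearson chi-square for an r x c contingency table, no continuity
    correction; ``df = (r-1)(c-1)``.

    Raises
    ------
    StatError
        If any row or column margin is zero (drop the offending row/column
        before testing).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0):
        raise StatError("table must be a 2-D array of non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise StatError(
            "contingency table has a zero row/column margin; drop that "
            "row/column before testing"
        )
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)
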