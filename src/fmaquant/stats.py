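"""Glomerulosclerosis scoring and group-comparison statistics.

The glomerulosclerosis index (GSI) summarises per-glomerulus sclerosis grades
(0 = normal … 4 = sclerotic area 75–100%) as the severity-weighted mean
GSI = Σ_i i·F_i / 100, where F_i is the percentage of examined glomeruli at
grade i. Group comparisons follow the study's convention: means ± SEM with a
two-sample Student's t-test; skew-distributed quantities (e.g. proteinuria)
are log-transformed first and summarised as geometric mean ×/÷ tolerance
factor, the tolerance factor being exp(SEM of the log values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

GRADES = (0, 1, 2, 3, 4)

#: Conventional number of glomeruli graded per kidney section.
CONVENTIONAL_N_GLOMERULI = 80


@dataclass(frozen=True)
class GradeDistribution:
    """Percentages of glomeruli at each sclerosis grade 0..4 (sum = 100)."""

    F: tuple[float, float, float, float, float]
    n_glomeruli: int

    def __post_init__(self) -> None:
        if len(self.F) != 5:
            raise ValueError("need exactly five grade percentages F0..F4")
        if any(f < 0 for f in self.F):
            raise ValueError(f"negative grade percentage in {self.F}")
        total = float(sum(self.F))
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"grade percentages must sum to 100, got {total}")
        if self.n_glomeruli < 1:
            raise ValueError("n_glomeruli must be >= 1")


def grades_to_distribution(grades: list[int] | np.ndarray) -> GradeDistribution:
    """Tally integer grades 0..4 into a percentage distribution."""
    grades = np.asarray(grades)
    if grades.size == 0:
        raise ValueError("no grades given")
    bad = np.flatnonzero((grades < 0) | (grades > 4) | (grades != grades.astype(int)))
    if bad.size:
        raise ValueError(
            f"grade out of range 0..4 at index {int(bad[0])}: {grades[bad[0]]!r}"
        )
    counts = np.bincount(grades.astype(int), minlength=5)
    F = tuple(100.0 * c / grades.size for c in counts)
    return GradeDistribution(F=F, n_glomeruli=int(grades.size))


def gsi(dist: GradeDistribution) -> float:
    """Glomerulosclerosis index: Σ_i i·F_i/100, linear in F, bounded [0, 4]."""
    return float(sum(i * f for i, f in zip(GRADES, dist.F)) / 100.0)


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive summary of one group for one endpoint.

    Normal mode reports mean ± SEM; skewed mode reports geometric mean with a
    multiplicative ×/÷ tolerance factor.
    """

    n: int
    mean: float
    sem: float
    geometric_mean: float | None = None
    tolerance_factor: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.tolerance_factor is not None and self.tolerance_factor < 1.0:
            raise ValueError("tolerance factor must be >= 1")


def geometric_summary(values: np.ndarray | list[float]) -> tuple[float, float]:
    """Geometric mean and ×/÷ tolerance factor of positive values.

    geometric_mean = exp(mean(ln x)); tolerance_factor = exp(SEM(ln x)), an
    SEM-like multiplicative dispersion band (reported as g ×/÷ tf).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    if np.any(x <= 0):
        raise ValueError("geometric summary requires strictly positive values")
    logs = np.log(x)
    gm = float(np.exp(logs.mean()))
    sem = float(np.std(logs, ddof=1) / np.sqrt(x.size))
    return gm, float(np.exp(sem))


def _summarise(x: np.ndarray, skewed: bool, p: float) -> GroupSummary:
    gm = tf = None
    if skewed:
        gm, tf = geometric_summary(x)
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return GroupSummary(n=int(x.size), mean=float(x.mean()), sem=sem,
                        geometric_mean=gm, tolerance_factor=tf, p_value=p)


def compare_groups(
    a: np.ndarray | list[float],
    b: np.ndarray | list[float],
    skewed: bool = False,
    welch: bool = False,
) -> tuple[GroupSummary, GroupSummary, float]:
    """Two-sided two-sample t-test between groups.

    Equal-variance Student's t-test by default (``welch=True`` for the
    unequal-variance variant). With ``skewed=True`` the values are
    log-transformed before testing and each group additionally carries its
    geometric mean and tolerance factor. Significance convention: p < 0.05.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("need n >= 2 per group")
    if skewed:
        if np.any(xa <= 0) or np.any(xb <= 0):
            raise ValueError("skewed mode requires strictly positive values")
        ta, tb = np.log(xa), np.log(xb)
    else:
        ta, tb = xa, xb
    res = sps.ttest_ind(ta, tb, equal_var=not welch)
    p = float(res.pvalue)
    return _summarise(xa, skewed, p), _summarise(xb, skewed, p), p
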