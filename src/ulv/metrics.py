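"""Stage-1 pairwise difference metrics between subjects.

The central quantity is the probabilistic index (PI) between the cells of a
case subject and the cells of a control subject,

    PI(x, y) = P(X > Y) + 1/2 P(X = Y),

estimated by the rescaled Mann-Whitney U statistic with half-weighted ties.
PI = 0.5 means the two cell-value distributions overlap completely; PI = 1
means every case cell exceeds every control cell.  PI equals the area under
the ROC curve when the feature's value is used to classify the two subjects'
cells, which is why it is a natural, outlier-robust "degree of separation".

Classical Wilcoxon rank-sum tests (cell-level, which wrongly treats cells as
independent, and pseudobulk, which tests subject summaries) are provided as
benchmarking comparators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats

Metric = Literal["pi", "logit_pi", "mean_diff", "median_diff", "indicator"]

__all__ = [
    "DifferenceMatrix",
    "difference_matrix",
    "logit_pi",
    "probabilistic_index",
    "wilcoxon_cell_level_test",
    "wilcoxon_min_pvalue",
    "wilcoxon_pseudobulk_test",
]


@dataclass
class DifferenceMatrix:
    """m x n matrix of pairwise case-vs-control differences d_ij.

    Attributes
    ----------
    d : (m, n) array — entry (i, j) compares case subject i to control j.
    case_ids, control_ids : subject labels for rows and columns.
    k_case, k_control : cells per subject (cluster sizes), used by the
        weighted latent-model fit.
    scale : "pi" (entries in [0, 1], null value 0.5), "logit" (real line,
        null value 0), or "separable" for metrics of the form g(x) - g(y).
    """

    d: np.ndarray
    case_ids: list = field(default_factory=list)
    control_ids: list = field(default_factory=list)
    k_case: np.ndarray | None = None
    k_control: np.ndarray | None = None
    scale: str = "pi"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2:
            raise ValueError("difference matrix must be 2-dimensional")
        m, n = self.d.shape
        if not self.case_ids:
            self.case_ids = [f"case{i}" for i in range(m)]
        if not self.control_ids:
            self.control_ids = [f"control{j}" for j in range(n)]
        if len(self.case_ids) != m or len(self.control_ids) != n:
            raise ValueError(
                f"id lists ({len(self.case_ids)}, {len(self.control_ids)}) do not "
                f"match matrix shape {self.d.shape}"
            )
        if self.k_case is not None:
            self.k_case = np.asarray(self.k_case, dtype=int)
            if self.k_case.shape != (m,) or np.any(self.k_case < 1):
                raise ValueError("k_case must be m positive integers")
        if self.k_control is not None:
            self.k_control = np.asarray(self.k_control, dtype=int)
            if self.k_control.shape != (n,) or np.any(self.k_control < 1):
                raise ValueError("k_control must be n positive integers")
        if self.scale == "pi" and (np.any(self.d < 0) or np.any(self.d > 1)):
            raise ValueError("scale='pi' requires all entries in [0, 1]")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("difference matrix entries must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.d.shape

    @property
    def mu0(self) -> float:
        """Null value of the group difference on this scale."""
        return 0.5 if self.scale == "pi" else 0.0


def _as_cells(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must contain at least one cell value")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values; run QC first")
    return arr


def probabilistic_index(x: Sequence[float], y: Sequence[float]) -> float:
    """PI estimate P(X > Y) + 1/2 P(X = Y) over all cell pairs of two subjects.

    Computed from midranks of the pooled sample, which reproduces the
    half-weight tie kernel (1/(K1*K0)) * sum_k sum_k' [I(x_k > y_k') +
    1/2 I(x_k = y_k')] exactly, in O((K1+K0) log(K1+K0)).

    Satisfies PI(x, y) + PI(y, x) = 1 and is invariant under any strictly
    increasing transform of the pooled values.
    """
    x = _as_cells(x, "x")
    y = _as_cells(y, "y")
    k1, k0 = x.size, y.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    # U = (rank sum of x) - k1(k1+1)/2, with midranks handling ties
    u = ranks[:k1].sum() - k1 * (k1 + 1) / 2.0
    return float(u / (k1 * k0))


def pi_matrix_multi(
    case_cells: Sequence[np.ndarray], control_cells: Sequence[np.ndarray]
) -> np.ndarray:
    """Vectorised PI over many features at once.

    Each element of ``case_cells`` / ``control_cells`` is a (n_features, K)
    matrix of one subject's cell values.  Returns (n_features, m, n).  This is
    the pipeline's fast path; it matches `probabilistic_index` per feature.
    """
    m, n = len(case_cells), len(control_cells)
    n_feat = case_cells[0].shape[0]
    out = np.empty((n_feat, m, n))
    for i in range(m):
        xi = np.asarray(case_cells[i], dtype=float)
        k1 = xi.shape[1]
        for j in range(n):
            yj = np.asarray(control_cells[j], dtype=float)
            k0 = yj.shape[1]
            pooled = np.concatenate([xi, yj], axis=1)
            ranks = stats.rankdata(pooled, axis=1)
            u = ranks[:, :k1].sum(axis=1) - k1 * (k1 + 1) / 2.0
            out[:, i, j] = u / (k1 * k0)
    return out


def logit_pi(p: float, k1: int, k0: int) -> float:
    """Logit of a PI estimate, clamped away from {0, 1} by a half count.

    A PI computed from K1 x K0 pairwise comparisons has resolution
    1/(K1*K0); boundary values are clamped to within half that resolution,
    p* = clamp(p, 1/(2 K1 K0), 1 - 1/(2 K1 K0)), so the transform stays
    finite and monotone.  logit_pi(0.5) = 0 for any cluster sizes.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"PI value {p} outside [0, 1]")
    if k1 < 1 or k0 < 1:
        raise ValueError("cluster sizes must be positive")
    eps = 1.0 / (2.0 * k1 * k0)
    p_star = min(max(p, eps), 1.0 - eps)
    return float(np.log(p_star / (1.0 - p_star)))


_SUMMARY: dict[str, Callable[[np.ndarray], float]] = {
    "mean_diff": np.mean,
    "median_diff": np.median,
    "indicator": np.mean,
}


def difference_matrix(
    cases: Sequence[Sequence[float]],
    controls: Sequence[Sequence[float]],
    metric: Metric = "pi",
    case_ids: Sequence | None = None,
    control_ids: Sequence | None = None,
) -> DifferenceMatrix:
    """Build the m x n pairwise difference matrix between subjects.

    metric:
      * ``pi`` — probabilistic index (default; entries in [0, 1]).
      * ``logit_pi`` — clamped logit of the PI (real line).
      * ``mean_diff`` / ``median_diff`` — separable subject-summary
        differences g(x_i) - g(y_j); these make the latent-level least
        squares exact.
      * ``indicator`` — I(mean_i > mean_j), the kernel of the subject-level
        one-sided Wilcoxon test (ties get weight 1/2).

    Requires at least two subjects per group: the latent model cannot
    estimate a between-subject variance from a single subject.
    """
    if len(cases) < 2:
        raise ValueError(f"need >= 2 case subjects, got {len(cases)}")
    if len(controls) < 2:
        raise ValueError(f"need >= 2 control subjects, got {len(controls)}")
    xs = [_as_cells(c, f"case {i}") for i, c in enumerate(cases)]
    ys = [_as_cells(c, f"control {j}") for j, c in enumerate(controls)]
    m, n = len(xs), len(ys)
    d = np.empty((m, n))
    if metric == "pi":
        scale = "pi"
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                d[i, j] = probabilistic_index(x, y)
    elif metric == "logit_pi":
        scale = "logit"
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                d[i, j] = logit_pi(probabilistic_index(x, y), x.size, y.size)
    elif metric in ("mean_diff", "median_diff"):
        scale = "separable"
        g = _SUMMARY[metric]
        gx = np.array([g(x) for x in xs])
        gy = np.array([g(y) for y in ys])
        d = gx[:, None] - gy[None, :]
    elif metric == "indicator":
        scale = "pi"
        gx = np.array([np.mean(x) for x in xs])
        gy = np.array([np.mean(y) for y in ys])
        d = (gx[:, None] > gy[None, :]) + 0.5 * (gx[:, None] == gy[None, :])
        d = d.astype(float)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DifferenceMatrix(
        d=d,
        case_ids=list(case_ids) if case_ids is not None else [],
        control_ids=list(control_ids) if control_ids is not None else [],
        k_case=np.array([x.size for x in xs]),
        k_control=np.array([y.size for y in ys]),
        scale=scale,
    )


def wilcoxon_min_pvalue(m: int, n: int) -> float:
    """Minimum attainable one-sided rank-sum p-value with m cases, n controls.

    The subject-level Wilcoxon test is discrete: with all C(m+n, m) rank
    assignments equally likely under the null, no p-value can fall below
    1 / C(m+n, m) (the two-sided minimum is twice that).  With m = n = 5
    this is 1/252 ~ 0.004, which is why pseudobulk rank tests cannot reach
    genome-wide significance in small cohorts.
    """
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    return 1.0 / comb(m + n, m)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U with half-weighted ties (double-sum kernel, vectorised)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def _exact_rank_sum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p by exhaustive enumeration of group assignments.

    Enumerates all C(m+n, m) case/control labelings of the pooled values and
    counts those whose U deviates from mn/2 at least as much as observed.
    Handles ties exactly via the half-weight kernel.  Used when m + n <= 12.
    """
    m, n = x.size, y.size
    pooled = np.concatenate([x, y])
    center = m * n / 2.0
    obs = abs(_u_statistic(x, y) - center)
    total = 0
    extreme = 0
    idx = np.arange(m + n)
    for case_idx in combinations(idx, m):
        mask = np.zeros(m + n, dtype=bool)
        mask[list(case_idx)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - center) >= obs - 1e-12:
            extreme += 1
    return extreme / total


def wilcoxon_pseudobulk_test(
    cases: Sequence[float], controls: Sequence[float]
) -> float:
    """Two-sided rank-sum p-value on subject-level summaries.

    The "pseudobulk" comparator: each subject contributes one value (mean,
    median or detection fraction of its cells — computed upstream).  Exact
    enumeration over all group assignments when m + n <= 12, otherwise the
    normal approximation with tie correction.  Degenerate all-tied input
    yields p = 1.
    """
    x = _as_cells(cases, "cases")
    y = _as_cells(controls, "controls")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if x.size + y.size <= 12:
        return _exact_rank_sum_pvalue(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def wilcoxon_cell_level_test(
    case_cells: Sequence[float], control_cells: Sequence[float]
) -> float:
    """Rank-sum p-value on pooled cells, ignoring subject structure.

    Benchmarking anti-pattern: treating cells as independent units inflates
    the type-I error badly whenever subjects are heterogeneous, because the
    effective sample size is the number of subjects, not cells.  Kept only
    so the benchmark harness can demonstrate the inflation.
    """
    return wilcoxon_pseudobulk_test(case_cells, control_cells)
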