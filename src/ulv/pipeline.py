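"""End-to-end per-feature differential expression and the benchmark harness.

The main entry point `run_ulv` chains QC -> pairwise PI matrices -> latent
model fits -> BH-FDR -> DE calls.  A feature is called differentially
expressed when its FDR-adjusted p-value falls below the threshold *and* its
PI estimate lies outside the practical-equivalence window [0.45, 0.55] —
the window guards against statistically significant but biologically
negligible separations.

The harness section implements the type-I-error and power studies on ZINB
simulations, with cell-level and pseudobulk Wilcoxon tests as comparators,
and balanced subject-label permutations for null calibration on a fixed
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ulv.io import ClusteredExpression
from ulv.latent import LatentModelSpec, fit_closed_form, fit_ml
from ulv.metrics import DifferenceMatrix, logit_pi, pi_matrix_multi
from ulv.simulate import (
    SimDesign,
    admissible_reference_params,
    simulate_counts,
    synth_reference_params,
)

__all__ = [
    "DECallConfig",
    "QCConfig",
    "balanced_permutations",
    "bh_adjust",
    "clr_normalize",
    "count_balanced_permutations",
    "library_size_normalize",
    "power_study",
    "qc_filter",
    "relabel_subjects",
    "run_ulv",
    "type1_error_study",
]


@dataclass
class QCConfig:
    """Quality-control thresholds applied before testing.

    Subjects with fewer than ``min_cells_per_subject`` cells are dropped
    first; then features detected (value > 0) in at most
    ``min_expressed_fraction`` of the evaluation group's cells are dropped.
    ``expressed_in_group`` names the condition whose cells the detection
    fraction is computed in (None = all cells).
    """

    min_cells_per_subject: int = 50
    min_expressed_fraction: float = 0.10
    expressed_in_group: str | None = None

    def __post_init__(self) -> None:
        if self.min_cells_per_subject < 0:
            raise ValueError("min_cells_per_subject must be >= 0")
        if not 0.0 <= self.min_expressed_fraction <= 1.0:
            raise ValueError("min_expressed_fraction must lie in [0, 1]")


@dataclass
class DECallConfig:
    """Differential-expression calling rule.

    A feature is called DE when q < fdr_threshold and its PI estimate is
    below pi_low or above pi_high.  Either condition can be disabled by
    setting the threshold to its trivial value (fdr_threshold = 1, or
    pi_low = pi_high = 0.5).
    """

    fdr_threshold: float = 0.1
    pi_low: float = 0.45
    pi_high: float = 0.55
    fdr_method: str = "bh"  # "bh" or "by"

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi_low <= 0.5 <= self.pi_high <= 1.0):
            raise ValueError("need 0 <= pi_low <= 0.5 <= pi_high <= 1")


def qc_filter(
    data: ClusteredExpression, cfg: QCConfig | None = None
) -> tuple[ClusteredExpression, pd.DataFrame]:
    """Drop under-sampled subjects, then rarely expressed features.

    Subjects go first so that the feature detection fraction is computed on
    the retained cells only.  Returns the filtered data plus a report table
    listing every dropped entity and the reason.  Raises if fewer than two
    subjects per condition survive — the latent model needs at least two.
    """
    if cfg is None:
        cfg = QCConfig()
    report_rows = []
    keep_subj = data.subjects[data.subjects["cell_count"] > cfg.min_cells_per_subject]
    for _, row in data.subjects.iterrows():
        if row["cell_count"] <= cfg.min_cells_per_subject:
            report_rows.append(
                {
                    "entity": "subject",
                    "id": row["subject_id"],
                    "reason": f"cell_count {row['cell_count']} <= "
                    f"{cfg.min_cells_per_subject}",
                }
            )
    keep_ids = set(keep_subj["subject_id"])
    cell_mask = data.cells["subject_id"].isin(keep_ids).to_numpy()
    matrix = data.matrix[:, cell_mask]
    cells = data.cells[cell_mask].reset_index(drop=True)

    if cfg.expressed_in_group is not None:
        subj_in_group = set(
            keep_subj[keep_subj[data.condition_col] == cfg.expressed_in_group][
                "subject_id"
            ]
        )
        frac_mask = cells["subject_id"].isin(subj_in_group).to_numpy()
        if not frac_mask.any():
            raise ValueError(
                f"no cells from condition {cfg.expressed_in_group!r} to "
                "evaluate the expressed fraction in"
            )
    else:
        frac_mask = np.ones(matrix.shape[1], dtype=bool)
    if matrix.shape[1] == 0 or not frac_mask.any():
        raise ValueError("no cells survive the subject filter")
    frac = (matrix[:, frac_mask] > 0).mean(axis=1)
    feat_keep = frac > cfg.min_expressed_fraction
    if cfg.min_expressed_fraction == 0.0:
        feat_keep = np.ones(matrix.shape[0], dtype=bool)
    for i in np.flatnonzero(~feat_keep):
        report_rows.append(
            {
                "entity": "feature",
                "id": data.feature_ids[i],
                "reason": f"expressed fraction {frac[i]:.3f} <= "
                f"{cfg.min_expressed_fraction}",
            }
        )
    filtered = ClusteredExpression(
        matrix=matrix[feat_keep],
        feature_ids=[f for f, k in zip(data.feature_ids, feat_keep) if k],
        cell_ids=list(cells["cell_id"]),
        cells=cells,
        subjects=keep_subj.drop(columns=["cell_count"]).reset_index(drop=True),
        condition_col=data.condition_col,
    )
    for cond in filtered.conditions():
        if len(filtered.subjects_of(cond)) < 2:
            raise ValueError(
                f"fewer than 2 subjects left in condition {cond!r} after QC"
            )
    return filtered, pd.DataFrame(report_rows, columns=["entity", "id", "reason"])


def clr_normalize(matrix: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform per cell (column).

    x -> log(x + pseudocount) - mean_features log(x + pseudocount).  The
    standard normalization for compositional protein counts; output columns
    have mean exactly zero.  All-zero cells are well defined through the
    pseudocount.
    """
    matrix = np.asarray(matrix, dtype=float)
    if np.any(matrix < 0):
        raise ValueError("CLR expects nonnegative values")
    logged = np.log(matrix + pseudocount)
    return logged - logged.mean(axis=0, keepdims=True)


def library_size_normalize(
    counts: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Median-library-size scaling followed by log1p.

    Each cell is rescaled so its total count equals the median library size
    across cells, then log1p-transformed.  Zero-depth cells cannot be
    scaled; they are dropped and reported (second return value holds the
    indices of retained columns).
    """
    counts = np.asarray(counts, dtype=float)
    depths = counts.sum(axis=0)
    keep = depths > 0
    depths_kept = depths[keep]
    target = np.median(depths_kept)
    scaled = counts[:, keep] * (target / depths_kept)[None, :]
    return np.log1p(scaled), np.flatnonzero(keep)


def bh_adjust(p_values, method: str = "bh") -> np.ndarray:
    """FDR adjustment (Benjamini-Hochberg step-up; "by" for the
    Benjamini-Yekutieli variant).  NaN entries are excluded from the
    procedure and returned as NaN."""
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        sm_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
        q[ok] = multipletests(p[ok], method=sm_method)[1]
    return q


def _group_cell_matrices(
    data: ClusteredExpression, condition: str
) -> tuple[list[str], list[np.ndarray]]:
    ids = data.subjects_of(condition)
    return ids, [data.cell_matrix(s) for s in ids]


def _resolve_conditions(
    data: ClusteredExpression, case_condition: str | None, control_condition: str | None
) -> tuple[str, str]:
    conds = data.conditions()
    if case_condition is None or control_condition is None:
        if sorted(conds) == ["case", "control"]:
            return "case", "control"
        if len(conds) == 2:
            # deterministic fallback: lexicographically later label is "case"
            return conds[1], conds[0]
        raise ValueError(
            f"cannot infer case/control from conditions {conds}; pass them explicitly"
        )
    return case_condition, control_condition


def closed_form_pvalues(pis: np.ndarray, mu0: float = 0.5) -> tuple[np.ndarray, ...]:
    """Vectorised closed-form latent-model test over a stack of difference
    matrices (shape n_features x m x n).

    Returns (mu_hat, statistic, p_value); identical per feature to
    `fit_closed_form`.  Degenerate (zero-variance) features get NaN.
    """
    f, m, n = pis.shape
    row = pis.mean(axis=2)
    col = pis.mean(axis=1)
    grand = pis.mean(axis=(1, 2))
    ms_row = ((row - grand[:, None]) ** 2).sum(axis=1) / (m - 1)
    ms_col = ((col - grand[:, None]) ** 2).sum(axis=1) / (n - 1)
    var_mu = ms_row / m + ms_col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var_mu > 0, (grand - mu0) / np.sqrt(var_mu), np.nan)
    p = 2.0 * stats.t.sf(np.abs(t), m + n - 2)
    return grand, t, p


def run_ulv(
    data: ClusteredExpression,
    model: LatentModelSpec | None = None,
    qc: QCConfig | None = None,
    call: DECallConfig | None = None,
    case_condition: str | None = None,
    control_condition: str | None = None,
    covariate_columns: list[str] | None = None,
    standardize_covariates: bool = False,
) -> pd.DataFrame:
    """Per-feature two-group differential expression with the latent model.

    For every feature: build the m x n matrix of pairwise probabilistic
    indices between case and control subjects, fit the latent model (closed
    form when unadjusted and unweighted, maximum likelihood otherwise), and
    test H0: PI = 0.5 (or logit PI = 0).  P-values are BH-adjusted across
    features; the DE call combines the FDR threshold with the PI window.

    Features whose fit is degenerate (constant difference matrix) are
    reported with a status code and excluded from the BH denominator.
    Passing ``qc=None`` skips filtering (input assumed pre-filtered).
    """
    if model is None:
        model = LatentModelSpec()
    if call is None:
        call = DECallConfig()
    if qc is not None:
        data, _ = qc_filter(data, qc)
    case_cond, control_cond = _resolve_conditions(
        data, case_condition, control_condition
    )
    case_ids, case_cells = _group_cell_matrices(data, case_cond)
    control_ids, control_cells = _group_cell_matrices(data, control_cond)
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValueError("need >= 2 subjects per condition")
    k_case = np.array([c.shape[1] for c in case_cells])
    k_control = np.array([c.shape[1] for c in control_cells])
    pis = pi_matrix_multi(case_cells, control_cells)

    need_ml = model.weighted or covariate_columns
    X = None
    if covariate_columns:
        X = data.covariate_matrix(covariate_columns, case_ids + control_ids)
        if standardize_covariates:
            X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)

    n_feat = pis.shape[0]
    pi_est = np.full(n_feat, np.nan)
    statistic = np.full(n_feat, np.nan)
    p_value = np.full(n_feat, np.nan)
    status = np.array(["ok"] * n_feat, dtype=object)

    if not need_ml and model.scale == "pi":
        pi_est, statistic, p_value = closed_form_pvalues(pis, mu0=model.null_value)
        status[~np.isfinite(p_value)] = "degenerate_variance"
    else:
        for i in range(n_feat):
            d = pis[i]
            if model.scale == "logit":
                d = np.array(
                    [
                        [
                            logit_pi(d[a, b], int(k_case[a]), int(k_control[b]))
                            for b in range(d.shape[1])
                        ]
                        for a in range(d.shape[0])
                    ]
                )
            D = DifferenceMatrix(
                d=d,
                case_ids=case_ids,
                control_ids=control_ids,
                k_case=k_case,
                k_control=k_control,
                scale=model.scale if model.scale == "pi" else "logit",
            )
            try:
                if need_ml:
                    spec_i = replace(model, covariates=X)
                    fit = fit_ml(D, spec_i)
                else:
                    fit = fit_closed_form(D, model.null_value)
                pi_est[i] = pis[i].mean()  # always report on the PI scale
                statistic[i] = fit.statistic
                p_value[i] = fit.p_value
                status[i] = fit.status
            except Exception as exc:  # pragma: no cover - defensive
                status[i] = f"fit_error: {exc}"

    q_value = bh_adjust(p_value, method=call.fdr_method)
    de_call = (
        np.isfinite(q_value)
        & (q_value < call.fdr_threshold)
        & ((pi_est < call.pi_low) | (pi_est > call.pi_high))
    )
    return pd.DataFrame(
        {
            "feature_id": data.feature_ids,
            "pi_estimate": pi_est,
            "statistic": statistic,
            "p_value": p_value,
            "q_value": q_value,
            "de_call": de_call,
            "status": status,
            "n_case_subjects": len(case_ids),
            "n_control_subjects": len(control_ids),
        }
    )


# ---------------------------------------------------------------------------
# Balanced subject-label permutations


def count_balanced_permutations(
    n_cases: int, n_controls: int, g1_cases: int, g1_controls: int
) -> int:
    """Number of distinct balanced label splits.

    Group 1 takes g1_cases cases and g1_controls controls; group 2 the
    rest.  When the two groups have identical composition (the split is
    exactly half of each pool) a split and its group-label mirror describe
    the same partition, so the raw product of binomials is halved.  With 16
    cases and 4 controls split (8, 2) this gives C(16,8) C(4,2) / 2 = 38610.
    """
    if g1_cases > n_cases or g1_controls > n_controls:
        raise ValueError("group-1 sizes exceed the available subjects")
    total = comb(n_cases, g1_cases) * comb(n_controls, g1_controls)
    symmetric = (2 * g1_cases == n_cases) and (2 * g1_controls == n_controls)
    return total // 2 if symmetric else total


def balanced_permutations(
    case_ids,
    control_ids,
    g1_cases: int,
    g1_controls: int,
    n_sample: int,
    seed: int = 0,
):
    """Sample distinct balanced label assignments without replacement.

    Each assignment is a pair ``(group1, group2)`` of sorted subject-id
    tuples; group 1 holds g1_cases original cases and g1_controls original
    controls.  Mirror assignments (group labels swapped) are counted once
    when the split is symmetric.  If ``n_sample`` is at least the number of
    distinct assignments, all of them are returned (in deterministic
    order); otherwise a seeded random sample is drawn.
    """
    case_ids = list(case_ids)
    control_ids = list(control_ids)
    total = count_balanced_permutations(
        len(case_ids), len(control_ids), g1_cases, g1_controls
    )
    symmetric = (2 * g1_cases == len(case_ids)) and (
        2 * g1_controls == len(control_ids)
    )
    all_ids = case_ids + control_ids

    def make(g1_c, g1_k):
        g1 = tuple(sorted(list(g1_c) + list(g1_k)))
        g2 = tuple(sorted(s for s in all_ids if s not in set(g1)))
        if symmetric and g2 < g1:
            g1, g2 = g2, g1
        return g1, g2

    if n_sample >= total:
        seen = set()
        out = []
        for g1_c in combinations(case_ids, g1_cases):
            for g1_k in combinations(control_ids, g1_controls):
                a = make(g1_c, g1_k)
                if a not in seen:
                    seen.add(a)
                    out.append(a)
        return out
    rng = np.random.default_rng(seed)
    seen = set()
    out = []
    while len(out) < n_sample:
        g1_c = rng.choice(len(case_ids), size=g1_cases, replace=False)
        g1_k = rng.choice(len(control_ids), size=g1_controls, replace=False)
        a = make(
            [case_ids[i] for i in g1_c], [control_ids[i] for i in g1_k]
        )
        if a not in seen:
            seen.add(a)
            out.append(a)
    return out


def relabel_subjects(
    data: ClusteredExpression, group1_ids
) -> ClusteredExpression:
    """Return a copy with conditions set by membership in group 1
    ("case" for group-1 subjects, "control" otherwise) — the permutation
    protocol's relabeling step."""
    g1 = set(group1_ids)
    subjects = data.subjects.drop(columns=["cell_count"], errors="ignore").copy()
    subjects[data.condition_col] = [
        "case" if s in g1 else "control" for s in subjects["subject_id"]
    ]
    return ClusteredExpression(
        matrix=data.matrix,
        feature_ids=list(data.feature_ids),
        cell_ids=list(data.cell_ids),
        cells=data.cells,
        subjects=subjects,
        condition_col=data.condition_col,
    )


# ---------------------------------------------------------------------------
# Simulation benchmark harness


def _pseudobulk_pvalues(
    case_cells: list[np.ndarray], control_cells: list[np.ndarray]
) -> np.ndarray:
    """Subject-mean rank-sum p per feature (exact when m + n <= 12)."""
    means_case = np.column_stack([c.mean(axis=1) for c in case_cells])
    means_ctrl = np.column_stack([c.mean(axis=1) for c in control_cells])
    m, n = means_case.shape[1], means_ctrl.shape[1]
    method = "exact" if m + n <= 12 else "asymptotic"
    res = stats.mannwhitneyu(
        means_case, means_ctrl, axis=1, alternative="two-sided", method=method
    )
    return np.asarray(res.pvalue)


def _cell_level_pvalues(
    case_cells: list[np.ndarray], control_cells: list[np.ndarray]
) -> np.ndarray:
    pooled_case = np.concatenate(case_cells, axis=1)
    pooled_ctrl = np.concatenate(control_cells, axis=1)
    res = stats.mannwhitneyu(
        pooled_case, pooled_ctrl, axis=1, alternative="two-sided", method="asymptotic"
    )
    return np.asarray(res.pvalue)


def feature_pvalues(
    sim_data,
    method: str,
    covariate: np.ndarray | None = None,
) -> np.ndarray:
    """Per-feature p-values of one testing method on a simulated dataset.

    method: "ulv" (closed form on PI), "ulv_adj" (ML with covariate),
    "ulv_wt" (ML with 1/K-weighted latent variances), "wilcoxon_sc"
    (pooled cells) or "wilcoxon_pseudobulk" (subject means).
    """
    n_subj = len(sim_data.subject_ids)
    is_case = sim_data.condition == "case"
    case_cells = [sim_data.cells_of(j) for j in range(n_subj) if is_case[j]]
    control_cells = [sim_data.cells_of(j) for j in range(n_subj) if not is_case[j]]
    if method == "wilcoxon_sc":
        return _cell_level_pvalues(case_cells, control_cells)
    if method == "wilcoxon_pseudobulk":
        return _pseudobulk_pvalues(case_cells, control_cells)
    pis = pi_matrix_multi(case_cells, control_cells)
    if method == "ulv":
        return closed_form_pvalues(pis)[2]
    k_case = np.array([c.shape[1] for c in case_cells])
    k_control = np.array([c.shape[1] for c in control_cells])
    if method == "ulv_adj":
        if covariate is None:
            covariate = sim_data.covariate
        if covariate is None:
            raise ValueError("ulv_adj needs a covariate")
        cov = np.concatenate([covariate[is_case], covariate[~is_case]])[:, None]
        spec = LatentModelSpec(covariates=cov)
    elif method == "ulv_wt":
        spec = LatentModelSpec(weighted=True)
    else:
        raise ValueError(f"unknown method {method!r}")
    out = np.empty(pis.shape[0])
    for i in range(pis.shape[0]):
        D = DifferenceMatrix(
            d=pis[i], k_case=k_case, k_control=k_control, scale="pi"
        )
        out[i] = fit_ml(D, spec).p_value
    return out


def type1_error_study(
    design: SimDesign,
    methods=("ulv", "wilcoxon_sc", "wilcoxon_pseudobulk"),
    alphas=(0.001, 0.01, 0.05, 0.2),
    n_reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical type-I error rates on null (r = 1) ZINB simulations.

    Each replicate simulates ``design.n_features`` null features with fresh
    synthetic reference parameters, applies every method per feature, and
    records the fraction of p-values below each significance level.
    Returns a long table (method, alpha, replicate, rate).
    """
    design = replace(design, r=1.0)
    rng = np.random.default_rng(seed)
    rows = []
    n_subj = design.n_case + design.n_control
    for rep in range(n_reps):
        s1, s2 = rng.integers(2**31, size=2)
        params = synth_reference_params(design.n_features, n_subj, seed=int(s1))
        data = simulate_counts(params, replace(design, seed=int(s2)))
        for method in methods:
            p = feature_pvalues(data, method)
            p = p[np.isfinite(p)]
            for alpha in alphas:
                rows.append(
                    {
                        "method": method,
                        "alpha": alpha,
                        "replicate": rep,
                        "rate": float(np.mean(p < alpha)),
                    }
                )
    return pd.DataFrame(rows)


def power_study(
    design: SimDesign,
    r_values=(1.5, 2.0),
    methods=("ulv", "wilcoxon_pseudobulk"),
    alpha: float = 0.05,
    n_reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical power on ZINB simulations with fold change r > 1.

    All features carry the fold change (the estimand is per-feature
    detection probability); power is the fraction detected at ``alpha``.
    Parameter draws are restricted to the fold-change-admissible region
    (the reparameterization needs r < 1 + mu/phi per person-gene pair; see
    `admissible_reference_params`).  Returns a long table
    (method, r, replicate, power).
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_subj = design.n_case + design.n_control
    r_max = max(r_values)
    for rep in range(n_reps):
        s1, s2 = rng.integers(2**31, size=2)
        params = admissible_reference_params(
            design.n_features, n_subj, r_max=r_max, seed=int(s1)
        )
        for r in r_values:
            data = simulate_counts(
                params, replace(design, r=float(r), de_fraction=1.0, seed=int(s2))
            )
            for method in methods:
                p = feature_pvalues(data, method)
                p = p[np.isfinite(p)]
                rows.append(
                    {
                        "method": method,
                        "r": float(r),
                        "replicate": rep,
                        "power": float(np.mean(p < alpha)),
                    }
                )
    return pd.DataFrame(rows)
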