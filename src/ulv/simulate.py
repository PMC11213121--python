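"""Synthetic multi-subject single-cell data generators.

Two generators feed the benchmark harness:

* a zero-inflated negative binomial (ZINB) count simulator with per
  feature-subject parameters (mu, phi, z, sigma).  Within a subject, the
  cell-level mean is perturbed around the subject's mean by a normal draw
  with sd sigma — this subject-level heterogeneity is exactly what makes
  cell-level tests anti-conservative.  Differential expression is injected
  by a fold change r applied to the case group's (mu, phi) in a way that
  multiplies the mean by r while preserving the mean-variance relationship,
  and covariate effects act multiplicatively on the subject mean.

* a direct generator from the latent model d_ij = a_i - b_j + eps_ij, used
  for calibration and parameter-recovery checks of the stage-2 inference.

Parameter grids mimic resampling from a reference estimate pool: a source
pool of 100 features is drawn once, then feature rows are resampled with
replacement to the requested number of features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ulv.metrics import DifferenceMatrix

__all__ = [
    "FeatureSubjectParams",
    "SimDesign",
    "default_covariate_grid",
    "fold_change_adjust",
    "simulate_counts",
    "simulate_latent_direct",
    "synth_reference_params",
]

_SOURCE_POOL_FEATURES = 100  # size of the synthetic reference pool (features)
_MEAN_FLOOR = 0.01  # lower truncation of the perturbed cell-level NB mean


@dataclass
class FeatureSubjectParams:
    """ZINB parameter grids, one value per (feature, subject).

    mu    : NB mean (> 0)
    phi   : NB dispersion as the *size* parameter — variance = mu + mu^2/phi
    z     : dropout probability in [0, 1] (extra point mass at zero)
    sigma : sd of the cell-level mean perturbation around mu (natural scale)
    """

    mu: np.ndarray
    phi: np.ndarray
    z: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.mu, self.phi, self.z, self.sigma)}
        if len(shapes) != 1:
            raise ValueError("parameter grids must share one shape")
        if np.any(self.mu <= 0) or np.any(self.phi <= 0):
            raise ValueError("mu and phi must be positive")
        if np.any((self.z < 0) | (self.z > 1)):
            raise ValueError("dropout z must lie in [0, 1]")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be nonnegative")

    @property
    def n_features(self) -> int:
        return self.mu.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.mu.shape[1]


@dataclass
class SimDesign:
    """Design of one simulated two-group study.

    cells_per_subject: a fixed integer, or a (min, max) tuple for
    subject-wise discrete-uniform cluster sizes (both endpoints inclusive),
    mirroring unbalanced real studies.  ``de_fraction`` of features receive
    the fold change r in the case group; r = 1 is the global null.
    ``beta`` multiplies the subject covariate on the log mean scale.
    """

    n_case: int = 5
    n_control: int = 5
    cells_per_subject: int | tuple[int, int] = 100
    n_features: int = 1000
    r: float = 1.0
    de_fraction: float = 1.0
    beta: float = 0.0
    covariate_values: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need >= 2 subjects per condition")
        if self.r < 1.0:
            raise ValueError("fold change r must be >= 1 (case over-expression)")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")

    def cluster_sizes(self, n_subjects: int, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.cells_per_subject, (tuple, list)):
            lo, hi = self.cells_per_subject
            return rng.integers(int(lo), int(hi) + 1, size=n_subjects)
        return np.full(n_subjects, int(self.cells_per_subject))


_SUBJECT_LOGMEAN_SD = 0.3  # lognormal sd of between-person mean variation
_SUBJECT_DROPOUT_SD = 0.05  # between-person jitter of the dropout rate


def _draw_param_pool(
    rng: np.random.Generator, n_rows: int, n_subjects: int
) -> FeatureSubjectParams:
    """One pool of per-(feature, subject) ZINB parameters.

    Feature-level draws: mu log-uniform on [0.1, 20], phi log-uniform on
    [0.5, 10], z uniform on [0, 0.7] — spanning lowly to moderately
    expressed features with realistic overdispersion and dropout for
    droplet-style data.  Each subject then perturbs the feature's mean by a
    lognormal factor (sd 0.3 on the log scale, ~±35%) and its dropout rate
    by a small normal jitter: the same feature is correlated across people,
    but no two subjects share exactly the same parameters — this
    between-person heterogeneity is what clustered tests must absorb.
    """
    shape = (n_rows, n_subjects)
    mu_f = np.exp(rng.uniform(np.log(0.1), np.log(20.0), size=n_rows))
    phi_f = np.exp(rng.uniform(np.log(0.5), np.log(10.0), size=n_rows))
    z_f = rng.uniform(0.0, 0.7, size=n_rows)
    mu = mu_f[:, None] * np.exp(rng.normal(0.0, _SUBJECT_LOGMEAN_SD, size=shape))
    phi = np.broadcast_to(phi_f[:, None], shape).copy()
    z = np.clip(z_f[:, None] + rng.normal(0.0, _SUBJECT_DROPOUT_SD, size=shape), 0.0, 0.95)
    sigma = rng.uniform(0.0, 0.3, size=shape) * mu
    return FeatureSubjectParams(mu=mu, phi=phi, z=z, sigma=sigma)


def synth_reference_params(
    n_features: int, n_subjects: int, seed: int = 0
) -> FeatureSubjectParams:
    """Draw a synthetic reference parameter grid (stand-in pool).

    A source pool of 100 features x ``n_subjects`` person-feature parameter
    combinations is drawn (see `_draw_param_pool` for the distributions),
    then feature rows are resampled with replacement until the requested
    grid size is reached, imitating resampling person-feature parameter
    estimates from a small reference dataset.
    """
    if n_features < 1 or n_subjects < 1:
        raise ValueError("grid sizes must be >= 1")
    rng = np.random.default_rng(seed)
    pool = _draw_param_pool(rng, _SOURCE_POOL_FEATURES, n_subjects)
    rows = rng.integers(0, _SOURCE_POOL_FEATURES, size=n_features)
    return FeatureSubjectParams(
        mu=pool.mu[rows], phi=pool.phi[rows], z=pool.z[rows], sigma=pool.sigma[rows]
    )


def admissible_reference_params(
    n_features: int, n_subjects: int, r_max: float, seed: int = 0
) -> FeatureSubjectParams:
    """Synthetic reference grid restricted to fold-change-admissible draws.

    The fold-change reparameterization requires r < 1 + mu/phi for every
    adjusted (feature, subject) parameter pair; features whose draws
    violate the bound at ``r_max`` for any subject are rejection-resampled
    from the same distributions (a truncation of the parameter pool, not a
    change of its ranges).  Used by the power harness, where every feature
    carries the fold change.
    """
    rng = np.random.default_rng(seed)
    pools = []
    n_rows = 0
    tries = 0
    while n_rows < _SOURCE_POOL_FEATURES:
        cand = _draw_param_pool(rng, _SOURCE_POOL_FEATURES, n_subjects)
        ok = np.all(1.0 + cand.mu / cand.phi > r_max * (1.0 + 1e-9), axis=1)
        if ok.any():
            pools.append(
                FeatureSubjectParams(
                    mu=cand.mu[ok], phi=cand.phi[ok], z=cand.z[ok], sigma=cand.sigma[ok]
                )
            )
            n_rows += int(ok.sum())
        tries += 1
        if tries > 1000:  # pragma: no cover - admissible region nonempty
            raise RuntimeError(f"cannot satisfy r_max={r_max} with these ranges")
    mu = np.concatenate([p.mu for p in pools])[:_SOURCE_POOL_FEATURES]
    phi = np.concatenate([p.phi for p in pools])[:_SOURCE_POOL_FEATURES]
    z = np.concatenate([p.z for p in pools])[:_SOURCE_POOL_FEATURES]
    sigma = np.concatenate([p.sigma for p in pools])[:_SOURCE_POOL_FEATURES]
    rows = rng.integers(0, _SOURCE_POOL_FEATURES, size=n_features)
    return FeatureSubjectParams(mu=mu[rows], phi=phi[rows], z=z[rows], sigma=sigma[rows])


def fold_change_adjust(
    mu: float | np.ndarray, phi: float | np.ndarray, r: float
) -> tuple[np.ndarray, np.ndarray]:
    """Reparameterize (mu, phi) so the mean is multiplied by r.

        mu'  = mu * r
        phi' = phi * mu / (mu + (1 - r) * phi)

    The dispersion adjustment keeps the NB mean-variance relationship of the
    "mean DE" scheme consistent; it requires r < 1 + mu/phi so that the
    denominator — and hence phi' — stays positive.
    """
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if r < 1.0:
        raise ValueError("fold change r must be >= 1")
    denom = mu + (1.0 - r) * phi
    if np.any(denom <= 0):
        bad = float(np.min(1.0 + mu / phi))
        raise ValueError(
            f"fold change r={r} too large for some features: "
            f"requires r < 1 + mu/phi (smallest admissible bound {bad:.3f}); "
            "cap r below that bound"
        )
    return mu * r, phi * mu / denom


def default_covariate_grid(n_case: int, n_control: int) -> np.ndarray:
    """Fixed per-subject covariate values: cases equally spaced on
    [-0.9, 1.1], controls on [-1, 1] (endpoints inclusive).

    Deterministic grids, not random draws — with 5-10 subjects per group a
    random covariate would be dominated by sampling noise.  Returned cases
    first, then controls.
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("need >= 2 subjects per group")
    return np.concatenate(
        [np.linspace(-0.9, 1.1, n_case), np.linspace(-1.0, 1.0, n_control)]
    )


@dataclass
class SimulatedData:
    """In-memory simulated study: counts plus subject/condition structure.

    ``counts`` is features x cells; ``cell_subject`` holds the column index
    of each cell's subject in ``subject_ids``; conditions are "case" /
    "control".  ``de_features`` marks features carrying the fold change.
    """

    counts: np.ndarray
    subject_ids: list[str]
    condition: np.ndarray
    cell_subject: np.ndarray
    cluster_sizes: np.ndarray
    covariate: np.ndarray | None = None
    de_features: np.ndarray | None = None
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.feature_ids:
            self.feature_ids = [f"feature{i}" for i in range(self.counts.shape[0])]

    def cells_of(self, subject_index: int) -> np.ndarray:
        """Count submatrix (features x K) of one subject."""
        return self.counts[:, self.cell_subject == subject_index]

    def to_clustered_expression(self):
        """Convert to the pipeline's I/O container."""
        from ulv.io import ClusteredExpression
        import pandas as pd

        cells = pd.DataFrame(
            {
                "cell_id": [f"cell{k}" for k in range(self.counts.shape[1])],
                "subject_id": [self.subject_ids[s] for s in self.cell_subject],
            }
        )
        subj = pd.DataFrame(
            {"subject_id": self.subject_ids, "condition": self.condition}
        )
        if self.covariate is not None:
            subj["x"] = self.covariate
        return ClusteredExpression(
            matrix=self.counts,
            feature_ids=list(self.feature_ids),
            cell_ids=list(cells["cell_id"]),
            cells=cells,
            subjects=subj,
        )


def simulate_counts(
    params: FeatureSubjectParams, design: SimDesign
) -> SimulatedData:
    """Simulate a two-group multi-subject count matrix from the ZINB model.

    For feature i of subject j, each cell k draws a perturbed mean
    mu_ijk ~ N(mu_ij, sigma_ij^2) truncated below at 0.01 (the subject-level
    normal is specified on the natural scale, so a small floor keeps the NB
    mean valid), then a count that is 0 with probability z_ij and otherwise
    NB(mean mu_ijk, size phi_ij).  DE features of case subjects use the
    fold-change-adjusted (mu', phi'); a covariate x_j with coefficient beta
    scales the subject mean via log mu* = log mu + beta x_j.

    Fully reproducible: one child random stream per subject is spawned from
    the design seed, so a subject's cells can be regenerated in isolation.
    """
    n_subj = design.n_case + design.n_control
    if params.n_subjects != n_subj:
        raise ValueError(
            f"parameter grid has {params.n_subjects} subjects, design needs {n_subj}"
        )
    n_feat = params.n_features
    root = np.random.SeedSequence(design.seed)
    rng_sizes = np.random.default_rng(root.spawn(1)[0])
    sizes = design.cluster_sizes(n_subj, rng_sizes)
    n_cells = int(sizes.sum())
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    cell_subject = np.repeat(np.arange(n_subj), sizes)

    is_case = np.arange(n_subj) < design.n_case
    n_de = int(round(design.de_fraction * n_feat)) if design.r > 1.0 else 0
    de_features = np.zeros(n_feat, dtype=bool)
    de_features[:n_de] = True

    covariate = design.covariate_values
    if design.beta != 0.0 and covariate is None:
        covariate = default_covariate_grid(design.n_case, design.n_control)
    if covariate is not None:
        covariate = np.asarray(covariate, dtype=float)
        if covariate.shape != (n_subj,):
            raise ValueError("covariate_values must have one value per subject")

    # effective per (feature, subject) parameters
    mu_eff = params.mu.copy()
    phi_eff = params.phi.copy()
    if n_de > 0:
        mu_adj, phi_adj = fold_change_adjust(
            params.mu[de_features][:, is_case],
            params.phi[de_features][:, is_case],
            design.r,
        )
        mu_eff[np.ix_(de_features, is_case)] = mu_adj
        phi_eff[np.ix_(de_features, is_case)] = phi_adj
    if covariate is not None and design.beta != 0.0:
        mu_eff = mu_eff * np.exp(design.beta * covariate)[None, :]

    counts = np.empty((n_feat, n_cells), dtype=np.int64)
    child_seeds = root.spawn(n_subj)
    for j in range(n_subj):
        rng = np.random.default_rng(child_seeds[j])
        k = int(sizes[j])
        means = rng.normal(
            mu_eff[:, j][:, None], params.sigma[:, j][:, None], size=(n_feat, k)
        )
        means = np.maximum(means, _MEAN_FLOOR)
        phi = phi_eff[:, j][:, None]
        # NB(mean, size): p = size / (size + mean)
        draws = rng.negative_binomial(phi, phi / (phi + means))
        drop = rng.random(size=(n_feat, k)) < params.z[:, j][:, None]
        draws[drop] = 0
        counts[:, offsets[j] : offsets[j + 1]] = draws

    condition = np.where(is_case, "case", "control")
    subject_ids = [
        f"case{i}" if is_case[i] else f"control{i - design.n_case}"
        for i in range(n_subj)
    ]
    return SimulatedData(
        counts=counts,
        subject_ids=subject_ids,
        condition=condition,
        cell_subject=cell_subject,
        cluster_sizes=sizes,
        covariate=covariate,
        de_features=de_features,
    )


def simulate_latent_direct(
    mu: float,
    sigma1: float,
    sigma0: float,
    sigma: float,
    m: int,
    n: int,
    seed: int = 0,
    scale: str = "logit",
) -> DifferenceMatrix:
    """Draw a difference matrix directly from the latent model.

    a_i ~ N(mu, sigma1^2), b_j ~ N(0, sigma0^2), eps_ij ~ N(0, sigma^2),
    d_ij = a_i - b_j + eps_ij.  Standard deviations (not variances) are
    passed.  Used for calibration and parameter-recovery tests of the
    stage-2 fits; entries are unconstrained reals, so the matrix is tagged
    with a non-PI scale by default.
    """
    if min(sigma1, sigma0, sigma) < 0:
        raise ValueError("standard deviations must be nonnegative")
    rng = np.random.default_rng(seed)
    a = rng.normal(mu, sigma1, size=m)
    b = rng.normal(0.0, sigma0, size=n)
    eps = rng.normal(0.0, sigma, size=(m, n))
    d = a[:, None] - b[None, :] + eps
    return DifferenceMatrix(d=d, scale=scale)
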