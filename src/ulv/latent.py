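"""Stage-2 inference: crossed random-effects ("latent level") models for
pairwise difference matrices.

Each case subject i carries an unobserved latent expression level a_i ~
N(mu, sigma1^2) and each control subject j a level b_j ~ N(0, sigma0^2); the
observed pairwise difference is

    d_ij = a_i - b_j + eps_ij,      eps_ij ~ N(0, sigma^2).

mu is the population-level case-minus-control difference on the chosen scale
(null value 0.5 for the probabilistic index, 0 after the logit transform).
Sharing a_i across row i (and b_j across column j) is what models the
correlation among pairwise differences that involve the same subject.

The plain design (no covariates, equal weights) is a two-way random-effects
layout with one observation per cell, so the fit is closed form: mu_hat is
the grand mean and its variance comes from the row/column/interaction mean
squares.  Covariate-adjusted, cluster-size-weighted and multi-condition
variants are fitted by maximum likelihood on the full mn x mn Gaussian
covariance with profiled fixed effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import linalg, optimize, stats

from ulv.metrics import DifferenceMatrix

__all__ = [
    "LatentFit",
    "LatentLevels",
    "LatentModelSpec",
    "VarianceEstimate",
    "fit_closed_form",
    "fit_ml",
    "fit_multigroup",
    "lse_latent_levels",
    "variance_of_mu_hat",
]

_VAR_FLOOR = 1e-10


@dataclass
class LatentModelSpec:
    """Configuration of the latent-variable fit.

    scale      : "pi" (null mu0 = 0.5) or "logit" (null mu0 = 0).
    mu0        : override of the null value; default derived from scale.
    covariates : optional (m + n, p) matrix of per-subject covariates,
                 rows ordered cases first then controls.  The model uses
                 the pairwise differences X_i - X_j as fixed effects.
    weighted   : scale latent-level variances by 1/cluster-size
                 (sigma1^2 / K1i, sigma0^2 / K0j) to reflect that a PI
                 computed from more cells is less noisy.
    reml       : REML variance components for Wald inference (default) —
                 on the balanced crossed layout these coincide with the
                 closed form's sums-of-squares estimates, which maximum
                 likelihood shrinks.  Likelihood ratio tests always refit
                 both mean structures by plain ML, whatever this flag says.
    df_method  : "residual" -> t reference with m + n - 2 - p degrees of
                 freedom; "normal" -> standard normal reference;
                 "satterthwaite" -> per-contrast moment-matched df from the
                 curvature of the (restricted) likelihood.
    method     : "wald" or "lrt" test of H0: mu = mu0.
    """

    scale: Literal["pi", "logit"] = "pi"
    mu0: float | None = None
    covariates: np.ndarray | None = None
    weighted: bool = False
    reml: bool = True
    df_method: Literal["residual", "normal", "satterthwaite"] = "residual"
    method: Literal["wald", "lrt"] = "wald"

    @property
    def null_value(self) -> float:
        if self.mu0 is not None:
            return self.mu0
        return 0.5 if self.scale == "pi" else 0.0


@dataclass
class LatentFit:
    """Result of a latent-model fit.

    Variance components: sigma1_sq (case latent levels; a vector of
    per-group components in the multi-group model), sigma0_sq (control
    latent levels), sigma_sq (residual / interaction).  ``statistic`` is a t
    (or z) for two-group fits and a chi-square for multi-group tests.
    ``status`` is "ok", "degenerate_variance" (constant difference matrix —
    p is NaN by design) or "no_converge".
    """

    mu_hat: float | np.ndarray
    sigma1_sq: float | np.ndarray
    sigma0_sq: float
    sigma_sq: float
    statistic: float
    df: float
    p_value: float
    method: str
    se_mu: float | None = None
    beta_hat: np.ndarray | None = None
    beta_se: np.ndarray | None = None
    beta_p: np.ndarray | None = None
    mu0: float = 0.5
    loglik: float | None = None
    status: str = "ok"
    n_case: int = 0
    n_control: int = 0

    def to_record(self) -> dict:
        """Flat key-value summary for result tables."""
        mu = self.mu_hat
        rec = {
            "mu_hat": float(mu) if np.ndim(mu) == 0 else list(np.asarray(mu)),
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "sigma1_sq": (
                float(self.sigma1_sq)
                if np.ndim(self.sigma1_sq) == 0
                else list(np.asarray(self.sigma1_sq))
            ),
            "sigma0_sq": self.sigma0_sq,
            "sigma_sq": self.sigma_sq,
            "method": self.method,
            "status": self.status,
            "n_case": self.n_case,
            "n_control": self.n_control,
        }
        if self.beta_hat is not None:
            rec["beta_hat"] = list(np.asarray(self.beta_hat))
        return rec


@dataclass
class LatentLevels:
    """Least-squares latent levels (a_hat for cases, b_hat for controls)."""

    a_hat: np.ndarray
    b_hat: np.ndarray
    constraint: str
    fitted: np.ndarray = field(repr=False, default=None)  # a_i - b_j
    residuals: np.ndarray = field(repr=False, default=None)


class VarianceEstimate(NamedTuple):
    """Estimated var(mu_hat): full three-term form and its two-term
    approximation (the interaction term sigma^2/(mn) is usually negligible)."""

    full: float
    approx: float


def _sums_of_squares(d: np.ndarray) -> tuple[float, float, float, float]:
    """Row/column/interaction mean squares of a difference matrix.

    Returns (grand_mean, ms_row, ms_col, ms_inter).  ms_row — the sample
    variance of the case (row) means — estimates sigma1^2 + sigma^2/n, and
    ms_col estimates sigma0^2 + sigma^2/m; ms_inter is an unbiased estimate
    of sigma^2.  The closed-form test consumes ms_row/m + ms_col/n directly,
    matching var(dbar) = sigma1^2/m + sigma0^2/n + sigma^2/(mn) up to a
    single sigma^2/(mn).
    """
    m, n = d.shape
    row = d.mean(axis=1)
    col = d.mean(axis=0)
    grand = d.mean()
    ms_row = float(np.sum((row - grand) ** 2) / (m - 1)) if m > 1 else 0.0
    ms_col = float(np.sum((col - grand) ** 2) / (n - 1)) if n > 1 else 0.0
    if m > 1 and n > 1:
        resid = d - row[:, None] - col[None, :] + grand
        ms_inter = float(np.sum(resid**2) / ((m - 1) * (n - 1)))
    else:
        ms_inter = 0.0
    return float(grand), ms_row, ms_col, ms_inter


def fit_closed_form(D: DifferenceMatrix, mu0: float | None = None) -> LatentFit:
    """Closed-form latent-model test (no covariates, no weights).

    mu_hat is the grand mean of the difference matrix (the maximum
    likelihood estimator in the balanced two-way random-effects layout);
    the test statistic

        t = (dbar - mu0) / sqrt(ms_row/m + ms_col/n)

    is referred to a t distribution with m + n - 2 degrees of freedom
    (two-sided).  ms_row is the variance of the m case-row means and ms_col
    the variance of the n control-column means, so the statistic is exactly
    the Welch two-sample t comparing the least-squares latent levels of the
    two groups.

    A constant matrix has no estimable variance: the fit is flagged
    ``degenerate_variance`` with a NaN p-value rather than dividing by zero.
    """
    m, n = D.shape
    if m < 2 or n < 2:
        raise ValueError(f"closed form needs >= 2 subjects per group, got {m} x {n}")
    if mu0 is None:
        mu0 = D.mu0
    grand, ms_row, ms_col, ms_inter = _sums_of_squares(D.d)
    var_mu = ms_row / m + ms_col / n
    df = m + n - 2
    if var_mu <= 0.0:
        return LatentFit(
            mu_hat=grand,
            sigma1_sq=ms_row,
            sigma0_sq=ms_col,
            sigma_sq=ms_inter,
            statistic=float("nan"),
            df=df,
            p_value=float("nan"),
            method="closed_form",
            se_mu=0.0,
            mu0=mu0,
            status="degenerate_variance",
            n_case=m,
            n_control=n,
        )
    t = (grand - mu0) / np.sqrt(var_mu)
    p = 2.0 * stats.t.sf(abs(t), df)
    return LatentFit(
        mu_hat=grand,
        sigma1_sq=ms_row,
        sigma0_sq=ms_col,
        sigma_sq=ms_inter,
        statistic=float(t),
        df=df,
        p_value=float(p),
        method="closed_form",
        se_mu=float(np.sqrt(var_mu)),
        mu0=mu0,
        status="ok",
        n_case=m,
        n_control=n,
    )


def variance_of_mu_hat(D: DifferenceMatrix) -> VarianceEstimate:
    """Estimated variance of the grand-mean estimator mu_hat.

    full   = ms_row/m + ms_col/n + ms_inter/(mn)
    approx = ms_row/m + ms_col/n

    full >= approx whenever the interaction mean square is nonnegative
    (always, being a sum of squares).  The closed-form test uses the
    two-term form; the difference sigma^2/(mn) is second order in 1/(mn).
    """
    m, n = D.shape
    _, ms_row, ms_col, ms_inter = _sums_of_squares(D.d)
    approx = ms_row / m + ms_col / n
    return VarianceEstimate(full=approx + ms_inter / (m * n), approx=approx)


def lse_latent_levels(
    D: DifferenceMatrix,
    constraint: Literal["sum_b_zero", "moore_penrose"] = "sum_b_zero",
) -> LatentLevels:
    """Least-squares latent levels for d_ij ~ a_i - b_j.

    The normal equations determine (a, b) only up to a common additive
    constant (adding c to every a_i and every b_j leaves all differences
    unchanged), so a constraint picks the representative:

    * ``sum_b_zero``    : sum_j b_hat_j = 0, consistent with the model's
                          assumption that control levels are centered at 0.
                          Then a_hat_i = dbar_i. and b_hat_j = dbar -
                          dbar_.j.
    * ``moore_penrose`` : minimum-norm solution (Moore-Penrose pseudoinverse
                          of the design); equals the sum_b_zero solution
                          shifted by -m/(m+n) * dbar on both a and b.

    Both yield identical fitted values a_hat_i - b_hat_j and residuals.  For
    separable metrics d_ij = g_i - h_j the residuals are exactly zero.
    """
    d = D.d
    m, n = d.shape
    row = d.mean(axis=1)
    col = d.mean(axis=0)
    grand = d.mean()
    a = row.copy()
    b = grand - col
    if constraint == "moore_penrose":
        shift = -m / (m + n) * grand
        a = a + shift
        b = b + shift
    elif constraint != "sum_b_zero":
        raise ValueError(f"unknown constraint {constraint!r}")
    fitted = a[:, None] - b[None, :]
    return LatentLevels(
        a_hat=a,
        b_hat=b,
        constraint=constraint,
        fitted=fitted,
        residuals=d - fitted,
    )


# ---------------------------------------------------------------------------
# Maximum likelihood machinery


class _MixedDesign:
    """Gaussian mixed model y = X beta + Z_a u_a + Z_b u_b + eps built
    explicitly on the mn (or stacked) observation vector.

    ``groups_a`` maps each case random effect to a variance-component index,
    so the two-group model (one component) and the multi-group model (one
    component per condition) share the same code path.  ``w_a``/``w_b`` hold
    per-effect variance multipliers (1/K for the weighted analysis).
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        za_idx: np.ndarray,
        zb_idx: np.ndarray,
        groups_a: np.ndarray,
        n_groups: int,
        w_a: np.ndarray,
        w_b: np.ndarray,
    ) -> None:
        self.y = y
        self.X = X
        self.za_idx = za_idx  # observation -> case-effect index
        self.zb_idx = zb_idx  # observation -> control-effect index
        self.groups_a = groups_a  # case-effect index -> variance group
        self.n_groups = n_groups
        self.w_a = w_a
        self.w_b = w_b
        self.n_obs = y.size
        self.n_a = groups_a.size
        self.n_b = int(zb_idx.max()) + 1

    def covariance(self, theta: np.ndarray) -> np.ndarray:
        """V(theta); theta = (sigma_a^2 per group..., sigma_b^2, sigma^2)."""
        sa = theta[: self.n_groups]
        sb = theta[self.n_groups]
        se = theta[self.n_groups + 1]
        var_a = sa[self.groups_a] * self.w_a  # per case effect
        var_b = sb * self.w_b
        same_a = self.za_idx[:, None] == self.za_idx[None, :]
        same_b = self.zb_idx[:, None] == self.zb_idx[None, :]
        V = np.where(same_a, var_a[self.za_idx][:, None], 0.0) + np.where(
            same_b, var_b[self.zb_idx][:, None], 0.0
        )
        V[np.diag_indices_from(V)] += se
        return V

    def profiled_nll(
        self, log_theta: np.ndarray, reml: bool = False
    ) -> tuple[float, np.ndarray, np.ndarray]:
        """-2 log likelihood with beta profiled out; returns (nll2, beta, cov_beta)."""
        theta = np.exp(log_theta)
        V = self.covariance(theta)
        try:
            c, low = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            return np.inf, None, None
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        Vi_y = linalg.cho_solve((c, low), self.y)
        if self.X.shape[1] > 0:
            Vi_X = linalg.cho_solve((c, low), self.X)
            XtViX = self.X.T @ Vi_X
            XtViy = self.X.T @ Vi_y
            try:
                cov_beta = linalg.inv(XtViX)
            except linalg.LinAlgError:
                return np.inf, None, None
            beta = cov_beta @ XtViy
            resid = self.y - self.X @ beta
            Vi_r = linalg.cho_solve((c, low), resid)
            quad = float(resid @ Vi_r)
        else:
            beta = np.zeros(0)
            cov_beta = np.zeros((0, 0))
            quad = float(self.y @ Vi_y)
            XtViX = None
        nll2 = logdet + quad + self.n_obs * np.log(2.0 * np.pi)
        if reml and self.X.shape[1] > 0:
            sign, ld = np.linalg.slogdet(XtViX)
            nll2 += ld
        return nll2, beta, cov_beta

    def fit(
        self, start: np.ndarray, reml: bool = False
    ) -> tuple[np.ndarray, float, np.ndarray, np.ndarray, bool]:
        """Optimize variance components on the log scale (Nelder-Mead).

        Returns (theta, loglik, beta, cov_beta, converged).
        """
        x0 = np.log(np.maximum(start, _VAR_FLOOR))
        res = optimize.minimize(
            lambda lt: self.profiled_nll(lt, reml)[0],
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000},
        )
        nll2, beta, cov_beta = self.profiled_nll(res.x, reml)
        theta = np.maximum(np.exp(res.x), _VAR_FLOOR)
        return theta, -0.5 * nll2, beta, cov_beta, bool(res.success)


def _two_group_design(
    D: DifferenceMatrix, spec: LatentModelSpec, with_mean: bool
) -> _MixedDesign:
    m, n = D.shape
    y = D.d.ravel()  # row-major: all controls for case 0, then case 1, ...
    ii, jj = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")
    za = ii.ravel()
    zb = jj.ravel()
    cols = []
    if with_mean:
        cols.append(np.ones(m * n))
    if spec.covariates is not None:
        Xsub = np.atleast_2d(np.asarray(spec.covariates, dtype=float))
        if Xsub.shape[0] != m + n:
            raise ValueError(
                f"covariate matrix has {Xsub.shape[0]} rows; expected "
                f"{m + n} (cases then controls)"
            )
        xc, xk = Xsub[:m], Xsub[m:]
        for p in range(Xsub.shape[1]):
            cols.append((xc[:, p][:, None] - xk[:, p][None, :]).ravel())
    X = np.column_stack(cols) if cols else np.zeros((m * n, 0))
    if spec.weighted:
        if D.k_case is None or D.k_control is None:
            raise ValueError("weighted fit requires cluster sizes on the matrix")
        w_a = 1.0 / D.k_case.astype(float)
        w_b = 1.0 / D.k_control.astype(float)
    else:
        w_a = np.ones(m)
        w_b = np.ones(n)
    return _MixedDesign(
        y=y,
        X=X,
        za_idx=za,
        zb_idx=zb,
        groups_a=np.zeros(m, dtype=int),
        n_groups=1,
        w_a=w_a,
        w_b=w_b,
    )


def _start_values(d: np.ndarray, n_groups: int = 1) -> np.ndarray:
    _, ms_row, ms_col, ms_inter = _sums_of_squares(d)
    m, n = d.shape
    se = max(ms_inter, 1e-6)
    sa = max(ms_row - se / n, 1e-6)
    sb = max(ms_col - se / m, 1e-6)
    return np.concatenate([np.full(n_groups, sa), [sb, se]])


def _null_start_values(d: np.ndarray, mu0: float) -> list[np.ndarray]:
    """Start values for a null (no-fixed-effects) fit.

    With the mean constrained to mu0, any residual level offset must be
    absorbed by one of the zero-mean random effects, so the likelihood
    surface has competing modes: the offset can sit in the case variance or
    in the control variance.  Both uncentered-moment starts are returned
    (plus the centered one); the optimizer keeps the best optimum.
    """
    _, ms_row, ms_col, ms_inter = _sums_of_squares(d)
    row = d.mean(axis=1) - mu0
    col = mu0 - d.mean(axis=0)  # level absorbed as -b_j
    se = max(ms_inter, 1e-6)
    sa_big = max(float(np.mean(row**2)), 1e-6)
    sb_big = max(float(np.mean(col**2)), 1e-6)
    m, n = d.shape
    sa0 = max(ms_row - se / n, 1e-6)
    sb0 = max(ms_col - se / m, 1e-6)
    return [
        np.array([sa_big, sb0, se]),
        np.array([sa0, sb_big, se]),
        np.array([sa_big, sb_big, se]),
    ]


def _fit_best(design: "_MixedDesign", starts, reml: bool = False):
    """Run the optimizer from several starts; keep the best optimum."""
    best = None
    for s in starts:
        res = design.fit(np.asarray(s, dtype=float), reml=reml)
        if best is None or res[1] > best[1]:
            best = res
    return best


def _satterthwaite_df(
    design: "_MixedDesign", theta: np.ndarray, contrast: int, reml: bool
) -> float:
    """Moment-matched degrees of freedom for one fixed-effect contrast.

    df = 2 f^2 / (g' A g) with f(theta) the contrast variance
    [(X'V^-1 X)^-1]_cc, g its gradient in log-theta, and A the inverse
    observed information of the (restricted) likelihood in log-theta —
    the quadratic approximation underlying lmerTest-style t tests.
    Numerical derivatives; falls back to +inf (normal reference) when the
    curvature is not positive definite.
    """
    lt = np.log(np.maximum(theta, _VAR_FLOOR))
    k = lt.size
    h = 1e-4

    def fvar(ltheta):
        _, _, cov_beta = design.profiled_nll(ltheta, reml)
        if cov_beta is None:
            return np.nan
        return cov_beta[contrast, contrast]

    def nll(ltheta):
        return design.profiled_nll(ltheta, reml)[0]

    f0 = fvar(lt)
    grad = np.zeros(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = h
        grad[i] = (fvar(lt + e) - fvar(lt - e)) / (2 * h)
    # observed information of -2 log L_R: Hessian via central differences
    H = np.zeros((k, k))
    base = nll(lt)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            if i == j:
                H[i, i] = (nll(lt + ei) - 2 * base + nll(lt - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    nll(lt + ei + ej)
                    - nll(lt + ei - ej)
                    - nll(lt - ei + ej)
                    + nll(lt - ei - ej)
                ) / (4 * h**2)
    try:
        # Var(log theta_hat) ~ 2 H^-1 since H is the Hessian of -2 logL
        A = 2.0 * linalg.inv(H)
        denom = float(grad @ A @ grad)
    except linalg.LinAlgError:
        return float("inf")
    if not np.isfinite(denom) or denom <= 0 or not np.isfinite(f0):
        return float("inf")
    return float(2.0 * f0**2 / denom)


def fit_ml(D: DifferenceMatrix, spec: LatentModelSpec | None = None) -> LatentFit:
    """Likelihood-based latent-model fit for two groups.

    Handles covariate adjustment (fixed effects on the pairwise covariate
    differences X_i - X_j) and the cluster-size-weighted variant (latent
    variances sigma1^2/K1i and sigma0^2/K0j).  The mn x mn marginal
    covariance is built explicitly and the fixed effects are profiled out;
    the optimizer works on log variance components started at the
    sums-of-squares estimates.  Variance components for Wald inference use
    REML by default (on the balanced layout these equal the closed form's
    sums-of-squares estimates; plain ML shrinks them and makes the t
    anti-conservative).

    The default test is a Wald t of H0: mu = mu0 with m + n - 2 - p degrees
    of freedom (p = number of covariates); ``df_method="satterthwaite"``
    computes a per-contrast moment-matched df instead.  ``spec.method =
    "lrt"`` refits both mean structures by plain ML with mu pinned at mu0
    under the null and refers 2*(LL1 - LL0) to chi-square(1).  Without
    covariates or weights the Wald fit reproduces `fit_closed_form`.
    """
    if spec is None:
        spec = LatentModelSpec()
    m, n = D.shape
    if m < 2 or n < 2:
        raise ValueError(f"need >= 2 subjects per group, got {m} x {n}")
    mu0 = spec.null_value
    if np.ptp(D.d) == 0.0:
        fit = fit_closed_form(D, mu0)
        fit.method = "ml_wald"
        return fit
    design = _two_group_design(D, spec, with_mean=True)
    use_reml = spec.reml and spec.method != "lrt"
    theta, ll, beta, cov_beta, ok = design.fit(_start_values(D.d), reml=use_reml)
    mu_hat = float(beta[0])
    se_mu = float(np.sqrt(cov_beta[0, 0]))
    n_cov = design.X.shape[1] - 1
    stat = (mu_hat - mu0) / se_mu

    def _wald_df(contrast: int) -> float:
        if spec.df_method == "normal":
            return float("inf")
        if spec.df_method == "satterthwaite":
            return _satterthwaite_df(design, theta, contrast, use_reml)
        return float(max(m + n - 2 - n_cov, 1))

    df = _wald_df(0)
    p = 2.0 * (
        stats.norm.sf(abs(stat)) if np.isinf(df) else stats.t.sf(abs(stat), df)
    )
    method = "ml_wald"
    if spec.method == "lrt":
        null_design = _two_group_design(D, spec, with_mean=False)
        null_design.y = design.y - mu0
        _, ll0, _, _, _ = _fit_best(
            null_design, _null_start_values(D.d, mu0), reml=False
        )
        lrt = max(2.0 * (ll - ll0), 0.0)
        stat, df, p = lrt, 1.0, stats.chi2.sf(lrt, 1)
        method = "lrt"
    beta_hat = beta[1:] if n_cov > 0 else None
    beta_se = (
        np.sqrt(np.diag(cov_beta)[1:]) if n_cov > 0 else None
    )
    beta_p = None
    if n_cov > 0:
        z = beta_hat / beta_se
        beta_p = np.empty(n_cov)
        for c in range(n_cov):
            dfc = _wald_df(1 + c)
            beta_p[c] = 2.0 * (
                stats.norm.sf(abs(z[c]))
                if np.isinf(dfc)
                else stats.t.sf(abs(z[c]), dfc)
            )
    return LatentFit(
        mu_hat=mu_hat,
        sigma1_sq=float(theta[0]),
        sigma0_sq=float(theta[1]),
        sigma_sq=float(theta[2]),
        statistic=float(stat),
        df=df,
        p_value=float(p),
        method=method,
        se_mu=se_mu,
        beta_hat=beta_hat,
        beta_se=beta_se,
        beta_p=beta_p,
        mu0=mu0,
        loglik=ll,
        status="ok" if ok else "no_converge",
        n_case=m,
        n_control=n,
    )


def fit_multigroup(
    D_list: Sequence[DifferenceMatrix],
    spec: LatentModelSpec | None = None,
) -> LatentFit:
    """Joint fit of M condition-vs-reference difference matrices.

    All matrices must share the same reference (control) subjects, whose
    latent levels b_0j are common across conditions; condition m gets its
    own mean mu_m and latent variance sigma_m^2.  H0: mu_1 = ... = mu_M =
    mu0 is tested by a likelihood ratio (default) or Wald chi-square with M
    degrees of freedom.
    """
    if spec is None:
        spec = LatentModelSpec(method="lrt")
    if len(D_list) < 1:
        raise ValueError("need at least one difference matrix")
    ref_ids = list(D_list[0].control_ids)
    for D in D_list[1:]:
        if list(D.control_ids) != ref_ids:
            raise ValueError(
                "all difference matrices must share the same reference subjects "
                f"(got {D.control_ids} vs {ref_ids})"
            )
    if spec.covariates is not None:
        raise NotImplementedError("multi-group fit does not take covariates")
    M = len(D_list)
    n = len(ref_ids)
    mu0 = spec.null_value

    ys, za, zb, ga = [], [], [], []
    w_a = []
    case_offset = 0
    for g, D in enumerate(D_list):
        mg = D.shape[0]
        ii, jj = np.meshgrid(np.arange(mg), np.arange(n), indexing="ij")
        ys.append(D.d.ravel())
        za.append(ii.ravel() + case_offset)
        zb.append(jj.ravel())
        ga.append(np.full(mg, g, dtype=int))
        if spec.weighted:
            if D.k_case is None:
                raise ValueError("weighted fit requires cluster sizes")
            w_a.append(1.0 / D.k_case.astype(float))
        else:
            w_a.append(np.ones(mg))
        case_offset += mg
    y = np.concatenate(ys)
    za = np.concatenate(za)
    zb = np.concatenate(zb)
    groups_a = np.concatenate(ga)
    w_a = np.concatenate(w_a)
    if spec.weighted:
        if D_list[0].k_control is None:
            raise ValueError("weighted fit requires cluster sizes")
        w_b = 1.0 / D_list[0].k_control.astype(float)
    else:
        w_b = np.ones(n)
    # group-indicator fixed effects: one mean per condition
    X = np.zeros((y.size, M))
    for g in range(M):
        X[groups_a[za] == g, g] = 1.0

    design = _MixedDesign(y, X, za, zb, groups_a, M, w_a, w_b)
    start = np.concatenate(
        [
            [_start_values(D.d)[0] for D in D_list],
            _start_values(D_list[0].d)[1:],
        ]
    )
    use_reml = spec.reml and spec.method != "lrt"
    theta, ll, beta, cov_beta, ok = design.fit(start, reml=use_reml)
    mu_hat = beta.copy()
    m_total = int(case_offset)

    if spec.method == "wald":
        delta = mu_hat - mu0
        try:
            stat = float(delta @ linalg.inv(cov_beta) @ delta)
        except linalg.LinAlgError:
            stat = float("nan")
        p = float(stats.chi2.sf(stat, M))
        method = "ml_wald"
    else:
        null_design = _MixedDesign(
            y - mu0, np.zeros((y.size, 0)), za, zb, groups_a, M, w_a, w_b
        )
        per_group = [_null_start_values(D.d, mu0) for D in D_list]
        tail = _start_values(D_list[0].d)[1:]
        col_big = max(
            float(np.mean((mu0 - np.concatenate([D.d.mean(axis=0) for D in D_list])) ** 2)),
        1e-6)
        null_starts = [
            np.concatenate([[sg[0][0] for sg in per_group], tail]),
            np.concatenate([[sg[1][0] for sg in per_group], [col_big, tail[1]]]),
            np.concatenate([[sg[2][0] for sg in per_group], [col_big, tail[1]]]),
        ]
        _, ll0, _, _, _ = _fit_best(null_design, null_starts, reml=False)
        stat = max(2.0 * (ll - ll0), 0.0)
        p = float(stats.chi2.sf(stat, M))
        method = "lrt"
    return LatentFit(
        mu_hat=mu_hat if M > 1 else float(mu_hat[0]),
        sigma1_sq=theta[:M] if M > 1 else float(theta[0]),
        sigma0_sq=float(theta[M]),
        sigma_sq=float(theta[M + 1]),
        statistic=float(stat),
        df=float(M),
        p_value=p,
        method=method,
        se_mu=float(np.sqrt(cov_beta[0, 0])) if M == 1 else None,
        mu0=mu0,
        loglik=ll,
        status="ok" if ok else "no_converge",
        n_case=m_total,
        n_control=n,
    )
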