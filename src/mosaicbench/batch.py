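"""Batch-effect tests: do mosaic VAF profiles differ between DNA batches?

The benchmark characterizes mosaic VAFs in one homogenized reference-material
(RM) DNA batch; other batches of the same cell line can drift as clones
expand.  The test models alt reads out of total reads per variant per sample
as binomial on the logit scale, with DNA source (RM vs non-RM) and
sequencing platform as fixed effects and a Gaussian random intercept per
variant absorbing baseline VAF heterogeneity:

    alt_ij ~ Binomial(n_ij, logit^-1(beta0 + beta_RM * RM_ij
                                     + beta_platform' z_ij + u_i)),
    u_i ~ N(0, sigma_u^2).

The marginal likelihood integrates the scalar random effect per variant by
adaptive Gauss-Hermite quadrature (Laplace mode/curvature per variant,
default 25 nodes) and is maximized directly.  A likelihood-ratio test of the
DNA-source term against the nested model without it gives the global
batch-effect p-value (chi-square, 1 df).  Per-variant binomial GLMs give
individual log-odds shifts with Benjamini-Hochberg adjusted q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

_SQRT2 = np.sqrt(2.0)
_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class VafObservation:
    """One sample's read counts for one variant in one DNA batch."""

    variant_id: str
    dna_source: str  # "RM" or "NONRM"
    platform: str
    alt_count: int
    ref_count: int

    def __post_init__(self) -> None:
        if self.alt_count < 0 or self.ref_count < 0:
            raise ValueError("read counts must be non-negative")


def observations_frame(obs: Sequence[VafObservation]) -> pd.DataFrame:
    return pd.DataFrame([o.__dict__ for o in obs])


# ---------------------------------------------------------------------------
# GLMM by adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

@dataclass
class GlmmFit:
    """A fitted binomial random-intercept GLMM."""

    terms: tuple[str, ...]
    beta: np.ndarray
    beta_se: np.ndarray | None
    sigma_u: float
    loglik: float
    converged: bool
    n_obs: int
    n_variants: int
    separation: bool = False

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def coef_se(self, term: str) -> float:
        if self.beta_se is None:
            raise ValueError("standard errors were not computed for this fit")
        return float(self.beta_se[self.terms.index(term)])


class _AgqModel:
    """Marginal binomial random-intercept log-likelihood, AGQ over u."""

    def __init__(self, y, n, X, groups, n_groups, nodes):
        self.y = y
        self.n = n
        self.X = X
        self.groups = groups
        self.n_groups = n_groups
        t, w = np.polynomial.hermite.hermgauss(nodes)
        self.t = t
        self.logw = np.log(w)
        self.logC = float(
            np.sum(special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1))
        )
        self._u_mode = np.zeros(n_groups)  # warm start across evaluations

    def _group_loglik_terms(self, eta):
        # sum_j [y eta - n log(1 + e^eta)] per group, without binomial constants
        vals = self.y * eta - self.n * np.logaddexp(0.0, eta)
        return np.bincount(self.groups, weights=vals, minlength=self.n_groups)

    def _mode(self, eta0, sigma2):
        u = self._u_mode.copy()
        for _ in range(60):
            eta = eta0 + u[self.groups]
            mu = special.expit(eta)
            g = (
                np.bincount(self.groups, weights=self.y - self.n * mu, minlength=self.n_groups)
                - u / sigma2
            )
            h = (
                -np.bincount(self.groups, weights=self.n * mu * (1.0 - mu), minlength=self.n_groups)
                - 1.0 / sigma2
            )
            step = g / h
            u = u - step
            if np.max(np.abs(step)) < 1e-11:
                break
        eta = eta0 + u[self.groups]
        mu = special.expit(eta)
        h = (
            -np.bincount(self.groups, weights=self.n * mu * (1.0 - mu), minlength=self.n_groups)
            - 1.0 / sigma2
        )
        self._u_mode = u
        return u, h

    def loglik(self, beta, sigma):
        eta0 = self.X @ beta
        if sigma <= 1e-8:
            # degenerate random effect: plain binomial GLM likelihood
            return float(self._group_loglik_terms(eta0).sum() + self.logC)
        sigma2 = sigma * sigma
        u_hat, h = self._mode(eta0, sigma2)
        tau = 1.0 / np.sqrt(-h)
        # node expansion: u_ik = u_hat_i + sqrt(2) tau_i t_k
        acc = np.empty((len(self.t), self.n_groups))
        for k, (t_k, logw_k) in enumerate(zip(self.t, self.logw)):
            u_k = u_hat + _SQRT2 * tau * t_k
            f_k = (
                self._group_loglik_terms(eta0 + u_k[self.groups])
                - u_k * u_k / (2.0 * sigma2)
                - np.log(sigma)
                - 0.5 * _LOG_2PI
            )
            acc[k] = logw_k + t_k * t_k + f_k
        log_integrals = np.log(_SQRT2 * tau) + special.logsumexp(acc, axis=0)
        return float(log_integrals.sum() + self.logC)


def _design(df: pd.DataFrame, include_source: bool, include_platform: bool):
    terms = ["intercept"]
    cols = [np.ones(len(df))]
    if include_source:
        terms.append("dna_source_RM")
        cols.append((df["dna_source"].astype(str) == "RM").to_numpy(float))
    platforms = sorted(df["platform"].astype(str).unique())
    if include_platform and len(platforms) >= 2:
        for p in platforms[1:]:
            terms.append(f"platform_{p}")
            cols.append((df["platform"].astype(str) == p).to_numpy(float))
    return np.column_stack(cols), tuple(terms)


def fit_glmm(
    observations: pd.DataFrame | Sequence[VafObservation],
    include_source: bool = True,
    include_platform: bool = True,
    nodes: int = 25,
    tol: float = 1e-8,
    compute_se: bool = True,
) -> GlmmFit:
    """Fit the binomial random-intercept GLMM by maximum likelihood.

    ``observations`` carries columns variant_id, dna_source, platform,
    alt_count, ref_count.  The platform term enters only when at least two
    platforms are present.  Raises on non-convergence.
    """
    if not isinstance(observations, pd.DataFrame):
        observations = observations_frame(observations)
    df = observations.sort_values("variant_id", kind="stable").reset_index(drop=True)
    variant_ids, groups = np.unique(df["variant_id"].to_numpy(), return_inverse=True)
    n_groups = len(variant_ids)
    if n_groups < 2:
        raise ValueError("need at least 2 variants to fit a random-intercept model")
    y = df["alt_count"].to_numpy(float)
    n = y + df["ref_count"].to_numpy(float)
    if (n <= 0).any():
        raise ValueError("every observation needs positive total depth")

    X, terms = _design(df, include_source, include_platform)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    model = _AgqModel(y, n, X, groups, n_groups, nodes)

    p0 = np.clip(y.sum() / n.sum(), 1e-6, 1 - 1e-6)
    theta0 = np.r_[np.zeros(X.shape[1]), np.log(0.5)]
    theta0[0] = special.logit(p0)

    def nll(theta):
        return -model.loglik(theta[:-1], np.exp(theta[-1]))

    bounds = [(None, None)] * X.shape[1] + [(np.log(1e-6), np.log(20.0))]
    res = optimize.minimize(
        nll, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": tol, "gtol": 1e-7},
    )
    if not res.success and "ABNORMAL" in str(res.message):
        raise RuntimeError(
            f"GLMM did not converge after {res.nit} iterations: {res.message}; "
            f"final gradient norm {np.max(np.abs(res.jac)):.3g}"
        )
    beta = res.x[:-1]
    sigma_u = float(np.exp(res.x[-1]))
    separation = bool(np.max(np.abs(beta)) > 15.0)

    beta_se = None
    if compute_se:
        hess = _numeric_hessian(nll, res.x)
        try:
            cov = np.linalg.inv(hess)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
            beta_se = se[:-1]
        except np.linalg.LinAlgError:
            beta_se = None

    return GlmmFit(
        terms=terms, beta=beta, beta_se=beta_se, sigma_u=sigma_u,
        loglik=-float(res.fun), converged=bool(res.success), n_obs=len(df),
        n_variants=n_groups, separation=separation,
    )


def glmm_loglik_at(
    observations: pd.DataFrame,
    beta: np.ndarray,
    sigma_u: float,
    include_source: bool = True,
    include_platform: bool = True,
    nodes: int = 25,
) -> float:
    """Marginal log-likelihood at fixed parameters (no optimization).

    With ``sigma_u = 0`` this is the pooled binomial GLM log-likelihood,
    which anchors the quadrature against closed-form results.
    """
    df = observations.sort_values("variant_id", kind="stable").reset_index(drop=True)
    _, groups = np.unique(df["variant_id"].to_numpy(), return_inverse=True)
    y = df["alt_count"].to_numpy(float)
    n = y + df["ref_count"].to_numpy(float)
    X, _ = _design(df, include_source, include_platform)
    model = _AgqModel(y, n, X, groups, int(groups.max()) + 1, nodes)
    return model.loglik(np.asarray(beta, float), float(sigma_u))


def _numeric_hessian(fun, x, eps: float = 1e-4) -> np.ndarray:
    k = len(x)
    hess = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            hess[i, j] = hess[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4 * eps * eps)
    return hess


def lrt(full: GlmmFit, reduced: GlmmFit, tol: float = 1e-6) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits; returns (stat, df=1, p)."""
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -tol:
        raise ValueError(
            f"negative LRT statistic ({stat:.4g}): models not nested or not converged"
        )
    stat = max(stat, 0.0)
    return stat, 1, float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# per-variant GLMs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantGlmResult:
    variant_id: str
    log_odds_rm: float
    ci95_low: float
    ci95_high: float
    p: float
    separation: bool = False


def fit_variant_glm(observations: pd.DataFrame, include_platform: bool = False) -> VariantGlmResult:
    """Binomial GLM for one variant: log-odds of the RM batch effect.

    Default is source-only (counts aggregated per source into a 2x2 table,
    fit by IRLS).  When a cell of the aggregated table is zero the estimate
    separates; the Haldane-Anscombe correction (add 0.5 to all four cells)
    is applied and the result flagged.
    """
    df = observations
    sources = set(df["dna_source"].astype(str))
    if not {"RM", "NONRM"} <= sources:
        raise ValueError("per-variant GLM needs observations from both RM and NONRM")
    variant_id = str(df["variant_id"].iloc[0])

    agg = df.groupby(df["dna_source"].astype(str))[["alt_count", "ref_count"]].sum()
    a, b = float(agg.loc["RM", "alt_count"]), float(agg.loc["RM", "ref_count"])
    c, d = float(agg.loc["NONRM", "alt_count"]), float(agg.loc["NONRM", "ref_count"])
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        est = np.log(a * d / (b * c))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = est / se
        return VariantGlmResult(
            variant_id, float(est), float(est - 1.959963984540054 * se),
            float(est + 1.959963984540054 * se), float(2 * stats.norm.sf(abs(z))),
            separation=True,
        )

    endog = df[["alt_count", "ref_count"]].to_numpy(float)
    exog_cols = {"const": np.ones(len(df)), "dna_source_RM": (df["dna_source"].astype(str) == "RM").to_numpy(float)}
    if include_platform:
        platforms = sorted(df["platform"].astype(str).unique())
        for p in platforms[1:]:
            exog_cols[f"platform_{p}"] = (df["platform"].astype(str) == p).to_numpy(float)
    exog = pd.DataFrame(exog_cols)
    fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    est = float(fit.params["dna_source_RM"])
    se = float(fit.bse["dna_source_RM"])
    ci = fit.conf_int().loc["dna_source_RM"]
    return VariantGlmResult(
        variant_id, est, float(ci[0]), float(ci[1]),
        float(fit.pvalues["dna_source_RM"]), separation=False,
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def per_variant_tests(observations: pd.DataFrame, include_platform: bool = False) -> pd.DataFrame:
    """Per-variant GLM log-odds, 95% CIs, p-values and BH q-values."""
    rows = []
    for _, sub in observations.groupby("variant_id", sort=True):
        r = fit_variant_glm(sub, include_platform=include_platform)
        rows.append(r.__dict__)
    table = pd.DataFrame(rows)
    table["q_bh"] = bh_adjust(table["p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

@dataclass
class BatchEffectFit:
    """Global GLMM + LRT plus per-variant GLM results."""

    full: GlmmFit
    reduced: GlmmFit
    lrt_stat: float
    lrt_p: float
    per_variant: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def beta(self) -> dict[str, float]:
        return {t: float(b) for t, b in zip(self.full.terms, self.full.beta)}

    @property
    def sigma_u(self) -> float:
        return self.full.sigma_u

    @property
    def loglik(self) -> float:
        return self.full.loglik


def batch_effect_test(
    observations: pd.DataFrame | Sequence[VafObservation],
    nodes: int = 25,
    include_platform: bool = True,
    per_variant: bool = True,
    compute_se: bool = True,
) -> BatchEffectFit:
    """Run the complete batch-effect analysis.

    Fits the full GLMM and the nested model without the DNA-source term,
    forms the LRT, and (optionally) the per-variant GLM table with BH FDR.
    """
    if not isinstance(observations, pd.DataFrame):
        observations = observations_frame(observations)
    full = fit_glmm(observations, include_source=True, include_platform=include_platform,
                    nodes=nodes, compute_se=compute_se)
    reduced = fit_glmm(observations, include_source=False, include_platform=include_platform,
                       nodes=nodes, compute_se=False)
    stat, _, p = lrt(full, reduced)
    pv = per_variant_tests(observations) if per_variant else pd.DataFrame()
    return BatchEffectFit(full=full, reduced=reduced, lrt_stat=stat, lrt_p=p, per_variant=pv)
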