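"""Proportional-odds regression of SNP genotype on multivariate phenotypes.

This module implements the "reverse regression" approach to genetic
association: the genotype G at a biallelic marker, coded 0/1/2 by allele
count, is treated as an ordinal response and the phenotype vector y (of any
mix of continuous and binary traits, entered as numeric codes) as the
covariates of a cumulative-logit (proportional odds) model

    P(G <= 0 | y) = expit(alpha1 + beta' y)
    P(G <= 1 | y) = expit(alpha2 + beta' y),       alpha1 < alpha2.

The null hypothesis of no association is beta = 0.  Its score test has a
closed form built entirely from the sample genotype proportions: with
p-hat = (p0, p1, p2), cumulative proportions gamma1 = p0, gamma2 = p0 + p1,
per-genotype weights

    c = (1 - gamma1,  1 - gamma1 - gamma2,  -gamma2),

score vector U = sum_i c(G_i) (y_i - ybar), variance
V = wbar * sum_i (y_i - ybar)(y_i - ybar)'  with  wbar = sum_g p_g c_g^2,
the statistic T = U' V^{-1} U is chi-square with q degrees of freedom under
the null.  No iterative fitting is needed per variant, which is what makes
the test usable genome-wide.

The likelihood-ratio test (numerical maximisation under the alternative) is
also provided, via Newton-Raphson with analytic gradient and Hessian.

The model class follows the statsmodels idiom: build ``GenotypePOModel``
from data, call ``score_test()`` / ``lrt()`` / ``fit()``; ``fit()`` returns
a ``GenotypePOResults`` with estimates, standard errors and ``summary()``.
Module-level functions (``score_test``, ``lrt_test``, ``fit_null``, ...)
wrap the class for one-shot use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit
from scipy.stats import chi2

__all__ = [
    "DegenerateMarkerError",
    "CollinearPhenotypesError",
    "NullGenotypeFit",
    "POModelParams",
    "ScoreTestResult",
    "LRTResult",
    "GenotypePOModel",
    "GenotypePOResults",
    "fit_null",
    "score_vector",
    "score_variance",
    "score_test",
    "po_loglik",
    "fit_po_mle",
    "lrt_test",
    "score_test_from_table",
    "lrt_test_from_table",
]


class DegenerateMarkerError(ValueError):
    """Marker has fewer than two observed genotype categories."""


class CollinearPhenotypesError(ValueError):
    """Phenotype covariance matrix is singular (collinear columns)."""


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NullGenotypeFit:
    """Null-model (beta = 0) fit: genotype proportions and score weights.

    Under the null the cumulative-logit MLEs are the sample cumulative
    genotype proportions; everything the score test needs derives from them.
    """

    counts: tuple[int, int, int]
    proportions: tuple[float, float, float]
    gamma1: float
    gamma2: float
    weights: tuple[float, float, float]
    wbar: float
    n: int

    @property
    def alpha(self) -> tuple[float, float]:
        """Null intercepts (logit of the cumulative proportions).

        Clipped to +/-36 (where expit saturates in double precision) when a
        boundary category is empty and the formal MLE is infinite.
        """
        return (float(np.clip(logit(self.gamma1), -36.0, 36.0)),
                float(np.clip(logit(self.gamma2), -36.0, 36.0)))

    @property
    def loglik(self) -> float:
        """Maximised trinomial log-likelihood under beta = 0."""
        ll = 0.0
        for n_g, p_g in zip(self.counts, self.proportions):
            if n_g > 0:
                ll += n_g * math.log(p_g)
        return ll


@dataclass(frozen=True)
class POModelParams:
    """Parameters (alpha1, alpha2, beta) of the cumulative-logit model."""

    alpha1: float
    alpha2: float
    beta: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, float)))
        if not self.alpha1 < self.alpha2:
            raise ValueError(
                f"alpha1 must be < alpha2 (got {self.alpha1} >= {self.alpha2}); "
                "cumulative probabilities must be ordered"
            )

    def as_vector(self) -> np.ndarray:
        return np.concatenate([[self.alpha1, self.alpha2], self.beta])


@dataclass(frozen=True)
class ScoreTestResult:
    """Closed-form score test of beta = 0."""

    U: np.ndarray | None
    V: np.ndarray | None
    statistic: float | None
    df: int | None
    p_value: float | None
    n_used: int
    status: str = "ok"  # ok | monomorphic
    reason: str | None = None

    @property
    def T(self) -> float | None:  # paper-agnostic alias used throughout
        return self.statistic


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of beta = 0."""

    loglik_null: float
    loglik_alt: float
    statistic: float
    df: int
    p_value: float
    converged: bool
    iterations: int


@dataclass
class GenotypePOResults:
    """MLE results of the proportional-odds genotype model.

    Attributes mirror statsmodels results objects: ``params`` is the packed
    vector (alpha1, alpha2, beta_1..beta_q), ``bse`` the standard errors from
    the inverse observed information, ``llf`` the maximised log-likelihood.
    """

    model: "GenotypePOModel"
    params: np.ndarray
    llf: float
    converged: bool
    iterations: int
    cov_params: np.ndarray | None = None
    separation_flag: bool = False
    _names: list[str] = field(default_factory=list)

    @property
    def po_params(self) -> POModelParams:
        return POModelParams(self.params[0], self.params[1], self.params[2:])

    @property
    def bse(self) -> np.ndarray:
        if self.cov_params is None:
            return np.full_like(self.params, np.nan)
        return np.sqrt(np.diag(self.cov_params))

    def summary(self) -> str:
        lines = [
            "Proportional-odds genotype-on-phenotypes model",
            f"  n = {self.model.nobs}, phenotypes = {self.model.q}",
            f"  log-likelihood = {self.llf:.6f}"
            f"  (null: {self.model.fit_null().loglik:.6f})",
            f"  converged = {self.converged} in {self.iterations} iterations"
            + ("  [possible separation]" if self.separation_flag else ""),
            f"  {'param':<14}{'estimate':>12}{'std err':>12}",
        ]
        for name, est, se in zip(self._names, self.params, self.bse):
            lines.append(f"  {name:<14}{est:>12.5f}{se:>12.5f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# input coercion
# ---------------------------------------------------------------------------

def _coerce_genotype(genotype) -> np.ndarray:
    """Return float array with NaN for missing; validate codes in {0,1,2}."""
    g = np.asarray(genotype, dtype=float)
    if g.ndim != 1:
        raise ValueError(f"genotype must be 1-D, got shape {g.shape}")
    if g.size == 0:
        raise ValueError("empty genotype vector")
    obs = g[~np.isnan(g)]
    if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
        bad = np.unique(obs[~np.isin(obs, (0.0, 1.0, 2.0))])
        raise ValueError(
            f"genotypes must be coded 0/1/2 (allele counts); got {bad[:5]}. "
            "Fractional dosages are not supported by this model."
        )
    return g


def _coerce_phenotypes(phenotypes, n: int) -> np.ndarray:
    y = np.asarray(phenotypes, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.ndim != 2:
        raise ValueError(f"phenotypes must be 1-D or 2-D, got shape {y.shape}")
    if y.shape[0] != n:
        raise ValueError(
            f"phenotype rows ({y.shape[0]}) do not match genotype length ({n})"
        )
    return y


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class GenotypePOModel:
    """Cumulative-logit model of a 0/1/2 genotype on a phenotype matrix.

    Parameters
    ----------
    genotype : array-like, shape (n,)
        Allele counts in {0, 1, 2}; NaN marks missing calls.
    phenotypes : array-like, shape (n,) or (n, q)
        Numeric phenotype values; NaN marks missing. Binary traits enter as
        0/1 codes. Rows with any missing value (genotype or phenotype) are
        dropped (complete-case analysis); the count is in ``n_dropped``.
    phenotype_names : sequence of str, optional
    freq_weights : array-like, optional
        Nonnegative replication weights (statsmodels-style); a row with
        weight w contributes like w identical observations. Used internally
        to fit case-control contingency tables through their sufficient
        statistics.
    """

    def __init__(self, genotype, phenotypes, phenotype_names=None,
                 freq_weights=None):
        g = _coerce_genotype(genotype)
        y = _coerce_phenotypes(phenotypes, g.shape[0])
        if freq_weights is None:
            w = np.ones(g.shape[0])
        else:
            w = np.asarray(freq_weights, dtype=float)
            if w.shape != g.shape or np.any(w < 0):
                raise ValueError("freq_weights must be nonnegative, length n")
        keep = ~np.isnan(g) & ~np.isnan(y).any(axis=1)
        self.n_dropped = int(np.sum(~keep))
        self.endog = g[keep].astype(np.int64)
        self.exog = y[keep]
        self.freq_weights = w[keep]
        self.nobs = int(round(self.freq_weights.sum()))
        self.q = self.exog.shape[1]
        if phenotype_names is None:
            phenotype_names = [f"y{k + 1}" for k in range(self.q)]
        self.phenotype_names = list(phenotype_names)
        if len(self.phenotype_names) != self.q:
            raise ValueError("phenotype_names length does not match q")
        if self.endog.size == 0:
            raise ValueError("no complete cases remain after filtering")
        self._null_fit: NullGenotypeFit | None = None

    @classmethod
    def from_dataframe(cls, data, genotype_col: str, phenotype_cols=None):
        """Build the model from a DataFrame column selection."""
        import pandas as pd  # local: keeps numpy-only paths light

        if not isinstance(data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")
        if phenotype_cols is None:
            phenotype_cols = [c for c in data.columns if c != genotype_col]
        return cls(
            data[genotype_col].to_numpy(),
            data[list(phenotype_cols)].to_numpy(),
            phenotype_names=list(phenotype_cols),
        )

    # -- null model ---------------------------------------------------------

    def fit_null(self) -> NullGenotypeFit:
        """Null MLE: sample genotype proportions and the score weights."""
        if self._null_fit is not None:
            return self._null_fit
        wsum = np.zeros(3)
        np.add.at(wsum, self.endog, self.freq_weights)
        ntot = wsum.sum()
        if np.count_nonzero(wsum) < 2:
            raise DegenerateMarkerError(
                "degenerate marker: fewer than two genotype categories observed"
            )
        p = wsum / ntot
        g1, g2 = p[0], p[0] + p[1]
        c = (1.0 - g1, 1.0 - g1 - g2, -g2)
        wbar = float(np.dot(p, np.square(c)))
        self._null_fit = NullGenotypeFit(
            counts=tuple(int(round(x)) for x in wsum),
            proportions=tuple(float(x) for x in p),
            gamma1=float(g1),
            gamma2=float(g2),
            weights=tuple(float(x) for x in c),
            wbar=wbar,
            n=int(round(ntot)),
        )
        return self._null_fit

    # -- score test ---------------------------------------------------------

    def score_vector(self, null_fit: NullGenotypeFit | None = None) -> np.ndarray:
        """U = sum_i c(G_i) (y_i - ybar): the score of the likelihood at beta=0.

        Because the weights have weighted mean zero, U is invariant to
        shifting y; centring is kept for numerical hygiene only.
        """
        nf = null_fit or self.fit_null()
        c = np.asarray(nf.weights)[self.endog] * self.freq_weights
        ybar = np.average(self.exog, axis=0, weights=self.freq_weights)
        return c @ (self.exog - ybar)

    def score_variance(self, null_fit: NullGenotypeFit | None = None,
                       pseudo_inverse: bool = False) -> np.ndarray:
        """V = wbar * sum_i (y_i - ybar)(y_i - ybar)' (sum form, 1/n in wbar)."""
        nf = null_fit or self.fit_null()
        ybar = np.average(self.exog, axis=0, weights=self.freq_weights)
        yc = self.exog - ybar
        V = nf.wbar * (yc.T * self.freq_weights) @ yc
        if not pseudo_inverse:
            # fail fast on collinearity so scan results are not silently wrong
            rank = np.linalg.matrix_rank(V) if V.size else 0
            if rank < self.q:
                raise CollinearPhenotypesError(
                    f"phenotype covariance is singular (rank {rank} < q={self.q}); "
                    "drop redundant columns or enable pseudo_inverse"
                )
        return V

    def score_test(self, pseudo_inverse: bool = False) -> ScoreTestResult:
        """Closed-form score test of H0: beta = 0; T ~ chi2(q) under H0."""
        try:
            nf = self.fit_null()
        except DegenerateMarkerError as exc:
            return ScoreTestResult(
                U=None, V=None, statistic=None, df=None, p_value=None,
                n_used=self.nobs, status="monomorphic", reason=str(exc),
            )
        U = self.score_vector(nf)
        V = self.score_variance(nf, pseudo_inverse=pseudo_inverse)
        if pseudo_inverse:
            Vinv = np.linalg.pinv(V)
            df = int(np.linalg.matrix_rank(V))
        else:
            Vinv = np.linalg.inv(V)
            df = self.q
        T = float(U @ Vinv @ U)
        return ScoreTestResult(
            U=U, V=V, statistic=T, df=df,
            p_value=float(chi2.sf(T, df)), n_used=self.nobs,
        )

    # -- likelihood, gradient, Hessian --------------------------------------

    def loglike(self, params) -> float:
        """Log-likelihood at packed params (alpha1, alpha2, beta).

        Returns -inf (never raises) when some category probability is
        non-positive, so line searches can treat it as an ordinary value.
        """
        params = np.asarray(params, float)
        pi = self._category_probs(params)
        p_obs = pi[np.arange(self.endog.size), self.endog]
        if np.any(p_obs <= 0.0):
            return -np.inf
        return float(self.freq_weights @ np.log(p_obs))

    def _category_probs(self, params: np.ndarray) -> np.ndarray:
        a1, a2 = params[0], params[1]
        eta = self.exog @ params[2:]
        F1 = expit(a1 + eta)
        F2 = expit(a2 + eta)
        return np.column_stack([F1, F2 - F1, 1.0 - F2])

    def score(self, params) -> np.ndarray:
        """Analytic gradient of ``loglike`` in (alpha1, alpha2, beta)."""
        return self._score_and_hessian(np.asarray(params, float))[0]

    def hessian(self, params) -> np.ndarray:
        """Analytic Hessian of ``loglike`` in (alpha1, alpha2, beta)."""
        return self._score_and_hessian(np.asarray(params, float))[1]

    def _score_and_hessian(self, params) -> tuple[np.ndarray, np.ndarray]:
        """Gradient and Hessian from one pass over the data."""
        u1, u2, h11, h22, h12 = self._per_obs_derivs(params)
        w = self.freq_weights
        y = self.exog
        grad = np.concatenate([
            [w @ u1, w @ u2],
            ((u1 + u2) * w) @ y,
        ])
        H = np.empty((2 + self.q, 2 + self.q))
        H[0, 0] = w @ h11
        H[1, 1] = w @ h22
        H[0, 1] = H[1, 0] = w @ h12
        H[0, 2:] = H[2:, 0] = ((h11 + h12) * w) @ y
        H[1, 2:] = H[2:, 1] = ((h22 + h12) * w) @ y
        H[2:, 2:] = (y.T * ((h11 + 2 * h12 + h22) * w)) @ y
        return grad, H

    def _per_obs_derivs(self, params):
        """Per-observation d/d(theta1, theta2) of log pi_{G_i}.

        theta1 = alpha1 + beta'y, theta2 = alpha2 + beta'y are the two
        cumulative logits; with F_j = expit(theta_j), f_j = F_j(1-F_j) and
        category probability pi, the per-observation derivatives are the
        standard cumulative-link expressions for log(F_upper - F_lower).
        """
        a1, a2 = params[0], params[1]
        eta = self.exog @ params[2:]
        F1 = expit(a1 + eta)
        F2 = expit(a2 + eta)
        f1 = F1 * (1.0 - F1)
        f2 = F2 * (1.0 - F2)
        g = self.endog
        n = g.size
        u1 = np.zeros(n)
        u2 = np.zeros(n)
        h11 = np.zeros(n)
        h22 = np.zeros(n)
        h12 = np.zeros(n)

        m0 = g == 0
        pi0 = F1[m0]
        u1[m0] = 1.0 - F1[m0]                       # f1/pi with pi = F1
        h11[m0] = (f1[m0] * (1 - 2 * F1[m0])) / pi0 - (f1[m0] / pi0) ** 2

        m1 = g == 1
        pi1 = F2[m1] - F1[m1]
        r1 = f1[m1] / pi1
        r2 = f2[m1] / pi1
        u1[m1] = -r1
        u2[m1] = r2
        h11[m1] = -(f1[m1] * (1 - 2 * F1[m1])) / pi1 - r1 ** 2
        h22[m1] = (f2[m1] * (1 - 2 * F2[m1])) / pi1 - r2 ** 2
        h12[m1] = r1 * r2

        m2 = g == 2
        pi2 = 1.0 - F2[m2]
        u2[m2] = -F2[m2]                            # -f2/pi with pi = 1-F2
        h22[m2] = -(f2[m2] * (1 - 2 * F2[m2])) / pi2 - (f2[m2] / pi2) ** 2
        return u1, u2, h11, h22, h12

    # -- MLE -----------------------------------------------------------------

    def fit(self, maxiter: int = 50, gtol: float = 1e-8,
            start_params=None) -> GenotypePOResults:
        """Newton-Raphson MLE with step-halving.

        Starts from the closed-form null fit (alpha = logit of cumulative
        proportions, beta = 0) unless ``start_params`` is given. A step that
        fails to improve the log-likelihood (or leaves the valid region,
        where ``loglike`` is -inf) is halved, up to 30 times. Convergence is
        declared when the gradient max-norm drops below ``gtol``.

        When a genotype category is unobserved the corresponding intercept
        is not identified (its MLE is infinite, or the two intercepts
        coincide when the heterozygote class is empty); the model then
        reduces to binary logistic regression and Newton runs on the free
        parameters only, with the unidentified intercept pinned at its
        boundary.
        """
        nf = self.fit_null()
        if start_params is None:
            theta = np.concatenate([nf.alpha, np.zeros(self.q)])
        else:
            theta = np.asarray(start_params, float).copy()
        # linear reparameterisation theta = M @ free + const handles empty
        # genotype categories (at most one, given fit_null's guard)
        dim = 2 + self.q
        counts = nf.counts
        if counts[1] == 0 and counts[0] > 0 and counts[2] > 0:
            # no heterozygotes: intercepts coincide at the optimum; tie them
            M = np.zeros((dim, dim - 1))
            M[0, 0] = M[1, 0] = 1.0
            M[2:, 1:] = np.eye(self.q)
            const = np.zeros(dim)
            const[1] = 1e-6
            theta[1] = theta[0] + 1e-6
        elif counts[0] == 0 or counts[2] == 0:
            pin = 0 if counts[0] == 0 else 1
            theta[pin] = -36.0 if pin == 0 else 36.0
            M = np.delete(np.eye(dim), pin, axis=1)
            const = np.zeros(dim)
            const[pin] = theta[pin]
        else:
            M = np.eye(dim)
            const = np.zeros(dim)
        free = np.linalg.lstsq(M, theta - const, rcond=None)[0]
        theta = M @ free + const
        ll = self.loglike(theta)
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            grad, H = self._score_and_hessian(theta)
            gfree = M.T @ grad
            if np.max(np.abs(gfree)) < gtol:
                converged = True
                it -= 1
                break
            Hfree = M.T @ H @ M
            try:
                step = np.linalg.solve(Hfree, -gfree)
            except np.linalg.LinAlgError:
                step = gfree  # fall back to steepest ascent
            scale = 1.0
            # accept any step not measurably worse: near the optimum the
            # log-likelihood is flat to machine precision while the gradient
            # still contracts under full Newton steps
            floor = ll - 1e-10 * (abs(ll) + 1.0)
            for _ in range(30):
                ll_new = self.loglike(M @ (free + scale * step) + const)
                if ll_new > floor:
                    break
                scale *= 0.5
            else:
                break  # no acceptable step: stop at current point
            free = free + scale * step
            theta = M @ free + const
            ll = ll_new
        else:
            it = maxiter
        if not converged and np.max(np.abs(M.T @ self.score(theta))) < gtol:
            converged = True
        separation = bool(np.linalg.norm(theta[2:]) > 50.0)
        cov = None
        if converged:
            try:
                Hfree = M.T @ self.hessian(theta) @ M
                cov = M @ np.linalg.inv(-Hfree) @ M.T
            except np.linalg.LinAlgError:
                cov = None
        names = ["alpha1", "alpha2"] + [f"beta[{nm}]" for nm in self.phenotype_names]
        return GenotypePOResults(
            model=self, params=theta, llf=ll, converged=converged,
            iterations=it, cov_params=cov, separation_flag=separation,
            _names=names,
        )

    def lrt(self, **fit_kwargs) -> LRTResult:
        """Likelihood-ratio test of beta = 0 (chi2 with q df)."""
        nf = self.fit_null()
        res = self.fit(**fit_kwargs)
        stat = 2.0 * (res.llf - nf.loglik)
        stat = max(stat, 0.0) if stat > -1e-8 else stat
        return LRTResult(
            loglik_null=nf.loglik, loglik_alt=res.llf, statistic=stat,
            df=self.q, p_value=float(chi2.sf(stat, self.q)),
            converged=res.converged, iterations=res.iterations,
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_null(genotype) -> NullGenotypeFit:
    """Null genotype fit (proportions, score weights, wbar) from a 0/1/2 vector."""
    g = _coerce_genotype(genotype)
    return GenotypePOModel(g, np.zeros(g.shape[0])).fit_null()


def score_vector(genotype, phenotypes, null_fit: NullGenotypeFit | None = None):
    return GenotypePOModel(genotype, phenotypes).score_vector(null_fit)


def score_variance(genotype, phenotypes, null_fit: NullGenotypeFit | None = None,
                   pseudo_inverse: bool = False):
    return GenotypePOModel(genotype, phenotypes).score_variance(
        null_fit, pseudo_inverse=pseudo_inverse)


def score_test(genotype, phenotypes, pseudo_inverse: bool = False) -> ScoreTestResult:
    return GenotypePOModel(genotype, phenotypes).score_test(
        pseudo_inverse=pseudo_inverse)


def po_loglik(genotype, phenotypes, params: POModelParams) -> float:
    return GenotypePOModel(genotype, phenotypes).loglike(params.as_vector())


def fit_po_mle(genotype, phenotypes, **fit_kwargs):
    """MLE of the cumulative-logit model; returns (params, llf, converged, iters)."""
    res = GenotypePOModel(genotype, phenotypes).fit(**fit_kwargs)
    return res.po_params, res.llf, res.converged, res.iterations


def lrt_test(genotype, phenotypes, **fit_kwargs) -> LRTResult:
    return GenotypePOModel(genotype, phenotypes).lrt(**fit_kwargs)


# ---------------------------------------------------------------------------
# contingency-table fast path (binary phenotype)
# ---------------------------------------------------------------------------

_TABLE_G = np.array([0, 1, 2, 0, 1, 2], dtype=float)
_TABLE_Y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])


def _table_model(table) -> GenotypePOModel:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 3) or np.any(t < 0):
        raise ValueError("table must be a nonnegative 2x3 array "
                         "(rows: control, case; cols: genotype 0/1/2)")
    return GenotypePOModel(_TABLE_G, _TABLE_Y, freq_weights=t.ravel())


def score_test_from_table(table) -> ScoreTestResult:
    """Score test for a binary phenotype given its 2x3 genotype table.

    The binary-phenotype likelihood depends on the data only through the six
    cell counts, so this is exactly ``score_test`` on the expanded vectors.
    """
    return _table_model(table).score_test()


def lrt_test_from_table(table, **fit_kwargs) -> LRTResult:
    """LRT for a binary phenotype given its 2x3 genotype table."""
    return _table_model(table).lrt(**fit_kwargs)
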