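"""REML linear mixed models with Gaussian spatial residual correlation.

The model for subject (fetus) i observed at gestational ages t_i is

    y_i = X_i beta + Z_i u_i + e_i,        Z_i = [1, t_i]

with per-subject random intercept and slope u_i ~ N(0, G),
G = [[tau00, tau01], [tau01, tau11]], and a residual Gaussian process
e_i ~ N(0, sigma2 * R_i), R_i[j,k] = exp(-((t_j - t_k)/rho)**2).

The spatial kernel lets temporally close, non-equidistant ultrasound
scans be more correlated than distant ones without forcing an AR grid.
Variance components are estimated by restricted maximum likelihood
(REML); fixed effects are profiled out by generalized least squares and
sigma2 is profiled analytically, leaving a 4-parameter optimization over
(log tau00/sigma2, log tau11/sigma2, atanh correlation, log rho) run
from three deterministic starting points with Nelder-Mead and polished
at the best optimum.

This module is deliberately self-contained: general mixed-model
packages do not expose this residual correlation family, and the
acceptance tests instead use an independent implementation as a frozen
cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VarianceComponents",
    "gaussian_correlation",
    "build_marginal_cov",
    "SpatialGrowthLMM",
    "SpatialLMMResults",
    "reml_fit",
]

log = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components of the random-intercept/slope spatial model.

    tau00, tau11 : variances of the per-fetus intercept and slope
    tau01        : their covariance (|tau01| <= sqrt(tau00*tau11))
    sigma2       : residual variance
    rho          : Gaussian correlation range in days
    """

    tau00: float
    tau01: float
    tau11: float
    sigma2: float
    rho: float

    def __post_init__(self) -> None:
        if self.tau00 < 0 or self.tau11 < 0:
            raise ValueError("random-effect variances must be non-negative")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        bound = np.sqrt(self.tau00 * self.tau11)
        if abs(self.tau01) > bound + 1e-12 * max(bound, 1.0):
            raise ValueError("tau01 violates |tau01| <= sqrt(tau00*tau11)")

    @property
    def random_effects_cov(self) -> np.ndarray:
        return np.array([[self.tau00, self.tau01], [self.tau01, self.tau11]])

    def as_dict(self) -> dict[str, float]:
        return {
            "tau00": self.tau00,
            "tau01": self.tau01,
            "tau11": self.tau11,
            "sigma2": self.sigma2,
            "rho": self.rho,
        }


def gaussian_correlation(distance_days, rho: float):
    """Gaussian spatial correlation exp(-(d/rho)**2).

    Equals 1 at zero distance and decays smoothly; ``rho`` (days) is the
    distance at which correlation has fallen to 1/e.
    """
    if rho <= 0:
        raise ValueError(f"rho must be positive, got {rho}")
    d = np.asarray(distance_days, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    out = np.exp(-((d / rho) ** 2))
    return float(out) if np.isscalar(distance_days) else out


def build_marginal_cov(times, vc: VarianceComponents) -> np.ndarray:
    """Marginal covariance V = Z G Z' + sigma2 * R at the given times.

    Z is the random-effects design [1, t]; R is the Gaussian spatial
    correlation matrix over pairwise time distances. Raises if the
    result is not positive definite (reporting the smallest eigenvalue),
    which happens e.g. with duplicated times and no nugget.
    """
    t = np.asarray(times, dtype=float)
    Z = np.column_stack([np.ones_like(t), t])
    D = np.abs(t[:, None] - t[None, :])
    V = Z @ vc.random_effects_cov @ Z.T + vc.sigma2 * np.exp(-((D / vc.rho) ** 2))
    V = (V + V.T) / 2.0
    eigmin = float(np.linalg.eigvalsh(V)[0])
    if eigmin <= 1e-10 * np.trace(V):
        raise np.linalg.LinAlgError(
            f"marginal covariance not positive definite (smallest eigenvalue {eigmin:.3e})"
        )
    return V


@dataclass
class _GroupBucket:
    """Groups with a common number of observations, stacked for vector math."""

    t: np.ndarray  # (g, k)
    dist: np.ndarray  # (g, k, k)
    cross: np.ndarray  # (g, k, k)  t_i + t_j
    prod: np.ndarray  # (g, k, k)  t_i * t_j
    X: np.ndarray  # (g, k, p)
    y: np.ndarray  # (g, k)


class SpatialGrowthLMM:
    """Linear mixed model with random intercept/slope per group and a
    Gaussian spatial residual process over observation times.

    Parameters
    ----------
    endog
        Outcome vector (here: log weight or log biometry).
    exog
        Fixed-effects design matrix, full column rank.
    groups
        Group (fetus) label per observation.
    times
        Observation time per row, in days; drives both the random slope
        and the spatial correlation.
    exog_names
        Optional column names for reporting.
    """

    def __init__(self, endog, exog, groups, times, exog_names=None):
        y = np.asarray(endog, dtype=float).reshape(-1)
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        t = np.asarray(times, dtype=float).reshape(-1)
        g = np.asarray(groups)
        n = y.shape[0]
        if not (X.shape[0] == n == t.shape[0] == g.shape[0]):
            raise ValueError("endog, exog, groups and times must have equal length")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
            raise ValueError("endog/exog contain non-finite values")
        if exog_names is None and isinstance(exog, pd.DataFrame):
            exog_names = list(exog.columns)
        if exog_names is None:
            exog_names = [f"x{j}" for j in range(X.shape[1])]
        if len(exog_names) != X.shape[1]:
            raise ValueError("exog_names length mismatch")

        # rank check with named collinear columns
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            _, R = np.linalg.qr(X)
            diag = np.abs(np.diag(R))
            bad = [exog_names[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
            raise ValueError(f"fixed-effects design is rank deficient (columns: {bad})")

        self.endog = y
        self.exog = X
        self.times = t
        self.groups = g
        self.exog_names = list(exog_names)
        self.n_obs = n
        self.k_fe = X.shape[1]

        # column scaling for numerical conditioning (GA^2 ~ 1e4 vs intercept 1)
        self._col_scale = np.maximum(np.abs(X).max(axis=0), 1e-300)

        # bucket groups by size for stacked linear algebra
        order = pd.unique(g)
        self.group_labels = order
        self.n_groups = len(order)
        idx_by_group = {lab: np.where(g == lab)[0] for lab in order}
        sizes: dict[int, list[np.ndarray]] = {}
        for lab in order:
            idx = idx_by_group[lab]
            sizes.setdefault(len(idx), []).append(idx)
        Xs = X / self._col_scale
        self._buckets: list[_GroupBucket] = []
        for k, idx_list in sorted(sizes.items()):
            ti = np.stack([t[i] for i in idx_list])
            self._buckets.append(
                _GroupBucket(
                    t=ti,
                    dist=np.abs(ti[:, :, None] - ti[:, None, :]),
                    cross=ti[:, :, None] + ti[:, None, :],
                    prod=ti[:, :, None] * ti[:, None, :],
                    X=np.stack([Xs[i] for i in idx_list]),
                    y=np.stack([y[i] for i in idx_list]),
                )
            )
        self._mean_t2 = float(np.mean(t**2))
        gaps = np.concatenate(
            [np.diff(np.sort(b.t, axis=1), axis=1).ravel() for b in self._buckets]
        )
        gaps = gaps[gaps > 0]
        self._median_gap = float(np.median(gaps)) if gaps.size else 30.0

    # ------------------------------------------------------------------
    # likelihood
    # ------------------------------------------------------------------
    def _profile_pieces(self, g00, g01, g11, rho):
        """Accumulate GLS pieces for C_i = Z G* Z' + R_i (unit sigma2).

        Returns (logdetC, XtCiX, XtCiy, ytCiy) or None when any block
        fails the Cholesky positive-definiteness check.
        """
        p = self.k_fe
        logdet = 0.0
        XtCiX = np.zeros((p, p))
        XtCiy = np.zeros(p)
        ytCiy = 0.0
        rho = max(rho, 1e-8)
        for b in self._buckets:
            with np.errstate(over="ignore"):  # (d/rho)^2 -> inf gives corr 0
                corr = np.exp(-np.minimum((b.dist / rho) ** 2, 745.0))
            C = g00 + g01 * b.cross + g11 * b.prod + corr
            try:
                L = np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                return None
            logdet += 2.0 * float(np.log(np.diagonal(L, axis1=1, axis2=2)).sum())
            Ci_X = np.linalg.solve(C, b.X)
            Ci_y = np.linalg.solve(C, b.y[:, :, None])[:, :, 0]
            XtCiX += np.einsum("gki,gkj->ij", b.X, Ci_X)
            XtCiy += np.einsum("gki,gk->i", b.X, Ci_y)
            ytCiy += float(np.einsum("gk,gk->", b.y, Ci_y))
        return logdet, XtCiX, XtCiy, ytCiy

    def _reml_at(self, g00, g01, g11, rho):
        """Profiled REML log-likelihood and GLS solution at variance ratios."""
        pieces = self._profile_pieces(g00, g01, g11, rho)
        if pieces is None:
            return None
        logdetC, XtCiX, XtCiy, ytCiy = pieces
        n, p = self.n_obs, self.k_fe
        try:
            cho = np.linalg.cholesky(XtCiX)
        except np.linalg.LinAlgError:
            return None
        beta_s = np.linalg.solve(XtCiX, XtCiy)
        quad = ytCiy - float(XtCiy @ beta_s)
        if quad <= 0:
            return None
        s2 = quad / (n - p)
        logdet_XtX = 2.0 * float(np.log(np.diag(cho)).sum())
        # log|X'C^-1 X| on the *unscaled* design differs by a constant
        # (2*sum log col_scale) which cancels in optimization but matters
        # for reporting a loglik comparable across parameterizations; keep
        # the scaled-design convention consistently.
        llf = -0.5 * (
            (n - p) * (_LOG2PI + np.log(s2) + 1.0)
            + logdetC
            + logdet_XtX
            + 2.0 * float(np.log(self._col_scale).sum())
        )
        return llf, s2, beta_s, XtCiX

    @staticmethod
    def _unpack(theta, no_re: bool, fixed_rho):
        if no_re:
            g00 = g01 = g11 = 0.0
            rho = fixed_rho if fixed_rho is not None else float(np.exp(theta[0]))
        else:
            g00 = float(np.exp(theta[0]))
            g11 = float(np.exp(theta[1]))
            r = float(np.tanh(theta[2]))
            g01 = r * np.sqrt(g00 * g11)
            rho = fixed_rho if fixed_rho is not None else float(np.exp(theta[3]))
        return g00, g01, g11, max(rho, 1e-8)

    def loglike_reml(self, vc: VarianceComponents) -> float:
        """REML log-likelihood at explicit variance components."""
        s2 = vc.sigma2
        pieces = self._profile_pieces(vc.tau00 / s2, vc.tau01 / s2, vc.tau11 / s2, vc.rho)
        if pieces is None:
            return -np.inf
        logdetC, XtCiX, XtCiy, ytCiy = pieces
        n, p = self.n_obs, self.k_fe
        beta_s = np.linalg.solve(XtCiX, XtCiy)
        quad = ytCiy - float(XtCiy @ beta_s)
        sign, logdet_XtX = np.linalg.slogdet(XtCiX)
        if sign <= 0:
            return -np.inf
        return -0.5 * (
            (n - p) * (_LOG2PI + np.log(s2))
            + logdetC
            + logdet_XtX
            + quad / s2
            + 2.0 * float(np.log(self._col_scale).sum())
        )

    # ------------------------------------------------------------------
    # fitting
    # ------------------------------------------------------------------
    def _starting_points(self, no_re: bool, fixed_rho):
        rho0 = max(self._median_gap / 2.0, 1e-3)
        if no_re:
            if fixed_rho is not None:
                return [np.array([])]
            return [np.array([np.log(r)]) for r in (rho0, rho0 / 4, rho0 * 2)]
        mt2 = self._mean_t2
        starts = []
        for g00, g11f, rho in (
            (1.0, 1.0, rho0),
            (0.1, 0.01, rho0 / 2),
            (5.0, 5.0, rho0 * 1.5),
        ):
            th = [np.log(g00), np.log(g11f / mt2), 0.0]
            if fixed_rho is None:
                th.append(np.log(rho))
            starts.append(np.array(th))
        return starts

    def fit(
        self,
        *,
        include_random_effects: bool = True,
        fix_rho: float | None = None,
        xtol: float = 1e-6,
        maxiter: int = 4000,
        restarts: int = 3,
        polish: bool = True,
    ) -> "SpatialLMMResults":
        """Maximize the REML likelihood and return a results object.

        ``include_random_effects=False`` removes the random intercept and
        slope (tau terms pinned at zero); combined with a tiny ``fix_rho``
        this reduces the model to i.i.d. residuals, where the GLS solution
        coincides with OLS — the degenerate limit used for closed-form
        validation.
        """
        no_re = not include_random_effects
        if fix_rho is None and no_re is False:
            pass

        def objective(theta):
            g00, g01, g11, rho = self._unpack(theta, no_re, fix_rho)
            out = self._reml_at(g00, g01, g11, rho)
            return np.inf if out is None else -out[0]

        best = None
        best_theta = None
        n_restarts = 0
        converged = False
        for theta0 in self._starting_points(no_re, fix_rho)[: max(restarts, 1)]:
            if theta0.size == 0:  # nothing to optimize
                best_theta = theta0
                converged = True
                break
            res = optimize.minimize(
                objective,
                theta0,
                method="Nelder-Mead",
                options={
                    "xatol": xtol,
                    "fatol": xtol,
                    "maxiter": maxiter,
                    "maxfev": maxiter,
                },
            )
            n_restarts += 1
            if np.isfinite(res.fun) and (best is None or res.fun < best):
                best = res.fun
                best_theta = res.x
                converged = bool(res.success)
        if best_theta is None:
            raise RuntimeError("REML optimization failed from every starting point")
        if best_theta.size and polish:
            # polish from the best optimum
            res = optimize.minimize(
                objective,
                best_theta,
                method="Nelder-Mead",
                options={
                    "xatol": xtol * 1e-2,
                    "fatol": xtol * 1e-2,
                    "maxiter": maxiter,
                    "maxfev": maxiter,
                },
            )
            if np.isfinite(res.fun) and res.fun <= best:
                best_theta = res.x
                converged = bool(res.success) or converged

        g00, g01, g11, rho = self._unpack(best_theta, no_re, fix_rho)
        out = self._reml_at(g00, g01, g11, rho)
        if out is None:
            raise RuntimeError("REML likelihood undefined at the returned optimum")
        llf, s2, beta_s, XtCiX = out
        beta = beta_s / self._col_scale
        cov_s = s2 * np.linalg.inv(XtCiX)
        cov = cov_s / np.outer(self._col_scale, self._col_scale)
        vc = VarianceComponents(
            tau00=g00 * s2, tau01=g01 * s2, tau11=g11 * s2, sigma2=s2, rho=rho
        )
        if not converged:
            log.warning("REML optimizer did not report convergence (llf=%.4f)", llf)
        return SpatialLMMResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_params_values=cov,
            vc=vc,
            llf=float(llf),
            converged=converged,
            n_restarts=n_restarts,
        )


@dataclass
class SpatialLMMResults:
    """REML fit results: fixed effects, their covariance, and variance
    components, with Wald-z inference (no small-sample df correction)."""

    model: SpatialGrowthLMM
    params: pd.Series
    cov_params_values: np.ndarray
    vc: VarianceComponents
    llf: float
    converged: bool
    n_restarts: int = 0
    bse: pd.Series = field(init=False)
    zvalues: pd.Series = field(init=False)
    pvalues: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        se = np.sqrt(np.diag(self.cov_params_values))
        self.bse = pd.Series(se, index=self.params.index)
        z = self.params / self.bse
        self.zvalues = z
        self.pvalues = pd.Series(
            2.0 * stats.norm.sf(np.abs(z.to_numpy())), index=self.params.index
        )

    @property
    def n_obs(self) -> int:
        return self.model.n_obs

    @property
    def n_groups(self) -> int:
        return self.model.n_groups

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cov_params_values, index=self.params.index, columns=self.params.index
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {
                "lower": self.params - zcrit * self.bse,
                "upper": self.params + zcrit * self.bse,
            }
        )

    def predict(self, exog) -> np.ndarray:
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return X @ self.params.to_numpy()

    def to_dict(self) -> dict:
        """JSON-serializable summary of the fit."""
        ci = self.conf_int()
        return {
            "coefficients": self.params.to_dict(),
            "standard_errors": self.bse.to_dict(),
            "p_values": self.pvalues.to_dict(),
            "conf_int": {k: [ci.loc[k, "lower"], ci.loc[k, "upper"]] for k in ci.index},
            "variance_components": self.vc.as_dict(),
            "reml_loglik": self.llf,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
        }

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Spatial growth LMM (REML)",
            "=" * 78,
            f"No. observations: {self.n_obs:>8}    No. groups: {self.n_groups:>6}    "
            f"Converged: {self.converged}",
            f"REML log-likelihood: {self.llf:.4f}",
            "-" * 78,
            f"{'term':<22}{'coef':>12}{'std err':>12}{'z':>9}{'P>|z|':>10}"
            f"{'[0.025':>12}{'0.975]':>12}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<22}{self.params[name]:>12.4g}{self.bse[name]:>12.4g}"
                f"{self.zvalues[name]:>9.3f}{self.pvalues[name]:>10.3g}"
                f"{ci.loc[name, 'lower']:>12.4g}{ci.loc[name, 'upper']:>12.4g}"
            )
        v = self.vc
        lines += [
            "-" * 78,
            f"tau00={v.tau00:.4g}  tau01={v.tau01:.4g}  tau11={v.tau11:.4g}  "
            f"sigma2={v.sigma2:.4g}  rho={v.rho:.4g} days",
            "=" * 78,
        ]
        return "\n".join(lines)


def reml_fit(
    exog,
    endog,
    groups,
    times,
    exog_names=None,
    **fit_kwargs,
) -> SpatialLMMResults:
    """Convenience wrapper: build a :class:`SpatialGrowthLMM` and fit it."""
    return SpatialGrowthLMM(
        endog, exog, groups, times, exog_names=exog_names
    ).fit(**fit_kwargs)
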