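"""Joint bivariate-normal meta-regression of log PM2.5 concentrations.

The model is a two-equation seemingly-unrelated regression on the log
scale: for record i the pair y_i = (ln traffic PM2.5, ln overall PM2.5) is
multivariate normal with means mu_ki = eta_k + gamma_k . X_ki and a shared
2x2 residual covariance Sigma that carries the cross-outcome dependence.
Priors are diffuse normals (mean 0, variance 100 by default) on every
intercept and coefficient, and a Wishart on the precision matrix
Sigma^-1 ~ Wishart(R, K) in the WinBUGS parameterisation, i.e. prior
expectation K R^-1, with K = 2 and R = diag(0.01) by default.

Both full conditionals are closed-form, so the posterior is explored with
a conjugate Gibbs sampler:

* coefficients | Sigma — one joint normal draw of all intercepts and
  slopes from the stacked generalized-least-squares form, so the two
  equations borrow strength through Sigma at every iteration;
* Sigma^-1 | residuals — Wishart(R + S, K + N) with S the residual
  cross-product matrix.

The default protocol runs two overdispersed chains of 15,000 iterations,
discards the first 5,000 of each, and keeps the remaining 20,000 draws
unthinned.  Convergence is checked with the Gelman-Rubin potential scale
reduction factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .records import DesignMatrices, FitError

__all__ = [
    "Priors",
    "McmcConfig",
    "PosteriorDraws",
    "JointMetaRegression",
    "JointMetaRegressionResults",
    "fit_joint_model",
    "gibbs_sampler",
    "gelman_rubin",
    "posterior_summary",
    "posterior_correlation",
]


@dataclass
class Priors:
    """Prior hyperparameters for the joint model."""

    coef_mean: float = 0.0
    coef_var: float = 100.0
    wishart_df: float = 2.0
    wishart_scale: np.ndarray = field(default_factory=lambda: np.diag([0.01, 0.01]))

    def validate(self, dim: int = 2) -> None:
        if self.coef_var <= 0:
            raise ValueError("coef_var must be > 0")
        R = np.asarray(self.wishart_scale, dtype=float)
        if R.shape != (dim, dim) or not np.allclose(R, R.T):
            raise ValueError(f"wishart_scale must be symmetric {dim}x{dim}")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("wishart_scale must be positive definite")
        if self.wishart_df < dim:
            raise ValueError("wishart_df must be at least the outcome dimension")


@dataclass
class McmcConfig:
    """Sampler protocol: chains, iterations, burn-in, seeding, starts."""

    n_chains: int = 2
    n_iter: int = 15000
    n_burn: int = 5000
    seed: int = 0
    init_dispersion: float = 1.0

    def validate(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not (0 <= self.n_burn < self.n_iter):
            raise ValueError("need 0 <= n_burn < n_iter")


class PosteriorDraws:
    """Post-burn-in MCMC draws of the coefficients and covariance matrix.

    ``beta`` stacks the traffic-equation block (intercept first) and then
    the overall-equation block; ``sigma`` holds one 2x2 covariance draw per
    retained iteration; ``chain_id`` maps each draw to its chain.
    """

    def __init__(self, beta: np.ndarray, sigma: np.ndarray, chain_id: np.ndarray,
                 x1_names: list[str], x2_names: list[str], fit_log: dict | None = None):
        self.beta = np.asarray(beta, dtype=float)
        self.sigma = np.asarray(sigma, dtype=float)
        self.chain_id = np.asarray(chain_id, dtype=int)
        self.x1_names = list(x1_names)
        self.x2_names = list(x2_names)
        self.fit_log = dict(fit_log or {})
        p = 1 + len(self.x1_names) + 1 + len(self.x2_names)
        if self.beta.shape[1] != p:
            raise ValueError("beta width inconsistent with regressor names")

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def _p1(self) -> int:
        return 1 + len(self.x1_names)

    @property
    def eta(self) -> np.ndarray:
        """Intercept draws, one column per outcome (traffic, overall)."""
        return self.beta[:, [0, self._p1]]

    @property
    def gamma1(self) -> np.ndarray:
        return self.beta[:, 1:self._p1]

    @property
    def gamma2(self) -> np.ndarray:
        return self.beta[:, self._p1 + 1:]

    @property
    def parameter_names(self) -> list[str]:
        return (["traffic:intercept"] + [f"traffic:{n}" for n in self.x1_names]
                + ["overall:intercept"] + [f"overall:{n}" for n in self.x2_names]
                + ["sigma_11", "sigma_12", "sigma_22"])

    def parameter_matrix(self) -> np.ndarray:
        """All scalar parameters per draw, columns per ``parameter_names``."""
        return np.column_stack([self.beta, self.sigma[:, 0, 0],
                                self.sigma[:, 0, 1], self.sigma[:, 1, 1]])

    def rho(self) -> np.ndarray:
        """Per-draw residual correlation Sigma12 / sqrt(Sigma11 Sigma22)."""
        return self.sigma[:, 0, 1] / np.sqrt(self.sigma[:, 0, 0] * self.sigma[:, 1, 1])

    def to_frame(self) -> pd.DataFrame:
        """Tidy (chain, iter, parameter, value) representation."""
        names = self.parameter_names
        mat = self.parameter_matrix()
        n, p = mat.shape
        iters = np.concatenate([np.arange((self.chain_id == c).sum())
                                for c in np.unique(self.chain_id)])
        return pd.DataFrame({
            "chain": np.repeat(self.chain_id, p),
            "iter": np.repeat(iters, p),
            "parameter": np.tile(names, n),
            "value": mat.ravel(),
        })


def _draw_wishart(rng: np.random.Generator, df: int, scale_inv: np.ndarray) -> np.ndarray:
    """One draw W ~ Wishart(scale_inv^-1 as scale, df) via Gaussian outer products.

    ``scale_inv`` is the INVERSE of the scipy-style scale matrix (here
    R + S); the draw has expectation df * scale_inv^-1.
    """
    d = scale_inv.shape[0]
    C = np.linalg.cholesky(scale_inv)
    # M with M M' = scale_inv^-1
    M = solve_triangular(C, np.eye(d), lower=True).T
    Z = rng.standard_normal((d, int(df)))
    A = M @ Z
    return A @ A.T


def gibbs_sampler(ys: list[np.ndarray], Xs: list[np.ndarray], priors: Priors,
                  n_iter: int, n_burn: int, rng: np.random.Generator,
                  beta_init: np.ndarray | None = None,
                  sigma_init: np.ndarray | None = None,
                  fixed_sigma: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, dict]:
    """Run one chain of the conjugate Gibbs sampler for K stacked equations.

    ``Xs[k]`` must already include any intercept column.  With
    ``fixed_sigma`` the covariance is held at the given value and only the
    coefficient block is updated (each retained coefficient draw is then an
    exact independent draw from its posterior).  Returns post-burn-in
    coefficient draws, covariance draws and a numerical log.
    """
    K = len(ys)
    N = len(ys[0])
    ps = [X.shape[1] for X in Xs]
    P = sum(ps)
    offs = np.concatenate([[0], np.cumsum(ps)])
    Y = np.column_stack(ys)

    XtX = [[Xs[k].T @ Xs[l] for l in range(K)] for k in range(K)]
    Xty = [[Xs[k].T @ ys[l] for l in range(K)] for k in range(K)]
    prior_prec = 1.0 / priors.coef_var
    prior_b = prior_prec * priors.coef_mean

    R = np.asarray(priors.wishart_scale, dtype=float)
    post_df = int(round(priors.wishart_df)) + N

    beta = np.zeros(P) if beta_init is None else np.asarray(beta_init, dtype=float).copy()
    if fixed_sigma is not None:
        sigma = np.asarray(fixed_sigma, dtype=float)
    elif sigma_init is not None:
        sigma = np.asarray(sigma_init, dtype=float).copy()
    else:
        sigma = np.eye(K)

    n_keep = n_iter - n_burn
    beta_out = np.empty((n_keep, P))
    sigma_out = np.empty((n_keep, K, K))
    n_pd_retries = 0

    A = np.empty((P, P))
    b = np.empty(P)
    for it in range(n_iter):
        omega = np.linalg.inv(sigma)
        # --- coefficients | Sigma: joint normal over all K blocks
        for k in range(K):
            b[offs[k]:offs[k + 1]] = prior_b + sum(
                omega[k, l] * Xty[k][l] for l in range(K))
            for l in range(K):
                A[offs[k]:offs[k + 1], offs[l]:offs[l + 1]] = omega[k, l] * XtX[k][l]
        A[np.diag_indices(P)] += prior_prec
        cf = cho_factor(A, lower=True)
        mean = cho_solve(cf, b)
        beta = mean + solve_triangular(cf[0].T, rng.standard_normal(P), lower=False)

        if fixed_sigma is None:
            # --- Sigma^-1 | residuals: Wishart(R + S, K0 + N)
            E = Y - np.column_stack([Xs[k] @ beta[offs[k]:offs[k + 1]]
                                     for k in range(K)])
            S = E.T @ E
            scale_inv = R + S
            try:
                omega_new = _draw_wishart(rng, post_df, scale_inv)
            except np.linalg.LinAlgError:
                n_pd_retries += 1
                scale_inv = scale_inv + 1e-10 * np.eye(K)
                omega_new = _draw_wishart(rng, post_df, scale_inv)
            sigma = np.linalg.inv(omega_new)
            sigma = 0.5 * (sigma + sigma.T)

        if it >= n_burn:
            beta_out[it - n_burn] = beta
            sigma_out[it - n_burn] = sigma
    return beta_out, sigma_out, {"n_pd_retries": n_pd_retries}


def _check_full_rank(X: np.ndarray, names: list[str], label: str) -> None:
    if X.shape[1] == 0:
        return
    _, Rq = np.linalg.qr(X)
    diag = np.abs(np.diag(Rq))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = [names[j] for j in range(len(names)) if diag[j] <= tol]
    if bad:
        raise FitError(f"{label} design matrix is rank deficient; "
                       f"collinear column(s): {bad}")


class JointMetaRegression:
    """Two-outcome meta-regression model for log traffic and overall PM2.5.

    Construct from a :class:`~trafficpm.records.DesignMatrices` (or a
    curated DataFrame via :meth:`from_dataframe`), then call :meth:`fit`.
    """

    def __init__(self, dm: DesignMatrices):
        self.dm = dm
        p_total = 2 + dm.X1.shape[1] + dm.X2.shape[1]
        if dm.nobs < p_total:
            raise FitError(f"need at least {p_total} rows for {p_total} coefficients, "
                           f"got {dm.nobs}")
        if np.ptp(dm.y2) == 0 and dm.X2.shape[1] == 0:
            raise FitError("degenerate second outcome: constant y2 with empty design")
        ones = np.ones((dm.nobs, 1))
        self._X1 = np.hstack([ones, dm.X1])
        self._X2 = np.hstack([ones, dm.X2])
        _check_full_rank(self._X1, ["intercept"] + dm.x1_names, "traffic")
        _check_full_rank(self._X2, ["intercept"] + dm.x2_names, "overall")

    @classmethod
    def from_dataframe(cls, curated: pd.DataFrame,
                       formula_cfg: dict | None = None) -> "JointMetaRegression":
        from .records import build_design

        return cls(build_design(curated, formula_cfg))

    def _ols_start(self) -> tuple[np.ndarray, np.ndarray]:
        """Equation-by-equation least squares: start values for the chains."""
        b1, *_ = np.linalg.lstsq(self._X1, self.dm.y1, rcond=None)
        b2, *_ = np.linalg.lstsq(self._X2, self.dm.y2, rcond=None)
        E = np.column_stack([self.dm.y1 - self._X1 @ b1, self.dm.y2 - self._X2 @ b2])
        dof = max(self.dm.nobs - max(self._X1.shape[1], self._X2.shape[1]), 1)
        return np.concatenate([b1, b2]), (E.T @ E) / dof

    def fit(self, priors: Priors | None = None,
            cfg: McmcConfig | None = None) -> "JointMetaRegressionResults":
        """Draw from the joint posterior with the conjugate Gibbs sampler."""
        priors = priors or Priors()
        cfg = cfg or McmcConfig()
        priors.validate()
        cfg.validate()
        beta0, sigma0 = self._ols_start()
        P = len(beta0)
        ss = np.random.SeedSequence(cfg.seed)
        chain_seeds = ss.spawn(cfg.n_chains)

        betas, sigmas, ids = [], [], []
        n_pd_retries = 0
        for c, cs in enumerate(chain_seeds):
            rng = np.random.default_rng(cs)
            # overdispersed starts around the prior mean
            start = (priors.coef_mean
                     + cfg.init_dispersion * np.sqrt(priors.coef_var)
                     * rng.standard_normal(P))
            b, s, log = gibbs_sampler(
                [self.dm.y1, self.dm.y2], [self._X1, self._X2], priors,
                cfg.n_iter, cfg.n_burn, rng, beta_init=start, sigma_init=sigma0)
            betas.append(b)
            sigmas.append(s)
            ids.append(np.full(b.shape[0], c))
            n_pd_retries += log["n_pd_retries"]

        draws = PosteriorDraws(
            np.vstack(betas), np.vstack(sigmas), np.concatenate(ids),
            self.dm.x1_names, self.dm.x2_names,
            fit_log={"n_pd_retries": n_pd_retries,
                     "priors": {"coef_mean": priors.coef_mean,
                                "coef_var": priors.coef_var,
                                "wishart_df": priors.wishart_df,
                                "wishart_scale": np.asarray(priors.wishart_scale).tolist()},
                     "mcmc": {"n_chains": cfg.n_chains, "n_iter": cfg.n_iter,
                              "n_burn": cfg.n_burn, "seed": cfg.seed,
                              "init_dispersion": cfg.init_dispersion}})
        return JointMetaRegressionResults(self, draws)


def fit_joint_model(dm: DesignMatrices, priors: Priors | None = None,
                    cfg: McmcConfig | None = None) -> PosteriorDraws:
    """Functional wrapper: fit the joint model and return the raw draws."""
    return JointMetaRegression(dm).fit(priors, cfg).draws


def gelman_rubin(draws: PosteriorDraws) -> pd.DataFrame:
    """Gelman-Rubin potential scale reduction factor per scalar parameter.

    Computed from the between- and within-chain variances of the retained
    draws; values above 1.1 are flagged as not converged.  Requires at
    least two chains.
    """
    chains = np.unique(draws.chain_id)
    if len(chains) < 2:
        raise ValueError("Gelman-Rubin diagnostic needs at least 2 chains")
    mat = draws.parameter_matrix()
    per_chain = [mat[draws.chain_id == c] for c in chains]
    n = min(len(x) for x in per_chain)
    per_chain = np.stack([x[:n] for x in per_chain])  # (m, n, P)
    chain_means = per_chain.mean(axis=1)
    W = per_chain.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = chain_means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B_over_n
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.sqrt(var_plus / W)
    rhat = np.where(W == 0, 1.0, rhat)
    out = pd.DataFrame({"rhat": rhat}, index=draws.parameter_names)
    out["converged"] = out["rhat"] < 1.1
    return out


def posterior_summary(draws: PosteriorDraws, level: float = 0.95) -> pd.DataFrame:
    """Mean, sd and equal-tailed credible interval per scalar parameter."""
    if draws.n_draws == 0:
        raise ValueError("no draws to summarise")
    mat = draws.parameter_matrix()
    lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    q = np.percentile(mat, [lo, hi], axis=0)
    return pd.DataFrame({
        "mean": mat.mean(axis=0),
        "sd": mat.std(axis=0, ddof=1) if len(mat) > 1 else np.zeros(mat.shape[1]),
        f"ci_{lo:g}%": q[0],
        f"ci_{hi:g}%": q[1],
    }, index=draws.parameter_names)


def posterior_correlation(draws: PosteriorDraws, level: float = 0.95) -> dict:
    """Posterior of the traffic/overall residual correlation."""
    rho = draws.rho()
    lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    qlo, qhi = np.percentile(rho, [lo, hi])
    return {"mean": float(rho.mean()),
            "sd": float(rho.std(ddof=1)) if len(rho) > 1 else 0.0,
            "ci_low": float(qlo), "ci_high": float(qhi), "draws": rho}


class JointMetaRegressionResults:
    """Posterior draws plus diagnostics, summaries and prediction."""

    def __init__(self, model: JointMetaRegression, draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Posterior summary table, traffic block first then overall block."""
        return posterior_summary(self.draws, level)

    def rhat(self) -> pd.DataFrame:
        return gelman_rubin(self.draws)

    def correlation(self, level: float = 0.95) -> dict:
        return posterior_correlation(self.draws, level)

    def predict_city(self, profile, transform: str = "median"):
        from .prediction import predict_city

        return predict_city(self.draws, profile, transform=transform)

    def exceedance_curve(self, profiles, threshold: float = 5.0,
                         transform: str = "median") -> pd.DataFrame:
        from .prediction import exceedance_curve

        return exceedance_curve(self.draws, profiles, threshold=threshold,
                                transform=transform)
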