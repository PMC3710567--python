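"""Panel stochastic cost frontier with time-varying-decay inefficiency.

The composed error of the log-cost equation is ``eps_it = v_it + u_i * h_it``
with ``v_it ~ N(0, sigma_v^2)``, ``u_i`` drawn from a normal distribution
truncated below at zero (location ``mu``; ``mu = 0`` gives the half-normal
special case) and ``h_it = exp(-eta * (t - T_i))`` the decay factor anchored
at the state's last observed year.  Inefficiency enters with a positive sign
because the frontier is a cost minimum.

The state-level marginal likelihood integrates ``u_i`` out analytically:
conditional on the residual vector the posterior of ``u_i`` is again a
truncated normal with

    1/s*^2 = 1/sigma_u^2 + sum_t h_it^2 / sigma_v^2
    m*_i   = s*^2 * (mu / sigma_u^2 + sum_t h_it eps_it / sigma_v^2)

and the log-likelihood contribution of state i with n_i observations is

    -n_i/2 log(2 pi) - n_i log sigma_v + log(s*/sigma_u)
    + log Phi(m*_i/s*) - log Phi(mu/sigma_u)
    - (sum_t eps_it^2/sigma_v^2 + mu^2/sigma_u^2 - m*_i^2/s*^2) / 2

The predictor of inefficiency is the posterior mean
``E[u_it | eps_i] = h_it * (m*_i + s* phi(m*_i/s*) / Phi(m*_i/s*))``.
Both the likelihood and the predictor are validated against adaptive
quadrature in the test suite.

Variance components are reported as ``sigma_sq = sigma_v^2 + sigma_u^2`` and
``gamma = sigma_u^2 / sigma_sq``.  Scores are reported as ``100 * u_hat`` so
their magnitudes are comparable to published efficiency tables; the raw
``u_hat`` and ``ce = exp(-u_hat)`` are always carried alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import ConfigurationError, ConvergenceError, DomainError
from .panel_io import PanelDataset

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))
_DISTRIBUTIONS = ("tnormal", "hnormal", "exponential")


@dataclass(frozen=True)
class FrontierSpec:
    """Model choices for the cost frontier."""

    distribution: str = "tnormal"
    time_varying: bool = True
    output_terms: str = "linear_logs"
    base_year: int = 2007

    def __post_init__(self) -> None:
        if self.distribution not in _DISTRIBUTIONS:
            raise ConfigurationError(f"unknown distribution {self.distribution!r}")
        if self.output_terms not in ("linear_logs", "with_squares_and_interaction"):
            raise ConfigurationError(f"unknown output_terms {self.output_terms!r}")
        if self.distribution == "exponential" and self.time_varying:
            raise ConfigurationError(
                "the exponential distribution is only available as a pooled, "
                "time-invariant model (no closed-form decay-panel likelihood)"
            )


@dataclass(frozen=True)
class FrontierParams:
    """Natural-scale parameters of the composed-error model."""

    beta: np.ndarray
    sigma_sq: float
    gamma: float
    mu: float = 0.0
    eta: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        if self.sigma_sq <= 0:
            raise ConfigurationError(f"sigma_sq must be > 0, got {self.sigma_sq}")
        if not 0 < self.gamma < 1:
            raise ConfigurationError(f"gamma must lie in (0, 1), got {self.gamma}")

    @property
    def sigma_v2(self) -> float:
        return self.sigma_sq * (1.0 - self.gamma)

    @property
    def sigma_u2(self) -> float:
        return self.sigma_sq * self.gamma

    @property
    def sigma_v(self) -> float:
        return float(np.sqrt(self.sigma_v2))

    @property
    def sigma_u(self) -> float:
        return float(np.sqrt(self.sigma_u2))


@dataclass
class FrontierData:
    """Design matrices plus the panel index needed by the likelihood."""

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    state_codes: list[str]
    state_idx: np.ndarray
    years: np.ndarray
    tmT: np.ndarray  # t - T_i, per observation (<= 0)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_states(self) -> int:
        return len(self.state_codes)


@dataclass
class FrontierFit:
    spec: FrontierSpec
    params: FrontierParams
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    se: dict[str, float]
    n_obs: int
    n_states: int
    columns: list[str]
    state_codes: list[str]
    messages: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "spec": {
                "distribution": self.spec.distribution,
                "time_varying": self.spec.time_varying,
                "output_terms": self.spec.output_terms,
                "base_year": self.spec.base_year,
            },
            "params": {
                "beta": dict(zip(self.columns, map(float, self.params.beta))),
                "sigma_sq": float(self.params.sigma_sq),
                "gamma": float(self.params.gamma),
                "mu": float(self.params.mu),
                "eta": float(self.params.eta),
            },
            "se": {k: float(v) for k, v in self.se.items()},
            "loglik": float(self.loglik),
            "convergence": {
                "converged": bool(self.converged),
                "n_iter": int(self.n_iter),
                "grad_norm": float(self.grad_norm),
                "messages": list(self.messages),
            },
            "n_obs": int(self.n_obs),
            "n_states": int(self.n_states),
        }


@dataclass
class ScorePanel:
    """Per state-year inefficiency prediction: ``score = 100 * u_hat``,
    ``ce = exp(-u_hat)``, so ``ce == exp(-score/100)`` identically."""

    frame: pd.DataFrame  # columns: state, year, u_hat, score, ce

    def __post_init__(self) -> None:
        required = {"state", "year", "u_hat", "score", "ce"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ConfigurationError(f"score frame missing columns {sorted(missing)}")
        if (self.frame["u_hat"] < 0).any():
            raise DomainError("negative predicted inefficiency")
        self.frame = self.frame.reset_index(drop=True)

    @classmethod
    def from_u_hat(cls, states, years, u_hat) -> "ScorePanel":
        u_hat = np.asarray(u_hat, dtype=float)
        return cls(
            pd.DataFrame(
                {
                    "state": np.asarray(states),
                    "year": np.asarray(years, dtype=int),
                    "u_hat": u_hat,
                    "score": 100.0 * u_hat,
                    "ce": np.exp(-u_hat),
                }
            )
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScorePanel":
        return cls(pd.read_csv(path))

    def wide(self) -> pd.DataFrame:
        """state x year matrix of scores."""
        return self.frame.pivot(index="state", columns="year", values="score")


def decay_factor(t, T, eta: float):
    """Time-decay multiplier ``exp(-eta * (t - T))`` for ``t <= T``."""
    t = np.asarray(t, dtype=float)
    return np.exp(-eta * (t - np.asarray(T, dtype=float)))


def build_design(data: PanelDataset, spec: FrontierSpec, offset: float = 0.0) -> FrontierData:
    """Build the response and regressor matrix for the cost frontier.

    Response is log deflated total cost.  Regressors: intercept, log of both
    participant counts, year dummies for every panel year except
    ``spec.base_year`` and, when requested, squared log outputs and their
    interaction (the flexible two-output cost form).  Records with a zero
    participant count are a domain error unless a positive ``offset`` is
    supplied (added inside the log).
    """
    frame = data.frame
    for col in ("q_hcbs", "q_inst"):
        bad = frame[col] + offset <= 0
        if bad.any():
            row = frame.loc[bad].iloc[0]
            raise DomainError(
                f"cannot take log of {col} = {row[col]} for ({row['state']}, {row['year']}); "
                "supply a positive offset or drop the record"
            )
    y = np.log(frame["total_cost"].to_numpy())
    lh = np.log(frame["q_hcbs"].to_numpy() + offset)
    li = np.log(frame["q_inst"].to_numpy() + offset)
    cols: list[tuple[str, np.ndarray]] = [
        ("const", np.ones(len(frame))),
        ("log_q_hcbs", lh),
        ("log_q_inst", li),
    ]
    if spec.output_terms == "with_squares_and_interaction":
        cols += [
            ("log_q_hcbs_sq", 0.5 * lh**2),
            ("log_q_inst_sq", 0.5 * li**2),
            ("log_q_hcbs_x_inst", lh * li),
        ]
    years = sorted(frame["year"].unique())
    base = spec.base_year
    if base not in years:
        base = years[-1]
        if len(years) > 1:
            logger.warning("base year %s not in panel; using %s", spec.base_year, base)
    for year in years:
        if year != base:
            cols.append((f"year_{year}", (frame["year"] == year).to_numpy(dtype=float)))
    X = np.column_stack([c for _, c in cols])
    state_codes = sorted(frame["state"].unique())
    state_idx = frame["state"].map({s: i for i, s in enumerate(state_codes)}).to_numpy()
    year_arr = frame["year"].to_numpy()
    last = frame.groupby("state")["year"].transform("max").to_numpy()
    return FrontierData(
        y=y, X=X, columns=[n for n, _ in cols],
        state_codes=state_codes, state_idx=state_idx,
        years=year_arr, tmT=(year_arr - last).astype(float),
    )


def _state_posterior(params: FrontierParams, fdata: FrontierData, eps: np.ndarray):
    """Per-state truncated-normal posterior of u_i: returns (m*, s*, sums)."""
    sv2, su2 = params.sigma_v2, params.sigma_u2
    h = np.exp(-params.eta * fdata.tmT)
    n_states = fdata.n_states
    shh = np.bincount(fdata.state_idx, weights=h * h, minlength=n_states)
    she = np.bincount(fdata.state_idx, weights=h * eps, minlength=n_states)
    see = np.bincount(fdata.state_idx, weights=eps * eps, minlength=n_states)
    n_i = np.bincount(fdata.state_idx, minlength=n_states).astype(float)
    denom = sv2 + su2 * shh
    sstar2 = sv2 * su2 / denom
    mstar = (params.mu * sv2 + su2 * she) / denom
    return mstar, np.sqrt(sstar2), {"shh": shh, "she": she, "see": see, "n_i": n_i, "h": h}


def loglik(params: FrontierParams, spec: FrontierSpec, fdata: FrontierData) -> float:
    """Exact marginal log-likelihood of the composed-error panel model."""
    eps = fdata.y - fdata.X @ params.beta
    if not np.all(np.isfinite(eps)):
        raise DomainError("non-finite residuals")
    if spec.distribution == "exponential":
        return _loglik_exponential(params, eps)
    mu = 0.0 if spec.distribution == "hnormal" else params.mu
    params_eff = params if mu == params.mu else replace(params, mu=mu)
    sv2, su2 = params_eff.sigma_v2, params_eff.sigma_u2
    sigma_v, sigma_u = params_eff.sigma_v, params_eff.sigma_u
    mstar, sstar, sums = _state_posterior(params_eff, fdata, eps)
    quad = sums["see"] / sv2 + mu**2 / su2 - mstar**2 / sstar**2
    ll_states = (
        -0.5 * sums["n_i"] * _LOG_2PI
        - sums["n_i"] * np.log(sigma_v)
        + np.log(sstar / sigma_u)
        + special.log_ndtr(mstar / sstar)
        - special.log_ndtr(mu / sigma_u)
        - 0.5 * quad
    )
    return float(np.sum(ll_states))


def _loglik_exponential(params: FrontierParams, eps: np.ndarray) -> float:
    # Pooled normal-exponential convolution; sigma_u is the exponential mean.
    sigma_v, sigma_u = params.sigma_v, params.sigma_u
    z = eps / sigma_v - sigma_v / sigma_u
    ll = -np.log(sigma_u) + 0.5 * (sigma_v / sigma_u) ** 2 - eps / sigma_u + special.log_ndtr(z)
    return float(np.sum(ll))


def _mills_ratio(z: np.ndarray) -> np.ndarray:
    # phi(z)/Phi(z), computed in log space for stability deep in the tail
    return np.exp(stats.norm.logpdf(z) - special.log_ndtr(z))


def predict_scores(fit: FrontierFit, data: PanelDataset, offset: float = 0.0) -> ScorePanel:
    """Posterior-mean inefficiency prediction for every record in ``data``.

    Uses ``E[u_it | eps_i] = h_it * E[u_i | eps_i]`` under the fitted
    truncated-normal posterior (per-observation Jondrow-style posterior for
    the pooled exponential model).  States absent from the fit raise
    ``KeyError``.
    """
    unknown = sorted(set(data.frame["state"].unique()) - set(fit.state_codes))
    if unknown:
        raise KeyError(f"states not present in the fitted panel: {unknown}")
    fdata = build_design(data, fit.spec, offset=offset)
    if fdata.columns != fit.columns:
        raise ConfigurationError(
            f"design columns {fdata.columns} do not match fitted columns {fit.columns}"
        )
    params = fit.params
    eps = fdata.y - fdata.X @ params.beta
    if fit.spec.distribution == "exponential":
        mtilde = eps - params.sigma_v2 / params.sigma_u
        u_hat = mtilde + params.sigma_v * _mills_ratio(mtilde / params.sigma_v)
    else:
        mu = 0.0 if fit.spec.distribution == "hnormal" else params.mu
        params_eff = replace(params, mu=mu)
        mstar, sstar, sums = _state_posterior(params_eff, fdata, eps)
        e_u_state = mstar + sstar * _mills_ratio(mstar / sstar)
        u_hat = sums["h"] * e_u_state[fdata.state_idx]
    u_hat = np.maximum(u_hat, 0.0)
    return ScorePanel.from_u_hat(data.frame["state"], data.frame["year"], u_hat)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings.  The internal parameterization is unconstrained:
    (beta, log sigma_sq, logit gamma, mu, eta)."""

    gamma_starts: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    gtol: float = 1e-5          # on the mean (per-observation) log-likelihood
    maxiter: int = 500
    offset: float = 0.0
    compute_se: bool = True


def _pack(spec: FrontierSpec, beta, sigma_sq, gamma, mu, eta) -> np.ndarray:
    theta = list(beta) + [np.log(sigma_sq), special.logit(gamma)]
    if spec.distribution == "tnormal":
        theta.append(mu)
    if spec.time_varying:
        theta.append(eta)
    return np.asarray(theta, dtype=float)


def _unpack(spec: FrontierSpec, theta: np.ndarray, k: int) -> FrontierParams:
    beta = theta[:k]
    sigma_sq = float(np.exp(np.clip(theta[k], -30, 30)))
    gamma = float(special.expit(np.clip(theta[k + 1], -30, 30)))
    gamma = min(max(gamma, 1e-12), 1 - 1e-12)
    pos = k + 2
    mu = 0.0
    if spec.distribution == "tnormal":
        mu = float(theta[pos])
        pos += 1
    eta = float(theta[pos]) if spec.time_varying else 0.0
    return FrontierParams(beta=beta, sigma_sq=sigma_sq, gamma=gamma, mu=mu, eta=eta)


def _num_grad(fun, theta: np.ndarray, step: float = 1e-6) -> np.ndarray:
    g = np.empty_like(theta)
    for j in range(len(theta)):
        e = np.zeros_like(theta)
        e[j] = step * max(1.0, abs(theta[j]))
        g[j] = (fun(theta + e) - fun(theta - e)) / (2 * e[j])
    return g


def _grad_norm(fun, theta: np.ndarray, step: float = 1e-6) -> float:
    return float(np.linalg.norm(_num_grad(fun, theta, step)))


def _num_hess(fun, theta: np.ndarray, step: float = 1e-4) -> np.ndarray:
    p = len(theta)
    H = np.empty((p, p))
    steps = step * np.maximum(np.abs(theta), 1.0)
    f0 = fun(theta)
    for i in range(p):
        ei = np.zeros(p); ei[i] = steps[i]
        H[i, i] = (fun(theta + ei) - 2 * f0 + fun(theta - ei)) / steps[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p); ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                fun(theta + ei + ej) - fun(theta + ei - ej)
                - fun(theta - ei + ej) + fun(theta - ei - ej)
            ) / (4 * steps[i] * steps[j])
    return H


def _newton_polish(fun, theta: np.ndarray, n_steps: int = 3) -> np.ndarray:
    """Damped Newton refinement near an optimum (numeric derivatives)."""
    f0 = fun(theta)
    for _ in range(n_steps):
        g = _num_grad(fun, theta)
        H = _num_hess(fun, theta)
        try:
            direction = -np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return theta
        if not np.all(np.isfinite(direction)):
            return theta
        scale = 1.0
        for _ in range(20):
            trial = theta + scale * direction
            f1 = fun(trial)
            if f1 <= f0:
                theta, f0 = trial, f1
                break
            scale /= 2
        else:
            return theta
    return theta


def fit_frontier(
    data: PanelDataset,
    spec: FrontierSpec = FrontierSpec(),
    options: FitOptions = FitOptions(),
) -> FrontierFit:
    """Maximize the marginal likelihood over an unconstrained parameterization.

    Multi-start strategy: beta and sigma_sq initialized from OLS, gamma from
    a grid, mu and eta from zero.  A fit that fails the gradient-norm
    convergence check on every start is returned with ``converged=False``
    carrying the best point found (never a silent success).
    """
    fdata = build_design(data, spec, offset=options.offset)
    if spec.time_varying and len(np.unique(fdata.years)) < 2:
        raise ConfigurationError("time-varying decay needs at least 2 panel years")
    if fdata.n_states < 2:
        raise ConfigurationError("need at least 2 states")
    k = fdata.X.shape[1]
    rank = np.linalg.matrix_rank(fdata.X)
    if rank < k:
        raise ConfigurationError(f"design matrix rank deficient ({rank} < {k})")

    beta_ols, *_ = np.linalg.lstsq(fdata.X, fdata.y, rcond=None)
    resid = fdata.y - fdata.X @ beta_ols
    s2_ols = float(resid @ resid) / max(fdata.n_obs - k, 1)
    n = fdata.n_obs

    def negmean(theta: np.ndarray) -> float:
        try:
            return -loglik(_unpack(spec, theta, k), spec, fdata) / n
        except (FloatingPointError, DomainError):
            return np.inf

    best = None
    messages: list[str] = []
    total_iter = 0
    with np.errstate(over="raise", invalid="raise", divide="raise"):
        for gamma0 in options.gamma_starts:
            theta0 = _pack(spec, beta_ols, max(s2_ols, 1e-8), gamma0, 0.0, 0.0)
            try:
                res = optimize.minimize(
                    negmean, theta0, method="BFGS",
                    options={"gtol": options.gtol / 10, "maxiter": options.maxiter},
                )
            except Exception as exc:  # pragma: no cover - defensive
                messages.append(f"start gamma={gamma0}: {exc}")
                continue
            total_iter += res.nit
            if best is None or res.fun < best.fun:
                best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("all optimizer starts failed; " + "; ".join(messages))

    gnorm = _grad_norm(negmean, best.x)
    if gnorm >= options.gtol:
        # damped Newton polish: BFGS stalls on the near-flat mu/gamma ridge
        x = _newton_polish(negmean, best.x)
        if negmean(x) <= best.fun:
            best.x, best.fun = x, negmean(x)
            gnorm = _grad_norm(negmean, best.x)
    converged = gnorm < options.gtol
    if not converged:
        messages.append(f"gradient norm {gnorm:.2e} above tolerance {options.gtol:.0e}")
    params = _unpack(spec, best.x, k)
    ll = -best.fun * n

    se = {}
    if options.compute_se:
        se = _standard_errors(params, spec, fdata)

    return FrontierFit(
        spec=spec, params=params, loglik=float(ll), converged=bool(converged),
        n_iter=int(total_iter), grad_norm=gnorm, se=se,
        n_obs=fdata.n_obs, n_states=fdata.n_states,
        columns=fdata.columns, state_codes=fdata.state_codes,
        messages=tuple(messages),
    )


def _natural_vector(params: FrontierParams, spec: FrontierSpec) -> tuple[np.ndarray, list[str]]:
    names = list(range(len(params.beta)))
    vec = list(params.beta) + [params.sigma_sq, params.gamma]
    labels = [f"beta_{i}" for i in names] + ["sigma_sq", "gamma"]
    if spec.distribution == "tnormal":
        vec.append(params.mu)
        labels.append("mu")
    if spec.time_varying:
        vec.append(params.eta)
        labels.append("eta")
    return np.asarray(vec, dtype=float), labels


def _params_from_natural(vec: np.ndarray, spec: FrontierSpec, k: int) -> FrontierParams:
    beta = vec[:k]
    sigma_sq, gamma = vec[k], vec[k + 1]
    pos = k + 2
    mu = 0.0
    if spec.distribution == "tnormal":
        mu = vec[pos]
        pos += 1
    eta = vec[pos] if spec.time_varying else 0.0
    return FrontierParams(beta=beta, sigma_sq=sigma_sq, gamma=gamma, mu=mu, eta=eta)


def _standard_errors(
    params: FrontierParams, spec: FrontierSpec, fdata: FrontierData
) -> dict[str, float]:
    """Inverse observed information on the natural scale (central differences).

    Returns NaN entries when the Hessian is not positive definite (typical
    when gamma sits near a boundary)."""
    k = len(params.beta)
    x0, labels = _natural_vector(params, spec)
    labels = [fdata.columns[i] if isinstance(i, int) else i for i in range(k)] + labels[k:]

    def nll(vec: np.ndarray) -> float:
        try:
            return -loglik(_params_from_natural(vec, spec, k), spec, fdata)
        except (ConfigurationError, FloatingPointError, DomainError):
            return np.nan

    p = len(x0)
    steps = 1e-4 * np.maximum(np.abs(x0), 1e-2)
    # keep gamma strictly inside (0, 1)
    g_idx = k + 1
    steps[g_idx] = min(steps[g_idx], 0.4 * min(params.gamma, 1 - params.gamma))
    H = np.full((p, p), np.nan)
    with np.errstate(all="ignore"):
        f0 = nll(x0)
        for i in range(p):
            for j in range(i, p):
                ei = np.zeros(p); ei[i] = steps[i]
                ej = np.zeros(p); ej[j] = steps[j]
                if i == j:
                    val = (nll(x0 + ei) - 2 * f0 + nll(x0 - ei)) / steps[i] ** 2
                else:
                    val = (
                        nll(x0 + ei + ej) - nll(x0 + ei - ej)
                        - nll(x0 - ei + ej) + nll(x0 - ei - ej)
                    ) / (4 * steps[i] * steps[j])
                H[i, j] = H[j, i] = val
    out = {name: float("nan") for name in labels}
    if np.all(np.isfinite(H)):
        try:
            cov = np.linalg.inv(H)
            diag = np.diag(cov)
            if np.all(diag > 0):
                for name, v in zip(labels, np.sqrt(diag)):
                    out[name] = float(v)
            else:
                logger.warning("observed information not positive definite; SEs set to NaN")
        except np.linalg.LinAlgError:
            logger.warning("observed information singular; SEs set to NaN")
    return out
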