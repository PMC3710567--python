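"""Fixed/random-effects regression of log efficiency scores on policy covariates.

Implements the within (fixed-effects) estimator with CR1 cluster-robust
standard errors, a Swamy-Arora random-effects GLS estimator, the classical
Hausman specification test, and the multiplicative effect transform used to
present coefficients.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DomainError, JoinError, SingularityError
from .frontier import ScorePanel
from .panel_io import PanelDataset

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES: tuple[str, ...] = (
    "hcbs_share", "waiver_share", "icfmr_share", "managed_care", "con",
    "log_population", "log_pc_income", "unemployment",
)

_LOG_TRANSFORMS = {"log_population": "population", "log_pc_income": "pc_income"}


@dataclass(frozen=True)
class SecondStageSpec:
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    estimator: str = "fe"
    cluster: str = "state"
    critical: str = "normal"  # 'normal' -> 1.96; 't' -> t with G-1 df

    def __post_init__(self) -> None:
        if self.estimator not in ("fe", "re"):
            raise ConfigurationError(f"unknown estimator {self.estimator!r}")
        if self.critical not in ("normal", "t"):
            raise ConfigurationError(f"unknown critical value rule {self.critical!r}")


@dataclass
class SecondStageFit:
    spec: SecondStageSpec
    estimator: str
    params: pd.Series
    cov_classical: pd.DataFrame
    se: pd.Series
    ci: pd.DataFrame  # columns low, high
    within_r2: float
    n_obs: int
    n_clusters: int
    dropped: tuple[str, ...] = ()
    robust: bool = False
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        stars = {
            name: _stars(self.params[name], self.se[name], self.n_clusters, self.spec)
            for name in self.params.index
        }
        return {
            "estimator": self.estimator,
            "coefficients": {
                name: {
                    "estimate": float(self.params[name]),
                    "se": float(self.se[name]),
                    "ci_low": float(self.ci.loc[name, "low"]),
                    "ci_high": float(self.ci.loc[name, "high"]),
                    "stars": stars[name],
                }
                for name in self.params.index
            },
            "within_r2": float(self.within_r2),
            "n_obs": int(self.n_obs),
            "n_clusters": int(self.n_clusters),
            "robust": bool(self.robust),
            "dropped": list(self.dropped),
        }


def _stars(estimate: float, se: float, g: int, spec: SecondStageSpec) -> str:
    if not (np.isfinite(se) and se > 0):
        return ""
    z = estimate / se
    if spec.critical == "t":
        p = 2 * stats.t.sf(abs(z), df=max(g - 1, 1))
    else:
        p = 2 * stats.norm.sf(abs(z))
    for threshold, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
        if p < threshold:
            return mark
    return ""


@dataclass
class HausmanResult:
    statistic: float
    df: int
    pvalue: float
    recommendation: str
    used_pinv: bool = False


def build_second_stage(
    scores: ScorePanel, data: PanelDataset, spec: SecondStageSpec = SecondStageSpec()
) -> pd.DataFrame:
    """Join scores with panel covariates; dependent variable is log(score).

    Rows present in only one of the two tables are dropped with a warning;
    an empty intersection raises :class:`JoinError`; non-positive scores are
    a domain error (their log is undefined).
    """
    if (scores.frame["score"] <= 0).any():
        bad = scores.frame.loc[scores.frame["score"] <= 0].iloc[0]
        raise DomainError(
            f"score must be > 0 to take logs; ({bad['state']}, {bad['year']}) has {bad['score']}"
        )
    panel = data.frame.copy()
    for new, src in _LOG_TRANSFORMS.items():
        panel[new] = np.log(panel[src])
    missing = [c for c in spec.covariates if c not in panel.columns]
    if missing:
        raise ConfigurationError(f"covariates absent from panel: {missing}")
    left = scores.frame[["state", "year", "score"]]
    merged = left.merge(panel[["state", "year", *spec.covariates]], on=["state", "year"], how="inner")
    n_dropped = max(len(left), len(panel)) - len(merged)
    if merged.empty:
        raise JoinError("scores and panel share no (state, year) keys")
    if len(merged) < len(left):
        logger.warning("dropped %d score rows without matching panel records", len(left) - len(merged))
    if len(merged) < len(panel):
        logger.warning("dropped %d panel rows without matching scores", len(panel) - len(merged))
    merged = merged.dropna()
    merged["log_score"] = np.log(merged["score"])
    cols = ["state", "year", "log_score", *spec.covariates]
    return merged[cols].reset_index(drop=True)


def _demean(table: pd.DataFrame, columns: Sequence[str], group: str = "state"):
    grouped = table.groupby(group)[list(columns)]
    return table[list(columns)] - grouped.transform("mean")


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if others.shape[1] == 0:
            continue
        coef, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ coef
        scale = max(np.linalg.norm(X[:, j]), 1.0)
        if np.linalg.norm(resid) < 1e-8 * scale:
            bad.append(names[j])
    return bad


def fit_within(table: pd.DataFrame, spec: SecondStageSpec = SecondStageSpec()) -> SecondStageFit:
    """Fixed-effects (within) estimator: demean by state, then least squares.

    Coefficients are identical to least squares with explicit state dummies.
    Covariates with no within-state variation are dropped with a warning.
    The reported classical covariance uses ``SSR / (N - G - K)``; the within
    R^2 is ``1 - SSR/SST`` on the demeaned data.
    """
    covariates = list(spec.covariates)
    demeaned = _demean(table, ["log_score", *covariates])
    dropped = [c for c in covariates if np.abs(demeaned[c]).max() < 1e-12]
    if dropped:
        logger.warning("dropping covariates with no within-state variation: %s", dropped)
        covariates = [c for c in covariates if c not in dropped]
    if not covariates:
        raise ConfigurationError("no covariates with within-state variation remain")
    X = demeaned[covariates].to_numpy()
    y = demeaned["log_score"].to_numpy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        cols = _collinear_columns(X, covariates)
        raise SingularityError(f"demeaned design rank deficient; collinear columns: {cols}", cols)
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ b
    ssr = float(resid @ resid)
    sst = float(y @ y)
    n = len(y)
    groups = table["state"]
    g = groups.nunique()
    k = X.shape[1]
    dof = max(n - g - k, 1)
    sigma2 = ssr / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    cov = pd.DataFrame(sigma2 * xtx_inv, index=covariates, columns=covariates)
    params = pd.Series(b, index=covariates)
    se = pd.Series(np.sqrt(np.diag(cov)), index=covariates)
    crit = _critical_value(spec, g)
    ci = pd.DataFrame({"low": params - crit * se, "high": params + crit * se})
    return SecondStageFit(
        spec=spec, estimator="fe", params=params, cov_classical=cov, se=se, ci=ci,
        within_r2=1.0 - ssr / sst if sst > 0 else float("nan"),
        n_obs=n, n_clusters=g, dropped=tuple(dropped),
        extras={"resid": resid, "X": X, "covariates": covariates, "ssr": ssr, "sigma2": sigma2},
    )


def _critical_value(spec: SecondStageSpec, g: int) -> float:
    if spec.critical == "t":
        return float(stats.t.ppf(0.975, df=max(g - 1, 1)))
    return 1.96


def cluster_robust_se(
    fit: SecondStageFit, table: pd.DataFrame, cluster: str = "state"
) -> SecondStageFit:
    """CR1 sandwich standard errors, clustered on ``cluster``.

    Small-sample factor ``G/(G-1) * (N-1)/(N-K)``.  With every cluster a
    singleton this reduces exactly to HC1.  Returns a new fit with robust
    SEs and confidence intervals (point estimates unchanged).
    """
    X = fit.extras["X"]
    resid = fit.extras["resid"]
    covariates = fit.extras["covariates"]
    groups = table[cluster].to_numpy()
    unique = np.unique(groups)
    g = len(unique)
    if g < 2:
        raise ConfigurationError("cluster-robust inference needs at least 2 clusters")
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    scores = X * resid[:, None]
    meat = np.zeros((k, k))
    for value in unique:
        s_g = scores[groups == value].sum(axis=0)
        meat += np.outer(s_g, s_g)
    factor = (g / (g - 1)) * ((n - 1) / (n - k))
    cov = factor * xtx_inv @ meat @ xtx_inv
    se = pd.Series(np.sqrt(np.diag(cov)), index=covariates)
    crit = _critical_value(fit.spec, g)
    ci = pd.DataFrame({"low": fit.params - crit * se, "high": fit.params + crit * se})
    return SecondStageFit(
        spec=fit.spec, estimator=fit.estimator, params=fit.params,
        cov_classical=fit.cov_classical, se=se, ci=ci, within_r2=fit.within_r2,
        n_obs=fit.n_obs, n_clusters=g, dropped=fit.dropped, robust=True,
        extras={**fit.extras, "cov_robust": pd.DataFrame(cov, index=covariates, columns=covariates)},
    )


def fit_re(table: pd.DataFrame, spec: SecondStageSpec = SecondStageSpec()) -> SecondStageFit:
    """Random-effects GLS with Swamy-Arora variance components.

    The idiosyncratic variance comes from the within residuals, the
    state-effect variance from the between regression (truncated at zero
    with a warning when negative); observations are quasi-demeaned with a
    per-state ``theta_i`` before pooled least squares.
    """
    covariates = list(spec.covariates)
    fe = fit_within(table, spec)
    sigma_e2 = fe.extras["sigma2"]
    kept = fe.extras["covariates"]

    means = table.groupby("state")[["log_score", *covariates]].mean()
    t_i = table.groupby("state").size()
    Xb = np.column_stack([np.ones(len(means)), means[covariates].to_numpy()])
    yb = means["log_score"].to_numpy()
    bb, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
    rb = yb - Xb @ bb
    dof_b = max(len(means) - Xb.shape[1], 1)
    sigma_b2 = float(rb @ rb) / dof_b
    sigma_a2 = sigma_b2 - sigma_e2 * float(np.mean(1.0 / t_i))
    if sigma_a2 < 0:
        logger.warning("negative estimated state-effect variance (%.3g); truncated at 0", sigma_a2)
        sigma_a2 = 0.0

    theta = 1.0 - np.sqrt(sigma_e2 / (sigma_e2 + t_i * sigma_a2))
    theta_obs = table["state"].map(theta).to_numpy()
    cols = ["log_score", *covariates]
    group_means = table.groupby("state")[cols].transform("mean")
    starred = table[cols].to_numpy() - theta_obs[:, None] * group_means.to_numpy()
    const = (1.0 - theta_obs)[:, None]
    X = np.hstack([const, starred[:, 1:]])
    y = starred[:, 0]
    names = ["const", *covariates]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise SingularityError(f"quasi-demeaned design rank deficient: {bad}", bad)
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ b
    n, k = X.shape
    sigma2 = float(resid @ resid) / max(n - k, 1)
    cov = pd.DataFrame(sigma2 * np.linalg.inv(X.T @ X), index=names, columns=names)
    params = pd.Series(b, index=names)
    se = pd.Series(np.sqrt(np.diag(cov)), index=names)
    g = table["state"].nunique()
    crit = _critical_value(spec, g)
    ci = pd.DataFrame({"low": params - crit * se, "high": params + crit * se})

    # within R^2 of the RE slope vector, for comparability with the FE fit
    demeaned = _demean(table, cols)
    Xw = demeaned[covariates].to_numpy()
    yw = demeaned["log_score"].to_numpy()
    rw = yw - Xw @ params[covariates].to_numpy()
    sst = float(yw @ yw)
    within_r2 = 1.0 - float(rw @ rw) / sst if sst > 0 else float("nan")

    return SecondStageFit(
        spec=spec, estimator="re", params=params, cov_classical=cov, se=se, ci=ci,
        within_r2=within_r2, n_obs=n, n_clusters=g, dropped=fe.dropped,
        extras={
            "sigma_e2": sigma_e2, "sigma_a2": sigma_a2, "sigma2": sigma2,
            "theta": theta, "X": X, "resid": resid, "covariates": names,
        },
    )


def hausman(fe: SecondStageFit, re: SecondStageFit) -> HausmanResult:
    """Classical Hausman test comparing FE and RE on their common covariates.

    ``H = d' (V_FE - V_RE)^+ d`` with ``d`` the coefficient difference and
    classical (non-robust) covariances.  Both covariances are put on a
    common error-variance scale (the FE idiosyncratic variance) before
    differencing, which keeps the difference positive definite when the RE
    residual variance is inflated by misspecification.  A pseudo-inverse is
    used (and flagged) whenever the difference is still not positive
    definite; degrees of freedom equal the rank of the difference.
    """
    common = [c for c in fe.params.index if c in re.params.index and c != "const"]
    if not common:
        raise ConfigurationError("no common covariates between FE and RE fits")
    d = (fe.params[common] - re.params[common]).to_numpy()
    v_re = re.cov_classical.loc[common, common]
    if "sigma2" in fe.extras and re.extras.get("sigma2"):
        v_re = v_re * (fe.extras["sigma2"] / re.extras["sigma2"])
    v = (fe.cov_classical.loc[common, common] - v_re).to_numpy()
    used_pinv = False
    try:
        np.linalg.cholesky(v)
        v_inv = np.linalg.inv(v)
    except np.linalg.LinAlgError:
        used_pinv = True
        v_inv = np.linalg.pinv(v)
    statistic = float(d @ v_inv @ d)
    statistic = max(statistic, 0.0)
    df = int(np.linalg.matrix_rank(v)) if used_pinv else len(common)
    df = max(df, 1)
    pvalue = float(stats.chi2.sf(statistic, df))
    return HausmanResult(
        statistic=statistic, df=df, pvalue=pvalue,
        recommendation="fe" if pvalue < 0.05 else "re",
        used_pinv=used_pinv,
    )


@dataclass(frozen=True)
class EffectSummary:
    """Multiplicative reading of a log-scale coefficient."""

    coefficient: float
    multiplier: float       # exp(b): score multiplier per unit covariate
    decrease: float         # 1 - exp(b): proportional score decrease (b < 0)
    multiplier_2dp: float   # presentation values, truncated to 2 decimals
    decrease_2dp: float


def _truncate_2dp(x: float) -> float:
    return math.trunc(round(x * 100, 9)) / 100


def effect_transform(b: float) -> EffectSummary:
    """Present a coefficient as a score multiplier ``exp(b)`` and, for
    negative coefficients, the proportional decrease ``1 - exp(b)``.
    Presentation values are truncated (not rounded) to two decimals."""
    if not np.isfinite(b):
        raise DomainError(f"coefficient must be finite, got {b}")
    multiplier = math.exp(b)
    decrease = 1.0 - multiplier
    return EffectSummary(
        coefficient=float(b),
        multiplier=multiplier,
        decrease=decrease,
        multiplier_2dp=_truncate_2dp(multiplier),
        decrease_2dp=_truncate_2dp(decrease),
    )
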