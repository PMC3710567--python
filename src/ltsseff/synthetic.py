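"""Seeded synthetic state-year panels with known ground truth.

Two generation modes are provided:

``bc92``
    The inefficiency process matches the frontier likelihood: one
    truncated-normal draw per state, scaled over time by an exponential
    decay factor anchored at the state's last panel year.  Used for
    parameter-recovery tests of the frontier estimator.

``covariate_driven``
    Log-inefficiency is a linear function of the policy covariates plus a
    state effect and noise.  This is *deliberately misspecified* with
    respect to the decay likelihood: it exists to exercise the full
    two-step procedure (frontier scores, then a fixed-effects regression)
    end to end, including the attenuation the first stage induces.

Covariate levels default to the descriptive statistics of the study panel
(shares in percentage points, population in persons, income in dollars).
"""

from __future__ import annotations

import itertools
import json
import string
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .panel_io import JURISDICTIONS, PanelDataset

#: Default covariate means (percentage points, proportions, persons, dollars).
DEFAULT_COVARIATE_MEANS: dict[str, float] = {
    "hcbs_share": 53.90,
    "waiver_share": 52.14,
    "icfmr_share": 5.70,
    "managed_care": 0.42,
    "con": 0.74,
    "unemployment": 4.70,
    "pc_income": 33_234.0,
    "population": 5_713_000.0,
}

#: Default covariate spreads (overall standard deviations; binaries use the
#: spread as an on/off switch for the adoption process).
DEFAULT_COVARIATE_SPREADS: dict[str, float] = {
    "hcbs_share": 13.28,
    "waiver_share": 20.23,
    "icfmr_share": 4.13,
    "managed_care": 1.0,
    "con": 1.0,
    "unemployment": 1.15,
    "pc_income": 5_495.0,
    "population": 6_412_000.0,
}

_BINARY = ("managed_care", "con")
_LOGNORMAL = ("pc_income", "population")
_AR_COEF = 0.7
_BETWEEN_FRACTION = 0.9
#: Secular drift per year, centered on the panel midpoint so overall means
#: are unchanged (community-services share grew steadily over the period).
_YEAR_DRIFT = {"hcbs_share": 1.2, "waiver_share": 0.8}


@dataclass(frozen=True)
class FrontierTruth:
    """Generating parameters of the cost frontier and composed error."""

    beta0: float = 13.68
    b_hcbs: float = 0.22
    b_inst: float = 0.17
    year_effects: tuple[float, ...] = (-0.31, -0.25, -0.19, -0.10, -0.10, -0.05, -0.03, -0.02)
    sigma_v: float = 0.10
    sigma_u: float = 0.35
    mu: float = 0.20
    eta: float = 0.011

    def __post_init__(self) -> None:
        if self.sigma_v <= 0:
            raise ConfigurationError(f"sigma_v must be > 0, got {self.sigma_v}")
        if self.sigma_u < 0:
            raise ConfigurationError(f"sigma_u must be >= 0, got {self.sigma_u}")


#: Second-stage generating coefficients for covariate_driven mode.  Signs
#: follow the study's estimates; magnitudes are scaled to keep exp(.) in a
#: sane range over realistic covariate spans (per-percentage-point slopes at
#: the published magnitudes would drive inefficiency across ~25 log-units).
DEFAULT_GAMMA_TRUTH: dict[str, float] = {
    "hcbs_share": -0.020,
    "waiver_share": -0.008,
    "icfmr_share": 0.040,
    "managed_care": -0.10,
    "con": 0.0,
    "log_population": 0.0,
    "log_pc_income": -0.05,
    "unemployment": -0.01,
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_states: int = 50
    years: tuple[int, int] = (1999, 2007)
    mode: str = "bc92"
    frontier: FrontierTruth = field(default_factory=FrontierTruth)
    covariate_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_COVARIATE_MEANS))
    covariate_spreads: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_COVARIATE_SPREADS))
    gamma_truth: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GAMMA_TRUTH))
    g0: float = 0.0
    state_effect_sd: float = 0.15
    u_noise_sd: float = 0.05
    participation_rate: float = 0.012
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ConfigurationError("n_states must be >= 2")
        first, last = self.years
        if last - first + 1 < 2:
            raise ConfigurationError("need at least 2 panel years")
        if self.mode not in ("bc92", "covariate_driven"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        for name, spread in self.covariate_spreads.items():
            if spread < 0:
                raise ConfigurationError(f"spread for {name} must be >= 0")
        if len(self.frontier.year_effects) < last - first:
            raise ConfigurationError(
                f"year_effects needs at least {last - first} entries "
                f"(all years but the base {last}), got {len(self.frontier.year_effects)}"
            )

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


@dataclass
class SyntheticTruth:
    """Ground truth paired with a generated panel, for recovery tests."""

    config: SyntheticConfig
    u_state: pd.Series            # per-state persistent draw (bc92 mode)
    frame: pd.DataFrame           # state, year, u, v, ce per record

    def to_json(self) -> str:
        payload = {
            "config": _config_dict(self.config),
            "u_state": {k: float(v) for k, v in self.u_state.items()},
            "records": self.frame.to_dict("records"),
        }
        return json.dumps(payload, indent=2)


def _config_dict(config: SyntheticConfig) -> dict:
    raw = asdict(config)
    raw["covariate_means"] = dict(config.covariate_means)
    raw["covariate_spreads"] = dict(config.covariate_spreads)
    raw["gamma_truth"] = dict(config.gamma_truth)
    return raw


def state_codes(n: int) -> list[str]:
    """Jurisdiction codes: the 51 real ones first, then synthetic pairs."""
    codes = list(JURISDICTIONS[:n])
    if n > len(JURISDICTIONS):
        pool = itertools.chain.from_iterable(
            ("".join(p) for p in itertools.product(string.ascii_uppercase, repeat=r))
            for r in (2, 3)
        )
        extras = (c for c in pool if c not in JURISDICTIONS)
        codes += list(itertools.islice(extras, n - len(JURISDICTIONS)))
    return codes


def sample_truncated_normal(
    mu: float, sigma: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw from Normal(mu, sigma^2) truncated below at 0 via inverse CDF.

    Inverse-CDF sampling on the truncated region stays exact for mu far
    below zero, where rejection sampling degenerates.
    """
    if sigma == 0:
        return np.full(size, max(mu, 0.0))
    a = (0.0 - mu) / sigma
    return stats.truncnorm.ppf(rng.uniform(size=size), a, np.inf, loc=mu, scale=sigma)


def truncated_normal_mean(mu: float, sigma: float) -> float:
    """Closed-form mean of Normal(mu, sigma^2) truncated below at 0."""
    if sigma == 0:
        return max(mu, 0.0)
    z = mu / sigma
    return mu + sigma * stats.norm.pdf(z) / stats.norm.cdf(z)


def _ar1_path(mean: float, stationary_sd: float, n_years: int, rng: np.random.Generator) -> np.ndarray:
    if stationary_sd == 0:
        return np.full(n_years, mean)
    x = np.empty(n_years)
    x[0] = rng.normal(mean, stationary_sd)
    innov_sd = stationary_sd * np.sqrt(1 - _AR_COEF**2)
    for t in range(1, n_years):
        x[t] = mean + _AR_COEF * (x[t - 1] - mean) + rng.normal(0, innov_sd)
    return x


def _binary_panel(mean: float, n_years: int, rng: np.random.Generator) -> np.ndarray:
    """State-level switch-on process with panel-wide mean ``mean``."""
    frac_if_adopting = (n_years + 1) / (2 * n_years)  # mean active share, uniform adoption year
    p_adopt = min(0.4, mean / frac_if_adopting, (1 - mean) / (1 - frac_if_adopting))
    p_always = mean - p_adopt * frac_if_adopting
    draw = rng.uniform()
    if draw < p_always:
        return np.ones(n_years)
    if draw < p_always + p_adopt:
        start = rng.integers(0, n_years)
        out = np.zeros(n_years)
        out[start:] = 1.0
        return out
    return np.zeros(n_years)


def generate_covariates(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Generate the state-year covariate panel.

    Continuous covariates follow an AR(1) path around a state-level mean;
    shares are clipped to [0, 100]; binary policies follow a switch-on
    process; population and income are log-normal.  With all spreads zero
    every record equals the configured means.
    """
    years = config.year_list
    n_years = len(years)
    mid = (years[0] + years[-1]) / 2.0
    rows = []
    for code in state_codes(config.n_states):
        values: dict[str, np.ndarray] = {}
        for name, mean in config.covariate_means.items():
            spread = config.covariate_spreads.get(name, 0.0)
            if name in _BINARY:
                if spread == 0:
                    values[name] = np.full(n_years, mean)
                else:
                    values[name] = _binary_panel(mean, n_years, rng)
                continue
            if name in _LOGNORMAL:
                if spread == 0:
                    values[name] = np.full(n_years, mean)
                    continue
                log_sd = np.sqrt(np.log1p((spread / mean) ** 2))
                log_mean = np.log(mean) - 0.5 * log_sd**2
                between = rng.normal(log_mean, log_sd * _BETWEEN_FRACTION)
                within_sd = log_sd * np.sqrt(1 - _BETWEEN_FRACTION**2)
                values[name] = np.exp(between + _ar1_path(0.0, within_sd, n_years, rng))
                continue
            between_sd = spread * _BETWEEN_FRACTION
            within_sd = spread * np.sqrt(1 - _BETWEEN_FRACTION**2)
            state_mean = mean + (rng.normal(0, between_sd) if between_sd else 0.0)
            path = _ar1_path(state_mean, within_sd, n_years, rng)
            drift = _YEAR_DRIFT.get(name, 0.0)
            if spread > 0 and drift:
                path = path + drift * (np.asarray(years) - mid)
            if name.endswith("_share"):
                path = np.clip(path, 0.0, 100.0)
            if name == "unemployment":
                path = np.clip(path, 0.1, 30.0)
            values[name] = path
        for j, year in enumerate(years):
            rows.append({"state": code, "year": year, **{k: v[j] for k, v in values.items()}})
    return pd.DataFrame(rows)


def generate_panel(config: SyntheticConfig) -> tuple[PanelDataset, SyntheticTruth]:
    """Generate a seeded panel plus its ground truth.

    Log total cost is built as intercept + output elasticities on the two
    participant counts + year effect + v + u, with v Gaussian noise and u
    the one-sided inefficiency from the configured mode.
    """
    rng = np.random.default_rng(config.seed)
    cov = generate_covariates(config, rng)
    years = config.year_list
    last_year = years[-1]
    truth = config.frontier

    # Output counts: total users proportional to population with log-normal
    # dispersion, split by the community-services share.
    rate = config.participation_rate * np.exp(rng.normal(0.0, 0.3, size=len(cov)))
    q_total = np.maximum(cov["population"].to_numpy() * rate, 10.0)
    share = np.clip(cov["hcbs_share"].to_numpy(), 0.5, 99.5)
    q_hcbs = q_total * share / 100.0
    q_inst = q_total * (1 - share / 100.0)

    # trailing entries apply to the years nearest the base (last) year
    effects = truth.year_effects[len(truth.year_effects) - (len(years) - 1):]
    year_effect = {y: e for y, e in zip(years[:-1], effects)}
    year_effect[last_year] = 0.0
    fe = cov["year"].map(year_effect).to_numpy()

    codes = state_codes(config.n_states)
    state_idx = cov["state"].map({c: i for i, c in enumerate(codes)}).to_numpy()

    if config.mode == "bc92":
        u_state = sample_truncated_normal(truth.mu, truth.sigma_u, config.n_states, rng)
        decay = np.exp(-truth.eta * (cov["year"].to_numpy() - last_year))
        u = u_state[state_idx] * decay
    else:
        x = cov.copy()
        x["log_population"] = np.log(x["population"])
        x["log_pc_income"] = np.log(x["pc_income"])
        lin = np.full(len(cov), config.g0)
        for name, coef in config.gamma_truth.items():
            lin += coef * x[name].to_numpy()
        state_eff = rng.normal(0.0, config.state_effect_sd, size=config.n_states)
        noise = rng.normal(0.0, config.u_noise_sd, size=len(cov))
        log_u = lin + state_eff[state_idx] + noise
        log_u -= log_u.mean() + 1.0  # center so typical u is near exp(-1)
        u = np.exp(log_u)
        u_state = np.full(config.n_states, np.nan)

    v = rng.normal(0.0, truth.sigma_v, size=len(cov))
    log_cost = (
        truth.beta0
        + truth.b_hcbs * np.log(q_hcbs)
        + truth.b_inst * np.log(q_inst)
        + fe + v + u
    )

    frame = cov.copy()
    frame["total_cost"] = np.exp(log_cost)
    frame["q_hcbs"] = q_hcbs
    frame["q_inst"] = q_inst
    dataset = PanelDataset(frame, provenance=(f"synthetic mode={config.mode} seed={config.seed}",))

    truth_frame = pd.DataFrame(
        {
            "state": cov["state"], "year": cov["year"],
            "u": u, "v": v, "ce": np.exp(-u),
        }
    )
    truth_obj = SyntheticTruth(
        config=config,
        u_state=pd.Series(u_state, index=codes, name="u_state"),
        frame=truth_frame,
    )
    return dataset, truth_obj
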