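"""Rankings, quartile trends, national averages and rank-correlation checks."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .frontier import ScorePanel

logger = logging.getLogger(__name__)

TIER_LABELS = ("high", "moderate", "low", "very_low")


@dataclass
class RankingTable:
    """Per-state mean scores, ranks (1 = most efficient) and quartile tiers."""

    frame: pd.DataFrame      # index state; columns mean_score, rank, tier
    per_year: pd.DataFrame   # state x year score matrix
    by: str

    def __post_init__(self) -> None:
        ranks = np.sort(self.frame["rank"].to_numpy())
        if not np.array_equal(ranks, np.arange(1, len(self.frame) + 1)):
            raise ConfigurationError("ranks must be a permutation of 1..n_states")


def _tiers(n: int) -> np.ndarray:
    """Quartile tier label for each rank 1..n (sizes differ by at most 1)."""
    sizes = [len(chunk) for chunk in np.array_split(np.arange(n), 4)]
    labels = [label for label, size in zip(TIER_LABELS, sizes) if size]
    return np.repeat(labels, [size for size in sizes if size])


def rank_states(scores: ScorePanel, by: str = "mean", year: int | None = None) -> RankingTable:
    """Rank states by ascending score (lower score = more efficient).

    ``by='mean'`` ranks on the state mean over years; ``by='year'`` on the
    given year.  Ties are broken alphabetically by state code and logged.
    """
    frame = scores.frame
    if frame.empty:
        raise ConfigurationError("cannot rank an empty score panel")
    if by == "mean":
        key = frame.groupby("state")["score"].mean()
    elif by == "year":
        if year is None or year not in set(frame["year"]):
            raise ConfigurationError(f"requested year {year} absent from scores")
        key = frame.loc[frame["year"] == year].set_index("state")["score"]
    else:
        raise ConfigurationError(f"unknown ranking key {by!r}")
    key = key.sort_index()
    dup = key.duplicated(keep=False)
    if dup.any():
        logger.info("score ties broken alphabetically: %s", sorted(key.index[dup]))
    order = key.reset_index().sort_values(["score", "state"])["state"].to_list()
    rank = pd.Series(np.arange(1, len(order) + 1), index=order, name="rank")
    out = pd.DataFrame({"mean_score": key, "rank": rank}).sort_values("rank")
    out["tier"] = _tiers(len(out))
    return RankingTable(frame=out, per_year=scores.wide(), by=by)


@dataclass
class QuartileTrends:
    means: pd.DataFrame        # index tier, columns years, values mean score
    improvement: pd.Series     # per tier: first-year mean minus last-year mean


def quartile_trends(scores: ScorePanel) -> QuartileTrends:
    """Per-quartile, per-year unweighted mean scores plus absolute improvement.

    Quartiles are assigned once, from mean scores across all years."""
    n_states = scores.frame["state"].nunique()
    if n_states < 4:
        raise ConfigurationError(f"need at least 4 states for quartiles, got {n_states}")
    ranking = rank_states(scores, by="mean")
    tier = ranking.frame["tier"]
    frame = scores.frame.merge(tier.rename("tier"), left_on="state", right_index=True)
    means = (
        frame.groupby(["tier", "year"])["score"].mean().unstack("year")
        .reindex([t for t in TIER_LABELS if t in set(tier)])
    )
    improvement = means.iloc[:, 0] - means.iloc[:, -1]
    return QuartileTrends(means=means, improvement=improvement.rename("improvement"))


def national_average(scores: ScorePanel) -> pd.Series:
    """Unweighted mean score per year (states as the unit of analysis).

    In unbalanced panels the mean is taken over the states observed that
    year; the per-year counts are logged."""
    frame = scores.frame
    if frame.empty:
        raise ConfigurationError("empty score panel")
    counts = frame.groupby("year")["state"].nunique()
    if counts.nunique() > 1:
        logger.info("unbalanced panel; per-year state counts: %s", counts.to_dict())
    return frame.groupby("year")["score"].mean().rename("national_mean_score")


def population_weighted_average(scores: ScorePanel, data) -> pd.Series:
    """Population-weighted national mean score per year."""
    merged = scores.frame.merge(
        data.frame[["state", "year", "population"]], on=["state", "year"], how="inner"
    )
    weighted = merged.groupby("year").apply(
        lambda g: float(np.average(g["score"], weights=g["population"])),
        include_groups=False,
    )
    return weighted.rename("national_weighted_score")


def spearman_rank(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value uses exact full-permutation enumeration for n <= 8 and the
    usual t approximation otherwise.  Inputs are paired sequences (aligned
    by position) of equal length >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ConfigurationError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    if n < 3:
        raise ConfigurationError("need at least 3 pairs")
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= 8:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        observed = abs(_pearson(rx, ry))
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_pearson(rx, np.asarray(perm))) >= observed - 1e-12:
                count += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else 0.0


def score_table(scores: ScorePanel) -> pd.DataFrame:
    """State x year score matrix ordered by rank, with an all-states mean row."""
    ranking = rank_states(scores, by="mean")
    wide = ranking.per_year.reindex(ranking.frame.index)
    wide.loc["ALL"] = national_average(scores)
    return wide
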