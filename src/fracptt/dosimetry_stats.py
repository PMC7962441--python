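"""Tumor-outcome analysis: caliper volumes, growth curves, exact rank tests.

The in-vivo arm of a photothermal-therapy comparison is small (n = 4 mice
per group) and ordinal/skewed, so group comparisons use *exact*
nonparametric tests: the Mann-Whitney U two-sample test with its null
distribution enumerated over all C(n_a+n_b, n_a) group labelings
(midranks for ties, so the enumeration is tie-aware), and the
Kruskal-Wallis H test with tie correction, enumerated exactly for small
total n and falling back to the chi-square approximation otherwise.
Pairwise p-values are Bonferroni-corrected.

Tumor volume follows the standard caliper ellipsoid formula
``V = l * w^2 / 2`` with l >= w in mm.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "CaliperTable",
    "GroupComparison",
    "tumor_volume",
    "growth_trajectories",
    "fit_log_growth",
    "mann_whitney_exact",
    "kruskal_wallis",
    "bonferroni",
    "score_comparison",
]

GROUPS = ("control", "flat", "mla")
DAYS = (0, 3, 7, 14)


@dataclass(frozen=True)
class GroupComparison:
    """One test result: statistic, exact/approximate p, corrected p."""

    test: str  # "mann-whitney-exact" | "kruskal-wallis-exact" | "kruskal-wallis-chi2"
    statistic: float
    p_value: float
    p_corrected: float
    n_per_group: tuple
    method: str = "exact"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CaliperTable:
    """Per-animal, per-day tumor length/width measurements.

    Columns: ``animal_id, group, day, length_mm, width_mm``.  Length is the
    longest axis; rows arriving with width > length are swapped with a log
    entry rather than rejected (caliper axes are easy to transpose in the
    field).
    """

    df: pd.DataFrame

    REQUIRED = ("animal_id", "group", "day", "length_mm", "width_mm")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.df).copy()
        missing = set(self.REQUIRED) - set(df.columns)
        if missing:
            raise ValueError(f"caliper table missing columns: {sorted(missing)}")
        if (df["length_mm"] <= 0).any() or (df["width_mm"] <= 0).any():
            raise ValueError("length and width must be positive")
        swapped = df["width_mm"] > df["length_mm"]
        if swapped.any():
            logger.warning(
                "caliper axes swapped (width > length) in %d row(s); auto-correcting",
                int(swapped.sum()),
            )
            l = df.loc[swapped, "width_mm"].copy()
            df.loc[swapped, "width_mm"] = df.loc[swapped, "length_mm"]
            df.loc[swapped, "length_mm"] = l
        dup = df.duplicated(subset=["animal_id", "day"])
        if dup.any():
            raise ValueError("duplicate (animal_id, day) measurements")
        self.df = df

    def with_volumes(self) -> pd.DataFrame:
        out = self.df.copy()
        out["volume_mm3"] = tumor_volume(
            out["length_mm"].to_numpy(), out["width_mm"].to_numpy()
        )
        return out

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CaliperTable":
        return cls(pd.read_csv(path))


def tumor_volume(length_mm, width_mm):
    """Caliper tumor volume ``V = l * w^2 / 2`` (mm^3); strictly increasing in both."""
    l = np.asarray(length_mm, float)
    w = np.asarray(width_mm, float)
    if np.any(l <= 0) or np.any(w <= 0):
        raise ValueError("length and width must be positive")
    out = l * w**2 / 2.0
    return out if out.ndim else float(out)


def growth_trajectories(table: CaliperTable, normalize: bool = False):
    """Per-group mean +/- sd volume versus day.

    With ``normalize`` each animal's trajectory is divided by its own day-0
    volume; animals lacking a day-0 measurement are then excluded (logged).
    Returns ``(summary, per_animal)`` DataFrames; summary columns are
    ``group, day, mean, sd, n``.
    """
    df = table.with_volumes()
    wide = df.pivot(index="animal_id", columns="day", values="volume_mm3")
    groups = df.groupby("animal_id")["group"].first()
    if normalize:
        if 0 not in wide.columns:
            raise ValueError("normalization requires day-0 measurements")
        has0 = wide[0].notna()
        dropped = wide.index[~has0]
        if len(dropped):
            logger.warning(
                "excluding %d animal(s) without day-0 measurement: %s",
                len(dropped),
                list(dropped),
            )
        wide = wide.loc[has0].div(wide.loc[has0, 0], axis=0)
    long = (
        wide.reset_index()
        .melt(id_vars="animal_id", var_name="day", value_name="volume")
        .dropna()
    )
    long["group"] = long["animal_id"].map(groups)
    summary = (
        long.groupby(["group", "day"])["volume"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    return summary, long


def fit_log_growth(days, volumes) -> float:
    """Least-squares slope of ln(V) vs day — the exponential growth rate /day."""
    days = np.asarray(days, float)
    volumes = np.asarray(volumes, float)
    if np.any(volumes <= 0):
        raise ValueError("volumes must be positive for log-slope fitting")
    res = sps.linregress(days, np.log(volumes))
    return float(res.slope)


# --------------------------------------------------------------------------
# exact rank tests


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney_exact(a, b, m_comparisons: int = 1) -> GroupComparison:
    """Exact two-sided Mann-Whitney U test by full enumeration.

    The U statistic is computed from midranks of the pooled sample (so ties
    are handled), and the two-sided p-value is the fraction of all
    C(n_a+n_b, n_a) group labelings whose U deviates from the null mean
    ``n_a n_b / 2`` at least as far as the observed one — a tie-aware
    permutation null.  Feasible comfortably up to n ~ 10 + 10.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing values are not supported")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    U_obs = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    mu = na * nb / 2.0
    dev_obs = abs(U_obs - mu)
    idx = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(na + nb), na)),
        dtype=np.intp,
    ).reshape(-1, na)
    U_all = ranks[idx].sum(axis=1) - na * (na + 1) / 2.0
    p = float(np.mean(np.abs(U_all - mu) >= dev_obs - 1e-9))
    return GroupComparison(
        test="mann-whitney-exact",
        statistic=U_obs,
        p_value=p,
        p_corrected=bonferroni(p, m_comparisons),
        n_per_group=(na, nb),
        method="exact-enumeration",
    )


def _kw_H(ranks: np.ndarray, sizes: list[int], tie_term: float) -> float:
    N = len(ranks)
    H = 0.0
    start = 0
    for n in sizes:
        R = ranks[start : start + n].sum()
        H += R * R / n
        start += n
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    return H / tie_term if tie_term > 0 else 0.0


def kruskal_wallis(groups, exact_max_n: int = 12, m_comparisons: int = 1) -> GroupComparison:
    """Kruskal-Wallis H with tie correction; exact enumeration for small n.

    For total n <= ``exact_max_n`` the p-value enumerates every partition
    of the pooled midranks into groups of the observed sizes; larger
    samples use the chi-square approximation with df = (#groups - 1).
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = _midranks(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - float(np.sum(counts**3 - counts)) / (N**3 - N) if N > 1 else 1.0
    H_obs = _kw_H(ranks, sizes, tie_term)
    if tie_term == 0.0:  # every observation identical
        return GroupComparison(
            "kruskal-wallis-exact", 0.0, 1.0, bonferroni(1.0, m_comparisons),
            tuple(sizes), "degenerate-ties",
        )
    if N <= exact_max_n:
        count_ge = 0
        total = 0
        idx_all = list(range(N))

        def rec(remaining: tuple, gi: int, chosen_ranks: list):
            nonlocal count_ge, total
            if gi == len(sizes) - 1:
                sums = chosen_ranks + [ranks[list(remaining)].sum()]
                H = (
                    12.0 / (N * (N + 1)) * sum(s * s / n for s, n in zip(sums, sizes))
                    - 3.0 * (N + 1)
                ) / tie_term
                total += 1
                if H >= H_obs - 1e-9:
                    count_ge += 1
                return
            for comb in itertools.combinations(remaining, sizes[gi]):
                rest = tuple(x for x in remaining if x not in comb)
                rec(rest, gi + 1, chosen_ranks + [ranks[list(comb)].sum()])

        rec(tuple(idx_all), 0, [])
        p = count_ge / total
        method = "exact-enumeration"
        test = "kruskal-wallis-exact"
    else:
        p = float(sps.chi2.sf(H_obs, df=len(sizes) - 1))
        method = "chi2-approximation"
        test = "kruskal-wallis-chi2"
    return GroupComparison(
        test=test,
        statistic=float(H_obs),
        p_value=float(p),
        p_corrected=bonferroni(float(p), m_comparisons),
        n_per_group=tuple(sizes),
        method=method,
    )


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value, ``min(1, m p)``."""
    if not (0 < p <= 1):
        raise ValueError("p must lie in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def score_comparison(scores: dict) -> dict:
    """Omnibus + pairwise comparison of ordinal (1-3) histology scores.

    ``scores`` maps group name -> list of per-sample scores.  Returns a dict
    with the Kruskal-Wallis omnibus result and all pairwise tie-aware exact
    Mann-Whitney tests, Bonferroni-corrected by the number of pairs.
    """
    for g, vals in scores.items():
        if any(v not in (1, 2, 3) for v in vals):
            raise ValueError(f"scores in group {g!r} must be in {{1, 2, 3}}")
    names = list(scores)
    kw = kruskal_wallis([scores[g] for g in names])
    pairs = list(itertools.combinations(names, 2))
    out = {"kruskal_wallis": kw, "pairwise": {}}
    for g1, g2 in pairs:
        out["pairwise"][f"{g1}_vs_{g2}"] = mann_whitney_exact(
            scores[g1], scores[g2], m_comparisons=len(pairs)
        )
    return out
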