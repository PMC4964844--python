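"""Kruskal-Wallis rank test, implemented from its definition.

The K-group rank test used throughout the analysis: pooled midranks, the
statistic

    H = [ 12 / (N (N+1)) * sum_i R_i^2 / n_i - 3 (N+1) ] / C,

with C = 1 - sum(t^3 - t) / (N^3 - N) the tie correction over tie-group
sizes t, compared against a chi-square distribution with k-1 degrees of
freedom.  A permutation p-value (exact enumeration for small samples,
Monte Carlo otherwise) serves as the finite-sample reference for the
chi-square approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaincc
from scipy.stats import rankdata

from .errors import DomainError, InsufficientDataError

__all__ = ["KWResult", "kruskal_wallis", "kw_permutation_p", "daily_tests"]


@dataclass
class KWResult:
    """Kruskal-Wallis statistic with its chi-square (and optional permutation) p.

    ``tie_correction`` is the divisor C in (0, 1]; C = 1 means no ties.
    When every pooled value is identical the statistic is defined as 0
    with p = 1 (the no-evidence limit) rather than raising on the
    degenerate 0/0 correction.
    """

    h: float
    df: int
    p_chisq: float
    tie_correction: float = 1.0
    p_perm: float | None = None


def _validate_groups(groups) -> list[np.ndarray]:
    if len(groups) < 2:
        raise InsufficientDataError(f"need >= 2 groups, got {len(groups)}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size == 0:
            raise InsufficientDataError(f"group {i} is empty")
        if not np.all(np.isfinite(g)):
            raise DomainError(f"group {i} contains non-finite values")
    if sum(g.size for g in arrays) < 3:
        raise InsufficientDataError("need at least 3 observations in total")
    return arrays


def _h_from_ranks(ranks: np.ndarray, sizes: np.ndarray, tie_c: float) -> float:
    """H for one assignment of the pooled ranks to groups of the given sizes."""
    n_total = ranks.size
    bounds = np.cumsum(sizes)[:-1]
    rank_sums = np.array([r.sum() for r in np.split(ranks, bounds)])
    h = 12.0 / (n_total * (n_total + 1)) * np.sum(rank_sums**2 / sizes) - 3.0 * (n_total + 1)
    return h / tie_c


def _ranks_and_correction(pooled: np.ndarray) -> tuple[np.ndarray, float]:
    ranks = rankdata(pooled)  # midranks
    n_total = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_c = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    return ranks, tie_c


def chisq_sf(x: float, df: int) -> float:
    """Upper-tail chi-square probability via the regularized incomplete gamma."""
    if x < 0:
        raise DomainError(f"x must be >= 0, got {x}")
    if df < 1:
        raise DomainError(f"df must be >= 1, got {df}")
    return float(gammaincc(df / 2.0, x / 2.0))


def kruskal_wallis(groups) -> KWResult:
    """Rank test for a location difference among k independent groups.

    Parameters
    ----------
    groups : sequence of k >= 2 non-empty value sequences (total N >= 3).

    Returns
    -------
    :class:`KWResult` with the tie-corrected H, df = k - 1 and the
    chi-square upper-tail p-value.
    """
    arrays = _validate_groups(groups)
    sizes = np.array([g.size for g in arrays])
    pooled = np.concatenate(arrays)
    df = len(arrays) - 1
    ranks, tie_c = _ranks_and_correction(pooled)
    if tie_c <= 0.0:
        # all N values identical: no evidence of any group difference
        return KWResult(h=0.0, df=df, p_chisq=1.0, tie_correction=1.0)
    h = _h_from_ranks(ranks, sizes, tie_c)
    h = max(h, 0.0)  # guard tiny negative rounding
    return KWResult(h=h, df=df, p_chisq=chisq_sf(h, df), tie_correction=tie_c)


def _distinct_assignments(n_total: int, sizes: np.ndarray):
    """Yield index tuples assigning pooled positions to groups, one per
    distinct partition of the N positions into groups of the given sizes."""
    positions = set(range(n_total))

    def rec(remaining: frozenset, gi: int, acc: list):
        if gi == len(sizes) - 1:
            yield acc + [tuple(sorted(remaining))]
            return
        for combo in itertools.combinations(sorted(remaining), sizes[gi]):
            yield from rec(remaining - set(combo), gi + 1, acc + [combo])

    yield from rec(frozenset(positions), 0, [])


def kw_permutation_p(groups, n_permutations: int | None = None, seed: int = 0) -> float:
    """Permutation p-value for the Kruskal-Wallis statistic.

    With ``n_permutations=None`` every distinct assignment of the pooled
    observations to groups of the observed sizes is enumerated and the
    p-value is the exact fraction with H at least the observed value
    (feasible for small samples only).  Otherwise ``n_permutations``
    random label shuffles are drawn and the add-one-smoothed estimate
    (b + 1) / (m + 1) is returned, which never reports exactly 0.
    """
    arrays = _validate_groups(groups)
    sizes = np.array([g.size for g in arrays])
    pooled = np.concatenate(arrays)
    ranks, tie_c = _ranks_and_correction(pooled)
    if tie_c <= 0.0:
        return 1.0
    h_obs = max(_h_from_ranks(ranks, sizes, tie_c), 0.0)
    tol = 1e-12
    if n_permutations is None:
        count = 0
        total = 0
        for assignment in _distinct_assignments(pooled.size, sizes):
            perm_ranks = np.concatenate([ranks[list(idx)] for idx in assignment])
            if _h_from_ranks(perm_ranks, sizes, tie_c) >= h_obs - tol:
                count += 1
            total += 1
        return count / total
    if n_permutations < 1:
        raise DomainError(f"n_permutations must be >= 1, got {n_permutations}")
    rng = np.random.default_rng(seed)
    n_total = ranks.size
    bounds = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    exceed = 0
    done = 0
    while done < n_permutations:
        m = min(500, n_permutations - done)
        perm = rng.permuted(np.tile(ranks, (m, 1)), axis=1)
        rank_sums = np.add.reduceat(perm, bounds, axis=1)
        h = 12.0 / (n_total * (n_total + 1)) * np.sum(rank_sums**2 / sizes, axis=1) - 3.0 * (
            n_total + 1
        )
        exceed += int(np.sum(h / tie_c >= h_obs - tol))
        done += m
    return (exceed + 1) / (n_permutations + 1)


def daily_tests(
    dt_table: pd.DataFrame,
    grouping: str = "all-four",
    control_label: str = "control",
    n_permutations: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-day Kruskal-Wallis tests on a ``Day, Phages, dt`` table.

    ``grouping='all-four'`` compares every treatment (control included;
    with the 4-treatment design df = 3); ``grouping='exposed-only'``
    drops the control and compares the phage-density treatments against
    each other (df = 2 with three densities).  Rows whose doubling time
    is flagged (NaN) are excluded from the ranks; a day left with fewer
    than two groups is flagged in the output rather than dropped.

    Returns a table with columns
    ``day, grouping, k, df, H, p_chisq, p_perm, flagged``.
    """
    if grouping not in ("all-four", "exposed-only"):
        raise DomainError(f"unknown grouping {grouping!r}")
    required = {"Day", "Phages", "dt"}
    if not required.issubset(dt_table.columns):
        raise DomainError(f"dt table must have columns {sorted(required)}")
    rows = []
    for day, day_table in dt_table.groupby("Day", sort=True):
        if grouping == "exposed-only":
            day_table = day_table[day_table["Phages"] != control_label]
        day_table = day_table.dropna(subset=["dt"])
        groups = [g["dt"].to_numpy() for _, g in day_table.groupby("Phages", sort=True)]
        base = {"day": int(day), "grouping": grouping, "k": len(groups)}
        if len(groups) < 2 or sum(len(g) for g in groups) < 3:
            rows.append(
                {**base, "df": np.nan, "H": np.nan, "p_chisq": np.nan, "p_perm": np.nan, "flagged": True}
            )
            continue
        res = kruskal_wallis(groups)
        p_perm = (
            kw_permutation_p(groups, n_permutations=n_permutations, seed=seed)
            if n_permutations
            else np.nan
        )
        rows.append(
            {
                **base,
                "df": res.df,
                "H": res.h,
                "p_chisq": res.p_chisq,
                "p_perm": p_perm,
                "flagged": False,
            }
        )
    return pd.DataFrame(rows, columns=["day", "grouping", "k", "df", "H", "p_chisq", "p_perm", "flagged"])
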