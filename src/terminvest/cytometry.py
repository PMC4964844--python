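"""Event-level flow-cytometry summaries and distribution comparisons.

Cell size is read from the forward-scatter (FSC) channel; side scatter
(SSC, granularity) is summarized alongside but not interpreted.  Samples
are compared with per-sample summaries (mean/sd/median), the control:
treated mean-FSC ratio, and a permutation two-sample test on the
ECDF-supremum distance D = sup_x |F_a(x) - F_b(x)| — no asymptotic
approximation, so subsampled event sets are handled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError, LengthMismatchError

__all__ = [
    "CytometrySample",
    "SampleSummary",
    "KSTestResult",
    "summarize",
    "summarize_table",
    "size_ratio",
    "ks_two_sample",
    "compare_table",
    "DEFAULT_COMPARISON_SUBSAMPLE",
]

#: Events per sample used in the permutation loop (summaries use all events).
DEFAULT_COMPARISON_SUBSAMPLE = 10_000


@dataclass
class CytometrySample:
    """Per-event forward/side scatter values of one (day, treatment) sample."""

    day: int
    treatment: str
    fsc: np.ndarray
    ssc: np.ndarray

    def __post_init__(self) -> None:
        self.fsc = np.asarray(self.fsc, dtype=float)
        self.ssc = np.asarray(self.ssc, dtype=float)
        if len(self.fsc) != len(self.ssc):
            raise LengthMismatchError(
                f"fsc ({len(self.fsc)}) and ssc ({len(self.ssc)}) lengths differ"
            )
        if len(self.fsc) < 1:
            raise InsufficientDataError("empty cytometry sample")
        for name, values in (("fsc", self.fsc), ("ssc", self.ssc)):
            if not np.all(np.isfinite(values)) or np.any(values < 0):
                raise DomainError(f"{name} values must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.fsc)


@dataclass
class SampleSummary:
    day: int
    treatment: str
    n_events: int
    mean_fsc: float
    sd_fsc: float
    median_fsc: float
    mean_ssc: float
    sd_ssc: float


@dataclass
class KSTestResult:
    """ECDF-supremum distance with its permutation p-value."""

    d: float
    p_perm: float
    n_permutations: int


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def summarize(sample: CytometrySample) -> SampleSummary:
    """Mean/sd/median forward scatter and mean/sd side scatter of a sample."""
    return SampleSummary(
        day=sample.day,
        treatment=sample.treatment,
        n_events=len(sample),
        mean_fsc=float(np.mean(sample.fsc)),
        sd_fsc=_sd(sample.fsc),
        median_fsc=float(np.median(sample.fsc)),
        mean_ssc=float(np.mean(sample.ssc)),
        sd_ssc=_sd(sample.ssc),
    )


_CYTO_COLUMNS = ["day", "treatment", "event", "fsc", "ssc"]


def samples_from_table(table: pd.DataFrame) -> list[CytometrySample]:
    """Split an event table (``day,treatment,event,fsc,ssc``) into samples."""
    missing = [c for c in _CYTO_COLUMNS if c not in table.columns]
    if missing:
        raise DomainError(f"cytometry table missing columns: {missing}")
    return [
        CytometrySample(
            day=int(day),
            treatment=str(treatment),
            fsc=grp["fsc"].to_numpy(float),
            ssc=grp["ssc"].to_numpy(float),
        )
        for (day, treatment), grp in table.groupby(["day", "treatment"], sort=True)
    ]


def summarize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(day, treatment) summaries of an event table."""
    rows = [summarize(s).__dict__ for s in samples_from_table(table)]
    return pd.DataFrame(
        rows,
        columns=["day", "treatment", "n_events", "mean_fsc", "sd_fsc", "median_fsc", "mean_ssc", "sd_ssc"],
    )


def size_ratio(reference: SampleSummary, treated: SampleSummary) -> float:
    """Fold change in mean cell size: reference mean FSC over treated mean FSC.

    A ratio of 2.5 means treated cells scatter 2.5x less forward light on
    average, i.e. are substantially smaller than the reference.
    """
    if treated.mean_fsc <= 0:
        raise DomainError(f"treated mean_fsc must be > 0, got {treated.mean_fsc}")
    if reference.mean_fsc <= 0:
        raise DomainError(f"reference mean_fsc must be > 0, got {reference.mean_fsc}")
    return reference.mean_fsc / treated.mean_fsc


def _ecdf_sup_distance(a: np.ndarray, b: np.ndarray) -> float:
    """D = sup_x |ECDF_a(x) - ECDF_b(x)| evaluated over the pooled support."""
    a = np.sort(a)
    b = np.sort(b)
    support = np.concatenate([a, b])
    fa = np.searchsorted(a, support, side="right") / len(a)
    fb = np.searchsorted(b, support, side="right") / len(b)
    return float(np.max(np.abs(fa - fb)))


def ks_two_sample(
    a, b, n_permutations: int = 999, seed: int = 0, batch: int = 200
) -> KSTestResult:
    """Two-sample ECDF-supremum test with a permutation p-value.

    D is the largest vertical gap between the two empirical CDFs; the
    p-value is estimated by shuffling the pooled sample labels
    ``n_permutations`` times with add-one smoothing, (b + 1) / (m + 1).
    The permutation loop exploits that, on the sorted pooled values, D is
    the maximum absolute value of a cumulative sum of +-1/n increments,
    evaluated at the last index of each distinct value (midrank-safe under
    ties); only the label vector has to be permuted.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    if n_permutations < 1:
        raise DomainError(f"n_permutations must be >= 1, got {n_permutations}")
    d_obs = _ecdf_sup_distance(a, b)

    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    sorted_vals = pooled[order]
    # D may only be attained at the last occurrence of each distinct value
    last_of_value = np.empty(pooled.size, dtype=bool)
    last_of_value[:-1] = sorted_vals[1:] != sorted_vals[:-1]
    last_of_value[-1] = True
    increments = np.where(np.arange(pooled.size) < a.size, 1.0 / a.size, -1.0 / b.size)

    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_permutations:
        m = min(batch, n_permutations - done)
        perms = np.tile(increments, (m, 1))
        perms = rng.permuted(perms, axis=1)
        gaps = np.abs(np.cumsum(perms, axis=1))[:, last_of_value]
        exceed += int(np.sum(gaps.max(axis=1) >= d_obs - 1e-12))
        done += m
    return KSTestResult(d=d_obs, p_perm=(exceed + 1) / (n_permutations + 1), n_permutations=n_permutations)


def compare_table(
    table: pd.DataFrame,
    channel: str = "fsc",
    reference: str = "control",
    n_permutations: int = 999,
    seed: int = 0,
    subsample: int | None = DEFAULT_COMPARISON_SUBSAMPLE,
) -> pd.DataFrame:
    """Per-day distribution tests of every treatment against the reference.

    Events are subsampled (without replacement, seeded) to ``subsample``
    per group before the permutation loop; summaries elsewhere always use
    the full data.  Returns columns ``day, pair, D, p_perm``.
    """
    if channel not in ("fsc", "ssc"):
        raise DomainError(f"channel must be 'fsc' or 'ssc', got {channel!r}")
    samples = samples_from_table(table)
    rng = np.random.default_rng(seed)
    rows = []
    by_day: dict[int, dict[str, CytometrySample]] = {}
    for s in samples:
        by_day.setdefault(s.day, {})[s.treatment] = s
    for day in sorted(by_day):
        day_samples = by_day[day]
        if reference not in day_samples:
            raise DomainError(f"day {day}: reference treatment {reference!r} missing")
        ref_values = getattr(day_samples[reference], channel)
        for treatment in sorted(day_samples):
            if treatment == reference:
                continue
            trt_values = getattr(day_samples[treatment], channel)
            x, y = ref_values, trt_values
            if subsample is not None:
                if len(x) > subsample:
                    x = rng.choice(x, size=subsample, replace=False)
                if len(y) > subsample:
                    y = rng.choice(y, size=subsample, replace=False)
            res = ks_two_sample(
                x, y, n_permutations=n_permutations, seed=int(rng.integers(2**31 - 1))
            )
            rows.append(
                {"day": day, "pair": f"{reference} vs {treatment}", "D": res.d, "p_perm": res.p_perm}
            )
    return pd.DataFrame(rows, columns=["day", "pair", "D", "p_perm"])
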