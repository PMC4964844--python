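"""Synthetic growth-curve, cytometry and phage-binding data generators.

These emulate the structure of the experiment's two deposited data
streams — daily OD650 growth curves for four treatments (a no-phage
control plus three inactivated-phage densities) over four days, and
event-level flow-cytometry scatter tables — together with per-cell
bound-phage counts, so every downstream stage of the analysis can be
exercised, and validated against a known truth table, without any
external data.

Growth curves follow a three-phase model: a flat lag at the inoculum
density, a pure exponential segment at the replicate's true specific
growth rate, and a logistic approach to carrying capacity once half of
K is reached, plus additive Gaussian read noise truncated at a positive
floor.  The per-day, per-treatment rate multipliers (the "effect
profile") encode the qualitative phage response: faster growth on day 1
scaling with phage density, a compensatory slowdown on days 2-3, and a
return to baseline by day 4.

All generators are deterministic for a fixed (configuration, seed) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, InvalidDesignError

__all__ = [
    "TREATMENTS",
    "PHAGE_DENSITY_PER_ML",
    "ExperimentDesign",
    "GrowthBaseline",
    "CytometryTruth",
    "default_effect_profile",
    "default_cytometry_truth",
    "generate_growth_dataset",
    "generate_cytometry_dataset",
    "generate_binding_counts",
]

#: Treatment labels, ordered: no-phage control, then phage:bacteria ratios
#: 1:10, 1:2 and 1:1.
TREATMENTS = ("control", "ratio_1_10", "ratio_1_2", "ratio_1_1")

#: Inactivated-phage density of each treatment, particles per ml.
PHAGE_DENSITY_PER_ML = {
    "control": 0.0,
    "ratio_1_10": 1e6,
    "ratio_1_2": 5e6,
    "ratio_1_1": 1e7,
}


@dataclass
class ExperimentDesign:
    """Shape of the exposure experiment.

    Defaults mirror the study design: 4 treatments x 6 replicates
    followed for 4 days with 250 OD650 reads per 24-hour growth period.
    """

    treatments: tuple[str, ...] = TREATMENTS
    phage_density_per_ml: dict[str, float] = field(
        default_factory=lambda: dict(PHAGE_DENSITY_PER_ML)
    )
    n_days: int = 4
    replicates_per_treatment: int = 6
    reads_per_day: int = 250
    read_span_h: float = 24.0

    def __post_init__(self) -> None:
        if len(set(self.treatments)) != len(self.treatments):
            raise InvalidDesignError("treatment labels must be unique")
        missing = [t for t in self.treatments if t not in self.phage_density_per_ml]
        if missing:
            raise InvalidDesignError(f"no phage density for treatments: {missing}")
        if any(d < 0 for d in self.phage_density_per_ml.values()):
            raise InvalidDesignError("phage densities must be non-negative")
        if self.n_days < 1:
            raise InvalidDesignError(f"n_days must be >= 1, got {self.n_days}")
        if self.replicates_per_treatment < 1:
            raise InvalidDesignError(
                f"replicates_per_treatment must be >= 1, got {self.replicates_per_treatment}"
            )
        if self.reads_per_day < 3:
            raise InvalidDesignError(f"reads_per_day must be >= 3, got {self.reads_per_day}")
        if self.read_span_h <= 0:
            raise InvalidDesignError(f"read_span_h must be > 0, got {self.read_span_h}")

    @property
    def days(self) -> range:
        return range(1, self.n_days + 1)


@dataclass
class GrowthBaseline:
    """Baseline growth-curve parameters shared by every well.

    The defaults describe a fast-growing pseudomonad in rich medium:
    specific growth rate 0.5/h (doubling time ~1.4 h), 1.5 h lag,
    carrying capacity 1.0 OD, inoculum 0.01 OD (a 1% transfer of a
    saturated culture).  ``rate_cv`` is the
    lognormal coefficient of variation of the replicate-level true rate
    around its treatment/day value; ``noise_sd`` is the additive OD read
    noise (truncated so OD stays above ``od_floor``).
    """

    r_per_h: float = 0.5
    lag_h: float = 1.5
    n_init: float = 0.01
    carrying_capacity: float = 1.0
    noise_sd: float = 0.01
    rate_cv: float = 0.02
    od_floor: float = 1e-4

    def __post_init__(self) -> None:
        if self.r_per_h <= 0:
            raise InvalidDesignError(f"r_per_h must be > 0, got {self.r_per_h}")
        if not 0 < self.n_init < self.carrying_capacity:
            raise InvalidDesignError(
                f"need 0 < n_init < carrying_capacity, got {self.n_init} vs {self.carrying_capacity}"
            )
        if self.lag_h < 0 or self.noise_sd < 0 or self.rate_cv < 0:
            raise InvalidDesignError("lag_h, noise_sd and rate_cv must be >= 0")
        if self.od_floor <= 0:
            raise InvalidDesignError(f"od_floor must be > 0, got {self.od_floor}")


def default_effect_profile(design: ExperimentDesign | None = None) -> dict[int, dict[str, float]]:
    """Per-day, per-treatment multipliers on the baseline growth rate.

    Encodes the qualitative response pattern: exposed populations grow
    faster on day 1 (up to 1.9x at the highest phage density, scaling
    with density), slower on days 2-3 (the compensatory cost), and match
    the control again on day 4.  Magnitudes are package choices — only
    the pattern is meaningful.
    """
    design = design or ExperimentDesign()
    day_effects = {
        1: {"control": 1.0, "ratio_1_10": 1.5, "ratio_1_2": 1.7, "ratio_1_1": 1.9},
        2: {"control": 1.0, "ratio_1_10": 0.85, "ratio_1_2": 0.80, "ratio_1_1": 0.75},
        3: {"control": 1.0, "ratio_1_10": 0.92, "ratio_1_2": 0.90, "ratio_1_1": 0.88},
        4: {"control": 1.0, "ratio_1_10": 1.0, "ratio_1_2": 1.0, "ratio_1_1": 1.0},
    }
    profile = {}
    for day in design.days:
        effects = day_effects.get(day, {t: 1.0 for t in design.treatments})
        profile[day] = {t: effects.get(t, 1.0) for t in design.treatments}
    return profile


def _three_phase_od(times: np.ndarray, r: float, lag: float, n_init: float, k: float) -> np.ndarray:
    """Lag -> pure exponential -> logistic cap at K.

    The exponential segment is exact (so rate recovery on noiseless
    curves is exact too); once density reaches K/2 the curve continues as
    the logistic K / (1 + exp(-r (t - t_half))), which is value-continuous
    at the switch and saturates at K.
    """
    t_half = lag + np.log(k / (2.0 * n_init)) / r
    od = np.where(
        times <= lag,
        n_init,
        np.where(
            times <= t_half,
            n_init * np.exp(r * np.clip(times - lag, 0.0, None)),
            k / (1.0 + np.exp(-r * (times - t_half))),
        ),
    )
    return od


def generate_growth_dataset(
    design: ExperimentDesign | None = None,
    effect_profile: dict[int, dict[str, float]] | None = None,
    seed: int = 0,
    baseline: GrowthBaseline | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one growth curve per (treatment, day, replicate).

    Returns
    -------
    (curves, truth)
        ``curves`` is a long table with columns
        ``well, day, treatment, replicate, time_h, od650``; ``truth``
        holds one row per curve with the true rate (baseline rate x
        day/treatment multiplier x replicate jitter), lag, carrying
        capacity, inoculum density and noise sd used, for
        parameter-recovery checks.

    Raises
    ------
    InvalidDesignError
        If any effect multiplier is not strictly positive.
    """
    design = design or ExperimentDesign()
    baseline = baseline or GrowthBaseline()
    profile = effect_profile if effect_profile is not None else default_effect_profile(design)
    for day in design.days:
        for t in design.treatments:
            mult = profile.get(day, {}).get(t, 1.0)
            if mult <= 0:
                raise InvalidDesignError(
                    f"effect multiplier for day {day}, treatment {t!r} must be > 0, got {mult}"
                )
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, design.read_span_h, design.reads_per_day)
    curve_frames = []
    truth_rows = []
    for day in design.days:
        for treatment in design.treatments:
            mult = profile.get(day, {}).get(treatment, 1.0)
            for rep in range(1, design.replicates_per_treatment + 1):
                jitter = (
                    rng.lognormal(mean=0.0, sigma=baseline.rate_cv)
                    if baseline.rate_cv > 0
                    else 1.0
                )
                r = baseline.r_per_h * mult * jitter
                od = _three_phase_od(
                    times, r, baseline.lag_h, baseline.n_init, baseline.carrying_capacity
                )
                if baseline.noise_sd > 0:
                    od = od + rng.normal(0.0, baseline.noise_sd, size=od.shape)
                od = np.maximum(od, baseline.od_floor)
                well = f"d{day}_{treatment}_r{rep}"
                curve_frames.append(
                    pd.DataFrame(
                        {
                            "well": well,
                            "day": day,
                            "treatment": treatment,
                            "replicate": rep,
                            "time_h": times,
                            "od650": od,
                        }
                    )
                )
                truth_rows.append(
                    {
                        "well": well,
                        "day": day,
                        "treatment": treatment,
                        "replicate": rep,
                        "r_per_h": r,
                        "multiplier": mult,
                        "lag_h": baseline.lag_h,
                        "n_init": baseline.n_init,
                        "carrying_capacity": baseline.carrying_capacity,
                        "noise_sd": baseline.noise_sd,
                    }
                )
    curves = pd.concat(curve_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return curves, truth


@dataclass
class CytometryTruth:
    """Log-scale scatter distributions per (day, treatment).

    ``fsc_meanlog``/``ssc_meanlog`` map (day, treatment) to the location
    of the lognormal forward/side-scatter distribution; ``fsc_sdlog`` and
    ``ssc_sdlog`` are the shared log-scale dispersions.  ``events`` is the
    number of recorded objects per sample (default 2x10^5 cells).
    """

    fsc_meanlog: dict[tuple[int, str], float]
    ssc_meanlog: dict[tuple[int, str], float]
    fsc_sdlog: float = 0.25
    ssc_sdlog: float = 0.25
    events: int = 200_000

    def __post_init__(self) -> None:
        if self.fsc_sdlog <= 0 or self.ssc_sdlog <= 0:
            raise InvalidDesignError("scatter dispersions must be > 0")
        if self.events < 1:
            raise InvalidDesignError(f"events must be >= 1, got {self.events}")
        if set(self.fsc_meanlog) != set(self.ssc_meanlog):
            raise InvalidDesignError("fsc and ssc truth must cover the same (day, treatment) keys")

    def mean_fsc(self, day: int, treatment: str) -> float:
        """Linear-scale mean forward scatter implied by the lognormal truth."""
        return float(np.exp(self.fsc_meanlog[(day, treatment)] + self.fsc_sdlog**2 / 2))


def default_cytometry_truth(
    design: ExperimentDesign | None = None,
    control_fsc_meanlog: float = np.log(250.0),
    size_ratio_by_day: dict[int, float] | None = None,
    events: int = 200_000,
) -> CytometryTruth:
    """Truth table encoding the observed cell-size response.

    Exposed cells are ``size_ratio_by_day[day]`` times smaller in mean
    forward scatter than the control (default: 2.5x on day 1, attenuating
    to 1.3x by day 4 without returning to baseline — exposed cells end
    the experiment still smaller).  The shift is identical for all three
    phage densities, and side scatter is left unshifted.
    """
    design = design or ExperimentDesign()
    ratios = size_ratio_by_day or {1: 2.5, 2: 2.0, 3: 1.6, 4: 1.3}
    fsc = {}
    ssc = {}
    ssc_meanlog = np.log(120.0)
    for day in design.days:
        ratio = ratios.get(day, 1.0)
        if ratio <= 0:
            raise InvalidDesignError(f"size ratio for day {day} must be > 0, got {ratio}")
        for treatment in design.treatments:
            shift = 0.0 if treatment == "control" else np.log(ratio)
            fsc[(day, treatment)] = control_fsc_meanlog - shift
            ssc[(day, treatment)] = ssc_meanlog
    return CytometryTruth(fsc_meanlog=fsc, ssc_meanlog=ssc, events=events)


def generate_cytometry_dataset(truth: CytometryTruth, seed: int = 0) -> pd.DataFrame:
    """Draw the configured number of lognormal scatter events per sample.

    Returns a long event table with columns ``day, treatment, event,
    fsc, ssc``; deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for day, treatment in sorted(truth.fsc_meanlog):
        fsc = rng.lognormal(truth.fsc_meanlog[(day, treatment)], truth.fsc_sdlog, truth.events)
        ssc = rng.lognormal(truth.ssc_meanlog[(day, treatment)], truth.ssc_sdlog, truth.events)
        frames.append(
            pd.DataFrame(
                {
                    "day": day,
                    "treatment": treatment,
                    "event": np.arange(1, truth.events + 1),
                    "fsc": fsc,
                    "ssc": ssc,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_binding_counts(mean_load: float, n_cells: int, seed: int = 0) -> np.ndarray:
    """Per-cell initially bound phage counts under a Poisson encounter model.

    Each cell's count is Poisson(``mean_load``); a zero mean yields all
    zeros, and ``n_cells=0`` returns an empty array.
    """
    if mean_load < 0:
        raise DomainError(f"mean_load must be >= 0, got {mean_load}")
    if n_cells < 0:
        raise DomainError(f"n_cells must be >= 0, got {n_cells}")
    rng = np.random.default_rng(seed)
    return rng.poisson(mean_load, size=n_cells).astype(np.int64)
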