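"""End-to-end orchestration: generate/load -> fit -> test -> report.

A single :func:`run` call takes a :class:`RunConfig`, produces every
module's CSV output in the configured directory, and writes a
machine-readable ``report.json`` whose structure is validated against
the bundled JSON schema.  Identical configuration and seed yield a
byte-identical report (no timestamps are embedded; provenance carries
the config hash, seed and package version instead).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from . import cytometry as cyto
from . import dilution as dil
from . import growth as gro
from . import io as tio
from . import stats as tstats
from . import synthetic_data as synth
from .errors import DomainError, PipelineStageError

__all__ = [
    "RunConfig",
    "AnalysisReportModel",
    "run",
    "sensitivity_comparison",
    "validate_report",
    "report_json_schema",
]

log = logging.getLogger("terminvest.pipeline")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, YAML-round-trippable.

    When ``growth_input`` / ``cytometry_input`` are None the corresponding
    dataset is generated synthetically with the design, baseline and
    truth parameters below; otherwise the CSVs are read verbatim.
    Cytometry event counts default to a scaled-down 2x10^4 per sample to
    keep full runs fast; the generator itself defaults to the assay's
    2x10^5.
    """

    seed: int = 0
    out_dir: str = "terminvest_run"
    growth_input: str | None = None
    cytometry_input: str | None = None
    # experiment shape
    n_days: int = 4
    replicates_per_treatment: int = 6
    reads_per_day: int = 250
    read_span_h: float = 24.0
    # growth-curve truth
    r_per_h: float = 0.5
    lag_h: float = 1.5
    n_init: float = 0.01
    carrying_capacity: float = 1.0
    noise_sd: float = 0.01
    rate_cv: float = 0.02
    effect_profile: dict[int, dict[str, float]] | None = None
    # fitting
    window_points: int | None = None
    window_frac: float = gro.DEFAULT_WINDOW_FRAC
    od_floor: float = gro.DEFAULT_OD_FLOOR
    # rank tests
    kw_permutations: int | None = None
    # cytometry
    cytometry_events: int = 20_000
    size_ratio_by_day: dict[int, float] | None = None
    comparison_subsample: int = cyto.DEFAULT_COMPARISON_SUBSAMPLE
    ks_permutations: int = 999
    # dilution predictions
    dilution_p0: tuple[float, ...] = (100.0, 500.0, 1000.0)
    control_label: str = "control"
    make_figures: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "effect_profile" in raw and raw["effect_profile"] is not None:
            raw["effect_profile"] = {
                int(day): {str(t): float(m) for t, m in trt.items()}
                for day, trt in raw["effect_profile"].items()
            }
        if "size_ratio_by_day" in raw and raw["size_ratio_by_day"] is not None:
            raw["size_ratio_by_day"] = {int(d): float(v) for d, v in raw["size_ratio_by_day"].items()}
        if "dilution_p0" in raw:
            raw["dilution_p0"] = tuple(float(v) for v in raw["dilution_p0"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dilution_p0"] = list(self.dilution_p0)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir")
        canonical = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()

    def design(self) -> synth.ExperimentDesign:
        return synth.ExperimentDesign(
            n_days=self.n_days,
            replicates_per_treatment=self.replicates_per_treatment,
            reads_per_day=self.reads_per_day,
            read_span_h=self.read_span_h,
        )

    def baseline(self) -> synth.GrowthBaseline:
        return synth.GrowthBaseline(
            r_per_h=self.r_per_h,
            lag_h=self.lag_h,
            n_init=self.n_init,
            carrying_capacity=self.carrying_capacity,
            noise_sd=self.noise_sd,
            rate_cv=self.rate_cv,
            od_floor=self.od_floor,
        )


# --- report schema ---------------------------------------------------------


class DtSummaryRow(BaseModel):
    day: int
    treatment: str
    mean_dt: float | None
    se_dt: float | None = Field(default=None)
    n: int


class KWRow(BaseModel):
    day: int
    grouping: str
    k: int
    df: int | None
    H: float | None
    p_chisq: float | None
    p_perm: float | None
    flagged: bool


class CytometrySummaryRow(BaseModel):
    day: int
    treatment: str
    n_events: int
    mean_fsc: float
    sd_fsc: float
    median_fsc: float
    mean_ssc: float
    sd_ssc: float


class ComparisonRow(BaseModel):
    day: int
    pair: str
    D: float
    p_perm: float


class SizeRatioRow(BaseModel):
    day: int
    treatment: str
    ratio_vs_control: float


class DilutionRow(BaseModel):
    p0: float
    divisions_to_sub_unity: int
    hours_to_sub_unity: float | None


class Section(BaseModel):
    skipped: bool = False


class GrowthSection(Section):
    summary: list[DtSummaryRow] = []


class KWSection(Section):
    tests: list[KWRow] = []


class CytometrySection(Section):
    summaries: list[CytometrySummaryRow] = []
    size_ratios: list[SizeRatioRow] = []
    comparisons: list[ComparisonRow] = []


class DilutionSection(Section):
    predictions: list[DilutionRow] = []
    reference_doubling_time_h: float | None = None


class Provenance(BaseModel):
    config_hash: str
    seed: int
    package_version: str


class AnalysisReportModel(BaseModel):
    """Schema of ``report.json``: every section present or marked skipped."""

    growth: GrowthSection
    kruskal_wallis: KWSection
    cytometry: CytometrySection
    dilution: DilutionSection
    provenance: Provenance


def report_json_schema() -> dict:
    return AnalysisReportModel.model_json_schema()


def bundled_schema() -> dict:
    """The JSON schema shipped with the package."""
    text = resources.files("terminvest").joinpath("report_schema.json").read_text()
    return json.loads(text)


def validate_report(report: dict) -> AnalysisReportModel:
    """Parse a report dict through the schema model; raises on mismatch."""
    return AnalysisReportModel.model_validate(report)


# --- orchestration ---------------------------------------------------------


def _none_if_nan(x):
    try:
        return None if x is None or (isinstance(x, float) and np.isnan(x)) else float(x)
    except TypeError:
        return None


def _growth_stage(cfg: RunConfig, out: Path, seeds, written: list[Path]):
    if cfg.growth_input:
        curves = tio.read_growth_csv(cfg.growth_input)
        truth = None
    else:
        curves, truth = synth.generate_growth_dataset(
            cfg.design(), cfg.effect_profile, seed=int(seeds[0]), baseline=cfg.baseline()
        )
        written.append(tio.write_growth_csv(curves, out / "growth_curves.csv"))
        truth_path = tio.truth_sidecar_path(out / "growth_curves.csv")
        truth.to_csv(truth_path, index=False)
        written.append(truth_path)
    log.info("growth stage: %d rows (%d curves)", len(curves), curves["well"].nunique())
    return curves, truth


def _fit_stage(cfg: RunConfig, curves, out: Path, written: list[Path]):
    dt_table, diagnostics = gro.fit_plate(
        curves, window_points=cfg.window_points, window_frac=cfg.window_frac, floor=cfg.od_floor
    )
    written.append(tio.write_dt_csv(dt_table, out / "doubling_times.csv"))
    diag_path = out / "fit_diagnostics.json"
    diag_path.write_text(json.dumps(diagnostics, indent=1, default=str))
    written.append(diag_path)
    # replicate identity is carried by the diagnostics; the dt CSV mirrors
    # the deposited Day/Phages/dt layout
    log.info("fit stage: %d doubling times (%d flagged)", len(dt_table), int(dt_table["dt"].isna().sum()))
    return dt_table, diagnostics


def _kw_stage(cfg: RunConfig, dt_table, out: Path, written: list[Path]) -> pd.DataFrame:
    frames = [
        tstats.daily_tests(
            dt_table,
            grouping=grouping,
            control_label=cfg.control_label,
            n_permutations=cfg.kw_permutations,
            seed=cfg.seed,
        )
        for grouping in ("all-four", "exposed-only")
    ]
    kw = pd.concat(frames, ignore_index=True)
    path = out / "kruskal_wallis.csv"
    kw.to_csv(path, index=False)
    written.append(path)
    log.info("rank-test stage: %d tests", len(kw))
    return kw


def _cytometry_stage(cfg: RunConfig, out: Path, seeds, written: list[Path]):
    if cfg.cytometry_input:
        events = tio.read_cytometry_csv(cfg.cytometry_input)
    else:
        truth = synth.default_cytometry_truth(
            cfg.design(), size_ratio_by_day=cfg.size_ratio_by_day, events=cfg.cytometry_events
        )
        events = synth.generate_cytometry_dataset(truth, seed=int(seeds[1]))
        written.append(tio.write_cytometry_csv(events, out / "cytometry_events.csv"))
    summaries = cyto.summarize_table(events)
    comparisons = cyto.compare_table(
        events,
        reference=cfg.control_label,
        n_permutations=cfg.ks_permutations,
        seed=int(seeds[2]),
        subsample=cfg.comparison_subsample,
    )
    s_path = out / "cytometry_summaries.csv"
    summaries.to_csv(s_path, index=False)
    written.append(s_path)
    c_path = out / "cytometry_comparisons.csv"
    comparisons.to_csv(c_path, index=False)
    written.append(c_path)
    log.info(
        "cytometry stage: %d events, %d summaries, %d comparisons",
        len(events), len(summaries), len(comparisons),
    )
    return summaries, comparisons


def _dilution_stage(cfg: RunConfig, dt_table) -> tuple[list[dict], float | None]:
    """Divisions and hours until the mean bound-phage load drops below one.

    The reference doubling time is the mean fitted day-1 doubling time of
    the exposed treatments (the populations that actually carry phage).
    """
    day1 = dt_table[(dt_table["Day"] == dt_table["Day"].min()) & (dt_table["Phages"] != cfg.control_label)]
    dts = day1["dt"].dropna()
    ref_dt = float(dts.mean()) if len(dts) else None
    rows = []
    for p0 in cfg.dilution_p0:
        n = dil.divisions_until_below_one(p0)
        rows.append(
            {
                "p0": float(p0),
                "divisions_to_sub_unity": n,
                "hours_to_sub_unity": (n * ref_dt) if ref_dt is not None else None,
            }
        )
    return rows, ref_dt


def _size_ratio_rows(summaries: pd.DataFrame, control_label: str) -> list[dict]:
    rows = []
    for day, grp in summaries.groupby("day", sort=True):
        by_treatment = {r["treatment"]: r for _, r in grp.iterrows()}
        if control_label not in by_treatment:
            continue
        ref = cyto.SampleSummary(**by_treatment[control_label])
        for treatment, rec in sorted(by_treatment.items()):
            if treatment == control_label:
                continue
            rows.append(
                {
                    "day": int(day),
                    "treatment": treatment,
                    "ratio_vs_control": cyto.size_ratio(ref, cyto.SampleSummary(**rec)),
                }
            )
    return rows


def _figure_stage(report: dict, out: Path, written: list[Path]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    rows = pd.DataFrame([r for r in report["growth"]["summary"] if r["mean_dt"] is not None])
    for treatment, grp in rows.groupby("treatment"):
        ax.errorbar(grp["day"], grp["mean_dt"], yerr=grp["se_dt"], marker="o", label=treatment)
    ax.set_xlabel("day post-exposure")
    ax.set_ylabel("doubling time (h)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = out / "doubling_time_by_day.svg"
    fig.savefig(path)
    plt.close(fig)
    written.append(path)


def run(config: RunConfig) -> dict:
    """Execute the full analysis and return the validated report dict.

    Writes every module's CSV plus ``report.json`` under
    ``config.out_dir``.  On a stage failure, files already written are
    renamed with a ``.partial`` suffix and a
    :class:`~terminvest.errors.PipelineStageError` naming the stage is
    raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31 - 1)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "growth-data"
        curves, truth = _growth_stage(config, out, seeds, written)
        stage = "growth-fit"
        dt_table, _ = _fit_stage(config, curves, out, written)
        stage = "rank-tests"
        kw = _kw_stage(config, dt_table, out, written)
        stage = "cytometry"
        summaries, comparisons = _cytometry_stage(config, out, seeds, written)
        stage = "dilution"
        dilution_rows, ref_dt = _dilution_stage(config, dt_table)
        stage = "report"
        growth_summary = []
        grouped = dt_table.groupby(["Day", "Phages"], sort=True)["dt"]
        for (day, treatment), values in grouped:
            clean = values.dropna()
            n = int(len(clean))
            growth_summary.append(
                {
                    "day": int(day),
                    "treatment": str(treatment),
                    "mean_dt": _none_if_nan(clean.mean()) if n else None,
                    "se_dt": float(clean.std(ddof=1) / np.sqrt(n)) if n > 1 else (0.0 if n else None),
                    "n": n,
                }
            )
        kw_rows = [
            {
                "day": int(r.day),
                "grouping": r.grouping,
                "k": int(r.k),
                "df": int(r.df) if not pd.isna(r.df) else None,
                "H": _none_if_nan(r.H),
                "p_chisq": _none_if_nan(r.p_chisq),
                "p_perm": _none_if_nan(r.p_perm),
                "flagged": bool(r.flagged),
            }
            for r in kw.itertuples()
        ]
        report = {
            "growth": {"skipped": False, "summary": growth_summary},
            "kruskal_wallis": {"skipped": False, "tests": kw_rows},
            "cytometry": {
                "skipped": False,
                "summaries": summaries.to_dict("records"),
                "size_ratios": _size_ratio_rows(summaries, config.control_label),
                "comparisons": comparisons.to_dict("records"),
            },
            "dilution": {
                "skipped": False,
                "predictions": dilution_rows,
                "reference_doubling_time_h": ref_dt,
            },
            "provenance": {
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "package_version": __version__,
            },
        }
        validate_report(report)
        report_path = out / "report.json"
        report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
        written.append(report_path)
        if config.make_figures:
            stage = "figures"
            _figure_stage(report, out, written)
    except Exception as exc:  # noqa: BLE001 - converted to a stage error
        for path in written:
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        raise PipelineStageError(stage, str(exc)) from exc
    log.info("run complete: report at %s", out / "report.json")
    return report


def sensitivity_comparison(cfu_counts: dict[str, list[float]]) -> tstats.KWResult:
    """Rank test for treatment effects on live-phage challenge outcomes.

    ``cfu_counts`` maps each (exposed) treatment to its replicate CFU
    counts after the live-phage challenge; with the three phage-density
    treatments df = 2.  A non-significant result means prior exposure to
    inactivated phage did not alter sensitivity to live phage.
    """
    if len(cfu_counts) < 2:
        raise DomainError(f"need >= 2 treatment groups, got {len(cfu_counts)}")
    groups = [cfu_counts[k] for k in sorted(cfu_counts)]
    return tstats.kruskal_wallis(groups)
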