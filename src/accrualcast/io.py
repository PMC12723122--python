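"""Delimited-table readers/writers, run configuration, and the pipeline.

Two input layouts are accepted (CSV with a header, dates in ISO 8601):

* quarterly — columns ``quarter_index, season, count, duration``
  (pre-aggregated seasonal quarters), optional ``start_date``;
* monthly — columns ``month_start, count`` (aggregated by
  :func:`accrualcast.accrual_data.quarterize`).

``run_pipeline`` ties the modules together: read → aggregate → elicit or
accept a prior → fit the selected model(s) → predict to the horizon →
compare seasons → DIC → optional rolling evaluation, and returns a single
JSON-serializable record that echoes the fully resolved configuration and
seed so every run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd

from .accrual_data import (
    SEASON_CYCLE,
    AccrualQuarter,
    AccrualSeries,
    MonthlyRecord,
    Season,
    quarterize,
    season_sets,
)
from .conjugate import (
    DEFAULT_DRAWS,
    DEFAULT_SEED,
    GammaRatePrior,
    elicit_prior,
    posterior_summary,
    update_homogeneous,
    update_seasonal,
)
from .model_eval import compute_dic, rolling_evaluation
from .predictive import PredictiveRequest, predict_total_homogeneous, predict_total_seasonal, summarize_predictive
from .seasonal_compare import compare_seasons

__all__ = [
    "read_accrual_table",
    "write_accrual_table",
    "RunConfig",
    "run_pipeline",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1"

_QUARTERLY_COLS = {"quarter_index", "season", "count", "duration"}
_MONTHLY_COLS = {"month_start", "count"}


class TableError(ValueError):
    """Input table failed validation; message carries row-level diagnostics."""


def _require_columns(df: pd.DataFrame, required: set[str], path: str) -> None:
    missing = required - set(df.columns)
    if missing:
        raise TableError(f"{path}: missing required column(s): {', '.join(sorted(missing))}")


def read_accrual_table(
    path: str | Path,
    layout: Literal["quarterly", "monthly"] = "quarterly",
) -> AccrualSeries | list[MonthlyRecord]:
    """Read and validate an accrual table; row numbers appear in errors."""
    path = Path(path)
    if not path.exists():
        raise TableError(f"input file not found: {path}")
    df = pd.read_csv(path)
    if layout == "quarterly":
        _require_columns(df, _QUARTERLY_COLS, str(path))
        quarters = []
        for i, row in df.iterrows():
            rowno = i + 2  # 1-based, after the header line
            try:
                season = Season(str(row["season"]).strip().lower())
            except ValueError:
                raise TableError(
                    f"{path} row {rowno}: unknown season {row['season']!r} "
                    f"(expected one of {[s.value for s in SEASON_CYCLE]})"
                ) from None
            start = None
            if "start_date" in df.columns and not pd.isna(row.get("start_date")):
                start = _parse_date(str(row["start_date"]), path, rowno)
            try:
                quarters.append(
                    AccrualQuarter(
                        index=int(row["quarter_index"]),
                        count=int(row["count"]),
                        duration=float(row["duration"]),
                        season=season,
                        start_date=start,
                    )
                )
            except (TypeError, ValueError) as exc:
                raise TableError(f"{path} row {rowno}: {exc}") from None
        try:
            return AccrualSeries(tuple(quarters), trial_label=path.stem)
        except ValueError as exc:
            raise TableError(f"{path}: {exc}") from None
    if layout == "monthly":
        _require_columns(df, _MONTHLY_COLS, str(path))
        records = []
        for i, row in df.iterrows():
            rowno = i + 2
            date = _parse_date(str(row["month_start"]), path, rowno)
            try:
                records.append(MonthlyRecord(month_start=date, count=int(row["count"])))
            except (TypeError, ValueError) as exc:
                raise TableError(f"{path} row {rowno}: {exc}") from None
        return records
    raise ValueError(f"unknown layout {layout!r}")


def _parse_date(text: str, path: Path, rowno: int) -> dt.date:
    try:
        return dt.date.fromisoformat(text.strip())
    except ValueError:
        raise TableError(f"{path} row {rowno}: unparseable ISO date {text!r}") from None


def write_accrual_table(series: AccrualSeries, path: str | Path) -> None:
    """Write a quarterly table that `read_accrual_table` round-trips exactly."""
    df = pd.DataFrame(
        {
            "quarter_index": [q.index for q in series.quarters],
            "season": [q.season.value for q in series.quarters],
            "count": [q.count for q in series.quarters],
            "duration": [q.duration for q in series.quarters],
            "start_date": [q.start_date.isoformat() if q.start_date else "" for q in series.quarters],
        }
    )
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration for one reproducible pipeline run."""

    input_path: str
    layout: Literal["quarterly", "monthly"] = "quarterly"
    model: Literal["homogeneous", "seasonal", "both"] = "both"
    # prior: either explicit (shape, rate) or elicited from planning inputs
    prior_shape: float | None = None
    prior_rate: float | None = None
    target_enrollment: int | None = None
    planned_quarters: int | None = None
    confidence_p: float = 0.5
    horizon_q: int | None = None
    replicates_R: int = DEFAULT_DRAWS
    seed: int = DEFAULT_SEED
    level: float = 0.95
    trial_start: str | None = None
    drop_partial_first: bool = False
    partial_threshold: float = 0.5
    full_first_quarter: bool = True
    rolling: bool = False

    def resolve_prior(self) -> GammaRatePrior:
        if self.prior_shape is not None and self.prior_rate is not None:
            return GammaRatePrior(self.prior_shape, self.prior_rate)
        if self.target_enrollment is not None and self.planned_quarters is not None:
            return elicit_prior(self.target_enrollment, self.planned_quarters, self.confidence_p)
        raise ValueError(
            "prior underspecified: give prior_shape+prior_rate or "
            "target_enrollment+planned_quarters (+confidence_p)"
        )


def _load_series(config: RunConfig) -> AccrualSeries:
    data = read_accrual_table(config.input_path, config.layout)
    if isinstance(data, AccrualSeries):
        return data
    start = dt.date.fromisoformat(config.trial_start) if config.trial_start else None
    return quarterize(
        data,
        trial_start=start,
        drop_partial_first=config.drop_partial_first,
        partial_threshold=config.partial_threshold,
        full_first_quarter=config.full_first_quarter,
        trial_label=Path(config.input_path).stem,
    )


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured analysis; return the structured result record."""
    series = _load_series(config)
    prior = config.resolve_prior()
    record: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "config": dataclasses.asdict(config),
        "prior": {"shape": prior.shape, "rate": prior.rate},
        "series": {
            "trial_label": series.trial_label,
            "J": series.J,
            "total_count": series.total_count,
            "total_exposure": series.total_exposure,
            "excluded_count": series.excluded_count,
            "per_season": {
                s.value: {"count": sub.count, "exposure": sub.exposure, "n_quarters": sub.n_quarters}
                for s, sub in season_sets(series).items()
            },
        },
        "models": {},
    }
    horizon = config.horizon_q if config.horizon_q is not None else series.J
    want = ("homogeneous", "seasonal") if config.model == "both" else (config.model,)
    children = np.random.SeedSequence(config.seed).spawn(4)
    sub_seed = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    if "homogeneous" in want:
        post = update_homogeneous(prior, series)
        summ = posterior_summary(post, level=config.level)
        request = PredictiveRequest.continue_series(
            series, horizon, replicates_R=config.replicates_R, seed=sub_seed[0]
        )
        pred = summarize_predictive(predict_total_homogeneous(post, request), config.level)
        entry: dict[str, Any] = {
            "posterior": {"shape": post.shape, "rate": post.rate},
            "rate_mean": summ.mean,
            "rate_interval": [summ.lower, summ.upper],
            "predictive": {
                "horizon_q": horizon,
                "mean": pred.mean,
                "interval": [pred.lower, pred.upper],
                "replicates_R": pred.replicates,
            },
            "dic": dataclasses.asdict(compute_dic(series, post, seed=sub_seed[2])),
        }
        if config.rolling:
            entry["rolling"] = [
                dataclasses.asdict(r)
                for r in rolling_evaluation(
                    series, prior, "homogeneous", replicates_R=config.replicates_R, seed=sub_seed[3]
                )
            ]
        record["models"]["homogeneous"] = entry

    if "seasonal" in want:
        post_s = update_seasonal(prior, series)
        request = PredictiveRequest.continue_series(
            series, horizon, replicates_R=config.replicates_R, seed=sub_seed[0]
        )
        pred = summarize_predictive(predict_total_seasonal(post_s, request), config.level)
        comparison = compare_seasons(post_s, draws=config.replicates_R, seed=sub_seed[1])
        entry = {
            "posterior": {
                s.value: {
                    "shape": post_s[s].shape,
                    "rate": post_s[s].rate,
                    "mean": post_s[s].mean,
                    "interval": list(post_s[s].interval(config.level)),
                    "prior_only": post_s[s].n_quarters_used == 0,
                }
                for s in SEASON_CYCLE
            },
            "prior_only_seasons": [s.value for s in post_s.prior_only_seasons()],
            "predictive": {
                "horizon_q": horizon,
                "mean": pred.mean,
                "interval": [pred.lower, pred.upper],
                "replicates_R": pred.replicates,
            },
            "comparison": {
                "pairwise": {f"{s.value}>{k.value}": p for (s, k), p in comparison.pairwise.items()},
                "extreme": {s.value: comparison.extreme[s] for s in SEASON_CYCLE},
            },
            "dic": dataclasses.asdict(compute_dic(series, post_s, seed=sub_seed[2])),
        }
        if config.rolling:
            entry["rolling"] = [
                dataclasses.asdict(r)
                for r in rolling_evaluation(
                    series, prior, "seasonal", replicates_R=config.replicates_R, seed=sub_seed[3]
                )
            ]
        record["models"]["seasonal"] = entry
    return record


def write_record(record: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
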