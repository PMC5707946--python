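"""CSV/JSON input-output and the end-to-end pipeline configuration.

Input CSVs carry a ``year`` column plus either one value column per series
(wide layout) or ``label``/``value`` columns (long layout). Reports are
written as JSON with both full-precision and display-rounded fields; output
is atomic — nothing is written until the whole run has succeeded.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model import GM11, GM11Results
from .sequences import AnnualSeries, round_display, strengthen_buffer, validate

__all__ = ["RunConfig", "read_series_csv", "run_pipeline", "write_report"]


@dataclass
class RunConfig:
    """Configuration of an end-to-end run (buffer -> fit -> diagnose -> forecast)."""

    input: str
    columns: list[str] = field(default_factory=list)  # empty = all value columns
    buffer: list[str] = field(default_factory=list)  # columns to buffer first
    init_variant: str = "optimized"
    objective_k1: str = "ratio_to_first"
    mre_divisor: str = "n_minus_1"
    horizon: int = 6
    out: str = "greycast_report.json"
    rounding: int = 2
    seed: int = 0
    plot: str = ""  # optional PNG/SVG path prefix

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def read_series_csv(
    path: str | Path,
    columns: list[str] | None = None,
    year_column: str = "year",
) -> dict[str, AnnualSeries]:
    """Read annual series from a wide or long CSV, keyed by label.

    Wide layout: ``year`` plus one column per series. Long layout:
    ``year``, ``label``, ``value`` rows.
    """
    df = pd.read_csv(path)
    if year_column not in df.columns:
        raise ValueError(f"{path}: missing required column {year_column!r}")
    out: dict[str, AnnualSeries] = {}
    if {"label", "value"}.issubset(df.columns):
        for label, grp in df.groupby("label", sort=False):
            grp = grp.sort_values(year_column)
            if columns and label not in columns:
                continue
            out[str(label)] = AnnualSeries(
                label=str(label),
                start_year=int(grp[year_column].iloc[0]),
                values=grp["value"].to_numpy(dtype=float),
            )
    else:
        df = df.sort_values(year_column)
        value_cols = [c for c in df.columns if c != year_column]
        for col in columns or value_cols:
            out[col] = AnnualSeries(
                label=col,
                start_year=int(df[year_column].iloc[0]),
                values=df[col].to_numpy(dtype=float),
            )
    if not out:
        raise ValueError(f"{path}: no series selected")
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full procedure for every configured series.

    Returns the consolidated report dict and writes it (plus a fitted/
    forecast CSV next to it) only after every series has been processed.
    """
    series_map = read_series_csv(config.input, columns=config.columns or None)
    report: dict = {"config": dataclasses.asdict(config), "series": {}}
    frames = []
    results: dict[str, GM11Results] = {}
    for label, series in series_map.items():
        if label in config.buffer:
            series = strengthen_buffer(series)
        validate(series)
        res = GM11(series).fit(
            init=config.init_variant, objective_k1=config.objective_k1
        )
        results[label] = res
        report["series"][label] = res.to_report(horizon=config.horizon)
        frame = pd.DataFrame(
            {
                "label": label,
                "year": series.years,
                "observed": series.values,
                "fitted": round_display(res.fittedvalues, config.rounding),
            }
        )
        if config.horizon > 0:
            fc = res.forecast(config.horizon)
            frame = pd.concat(
                [
                    frame,
                    pd.DataFrame(
                        {
                            "label": label,
                            "year": fc.years,
                            "observed": float("nan"),
                            "fitted": round_display(fc.values, config.rounding),
                        }
                    ),
                ],
                ignore_index=True,
            )
        frames.append(frame)
    # all series processed: now write outputs atomically
    out = Path(config.out)
    write_report(report, out)
    pd.concat(frames, ignore_index=True).to_csv(
        out.with_suffix(".csv"), index=False
    )
    if config.plot:
        for label, res in results.items():
            ax = res.plot(horizon=config.horizon)
            ax.figure.savefig(f"{config.plot}_{label}.png", dpi=120)
    return report


def write_report(report: dict, path: str | Path) -> None:
    """Serialise a report dict to JSON (sorted keys, deterministic)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
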