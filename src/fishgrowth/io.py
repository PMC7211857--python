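"""CSV input/output and run configuration.

One tabular dialect everywhere: comma-separated, UTF-8, header required.
Ages are stored as plain numbers of years (the field notation "0+", "1+"
maps to 0, 1, ...). Output files are deterministic given the inputs, so
a rerun with the same seed reproduces byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .design import GrowthDataset, ModelSpec
from .model import GrowthResults
from .validate import ValidationReport

__all__ = [
    "RunConfig",
    "load_run_config",
    "read_growth_csv",
    "write_growth_csv",
    "write_outputs",
]

_COLUMN_ALIASES = {"length_mm": "length"}
_MANDATORY = ("fish_id", "species", "population", "age", "length")


def read_growth_csv(path) -> GrowthDataset:
    """Read and validate a long-format growth CSV.

    Mandatory columns: fish_id, species, population, age, length (or
    length_mm); optional: cohort, season, covariates. Malformed rows are
    reported with their line number (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path}: file contains no data rows")
    df = df.rename(columns=_COLUMN_ALIASES)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    for col in ("age", "length"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: unparseable {col!r} value {df.loc[bad[0], col]!r} "
                f"at line {bad[0] + 2}"
            )
        df[col] = coerced
    dup = df.duplicated(subset=["fish_id", "age"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicated (fish_id, age) record at line {df.index[dup][0] + 2}"
        )
    bad = df.index[(df["length"] <= 0) | df["length"].isna()]
    if len(bad):
        raise ValueError(f"{path}: non-positive or missing length at line {bad[0] + 2}")
    bad = df.index[(df["age"] < 0) | df["age"].isna()]
    if len(bad):
        raise ValueError(f"{path}: negative or missing age at line {bad[0] + 2}")
    return GrowthDataset(df)


def write_growth_csv(data: GrowthDataset, path) -> None:
    data.frame.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of a validation run, loadable from YAML or JSON."""

    input: str
    specs: list = field(default_factory=list)  # list[ModelSpec]
    min_captures: int = 4
    fraction: float = 1.0 / 3.0
    replicates: int = 5
    seed: int = 0
    outdir: str = "results"
    verbosity: int = 1


def load_run_config(path) -> RunConfig:
    """Parse a YAML/JSON run configuration file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    specs = [ModelSpec.from_dict(d) for d in raw.get("specs", [])]
    kwargs = {k: v for k, v in raw.items() if k != "specs"}
    return RunConfig(specs=specs, **kwargs)


def write_outputs(
    outdir,
    fit: GrowthResults | None = None,
    report: ValidationReport | None = None,
    predictions: pd.DataFrame | None = None,
    log_lines: list | None = None,
) -> list:
    """Write the deterministic output file set; returns the paths written.

    ranking.csv (rank-eligible models), estimates.csv (packed-scale
    coefficients and SEs), individual_params.csv (per-fish natural-scale
    parameters and EB effects), predictions.csv, run.log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(name, frame):
        p = outdir / name
        frame.to_csv(p, index=False)
        written.append(p)

    if report is not None:
        table = report.table()
        _w("ranking.csv", table[table["rank_eligible"]].drop(columns="rank_eligible"))
    if fit is not None:
        est = pd.DataFrame({"parameter": fit.model.layout.names, "estimate": fit.x})
        est["se"] = fit.bse_ if fit.bse_ is not None else float("nan")
        _w("estimates.csv", est)
        ip = fit.individual_parameters().join(fit.random_effects())
        _w("individual_params.csv", ip.reset_index(names="fish_id"))
    if predictions is not None:
        _w("predictions.csv", predictions)
    log = outdir / "run.log"
    log.write_text("\n".join(log_lines or []) + "\n")
    written.append(log)
    return written
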