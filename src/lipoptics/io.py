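"""Tabular I/O and configuration loading.

CSV dialect: comma-separated, dot decimal, UTF-8, header row required.
Titration files carry the columns ``wavelength_nm``, ``concentration_vv``
and ``musp_mm1``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .blood import ScenarioResult
from .datasets import TitrationDataset

__all__ = [
    "TITRATION_COLUMNS",
    "read_titration_csv",
    "write_titration_csv",
    "write_scenarios_csv",
    "write_sweep_csv",
    "load_config",
]

TITRATION_COLUMNS = ("wavelength_nm", "concentration_vv", "musp_mm1")


class ParseError(ValueError):
    """Malformed input file (missing columns, non-numeric cells...)."""


class EmptyDatasetError(ParseError):
    """Structurally valid file containing no data rows."""


def read_titration_csv(path: str | Path) -> list[TitrationDataset]:
    """Read titration curves, one dataset per wavelength found."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    missing = set(TITRATION_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise EmptyDatasetError(f"{path}: header only, no data rows")
    for col in TITRATION_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0]) + 2  # 1-based + header
            raise ParseError(f"{path}: non-numeric value in {col!r} "
                             f"near line {row}")
        df[col] = vals
    datasets = []
    for wl, grp in df.groupby("wavelength_nm", sort=True):
        grp = grp.sort_values("concentration_vv")
        datasets.append(
            TitrationDataset(
                wavelength=float(wl),
                concentrations=grp["concentration_vv"].to_numpy(),
                musp_measured=grp["musp_mm1"].to_numpy(),
            )
        )
    return datasets


def write_titration_csv(datasets: Iterable[TitrationDataset],
                        path: str | Path) -> None:
    """Write titration curves in the standard three-column schema."""
    rows = []
    for ds in datasets:
        for c, m in zip(ds.concentrations, ds.musp_measured):
            rows.append((ds.wavelength, c, m))
    df = pd.DataFrame(rows, columns=list(TITRATION_COLUMNS))
    df.to_csv(path, index=False, float_format="%.12g")


def write_scenarios_csv(results: Iterable[ScenarioResult],
                        path: str | Path) -> None:
    """Write postprandial scenario results (percent-change table)."""
    df = pd.DataFrame(
        [
            {
                "scenario": r.label,
                "wavelength_nm": r.wavelength,
                "musp_fasting_mm1": r.musp_baseline,
                "musp_postprandial_mm1": r.musp_post,
                "delta_musp_percent": r.delta_musp_percent,
            }
            for r in results
        ]
    )
    df.to_csv(path, index=False, float_format="%.6g")


def write_sweep_csv(sweep: Iterable[Mapping], path: str | Path) -> None:
    """Write a TG-sweep result (one row per step and wavelength)."""
    rows = []
    for rec in sweep:
        for wl, props in rec["properties"].items():
            rows.append(
                {
                    "step": rec["step"],
                    "tg_total_mgdl": rec["tg_total"],
                    "cm_mean_diameter_nm": rec["cm_mean_diameter"],
                    "cm_refractive_index": rec["cm_refractive_index"],
                    "wavelength_nm": wl,
                    "mus_mm1": props.mus,
                    "g": props.g,
                    "musp_mm1": props.musp,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: invalid YAML: {exc}") from exc
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: top level must be a mapping")
    return cfg
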