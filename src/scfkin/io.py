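"""Readers and writers for the package's plain-text table formats.

Formats (all with headers):

- time-course CSV:  ``time_s, S0, S1, ..., S_ge_<n>[, replicate]``
- raw lane CSV:     ``time_s, band_S0, band_S1, ...[, replicate]``
- titration CSV:    ``enzyme_conc_nM, fraction_converted,
  substrate_conc_nM, scf_conc_nM, time_min[, replicate]``
- SRM CSV:          ``protein, heavy_light_ratio, spike_fmol, n_cells,
  mean_diameter_um[, replicate]``
- score TSV:        ``gene<TAB>score``

Parsing is delegated to pandas; these helpers only validate the column
contract and build the domain objects.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .chain import TimeCourse
from .michaelis import MMDataset, VelocityPoint
from .quench import lane_to_fractions
from .screen import GeneScoreTable
from .srm import SRMSample

__all__ = [
    "read_timecourses",
    "write_timecourses",
    "timecourses_from_frame",
    "read_lanes",
    "read_titration",
    "write_titration",
    "read_srm_samples",
    "read_score_table",
    "write_score_table",
    "write_json_report",
]


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing column(s) {missing}")


def timecourses_from_frame(df: pd.DataFrame) -> list[TimeCourse]:
    """Split a tidy time-course frame into per-replicate `TimeCourse`s."""
    _require(df, ["time_s"], "time-course table")
    species = [c for c in df.columns if c not in ("time_s", "replicate")]
    if not species:
        raise ValidationError("time-course table: no species columns")
    groups = (
        df.groupby("replicate", sort=False)
        if "replicate" in df.columns
        else [(None, df)]
    )
    out = []
    for rep, sub in groups:
        sub = sub.sort_values("time_s")
        out.append(TimeCourse(
            times=sub["time_s"].to_numpy(dtype=float),
            fractions=sub[species].to_numpy(dtype=float),
            replicate_id=None if rep is None else str(rep),
            species_names=list(species),
        ))
    return out


def read_timecourses(path) -> list[TimeCourse]:
    return timecourses_from_frame(pd.read_csv(path))


def write_timecourses(timecourses, path) -> None:
    frames = [tc.to_frame() for tc in timecourses]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_lanes(path) -> list[TimeCourse]:
    """Read raw band intensities and normalise each lane to fractions."""
    df = pd.read_csv(path)
    _require(df, ["time_s"], "lane table")
    bands = [c for c in df.columns if c.startswith("band_")]
    if not bands:
        raise ValidationError("lane table: no band_* columns")
    frac = np.vstack([
        lane_to_fractions(row[bands].to_numpy(dtype=float))
        for _, row in df.iterrows()
    ])
    tidy = pd.DataFrame(frac, columns=[c.removeprefix("band_") for c in bands])
    tidy.insert(0, "time_s", df["time_s"].to_numpy())
    if "replicate" in df.columns:
        tidy["replicate"] = df["replicate"].to_numpy()
    return timecourses_from_frame(tidy)


_TITRATION_COLS = ["enzyme_conc_nM", "fraction_converted",
                   "substrate_conc_nM", "scf_conc_nM", "time_min"]


def read_titration(path, substrate: str = "") -> MMDataset:
    df = pd.read_csv(path)
    _require(df, _TITRATION_COLS, "titration table")
    points = [
        VelocityPoint(
            enzyme_conc=row["enzyme_conc_nM"],
            fraction_converted=row["fraction_converted"],
            substrate_conc=row["substrate_conc_nM"],
            scf_conc=row["scf_conc_nM"],
            incubation_time=row["time_min"],
        )
        for _, row in df.iterrows()
    ]
    return MMDataset(points, substrate=substrate)


def write_titration(data: MMDataset, path) -> None:
    df = data.to_frame().drop(columns=["velocity_per_min"])
    df.to_csv(path, index=False)


def read_srm_samples(path) -> list[SRMSample]:
    df = pd.read_csv(path)
    _require(df, ["protein", "heavy_light_ratio", "spike_fmol", "n_cells",
                  "mean_diameter_um"], "SRM table")
    return [
        SRMSample(
            protein=str(row["protein"]),
            heavy_light_ratio=row["heavy_light_ratio"],
            spike_amount=row["spike_fmol"],
            n_cells=row["n_cells"],
            mean_cell_diameter=row["mean_diameter_um"],
            replicate=str(row["replicate"]) if "replicate" in df.columns
            else None,
        )
        for _, row in df.iterrows()
    ]


def write_srm_samples(samples, path) -> None:
    pd.DataFrame({
        "protein": [s.protein for s in samples],
        "heavy_light_ratio": [s.heavy_light_ratio for s in samples],
        "spike_fmol": [s.spike_amount for s in samples],
        "n_cells": [s.n_cells for s in samples],
        "mean_diameter_um": [s.mean_cell_diameter for s in samples],
        "replicate": [s.replicate for s in samples],
    }).to_csv(path, index=False)


def read_score_table(path, label: str = "") -> GeneScoreTable:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"],
                     comment="#")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ValidationError(f"duplicate gene identifiers: {dup[:5]}")
    return GeneScoreTable(
        dict(zip(df["gene"].astype(str), df["score"].astype(float))),
        label=label or Path(str(path)).stem,
    )


def write_score_table(table: GeneScoreTable, path) -> None:
    table.to_series().to_csv(path, sep="\t", header=False)


def write_json_report(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
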