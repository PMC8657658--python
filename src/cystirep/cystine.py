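"""Cystine-depletion screen: normalization and hit calling.

Raw per-well cystine (nmol) is normalized to protein content (mg),
expressed as a percent of the same plate's vehicle (DMSO) mean, averaged
across replicate wells, and thresholded: a compound is a hit when it
reduces cystine by at least ``threshold_reduction`` percent (default 50,
boundary inclusive).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "normalize_cystine",
    "percent_of_vehicle",
    "compound_activities",
    "call_cystine_hits",
]

VEHICLE_ROLE = "vehicle"


def normalize_cystine(cystine_nmol: float, protein_mg: float) -> float:
    """Cystine per mg protein; protein must be strictly positive."""
    if protein_mg <= 0:
        raise ValueError(f"protein content must be > 0 mg, got {protein_mg}")
    return cystine_nmol / protein_mg


def percent_of_vehicle(value: float, vehicle_values: Iterable[float]) -> float:
    """Express a normalized readout as percent of the plate's vehicle mean."""
    veh = np.asarray(list(vehicle_values), dtype=float)
    if veh.size == 0:
        raise ValueError("no vehicle wells on plate")
    mean = float(veh.mean())
    if mean <= 0:
        raise ValueError(f"vehicle mean must be > 0, got {mean}")
    return 100.0 * value / mean


def compound_activities(
    plates: pd.DataFrame,
    replicate_policy: Literal["mean", "min", "max"] = "mean",
    role_col: str = "role",
    vehicle_role: str = VEHICLE_ROLE,
) -> pd.DataFrame:
    """Per-compound percent-of-vehicle activity from a raw plate table.

    Expects columns plate_id, compound_id, role, cystine_nmol, protein_mg.
    Normalization is plate-wise: each well is divided by the mean
    protein-normalized cystine of the vehicle wells on its own plate.
    Replicate wells of a compound (possibly on different plates) are
    combined on the percent scale by ``replicate_policy``.
    """
    df = plates.copy()
    if (df["protein_mg"] <= 0).any():
        bad = df.loc[df["protein_mg"] <= 0, "plate_id"].unique()
        raise ValueError(f"non-positive protein content on plate(s) {list(bad)}")
    df["normalized"] = df["cystine_nmol"] / df["protein_mg"]

    veh_mean = (
        df[df[role_col] == vehicle_role].groupby("plate_id")["normalized"].mean()
    )
    missing = set(df["plate_id"].unique()) - set(veh_mean.index)
    if missing:
        raise ValueError(f"plate(s) without vehicle wells: {sorted(missing)}")
    if (veh_mean <= 0).any():
        raise ValueError("vehicle mean <= 0 on some plate; cannot normalize")

    df["activity"] = 100.0 * df["normalized"] / df["plate_id"].map(veh_mean)
    cmpd = df[df[role_col] == "compound"]
    agg = {"mean": "mean", "min": "min", "max": "max"}[replicate_policy]
    out = (
        cmpd.groupby("compound_id", sort=True)["activity"].agg(agg).reset_index()
    )
    return out


def call_cystine_hits(
    activities: pd.DataFrame,
    threshold_reduction: float = 50.0,
) -> pd.DataFrame:
    """Flag compounds whose cystine reduction meets the threshold.

    ``activities`` carries one row per compound with columns compound_id
    and activity (percent of vehicle).  Returns a screen-result table
    with columns compound_id, phenotype, activity, reduction, hit.
    """
    if activities["compound_id"].duplicated().any():
        dups = activities.loc[activities["compound_id"].duplicated(), "compound_id"]
        raise ValueError(f"duplicate compound ids: {sorted(set(dups))}")
    out = activities[["compound_id", "activity"]].copy()
    out.insert(1, "phenotype", "cystine")
    out["reduction"] = 100.0 - out["activity"]
    out["hit"] = out["reduction"] >= threshold_reduction
    return out.reset_index(drop=True)


def write_screen_results(results: pd.DataFrame, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("# cystirep screen-result v1\n")
        results.to_csv(fh, sep="\t", index=False)
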