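"""Apoptosis-protection screen: caspase-3/7 positivity and hit calling.

Each well's apoptosis rate is the fraction of caspase-3/7-positive
nuclei over total nuclei.  Wells are normalized to the mean rate of the
same plate's induced-untreated wells (cells exposed to the apoptotic
stimulus with no drug), replicate plates are averaged, and a compound
is a hit when it reduces apoptosis by at least ``threshold_reduction``
percent (default 40, boundary inclusive).  Non-induced vehicle wells
are carried through as a baseline reference series but never enter hit
calling; together with the induced wells they feed the Z-factor QC.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "apoptosis_fraction",
    "normalize_to_induced",
    "compound_apoptosis",
    "call_apoptosis_hits",
]

INDUCED_ROLE = "induced"          # apoptosis stimulus, no drug (100% reference)
NON_INDUCED_ROLE = "non_induced"  # vehicle only, no stimulus (floor reference)


def apoptosis_fraction(positive: int, total: int) -> float:
    """Caspase-positive nuclei over total nuclei, in [0, 1]."""
    if total <= 0:
        raise ValueError(f"total nuclei must be > 0, got {total}")
    if positive < 0 or positive > total:
        raise ValueError(f"positive nuclei {positive} outside [0, {total}]")
    return positive / total


def normalize_to_induced(fraction: float, induced_fractions: Iterable[float]) -> float:
    """Percent of the plate's induced-untreated mean apoptosis rate."""
    ind = np.asarray(list(induced_fractions), dtype=float)
    if ind.size == 0:
        raise ValueError("no induced-untreated wells on plate")
    mean = float(ind.mean())
    if mean == 0:
        raise ValueError("induced-untreated mean is zero; cannot normalize")
    return 100.0 * fraction / mean


def compound_apoptosis(
    plates: pd.DataFrame,
    role_col: str = "role",
    induced_role: str = INDUCED_ROLE,
) -> pd.DataFrame:
    """Per-compound normalized apoptosis from a raw plate table.

    Expects columns plate_id, compound_id, role, positive_nuclei,
    total_nuclei (and optionally replicate).  Wells are normalized
    within their own plate, then replicate wells of each compound are
    averaged on the percent scale.
    """
    df = plates.copy()
    if (df["total_nuclei"] <= 0).any():
        raise ValueError("wells with zero total nuclei")
    if (df["positive_nuclei"] > df["total_nuclei"]).any():
        raise ValueError("wells with positive_nuclei > total_nuclei")
    df["fraction"] = df["positive_nuclei"] / df["total_nuclei"]

    ind_mean = (
        df[df[role_col] == induced_role].groupby("plate_id")["fraction"].mean()
    )
    missing = set(df["plate_id"].unique()) - set(ind_mean.index)
    if missing:
        raise ValueError(f"plate(s) without induced-untreated wells: {sorted(missing)}")
    if (ind_mean == 0).any():
        raise ValueError("induced-untreated mean is zero on some plate")

    df["normalized"] = 100.0 * df["fraction"] / df["plate_id"].map(ind_mean)
    cmpd = df[df[role_col] == "compound"]
    return (
        cmpd.groupby("compound_id", sort=True)["normalized"].mean().reset_index()
    )


def call_apoptosis_hits(
    normalized: pd.DataFrame,
    threshold_reduction: float = 40.0,
) -> pd.DataFrame:
    """Flag compounds whose apoptosis reduction meets the threshold.

    ``normalized`` has one row per compound with columns compound_id and
    normalized (percent of induced-untreated).  Returns a screen-result
    table with columns compound_id, phenotype, activity, reduction, hit.
    """
    if normalized["compound_id"].duplicated().any():
        dups = normalized.loc[normalized["compound_id"].duplicated(), "compound_id"]
        raise ValueError(f"duplicate compound ids: {sorted(set(dups))}")
    out = pd.DataFrame(
        {
            "compound_id": normalized["compound_id"],
            "phenotype": "apoptosis",
            "activity": normalized["normalized"].astype(float),
        }
    )
    out["reduction"] = 100.0 - out["activity"]
    out["hit"] = out["reduction"] >= threshold_reduction
    return out.reset_index(drop=True)
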