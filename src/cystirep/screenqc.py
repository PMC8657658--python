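"""Assay-quality statistics for plate-based screens.

The Z-factor compares the separation of positive and negative control
populations to their spread:

    Z = 1 - 3 * (sigma_p + sigma_n) / |mu_p - mu_n|

Z = 1 is a perfect assay (zero-variance controls); Z >= 0.5 is the
conventional "excellent assay" band.  For imaging screens whose
per-compound values are averages over r replicate wells/plates, the
replicate-adjusted variant shrinks the spread term by sqrt(r),
reflecting the standard error of a replicate mean:

    Z_r = 1 - [3 * (sigma_p + sigma_n) / |mu_p - mu_n|] / sqrt(r)

(The alternative reading — dividing the whole expression by sqrt(r) —
is selectable via ``mode="whole"`` but caps a perfect assay at
1/sqrt(r), which is why it is not the default.)
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "ControlSummary",
    "ZFactorReport",
    "z_factor",
    "z_factor_replicate_adjusted",
    "plate_qc",
    "qc_all_plates",
]


class QCError(ValueError):
    """A plate failed a structural QC precondition (e.g. missing controls)."""


@dataclass(frozen=True)
class ControlSummary:
    """Means and sample SDs of the positive and negative control wells."""

    mu_p: float
    sigma_p: float
    mu_n: float
    sigma_n: float
    n_p: int = 2
    n_n: int = 2

    def __post_init__(self) -> None:
        if self.sigma_p < 0 or self.sigma_n < 0:
            raise ValueError("control SDs must be non-negative")
        if self.n_p < 2 or self.n_n < 2:
            raise ValueError("need >=2 wells per control group to estimate an SD")

    @classmethod
    def from_values(cls, positive: Iterable[float], negative: Iterable[float]) -> "ControlSummary":
        pos = np.asarray(list(positive), dtype=float)
        neg = np.asarray(list(negative), dtype=float)
        if pos.size < 2 or neg.size < 2:
            raise QCError(
                f"need >=2 wells per control group, got {pos.size} positive / {neg.size} negative"
            )
        return cls(
            mu_p=float(pos.mean()),
            sigma_p=float(pos.std(ddof=1)),
            mu_n=float(neg.mean()),
            sigma_n=float(neg.std(ddof=1)),
            n_p=int(pos.size),
            n_n=int(neg.size),
        )

    def swapped(self) -> "ControlSummary":
        return ControlSummary(self.mu_n, self.sigma_n, self.mu_p, self.sigma_p, self.n_n, self.n_p)


@dataclass(frozen=True)
class ZFactorReport:
    """Per-plate QC verdict: the Z value, its variant, and pass/fail."""

    plate_id: str
    summary: ControlSummary
    z: float
    replicates: int
    adjusted: bool
    pass_threshold: float
    passed: bool

    def to_dict(self) -> dict:
        d = asdict(self)
        d["summary"] = asdict(self.summary)
        return d


def z_factor(summary: ControlSummary) -> float:
    """Plain Z-factor; symmetric in the two control groups and always <= 1."""
    sep = abs(summary.mu_p - summary.mu_n)
    if sep == 0:
        raise ZeroDivisionError("Z-factor undefined: control means are identical")
    return 1.0 - 3.0 * (summary.sigma_p + summary.sigma_n) / sep


def z_factor_replicate_adjusted(
    summary: ControlSummary,
    r: int,
    mode: Literal["spread", "whole"] = "spread",
) -> float:
    """Replicate-adjusted Z-factor for r-fold replicated measurements.

    ``mode="spread"`` (default) divides the spread term by sqrt(r) so that a
    zero-variance assay still scores 1; ``mode="whole"`` divides the entire
    plain Z by sqrt(r).
    """
    if r < 1:
        raise ValueError(f"replicate count must be >= 1, got {r}")
    sep = abs(summary.mu_p - summary.mu_n)
    if sep == 0:
        raise ZeroDivisionError("Z-factor undefined: control means are identical")
    if mode == "spread":
        return 1.0 - (3.0 * (summary.sigma_p + summary.sigma_n) / sep) / math.sqrt(r)
    if mode == "whole":
        return (1.0 - 3.0 * (summary.sigma_p + summary.sigma_n) / sep) / math.sqrt(r)
    raise ValueError(f"unknown mode {mode!r}")


def plate_qc(
    plate: pd.DataFrame,
    value_col: str,
    pos_role: str,
    neg_role: str,
    threshold: float = 0.5,
    r: int = 1,
    adjusted: bool = False,
    role_col: str = "role",
    plate_id: str | None = None,
    mode: Literal["spread", "whole"] = "spread",
) -> ZFactorReport:
    """QC one plate's control wells and return its Z-factor verdict.

    Raises :class:`QCError` naming the plate if either control role is
    missing or has fewer than two wells.
    """
    pid = plate_id if plate_id is not None else str(plate["plate_id"].iloc[0]) if "plate_id" in plate else "?"
    pos = plate.loc[plate[role_col] == pos_role, value_col]
    neg = plate.loc[plate[role_col] == neg_role, value_col]
    if len(pos) < 2 or len(neg) < 2:
        raise QCError(
            f"plate {pid}: need >=2 wells for roles {pos_role!r}/{neg_role!r}, "
            f"got {len(pos)}/{len(neg)}"
        )
    summary = ControlSummary.from_values(pos, neg)
    z = z_factor_replicate_adjusted(summary, r, mode=mode) if adjusted else z_factor(summary)
    return ZFactorReport(
        plate_id=pid,
        summary=summary,
        z=float(z),
        replicates=int(r),
        adjusted=bool(adjusted),
        pass_threshold=float(threshold),
        passed=bool(z >= threshold),
    )


def qc_all_plates(
    plates: pd.DataFrame,
    value_col: str,
    pos_role: str,
    neg_role: str,
    threshold: float = 0.5,
    r: int = 1,
    adjusted: bool = False,
    role_col: str = "role",
) -> list[ZFactorReport]:
    """Run :func:`plate_qc` on every plate_id group of a well table."""
    return [
        plate_qc(
            grp, value_col, pos_role, neg_role,
            threshold=threshold, r=r, adjusted=adjusted,
            role_col=role_col, plate_id=str(pid),
        )
        for pid, grp in plates.groupby("plate_id", sort=True)
    ]


def write_qc_reports(reports: list[ZFactorReport], tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    rows = []
    for rep in reports:
        rows.append(
            {
                "plate_id": rep.plate_id,
                "z": rep.z,
                "mu_p": rep.summary.mu_p,
                "sigma_p": rep.summary.sigma_p,
                "mu_n": rep.summary.mu_n,
                "sigma_n": rep.summary.sigma_n,
                "n_p": rep.summary.n_p,
                "n_n": rep.summary.n_n,
                "replicates": rep.replicates,
                "adjusted": rep.adjusted,
                "pass_threshold": rep.pass_threshold,
                "passed": rep.passed,
            }
        )
    df = pd.DataFrame(rows)
    path = Path(tsv_path)
    with open(path, "w") as fh:
        fh.write("# cystirep qc-report v1\n")
        df.to_csv(fh, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps([r.to_dict() for r in reports], indent=2))
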