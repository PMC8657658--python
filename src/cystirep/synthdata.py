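"""Synthetic study generator with planted ground truth.

Generates every input the pipeline consumes, so each stage (and the
whole chain) can be validated against known answers:

* a plate-based cystine-depletion screen (vehicle and cysteamine-like
  controls, planted depleters, gaussian readout noise);
* a plate-based apoptosis screen (induced-untreated and non-induced
  controls, planted protectors, per-well nucleus counts);
* a negative-binomial gene x sample count matrix with planted up/down
  genes;
* per-compound prototype ranked lists (PRLs) with planted consensus
  reversal genes placed in the relevant tails of exactly their
  configured supporting compounds;
* small GMT gene-set collections with one set enriched for chosen
  focus genes.

All randomness flows from explicit per-config seeds; identical seeds
give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from cystirep.enrich import GeneSetCollection
from cystirep.reversal import RankedList

__all__ = [
    "ScreenSimConfig",
    "CountsSimConfig",
    "PRLSimConfig",
    "simulate_screen",
    "simulate_apoptosis_screen",
    "simulate_counts",
    "simulate_prls",
    "simulate_gene_sets",
    "compound_ids",
    "gene_ids",
]


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


def compound_ids(n: int) -> list[str]:
    return [f"CPD{i:04d}" for i in range(1, n + 1)]


def gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


_PLATE_GEOMETRY = {48: (6, 8), 96: (8, 12), 384: (16, 24)}


def _well_names(wells_per_plate: int) -> list[str]:
    rows, cols = _PLATE_GEOMETRY.get(wells_per_plate, (1, wells_per_plate))
    return [f"{chr(ord('A') + r)}{c + 1:02d}" for r in range(rows) for c in range(cols)]


# ---------------------------------------------------------------------------
# plate screens
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSimConfig:
    """Design of one plate-based screen with planted true actives.

    ``planted_hits`` maps compound id -> true effect (fractional
    reduction of the readout relative to vehicle, in [0, 1]).
    ``noise_sd`` is the per-well gaussian noise SD as a fraction of the
    negative-control mean.  ``n_plates=None`` uses the minimum number
    of plates that fits the library.
    """

    n_compounds: int = 1200
    wells_per_plate: int = 48
    neg_ctrl_per_plate: int = 4
    pos_ctrl_per_plate: int = 4
    planted_hits: tuple[tuple[str, float], ...] = ()
    noise_sd: float = 0.05
    n_plates: int | None = None
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds <= 0:
            raise ConfigError("n_compounds must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.neg_ctrl_per_plate < 2 or self.pos_ctrl_per_plate < 2:
            raise ConfigError("need >= 2 control wells per role per plate for QC")
        if self.capacity_per_plate <= 0:
            raise ConfigError(
                f"{self.wells_per_plate}-well plate cannot hold "
                f"{self.neg_ctrl_per_plate}+{self.pos_ctrl_per_plate} controls plus compounds"
            )
        lib = set(compound_ids(self.n_compounds))
        for cid, effect in self.planted_hits:
            if cid not in lib:
                raise ConfigError(f"planted compound {cid!r} not in the {self.n_compounds}-compound library")
            if not 0.0 <= effect <= 1.0:
                raise ConfigError(f"true effect must be in [0, 1], got {effect} for {cid}")
        if len({c for c, _ in self.planted_hits}) != len(self.planted_hits):
            raise ConfigError("duplicate planted compound ids")
        if self.plates_needed > (self.n_plates or self.plates_needed):
            raise ConfigError(
                f"{self.n_compounds} compounds need {self.plates_needed} plates, "
                f"only {self.n_plates} configured"
            )

    @property
    def capacity_per_plate(self) -> int:
        return self.wells_per_plate - self.neg_ctrl_per_plate - self.pos_ctrl_per_plate

    @property
    def plates_needed(self) -> int:
        return math.ceil(self.n_compounds / self.capacity_per_plate)


# baseline study constants (see docs/methods.md for the rationale)
VEHICLE_CYSTINE = 6.0      # nmol/mg protein in untreated cystinotic cells
CYSTEAMINE_RESIDUAL = 0.02  # cysteamine clears ~98% of lysosomal cystine
PROTEIN_MG = 0.02           # per-well protein mass
INDUCED_FRACTION = 0.40     # caspase-positive fraction under Fas-L + CHX
NON_INDUCED_FRACTION = 0.04
TOTAL_NUCLEI = 1200         # nuclei imaged per well


def _screen_truth(cfg: ScreenSimConfig, phenotype: str) -> pd.DataFrame:
    effects = dict(cfg.planted_hits)
    ids = compound_ids(cfg.n_compounds)
    return pd.DataFrame(
        {
            "compound_id": ids,
            "phenotype": phenotype,
            "true_effect": [effects.get(c, 0.0) for c in ids],
        }
    )


def simulate_screen(cfg: ScreenSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the cystine HTS; returns (well table, ground-truth table).

    Vehicle wells read the baseline protein-normalized cystine level,
    cysteamine-like positive controls read near zero, and a planted
    depleter of effect e reads (1 - e) times the vehicle level, all
    perturbed by gaussian noise of SD noise_sd x vehicle level (clipped
    at zero).  Protein content carries its own small jitter; it cancels
    in percent-of-vehicle so the planted effects are exact at zero noise.
    """
    rng = np.random.default_rng(cfg.seed)
    effects = dict(cfg.planted_hits)
    ids = compound_ids(cfg.n_compounds)
    n_plates = cfg.n_plates or cfg.plates_needed
    wells = _well_names(cfg.wells_per_plate)

    rows = []
    for rep in range(1, cfg.n_replicates + 1):
        cursor = 0
        for p in range(1, n_plates + 1):
            plate_id = f"CY-R{rep}-P{p:02d}"
            n_cmpd = min(cfg.capacity_per_plate, cfg.n_compounds - cursor)
            roles = (
                ["vehicle"] * cfg.neg_ctrl_per_plate
                + ["positive"] * cfg.pos_ctrl_per_plate
                + ["compound"] * n_cmpd
            )
            plate_cmpds = ids[cursor : cursor + n_cmpd]
            cursor += n_cmpd
            ci = iter(plate_cmpds)
            for well, role in zip(wells, roles):
                if role == "vehicle":
                    cid, true = "DMSO", VEHICLE_CYSTINE
                elif role == "positive":
                    cid, true = "CYSTEAMINE", VEHICLE_CYSTINE * CYSTEAMINE_RESIDUAL
                else:
                    cid = next(ci)
                    true = VEHICLE_CYSTINE * (1.0 - effects.get(cid, 0.0))
                observed = true + cfg.noise_sd * VEHICLE_CYSTINE * rng.standard_normal()
                observed = max(observed, 0.0)
                protein = PROTEIN_MG * max(0.1, 1.0 + cfg.noise_sd * rng.standard_normal())
                rows.append(
                    {
                        "plate_id": plate_id,
                        "well": well,
                        "replicate": rep,
                        "compound_id": cid,
                        "role": role,
                        "cystine_nmol": observed * protein,
                        "protein_mg": protein,
                    }
                )
    return pd.DataFrame(rows), _screen_truth(cfg, "cystine")


def simulate_apoptosis_screen(cfg: ScreenSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the caspase-3/7 HCS; returns (well table, truth table).

    Control roles: ``induced`` (apoptotic stimulus, no drug — the 100%
    reference, configured by ``neg_ctrl_per_plate``) and ``non_induced``
    (vehicle only, configured by ``pos_ctrl_per_plate``).  A planted
    protector of effect e lowers the caspase-positive fraction to
    (1 - e) times the induced level.  Per-well output is nucleus counts,
    the imaging pipeline's native readout.
    """
    rng = np.random.default_rng(cfg.seed)
    effects = dict(cfg.planted_hits)
    ids = compound_ids(cfg.n_compounds)
    n_plates = cfg.n_plates or cfg.plates_needed
    wells = _well_names(cfg.wells_per_plate)

    rows = []
    for rep in range(1, cfg.n_replicates + 1):
        cursor = 0
        for p in range(1, n_plates + 1):
            plate_id = f"AP-R{rep}-P{p:02d}"
            n_cmpd = min(cfg.capacity_per_plate, cfg.n_compounds - cursor)
            roles = (
                ["induced"] * cfg.neg_ctrl_per_plate
                + ["non_induced"] * cfg.pos_ctrl_per_plate
                + ["compound"] * n_cmpd
            )
            plate_cmpds = ids[cursor : cursor + n_cmpd]
            cursor += n_cmpd
            ci = iter(plate_cmpds)
            for well, role in zip(wells, roles):
                if role == "induced":
                    cid, true = "FASL_CHX", INDUCED_FRACTION
                elif role == "non_induced":
                    cid, true = "DMSO", NON_INDUCED_FRACTION
                else:
                    cid = next(ci)
                    true = INDUCED_FRACTION * (1.0 - effects.get(cid, 0.0))
                frac = true + cfg.noise_sd * INDUCED_FRACTION * rng.standard_normal()
                frac = min(max(frac, 0.0), 1.0)
                rows.append(
                    {
                        "plate_id": plate_id,
                        "well": well,
                        "replicate": rep,
                        "compound_id": cid,
                        "role": role,
                        "positive_nuclei": int(round(frac * TOTAL_NUCLEI)),
                        "total_nuclei": TOTAL_NUCLEI,
                    }
                )
    return pd.DataFrame(rows), _screen_truth(cfg, "apoptosis")


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountsSimConfig:
    """NB count-matrix design: two groups, planted log2 effects.

    ``planted_up`` / ``planted_down`` map gene id -> log2 effect of the
    knockout group relative to wild-type (>= 1 for up, <= -1 for down).
    The NB law has Var(K) = mu + dispersion * mu^2.
    """

    n_genes: int = 10000
    n_per_group: int = 3
    baseline_mean: float = 100.0
    dispersion: float = 0.02
    planted_up: tuple[tuple[str, float], ...] = ()
    planted_down: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_per_group <= 0:
            raise ConfigError("n_genes and n_per_group must be positive integers")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be > 0")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        up = {g for g, _ in self.planted_up}
        down = {g for g, _ in self.planted_down}
        if up & down:
            raise ConfigError(f"genes planted both up and down: {sorted(up & down)[:5]}")
        genome = set(gene_ids(self.n_genes))
        missing = (up | down) - genome
        if missing:
            raise ConfigError(f"planted genes outside the genome: {sorted(missing)[:5]}")
        for g, e in self.planted_up:
            if e < 1:
                raise ConfigError(f"planted_up effect for {g} must be >= 1, got {e}")
        for g, e in self.planted_down:
            if e > -1:
                raise ConfigError(f"planted_down effect for {g} must be <= -1, got {e}")


def simulate_counts(cfg: CountsSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the count matrix; returns (counts, truth table).

    Counts has gene rows and columns WT_1..WT_n, KO_1..KO_n; truth has
    columns gene and log2_effect (0 for unplanted genes).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = gene_ids(cfg.n_genes)
    effect = pd.Series(0.0, index=genes)
    for g, e in cfg.planted_up:
        effect[g] = e
    for g, e in cfg.planted_down:
        effect[g] = e

    mu_wt = np.full(cfg.n_genes, cfg.baseline_mean)
    mu_ko = cfg.baseline_mean * np.power(2.0, effect.to_numpy())

    r = 1.0 / cfg.dispersion  # NB size parameter
    def draw(mu: np.ndarray, n: int) -> np.ndarray:
        p = r / (r + mu)
        return rng.negative_binomial(r, p[:, None], size=(cfg.n_genes, n))

    wt = draw(mu_wt, cfg.n_per_group)
    ko = draw(mu_ko, cfg.n_per_group)
    cols = [f"WT_{i+1}" for i in range(cfg.n_per_group)] + [
        f"KO_{i+1}" for i in range(cfg.n_per_group)
    ]
    counts = pd.DataFrame(np.hstack([wt, ko]), index=pd.Index(genes, name="gene"), columns=cols)
    truth = pd.DataFrame({"gene": genes, "log2_effect": effect.to_numpy()})
    return counts, truth


# ---------------------------------------------------------------------------
# prototype ranked lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PRLSimConfig:
    """Per-compound ranked-list design with planted consensus reversers.

    ``planted_reversers`` maps gene -> (disease direction "up"/"down",
    number of supporting compounds).  A disease-up gene is placed in the
    bottom (compound-down) tail of exactly its supporting compounds'
    lists and strictly outside both tails elsewhere; symmetric for
    disease-down genes.  ``tail_size`` defines the tails used for
    placement and must match the voting stage's tail size.
    """

    genome: tuple[str, ...]
    n_compounds: int = 5
    planted_reversers: tuple[tuple[str, tuple[str, int]], ...] = ()
    tail_size: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds <= 0:
            raise ConfigError("n_compounds must be > 0")
        if len(set(self.genome)) != len(self.genome):
            raise ConfigError("genome contains duplicate gene ids")
        if 2 * self.tail_size >= len(self.genome):
            raise ConfigError("tail_size too large: tails must leave a middle zone")
        genome = set(self.genome)
        for gene, (direction, support) in self.planted_reversers:
            if gene not in genome:
                raise ConfigError(f"planted gene {gene!r} absent from genome")
            if direction not in ("up", "down"):
                raise ConfigError(f"direction for {gene} must be 'up' or 'down'")
            if not 0 <= support <= self.n_compounds:
                raise ConfigError(
                    f"support {support} for {gene} exceeds {self.n_compounds} compounds"
                )
        if len({g for g, _ in self.planted_reversers}) != len(self.planted_reversers):
            raise ConfigError("duplicate planted genes")


def simulate_prls(
    cfg: PRLSimConfig, compound_names: Sequence[str] | None = None
) -> tuple[list[RankedList], pd.DataFrame]:
    """Build the per-compound PRLs; returns (ranked lists, truth table).

    Truth columns: gene, disease_direction, support, compounds (comma-
    joined supporting compound ids).
    """
    rng = np.random.default_rng(cfg.seed)
    if compound_names is None:
        compound_names = [f"DRUG{i+1}" for i in range(cfg.n_compounds)]
    if len(compound_names) != cfg.n_compounds:
        raise ConfigError("compound_names length must equal n_compounds")

    planted = {g: spec for g, spec in cfg.planted_reversers}
    supporters: dict[str, set[int]] = {
        g: set(rng.choice(cfg.n_compounds, size=spec[1], replace=False).tolist())
        for g, spec in cfg.planted_reversers
    }
    non_planted = [g for g in cfg.genome if g not in planted]
    N, T = len(cfg.genome), cfg.tail_size

    lists = []
    for j in range(cfg.n_compounds):
        forced_top: list[str] = []     # compound-up tail
        forced_bottom: list[str] = []  # compound-down tail
        forced_mid: list[str] = []
        for g, (direction, _) in planted.items():
            if j in supporters[g]:
                (forced_bottom if direction == "up" else forced_top).append(g)
            else:
                forced_mid.append(g)
        if len(forced_top) > T or len(forced_bottom) > T:
            raise ConfigError("more planted genes than tail slots; increase tail_size")
        if len(forced_mid) > N - 2 * T:
            raise ConfigError("more planted genes than middle slots")

        stream = iter(rng.permutation(non_planted))
        top = forced_top + [next(stream) for _ in range(T - len(forced_top))]
        mid = forced_mid + [next(stream) for _ in range(N - 2 * T - len(forced_mid))]
        bottom = forced_bottom + [next(stream) for _ in range(T - len(forced_bottom))]
        for zone in (top, mid, bottom):
            rng.shuffle(zone)
        lists.append(RankedList(compound_names[j], tuple(top + mid + bottom)))

    truth = pd.DataFrame(
        [
            {
                "gene": g,
                "disease_direction": planted[g][0],
                "support": planted[g][1],
                "compounds": ",".join(sorted(compound_names[j] for j in supporters[g])),
            }
            for g in planted
        ],
        columns=["gene", "disease_direction", "support", "compounds"],
    ).sort_values("gene").reset_index(drop=True)
    return lists, truth


# ---------------------------------------------------------------------------
# dose-response confirmation data
# ---------------------------------------------------------------------------

def simulate_dose_response(
    compounds: Sequence[str],
    doses: Sequence[float] = (1.0, 2.5, 5.0, 10.0),
    n_replicates: int = 3,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Four-parameter-logistic response data for lead compounds.

    Each compound gets true parameters drawn once (top 100%, bottom in
    [10, 30]%, EC50 log-uniform within the dose range, Hill slope in
    [0.8, 2]) and ``n_replicates`` noisy responses per dose (gaussian,
    percent scale).  Returns (measurements, truth table).
    """
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for cid in compounds:
        top = 100.0
        bottom = float(rng.uniform(10.0, 30.0))
        ec50 = float(np.exp(rng.uniform(np.log(min(doses)), np.log(max(doses)))))
        hill = float(rng.uniform(0.8, 2.0))
        truth.append({"compound_id": cid, "top": top, "bottom": bottom, "ec50": ec50, "hill": hill})
        for dose in doses:
            y_true = bottom + (top - bottom) / (1.0 + (dose / ec50) ** hill)
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "compound_id": cid,
                        "dose_uM": dose,
                        "replicate": rep,
                        "response_percent": y_true + noise_sd * rng.standard_normal(),
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def simulate_gene_sets(
    genome: Sequence[str],
    focus_genes: Iterable[str] = (),
    n_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 50),
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene sets over a genome, plus one set enriched in focus genes.

    The focus set (id SET000) contains every focus gene plus random
    padding, guaranteeing a strongly over-represented term when the
    focus genes are later used as the query.
    """
    rng = np.random.default_rng(seed)
    genome = list(genome)
    focus = [g for g in focus_genes if g in set(genome)]
    sets: dict[str, tuple[str, list[str]]] = {}
    if focus:
        pad = rng.choice([g for g in genome if g not in set(focus)], size=min(10, len(genome) - len(focus)), replace=False)
        sets["SET000"] = ("focus_module", focus + pad.tolist())
    lo, hi = set_size_range
    for i in range(1, n_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genome, size=size, replace=False)
        sets[f"SET{i:03d}"] = (f"random_module_{i}", members.tolist())
    return GeneSetCollection.from_sets(sets, genome)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t", index: bool = False, schema: str = "table") -> None:
    """Write a table with the package's schema-version comment line."""
    with open(Path(path), "w") as fh:
        fh.write(f"# cystirep {schema} v1\n")
        df.to_csv(fh, sep=sep, index=index)
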