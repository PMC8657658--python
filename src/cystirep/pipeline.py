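"""End-to-end orchestration of the drug-repurposing analysis.

The default study mirrors the published screen design: a 1200-compound
library screened for cystine depletion (24 planted depleters, ≥50%
reduction calls) and apoptosis protection (27 planted protectors, 6
overlapping with the depleters, ≥40% reduction calls); plate-level
Z-factor QC; dose-response and ANOVA confirmation of the crossed leads
(one lead excluded as toxic, leaving five); a 10,000-gene triplicate
NB count matrix with 200 planted differentially expressed genes; five
lead-compound PRLs carrying 23 disease-up and 16 disease-down planted
reversal genes at support >= 4 plus support-3 decoys; and a
hypergeometric enrichment of the voted reversal genes.

:func:`run_pipeline` executes qc -> cystine -> apoptosis -> cross ->
dose-response -> dge -> reversal -> enrich and returns a manifest of
summary counts, QC verdicts, and planted-truth recovery diagnostics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cystirep import apoptosis as apo
from cystirep import cystine as cys
from cystirep import dge, enrich, integrate, reversal, screenqc
from cystirep import synthdata as sd

__all__ = ["PipelineConfig", "StudySpec", "default_study", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable analysis constant in one place."""

    cystine_threshold: float = 50.0   # percent reduction
    apoptosis_threshold: float = 40.0
    fdr_cut: float = 0.05
    lfc_cut: float = 1.0
    k: int = 4                        # voting quorum
    tail_size: int = 250              # PRL tail defining a compound's up/down sets
    z_pass_threshold: float = 0.5     # reported per-plate QC band
    z_exclude_threshold: float = 0.0  # plates below this are dropped from analysis
    z_mode: str = "spread"            # replicate-adjusted Z variant
    exclusions: tuple[str, ...] = ()  # e.g. toxic compounds dropped before dose-response

    def __post_init__(self) -> None:
        if not 0 < self.cystine_threshold < 100 or not 0 < self.apoptosis_threshold < 100:
            raise ValueError("reduction thresholds must lie in (0, 100)")
        if not 0 < self.fdr_cut < 1:
            raise ValueError("fdr_cut must lie in (0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class StudySpec:
    """A fully seeded synthetic study: one config per generated input."""

    screen_cfg: sd.ScreenSimConfig
    apoptosis_cfg: sd.ScreenSimConfig
    counts_cfg: sd.CountsSimConfig
    prl_seed: int
    dose_seed: int
    geneset_seed: int
    toxic_lead: str
    n_reversal_up: int = 23
    n_reversal_down: int = 16
    n_decoys_per_direction: int = 3
    config: PipelineConfig = field(default_factory=PipelineConfig)


def default_study(
    seed: int,
    n_compounds: int = 1200,
    n_depleters: int = 24,
    n_protectors: int = 27,
    n_overlap: int = 6,
    n_genes: int = 10000,
    n_per_group: int = 3,
    n_planted_degs: int = 200,
    n_reversal_up: int = 23,
    n_reversal_down: int = 16,
    n_decoys_per_direction: int = 3,
    noise_sd: float = 0.05,
    config: PipelineConfig | None = None,
) -> StudySpec:
    """Build the seeded default study (sizes overridable for small tests)."""
    if config is None:
        config = PipelineConfig()
    ss = np.random.default_rng(seed)
    seeds = ss.integers(0, 2**31 - 1, size=6)

    lib = sd.compound_ids(n_compounds)
    pick = np.random.default_rng(seeds[0])
    chosen = pick.choice(n_compounds, size=n_depleters + n_protectors - n_overlap, replace=False)
    depleters = [lib[i] for i in chosen[:n_depleters]]
    overlap = depleters[:n_overlap]
    protectors = overlap + [lib[i] for i in chosen[n_depleters:]]

    screen_cfg = sd.ScreenSimConfig(
        n_compounds=n_compounds,
        wells_per_plate=48,
        neg_ctrl_per_plate=4,
        pos_ctrl_per_plate=4,
        planted_hits=tuple((c, 0.8) for c in depleters),
        noise_sd=noise_sd,
        seed=int(seeds[1]),
    )
    apoptosis_cfg = sd.ScreenSimConfig(
        n_compounds=n_compounds,
        wells_per_plate=384,
        neg_ctrl_per_plate=32,
        pos_ctrl_per_plate=32,
        planted_hits=tuple((c, 0.6) for c in protectors),
        noise_sd=noise_sd,
        n_replicates=3,
        seed=int(seeds[2]),
    )

    genes = sd.gene_ids(n_genes)
    n_special_up = n_reversal_up + n_decoys_per_direction
    n_special_down = n_reversal_down + n_decoys_per_direction
    n_up = n_planted_degs // 2
    n_down = n_planted_degs - n_up
    if n_special_up > n_up or n_special_down > n_down:
        raise ValueError("reversal/decoy genes must fit within the planted DEG budget")
    gpick = np.random.default_rng(seeds[3])
    planted_idx = gpick.choice(n_genes, size=n_planted_degs, replace=False)
    up_genes = [genes[i] for i in planted_idx[:n_up]]
    down_genes = [genes[i] for i in planted_idx[n_up:]]
    # strong, unambiguous effects for the reversal-designated genes;
    # ordinary planted DEGs span the detection boundary
    planted_up = tuple(
        (g, 3.0) if i < n_special_up else (g, float(gpick.uniform(1.0, 2.5)))
        for i, g in enumerate(up_genes)
    )
    planted_down = tuple(
        (g, -3.0) if i < n_special_down else (g, -float(gpick.uniform(1.0, 2.5)))
        for i, g in enumerate(down_genes)
    )
    counts_cfg = sd.CountsSimConfig(
        n_genes=n_genes,
        n_per_group=n_per_group,
        baseline_mean=100.0,
        dispersion=0.02,
        planted_up=planted_up,
        planted_down=planted_down,
        seed=int(seeds[4]),
    )
    return StudySpec(
        screen_cfg=screen_cfg,
        apoptosis_cfg=apoptosis_cfg,
        counts_cfg=counts_cfg,
        prl_seed=int(seeds[5]),
        dose_seed=int(seeds[0]) ^ 0x5A5A5A,
        geneset_seed=int(seeds[1]) ^ 0x5A5A5A,
        toxic_lead=overlap[0] if overlap else "",
        n_reversal_up=n_reversal_up,
        n_reversal_down=n_reversal_down,
        n_decoys_per_direction=n_decoys_per_direction,
        config=config,
    )


def _planted_reversers(spec: StudySpec) -> tuple[tuple[str, tuple[str, int]], ...]:
    """Support assignment for the reversal-designated genes of the study.

    The first genes of each direction block get full (5) support, the
    rest of the true reversers get the quorum (4), and the trailing
    decoys get 3 — one short of the default quorum, so a correct voter
    must leave them out.
    """
    cfg = spec.counts_cfg
    up = [g for g, e in cfg.planted_up if e == 3.0]
    down = [g for g, e in cfg.planted_down if e == -3.0]
    assert len(up) == spec.n_reversal_up + spec.n_decoys_per_direction
    assert len(down) == spec.n_reversal_down + spec.n_decoys_per_direction
    out: list[tuple[str, tuple[str, int]]] = []
    for genes, n_true, direction in (
        (up, spec.n_reversal_up, "up"),
        (down, spec.n_reversal_down, "down"),
    ):
        half = n_true // 2
        out += [(g, (direction, 5)) for g in genes[:half]]
        out += [(g, (direction, 4)) for g in genes[half:n_true]]
        out += [(g, (direction, 3)) for g in genes[n_true:]]
    return tuple(out)


def run_pipeline(spec: StudySpec, outdir: str | Path | None = None) -> dict:
    """Run the whole analysis on a synthetic study; return the manifest.

    The manifest records per-stage summary counts, QC verdicts, and —
    because the study is synthetic — recovery diagnostics against the
    planted truth.  With ``outdir`` set, every intermediate table and
    the manifest itself are written there.
    """
    cfg = spec.config
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": []}

    # --- simulate inputs -------------------------------------------------
    cys_plates, cys_truth = sd.simulate_screen(spec.screen_cfg)
    apo_plates, apo_truth = sd.simulate_apoptosis_screen(spec.apoptosis_cfg)
    if cys_plates[cys_plates["role"] == "compound"].empty:
        raise RuntimeError("stage cystine: no compound wells in the screen input")

    # --- QC ---------------------------------------------------------------
    cys_plates = cys_plates.assign(
        normalized=cys_plates["cystine_nmol"] / cys_plates["protein_mg"]
    )
    cys_qc = screenqc.qc_all_plates(
        cys_plates, "normalized", pos_role="positive", neg_role="vehicle",
        threshold=cfg.z_pass_threshold,
    )
    apo_plates = apo_plates.assign(
        fraction=apo_plates["positive_nuclei"] / apo_plates["total_nuclei"]
    )
    apo_qc = screenqc.qc_all_plates(
        apo_plates, "fraction", pos_role="non_induced", neg_role="induced",
        threshold=cfg.z_pass_threshold, r=spec.apoptosis_cfg.n_replicates, adjusted=True,
    )
    excluded_cys = {r.plate_id for r in cys_qc if r.z < cfg.z_exclude_threshold}
    excluded_apo = {r.plate_id for r in apo_qc if r.z < cfg.z_exclude_threshold}
    if excluded_cys or excluded_apo:
        log.warning("QC excluded plates: %s", sorted(excluded_cys | excluded_apo))
    cys_kept = cys_plates[~cys_plates["plate_id"].isin(excluded_cys)]
    apo_kept = apo_plates[~apo_plates["plate_id"].isin(excluded_apo)]

    # assay-level Z on all control wells pooled, as for a single big assay
    hts_summary = screenqc.ControlSummary.from_values(
        cys_plates.loc[cys_plates["role"] == "positive", "normalized"],
        cys_plates.loc[cys_plates["role"] == "vehicle", "normalized"],
    )
    hcs_summary = screenqc.ControlSummary.from_values(
        apo_plates.loc[apo_plates["role"] == "non_induced", "fraction"],
        apo_plates.loc[apo_plates["role"] == "induced", "fraction"],
    )
    manifest["qc"] = {
        "hts_z": screenqc.z_factor(hts_summary),
        "hcs_z_adjusted": screenqc.z_factor_replicate_adjusted(
            hcs_summary, spec.apoptosis_cfg.n_replicates, mode=cfg.z_mode
        ),
        "cystine_plates": len(cys_qc),
        "cystine_plates_passed": sum(r.passed for r in cys_qc),
        "apoptosis_plates": len(apo_qc),
        "apoptosis_plates_passed": sum(r.passed for r in apo_qc),
        "excluded_plates": sorted(excluded_cys | excluded_apo),
    }
    manifest["stages"].append("qc")

    # --- cystine screen ---------------------------------------------------
    activities = cys.compound_activities(cys_kept)
    cystine_results = cys.call_cystine_hits(activities, cfg.cystine_threshold)
    cystine_hits = set(cystine_results.loc[cystine_results["hit"], "compound_id"])
    planted_depleters = {c for c, e in spec.screen_cfg.planted_hits}
    manifest["cystine"] = {
        "n_hits": len(cystine_hits),
        "hits": sorted(cystine_hits),
        "planted_recovered_exactly": cystine_hits == planted_depleters,
    }
    manifest["stages"].append("cystine")

    # --- apoptosis screen ---------------------------------------------------
    normalized = apo.compound_apoptosis(apo_kept)
    apoptosis_results = apo.call_apoptosis_hits(normalized, cfg.apoptosis_threshold)
    apoptosis_hits = set(apoptosis_results.loc[apoptosis_results["hit"], "compound_id"])
    planted_protectors = {c for c, e in spec.apoptosis_cfg.planted_hits}
    manifest["apoptosis"] = {
        "n_hits": len(apoptosis_hits),
        "hits": sorted(apoptosis_hits),
        "planted_recovered_exactly": apoptosis_hits == planted_protectors,
    }
    manifest["stages"].append("apoptosis")

    # --- cross + dose-response confirmation -------------------------------
    crossed = integrate.cross_screens(cystine_hits, apoptosis_hits)
    exclusions = set(cfg.exclusions) | {spec.toxic_lead}
    leads = sorted(crossed - exclusions)
    manifest["cross"] = {
        "n_crossed": len(crossed),
        "crossed": sorted(crossed),
        "excluded_toxic": sorted(crossed & exclusions),
        "leads": leads,
    }
    manifest["stages"].append("cross")

    if not leads:
        raise RuntimeError("stage cross: no lead compounds survive crossing and exclusion")
    dr_data, dr_truth = sd.simulate_dose_response(leads, seed=spec.dose_seed)
    fits, anova_sig = {}, 0
    for cid, grp in dr_data.groupby("compound_id"):
        fit = integrate.fit_4pl(
            grp["dose_uM"].to_numpy(), grp["response_percent"].to_numpy(), compound_id=cid
        )
        fits[cid] = fit
        groups = [g["response_percent"].to_numpy() for _, g in grp.groupby("dose_uM")]
        res = integrate.confirm_by_anova(groups)
        anova_sig += res.p < 0.05
    manifest["dose_response"] = {
        "n_fit": len(fits),
        "n_converged": sum(f.converged for f in fits.values()),
        "ec50": {c: f.ec50 for c, f in fits.items() if f.converged},
        "anova_significant": int(anova_sig),
    }
    manifest["stages"].append("dose_response")

    # --- differential expression -------------------------------------------
    counts, counts_truth = sd.simulate_counts(spec.counts_cfg)
    groups = ["wild_type"] * spec.counts_cfg.n_per_group + ["knockout"] * spec.counts_cfg.n_per_group
    factors = dge.size_factors(counts)
    deg = dge.nb_wald_test(counts, groups, reference="wild_type", factors=factors)
    deg = dge.label_degs(deg, cfg.fdr_cut, cfg.lfc_cut)
    summary = dge.deg_summary(deg, cfg.fdr_cut, cfg.lfc_cut)

    truth_dir = np.where(
        counts_truth["log2_effect"] >= 1, "up",
        np.where(counts_truth["log2_effect"] <= -1, "down", "ns"),
    )
    merged = deg.merge(
        counts_truth.assign(true_direction=truth_dir), on="gene", validate="1:1"
    )
    planted = merged["true_direction"] != "ns"
    called = merged["direction"] != "ns"
    tp = int((planted & (merged["direction"] == merged["true_direction"])).sum())
    fp = int((called & ~planted).sum())
    sensitivity = tp / int(planted.sum()) if planted.any() else float("nan")
    observed_fdr = fp / max(int(called.sum()), 1)
    manifest["dge"] = {
        **summary,
        "sensitivity": sensitivity,
        "observed_fdr": observed_fdr,
    }
    manifest["stages"].append("dge")

    # --- signature reversal -------------------------------------------------
    planted_reversers = _planted_reversers(spec)
    prl_cfg = sd.PRLSimConfig(
        genome=tuple(counts.index),
        n_compounds=max(len(leads), 1),
        planted_reversers=planted_reversers,
        tail_size=cfg.tail_size,
        seed=spec.prl_seed,
    )
    prls, prl_truth = sd.simulate_prls(prl_cfg, compound_names=leads or None)
    signatures = [reversal.tails_to_signature(rl, cfg.tail_size) for rl in prls]
    candidates, vote_summary = reversal.vote_reversal(deg, signatures, k=cfg.k)
    expected = set(
        prl_truth.loc[prl_truth["support"] >= cfg.k, "gene"]
    )
    manifest["reversal"] = {
        **vote_summary,
        "genes": sorted(candidates["gene"]),
        "planted_recovered_exactly": set(candidates["gene"]) == expected,
    }
    manifest["stages"].append("reversal")

    # --- enrichment -----------------------------------------------------------
    query = list(candidates["gene"])
    collection = sd.simulate_gene_sets(
        list(counts.index), focus_genes=query, seed=spec.geneset_seed
    )
    enr = enrich.hypergeom_enrich(query, collection)
    clustered = enrich.summarize_clusters(enr, collection)
    manifest["enrich"] = {
        "n_sets_tested": int(len(enr)),
        "n_significant": int((enr["fdr"] < cfg.fdr_cut).sum()),
        "top_set": enr.iloc[0]["set_id"],
        "top_p": float(enr.iloc[0]["p"]),
        "n_clusters": int(clustered["cluster"].nunique()) if not clustered.empty else 0,
    }
    manifest["stages"].append("enrich")

    # --- outputs ---------------------------------------------------------------
    if out is not None:
        sd.write_table(cys_plates, out / "cystine_plates.csv", sep=",", schema="plate-table")
        sd.write_table(apo_plates, out / "apoptosis_plates.csv", sep=",", schema="plate-table")
        screenqc.write_qc_reports(cys_qc + apo_qc, out / "qc_report.tsv", out / "qc_report.json")
        cys.write_screen_results(cystine_results, out / "cystine_results.tsv")
        cys.write_screen_results(apoptosis_results, out / "apoptosis_results.tsv")
        sd.write_table(dr_data, out / "dose_response.csv", sep=",", schema="dose-response")
        sd.write_table(deg, out / "deg_table.tsv", schema="deg-table")
        sd.write_table(candidates, out / "reversal_candidates.tsv", schema="reversal-candidates")
        sd.write_table(enr, out / "enrichment.tsv", schema="enrichment")
        for rl in prls:
            reversal.write_ranked_list(rl, out / f"prl_{rl.compound_id}.txt")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
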