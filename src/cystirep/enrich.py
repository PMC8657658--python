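"""Hypergeometric over-representation analysis against GMT gene sets.

For a query of n genes drawn from a universe of M genes, a set with K
members in the universe and x members in the query is scored with the
upper-tail hypergeometric probability P(X >= x) (one-sided Fisher),
BH-adjusted over all tested sets.  A greedy Jaccard grouping collapses
redundant significant sets under a representative (lowest-p) term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from cystirep.dge import bh_adjust

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeom_enrich",
    "summarize_clusters",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets harmonized to a background universe."""

    sets: dict[str, tuple[str, frozenset[str]]]  # set_id -> (name, genes)
    universe: frozenset[str]

    @classmethod
    def from_sets(
        cls,
        sets: Mapping[str, tuple[str, Iterable[str]]],
        universe: Iterable[str],
    ) -> "GeneSetCollection":
        uni = frozenset(universe)
        harmonized: dict[str, tuple[str, frozenset[str]]] = {}
        dropped = 0
        for sid, (name, genes) in sets.items():
            g = frozenset(genes)
            inside = g & uni
            dropped += len(g) - len(inside)
            if not inside:
                continue
            harmonized[sid] = (name, inside)
        if dropped:
            log.info("dropped %d gene-set members outside the universe", dropped)
        if not harmonized:
            raise ValueError("no gene set overlaps the universe")
        return cls(sets=harmonized, universe=uni)


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (set_id <tab> name <tab> gene...).

    If no universe is given, the union of all set members is used.
    """
    raw: dict[str, tuple[str, list[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        raw[parts[0]] = (parts[1], parts[2:])
    if universe is None:
        universe = set().union(*(set(g) for _, g in raw.values()))
    return GeneSetCollection.from_sets(raw, universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for sid, (name, genes) in sorted(collection.sets.items()):
            fh.write("\t".join([sid, name, *sorted(genes)]) + "\n")


def hypergeom_enrich(query: Iterable[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric ORA of a query set against every gene set.

    Query genes outside the universe are dropped (and counted in a log
    message).  Returns a table sorted by ascending p with columns
    set_id, name, overlap, set_size, query_size, universe_size, p, fdr.
    """
    q_all = set(query)
    q = q_all & collection.universe
    dropped = len(q_all) - len(q)
    if dropped:
        log.info("dropped %d query genes outside the universe", dropped)
    if not q:
        raise ValueError("query is empty after harmonization to the universe")
    M = len(collection.universe)
    n = len(q)
    rows = []
    for sid, (name, genes) in collection.sets.items():
        K = len(genes)
        x = len(q & genes)
        # P(X >= x) with X ~ Hypergeom(M, K, n); sf(x-1) is the upper tail
        p = float(hypergeom.sf(x - 1, M, K, n))
        rows.append(
            {
                "set_id": sid,
                "name": name,
                "overlap": x,
                "set_size": K,
                "query_size": n,
                "universe_size": M,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).sort_values(["p", "set_id"]).reset_index(drop=True)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def summarize_clusters(
    results: pd.DataFrame,
    collection: GeneSetCollection,
    similarity_cut: float = 0.3,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Greedy Jaccard grouping of significant sets under representatives.

    Sets are visited by ascending p; each joins the first existing group
    whose representative's gene membership has Jaccard similarity >= cut,
    else founds a new group.  The representative is therefore always the
    group's lowest-p member.  Deterministic given the p-sorted input.
    """
    if results.empty:
        raise ValueError("no enrichment results to cluster")
    sig = results[results["fdr"] < fdr_cut].sort_values(["p", "set_id"])
    reps: list[str] = []
    assignment: dict[str, int] = {}
    for sid in sig["set_id"]:
        genes = collection.sets[sid][1]
        placed = False
        for gi, rep in enumerate(reps):
            rep_genes = collection.sets[rep][1]
            jac = len(genes & rep_genes) / len(genes | rep_genes)
            if jac >= similarity_cut:
                assignment[sid] = gi
                placed = True
                break
        if not placed:
            assignment[sid] = len(reps)
            reps.append(sid)
    out = sig.copy()
    out["cluster"] = [assignment[s] for s in out["set_id"]]
    out["representative"] = [reps[assignment[s]] for s in out["set_id"]]
    return out.reset_index(drop=True)
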