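"""Signature reversal: opposite-direction voting between disease and drugs.

Each compound contributes a ranked gene list (rank 1 = gene most
upregulated by the compound, last rank = most downregulated).  The top
and bottom ``tail_size`` genes form the compound's up/down signature.
A disease-upregulated gene is a reversal candidate when at least k of
the n compounds place it in their DOWN tail (the compounds are
predicted to push it back down); symmetrically for disease-down genes.
Genes the disease signature calls ns never qualify.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "RankedList",
    "CompoundSignature",
    "tails_to_signature",
    "aggregate_ranked_lists",
    "vote_reversal",
    "read_ranked_list",
    "write_ranked_list",
]


@dataclass(frozen=True)
class RankedList:
    """A total order over the genome for one compound, most-upregulated first."""

    compound_id: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            dupes = pd.Series(self.genes)
            raise ValueError(
                f"{self.compound_id}: ranked list is not a permutation "
                f"(duplicates: {sorted(set(dupes[dupes.duplicated()]))[:5]})"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class CompoundSignature:
    compound_id: str
    up_set: frozenset[str]
    down_set: frozenset[str]
    tail_size: int = field(default=0)

    def __post_init__(self) -> None:
        if self.up_set & self.down_set:
            raise ValueError(f"{self.compound_id}: up and down sets overlap")


def tails_to_signature(ranked: RankedList, tail_size: int) -> CompoundSignature:
    """Top tail = compound-up set, bottom tail = compound-down set."""
    if tail_size < 1:
        raise ValueError("tail_size must be >= 1")
    if 2 * tail_size > ranked.n_genes:
        raise ValueError(
            f"tail_size {tail_size} too large for a {ranked.n_genes}-gene list "
            "(tails would overlap)"
        )
    return CompoundSignature(
        compound_id=ranked.compound_id,
        up_set=frozenset(ranked.genes[:tail_size]),
        down_set=frozenset(ranked.genes[-tail_size:]),
        tail_size=tail_size,
    )


def aggregate_ranked_lists(lists: Sequence[RankedList], compound_id: str | None = None) -> RankedList:
    """Mean-rank (Borda) consensus of several rankings of one genome.

    Output is ordered by ascending mean rank; exact ties are broken
    lexicographically by gene id.  A single list is returned unchanged.
    """
    if not lists:
        raise ValueError("no ranked lists to aggregate")
    genome = set(lists[0].genes)
    for rl in lists[1:]:
        if set(rl.genes) != genome:
            raise ValueError(
                f"genome mismatch between {lists[0].compound_id!r} and {rl.compound_id!r}"
            )
    cid = compound_id if compound_id is not None else lists[0].compound_id
    if len(lists) == 1:
        return RankedList(cid, lists[0].genes)
    mean_rank: dict[str, float] = {g: 0.0 for g in genome}
    for rl in lists:
        for rank, gene in enumerate(rl.genes, start=1):
            mean_rank[gene] += rank
    order = sorted(genome, key=lambda g: (mean_rank[g], g))
    return RankedList(cid, tuple(order))


def vote_reversal(
    deg: pd.DataFrame,
    signatures: Sequence[CompoundSignature],
    k: int = 4,
) -> tuple[pd.DataFrame, dict]:
    """Opposite-direction k-of-n voting.

    ``deg`` must carry gene and direction (up/down/ns) columns.  Returns
    a candidate table (gene, disease_direction, supporting_compounds,
    compounds) sorted by support then gene id, plus summary counts for
    the two direction classes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(signatures):
        raise ValueError(f"k={k} exceeds the {len(signatures)} available signatures")
    rows = []
    for gene, direction in zip(deg["gene"], deg["direction"]):
        if direction == "up":
            support = [s.compound_id for s in signatures if gene in s.down_set]
        elif direction == "down":
            support = [s.compound_id for s in signatures if gene in s.up_set]
        else:
            continue
        if len(support) >= k:
            rows.append(
                {
                    "gene": gene,
                    "disease_direction": direction,
                    "supporting_compounds": len(support),
                    "compounds": ",".join(sorted(support)),
                }
            )
    table = pd.DataFrame(rows, columns=["gene", "disease_direction", "supporting_compounds", "compounds"])
    table = table.sort_values(
        ["supporting_compounds", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    summary = {
        "disease_up_drug_down": int((table["disease_direction"] == "up").sum()),
        "disease_down_drug_up": int((table["disease_direction"] == "down").sum()),
        "k": int(k),
        "n_signatures": len(signatures),
    }
    return table, summary


def read_ranked_list(path: str | Path, compound_id: str | None = None) -> RankedList:
    """Read a two-column (rank, gene) ranked-list text file.

    Ranks must be the contiguous integers 1..N with no ties; a shared
    rank value is rejected rather than silently broken.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", comment="#", names=["rank", "gene"], dtype={"rank": int, "gene": str})
    if df["rank"].duplicated().any():
        raise ValueError(f"{path.name}: tied ranks are not allowed (PRLs are total orders)")
    if sorted(df["rank"]) != list(range(1, len(df) + 1)):
        raise ValueError(f"{path.name}: ranks must be contiguous 1..{len(df)}")
    df = df.sort_values("rank")
    cid = compound_id if compound_id is not None else path.stem
    return RankedList(cid, tuple(df["gene"]))


def write_ranked_list(ranked: RankedList, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write(f"# cystirep ranked-list v1 compound={ranked.compound_id}\n")
        for rank, gene in enumerate(ranked.genes, start=1):
            fh.write(f"{rank}\t{gene}\n")


def signatures_from_gene_lists(
    compound_id: str, up_genes: Iterable[str], down_genes: Iterable[str]
) -> CompoundSignature:
    """Build a signature from explicit up/down gene-list files (used verbatim)."""
    return CompoundSignature(
        compound_id=compound_id,
        up_set=frozenset(up_genes),
        down_set=frozenset(down_genes),
        tail_size=0,
    )
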