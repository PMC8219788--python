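"""Taxonomic binning of gene trees by clan membership.

A gene tree is assigned to a taxonomic bin when the query organism's
sequences sit inside a *clan* - one side of a bipartition of the unrooted
tree - whose other members all belong to a single bin and whose bootstrap
support reaches a threshold (75 by default).  Among several qualifying
clans the smallest wins: the closest relatives carry the signal.  Trees
with no qualifying clan are tallied as low-support or mixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .io import Source, read_table
from .trees import Tree

SUPPORT_THRESHOLD_DEFAULT = 75


class TaxonMap:
    """Leaf label -> taxonomic bin, plus the query-organism label prefix.

    Leaves whose label starts with ``query_prefix`` belong to the study
    organism and are never looked up in the map.
    """

    def __init__(self, mapping: Mapping[str, str], query_prefix: str):
        if not query_prefix:
            raise ValueError("query_prefix must be non-empty")
        self.mapping = dict(mapping)
        self.query_prefix = query_prefix

    @classmethod
    def from_table(cls, source: Source, query_prefix: str) -> "TaxonMap":
        df = read_table(source)
        required = {"leaf_label", "bin"}
        if not required <= set(df.columns):
            raise ValueError(f"taxon map needs columns {sorted(required)}")
        return cls(dict(zip(df["leaf_label"], df["bin"])), query_prefix)

    def is_query(self, label: str) -> bool:
        return label.startswith(self.query_prefix)

    def bin_of(self, label: str) -> str:
        try:
            return self.mapping[label]
        except KeyError:
            raise KeyError(f"leaf {label!r} not resolvable to a bin") from None


@dataclass
class BinResult:
    """Outcome of clan assignment for one tree."""

    tree_id: Optional[str]
    assigned_bin: Optional[str]
    clan_leaves: FrozenSet[str] = frozenset()
    support: int = 0
    reason: str = "assigned"  # assigned | low_support | mixed_clan | query_absent


def clan_assign(
    tree: Tree,
    taxa: TaxonMap,
    support_threshold: int = SUPPORT_THRESHOLD_DEFAULT,
    tree_id: Optional[str] = None,
) -> BinResult:
    """Assign one gene tree to a bin from its best query-containing clan.

    Every bipartition of the unrooted tree is enumerated.  A candidate clan
    is a side that contains *all* query leaves, at least one non-query
    leaf, and whose non-query leaves map to exactly one bin.  Candidates
    with support >= ``support_threshold`` qualify; the smallest qualifies
    first (ties: higher support, then lexicographically smaller bin).  When
    no candidate qualifies the reason distinguishes homogeneous clans below
    the threshold (``low_support``) from none existing (``mixed_clan``).
    """
    leaves = tree.leaves()
    queries = frozenset(l for l in leaves if taxa.is_query(l))
    # every non-query leaf must resolve to a bin before any clan is judged
    bin_of = {l: taxa.bin_of(l) for l in leaves - queries}
    if not queries:
        return BinResult(tree_id, None, reason="query_absent")
    candidates: List[Tuple[int, int, str, FrozenSet[str]]] = []
    homogeneous_exists = False
    for side_a, side_b, support in tree.splits():
        for side in (side_a, side_b):
            if not queries <= side:
                continue
            others = side - queries
            if not others:
                continue
            bins = {bin_of[l] for l in others}
            if len(bins) != 1:
                continue
            homogeneous_exists = True
            if support >= support_threshold:
                candidates.append((len(side), -support, bins.pop(), side))
    if candidates:
        size, neg_support, bin_name, side = min(candidates)
        return BinResult(
            tree_id,
            assigned_bin=bin_name,
            clan_leaves=side,
            support=-neg_support,
            reason="assigned",
        )
    reason = "low_support" if homogeneous_exists else "mixed_clan"
    return BinResult(tree_id, None, reason=reason)


@dataclass
class BinSummary:
    """Per-bin proportions over assigned trees plus the unassigned tally."""

    bins: pd.DataFrame  # columns: bin, count, percent (over assigned trees)
    unassigned: pd.Series  # reason -> count
    n_assigned: int
    n_total: int


def summarize_bins(results: Sequence[BinResult]) -> BinSummary:
    if not results:
        raise ValueError("no binning results to summarise")
    assigned = [r for r in results if r.assigned_bin is not None]
    counts: Dict[str, int] = {}
    for r in assigned:
        counts[r.assigned_bin] = counts.get(r.assigned_bin, 0) + 1
    n_assigned = len(assigned)
    bins = pd.DataFrame(
        {
            "bin": sorted(counts, key=lambda b: (-counts[b], b)),
        }
    )
    bins["count"] = [counts[b] for b in bins["bin"]]
    bins["percent"] = 100.0 * bins["count"] / n_assigned if n_assigned else 0.0
    unassigned = pd.Series(
        [r.reason for r in results if r.assigned_bin is None], dtype=object
    ).value_counts()
    return BinSummary(
        bins=bins,
        unassigned=unassigned,
        n_assigned=n_assigned,
        n_total=len(results),
    )


def results_to_frame(results: Sequence[BinResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tree_id": [r.tree_id for r in results],
            "bin": [r.assigned_bin or "" for r in results],
            "support": [r.support for r in results],
            "clan_size": [len(r.clan_leaves) for r in results],
            "reason": [r.reason for r in results],
        }
    )
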