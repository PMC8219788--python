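"""In-silico mitochondrial proteome candidate selection.

Candidates are admitted through three evidence channels and one final
filter.  Channel 1 combines similarity to a mitochondrial protein database
(best-hit e-value below a cutoff, deduplicated to the best query per
database subject) with an N-terminal targeting-signal probability >= 0.5
from at least one of two predictors.  Channel 2 admits orthologues of an
experimentally established reference mitoproteome, channel 3 a curated
always-include list (respiratory chain, import machinery, carrier family).
Finally every candidate must either carry a partial spliced leader at its
5' end or have a eukaryotic best hit; the rest are removed as probable
contaminants.  External tools (BLAST, targeting predictors, orthology
clustering) are run upstream; this module consumes their outputs as a
feature table and implements the decision logic with full provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set

import pandas as pd

EVALUE_MAX_DEFAULT = 1e-4
P_TARGET_MIN_DEFAULT = 0.5

REQUIRED_COLUMNS = (
    "protein_id",
    "mito_db_evalue",
    "p_target1",
    "p_target2",
    "ortholog_flag",
    "curated_flag",
    "sl_flag",
    "best_hit_domain",
)


@dataclass
class MitoDecision:
    protein_id: str
    included: bool
    channels: Set[str] = field(default_factory=set)
    exclusion_reason: Optional[str] = None


def dedup_best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Keep the single best query per database subject.

    ``hits`` needs columns (query, subject, evalue, bitscore).  Per subject
    the query with the lowest e-value wins; ties go to the higher bitscore,
    then to the lexicographically smallest query id.  A query may survive
    for several subjects (the union is taken downstream).
    """
    required = {"query", "subject", "evalue", "bitscore"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns {sorted(missing)}")
    if (hits["evalue"] < 0).any():
        raise ValueError("negative e-values in hit table")
    ordered = hits.sort_values(
        ["subject", "evalue", "bitscore", "query"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return ordered.groupby("subject", as_index=False).head(1).reset_index(drop=True)


def select_candidates(
    features: pd.DataFrame,
    evalue_max: float = EVALUE_MAX_DEFAULT,
    p_min: float = P_TARGET_MIN_DEFAULT,
) -> tuple[List[MitoDecision], Dict[str, int]]:
    """Apply the three-channel selection and the SL/eukaryote filter.

    ``features`` has one row per protein with the columns listed in
    ``REQUIRED_COLUMNS``; e-values and targeting probabilities may be NaN
    (absent evidence; a missing probability counts as 0).  Returns the
    per-protein decisions and the stage counts:

    * ``similarity`` - proteins with a database hit below ``evalue_max``;
    * ``channel1`` - similarity AND max(p_target1, p_target2) >= ``p_min``;
    * ``channel2`` - reference-orthologue proteins; ``channel1_and_2`` their
      overlap with channel 1; ``channel3`` - curated additions;
    * ``preliminary`` - union of the three channels;
    * ``removed_by_filter`` - preliminary candidates with neither a spliced
      leader nor a eukaryotic best hit; ``final`` - the admitted set.
    """
    missing = set(REQUIRED_COLUMNS) - set(features.columns)
    if missing:
        raise ValueError(f"feature table missing columns {sorted(missing)}")
    ev = features["mito_db_evalue"].astype(float)
    if (ev.dropna() < 0).any():
        raise ValueError("negative e-values in feature table")
    p1 = features["p_target1"].astype(float).fillna(0.0)
    p2 = features["p_target2"].astype(float).fillna(0.0)

    similarity = ev.notna() & (ev < evalue_max)
    targeting = (p1 >= p_min) | (p2 >= p_min)
    channel1 = similarity & targeting
    channel2 = features["ortholog_flag"].astype(bool)
    channel3 = features["curated_flag"].astype(bool)
    preliminary = channel1 | channel2 | channel3
    admitted = features["sl_flag"].astype(bool) | (
        features["best_hit_domain"] == "eukaryote"
    )
    included = preliminary & admitted

    decisions: List[MitoDecision] = []
    for i, row in enumerate(features.itertuples(index=False)):
        channels: Set[str] = set()
        if channel1.iloc[i]:
            channels.update({"A_similarity", "B_targeting"})
        if channel2.iloc[i]:
            channels.add("C_orthology")
        if channel3.iloc[i]:
            channels.add("D_curated")
        if included.iloc[i]:
            decisions.append(MitoDecision(row.protein_id, True, channels))
        elif not preliminary.iloc[i]:
            decisions.append(
                MitoDecision(row.protein_id, False, channels, "no_channel")
            )
        else:
            decisions.append(
                MitoDecision(row.protein_id, False, channels, "admission_filter")
            )

    stage_counts = {
        "similarity": int(similarity.sum()),
        "channel1": int(channel1.sum()),
        "channel2": int(channel2.sum()),
        "channel1_and_2": int((channel1 & channel2).sum()),
        "channel3": int(channel3.sum()),
        "preliminary": int(preliminary.sum()),
        "removed_by_filter": int((preliminary & ~admitted).sum()),
        "final": int(included.sum()),
    }
    return decisions, stage_counts


def decisions_to_frame(decisions: Sequence[MitoDecision]) -> pd.DataFrame:
    """Tabular view of decisions for TSV export."""
    return pd.DataFrame(
        {
            "protein_id": [d.protein_id for d in decisions],
            "included": [d.included for d in decisions],
            "channels": ["|".join(sorted(d.channels)) for d in decisions],
            "exclusion_reason": [d.exclusion_reason or "" for d in decisions],
        }
    )
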