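"""Spliced-leader (SL) detection at transcript ends.

Mature euglenozoan mRNAs carry a short spliced leader trans-spliced onto
their 5' end.  In assembled transcripts only a 3'-terminal fragment of the
leader usually survives, and transcript orientation is unknown, so the scan
looks for an exact match of an SL *suffix* as a transcript prefix, or the
reverse complement of that suffix as a transcript suffix.  Matching is
exact by design: internal occurrences do not count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .records import SeqRecord, revcomp

#: Full-length R. costata spliced leader (27 nt); its 10-nt 3' suffix is the
#: commonly observed partial leader CATTTTTTCG.
SL_SEQUENCE = "ACATTACTGGGTGTAATCATTTTTTCG"

MIN_SL_LEN_DEFAULT = 10


@dataclass
class SLHit:
    transcript_id: str
    end: str  # "five_prime_as_is" | "three_prime_revcomp"
    match_len: int
    matched_seq: str


def scan_sl(
    transcript: SeqRecord,
    sl: str = SL_SEQUENCE,
    min_len: int = MIN_SL_LEN_DEFAULT,
    forward_only: bool = False,
) -> Optional[SLHit]:
    """Longest terminal SL fragment of a transcript, or ``None``.

    Reports the largest k >= ``min_len`` such that the length-k suffix of
    the leader is an exact transcript prefix (5' as-is), or - unless
    ``forward_only`` - its reverse complement is an exact transcript suffix
    (3', antisense assembly).  When both ends match, the longer match wins;
    ties go to the 5' end.
    """
    if not sl:
        raise ValueError("SL sequence must be non-empty")
    if not 1 <= min_len <= len(sl):
        raise ValueError(f"min_len must be in [1, {len(sl)}], got {min_len}")
    sl = sl.upper()
    seq = transcript.seq.upper()
    best5 = 0
    best3 = 0
    for k in range(len(sl), min_len - 1, -1):
        suffix = sl[-k:]
        if best5 == 0 and seq.startswith(suffix):
            best5 = k
        if not forward_only and best3 == 0 and seq.endswith(revcomp(suffix)):
            best3 = k
        if best5 and (forward_only or best3):
            break
    if best5 == 0 and best3 == 0:
        return None
    if best5 >= best3:
        return SLHit(transcript.id, "five_prime_as_is", best5, sl[-best5:])
    return SLHit(transcript.id, "three_prime_revcomp", best3, sl[-best3:])


def summarize_sl(
    transcripts: Sequence[SeqRecord],
    sl: str = SL_SEQUENCE,
    min_lens: Sequence[int] = (10,),
    forward_only: bool = False,
) -> pd.DataFrame:
    """Corpus-level SL statistics.

    Returns one row per requested minimum match length with the number and
    percentage of transcripts carrying a terminal SL fragment of at least
    that length.  The fraction is non-increasing in ``min_len``.
    """
    if not transcripts:
        raise ValueError("empty transcript corpus")
    # One scan at the loosest requested length; per-threshold counts follow
    # from the match-length distribution because hits are nested.
    floor = min(min_lens)
    hits = [
        scan_sl(t, sl=sl, min_len=floor, forward_only=forward_only)
        for t in transcripts
    ]
    lens = [h.match_len for h in hits if h is not None]
    n = len(transcripts)
    rows = []
    for ml in min_lens:
        count = sum(1 for l in lens if l >= ml)
        rows.append(
            {
                "min_len": ml,
                "n_transcripts": n,
                "n_with_sl": count,
                "percent_with_sl": 100.0 * count / n,
            }
        )
    return pd.DataFrame(rows)


def match_length_distribution(
    transcripts: Sequence[SeqRecord],
    sl: str = SL_SEQUENCE,
    min_len: int = MIN_SL_LEN_DEFAULT,
    forward_only: bool = False,
) -> pd.Series:
    """Counts of transcripts by longest terminal SL match length."""
    lens = []
    for t in transcripts:
        hit = scan_sl(t, sl=sl, min_len=min_len, forward_only=forward_only)
        if hit is not None:
            lens.append(hit.match_len)
    return pd.Series(lens, dtype=int).value_counts().sort_index()
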