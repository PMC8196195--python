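"""Pairwise-alignment primitives shared across modules.

Local alignments go through Biopython's C-accelerated PairwiseAligner;
edit distances through edlib.  The semi-global match-counting DP used for
guide capture bounds is implemented here directly because no installed
library reports "identical bases on the best-scoring placement" for a
query anchored end-to-end inside a longer target.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Optional

import edlib
import numpy as np
from Bio import Align

from .seqio import revcomp

__all__ = [
    "make_aligner",
    "scan_aligner",
    "best_local",
    "edit_distance_semiglobal",
    "semiglobal_best_matches",
]


def make_aligner(
    match: float,
    mismatch: float,
    open_gap: float,
    extend_gap: float,
    mode: str = "local",
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


@lru_cache(maxsize=None)
def scan_aligner() -> Align.PairwiseAligner:
    """Default end-scan scoring: match 2 / mismatch -3 / open -5 / extend -2."""
    return make_aligner(2, -3, -5, -2, "local")


def best_local(
    query: str,
    target: str,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> tuple[float, int, int, int, int]:
    """Best local alignment of query inside target.

    Returns (score, target_start, target_end, query_start, query_end).
    """
    aligner = aligner or scan_aligner()
    alignments = aligner.align(target, query)
    try:
        best = alignments[0]
    except IndexError:  # pragma: no cover - empty inputs
        return 0.0, 0, 0, 0, 0
    tblocks, qblocks = best.aligned
    return (
        float(best.score),
        int(tblocks[0][0]),
        int(tblocks[-1][1]),
        int(qblocks[0][0]),
        int(qblocks[-1][1]),
    )


def local_score(query: str, target: str, aligner: Optional[Align.PairwiseAligner] = None) -> float:
    aligner = aligner or scan_aligner()
    return float(aligner.score(target, query))


def edit_distance_semiglobal(query: str, target: str, max_dist: int = -1) -> int:
    """Edit distance of query against the best-matching window of target."""
    res = edlib.align(query, target, mode="HW", task="distance", k=max_dist)
    return int(res["editDistance"])


_M_BITS = 6  # match counts fit in 6 bits (queries here are <= 63 bp)
_M_MASK = (1 << _M_BITS) - 1


def semiglobal_best_matches(query: str, target: str) -> tuple[int, int]:
    """Best semi-global placement of query in target with unit scores.

    The query is aligned end-to-end (its terminal gaps are charged), the
    target's ends are free; match +1 / mismatch -1 / gap -1.  Returns
    ``(best_score, matches)`` where ``matches`` is the maximum number of
    aligned identical bases over all optimal-scoring alignments.  ``N``
    never matches anything.

    The row recurrence packs (score, matches) into one integer so that a
    prefix running maximum resolves arbitrary-length target-gap chains and
    score ties (broken toward more matches) in a single vectorised pass.
    """
    m, n = len(query), len(target)
    if m == 0 or m >= (1 << _M_BITS):
        raise ValueError("query length must be in [1, 63]")
    if n == 0:
        return -m, 0
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    # comb[j] = score * 2^6 + matches for the best alignment of the query
    # prefix ending at target position j (j = 0 means "before the target").
    comb = np.zeros(n + 1, dtype=np.int64)  # row 0: free start, 0 matches
    for i in range(1, m + 1):
        q = query[i - 1]
        if q == "N":
            s = np.full(n, -1, dtype=np.int64)
            is_match = np.zeros(n, dtype=np.int64)
        else:
            is_match = (t == ord(q)).astype(np.int64)
            s = 2 * is_match - 1
        prev = comb
        cur = np.empty(n + 1, dtype=np.int64)
        cur[0] = prev[0] - (1 << _M_BITS)  # query gap before target start
        diag = prev[:-1] + (s << _M_BITS) + is_match
        up = prev[1:] - (1 << _M_BITS)
        best = np.maximum(diag, up)
        # target-gap chains: cur[j] = max_k<=j best[k] - (j - k) in score
        shifted = best + (np.arange(1, n + 1) << _M_BITS)
        run = np.maximum.accumulate(np.maximum(shifted, cur[0] + (0 << _M_BITS)))
        cur[1:] = run - (np.arange(1, n + 1) << _M_BITS)
        comb = cur
    final = int(comb.max())  # free end on the target
    score = final >> _M_BITS
    matches = final & _M_MASK
    return score, matches


def best_matches_both_strands(query: str, target: str) -> int:
    """Max aligned identical bases over both target strands."""
    _, fwd = semiglobal_best_matches(query, target)
    _, rev = semiglobal_best_matches(query, revcomp(target))
    return max(fwd, rev)
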