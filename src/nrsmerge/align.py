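"""Dynamic-programming alignment primitives used by placing.

Scoring is deliberately simple (match +1, mismatch -2, gap -3, no affine
extension), echoing the alignment-score-to-length ratio used for read
selection. Two flavors are provided:

* :func:`infix_score` — the whole query aligned inside the target with free
  end gaps on the target (read-to-NRS scoring).
* :func:`prefix_split` — a query *prefix* aligned to a target infix, free
  start anywhere in the target; returns the best score together with the
  query prefix length and the target end column, which is how contig ends
  are split-aligned to a reference interval to pin a breakpoint.
"""

from __future__ import annotations

import numpy as np

MATCH = 1
MISMATCH = -2
GAP = -3

_ENC = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i + 1


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def _row_update(prev: np.ndarray, q_char: int, target: np.ndarray, left0: int) -> np.ndarray:
    """One DP row with an O(n) max-scan for the horizontal gap term."""
    sub = np.where(target == q_char, MATCH, MISMATCH)
    tmp = np.maximum(prev[:-1] + sub, prev[1:] + GAP)
    n = len(target)
    a = np.empty(n + 1, dtype=np.int64)
    idx = np.arange(n + 1)
    a[0] = left0
    a[1:] = tmp - GAP * idx[1:]
    np.maximum.accumulate(a, out=a)
    return a + GAP * idx


def infix_score(query: str, target: str) -> int:
    """Best score of the full query aligned within the target.

    End gaps in the target are free; the query must be consumed entirely
    (leading/trailing query gaps are penalized).
    """
    q = encode(query)
    t = encode(target)
    prev = np.zeros(len(t) + 1, dtype=np.int64)
    for i, qc in enumerate(q, 1):
        prev = _row_update(prev, qc, t, GAP * i)
    return int(prev.max())


def ungapped_prefix_split(
    query: str, target: str, min_identity: float = 0.8, min_len: int = 1
) -> tuple[int, int, int]:
    """Best high-identity ungapped alignment of a query prefix to the target.

    Used for pinning breakpoints: without gaps the alignment cannot bridge
    across an inserted sequence to the far flank, and among prefixes whose
    score stays at least ``min_identity`` per base the score peaks exactly
    at the junction (it falls by the mismatch penalty past it). Returns
    ``(score, query_prefix_len, target_end)``; all zeros when no prefix of
    at least ``min_len`` bases qualifies.
    """
    q = encode(query)
    t = encode(target)
    m, n = len(q), len(t)
    if m == 0 or n == 0 or n < min_len:
        return 0, 0, 0
    if n < m:
        q = q[:n]
        m = n
    # cum[i, o]: score of q[:i+1] against t[o:o+i+1] (ungapped diagonal o)
    idx = np.arange(m)[:, None] + np.arange(n - m + 1)[None, :]
    sub = np.where(t[idx] == q[:, None], MATCH, MISMATCH)
    cum = np.cumsum(sub, axis=0)
    lens = np.arange(1, m + 1)[:, None]
    ok = (cum >= min_identity * lens) & (lens >= min_len)
    if not ok.any():
        return 0, 0, 0
    masked = np.where(ok, cum, np.iinfo(np.int64).min)
    best = int(masked.max())
    cand_i, cand_o = np.nonzero(masked == best)
    j = int(np.argmin(cand_i))  # tie-break: shortest prefix, leftmost diagonal
    i, o = int(cand_i[j]), int(cand_o[j])
    return best, i + 1, o + i + 1


def prefix_split(query: str, target: str) -> tuple[int, int, int]:
    """Best alignment of any query prefix to any target infix.

    The alignment is anchored at query position 0 (no query bases skipped at
    the start) but may begin anywhere in the target and end anywhere in
    both. Returns ``(score, query_prefix_len, target_end)`` — the split
    point: ``query[:query_prefix_len]`` aligns to ``target[..target_end]``.
    """
    q = encode(query)
    t = encode(target)
    prev = np.zeros(len(t) + 1, dtype=np.int64)
    best = (0, 0, 0)
    for i, qc in enumerate(q, 1):
        prev = _row_update(prev, qc, t, GAP * i)
        j = int(prev.argmax())
        s = int(prev[j])
        if s > best[0]:
            best = (s, i, j)
    return best
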