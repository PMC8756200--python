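"""Scoring a candidate NRS set against a simulated truth set.

Every truth sequence is aligned against every candidate (local alignment,
both strands). A truth sequence ``t`` counts as a true positive if a
*single* alignment with some candidate covers at least 90% of ``|t|`` and a
bipartite matching assigns each candidate to at most one truth sequence
(and vice versa). Everything else in the truth set is a false negative,
and the number of false positives is ``|C| - TP`` — i.e. redundant
candidates covering an already-matched truth sequence count as false
positives, which makes the precision criterion deliberately stringent.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .dna import revcomp

DEFAULT_MIN_LEN = 50
DEFAULT_MIN_IDENTITY = 0.95
COVER_FRACTION = 0.9


@dataclass
class AlignmentHit:
    """Best local alignment between one truth and one candidate sequence."""

    truth_id: str
    cand_id: str
    t_start: int
    t_end: int
    identity: float
    score: float
    covered_frac: float


@dataclass
class EvalResult:
    tp: int
    fn: int
    fp: int
    redundant: int
    precision: float
    recall: float
    f1: float
    n_truth: int
    n_candidates: int


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -5
    return aligner


def all_vs_all(
    truth: dict[str, str],
    candidates: dict[str, str],
    min_len: int = DEFAULT_MIN_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[AlignmentHit]:
    """Local alignments (both strands) of every (truth, candidate) pair.

    Hits spanning less than ``min_len`` bases of the truth sequence or
    below ``min_identity`` are discarded; the best hit per pair is kept.
    """
    aligner = _aligner()
    hits: list[AlignmentHit] = []
    for t_id, t_seq in truth.items():
        for c_id, c_seq in candidates.items():
            if not t_seq or not c_seq:
                continue
            best = None
            for strand_seq in (c_seq, revcomp(c_seq)):
                score = aligner.score(t_seq, strand_seq)
                if best is None or score > best[0]:
                    best = (score, strand_seq)
            score, strand_seq = best
            if score <= 0:
                continue
            aln = aligner.align(t_seq, strand_seq)[0]
            blocks = aln.aligned[0]
            if len(blocks) == 0:
                continue
            t_start, t_end = int(blocks[0][0]), int(blocks[-1][1])
            counts = aln.counts()
            columns = counts.gaps + counts.identities + counts.mismatches
            identity = counts.identities / columns if columns else 0.0
            if t_end - t_start < min_len or identity < min_identity:
                continue
            hits.append(
                AlignmentHit(
                    truth_id=t_id,
                    cand_id=c_id,
                    t_start=t_start,
                    t_end=t_end,
                    identity=identity,
                    score=float(score),
                    covered_frac=(t_end - t_start) / len(t_seq),
                )
            )
    return hits


def _maximum_matching(
    edges: list[tuple[str, str, float]]
) -> dict[str, str]:
    """Deterministic maximum-cardinality bipartite matching.

    Edges are seeded greedily in order of decreasing covered fraction and
    the matching is then completed with augmenting paths, so its
    cardinality equals the exhaustive maximum while the greedy order
    decides between equal-cardinality alternatives.
    """
    edges = sorted(edges, key=lambda e: (-e[2], e[0], e[1]))
    adj: dict[str, list[str]] = {}
    for t, c, _ in edges:
        adj.setdefault(t, []).append(c)
    match_t: dict[str, str] = {}
    match_c: dict[str, str] = {}
    for t, c, _ in edges:
        if t not in match_t and c not in match_c:
            match_t[t] = c
            match_c[c] = t

    def augment(t: str, visited: set[str]) -> bool:
        for c in adj.get(t, []):
            if c in visited:
                continue
            visited.add(c)
            if c not in match_c or augment(match_c[c], visited):
                match_t[t] = c
                match_c[c] = t
                return True
        return False

    for t in sorted(adj):
        if t not in match_t:
            augment(t, set())
    return match_t


def match_and_score(
    hits: list[AlignmentHit],
    truth: dict[str, str],
    candidates: dict[str, str],
    cover_fraction: float = COVER_FRACTION,
) -> EvalResult:
    """Bipartite matching of eligible hits and the stringent P/R bookkeeping."""
    eligible = [
        (h.truth_id, h.cand_id, h.covered_frac)
        for h in hits
        if h.covered_frac >= cover_fraction
    ]
    matching = _maximum_matching(eligible)
    tp = len(matching)
    n_t, n_c = len(truth), len(candidates)
    fn = n_t - tp
    fp = n_c - tp
    covering_cands = {c for _, c, _ in eligible}
    redundant = len(covering_cands) - tp
    precision = tp / n_c if n_c else 0.0
    recall = tp / n_t if n_t else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalResult(
        tp=tp,
        fn=fn,
        fp=fp,
        redundant=redundant,
        precision=precision,
        recall=recall,
        f1=f1,
        n_truth=n_t,
        n_candidates=n_c,
    )


def evaluate(
    truth: dict[str, str],
    candidates: dict[str, str],
    min_len: int = DEFAULT_MIN_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    trim_flanks: int = 0,
) -> tuple[EvalResult, list[AlignmentHit]]:
    """All-vs-all alignment plus matching; optionally trim candidate flanks."""
    if trim_flanks:
        candidates = {
            cid: seq[trim_flanks : len(seq) - trim_flanks]
            for cid, seq in candidates.items()
        }
        candidates = {cid: seq for cid, seq in candidates.items() if seq}
    hits = all_vs_all(truth, candidates, min_len=min_len, min_identity=min_identity)
    return match_and_score(hits, truth, candidates), hits
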