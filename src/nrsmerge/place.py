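"""Placing merged NRS on the reference via one-end-anchored read pairs.

A read pair with one mate mapped to the reference and the other unmapped is
evidence for an insertion near the mapped mate: the unmapped mate is
aligned (end-gap-free) against every candidate NRS and, if it has a unique
best hit scoring at least ``min_score_frac * read_length``, an anchor
interval downstream (or upstream, depending on strand) of the mapped mate
is recorded. Anchors for the same NRS and locus are pooled, and breakpoints
are refined by split-aligning the NRS ends against the anchored reference
interval: assembled NRS typically carry short stretches of reference flank
at their ends, and the position where the flank alignment stops is the
insertion point, reported at base-pair resolution. Variants whose ends
yield no split alignment fall back to interval resolution.

Coordinates are 0-based half-open internally; VCF output is 1-based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import edlib
import numpy as np
import pysam

from .align import MATCH, MISMATCH, infix_score, ungapped_prefix_split
from .dna import revcomp

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE_FRAC = 0.67
DEFAULT_MIN_FLANK = 15
SPLIT_IDENTITY = 0.8  # min score per aligned flank base for a split to count
EXACT = "exact"
INTERVAL = "interval"


@dataclass
class FragmentStats:
    mean: float
    sd: float

    @property
    def reach(self) -> int:
        """How far from the mapped mate an insertion point can sit."""
        return int(self.mean + 3 * self.sd)


def estimate_fragment_stats(sam_path: str, max_pairs: int = 10000) -> FragmentStats:
    """Estimate fragment size mean/SD from proper pairs."""
    tlens: list[int] = []
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
            for rec in fh:
                if (
                    rec.is_proper_pair
                    and not rec.is_secondary
                    and not rec.is_supplementary
                    and rec.template_length > 0
                ):
                    tlens.append(rec.template_length)
                    if len(tlens) >= max_pairs:
                        break
    finally:
        pysam.set_verbosity(save)
    if not tlens:
        return FragmentStats(500.0, 100.0)
    arr = np.asarray(tlens, dtype=float)
    return FragmentStats(float(arr.mean()), float(arr.std()))


@dataclass
class AnchorEvidence:
    """Pooled one-end-anchored evidence for one NRS at one locus."""

    nrs_id: str
    chrom: str
    start: int  # 0-based half-open candidate interval for the insertion point
    end: int
    orientation: str  # '+'/'-': NRS as emitted vs. reverse-complemented
    support: int


@dataclass
class PlacedVariant:
    nrs_id: str
    chrom: str
    pos: int  # 1-based position of the base before the insertion
    orientation: str
    resolution: str  # 'exact' or 'interval'
    split_support: int = 0
    ci: tuple[int, int] = (0, 0)
    trim_start: int = 0  # reference-flank trim on the oriented NRS
    trim_end: int = 0
    support: int = 0
    nrs_length: int = 0

    def inserted_sequence(self, nrs_seq: str) -> str:
        oriented = nrs_seq if self.orientation == "+" else revcomp(nrs_seq)
        end = len(oriented) - self.trim_end
        return oriented[self.trim_start : end]


def _best_nrs_hit(
    seq: str, nrs_seqs: dict[str, str], min_score: int
) -> tuple[str, str] | None:
    """Unique best NRS for an unmapped read, or None.

    An edit-distance screen (infix mode, both strands) ranks the candidate
    NRS; the winner must beat the runner-up and pass the score threshold
    under the match/mismatch/gap scoring.
    """
    L = len(seq)
    dmax = (L - min_score) // (MATCH - MISMATCH) + 2
    rc = revcomp(seq)
    per_nrs: dict[str, tuple[int, str]] = {}
    for nrs_id, nrs in nrs_seqs.items():
        for strand, query in (("+", seq), ("-", rc)):
            res = edlib.align(query, nrs, mode="HW", task="distance", k=dmax)
            d = res["editDistance"]
            if d < 0:
                continue
            cur = per_nrs.get(nrs_id)
            if cur is None or d < cur[0]:
                per_nrs[nrs_id] = (d, strand)
    if not per_nrs:
        return None
    ranked = sorted((d, nrs_id, strand) for nrs_id, (d, strand) in per_nrs.items())
    if len(ranked) > 1 and ranked[0][0] == ranked[1][0]:
        return None  # ambiguous between two NRS
    _, nrs_id, strand = ranked[0]
    query = seq if strand == "+" else rc
    if infix_score(query, nrs_seqs[nrs_id]) < min_score:
        return None
    return nrs_id, strand


def collect_anchors(
    sam_paths: list[str] | str,
    nrs_seqs: dict[str, str],
    min_score_frac: float = DEFAULT_MIN_SCORE_FRAC,
    frag_stats: FragmentStats | None = None,
) -> list[AnchorEvidence]:
    """Collect and pool one-end-anchored evidence across samples."""
    if isinstance(sam_paths, str):
        sam_paths = [sam_paths]
    raw: list[tuple[str, str, int, int, str]] = []
    for sam_path in sam_paths:
        stats = frag_stats or estimate_fragment_stats(sam_path)
        reach = stats.reach
        pending: dict[str, pysam.AlignedSegment] = {}
        save = pysam.set_verbosity(0)
        try:
            with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
                for rec in fh:
                    if rec.is_secondary or rec.is_supplementary:
                        continue
                    if not rec.is_paired:
                        continue
                    if rec.is_unmapped == rec.mate_is_unmapped:
                        continue  # need exactly one mapped mate
                    other = pending.pop(rec.query_name, None)
                    if other is None:
                        pending[rec.query_name] = rec
                        continue
                    mapped, unmapped = (
                        (rec, other) if not rec.is_unmapped else (other, rec)
                    )
                    anchor = _anchor_from_pair(
                        mapped, unmapped, nrs_seqs, min_score_frac, reach, fh
                    )
                    if anchor is not None:
                        raw.append(anchor)
        finally:
            pysam.set_verbosity(save)
    return _pool_anchors(raw, frag_stats.mean if frag_stats else 350.0)


def _anchor_from_pair(
    mapped: pysam.AlignedSegment,
    unmapped: pysam.AlignedSegment,
    nrs_seqs: dict[str, str],
    min_score_frac: float,
    reach: int,
    fh: pysam.AlignmentFile,
) -> tuple[str, str, int, int, str] | None:
    seq = unmapped.query_sequence
    if not seq:
        return None
    min_score = math.ceil(min_score_frac * len(seq))
    hit = _best_nrs_hit(seq, nrs_seqs, min_score)
    if hit is None:
        return None
    nrs_id, strand = hit
    chrom = fh.get_reference_name(mapped.reference_id)
    if mapped.is_reverse:
        start = max(0, mapped.reference_start - reach)
        end = mapped.reference_start + 1
        mate_strand = "-"
    else:
        start = mapped.reference_end or mapped.reference_start
        end = start + reach
        mate_strand = "+"
    orientation = "+" if strand != mate_strand else "-"
    return nrs_id, chrom, start, end, orientation


def _pool_anchors(
    raw: list[tuple[str, str, int, int, str]], merge_distance: float
) -> list[AnchorEvidence]:
    """Pool anchors per (nrs, chrom) whose intervals lie within merge distance."""
    out: list[AnchorEvidence] = []
    by_key: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for nrs_id, chrom, start, end, ori in raw:
        by_key.setdefault((nrs_id, chrom), []).append((start, end, ori))
    for (nrs_id, chrom), items in sorted(by_key.items()):
        items.sort()
        cluster: list[tuple[int, int, str]] = []

        def flush() -> None:
            if not cluster:
                return
            starts = [s for s, _, _ in cluster]
            ends = [e for _, e, _ in cluster]
            lo, hi = max(starts), min(ends)
            if lo >= hi:  # disjoint after intersection: fall back to span
                lo, hi = min(starts), max(ends)
            n_plus = sum(1 for _, _, o in cluster if o == "+")
            ori = "+" if n_plus * 2 >= len(cluster) else "-"
            out.append(AnchorEvidence(nrs_id, chrom, lo, hi, ori, len(cluster)))

        prev_start = None
        for s, e, o in items:
            if prev_start is not None and s - prev_start > merge_distance:
                flush()
                cluster = []
            cluster.append((s, e, o))
            prev_start = s
        flush()
    return out


def refine_breakpoint(
    anchor: AnchorEvidence,
    nrs_seq: str,
    reference: str,
    read_length: int = 100,
    min_flank: int = DEFAULT_MIN_FLANK,
    max_flank: int = 700,
) -> PlacedVariant:
    """Refine an anchor to base-pair resolution by split-aligning NRS ends.

    Assembled NRS typically extend into the reference by up to a fragment
    length on either side (mates of junction-spanning reads are
    co-assembled), so up to ``max_flank`` bases of each end are
    split-aligned against a reference window around the anchor interval.
    The split score rises while the contig end tracks the reference and
    falls past the insertion point, so the DP maximum pins the junction:
    if at least ``min_flank`` NRS bases align with sufficient score, the
    alignment end is the insertion point and the aligned flank is trimmed
    from the NRS. With no acceptable split on either end, the variant
    keeps interval resolution over the pooled anchor interval.
    """
    pad = max_flank + read_length
    lo = max(0, anchor.start - pad)
    hi = min(len(reference), anchor.end + pad)
    window = reference[lo:hi]
    oriented = nrs_seq if anchor.orientation == "+" else revcomp(nrs_seq)

    splits = 0
    pos_left = pos_right = None
    trim_start = trim_end = 0

    def split_run(query: str, target: str) -> tuple[int, int] | None:
        """(flank length, junction offset on the target) or None.

        The scored split selects the flank diagonal; the junction itself
        is the end of the initial exact-match run on it, so any extension
        past the true breakpoint is pure breakpoint homology (an
        equivalent representation) rather than a noisy-score overshoot.
        """
        score, qlen, tend = ungapped_prefix_split(
            query, target, min_identity=SPLIT_IDENTITY, min_len=min_flank
        )
        if qlen < min_flank:
            return None
        off = tend - qlen
        run = 0
        for a, b in zip(query, target[off:]):
            if a != b:
                break
            run += 1
        if run < min_flank:
            return None
        return run, off + run

    q = oriented[: min(max_flank, len(oriented))]
    left = split_run(q, window)
    if left is not None:
        trim_start, end = left
        pos_left = lo + end
        splits += 1

    qr = oriented[-min(max_flank, len(oriented)) :][::-1]
    right = split_run(qr, window[::-1])
    if right is not None:
        trim_end, end_rev = right
        pos_right = lo + (len(window) - end_rev)
        splits += 1

    if pos_left is not None and pos_right is not None:
        # breakpoint homology can place the two junctions delta bases
        # apart; relative to the left junction the insertion must extend
        # delta bases further right, or it loses the homologous stretch
        delta = pos_left - pos_right
        if delta >= 0:
            trim_end = max(0, trim_end - delta)
    if splits:
        pos0 = pos_left if pos_left is not None else pos_right
        return PlacedVariant(
            nrs_id=anchor.nrs_id,
            chrom=anchor.chrom,
            pos=pos0,  # 0-based insertion offset == 1-based preceding base
            orientation=anchor.orientation,
            resolution=EXACT,
            split_support=splits,
            trim_start=trim_start,
            trim_end=trim_end,
            support=anchor.support,
            nrs_length=len(nrs_seq),
        )
    return PlacedVariant(
        nrs_id=anchor.nrs_id,
        chrom=anchor.chrom,
        pos=max(1, anchor.start),
        orientation=anchor.orientation,
        resolution=INTERVAL,
        ci=(0, anchor.end - anchor.start),
        support=anchor.support,
        nrs_length=len(nrs_seq),
    )


def place(
    sam_paths: list[str],
    nrs_seqs: dict[str, str],
    reference: str,
    chrom: str = "ref",
    min_score_frac: float = DEFAULT_MIN_SCORE_FRAC,
    read_length: int = 100,
    min_support: int = 1,
) -> list[PlacedVariant]:
    """Anchor collection plus breakpoint refinement over many samples."""
    frag = estimate_fragment_stats(sam_paths[0]) if sam_paths else None
    anchors = collect_anchors(
        sam_paths, nrs_seqs, min_score_frac=min_score_frac, frag_stats=frag
    )
    variants = []
    best_by_nrs: dict[str, AnchorEvidence] = {}
    for a in anchors:
        cur = best_by_nrs.get(a.nrs_id)
        if cur is None or a.support > cur.support:
            best_by_nrs[a.nrs_id] = a
    for nrs_id in sorted(best_by_nrs):
        a = best_by_nrs[nrs_id]
        if a.support < min_support:
            continue
        variants.append(
            refine_breakpoint(a, nrs_seqs[nrs_id], reference, read_length=read_length)
        )
    return variants


# ---------------------------------------------------------------------------
# VCF output


def _bnd_records(v: PlacedVariant, reference: str) -> list[tuple[int, str, str, str]]:
    """(pos1, id, ref, alt) tuples for the breakends of one exact variant."""
    p = v.pos  # 1-based base before the insertion
    base_l = reference[p - 1]
    base_r = reference[p] if p < len(reference) else "N"
    n = v.nrs_length
    if v.orientation == "+":
        first = v.trim_start + 1
        last = n - v.trim_end
        alt_l = f"{base_l}[{v.nrs_id}:{first}["
        alt_r = f"]{v.nrs_id}:{last}]{base_r}"
    else:
        first = n - v.trim_start
        last = v.trim_end + 1
        alt_l = f"{base_l}]{v.nrs_id}:{first}]"
        alt_r = f"[{v.nrs_id}:{last}[{base_r}"
    return [
        (p, f"{v.nrs_id}_bnd_L", base_l, alt_l),
        (p + 1, f"{v.nrs_id}_bnd_R", base_r, alt_r),
    ]


def write_breakends(
    variants: list[PlacedVariant],
    reference: str,
    out_path: str,
    chrom: str = "ref",
) -> None:
    """Write placed variants as a VCF 4.2 with breakend (BND) notation.

    Exact insertions produce two BND records (left and right junction);
    interval-resolution calls produce a single imprecise symbolic record
    with a CIPOS spanning the anchor interval.
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##source=nrsmerge",
        f"##contig=<ID={chrom},length={len(reference)}>",
        '##ALT=<ID=INS,Description="Insertion of a non-reference sequence">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">',
        '##INFO=<ID=NRSID,Number=1,Type=String,Description="NRS contig id">',
        '##INFO=<ID=NRSORI,Number=1,Type=String,Description="NRS orientation">',
        '##INFO=<ID=TRIM,Number=2,Type=Integer,Description="Reference-flank trim on the oriented NRS (start,end)">',
        '##INFO=<ID=RES,Number=1,Type=String,Description="Breakpoint resolution">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting pair count">',
        '##INFO=<ID=SPLIT,Number=1,Type=Integer,Description="Split alignments at the junction">',
        '##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="Confidence interval around POS">',
        '##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise variant">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for v in variants:
        if v.pos < 1 or v.pos > len(reference):
            logger.warning("dropping %s: position %d outside reference", v.nrs_id, v.pos)
            continue
        common = (
            f"NRSID={v.nrs_id};NRSORI={v.orientation};TRIM={v.trim_start},{v.trim_end};"
            f"RES={v.resolution};SUPPORT={v.support};SPLIT={v.split_support}"
        )
        if v.resolution == EXACT:
            recs = _bnd_records(v, reference)
            for (pos1, rid, ref, alt), mate in zip(recs, reversed(recs)):
                info = f"SVTYPE=BND;MATEID={mate[1]};{common}"
                lines.append(
                    f"{v.chrom}\t{pos1}\t{rid}\t{ref}\t{alt}\t.\tPASS\t{info}"
                )
        else:
            ref = reference[v.pos - 1]
            info = f"SVTYPE=INS;IMPRECISE;CIPOS={v.ci[0]},{v.ci[1]};{common}"
            lines.append(
                f"{v.chrom}\t{v.pos}\t{v.nrs_id}_ins\t{ref}\t<INS>\t.\tPASS\t{info}"
            )
    with open(out_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_placed_vcf(path: str) -> list[PlacedVariant]:
    """Reconstruct PlacedVariant objects from a VCF written by this module."""
    variants: dict[str, PlacedVariant] = {}
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            nrs_id = rec.info["NRSID"]
            if nrs_id in variants:
                continue
            res = rec.info["RES"]
            trim = rec.info.get("TRIM", (0, 0))
            ci = rec.info.get("CIPOS", (0, 0))
            variants[nrs_id] = PlacedVariant(
                nrs_id=nrs_id,
                chrom=rec.chrom,
                pos=rec.pos,
                orientation=rec.info["NRSORI"],
                resolution=res,
                split_support=int(rec.info.get("SPLIT", 0)),
                ci=(int(ci[0]), int(ci[1])),
                trim_start=int(trim[0]),
                trim_end=int(trim[1]),
                support=int(rec.info.get("SUPPORT", 0)),
            )
    return list(variants.values())
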