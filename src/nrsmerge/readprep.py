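"""Per-sample read selection and contig assembly.

The assembly step of the pipeline processes one genome at a time: reads
that are unmapped, or mapped with an alignment-score-to-length ratio below
the alignment score factor (ASF, default 0.67), are selected together with
their mates and assembled into contigs. The assembler is a minimal
coverage-filtered unitig assembler: a single-color de Bruijn graph of read
k-mers with low-multiplicity k-mers dropped, compacted into unitigs.
External assemblies (e.g. from Minia or Velvet) can be used instead via the
contig import path of the CLI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pysam

from . import cdbg
from .dna import revcomp, split_at_ambiguous

logger = logging.getLogger(__name__)

DEFAULT_ASF = 0.67
DEFAULT_K_ASSEMBLY = 31
DEFAULT_C_MIN = 2

SELECT = "select"
KEEP = "keep"


@dataclass
class SelectionConfig:
    """Read selection thresholds. ``asf`` must lie in (0, 1]."""

    asf: float = DEFAULT_ASF
    min_read_len: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.asf <= 1:
            raise ValueError("asf must be in (0, 1]")


@dataclass
class ReadRecord:
    """Light-weight view of one primary alignment record."""

    name: str
    sequence: str
    qualities: str
    mapped: bool
    alignment_score: int | None
    is_read1: bool


def from_pysam(rec: pysam.AlignedSegment) -> ReadRecord:
    seq = rec.get_forward_sequence() or ""
    quals = rec.get_forward_qualities()
    qual_str = (
        "".join(chr(q + 33) for q in quals) if quals is not None else "I" * len(seq)
    )
    score = None
    if rec.has_tag("AS"):
        score = int(rec.get_tag("AS"))
    return ReadRecord(
        name=rec.query_name or "",
        sequence=seq,
        qualities=qual_str,
        mapped=not rec.is_unmapped,
        alignment_score=score,
        is_read1=not rec.is_read2,
    )


def classify_read(rec: ReadRecord, cfg: SelectionConfig) -> str:
    """Classify a read as ``select`` (for assembly) or ``keep`` (well aligned).

    Unmapped reads are always selected; a mapped read is selected when its
    alignment score divided by its read length falls below the ASF.
    """
    if not rec.mapped:
        return SELECT
    if rec.alignment_score is None:
        logger.warning("mapped read %s lacks an AS tag; selecting it", rec.name)
        return SELECT
    length = len(rec.sequence)
    if length == 0 or length < cfg.min_read_len:
        return SELECT
    return SELECT if rec.alignment_score / length < cfg.asf else KEEP


def _primary_pairs(
    bam_path: str,
) -> Iterator[tuple[ReadRecord | None, ReadRecord | None]]:
    """Yield (read1, read2) primary records grouped by name.

    Secondary/supplementary records and duplicate- or QC-fail-marked
    records are ignored. Works on SAM or BAM in any record order.
    """
    pairs: dict[str, list[ReadRecord | None]] = {}
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(bam_path, check_sq=False) as fh:
            for rec in fh:
                if rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.is_duplicate or rec.is_qcfail:
                    continue
                slot = pairs.setdefault(rec.query_name, [None, None])
                slot[0 if not rec.is_read2 else 1] = from_pysam(rec)
    finally:
        pysam.set_verbosity(save)
    for name in pairs:
        r1, r2 = pairs[name]
        yield r1, r2


def select_pairs(
    bam_path: str,
    cfg: SelectionConfig | None = None,
) -> tuple[list[tuple[ReadRecord, ReadRecord]], list[ReadRecord]]:
    """Select read pairs for assembly from one sample's alignments.

    A pair is selected if either mate is selected; both mates are then
    emitted, keeping pairs orphan-free. Records without a stored mate go to
    the singles list (if selected).
    """
    cfg = cfg or SelectionConfig()
    selected_pairs: list[tuple[ReadRecord, ReadRecord]] = []
    singles: list[ReadRecord] = []
    for r1, r2 in _primary_pairs(bam_path):
        if r1 is not None and r2 is not None:
            if classify_read(r1, cfg) == SELECT or classify_read(r2, cfg) == SELECT:
                selected_pairs.append((r1, r2))
        else:
            rec = r1 if r1 is not None else r2
            if rec is not None and classify_read(rec, cfg) == SELECT:
                singles.append(rec)
    return selected_pairs, singles


def write_fastq_pairs(
    pairs: list[tuple[ReadRecord, ReadRecord]],
    singles: list[ReadRecord],
    prefix: str,
) -> None:
    with open(f"{prefix}_1.fastq", "w") as f1, open(f"{prefix}_2.fastq", "w") as f2:
        for r1, r2 in pairs:
            f1.write(f"@{r1.name}/1\n{r1.sequence}\n+\n{r1.qualities}\n")
            f2.write(f"@{r2.name}/2\n{r2.sequence}\n+\n{r2.qualities}\n")
    if singles:
        with open(f"{prefix}_single.fastq", "w") as fs:
            for r in singles:
                fs.write(f"@{r.name}\n{r.sequence}\n+\n{r.qualities}\n")


def assemble_contigs(
    reads: Iterable[str],
    k_a: int = DEFAULT_K_ASSEMBLY,
    c_min: int = DEFAULT_C_MIN,
    min_len: int | None = None,
) -> list[str]:
    """Assemble read sequences into unitig contigs.

    Counts canonical k-mers over the reads, drops those with multiplicity
    below ``c_min`` and compacts the surviving single-color de Bruijn graph.
    Contigs shorter than ``min_len`` (default ``2 * k_a``) are discarded.
    """
    if k_a % 2 == 0 or k_a < 3:
        raise ValueError("assembly k must be odd and >= 3")
    if min_len is None:
        min_len = 2 * k_a
    counts: dict[str, int] = {}
    for read in reads:
        for stretch in split_at_ambiguous(read):
            if len(stretch) < k_a:
                continue
            for j in range(len(stretch) - k_a + 1):
                c = cdbg.canonical(stretch[j : j + k_a])
                counts[c] = counts.get(c, 0) + 1
    ones = np.ones(1, dtype=bool)
    kmers = {km: ones for km, n in counts.items() if n >= c_min}
    graph = cdbg.compact_kmers(kmers, k_a, 1)
    return [u.sequence for u in graph.unitigs if len(u.sequence) >= min_len]


def assemble_sample(
    bam_path: str,
    cfg: SelectionConfig | None = None,
    k_a: int = DEFAULT_K_ASSEMBLY,
    c_min: int = DEFAULT_C_MIN,
    min_len: int | None = None,
) -> list[str]:
    """Full per-sample assembly: selection then contig assembly."""
    pairs, singles = select_pairs(bam_path, cfg)
    reads = [r.sequence for pair in pairs for r in pair]
    reads.extend(r.sequence for r in singles)
    return assemble_contigs(reads, k_a=k_a, c_min=c_min, min_len=min_len)
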