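"""Synthetic diploid insertion datasets for end-to-end testing.

The generator mirrors a cut-and-reinsert design: a reference sequence is
generated, ``n_insertions`` non-overlapping stretches are cut out of it
(yielding the depleted reference ``ref_minus`` and the pool of candidate
insertion sequences), and each haplotype of each diploid individual carries
each insertion independently with its allele frequency. Paired-end short
reads with substitution errors are sampled from both haplotypes, and
alignment records against ``ref_minus`` are derived from the known
simulation coordinates instead of running a mapper: reads falling entirely
in retained reference sequence are mapped at their true position, reads
entirely inside an inserted sequence are unmapped, and junction-spanning
reads are soft-clipped with a correspondingly reduced alignment score
(AS = matches - 2*mismatches over the aligned part). This reproduces
exactly the signal the downstream modules consume — unmapped flags,
soft-clips, AS ratios and one-end-anchored pairs.

Truth outputs: the depleted reference, the truth FASTA of sequences carried
by at least one haplotype, and a table of insertion positions (0-based
offsets into ``ref_minus``: the insertion sits between ``pos-1`` and
``pos``) with per-individual genotypes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pysam
import yaml

from .dna import revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
REFERENCE_NAME = "ref"


@dataclass
class SimulationConfig:
    reference_length: int = 200_000
    n_insertions: int = 20
    ins_min: int = 100
    ins_max: int = 2000
    ins_mean: float = 1455.17
    ins_sd: float = 1526.08
    min_distance: int = 1000
    n_individuals: int = 5
    af_min: float = 0.05
    af_max: float = 0.95
    coverage: float = 30.0
    read_length: int = 100
    fragment_mean: float = 350.0
    fragment_sd: float = 50.0
    error_rate: float = 0.001
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class TruthSet:
    """Simulated truth: inserted sequences and who carries them.

    ``sequences`` holds every cut sequence; ``positions[j]`` is the 0-based
    offset in ``ref_minus`` before which insertion ``j`` sits. ``carriers``
    is a boolean array of shape (n_individuals, 2, n_insertions). The truth
    set proper (sequences carried by >= 1 haplotype) is
    :meth:`carried_sequences`.
    """

    sequences: list[str]
    positions: list[int]
    allele_freqs: np.ndarray
    carriers: np.ndarray

    def carried_ids(self) -> list[int]:
        return [j for j in range(len(self.sequences)) if self.carriers[:, :, j].any()]

    def carried_sequences(self) -> dict[str, str]:
        return {f"ins_{j}": self.sequences[j] for j in self.carried_ids()}

    def genotype(self, individual: int, insertion: int) -> int:
        """Number of carrying haplotypes (0, 1 or 2)."""
        return int(self.carriers[individual, :, insertion].sum())


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _sample_lengths(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Truncated log-normal insertion lengths matching the configured moments."""
    sigma2 = np.log(1.0 + (cfg.ins_sd / cfg.ins_mean) ** 2)
    mu = np.log(cfg.ins_mean) - sigma2 / 2.0
    out = np.empty(cfg.n_insertions, dtype=np.int64)
    got = 0
    while got < cfg.n_insertions:
        draw = rng.lognormal(mu, np.sqrt(sigma2), size=4 * cfg.n_insertions)
        ok = draw[(draw >= cfg.ins_min) & (draw <= cfg.ins_max)]
        take = min(len(ok), cfg.n_insertions - got)
        out[got : got + take] = ok[:take].astype(np.int64)
        got += take
    return out


def make_reference_and_cuts(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[str, list[str], list[int], np.ndarray]:
    """Generate the reference, cut out insertion sequences, return the rest.

    Returns ``(ref_minus, sequences, positions, lengths)`` with positions in
    ``ref_minus`` coordinates.
    """
    lengths = _sample_lengths(cfg, rng)
    total = int(lengths.sum()) + (cfg.n_insertions + 1) * cfg.min_distance
    if total > cfg.reference_length:
        raise ValueError(
            f"cannot pack {cfg.n_insertions} insertions (total {total} bp incl. "
            f"spacing) into a {cfg.reference_length} bp reference"
        )
    reference = _random_dna(rng, cfg.reference_length)
    free = cfg.reference_length - int(lengths.sum()) - (cfg.n_insertions + 1) * cfg.min_distance
    # split the slack into n+1 gaps, then place cuts left to right
    if cfg.n_insertions:
        extra = rng.multinomial(free, np.ones(cfg.n_insertions + 1) / (cfg.n_insertions + 1))
    else:
        extra = np.array([free])
    starts = []
    cursor = 0
    for j in range(cfg.n_insertions):
        cursor += cfg.min_distance + int(extra[j])
        starts.append(cursor)
        cursor += int(lengths[j])
    sequences = [reference[s : s + int(l)] for s, l in zip(starts, lengths)]
    pieces = []
    prev = 0
    positions = []
    removed = 0
    for s, l in zip(starts, lengths):
        pieces.append(reference[prev:s])
        positions.append(s - removed)
        removed += int(l)
        prev = s + int(l)
    pieces.append(reference[prev:])
    ref_minus = "".join(pieces)
    return ref_minus, sequences, positions, lengths


def assign_genotypes(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw allele frequencies and per-haplotype carrier states."""
    f = rng.uniform(cfg.af_min, cfg.af_max, size=cfg.n_insertions)
    carriers = rng.random((cfg.n_individuals, 2, cfg.n_insertions)) < f
    return f, carriers


@dataclass
class _Block:
    """One contiguous block of a haplotype: retained reference or insertion."""

    hap_start: int
    hap_end: int
    is_insertion: bool
    ref_start: int  # valid for reference blocks


def _haplotype_blocks(
    ref_minus: str, truth: TruthSet, individual: int, hap: int
) -> tuple[str, list[_Block]]:
    """Build one haplotype sequence and its block map against ref_minus."""
    carried = [
        j for j in range(len(truth.sequences)) if truth.carriers[individual, hap, j]
    ]
    blocks: list[_Block] = []
    parts: list[str] = []
    prev_ref = 0
    cursor = 0
    for j in carried:
        pos = truth.positions[j]
        if pos > prev_ref:
            seg = ref_minus[prev_ref:pos]
            blocks.append(_Block(cursor, cursor + len(seg), False, prev_ref))
            parts.append(seg)
            cursor += len(seg)
        ins = truth.sequences[j]
        blocks.append(_Block(cursor, cursor + len(ins), True, -1))
        parts.append(ins)
        cursor += len(ins)
        prev_ref = pos
    seg = ref_minus[prev_ref:]
    blocks.append(_Block(cursor, cursor + len(seg), False, prev_ref))
    parts.append(seg)
    return "".join(parts), blocks


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> tuple[str, np.ndarray]:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = BASES[BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode(), hits


def _alignment_for(
    blocks: list[_Block], start: int, end: int, errors: np.ndarray
) -> tuple[bool, int, str, int]:
    """Derive the truth alignment of a haplotype interval [start, end).

    Returns (mapped, ref_pos, cigar, alignment_score). The aligned segment
    is the read's overlap with the reference block overlapping it most;
    everything else is soft-clipped. ``errors`` holds 0-based offsets of
    substitution errors within the read.
    """
    length = end - start
    best: _Block | None = None
    best_ov = 0
    for b in blocks:
        if b.is_insertion or b.hap_end <= start or b.hap_start >= end:
            continue
        ov = min(end, b.hap_end) - max(start, b.hap_start)
        if ov > best_ov:
            best_ov = ov
            best = b
    if best is None or best_ov == 0:
        return False, -1, "", 0
    a = max(start, best.hap_start)
    b_ = min(end, best.hap_end)
    left_clip = a - start
    right_clip = end - b_
    aligned = b_ - a
    n_err = int(np.sum((errors >= left_clip) & (errors < left_clip + aligned)))
    score = (aligned - n_err) - 2 * n_err
    cigar = ""
    if left_clip:
        cigar += f"{left_clip}S"
    cigar += f"{aligned}M"
    if right_clip:
        cigar += f"{right_clip}S"
    ref_pos = best.ref_start + (a - best.hap_start)
    return True, ref_pos, cigar, score


def simulate_reads_and_sam(
    cfg: SimulationConfig,
    ref_minus: str,
    truth: TruthSet,
    out_dir: str,
    rng: np.random.Generator,
) -> list[str]:
    """Simulate reads for every individual; write SAM and FASTQ files.

    Returns the list of SAM paths (one per individual). Mate records carry
    standard pair flags; an unmapped mate inherits the position of its
    mapped mate so one-end-anchored pairs are discoverable by position.
    """
    os.makedirs(out_dir, exist_ok=True)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": REFERENCE_NAME, "LN": len(ref_minus)}],
        }
    )
    sam_paths = []
    L = cfg.read_length
    for ind in range(cfg.n_individuals):
        sam_path = os.path.join(out_dir, f"sample_{ind}.sam")
        fq1 = os.path.join(out_dir, f"sample_{ind}_1.fastq")
        fq2 = os.path.join(out_dir, f"sample_{ind}_2.fastq")
        sam_paths.append(sam_path)
        with pysam.AlignmentFile(sam_path, "wh", header=header) as sam, open(
            fq1, "w"
        ) as f1, open(fq2, "w") as f2:
            counter = 0
            for hap in (0, 1):
                hap_seq, blocks = _haplotype_blocks(ref_minus, truth, ind, hap)
                n_frags = int(round(len(hap_seq) * cfg.coverage / 2.0 / (2 * L)))
                frag_lens = np.clip(
                    rng.normal(cfg.fragment_mean, cfg.fragment_sd, n_frags),
                    2 * L,
                    None,
                ).astype(np.int64)
                starts = rng.integers(
                    0, np.maximum(1, len(hap_seq) - frag_lens), size=n_frags
                )
                flips = rng.random(n_frags) < 0.5
                for fi in range(n_frags):
                    s = int(starts[fi])
                    e = s + int(frag_lens[fi])
                    name = f"sim{ind}h{hap}f{counter}"
                    counter += 1
                    # left read forward, right read reverse-complemented;
                    # a coin flip decides which mate is which
                    left_raw = hap_seq[s : s + L]
                    right_raw = hap_seq[e - L : e]
                    left_seq, left_err = _mutate(left_raw, rng, cfg.error_rate)
                    right_seq, right_err = _mutate(right_raw, rng, cfg.error_rate)
                    left_aln = _alignment_for(blocks, s, s + L, left_err)
                    right_aln = _alignment_for(blocks, e - L, e, right_err)
                    # the right read is sequenced on the reverse strand; a
                    # coin flip decides which mate is read1
                    left = (left_seq, left_aln, False)
                    right = (right_seq, right_aln, True)
                    read1, read2 = (right, left) if flips[fi] else (left, right)
                    _write_pair(sam, name, read1, read2, f1, f2, L)
    return sam_paths


def _write_pair(sam, name, read1, read2, f1, f2, L) -> None:
    """Emit one mate pair to SAM and FASTQ.

    Each read triple is ``(fwd_seq, truth_alignment, on_reverse)`` where
    ``fwd_seq`` is the haplotype-forward sequence the alignment refers to
    and ``on_reverse`` says the machine sequenced its reverse complement.
    Mapped records store the reference-forward sequence with the reverse
    flag; unmapped records store the sequence as sequenced.
    """
    recs = []
    for idx, (fwd_seq, aln, on_rev) in enumerate((read1, read2)):
        mapped, ref_pos, cigar, score = aln
        rec = pysam.AlignedSegment(header=sam.header)
        rec.query_name = name
        rec.is_paired = True
        rec.is_read1 = idx == 0
        rec.is_read2 = idx == 1
        if mapped:
            rec.reference_id = 0
            rec.reference_start = ref_pos
            rec.mapping_quality = 60
            rec.is_reverse = on_rev
            rec.query_sequence = fwd_seq
            rec.cigarstring = cigar
            rec.set_tag("AS", int(score))
        else:
            rec.is_unmapped = True
            rec.query_sequence = revcomp(fwd_seq) if on_rev else fwd_seq
        rec.query_qualities = pysam.qualitystring_to_array("I" * len(fwd_seq))
        recs.append(rec)
    r1, r2 = recs
    for rec, mate in ((r1, r2), (r2, r1)):
        if not mate.is_unmapped:
            rec.next_reference_id = 0
            rec.next_reference_start = mate.reference_start
            rec.mate_is_reverse = mate.is_reverse
        else:
            rec.mate_is_unmapped = True
            if not rec.is_unmapped:
                rec.next_reference_id = 0
                rec.next_reference_start = rec.reference_start
        if rec.is_unmapped and not mate.is_unmapped:
            # convention: unmapped mate sits at its mapped mate's position
            rec.reference_id = 0
            rec.reference_start = mate.reference_start
            rec.next_reference_id = 0
            rec.next_reference_start = mate.reference_start
    if not r1.is_unmapped and not r2.is_unmapped:
        r1.is_proper_pair = True
        r2.is_proper_pair = True
        tlen = max(
            r1.reference_end or 0, r2.reference_end or 0
        ) - min(r1.reference_start, r2.reference_start)
        r1.template_length = tlen if r1.reference_start <= r2.reference_start else -tlen
        r2.template_length = -r1.template_length
    sam.write(r1)
    sam.write(r2)
    # FASTQ sequences exactly as sequenced
    for (fwd_seq, _aln, on_rev), fh, tag in ((read1, f1, "/1"), (read2, f2, "/2")):
        seq = revcomp(fwd_seq) if on_rev else fwd_seq
        fh.write(f"@{name}{tag}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate(cfg: SimulationConfig, out_dir: str) -> tuple[str, TruthSet, list[str]]:
    """Run the full simulation and write all outputs under ``out_dir``.

    Emits ``ref_minus.fa``, ``truth.fa`` (carried sequences only),
    ``truth_table.tsv`` and per-sample SAM/FASTQ files. Returns
    ``(ref_minus, truth, sam_paths)``.
    """
    rng = np.random.default_rng(cfg.seed)
    os.makedirs(out_dir, exist_ok=True)
    ref_minus, sequences, positions, _ = make_reference_and_cuts(cfg, rng)
    freqs, carriers = assign_genotypes(cfg, rng)
    truth = TruthSet(
        sequences=sequences,
        positions=positions,
        allele_freqs=freqs,
        carriers=carriers,
    )
    with open(os.path.join(out_dir, "ref_minus.fa"), "w") as fh:
        fh.write(f">{REFERENCE_NAME}\n{ref_minus}\n")
    with open(os.path.join(out_dir, "truth.fa"), "w") as fh:
        for name, seq in truth.carried_sequences().items():
            fh.write(f">{name}\n{seq}\n")
    with open(os.path.join(out_dir, "truth_table.tsv"), "w") as fh:
        cols = "\t".join(f"sample_{i}" for i in range(cfg.n_individuals))
        fh.write(f"id\tpos\tlength\taf\t{cols}\n")
        for j in truth.carried_ids():
            gts = "\t".join(
                str(truth.genotype(i, j)) for i in range(cfg.n_individuals)
            )
            fh.write(
                f"ins_{j}\t{positions[j]}\t{len(sequences[j])}\t"
                f"{freqs[j]:.4f}\t{gts}\n"
            )
    with open(os.path.join(out_dir, "sim_config.yaml"), "w") as fh:
        yaml.safe_dump(asdict(cfg), fh)
    sam_paths = simulate_reads_and_sam(cfg, ref_minus, truth, out_dir, rng)
    return ref_minus, truth, sam_paths
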