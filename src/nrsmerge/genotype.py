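"""Diploid genotype likelihoods for placed NRS variants.

For every exactly placed variant and every sample, the reference allele
(the local reference window without the NRS) and the alternative allele
(the same window with the NRS inserted) are constructed, reads from the
variant neighborhood are aligned to both, and a standard diploid mixture
likelihood over per-read allele likelihoods is computed:

    P(r | A) = eps^d * (1 - eps)^(L - d)

with ``d`` the best end-gap-free (infix) alignment edit distance of read
``r`` against allele ``A`` and ``L`` the read length, and

    GL(g) = sum_r log10[ (2 - g)/2 * P(r | ref) + g/2 * P(r | alt) ]

for ``g`` in {0, 1, 2} copies of the NRS. Only reads whose alignment
crosses an allele junction by at least ``min_overlap`` bases are used;
reads equally consistent with both alleles cancel out of the argmax but
are excluded up front for robustness. Interval-resolution variants are
reported as missing genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pysam

from .dna import revcomp
from .place import EXACT, PlacedVariant

DEFAULT_EPS = 0.01
DEFAULT_MIN_OVERLAP = 10
DEFAULT_FLANK = 150

MISSING = "./."
GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}


@dataclass
class AllelePair:
    """Reference and alternative allele windows around one insertion point."""

    ref_allele: str
    alt_allele: str
    flank_left: int
    nrs_length: int

    @property
    def ref_junction(self) -> int:
        """Insertion point in reference-allele coordinates."""
        return self.flank_left

    @property
    def alt_junctions(self) -> tuple[int, int]:
        return self.flank_left, self.flank_left + self.nrs_length


@dataclass
class GenotypeCall:
    gt: str
    gl: tuple[float, float, float] | None
    gq: int
    n_reads: int


def build_alleles(
    reference: str, variant: PlacedVariant, nrs_seq: str, flank: int = DEFAULT_FLANK
) -> AllelePair | None:
    """Construct the two alleles; None for interval-resolution variants.

    Flanks are truncated at chromosome ends. The inserted sequence is the
    oriented NRS with any reference-flank trim applied.
    """
    if variant.resolution != EXACT:
        return None
    p = variant.pos  # 0-based insertion offset
    ins = variant.inserted_sequence(nrs_seq)
    left = reference[max(0, p - flank) : p]
    right = reference[p : p + flank]
    return AllelePair(
        ref_allele=left + right,
        alt_allele=left + ins + right,
        flank_left=len(left),
        nrs_length=len(ins),
    )


def _best_alignment(read: str, allele: str) -> tuple[int, int, int]:
    """(edit distance, start, end) of the best infix alignment, both strands."""
    best = None
    for query in (read, revcomp(read)):
        res = edlib.align(query, allele, mode="HW", task="locations")
        d = res["editDistance"]
        if d < 0:
            continue
        start, end = res["locations"][0]
        if best is None or d < best[0]:
            best = (d, start, end + 1)
    if best is None:
        return len(read), 0, 0
    return best


def _crosses(start: int, end: int, junction: int, min_overlap: int) -> bool:
    return start <= junction - min_overlap and end >= junction + min_overlap


def genotype_likelihoods(
    reads: list[str],
    alleles: AllelePair,
    eps: float = DEFAULT_EPS,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> GenotypeCall:
    """Compute the diploid genotype call from reads over one allele pair."""
    if not 0 < eps < 0.5:
        raise ValueError("eps must be in (0, 0.5)")
    log_eps = np.log10(eps)
    log_keep = np.log10(1.0 - eps)
    gl = np.zeros(3)
    n_used = 0
    jr = alleles.ref_junction
    ja1, ja2 = alleles.alt_junctions
    for read in reads:
        L = len(read)
        if L == 0:
            continue
        d_ref, rs, re_ = _best_alignment(read, alleles.ref_allele)
        d_alt, as_, ae = _best_alignment(read, alleles.alt_allele)
        # the read must genuinely come from this locus: a clean fit to at
        # least one allele (otherwise it is a window-edge or stray read
        # whose forced infix alignment would smear across the junction)
        if min(d_ref, d_alt) > 0.1 * L + 2:
            continue
        # junction crossing is judged on the allele the read fits better
        if d_ref < d_alt:
            informative = _crosses(rs, re_, jr, min_overlap)
        elif d_alt < d_ref:
            informative = any(
                _crosses(as_, ae, j, min_overlap) for j in (ja1, ja2)
            )
        else:
            informative = _crosses(rs, re_, jr, min_overlap) or any(
                _crosses(as_, ae, j, min_overlap) for j in (ja1, ja2)
            )
        if not informative:
            continue
        n_used += 1
        lp_ref = d_ref * log_eps + (L - d_ref) * log_keep
        lp_alt = d_alt * log_eps + (L - d_alt) * log_keep
        # GL contributions: g copies of the alt allele out of 2
        for g in (0, 1, 2):
            w_ref, w_alt = (2 - g) / 2.0, g / 2.0
            terms = []
            if w_ref > 0:
                terms.append(np.log10(w_ref) + lp_ref)
            if w_alt > 0:
                terms.append(np.log10(w_alt) + lp_alt)
            m = max(terms)
            gl[g] += m + np.log10(sum(10.0 ** (t - m) for t in terms))
    if n_used == 0:
        return GenotypeCall(gt=MISSING, gl=None, gq=0, n_reads=0)
    order = np.argsort(gl)[::-1]
    best, second = int(order[0]), int(order[1])
    gq = int(round(10.0 * (gl[best] - gl[second])))
    return GenotypeCall(
        gt=GT_STRINGS[best],
        gl=(float(gl[0]), float(gl[1]), float(gl[2])),
        gq=gq,
        n_reads=n_used,
    )


def collect_reads_near(
    sam_path: str, positions: dict[str, int], window: int
) -> dict[str, list[str]]:
    """One pass over a SAM: reads whose position falls near each variant.

    ``positions`` maps variant id to the 0-based insertion offset. Unmapped
    mates carry their mapped mate's position, so one-end-anchored evidence
    is collected too. Returns variant id -> read sequences (as stored).
    """
    out: dict[str, list[str]] = {vid: [] for vid in positions}
    items = sorted(positions.items(), key=lambda kv: kv[1])
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
            for rec in fh:
                if rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                    continue
                pos = rec.reference_start
                if pos is None or pos < 0:
                    continue
                seq = rec.query_sequence
                if not seq:
                    continue
                for vid, vpos in items:
                    if vpos - window <= pos <= vpos + window:
                        out[vid].append(seq)
    finally:
        pysam.set_verbosity(save)
    return out


def genotype_samples(
    sam_paths: list[str],
    variants: list[PlacedVariant],
    nrs_seqs: dict[str, str],
    reference: str,
    flank: int = DEFAULT_FLANK,
    eps: float = DEFAULT_EPS,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    read_length: int = 100,
) -> dict[tuple[str, int], GenotypeCall]:
    """Genotype every variant in every sample.

    Returns a mapping ``(variant id, sample index) -> GenotypeCall``.
    """
    calls: dict[tuple[str, int], GenotypeCall] = {}
    allele_pairs = {
        v.nrs_id: build_alleles(reference, v, nrs_seqs[v.nrs_id], flank=flank)
        for v in variants
    }
    positions = {v.nrs_id: v.pos for v in variants if allele_pairs[v.nrs_id]}
    window = flank + read_length
    for si, sam_path in enumerate(sam_paths):
        reads_by_var = collect_reads_near(sam_path, positions, window)
        for v in variants:
            pair = allele_pairs[v.nrs_id]
            if pair is None:
                calls[(v.nrs_id, si)] = GenotypeCall(MISSING, None, 0, 0)
                continue
            calls[(v.nrs_id, si)] = genotype_likelihoods(
                reads_by_var[v.nrs_id], pair, eps=eps, min_overlap=min_overlap
            )
    return calls


def write_genotyped_vcf(
    calls: dict[tuple[str, int], GenotypeCall],
    vcf_in: str,
    out_path: str,
    sample_names: list[str],
) -> None:
    """Add FORMAT GT:GL:GQ columns per sample to the placing VCF."""
    n = len(sample_names)
    with open(vcf_in) as fh:
        lines = [line.rstrip("\n") for line in fh]
    out: list[str] = []
    for line in lines:
        if line.startswith("##"):
            out.append(line)
            continue
        if line.startswith("#CHROM"):
            out.append(
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
            )
            out.append(
                '##FORMAT=<ID=GL,Number=G,Type=Float,Description="Log10 genotype likelihoods">'
            )
            out.append(
                '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">'
            )
            out.append(line + "\tFORMAT\t" + "\t".join(sample_names))
            continue
        fields = line.split("\t")
        info = dict(
            kv.split("=", 1) if "=" in kv else (kv, True)
            for kv in fields[7].split(";")
        )
        nrs_id = info.get("NRSID")
        cols = []
        for si in range(n):
            call = calls.get((str(nrs_id), si))
            if call is None or call.gl is None:
                cols.append("./.")
            else:
                gl = ",".join(f"{x:.4f}" for x in call.gl)
                cols.append(f"{call.gt}:{gl}:{call.gq}")
        out.append("\t".join(fields[:8]) + "\tGT:GL:GQ\t" + "\t".join(cols))
    with open(out_path, "w") as fh:
        fh.write("\n".join(out) + "\n")
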