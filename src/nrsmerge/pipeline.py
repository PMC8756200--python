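"""End-to-end orchestration: simulate -> assemble -> merge -> place -> genotype.

Primarily a convenience layer for validation runs: it wires the per-module
functions together with consistent parameters and returns every
intermediate product, so tests and the reproduction script can measure
precision/recall of the merged NRS set and genotype concordance against
the simulated truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from . import evaluate as ev
from . import genotype as gt
from . import merge as mg
from . import place as pl
from . import readprep as rp
from .simulate import SimulationConfig, TruthSet, simulate


@dataclass
class PipelineResult:
    ref_minus: str
    truth: TruthSet
    sam_paths: list[str]
    contig_sets: list[list[str]]
    nrs_records: list[mg.NRSRecord]
    variants: list[pl.PlacedVariant]
    calls: dict[tuple[str, int], gt.GenotypeCall]
    eval_result: ev.EvalResult
    hits: list[ev.AlignmentHit]


def run_pipeline(
    cfg: SimulationConfig,
    out_dir: str,
    k: int = 31,
    tau: int = 30,
    asf: float = rp.DEFAULT_ASF,
    k_assembly: int = rp.DEFAULT_K_ASSEMBLY,
    c_min: int = rp.DEFAULT_C_MIN,
) -> PipelineResult:
    """Run the full chain on a fresh simulation and score it."""
    ref_minus, truth, sam_paths = simulate(cfg, out_dir)
    sel_cfg = rp.SelectionConfig(asf=asf)
    contig_sets = [
        rp.assemble_sample(p, cfg=sel_cfg, k_a=k_assembly, c_min=c_min)
        for p in sam_paths
    ]
    records = mg.merge(contig_sets, k=k, tau=tau)
    nrs_seqs = {rec.id: rec.sequence for rec in records}
    variants = pl.place(
        sam_paths,
        nrs_seqs,
        ref_minus,
        read_length=cfg.read_length,
    )
    calls = gt.genotype_samples(
        sam_paths,
        variants,
        nrs_seqs,
        ref_minus,
        read_length=cfg.read_length,
    )
    truth_seqs = truth.carried_sequences()
    result, hits = ev.evaluate(truth_seqs, nrs_seqs)
    return PipelineResult(
        ref_minus=ref_minus,
        truth=truth,
        sam_paths=sam_paths,
        contig_sets=contig_sets,
        nrs_records=records,
        variants=variants,
        calls=calls,
        eval_result=result,
        hits=hits,
    )


def genotype_concordance(
    result: PipelineResult, max_pos_error: int = 50
) -> tuple[float, int, dict[str, int]]:
    """Concordance of called genotypes with simulated truth.

    Each exactly placed variant is matched to the nearest truth insertion
    (within ``max_pos_error`` bp); called genotypes (0/0, 0/1, 1/1) are
    compared with the truth carrier counts over all samples. Returns
    ``(concordance, n_compared, per_class_counts)``.
    """
    truth = result.truth
    gt_to_int = {"0/0": 0, "0/1": 1, "1/1": 2}
    n_ok = 0
    n_all = 0
    per_class = {"0/0": 0, "0/1": 0, "1/1": 0}
    carried = truth.carried_ids()
    for v in result.variants:
        if v.resolution != pl.EXACT:
            continue
        dists = [(abs(truth.positions[j] - v.pos), j) for j in carried]
        if not dists:
            continue
        dist, j = min(dists)
        if dist > max_pos_error:
            continue
        for si in range(truth.carriers.shape[0]):
            call = result.calls.get((v.nrs_id, si))
            if call is None or call.gt not in gt_to_int:
                continue
            expected = truth.genotype(si, j)
            n_all += 1
            if gt_to_int[call.gt] == expected:
                n_ok += 1
                per_class[call.gt] += 1
    return (n_ok / n_all if n_all else 0.0), n_all, per_class


def equivalent_placement(
    reference: str, pos_c: int, ins_c: str, pos_t: int, ins_t: str, pad: int = 10
) -> bool:
    """Whether two (position, insertion) calls spell the same haplotype.

    Breakpoints of an insertion flanked by homologous bases are ambiguous
    by up to the homology length; two representations are the same variant
    iff applying them to the reference yields identical sequence.
    """
    if abs(pos_c - pos_t) > max(len(ins_c), len(ins_t)):
        return False
    lo = max(0, min(pos_c, pos_t) - pad)
    hi = min(len(reference), max(pos_c, pos_t) + pad)
    a = reference[lo:pos_c] + ins_c + reference[pos_c:hi]
    b = reference[lo:pos_t] + ins_t + reference[pos_t:hi]
    return a == b


def exact_placement_stats(
    result: PipelineResult, max_pos_error: int = 50
) -> tuple[float, float, int]:
    """(exact fraction, fraction of exact calls with zero placement error, n).

    Zero placement error means the called (position, inserted sequence)
    pair spells exactly the haplotype of some truth insertion — positions
    shifted within a breakpoint-homology stretch count as exact.
    """
    truth = result.truth
    carried = truth.carried_ids()
    n = len(result.variants)
    if n == 0:
        return 0.0, 0.0, 0
    nrs_seqs = {r.id: r.sequence for r in result.nrs_records}
    exact = [v for v in result.variants if v.resolution == pl.EXACT]
    n_exact0 = 0
    for v in exact:
        ins_c = v.inserted_sequence(nrs_seqs[v.nrs_id])
        for j in carried:
            if abs(truth.positions[j] - v.pos) > max_pos_error:
                continue
            if equivalent_placement(
                result.ref_minus, v.pos, ins_c, truth.positions[j], truth.sequences[j]
            ):
                n_exact0 += 1
                break
    frac_exact = len(exact) / n
    frac_err0 = n_exact0 / len(exact) if exact else 0.0
    return frac_exact, frac_err0, n
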