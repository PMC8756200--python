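"""Bidirected colored compacted de Bruijn graph (CCDBG) over many contig sets.

A CCDBG is built from ``n`` sequence sets (one per genome, "colors"). Every
canonical k-mer occurring in any set becomes part of exactly one unitig — a
maximal non-branching path of the underlying k-mer graph — and carries a
bitvector of length ``n`` recording which sets contain it. Unitigs are
bidirected: a single vertex represents a sequence and its reverse complement,
and edges are orientation-typed 4-tuples ``(uid, ori, vid, ori)`` with
``ori`` one of ``'+'``/``'-'``. An edge exists iff the (k-1)-suffix of the
source in its orientation equals the (k-1)-prefix of the target in its
orientation.

Color bitvectors at unitig junctions drive the merge heuristic: the Jaccard
similarity of the last k-mer colors of one unitig and the first k-mer colors
of its successor measures how consistently the two unitigs co-occur across
genomes, and ``1 - J`` serves as an edge weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .dna import revcomp, split_at_ambiguous, is_valid_dna

logger = logging.getLogger(__name__)

FWD = "+"
REV = "-"

#: default k-mer length for merging contigs of many genomes
DEFAULT_K = 63


def flip(ori: str) -> str:
    return REV if ori == FWD else FWD


@dataclass(frozen=True)
class Kmer:
    """A canonical k-mer.

    ``sequence`` is the lexicographic minimum of the input and its reverse
    complement; ``canonical`` records whether the input was already in
    canonical form.
    """

    sequence: str
    canonical: bool

    def __len__(self) -> int:
        return len(self.sequence)


def canonicalize(seq: str) -> Kmer:
    """Return the canonical form of a k-mer.

    Raises ``ValueError`` on non-ACGT input; k-mers containing ambiguous
    symbols are expected to be skipped upstream.
    """
    seq = seq.upper()
    if not is_valid_dna(seq):
        raise ValueError(f"k-mer contains non-ACGT symbols: {seq!r}")
    rc = revcomp(seq)
    if seq <= rc:
        return Kmer(seq, True)
    return Kmer(rc, False)


def canonical(seq: str) -> str:
    """Canonical string form of ``seq`` (min of itself and its revcomp)."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


@dataclass
class Unitig:
    """A unitig: the sequence of a maximal non-branching path.

    ``sequence`` is stored in canonical orientation (lexicographic minimum of
    the spelled sequence and its reverse complement). ``kmer_colors`` is an
    ``(l - k + 1, n_colors)`` boolean matrix, row ``i`` giving the color
    bitvector of the k-mer starting at offset ``i`` of the stored sequence.
    """

    id: int
    sequence: str
    kmer_colors: np.ndarray

    @property
    def n_kmers(self) -> int:
        return self.kmer_colors.shape[0]

    def oriented_sequence(self, ori: str) -> str:
        return self.sequence if ori == FWD else revcomp(self.sequence)

    def first_colors(self, ori: str) -> np.ndarray:
        """Color bitvector of the first k-mer in traversal orientation."""
        return self.kmer_colors[0] if ori == FWD else self.kmer_colors[-1]

    def last_colors(self, ori: str) -> np.ndarray:
        """Color bitvector of the last k-mer in traversal orientation."""
        return self.kmer_colors[-1] if ori == FWD else self.kmer_colors[0]


@dataclass
class OrientedPath:
    """A sequence of (unitig id, orientation) steps spelling one candidate NRS."""

    steps: list[tuple[int, str]]
    novel_kmer_count: int = 0

    def __len__(self) -> int:
        return len(self.steps)

    def ids(self) -> list[int]:
        return [uid for uid, _ in self.steps]


class CCDBG:
    """Bidirected colored compacted de Bruijn graph."""

    def __init__(self, k: int, n_colors: int):
        self.k = k
        self.n_colors = n_colors
        self.unitigs: list[Unitig] = []
        self.edges: set[tuple[int, str, int, str]] = set()
        # adjacency: (uid, ori) -> sorted list of (vid, ori)
        self._succ: dict[tuple[int, str], list[tuple[int, str]]] = {}
        # canonical k-mer -> (uid, offset, strand of the k-mer at that offset)
        self._kmer_index: dict[str, tuple[int, int, str]] = {}

    # -- queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.unitigs)

    def successors(self, uid: int, ori: str) -> list[tuple[int, str]]:
        return self._succ.get((uid, ori), [])

    def predecessors(self, uid: int, ori: str) -> list[tuple[int, str]]:
        """Predecessors of (uid, ori): mirrors of the successors of the flip."""
        return [(v, flip(o)) for v, o in self.successors(uid, flip(ori))]

    def has_kmer(self, kmer: str) -> bool:
        return canonical(kmer) in self._kmer_index

    def locate(self, kmer: str) -> tuple[int, int, str] | None:
        return self._kmer_index.get(canonical(kmer))

    def canonical_kmers(self) -> set[str]:
        return set(self._kmer_index)

    # -- construction helpers -------------------------------------------

    def _index_unitig(self, u: Unitig) -> None:
        k = self.k
        for off in range(u.n_kmers):
            km = u.sequence[off : off + k]
            c = canonical(km)
            self._kmer_index[c] = (u.id, off, FWD if c == km else REV)

    def _build_edges(self) -> None:
        k = self.k
        first_index: dict[str, list[tuple[int, str]]] = {}
        for u in self.unitigs:
            first_index.setdefault(u.sequence[:k], []).append((u.id, FWD))
            first_index.setdefault(revcomp(u.sequence[-k:]), []).append((u.id, REV))
        for u in self.unitigs:
            for ori in (FWD, REV):
                last = u.oriented_sequence(ori)[-k:]
                for b in "ACGT":
                    q = last[1:] + b
                    if not self.has_kmer(q):
                        continue
                    for vid, vori in first_index.get(q, []):
                        self.edges.add((u.id, ori, vid, vori))
        succ: dict[tuple[int, str], list[tuple[int, str]]] = {}
        for a, oa, b, ob in self.edges:
            succ.setdefault((a, oa), []).append((b, ob))
        for key in succ:
            succ[key].sort(key=lambda vo: (self.unitigs[vo[0]].sequence, vo[1]))
        self._succ = succ

    # -- equality (structural; used by GFA round trip) -------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CCDBG):
            return NotImplemented
        if (self.k, self.n_colors) != (other.k, other.n_colors):
            return False
        if [u.sequence for u in self.unitigs] != [u.sequence for u in other.unitigs]:
            return False
        for a, b in zip(self.unitigs, other.unitigs):
            if not np.array_equal(a.kmer_colors, b.kmer_colors):
                return False
        return self.edges == other.edges


# ---------------------------------------------------------------------------
# construction


def _collect_kmers(
    contig_sets: Sequence[Iterable[str]], k: int
) -> dict[str, np.ndarray]:
    """Canonical k-mer -> color bitvector over the input sets.

    Sequences shorter than k and k-mers containing ambiguous symbols are
    skipped (contigs are split at non-ACGT symbols first).
    """
    n = len(contig_sets)
    kmers: dict[str, np.ndarray] = {}
    for i, contigs in enumerate(contig_sets):
        for seq in contigs:
            for stretch in split_at_ambiguous(seq):
                if len(stretch) < k:
                    logger.warning(
                        "skipping sequence stretch shorter than k=%d (len %d)",
                        k,
                        len(stretch),
                    )
                    continue
                for j in range(len(stretch) - k + 1):
                    c = canonical(stretch[j : j + k])
                    bits = kmers.get(c)
                    if bits is None:
                        bits = np.zeros(n, dtype=bool)
                        kmers[c] = bits
                    bits[i] = True
    return kmers


def _oriented_neighbors(
    kmer: str, kmers: dict[str, np.ndarray], side: str
) -> list[str]:
    """Successors (side='succ') or predecessors (side='pred') of an oriented k-mer."""
    out = []
    if side == "succ":
        core = kmer[1:]
        for b in "ACGT":
            q = core + b
            if canonical(q) in kmers:
                out.append(q)
    else:
        core = kmer[:-1]
        for b in "ACGT":
            q = b + core
            if canonical(q) in kmers:
                out.append(q)
    return out


def compact_kmers(kmers: dict[str, np.ndarray], k: int, n_colors: int) -> CCDBG:
    """Build a CCDBG by compacting a canonical-k-mer -> colors mapping.

    Unitigs are maximal non-branching paths of the bidirected k-mer graph.
    Extension from an oriented k-mer x to its unique successor y requires y's
    unique predecessor to be x; circular components are broken at the
    (deterministic) smallest canonical k-mer.
    """
    graph = CCDBG(k, n_colors)
    if not kmers:
        return graph
    visited: set[str] = set()
    unitig_seqs: list[str] = []

    def extend_right(start: str, seen_local: set[str]) -> list[str]:
        chain = [start]
        seen_local.add(canonical(start))
        current = start
        while True:
            succs = _oriented_neighbors(current, kmers, "succ")
            if len(succs) != 1:
                break
            nxt = succs[0]
            if canonical(nxt) in seen_local:
                break  # circular or hairpin: stop (cycles linearize here)
            preds = _oriented_neighbors(nxt, kmers, "pred")
            if len(preds) != 1:
                break
            chain.append(nxt)
            seen_local.add(canonical(nxt))
            current = nxt
        return chain

    def spell_chain(chain: list[str]) -> str:
        s = chain[0]
        for km in chain[1:]:
            s += km[-1]
        return s

    for start in sorted(kmers):
        if start in visited:
            continue
        seen_local: set[str] = set()
        right = extend_right(start, seen_local)
        left = extend_right(revcomp(start), seen_local)
        # left chain extends rightward from the reverse strand; its revcomp
        # ends exactly at `start`, to which the right chain is appended
        seq = revcomp(spell_chain(left)) + spell_chain(right)[k:]
        cano_seq = canonical(seq)
        # mark constituent k-mers visited
        for j in range(len(seq) - k + 1):
            visited.add(canonical(seq[j : j + k]))
        unitig_seqs.append(cano_seq)

    unitig_seqs.sort()
    for uid, seq in enumerate(unitig_seqs):
        colors = np.stack(
            [kmers[canonical(seq[j : j + k])] for j in range(len(seq) - k + 1)]
        )
        u = Unitig(uid, seq, colors)
        graph.unitigs.append(u)
        graph._index_unitig(u)
    graph._build_edges()
    return graph


def build_ccdbg(contig_sets: Sequence[Iterable[str]], k: int = DEFAULT_K) -> CCDBG:
    """Build the bidirected CCDBG over ``n`` contig sets (one set per color).

    ``k`` must be odd (so no k-mer equals its own reverse complement) and at
    least 3. An empty input yields an empty graph.
    """
    if k < 3 or k % 2 == 0:
        raise ValueError("k must be odd and >= 3")
    kmers = _collect_kmers(contig_sets, k)
    return compact_kmers(kmers, k, len(contig_sets))


# ---------------------------------------------------------------------------
# color arithmetic


def jaccard(x: np.ndarray, y: np.ndarray) -> float:
    """Jaccard index of two color bitvectors: |x AND y| / |x OR y|.

    Two all-zero vectors compare as 0 (cannot occur for k-mers present in
    the graph, but defensive).
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"bitvector length mismatch: {x.shape} vs {y.shape}")
    union = int(np.logical_or(x, y).sum())
    if union == 0:
        return 0.0
    return int(np.logical_and(x, y).sum()) / union


def edge_weight(graph: CCDBG, u: tuple[int, str], v: tuple[int, str]) -> float:
    """Weight of the oriented edge u -> v: 1 - J(last(u), first(v))."""
    uu = graph.unitigs[u[0]]
    vv = graph.unitigs[v[0]]
    return 1.0 - jaccard(uu.last_colors(u[1]), vv.first_colors(v[1]))


def spell(path: OrientedPath, graph: CCDBG) -> str:
    """Sequence spelled by a path with (k-1)-overlaps collapsed."""
    k = graph.k
    uid, ori = path.steps[0]
    seq = graph.unitigs[uid].oriented_sequence(ori)
    for vid, vori in path.steps[1:]:
        nxt = graph.unitigs[vid].oriented_sequence(vori)
        if seq[-(k - 1):] != nxt[: k - 1]:
            raise RuntimeError(
                "path steps do not overlap by k-1 bases; graph is inconsistent"
            )
        seq += nxt[k - 1:]
    return seq


def path_color_weight(path: OrientedPath, graph: CCDBG) -> float:
    """Color weight of a path: 1 minus the minimum Jaccard similarity between
    the junction color bitvectors of consecutive vertices.

    A single-vertex path has weight 0 (the minimum over an empty set of
    junctions is taken as 1).
    """
    if len(path.steps) < 2:
        return 0.0
    best = min(
        jaccard(
            graph.unitigs[a].last_colors(oa),
            graph.unitigs[b].first_colors(ob),
        )
        for (a, oa), (b, ob) in zip(path.steps, path.steps[1:])
    )
    return 1.0 - best


# ---------------------------------------------------------------------------
# GFA1 serialization


def write_gfa(graph: CCDBG, gfa_path: str, colors_path: str | None = None) -> None:
    """Write the graph as GFA1 plus an optional color sidecar TSV.

    Segments carry the canonical unitig sequence; each bidirected edge is
    written once as an L line (its mirror is implied). The header records k
    in a ``KL`` tag. The sidecar has one row per k-mer: unitig id, offset,
    color bitstring.
    """
    with open(gfa_path, "w") as fh:
        fh.write(f"H\tVN:Z:1.0\tKL:i:{graph.k}\tNC:i:{graph.n_colors}\n")
        for u in graph.unitigs:
            fh.write(f"S\t{u.id}\t{u.sequence}\n")
        written = set()
        for a, oa, b, ob in sorted(graph.edges):
            mirror = (b, flip(ob), a, flip(oa))
            if mirror in written:
                continue
            written.add((a, oa, b, ob))
            fh.write(f"L\t{a}\t{oa}\t{b}\t{ob}\t{graph.k - 1}M\n")
    if colors_path is not None:
        with open(colors_path, "w") as fh:
            fh.write("unitig\toffset\tcolors\n")
            for u in graph.unitigs:
                for off in range(u.n_kmers):
                    bits = "".join("1" if b else "0" for b in u.kmer_colors[off])
                    fh.write(f"{u.id}\t{off}\t{bits}\n")


def read_gfa(gfa_path: str, colors_path: str | None = None) -> CCDBG:
    """Read a GFA1 file written by :func:`write_gfa` back into a CCDBG."""
    k = None
    n_colors = 0
    seqs: dict[int, str] = {}
    links: list[tuple[int, str, int, str]] = []
    with open(gfa_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            tag = fields[0]
            try:
                if tag == "H":
                    for f in fields[1:]:
                        if f.startswith("KL:i:"):
                            k = int(f[5:])
                        elif f.startswith("NC:i:"):
                            n_colors = int(f[5:])
                elif tag == "S":
                    seqs[int(fields[1])] = fields[2]
                elif tag == "L":
                    links.append((int(fields[1]), fields[2], int(fields[3]), fields[4]))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"malformed GFA line {lineno}: {line!r}") from exc
    if k is None:
        raise ValueError("GFA header lacks the KL:i:<k> tag")
    colors: dict[tuple[int, int], str] = {}
    if colors_path is not None:
        with open(colors_path) as fh:
            header = fh.readline()
            for line in fh:
                uid, off, bits = line.rstrip("\n").split("\t")
                colors[(int(uid), int(off))] = bits
                n_colors = max(n_colors, len(bits))
    graph = CCDBG(k, n_colors)
    for uid in sorted(seqs):
        seq = seqs[uid]
        n_km = len(seq) - k + 1
        mat = np.zeros((n_km, n_colors), dtype=bool)
        for off in range(n_km):
            bits = colors.get((uid, off))
            if bits is not None:
                mat[off] = [ch == "1" for ch in bits]
        u = Unitig(uid, seq, mat)
        graph.unitigs.append(u)
        graph._index_unitig(u)
    for a, oa, b, ob in links:
        graph.edges.add((a, oa, b, ob))
        graph.edges.add((b, flip(ob), a, flip(oa)))
    succ: dict[tuple[int, str], list[tuple[int, str]]] = {}
    for a, oa, b, ob in graph.edges:
        succ.setdefault((a, oa), []).append((b, ob))
    for key in succ:
        succ[key].sort(key=lambda vo: (graph.unitigs[vo[0]].sequence, vo[1]))
    graph._succ = succ
    return graph
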