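"""Greedy color-guided path cover of the CCDBG: the merging step.

Candidate non-reference sequences (NRS) correspond to maximal unitig paths
in the colored compacted de Bruijn graph built over contig sets of many
genomes. Finding a path cover of minimum total color weight is NP-hard, so
the merge runs a greedy depth-first search from each source vertex,
prioritizing successors by color similarity (lowest ``1 - J`` edge weight)
and emitting a source-to-sink path whenever it contributes more than ``tau``
k-mers not yet covered by earlier paths.

The traversal is fully deterministic: sources are visited in lexicographic
order of their canonical unitig sequence (forward orientation first) and
ties among equally weighted successors break on the smaller canonical
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cdbg import CCDBG, FWD, REV, OrientedPath, build_ccdbg, edge_weight, flip, spell

#: default minimum number of novel k-mers an emitted path must contribute
def default_tau(k: int) -> int:
    return k - 1


@dataclass
class TraversalState:
    """Mutable state across one merge run.

    ``seen`` marks (unitig id, orientation) pairs during the current source
    traversal and is reset between sources; ``covered`` is the global set D
    of unitig ids already part of an emitted path and only grows.
    """

    tau: int
    seen: set[tuple[int, str]] = field(default_factory=set)
    covered: set[int] = field(default_factory=set)


@dataclass
class NRSRecord:
    """One emitted candidate NRS."""

    id: str
    sequence: str
    source_path: OrientedPath
    n_novel_kmers: int


def classify_vertices(
    graph: CCDBG,
) -> tuple[list[int], list[tuple[int, str]], list[int]]:
    """Partition vertices into singletons, oriented sources and the rest.

    A vertex is a singleton if it has neither predecessors nor successors in
    either orientation. ``(uid, ori)`` is a source if the vertex has no
    predecessors but at least one successor when traversed in ``ori``.
    """
    singletons: list[int] = []
    sources: list[tuple[int, str]] = []
    others: list[int] = []
    for u in graph.unitigs:
        succ_f = graph.successors(u.id, FWD)
        succ_r = graph.successors(u.id, REV)
        if not succ_f and not succ_r:
            singletons.append(u.id)
            continue
        is_source = False
        for ori in (FWD, REV):
            # predecessors in ori are mirrors of successors in the flip
            if graph.successors(u.id, ori) and not graph.successors(u.id, flip(ori)):
                sources.append((u.id, ori))
                is_source = True
        if not is_source:
            others.append(u.id)
    return singletons, sources, others


def _novel_kmers(graph: CCDBG, ids: list[int], covered: set[int]) -> int:
    """Novel k-mers at vertex granularity: k-mers of unitigs not in D."""
    return sum(graph.unitigs[uid].n_kmers for uid in set(ids) if uid not in covered)


def traverse_from_source(
    graph: CCDBG, source: tuple[int, str], state: TraversalState
) -> OrientedPath | None:
    """Greedy DFS from one source; return the emitted path or None.

    Successors are tried in order of increasing edge weight
    ``1 - J(last(u), first(v))``; the first sink reached ends the search.
    If the path past the sink contains more than ``state.tau`` k-mers not in
    any covered vertex, the path's vertices join the covered set and the
    path is returned. A traversal that backtracks to exhaustion (all
    successors seen — an unresolvable local substructure) returns None.
    Seen marks are reset afterwards in every case.
    """
    state.seen = {source}
    path: list[tuple[int, str]] = [source]
    path_ids: set[int] = {source[0]}

    def candidates(node: tuple[int, str]) -> list[tuple[int, str]]:
        succ = graph.successors(*node)
        return sorted(
            succ,
            key=lambda v: (
                edge_weight(graph, node, v),
                graph.unitigs[v[0]].sequence,
                v[1],
            ),
        )

    stack: list[list[tuple[int, str]]] = [candidates(source)]
    reached_sink = False
    while stack:
        node = path[-1]
        if not graph.successors(*node):
            reached_sink = True
            break
        advanced = False
        while stack[-1]:
            v = stack[-1].pop(0)
            if v in state.seen or v[0] in path_ids:
                continue
            state.seen.add(v)
            path.append(v)
            path_ids.add(v[0])
            stack.append(candidates(v))
            advanced = True
            break
        if not advanced:
            stack.pop()
            dropped = path.pop()
            path_ids.discard(dropped[0])
    state.seen = set()
    if not reached_sink:
        return None
    novel = _novel_kmers(graph, [uid for uid, _ in path], state.covered)
    if novel <= state.tau:
        return None
    state.covered.update(uid for uid, _ in path)
    return OrientedPath(steps=path, novel_kmer_count=novel)


def merge_graph(graph: CCDBG, tau: int) -> list[NRSRecord]:
    """Run the greedy path cover on a built CCDBG and emit NRS records.

    Emission order: singleton unitigs first, then one path per source in
    deterministic source order, finally any unitig of a source-free (fully
    cyclic) component that still has more than ``tau`` uncovered k-mers, as
    a single-unitig NRS.
    """
    state = TraversalState(tau=tau)
    records: list[NRSRecord] = []
    singletons, sources, _ = classify_vertices(graph)

    def emit(path: OrientedPath) -> None:
        records.append(
            NRSRecord(
                id=f"nrs_{len(records)}",
                sequence=spell(path, graph),
                source_path=path,
                n_novel_kmers=path.novel_kmer_count,
            )
        )

    for uid in sorted(singletons, key=lambda i: graph.unitigs[i].sequence):
        path = OrientedPath(
            steps=[(uid, FWD)], novel_kmer_count=graph.unitigs[uid].n_kmers
        )
        state.covered.add(uid)
        emit(path)

    sources.sort(key=lambda s: (graph.unitigs[s[0]].sequence, s[1]))
    for source in sources:
        path = traverse_from_source(graph, source, state)
        if path is not None:
            emit(path)

    # source-free substructures (cycles): emit leftover unitigs one by one
    for u in sorted(graph.unitigs, key=lambda u: u.sequence):
        if u.id in state.covered:
            continue
        if u.n_kmers > tau:
            state.covered.add(u.id)
            emit(OrientedPath(steps=[(u.id, FWD)], novel_kmer_count=u.n_kmers))
    return records


def merge(contig_sets, k: int, tau: int | None = None) -> list[NRSRecord]:
    """Build the CCDBG over ``contig_sets`` and emit merged candidate NRS."""
    if tau is None:
        tau = default_tau(k)
    graph = build_ccdbg(contig_sets, k)
    return merge_graph(graph, tau)


def write_nrs_fasta(records: list[NRSRecord], path: str) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
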