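"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with different algorithms than the
package: compaction by degree-marking over the uncompacted k-mer graph,
path covers by exhaustive enumeration plus set-cover DP, and bipartite
matching by exhaustive recursion.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def canon(s: str) -> str:
    r = rc(s)
    return s if s <= r else r


# ---------------------------------------------------------------------------
# brute-force bidirected compaction


def brute_kmers(contig_sets, k):
    """Canonical k-mer -> color tuple, scanning plainly."""
    n = len(contig_sets)
    out = {}
    for i, contigs in enumerate(contig_sets):
        for seq in contigs:
            seq = seq.upper()
            for j in range(len(seq) - k + 1):
                km = seq[j : j + k]
                if set(km) - set("ACGT"):
                    continue
                c = canon(km)
                if c not in out:
                    out[c] = [False] * n
                out[c][i] = True
    return {km: tuple(bits) for km, bits in out.items()}


def _oriented(kmer_set, km, ori):
    return km if ori == "+" else rc(km)


def _succs(kmer_set, km, ori):
    """Oriented successors of canonical vertex km in orientation ori."""
    s = _oriented(kmer_set, km, ori)
    out = []
    for b in "ACGT":
        q = s[1:] + b
        cq = canon(q)
        if cq in kmer_set:
            out.append((cq, "+" if q == cq else "-"))
    return out


def brute_compact(contig_sets, k):
    """Maximal non-branching chains of the bidirected canonical k-mer graph.

    Returns (unitig sequences sorted, per-kmer colors of each unitig,
    edge set between unitigs as (seq_u, ou, seq_v, ov) tuples).
    """
    kmer_set = brute_kmers(contig_sets, k)

    def preds(km, ori):
        return [(v, "-" if o == "+" else "+") for v, o in _succs(kmer_set, km, "-" if ori == "+" else "+")]

    # joinable: unique successor with unique predecessor, distinct vertex
    def joinable_next(km, ori):
        ss = _succs(kmer_set, km, ori)
        if len(ss) != 1:
            return None
        w, p = ss[0]
        if w == km:
            return None
        if len(preds(w, p)) != 1:
            return None
        return (w, p)

    def joinable_prev(km, ori):
        ps = preds(km, ori)
        if len(ps) != 1:
            return None
        w, p = ps[0]
        if w == km:
            return None
        ss = _succs(kmer_set, w, p)
        if len(ss) != 1:
            return None
        return (w, p)

    visited = set()
    chains = []
    # chain starts: oriented nodes without a joinable predecessor
    for km in sorted(kmer_set):
        for ori in "+-":
            if km in visited:
                continue
            if joinable_prev(km, ori) is not None:
                continue
            node = (km, ori)
            chain = []
            while node is not None and node[0] not in visited:
                visited.add(node[0])
                chain.append(node)
                node = joinable_next(*node)
            if chain:
                chains.append(chain)
    # remaining vertices form pure cycles: break at the smallest canonical kmer
    for km in sorted(kmer_set):
        if km in visited:
            continue
        node = (km, "+")
        chain = []
        while node[0] not in visited:
            visited.add(node[0])
            chain.append(node)
            nxt = joinable_next(*node)
            if nxt is None:
                break
            node = nxt
        chains.append(chain)

    def spell(chain):
        s = _oriented(kmer_set, *chain[0])
        for node in chain[1:]:
            s += _oriented(kmer_set, *node)[-1]
        return s

    seqs = sorted(canon(spell(c)) for c in chains)
    colors = {}
    for seq in seqs:
        colors[seq] = [kmer_set[canon(seq[j : j + k])] for j in range(len(seq) - k + 1)]

    # unitig-level edges, by (k-1)-overlap of oriented ends
    first_index = {}
    for seq in seqs:
        first_index.setdefault(seq[:k], []).append((seq, "+"))
        first_index.setdefault(rc(seq[-k:]), []).append((seq, "-"))
    edges = set()
    for seq in seqs:
        for ori in "+-":
            s = seq if ori == "+" else rc(seq)
            last = s[-k:]
            for b in "ACGT":
                q = last[1:] + b
                if canon(q) not in kmer_set:
                    continue
                for vseq, vori in first_index.get(q, []):
                    edges.add((seq, ori, vseq, vori))
    return seqs, colors, edges


# ---------------------------------------------------------------------------
# exhaustive path cover


def enumerate_source_sink_paths(graph):
    """All oriented simple source-to-sink paths of a CCDBG, by brute DFS."""
    from nrsmerge.merge import classify_vertices

    _, sources, _ = classify_vertices(graph)
    paths = []

    def walk(path, ids):
        node = path[-1]
        succs = graph.successors(*node)
        if not succs:
            paths.append(list(path))
            return
        for v in succs:
            if v[0] in ids:
                continue
            path.append(v)
            ids.add(v[0])
            walk(path, ids)
            path.pop()
            ids.discard(v[0])

    for s in sources:
        walk([s], {s[0]})
    return paths


def phi(graph, steps):
    """Independent color-weight: 1 - min Jaccard across junctions."""
    if len(steps) < 2:
        return 0.0
    vals = []
    for (a, oa), (b, ob) in zip(steps, steps[1:]):
        x = graph.unitigs[a].last_colors(oa)
        y = graph.unitigs[b].first_colors(ob)
        inter = sum(1 for p, q in zip(x, y) if p and q)
        union = sum(1 for p, q in zip(x, y) if p or q)
        vals.append(inter / union if union else 0.0)
    return 1.0 - min(vals)


def coverable_vertices(graph):
    """Vertices on some source-to-sink path, or singletons."""
    from nrsmerge.merge import classify_vertices

    paths = enumerate_source_sink_paths(graph)
    singles, _, _ = classify_vertices(graph)
    out = set(singles)
    for p in paths:
        out.update(uid for uid, _ in p)
    return out


def min_cover_weight(graph, targets=None):
    """Exhaustive minimum total phi over source-to-sink path covers.

    Singleton vertices cover themselves at zero weight. The cover must
    include every vertex in ``targets`` (default: every coverable vertex);
    vertices on no source-to-sink path are never required. Returns
    (min_weight, number of vertices required) or (None, n) if unreachable.
    """
    paths = enumerate_source_sink_paths(graph)
    from nrsmerge.merge import classify_vertices

    singles, _, _ = classify_vertices(graph)
    items = [(frozenset(uid for uid, _ in p), phi(graph, p)) for p in paths]
    items += [(frozenset([uid]), 0.0) for uid in singles]
    coverable = set().union(*[m for m, _ in items]) if items else set()
    required = coverable if targets is None else (set(targets) & coverable)
    if not required:
        return 0.0, 0
    order = sorted(required)
    full = (1 << len(order)) - 1
    idx = {uid: i for i, uid in enumerate(order)}
    masks = [
        (sum(1 << idx[u] for u in m if u in idx), w) for m, w in items
    ]
    import heapq

    # Dijkstra over covered-subset states (weights are non-negative)
    dist = {0: 0.0}
    heap = [(0.0, 0)]
    while heap:
        d, state = heapq.heappop(heap)
        if d > dist.get(state, float("inf")):
            continue
        if state == full:
            return d, len(order)
        for m, w in masks:
            ns = state | m
            if ns != state and d + w < dist.get(ns, float("inf")):
                dist[ns] = d + w
                heapq.heappush(heap, (d + w, ns))
    return None, len(order)


# ---------------------------------------------------------------------------
# exhaustive bipartite matching


def max_matching_size(edges):
    """Maximum bipartite matching cardinality by exhaustive recursion."""
    ts = sorted({t for t, _ in edges})
    adj = {t: sorted({c for tt, c in edges if tt == t}) for t in ts}

    def rec(i, used):
        if i == len(ts):
            return 0
        best = rec(i + 1, used)  # leave ts[i] unmatched
        for c in adj[ts[i]]:
            if c not in used:
                used.add(c)
                best = max(best, 1 + rec(i + 1, used))
                used.discard(c)
        return best

    return rec(0, set())
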