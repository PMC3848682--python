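"""Graph traversal: complex-node marking and contig construction.

The membership structure is immutable and cannot hold a visited bit
per node, so traversal progress is recorded only for *complex* nodes
(in-degree or out-degree different from 1), kept in a separate hash
table.  Nodes inside simple paths are either all visited or all
unvisited together with their bounding complex nodes, so they never
need to be stored.  Each marking entry costs about 2k+8 bits: the
packed k-mer plus an 8-bit payload with one bit per extension "port",
which records *which* edges of a complex node have been traversed.

Contigs are gap-less sequences obtained by walking simple paths,
ignoring short dead ends (tips shorter than 2k+1 nodes), and resolving
short locally complex regions with a bounded-breadth (<= 20),
bounded-depth (<= 500) BFS that succeeds only when the region
reconverges to a single node; one path through such a region is chosen
deterministically (lexicographically smallest base string).  Contigs
shorter than a minimum length (default 100 bp) are discarded.

Traversal works on *oriented* k-mers (plain packed values); membership
is always tested on the canonical form.  The same engine runs on the
exact structure, on a Bloom-only structure and on a plain hash-set
graph, which is how exactness is tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np

from .kmer_core import (
    BASES,
    canonical,
    decode_kmer,
    left_extensions,
    reverse_complement,
    right_extensions,
)
from .kmer_counting import SolidKmerList


# ---------------------------------------------------------------------------
# cached oriented view of a membership structure


class GraphView:
    """Oriented neighbor queries over any structure exposing
    ``contains_batch`` and ``k``, with memoisation (traversal revisits
    the same nodes many times)."""

    def __init__(self, graph):
        self.graph = graph
        self.k = graph.k
        self._fwd: dict[int, tuple[int, ...]] = {}
        self._back: dict[int, tuple[int, ...]] = {}

    def fwd(self, v: int) -> tuple[int, ...]:
        """Contained right extensions of oriented k-mer v."""
        out = self._fwd.get(v)
        if out is None:
            ext = right_extensions(v, self.k)
            canon = np.fromiter(
                (canonical(e, self.k) for e in ext), dtype=np.uint64, count=4
            )
            hit = self.graph.contains_batch(canon)
            out = tuple(e for e, h in zip(ext, hit) if h)
            self._fwd[v] = out
        return out

    def back(self, v: int) -> tuple[int, ...]:
        """Contained left extensions of oriented k-mer v."""
        out = self._back.get(v)
        if out is None:
            ext = left_extensions(v, self.k)
            canon = np.fromiter(
                (canonical(e, self.k) for e in ext), dtype=np.uint64, count=4
            )
            hit = self.graph.contains_batch(canon)
            out = tuple(e for e, h in zip(ext, hit) if h)
            self._back[v] = out
        return out

    def degrees(self, c: int) -> tuple[int, int]:
        """(forward, backward) degree of a node in its canonical
        orientation."""
        return len(self.fwd(c)), len(self.back(c))

    def is_complex(self, c: int) -> bool:
        f, b = self.degrees(c)
        return f != 1 or b != 1


def node_degrees(graph, x: int) -> tuple[int, int]:
    """(out-degree, in-degree) of canonical node x in its canonical
    orientation."""
    return GraphView(graph).degrees(x)


def is_complex(graph, x: int) -> bool:
    """True iff the node's in-degree or out-degree differs from 1 —
    the only nodes the marking structure ever stores."""
    return GraphView(graph).is_complex(x)


# ---------------------------------------------------------------------------
# marking structure


class MarkingStructure:
    """Visited-marking for complex nodes only.

    Maps a canonical complex k-mer to a small bitmask: bits 0-3 are the
    right-extension ports (base A,C,G,T in canonical orientation), bits
    4-7 the left-extension ports, bit 8 a plain "touched" flag used by
    whole-node marks.  Marking a non-complex node is a contract
    violation and is rejected.
    """

    _TOUCH = 1 << 8
    _FULL = (1 << 9) - 1

    def __init__(self, graph=None, is_complex_fn: Optional[Callable[[int], bool]] = None):
        if is_complex_fn is None:
            if graph is None:
                raise ValueError("need a graph or an is_complex predicate")
            is_complex_fn = GraphView(graph).is_complex
        self._is_complex = is_complex_fn
        self._masks: dict[int, int] = {}
        self.k = graph.k if graph is not None else None

    def _require_complex(self, x: int) -> None:
        if not self._is_complex(x):
            raise ValueError(f"node {x} is not complex; only complex nodes are marked")

    def mark(self, x: int) -> None:
        """Mark a complex node as fully visited (idempotent)."""
        self._require_complex(x)
        self._masks[x] = self._FULL

    def is_marked(self, x: int) -> bool:
        return self._masks.get(x, 0) != 0

    def mark_port(self, x: int, port: int) -> None:
        self._require_complex(x)
        self._masks[x] = self._masks.get(x, 0) | (1 << port)

    def is_port_marked(self, x: int, port: int) -> bool:
        return bool(self._masks.get(x, 0) & (1 << port))

    def touch(self, x: int) -> None:
        self._require_complex(x)
        self._masks[x] = self._masks.get(x, 0) | self._TOUCH

    @property
    def n_complex(self) -> int:
        return len(self._masks)

    def size_bits(self, k: Optional[int] = None) -> int:
        """Nominal memory cost: n_c * (2k + 8) bits."""
        k = k if k is not None else self.k
        return self.n_complex * (2 * k + 8)


def _port(is_canonical_orientation: bool, side_right: bool, base: int) -> int:
    """Port index (0..7) of an edge in the node's canonical frame."""
    if side_right:
        return base if is_canonical_orientation else 4 + (3 - base)
    return 4 + base if is_canonical_orientation else (3 - base)


# ---------------------------------------------------------------------------
# spec'd path operations


def extend_simple_path(graph, start: int, view: Optional[GraphView] = None) -> list[int]:
    """Maximal unambiguous forward extension from oriented k-mer
    ``start``: repeatedly move to the unique forward neighbor while that
    neighbor has exactly one backward neighbor.  Never revisits a node
    (cycles terminate).  Returns the oriented nodes appended after
    ``start`` (possibly empty)."""
    view = view or GraphView(graph)
    k = view.k
    path: list[int] = []
    seen = {canonical(start, k)}
    cur = start
    while True:
        f = view.fwd(cur)
        if len(f) != 1:
            break
        nxt = f[0]
        if len(view.back(nxt)) != 1:
            break
        c = canonical(nxt, k)
        if c in seen:
            break
        path.append(nxt)
        seen.add(c)
        cur = nxt
    return path


def is_short_tip(graph, start: int, view: Optional[GraphView] = None,
                 limit: Optional[int] = None) -> bool:
    """True iff the branch beginning at oriented k-mer ``start`` dead-ends
    within fewer than 2k+1 nodes without branching or merging."""
    view = view or GraphView(graph)
    k = view.k
    limit = limit if limit is not None else 2 * k + 1
    cur = start
    count = 1
    seen = {canonical(start, k)}
    while count < limit:
        f = view.fwd(cur)
        if len(f) == 0:
            return True  # dead end before reaching 2k+1 nodes
        if len(f) > 1:
            return False  # branches: not a simple dead end
        nxt = f[0]
        if len(view.back(nxt)) != 1:
            return False  # merges into other paths
        c = canonical(nxt, k)
        if c in seen:
            return False  # cycle
        seen.add(c)
        cur = nxt
        count += 1
    return False  # alive at 2k+1 nodes: not "shorter than 2k+1"


def skip_tips(graph, at: int, view: Optional[GraphView] = None) -> list[int]:
    """Forward neighbors of oriented k-mer ``at`` with short dead-end
    branches removed (only applied when there is a choice)."""
    view = view or GraphView(graph)
    f = list(view.fwd(at))
    if len(f) <= 1:
        return f
    kept = [x for x in f if not is_short_tip(graph, x, view=view)]
    return kept


def bounded_bfs(
    graph,
    origin: int,
    branches: Optional[Iterable[int]] = None,
    max_depth: int = 500,
    max_breadth: int = 20,
    view: Optional[GraphView] = None,
):
    """Traverse a short locally complex region starting at a branching
    oriented k-mer.

    Explores forward BFS levels from ``branches`` (default: all forward
    neighbors of ``origin``).  Fails — returns None — if a level
    exceeds ``max_breadth`` nodes, if no level collapses to a single
    node within ``max_depth``, or if all paths die out.  On success
    returns ``(path, explored)``: one deterministic path (the
    lexicographically smallest base string) from the first node after
    ``origin`` to the single reconvergence node inclusive, and the set
    of all oriented nodes explored in the region.
    """
    view = view or GraphView(graph)
    k = view.k
    if branches is None:
        branches = view.fwd(origin)
    origin_c = canonical(origin, k)
    # frontier: oriented value -> (bases, path, set of canonical on path)
    frontier: dict[int, tuple[str, list[int], frozenset]] = {}
    for b in branches:
        entry = (BASES[b & 3], [b], frozenset({canonical(b, k)}))
        old = frontier.get(b)
        if old is None or entry[0] < old[0]:
            frontier[b] = entry
    if not frontier:
        return None
    explored = set(frontier)
    depth = 1
    while True:
        if len(frontier) > max_breadth:
            return None
        if len(frontier) == 1:
            (_, path, _), = frontier.values()
            return path, explored
        if depth >= max_depth:
            return None
        nxt_frontier: dict[int, tuple[str, list[int], frozenset]] = {}
        for v in sorted(frontier, key=lambda x: frontier[x][0]):
            bases, path, pset = frontier[v]
            for w in view.fwd(v):
                cw = canonical(w, k)
                if cw in pset or cw == origin_c:
                    continue
                entry = (bases + BASES[w & 3], path + [w], pset | {cw})
                old = nxt_frontier.get(w)
                if old is None or entry[0] < old[0]:
                    nxt_frontier[w] = entry
        if not nxt_frontier:
            return None
        frontier = nxt_frontier
        explored |= set(frontier)
        depth += 1


# ---------------------------------------------------------------------------
# coverage bookkeeping (which seeds still need a contig)


class _PortCoverage:
    """The real thing: per-port marks on complex nodes only."""

    def __init__(self, view: GraphView):
        self.view = view
        self.k = view.k
        self.marking = MarkingStructure(is_complex_fn=view.is_complex)
        self.marking.k = view.k

    def _mark_endpoint(self, oriented: int, side_right: bool, base: int) -> None:
        c = canonical(oriented, self.k)
        if self.view.is_complex(c):
            self.marking.mark_port(c, _port(oriented == c, side_right, base))
            self.marking.touch(c)

    def mark_edge(self, u: int, nxt: int) -> None:
        self._mark_endpoint(u, True, nxt & 3)
        self._mark_endpoint(nxt, False, u >> (2 * (self.k - 1)))

    def _edge_marked_from(self, u: int, nxt: int) -> bool:
        c = canonical(u, self.k)
        return self.marking.is_port_marked(c, _port(u == c, True, nxt & 3))

    # seed-coverage predicates -----------------------------------------

    def start_covered_after(self, b: int, v0: int) -> bool:
        return self._edge_marked_from(b, v0)

    def covered_out_edge(self, o: int, succ: int) -> bool:
        return self._edge_marked_from(o, succ)

    def node_touched(self, o: int) -> bool:
        return self.marking.is_marked(canonical(o, self.k))

    # traversal events --------------------------------------------------

    def on_start(self, start: int) -> None:
        c = canonical(start, self.k)
        if self.view.is_complex(c):
            self.marking.touch(c)

    def mark_start_edge(self, b: int, v0: int) -> None:
        self.mark_edge(b, v0)

    def convergence_stop(self, cur: int, nxt: int) -> None:
        self.mark_edge(cur, nxt)

    def on_region(self, origin: int, branches: Iterable[int],
                  explored: Iterable[int]) -> None:
        # the whole region is resolved: close the origin's ports into it
        # (including unchosen branches) and fully mark its complex nodes
        for b in branches:
            self.mark_edge(origin, b)
        for v in explored:
            c = canonical(v, self.k)
            if self.view.is_complex(c):
                self.marking.mark(c)


class _FullCoverage:
    """Reference bookkeeping that (inefficiently) stores traversal marks
    for *every* node: each traversed edge is recorded under its
    canonical (k+1)-mer regardless of whether its endpoints are
    complex.  The traversal consults coverage exactly where it consults
    the compact structure, so assembly output is identical iff the
    complex-only port masks capture every mark the engine ever reads —
    which is the claim that simple-path nodes never need storing."""

    def __init__(self, view: GraphView):
        self.view = view
        self.k = view.k
        # (node, edge) marks: the edge identified by its canonical
        # (k+1)-mer, recorded on each endpoint separately
        self.marks: set[tuple[int, int]] = set()
        self.touched: set[int] = set()
        self.marking = None

    def _edge_id(self, u: int, base: int) -> int:
        # the (k+1)-mer spelling the edge, strand-collapsed
        return canonical((u << 2) | base, self.k + 1)

    def _touch(self, oriented: int) -> None:
        c = canonical(oriented, self.k)
        if self.view.is_complex(c):
            self.touched.add(c)

    def mark_edge(self, u: int, nxt: int) -> None:
        eid = self._edge_id(u, nxt & 3)
        self.marks.add((canonical(u, self.k), eid))
        self.marks.add((canonical(nxt, self.k), eid))
        self._touch(u)
        self._touch(nxt)

    def start_covered_after(self, b: int, v0: int) -> bool:
        return (canonical(b, self.k), self._edge_id(b, v0 & 3)) in self.marks

    def covered_out_edge(self, o: int, succ: int) -> bool:
        return (canonical(o, self.k), self._edge_id(o, succ & 3)) in self.marks

    def node_touched(self, o: int) -> bool:
        return canonical(o, self.k) in self.touched

    def on_start(self, start: int) -> None:
        self._touch(start)

    def mark_start_edge(self, b: int, v0: int) -> None:
        self.mark_edge(b, v0)

    def convergence_stop(self, cur: int, nxt: int) -> None:
        self.mark_edge(cur, nxt)

    def on_region(self, origin: int, branches: Iterable[int],
                  explored: Iterable[int]) -> None:
        for b in branches:
            self.mark_edge(origin, b)
        for v in explored:
            self._touch(v)
            c = canonical(v, self.k)
            for w in self.view.fwd(v):
                self.marks.add((c, self._edge_id(v, w & 3)))
            for w in self.view.back(v):
                self.marks.add((c, self._edge_id(w, v & 3)))


# ---------------------------------------------------------------------------
# assembly


@dataclass
class AssemblyParams:
    min_contig: int = 100
    max_depth: int = 500
    max_breadth: int = 20
    mark_all_nodes: bool = False  # use the reference full-set bookkeeping


@dataclass
class Contig:
    """A gap-less assembled sequence; stored in its lexicographically
    smaller orientation for deterministic output."""

    sequence: str
    start_node: int

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AssemblyResult:
    contigs: list
    marking: Optional[MarkingStructure]
    stats: dict = field(default_factory=dict)


def _revcomp_str(seq: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return seq.translate(comp)[::-1]


def _emit(view: GraphView, cov, start: int, entry: Optional[int],
          params: AssemblyParams) -> tuple[str, list[int]]:
    """Extend a contig forward from oriented k-mer ``start``; returns the
    base string and the oriented node path."""
    k = view.k
    pieces = [decode_kmer(start, k)]
    nodes = [start]
    cset = {canonical(start, k)}
    if entry is not None:
        cov.mark_start_edge(entry, start)
    cov.on_start(start)
    cur = start
    while True:
        f = list(view.fwd(cur))
        if len(f) > 1:
            f = [x for x in f if not is_short_tip(view.graph, x, view=view)]
        if len(f) == 0:
            break
        if len(f) == 1:
            nxt = f[0]
            if canonical(nxt, k) in cset:
                break  # cycle guard
            if len(view.back(nxt)) != 1:
                cov.convergence_stop(cur, nxt)
                break  # another path converges here; it owns this node
            if len(view.fwd(nxt)) != 1 and cov.node_touched(nxt):
                # junction already reached by an earlier traversal:
                # entering would re-walk territory seen from its side
                cov.convergence_stop(cur, nxt)
                break
            cov.mark_edge(cur, nxt)
            nodes.append(nxt)
            cset.add(canonical(nxt, k))
            pieces.append(BASES[nxt & 3])
            cur = nxt
        else:
            res = bounded_bfs(view.graph, cur, branches=f, view=view,
                              max_depth=params.max_depth,
                              max_breadth=params.max_breadth)
            if res is None:
                break
            path, explored = res
            pcanon = [canonical(p, k) for p in path]
            if any(c in cset for c in pcanon):
                break
            if any(cov.node_touched(p) for p in explored):
                # region overlaps territory an earlier traversal reached
                break
            prev = cur
            for p, c in zip(path, pcanon):
                cov.mark_edge(prev, p)
                nodes.append(p)
                cset.add(c)
                pieces.append(BASES[p & 3])
                prev = p
            cov.on_region(cur, f, explored)
            cur = prev
    return "".join(pieces), nodes


def assemble(graph, solid: SolidKmerList,
             params: Optional[AssemblyParams] = None) -> AssemblyResult:
    """Assemble contigs by enumerating the solid k-mers in ascending
    (on-disk) order and starting a contig at every uncovered simple-path
    start.

    A node is a path start, in a given orientation, when its backward
    degree differs from 1 or when its unique predecessor is a branching
    node; interior simple-path nodes are never seeds, which is what
    makes coverage checks O(1) against the complex-node marking
    structure.  All-simple cycles (no complex node anywhere) have no
    path start and are recovered in a second pass.  Output is
    deterministic given (graph, seed list).
    """
    params = params or AssemblyParams()
    view = GraphView(graph)
    k = view.k
    cov = _FullCoverage(view) if params.mark_all_nodes else _PortCoverage(view)
    contigs: list[Contig] = []
    n_discarded = 0

    def finish(seq: str, start: int) -> None:
        nonlocal n_discarded
        if len(seq) >= params.min_contig:
            out = min(seq, _revcomp_str(seq))
            contigs.append(Contig(sequence=out, start_node=canonical(start, k)))
        else:
            n_discarded += 1

    for v in solid.values:
        v = int(v)
        rc = reverse_complement(v, k)
        for o in (v, rc) if rc != v else (v,):
            back = view.back(o)
            if len(back) == 1:
                b = back[0]
                if len(view.fwd(b)) == 1:
                    continue  # interior of a simple path
                if cov.start_covered_after(b, o):
                    continue
                seq, _ = _emit(view, cov, o, entry=b, params=params)
                finish(seq, o)
            else:
                f = view.fwd(o)
                if len(f) == 1:
                    if cov.covered_out_edge(o, f[0]):
                        continue
                else:
                    if cov.node_touched(o):
                        continue
                seq, _ = _emit(view, cov, o, entry=None, params=params)
                finish(seq, o)

    # second pass: all-simple cycles (no complex node, hence no path
    # start and nothing for the marking structure to record)
    pass2_seen: set[int] = set()
    for v in solid.values:
        c = int(v)
        if c in pass2_seen:
            continue
        fwd, back = view.fwd(c), view.back(c)
        if len(fwd) != 1 or len(back) != 1:
            continue  # complex: handled in pass 1
        if len(view.fwd(back[0])) != 1 or len(view.back(fwd[0])) != 1:
            continue  # path start in one orientation: handled in pass 1
        walk = {c}
        cur = back[0]
        cycle = False
        while True:
            cc = canonical(cur, k)
            if cc in pass2_seen:
                break
            if cc in walk:
                cycle = True
                break
            fb, ff = view.back(cur), view.fwd(cur)
            if len(fb) != 1 or len(ff) != 1:
                break  # bounded by a complex node: covered by pass 1
            walk.add(cc)
            cur = fb[0]
        pass2_seen |= walk
        if cycle:
            pieces = [decode_kmer(c, k)]
            cset = {c}
            cur = c
            while True:
                f = view.fwd(cur)
                if len(f) != 1:
                    break
                nxt = f[0]
                cn = canonical(nxt, k)
                if cn in cset:
                    break
                pieces.append(BASES[nxt & 3])
                cset.add(cn)
                cur = nxt
            pass2_seen |= cset
            finish("".join(pieces), c)

    marking = cov.marking
    stats = {
        "n_contigs": len(contigs),
        "n_discarded_short": n_discarded,
        "total_bases": sum(c.length for c in contigs),
        "n_complex_marked": marking.n_complex if marking is not None else None,
        "marking_bits": marking.size_bits(k) if marking is not None else None,
    }
    return AssemblyResult(contigs=contigs, marking=marking, stats=stats)
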