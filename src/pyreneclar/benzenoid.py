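"""Hexagon-lattice representation of polybenzenoid hydrocarbons (PBHs).

A benzenoid is modelled as a set of fused hexagons.  The authoritative
structure is the *dualist* graph: one node per ring, one edge per fused
ring pair, each edge annotated with its lattice direction (one of six,
at multiples of 60 degrees).  Axial coordinates are derived from the
directions, so helicenes — whose rings may wind over already-occupied
lattice cells — are represented without ambiguity; an integer ``layer``
index distinguishes rings that share a lattice cell.

The carbon (molecular) graph, the perimeter walk with its H/F degree
code, and a canonical code for constitutional-isomer identity are all
derived from the dualist graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

#: Axial-coordinate offsets of the six lattice directions.  Rotation by
#: 60 degrees maps direction d to d+1 (mod 6); the reflection (q, r) ->
#: (r, q) maps direction d to (1 - d) mod 6.
AXIAL_DIRS: tuple[tuple[int, int], ...] = (
    (1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1),
)

_DIR_INDEX = {v: i for i, v in enumerate(AXIAL_DIRS)}

MAX_RINGS = 12


class BenzenoidError(ValueError):
    """Raised for structurally invalid benzenoid input."""


@dataclass(frozen=True, order=True)
class Hexagon:
    """One benzene ring: axial lattice coordinate plus winding layer."""

    q: int
    r: int
    layer: int = 0

    @property
    def coord(self) -> tuple[int, int]:
        return (self.q, self.r)


def _rotate60(q: int, r: int) -> tuple[int, int]:
    return (-r, q + r)


def _reflect(q: int, r: int) -> tuple[int, int]:
    return (r, q)


def lattice_symmetry(hexes: Iterable[Hexagon], rot: int, mirror: bool) -> list[Hexagon]:
    """Apply one of the 12 lattice point symmetries to a hexagon list."""
    out = []
    for h in hexes:
        q, r = h.q, h.r
        if mirror:
            q, r = _reflect(q, r)
        for _ in range(rot % 6):
            q, r = _rotate60(q, r)
        out.append(Hexagon(q, r, h.layer))
    return out


def _transform_dir(d: int, rot: int, mirror: bool) -> int:
    if mirror:
        d = (1 - d) % 6
    return (d + rot) % 6


class Benzenoid:
    """A PBH as fused hexagons with an explicit, direction-annotated dualist.

    Parameters
    ----------
    rings:
        Hexagons, one per benzene ring.  Coordinates live on the axial
        lattice; the ``layer`` index separates rings stacked over the
        same cell by helicenic winding.
    edges:
        Dualist edges as ``(i, j, d)`` triples: ring ``j`` lies in
        lattice direction ``d`` as seen from ring ``i``.
    name:
        Free-text label.
    """

    def __init__(self, rings: Sequence[Hexagon],
                 edges: Iterable[tuple[int, int, int]],
                 name: str = "") -> None:
        rings = tuple(rings)
        if not rings:
            raise BenzenoidError("empty ring list")
        if len(rings) > MAX_RINGS:
            raise BenzenoidError(f"more than {MAX_RINGS} rings")
        if len(set(rings)) != len(rings):
            raise BenzenoidError("duplicate hexagon (same coord and layer)")
        self.rings = rings
        self.name = name
        self._nbr: list[dict[int, int]] = [dict() for _ in rings]
        for i, j, d in edges:
            dq, dr = AXIAL_DIRS[d]
            if (rings[i].q + dq, rings[i].r + dr) != rings[j].coord:
                raise BenzenoidError(
                    f"edge ({i},{j}) direction {d} inconsistent with coordinates")
            if d in self._nbr[i] and self._nbr[i][d] != j:
                raise BenzenoidError("two rings fused on the same edge")
            self._nbr[i][d] = j
            self._nbr[j][(d + 3) % 6] = i
        # connectivity
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in self._nbr[u].values():
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(seen) != len(rings):
            raise BenzenoidError("disconnected: dualist graph is not connected")
        self._carbon: CarbonGraph | None = None
        self._code: str | None = None
        # simple-connectivity (no coronoid hole): Euler characteristic of
        # the abstract hexagon complex must be 1.
        cg = self.carbon_graph()
        if cg.n_atoms - cg.n_bonds + self.n_rings != 1:
            raise BenzenoidError("hole detected: coronoids are not supported")

    # -- basic accessors -------------------------------------------------

    @property
    def n_rings(self) -> int:
        return len(self.rings)

    def neighbors(self, i: int) -> dict[int, int]:
        """Fused neighbours of ring ``i`` as a ``direction -> ring`` map."""
        return dict(self._nbr[i])

    @property
    def dualist(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_rings))
        for i, nb in enumerate(self._nbr):
            for d, j in nb.items():
                if i < j:
                    g.add_edge(i, j, direction=d)
        return g

    def dualist_edges(self) -> list[tuple[int, int, int]]:
        out = []
        for i, nb in enumerate(self._nbr):
            for d, j in nb.items():
                if i < j:
                    out.append((i, j, d))
        return sorted(out)

    # -- derived structure ----------------------------------------------

    def carbon_graph(self) -> "CarbonGraph":
        if self._carbon is None:
            self._carbon = _build_carbon_graph(self)
        return self._carbon

    def perimeter_walk(self) -> "PerimeterWalk":
        return perimeter_walk(self)

    def canonical_code(self) -> str:
        if self._code is None:
            self._code = canonical_code(self)
        return self._code

    # -- conveniences ----------------------------------------------------

    def with_name(self, name: str) -> "Benzenoid":
        b = Benzenoid(self.rings, self.dualist_edges(), name)
        b._carbon = self._carbon
        b._code = self._code
        return b

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        label = self.name or "benzenoid"
        return f"<Benzenoid {label!r} n_rings={self.n_rings}>"


# ---------------------------------------------------------------------------
# construction


def infer_edges(rings: Sequence[Hexagon]) -> list[tuple[int, int, int]]:
    """Dualist edges inferred from coordinates: same layer, adjacent cells."""
    index = {(h.coord, h.layer): i for i, h in enumerate(rings)}
    edges = []
    for i, h in enumerate(rings):
        for d, (dq, dr) in enumerate(AXIAL_DIRS):
            j = index.get(((h.q + dq, h.r + dr), h.layer))
            if j is not None and i < j:
                edges.append((i, j, d))
    return edges


def build_benzenoid(hex_list: Iterable[tuple | Hexagon],
                    name: str = "",
                    edges: Iterable[tuple[int, int, int]] | None = None) -> Benzenoid:
    """Build a :class:`Benzenoid` from hexagon coordinates.

    ``hex_list`` entries are ``Hexagon`` objects or ``(q, r)`` /
    ``(q, r, layer)`` tuples.  Unless ``edges`` is given, fusion is
    inferred: two rings are fused iff they occupy lattice-adjacent cells
    on the same layer.  Explicit edges are needed only for helicenic
    structures in which lattice-adjacent same-layer rings clash without
    being fused.
    """
    rings = []
    for h in hex_list:
        if isinstance(h, Hexagon):
            rings.append(h)
        elif len(h) == 2:
            rings.append(Hexagon(int(h[0]), int(h[1])))
        else:
            rings.append(Hexagon(int(h[0]), int(h[1]), int(h[2])))
    if edges is None:
        edges = infer_edges(rings)
    return Benzenoid(rings, edges, name)


# ---------------------------------------------------------------------------
# carbon graph


@dataclass
class CarbonGraph:
    """Carbon skeleton derived from the hexagon union.

    Atoms are identified across fused rings; each atom knows the set of
    rings containing it, and each bond the set of rings it belongs to.
    Degree-2 atoms carry an implicit hydrogen.
    """

    graph: nx.Graph
    ring_atoms: list[tuple]  # per ring: its 6 atoms in cyclic order

    @property
    def n_atoms(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_bonds(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_hydrogens(self) -> int:
        return sum(1 for _, deg in self.graph.degree if deg == 2)

    def atom_rings(self, atom) -> frozenset:
        return self.graph.nodes[atom]["rings"]


def _build_carbon_graph(b: Benzenoid) -> CarbonGraph:
    # union-find over ring-local vertices (i, k); vertex k of ring i sits
    # between edge directions k-1 and k, so edge d joins vertices d, d+1.
    parent: dict[tuple[int, int], tuple[int, int]] = {}

    def find(x):
        root = x
        while parent.get(root, root) != root:
            root = parent[root]
        while parent.get(x, x) != x:
            parent[x], x = root, parent[x]
        return root

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            if ry < rx:
                rx, ry = ry, rx
            parent[ry] = rx

    for i in range(b.n_rings):
        for d, j in b.neighbors(i).items():
            # shared edge: (i, d)~(j, d+4) and (i, d+1)~(j, d+3)
            union((i, d), (j, (d + 4) % 6))
            union((i, (d + 1) % 6), (j, (d + 3) % 6))

    g = nx.Graph()
    ring_atoms: list[tuple] = []
    for i in range(b.n_rings):
        atoms = tuple(find((i, k)) for k in range(6))
        ring_atoms.append(atoms)
        for k in range(6):
            a = atoms[k]
            if a not in g:
                g.add_node(a, rings=set())
            g.nodes[a]["rings"].add(i)
        for k in range(6):
            a, c = atoms[k], atoms[(k + 1) % 6]
            if g.has_edge(a, c):
                g.edges[a, c]["rings"].add(i)
            else:
                g.add_edge(a, c, rings={i})
    for a in g.nodes:
        g.nodes[a]["rings"] = frozenset(g.nodes[a]["rings"])
        deg = g.degree[a]
        if deg not in (2, 3):
            raise BenzenoidError(f"atom of degree {deg}: invalid fusion")
        if len(g.nodes[a]["rings"]) > 3:
            raise BenzenoidError("atom shared by more than three rings")
    for e in g.edges:
        g.edges[e]["rings"] = frozenset(g.edges[e]["rings"])
    return CarbonGraph(g, ring_atoms)


# ---------------------------------------------------------------------------
# perimeter walk


@dataclass
class PerimeterWalk:
    """Cyclic boundary walk with the H/F degree code.

    ``atoms`` is the perimeter cycle; ``code[k]`` is ``'H'`` if
    ``atoms[k]`` is a degree-2 (CH) vertex and ``'F'`` if it is a
    degree-3 fusion vertex.  The cycle is rotated and oriented so that
    ``code`` is the lexicographically smallest among all rotations of
    both orientations, which makes the code independent of how the
    molecule was drawn.
    """

    atoms: tuple
    code: str
    carbon: CarbonGraph

    def __len__(self) -> int:
        return len(self.atoms)


def _min_rotation(seq: Sequence) -> int:
    """Index of the lexicographically smallest rotation (Booth-style scan)."""
    best = 0
    n = len(seq)
    doubled = list(seq) + list(seq)
    for i in range(1, n):
        if doubled[i:i + n] < doubled[best:best + n]:
            best = i
    return best


def perimeter_walk(b: Benzenoid) -> PerimeterWalk:
    """Boundary walk of a simply connected benzenoid.

    The walk is combinatorial — the boundary of the abstract hexagon
    complex — so helicenic self-overlap on the lattice does not disturb
    it.
    """
    cg = b.carbon_graph()
    g = cg.graph
    boundary = nx.Graph(
        (a, c) for a, c, data in g.edges(data=True) if len(data["rings"]) == 1)
    if boundary.number_of_nodes() == 0:
        raise BenzenoidError("no perimeter found")
    for a in boundary.nodes:
        if boundary.degree[a] != 2:
            raise BenzenoidError("perimeter is not a simple cycle")
    start = min(boundary.nodes)
    cycle = [start]
    prev, cur = None, start
    while True:
        nxt = [x for x in boundary.neighbors(cur) if x != prev]
        step = nxt[0] if prev is None else nxt[0]
        if step == start:
            break
        cycle.append(step)
        prev, cur = cur, step
    if len(cycle) != boundary.number_of_nodes():
        raise BenzenoidError("perimeter is not a single cycle")

    def code_of(atoms):
        return ["H" if g.degree[a] == 2 else "F" for a in atoms]

    candidates = []
    for atoms in (cycle, [cycle[0]] + cycle[1:][::-1]):
        rot = _min_rotation(code_of(atoms))
        rotated = atoms[rot:] + atoms[:rot]
        candidates.append((code_of(rotated), rotated))
    code, atoms = min(candidates)
    return PerimeterWalk(tuple(atoms), "".join(code), cg)


# ---------------------------------------------------------------------------
# canonical code


def _bfs_code(b: Benzenoid, root: int, rot: int, mirror: bool) -> tuple:
    label = {root: 0}
    order = [root]
    seq: list[int] = []
    head = 0
    while head < len(order):
        u = order[head]
        head += 1
        trans = {}
        for d, v in b.neighbors(u).items():
            trans[_transform_dir(d, rot, mirror)] = v
        for dp in range(6):
            v = trans.get(dp)
            if v is None:
                continue
            if v not in label:
                label[v] = len(order)
                order.append(v)
            seq.append(dp)
            seq.append(label[v])
        seq.append(-1)  # ring separator
    return tuple(seq)


def canonical_code(b: Benzenoid) -> str:
    """Constitutional-isomer identifier.

    Two benzenoids receive the same code iff their direction-annotated
    dualist graphs are equal up to lattice rotation, translation and
    reflection (mirror images, and hence helical senses, are
    identified).  Layers never enter the code: stacking is a drawing
    artefact, not a constitutional feature.
    """
    best: tuple | None = None
    for mirror in (False, True):
        for rot in range(6):
            for root in range(b.n_rings):
                code = _bfs_code(b, root, rot, mirror)
                if best is None or code < best:
                    best = code
    return ",".join(map(str, best))


# ---------------------------------------------------------------------------
# layer assignment (used when writing .hexlist files)


def assign_coordinates(edges: Iterable[tuple[int, int, int]], n_rings: int,
                       ) -> list[Hexagon]:
    """Embed a direction-annotated dualist into lattice coordinates.

    Coordinates follow from the edge directions by BFS from ring 0;
    layers are assigned greedily so that no two rings share a
    (cell, layer) slot.
    """
    nbr: list[dict[int, int]] = [dict() for _ in range(n_rings)]
    for i, j, d in edges:
        nbr[i][d] = j
        nbr[j][(d + 3) % 6] = i
    coord: dict[int, tuple[int, int]] = {0: (0, 0)}
    order = [0]
    head = 0
    while head < len(order):
        u = order[head]
        head += 1
        for d in range(6):
            v = nbr[u].get(d)
            if v is None:
                continue
            dq, dr = AXIAL_DIRS[d]
            pos = (coord[u][0] + dq, coord[u][1] + dr)
            if v in coord:
                if coord[v] != pos:
                    raise BenzenoidError("inconsistent edge directions")
            else:
                coord[v] = pos
                order.append(v)
    used: set[tuple[tuple[int, int], int]] = set()
    rings: list[Hexagon | None] = [None] * n_rings
    for i in range(n_rings):
        layer = 0
        while (coord[i], layer) in used:
            layer += 1
        used.add((coord[i], layer))
        rings[i] = Hexagon(coord[i][0], coord[i][1], layer)
    return rings


def from_dualist(edges: Iterable[tuple[int, int, int]], n_rings: int,
                 name: str = "") -> Benzenoid:
    """Build a benzenoid from its direction-annotated dualist alone."""
    edges = list(edges)
    if n_rings == 1 and not edges:
        return Benzenoid([Hexagon(0, 0)], [], name)
    return Benzenoid(assign_coordinates(edges, n_rings), edges, name)
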