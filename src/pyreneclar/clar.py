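"""Kekulé and Clar structure enumeration for benzenoids.

A Kekulé structure is a perfect matching of the carbon graph.  A Clar
structure places the maximum possible number of aromatic sextets on
pairwise vertex-disjoint rings such that the remaining atoms still
admit a perfect matching.  Sextets that sit on the same ring in every
Clar structure are *fixed*; the remainder of the Clar number is carried
by *migrating* sextets (the arrow notation of resonance-structure
drawings).  The molecule-level summary statistic is

    delta_clar = n_fix - n_mig,

which rises along the annelation-pattern ordering of the electronic
properties (see the ``trends`` module).

Two counting conventions are provided.  Plain enumeration admits a
sextet on any ring.  The *core-sextet convention* used for the
pattern-level analysis keeps sextets off the peri-fused b rings of the
pyrene core: the core's own Clar structure places its two sextets on
the a rings, and annelation makes those sextets migrate outward, so
the pattern table is defined with the b rings as pure double-bond
scaffolding.  Only under this convention is the fixed/migrating split
identical across all single-annelation isomers of a pattern.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

import networkx as nx

from .benzenoid import Benzenoid, CarbonGraph


class NonKekuleanError(ValueError):
    """Raised when a molecule has no Kekulé structure."""


@dataclass(frozen=True)
class KekuleStructure:
    """One resonance structure: the set of formal double bonds."""

    double_bonds: frozenset


@dataclass(frozen=True)
class ClarStructure:
    """A maximum sextet placement plus one residual matching."""

    sextet_rings: frozenset
    residual_matching: frozenset


@dataclass(frozen=True)
class ClarCounts:
    n_tot: int
    n_fix: int
    n_mig: int

    @property
    def delta_clar(self) -> int:
        return self.n_fix - self.n_mig


def enumerate_kekule(cg: CarbonGraph) -> list[KekuleStructure]:
    """All perfect matchings of the carbon graph, by backtracking.

    Returns an empty list for non-Kekuléan graphs (odd atom count
    included).
    """
    g = cg.graph
    atoms = sorted(g.nodes)
    if len(atoms) % 2:
        return []
    pos = {a: i for i, a in enumerate(atoms)}
    adj = [sorted(pos[b] for b in g.neighbors(a)) for a in atoms]
    n = len(atoms)
    covered = [False] * n
    out: list[KekuleStructure] = []
    chosen: list[tuple] = []

    def rec(start: int) -> None:
        i = start
        while i < n and covered[i]:
            i += 1
        if i == n:
            out.append(KekuleStructure(frozenset(chosen)))
            return
        covered[i] = True
        for j in adj[i]:
            if not covered[j]:
                covered[j] = True
                chosen.append((atoms[i], atoms[j]))
                rec(i + 1)
                chosen.pop()
                covered[j] = False
        covered[i] = False

    rec(0)
    return out


def _has_perfect_matching(g: nx.Graph) -> bool:
    """Perfect-matching existence via Hopcroft–Karp (benzenoids are bipartite)."""
    n = g.number_of_nodes()
    if n == 0:
        return True
    if n % 2:
        return False
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) % 2:
            return False
        try:
            colors = nx.bipartite.color(sub)
        except nx.NetworkXError:  # pragma: no cover - benzenoids are bipartite
            return False
        top = {u for u, c in colors.items() if c == 0}
        match = nx.bipartite.hopcroft_karp_matching(sub, top)
        if len(match) != len(comp):
            return False
    return True


def _one_matching(g: nx.Graph) -> frozenset:
    m = nx.max_weight_matching(g, maxcardinality=True)
    return frozenset(tuple(sorted(e)) for e in m)


def _sextet_candidates(b: Benzenoid) -> list[frozenset]:
    cg = b.carbon_graph()
    return [frozenset(set(atoms)) for atoms in cg.ring_atoms]


def enumerate_clar(b: Benzenoid,
                   eligible: Iterable[int] | None = None) -> list[ClarStructure]:
    """All Clar structures: every maximum-cardinality sextet placement.

    Distinct sextet-ring sets only; the residual matchings are not
    multiplied out (one witness matching is attached to each).

    ``eligible`` restricts which rings may host a sextet (default: all).
    The pyrene-pattern analysis uses this to keep sextets off the
    peri-fused core b rings (see :func:`core_clar_counts`).
    """
    cg = b.carbon_graph()
    if not _has_perfect_matching(cg.graph):
        raise NonKekuleanError(
            f"{b.name or 'molecule'} has no Kekulé structure")
    ring_sets = _sextet_candidates(b)
    pool = sorted(eligible) if eligible is not None else list(range(b.n_rings))
    n = len(pool)
    best_k = -1
    found: list[ClarStructure] = []
    for k in range(n, -1, -1):
        if best_k >= 0 and k < best_k:
            break
        for combo in itertools.combinations(pool, k):
            # sextet rings must be pairwise vertex-disjoint
            atoms: set = set()
            ok = True
            for i in combo:
                if atoms & ring_sets[i]:
                    ok = False
                    break
                atoms |= ring_sets[i]
            if not ok:
                continue
            residual = cg.graph.subgraph(set(cg.graph.nodes) - atoms)
            if _has_perfect_matching(residual):
                if best_k < 0:
                    best_k = k
                found.append(ClarStructure(frozenset(combo),
                                           _one_matching(residual)))
        if best_k >= 0:
            break
    return found


def clar_number(b: Benzenoid, eligible: Iterable[int] | None = None) -> int:
    """Maximum number of disjoint aromatic sextets (the Clar number)."""
    structures = enumerate_clar(b, eligible)
    return len(next(iter(structures)).sextet_rings) if structures else 0


def clar_counts(b: Benzenoid, eligible: Iterable[int] | None = None) -> ClarCounts:
    """Total, fixed and migrating sextet counts.

    A ring is *fixed* when it carries a sextet in every Clar structure;
    the migrating count is the Clar number minus the fixed count.
    """
    structures = enumerate_clar(b, eligible)
    n_tot = len(next(iter(structures)).sextet_rings)
    fixed = frozenset.intersection(*(s.sextet_rings for s in structures))
    n_fix = len(fixed)
    return ClarCounts(n_tot=n_tot, n_fix=n_fix, n_mig=n_tot - n_fix)


def core_clar_counts(b: Benzenoid) -> ClarCounts:
    """Clar counts of a pyrene-cored PBH under the core-sextet convention.

    The pyrene core contributes its sextets through the *a* rings, from
    which they migrate into attached rings; the peri-fused *b* rings
    never host a sextet.  Under this convention the fixed/migrating
    split is identical for every single-annelation isomer of a pattern,
    which is what makes the pattern-level table well defined.
    """
    from .annelation import annelation_report  # local: avoids module cycle

    report = annelation_report(b)
    eligible = set(range(b.n_rings)) - set(report.b_rings)
    return clar_counts(b, eligible)


@lru_cache(maxsize=None)
def pattern_delta_clar(pattern: str) -> ClarCounts:
    """Pattern-level Clar counts from the single-annelation isomers.

    Computes :func:`core_clar_counts` for every single-annelation
    isomer of ``pattern`` (the strain sample set) and checks that they
    all agree before returning the shared value.
    """
    from .annelation import PATTERNS
    from .synthetic_data import sample_strain_set  # local: avoids module cycle

    if pattern not in PATTERNS:
        raise ValueError(f"unknown annelation pattern {pattern!r}")
    values = {name: core_clar_counts(b)
              for name, b in sample_strain_set().items()
              if name.startswith(f"{pattern}_")}
    distinct = set(values.values())
    if len(distinct) != 1:
        raise AssertionError(
            f"Clar counts differ across {pattern} isomers: {values}")
    return distinct.pop()
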