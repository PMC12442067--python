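"""Pyrene-core detection, a/b ring labelling, pattern classification, n_LL.

Pyrene contains two ring types: the *a* rings (each fused to two other
core rings) and the *b* rings (each fused to three).  Fusing extra
benzenes onto the core's free edges gives eight possible annelation
patterns — a, b, aa, bb, ab, aab, abb, aabb — named by which core rings
carry at least one directly attached ring.

The longest linear stretch n_LL is the maximum number of rings on a
dualist path whose consecutive steps keep a single lattice direction
(an acene-like run); it is the dominant structural feature for the
frontier-orbital properties of cata-condensed PBHs and competes with
the core pattern here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .benzenoid import Benzenoid

PATTERNS = ("a", "b", "aa", "bb", "ab", "aab", "abb", "aabb")


class AnnelationError(ValueError):
    """Raised when pyrene-core detection or classification fails."""


@dataclass(frozen=True)
class AnnelationReport:
    """Core location, ring labels, pattern and longest linear stretch."""

    core: tuple[int, int, int, int]      # ring indices: (a1, a2, b1, b2)
    labels: dict                          # ring index -> 'a'|'b'|'attached'|'remote'
    pattern: str
    n_ll: int

    @property
    def a_rings(self) -> tuple[int, int]:
        return self.core[:2]

    @property
    def b_rings(self) -> tuple[int, int]:
        return self.core[2:]


def find_pyrene_core(b: Benzenoid) -> list[tuple[int, int, int, int]]:
    """All 4-ring subsets forming a pyrene unit, as (a1, a2, b1, b2).

    The induced dualist subgraph must be the pyrene rhombus: two
    mutually fused rings (the b rings) each fused to both of the other
    two (the a rings, themselves not fused); additionally the carbon
    union must contain the two atoms shared by three rings.  An empty
    list means "no pyrene core".
    """
    cg = b.carbon_graph()
    out = []
    for b1, b2, d in b.dualist_edges():
        common = sorted(set(b.neighbors(b1).values())
                        & set(b.neighbors(b2).values()))
        for a1, a2 in itertools.combinations(common, 2):
            if a2 in b.neighbors(a1).values():
                continue  # a rings must not be fused to each other
            rings = {a1, a2, b1, b2}
            peri = [a for a in cg.graph.nodes
                    if cg.atom_rings(a) >= {b1, b2} and len(cg.atom_rings(a) & rings) == 3]
            if len(peri) == 2:
                out.append((a1, a2, b1, b2))
    return out


def label_core_rings(b: Benzenoid, core: tuple[int, int, int, int]) -> dict:
    """Label every ring relative to a pyrene core.

    Core rings are 'a' or 'b' by their degree in the core's induced
    dualist subgraph; non-core rings fused to a core ring are
    'attached'; everything else is 'remote'.
    """
    a1, a2, b1, b2 = core
    core_set = {a1, a2, b1, b2}
    for ring in core:
        deg = len(set(b.neighbors(ring).values()) & core_set)
        expected = 3 if ring in (b1, b2) else 2
        if deg != expected:
            raise AnnelationError("malformed pyrene core")
    labels = {}
    for i in range(b.n_rings):
        if i in (a1, a2):
            labels[i] = "a"
        elif i in (b1, b2):
            labels[i] = "b"
        elif set(b.neighbors(i).values()) & core_set:
            labels[i] = "attached"
        else:
            labels[i] = "remote"
    return labels


def classify_pattern(b: Benzenoid, core: tuple[int, int, int, int] | None = None) -> str:
    """One of the eight annelation patterns.

    The pattern is the multiset of core-ring letters that carry at
    least one directly attached ring (a core ring with two attached
    rings still contributes its letter once), written a-before-b.
    """
    if core is None:
        cores = find_pyrene_core(b)
        if not cores:
            raise AnnelationError("no pyrene core found")
        if len(cores) > 1:
            raise AnnelationError(f"{len(cores)} pyrene cores found")
        core = cores[0]
    labels = label_core_rings(b, core)
    letters = []
    for ring in core:
        attached = [j for j in b.neighbors(ring).values()
                    if labels[j] == "attached"]
        if attached:
            letters.append(labels[ring])
    code = "".join(sorted(letters))
    if code not in PATTERNS:
        raise AnnelationError(f"unannelated or unclassifiable core ({code!r})")
    return code


def longest_linear_stretch(b: Benzenoid) -> int:
    """Rings in the longest acene-like (straight) dualist path.

    A stretch continues while consecutive dualist steps keep the same
    lattice direction; it may run through the pyrene core.  Always >= 1.
    """
    best = 1
    for i in range(b.n_rings):
        for d in range(6):
            back = b.neighbors(i).get((d + 3) % 6)
            if back is not None and b.neighbors(back).get(d) == i:
                continue  # not a stretch start in direction d
            length = 1
            cur = i
            while True:
                nxt = b.neighbors(cur).get(d)
                if nxt is None:
                    break
                length += 1
                cur = nxt
            best = max(best, length)
    return best


def annelation_report(b: Benzenoid) -> AnnelationReport:
    """Full annelation analysis of a single-pyrene-core benzenoid."""
    cores = find_pyrene_core(b)
    if not cores:
        raise AnnelationError("no pyrene core found")
    if len(cores) > 1:
        raise AnnelationError(f"{len(cores)} pyrene cores found")
    core = cores[0]
    labels = label_core_rings(b, core)
    return AnnelationReport(core=core, labels=labels,
                            pattern=classify_pattern(b, core),
                            n_ll=longest_linear_stretch(b))
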