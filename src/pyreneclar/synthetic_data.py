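"""Generated inputs: chemical-space enumeration and simulated properties.

Everything the analysis pipeline consumes can be produced here without
external data:

* exhaustive enumeration of the pyrene-based chemical space — a single
  pyrene core with purely cata-condensed attachments, 5–10 rings,
  helicenic winding allowed, mirror images identified;
* the 13-molecule strain sample set (at most one annelated benzene on
  each of the four core rings);
* property tables simulated as linear functions of the structural
  descriptors (delta_clar, n_LL, n_strain) plus Gaussian noise, which
  carry the statistical structure the trend analysis assumes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annelation import annelation_report, find_pyrene_core
from .benzenoid import AXIAL_DIRS, Benzenoid, Hexagon
from .clar import pattern_delta_clar
from .molecules import pyrene
from .strain import DEFAULT_WEIGHTS, StrainWeights, molecule_motifs, n_strain


@dataclass(frozen=True)
class EnumerationSpec:
    """The pyrene-based chemical space: core + cata-condensed attachments."""

    min_rings: int = 5
    max_rings: int = 10
    allow_helicenic: bool = True

    def __post_init__(self) -> None:
        if not 5 <= self.min_rings <= self.max_rings <= 10:
            raise ValueError("ring range must satisfy 5 <= min <= max <= 10")


@dataclass(frozen=True)
class SimulationSpec:
    """Linear-model coefficients for simulated molecular properties.

    ``coefficients`` maps a property name to
    ``(intercept, c_delta_clar, c_n_ll, c_n_strain)``; ``noise_sd``
    gives the Gaussian noise level per property (0 where omitted).
    """

    coefficients: dict = field(default_factory=dict)
    noise_sd: dict = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# growth


def free_edges(b: Benzenoid) -> list[tuple[int, int]]:
    """(ring, direction) slots where a new benzene can be cata-fused.

    An edge is free when no ring is already fused there and both of its
    atoms belong to exactly one ring — attaching elsewhere would create
    an atom in three rings (a second peri-fusion).
    """
    cg = b.carbon_graph()
    out = []
    for i in range(b.n_rings):
        nbr = b.neighbors(i)
        atoms = cg.ring_atoms[i]
        for d in range(6):
            if d in nbr:
                continue
            a1, a2 = atoms[d], atoms[(d + 1) % 6]
            if len(cg.atom_rings(a1)) == 1 and len(cg.atom_rings(a2)) == 1:
                out.append((i, d))
    return out


def attach(b: Benzenoid, ring: int, direction: int, name: str = "") -> Benzenoid:
    """Fuse a new benzene onto a free edge of ring ``ring``.

    The new ring is fused to its parent only; if the target cell is
    already occupied the new ring winds onto the next layer (helicenic
    overlap).
    """
    h = b.rings[ring]
    dq, dr = AXIAL_DIRS[direction]
    cell = (h.q + dq, h.r + dr)
    taken = {(r.coord, r.layer) for r in b.rings}
    layer = 0
    while (cell, layer) in taken:
        layer += 1
    rings = list(b.rings) + [Hexagon(cell[0], cell[1], layer)]
    edges = b.dualist_edges() + [(ring, len(rings) - 1, direction)]
    return Benzenoid(rings, edges, name)


# ---------------------------------------------------------------------------
# enumeration


def _lattice_clashes(b: Benzenoid) -> int:
    """Unfused ring pairs on lattice-adjacent cells (layers ignored)."""
    fused = {frozenset((i, j)) for i, j, _ in b.dualist_edges()}
    n = 0
    for i in range(b.n_rings):
        for j in range(i + 1, b.n_rings):
            dq = b.rings[j].q - b.rings[i].q
            dr = b.rings[j].r - b.rings[i].r
            if (dq, dr) in AXIAL_DIRS and frozenset((i, j)) not in fused:
                n += 1
    return n


def _has_overlap(b: Benzenoid) -> bool:
    return len({r.coord for r in b.rings}) < b.n_rings


def is_feasible(b: Benzenoid) -> bool:
    """Steric feasibility of a lattice-drawn PBH.

    Three regimes:

    * a plain planar polyhex (no overlap, no unfused lattice
      adjacency) is always feasible;
    * a single unfused lattice adjacency is the [6]helicene motif —
      the winding path twists out of plane and the two clashing rings
      stack; feasible;
    * a ring wound over an occupied cell ([7]helicene and beyond) has
      already climbed to the next layer; feasible regardless of how
      many lattice adjacencies its drawing shows, since the winding
      separates them vertically.

    What remains — two or more unfused adjacencies without any actual
    winding overlap — pins at least one ring between neighbours it
    cannot twist away from, and no such molecule is realizable.
    """
    if _has_overlap(b):
        return True
    return _lattice_clashes(b) <= 1


def is_planar(b: Benzenoid) -> bool:
    """True for plain planar polyhexes (no winding, no clash)."""
    return not _has_overlap(b) and _lattice_clashes(b) == 0


def enumerate_space(spec: EnumerationSpec = EnumerationSpec()) -> list[Benzenoid]:
    """All constitutional isomers of the pyrene-based space.

    Breadth-first hexagon attachment starting from pyrene: every child
    adds one ring on a free edge, so attachments stay cata-condensed by
    construction; duplicates are removed at every size via the
    canonical code (which identifies mirror images and ignores
    layers).  The growth itself is unrestricted — a sterically pinched
    intermediate can still be the only drawing of a feasible larger
    helicene — and the feasibility filter (or planarity filter, when
    ``allow_helicenic`` is off) is applied to the collected output.
    """
    frontier: dict[str, Benzenoid] = {}
    seed = pyrene()
    frontier[seed.canonical_code()] = seed
    collected: list[Benzenoid] = []
    keep = is_feasible if spec.allow_helicenic else is_planar
    for size in range(5, spec.max_rings + 1):
        children: dict[str, Benzenoid] = {}
        for parent in frontier.values():
            for ring, direction in free_edges(parent):
                child = attach(parent, ring, direction)
                code = child.canonical_code()
                if code not in children:
                    children[code] = child
        frontier = children
        if size >= spec.min_rings:
            collected.extend(b for b in frontier.values() if keep(b))
    for k, b in enumerate(collected):
        b.name = b.name or f"pbh{b.n_rings}-{k}"
    return collected


def sample_strain_set(weights: StrainWeights = DEFAULT_WEIGHTS,
                      ) -> dict[str, Benzenoid]:
    """The 13-molecule strain sample set, deterministically named.

    Every structure with at most one annelated benzene on each of the
    four pyrene core rings: each *a* ring offers two (mirror-related)
    free edges and each *b* ring one (the K-region), giving 13 unique
    constitutional isomers.  Names are ``<pattern>_sN`` with N assigned
    within a pattern by decreasing n_strain (ties broken by canonical
    code), which pins e.g. the two-cove aab isomer to ``aab_s1``.
    """
    core = pyrene()
    core_rings = find_pyrene_core(core)[0]
    slots: list[list[tuple[int, int] | None]] = []
    for ring in core_rings:
        opts: list[tuple[int, int] | None] = [None]
        opts.extend(slot for slot in free_edges(core) if slot[0] == ring)
        slots.append(opts)
    unique: dict[str, Benzenoid] = {}
    for combo in itertools.product(*slots):
        picks = [slot for slot in combo if slot is not None]
        if not picks:
            continue  # bare pyrene is the reference, not a sample molecule
        b = core
        for ring, direction in picks:
            b = attach(b, ring, direction)
        unique.setdefault(b.canonical_code(), b)
    keyed = []
    for code, b in unique.items():
        rep = annelation_report(b)
        score = n_strain(molecule_motifs(b, rep), weights)
        keyed.append((rep.pattern, -score, code, b))
    named: dict[str, Benzenoid] = {}
    for pattern in sorted({k[0] for k in keyed}):
        members = sorted(k for k in keyed if k[0] == pattern)
        for idx, (_, _, _, b) in enumerate(members, start=1):
            name = f"{pattern}_s{idx}"
            named[name] = b.with_name(name)
    return named


# ---------------------------------------------------------------------------
# simulated property tables


#: Default simulation: property trends with the qualitative structure of
#: the DFT data — gap/LUMO/aIP/aEA rise and HOMO falls with delta_clar,
#: n_LL pulls the gap down, and the relative-energy plane uses the
#: pattern-level strain/Clar coefficients (kcal/mol).
DEFAULT_SIMULATION = SimulationSpec(
    coefficients={
        "HOMO_eV": (-5.8, -0.05, 0.05, 0.0),
        "LUMO_eV": (-1.9, 0.10, -0.10, 0.0),
        "gap_eV": (3.9, 0.15, -0.15, 0.0),
        "aIP_eV": (6.5, 0.08, -0.05, 0.0),
        "aEA_eV": (1.1, 0.06, -0.04, 0.0),
        "Erel_kcalmol": (13.4, -0.3, 0.0, 0.8),
    },
    noise_sd={},
    seed=0,
)


def simulate_properties(structures: dict[str, Benzenoid] | list[Benzenoid],
                        spec: SimulationSpec = DEFAULT_SIMULATION,
                        weights: StrainWeights = DEFAULT_WEIGHTS,
                        ) -> pd.DataFrame:
    """Simulated per-molecule property table.

    Each property is a linear combination of the molecule's pattern
    delta_clar, n_LL and n_strain plus Gaussian noise.  The total
    energy column is constructed (in kcal/mol) so that, within each
    ring-count group, the relative energy equals the simulated
    ``Erel_kcalmol`` column up to the group-minimum shift that the
    relative-energy definition removes.
    """
    if isinstance(structures, dict):
        items = list(structures.items())
    else:
        items = [(b.name or f"mol{i}", b) for i, b in enumerate(structures)]
    rng = np.random.default_rng(spec.seed)
    rows = []
    for name, b in items:
        rep = annelation_report(b)
        dclar = pattern_delta_clar(rep.pattern).delta_clar
        score = n_strain(molecule_motifs(b, rep), weights)
        feats = (1.0, float(dclar), float(rep.n_ll), score)
        row = {"id": name, "n_rings": b.n_rings, "pattern": rep.pattern,
               "delta_clar": dclar, "n_LL": rep.n_ll,
               "n_strain": score}
        for prop, coefs in spec.coefficients.items():
            value = float(np.dot(coefs, feats))
            sd = spec.noise_sd.get(prop, 0.0)
            if sd:
                value += rng.normal(0.0, sd)
            row[prop] = value
        rows.append(row)
    df = pd.DataFrame(rows)
    if "Erel_kcalmol" in df.columns:
        df["Etot"] = df["Erel_kcalmol"]
        df["Etot_unit"] = "kcal/mol"
    df.attrs["seed"] = spec.seed
    return df
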