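"""Constructors for small reference PBHs used throughout the package."""

from __future__ import annotations

from importlib import resources

from .benzenoid import Benzenoid, build_benzenoid


def load_fixtures() -> dict[str, Benzenoid]:
    """The shipped .hexlist fixture library, keyed by molecule name."""
    from . import hexlist

    text = (resources.files("pyreneclar") / "data" /
            "fixtures.hexlist").read_text()
    return {b.name: b for b in hexlist.loads(text)}

PYRENE_CELLS = [(0, 0), (1, 0), (0, 1), (1, -1)]


def benzene() -> Benzenoid:
    return build_benzenoid([(0, 0)], "benzene")


def acene(k: int) -> Benzenoid:
    """Linear acene of k rings (naphthalene, anthracene, ...)."""
    names = {1: "benzene", 2: "naphthalene", 3: "anthracene",
             4: "tetracene", 5: "pentacene", 6: "hexacene"}
    return build_benzenoid([(i, 0) for i in range(k)], names.get(k, f"acene-{k}"))


def naphthalene() -> Benzenoid:
    return acene(2)


def anthracene() -> Benzenoid:
    return acene(3)


def phenanthrene() -> Benzenoid:
    return build_benzenoid([(0, 0), (1, 0), (1, 1)], "phenanthrene")


def triphenylene() -> Benzenoid:
    return build_benzenoid([(0, 0), (1, 0), (-1, 1), (0, -1)], "triphenylene")


def benzo_c_phenanthrene() -> Benzenoid:
    """[4]helicene: four angularly fused rings with the classic cove."""
    return build_benzenoid([(1, 0), (0, 1), (-1, 1), (-1, 0)],
                           "benzo[c]phenanthrene")


def pyrene() -> Benzenoid:
    """Pyrene: the smallest Kekulean peri-condensed PBH (C16H10)."""
    return build_benzenoid(PYRENE_CELLS, "pyrene")


def hexahelicene() -> Benzenoid:
    """[6]helicene: terminal rings are lattice-adjacent but not fused."""
    cells = [(1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1)]
    edges = [(i, i + 1, None) for i in range(5)]
    # directions derived from coordinates
    from .benzenoid import AXIAL_DIRS
    fixed = []
    for i, j, _ in edges:
        dq = cells[j][0] - cells[i][0]
        dr = cells[j][1] - cells[i][1]
        fixed.append((i, j, AXIAL_DIRS.index((dq, dr))))
    return build_benzenoid(cells, "hexahelicene", edges=fixed)
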