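"""Plain-text .hexlist format: one molecule per block.

A block is a ``name`` line followed by one ``q r layer`` integer triple
per ring; blocks are separated by blank lines.  Fusion is normally
inferred (lattice-adjacent rings on the same layer are fused); for
helicenic structures whose fusion pattern cannot be recovered from
coordinates alone — e.g. [6]helicene, whose terminal rings are
lattice-adjacent but *not* fused — the block carries explicit
``edge i j d`` lines instead, and the parser uses those verbatim.
Parsing and writing round-trip exactly.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, TextIO

from .benzenoid import Benzenoid, build_benzenoid, infer_edges


def dump(mols: Iterable[Benzenoid], fh: TextIO) -> None:
    first = True
    for b in mols:
        if not first:
            fh.write("\n")
        first = False
        fh.write(f"{b.name or 'unnamed'}\n")
        for h in b.rings:
            fh.write(f"{h.q} {h.r} {h.layer}\n")
        actual = set(b.dualist_edges())
        inferred = {(i, j, d) for i, j, d in infer_edges(b.rings)}
        if inferred != actual:
            for i, j, d in sorted(actual):
                fh.write(f"edge {i} {j} {d}\n")


def dumps(mols: Iterable[Benzenoid]) -> str:
    buf = io.StringIO()
    dump(mols, buf)
    return buf.getvalue()


def load(fh: TextIO) -> list[Benzenoid]:
    mols = []
    block: list[str] = []
    for raw in fh:
        line = raw.strip()
        if not line:
            if block:
                mols.append(_parse_block(block))
                block = []
            continue
        block.append(line)
    if block:
        mols.append(_parse_block(block))
    return mols


def loads(text: str) -> list[Benzenoid]:
    return load(io.StringIO(text))


def _parse_block(lines: list[str]) -> Benzenoid:
    name = lines[0]
    hexes: list[tuple[int, int, int]] = []
    edges: list[tuple[int, int, int]] = []
    for line in lines[1:]:
        parts = line.split()
        if parts[0] == "edge":
            if len(parts) != 4:
                raise ValueError(f"malformed edge line: {line!r}")
            edges.append((int(parts[1]), int(parts[2]), int(parts[3])))
        else:
            if len(parts) != 3:
                raise ValueError(f"malformed ring line: {line!r}")
            hexes.append((int(parts[0]), int(parts[1]), int(parts[2])))
    return build_benzenoid(hexes, name, edges=edges or None)


def read(path: str | Path) -> list[Benzenoid]:
    with open(path, encoding="utf-8") as fh:
        return load(fh)


def write(path: str | Path, mols: Iterable[Benzenoid]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        dump(mols, fh)
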