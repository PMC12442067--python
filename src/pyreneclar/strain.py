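"""Perimeter strain motifs and the weighted strain score n_strain.

Concave stretches of the perimeter force hydrogens on the flanking
rings towards each other, bending the molecule out of plane.  The
operational taxonomy is run-length based: a maximal run of consecutive
fusion (degree-3, 'F') perimeter vertices flanked by CH ('H') vertices
is a fissure (length 1), bay (2), cove (3) or fjord (4); runs of five
or more arise only in strongly helicenic systems and are tallied as
helical runs.

Bays are attributed to the annelation that created them: a bay touching
a ring attached to an *a* core ring is an a-bay, one touching a ring
attached to a *b* core ring is a b-bay (a b-annelation creates two bays,
an a-annelation only one).  Reference frozen-core strain energies give
the relative weights of the motifs; with the published weighting the
score is

    n_strain = n_bays_a + 0.7 * n_bays_b + 4.3 * n_coves.

Fissures are unstrained and fjords/helical runs fall outside the
weighting model: they are reported but never scored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from .annelation import AnnelationReport
from .benzenoid import Benzenoid, PerimeterWalk

logger = logging.getLogger(__name__)

MOTIF_NAMES = {1: "fissure", 2: "bay", 3: "cove", 4: "fjord"}


class StrainError(ValueError):
    """Raised for ambiguous bay attribution or missing references."""


@dataclass(frozen=True)
class MotifRun:
    """One maximal F-run on the perimeter: its atoms and classification."""

    atoms: tuple
    kind: str  # fissure | bay | cove | fjord | helical

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class MotifCounts:
    n_fissures: int = 0
    n_bays: int = 0
    n_coves: int = 0
    n_fjords: int = 0
    n_helical: int = 0
    n_bays_a: int | None = None  # filled by attribute_bays
    n_bays_b: int | None = None
    runs: tuple = field(default=(), compare=False)

    def signature(self) -> tuple[int, int, int]:
        """(n_coves, n_bays_a, n_bays_b) — the strain-model inputs."""
        if self.n_bays_a is None or self.n_bays_b is None:
            raise StrainError("bays not yet attributed to a/b annelation")
        return (self.n_coves, self.n_bays_a, self.n_bays_b)


@dataclass(frozen=True)
class StrainWeights:
    """Relative motif weights, normalised to the a-bay."""

    w_bay_a: float = 1.0
    w_bay_b: float = 0.7
    w_cove: float = 4.3


#: Published weighting 1 : 0.7 : 4.3 for a-bay : b-bay : cove.
DEFAULT_WEIGHTS = StrainWeights()


@dataclass(frozen=True)
class StrainReference:
    """A reference molecule with its frozen-core strain energy (kcal/mol)."""

    molecule_id: str
    e_strain: float
    motifs: MotifCounts


#: The two reference strain energies reported for the single-motif bay
#: systems: one a-bay costs 2.6 kcal/mol, two b-bays cost 3.5 kcal/mol.
REFERENCE_E_STRAIN = {"a_s1": 2.6, "b_s1": 3.5}


def detect_motifs(walk: PerimeterWalk) -> MotifCounts:
    """Classify the maximal fusion-vertex runs of a perimeter walk."""
    code = walk.code
    n = len(code)
    if "H" not in code:
        raise StrainError("degenerate perimeter with no CH vertex")
    runs: list[MotifRun] = []
    seen: set[int] = set()
    for start in range(n):
        if code[start] != "F" or start in seen or code[(start - 1) % n] == "F":
            continue
        atoms = []
        k = start
        while code[k % n] == "F":
            atoms.append(walk.atoms[k % n])
            seen.add(k % n)
            k += 1
        runs.append(MotifRun(tuple(atoms),
                             MOTIF_NAMES.get(len(atoms), "helical")))
    counts = {"fissure": 0, "bay": 0, "cove": 0, "fjord": 0, "helical": 0}
    for run in runs:
        counts[run.kind] += 1
    if counts["fjord"] or counts["helical"]:
        logger.warning("fjord/helical motifs present; they are excluded "
                       "from n_strain")
    return MotifCounts(n_fissures=counts["fissure"], n_bays=counts["bay"],
                       n_coves=counts["cove"], n_fjords=counts["fjord"],
                       n_helical=counts["helical"], runs=tuple(runs))


def attribute_bays(b: Benzenoid, report: AnnelationReport,
                   motifs: MotifCounts) -> MotifCounts:
    """Split the bay count into a-annelation and b-annelation bays.

    A bay whose fusion vertices touch a ring attached to an *a* core
    ring counts as an a-bay; attached to a *b* core ring, as a b-bay.
    Bays entirely within a non-core tail get the generic (a-bay)
    weight: they are ordinary phenanthrene-like H–H clashes.  A bay
    touching both an a- and a b-attached ring would be ambiguous and is
    reported as an error rather than guessed.
    """
    cg = b.carbon_graph()
    core_set = set(report.core)
    n_a = n_b = 0
    for run in motifs.runs:
        if run.kind != "bay":
            continue
        rings = set()
        for atom in run.atoms:
            rings |= cg.atom_rings(atom)
        anchors = set()
        for ring in rings:
            if report.labels.get(ring) != "attached":
                continue
            for core_ring in set(b.neighbors(ring).values()) & core_set:
                anchors.add(report.labels[core_ring])
        if anchors == {"a"}:
            n_a += 1
        elif anchors == {"b"}:
            n_b += 1
        elif not anchors:
            n_a += 1  # tail-internal bay: generic phenanthrene-like clash
        else:
            raise StrainError(
                f"bay touches both a- and b-attached rings: {run.atoms}")
    return MotifCounts(n_fissures=motifs.n_fissures, n_bays=motifs.n_bays,
                       n_coves=motifs.n_coves, n_fjords=motifs.n_fjords,
                       n_helical=motifs.n_helical,
                       n_bays_a=n_a, n_bays_b=n_b, runs=motifs.runs)


def molecule_motifs(b: Benzenoid, report: AnnelationReport) -> MotifCounts:
    """Detect and attribute perimeter motifs in one step."""
    return attribute_bays(b, report, detect_motifs(b.perimeter_walk()))


def derive_weights(refs: list[StrainReference], round_to: int | None = 1,
                   ) -> StrainWeights:
    """Motif weights from single-motif reference strain energies.

    Each reference must feature exactly one motif type; its strain
    energy is divided by the a-bay reference energy and by the number
    of motifs it accounts for.  Weights are rounded to ``round_to``
    decimals (pass ``None`` to keep full precision).
    """
    a_ref = b_ref = c_ref = None
    for ref in refs:
        cov, ba, bb = ref.motifs.signature()
        if (cov, ba, bb) == (0, 0, 0):
            continue
        if cov and not (ba or bb):
            c_ref = ref
        elif ba and not (cov or bb):
            a_ref = ref
        elif bb and not (cov or ba):
            b_ref = ref
        else:
            raise StrainError(
                f"{ref.molecule_id}: mixed motifs cannot anchor a weight")
    if a_ref is None or b_ref is None or c_ref is None:
        missing = [name for name, ref in
                   (("a-bay", a_ref), ("b-bay", b_ref), ("cove", c_ref))
                   if ref is None]
        raise StrainError(f"missing reference class(es): {', '.join(missing)}")

    def norm(ref: StrainReference, count: int) -> float:
        w = (ref.e_strain / a_ref.e_strain) / count
        return round(w, round_to) if round_to is not None else w

    return StrainWeights(
        w_bay_a=norm(a_ref, a_ref.motifs.n_bays_a),
        w_bay_b=norm(b_ref, b_ref.motifs.n_bays_b),
        w_cove=norm(c_ref, c_ref.motifs.n_coves),
    )


def n_strain(counts: MotifCounts, weights: StrainWeights = DEFAULT_WEIGHTS,
             ) -> float:
    """Weighted strain score (fissures, fjords and helical runs excluded)."""
    cov, ba, bb = counts.signature()
    return weights.w_bay_a * ba + weights.w_bay_b * bb + weights.w_cove * cov
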