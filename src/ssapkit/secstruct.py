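"""C-alpha-geometry secondary-structure assignment and motif composition.

Assignment follows P-SEA-style distance / pseudo-dihedral criteria on
the C-alpha trace only, so it works on predicted models and bare
C-alpha traces alike.  Strand labels are reported as 'E' internally and
as 'S' counts in compositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .structio import StructureModel

if TYPE_CHECKING:  # pragma: no cover
    from .superpose import AlignmentResult

__all__ = [
    "MotifAnnotation",
    "MotifComposition",
    "assign_ss",
    "motif_composition",
    "aggregate_composition",
]

# helix: d(i,i+3) and d(i,i+4) windows (Angstrom)
HELIX_D13 = (4.7, 5.7)
HELIX_D14 = (5.7, 7.0)
# strand: d(i,i+2) window and pseudo-dihedral window (degrees, mod 360)
STRAND_D12 = (6.4, 7.4)
STRAND_TAU = (150.0, 215.0)


@dataclass
class MotifAnnotation:
    """Half-open residue-index spans of the two motifs on a representative."""

    sheet_spans: list[tuple[int, int]]
    hairpin_spans: list[tuple[int, int]]

    def validate(self, n_residues: int) -> None:
        allspans = self.sheet_spans + self.hairpin_spans
        for start, stop in allspans:
            if not (0 <= start < stop <= n_residues):
                raise ValueError(f"span ({start},{stop}) outside structure "
                                 f"of {n_residues} residues")
        sheet = set()
        for start, stop in self.sheet_spans:
            sheet.update(range(start, stop))
        for start, stop in self.hairpin_spans:
            if sheet.intersection(range(start, stop)):
                raise ValueError("sheet and hairpin spans overlap")

    def sheet_indices(self) -> list[int]:
        return [i for s, e in self.sheet_spans for i in range(s, e)]

    def hairpin_indices(self) -> list[int]:
        return [i for s, e in self.hairpin_spans for i in range(s, e)]


@dataclass
class MotifComposition:
    """Helix/strand residue counts inside the two transferred motifs."""

    sheet_h: int
    sheet_s: int
    hairpin_h: int
    hairpin_s: int
    empty_spans: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, int]:
        return {"sheet_h": self.sheet_h, "sheet_s": self.sheet_s,
                "hairpin_h": self.hairpin_h, "hairpin_s": self.hairpin_s}


def _pseudo_dihedrals(ca: np.ndarray) -> np.ndarray:
    """Dihedral of CA(i..i+3) in degrees, mapped to [0, 360)."""
    b1 = ca[1:-2] - ca[:-3]
    b2 = ca[2:-1] - ca[1:-2]
    b3 = ca[3:] - ca[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    return np.mod(ang, 360.0)


def assign_ss(m: StructureModel | np.ndarray) -> str:
    """Per-residue secondary structure string over {H, E, C}.

    A position ``i`` supports a helix when d(i,i+3) and d(i,i+4) fall
    in the canonical alpha-helical windows, and a strand when d(i,i+2)
    and the pseudo-dihedral of CA(i..i+3) fall in the extended windows;
    each support marks its whole geometric window (5 residues for
    helix, 4 for strand).  Strand takes precedence (helical geometry
    cannot satisfy the strand d(i,i+2) window, so only loop-edge
    ambiguity is affected); termini that support nothing stay coil.
    """
    model = None if isinstance(m, np.ndarray) else m
    if model is not None and "_ss_cache" in model.__dict__:
        return model.__dict__["_ss_cache"]
    ca = m if isinstance(m, np.ndarray) else m.ca_coords
    n = len(ca)
    if n < 5:
        return "C" * n

    d12 = np.linalg.norm(ca[2:] - ca[:-2], axis=1)      # i .. n-3
    d13 = np.linalg.norm(ca[3:] - ca[:-3], axis=1)      # i .. n-4
    d14 = np.linalg.norm(ca[4:] - ca[:-4], axis=1)      # i .. n-5
    tau = _pseudo_dihedrals(ca)                          # i .. n-4

    helix_support = ((HELIX_D13[0] <= d13[:n - 4]) & (d13[:n - 4] <= HELIX_D13[1])
                     & (HELIX_D14[0] <= d14) & (d14 <= HELIX_D14[1]))
    strand_support = ((STRAND_D12[0] <= d12[:n - 3]) & (d12[:n - 3] <= STRAND_D12[1])
                      & (STRAND_TAU[0] <= tau) & (tau <= STRAND_TAU[1]))

    labels = np.full(n, "C", dtype="<U1")
    for i in np.nonzero(strand_support)[0]:
        labels[i:i + 4] = "E"
    for i in np.nonzero(helix_support)[0]:
        window = labels[i:i + 5]
        window[window != "E"] = "H"
    result = "".join(labels.tolist())
    if model is not None:
        model.__dict__["_ss_cache"] = result
    return result


def motif_composition(member: StructureModel, rep: StructureModel,
                      rep_motifs: MotifAnnotation,
                      aln: "AlignmentResult") -> MotifComposition:
    """Transfer representative motif spans to a member and count H/S.

    ``aln`` must be the alignment of ``rep`` (A side) onto ``member``
    (B side); spans are pushed through the residue mapping and member
    residues labeled H / E inside the transferred spans are counted
    (E is reported as "S").
    """
    rep_motifs.validate(len(rep))
    rep_to_member = dict(aln.mapping.pairs)
    ss = assign_ss(member)

    def counts(rep_indices: list[int]) -> tuple[int, int, bool]:
        mapped = [rep_to_member[i] for i in rep_indices if i in rep_to_member]
        h = sum(1 for j in mapped if ss[j] == "H")
        s = sum(1 for j in mapped if ss[j] == "E")
        return h, s, len(mapped) == 0

    sheet_h, sheet_s, sheet_empty = counts(rep_motifs.sheet_indices())
    hp_h, hp_s, hp_empty = counts(rep_motifs.hairpin_indices())
    empty = ([] + (["sheet"] if sheet_empty else [])
             + (["hairpin"] if hp_empty else []))
    return MotifComposition(sheet_h=sheet_h, sheet_s=sheet_s,
                            hairpin_h=hp_h, hairpin_s=hp_s,
                            empty_spans=empty)


def aggregate_composition(
    group: list[MotifComposition],
) -> dict[str, tuple[float, float]]:
    """Per-field (median, population std) over a group of compositions."""
    if not group:
        raise ValueError("cannot aggregate an empty group")
    out: dict[str, tuple[float, float]] = {}
    for f in ("sheet_h", "sheet_s", "hairpin_h", "hairpin_s"):
        vals = np.array([getattr(c, f) for c in group], dtype=float)
        out[f] = (float(np.median(vals)), float(np.std(vals)))
    return out
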