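"""Ring / filament assembly building and inter-chain clash counting.

A monomer is superposed independently onto every chain of a multi-chain
template; the resulting copies inherit the template's chain order, and
clashes are counted as *distinct heavy atoms of a reference copy* lying
strictly within a distance cutoff of any atom of a neighboring copy
(neighboring = adjacent in chain order; wrap-around for rings).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .structio import StructureModel
from .superpose import align_structures

__all__ = [
    "Assembly",
    "ClashReport",
    "build_assembly",
    "count_clashes",
    "clash_report_json",
]

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class Assembly:
    """Ordered transformed copies plus chain adjacency."""

    copies: list[StructureModel]
    adjacency: list[tuple[int, int]]
    topology: str  # "ring" | "filament"


@dataclass
class ClashReport:
    cutoff: float
    per_interface: list[tuple[tuple[int, int], int]]
    clashing_atoms_of_reference_monomer: int
    total_atoms_of_reference_monomer: int
    nonadjacent_clashing_atoms: int
    reference_index: int

    @property
    def clash_fraction(self) -> float:
        return (self.clashing_atoms_of_reference_monomer
                / self.total_atoms_of_reference_monomer)


def make_adjacency(n: int, topology: str) -> list[tuple[int, int]]:
    if topology not in ("ring", "filament"):
        raise ValueError(f"unknown topology {topology!r}")
    pairs = [(i, i + 1) for i in range(n - 1)]
    if topology == "ring":
        pairs.append((n - 1, 0))
    return pairs


def build_assembly(monomer: StructureModel,
                   template_chains: list[StructureModel],
                   topology: str = "ring") -> Assembly:
    """Superpose the monomer onto each template chain.

    Each copy carries all heavy atoms of the monomer, moved by the
    rigid transform from the C-alpha alignment against that chain.
    """
    if len(template_chains) < 2:
        raise ValueError("need at least 2 template chains")
    copies = []
    for k, chain in enumerate(template_chains):
        res = align_structures(monomer, chain)
        if res.aligned_length < 3:
            raise ValueError(
                f"alignment against template chain {chain.id} failed")
        tr = res.transform
        copies.append(monomer.transformed(
            tr.rotation, tr.translation,
            new_id=f"{monomer.id}|{k}",
            chain_id=_CHAIN_IDS[k % len(_CHAIN_IDS)]))
    return Assembly(copies=copies,
                    adjacency=make_adjacency(len(copies), topology),
                    topology=topology)


def _spatial_hash(coords: np.ndarray, cell: float) -> dict:
    grid: dict[tuple[int, int, int], list[int]] = {}
    keys = np.floor(coords / cell).astype(np.int64)
    for idx, key in enumerate(map(tuple, keys)):
        grid.setdefault(key, []).append(idx)
    return grid


def atoms_within(query: np.ndarray, target: np.ndarray,
                 cutoff: float) -> np.ndarray:
    """Boolean mask over query atoms with any target atom strictly
    within ``cutoff``, via a uniform-grid spatial hash."""
    if len(target) == 0 or len(query) == 0:
        return np.zeros(len(query), dtype=bool)
    grid = _spatial_hash(target, cutoff)
    cut2 = cutoff * cutoff
    mask = np.zeros(len(query), dtype=bool)
    keys = np.floor(query / cutoff).astype(np.int64)
    for qi in range(len(query)):
        kx, ky, kz = keys[qi]
        q = query[qi]
        found = False
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    cellidx = grid.get((kx + dx, ky + dy, kz + dz))
                    if not cellidx:
                        continue
                    pts = target[cellidx]
                    d2 = np.sum((pts - q) ** 2, axis=1)
                    if np.any(d2 < cut2):
                        found = True
                        break
                if found:
                    break
            if found:
                break
        mask[qi] = found
    return mask


def count_clashes(a: Assembly, cutoff: float = 2.0,
                  reference: int = 0) -> ClashReport:
    """Count reference-copy atoms clashing with adjacent copies.

    Per-interface counts are atoms of the first copy of each adjacent
    pair within ``cutoff`` of the second.  The headline count is the
    number of *distinct* heavy atoms of the reference copy within
    ``cutoff`` of any adjacent neighbor; contacts with non-adjacent
    copies are tallied separately.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = [c.heavy_atom_coords() for c in a.copies]

    per_interface = []
    for (i, j) in a.adjacency:
        mask = atoms_within(coords[i], coords[j], cutoff)
        per_interface.append(((i, j), int(mask.sum())))

    neighbors = {reference: set()}
    for (i, j) in a.adjacency:
        if i == reference:
            neighbors[reference].add(j)
        if j == reference:
            neighbors[reference].add(i)
    ref_xyz = coords[reference]
    adj_mask = np.zeros(len(ref_xyz), dtype=bool)
    for k in sorted(neighbors[reference]):
        adj_mask |= atoms_within(ref_xyz, coords[k], cutoff)
    nonadj_mask = np.zeros(len(ref_xyz), dtype=bool)
    for k in range(len(a.copies)):
        if k == reference or k in neighbors[reference]:
            continue
        nonadj_mask |= atoms_within(ref_xyz, coords[k], cutoff)

    return ClashReport(
        cutoff=cutoff,
        per_interface=per_interface,
        clashing_atoms_of_reference_monomer=int(adj_mask.sum()),
        total_atoms_of_reference_monomer=len(ref_xyz),
        nonadjacent_clashing_atoms=int(nonadj_mask.sum()),
        reference_index=reference,
    )


def clash_report_json(report: ClashReport) -> str:
    return json.dumps({
        "cutoff": report.cutoff,
        "reference_index": report.reference_index,
        "per_interface": [
            {"pair": list(pair), "clash_atom_count": n}
            for pair, n in report.per_interface],
        "clashing_atoms_of_reference_monomer":
            report.clashing_atoms_of_reference_monomer,
        "total_atoms_of_reference_monomer":
            report.total_atoms_of_reference_monomer,
        "nonadjacent_clashing_atoms": report.nonadjacent_clashing_atoms,
        "clash_fraction": report.clash_fraction,
    }, indent=2)
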