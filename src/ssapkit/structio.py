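"""Structure I/O: PDB parsing, per-residue confidence, quality filtering.

Predicted models carry a 0-100 per-residue confidence in the B-factor
column of the C-alpha atom; experimental templates are assigned 100 by
convention.  Only the first MODEL of multi-model files is read, alternate
locations are resolved by keeping the first, and residues lacking a
C-alpha atom are dropped (and counted in ``StructureModel.n_dropped``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Residue",
    "StructureModel",
    "StructureSet",
    "PDBParseError",
    "ChainNotFoundError",
    "read_structure",
    "write_structure",
    "mean_confidence",
    "filter_by_confidence",
    "extract_sequence",
    "removal_log_tsv",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


class PDBParseError(ValueError):
    """Raised when a text blob contains no usable ATOM records."""


class ChainNotFoundError(KeyError):
    """Raised when the requested chain is absent from the file."""


@dataclass
class Residue:
    """One residue: name, C-alpha position, heavy atoms, confidence."""

    name: str
    ca: np.ndarray
    heavy_atoms: list[tuple[str, np.ndarray]]
    confidence: float


@dataclass
class StructureModel:
    """Ordered single-chain structure with per-residue confidence."""

    id: str
    residues: list[Residue]
    chain_id: str = "A"
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of C-alpha coordinates in file order."""
        return np.array([r.ca for r in self.residues], dtype=float)

    @property
    def confidences(self) -> np.ndarray:
        return np.array([r.confidence for r in self.residues], dtype=float)

    @property
    def sequence(self) -> str:
        return extract_sequence(self)

    def heavy_atom_coords(self) -> np.ndarray:
        """(m, 3) array over all heavy atoms of all residues."""
        coords = [xyz for r in self.residues for _, xyz in r.heavy_atoms]
        return np.array(coords, dtype=float).reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    new_id: str | None = None,
                    chain_id: str | None = None) -> "StructureModel":
        """Copy with all coordinates mapped through ``x -> R x + t``."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        residues = [
            Residue(
                name=r.name,
                ca=R @ r.ca + t,
                heavy_atoms=[(n, R @ xyz + t) for n, xyz in r.heavy_atoms],
                confidence=r.confidence,
            )
            for r in self.residues
        ]
        return StructureModel(
            id=new_id if new_id is not None else self.id,
            residues=residues,
            chain_id=chain_id if chain_id is not None else self.chain_id,
            n_dropped=self.n_dropped,
        )


@dataclass
class StructureSet:
    """Collection of models with optional id -> group labels."""

    members: list[StructureModel]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate structure ids in StructureSet")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def get(self, id_: str) -> StructureModel:
        for m in self.members:
            if m.id == id_:
                return m
        raise KeyError(id_)


def read_structure(pdb_text: str, chain: str | None = None,
                   id: str = "structure",
                   confidence_override: float | None = None,
                   ) -> StructureModel:
    """Parse PDB text into a :class:`StructureModel`.

    Parameters
    ----------
    pdb_text:
        PDB-format text with ATOM/HETATM records.
    chain:
        Chain identifier to extract; defaults to the first chain in
        the file.
    confidence_override:
        Replace every per-residue confidence with this value.  Use 100
        for experimental structures, whose B-factor column holds real
        B-factors rather than a confidence.

    Notes
    -----
    Confidence is read from the B-factor of the C-alpha atom.  Residues
    are ordered by (residue number, insertion code); only the first
    model is read and first alternate locations are kept.  Hydrogens
    and waters are ignored.
    """
    pdb = PDBFile.read(io.StringIO(pdb_text))
    try:
        arr = pdb.get_structure(model=1, altloc="first",
                                extra_fields=["b_factor"])
    except Exception as exc:  # malformed / empty coordinate section
        raise PDBParseError(f"cannot parse PDB text: {exc}") from exc
    if arr.array_length() == 0:
        raise PDBParseError("no ATOM records found")

    # drop hydrogens and waters
    keep = (arr.element != "H") & (arr.res_name != "HOH")
    arr = arr[keep]
    if arr.array_length() == 0:
        raise PDBParseError("no heavy atoms found")

    chains = list(dict.fromkeys(arr.chain_id.tolist()))
    if chain is None:
        chain = chains[0]
    elif chain not in chains:
        raise ChainNotFoundError(
            f"chain {chain!r} not in file (available: {chains})")
    arr = arr[arr.chain_id == chain]

    # group atoms by residue, ordered by (res_id, ins_code)
    keys = list(zip(arr.res_id.tolist(), arr.ins_code.tolist()))
    groups: dict[tuple[int, str], list[int]] = {}
    for idx, key in enumerate(keys):
        groups.setdefault(key, []).append(idx)

    residues: list[Residue] = []
    n_dropped = 0
    for key in sorted(groups):
        idxs = groups[key]
        names = arr.atom_name[idxs]
        ca_pos = [i for i, n in zip(idxs, names) if n == "CA"]
        if not ca_pos:
            n_dropped += 1
            continue
        ca_i = ca_pos[0]
        residues.append(Residue(
            name=str(arr.res_name[ca_i]),
            ca=np.array(arr.coord[ca_i], dtype=float),
            heavy_atoms=[(str(arr.atom_name[i]),
                          np.array(arr.coord[i], dtype=float))
                         for i in idxs],
            confidence=(float(arr.b_factor[ca_i])
                        if confidence_override is None
                        else float(confidence_override)),
        ))
    if not residues:
        raise PDBParseError("no residues with C-alpha atoms")
    return StructureModel(id=id, residues=residues, chain_id=chain,
                          n_dropped=n_dropped)


def read_chains(pdb_text: str, id: str = "structure",
                confidence_override: float | None = None,
                ) -> list[StructureModel]:
    """Read every chain of the first model as separate models."""
    pdb = PDBFile.read(io.StringIO(pdb_text))
    arr = pdb.get_structure(model=1, altloc="first",
                            extra_fields=["b_factor"])
    chains = list(dict.fromkeys(arr.chain_id.tolist()))
    out = []
    for ch in chains:
        try:
            out.append(read_structure(pdb_text, chain=ch, id=f"{id}_{ch}",
                                      confidence_override=confidence_override))
        except PDBParseError:
            continue  # e.g. nucleic-acid or ligand-only chains
    if not out:
        raise PDBParseError("no protein chains found")
    return out


def write_structure(*models: StructureModel) -> str:
    """Serialize one or more models as PDB text (one chain each)."""
    n_atoms = sum(len(r.heavy_atoms) for m in models for r in m.residues)
    arr = AtomArray(n_atoms)
    arr.add_annotation("b_factor", dtype=float)
    arr.add_annotation("occupancy", dtype=float)
    i = 0
    for model in models:
        for res_i, res in enumerate(model.residues, start=1):
            for atom_name, xyz in res.heavy_atoms:
                arr.chain_id[i] = model.chain_id
                arr.res_id[i] = res_i
                arr.res_name[i] = res.name
                arr.atom_name[i] = atom_name
                arr.hetero[i] = False
                arr.element[i] = atom_name[0]
                arr.coord[i] = xyz
                arr.b_factor[i] = res.confidence
                arr.occupancy[i] = 1.0
                i += 1
    pdb = PDBFile()
    pdb.set_structure(arr)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


def mean_confidence(m: StructureModel) -> float:
    """Arithmetic mean of per-residue confidence (0-100)."""
    if len(m) == 0:
        raise ValueError("cannot compute mean confidence of empty model")
    return float(np.mean(m.confidences))


def filter_by_confidence(
    s: StructureSet, threshold: float = 70.0
) -> tuple[StructureSet, list[tuple[str, float, bool]]]:
    """Drop models whose mean confidence is strictly below ``threshold``.

    Returns the filtered set and a removal log of
    ``(id, mean_confidence, kept)`` tuples, one per input model.
    Models with mean confidence exactly at the threshold are kept.
    """
    log: list[tuple[str, float, bool]] = []
    kept: list[StructureModel] = []
    for m in s.members:
        mc = mean_confidence(m)
        keep = mc >= threshold
        log.append((m.id, mc, keep))
        if keep:
            kept.append(m)
    labels = {m.id: s.labels[m.id] for m in kept if m.id in s.labels}
    return StructureSet(members=kept, labels=labels), log


def removal_log_tsv(log: list[tuple[str, float, bool]]) -> str:
    lines = ["id\tmean_confidence\tkept"]
    lines += [f"{i}\t{c:.3f}\t{int(k)}" for i, c, k in log]
    return "\n".join(lines) + "\n"


def extract_sequence(m: StructureModel) -> str:
    """One-letter sequence; unknown three-letter codes map to 'X'."""
    return "".join(_THREE_TO_ONE.get(r.name, "X") for r in m.residues)


def one_to_three(letter: str) -> str:
    """Inverse residue-code lookup used by the synthetic generators."""
    return _ONE_TO_THREE.get(letter, "UNK")
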