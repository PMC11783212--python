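"""Benchmark computations against real predicted models and templates.

These functions reproduce the published reference comparisons when the
required public structure files are available locally (they cannot be
redistributed with the package and the build environment has no
network access).  Expected layout under a ``data/external/`` directory:

    AF-A0A2D6XHC3-F1.pdb   predicted archaeal model resembling human Rad52
    AF-A0A842UJM1-F1.pdb   \\
    AF-A0A843GZ30-F1.pdb    | the four archaeal family representatives
    AF-L0KZL4-F1.pdb        |
    AF-A0A2D6XBR4-F1.pdb   /
    1KN0.pdb               human Rad52 N-terminal undecameric ring
    7UB2.pdb               RecT filament template
    7UJL.pdb               Redbeta filament template

All files are plain-text PDB as served by the AlphaFold DB / RCSB.
"""

from __future__ import annotations

from pathlib import Path

from .oligomer import ClashReport, build_assembly, count_clashes
from .structio import StructureModel, read_chains, read_structure
from .superpose import AlignmentResult, align_structures

__all__ = [
    "REPRESENTATIVE_ACCESSIONS",
    "ExternalData",
    "load_external_data",
    "tm_vs_template",
    "identify_representatives",
    "ring_clash_report",
]

REPRESENTATIVE_ACCESSIONS = (
    "A0A842UJM1", "A0A843GZ30", "L0KZL4", "A0A2D6XBR4")

HUMAN_RAD52_LIKE_ACCESSION = "A0A2D6XHC3"


class ExternalData:
    """Loaded external models/templates keyed by accession / PDB id."""

    def __init__(self, models: dict[str, StructureModel],
                 template_chains: dict[str, list[StructureModel]]):
        self.models = models
        self.template_chains = template_chains


def load_external_data(root: Path) -> ExternalData:
    """Load the external structure files; raise with the missing list."""
    root = Path(root)
    wanted_models = [HUMAN_RAD52_LIKE_ACCESSION, *REPRESENTATIVE_ACCESSIONS]
    wanted_templates = ["1KN0", "7UB2", "7UJL"]
    missing = []
    models: dict[str, StructureModel] = {}
    templates: dict[str, list[StructureModel]] = {}
    for acc in wanted_models:
        path = root / f"AF-{acc}-F1.pdb"
        if not path.exists():
            missing.append(path.name)
            continue
        models[acc] = read_structure(path.read_text(), id=acc)
    for pdb_id in wanted_templates:
        path = root / f"{pdb_id}.pdb"
        if not path.exists():
            missing.append(path.name)
            continue
        templates[pdb_id] = read_chains(path.read_text(), id=pdb_id,
                                        confidence_override=100.0)
    if missing:
        raise FileNotFoundError(
            "external reference structures not available (no-download "
            f"environment); missing from {root}: {', '.join(missing)}")
    return ExternalData(models=models, template_chains=templates)


def tm_vs_template(model: StructureModel,
                   template_chain: StructureModel) -> AlignmentResult:
    """Align a predicted model to one experimental chain.

    The headline TM is ``tm_norm_b`` — normalized by the template chain
    length (the fixed reference), consistent with the screening module.
    """
    return align_structures(model, template_chain)


def identify_representatives(
    data: ExternalData,
) -> dict[str, str]:
    """Assign the four representative accessions to fold families.

    The RecT / Redbeta representatives are the candidates scoring
    highest against the corresponding experimental template (7UB2 /
    7UJL); the remaining two are the Rad52-like pair, distinguished as
    "rad52-long" (more heavy atoms) and "rad52-short".
    """
    candidates = set(REPRESENTATIVE_ACCESSIONS)
    assignment: dict[str, str] = {}
    for family, pdb_id in (("rect", "7UB2"), ("redbeta", "7UJL")):
        chain = data.template_chains[pdb_id][0]
        scored = sorted(
            ((tm_vs_template(data.models[acc], chain).tm_norm_b, acc)
             for acc in candidates), reverse=True)
        best = scored[0][1]
        assignment[family] = best
        candidates.discard(best)
    rad52 = sorted(candidates,
                   key=lambda acc: -len(data.models[acc].heavy_atom_coords()))
    assignment["rad52-long"] = rad52[0]
    assignment["rad52-short"] = rad52[1]
    return assignment


def ring_clash_report(monomer: StructureModel,
                      ring_chains: list[StructureModel],
                      cutoff: float = 2.0) -> ClashReport:
    """Superpose the monomer onto every ring chain and count clashes."""
    assembly = build_assembly(monomer, ring_chains, topology="ring")
    return count_clashes(assembly, cutoff=cutoff)
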