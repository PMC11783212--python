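"""Shared fixtures: synthetic structures and a warm numba cache."""

from dataclasses import replace

import numpy as np
import pytest

from ssapkit import synthetic_data as sd
from ssapkit import superpose


def make_pdb_text(residues, chain="A", bfactors=None, altloc=None):
    """Hand-rolled fixed-column PDB text, independent of the writer.

    ``residues``: list of (res_name, (x, y, z)) with one CA atom each.
    """
    lines = []
    serial = 1
    for i, (name, xyz) in enumerate(residues, start=1):
        b = bfactors[i - 1] if bfactors else 50.0
        alt = altloc or " "
        lines.append(
            f"ATOM  {serial:5d}  CA {alt}{name:<3s} {chain}{i:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{b:6.2f}"
            f"          {'C':>2s}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session", autouse=True)
def warm_numba():
    """Compile the jit kernels once so timing-sensitive tests are fair."""
    a = np.random.default_rng(0).normal(size=(10, 3))
    superpose.kabsch(a, a + 1.0)
    m, _ = sd.make_ssap_monomer(
        replace(sd.FAMILY_PRESETS["sak3-like"], seed=0), "warm")
    superpose.align_structures(m, m)


@pytest.fixture(scope="session")
def long_monomer():
    p = replace(sd.FAMILY_PRESETS["rad52-long"], seed=3)
    return sd.make_ssap_monomer(p, "long")


@pytest.fixture(scope="session")
def short_monomer():
    p = replace(sd.FAMILY_PRESETS["rad52-short"], seed=4)
    return sd.make_ssap_monomer(p, "short")


@pytest.fixture(scope="session")
def two_family_set():
    """2 x 6 members from clearly distinct presets, with labels."""
    from ssapkit.structio import StructureSet

    members, labels = [], {}
    manifests = {}
    for i, name in enumerate(["rad52-long", "sak3-like"]):
        p = replace(sd.FAMILY_PRESETS[name], seed=11 + i)
        fam, man = sd.make_family(6, p, divergence_sigma=0.5, family=name)
        members += fam.members
        labels.update(fam.labels)
        manifests[name] = man
    return StructureSet(members=members, labels=labels), manifests
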