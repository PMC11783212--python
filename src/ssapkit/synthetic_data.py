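"""Deterministic synthetic structure generators.

Emits monomers built from ideal secondary-structure elements (a
3-stranded antiparallel sheet crossed by a helix, plus a strand-turn-
strand hairpin with an optional inserted helix), families of perturbed
copies with ground-truth manifests, fragment decoys, n-fold symmetric
ring templates, and compact random-coil decoys.  Everything is
reproducible bit-for-bit from integer seeds.

Backbones are C-alpha traces plus deterministic heavy-atom stubs
(N, C, O, CB) — enough for clash counting and C-alpha secondary-
structure analysis, with no pretense of side-chain realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .oligomer import Assembly, count_clashes, make_adjacency
from .secstruct import MotifAnnotation
from .structio import Residue, StructureModel, StructureSet, one_to_three

__all__ = [
    "FamilyParams",
    "GeneratorManifest",
    "FAMILY_PRESETS",
    "make_helix",
    "make_strand",
    "make_ssap_monomer",
    "make_family",
    "make_ring",
    "make_decoy",
]

HELIX_RADIUS = 2.3       # Angstrom
HELIX_RISE = 1.5         # Angstrom / residue
HELIX_TWIST = 100.0      # degrees / residue
STRAND_STEP_X = 3.45     # along-strand advance per residue
STRAND_PLEAT = 0.797     # +- pleat so consecutive CA-CA = 3.8
SHEET_SPACING = 4.8      # inter-strand spacing
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FamilyParams:
    """Geometry of one synthetic fold family."""

    strand_len: int
    sheet_helix_len: int
    hairpin_len: int            # residues per hairpin strand
    hairpin_helix_len: int = 0  # 0 allowed: hairpin without helix
    n_strands: int = 3
    loop_len: int = 4
    noise_sigma: float = 0.0    # iid Gaussian coordinate noise
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("strand_len", "sheet_helix_len", "hairpin_len",
                     "hairpin_helix_len", "n_strands", "loop_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class GeneratorManifest:
    """Ground truth for every emitted structure."""

    records: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def record_for(self, id_: str) -> dict:
        for r in self.records:
            if r["id"] == id_:
                return r
        raise KeyError(id_)


# Presets echoing the distinct helix/strand length regimes of the five
# fold families (per-strand length = sheet strand-residue median / 3).
FAMILY_PRESETS: dict[str, FamilyParams] = {
    "rad52-long": FamilyParams(strand_len=12, sheet_helix_len=15,
                               hairpin_len=6, hairpin_helix_len=18),
    "rad52-short": FamilyParams(strand_len=9, sheet_helix_len=17,
                                hairpin_len=7, hairpin_helix_len=12),
    "redbeta-like": FamilyParams(strand_len=11, sheet_helix_len=26,
                                 hairpin_len=6, hairpin_helix_len=28),
    "rect-like": FamilyParams(strand_len=12, sheet_helix_len=32,
                              hairpin_len=6, hairpin_helix_len=42),
    "sak3-like": FamilyParams(strand_len=9, sheet_helix_len=15,
                              hairpin_len=8, hairpin_helix_len=0),
}


def make_helix(n: int) -> np.ndarray:
    """Ideal alpha-helical C-alpha trace along +x from the origin."""
    if n < 1:
        raise ValueError("n must be >= 1")
    k = np.arange(n)
    theta = np.radians(HELIX_TWIST * k)
    return np.column_stack([
        HELIX_RISE * k,
        HELIX_RADIUS * np.cos(theta),
        HELIX_RADIUS * np.sin(theta),
    ])


def make_strand(n: int) -> np.ndarray:
    """Ideal extended strand along +x with alternating pleat."""
    if n < 1:
        raise ValueError("n must be >= 1")
    k = np.arange(n)
    return np.column_stack([
        STRAND_STEP_X * k,
        STRAND_PLEAT * np.where(k % 2 == 0, 1.0, -1.0),
        np.zeros(n),
    ])


def _place(coords: np.ndarray, start: np.ndarray,
           direction: np.ndarray) -> np.ndarray:
    """Rotate canonical +x-axis coords onto ``direction``, then shift."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(x, d)
    c = float(np.dot(x, d))
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx / (1.0 + c)
    return coords @ R.T + np.asarray(start, dtype=float)


def _loop(a: np.ndarray, b: np.ndarray, n: int,
          bulge_dir: np.ndarray) -> np.ndarray:
    """``n`` connective points between anchors with an out-of-plane
    wobble so the loop never mimics strand geometry."""
    if n == 0:
        return np.zeros((0, 3))
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    chord = b - a
    clen = np.linalg.norm(chord)
    target = 3.8 * (n + 1)
    u = bulge_dir / np.linalg.norm(bulge_dir)
    # second normal for torsion
    w = np.cross(chord / max(clen, 1e-9), u)
    wn = np.linalg.norm(w)
    w = w / wn if wn > 1e-9 else np.array([0.0, 0.0, 1.0])
    # pick the bulge amplitude whose arc length best matches 3.8 A steps
    t = np.linspace(0.0, 1.0, n + 2)
    best = None
    for h in np.arange(0.0, 20.1, 0.25):
        pts = (a + np.outer(t, chord)
               + np.outer(np.sin(np.pi * t) * h, u)
               + np.outer(np.sin(2 * np.pi * t) * 0.35 * h + 0.8
                          * np.sin(3 * np.pi * t), w))
        plen = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        err = abs(plen - target)
        if best is None or err < best[0]:
            best = (err, pts)
    return best[1][1:-1]


def _segment_frames(ca: np.ndarray) -> list[np.ndarray]:
    """Per-residue tangent vectors of a C-alpha trace."""
    n = len(ca)
    tangents = []
    for i in range(n):
        lo = max(0, i - 1)
        hi = min(n - 1, i + 1)
        t = ca[hi] - ca[lo]
        norm = np.linalg.norm(t)
        tangents.append(t / norm if norm > 1e-9 else np.array([1.0, 0, 0]))
    return tangents


def _heavy_stubs(ca: np.ndarray) -> list[list[tuple[str, np.ndarray]]]:
    """Deterministic N/C/O/CB stub positions around each C-alpha."""
    tangents = _segment_frames(ca)
    out = []
    for i, (pos, u) in enumerate(zip(ca, tangents)):
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(u, ref)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        v = np.cross(u, ref)
        v /= np.linalg.norm(v)
        w = np.cross(u, v)
        out.append([
            ("N", pos - 1.2 * u + 0.5 * v),
            ("CA", pos),
            ("C", pos + 1.2 * u + 0.5 * v),
            ("O", pos + 1.4 * u + 1.3 * v),
            ("CB", pos + 1.5 * w),
        ])
    return out


def _random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n).tolist())


def _assemble_geometry(p: FamilyParams) -> tuple[np.ndarray, MotifAnnotation]:
    """Ideal (noise-free) monomer trace plus true motif spans."""
    segments: list[np.ndarray] = []
    sheet_spans: list[tuple[int, int]] = []
    hairpin_spans: list[tuple[int, int]] = []
    count = 0

    def add(seg: np.ndarray, span_list=None):
        nonlocal count
        if len(seg) == 0:
            return
        segments.append(seg)
        if span_list is not None:
            span_list.append((count, count + len(seg)))
        count += len(seg)

    def connect(next_start: np.ndarray, bulge: np.ndarray, n: int):
        prev_end = segments[-1][-1]
        add(_loop(prev_end, next_start, n, bulge))

    sheet_x = STRAND_STEP_X * (p.strand_len - 1)
    down = np.array([0.0, 0.0, -1.0])
    up = np.array([0.0, 0.0, 1.0])

    # antiparallel sheet in the z=0 plane
    for s in range(p.n_strands):
        y = SHEET_SPACING * s
        forward = s % 2 == 0
        start = np.array([0.0 if forward else sheet_x, y, 0.0])
        direction = np.array([1.0 if forward else -1.0, 0.0, 0.0])
        seg = _place(make_strand(p.strand_len), start, direction)
        if s > 0:
            connect(seg[0], down, p.loop_len)
        add(seg, sheet_spans)

    # crossing helix above the sheet midline
    if p.sheet_helix_len > 0:
        hx = HELIX_RISE * (p.sheet_helix_len - 1)
        ymid = SHEET_SPACING * (p.n_strands - 1) / 2.0
        start = np.array([sheet_x / 2.0 + hx / 2.0, ymid, 6.0])
        seg = _place(make_helix(p.sheet_helix_len), start,
                     np.array([-1.0, 0.0, 0.0]))
        connect(seg[0], up, p.loop_len)
        add(seg, sheet_spans)

    # hairpin: strand A - (optional helix) - strand B
    y_hp = SHEET_SPACING * p.n_strands + 4.0
    if p.hairpin_len > 0:
        segA = _place(make_strand(p.hairpin_len),
                      np.array([0.0, y_hp, 0.0]), np.array([1.0, 0.0, 0.0]))
        connect(segA[0], up, p.loop_len)
        add(segA, hairpin_spans)
        hp_x = STRAND_STEP_X * (p.hairpin_len - 1)
        if p.hairpin_helix_len > 0:
            seg = _place(make_helix(p.hairpin_helix_len),
                         np.array([hp_x + 4.0, y_hp + 2.0, 5.0]),
                         np.array([1.0, 0.3, 0.0]))
            connect(seg[0], up, max(2, p.loop_len - 1))
            add(seg, hairpin_spans)
        segB = _place(make_strand(p.hairpin_len),
                      np.array([hp_x, y_hp + SHEET_SPACING, 0.0]),
                      np.array([-1.0, 0.0, 0.0]))
        connect(segB[0], up if p.hairpin_helix_len else down,
                max(2, p.loop_len - 1))
        add(segB, hairpin_spans)

    coords = np.vstack(segments)
    return coords, MotifAnnotation(sheet_spans=sheet_spans,
                                   hairpin_spans=hairpin_spans)


def _model_from_trace(id_: str, ca: np.ndarray, sequence: str,
                      confidence: np.ndarray,
                      chain_id: str = "A") -> StructureModel:
    stubs = _heavy_stubs(ca)
    residues = [
        Residue(name=one_to_three(sequence[i]), ca=ca[i].copy(),
                heavy_atoms=[(nm, xyz.copy()) for nm, xyz in stubs[i]],
                confidence=float(confidence[i]))
        for i in range(len(ca))
    ]
    return StructureModel(id=id_, residues=residues, chain_id=chain_id)


def _confidences(n: int, rng: np.random.Generator,
                 mean: float = 90.0, sd: float = 5.0) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size=n), 0.0, 100.0)


def make_ssap_monomer(
    p: FamilyParams, id_: str = "monomer",
) -> tuple[StructureModel, MotifAnnotation]:
    """Build one monomer from family parameters.

    Deterministic for a fixed ``p.seed``; iid Gaussian noise of
    ``p.noise_sigma`` is added to every coordinate and confidences are
    drawn from N(90, 5) clipped to [0, 100].
    """
    rng = np.random.default_rng(p.seed)
    ca, motifs = _assemble_geometry(p)
    seq = _random_sequence(len(ca), rng)
    if p.noise_sigma > 0:
        ca = ca + rng.normal(0.0, p.noise_sigma, size=ca.shape)
    conf = _confidences(len(ca), rng)
    model = _model_from_trace(id_, ca, seq, conf)
    motifs.validate(len(model))
    return model, motifs


def _smooth_noise(n: int, sigma: float, rng: np.random.Generator,
                  corr_len: float = 6.0) -> np.ndarray:
    """Sequence-correlated displacement field with per-residue std
    ``sigma`` — divergence that bends the fold without shredding local
    geometry."""
    white = rng.normal(0.0, 1.0, size=(n, 3))
    smooth = gaussian_filter1d(white, sigma=corr_len, axis=0,
                               mode="nearest")
    sd = smooth.std()
    if sd < 1e-12:
        return np.zeros((n, 3))
    return smooth / sd * sigma


def make_family(
    n_members: int,
    p: FamilyParams,
    divergence_sigma: float = 0.5,
    family: str = "family",
    fragments: int = 0,
    fragment_keep: float = 0.6,
    mutation_rate: float = 0.1,
) -> tuple[StructureSet, GeneratorManifest]:
    """Generate ``n_members`` perturbed family members (+ fragments).

    Per-member seeds derive from ``p.seed``.  Divergence is a smooth
    sequence-correlated displacement field of per-residue std
    ``divergence_sigma`` plus loop-length jitter of +-1 residue;
    sequences share a family consensus with ``mutation_rate`` point
    mutations.  Fragments are extra members truncated to the first
    ``fragment_keep`` fraction of residues.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    base_rng = np.random.default_rng(p.seed)
    base_ca, _ = _assemble_geometry(p)
    consensus = _random_sequence(len(base_ca), base_rng)

    members: list[StructureModel] = []
    manifest = GeneratorManifest()
    labels: dict[str, str] = {}

    def emit(k: int, is_fragment: bool) -> None:
        rng = np.random.default_rng(
            np.random.SeedSequence([p.seed, 7919, k]))
        jitter = int(rng.integers(-1, 2))
        pk = replace(p, loop_len=max(2, p.loop_len + jitter))
        ca, motifs = _assemble_geometry(pk)
        ca = ca + _smooth_noise(len(ca), divergence_sigma, rng)
        ca = ca + rng.normal(0.0, 0.05, size=ca.shape)
        seq = _mutate(consensus, len(ca), mutation_rate, rng)
        if is_fragment:
            keep = max(10, int(len(ca) * fragment_keep))
            ca = ca[:keep]
            seq = seq[:keep]
            motifs = _clip_motifs(motifs, keep)
        conf = _confidences(len(ca), rng)
        tag = "frag" if is_fragment else "m"
        mid = f"{family}_{tag}{k:03d}"
        model = _model_from_trace(mid, ca, seq, conf)
        members.append(model)
        labels[mid] = family
        manifest.records.append({
            "id": mid,
            "family": family,
            "seed": int(p.seed),
            "member": k,
            "is_fragment": is_fragment,
            "sheet_spans": list(motifs.sheet_spans),
            "hairpin_spans": list(motifs.hairpin_spans),
            "true_sheet_s": pk.n_strands * pk.strand_len,
            "true_sheet_h": pk.sheet_helix_len,
            "true_hairpin_s": 2 * pk.hairpin_len,
            "true_hairpin_h": pk.hairpin_helix_len,
            "n_residues": len(model),
        })

    for k in range(n_members):
        emit(k, is_fragment=False)
    for k in range(n_members, n_members + fragments):
        emit(k, is_fragment=True)

    return StructureSet(members=members, labels=labels), manifest


def _mutate(consensus: str, n: int, rate: float,
            rng: np.random.Generator) -> str:
    seq = list(consensus[:n].ljust(n, "A"))
    for i in range(n):
        if rng.random() < rate:
            seq[i] = AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]
    return "".join(seq)


def _clip_motifs(m: MotifAnnotation, keep: int) -> MotifAnnotation:
    def clip(spans):
        return [(s, min(e, keep)) for s, e in spans if s < keep]
    return MotifAnnotation(sheet_spans=clip(m.sheet_spans),
                           hairpin_spans=clip(m.hairpin_spans))


def _rotz(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ring_at_radius(monomer: StructureModel, n_copies: int,
                    radius: float) -> Assembly:
    ca = monomer.ca_coords
    centroid = ca.mean(axis=0)
    copies = []
    for k in range(n_copies):
        R = _rotz(2.0 * math.pi * k / n_copies)
        t = R @ (np.array([radius, 0.0, 0.0]) - centroid)
        copies.append(monomer.transformed(
            R, t, new_id=f"{monomer.id}|ring{k}",
            chain_id="ABCDEFGHIJKLMNOPQRSTUVWXYZ"[k % 26]))
    return Assembly(copies=copies,
                    adjacency=make_adjacency(n_copies, "ring"),
                    topology="ring")


def make_ring(monomer: StructureModel, n_copies: int = 11,
              radius: float | None = None,
              clash_cutoff: float = 2.0,
              margin: float = 0.5) -> Assembly:
    """n-fold symmetric ring of the monomer about the z axis.

    With ``radius=None`` the smallest radius (0.5 A scan) yielding zero
    clashes at ``clash_cutoff`` is chosen and ``margin`` is added, so
    adjacent copies sit near contact but clash-free.
    """
    if n_copies < 3:
        raise ValueError("need at least 3 copies for a ring")
    if radius is not None:
        return _ring_at_radius(monomer, n_copies, radius)

    from .oligomer import atoms_within

    atoms = monomer.heavy_atom_coords() - monomer.ca_coords.mean(axis=0)
    angle = 2.0 * math.pi / n_copies
    R1 = _rotz(angle)

    def adjacent_clash_free(r: float) -> bool:
        a = atoms + np.array([r, 0.0, 0.0])
        b = a @ R1.T
        return not atoms_within(a, b, clash_cutoff).any()

    span = float(np.linalg.norm(atoms, axis=1).max())
    lo, hi = 0.5, 2.0 * span / math.sin(math.pi / n_copies) + 10.0
    while hi - lo > 0.25:  # smallest clash-free radius on a 0.5 A grid
        mid = 0.5 * (lo + hi)
        if adjacent_clash_free(mid):
            hi = mid
        else:
            lo = mid
    r = math.ceil(hi / 0.5) * 0.5
    # verify against the full ring (non-adjacent contacts included)
    while True:
        asm = _ring_at_radius(monomer, n_copies, r + margin)
        rep = count_clashes(asm, cutoff=clash_cutoff)
        if (rep.clashing_atoms_of_reference_monomer == 0
                and rep.nonadjacent_clashing_atoms == 0):
            return asm
        r += 0.5


def make_decoy(length: int, seed: int = 0,
               id_: str = "decoy") -> StructureModel:
    """Compact self-avoiding C-alpha random walk (step 3.8 A).

    Non-consecutive residues stay >= 3.5 A apart and the chain is kept
    inside a compactness sphere.  Successive bond angles are drawn
    outside the canonical extended band (cos angle <= 0.35), i.e. the
    walk turns like a coil rather than running straight; deterministic
    per seed.
    """
    if length < 10:
        raise ValueError("length must be >= 10")
    rng = np.random.default_rng(seed)
    step = 3.8
    min_sep = 3.5
    cap = 4.0 * length ** (1.0 / 3.0) + 6.0

    pts = [np.zeros(3)]
    direction = _rand_unit(rng)
    attempts_left = 4000
    while len(pts) < length and attempts_left > 0:
        attempts_left -= 1
        r = _rand_unit(rng)
        perp = r - np.dot(r, direction) * direction
        pnorm = np.linalg.norm(perp)
        if pnorm < 1e-9:
            continue
        perp /= pnorm
        cos_a = rng.uniform(-0.45, 0.35)
        proposal = cos_a * direction + math.sqrt(1 - cos_a ** 2) * perp
        cand = pts[-1] + step * proposal
        prev = np.array(pts[:-1]) if len(pts) > 1 else None
        ok = np.linalg.norm(cand - np.mean(pts, axis=0)) <= cap
        if ok and prev is not None:
            ok = bool(np.all(np.linalg.norm(prev - cand, axis=1) >= min_sep))
        if ok:
            pts.append(cand)
            direction = proposal
        elif attempts_left % 50 == 0 and len(pts) > 5:
            # stuck: backtrack a few steps
            del pts[-3:]
            direction = _rand_unit(rng)
    if len(pts) < length:  # pathological seed: relax compactness
        return make_decoy(length, seed + 104729, id_=id_)
    ca = np.array(pts)
    seq = _random_sequence(length, rng)
    conf = _confidences(length, rng, mean=88.0)
    return _model_from_trace(id_, ca, seq, conf)


def _rand_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)
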