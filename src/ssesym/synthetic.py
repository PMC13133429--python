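"""Synthetic Cα-trace generator with planted structural rearrangements.

Builds toy protein chains from ideal secondary-structure geometry — α-helices
with a 1.5 Å rise and 100° twist per residue, extended β-strands with a
~3.3 Å axial rise — joined by self-avoiding random-walk coil linkers, all
deterministic per seed.  Operators plant the events the detection pipeline
must recover: circular permutations (residue reordering with coordinates
untouched), insertions/deletions, and tandem repeats (rigid translated
copies of a unit, so repeat units are exactly superposable).

Fixtures carry ground-truth 3-state labels assigned at construction time, so
encoding and alignment tests do not depend on any geometric assigner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain import ProteinChain, Residue

CA_STEP = 3.8          # consecutive Cα-Cα distance, Å
HELIX_RADIUS = 2.3     # Å
HELIX_RISE = 1.5       # Å per residue
HELIX_TWIST = 100.0    # degrees per residue
STRAND_RISE = 3.3      # axial rise per residue, Å
CLASH_TOL = 2.5        # Å, minimum non-bonded Cα separation in linkers
LINKER_TRIES = 100


@dataclass
class FixtureSpec:
    """Recipe for one synthetic chain.

    ``elements`` lists (ss_type, length_residues) with ss_type in
    {"helix", "strand"}; ``operators`` is an ordered list of planted events,
    each a tuple: ("circular_permute", boundary_res), ("insert", pos, length),
    ("delete", pos, length), ("tandem_repeat", k).
    """

    seed: int
    elements: list[tuple[str, int]]
    linker_length: int = 4
    operators: list[tuple] = field(default_factory=list)
    chain_id: str = "synth_A"


def _helix_coords(n: int) -> np.ndarray:
    i = np.arange(n)
    theta = np.deg2rad(HELIX_TWIST) * i
    return np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
    )


def _strand_coords(n: int) -> np.ndarray:
    # zigzag with 3.8 Å steps and 3.3 Å axial rise
    i = np.arange(n)
    lateral = 0.5 * np.sqrt(CA_STEP**2 - STRAND_RISE**2)
    return np.column_stack(
        [lateral * (-1.0) ** i, np.zeros(n), STRAND_RISE * i]
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _min_dist(point: np.ndarray, cloud: list[np.ndarray]) -> float:
    if not cloud:
        return np.inf
    arr = np.array(cloud)
    return float(np.min(np.linalg.norm(arr - point, axis=1)))


def _walk_linker(
    start: np.ndarray, n: int, rng: np.random.Generator, placed: list[np.ndarray]
) -> np.ndarray:
    """Self-avoiding random walk of n points with fixed 3.8 Å steps."""
    pts = []
    cur = start
    for _ in range(n):
        best = None
        for _try in range(LINKER_TRIES):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            cand = cur + CA_STEP * d
            if _min_dist(cand, placed) >= CLASH_TOL:
                best = cand
                break
            if best is None:
                best = cand
        cur = best
        pts.append(cur)
        placed.append(cur)
    return np.array(pts).reshape(n, 3)


def make_chain(spec: FixtureSpec) -> ProteinChain:
    """Build the chain described by ``spec``, applying planted operators.

    Deterministic for a fixed spec (including seed).
    """
    for ss_type, length in spec.elements:
        if ss_type not in ("helix", "strand"):
            raise ValueError(f"unknown element type {ss_type!r}")
        if length < 2:
            raise ValueError("element shorter than 2 residues")
    rng = np.random.default_rng(spec.seed)

    coords: list[np.ndarray] = []
    ss3: list[str] = []
    placed: list[np.ndarray] = []
    for k, (ss_type, length) in enumerate(spec.elements):
        local = _helix_coords(length) if ss_type == "helix" else _strand_coords(length)
        local = local - local[0]
        # try orientations until the element does not clash with placed atoms
        for _try in range(LINKER_TRIES):
            rot = _random_rotation(rng)
            if not coords:
                origin = np.zeros(3)
            else:
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                origin = coords[-1] + CA_STEP * d
            cand = local @ rot.T + origin
            if not placed or float(
                np.min(
                    np.linalg.norm(
                        np.array(placed)[:, None, :] - cand[None, :, :], axis=2
                    )
                )
            ) >= CLASH_TOL:
                break
        coords.extend(cand)
        placed.extend(cand)
        ss3.extend(("H" if ss_type == "helix" else "E") * length)
        if k < len(spec.elements) - 1 and spec.linker_length > 0:
            link = _walk_linker(coords[-1], spec.linker_length, rng, placed)
            coords.extend(link)
            ss3.extend("C" * spec.linker_length)

    chain = ProteinChain(
        spec.chain_id,
        [
            Residue(author_number=i + 1, ca=c, ss3=s)
            for i, (c, s) in enumerate(zip(coords, ss3))
        ],
    )

    for op in spec.operators:
        name = op[0]
        if name == "circular_permute":
            chain = circular_permute(chain, op[1])
        elif name == "insert":
            chain = apply_indel(chain, op[1], op[2], mode="insert", seed=spec.seed + 7)
        elif name == "delete":
            chain = apply_indel(chain, op[1], op[2], mode="delete")
        elif name == "tandem_repeat":
            chain = tandem_repeat(chain, op[1], linker_length=spec.linker_length)
        else:
            raise ValueError(f"unknown operator {name!r}")
    return chain


def circular_permute(chain: ProteinChain, boundary_res: int) -> ProteinChain:
    """Reorder residues as [boundary..end] + [start..boundary).

    Coordinates are untouched; labels travel with their residues.  The
    operation at the complementary boundary is its inverse.
    """
    n = len(chain)
    if not (0 < boundary_res < n):
        raise ValueError("boundary must be strictly inside the chain")
    order = list(range(boundary_res, n)) + list(range(boundary_res))
    return chain.reordered(order, chain_id=chain.chain_id + "_cp")


def apply_indel(
    chain: ProteinChain,
    position: int,
    length: int,
    mode: str,
    seed: int = 0,
) -> ProteinChain:
    """Insert a seeded coil segment at ``position`` or delete ``length``
    residues starting there.

    On deletion the C-terminal part is rigidly translated so the junction
    keeps a ~3.8 Å Cα step; local geometry of both parts is preserved.
    """
    n = len(chain)
    if mode == "insert":
        if not (0 < position < n):
            raise ValueError("insert position out of range")
        rng = np.random.default_rng(seed)
        placed = [r.ca for r in chain.residues]
        start = chain.residues[position - 1].ca
        ins = _walk_linker(start, length, rng, placed)
        # translate C-part to follow the inserted segment's end
        old_c_start = chain.residues[position].ca
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        shift = (ins[-1] + CA_STEP * d) - old_c_start
        residues = [Residue(r.author_number, r.ca, r.insertion_code, r.ss3)
                    for r in chain.residues[:position]]
        residues += [
            Residue(author_number=0, ca=c, ss3="C") for c in ins
        ]
        residues += [
            Residue(r.author_number, r.ca + shift, r.insertion_code, r.ss3)
            for r in chain.residues[position:]
        ]
        for i, r in enumerate(residues):
            r.author_number = i + 1
        return ProteinChain(chain.chain_id + "_ins", residues)
    if mode == "delete":
        if not (0 <= position and position + length <= n and length < n):
            raise ValueError("delete span out of range")
        n_part = chain.residues[:position]
        c_part = chain.residues[position + length:]
        coords = chain.coords
        # re-join preserving local geometry: rigidly move the C-part so the
        # frame at the first kept residue matches the frame the deleted
        # span's start had (an ideal helix shortens into an ideal helix)
        rot = np.eye(3)
        shift = np.zeros(3)
        if n_part and c_part:
            if position + length + 3 <= n and position + 3 <= n:
                from .tmscore import kabsch

                try:
                    sup = kabsch(
                        coords[position : position + 3],
                        coords[position + length : position + length + 3],
                    )
                    rot, shift = sup.rotation, sup.translation
                except ValueError:
                    pass
            if np.allclose(rot, np.eye(3)) and np.allclose(shift, 0.0):
                gap = c_part[0].ca - n_part[-1].ca
                norm = np.linalg.norm(gap)
                if norm > 0:
                    shift = -gap + gap / norm * CA_STEP
        residues = [Residue(r.author_number, r.ca, r.insertion_code, r.ss3) for r in n_part]
        residues += [
            Residue(r.author_number, rot @ r.ca + shift, r.insertion_code, r.ss3)
            for r in c_part
        ]
        return ProteinChain(chain.chain_id + "_del", residues)
    raise ValueError(f"unknown indel mode {mode!r}")


def tandem_repeat(
    chain: ProteinChain, k: int, linker_length: int = 4
) -> ProteinChain:
    """Concatenate k rigid translated copies of ``chain`` joined by straight
    coil linkers.

    Copies are pure translations, so any two repeat units superpose with
    zero RMSD.  Translation is along x by the unit's x-extent plus a margin,
    keeping copies clash-free.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    coords = chain.coords
    extent = float(coords[:, 0].max() - coords[:, 0].min())
    offset = np.array([extent + 2.0 * CA_STEP, 0.0, 0.0])
    residues: list[Residue] = []
    for copy in range(k):
        shift = copy * offset
        if copy > 0 and linker_length > 0:
            a = residues[-1].ca
            b = chain.residues[0].ca + shift
            ts = np.linspace(0.0, 1.0, linker_length + 2)[1:-1]
            for t in ts:
                residues.append(Residue(author_number=0, ca=a + t * (b - a), ss3="C"))
        for r in chain.residues:
            residues.append(Residue(r.author_number, r.ca + shift, r.insertion_code, r.ss3))
    for i, r in enumerate(residues):
        r.author_number = i + 1
    return ProteinChain(chain.chain_id + f"_x{k}", residues)
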