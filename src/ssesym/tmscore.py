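"""TM-score computation by Kabsch superposition with iterative refinement.

The TM-score between two Cα sets under a residue correspondence is

    TM = max over superpositions of (1/Lt) * sum_i 1 / (1 + (d_i/d0)^2)

with d0 = max(1.24 * (Lt - 15)^(1/3) - 1.8, 0.5) and Lt the length of the
normalization chain.  The maximization follows the classic strategy:
superpositions are seeded from contiguous alignment fragments of several
lengths, then refined by repeatedly refitting on the pairs that fall under
a distance cutoff until the included set is stable.

``tm_align_sequential`` builds the correspondence itself — a sequence-order
respecting alignment obtained by dynamic programming over superposed
distances, iterated with superposition re-estimation from several initial
registers (identity, gapless threadings, secondary-structure alignment).
It is deliberately lighter than a full TM-align reimplementation: in this
pipeline alignments are short and pre-seeded by SSE correspondences, so a
handful of initials suffices.  An external TM-align binary can be plugged
in for bit-faithful replication.
"""

from __future__ import annotations

import re
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chain import ProteinChain

DP_GAP = 0.6  # gap penalty in the distance-score dynamic program
MAX_REFINE = 30
MAX_ALIGN_ITER = 6


@dataclass
class Superposition:
    """Rigid transform mapping the second coordinate set onto the first."""

    rotation: np.ndarray  # 3x3, proper (det +1)
    translation: np.ndarray  # 3-vector, Å
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class TMResult:
    tm: float
    d0: float
    normalized_length: int
    aligned_pairs: list[tuple[int, int]]
    superposition: Superposition | None = None
    provenance: str = "internal"


def d0_scale(lt: int) -> float:
    """Length-dependent distance scale; floored at 0.5 Å for short chains."""
    return max(1.24 * np.cbrt(lt - 15.0) - 1.8, 0.5)


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares superposition of ``coords_b`` onto ``coords_a``.

    Reflections are excluded; degenerate (strictly collinear) inputs raise.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must be matching (N, 3) arrays")
    if len(a) < 3:
        raise ValueError("need at least 3 points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) coordinates")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ca - rot @ cb
    diff = (b @ rot.T + trans) - a
    rmsd = float(np.sqrt((diff**2).sum() / len(a)))
    return Superposition(rot, trans, rmsd)


def _score_from_distances(d: np.ndarray, d0: float, lt: int) -> float:
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / lt)


def _refine(
    pa: np.ndarray, pb: np.ndarray, seed_sel: np.ndarray, d0: float, lt: int
) -> tuple[float, Superposition | None]:
    """Cutoff refinement from one seed selection; returns best (tm, sup)."""
    best_tm, best_sup = 0.0, None
    sel = seed_sel
    dcut = max(d0, 4.5)
    for _ in range(MAX_REFINE):
        if sel.sum() < 3:
            break
        try:
            sup = kabsch(pa[sel], pb[sel])
        except ValueError:
            break
        d = np.linalg.norm(sup.apply(pb) - pa, axis=1)
        tm = _score_from_distances(d, d0, lt)
        if tm > best_tm:
            best_tm, best_sup = tm, sup
        new_sel = d < dcut
        while new_sel.sum() < 3 and dcut < 50.0:
            dcut += 0.5
            new_sel = d < dcut
        if np.array_equal(new_sel, sel):
            break
        sel = new_sel
    return best_tm, best_sup


def tm_score(
    chain_a: ProteinChain,
    chain_b: ProteinChain,
    pairs: list[tuple[int, int]],
    normalize_on: str = "shorter",
) -> TMResult:
    """TM-score of a fixed residue correspondence.

    ``pairs`` are (index in chain_a, index in chain_b); the correspondence
    is kept fixed and only the superposition is optimized.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 aligned pairs")
    lt = _normalized_length(len(chain_a), len(chain_b), normalize_on)
    d0 = d0_scale(lt)
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    pa = chain_a.coords[ia]
    pb = chain_b.coords[ib]
    n = len(pairs)
    best_tm, best_sup = 0.0, None
    seed_lengths = sorted({n, max(n // 2, 4), max(n // 4, 4)}, reverse=True)
    for sl in seed_lengths:
        if sl > n:
            continue
        step = max(1, (n - sl) // 10) if sl < n else 1
        for start in range(0, n - sl + 1, step):
            sel = np.zeros(n, dtype=bool)
            sel[start : start + sl] = True
            tm, sup = _refine(pa, pb, sel, d0, lt)
            if tm > best_tm:
                best_tm, best_sup = tm, sup
    if best_sup is None:
        raise ValueError("no valid superposition found (degenerate input?)")
    return TMResult(best_tm, d0, lt, list(pairs), best_sup)


def _normalized_length(la: int, lb: int, normalize_on: str) -> int:
    if normalize_on == "a":
        return la
    if normalize_on == "b":
        return lb
    if normalize_on == "shorter":
        return min(la, lb)
    raise ValueError(f"unknown normalize_on {normalize_on!r}")


def _dp_trace(sim: np.ndarray, gap: float) -> list[tuple[int, int]]:
    """Sequence-order alignment maximizing sum(sim) - gap penalties, with
    free end gaps; returns matched index pairs."""
    la, lb = sim.shape
    h = np.zeros((la + 1, lb + 1))
    jj = np.arange(lb + 1)
    for i in range(1, la + 1):
        diag = h[i - 1, :-1] + sim[i - 1, :]
        up = h[i - 1, 1:] - gap
        pre = np.maximum(diag, up)
        pre = np.concatenate(([h[i - 1, 0] - gap], pre))
        pre[0] = 0.0  # free gap in leading column
        a = pre + gap * jj
        h[i] = np.maximum.accumulate(a) - gap * jj
        h[i, 0] = 0.0
    # free end gaps: start traceback at the best cell on the last row/col
    end_candidates = [(h[la, j], la, j) for j in range(lb + 1)]
    end_candidates += [(h[i, lb], i, lb) for i in range(la + 1)]
    _, i, j = max(end_candidates, key=lambda x: (x[0], -x[1], -x[2]))
    pairs: list[tuple[int, int]] = []
    while i > 0 and j > 0:
        if abs(h[i][j] - (h[i - 1][j - 1] + sim[i - 1][j - 1])) < 1e-9:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif abs(h[i][j] - (h[i - 1][j] - gap)) < 1e-9 or (
            j == lb and abs(h[i][j] - h[i - 1][j]) < 1e-9
        ):
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def _sim_matrix(
    coords_a: np.ndarray, coords_b_t: np.ndarray, d0: float
) -> np.ndarray:
    diff = coords_a[:, None, :] - coords_b_t[None, :, :]
    d2 = np.sum(diff**2, axis=2)
    return 1.0 / (1.0 + d2 / d0**2)


def _quick_tm(
    pa: np.ndarray, pb: np.ndarray, d0: float, lt: int
) -> float:
    try:
        sup = kabsch(pa, pb)
    except ValueError:
        return 0.0
    d = np.linalg.norm(sup.apply(pb) - pa, axis=1)
    return _score_from_distances(d, d0, lt)


def _initial_pairings(
    chain_a: ProteinChain, chain_b: ProteinChain, d0: float, lt: int
) -> list[list[tuple[int, int]]]:
    la, lb = len(chain_a), len(chain_b)
    ca, cb = chain_a.coords, chain_b.coords
    inits: list[list[tuple[int, int]]] = []
    # identity register
    nmin = min(la, lb)
    inits.append([(i, i) for i in range(nmin)])
    # gapless threadings, ranked by quick TM; fractional offsets are added
    # explicitly so permuted-register matches (e.g. half-length shifts) are
    # always among the candidates
    step = max(4, (la + lb) // 24)
    offsets = set(range(-(lb - 8), la - 8 + 1, step))
    for frac in (2, 3, 4):
        offsets.update({la // frac, -(lb // frac)})
    scored: list[tuple[float, list[tuple[int, int]]]] = []
    for off in sorted(offsets):
        pairs = [(i, i - off) for i in range(max(0, off), min(la, lb + off))]
        if len(pairs) < 8:
            continue
        ia = np.array([p[0] for p in pairs])
        ib = np.array([p[1] for p in pairs])
        scored.append((_quick_tm(ca[ia], cb[ib], d0, lt), pairs))
    scored.sort(key=lambda x: -x[0])
    inits.extend(p for _, p in scored[:4])
    # secondary-structure register
    match = {("H", "H"): 1.0, ("E", "E"): 1.0, ("C", "C"): 0.2}
    sim = np.array(
        [[match.get((x, y), -0.5) for y in chain_b.ss3] for x in chain_a.ss3]
    )
    ss_pairs = _dp_trace(sim, gap=0.6)
    if len(ss_pairs) >= 8:
        inits.append(ss_pairs)
    return inits


def tm_align_sequential(
    chain_a: ProteinChain,
    chain_b: ProteinChain,
    normalize_on: str = "shorter",
    tmalign_bin: str | None = None,
) -> TMResult:
    """Sequence-order-respecting structural alignment and TM-score.

    Internal path: distance-matrix DP iterated with superposition
    re-estimation from several initial registers.  If ``tmalign_bin`` is
    set, shells out to an external TM-align executable instead.
    """
    if len(chain_a) < 5 or len(chain_b) < 5:
        raise ValueError("chains must have at least 5 residues")
    if tmalign_bin is not None:
        return _tm_align_external(chain_a, chain_b, normalize_on, tmalign_bin)
    lt = _normalized_length(len(chain_a), len(chain_b), normalize_on)
    d0 = d0_scale(lt)
    ca, cb = chain_a.coords, chain_b.coords
    best: TMResult | None = None
    for init in _initial_pairings(chain_a, chain_b, d0, lt):
        pairs = init
        seen: set[tuple] = set()
        for _it in range(MAX_ALIGN_ITER):
            if len(pairs) < 3:
                break
            try:
                result = tm_score(chain_a, chain_b, pairs, normalize_on)
            except ValueError:
                break
            if best is None or result.tm > best.tm:
                best = result
            key = tuple(pairs)
            if key in seen:
                break
            seen.add(key)
            sup = result.superposition
            sim = _sim_matrix(ca, sup.apply(cb), d0)
            pairs = _dp_trace(sim, DP_GAP)
    if best is None:
        raise ValueError("alignment failed: no valid superposition")
    return best


_TM_RE = re.compile(
    r"TM-score=\s*([0-9.]+)\s*\(.*normalized by length of Chain_([12])", re.I
)


def _tm_align_external(
    chain_a: ProteinChain,
    chain_b: ProteinChain,
    normalize_on: str,
    tmalign_bin: str,
) -> TMResult:
    """Adapter: run an external TM-align binary on temporary PDB files."""
    from .structure_io import write_pdb

    lt = _normalized_length(len(chain_a), len(chain_b), normalize_on)
    with tempfile.TemporaryDirectory(prefix="ssesym_tm") as tmp:
        pa = Path(tmp) / "a.pdb"
        pb = Path(tmp) / "b.pdb"
        write_pdb(chain_a, pa)
        write_pdb(chain_b, pb)
        proc = subprocess.run(
            [tmalign_bin, str(pa), str(pb)], capture_output=True, text=True
        )
    if proc.returncode != 0:
        raise RuntimeError(
            f"external TM-align failed (exit {proc.returncode}): {proc.stderr.strip()}"
        )
    by_chain: dict[str, float] = {}
    for m in _TM_RE.finditer(proc.stdout):
        by_chain[m.group(2)] = float(m.group(1))
    if not by_chain:
        raise RuntimeError("could not parse TM-score from external TM-align output")
    if normalize_on == "a":
        tm = by_chain.get("1")
    elif normalize_on == "b":
        tm = by_chain.get("2")
    else:
        key = "1" if len(chain_a) <= len(chain_b) else "2"
        tm = by_chain.get(key, max(by_chain.values()))
    if tm is None:
        raise RuntimeError("external TM-align output missing requested normalization")
    return TMResult(tm, d0_scale(lt), lt, [], None, provenance="external")
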