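"""Reading and writing chain coordinates and secondary-structure assignments.

Coordinates come from PDB or mmCIF files (via gemmi); only Cα atoms are
kept, first model only, alternate locations resolved to the highest
occupancy (ties to the first encountered).  Secondary structure can be
supplied three ways: a classic DSSP output file (parsed with Biopython and
reduced 8-state -> 3-state), a plain FASTA-like sidecar of H/E/C letters,
or the built-in Cα-geometry assigner for self-contained fixtures.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gemmi
import numpy as np

from .chain import ProteinChain, Residue

logger = logging.getLogger("ssesym")

# 8-state -> 3-state reduction; G (3-10 helix) and I (pi helix) fold into H,
# B (isolated bridge) into E, everything else is coil
DEFAULT_DSSP_REDUCTION = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
}


class ChainNotFoundError(KeyError):
    pass


class AssignmentNotFoundError(KeyError):
    pass


def read_chain(path, chain_id: str, format: str = "auto") -> ProteinChain:
    """Read one chain's Cα trace from a PDB/mmCIF file.

    ``chain_id`` is the chain name as it appears in the file; the returned
    chain is labelled ``<file stem>_<chain_id>`` with ss3 all-coil
    (assignment is a separate step).
    """
    path = Path(path)
    if format == "pdb":
        st = gemmi.read_pdb(str(path))
    elif format == "mmcif":
        st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
    elif format == "auto":
        st = gemmi.read_structure(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ChainNotFoundError(f"chain not found: {chain_id!r} in {path}")
    residues: list[Residue] = []
    dropped = 0
    for res in chain:
        best = None
        for atom in res:
            if atom.name != "CA":
                continue
            if best is None or atom.occ > best.occ:
                best = atom
        if best is None:
            dropped += 1
            continue
        residues.append(
            Residue(
                author_number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                ca=np.array([best.pos.x, best.pos.y, best.pos.z]),
            )
        )
    if dropped:
        logger.warning(
            "%s chain %s: dropped %d residue(s) lacking a Cα atom",
            path.name, chain_id, dropped,
        )
    if not residues:
        raise ValueError(f"empty chain: no Cα atoms in chain {chain_id!r}")
    return ProteinChain(f"{path.stem}_{chain_id}", residues)


def write_pdb(chain: ProteinChain, path) -> None:
    """Write the Cα trace as a single-chain PDB file (poly-ALA trace)."""
    st = gemmi.Structure()
    st.name = chain.chain_id
    model = gemmi.Model("1")
    ch = gemmi.Chain("A")
    for r in chain.residues:
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(r.author_number, r.insertion_code or " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*r.ca)
        atom.occ = 1.0
        res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def reduce_dssp_letter(ss8: str, reduction: dict[str, str] | None = None) -> str:
    table = DEFAULT_DSSP_REDUCTION if reduction is None else reduction
    return table.get(ss8, "C")


def apply_dssp_assignment(
    chain: ProteinChain,
    dssp_path,
    dssp_chain: str | None = None,
    reduction: dict[str, str] | None = None,
) -> ProteinChain:
    """Set ss3 from a classic DSSP output file.

    Residues are matched by (author number, insertion code) on the DSSP
    chain named ``dssp_chain`` (defaults to the letter after the last '_'
    in the chain id).  Residues absent from the DSSP record keep coil.
    Coordinates and chain length are never changed.
    """
    from Bio.PDB.DSSP import make_dssp_dict

    if dssp_chain is None:
        dssp_chain = chain.chain_id.rsplit("_", 1)[-1]
    dssp_dict, _keys = make_dssp_dict(str(dssp_path))
    by_residue: dict[tuple[int, str], str] = {}
    for (cid, res_id), values in dssp_dict.items():
        if cid != dssp_chain:
            continue
        _het, num, icode = res_id
        by_residue[(num, icode.strip())] = values[1]
    if not by_residue:
        raise AssignmentNotFoundError(
            f"assignment not found: chain {dssp_chain!r} absent from {dssp_path}"
        )
    ss3 = "".join(
        reduce_dssp_letter(
            by_residue.get((r.author_number, r.insertion_code), "-"), reduction
        )
        for r in chain.residues
    )
    return chain.with_ss3(ss3)


def read_ss3_sidecar(path) -> dict[str, str]:
    """Parse a FASTA-like sidecar: '>chain_id' header + H/E/C letters."""
    records: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif name is not None:
                parts.append(line)
    if name is not None:
        records[name] = "".join(parts)
    return records


def apply_ss3_sidecar(chain: ProteinChain, path) -> ProteinChain:
    """Apply a precomputed ss3 string from a sidecar file to the chain."""
    records = read_ss3_sidecar(path)
    if chain.chain_id in records:
        ss3 = records[chain.chain_id]
    elif len(records) == 1:
        ss3 = next(iter(records.values()))
    else:
        raise AssignmentNotFoundError(
            f"assignment not found: {chain.chain_id!r} not in {path}"
        )
    return chain.with_ss3(ss3)


# Cα-geometry windows (Å), from ideal-geometry distances: an α-helix has
# i->i+3 ≈ 5.1 and i->i+4 ≈ 6.2; an extended strand has i->i+2 ≈ 6.6 and
# i->i+3 ≈ 10.1.  P-SEA-style short-range distance criteria.
_HELIX_D3 = (4.2, 5.7)
_HELIX_D4 = (5.3, 7.0)
_STRAND_D2 = (5.9, 7.4)
_STRAND_D3 = (8.8, 10.8)


def assign_ss_geometric(chain: ProteinChain) -> ProteinChain:
    """Assign ss3 from Cα geometry alone (deterministic fallback assigner).

    Chains shorter than 5 residues get all-coil with a warning.
    """
    n = len(chain)
    if n < 5:
        logger.warning(
            "%s: chain too short for geometric assignment (%d residues)",
            chain.chain_id, n,
        )
        return chain.with_ss3("C" * n)
    coords = chain.coords

    def dist(i: int, j: int) -> float:
        return float(np.linalg.norm(coords[i] - coords[j]))

    labels = ["C"] * n
    for i in range(n - 4):
        d3 = dist(i, i + 3)
        d4 = dist(i, i + 4)
        if _HELIX_D3[0] <= d3 <= _HELIX_D3[1] and _HELIX_D4[0] <= d4 <= _HELIX_D4[1]:
            for k in range(i, i + 5):
                labels[k] = "H"
    for i in range(n - 3):
        if any(labels[k] == "H" for k in range(i, min(i + 4, n))):
            continue
        d2 = dist(i, i + 2)
        d3 = dist(i, i + 3)
        if _STRAND_D2[0] <= d2 <= _STRAND_D2[1] and _STRAND_D3[0] <= d3 <= _STRAND_D3[1]:
            for k in range(i, i + 4):
                if labels[k] == "C":
                    labels[k] = "E"
    # suppress singleton runs (cannot form an element)
    for i in range(n):
        left = labels[i - 1] if i > 0 else None
        right = labels[i + 1] if i < n - 1 else None
        if labels[i] != "C" and labels[i] != left and labels[i] != right:
            labels[i] = "C"
    return chain.with_ss3("".join(labels))
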