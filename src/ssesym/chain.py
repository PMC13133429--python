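"""Canonical in-memory representation of a protein chain.

The whole pipeline operates on Cα traces only: a chain is an ordered list of
residues, each carrying its author-assigned number, an optional insertion
code, a 3-vector of Cα coordinates (Å) and a 3-state secondary-structure
letter (H = helix, E = strand, C = coil).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

VALID_SS3 = frozenset("HEC")


@dataclass
class Residue:
    """One residue of a Cα trace."""

    author_number: int
    ca: np.ndarray
    insertion_code: str = ""
    ss3: str = "C"

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        if self.ca.shape != (3,) or not np.all(np.isfinite(self.ca)):
            raise ValueError("Cα coordinate must be a finite 3-vector")
        if self.ss3 not in VALID_SS3:
            raise ValueError(f"ss3 must be one of H/E/C, got {self.ss3!r}")


@dataclass
class ProteinChain:
    """An ordered Cα trace with secondary-structure labels.

    ``chain_id`` conventionally combines structure id and chain letter,
    e.g. ``"1u0a_A"``.
    """

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty chain")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of Cα coordinates in residue order."""
        return np.array([r.ca for r in self.residues], dtype=float)

    @property
    def ss3(self) -> str:
        return "".join(r.ss3 for r in self.residues)

    def with_ss3(self, ss3: str) -> "ProteinChain":
        """Return a copy with the given 3-state string applied."""
        if len(ss3) != len(self.residues):
            raise ValueError(
                f"ss3 length {len(ss3)} != chain length {len(self.residues)}"
            )
        bad = set(ss3) - VALID_SS3
        if bad:
            raise ValueError(f"invalid ss3 letters: {sorted(bad)}")
        residues = [replace(r, ss3=s) for r, s in zip(self.residues, ss3)]
        return ProteinChain(self.chain_id, residues)

    def subchain(self, start: int, stop: int, chain_id: str | None = None) -> "ProteinChain":
        """Residues ``[start, stop)`` as a new chain (labels preserved)."""
        if not (0 <= start < stop <= len(self.residues)):
            raise ValueError(f"invalid subchain range [{start}, {stop})")
        cid = chain_id if chain_id is not None else f"{self.chain_id}[{start}:{stop}]"
        return ProteinChain(cid, [replace(r) for r in self.residues[start:stop]])

    def reordered(self, order: list[int] | np.ndarray, chain_id: str | None = None) -> "ProteinChain":
        """Chain with residues permuted into the given index order."""
        cid = chain_id if chain_id is not None else self.chain_id
        return ProteinChain(cid, [replace(self.residues[i]) for i in order])
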