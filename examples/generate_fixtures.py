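"""Generate synthetic structures with planted rearrangements.

Writes a base chain, its circular permutant and an insertion variant as
PDB files with ss3 sidecars — the same inputs the CLI consumes — plus a
manifest of the planted ground truth.
"""

import json
from pathlib import Path

from ssesym import FixtureSpec, apply_indel, circular_permute, make_chain, write_pdb

outdir = Path("scratch/fixtures")
outdir.mkdir(parents=True, exist_ok=True)

base = make_chain(
    FixtureSpec(
        seed=7,
        elements=[("helix", 10), ("strand", 5), ("helix", 9),
                  ("strand", 9), ("helix", 10), ("strand", 9)],
        linker_length=4,
        chain_id="demo_A",
    )
)
variants = {
    "demo_A": base,
    "demo_A_cp": circular_permute(base, len(base) // 2),
    "demo_A_ins": apply_indel(base, 30, 45, mode="insert", seed=3),
}
manifest = []
for name, chain in variants.items():
    write_pdb(chain, outdir / f"{name}.pdb")
    (outdir / f"{name}.ss3").write_text(f">{name}\n{chain.ss3}\n")
    manifest.append({"chain_id": name, "n_residues": len(chain)})
    print(f"wrote {name}: {len(chain)} residues")
(outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
print(f"files under {outdir}/ — feed them to `ssesym cpscan/selfscan`.")
print("The permutant has identical coordinates in rotated residue order;")
print("the insertion variant carries a 45-residue coil insert (indel-scale).")
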