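# ssesym

Detection of circular permutations, indel mutations and internal symmetry
in protein tertiary structures, using secondary-structure-element (SSE)
strings as an ultra-compact structural alphabet.

## The problem and the approach

Circular permutations (a chain whose N- and C-terminal segments are swapped
relative to a homolog), indels and internal repeats are structural features
that residue-level comparison tools handle slowly or miss. `ssesym`
compresses each chain into a short token string — coil is discarded, each
maximal helix or strand run becomes one character whose case encodes the
element type (lowercase helix, uppercase-class strand) and whose letter
encodes a length bin (exact for lengths 2–10, width-2 bins for 11–30,
width-3 above) — and runs sequence algorithms on that alphabet:

- **Circular permutations** (query doubling): concatenating the query token
  string with itself makes a permuted match appear as one contiguous
  Smith–Waterman local alignment crossing the duplication seam. The
  detected boundary is mapped back to residues, the query is rearranged
  (C-segment moved in front), and both orders are verified with exact
  TM-scores. A CP requires a rearranged TM-score ≥ 0.5 with an improvement
  ≥ 0.1 over the native order; for two chains with identical coordinates
  and equal permuted segments, TM ≈ 0.5 in the original order rises to
  ≈ 1.0 after rearrangement.
- **Indels**: a cross-boundary hit whose two segment images on the partner
  chain are separated by ≥ 40 residues, or ≥ 60% of the smaller segment,
  is flagged as an indel pair (20–30-residue gaps are loop-variation noise).
- **Internal symmetry** (self-scanning): a window starting at 3 SSEs is
  extended one SSE at a time and aligned against the chain remainder; pairs
  verified at TM > 0.5 (≥ 3 SSEs per unit) are consolidated greedily
  (higher TM wins at a ≥ 0.05 margin, otherwise the longer residue span)
  and summarized into repeat counts = covered SSEs / minimal unit length.
- **Families**: chains linked by detected CPs form a pair graph clustered
  with Leiden (or deterministic connected components).

The TM-score engine is built in: Kabsch superposition with fragment-seeded,
distance-cutoff-refined optimization of
TM = (1/Lt) Σᵢ 1/(1 + (dᵢ/d0)²), d0 = max(1.24·(Lt−15)^⅓ − 1.8, 0.5),
plus a sequence-order-respecting aligner (iterated DP over superposed
distances). An external TM-align binary can be plugged in via the
`tmalign_bin` config key.

Inputs are PDB/mmCIF files (Cα only), with secondary structure from a
classic DSSP file (8→3-state reduction {H,G,I}→H, {E,B}→E, else C), a
FASTA-like ss3 sidecar, or a built-in Cα-geometry assigner. A synthetic
generator (ideal helices/strands, coil linkers, planted CP/indel/repeat
operators) makes the whole pipeline testable with no downloads.

## Worked example

```sh
python examples/detect_circular_permutation.py
```

```
query synth_A_cp vs target synth_A
boundary residue (author numbering): 1
TM-score, original order:   0.500
TM-score, rearranged order: 1.000
delta TM: 0.500  ->  is_cp = True
```

The fixture is a 72-residue chain of six ideal elements and its midpoint
circular permutant (identical coordinates, rotated residue order). In
native order only one half can superpose, giving TM = 0.5; after the
pipeline detects the seam and rearranges the query, the chains coincide
and TM = 1.0 — the analytic signature of an equal-segment permutant.
Other capabilities: `examples/encode_tokens.py` (tokenization and
compression ratio), `examples/find_internal_repeats.py` (self-scan),
`examples/cluster_cp_network.py` (communities),
`examples/generate_fixtures.py` (synthetic inputs for the CLI).

The same operations are exposed as a thin CLI:

```sh
ssesym encode chain.pdb --ss chain.ss3
ssesym cpscan --query q.pdb --target t.pdb --ss q.ss3 t.ss3 -o out.tsv
ssesym selfscan chain.pdb --ss chain.ss3 -o repeats.tsv
ssesym cluster out.tsv --method leiden -o communities.tsv
ssesym fixtures --spec spec.json -o fixtures/
```

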