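"""Find internal repeats by SSE self-scanning.

Builds a 3x tandem repeat (unit: helix-strand-helix, rigid translated
copies), slides the 3-SSE window against the chain remainder, consolidates
overlapping hits and summarizes repeat units.
"""

from ssesym import (
    FixtureSpec,
    classify_symmetric,
    consolidate,
    encode_chain,
    make_chain,
    scan_chain,
    summarize_repeats,
    tandem_repeat,
)

unit = make_chain(
    FixtureSpec(seed=5, elements=[("helix", 10), ("strand", 5), ("helix", 7)],
                linker_length=3)
)
chain = tandem_repeat(unit, 3, linker_length=3)
tokens = encode_chain(chain)

hits = scan_chain(chain, tokens)
kept = consolidate(hits)
summary = summarize_repeats(chain.chain_id, kept)

print(f"chain {chain.chain_id}: {len(chain)} residues, {len(tokens)} SSEs")
print(f"scan produced {len(hits)} verified hits, {len(kept)} after consolidation")
for h in kept:
    print(f"  unit {h.left_range} ~ unit {h.right_range}  TM={h.tm:.3f}")
print(f"repeat count: {summary.repeat_count} "
      f"(minimal unit: {summary.min_unit_length} SSEs)")
print(f"symmetric: {classify_symmetric(summary, kept)}")
print("Units are SSE-index intervals; the repeat count is total covered")
print("SSEs divided by the minimal unit length within each repeat region.")
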