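# Methods

## SSE encoding

Secondary structure is reduced to three states (H helix, E strand, C coil).
The 8→3 reduction used for DSSP input is {H, G, I} → H, {E, B} → E,
everything else (T, S, P, blank) → C; the table is configurable because
assignment schemes differ at G/I/B membership. Maximal H/E runs of at least
`min_segment_length` residues (default 2, matching the first token bin)
become segments; shorter runs and all coil are discarded. Token letters
encode length bins: exact for 2–10 (2→'A' … 10→'I'), width-2 bins for
11–30 (length 11 joins the first width-2 bin {11, 12} so the map is
gap-free and monotone), width-3 bins for 31 up to a configurable cap
(default 60), and a single overflow token above the cap. Helix tokens are
the lowercase-class counterparts of strand tokens. Thirty bins per class
exceed the Latin alphabet, so the strand symbol set extends into digits and
the helix set into a fixed punctuation range; `ssesym encode
--dump-alphabet` emits the full map for bit-exact reproducibility.

The compression ratio is an information-length ratio:
(residue count × residue-alphabet entropy) / (token count × token-alphabet
entropy), with entropies either empirical over a corpus or the maximal
log₂(alphabet size). It is a metric only; its value depends on the corpus.

## Token alignment

Local alignment uses Smith–Waterman with affine, element-specific gaps:
the penalty charged for each skipped token is the gap-open/extend penalty
of that token's class. Defaults are −4/−1 for both classes (the source
work's genetically optimized matrix is not published; any matrix can be
loaded from JSON). The default substitution matrix scores same-class pairs
as 4 − |Δbin| (floored at −2) and cross-class pairs at −4, so identical
tokens beat near-length tokens beat cross-type matches. Tie-breaking is
deterministic: diagonal over vertical over horizontal, traceback from the
highest cell with ties at the smallest (row, col), so outputs are
bit-stable. `prescreen_score` is a cheap monotone surrogate in [0, 1]
(mean of self-score-normalized alignment score and identity × coverage,
anchored at 1.0 for identical sequences and 0.0 for empty alignments); it
replaces the learned TM regressor of the upstream search work and only
gates which candidates reach exact TM verification — accepted hits are
always re-verified, so the surrogate affects recall and speed, not the
correctness of accepted calls.

## TM-score engine

Given a fixed residue correspondence, TM = max over superpositions of
(1/Lt) Σ 1/(1 + (dᵢ/d0)²) with d0 = max(1.24(Lt−15)^⅓ − 1.8, 0.5) Å; the
floor keeps d0 positive for Lt ≤ 21. The maximization seeds Kabsch
superpositions from contiguous alignment fragments of lengths
{L, L/2, L/4} (≥ 4) at stepped starts and refines each by refitting on
pairs under a distance cutoff (starting at max(d0, 4.5) Å, relaxed in
0.5 Å steps when fewer than three pairs survive) until the included set is
stable. Kabsch uses SVD with reflection exclusion; strictly collinear
point sets are rejected (and skipped inside refinement loops).

The sequence-order aligner (`tm_align_sequential`) is deliberately lighter
than a full TM-align reimplementation — in this pipeline alignments are
short and pre-seeded by SSE correspondences. Initial registers are the
identity pairing, gapless threadings at stepped offsets plus explicit
fractional offsets (±L/2, ±L/3, ±L/4, so permuted-register matches are
always candidates), and a secondary-structure-string alignment. Each
initial is iterated (≤ 6 rounds): superpose on the current pairs, rebuild
the similarity matrix 1/(1 + d²/d0²), realign by dynamic programming with
free end gaps and a 0.6 gap penalty, and keep the best TM seen.
Normalization defaults to the shorter chain (`normalize_on` is
configurable; unit-vs-unit comparisons in symmetry checks always use the
shorter). An external TM-align binary can replace the internal path via
`tmalign_bin`; chains are exchanged as temporary PDB files and the
printed normalized scores are parsed.

## Duplication pipeline

Chains need ≥ 5 SSEs. The query token string is doubled and aligned to the
target; a hit is cross-boundary iff its aligned query indices span the seam
at |query|. The boundary token is the first aligned doubled index
modulo |query| — the cut that produced the permutant — and maps to the
start residue of its backing segment, with any preceding coil assigned to
the N-side segment. This convention reconstructs the original chain
exactly when the planted permutation cut at an SSE start; a cut inside a
linker is recovered to within the linker's length. The rearranged query is
the circular permutation at that residue. Decision rules, all
config-exposed with these defaults: CP iff rearranged TM ≥ 0.5 and
ΔTM ≥ 0.1; indel iff the unaligned target span between the two
cross-boundary block images is ≥ 40 residues or ≥ 60% of the smaller query
segment; split-symmetry iff the two halves at the boundary (each ≥ 3 SSEs)
align at TM ≥ 0.5 normalized on the shorter half. Each unordered pair is
evaluated in both role assignments (doubling applies to the query only)
and the record with the better rearranged TM is kept.

## Self-scanning

For each left start position the window grows from 3 SSEs until fewer than
3 SSEs remain beyond it (a 19-SSE chain gives 14 extensions per start);
the window tokens are aligned against the remainder, and aligned subranges
with ≥ 3 SSEs on both sides are verified with the exact TM engine on the
back-mapped residue ranges (never the prescreen), retaining TM > 0.5
(strict, config-exposed). Consolidation processes candidates sorted by
start position; two hits conflict when their covered SSE sets overlap by
more than half of either; at a TM margin ≥ 0.05 the higher score wins,
otherwise the longer residue span. The pass is idempotent. Surviving unit
ranges become graph nodes, edges join the two units of each hit and any
overlapping ranges; connected components are split where SSE coverage
gaps by ≥ 3, and each sub-region contributes covered-SSEs // minimal-unit-
length repeats. Identical adjacent units can consolidate into double-size
units (a 4× repeat may be counted as 2 larger units); counts never exceed
the planted multiplicity. Boundary-shift statistics are reported only as
diagnostics; unit sizing authority is the component summarization.

## Synthetic generator

Fixtures are Cα-only chains from ideal geometry: helices with 2.3 Å
radius, 1.5 Å rise and 100°/residue twist; strands as 3.8 Å zigzags with
3.3 Å axial rise; elements are placed with seeded random orientations and
joined by self-avoiding random-walk coil linkers (3.8 Å steps, 2.5 Å clash
tolerance, up to 100 resamples). Ground-truth ss3 is set at construction,
so encoding tests are independent of any assigner. Operators plant the
events the pipeline must invert: `circular_permute` reorders residues with
coordinates untouched; `insert` splices a seeded coil walk (translating
the C-part to follow); `delete` removes a span and rigidly rejoins the
C-part so the local frame continues where the deleted span began (an ideal
helix shortens into an ideal helix); `tandem_repeat` lays down rigid
translated copies joined by straight interpolated linkers, so units
superpose with zero RMSD. What the generator does not emulate: real
packing, loop conformational diversity, distorted or kinked elements, and
sequence-level features. Passing tests therefore demonstrate correctness
of the algorithms and thresholds on clean geometry, not detection
sensitivity on real structures — on experimental data the limiting factors
are assignment noise and non-ideal element geometry.

The geometric fallback assigner uses Cα-only distance windows derived from
ideal geometry (helix: d(i,i+3) ∈ [4.2, 5.7] and d(i,i+4) ∈ [5.3, 7.0] Å;
strand: d(i,i+2) ∈ [5.9, 7.4] and d(i,i+3) ∈ [8.8, 10.8] Å), with helix
taking precedence and singleton labels suppressed. It is a convenience for
self-contained inputs; DSSP output or precomputed ss3 sidecars are the
intended production path.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for a single CPU: the equal-half
CP fixture is 72 residues (six elements, two equal 36-residue halves);
boundary recovery uses 50 seeded fixtures of 6–8 SSEs; alignment-oracle
equivalence covers every token pair of length ≤ 3 over a 4-token alphabet
plus 3,000 seeded longer pairs (~10⁴ cases); the random-chain null for the
sequential aligner uses 25 pairs of 50-residue walks and the self-scan
null 20 chains; planted-repeat sweeps use k ∈ {2, 3, 4} with three seeds
each. Floating-point ties in DP tracebacks are resolved with a 1e-9
tolerance; Leiden uses seed 42 and resolution 1.0 by default (both
config-exposed); community edges are unweighted for clustering, with TM
weights retained for reporting.

## Known limitations

Only single-seam (two-fold) permutations are modeled; multi-boundary
rearrangements and open-vs-closed symmetry classification are out of
scope. Chains with sparse or short SSEs (< 5 elements) are filtered, and
detection weakens when element token strings are nearly uniform (e.g.
long runs of identical helix bins). The internal sequential aligner is not
a drop-in TM-align replacement for arbitrary remote homologs; for
publication-grade numbers on real structures, configure `tmalign_bin`.
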