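"""Query-doubling pipeline: seam detection, rearrangement verification,
CP/indel/symmetry classification."""

import pytest

from ssesym import (
    FixtureSpec,
    PipelineConfig,
    TokenSequence,
    apply_indel,
    circular_permute,
    classify_symmetry_by_split,
    default_matrix,
    double_and_align,
    encode_chain,
    make_chain,
    run_pair,
    tandem_repeat,
)
from ssesym.duplication import BelowSSECountError, indel_flag, rearrange_and_verify
from ssesym.encoding import HELIX, STRAND, SSESegment

from conftest import EQUAL_HALF_ELEMENTS


def tokens_from_string(s: str, chain_id="x") -> TokenSequence:
    segs = [SSESegment(HELIX if c.islower() else STRAND, 10 * i, 10 * i + 5)
            for i, c in enumerate(s)]
    return TokenSequence(chain_id, list(s), segs)


@pytest.fixture(scope="module")
def matrix():
    return default_matrix()


@pytest.fixture(scope="module")
def cp_pair():
    chain = make_chain(FixtureSpec(seed=11, elements=EQUAL_HALF_ELEMENTS, linker_length=4))
    tokens = encode_chain(chain)
    cut = tokens.segments[3].start_res
    return circular_permute(chain, cut), chain


class TestDoubleAndAlign:
    def test_permuted_tokens_cross_the_seam(self, matrix):
        q = tokens_from_string("deabc")  # 'abcde' cut at token 3
        t = tokens_from_string("abcde")
        hit = double_and_align(q, t, matrix)
        assert hit.crosses_seam
        assert hit.boundary_token == 2  # 'abc' block starts at query index 2
        assert len(hit.alignment.aligned_pairs) == 5

    def test_boundary_maps_to_original_cut_index(self, matrix):
        """Query 'abcde' against target 'deabc': the doubled query aligns
        across the seam and the cut maps to original token index 3."""
        hit = double_and_align(
            tokens_from_string("abcde"), tokens_from_string("deabc"), matrix
        )
        assert hit.crosses_seam
        assert hit.boundary_token == 3
        assert hit.query_tokens_pre == [3, 4]
        assert hit.query_tokens_post == [0, 1, 2]

    def test_identical_sequences_do_not_cross(self, matrix):
        q = tokens_from_string("abcde")
        hit = double_and_align(q, tokens_from_string("abcde"), matrix)
        assert not hit.crosses_seam

    def test_few_sse_rejected(self, matrix):
        with pytest.raises(BelowSSECountError, match="below SSE-count"):
            double_and_align(
                tokens_from_string("abcd"), tokens_from_string("abcde"), matrix
            )


class TestIndelRule:
    config = PipelineConfig()

    @pytest.mark.parametrize(
        "gap,n_len,c_len,expected",
        [
            (40, 200, 200, True),   # absolute threshold, inclusive
            (39, 200, 200, False),
            (30, 50, 80, True),     # 30 >= 0.6 * 50
            (29, 50, 80, False),    # 29 < 30 and < 40
            (45, 300, 300, True),
            (20, 100, 150, False),  # minor loop variation regime
        ],
    )
    def test_threshold_edges(self, gap, n_len, c_len, expected):
        assert indel_flag(gap, n_len, c_len, self.config) is expected

    def test_fractional_edge_exact(self):
        # gap exactly at 60% of the smaller segment flips the flag
        assert indel_flag(30, 50, 100, self.config) is True
        assert indel_flag(29, 50, 100, self.config) is False


class TestRearrangeAndVerify:
    def test_equal_half_cp_pair(self, cp_pair, matrix):
        perm, chain = cp_pair
        qt, tt = encode_chain(perm), encode_chain(chain)
        hit = double_and_align(qt, tt, matrix)
        assert hit.crosses_seam
        rec = rearrange_and_verify(perm, chain, qt, tt, hit)
        assert rec.tm_original == pytest.approx(0.5, abs=0.08)
        assert rec.tm_rearranged == pytest.approx(1.0, abs=0.02)
        assert rec.is_cp
        assert not rec.is_indel

    def test_recomputing_tm_from_serialized_segments_reproduces_value(
        self, cp_pair, matrix
    ):
        from ssesym import tm_align_sequential

        perm, chain = cp_pair
        qt, tt = encode_chain(perm), encode_chain(chain)
        hit = double_and_align(qt, tt, matrix)
        rec = rearrange_and_verify(perm, chain, qt, tt, hit)
        cut = rec.segment_c[0]
        rebuilt = circular_permute(perm, cut)
        again = tm_align_sequential(rebuilt, chain, "shorter")
        assert again.tm == pytest.approx(rec.tm_rearranged, abs=1e-9)

    def test_cp_with_long_insertion_flags_indel(self, matrix):
        chain = make_chain(
            FixtureSpec(seed=21, elements=EQUAL_HALF_ELEMENTS, linker_length=4)
        )
        tokens = encode_chain(chain)
        cut = tokens.segments[3].start_res
        perm = circular_permute(chain, cut)
        target = apply_indel(chain, tokens.segments[3].start_res, 45,
                             mode="insert", seed=5)
        recs = run_pair(perm, target)
        assert recs
        assert recs[0].is_indel
        assert recs[0].gap_residues >= 40


class TestSymmetryBySplit:
    def test_tandem_duplication_is_symmetric(self):
        unit = make_chain(
            FixtureSpec(seed=5, elements=[("helix", 10), ("strand", 5), ("helix", 7)],
                        linker_length=3)
        )
        doubled = tandem_repeat(unit, 2, linker_length=3)
        tokens = encode_chain(doubled)
        sym, res = classify_symmetry_by_split(doubled, tokens, 3)
        assert sym
        assert res.tm > 0.95

    def test_incompatible_halves_not_symmetric(self):
        chain = make_chain(
            FixtureSpec(
                seed=6,
                elements=[("helix", 10), ("helix", 8), ("helix", 12),
                          ("strand", 4), ("strand", 6), ("strand", 5)],
                linker_length=4,
            )
        )
        tokens = encode_chain(chain)
        sym, res = classify_symmetry_by_split(chain, tokens, 3)
        assert not sym
        assert res.tm < 0.5

    def test_half_with_two_sse_rejected(self):
        chain = make_chain(
            FixtureSpec(seed=7, elements=EQUAL_HALF_ELEMENTS, linker_length=4)
        )
        tokens = encode_chain(chain)
        with pytest.raises(ValueError, match="half too short"):
            classify_symmetry_by_split(chain, tokens, 2)


class TestRunPair:
    def test_cp_fixture_yields_cp_record(self, cp_pair):
        perm, chain = cp_pair
        recs = run_pair(perm, chain)
        assert len(recs) == 1
        assert recs[0].is_cp

    def test_identical_chains_yield_no_cp(self):
        chain = make_chain(
            FixtureSpec(seed=13, elements=EQUAL_HALF_ELEMENTS, linker_length=4)
        )
        recs = run_pair(chain, chain)
        assert all(not r.is_cp for r in recs)

    def test_all_coil_chain_rejected(self):
        chain = make_chain(
            FixtureSpec(seed=13, elements=EQUAL_HALF_ELEMENTS, linker_length=4)
        )
        coil = chain.with_ss3("C" * len(chain))
        with pytest.raises(BelowSSECountError):
            run_pair(coil, chain)

    def test_role_swap_agrees_on_rearranged_tm(self, cp_pair):
        perm, chain = cp_pair
        fwd = run_pair(perm, chain)[0]
        rev = run_pair(chain, perm)[0]
        assert fwd.tm_rearranged == pytest.approx(rev.tm_rearranged, abs=0.05)
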