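"""Tokenization: run segmentation, length binning, compression statistics."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssesym import (
    FixtureSpec,
    TokenSequence,
    compression_ratio,
    encode_chain,
    length_to_token,
    make_chain,
    segment_ss3,
)
from ssesym.chain import ProteinChain, Residue
from ssesym.encoding import (
    HELIX,
    STRAND,
    bin_index,
    empirical_entropy,
    n_bins,
    token_info,
)


def chain_from_ss3(ss3: str) -> ProteinChain:
    residues = [
        Residue(author_number=i + 1, ca=[3.8 * i, 0.0, 0.0], ss3=s)
        for i, s in enumerate(ss3)
    ]
    return ProteinChain("toy_A", residues)


@pytest.mark.parametrize(
    "ss3,expected",
    [
        ("CCHHHHCCEEECC", [(HELIX, 2, 6), (STRAND, 8, 11)]),
        ("CCCCC", []),
        ("HEHEH", []),  # all runs length 1 are discarded
        ("HHHHH", [(HELIX, 0, 5)]),
        ("HHEE", [(HELIX, 0, 2), (STRAND, 2, 4)]),
    ],
)
def test_segment_ss3_runs(ss3, expected):
    segs = segment_ss3(chain_from_ss3(ss3), min_segment_length=2)
    assert [(s.ss_type, s.start_res, s.end_res) for s in segs] == expected


@pytest.mark.parametrize(
    "length,ss_type,token",
    [
        (2, STRAND, "A"),
        (3, STRAND, "B"),
        (3, HELIX, "b"),
        (10, STRAND, "I"),
        (11, STRAND, "J"),   # first width-2 bin {11,12}
        (12, STRAND, "J"),
        (13, STRAND, "K"),
        (30, STRAND, "S"),
        (31, STRAND, "T"),   # first width-3 bin {31,32,33}
        (33, STRAND, "T"),
        (34, STRAND, "U"),
        (60, HELIX, "$"),    # last regular bin under the default cap
        (61, STRAND, "3"),   # overflow
        (500, STRAND, "3"),
    ],
)
def test_length_to_token_bins(length, ss_type, token):
    assert length_to_token(length, ss_type) == token


def test_length_below_two_rejected():
    with pytest.raises(ValueError, match="too short"):
        length_to_token(1, STRAND)


def test_encode_chain_composes_segmentation_and_tokens():
    ts = encode_chain(chain_from_ss3("CCHHHHCCEEECC"))
    assert ts.string == "cB"
    assert [(s.start_res, s.end_res) for s in ts.segments] == [(2, 6), (8, 11)]
    assert encode_chain(chain_from_ss3("CCCCC")).string == ""
    assert encode_chain(chain_from_ss3("HHH")).string == "b"


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    la=st.integers(min_value=2, max_value=120),
    lb=st.integers(min_value=2, max_value=120),
    ta=st.sampled_from([HELIX, STRAND]),
    tb=st.sampled_from([HELIX, STRAND]),
)
def test_tokenization_injective_on_type_and_bin(la, lb, ta, tb):
    """Distinct (type, bin) pairs never share a token; equal pairs always do."""
    tok_a = length_to_token(la, ta)
    tok_b = length_to_token(lb, tb)
    same = (ta, bin_index(la)) == (tb, bin_index(lb))
    assert (tok_a == tok_b) == same
    assert token_info(tok_a) == (ta, bin_index(la))


def test_case_classes_are_disjoint():
    nb = n_bins()
    strand_toks = {length_to_token(l, STRAND) for l in range(2, 70)}
    helix_toks = {length_to_token(l, HELIX) for l in range(2, 70)}
    assert not strand_toks & helix_toks
    assert len(strand_toks) == nb and len(helix_toks) == nb


def test_encode_is_stable_under_reencoding():
    chain = make_chain(
        FixtureSpec(
            seed=8, elements=[("helix", 11), ("strand", 4)], linker_length=3
        )
    )
    ts1 = encode_chain(chain)
    # rebuild an ss3 string from the segment back-map and re-encode
    ss3 = ["C"] * len(chain)
    for seg in ts1.segments:
        for i in range(seg.start_res, seg.end_res):
            ss3[i] = "H" if seg.ss_type == HELIX else "E"
    ts2 = encode_chain(chain.with_ss3("".join(ss3)))
    assert ts1.tokens == ts2.tokens
    assert ts1.segments == ts2.segments


def test_segments_never_overlap():
    chain = make_chain(
        FixtureSpec(
            seed=12,
            elements=[("helix", 6), ("strand", 3), ("helix", 4)],
            linker_length=2,
        )
    )
    segs = encode_chain(chain).segments
    for a, b in zip(segs, segs[1:]):
        assert a.end_res <= b.start_res


def test_compression_ratio_arithmetic():
    ts = TokenSequence("x", ["a"] * 10, _dummy_segments(10))
    assert compression_ratio(100, ts, 4.0, 4.0) == pytest.approx(10.0)
    ts_same = TokenSequence("x", ["a"] * 100, _dummy_segments(100))
    assert compression_ratio(100, ts_same, 4.0, 4.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        compression_ratio(100, TokenSequence("x", [], []), 4.0, 4.0)


def _dummy_segments(n):
    from ssesym import SSESegment

    return [SSESegment(HELIX, 3 * i, 3 * i + 2) for i in range(n)]


def test_corpus_ratio_matches_entropy_oracle():
    """Corpus-level compression ratio equals a direct Shannon-entropy
    computation over generated chains."""
    chains = [
        make_chain(
            FixtureSpec(
                seed=100 + i,
                elements=[("helix", 5 + i % 7), ("strand", 3 + i % 5), ("helix", 4 + i % 3)],
                linker_length=3,
            )
        )
        for i in range(20)
    ]
    token_stream = []
    aa_total = tok_total = 0
    for c in chains:
        ts = encode_chain(c)
        token_stream.extend(ts.tokens)
        aa_total += len(c)
        tok_total += len(ts)
    h_tok = empirical_entropy(token_stream)
    # residue alphabet entropy: uniform 20-letter baseline for the toy corpus
    h_aa = math.log2(20)
    ratios = []
    for c in chains:
        ts = encode_chain(c)
        ratios.append(compression_ratio(len(c), ts, h_aa, h_tok))
    oracle = (aa_total * h_aa) / (tok_total * h_tok)
    pooled = sum(len(c) for c in chains) * h_aa / (tok_total * h_tok)
    assert pooled == pytest.approx(oracle)
    assert all(r > 1.0 for r in ratios)
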