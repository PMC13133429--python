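"""Compression of 3-state secondary-structure strings into SSE token strings.

A chain's per-residue H/E/C string is reduced to its topological core:
coil is discarded, maximal runs of H or E become single tokens, and the
token letter encodes the run length through a variable-resolution binning —
exact letters for lengths 2–10 (2 → 'A', 3 → 'B', …, 10 → 'I'), bins of
width 2 for lengths 11–30, bins of width 3 above that, with one overflow
token past a configurable cap.  Case encodes the element type: strands are
uppercase-class tokens, helices their lowercase-class counterparts.

Because the default cap (60) needs more bins than the Latin alphabet has
letters, the strand token set extends into digits and the helix set into a
fixed punctuation range; the full map is available via :func:`alphabet_table`.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .chain import ProteinChain

HELIX = "helix"
STRAND = "strand"

DEFAULT_CAP = 60
DEFAULT_MIN_SEGMENT = 2

# one symbol per length bin, index-aligned between the two classes
_STRAND_SYMBOLS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
_HELIX_SYMBOLS = "abcdefghijklmnopqrstuvwxyz!#$%&*+-/="


@dataclass(frozen=True)
class SSESegment:
    """A maximal helix or strand run, as half-open residue indices."""

    ss_type: str
    start_res: int
    end_res: int

    def __post_init__(self) -> None:
        if self.ss_type not in (HELIX, STRAND):
            raise ValueError(f"bad ss_type {self.ss_type!r}")
        if self.end_res <= self.start_res:
            raise ValueError("empty segment")

    @property
    def length(self) -> int:
        return self.end_res - self.start_res


@dataclass
class TokenSequence:
    """SSE tokens for one chain, with the back-map to residue ranges."""

    chain_id: str
    tokens: list[str] = field(default_factory=list)
    segments: list[SSESegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.segments):
            raise ValueError("tokens and segments must be index-aligned")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def string(self) -> str:
        return "".join(self.tokens)


def n_bins(cap: int = DEFAULT_CAP) -> int:
    """Number of length bins per element class, including the overflow bin."""
    if cap < 31 or (cap - 31) % 3 != 2:
        raise ValueError("cap must close a width-3 bin (31 + 3k + 2)")
    return 9 + 10 + (cap - 30) // 3 + 1


def bin_index(length: int, cap: int = DEFAULT_CAP) -> int:
    """Length bin: exact for 2–10, width 2 for 11–30, width 3 for 31–cap,
    overflow above cap."""
    if length < 2:
        raise ValueError("segment too short")
    if length <= 10:
        return length - 2
    if length <= 30:
        return 9 + (length - 11) // 2
    if length <= cap:
        return 19 + (length - 31) // 3
    return n_bins(cap) - 1


def length_to_token(length: int, ss_type: str, cap: int = DEFAULT_CAP) -> str:
    """Token character for a segment of the given length and class."""
    if ss_type not in (HELIX, STRAND):
        raise ValueError(f"bad ss_type {ss_type!r}")
    b = bin_index(length, cap)
    symbols = _STRAND_SYMBOLS if ss_type == STRAND else _HELIX_SYMBOLS
    if b >= len(symbols):
        raise ValueError(f"bin {b} exceeds token alphabet")
    return symbols[b]


def token_info(token: str) -> tuple[str, int]:
    """Inverse map: token character -> (ss_type, bin index)."""
    i = _STRAND_SYMBOLS.find(token)
    if i >= 0:
        return STRAND, i
    i = _HELIX_SYMBOLS.find(token)
    if i >= 0:
        return HELIX, i
    raise ValueError(f"unknown token {token!r}")


def alphabet_table(cap: int = DEFAULT_CAP) -> list[dict]:
    """Full token map (for --dump-alphabet): one row per (class, bin)."""
    rows = []
    nb = n_bins(cap)
    edges: list[tuple[int, int]] = [(l, l) for l in range(2, 11)]
    edges += [(l, l + 1) for l in range(11, 30, 2)]
    edges += [(l, min(l + 2, cap)) for l in range(31, cap + 1, 3)]
    edges += [(cap + 1, -1)]  # overflow, open-ended
    assert len(edges) == nb
    for b, (lo, hi) in enumerate(edges):
        for ss_type, symbols in ((STRAND, _STRAND_SYMBOLS), (HELIX, _HELIX_SYMBOLS)):
            rows.append(
                {"ss_type": ss_type, "bin": b, "token": symbols[b],
                 "min_len": lo, "max_len": hi}
            )
    return rows


def segment_ss3(
    chain: ProteinChain, min_segment_length: int = DEFAULT_MIN_SEGMENT
) -> list[SSESegment]:
    """Maximal H/E runs of the chain's ss3 string; runs shorter than
    ``min_segment_length`` are treated as coil and dropped."""
    ss3 = chain.ss3
    segments: list[SSESegment] = []
    i = 0
    n = len(ss3)
    while i < n:
        c = ss3[i]
        j = i
        while j < n and ss3[j] == c:
            j += 1
        if c in "HE" and j - i >= min_segment_length:
            segments.append(
                SSESegment(HELIX if c == "H" else STRAND, i, j)
            )
        i = j
    return segments


def encode_chain(
    chain: ProteinChain,
    min_segment_length: int = DEFAULT_MIN_SEGMENT,
    cap: int = DEFAULT_CAP,
) -> TokenSequence:
    """Chain -> SSE token sequence (segment_ss3 composed with tokenization)."""
    segments = segment_ss3(chain, min_segment_length)
    tokens = [length_to_token(s.length, s.ss_type, cap) for s in segments]
    return TokenSequence(chain.chain_id, tokens, segments)


def empirical_entropy(symbols: Iterable[str]) -> float:
    """Shannon entropy (bits/symbol) of the empirical symbol distribution."""
    counts = Counter(symbols)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty symbol stream")
    return -sum(
        (c / total) * math.log2(c / total) for c in counts.values()
    )


def compression_ratio(
    aa_length: int,
    token_seq: TokenSequence,
    aa_alphabet_entropy: float = math.log2(20),
    token_alphabet_entropy: float | None = None,
) -> float:
    """Information-length ratio of the residue string to its token string.

    ratio = (aa_length x H_aa) / (n_tokens x H_token); entropies may be
    empirical (from a corpus) or the maximal log2(alphabet size) defaults.
    """
    if aa_length < 1:
        raise ValueError("aa_length must be >= 1")
    if len(token_seq) == 0:
        raise ValueError("compression ratio undefined for empty token sequence")
    if token_alphabet_entropy is None:
        token_alphabet_entropy = math.log2(2 * n_bins())
    if aa_alphabet_entropy <= 0 or token_alphabet_entropy <= 0:
        raise ValueError("entropies must be positive")
    return (aa_length * aa_alphabet_entropy) / (
        len(token_seq) * token_alphabet_entropy
    )


def write_token_fasta(seqs: Iterable[TokenSequence], handle) -> None:
    for ts in seqs:
        handle.write(f">{ts.chain_id}\n{ts.string}\n")


def write_segment_tsv(seqs: Iterable[TokenSequence], handle) -> None:
    handle.write("chain_id\ttoken_index\ttoken\tss_type\tstart_res\tend_res\n")
    for ts in seqs:
        for i, (tok, seg) in enumerate(zip(ts.tokens, ts.segments)):
            handle.write(
                f"{ts.chain_id}\t{i}\t{tok}\t{seg.ss_type}\t{seg.start_res}\t{seg.end_res}\n"
            )
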