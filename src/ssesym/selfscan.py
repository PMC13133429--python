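"""Internal repeat and symmetry detection by SSE self-scanning.

A window that starts at three SSEs is slid along the token string: for each
left start position the window is extended rightward one SSE at a time
(until fewer than three SSEs remain beyond it) and locally aligned against
the remainder of the chain.  Candidate segment pairs are verified with the
exact TM engine on the back-mapped residue ranges and retained above TM
0.5 with at least three SSEs per substructure.  Overlapping candidates are
consolidated by sequential maximization — the higher TM-score wins when the
scores differ by at least 0.05, otherwise the longer residue span wins —
and the surviving unit ranges are grouped into connected components,
split at coverage gaps of three or more SSEs, and summarized as
repeat count = total boundary coverage / minimal unit length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx

from .alignment import SubstitutionMatrix, default_matrix, smith_waterman
from .chain import ProteinChain
from .config import PipelineConfig
from .encoding import TokenSequence
from .tmscore import tm_align_sequential

logger = logging.getLogger("ssesym")


@dataclass
class ScanHit:
    """One verified self-alignment: window unit vs downstream unit."""

    left_range: tuple[int, int]   # half-open SSE-index interval
    right_range: tuple[int, int]
    tm: float
    span_residues: int

    def covered(self) -> set[int]:
        return set(range(*self.left_range)) | set(range(*self.right_range))


@dataclass
class RepeatSummary:
    chain_id: str
    unit_boundaries: list[tuple[int, int]] = field(default_factory=list)
    min_unit_length: int = 0
    repeat_count: int = 0
    mean_unit_tm: float = 0.0


def window_schedule(n_sse: int, min_unit: int = 3) -> list[tuple[int, int]]:
    """(start, width) pairs of the scan: width grows from ``min_unit`` while
    at least ``min_unit`` SSEs remain beyond the window."""
    schedule = []
    for start in range(0, n_sse - 2 * min_unit + 1):
        for width in range(min_unit, n_sse - min_unit - start + 1):
            schedule.append((start, width))
    return schedule


def _residue_range(tokens: TokenSequence, sse_range: tuple[int, int]) -> tuple[int, int]:
    lo, hi = sse_range
    return tokens.segments[lo].start_res, tokens.segments[hi - 1].end_res


def scan_chain(
    chain: ProteinChain,
    tokens: TokenSequence,
    matrix: SubstitutionMatrix | None = None,
    config: PipelineConfig | None = None,
) -> list[ScanHit]:
    """Sliding-window self-alignment; returns TM-verified hits."""
    config = config or PipelineConfig()
    matrix = matrix or default_matrix(config.token_cap)
    n = len(tokens)
    mu = config.min_unit_sse
    if n < 2 * mu:
        raise ValueError(
            f"chain too short for self-scan: {n} SSEs, need {2 * mu}"
        )
    hits: list[ScanHit] = []
    seen: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    for start, width in window_schedule(n, mu):
        left_tokens = tokens.tokens[start : start + width]
        rest_offset = start + width
        rest_tokens = tokens.tokens[rest_offset:]
        aln = smith_waterman(left_tokens, rest_tokens, matrix)
        if aln.is_empty:
            continue
        lq, hq = aln.query_range
        lt, ht = aln.target_range
        left_range = (start + lq, start + hq)
        right_range = (rest_offset + lt, rest_offset + ht)
        if hq - lq < mu or ht - lt < mu:
            continue
        key = (left_range, right_range)
        if key in seen:
            continue
        seen.add(key)
        lres = _residue_range(tokens, left_range)
        rres = _residue_range(tokens, right_range)
        sub_l = chain.subchain(*lres)
        sub_r = chain.subchain(*rres)
        try:
            result = tm_align_sequential(sub_l, sub_r, normalize_on="shorter")
        except ValueError:
            continue
        if result.tm > config.scan_tm:
            hits.append(
                ScanHit(
                    left_range,
                    right_range,
                    result.tm,
                    span_residues=(lres[1] - lres[0]) + (rres[1] - rres[0]),
                )
            )
    logger.info("%s: self-scan retained %d hit(s)", chain.chain_id, len(hits))
    return hits


def _conflict(a: ScanHit, b: ScanHit) -> bool:
    """Redundant iff covered SSE sets overlap on more than half of either."""
    ca, cb = a.covered(), b.covered()
    inter = len(ca & cb)
    return inter > 0.5 * len(ca) or inter > 0.5 * len(cb)


def _winner(a: ScanHit, b: ScanHit, delta: float) -> ScanHit:
    if abs(a.tm - b.tm) >= delta:
        return a if a.tm > b.tm else b
    if a.span_residues != b.span_residues:
        return a if a.span_residues > b.span_residues else b
    if a.tm != b.tm:
        return a if a.tm > b.tm else b
    return a if a.left_range <= b.left_range else b


def consolidate(hits: list[ScanHit], delta: float = 0.05) -> list[ScanHit]:
    """Sequential maximization over overlapping candidates.

    Candidates are processed sorted by start position; on conflict the
    higher TM-score is kept when the difference reaches ``delta``,
    otherwise the longer residue span.  Idempotent.
    """
    ordered = sorted(hits, key=lambda h: (h.left_range, h.right_range))
    accepted: list[ScanHit] = []
    for cand in ordered:
        conflicts = [h for h in accepted if _conflict(h, cand)]
        if not conflicts:
            accepted.append(cand)
            continue
        if all(_winner(cand, h, delta) is cand for h in conflicts):
            accepted = [h for h in accepted if h not in conflicts]
            accepted.append(cand)
    return sorted(accepted, key=lambda h: (h.left_range, h.right_range))


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def summarize_repeats(
    chain_id: str,
    hits: list[ScanHit],
    gap_sse: int = 3,
) -> RepeatSummary:
    """Group unit ranges, split at coverage gaps, and count repeats.

    Nodes are the unit ranges of consolidated hits; edges join the two
    units of each hit (a structural match) and any overlapping ranges.
    Each connected component is split where its SSE coverage has a gap of
    ``gap_sse`` or more; per sub-component,
    repeat count = covered SSEs // minimal unit length, summed per chain.
    """
    if not hits:
        return RepeatSummary(chain_id)
    g = nx.Graph()
    for h in hits:
        g.add_node(h.left_range)
        g.add_node(h.right_range)
        g.add_edge(h.left_range, h.right_range)
    units = sorted(g.nodes)
    for i, u in enumerate(units):
        for v in units[i + 1 :]:
            if _overlaps(u, v):
                g.add_edge(u, v)

    total = 0
    min_unit_overall = min(u[1] - u[0] for u in units)
    for comp in nx.connected_components(g):
        ranges = sorted(comp)
        covered = sorted(set().union(*(range(*r) for r in ranges)))
        # split coverage into blocks separated by >= gap_sse missing SSEs
        blocks: list[set[int]] = []
        cur = {covered[0]}
        for prev, nxt in zip(covered, covered[1:]):
            if nxt - prev >= gap_sse + 1:
                blocks.append(cur)
                cur = set()
            cur.add(nxt)
        blocks.append(cur)
        for block in blocks:
            members = [r for r in ranges if r[0] in block]
            if not members:
                continue
            min_len = min(r[1] - r[0] for r in members)
            total += len(block) // min_len
    mean_tm = math.fsum(sorted(h.tm for h in hits)) / len(hits)
    return RepeatSummary(
        chain_id=chain_id,
        unit_boundaries=units,
        min_unit_length=min_unit_overall,
        repeat_count=total,
        mean_unit_tm=mean_tm,
    )


def classify_symmetric(
    summary: RepeatSummary,
    hits: list[ScanHit],
    config: PipelineConfig | None = None,
) -> bool:
    """Symmetric iff some consolidated hit exceeds the TM threshold
    (strictly) with both units at the minimum SSE size."""
    config = config or PipelineConfig()
    mu = config.min_unit_sse
    return any(
        h.tm > config.scan_tm
        and h.left_range[1] - h.left_range[0] >= mu
        and h.right_range[1] - h.right_range[0] >= mu
        for h in hits
    )
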