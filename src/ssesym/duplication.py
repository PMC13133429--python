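"""Circular-permutation, indel and boundary-split symmetry detection.

The core trick is query doubling: concatenating a query's SSE token string
with itself makes a circularly permuted match appear as one contiguous
local alignment crossing the duplication seam.  A seam-crossing hit
proposes a boundary; the query is rearranged at that boundary (C-terminal
segment moved in front of the N-terminal one) and both orders are verified
with exact TM-scores.  A circular permutation requires a rearranged TM-score
above the fold threshold (0.5) and an improvement of at least 0.1 over the
native order; an indel is flagged when the two cross-boundary segment images
on the partner chain are separated by at least 40 residues or at least 60%
of the smaller segment; near-symmetric chains are recognized by splitting at
the boundary and scoring the halves against each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment import (
    LocalAlignment,
    SubstitutionMatrix,
    default_matrix,
    prescreen_score,
    smith_waterman,
)
from .chain import ProteinChain
from .config import PipelineConfig
from .encoding import TokenSequence, encode_chain
from .synthetic import circular_permute
from .tmscore import TMResult, tm_align_sequential

logger = logging.getLogger("ssesym")


class BelowSSECountError(ValueError):
    pass


@dataclass
class BoundaryHit:
    """Seam-crossing alignment between a doubled query and a target."""

    alignment: LocalAlignment
    crosses_seam: bool
    boundary_token: int | None  # cut position in the original query tokens
    query_tokens_pre: list[int] = field(default_factory=list)   # C-side, orig idx
    query_tokens_post: list[int] = field(default_factory=list)  # N-side, orig idx
    target_tokens_pre: list[int] = field(default_factory=list)
    target_tokens_post: list[int] = field(default_factory=list)


@dataclass
class DuplicationResult:
    query_id: str
    target_id: str
    boundary_token: int
    boundary_res: int
    segment_n: tuple[int, int]  # query residue range [0, cut)
    segment_c: tuple[int, int]  # query residue range [cut, len)
    gap_residues: int
    tm_original: float
    tm_rearranged: float
    delta_tm: float
    is_cp: bool
    is_indel: bool
    is_symmetric: bool

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "target_id": self.target_id,
            "boundary_res": self.boundary_res,
            "seg_n_range": f"{self.segment_n[0]}-{self.segment_n[1]}",
            "seg_c_range": f"{self.segment_c[0]}-{self.segment_c[1]}",
            "gap_residues": self.gap_residues,
            "tm_original": round(self.tm_original, 4),
            "tm_rearranged": round(self.tm_rearranged, 4),
            "delta_tm": round(self.delta_tm, 4),
            "is_cp": self.is_cp,
            "is_indel": self.is_indel,
            "is_symmetric": self.is_symmetric,
        }


TSV_COLUMNS = [
    "query_id", "target_id", "boundary_res", "seg_n_range", "seg_c_range",
    "gap_residues", "tm_original", "tm_rearranged", "delta_tm",
    "is_cp", "is_indel", "is_symmetric",
]


def double_and_align(
    query: TokenSequence,
    target: TokenSequence,
    matrix: SubstitutionMatrix,
    min_sse: int = 5,
) -> BoundaryHit:
    """Align the doubled query token string against the target.

    A hit is cross-boundary iff its aligned query range spans the
    duplication seam at index |query|.  The boundary token is the seam
    position mapped back to the original query (the cut that produced the
    permutant): the first aligned doubled index modulo |query|.
    """
    n, m = len(query), len(target)
    if n < min_sse or m < min_sse:
        raise BelowSSECountError(
            f"below SSE-count filter: query has {n}, target has {m}, need {min_sse}"
        )
    doubled = query.tokens + query.tokens
    aln = smith_waterman(doubled, target.tokens, matrix)
    if aln.is_empty:
        return BoundaryHit(aln, False, None)
    q_idx = [q for q, t in aln.aligned_pairs]
    crosses = min(q_idx) < n <= max(q_idx)
    if not crosses:
        return BoundaryHit(aln, False, None)
    boundary = min(q_idx) % n
    pre = [(q, t) for q, t in aln.aligned_pairs if q < n]
    post = [(q, t) for q, t in aln.aligned_pairs if q >= n]
    return BoundaryHit(
        aln,
        True,
        boundary,
        query_tokens_pre=[q for q, _ in pre],
        query_tokens_post=[q - n for q, _ in post],
        target_tokens_pre=[t for _, t in pre],
        target_tokens_post=[t for _, t in post],
    )


def indel_flag(
    gap_residues: int, seg_n_len: int, seg_c_len: int, config: PipelineConfig
) -> bool:
    """Gap rule: indel iff the cross-boundary gap reaches 40 residues or
    60% of the smaller segment (thresholds configurable)."""
    smaller = min(seg_n_len, seg_c_len)
    return (
        gap_residues >= config.indel_min_gap
        or gap_residues >= config.indel_frac * smaller
    )


def rearrange_and_verify(
    query_chain: ProteinChain,
    target_chain: ProteinChain,
    query_tokens: TokenSequence,
    target_tokens: TokenSequence,
    hit: BoundaryHit,
    config: PipelineConfig | None = None,
) -> DuplicationResult:
    """Verify a seam-crossing hit with exact TM-scores.

    The boundary token maps to the start residue of its backing segment
    (preceding coil stays with the N-side); the rearranged query moves the
    C-terminal segment in front.  TM-scores are computed in native and
    rearranged order; CP, indel and split-symmetry flags follow the
    configured thresholds.
    """
    config = config or PipelineConfig()
    if not hit.crosses_seam or hit.boundary_token is None:
        raise ValueError("hit does not cross the duplication seam")
    b = hit.boundary_token
    if not (0 < b < len(query_tokens)):
        raise ValueError(f"boundary token {b} maps outside the query")
    cut = query_tokens.segments[b].start_res
    if not (0 < cut < len(query_chain)):
        raise ValueError(f"boundary residue {cut} maps outside the chain")
    seg_n = (0, cut)
    seg_c = (cut, len(query_chain))

    rearranged = circular_permute(query_chain, cut)
    tm_orig = tm_align_sequential(
        query_chain, target_chain, config.normalize_on,
        tmalign_bin=config.tmalign_bin,
    )
    tm_rearr = tm_align_sequential(
        rearranged, target_chain, config.normalize_on,
        tmalign_bin=config.tmalign_bin,
    )
    delta = tm_rearr.tm - tm_orig.tm
    is_cp = tm_rearr.tm >= config.cp_tm and delta >= config.cp_delta_tm

    # gap on the target between the images of the two cross-boundary blocks
    gap = 0
    if hit.target_tokens_pre and hit.target_tokens_post:
        end_pre = target_tokens.segments[max(hit.target_tokens_pre)].end_res
        start_post = target_tokens.segments[min(hit.target_tokens_post)].start_res
        gap = max(0, start_post - end_pre)
    is_indel = indel_flag(gap, cut, len(query_chain) - cut, config)

    is_sym = False
    try:
        is_sym, _ = classify_symmetry_by_split(
            query_chain, query_tokens, b, config
        )
    except ValueError:
        pass

    return DuplicationResult(
        query_id=query_chain.chain_id,
        target_id=target_chain.chain_id,
        boundary_token=b,
        boundary_res=query_chain.residues[cut].author_number,
        segment_n=seg_n,
        segment_c=seg_c,
        gap_residues=gap,
        tm_original=tm_orig.tm,
        tm_rearranged=tm_rearr.tm,
        delta_tm=delta,
        is_cp=is_cp,
        is_indel=is_indel,
        is_symmetric=is_sym,
    )


def classify_symmetry_by_split(
    chain: ProteinChain,
    tokens: TokenSequence,
    boundary_token: int,
    config: PipelineConfig | None = None,
) -> tuple[bool, TMResult]:
    """Split the chain at the boundary and score the halves against each
    other; symmetric iff TM >= 0.5 (normalized on the shorter half)."""
    config = config or PipelineConfig()
    n_sse = len(tokens)
    left_sse = boundary_token
    right_sse = n_sse - boundary_token
    if min(left_sse, right_sse) < config.min_unit_sse:
        raise ValueError(
            f"half too short: {min(left_sse, right_sse)} SSEs, "
            f"need {config.min_unit_sse}"
        )
    cut = tokens.segments[boundary_token].start_res
    half1 = chain.subchain(0, cut)
    half2 = chain.subchain(cut, len(chain))
    result = tm_align_sequential(
        half1, half2, normalize_on="shorter", tmalign_bin=config.tmalign_bin
    )
    return result.tm >= config.sym_tm, result


def run_pair(
    chain_a: ProteinChain,
    chain_b: ProteinChain,
    config: PipelineConfig | None = None,
    matrix: SubstitutionMatrix | None = None,
) -> list[DuplicationResult]:
    """End-to-end cross-boundary scan of one chain pair (ss3 already set).

    The doubling is applied to the query only, so both role assignments are
    evaluated and the record with the better rearranged TM-score is kept.
    """
    config = config or PipelineConfig()
    matrix = matrix or default_matrix(config.token_cap)
    ta = encode_chain(chain_a, config.min_segment_length, config.token_cap)
    tb = encode_chain(chain_b, config.min_segment_length, config.token_cap)
    if len(ta) < config.min_sse or len(tb) < config.min_sse:
        raise BelowSSECountError(
            f"below SSE-count filter: {chain_a.chain_id} has {len(ta)} SSEs, "
            f"{chain_b.chain_id} has {len(tb)}, need {config.min_sse}"
        )
    candidates: list[DuplicationResult] = []
    for (qc, qt, tc, tt) in (
        (chain_a, ta, chain_b, tb),
        (chain_b, tb, chain_a, ta),
    ):
        hit = double_and_align(qt, tt, matrix, config.min_sse)
        if not hit.crosses_seam:
            logger.info(
                "%s vs %s: no seam-crossing alignment", qc.chain_id, tc.chain_id
            )
            continue
        ps = prescreen_score(hit.alignment, qt.tokens + qt.tokens, tt, matrix)
        if ps < config.prescreen_threshold:
            logger.info(
                "%s vs %s: seam hit rejected by prescreen (%.3f < %.3f)",
                qc.chain_id, tc.chain_id, ps, config.prescreen_threshold,
            )
            continue
        try:
            rec = rearrange_and_verify(qc, tc, qt, tt, hit, config)
        except ValueError as exc:
            logger.warning(
                "%s vs %s: verification failed: %s", qc.chain_id, tc.chain_id, exc
            )
            continue
        candidates.append(rec)
    if not candidates:
        return []
    best = max(candidates, key=lambda r: r.tm_rearranged)
    logger.info(
        "%s vs %s: tm_original=%.3f tm_rearranged=%.3f cp=%s indel=%s",
        best.query_id, best.target_id, best.tm_original, best.tm_rearranged,
        best.is_cp, best.is_indel,
    )
    return [best]


def run_pairwise(
    query_path,
    target_path,
    config: PipelineConfig | None = None,
    matrix: SubstitutionMatrix | None = None,
    query_chain: str = "A",
    target_chain: str = "A",
    query_ss3=None,
    target_ss3=None,
) -> list[DuplicationResult]:
    """File-level wrapper: read both chains, assign secondary structure
    (sidecar file if given, else the geometric assigner), then run_pair."""
    from .structure_io import apply_ss3_sidecar, assign_ss_geometric, read_chain

    config = config or PipelineConfig()
    chains = []
    for path, cid, ss3 in (
        (query_path, query_chain, query_ss3),
        (target_path, target_chain, target_ss3),
    ):
        chain = read_chain(path, cid)
        if ss3 is not None:
            chain = apply_ss3_sidecar(chain, ss3)
        else:
            chain = assign_ss_geometric(chain)
        chains.append(chain)
    return run_pair(chains[0], chains[1], config, matrix)
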