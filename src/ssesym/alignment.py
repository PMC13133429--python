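"""Smith–Waterman local alignment of SSE token sequences.

Alignment runs on the compressed token alphabet, so sequences are short
(tens of tokens) and an exact affine-gap dynamic program is cheap.  Gap
penalties are element-specific: the penalty charged for a gap is that of
the token class (helix or strand) being skipped.  Tie-breaking is fixed —
on equal cell scores the diagonal move wins over the vertical, which wins
over the horizontal, and traceback starts from the highest-scoring cell
with ties broken by the smallest (row, col) — so outputs are bit-stable.

The substitution matrix is a loadable asset.  The built-in default scores
same-class token pairs by closeness of their length bins and penalizes
helix-vs-strand matches; the genetic-algorithm-optimized matrix of the
upstream SSE search work can be dropped in via :func:`load_matrix`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .encoding import (
    DEFAULT_CAP,
    HELIX,
    STRAND,
    TokenSequence,
    _HELIX_SYMBOLS,
    _STRAND_SYMBOLS,
    n_bins,
    token_info,
)


@dataclass
class SubstitutionMatrix:
    """Symmetric token-pair scores plus per-class affine gap penalties."""

    tokens: list[str]
    scores: dict[tuple[str, str], float]
    gap_open: dict[str, float]
    gap_extend: dict[str, float]

    def __post_init__(self) -> None:
        for cls in (HELIX, STRAND):
            if cls not in self.gap_open or cls not in self.gap_extend:
                raise ValueError(f"missing gap penalties for class {cls!r}")
            if self.gap_open[cls] > 0 or self.gap_extend[cls] > 0:
                raise ValueError("gap penalties must be <= 0")
        for a in self.tokens:
            for b in self.tokens:
                if (a, b) not in self.scores:
                    raise ValueError(f"incomplete matrix: missing ({a!r},{b!r})")
                if abs(self.scores[(a, b)] - self.scores[(b, a)]) > 1e-9:
                    raise ValueError(f"asymmetric matrix at ({a!r},{b!r})")

    def score(self, a: str, b: str) -> float:
        return self.scores[(a, b)]

    def gap_for(self, token: str) -> tuple[float, float]:
        """(open, extend) penalty for skipping ``token``."""
        cls, _ = token_info(token)
        return self.gap_open[cls], self.gap_extend[cls]


def default_matrix(
    cap: int = DEFAULT_CAP,
    match: float = 4.0,
    bin_slope: float = 1.0,
    same_class_floor: float = -2.0,
    cross_class: float = -4.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> SubstitutionMatrix:
    """Length-bin-aware default: score(a,a) > score within class decaying
    with bin distance > any cross-class score."""
    nb = n_bins(cap)
    tokens = list(_STRAND_SYMBOLS[:nb]) + list(_HELIX_SYMBOLS[:nb])
    scores: dict[tuple[str, str], float] = {}
    for a in tokens:
        ca, ba = token_info(a)
        for b in tokens:
            cb, bb = token_info(b)
            if ca == cb:
                s = max(match - bin_slope * abs(ba - bb), same_class_floor)
            else:
                s = cross_class
            scores[(a, b)] = s
    return SubstitutionMatrix(
        tokens,
        scores,
        {HELIX: gap_open, STRAND: gap_open},
        {HELIX: gap_extend, STRAND: gap_extend},
    )


def save_matrix(matrix: SubstitutionMatrix, path) -> None:
    dense = [[matrix.scores[(a, b)] for b in matrix.tokens] for a in matrix.tokens]
    payload = {
        "tokens": matrix.tokens,
        "scores": dense,
        "gap_open": matrix.gap_open,
        "gap_extend": matrix.gap_extend,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_matrix(path) -> SubstitutionMatrix:
    """Read a JSON matrix file (keys: tokens, scores, gap_open, gap_extend)."""
    with open(path) as fh:
        payload = json.load(fh)
    for key in ("tokens", "scores", "gap_open", "gap_extend"):
        if key not in payload:
            raise ValueError(f"matrix file missing key {key!r}")
    tokens = list(payload["tokens"])
    dense = payload["scores"]
    if len(dense) != len(tokens) or any(len(row) != len(tokens) for row in dense):
        raise ValueError("scores must be a dense |tokens| x |tokens| matrix")
    scores = {
        (a, b): float(dense[i][j])
        for i, a in enumerate(tokens)
        for j, b in enumerate(tokens)
    }
    return SubstitutionMatrix(
        tokens,
        scores,
        {k: float(v) for k, v in payload["gap_open"].items()},
        {k: float(v) for k, v in payload["gap_extend"].items()},
    )


@dataclass
class LocalAlignment:
    """A scored local alignment between two token sequences.

    ``pairs`` lists (query_index, target_index) tuples where a gap is
    represented by None on the skipped side; indices strictly increase.
    """

    query_range: tuple[int, int]
    target_range: tuple[int, int]
    pairs: list[tuple[int | None, int | None]]
    score: float
    identity: float
    coverage: float

    @property
    def aligned_pairs(self) -> list[tuple[int, int]]:
        return [(q, t) for q, t in self.pairs if q is not None and t is not None]

    @property
    def is_empty(self) -> bool:
        return not self.pairs


_EMPTY = LocalAlignment((0, 0), (0, 0), [], 0.0, 0.0, 0.0)


def smith_waterman(
    query: TokenSequence | list[str],
    target: TokenSequence | list[str],
    matrix: SubstitutionMatrix,
) -> LocalAlignment:
    """Maximal-scoring local alignment under element-specific affine gaps."""
    q = query.tokens if isinstance(query, TokenSequence) else list(query)
    t = target.tokens if isinstance(target, TokenSequence) else list(target)
    if not q or not t:
        raise ValueError("cannot align empty token sequence")
    n, m = len(q), len(t)
    NEG = float("-inf")
    # M: ends in a match; X: ends skipping a query token (vertical/up);
    # Y: ends skipping a target token (horizontal/left)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, best_cell = 0.0, None
    for i in range(1, n + 1):
        qo, qe = matrix.gap_for(q[i - 1])
        for j in range(1, m + 1):
            s = matrix.score(q[i - 1], t[j - 1])
            M[i][j] = max(
                0.0, s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            )
            X[i][j] = max(M[i - 1][j] + qo, X[i - 1][j] + qe)
            to, te = matrix.gap_for(t[j - 1])
            Y[i][j] = max(M[i][j - 1] + to, Y[i][j - 1] + te)
            if M[i][j] > best:
                best, best_cell = M[i][j], (i, j)
    if best_cell is None:
        return _EMPTY

    # traceback from the highest M cell; ties already resolved by scan order
    pairs: list[tuple[int | None, int | None]] = []
    i, j = best_cell
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            if M[i][j] <= 0:
                break
            pairs.append((i - 1, j - 1))
            s = matrix.score(q[i - 1], t[j - 1])
            prev = M[i][j] - s
            if abs(prev) < 1e-9 and M[i - 1][j - 1] <= 0 and X[i - 1][j - 1] <= 0 \
                    and Y[i - 1][j - 1] <= 0:
                i, j = i - 1, j - 1
                break
            # preference: diagonal (M) then up (X) then left (Y)
            if abs(M[i - 1][j - 1] - prev) < 1e-9:
                state = "M"
            elif abs(X[i - 1][j - 1] - prev) < 1e-9:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "X":
            qo, qe = matrix.gap_for(q[i - 1])
            pairs.append((i - 1, None))
            if abs(M[i - 1][j] + qo - X[i][j]) < 1e-9:
                state = "M"
            else:
                state = "X"
            i -= 1
        else:  # Y
            to, te = matrix.gap_for(t[j - 1])
            pairs.append((None, j - 1))
            if abs(M[i][j - 1] + to - Y[i][j]) < 1e-9:
                state = "M"
            else:
                state = "Y"
            j -= 1
    pairs.reverse()
    aligned = [(qq, tt) for qq, tt in pairs if qq is not None and tt is not None]
    if not aligned:
        return _EMPTY
    q_idx = [qq for qq, _ in aligned]
    t_idx = [tt for _, tt in aligned]
    identical = sum(1 for qq, tt in aligned if q[qq] == t[tt])
    identity = identical / len(aligned)
    coverage = len(aligned) / min(n, m)
    return LocalAlignment(
        query_range=(min(q_idx), max(q_idx) + 1),
        target_range=(min(t_idx), max(t_idx) + 1),
        pairs=pairs,
        score=best,
        identity=identity,
        coverage=coverage,
    )


def self_score(tokens: list[str] | TokenSequence, matrix: SubstitutionMatrix) -> float:
    toks = tokens.tokens if isinstance(tokens, TokenSequence) else tokens
    return sum(matrix.score(a, a) for a in toks)


def prescreen_score(
    aln: LocalAlignment,
    query: TokenSequence | list[str],
    target: TokenSequence | list[str],
    matrix: SubstitutionMatrix,
) -> float:
    """Cheap monotone surrogate for structural similarity in [0, 1].

    Combines the alignment score (normalized by the smaller self-score)
    with identity x coverage; identical sequences score 1.0 and empty
    alignments 0.0.  Used only as a filter before exact TM verification,
    so it trades calibration for monotonicity and speed.
    """
    if aln.is_empty:
        return 0.0
    q = query.tokens if isinstance(query, TokenSequence) else list(query)
    t = target.tokens if isinstance(target, TokenSequence) else list(target)
    denom = min(self_score(q, matrix), self_score(t, matrix))
    score_norm = min(max(aln.score / denom, 0.0), 1.0) if denom > 0 else 0.0
    return 0.5 * score_norm + 0.5 * aln.identity * aln.coverage
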