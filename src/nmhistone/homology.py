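"""Homolog identification, reference-anchored alignment and indel segmentation.

This module does three jobs:

1. **Pairwise alignment** (:func:`align_pair`): affine-gap global
   (Needleman–Wunsch) and local (Smith–Waterman) alignment under a
   substitution matrix (BLOSUM62 by default).  A gap of length *L* costs
   ``gap_open + L * gap_extend``.  The dynamic-programming traceback is
   fully deterministic: ties are broken diagonal > up-gap > left-gap, so
   repeated runs are bit-stable.  The fill is a numba kernel, which keeps
   Rpb1-sized problems (~2000 x 2000) well under a second.

2. **Family classification** (:func:`classify_family`): best-hit local
   alignment of a query against the packaged human reference panel
   (H2A, H2B, H3.3, H4 and an Rpb1-like reference).  A family is called
   when the best hit clears an identity threshold over its aligned
   columns and a minimum aligned length; otherwise the call is ``none``.

3. **Coordinate mapping and indel segmentation**
   (:func:`map_positions`, :func:`segment_indels`): from a global
   alignment against the scoring reference, build the reference→query
   position map (mature numbering on both sides) and report maximal
   insertion/deletion blocks anchored in reference coordinates, tagged
   as N-terminal tail, histone-fold core or C-terminal tail.  These are
   the primitives behind statements like "the H3 N-terminal tail between
   residues 10 and 38 is missing" or "a 10-amino-acid insertion in the
   core".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .seqio import SequenceRecord, read_sequences

NEG = -1.0e18

# N-terminal tail extents in mature reference coordinates; the C-terminal
# tail is the last C_TAIL_LEN residues.  Configurable per call.
TAIL_BOUNDS: dict[str, tuple[int, int]] = {"H3": (1, 38), "H4": (1, 24), "H2B": (1, 34)}
C_TAIL_LEN = 5

PANEL_ORDER = ("H2A", "H2B", "H3", "H4", "Rpb1")


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentParams:
    """Substitution matrix and affine gap penalties.

    A gap of length L costs ``gap_open + L * gap_extend`` (both negative).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -1.0
    mode: str = "global"

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend < 0):
            raise AlignmentError("require gap_open <= gap_extend < 0")
        if self.mode not in ("global", "local"):
            raise AlignmentError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class ClassifierParams:
    """Best-hit acceptance thresholds.

    tau is the minimum identity fraction over aligned (non-gap) columns;
    min_aligned is the minimum number of aligned columns (the Rpb1 value
    is higher because Rpb1 is a ~2000-residue protein and short spurious
    local hits are common).
    """

    tau: float = 0.35
    min_aligned: int = 50
    min_aligned_rpb1: int = 300

    def __post_init__(self) -> None:
        if not (0 < self.tau <= 1):
            raise AlignmentError("require 0 < tau <= 1")

    def min_aligned_for(self, family: str) -> int:
        return self.min_aligned_rpb1 if family == "Rpb1" else self.min_aligned


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped alignment of a reference/query pair (reference first)."""

    gapped_ref: str
    gapped_query: str
    score: float
    params: AlignmentParams
    ref_id: str = ""
    query_id: str = ""
    # offsets of the aligned region (0-based, local mode only)
    ref_start: int = 0
    query_start: int = 0

    def __post_init__(self) -> None:
        if len(self.gapped_ref) != len(self.gapped_query):
            raise AlignmentError("gapped strings differ in length")
        for x, y in zip(self.gapped_ref, self.gapped_query):
            if x == "-" and y == "-":
                raise AlignmentError("gap/gap column in alignment")

    @property
    def ref_ungapped(self) -> str:
        return self.gapped_ref.replace("-", "")

    @property
    def query_ungapped(self) -> str:
        return self.gapped_query.replace("-", "")

    @property
    def n_aligned(self) -> int:
        return sum(
            1 for x, y in zip(self.gapped_ref, self.gapped_query) if x != "-" and y != "-"
        )

    @property
    def n_identical(self) -> int:
        return sum(
            1
            for x, y in zip(self.gapped_ref, self.gapped_query)
            if x != "-" and x == y
        )

    @property
    def identity(self) -> float:
        n = self.n_aligned
        return self.n_identical / n if n else 0.0

    def __str__(self) -> str:
        match = "".join(
            "|" if x == y and x != "-" else " "
            for x, y in zip(self.gapped_ref, self.gapped_query)
        )
        return "\n".join([self.gapped_ref, match, self.gapped_query])


@dataclass(frozen=True)
class FamilyCall:
    query_id: str
    family: str  # H2A / H2B / H3 / H4 / Rpb1 / none
    score: float
    identity: float


@dataclass(frozen=True)
class IndelBlock:
    """A maximal insertion or deletion run, anchored in reference coordinates.

    For deletions, (ref_start, ref_end) is the closed 1-based reference
    interval missing from the query.  For insertions, ref_start == ref_end
    is the reference position after which the insertion occurs (0 means
    before position 1).
    """

    kind: str  # insertion_in_query | deletion_in_query
    ref_start: int
    ref_end: int
    length: int
    region: str  # n_tail | core | c_tail

    def __post_init__(self) -> None:
        if self.kind not in ("insertion_in_query", "deletion_in_query"):
            raise AlignmentError(f"bad indel kind {self.kind!r}")
        if self.length < 1:
            raise AlignmentError("indel length must be >= 1")


class PositionMap:
    """Total map from reference mature positions to query mature positions.

    ``map[p]`` is the query position aligned to reference position ``p``,
    or ``None`` when the reference residue falls in a gap column (absent
    from the query).  Mapped positions are strictly increasing.
    """

    def __init__(self, mapping: dict[int, int | None], ref_length: int, query_length: int):
        self._map = mapping
        self.ref_length = ref_length
        self.query_length = query_length
        prev = 0
        for p in range(1, ref_length + 1):
            if p not in mapping:
                raise AlignmentError(f"position map not total: missing {p}")
            q = mapping[p]
            if q is not None:
                if q <= prev:
                    raise AlignmentError("position map not strictly increasing")
                prev = q

    def get(self, ref_pos: int) -> int | None:
        return self._map[ref_pos]

    def __getitem__(self, ref_pos: int) -> int | None:
        return self._map[ref_pos]

    def items(self):
        return self._map.items()


# ---------------------------------------------------------------------------
# substitution matrix handling

@lru_cache(maxsize=4)
def _matrix(name: str) -> tuple[str, np.ndarray]:
    try:
        m = substitution_matrices.load(name)
    except Exception as exc:  # unknown name
        raise AlignmentError(f"unknown substitution matrix {name!r}") from exc
    return str(m.alphabet), np.asarray(m, dtype=np.float64)


def _encode(seq: str, alphabet: str) -> np.ndarray:
    idx = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq):
        k = alphabet.find(c)
        if k < 0:
            raise AlignmentError(f"residue {c!r} not in matrix alphabet")
        idx[i] = k
    return idx


# ---------------------------------------------------------------------------
# numba DP kernels.  States: 0 = M (diagonal), 1 = X (up, gap in query),
# 2 = Y (left, gap in reference).  Ties resolved by state order 0 > 1 > 2.

@njit(cache=True)
def _fill_global(a, b, S, go, ge):
    n, m = a.size, b.size
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    TM = np.zeros((n + 1, m + 1), dtype=np.int8)
    TX = np.zeros((n + 1, m + 1), dtype=np.int8)
    TY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + i * ge
        TX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = go + j * ge
        TY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # diagonal state
            best = M[i - 1, j - 1]
            st = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                st = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                st = 2
            M[i, j] = best + S[a[i - 1], b[j - 1]]
            TM[i, j] = st
            # up state (consume reference residue, gap in query)
            best = M[i - 1, j] + go + ge
            st = 0
            v = X[i - 1, j] + ge
            if v > best:
                best = v
                st = 1
            v = Y[i - 1, j] + go + ge
            if v > best:
                best = v
                st = 2
            X[i, j] = best
            TX[i, j] = st
            # left state (consume query residue, gap in reference)
            best = M[i, j - 1] + go + ge
            st = 0
            v = X[i, j - 1] + go + ge
            if v > best:
                best = v
                st = 1
            v = Y[i, j - 1] + ge
            if v > best:
                best = v
                st = 2
            Y[i, j] = best
            TY[i, j] = st
    return M, X, Y, TM, TX, TY


@njit(cache=True)
def _fill_local(a, b, S, go, ge):
    n, m = a.size, b.size
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    TM = np.full((n + 1, m + 1), 3, dtype=np.int8)  # 3 = start (zero floor)
    TX = np.zeros((n + 1, m + 1), dtype=np.int8)
    TY = np.zeros((n + 1, m + 1), dtype=np.int8)
    best_score = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = M[i - 1, j - 1]
            st = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                st = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                st = 2
            v = best + S[a[i - 1], b[j - 1]]
            if v <= 0.0:
                M[i, j] = 0.0
                TM[i, j] = 3
            else:
                M[i, j] = v
                # best <= 0 means the predecessor was the zero floor: this
                # column starts the local alignment
                TM[i, j] = 3 if (st == 0 and best <= 0.0) else st
            if M[i, j] > best_score:
                best_score = M[i, j]
                bi = i
                bj = j
            best = M[i - 1, j] + go + ge
            st = 0
            v = X[i - 1, j] + ge
            if v > best:
                best = v
                st = 1
            v = Y[i - 1, j] + go + ge
            if v > best:
                best = v
                st = 2
            X[i, j] = best
            TX[i, j] = st
            best = M[i, j - 1] + go + ge
            st = 0
            v = X[i, j - 1] + go + ge
            if v > best:
                best = v
                st = 1
            v = Y[i, j - 1] + ge
            if v > best:
                best = v
                st = 2
            Y[i, j] = best
            TY[i, j] = st
    return M, X, Y, TM, TX, TY, best_score, bi, bj


def _traceback(a: str, b: str, i: int, j: int, state: int, TM, TX, TY, local: bool):
    cols_a: list[str] = []
    cols_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            nxt = TM[i, j]
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            i -= 1
            j -= 1
            state = nxt
            if local and state == 3:
                break
        elif state == 1:
            nxt = TX[i, j]
            cols_a.append(a[i - 1])
            cols_b.append("-")
            i -= 1
            state = nxt
        elif state == 2:
            nxt = TY[i, j]
            cols_a.append("-")
            cols_b.append(b[j - 1])
            j -= 1
            state = nxt
        else:  # pragma: no cover - defensive
            break
    return "".join(reversed(cols_a)), "".join(reversed(cols_b)), i, j


def _as_seq(x) -> tuple[str, str]:
    """Accept a SequenceRecord or a bare string (possibly empty)."""
    if isinstance(x, str):
        return "", x
    return x.id, x.residues


def align_pair(
    a: SequenceRecord | str, b: SequenceRecord | str, params: AlignmentParams | None = None
) -> PairwiseAlignment:
    """Optimal affine-gap pairwise alignment of *a* (reference) and *b* (query).

    Global mode is end-gap-penalised Needleman–Wunsch; local mode is
    Smith–Waterman.  Traceback ties are broken diagonal > up > left, so the
    returned alignment is deterministic.  Global mode tolerates an empty
    query/reference (pass a bare string), scoring it as a single gap run.
    """
    params = params or AlignmentParams()
    alphabet, S = _matrix(params.matrix)
    id_a, sa = _as_seq(a)
    id_b, sb = _as_seq(b)
    # degenerate empty-sequence cases (global convention: one gap run)
    if params.mode == "global" and (len(sa) == 0 or len(sb) == 0):
        if len(sa) == 0 and len(sb) == 0:
            return PairwiseAlignment("", "", 0.0, params, id_a, id_b)
        gap_len = max(len(sa), len(sb))
        score = params.gap_open + gap_len * params.gap_extend
        return PairwiseAlignment(
            sa if sa else "-" * gap_len,
            sb if sb else "-" * gap_len,
            score,
            params,
            id_a,
            id_b,
        )
    ia, ib = _encode(sa, alphabet), _encode(sb, alphabet)
    go, ge = float(params.gap_open), float(params.gap_extend)
    if params.mode == "global":
        M, X, Y, TM, TX, TY = _fill_global(ia, ib, S, go, ge)
        n, m = len(sa), len(sb)
        score = M[n, m]
        state = 0
        if X[n, m] > score:
            score, state = X[n, m], 1
        if Y[n, m] > score:
            score, state = Y[n, m], 2
        ga, gb, _, _ = _traceback(sa, sb, n, m, state, TM, TX, TY, local=False)
        return PairwiseAlignment(ga, gb, float(score), params, id_a, id_b)
    M, X, Y, TM, TX, TY, score, bi, bj = _fill_local(ia, ib, S, go, ge)
    if score <= 0.0:
        raise AlignmentError(
            f"no positive-scoring local alignment between {id_a!r} and {id_b!r}"
        )
    ga, gb, i0, j0 = _traceback(sa, sb, bi, bj, 0, TM, TX, TY, local=True)
    return PairwiseAlignment(
        ga, gb, float(score), params, id_a, id_b, ref_start=i0, query_start=j0
    )


# ---------------------------------------------------------------------------
# reference panel

@dataclass(frozen=True)
class ReferencePanel:
    """One reference per family: human mature histones plus an Rpb1-like
    reference (the packaged Rpb1 entry is synthetic — see its FASTA header)."""

    members: dict[str, SequenceRecord]

    def __post_init__(self) -> None:
        for fam in PANEL_ORDER:
            if fam not in self.members:
                raise AlignmentError(f"panel missing family {fam}")
        if len(self.members["H3"]) != 135:
            raise AlignmentError("mature H3 reference must be 135 residues")
        if len(self.members["H4"]) != 102:
            raise AlignmentError("mature H4 reference must be 102 residues")

    def __getitem__(self, family: str) -> SequenceRecord:
        return self.members[family]

    @property
    def families(self) -> tuple[str, ...]:
        return PANEL_ORDER

    @classmethod
    def load(cls) -> "ReferencePanel":
        members: dict[str, SequenceRecord] = {}
        for fname in ("reference_panel.fasta", "rpb1_synthetic.fasta"):
            ref = resources.files("nmhistone.data").joinpath(fname)
            with resources.as_file(ref) as p:
                for rec in read_sequences(p, "fasta"):
                    members[rec.id] = rec
        return cls(members)


_panel_cache: ReferencePanel | None = None


def load_panel() -> ReferencePanel:
    global _panel_cache
    if _panel_cache is None:
        _panel_cache = ReferencePanel.load()
    return _panel_cache


def classify_family(
    query: SequenceRecord,
    panel: ReferencePanel | None = None,
    cparams: ClassifierParams | None = None,
    aparams: AlignmentParams | None = None,
) -> FamilyCall:
    """Best-hit family call by local alignment against the reference panel.

    The family is the highest-scoring panel member whose local alignment
    clears the identity threshold tau over aligned columns and the
    family-specific minimum aligned length; ``none`` if no member passes.
    """
    panel = panel or load_panel()
    cparams = cparams or ClassifierParams()
    aparams = aparams or AlignmentParams()
    local = replace(aparams, mode="local")
    best: tuple[float, float, str] | None = None
    best_any: tuple[float, float] = (0.0, 0.0)
    for fam in panel.families:
        try:
            aln = align_pair(panel[fam], query, local)
        except AlignmentError:
            continue
        if (aln.score, aln.identity) > best_any:
            best_any = (aln.score, aln.identity)
        passes = aln.identity >= cparams.tau and aln.n_aligned >= cparams.min_aligned_for(fam)
        if passes and (best is None or aln.score > best[0]):
            best = (aln.score, aln.identity, fam)
    if best is None:
        return FamilyCall(query.id, "none", best_any[0], best_any[1])
    return FamilyCall(query.id, best[2], best[0], best[1])


# ---------------------------------------------------------------------------
# coordinate mapping and indel segmentation

def map_positions(aln: PairwiseAlignment) -> PositionMap:
    """Reference→query coordinate map induced by a global alignment."""
    if aln.params.mode != "global":
        raise AlignmentError("position maps require a global alignment")
    mapping: dict[int, int | None] = {}
    i = j = 0
    for x, y in zip(aln.gapped_ref, aln.gapped_query):
        if x != "-" and y != "-":
            i += 1
            j += 1
            mapping[i] = j
        elif x != "-":
            i += 1
            mapping[i] = None
        else:
            j += 1
    return PositionMap(mapping, i, j)


def _region_of_interval(
    start: int, end: int, ref_len: int, n_tail: tuple[int, int] | None, c_tail_len: int
) -> str:
    c_start = ref_len - c_tail_len + 1
    if n_tail is not None and start >= n_tail[0] and end <= n_tail[1]:
        return "n_tail"
    if start >= c_start:
        return "c_tail"
    # majority vote for straddling blocks, ties to the earlier region
    span = range(start, end + 1)
    n_n = sum(1 for p in span if n_tail is not None and n_tail[0] <= p <= n_tail[1])
    n_c = sum(1 for p in span if p >= c_start)
    n_core = (end - start + 1) - n_n - n_c
    counts = [("n_tail", n_n), ("core", n_core), ("c_tail", n_c)]
    return max(counts, key=lambda t: t[1])[0]


def _region_of_anchor(
    anchor: int, ref_len: int, n_tail: tuple[int, int] | None, c_tail_len: int
) -> str:
    pos = max(anchor, 1)
    return _region_of_interval(pos, pos, ref_len, n_tail, c_tail_len)


def segment_indels(
    aln: PairwiseAlignment,
    family: str | None = None,
    n_tail: tuple[int, int] | None = None,
    c_tail_len: int = C_TAIL_LEN,
) -> list[IndelBlock]:
    """Maximal insertion/deletion blocks of a global alignment, in reference
    coordinates, tagged n_tail / core / c_tail.

    Tail bounds come from ``TAIL_BOUNDS[family]`` unless *n_tail* is given
    explicitly; with neither, everything before the C-terminal tail is core.
    """
    if aln.params.mode != "global":
        raise AlignmentError("indel segmentation requires a global alignment")
    if n_tail is None and family is not None:
        n_tail = TAIL_BOUNDS.get(family)
    ref_len = len(aln.ref_ungapped)
    blocks: list[IndelBlock] = []
    i = 0  # reference position consumed so far
    run_kind: str | None = None
    run_start = 0
    run_len = 0

    def flush():
        nonlocal run_kind, run_len
        if run_kind is None:
            return
        if run_kind == "deletion_in_query":
            start, end = run_start, run_start + run_len - 1
            region = _region_of_interval(start, end, ref_len, n_tail, c_tail_len)
            blocks.append(IndelBlock(run_kind, start, end, run_len, region))
        else:
            anchor = run_start
            region = _region_of_anchor(anchor, ref_len, n_tail, c_tail_len)
            blocks.append(IndelBlock(run_kind, anchor, anchor, run_len, region))
        run_kind = None
        run_len = 0

    for x, y in zip(aln.gapped_ref, aln.gapped_query):
        if x != "-" and y != "-":
            flush()
            i += 1
        elif y == "-":  # reference residue missing from query
            i += 1
            if run_kind == "deletion_in_query":
                run_len += 1
            else:
                flush()
                run_kind = "deletion_in_query"
                run_start = i
                run_len = 1
        else:  # insertion in query, anchored after reference position i
            if run_kind == "insertion_in_query":
                run_len += 1
            else:
                flush()
                run_kind = "insertion_in_query"
                run_start = i
                run_len = 1
    flush()
    return blocks
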