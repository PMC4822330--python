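"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the package's dynamic-programming code paths:
the alignment oracle enumerates every monotone alignment of a sequence
pair explicitly and scores gap runs by scanning columns, and the motif
oracle counts substring occurrences by direct comparison.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def score_alignment_columns(cols: list[tuple[str, str]], go: float, ge: float) -> float:
    """Affine score of an explicit column list: each maximal run of L gap
    columns on one side costs go + L * ge."""
    score = 0.0
    run_side = None  # 'a' when the a-side residue aligns to a gap, 'b' otherwise
    for x, y in cols:
        if x != "-" and y != "-":
            score += _B62[x][y]
            run_side = None
        else:
            side = "a" if y == "-" else "b"
            if side != run_side:
                score += go
                run_side = side
            score += ge
    return score


def brute_force_global_score(a: str, b: str, go: float = -10.0, ge: float = -1.0) -> float:
    """Optimal global affine-gap score by exhaustive enumeration of all
    alignments (exponential; use only for short sequences)."""
    best = [float("-inf")]

    def rec(i: int, j: int, cols: list[tuple[str, str]]):
        if i == len(a) and j == len(b):
            s = score_alignment_columns(cols, go, ge)
            if s > best[0]:
                best[0] = s
            return
        if i < len(a) and j < len(b):
            cols.append((a[i], b[j]))
            rec(i + 1, j + 1, cols)
            cols.pop()
        if i < len(a):
            cols.append((a[i], "-"))
            rec(i + 1, j, cols)
            cols.pop()
        if j < len(b):
            cols.append(("-", b[j]))
            rec(i, j + 1, cols)
            cols.pop()

    rec(0, 0, [])
    return best[0]


def count_exact_occurrences(seq: str, motif: str) -> int:
    """Overlapping exact-substring count by direct window comparison."""
    return sum(1 for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif)
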