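"""Detection of RNA polymerase II CTD heptad repeats.

The C-terminal domain (CTD) of Rpb1, the largest subunit of RNA Pol II,
is ancestrally built of tandem repeats of the consensus heptad YSPTSPS —
five phosphorylatable residues (S/T/Y) and two prolines per repeat.
Real CTDs contain degenerate repeats, so the scan admits up to *m*
mismatches per heptad window.  Hits at exact 7-residue phase spacing are
chained into tandem arrays; the total number of heptads inside arrays is
the operational "repeat count", and its being zero (at the default
mismatch budget) is how "this Rpb1 lacks a CTD" is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import SequenceRecord

CONSENSUS = "YSPTSPS"
PHOSPHO = set("STY")


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class ScanParams:
    """m: max mismatches per heptad; min_run: minimum chained heptads for a
    tandem array; c_terminal_fraction: restrict the scan to the last part of
    the sequence (1.0 = whole sequence)."""

    m: int = 1
    min_run: int = 2
    c_terminal_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.m <= 3):
            raise ScanError("require 0 <= m <= 3")
        if self.min_run < 1:
            raise ScanError("require min_run >= 1")
        if not (0 < self.c_terminal_fraction <= 1):
            raise ScanError("require 0 < c_terminal_fraction <= 1")


@dataclass(frozen=True)
class HeptadHit:
    start: int  # 1-based position of the window in the query
    mismatches: int
    phospho_count: int
    proline_count: int


@dataclass(frozen=True)
class HeptadArray:
    start: int  # 1-based position of the first heptad
    n_heptads: int

    @property
    def end(self) -> int:
        return self.start + 7 * self.n_heptads - 1


@dataclass
class HeptadScanResult:
    query_id: str
    consensus: str
    params: ScanParams
    hits: list[HeptadHit] = field(default_factory=list)
    arrays: list[HeptadArray] = field(default_factory=list)

    @property
    def total_in_arrays(self) -> int:
        return sum(a.n_heptads for a in self.arrays)

    @property
    def n_exact(self) -> int:
        return sum(1 for h in self.hits if h.mismatches == 0)


def heptad_stats(h: str) -> tuple[int, int]:
    """(phosphorylatable S/T/Y count, proline count) of a 7-residue window."""
    if len(h) != 7:
        raise ScanError(f"heptad must have length 7, got {len(h)}")
    return sum(1 for c in h if c in PHOSPHO), h.count("P")


def scan_heptads(
    seq: SequenceRecord,
    consensus: str = CONSENSUS,
    params: ScanParams | None = None,
) -> HeptadScanResult:
    """Scan for heptad windows within the mismatch budget and chain them
    into tandem arrays.

    Every length-7 window with Hamming distance <= m to the consensus is a
    hit (hits may overlap).  Arrays are assembled greedily left to right
    from hits at exact 7-residue phase spacing; runs shorter than min_run
    are discarded.
    """
    if len(consensus) != 7:
        raise ScanError("consensus must have length 7")
    params = params or ScanParams()
    s = seq.residues
    result = HeptadScanResult(seq.id, consensus, params)
    if len(s) < 7:
        return result
    start_at = 0
    if params.c_terminal_fraction < 1.0:
        start_at = int(len(s) * (1 - params.c_terminal_fraction))
    hits: list[HeptadHit] = []
    for i in range(start_at, len(s) - 6):
        window = s[i : i + 7]
        mm = sum(1 for a, b in zip(window, consensus) if a != b)
        if mm <= params.m:
            ph, pr = heptad_stats(window)
            hits.append(HeptadHit(i + 1, mm, ph, pr))
    result.hits = hits
    # Greedy left-to-right chaining at phase-7 spacing.  A window already
    # covered by a recorded array cannot seed or join another array, which
    # keeps arrays disjoint even when degenerate hits overlap them.
    starts = {h.start for h in hits}

    def free(s: int) -> bool:
        return all(s + 6 < a.start or s > a.end for a in result.arrays)

    for h in hits:
        if not free(h.start):
            continue
        run = [h.start]
        nxt = h.start + 7
        while nxt in starts and free(nxt):
            run.append(nxt)
            nxt += 7
        if len(run) >= params.min_run:
            result.arrays.append(HeptadArray(run[0], len(run)))
    return result
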