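"""Synthetic histone- and Rpb1-like sequences with recorded ground truth.

The generator derives queries from the packaged human references by
planting events a reduced nucleomorph genome actually shows: substitutions
at or near PTM sites, insertions and deletions (including N-terminal tail
truncations), plus background substitution at a per-residue rate theta.
Every planted event is recorded, and the expected conservation scores and
indel blocks are computed from the event list itself — never by
re-alignment — so the generator's output doubles as an exact oracle for
the identification → alignment → scoring pipeline.

To keep that oracle exact, background substitutions are excluded from the
radius-2 neighbourhood of every catalogued site and from a 2-residue
margin around planted indel boundaries (a substitution at an indel
junction can make the optimal gap placement ambiguous).  An unrestricted
mode exists for stress testing; its ground truth for conservation is
still exact with respect to substitutions, but indel recovery is no
longer guaranteed.

All randomness flows from the integer seed in the MutationSpec; identical
(spec, seed) pairs produce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ctd_scan import CONSENSUS
from .homology import (
    IndelBlock,
    ReferencePanel,
    TAIL_BOUNDS,
    C_TAIL_LEN,
    _region_of_anchor,
    _region_of_interval,
    load_panel,
)
from .ptm_catalog import PTMCatalog, load_catalog
from .seqio import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class IndelEvent:
    """A planted indel.  Deletions remove the closed reference interval
    [anchor, anchor+length-1]; insertions add residues after position
    anchor (0 = before position 1), drawn from the RNG when not given."""

    anchor: int
    kind: str  # insertion | deletion
    length: int
    residues: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise SyntheticError(f"bad indel kind {self.kind!r}")
        if self.length < 1:
            raise SyntheticError("indel length must be >= 1")
        if self.residues is not None and len(self.residues) != self.length:
            raise SyntheticError("inserted residues do not match length")


@dataclass(frozen=True)
class MutationSpec:
    """Planted events plus background substitution rate theta and a seed."""

    substitutions: tuple[tuple[int, str], ...] = ()
    indels: tuple[IndelEvent, ...] = ()
    tail_truncation: int | None = None  # keep residues from this position on
    theta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.theta < 1):
            raise SyntheticError("require 0 <= theta < 1")
        if self.tail_truncation is not None and self.tail_truncation < 2:
            raise SyntheticError("tail_truncation keeps from position >= 2")


@dataclass
class GroundTruth:
    """Expected pipeline output for one generated query."""

    family: str
    site_scores: dict[tuple[int, int], int]  # (mature position, r) -> 0/1
    indel_blocks: list[IndelBlock]
    n_background: int


def _deletions(spec: MutationSpec) -> list[tuple[int, int]]:
    dels = [
        (ev.anchor, ev.anchor + ev.length - 1)
        for ev in spec.indels
        if ev.kind == "deletion"
    ]
    if spec.tail_truncation is not None:
        dels.append((1, spec.tail_truncation - 1))
    return sorted(dels)


def mutate_reference(
    family: str,
    spec: MutationSpec,
    panel: ReferencePanel | None = None,
    catalog: PTMCatalog | None = None,
    record_id: str | None = None,
    restrict_background: bool = True,
) -> tuple[SequenceRecord, GroundTruth]:
    """Apply a MutationSpec to the packaged reference of *family*.

    Returns the mutated record and the exact expected conservation scores
    and indel blocks, both derived from the event list.
    """
    panel = panel or load_panel()
    catalog = catalog or load_catalog()
    ref = panel[family].residues
    L = len(ref)
    rng = np.random.default_rng(spec.seed)

    dels = _deletions(spec)
    for (s1, e1), (s2, e2) in zip(dels, dels[1:]):
        if s2 <= e1:
            raise SyntheticError("overlapping planted deletions")
    for s, e in dels:
        if s < 1 or e > L:
            raise SyntheticError(f"deletion [{s},{e}] outside reference 1..{L}")
    deleted = {p for s, e in dels for p in range(s, e + 1)}

    insertions: dict[int, str] = {}
    for ev in spec.indels:
        if ev.kind != "insertion":
            continue
        if not (0 <= ev.anchor <= L):
            raise SyntheticError(f"insertion anchor {ev.anchor} outside 0..{L}")
        if ev.anchor in deleted or ev.anchor in insertions:
            raise SyntheticError("overlapping planted indels")
        res = ev.residues or "".join(rng.choice(list(AA20), size=ev.length))
        insertions[ev.anchor] = res

    subs: dict[int, str] = {}
    for pos, new in spec.substitutions:
        if not (1 <= pos <= L):
            raise SyntheticError(f"substitution position {pos} outside 1..{L}")
        if new == ref[pos - 1]:
            raise SyntheticError(f"substitution at {pos} is a no-op ({new})")
        if pos in deleted or pos in subs:
            raise SyntheticError(f"conflicting events at position {pos}")
        subs[pos] = new

    # background substitutions
    protected: set[int] = set(deleted) | set(subs)
    if restrict_background:
        for site in catalog.for_family(family):
            protected.update(range(site.position - 2, site.position + 3))
        for s, e in dels:
            protected.update(range(s - 2, e + 3))
        for a in insertions:
            protected.update(range(a - 1, a + 3))
    eligible = [p for p in range(1, L + 1) if p not in protected]
    n_background = 0
    draws = rng.random(len(eligible))
    for p, u in zip(eligible, draws):
        if u < spec.theta:
            old = ref[p - 1]
            choices = [c for c in AA20 if c != old]
            subs[p] = choices[int(rng.integers(len(choices)))]
            n_background += 1

    # assemble query
    parts: list[str] = []
    if 0 in insertions:
        parts.append(insertions[0])
    for p in range(1, L + 1):
        if p not in deleted:
            parts.append(subs.get(p, ref[p - 1]))
        if p in insertions:
            parts.append(insertions[p])
    residues = "".join(parts)
    if not residues:
        raise SyntheticError("spec deletes the entire reference")
    rec = SequenceRecord(record_id or f"{family}_synthetic", residues)

    # expected conservation scores from the event list
    site_scores: dict[tuple[int, int], int] = {}
    for site in catalog.for_family(family):
        for r in (0, 1, 2):
            lo = max(1, site.position - r)
            hi = min(L, site.position + r)
            ok = all(p not in deleted and p not in subs for p in range(lo, hi + 1))
            if ok and any(lo <= a < hi for a in insertions):
                ok = False
            site_scores[(site.position, r)] = int(ok)

    # expected indel blocks, with the same region tagging the segmenter uses
    n_tail = TAIL_BOUNDS.get(family)
    blocks: list[IndelBlock] = []
    for s, e in dels:
        blocks.append(
            IndelBlock(
                "deletion_in_query",
                s,
                e,
                e - s + 1,
                _region_of_interval(s, e, L, n_tail, C_TAIL_LEN),
            )
        )
    for a, res in sorted(insertions.items()):
        blocks.append(
            IndelBlock(
                "insertion_in_query",
                a,
                a,
                len(res),
                _region_of_anchor(a, L, n_tail, C_TAIL_LEN),
            )
        )
    blocks.sort(key=lambda b: (b.ref_start, b.kind))
    return rec, GroundTruth(family, site_scores, blocks, n_background)


@dataclass
class PanelTruth:
    """Ground truth for a whole generated multi-species panel."""

    families: tuple[str, ...]  # catalog families attempted anywhere
    per_species: dict[str, dict[str, GroundTruth]]

    def expected_records(self, catalog: PTMCatalog) -> set[tuple]:
        """Comparable (species, family, position, r, status, score) tuples,
        mirroring ConservationMatrix records."""
        out = set()
        for species, fams in self.per_species.items():
            for family in catalog.families:
                for site in catalog.for_family(family):
                    for r in (0, 1, 2):
                        if family in fams:
                            score = fams[family].site_scores[(site.position, r)]
                            out.add((species, family, site.position, r, "scored", score))
                        else:
                            out.add((species, family, site.position, r, "no_homolog", None))
        return out


def make_panel(
    species_specs: list[tuple[str, dict[str, MutationSpec]]],
    panel: ReferencePanel | None = None,
    catalog: PTMCatalog | None = None,
) -> tuple[list[tuple[str, SequenceRecord]], PanelTruth]:
    """Generate one record per (species, family in that species' spec).

    Omitted families are recorded as absent homologs in the truth — e.g.
    chlorarachniophyte-like species carry only H3 and H4.
    """
    panel = panel or load_panel()
    catalog = catalog or load_catalog()
    labels = [label for label, _ in species_specs]
    if len(labels) != len(set(labels)):
        raise SyntheticError("duplicate species labels")
    records: list[tuple[str, SequenceRecord]] = []
    per_species: dict[str, dict[str, GroundTruth]] = {}
    seen_families: list[str] = []
    for label, fam_specs in species_specs:
        per_species[label] = {}
        for family, spec in fam_specs.items():
            rec, truth = mutate_reference(
                family, spec, panel, catalog, record_id=f"{label}_{family}"
            )
            records.append((label, rec))
            per_species[label][family] = truth
            if family not in seen_families:
                seen_families.append(family)
    return records, PanelTruth(tuple(seen_families), per_species)


def make_ctd(
    k: int,
    sub_rate: float = 0.0,
    flanks: tuple[int, int] = (50, 10),
    seed: int = 0,
    consensus: str = CONSENSUS,
    record_id: str | None = None,
) -> SequenceRecord:
    """An Rpb1-CTD-like record: random flanks around k tandem heptads, each
    position independently substituted with probability sub_rate (always to
    a different residue).  Deterministic under the seed."""
    if k < 0:
        raise SyntheticError("require k >= 0")
    if not (0 <= sub_rate <= 1):
        raise SyntheticError("require 0 <= sub_rate <= 1")
    rng = np.random.default_rng(seed)
    n_flank = "".join(rng.choice(list(AA20), size=flanks[0])) if flanks[0] else ""
    heptads: list[str] = []
    for _ in range(k):
        h = list(consensus)
        for i in range(7):
            if rng.random() < sub_rate:
                choices = [c for c in AA20 if c != h[i]]
                h[i] = choices[int(rng.integers(len(choices)))]
        heptads.append("".join(h))
    c_flank = "".join(rng.choice(list(AA20), size=flanks[1])) if flanks[1] else ""
    residues = n_flank + "".join(heptads) + c_flank
    if not residues:
        raise SyntheticError("empty CTD construct (k=0 with zero flanks)")
    return SequenceRecord(record_id or f"ctd_k{k}_seed{seed}", residues)
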