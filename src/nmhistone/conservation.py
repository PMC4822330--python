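"""Radius-based binary conservation scoring of histone PTM sites.

A catalogued site at mature reference position *p* is scored against a
query at three context radii r = 0, 1, 2 (0, 1 or 2 flanking residues on
each side; windows of 1, 3 and 5 residues).  The score is strictly
binary: 1 when every reference position in the window maps to a query
position (no deletion touching the window), the mapped positions are
contiguous (no insertion interrupting the window), and the query residue
at every mapped position is identical to the reference residue; 0
otherwise.  Conservative substitutions do not count.  Windows are
clipped at the reference termini (e.g. H4S1 has no N-terminal flank);
clipping is recorded per record.

Scoring is anchored on the human references: each query is globally
aligned to its family's panel member and scored through the induced
reference→query position map.  Assembling the scores over a set of
species gives the species x site x radius conservation matrix — the
machine-readable form of the "which marks survive in which nucleomorph"
summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .homology import (
    AlignmentParams,
    FamilyCall,
    PositionMap,
    ReferencePanel,
    align_pair,
    map_positions,
)
from .ptm_catalog import PTMCatalog, PTMSite
from .seqio import SequenceRecord

RADII = (0, 1, 2)


class ConservationError(ValueError):
    pass


@dataclass(frozen=True)
class ConservationRecord:
    species: str
    query_id: str
    site: PTMSite
    r: int
    status: str  # scored | no_homolog
    score: int | None = None
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.status == "scored" and self.score not in (0, 1):
            raise ConservationError("scored records need a binary score")
        if self.status == "no_homolog" and self.score is not None:
            raise ConservationError("no_homolog records carry no score")


@dataclass
class ConservationMatrix:
    records: list[ConservationRecord]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": rec.species,
                    "query_id": rec.query_id,
                    "family": rec.site.family,
                    "position": rec.site.position,
                    "mark_label": rec.site.mark_label,
                    "category": rec.site.category,
                    "r": rec.r,
                    "status": rec.status,
                    "score": rec.score if rec.score is not None else "",
                    "clipped": int(rec.clipped),
                }
                for rec in self.records
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "metadata": self.metadata,
            "records": self.to_dataframe().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def score_site(
    site: PTMSite,
    ref: SequenceRecord,
    query: SequenceRecord,
    pmap: PositionMap,
    r: int,
) -> int:
    """Binary conservation of *site* in *query* at context radius *r*.

    Requires the window [position-r, position+r] (clipped to the reference)
    to be fully mapped, contiguous in the query, and residue-identical.
    """
    if ref.id != site.family:
        raise ConservationError(
            f"site {site.mark_label} scored against reference {ref.id!r}"
        )
    if site.position > pmap.ref_length:
        raise ConservationError(f"{site.mark_label}: position beyond reference")
    lo = max(1, site.position - r)
    hi = min(pmap.ref_length, site.position + r)
    prev_q: int | None = None
    for p in range(lo, hi + 1):
        q = pmap.get(p)
        if q is None:
            return 0
        if prev_q is not None and q != prev_q + 1:
            return 0  # insertion interrupts the context window
        if query.residues[q - 1] != ref.residues[p - 1]:
            return 0
        prev_q = q
    return 1


def _is_clipped(site: PTMSite, r: int, ref_len: int) -> bool:
    return site.position - r < 1 or site.position + r > ref_len


def score_query(
    species: str,
    query: SequenceRecord,
    family: str,
    catalog: PTMCatalog,
    panel: ReferencePanel,
    aparams: AlignmentParams | None = None,
) -> list[ConservationRecord]:
    """Score every catalogued site of *family* on one query at all radii."""
    aparams = aparams or AlignmentParams()
    ref = panel[family]
    aln = align_pair(ref, query, aparams)
    pmap = map_positions(aln)
    out = []
    for site in catalog.for_family(family):
        for r in RADII:
            out.append(
                ConservationRecord(
                    species,
                    query.id,
                    site,
                    r,
                    "scored",
                    score_site(site, ref, query, pmap, r),
                    clipped=_is_clipped(site, r, len(ref)),
                )
            )
    return out


def score_matrix(
    queries: list[tuple[str, SequenceRecord, FamilyCall]],
    catalog: PTMCatalog,
    panel: ReferencePanel,
    aparams: AlignmentParams | None = None,
) -> ConservationMatrix:
    """Assemble the species x site x radius conservation matrix.

    *queries* pairs each record with its species label and family call.
    For every species and every catalog site: if the species has a called
    query of that family, the site is scored at r = 0, 1, 2; families with
    no called query yield status ``no_homolog`` for all their sites (this
    is how the absence of a nucleomorph-encoded H2B shows up).  Two called
    queries for the same (species, family) are an error — pick one upstream.
    """
    aparams = aparams or AlignmentParams()
    by_species: dict[str, dict[str, SequenceRecord]] = {}
    species_order: list[str] = []
    for species, record, call in queries:
        if species not in by_species:
            by_species[species] = {}
            species_order.append(species)
        if call.family in ("none",) or call.family not in catalog.families:
            continue
        if call.family in by_species[species]:
            raise ConservationError(
                f"duplicate {call.family} query for species {species!r}"
            )
        by_species[species][call.family] = record
    records: list[ConservationRecord] = []
    for species in species_order:
        calls = by_species[species]
        for family in catalog.families:
            if family in calls:
                records.extend(
                    score_query(species, calls[family], family, catalog, panel, aparams)
                )
            else:
                for site in catalog.for_family(family):
                    for r in RADII:
                        records.append(
                            ConservationRecord(species, "", site, r, "no_homolog")
                        )
    metadata = {
        "reference": "Homo sapiens panel (H3.3, H4, H2B)",
        "mapping": "pairwise global alignment, reference-anchored",
        "radius_convention": "r = flanking residues per side (windows 1/3/5)",
        "matrix": aparams.matrix,
        "gap_open": aparams.gap_open,
        "gap_extend": aparams.gap_extend,
    }
    return ConservationMatrix(records, metadata)


def plot_heatmap(matrix: ConservationMatrix, family: str, path: str | Path) -> None:
    """Render one family's conservation matrix as a heatmap (rows: species x r,
    columns: sites); requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    df = matrix.to_dataframe()
    df = df[df["family"] == family]
    sites = sorted(df["position"].unique())
    species = list(dict.fromkeys(df["species"]))
    rows = [(sp, r) for sp in species for r in RADII]
    grid = np.full((len(rows), len(sites)), np.nan)
    for (sp, r), i in zip(rows, range(len(rows))):
        for j, pos in enumerate(sites):
            sel = df[(df["species"] == sp) & (df["r"] == r) & (df["position"] == pos)]
            if len(sel) and sel.iloc[0]["status"] == "scored":
                grid[i, j] = float(sel.iloc[0]["score"])
    fig, ax = plt.subplots(figsize=(max(6, len(sites) * 0.5), max(3, len(rows) * 0.3)))
    ax.imshow(grid, cmap="Greys_r", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(len(sites)))
    labels = {
        rec.site.position: rec.site.mark_label
        for rec in matrix.records
        if rec.site.family == family
    }
    ax.set_xticklabels([labels[p] for p in sites], rotation=90)
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels([f"{sp} r={r}" for sp, r in rows])
    ax.set_title(f"{family} PTM-site conservation (grey = absent homolog)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
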