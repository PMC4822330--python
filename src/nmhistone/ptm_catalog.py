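"""Catalog of functionally characterised histone PTM sites.

The catalog lists the best-understood posttranslationally modified
residues on histones H3, H4 and H2B — the marks whose presence or absence
is diagnostic for heterochromatin formation, mitotic phosphorylation,
transcription elongation, promoter definition, and general activation or
repression of transcription.  Positions use mature-protein numbering
(initiator methionine stripped, 1-based), the convention under which
H3K4 is the fourth residue of ARTK...

The catalog ships as a versioned TSV inside the package
(``data/ptm_catalog.tsv``) so users can extend it; :func:`load_catalog`
validates every row against the mark-name grammar and, when a reference
panel is available, against the reference residue itself.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

FAMILIES = ("H3", "H4", "H2B")
CATEGORIES = (
    "heterochromatin",
    "mitosis_phospho",
    "elongation",
    "promoter",
    "activation_repression",
)
MODIFIABLE = set("KRSTY")

_MARK_RE = re.compile(r"^(H3|H4|H2A|H2B)([KRSTY])(\d+)")


class CatalogError(ValueError):
    """Packaged catalog failed validation — treat as fatal."""


@dataclass(frozen=True)
class PTMSite:
    """One modified residue: family, mature 1-based position, residue, mark."""

    family: str
    position: int
    expected_residue: str
    mark_label: str
    category: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise CatalogError(f"unknown family {self.family!r}")
        if self.category not in CATEGORIES:
            raise CatalogError(f"unknown category {self.category!r}")
        if self.expected_residue not in MODIFIABLE:
            raise CatalogError(
                f"{self.mark_label}: residue {self.expected_residue!r} is not modifiable"
            )
        if self.position < 1:
            raise CatalogError(f"{self.mark_label}: position must be 1-based")
        m = _MARK_RE.match(self.mark_label)
        if m is None:
            raise CatalogError(f"unparseable mark label {self.mark_label!r}")
        fam, res, pos = m.group(1), m.group(2), int(m.group(3))
        if (fam, res, pos) != (self.family, self.expected_residue, self.position):
            raise CatalogError(
                f"mark label {self.mark_label!r} inconsistent with "
                f"({self.family}, {self.expected_residue}, {self.position})"
            )


@dataclass(frozen=True)
class PTMCatalog:
    sites: tuple[PTMSite, ...]

    def __post_init__(self) -> None:
        keys = [(s.family, s.position) for s in self.sites]
        if len(keys) != len(set(keys)):
            raise CatalogError("duplicate (family, position) pairs in catalog")
        present = {s.category for s in self.sites}
        missing = set(CATEGORIES) - present
        if missing:
            raise CatalogError(f"categories with no sites: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def lookup(self, family: str, position: int) -> PTMSite | None:
        for s in self.sites:
            if s.family == family and s.position == position:
                return s
        return None

    def for_family(self, family: str) -> tuple[PTMSite, ...]:
        return tuple(s for s in self.sites if s.family == family)

    @property
    def families(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.sites:
            if s.family not in seen:
                seen.append(s.family)
        return tuple(seen)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "family": s.family,
                    "position": s.position,
                    "residue": s.expected_residue,
                    "mark_label": s.mark_label,
                    "category": s.category,
                }
                for s in self.sites
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _from_dataframe(df: pd.DataFrame) -> PTMCatalog:
    required = {"family", "position", "residue", "mark_label", "category"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogError(f"catalog table missing columns: {sorted(missing)}")
    sites = tuple(
        PTMSite(
            family=str(row.family),
            position=int(row.position),
            expected_residue=str(row.residue),
            mark_label=str(row.mark_label),
            category=str(row.category),
        )
        for row in df.itertuples()
    )
    return PTMCatalog(sites)


def load_catalog(path: str | Path | None = None) -> PTMCatalog:
    """Load and validate the PTM-site catalog (packaged TSV by default)."""
    if path is None:
        ref = resources.files("nmhistone.data").joinpath("ptm_catalog.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return _from_dataframe(df)
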