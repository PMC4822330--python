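"""Protein sequence input/output.

Reads FASTA and GenBank flat files into plain :class:`SequenceRecord`
objects and writes FASTA back out.  GenBank ingestion extracts one record
per annotated CDS (the protein product), which is how the nucleomorph
genome flat files are turned into a proteome without any external tools.

Normalisation rules applied on ingest:

* residues are uppercased;
* a single terminal ``*`` (stop) is stripped;
* the rare letters U (selenocysteine) and O (pyrrolysine) are mapped to
  ``X`` with a warning;
* an internal ``*`` is an error — it almost always signals a frameshifted
  or mis-annotated CDS and silently keeping it would poison alignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
ALPHABET = AMINO_ACIDS | {"X"}


class SequenceFormatError(ValueError):
    """Raised when an input file or record violates the sequence contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with a unique id and free-text description."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceFormatError("sequence record has an empty id")
        if not self.residues:
            raise SequenceFormatError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise SequenceFormatError(
                f"record {self.id!r} contains non-amino-acid letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def _normalize(raw: str, rec_id: str) -> str:
    s = raw.upper()
    if s.endswith("*"):
        s = s[:-1]
    if "*" in s:
        raise SequenceFormatError(f"record {rec_id!r} contains an internal stop codon '*'")
    if "U" in s or "O" in s:
        warnings.warn(
            f"record {rec_id!r}: U/O residues mapped to X", stacklevel=3
        )
        s = s.replace("U", "X").replace("O", "X")
    return s


def _check_unique(records: list[SequenceRecord]) -> list[SequenceRecord]:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise SequenceFormatError(f"duplicate record id {r.id!r}")
        seen.add(r.id)
    return records


def _read_fasta(path: Path) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(rec.id, _normalize(str(rec.seq), rec.id), rec.description)
        )
    return records


def _cds_id(feature, index: int) -> str:
    q = feature.qualifiers
    for key in ("locus_tag", "protein_id", "gene"):
        if key in q:
            return q[key][0]
    return f"CDS_{index}"


def _read_genbank(path: Path) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    for gb in SeqIO.parse(str(path), "genbank"):
        for i, feat in enumerate(gb.features):
            if feat.type != "CDS":
                continue
            rid = _cds_id(feat, i)
            if "translation" in feat.qualifiers:
                raw = feat.qualifiers["translation"][0]
            else:
                # Translate from coordinates: standard code, joins honored.
                if feat.location is None or any(
                    p is None for p in (feat.location.start, feat.location.end)
                ):
                    warnings.warn(f"skipping CDS {rid!r}: unresolvable location")
                    continue
                nt: Seq = feat.extract(gb.seq)
                if len(nt) % 3 != 0:
                    warnings.warn(f"skipping partial CDS {rid!r} (length not multiple of 3)")
                    continue
                raw = str(nt.translate(table=1))
            records.append(SequenceRecord(rid, _normalize(raw, rid), gb.id))
    return records


def read_sequences(path: str | Path, format: str = "fasta") -> list[SequenceRecord]:
    """Read protein records from *path* in the given format.

    ``format="fasta"`` yields one record per entry; ``format="genbank"``
    yields one record per annotated CDS (translation qualifier preferred,
    coordinate translation as fallback; partial CDS skipped with warning).
    """
    path = Path(path)
    if not path.exists():
        raise SequenceFormatError(f"no such file: {path}")
    if format == "fasta":
        records = _read_fasta(path)
    elif format == "genbank":
        records = _read_genbank(path)
    else:
        raise SequenceFormatError(f"unknown format {format!r}")
    if not records:
        raise SequenceFormatError(f"no sequence records found in {path}")
    return _check_unique(records)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at *width* columns."""
    path = Path(path)
    with path.open("w") as fh:
        for r in records:
            header = f">{r.id}" + (f" {r.description}" if r.description else "")
            fh.write(header + "\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i : i + width] + "\n")
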