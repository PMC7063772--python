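"""Reading, validating and filtering protein-coding sequences.

A CDS enters the analysis only if it looks like a complete, unambiguous
coding sequence: at least 150 nt, length divisible by 3, pure A/C/G/T,
and no in-frame stop codon before the final codon.  Incomplete-CDS
detection is sequence-level (frame, internal stop) because annotation
flags are not assumed to be available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "CodingSequence",
    "GenomeDataset",
    "read_fasta_cds",
    "apply_cds_filters",
    "translate_cds",
    "MIN_CDS_LENGTH",
]

MIN_CDS_LENGTH = 150

_VALID = set("ACGT")


@dataclass
class CodingSequence:
    """One coding sequence: id, DNA string, NCBI translation-table id."""

    id: str
    seq: str
    genetic_code: int = 1

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def codons(self) -> list[str]:
        return [self.seq[i:i + 3] for i in range(0, len(self.seq) - len(self.seq) % 3, 3)]


@dataclass
class GenomeDataset:
    """All kept CDSs of one species plus its trait record."""

    species_id: str
    cds_list: list[CodingSequence]
    traits: "object | None" = None  # SpeciesTraits; untyped to avoid cycle

    def __post_init__(self):
        ids = [c.id for c in self.cds_list]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate CDS ids in species {self.species_id}")


def read_fasta_cds(path: str | Path, genetic_code: int = 1) -> list[CodingSequence]:
    """Read a (possibly wrapped) multi-FASTA of CDSs.

    Ids are taken from headers up to the first whitespace; sequences are
    upper-cased.  An empty file returns an empty list.
    """
    path = Path(path)
    records = []
    with open(path) as fh:
        # fail with a line number on malformed input (sequence before header)
        for lineno, line in enumerate(fh, 1):
            if line.strip() and not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: sequence data before any FASTA header")
            if line.strip():
                break
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(CodingSequence(rec.id, str(rec.seq).upper(), genetic_code))
    return records


def _stop_codons(genetic_code: int) -> set[str]:
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    return set(table.stop_codons)


def apply_cds_filters(cds_list: Iterable[CodingSequence],
                      min_len: int = MIN_CDS_LENGTH,
                      ) -> tuple[list[CodingSequence], list[tuple[CodingSequence, str]]]:
    """Partition CDSs into (kept, rejected-with-reason).

    Reason codes: ``too_short``, ``frame`` (length not divisible by 3),
    ``ambiguity`` (non-ACGT character), ``internal_stop``.  The first
    failing check in that order is reported.  Filtering is total and
    idempotent; kept + rejected reconstitutes the input exactly.
    """
    kept: list[CodingSequence] = []
    rejected: list[tuple[CodingSequence, str]] = []
    for cds in cds_list:
        reason = None
        if len(cds.seq) < min_len:
            reason = "too_short"
        elif len(cds.seq) % 3 != 0:
            reason = "frame"
        elif not set(cds.seq) <= _VALID:
            reason = "ambiguity"
        else:
            stops = _stop_codons(cds.genetic_code)
            if any(c in stops for c in cds.codons[:-1]):
                reason = "internal_stop"
        if reason is None:
            kept.append(cds)
        else:
            rejected.append((cds, reason))
    return kept, rejected


def translate_cds(cds: CodingSequence) -> str:
    """Translate under the CDS's NCBI table; terminal stop rendered '*'."""
    if len(cds.seq) % 3 != 0:
        raise ValueError(f"{cds.id}: length {len(cds.seq)} not divisible by 3")
    table = CodonTable.unambiguous_dna_by_id[cds.genetic_code]
    stops = set(table.stop_codons)
    out = []
    for codon in cds.codons:
        out.append("*" if codon in stops else table.forward_table[codon])
    return "".join(out)


def write_rejection_report(rejected, path: str | Path) -> None:
    """TSV report of filtered-out CDSs (columns: cds_id, reason)."""
    with open(path, "w") as fh:
        fh.write("cds_id\treason\n")
        for cds, reason in rejected:
            fh.write(f"{cds.id}\t{reason}\n")
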