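"""Sequence containers and readers/writers for FASTA, GenBank and label tables.

All coordinates are 0-based half-open internally; 1-based inclusive
coordinates exist only at the GenBank boundary (Biopython already performs
that conversion). Sequences are normalized to uppercase ACGT; IUPAC
ambiguity codes are rejected under the default strict policy or dropped
record-wise under ``iupac="skip"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

from ._util import revcomp

logger = logging.getLogger(__name__)

GENETIC_CODE_TABLE = 11  # standard bacterial/archaeal code

_VALID = frozenset("ACGT")


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass(frozen=True)
class NucSequence:
    """A DNA record: identifier plus bases over the strict {A,C,G,T} alphabet."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        norm = self.bases.upper()
        if not norm:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(norm) - _VALID
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains disallowed characters {sorted(bad)}"
            )
        object.__setattr__(self, "bases", norm)

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(self.id, revcomp(self.bases))


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene: CDS on the coding strand plus genomic placement.

    ``genome_start``/``genome_end`` are 0-based half-open on the forward
    genome strand; ``cds.bases`` always starts with the start codon.
    """

    gene_id: str
    cds: NucSequence
    strand: str = "+"
    genome_start: int = 0
    genome_end: int = 0
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.cds) % 3 != 0:
            raise ValueError(
                f"CDS of {self.gene_id!r} has length {len(self.cds)}, not a multiple of 3"
            )

    def with_flags(self, extra: Iterable[str]) -> "GeneRecord":
        return replace(self, flags=self.flags | frozenset(extra))


def translate_cds(bases: str) -> str:
    """Translate a CDS with the bacterial genetic code; stops appear as '*'."""
    return str(Seq(bases).translate(table=GENETIC_CODE_TABLE))


def read_fasta(path, iupac: str = "strict") -> list[NucSequence]:
    """Read a FASTA file into NucSequence records.

    iupac: "strict" raises on any non-ACGT base, "skip" drops the record
    with a logged warning.
    """
    if iupac not in {"strict", "skip"}:
        raise ValueError(f"unknown iupac policy {iupac!r}")
    path = Path(path)
    text_head = path.read_text()[:1] if path.exists() else ""
    if text_head != ">":
        raise FormatError(f"{path}: not a FASTA file (missing '>' header)")
    out: list[NucSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            out.append(NucSequence(rec.id, str(rec.seq)))
        except ValueError as exc:
            if iupac == "skip":
                logger.warning("skipping record %s: %s", rec.id, exc)
            else:
                raise FormatError(f"{path}: {exc}") from exc
    if not out:
        raise FormatError(f"{path}: no FASTA records")
    return out


def write_fasta(seqs: Iterable[NucSequence], path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), width):
                fh.write(s.bases[i : i + width] + "\n")


def read_genbank_cds(path) -> list[GeneRecord]:
    """Extract one GeneRecord per non-pseudogene CDS from a GenBank flat file.

    Minus-strand features are reverse-complemented onto the coding strand;
    compound (join) locations are concatenated in feature order, which also
    covers genes wrapping the origin of a circular genome. CDSs whose
    length is not a multiple of 3 are skipped with a warning.
    """
    out: list[GeneRecord] = []
    n_cds = 0
    for rec in SeqIO.parse(str(path), "genbank"):
        counter = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            n_cds += 1
            if "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers:
                continue
            counter += 1
            quals = feat.qualifiers
            gene_id = (
                quals.get("locus_tag", quals.get("gene", [f"{rec.id}_cds{counter}"]))
            )[0]
            cds_seq = str(feat.location.extract(rec.seq))
            if len(cds_seq) % 3 != 0:
                logger.warning(
                    "skipping CDS %s: length %d not a multiple of 3", gene_id, len(cds_seq)
                )
                continue
            strand = "-" if feat.location.strand == -1 else "+"
            try:
                cds = NucSequence(gene_id, cds_seq)
            except ValueError as exc:
                logger.warning("skipping CDS %s: %s", gene_id, exc)
                continue
            out.append(
                GeneRecord(
                    gene_id=gene_id,
                    cds=cds,
                    strand=strand,
                    genome_start=int(feat.location.start),
                    genome_end=int(feat.location.end),
                )
            )
    if n_cds == 0:
        logger.warning("%s: no CDS features found", path)
    return out


def read_label_table(path, label: str = "") -> set[str]:
    """Read a one-id-per-line plain-text table; '#' comments and blanks ignored."""
    ids: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.add(line.split()[0])
    if not ids:
        logger.warning("%s: empty label table%s", path, f" for {label!r}" if label else "")
    return ids


def attach_flags(genes: list[GeneRecord], label: str, ids: set[str]) -> list[GeneRecord]:
    """Return genes with `label` added to the flags of every gene in `ids`."""
    present = {g.gene_id for g in genes}
    missing = ids - present
    if missing:
        logger.warning(
            "%d %s ids absent from the gene set (e.g. %s)",
            len(missing), label, sorted(missing)[:3],
        )
    return [g.with_flags([label]) if g.gene_id in ids else g for g in genes]
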