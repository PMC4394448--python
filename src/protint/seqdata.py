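"""Protein sequence and domain-annotation input handling.

Proteins are modelled as :class:`ProteinRecord` objects: an accession, a
sanitized amino-acid sequence over the 20 standard residues, and a set of
functional-domain identifiers (InterPro-style).  A :class:`Proteome` is an
ordered, accession-indexed collection of records.

Sanitization policy for non-standard residues: the ambiguity codes are
mapped to their most common resolution (B→D, Z→E, J→L), the rare translated
residues to their structural analogue (U→C selenocysteine, O→K
pyrrolysine), and stop marks (``*``) and fully unknown residues (``X``) are
dropped, so composition denominators count only informative residues.  Any
other letter is a hard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, fixed alphabetical order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(AMINO_ACIDS)

#: Ambiguity / non-standard residue resolution applied before any analysis.
NONSTANDARD_MAP: Mapping[str, str] = {
    "B": "D",  # Asx -> Asp
    "Z": "E",  # Glx -> Glu
    "J": "L",  # Leu/Ile -> Leu
    "U": "C",  # selenocysteine -> cysteine
    "O": "K",  # pyrrolysine -> lysine
    "X": "",   # unknown residue: dropped
    "*": "",   # stop/translation artifact: dropped
}


class SequenceError(ValueError):
    """Raised for malformed sequence or annotation input."""


def sanitize_sequence(raw: str, *, accession: str = "?") -> str:
    """Uppercase ``raw`` and resolve non-standard residues.

    Returns a sequence over the 20-letter alphabet.  Raises
    :class:`SequenceError` if an unknown character is met or nothing is left
    after dropping X/* characters.
    """
    out = []
    for ch in raw.upper():
        if ch in _AA_SET:
            out.append(ch)
        elif ch in NONSTANDARD_MAP:
            out.append(NONSTANDARD_MAP[ch])
        elif ch.isspace():
            continue
        else:
            raise SequenceError(
                f"{accession}: unexpected character {ch!r} in sequence"
            )
    seq = "".join(out)
    if not seq:
        raise SequenceError(f"{accession}: empty sequence after sanitization")
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: accession, sanitized sequence, domain-identifier set."""

    accession: str
    sequence: str
    domains: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.accession:
            raise SequenceError("accession must be non-empty")
        if not self.sequence:
            raise SequenceError(f"{self.accession}: sequence must be non-empty")
        object.__setattr__(self, "domains", frozenset(self.domains))

    def with_domains(self, domains: Iterable[str]) -> "ProteinRecord":
        return ProteinRecord(self.accession, self.sequence, frozenset(domains))

    def with_accession(self, accession: str) -> "ProteinRecord":
        return ProteinRecord(accession, self.sequence, self.domains)


class Proteome:
    """Ordered collection of :class:`ProteinRecord` with accession lookup."""

    def __init__(self, records: Iterable[ProteinRecord]):
        self.records: list[ProteinRecord] = list(records)
        self.index: dict[str, ProteinRecord] = {}
        for rec in self.records:
            if rec.accession in self.index:
                raise SequenceError(f"duplicate accession: {rec.accession}")
            self.index[rec.accession] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __contains__(self, accession: str) -> bool:
        return accession in self.index

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self.index[accession]

    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]

    def subset(self, accessions: Iterable[str]) -> "Proteome":
        """Records for ``accessions``, in the given order; missing ones error."""
        try:
            return Proteome(self.index[a] for a in accessions)
        except KeyError as exc:
            raise SequenceError(f"accession not in proteome: {exc.args[0]}") from None


def _accession_from_header(header_token: str) -> str:
    # UniProt pipe dialect "sp|P06401|PRGR_HUMAN" -> middle token
    if header_token.count("|") == 2:
        parts = header_token.split("|")
        if parts[0] in ("sp", "tr") and parts[1]:
            return parts[1]
    return header_token


def read_fasta(path: str | Path) -> Proteome:
    """Read a FASTA file into a :class:`Proteome`.

    The accession is the first whitespace-delimited header token
    (UniProt ``sp|ACC|NAME`` headers are reduced to the accession), sequences
    are uppercased and sanitized, and domain sets start empty.  Duplicate
    accessions and empty sequences are hard errors.
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        acc = _accession_from_header(entry.id)
        if not acc:
            raise SequenceError(f"{path}: FASTA entry with empty identifier")
        if acc in seen:
            raise SequenceError(f"{path}: duplicate accession {acc}")
        seen.add(acc)
        seq = str(entry.seq)
        if not seq:
            raise SequenceError(f"{path}: empty sequence for {acc}")
        records.append(ProteinRecord(acc, sanitize_sequence(seq, accession=acc)))
    if not records and path.stat().st_size > 0:
        raise SequenceError(f"{path}: no FASTA entries parsed")
    return Proteome(records)


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as plain FASTA (accession-only headers)."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_domain_table(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column TSV (accession<TAB>domain-id) into accession → domain set.

    Repeated pairs collapse (presence/absence semantics).  A line without
    exactly two non-empty columns is a hard error naming the line number.
    """
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 2 or not cols[0].strip() or not cols[1].strip():
                raise SequenceError(
                    f"{path}: line {lineno}: expected 'accession<TAB>domain', got {line!r}"
                )
            table.setdefault(cols[0].strip(), set()).add(cols[1].strip())
    return table


def read_accession_list(path: str | Path) -> list[str]:
    """Plain-text accession list, one per line; blanks and '#' comments skipped."""
    out: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            acc = line.strip()
            if not acc or acc.startswith("#"):
                continue
            if acc not in seen:
                seen.add(acc)
                out.append(acc)
    return out


def attach_domains(proteome: Proteome, annotations: Mapping[str, Iterable[str]]) -> Proteome:
    """Return a new proteome with each record's domain set replaced.

    Accessions absent from ``annotations`` get the empty set; annotation keys
    not present in the proteome are ignored with a logged warning.
    """
    unknown = sorted(set(annotations) - set(proteome.index))
    if unknown:
        logger.warning(
            "attach_domains: %d annotated accession(s) not in proteome (e.g. %s)",
            len(unknown), ", ".join(unknown[:5]),
        )
    return Proteome(
        rec.with_domains(annotations.get(rec.accession, ()))
        for rec in proteome
    )
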