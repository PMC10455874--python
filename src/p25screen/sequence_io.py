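"""FASTA input/output and nucleotide-to-protein plumbing.

TSA/EST records are nucleotide-level, while the p25alpha motif grammar is a
protein grammar, so every screening run starts by reading FASTA and producing
six-frame conceptual translations.  One internal DNA alphabet is used: U is
normalized to T on input (TSA records are mRNA-derived).  Translation never
stops at ``*`` — assembled transcripts routinely contain spurious in-frame
stops upstream of a real domain, so the full frame is always emitted.

Coordinates are 0-based half-open internally; everything user-facing
(motif hit positions, reports) is 1-based inclusive, matching BLAST
conventions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio.Data import CodonTable
from Bio.Data.IUPACData import ambiguous_dna_complement
from Bio import SeqIO

__all__ = [
    "Alphabet",
    "SequenceRecord",
    "FrameTranslation",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "translate_frame",
    "six_frame_translate",
]

NUCLEOTIDE_CHARS = frozenset("ACGTUNRYSWKMBDHV")
PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X*")
# residues unambiguous to protein: anything outside the nucleotide set
_PROTEIN_ONLY = PROTEIN_CHARS - NUCLEOTIDE_CHARS

_COMPLEMENT = {k.upper(): v.upper() for k, v in ambiguous_dna_complement.items()}


class Alphabet(str, enum.Enum):
    nucleotide = "nucleotide"
    protein = "protein"


class FastaFormatError(ValueError):
    """Malformed FASTA input (sequence before header, duplicate ids...)."""


class AlphabetError(ValueError):
    """Operation applied to a sequence of the wrong alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry.

    ``residues`` are stored uppercase; for nucleotide records U has already
    been normalized to T.
    """

    id: str
    residues: str
    alphabet: Alphabet
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        allowed = (
            NUCLEOTIDE_CHARS if self.alphabet is Alphabet.nucleotide else PROTEIN_CHARS
        )
        bad = set(self.residues) - allowed
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: residues {sorted(bad)} not valid for "
                f"{self.alphabet.value} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FrameTranslation:
    """Conceptual translation of one of the six reading frames.

    ``frame`` is one of +1..+3 (forward strand, offset ``frame-1``) or
    -1..-3 (same offsets on the reverse complement).
    """

    frame: int
    peptide: str
    source_id: str

    def __post_init__(self) -> None:
        if self.frame not in (1, 2, 3, -1, -2, -3):
            raise ValueError(f"invalid frame {self.frame}")


def guess_alphabet(residues: str) -> Alphabet:
    """Guess the alphabet of a sequence.

    Protein-only letters (E, F, I, L, P, Q, ...) force protein; otherwise the
    sequence is nucleotide when at least 90% of its letters are plain
    A/C/G/T/U/N — every amino-acid letter except those six doubles as an
    IUPAC ambiguity code, so letter membership alone cannot decide.
    """
    residues = residues.upper()
    if not residues:
        return Alphabet.nucleotide
    if set(residues) & _PROTEIN_ONLY:
        return Alphabet.protein
    plain = sum(residues.count(c) for c in "ACGTUN")
    return Alphabet.nucleotide if plain / len(residues) >= 0.9 else Alphabet.protein


def _normalize(residues: str, alphabet: Alphabet) -> str:
    residues = residues.upper()
    if alphabet is Alphabet.nucleotide:
        residues = residues.replace("U", "T")
    return residues


def read_fasta(path: str | Path, alphabet: Alphabet | None = None) -> list[SequenceRecord]:
    """Read a (possibly wrapped) multi-record FASTA file.

    Parameters
    ----------
    path:
        FASTA file; must exist.
    alphabet:
        Force an alphabet; by default each record's alphabet is guessed
        (nucleotide unless protein-only letters occur).

    Raises
    ------
    FileNotFoundError, FastaFormatError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # reject sequence data before any header up front; SeqIO silently skips it
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaFormatError(
                    f"{path}: sequence line before any '>' header"
                )
            break
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        ab = alphabet or guess_alphabet(residues)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=_normalize(residues, ab),
                alphabet=ab,
                description=desc,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC codes included).

    U is treated as T.  Raises :class:`AlphabetError` on protein input.
    """
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - NUCLEOTIDE_CHARS
    if bad:
        raise AlphabetError(f"not a nucleotide sequence, offending: {sorted(bad)}")
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def translate_frame(nucleotides: str, frame: int, table: str | int = "Standard") -> str:
    """Translate one reading frame; trailing partial codon dropped.

    Stop codons are rendered ``*`` and translation continues past them.
    Codons containing N or any other ambiguity code are rendered ``X``.
    """
    if frame < 0:
        nucleotides = reverse_complement(nucleotides)
    offset = abs(frame) - 1
    if isinstance(table, str):
        codon_table = CodonTable.unambiguous_dna_by_name[table]
    else:
        codon_table = CodonTable.unambiguous_dna_by_id[table]
    stops = set(codon_table.stop_codons)
    fwd = codon_table.forward_table
    chunk = nucleotides[offset:]
    peptide = []
    for i in range(0, len(chunk) - len(chunk) % 3, 3):
        codon = chunk[i : i + 3]
        if codon in stops:
            peptide.append("*")
        else:
            peptide.append(fwd.get(codon, "X"))
    return "".join(peptide)


def six_frame_translate(
    rec: SequenceRecord, table: str | int = "Standard"
) -> list[FrameTranslation]:
    """All six conceptual translations of a nucleotide record.

    Frames are ordered +1, +2, +3, -1, -2, -3.  Raises
    :class:`AlphabetError` on protein input.
    """
    if rec.alphabet is not Alphabet.nucleotide:
        raise AlphabetError(f"record {rec.id!r} is not nucleotide")
    return [
        FrameTranslation(frame=f, peptide=translate_frame(rec.residues, f, table), source_id=rec.id)
        for f in (1, 2, 3, -1, -2, -3)
    ]
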