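"""FASTA I/O and six-frame conceptual translation for EST banks.

Translation renders stop codons as ``.`` (the symbol the pattern language
builds on), ambiguous codons containing ``N`` as ``X`` unless every
resolution of the ambiguity agrees, and maps amino acid coordinates back
to nucleotide coordinates on the original strand.  Coordinates are 1-based
closed intervals throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, List, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import STOP, SrdaError

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
FRAMES = (1, 2, 3, -1, -2, -3)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(SrdaError):
    """Raised when a FASTA file violates the format contract."""


@dataclass(frozen=True)
class NucleotideRecord:
    """One EST entry: identifier, free-text description and DNA sequence."""

    id: str
    description: str
    seq: str

    def __post_init__(self):
        if not self.id:
            raise SrdaError("record id must be non-empty")
        if not self.seq:
            raise SrdaError(f"record {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class TranslatedFrame:
    """The conceptual translation of one record in one reading frame."""

    record_id: str
    frame: int  # 1, 2, 3, -1, -2, -3
    aa_seq: str


def _validate_dna(seq: str, context: str = "sequence") -> str:
    seq = seq.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in DNA_ALPHABET:
            raise SrdaError(
                f"{context}: character {ch!r} at position {pos} is not in ACGTN"
            )
    return seq


def read_fasta(path) -> List[NucleotideRecord]:
    """Read a FASTA file into a list of records, order preserved.

    Whitespace and gap characters are stripped from sequence lines and the
    sequence is upcased.  A file whose first non-blank line is not a header
    raises :class:`FastaFormatError` naming the line; duplicate ids raise
    an error listing the offending id.  An empty file yields an empty list
    with a logged warning.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: line {lineno}: expected FASTA header "
                        f"starting with '>', got {line.strip()[:30]!r}"
                    )
                break
        else:
            logger.warning("%s: empty FASTA file", path)
            return []

    records: List[NucleotideRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).replace("-", "").replace(" ", "").upper()
        records.append(NucleotideRecord(rec.id, rec.description, seq))
    return records


def write_fasta(records: Iterable[NucleotideRecord], path, width: int = 70) -> None:
    seqrecords = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def reverse_complement(seq: str) -> str:
    """Watson-Crick complement, reversed; ``N`` maps to ``N``."""
    seq = _validate_dna(seq, "reverse_complement")
    return seq.translate(_COMPLEMENT)[::-1]


def _codon_maps(table_id: int = 1):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    forward = dict(table.forward_table)
    for stop in table.stop_codons:
        forward[stop] = STOP
    return forward


_STANDARD_FORWARD = _codon_maps(1)


@lru_cache(maxsize=4096)
def _translate_codon(codon: str, table_id: int = 1) -> str:
    """Translate one codon; N-containing codons resolve to 'X' unless all
    resolutions of the ambiguity agree (including agreement on stop)."""
    forward = _STANDARD_FORWARD if table_id == 1 else _codon_maps(table_id)
    aa = forward.get(codon)
    if aa is not None:
        return aa
    # enumerate every resolution of the N positions
    resolved = {codon}
    while any("N" in c for c in resolved):
        nxt = set()
        for c in resolved:
            if "N" in c:
                i = c.index("N")
                for b in "ACGT":
                    nxt.add(c[:i] + b + c[i + 1:])
            else:
                nxt.add(c)
        resolved = nxt
    aas = {forward[c] for c in resolved}
    return aas.pop() if len(aas) == 1 else "X"


def translate(seq: str, frame: int, table_id: int = 1) -> str:
    """Conceptually translate ``seq`` in one reading frame.

    Frames 1-3 read the given strand with offsets 0-2; frames -1..-3 read
    the reverse complement the same way.  Stops are rendered ``.``, a
    trailing partial codon is dropped, and ``frame=0`` returns the reverse
    complement nucleotide string (compatibility mode inherited from the
    original spreadsheet tooling).
    """
    if frame not in (0, 1, 2, 3, -1, -2, -3):
        raise SrdaError(f"invalid frame {frame!r}; expected 0, +/-1, +/-2 or +/-3")
    seq = _validate_dna(seq, "translate")
    if frame == 0:
        return seq.translate(_COMPLEMENT)[::-1]
    if frame < 0:
        seq = seq.translate(_COMPLEMENT)[::-1]
    offset = abs(frame) - 1
    usable = seq[offset: offset + 3 * ((len(seq) - offset) // 3)]
    return "".join(
        _translate_codon(usable[i: i + 3], table_id)
        for i in range(0, len(usable), 3)
    )


def six_frames(rec: NucleotideRecord, table_id: int = 1) -> List[TranslatedFrame]:
    """Translate a record in frames 1, 2, 3, -1, -2, -3, in that order."""
    if len(rec.seq) < 3:
        logger.warning(
            "record %s is shorter than one codon; all frames empty", rec.id
        )
    return [
        TranslatedFrame(rec.id, f, translate(rec.seq, f, table_id)) for f in FRAMES
    ]


def aa_to_nt(aa_pos: int, frame: int, record_length: int) -> int:
    """Map a 1-based amino acid position to the 1-based original-strand
    position of the first nucleotide of its codon.

    For reverse frames the codon is read on the minus strand; the returned
    coordinate is the smallest (leftmost) of the three codon positions on
    the original strand.
    """
    if frame not in FRAMES:
        raise SrdaError(f"invalid frame {frame!r}")
    offset = abs(frame) - 1
    aa_len = (record_length - offset) // 3
    if not 1 <= aa_pos <= aa_len:
        raise SrdaError(
            f"aa position {aa_pos} outside translated length {aa_len} "
            f"(frame {frame}, record length {record_length})"
        )
    if frame > 0:
        return frame + 3 * (aa_pos - 1)
    f = -frame
    return record_length - (f - 1) - 3 * (aa_pos - 1) - 2


def translations_table(records: Sequence[NucleotideRecord], table_id: int = 1):
    """Six-frame translations of a bank as a tidy DataFrame
    (record_id, frame, aa_seq) for TSV export."""
    import pandas as pd

    rows = [
        (tf.record_id, tf.frame, tf.aa_seq)
        for rec in records
        for tf in six_frames(rec, table_id)
    ]
    return pd.DataFrame(rows, columns=["record_id", "frame", "aa_seq"])
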