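"""Single Residue Distribution Analysis (SRDA) pattern conversion.

SRDA reduces a protein sequence to the spacing of a small set of *key*
residues: key residues are kept verbatim, and every maximal run of other
residues is replaced by its length written in decimal.  With cysteine as
the key residue and translation stops included, a disulfide-rich toxin
such as ``...C ADW C NNHGPTI C...`` becomes ``...C3C7C...`` — a compact
scaffold fingerprint that survives the sequence variation of natural
combinatorial toxin libraries.

Conventions:

* Adjacent key residues are juxtaposed with no intervening digit
  (``CC``, never ``C0C``).
* Counts are plain decimal with no padding, so a two-digit spacing is
  exactly two characters wide.
* The translation stop is written ``.`` and is carried by
  ``KeySpec.include_stop`` rather than by the key set itself.
* ``X`` (ambiguous codon) is never a key residue and counts as one
  nonconserved position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Union

AA20 = "ACDEFGHIKLMNPQRSTVWY"
STOP = "."
#: residues legal in a translated sequence handed to :func:`srda_convert`
AA_ALPHABET = frozenset(AA20) | {"X", STOP}


class SrdaError(ValueError):
    """Base class for all toolkit errors."""


class AlphabetError(SrdaError):
    """A sequence contains a character outside the expected alphabet."""


class PatternSyntaxError(SrdaError):
    """A pattern or motif string violates the pattern grammar."""


@dataclass(frozen=True)
class KeySpec:
    """The key residues parameterizing an SRDA conversion.

    Parameters
    ----------
    keys:
        Uppercase one-letter amino acid codes whose positions are preserved.
    include_stop:
        Whether the translation stop symbol ``.`` is also treated as a key
        symbol.  ``KeySpec({'C'}, include_stop=True)`` is the conversion
        written SRDA("C.") and is the default throughout the toolkit.
    """

    keys: frozenset = field(default_factory=frozenset)
    include_stop: bool = True

    def __post_init__(self):
        keys = frozenset(self.keys)
        object.__setattr__(self, "keys", keys)
        if not keys and not self.include_stop:
            raise SrdaError("KeySpec needs at least one key residue or include_stop")
        bad = keys - frozenset(AA20)
        if bad:
            raise SrdaError(
                f"key residues must be standard amino acids, got {sorted(bad)!r}"
            )

    @classmethod
    def from_string(cls, text: str) -> "KeySpec":
        """Parse the compact notation used in the field, e.g. ``"C."`` or ``"CK"``.

        A trailing ``.`` sets ``include_stop``; all other characters are key
        residues.
        """
        text = text.strip()
        include_stop = text.endswith(STOP)
        if include_stop:
            text = text[:-1]
        if STOP in text:
            raise SrdaError("'.' may only appear at the end of a key specification")
        return cls(frozenset(text.upper()), include_stop)

    @property
    def key_symbols(self) -> frozenset:
        """Key residues plus ``.`` when stops are included."""
        return self.keys | {STOP} if self.include_stop else self.keys

    def __str__(self) -> str:
        return "".join(sorted(self.keys)) + (STOP if self.include_stop else "")


#: the conversion used for EST screening throughout: SRDA("C.")
DEFAULT_KEYSPEC = KeySpec(frozenset("C"), include_stop=True)


class PatternString(str):
    """A converted sequence: key symbols separated by decimal spacing counts.

    Subclasses :class:`str`, so a pattern can be used anywhere its text is
    expected; :attr:`tokens` exposes the alternating count/key structure.
    """

    @property
    def tokens(self) -> list:
        return tokenize_pattern(self)

    @property
    def source_length(self) -> int:
        """Length of the amino acid sequence the pattern was derived from."""
        return sum(t if isinstance(t, int) else 1 for t in self.tokens)


Token = Union[int, str]  # int = spacing count, str = single key symbol


def srda_convert(seq: str, spec: KeySpec = DEFAULT_KEYSPEC) -> PatternString:
    """Convert an amino acid sequence into its SRDA pattern.

    A left-to-right scan emits key symbols verbatim and each maximal run of
    non-key characters as its decimal length; zero-length runs emit nothing,
    so adjacent keys appear juxtaposed.  A trailing non-key run is emitted
    as a trailing number.  Pure function: equal inputs give byte-identical
    patterns.

    >>> srda_convert("MKACCGA", KeySpec(frozenset("C"), include_stop=False))
    '3CC2'
    """
    symbols = spec.key_symbols
    out: list[str] = []
    run = 0
    for pos, ch in enumerate(seq, start=1):
        if ch not in AA_ALPHABET:
            raise AlphabetError(
                f"character {ch!r} at position {pos} is not an amino acid, 'X' or '.'"
            )
        if ch in symbols:
            if run:
                out.append(str(run))
                run = 0
            out.append(ch)
        else:
            run += 1
    if run:
        out.append(str(run))
    return PatternString("".join(out))


def tokenize_pattern(text: str) -> list:
    """Split pattern text into alternating Count (int) and Key (str) tokens.

    Maximal digit runs become single counts; the operation is reversible
    (``"".join(map(str, tokens)) == text``).  Leading-zero counts are
    rejected — they cannot arise from :func:`srda_convert`.
    """
    tokens: list[Token] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isdigit():
            j = i
            while j < n and text[j].isdigit():
                j += 1
            run = text[i:j]
            if run[0] == "0":
                raise PatternSyntaxError(
                    f"count with leading zero at position {i + 1}: {run!r}"
                )
            tokens.append(int(run))
            i = j
        elif ch == STOP or ch.isalpha() and ch.isupper():
            tokens.append(ch)
            i += 1
        else:
            raise PatternSyntaxError(
                f"illegal pattern character {ch!r} at position {i + 1}"
            )
    return tokens


def detokenize(tokens: Iterable[Token]) -> PatternString:
    return PatternString("".join(str(t) for t in tokens))


def residue_counts(seq: str) -> Counter:
    """Exact residue multiset of ``seq``; the stop symbol is excluded.

    Supports the compound cytolysin query (lysine/cysteine count
    thresholds) and cross-checks against tokenized patterns.
    """
    counts = Counter(seq)
    counts.pop(STOP, None)
    return counts


_PATTERN_RE = re.compile(r"^(?:[A-Z.]|[1-9]\d*)*$")


def is_valid_pattern(text: str) -> bool:
    return bool(_PATTERN_RE.match(text))
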