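"""Screening-line motifs over SRDA patterns: grammar, matcher, registry.

A *screening line* is a wildcard query matched against converted pattern
text with the semantics of the classic VBA ``Like`` operator, applied as a
substring search (implicit gaps at both ends):

* ``?`` matches any single character,
* ``#`` matches any single digit 0-9,
* ``*`` matches a gap of zero or more characters,
* letters, digits and ``.`` match literally.

Matching is character-level, so ``#`` may legitimately match one digit of
a longer spacing count; an optional strict mode adds token-boundary guards.
A *compound* motif instead imposes residue-count thresholds on the
fragment's amino acid sequence (the cytolysin query: at least 6 lysines
and at most 2 cysteines per fragment).

The shipped registry carries the cysteine-scaffold sea anemone toxin
motifs together with the compound cytolysin motif; the two motifs that
proved too degenerate for screening (``###.`` and ``##C``) ship disabled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, List, Optional, Sequence, Tuple

from .core import (
    DEFAULT_KEYSPEC,
    KeySpec,
    PatternString,
    PatternSyntaxError,
    SrdaError,
    residue_counts,
    srda_convert,
    tokenize_pattern,
)

LINE_CHARS = re.compile(r"^[A-Z0-9.?#*]+$")


@dataclass(frozen=True)
class Predicate:
    """One residue-count threshold, e.g. K >= 6."""

    residue: str
    comparator: str  # "ge" or "le"
    threshold: int

    def holds(self, counts) -> bool:
        n = counts.get(self.residue, 0)
        return n >= self.threshold if self.comparator == "ge" else n <= self.threshold

    def __str__(self) -> str:
        op = ">=" if self.comparator == "ge" else "<="
        return f"{self.residue}{op}{self.threshold}"


@dataclass(frozen=True)
class MotifQuery:
    """A screening line or a compound residue-count predicate."""

    id: str
    line: Optional[str] = None
    compound: Optional[Tuple[Predicate, ...]] = None
    enabled_by_default: bool = True

    def __post_init__(self):
        if (self.line is None) == (self.compound is None):
            raise SrdaError(f"motif {self.id!r}: exactly one of line/compound required")
        if self.line is not None:
            _validate_line(self.line)
        if self.compound is not None and any(
            p.threshold < 0 for p in self.compound
        ):
            raise SrdaError(f"motif {self.id!r}: thresholds must be >= 0")

    @property
    def is_line(self) -> bool:
        return self.line is not None

    def __str__(self) -> str:
        if self.is_line:
            return self.line
        return " AND ".join(str(p) for p in self.compound)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one motif against one pattern or fragment."""

    motif_id: str
    matched: bool
    span: Optional[Tuple[int, int]] = None  # 1-based closed interval

    def __bool__(self) -> bool:
        return self.matched


def _validate_line(text: str) -> None:
    if not text:
        raise PatternSyntaxError("screening line must be non-empty")
    if not LINE_CHARS.match(text):
        bad = next(ch for ch in text if not LINE_CHARS.match(ch))
        raise PatternSyntaxError(f"illegal character {bad!r} in screening line {text!r}")
    if "**" in text:
        raise PatternSyntaxError(f"doubled gap '**' in screening line {text!r}")


_PRED_RE = re.compile(r"^\s*([A-Z])\s*([<>])\s*=?\s*(\d+)\s*$")


def parse_motif(text: str, id: str = "query", enabled: bool = True) -> MotifQuery:
    """Parse screening-line or compound syntax into a :class:`MotifQuery`.

    Compound syntax is one or more ``<residue> >= <n>`` / ``<= <n>``
    clauses joined with ``AND``; whitespace inside the comparator is
    tolerated (``K > = 6``).
    """
    text = text.strip()
    if not text:
        raise PatternSyntaxError("empty motif text")
    if "<" in text or ">" in text:
        preds = []
        for clause in re.split(r"\s+AND\s+", text, flags=re.IGNORECASE):
            m = _PRED_RE.match(clause)
            if not m:
                raise PatternSyntaxError(f"cannot parse predicate {clause!r}")
            residue, op, threshold = m.groups()
            preds.append(
                Predicate(residue, "ge" if op == ">" else "le", int(threshold))
            )
        return MotifQuery(id, compound=tuple(preds), enabled_by_default=enabled)
    return MotifQuery(id, line=text, enabled_by_default=enabled)


# ---------------------------------------------------------------------------
# Like-style matching


def _search(text: str, pat: str, start: int, memo: dict) -> Optional[int]:
    """Earliest (lazy) match end for ``pat`` anchored at ``start``; 0-based
    exclusive, or None.  Gap wildcards prefer the shortest expansion, like a
    non-greedy regex, so leftmost matches are leftmost-shortest."""

    def go(ti: int, pi: int) -> Optional[int]:
        key = (ti, pi)
        if key in memo:
            return memo[key]
        if pi == len(pat):
            res: Optional[int] = ti
        else:
            c = pat[pi]
            if c == "*":
                res = go(ti, pi + 1)
                if res is None and ti < len(text):
                    res = go(ti + 1, pi)
            elif ti < len(text) and (
                c == "?" or (c == "#" and text[ti].isdigit()) or c == text[ti]
            ):
                res = go(ti + 1, pi + 1)
            else:
                res = None
        memo[key] = res
        return res

    return go(start, 0)


def _all_ends(text: str, pat: str, start: int) -> List[int]:
    """Every feasible match end for ``pat`` anchored at ``start`` (strict
    mode needs alternatives when the lazy end fails a boundary guard)."""
    memo: dict = {}

    def go(ti: int, pi: int) -> frozenset:
        key = (ti, pi)
        if key in memo:
            return memo[key]
        if pi == len(pat):
            res = frozenset([ti])
        else:
            c = pat[pi]
            if c == "*":
                res = go(ti, pi + 1)
                if ti < len(text):
                    res = res | go(ti + 1, pi)
            elif ti < len(text) and (
                c == "?" or (c == "#" and text[ti].isdigit()) or c == text[ti]
            ):
                res = go(ti + 1, pi + 1)
            else:
                res = frozenset()
        memo[key] = res
        return res

    return sorted(go(start, 0))


def _strict_ok(text: str, pat: str, s: int, e: int) -> bool:
    """Token-boundary guards: a matched spacing count may not be flanked by
    further digits of the same count."""
    first, last = pat[0], pat[-1]
    if (first == "#" or first.isdigit()) and s > 0 and text[s - 1].isdigit():
        return False
    if (last == "#" or last.isdigit()) and e < len(text) and text[e].isdigit():
        return False
    return True


def match_motif(q: MotifQuery, p, strict: bool = False) -> MatchResult:
    """Match a line motif against pattern text as a substring search.

    Returns the leftmost match with its 1-based closed character span in
    the pattern text.  ``strict=True`` additionally requires that digits at
    the edges of the match not be adjacent to more digits in the text
    (token-boundary guard); the default reproduces plain character-level
    ``Like`` behaviour.
    """
    if not q.is_line:
        raise SrdaError(f"motif {q.id!r} is compound; use match_compound")
    text = str(p)
    pat = q.line
    memo: dict = {}
    for s in range(len(text) + 1):
        e = _search(text, pat, s, memo)
        if e is None:
            continue
        if strict and not _strict_ok(text, pat, s, e):
            for e2 in _all_ends(text, pat, s):
                if _strict_ok(text, pat, s, e2):
                    e = e2
                    break
            else:
                continue
        return MatchResult(q.id, True, (s + 1, e))
    return MatchResult(q.id, False, None)


def match_compound(q: MotifQuery, fragment_seq: str) -> MatchResult:
    """Evaluate a compound motif's residue-count thresholds on one
    stop-terminated fragment (counts exclude the stop symbol)."""
    if q.is_line:
        raise SrdaError(f"motif {q.id!r} is a line motif; use match_motif")
    counts = residue_counts(fragment_seq)
    return MatchResult(q.id, all(p.holds(counts) for p in q.compound))


def strip_stops(q: MotifQuery) -> MotifQuery:
    """Protein-mode variant: remove every stop symbol from a line motif.

    Reference protein databases hold mature sequences with no stop context,
    so termination symbols are eliminated from the queries before scanning.
    Idempotent; identity on compound motifs.
    """
    if not q.is_line or "." not in q.line:
        return q
    return replace(q, line=q.line.replace(".", ""))


# ---------------------------------------------------------------------------
# Registry


@dataclass
class MotifRegistry:
    """Ordered collection of uniquely-named motifs."""

    motifs: List[MotifQuery]
    provenance: str = ""

    def __post_init__(self):
        ids = [m.id for m in self.motifs]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise SrdaError(f"duplicate motif id {dup!r} in registry")

    def __iter__(self):
        return iter(self.motifs)

    def __len__(self):
        return len(self.motifs)

    def enabled(self) -> List[MotifQuery]:
        return [m for m in self.motifs if m.enabled_by_default]

    def get(self, motif_id: str) -> MotifQuery:
        for m in self.motifs:
            if m.id == motif_id:
                return m
        raise KeyError(motif_id)

    def ids(self) -> List[str]:
        return [m.id for m in self.motifs]

    def lines(self) -> List[str]:
        return [m.line for m in self.motifs if m.is_line]


def load_registry(path=None) -> MotifRegistry:
    """Load a motif registry from a TSV file (id, kind, query, enabled).

    With no path, loads the packaged sea anemone toxin registry.
    """
    if path is None:
        source = resources.files("srda").joinpath("data/motifs.tsv")
        text = source.read_text()
        provenance = "packaged sea anemone toxin screening lines"
    else:
        with open(path) as fh:
            text = fh.read()
        provenance = str(path)
    motifs = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) != 4:
            raise SrdaError(
                f"registry line {lineno}: expected 4 tab-separated fields, "
                f"got {len(parts)}"
            )
        motif_id, kind, query, enabled = parts
        if kind not in ("line", "compound"):
            raise SrdaError(f"registry line {lineno}: unknown kind {kind!r}")
        q = parse_motif(query, id=motif_id, enabled=enabled.strip() == "1")
        if (kind == "line") != q.is_line:
            raise SrdaError(
                f"registry line {lineno}: declared kind {kind!r} does not "
                f"match parsed query"
            )
        motifs.append(q)
    return MotifRegistry(motifs, provenance)


# ---------------------------------------------------------------------------
# Motif derivation from training patterns


def _pattern_to_consensus(tokens) -> list:
    out = []
    for t in tokens:
        if isinstance(t, int):
            out.append(("num", str(t)))
        else:
            out.append(("key", t))
    return out


def _merge(a, b):
    """Consensus of two motif tokens; None when structurally divergent."""
    if a == ("star",) or b == ("star",):
        return ("star",)
    ka, va = a[0], a[1]
    kb, vb = b[0], b[1]
    if ka == "key" or kb == "key":
        return a if a == b else None
    # both numeric-ish: num or hash
    la = len(va) if ka == "num" else a[1]
    lb = len(vb) if kb == "num" else b[1]
    if ka == "num" and kb == "num" and va == vb:
        return a
    if la == lb:
        return ("hash", la)
    return None


def _consensus_pair(a: list, b: list) -> list:
    la, lb = len(a), len(b)
    if la == lb:
        merged = [_merge(x, y) for x, y in zip(a, b)]
        if all(m is not None for m in merged):
            return _collapse_stars(
                [("star",) if m is None else m for m in merged]
            )
        return _collapse_stars([m if m is not None else ("star",) for m in merged])
    # unequal length: compatible prefix + suffix, divergent middle -> gap
    limit = min(la, lb)
    pre = []
    i = 0
    while i < limit:
        m = _merge(a[i], b[i])
        if m is None or m == ("star",):
            break
        pre.append(m)
        i += 1
    suf = []
    j = 0
    while j < limit - i:
        m = _merge(a[la - 1 - j], b[lb - 1 - j])
        if m is None or m == ("star",):
            break
        suf.append(m)
        j += 1
    suf.reverse()
    return _collapse_stars(pre + [("star",)] + suf)


def _collapse_stars(tokens: list) -> list:
    out = []
    for t in tokens:
        if t == ("star",) and out and out[-1] == ("star",):
            continue
        out.append(t)
    return out


def _render(tokens: list) -> str:
    parts = []
    for t in tokens:
        if t == ("star",):
            parts.append("*")
        elif t[0] == "hash":
            parts.append("#" * t[1])
        else:
            parts.append(t[1])
    return "".join(parts)


def generalize_patterns(patterns: Iterable[str]) -> str:
    """Derive a screening line as the greedy consensus of training patterns.

    Identical tokens stay literal; spacing counts that differ but share a
    digit length become that many ``#``; counts of different width or
    structurally divergent stretches collapse into a single ``*``.  Ties
    prefer ``#`` over ``*`` (the more specific wildcard).  Patterns are
    canonicalized by lexicographic sort first, so the result is independent
    of input order.

    >>> generalize_patterns(["C1C12C6C2CC", "C1C13C6C3CC"])
    'C1C##C6C#CC'
    """
    texts = sorted(str(p) for p in patterns)
    if not texts:
        raise SrdaError("generalize_patterns needs at least one pattern")
    consensus = _pattern_to_consensus(tokenize_pattern(texts[0]))
    for text in texts[1:]:
        consensus = _consensus_pair(
            consensus, _pattern_to_consensus(tokenize_pattern(text))
        )
    line = _render(consensus)
    _validate_line(line)
    return line


# ---------------------------------------------------------------------------
# Specificity evaluation on labeled protein sets


def evaluate_specificity(
    registry: MotifRegistry,
    labeled: Sequence[Tuple[str, str, str]],
    target_group: str,
    mode: str = "protein",
    spec: KeySpec = DEFAULT_KEYSPEC,
    strict: bool = False,
):
    """Count distinct sequences retrieved per motif on a labeled set.

    ``labeled`` is a sequence of ``(id, amino_acid_seq, group)`` triples.
    In protein mode stop symbols are stripped from the motifs and each
    whole sequence is treated as one fragment; in est mode sequences may
    contain stops and a motif may match any stop-terminated fragment.
    Returns a DataFrame with one row per enabled motif plus a ``distinct``
    union row; specificity is the integer percentage of retrieved sequences
    belonging to ``target_group``.
    """
    import pandas as pd

    from .screening import extract_fragments
    from .seqio import TranslatedFrame

    if mode not in ("protein", "est"):
        raise SrdaError(f"unknown mode {mode!r}; expected 'protein' or 'est'")
    if not labeled:
        raise SrdaError("labeled set must be non-empty")

    groups = sorted({g for _, _, g in labeled})
    motifs = registry.enabled()
    matched: dict[str, set] = {m.id: set() for m in motifs}
    group_of = {sid: g for sid, _, g in labeled}

    for sid, seq, _ in labeled:
        if mode == "protein":
            if "." in seq:
                raise SrdaError(
                    f"sequence {sid!r} contains a stop symbol; use est mode"
                )
            fragments = [(seq, srda_convert(seq, spec))]
        else:
            tf = TranslatedFrame(sid, 1, seq)
            fragments = [
                (f.seq, f.pattern) for f in extract_fragments(tf, spec=spec)
            ]
        for m in motifs:
            query = strip_stops(m) if mode == "protein" else m
            for frag_seq, pattern in fragments:
                hit = (
                    match_motif(query, pattern, strict=strict)
                    if query.is_line
                    else match_compound(query, frag_seq)
                )
                if hit.matched:
                    matched[m.id].add(sid)
                    break

    rows = []
    index = []
    union: set = set()
    for m in motifs:
        ids = matched[m.id]
        union |= ids
        rows.append(_specificity_row(ids, groups, group_of, target_group))
        index.append(m.id)
    rows.append(_specificity_row(union, groups, group_of, target_group))
    index.append("distinct")
    return pd.DataFrame(
        rows, index=index, columns=["total", *groups, "specificity_pct"]
    )


def _specificity_row(ids, groups, group_of, target_group):
    per_group = {g: sum(1 for i in ids if group_of[i] == g) for g in groups}
    total = len(ids)
    spec_pct = round(100 * per_group.get(target_group, 0) / total) if total else 0
    return [total, *(per_group[g] for g in groups), spec_pct]
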