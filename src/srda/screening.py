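"""Stop-bounded fragment extraction and whole-bank motif scanning.

A match is only ever allowed inside a single *fragment*: a maximal
stop-free stretch of one translated frame together with its terminating
stop.  A trailing stretch with no terminating stop is rejected as
partially identified.  This restriction is what keeps the degenerate
cysteine-spacing motifs usable on six-frame translations — a spacing run
that only lines up with a motif across an internal stop is never a hit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .core import DEFAULT_KEYSPEC, KeySpec, PatternString, SrdaError, srda_convert
from .motifs import MotifQuery, MotifRegistry, match_compound, match_motif
from .seqio import NucleotideRecord, TranslatedFrame, aa_to_nt, six_frames

STAGES = ("retrieved", "signal_approved", "deduplicated")


@dataclass(frozen=True)
class Fragment:
    """One stop-terminated stretch of a translated frame.

    ``seq`` ends with ``.`` and contains no internal stop; ``aa_start`` /
    ``aa_end`` are 1-based closed coordinates in the frame's amino acid
    string, including the terminating stop.
    """

    record_id: str
    frame: int
    aa_start: int
    aa_end: int
    seq: str
    pattern: PatternString


@dataclass(frozen=True)
class Hit:
    """One (record, frame, fragment, motif) match."""

    record_id: str
    frame: int
    motif_id: str
    aa_start: int
    aa_end: int
    nt_start: Optional[int]
    nt_end: Optional[int]
    fragment_seq: str
    pattern: str


def extract_fragments(
    tf: TranslatedFrame,
    min_len: int = 0,
    spec: KeySpec = DEFAULT_KEYSPEC,
) -> List[Fragment]:
    """Cut one translated frame into stop-terminated fragments.

    Fragments shorter than ``min_len`` residues (the stop excluded) are
    dropped, as is any trailing stretch lacking a terminating stop.
    """
    fragments: List[Fragment] = []
    aa = tf.aa_seq
    start = 0  # 0-based index of current run start
    for i, ch in enumerate(aa):
        if ch == ".":
            run_len = i - start
            if run_len >= max(min_len, 1):
                seq = aa[start : i + 1]
                fragments.append(
                    Fragment(
                        tf.record_id,
                        tf.frame,
                        start + 1,
                        i + 1,
                        seq,
                        srda_convert(seq, spec),
                    )
                )
            start = i + 1
    return fragments


@lru_cache(maxsize=512)
def _line_letter_needs(line: str) -> Tuple[Tuple[str, int], ...]:
    """Literal letter requirements of a screening line, for cheap
    pre-screening of fragments (a fragment lacking enough cysteines cannot
    match a five-cysteine motif)."""
    counts = Counter(ch for ch in line if ch.isalpha() and ch.isupper())
    return tuple(counts.items())


def _motif_hits_fragment(
    motif: MotifQuery, frag: Fragment, strict: bool
) -> bool:
    if motif.is_line:
        for letter, needed in _line_letter_needs(motif.line):
            if frag.seq.count(letter) < needed:
                return False
        return match_motif(motif, frag.pattern, strict=strict).matched
    return match_compound(motif, frag.seq).matched


def scan_record(
    rec: NucleotideRecord,
    registry: MotifRegistry,
    spec: KeySpec = DEFAULT_KEYSPEC,
    min_len: int = 0,
    strict: bool = False,
    table_id: int = 1,
) -> List[Hit]:
    """Scan all six frames of one record against every enabled motif.

    Line motifs are matched against the fragment's SRDA pattern, compound
    motifs against the fragment's amino acid sequence.  Nucleotide
    coordinates are the original-strand closed interval covered by the
    fragment's codons (stop codon included).
    """
    if not len(registry):
        raise SrdaError("registry is empty")
    hits: List[Hit] = []
    L = len(rec.seq)
    for tf in six_frames(rec, table_id):
        for frag in extract_fragments(tf, min_len=min_len, spec=spec):
            nt_a = aa_to_nt(frag.aa_start, frag.frame, L)
            nt_b = aa_to_nt(frag.aa_end, frag.frame, L)
            if frag.frame > 0:
                nt_start, nt_end = nt_a, nt_b + 2
            else:
                nt_start, nt_end = nt_b, nt_a + 2
            for motif in registry.enabled():
                if _motif_hits_fragment(motif, frag, strict):
                    hits.append(
                        Hit(
                            rec.id,
                            frag.frame,
                            motif.id,
                            frag.aa_start,
                            frag.aa_end,
                            nt_start,
                            nt_end,
                            frag.seq,
                            str(frag.pattern),
                        )
                    )
    return hits


@dataclass
class StageReport:
    """Per-motif clone counts at each pipeline stage.

    Counts are distinct EST clones per motif for the retrieval and
    signal-approval stages and unique mature domains for the deduplicated
    stage; they are non-increasing across stages.
    """

    motif_ids: List[str]
    counts: Dict[str, Dict[str, int]] = field(default_factory=dict)
    totals: Dict[str, int] = field(default_factory=dict)
    stages: Tuple[str, ...] = STAGES

    def count(self, motif_id: str, stage: str) -> int:
        return self.counts.get(motif_id, {}).get(stage, 0)

    def assert_monotone(self) -> None:
        for mid in self.motif_ids:
            row = [self.count(mid, s) for s in self.stages if s in self._present()]
            if any(a < b for a, b in zip(row, row[1:])):
                raise AssertionError(
                    f"stage counts increased for {mid!r}: {row}"
                )

    def _present(self) -> List[str]:
        seen = set()
        for per_stage in self.counts.values():
            seen.update(per_stage)
        seen.update(self.totals)
        return [s for s in self.stages if s in seen]

    def to_frame(self):
        import pandas as pd

        stages = self._present()
        rows = [
            [self.count(mid, s) for s in stages] for mid in self.motif_ids
        ]
        rows.append([self.totals.get(s, 0) for s in stages])
        return pd.DataFrame(
            rows, index=[*self.motif_ids, "TOTAL"], columns=stages
        )


def build_stage_report(
    registry: MotifRegistry,
    hits: Sequence[Hit],
    approved_hits: Optional[Sequence[Hit]] = None,
    dedup_motif_counts: Optional[Dict[str, int]] = None,
    n_unique: Optional[int] = None,
) -> StageReport:
    report = StageReport([m.id for m in registry.enabled()])

    def tally(stage: str, subset: Sequence[Hit]) -> None:
        per_motif: Dict[str, set] = {}
        union: set = set()
        for h in subset:
            per_motif.setdefault(h.motif_id, set()).add(h.record_id)
            union.add(h.record_id)
        for mid, ids in per_motif.items():
            report.counts.setdefault(mid, {})[stage] = len(ids)
        report.totals[stage] = len(union)

    tally("retrieved", hits)
    if approved_hits is not None:
        tally("signal_approved", approved_hits)
    if dedup_motif_counts is not None:
        for mid, n in dedup_motif_counts.items():
            report.counts.setdefault(mid, {})["deduplicated"] = n
        report.totals["deduplicated"] = n_unique or 0
    return report


def scan_bank(
    bank: Iterable[NucleotideRecord],
    registry: MotifRegistry,
    spec: KeySpec = DEFAULT_KEYSPEC,
    min_len: int = 0,
    strict: bool = False,
    table_id: int = 1,
) -> Tuple[List[Hit], StageReport]:
    """Scan a stream of records; returns all hits plus the retrieval-stage
    report (distinct clones per motif).  Memory is constant in bank size
    apart from the accumulated hits."""
    hits: List[Hit] = []
    for rec in bank:
        hits.extend(
            scan_record(
                rec, registry, spec=spec, min_len=min_len, strict=strict,
                table_id=table_id,
            )
        )
    return hits, build_stage_report(registry, hits)


def scan_protein_set(
    seqs: Iterable[Tuple[str, str]],
    registry: MotifRegistry,
    spec: KeySpec = DEFAULT_KEYSPEC,
    strict: bool = False,
) -> List[Hit]:
    """Scan whole protein sequences (no stop context) against the registry.

    Each sequence is treated as a single fragment; stop symbols are
    stripped from line motifs first.  Sequences containing ``.`` are
    rejected — translated EST material belongs in :func:`scan_bank`.
    """
    from .motifs import strip_stops

    hits: List[Hit] = []
    for sid, seq in seqs:
        if "." in seq:
            raise SrdaError(
                f"sequence {sid!r} contains a stop symbol; protein mode "
                "expects mature sequences — use EST scanning instead"
            )
        pattern = srda_convert(seq, spec)
        for motif in registry.enabled():
            query = strip_stops(motif)
            if query.is_line:
                ok = all(
                    seq.count(letter) >= needed
                    for letter, needed in _line_letter_needs(query.line)
                ) and match_motif(query, pattern, strict=strict).matched
            else:
                ok = match_compound(query, seq).matched
            if ok:
                hits.append(
                    Hit(sid, 0, motif.id, 1, len(seq), None, None, seq, str(pattern))
                )
    return hits


def hits_to_frame(hits: Sequence[Hit]):
    import pandas as pd

    return pd.DataFrame(
        [
            (
                h.record_id,
                h.frame,
                h.motif_id,
                h.aa_start,
                h.aa_end,
                h.nt_start,
                h.nt_end,
                h.fragment_seq,
                h.pattern,
            )
            for h in hits
        ],
        columns=[
            "record_id",
            "frame",
            "motif_id",
            "aa_start",
            "aa_end",
            "nt_start",
            "nt_end",
            "fragment_seq",
            "pattern",
        ],
    )


def hits_from_frame(df) -> List[Hit]:
    def _opt(v):
        import pandas as pd

        return None if pd.isna(v) else int(v)

    return [
        Hit(
            str(r.record_id),
            int(r.frame),
            str(r.motif_id),
            int(r.aa_start),
            int(r.aa_end),
            _opt(r.nt_start),
            _opt(r.nt_end),
            str(r.fragment_seq),
            str(r.pattern),
        )
        for r in df.itertuples(index=False)
    ]
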