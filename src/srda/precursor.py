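"""Secreted precursor calling: signal peptides, maturation, deduplication.

Toxin precursors are secreted, so a retrieved fragment is only accepted
when a plausible signal peptide starts it.  The built-in scorer is a
transparent reconstruction of classic signal peptide anatomy — an
initiator Met near the fragment start, a hydrophobic core (Kyte-Doolittle
sliding window) and small residues at the -3/-1 positions of the cleavage
site — with every window, weight and threshold exposed in
:class:`SignalScoringParams`.  Production-grade calls can instead be
supplied from SignalP short-format output, which overrides the heuristic.

Downstream of the signal, the propeptide is cleaved at dibasic sites
(KR/RR/KK) or at an arginine preceded by a glutamate two to four residues
upstream, whichever lies nearest the signal; mature domains identical
after processing are collapsed to one representative with a multiplicity
count, because homologous clones of a natural combinatorial toxin library
differ in the mature domain, not in its duplicated carriers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .core import SrdaError
from .motifs import MotifRegistry
from .screening import Hit, StageReport, build_stage_report

logger = logging.getLogger(__name__)

#: Kyte-Doolittle hydropathy; ambiguous 'X' scores neutral.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

#: residues tolerated at the -3 and -1 positions of a signal cleavage site
SMALL_RESIDUES = frozenset("AGSCT")

DIBASIC_PAIRS = frozenset({"KR", "RR", "KK"})


@dataclass(frozen=True)
class SignalScoringParams:
    """Tunable anatomy of the signal peptide scorer.

    All positions are 1-based and relative to the candidate initiator Met
    (the Met itself is residue 1).
    """

    limit_met: int = 30          # deepest fragment position searched for Met
    core_window: int = 8         # hydrophobic core window length (residues)
    core_span: Tuple[int, int] = (6, 20)       # window start positions
    cleavage_span: Tuple[int, int] = (15, 45)  # last signal residue positions
    small_residues: frozenset = SMALL_RESIDUES
    w_hydro: float = 1.0         # weight of the best core window sum
    w_cleavage: float = 8.0      # weight of the -3/-1 indicator
    threshold: float = 20.0      # acceptance threshold on the total score

    def __post_init__(self):
        if not (0 < self.core_span[0] <= self.core_span[1]):
            raise SrdaError("core_span must be positive and ordered")
        if not (0 < self.cleavage_span[0] <= self.cleavage_span[1]):
            raise SrdaError("cleavage_span must be positive and ordered")


DEFAULT_SIGNAL_PARAMS = SignalScoringParams()


@dataclass(frozen=True)
class SignalCall:
    """A scored signal peptide candidate within one fragment."""

    met_pos: int          # 1-based position of the initiator Met
    cleavage_after: int   # 1-based position of the last signal residue
    score: float
    accepted: bool


@dataclass(frozen=True)
class PrecursorCall:
    """An accepted open reading frame, decomposed into its domains."""

    record_id: str
    frame: int
    motif_ids: Tuple[str, ...]
    signal: SignalCall
    propeptide_span: Optional[Tuple[int, int]]  # fragment coords, or None
    mature_seq: str
    multiplicity: int = 1
    fragment_seq: str = ""

    @property
    def precursor_seq(self) -> str:
        """Full precursor: fragment minus the terminal stop."""
        return self.fragment_seq.rstrip(".")

    @property
    def mature_start(self) -> int:
        """1-based fragment position of the first mature residue."""
        return len(self.precursor_seq) - len(self.mature_seq) + 1


def _cleavage_indicator(body: str, c: int, small: frozenset) -> float:
    """-3/-1 rule at a cleavage after 1-based position c: 1.0 when both
    positions hold small residues, 0.5 for -1 only, else 0."""
    minus1 = body[c - 1]
    minus3 = body[c - 3] if c >= 3 else ""
    if minus1 in small:
        return 1.0 if minus3 in small else 0.5
    return 0.0


def signal_from(
    fragment_seq: str,
    params: SignalScoringParams = DEFAULT_SIGNAL_PARAMS,
) -> Optional[SignalCall]:
    """Score candidate signal peptides in a stop-terminated fragment.

    For every Met within ``limit_met`` of the fragment start the score is
    ``w_hydro * (best hydropathy window sum over the core span)`` plus
    ``w_cleavage * (-3/-1 small-residue indicator at the best cleavage
    position)``; the best cleavage maximizes the indicator, earliest
    position winning ties.  The arg-max Met is returned with
    ``accepted = score >= threshold``; with no Met in range the fragment
    draws no call at all (rejected as non-secreted).
    """
    body = fragment_seq.rstrip(".")
    n = len(body)
    best: Optional[SignalCall] = None
    for i in range(min(params.limit_met, n)):
        if body[i] != "M":
            continue
        m = i + 1  # 1-based Met position
        # hydrophobic core: best window sum, window starts at m+span
        lo = m + params.core_span[0] - 1
        hi = m + params.core_span[1] - 1
        core = float("-inf")
        for start in range(lo, hi + 1):
            if start + params.core_window - 1 > n:
                break
            window = body[start - 1 : start - 1 + params.core_window]
            core = max(core, sum(KYTE_DOOLITTLE.get(ch, 0.0) for ch in window))
        if core == float("-inf"):
            continue
        # cleavage: best -3/-1 indicator in the cleavage span, at least one
        # mature residue must remain before the stop
        c_lo = m + params.cleavage_span[0] - 1
        c_hi = min(m + params.cleavage_span[1] - 1, n - 1)
        best_c, best_ind = None, -1.0
        for c in range(c_lo, c_hi + 1):
            ind = _cleavage_indicator(body, c, params.small_residues)
            if ind > best_ind:
                best_c, best_ind = c, ind
        if best_c is None:
            continue
        score = params.w_hydro * core + params.w_cleavage * best_ind
        call = SignalCall(m, best_c, score, score >= params.threshold)
        if best is None or call.score > best.score:
            best = call
    return best


def signal_from_vba(
    seq: str,
    limit_met: int,
    frame: int,
    fmt: int,
    record_length: Optional[int] = None,
    params: SignalScoringParams = DEFAULT_SIGNAL_PARAMS,
) -> Optional[float]:
    """Format-switch wrapper mirroring the legacy spreadsheet interface.

    ``fmt`` 0: first nucleotide of the Met codon, 1: Met position,
    2: last nucleotide of the predicted signal, 3: last amino acid of the
    predicted signal, anything else: the best score.  Nucleotide formats
    need ``record_length``; ``frame`` is signed as in :mod:`srda.seqio`.
    """
    from .seqio import aa_to_nt

    call = signal_from(seq, params=replace_limit(params, limit_met))
    if call is None:
        return None
    if fmt == 1:
        return call.met_pos
    if fmt == 3:
        return call.cleavage_after
    if fmt in (0, 2):
        if record_length is None:
            raise SrdaError("nucleotide output formats require record_length")
        if fmt == 0:
            return aa_to_nt(call.met_pos, frame, record_length)
        start = aa_to_nt(call.cleavage_after, frame, record_length)
        return start + 2 if frame > 0 else start
    return call.score


def replace_limit(
    params: SignalScoringParams, limit_met: int
) -> SignalScoringParams:
    from dataclasses import replace

    return replace(params, limit_met=limit_met)


def load_signalp_output(path) -> Dict[str, SignalCall]:
    """Parse SignalP short-format output into fragment-id keyed calls.

    Expects the classic whitespace-column layout: comment lines start with
    ``#``; each data line carries the sequence name first, the Y-max
    position in the fifth column (cleavage is before that position), the
    D-score in the ninth and the Y/N decision in the tenth.  External calls
    take precedence over the internal heuristic when supplied.
    """
    calls: Dict[str, SignalCall] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fieldsv = line.split()
            try:
                name = fieldsv[0]
                ymax_pos = int(fieldsv[4])
                d_score = float(fieldsv[8])
                decision = fieldsv[9]
            except (IndexError, ValueError) as exc:
                raise SrdaError(
                    f"{path}: line {lineno}: cannot parse SignalP record "
                    f"({exc})"
                ) from exc
            calls[name] = SignalCall(
                met_pos=1,
                cleavage_after=ymax_pos - 1,
                score=d_score,
                accepted=decision.upper().startswith("Y"),
            )
    return calls


def mature_chain(seq: str, start: int) -> Tuple[str, int]:
    """Substring from ``start`` (1-based) to the residue before the first
    stop at or after ``start``, plus the 1-based end position.

    A sequence with no downstream stop raises — mirroring the rejection of
    partially identified fragments.
    """
    if not 1 <= start <= len(seq):
        raise SrdaError(f"start {start} outside sequence of length {len(seq)}")
    idx = seq.find(".", start - 1)
    if idx < 0:
        raise SrdaError("unterminated sequence: no stop symbol downstream")
    return seq[start - 1 : idx], idx


def predict_mature_start(precursor_after_signal: str) -> int:
    """1-based offset of the mature domain within the post-signal chain.

    Candidate cleavage sites are (a) after a dibasic KR/RR/KK pair and
    (b) after an arginine with a glutamate at position -2, -3 or -4
    (processing-quadruplet-style rule); the site nearest the signal
    cleavage wins.  With no candidate the mature domain starts immediately
    (offset 1, empty propeptide).
    """
    s = precursor_after_signal
    if not s:
        raise SrdaError("empty post-signal sequence")
    candidates = []
    for j in range(1, len(s) - 1):  # j: 0-based index of the site's last residue
        if s[j - 1 : j + 1] in DIBASIC_PAIRS:
            candidates.append(j + 2)
        elif s[j] == "R" and "E" in {
            s[j - k] for k in (2, 3, 4) if j - k >= 0
        }:
            candidates.append(j + 2)
    return min(candidates) if candidates else 1


def dedup_matures(calls: Sequence[PrecursorCall]) -> List[PrecursorCall]:
    """Collapse calls sharing an identical mature domain.

    The first-seen call represents each group and carries the group size
    as its multiplicity; representative order is first occurrence.
    Variation confined to the signal peptide or propeptide does not keep
    clones apart.
    """
    groups: Dict[str, PrecursorCall] = {}
    sizes: Dict[str, int] = {}
    for call in calls:
        if call.mature_seq not in groups:
            groups[call.mature_seq] = call
        sizes[call.mature_seq] = sizes.get(call.mature_seq, 0) + 1
    from dataclasses import replace

    return [
        replace(rep, multiplicity=sizes[mat]) for mat, rep in groups.items()
    ]


def call_precursors(
    hits: Sequence[Hit],
    registry: MotifRegistry,
    params: SignalScoringParams = DEFAULT_SIGNAL_PARAMS,
    signalp: Optional[Dict[str, SignalCall]] = None,
) -> Tuple[List[PrecursorCall], StageReport]:
    """Turn motif hits into deduplicated precursor calls plus stage counts.

    Hits are grouped per fragment; each fragment is screened by the signal
    scorer (or by external SignalP calls keyed ``record|frame|aa_start``),
    the propeptide and mature domain are assigned, and identical mature
    domains are collapsed.  Returns the calls and a report whose per-motif
    counts are non-increasing across stages.
    """
    # group hits per fragment, preserving first-seen order
    frag_hits: Dict[Tuple[str, int, int], List[Hit]] = {}
    for h in hits:
        frag_hits.setdefault((h.record_id, h.frame, h.aa_start), []).append(h)

    calls: List[PrecursorCall] = []
    approved_hits: List[Hit] = []
    for (rid, frame, aa_start), group in frag_hits.items():
        frag_seq = group[0].fragment_seq
        if signalp is not None:
            sig = signalp.get(f"{rid}|{frame}|{aa_start}")
        else:
            sig = signal_from(frag_seq, params)
        if sig is None or not sig.accepted:
            continue
        approved_hits.extend(group)
        body = frag_seq.rstrip(".")
        after_signal = body[sig.cleavage_after :]
        offset = predict_mature_start(after_signal)
        mature = after_signal[offset - 1 :]
        prop_span = (
            (sig.cleavage_after + 1, sig.cleavage_after + offset - 1)
            if offset > 1
            else None
        )
        motif_ids = tuple(dict.fromkeys(h.motif_id for h in group))
        calls.append(
            PrecursorCall(
                rid, frame, motif_ids, sig, prop_span, mature,
                fragment_seq=frag_seq,
            )
        )

    unique = dedup_matures(calls)
    dedup_motif_counts: Dict[str, int] = {}
    for call in unique:
        for mid in call.motif_ids:
            dedup_motif_counts[mid] = dedup_motif_counts.get(mid, 0) + 1
    report = build_stage_report(
        registry, hits, approved_hits, dedup_motif_counts, n_unique=len(unique)
    )
    return unique, report


def precursors_to_fasta(calls: Sequence[PrecursorCall], path) -> None:
    """Write accepted precursors as FASTA with domain offsets in the header:
    ``>record|frame|motifs|xN signal=1..s mature=m..e``."""
    with open(path, "w") as fh:
        for call in calls:
            seq = call.precursor_seq
            motifs = "+".join(call.motif_ids)
            fh.write(
                f">{call.record_id}|{call.frame}|{motifs}|x{call.multiplicity}"
                f" signal={call.signal.met_pos}..{call.signal.cleavage_after}"
                f" mature={call.mature_start}..{len(seq)}\n"
            )
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def load_blastp_annotations(path):
    """Adapter for blastp tabular output (-outfmt 6): returns a DataFrame
    keyed by query id, for joining homology annotations onto calls.  The
    toolkit never executes BLAST itself."""
    import pandas as pd

    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    return pd.read_csv(path, sep="\t", names=cols, comment="#")
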