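"""Synthetic EST banks with planted toxin precursors, decoys and noise.

The generator emulates the structure of a single-pass cDNA bank from a
venomous animal: a large background of non-coding reads, a minority of
reads carrying secreted precursor ORFs (signal peptide + acidic
propeptide + cysteine-patterned mature domain) embedded at random frames
and strands between untranslated regions, decoy reads that exercise the
pipeline's rejection rules (motif shapes split by an internal stop;
motif-bearing ORFs with no signal peptide), and point-mutant families
imitating a natural combinatorial toxin library.  A manifest records
every plant so expected hits, signal survivors and deduplication
multiplicities can be recomputed exactly; all randomness flows through a
single seeded generator, so equal seeds give byte-identical banks.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio.Data import CodonTable

from .core import AA20, DEFAULT_KEYSPEC, KeySpec, SrdaError, srda_convert
from .motifs import MotifQuery, load_registry, match_motif
from .precursor import DEFAULT_SIGNAL_PARAMS, predict_mature_start, signal_from
from .screening import extract_fragments
from .seqio import NucleotideRecord, TranslatedFrame, reverse_complement, translate

#: residues drawn for nonconserved positions: no Cys (key residue), no Lys
#: (kept clear of the compound cytolysin query), no Met (no spurious
#: initiators competing with the planted signal peptide).
NONKEY_RESIDUES = "ADEFGHILNPQRSTVWY"

#: hydrophobic core residues of generated signal peptides; deliberately
#: excludes Ala so that the only small--3/-1 context is the planted
#: cleavage site.
SIGNAL_CORE = "LIVF"

_BACK_TABLE: Dict[str, List[str]] = {}


def _back_table() -> Dict[str, List[str]]:
    if not _BACK_TABLE:
        table = CodonTable.unambiguous_dna_by_id[1]
        for codon, aa in table.forward_table.items():
            _BACK_TABLE.setdefault(aa, []).append(codon)
        _BACK_TABLE["."] = sorted(table.stop_codons)
        for codons in _BACK_TABLE.values():
            codons.sort()
    return _BACK_TABLE


@dataclass(frozen=True)
class GeneratorConfig:
    """Composition of a synthetic bank.

    Defaults produce a 5,000-read bank with 120 secreted precursors spread
    over the four discriminative cysteine-scaffold motifs — the scale at
    which every pipeline stage is exercised while a full scan stays
    desk-sized.
    """

    n_noise: int = 4830
    planted_per_motif: Mapping[str, int] = field(
        default_factory=lambda: {
            "motif 1": 30, "motif 2": 30, "motif 3": 30, "motif 4": 30,
        }
    )
    n_decoys: int = 50
    utr_len: Tuple[int, int] = (30, 150)
    noise_len: Tuple[int, int] = (250, 700)
    mutation_rate: float = 0.35
    max_family: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_noise < 0 or self.n_decoys < 0:
            raise SrdaError("counts must be >= 0")
        if any(v < 0 for v in self.planted_per_motif.values()):
            raise SrdaError("planted counts must be >= 0")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise SrdaError("mutation_rate must lie in [0, 1]")


@dataclass
class Plant:
    """One planted record and everything needed to recompute its calls."""

    record_id: str
    kind: str                 # "planted" | "decoy_signalless"
    motif_id: str
    frame: int                # signed frame on the stored strand
    strand: str               # "+" or "-"
    fragment_seq: str         # expected fragment, terminal '.' included
    signal_end: int           # 1-based last signal residue (0 for decoys)
    mature_start: int         # 1-based fragment position (0 for decoys)
    mature_seq: str
    nt_start: int             # ORF start on the stored strand, 1-based
    nt_end: int
    family: int


@dataclass
class PlantManifest:
    """Ground truth for a generated bank."""

    seed: int
    n_noise: int
    n_decoys: int
    plants: List[Plant] = field(default_factory=list)

    def planted(self) -> List[Plant]:
        return [p for p in self.plants if p.kind == "planted"]

    def decoys(self) -> List[Plant]:
        return [p for p in self.plants if p.kind != "planted"]

    def expected_multiplicities(self) -> Dict[str, int]:
        """Dedup multiplicity of every planted unique mature domain."""
        out: Dict[str, int] = {}
        for p in self.planted():
            out[p.mature_seq] = out.get(p.mature_seq, 0) + 1
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "n_noise": self.n_noise,
                    "n_decoys": self.n_decoys,
                    "plants": [asdict(p) for p in self.plants],
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "PlantManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            data["seed"],
            data["n_noise"],
            data["n_decoys"],
            [Plant(**p) for p in data["plants"]],
        )


# ---------------------------------------------------------------------------
# motif instantiation


def _instantiate_line(q: MotifQuery, rng: random.Random) -> List:
    """Turn a screening line into concrete pattern tokens (counts / keys)."""
    tokens: List = []
    i, line = 0, q.line
    while i < len(line):
        ch = line[i]
        if ch == "#":
            j = i
            while j < len(line) and line[j] == "#":
                j += 1
            width = j - i
            lo = 10 ** (width - 1) if width > 1 else 1
            tokens.append(rng.randint(lo, 10 ** width - 1))
            i = j
        elif ch.isdigit():
            j = i
            while j < len(line) and line[j].isdigit():
                j += 1
            tokens.append(int(line[i:j]))
            i = j
        elif ch == "*":
            # bounded random legal token run: up to 3 tokens, counts <= 99
            for _ in range(rng.randint(0, 3)):
                if rng.random() < 0.5:
                    tokens.append("C")
                else:
                    tokens.append(rng.randint(1, 99))
            i += 1
        elif ch == "?":
            tokens.append("C" if rng.random() < 0.5 else rng.randint(1, 9))
            i += 1
        else:  # literal key letter or '.'
            tokens.append(ch)
            i += 1
    return tokens


def sample_mature_for_motif(
    q: MotifQuery,
    rng: random.Random,
    spec: KeySpec = DEFAULT_KEYSPEC,
    max_len: int = 1500,
    max_tries: int = 50,
) -> str:
    """Draw a mature peptide whose SRDA pattern matches the line motif.

    Wildcards are instantiated uniformly within their constraints, the
    concrete pattern is realized with random nonconserved residues, and
    the result is verified by converting it back and matching the motif;
    unsatisfiable draws (over the length bound) raise after bounded
    retries.
    """
    if not q.is_line:
        raise SrdaError(f"motif {q.id!r} is compound; sample a cytolysin instead")
    for _ in range(max_tries):
        tokens = _instantiate_line(q, rng)
        # flanks: only where they cannot collide with edge wildcards
        first, last = q.line[0], q.line[-1]
        if first.isalpha() and rng.random() < 0.7:
            tokens.insert(0, rng.randint(1, 8))
        if last.isalpha() and rng.random() < 0.7:
            tokens.append(rng.randint(1, 8))
        parts: List[str] = []
        for t in tokens:
            if isinstance(t, int):
                parts.append(
                    "".join(rng.choice(NONKEY_RESIDUES) for _ in range(t))
                )
            elif t == ".":
                pass  # supplied by the fragment's terminal stop
            else:
                parts.append(t)
        mature = "".join(parts)
        if len(mature) > max_len:
            continue
        if match_motif(q, srda_convert(mature + ".", spec)).matched:
            return mature
    raise SrdaError(
        f"could not instantiate motif {q.id!r} within {max_len} residues"
    )


def sample_cytolysin_mature(rng: random.Random) -> str:
    """A lysine-rich, cysteine-free mature domain satisfying the compound
    cytolysin query (>= 6 K, <= 2 C) at the fragment level."""
    length = rng.randint(35, 60)
    n_lys = rng.randint(8, 14)
    positions = rng.sample(range(length), n_lys)
    residues = [rng.choice(NONKEY_RESIDUES) for _ in range(length)]
    for p in positions:
        residues[p] = "K"
    return "".join(residues)


def build_precursor(
    mature: str, rng: random.Random
) -> Tuple[str, int, int]:
    """Assemble signal + acidic propeptide + mature domain.

    Returns ``(precursor, signal_end, mature_start)`` with 1-based
    positions.  The signal is Met plus a Leu/Ile/Val/Phe core closed by an
    ``A-x-A`` cleavage context, sized so the planted cleavage falls inside
    the scorer's search span; the propeptide is Asp/Glu-rich and ends in a
    dibasic KR site, so the maturation rules recover the planted mature
    offset whatever cleavage the scorer picks within the signal tail.
    """
    core = "".join(rng.choice(SIGNAL_CORE) for _ in range(rng.randint(13, 17)))
    signal = "M" + core + "A" + rng.choice("QNLV") + "A"
    prop = "".join(rng.choice("DE") for _ in range(rng.randint(4, 10))) + "KR"
    precursor = signal + prop + mature
    return precursor, len(signal), len(signal) + len(prop) + 1


def embed_as_est(
    precursor: str,
    frame: int,
    strand: str,
    rng: random.Random,
    record_id: str = "EST",
    utr_len: Tuple[int, int] = (30, 150),
) -> Tuple[NucleotideRecord, int, int, int]:
    """Reverse-translate a peptide and embed it in an EST read.

    The ORF is padded with untranslated sequence so that it sits in the
    requested forward frame, an in-frame stop codon is placed immediately
    upstream (bounding the fragment at the first ORF residue) and a stop
    codon terminates it; on the minus strand the whole read is reverse
    complemented.  Returns ``(record, signed_frame, nt_start, nt_end)``
    with ORF coordinates on the stored strand.
    """
    if frame not in (1, 2, 3):
        raise SrdaError(f"embedding frame must be 1-3, got {frame!r}")
    if strand not in "+-":
        raise SrdaError(f"strand must be '+' or '-', got {strand!r}")
    back = _back_table()
    orf = "".join(rng.choice(back[aa]) for aa in precursor)
    orf += rng.choice(back["."])
    u5 = rng.randint(*utr_len)
    # junk + in-frame stop (3 nt) puts the ORF start at offset frame-1
    u5 += ((frame - 1) % 3 - u5) % 3
    utr5 = _random_dna(rng, u5) + rng.choice(back["."])
    utr3 = _random_dna(rng, rng.randint(*utr_len))
    seq = utr5 + orf + utr3
    nt_start = len(utr5) + 1
    nt_end = len(utr5) + len(orf)
    signed_frame = frame
    if strand == "-":
        L = len(seq)
        seq = reverse_complement(seq)
        nt_start, nt_end = L - nt_end + 1, L - nt_start + 1
        signed_frame = -frame
    return NucleotideRecord(record_id, "", seq), signed_frame, nt_start, nt_end


def _random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def sample_stop_split_pair(
    q: MotifQuery,
    rng: random.Random,
    spec: KeySpec = DEFAULT_KEYSPEC,
    max_tries: int = 50,
) -> Tuple[str, str]:
    """An (intact, split) peptide pair for the stop-spanning exclusion.

    The intact peptide's pattern matches the motif; the split variant has
    one internal residue replaced by a stop, placed so that no resulting
    fragment matches the motif on its own.  The pair demonstrates that a
    motif shape assembled across an internal stop is never reported.
    """
    for _ in range(max_tries):
        mature = sample_mature_for_motif(q, rng, spec=spec)
        order = sorted(
            (i for i, ch in enumerate(mature) if ch not in spec.key_symbols),
            key=lambda i: abs(i - len(mature) // 2),
        )
        for idx in order:
            split = mature[:idx] + "." + mature[idx + 1 :]
            tf = TranslatedFrame("split", 1, split + ".")
            if not any(
                match_motif(q, f.pattern).matched
                for f in extract_fragments(tf, spec=spec)
            ):
                return mature, split
    raise SrdaError(f"could not build a stop-split decoy for motif {q.id!r}")


def _verified_plant(
    precursor: str,
    signal_end: int,
    mature_start: int,
    rng: random.Random,
    motif: MotifQuery,
    spec: KeySpec,
    utr_len: Tuple[int, int],
    record_id: str,
    max_tries: int = 20,
) -> Tuple[NucleotideRecord, Plant]:
    """Embed a precursor and verify the full recovery chain: fragment
    boundaries, motif hit, accepted signal, exact mature recovery."""
    mature = precursor[mature_start - 1 :]
    for _ in range(max_tries):
        frame = rng.randint(1, 3)
        strand = rng.choice("+-")
        rec, signed, nt_start, nt_end = embed_as_est(
            precursor, frame, strand, rng, record_id, utr_len
        )
        aa = translate(rec.seq, signed)
        frags = [
            f
            for f in extract_fragments(
                TranslatedFrame(rec.id, signed, aa), spec=spec
            )
            if f.seq == precursor + "."
        ]
        if not frags:
            continue
        frag = frags[0]
        if motif.is_line:
            if not match_motif(motif, frag.pattern).matched:
                continue
        sig = signal_from(frag.seq, DEFAULT_SIGNAL_PARAMS)
        if sig is None or not sig.accepted:
            continue
        body = frag.seq.rstrip(".")
        offset = predict_mature_start(body[sig.cleavage_after :])
        if body[sig.cleavage_after + offset - 1 :] != mature:
            continue
        plant = Plant(
            record_id, "planted", motif.id, signed, strand,
            precursor + ".", signal_end, mature_start, mature,
            nt_start, nt_end, family=-1,
        )
        return rec, plant
    raise SrdaError(f"failed to verify plant for motif {motif.id!r}")


def generate_bank(
    cfg: GeneratorConfig,
    registry=None,
    spec: KeySpec = DEFAULT_KEYSPEC,
) -> Tuple[List[NucleotideRecord], PlantManifest]:
    """Generate a synthetic bank plus its plant manifest.

    Planted precursors are organized into point-mutant families: members
    drawn with probability ``mutation_rate`` carry a single nonconserved
    substitution in the mature domain (a distinct library member), the
    rest are exact clones whose matures collapse under deduplication.
    Decoy reads carry motif-conforming ORFs with no initiator Met within
    the scorer's search range, exercising the signal-stage rejection.
    """
    rng = random.Random(cfg.seed)
    registry = registry or load_registry()
    records: List[NucleotideRecord] = []
    manifest = PlantManifest(cfg.seed, cfg.n_noise, cfg.n_decoys)

    plant_no = 0
    family_no = 0
    for motif_id, n_wanted in cfg.planted_per_motif.items():
        motif = registry.get(motif_id)
        made = 0
        while made < n_wanted:
            family_no += 1
            if motif.is_line:
                base_mature = sample_mature_for_motif(motif, rng, spec=spec)
            else:
                base_mature = sample_cytolysin_mature(rng)
            family_size = min(rng.randint(1, cfg.max_family), n_wanted - made)
            for _ in range(family_size):
                mature = base_mature
                if rng.random() < cfg.mutation_rate:
                    mature = _point_mutate(base_mature, rng, spec, motif)
                precursor, sig_end, mat_start = build_precursor(mature, rng)
                plant_no += 1
                rec, plant = _verified_plant(
                    precursor, sig_end, mat_start, rng, motif, spec,
                    cfg.utr_len, f"PLT{plant_no:05d}",
                )
                plant.family = family_no
                records.append(rec)
                manifest.plants.append(plant)
                made += 1

    for d in range(cfg.n_decoys):
        motif = registry.get(rng.choice(list(cfg.planted_per_motif) or ["motif 1"]))
        if motif.is_line:
            mature = sample_mature_for_motif(motif, rng, spec=spec)
        else:
            mature = sample_cytolysin_mature(rng)
        prefix = "".join(rng.choice("DENQ") for _ in range(rng.randint(6, 12)))
        orf_aa = prefix + mature
        rec, signed, nt_start, nt_end = embed_as_est(
            orf_aa, rng.randint(1, 3), rng.choice("+-"), rng,
            f"DEC{d + 1:05d}", cfg.utr_len,
        )
        manifest.plants.append(
            Plant(
                rec.id, "decoy_signalless", motif.id, signed,
                "-" if signed < 0 else "+", orf_aa + ".", 0, 0, mature,
                nt_start, nt_end, family=0,
            )
        )
        records.append(rec)

    for i in range(cfg.n_noise):
        records.append(
            NucleotideRecord(
                f"NOISE{i + 1:05d}", "", _random_dna(rng, rng.randint(*cfg.noise_len))
            )
        )

    rng.shuffle(records)
    return records, manifest


def _point_mutate(
    mature: str, rng: random.Random, spec: KeySpec, motif: MotifQuery
) -> str:
    """Substitute one nonconserved residue for another; the SRDA pattern —
    and hence the motif relation — is untouched."""
    positions = [i for i, ch in enumerate(mature) if ch not in spec.key_symbols]
    if not positions:
        return mature
    i = rng.choice(positions)
    repl = rng.choice([r for r in NONKEY_RESIDUES if r != mature[i]])
    return mature[:i] + repl + mature[i + 1 :]
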