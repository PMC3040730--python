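# Methods

## The representation

Single Residue Distribution Analysis (SRDA) reduces a protein sequence to
the spacing of a chosen set of **key residues**. Every key residue is kept
verbatim; every maximal run of other residues is replaced by its decimal
length. With cysteine as the key and translation stops included — written
SRDA("C.") — a disulfide-rich toxin precursor becomes a short string such
as `18C1C13C6C2CC7.`: the cysteine scaffold and the position of the
terminating stop, nothing else. Because venom peptide families ("natural
combinatorial libraries") vary almost everywhere except the scaffold, this
fingerprint is stable across family members while remaining cheap to
compare.

Conversion rules, fixed by the representation:

* adjacent key residues are juxtaposed (`CC`, never `C0C`);
* counts are plain decimal with no padding, so a digit-width wildcard in a
  query means exactly "a count of that many digits";
* a trailing run of non-key residues is emitted as a trailing count;
* `X` (from an ambiguous codon) is an ordinary nonconserved residue;
* the stop symbol `.` is carried by the key specification
  (`KeySpec.include_stop`), not by the key set.

Length is conserved: the sum of counts plus the number of key tokens
always equals the source length. The test suite fuzzes this invariant and
the acceptance script re-measures it.

## Screening lines

Queries over converted text are **screening lines**: literals (key
letters, digits, `.`) plus `?` (any one character), `#` (any one digit)
and `*` (a gap of zero or more characters), matched with the semantics of
the classic VBA `Like` operator as a substring search — conceptually the
line is flanked by implicit `*` on both sides. Substring semantics is a
deliberate design choice: the published lines carry no leading spacing
count, yet must retrieve whole precursor-containing fragments, so a line
must be allowed to sit anywhere inside a fragment's pattern while never
crossing a fragment boundary.

Matching is character-level. One consequence is faithfully preserved: `#`
may match a single digit *inside* a longer count (`#C` matches `12C` by
taking the `2`). An optional strict mode adds token-boundary guards — a
digit at either edge of the match may not be adjacent to further digits —
for users who want counts treated atomically. The default remains the
character-level behaviour.

The matcher is a hand-written memoized backtracking scanner (lazy gap
expansion, leftmost match reported with its span). Its independent oracle
in the tests and the acceptance script compiles a line token-by-token into
a regular expression (`#`→`\d`, `?`→`.`, `*`→`.*?`) and the two routes are
compared on 10,000 random (motif, pattern) pairs.

The shipped registry contains the cysteine-scaffold screening lines for
sea anemone toxins plus one **compound** query for cysteine-free
cytolysins: at least 6 lysines and at most 2 cysteines per fragment,
evaluated on the fragment's amino acid sequence rather than its pattern.
The two lines too degenerate for bank screening (`###.`, `##C`) ship
disabled; the compound query is enabled in their place. A golden test pins
every line byte-for-byte.

**Deriving lines from training patterns.** `generalize_patterns` computes
a greedy consensus over tokenized patterns (sorted first, so the result is
input-order independent): identical tokens stay literal, counts of equal
digit width become that many `#`, and anything structurally divergent —
including length mismatches — collapses into a single `*`. Ties prefer
`#` over `*`: the narrower wildcard preserves more of the key-residue
distribution. The published derivation procedure is not stated in detail;
this is the package's documented reconstruction.

**Protein mode.** Reference protein databases hold mature sequences with
no stop context, so stop symbols are stripped from the queries before
scanning whole sequences. Stripping only removes constraints: anything
retrieved in EST mode (with the terminal stop present) is retrieved in
protein mode too, and the suite asserts that implication. The converse
does not hold — a stop-anchored line requires the match to sit at the
fragment's end, which protein mode cannot express.

## Fragments and the stop-spanning exclusion

Matches are only allowed inside a single **fragment**: a maximal stop-free
stretch of one translated frame together with its terminating stop. A
trailing stretch with no stop is rejected as partially identified; empty
stretches between consecutive stops are removed. This is the method's main
false-positive control on six-frame translations: a cysteine run that
lines up with a motif only across an internal stop is never a hit. The
acceptance script measures this directly with 200 generated decoy pairs
(split vs intact).

`min_len` defaults to 0 — no published length cut exists — and is exposed
in the API and CLI; around 30 residues is a sensible floor when mining
secreted precursors, since a signal peptide alone occupies ~16-22.

Translation uses the standard genetic code (table 1; configurable), stops
rendered `.`, codons containing `N` rendered `X` unless every resolution
of the ambiguity agrees. Coordinates are 1-based closed intervals; for
minus-strand frames the reported nucleotide position of a codon is the
leftmost of its three positions on the original strand.

## Signal peptides, maturation, deduplication

Secreted-precursor calling filters retrieved fragments on a signal
peptide, then assigns the mature domain.

The built-in signal scorer is a transparent reconstruction of classic
signal anatomy, not a reimplementation of any external predictor; the
original pipeline delegated final decisions to SignalP, and the
`load_signalp_output` adapter restores that behaviour when short-format
predictions are supplied. For each Met within `limit_met` (default 30)
residues of the fragment start:

    score = w_hydro * max window sum of Kyte-Doolittle hydropathy
            (window 8, window start 6-20 residues after the Met)
          + w_cleavage * best (-3,-1) small-residue indicator
            (small = {A,G,S,C,T}; 1.0 both positions, 0.5 for -1 only;
             cleavage candidates 15-45 residues after the Met,
             earliest position wins ties)

with defaults `w_hydro=1`, `w_cleavage=8`, acceptance threshold 20. The
weights put the two terms on comparable scales (a genuinely hydrophobic
8-residue core sums to roughly 22-36; the cleavage term contributes up to
8) and the threshold sits well above anything a hydrophilic fragment can
reach while accepting even an all-Ala core with a good cleavage box. All
knobs live in `SignalScoringParams` so results are reproducible fixtures,
not hidden constants.

Mature-domain assignment runs downstream of the signal cleavage: candidate
processing sites are (a) after a dibasic KR/RR/KK pair and (b) after an
arginine with a glutamate 2-4 residues upstream (a
processing-quadruplet-style rule); the candidate nearest the signal wins,
and with no candidate the mature domain starts immediately after the
signal. The published maturation procedure is cited but not restated in
the source material; these rules are labelled approximations and are kept
in one small function for replacement. Multi-peptide precursors (several
mature peptides from one ORF) are out of the default path.

Deduplication is exact string identity on the mature domain only —
variation in signal or propeptide does not keep clones apart — keeping the
first-seen call as representative with the group size as its
multiplicity. Near-duplicates (point mutants) are deliberately retained
as distinct: they are the combinatorial library, not sequencing noise.

Stage reports count distinct EST clones per motif at retrieval and signal
approval, and unique mature domains at deduplication; counts are
non-increasing across stages and the pipeline asserts this on every run.

## The synthetic bank generator

`generate_bank` emulates the structure of a venom-gland EST bank so that
every stage is testable offline. Defaults define the study conditions
used by the tests and the acceptance script: 5,000 reads — 4,830
random-DNA noise reads of 250-700 nt, 120 precursors planted across the
four discriminative motifs (30 each), and 50 signal-less decoys.

* **Mature domains** are drawn by inverting the motif relation:
  wildcards are instantiated uniformly within their constraints (`#` as a
  nonzero count digit, `##` as 10-99, `*` as up to three extra legal
  tokens with counts ≤ 99), counts realized with random nonconserved
  residues, and the draw verified by converting back and matching. The
  nonconserved alphabet excludes Cys (the key), Lys (kept clear of the
  compound cytolysin query) and Met (no spurious initiators).
* **Precursors** are Met + a 13-17 residue Leu/Ile/Val/Phe core + an
  `A-x-A` cleavage box, then an Asp/Glu-rich propeptide ending in KR, then
  the mature domain. The signal core deliberately avoids Ala so the only
  small-residue (-3,-1) context is the planted cleavage site; the
  propeptide contains no K/R before its terminal KR, so the maturation
  rules recover the planted mature domain exactly even if the scorer's
  cleavage lands a residue or two off.
* **Embedding** reverse-translates with random synonymous codons (no
  in-frame stops on the planted strand by construction), places an
  in-frame stop immediately upstream of the ORF — bounding the fragment at
  the initiator Met — pads with UTRs sized to put the ORF in the requested
  frame, and reverse-complements the whole read for minus-strand plants.
  Every plant is verified end-to-end (fragment boundaries, motif hit,
  accepted signal, exact mature recovery) before it enters the bank.
* **Families**: plants are grouped into families of up to 4 members;
  each member is either an exact clone or (with probability
  `mutation_rate`, default 0.35) a single nonconserved point mutant —
  pattern-preserving, so still motif-conforming. The manifest therefore
  predicts deduplication multiplicities exactly.
* **Decoys**: signal-less motif-bearing ORFs (no Met within the scorer's
  search depth) exercise the signal-stage rejection; stop-split decoy
  pairs (one internal residue replaced by a stop, verified unmatched)
  exercise the fragment rule.

All randomness flows through one seeded `random.Random`, so equal seeds
give byte-identical banks and manifests on any platform.

**What the generator does not emulate** — and therefore what passing
recovery tests do *not* show about real data: sequencing error and
chimeric reads, vector/adaptor contamination, codon-usage and GC bias
(codons are uniform), realistic transcript abundance distributions,
introns/UTR structure beyond length, and real signal-peptide diversity
(generated signals are idealized, which is why planted signal-stage
survival is ~100% rather than the messier rates real banks produce).
Wrong-frame translations of planted reads, however, do produce realistic
false hits on the degenerate motifs, and the pipeline demonstrably removes
them at the signal stage.

## Numerical and degenerate-input choices

* Leftmost match reported; gap wildcards expand lazily, so spans are
  leftmost-shortest (identical to the oracle's `.*?` behaviour).
* Cleavage-candidate ties break to the earliest position; Met candidates
  tie-break to the higher score, first-seen on equality.
* Empty FASTA files yield an empty bank with a warning; records shorter
  than one codon translate to six empty frames with a warning; fragments
  need at least one residue besides the stop.
* A fragment with no Met in range draws no signal call at all; a scored
  Met below threshold returns a call with `accepted=False` so callers can
  inspect near-misses.
* `frame=0` in `translate` returns the reverse-complement nucleotide
  string, mirroring the legacy spreadsheet interface this package's
  operation contracts descend from; `signal_from_vba` and `mature_chain`
  keep those format switches for the same reason.

## Problem sizes

The suite and the acceptance script use: 10,000 matcher/oracle pairs,
1,000 fuzzed sequences per invariant, 200 stop-split pairs, a 5,000-read
bank with 120 plants, and 1,000 generator draws per shipped line motif —
sizes at which every stage's behaviour is exercised at full coverage while
a complete run stays in the tens of seconds on one core.

## Known limitations

* The signal scorer is a heuristic; for publication-grade calls feed
  SignalP short-format output through the adapter.
* Maturation rules are approximations of the cited processing-site
  algorithms; complex precursors (multi-peptide, unusual quadruplets) need
  a custom rule set.
* Specificity evaluation reproduces the methodology (stripped-stop
  protein-mode scanning, per-motif distinct counts, union row), but
  published specificity tables depend on a historical database snapshot
  and cannot be regenerated from this package alone.
* No EST preprocessing (quality trimming, vector screening) and no contig
  assembly — by design: the method argues for scanning raw translated
  reads so rare point-mutant family members are not collapsed away.
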