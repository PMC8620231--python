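# Methods

## Model and assumptions

`txselect` treats transcript selection as a local competition governed by
extrinsic evidence. The unit of structure is the CDS chain: 1-based, fully
inclusive intervals, sorted and strictly separated, so the intron between
consecutive CDS `[a,b]` and `[c,d]` is `[b+1, c-1]` (AUGUSTUS/BRAKER hint
convention). UTRs and exon (non-CDS) coordinates play no role anywhere.

Evidence is a multiset of hints over feature identities
(seqname, start, end, type ∈ {intron, start, stop}, strand) with a source
label and a multiplicity. Matching is exact coordinate equality — no
tolerance window — because a hint "supports" a feature only when every
identifying characteristic matches. Duplicate hints from the same source are
merged by summing multiplicities: multiplicity is defined as the number of
supporting alignments, so duplicates are additive evidence, not noise.

Two transcripts compete only when they could be alternative readings of the
same coding region: they must share at least 3 adjacent coding nucleotides on
the same strand in the same reading frame. Frames are anchored at each
transcript's own translation start (cumulative coding length mod 3,
strand-aware). Because introns are at least 1 nt, three adjacent shared
coding positions always lie inside a single CDS interval of each transcript,
and the frame difference is constant across one interval intersection; the
implementation therefore checks CDS-interval intersections of length ≥ 3 at a
single position, which is exactly equivalent to per-nucleotide labelling (the
test suite verifies this equivalence against a brute-force labeller).

The comparison rule is deliberately lexicographic, not additive: differences
are examined in the fixed order s1 (intron fraction), s2 (codon fraction),
s3 (weighted intron support), s4 (weighted codon support), each against its
own threshold ε_j; the first difference strictly exceeding ε_j marks the
transcript with the smaller score, and equality with the threshold never
triggers. Marks accumulate over all overlapping pairs of the pre-removal
union and are applied once, so a transcript beaten by a stronger competitor
still eliminates weaker ones, and the outcome is independent of pair order.

## Tunable parameters

| name | meaning | default |
|---|---|---|
| `w_P, w_E, w_C, w_M` (`w_<SRC>`) | weight of one evidence source in a_f (dimensionless; multiplies alignment counts) | 0.1, 10, 5, 1 |
| `e_1, e_2` | thresholds on fraction differences (range 0–1) | 0, 0.5 |
| `e_3, e_4` | thresholds on weighted-support differences (weight × alignment-count units) | 25, 10 |
| `intron_support` | minimum supported intron fraction | 0.75 |
| `startstop_support` | minimum supported codon fraction | 1.0 |

The defaults are the published recommendation for combining an RNA-seq-based
with a protein-based prediction set and are used whenever a name is absent
from the configuration file.

## Design choices where the design was open

* **r_f for empty feature sets.** A single-CDS transcript has no introns, so
  r_i = 0/0. It is defined as 1.0: an intron-less transcript should not be
  automatically "low support" for lacking introns to support. a_i stays 0.
* **Start and stop are two features.** F_s holds them separately, so
  r_s ∈ {0, 0.5, 1}; protein alignments yield distinct start and stop hints.
* **Low-support removal is a joint (AND) condition** on s1 and s2. The OR
  reading, with the default codon threshold of 1.0, would discard every
  transcript with a single unsupported codon — an extreme behaviour that
  contradicts the rule's purpose of removing only weakly supported
  transcripts. The predicate is isolated in `low_support` so the alternative
  is a one-line change.
* **Absolute differences** are compared against the thresholds, and the
  transcript with the smaller decisive score is marked; with |Δ| > ε ≥ 0 the
  decisive scores can never be equal, so "smaller" is always well defined.
* **A feature counts once in |F_f ∩ E|** however many sources support it
  (set-intersection semantics); per-source contributions enter through a_f.
* **Start/stop hints are accepted from any source**, not just protein
  sources; the weight of non-protein codon hints is governed by their source
  weight anyway.
* **File indices are assigned by sorted path order**, not argument position.
  Identifier uniqueness across inputs still comes from an index prefix, but
  the combined output is byte-identical under any permutation of the input
  file list — output content is a pure function of input content. The merge
  representative (lowest file index, then identifier) is then equally stable.
* **Transcript-level accuracy counts unique CDS chains** within each set, as
  at the CDS level. This keeps the Sn/Sp swap symmetry exact and prevents
  duplicated structures from inflating either side.
* **Gene-level counting:** a predicted gene is correct if at least one of its
  isoforms exactly matches a reference isoform; each reference gene can be
  claimed by at most one predicted gene, matched greedily in coordinate
  order. Only the correctness of a predicted gene is externally defined; the
  claiming rule is this package's choice and is isolated in one function.
* **Stop-codon dialect.** Both GTF dialects are accepted: an explicit
  `stop_codon` row is authoritative (Ensembl-style, stop outside the CDS);
  otherwise the terminal 3 coding nucleotides of the chain are used
  (AUGUSTUS/BRAKER-style, stop inside the CDS). Likewise for `start_codon`.

## The synthetic world

The fixture generator emulates the *selection problem*, not the sequence
biology: loci are disjoint coordinate blocks on artificial contigs, so there
are no split or nested genes, no shared exons between distinct genes, and no
sequence content at all. Per locus it plants 1–2 isoforms (internal-exon
skipping or terminal extension, always in multiples of 3 nt so isoforms stay
frame-compatible), with probability 0.5 a conflicting decoy that overlaps a
true isoform in ≥ 3 in-frame coding nucleotides by construction, and with
probability 0.5 per isoform a duplicate in the second prediction file.

Default hint coverage reflects a typical two-evidence setting: RNA-seq (`E`)
hits 90% of true introns with multiplicities 1–10 (spliced-read stacks are
deep for expressed genes), proteins (`P`) hit 40% of introns and 80% of
codons at multiplicities 1–3 (conservation-limited), and decoy features
attract occasional multiplicity-1 protein hits (15% introns, 10% codons).
The `recovery` configuration is the stated best case: every true feature
hinted exactly once, decoys unsupported. Where a hint multiplicity exceeds 1
the writer sometimes splits it over two file rows, so parsers must sum.

A green fixture-based test therefore establishes that the algorithmic
contracts hold (scoring, comparison, clustering, determinism, recovery of a
planted truth) — it says nothing about accuracy on real genomes, where hint
error modes (misalignment, wrong splice variants, antisense RNA-seq) are
correlated with sequence, not independent coin flips.

Expected survival in the planted truth is computed by `oracle_select`, a
literal all-pairs transcription of the workflow with per-nucleotide frame
labelling, kept deliberately independent of the optimised implementation.

## Numerical and degenerate-input choices

* All score arithmetic is plain float; thresholds use strict `>` so ties at
  a threshold never mark (this also makes ε1 = 0 mean "any s1 difference
  decides", matching the default).
* Deterministic output: genes sorted by (seqname, leftmost, rightmost),
  renumbered `g1…`; members sorted by (span, identifier); no timestamps.
* Empty inputs are legal everywhere they are meaningful: empty prediction
  file → empty transcript list; empty selection → header-only GTF; empty
  prediction vs reference → Sp reported as 0 with a warning. An empty
  *reference* is an error (Sn undefined).
* CDS intervals that overlap or touch within one transcript are rejected at
  parse time (they would imply a zero-length intron).
* Transcripts whose CDS rows span mixed strands or sequences are an error;
  transcripts with no CDS rows are skipped with a warning.

## Known limitations

* No tolerance windows: evidence produced with different coordinate
  conventions (e.g. 0-based hints) will silently support nothing.
* Exon-body (coverage) evidence, alignment scores and UTRs are ignored;
  selection sees only introns and codon positions.
* Transcripts are kept or removed whole — no boundary adjustment, no merging
  of non-identical structures, no re-scoring after removal.
* The single-linkage gene definition can link chains of weakly related
  isoforms through intermediates, and conversely two isoforms that share no
  in-frame overlap are reported as separate genes.
* Scores ignore hint *absence* asymmetries between sources: a gene expressed
  at low level loses s3 competitions against highly expressed neighbours if
  they overlap, which is intended behaviour but worth knowing.
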