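# Methods

`crisparray` detects CRISPR arrays — runs of near-identical direct repeats
(typically 21–48 nt) separated by unique spacers — in bacterial and
archaeal genome sequences, refines their repeat/spacer boundaries, decides
their transcriptional orientation, indicates the likely CRISPR–Cas type,
and scores the confidence of each prediction. This note records the model
behind each stage, the parameters that matter, the numerical choices, and
what the synthetic fixtures do and do not demonstrate.

## Detection model

An array first appears as a short word (default 11-mer) repeating with
gaps in the spacer-length range. The permitted gap between occurrences of
a word of length *w* is

    min_space = max(0, 30 − w)        max_space = 125 + w

so that shorter seed words demand larger dissimilar gaps and longer words
tolerate them. The clamp at zero applies for *w* ≥ 30, where the raw
formula goes negative. Words may be as short as 6 (`word sizes > 5` is
enforced); the default of 11 is chosen so that even a ~23-nt repeat with
several substitutions still contains an exact shared 11-mer. Words
containing N never match — N is treated as mismatching every base,
including N. Maximal runs of one word whose successive gaps respect the
bounds become seed clusters; clusters with fewer than `min_repeats`
(default 3) occurrences are dropped, and clusters with overlapping genomic
spans — shifted copies of the same repeat region — are merged, keeping the
cluster with the most occurrences (ties: wider span, then leftmost, then
lexicographically smallest word). Arrays spanning the origin of a circular
genome are not sought; each sequence is scanned linearly.

## Alignment kernels

Three primitives, all specialised for short near-identical nucleotide
sequences, built on Biopython's `PairwiseAligner`:

* **Percent identity** (`repeat_identity`): the optimal global alignment
  under unit costs (match +1, mismatch 0, every gap −1) gives

      identity = max(0, matches − gaps) / |reference| × 100

  Gaps, insertions and deletions are all penalised equally (−1), and the
  denominator is always the reference length, so `identity(x, x) = 100`
  and a single terminal deletion against a 4-mer reference costs 50
  points ((3 − 1)/4).
* **Star multiple alignment** (`align_repeats`): every sequence is
  pairwise-aligned to the longest input and the alignments are merged on
  the common coordinate frame. For the near-identical inputs this package
  deals in, identical sequences align gap-free and a single insertion in
  one sequence yields exactly one gap column elsewhere. Consensus ties
  break alphabetically; columns where gaps are in the majority are dropped
  from the consensus.
* **Best ungapped local match** (`local_align_sweep`): Smith–Waterman with
  EMBOSS-water nucleotide scores (+5/−4) is run over a linear gap-penalty
  ladder from 5.5 to 10.0 in steps of 0.5; the first penalty level whose
  optimum is gap-free wins, otherwise the highest level's alignment is
  stripped to its longest contiguous block. Ties prefer the longer match,
  then the leftmost window position. A variant (`fit_align`) aligns a
  whole reference into a window under the same unit costs with free window
  ends, returning the subregion that maximises `repeat_identity` — used
  wherever a *region* rather than a block must be located (notably
  degenerate repeats carrying internal deletions, which occupy two
  ungapped blocks no single ungapped hit can span).

Column identity is the modal non-gap base count over the number of rows;
gaps and N count in the denominator only.

## Refinement cascade

A crude candidate (repeats = word occurrences) is refined by, in order:

1. **Repeat-end extension.** All repeats widen symmetrically while the
   flanking column identity is ≥ 75 %. That threshold automatically
   demands perfect identity for 2–3 repeats, allows one mismatch for 4–7,
   two for 8, and so on. Once per side, one weaker column (identity ≥ 50 %
   for arrays under 7 repeats, ≥ 40 % otherwise — e.g. 4/10 identical
   bases) may be crossed when the two columns beyond it are both above the
   primary threshold. If widening consumes every spacer the candidate is a
   tandem repeat.
2. **Tandem elimination.** Tandem repeats mimic arrays but lack the
   repeat-dissimilar spacer structure. Four tests: (a) widening consumed
   the majority of the "spacers" to zero length; (b) the spacer set aligns
   with fewer than 5 non-conserved columns; (c) the median over spacers of
   the best containment identity against the repeat (fitting the shorter
   into the longer, both directions) is ≥ 75 %; (d) a majority of spacers
   are *repeat-like*: an ungapped local match to the repeat covers ≥ 60 %
   of the shorter sequence at ≥ 80 % identity (spacers under 8 nt — slivers
   between period copies — count as repeat-like). Medians and majorities
   are used deliberately so that genuine arrays with a run of recently
   duplicated identical spacers (a documented natural pattern) survive.
   The filter runs right after extension and again at the end.
3. **Representative repeat.** The modal observed repeat sequence; ties go
   to the copy nearest the 5′ end; the runner-up is the alternative
   repeat. Re-selected after every mutating step, and once more after
   orientation is applied (the 5′ tie-break is only meaningful then —
   this also makes detection exactly strand-symmetric).
4. **Array extension.** Each flank is probed with a window of
   |repeat| + 1.33 × median spacer (2.5 × |repeat| when the median spacer
   is ≤ 15 or ≥ 70). The reference is the adjacent terminal repeat by
   default (`dynamic_adjacent_reference`, so a propagated end-mutation
   still matches), or the representative. The best ungapped hit is widened
   to the reference length and accepted as a new repeat when its identity
   is ≥ 67 % and its gap to the terminus is within [0, 125] — a zero gap
   encodes total spacer loss. Extension never removes units.
5. **Boundary refinement**, in priority order: a reference-bank match
   dictates the exact repeat extent (the bank stores validated repeats
   5′→3′; matching is strand-symmetric, exact-substring or ≥ 90 % of the
   entry length, and returns the boundary deltas to adopt the entry's
   extent); else an ATTGAAA motif ending within 4 bases of the repeat 3′
   end places the boundary one base after the motif (the "ATTGAAA(N)"
   rule); else terminal alignment columns whose mismatch fraction is
   ≥ 20 % are returned to the spacers, back to the first conserved column.
   Degeneracy is measured on the repeat *alignment* so that repeats
   carrying insertions cannot shift the frame, and gap characters are
   excluded — a terminal gap is a boundary error for step 7, not sequence
   degeneracy.
6. **Trimming.** Terminal repeats whose identity to the representative is
   not strictly above 66 % are removed with their flanking spacer, from
   each end inward, never below 3 repeats. The 66/67 pairing matters: two
   successive extensions at 67 % can compound to ~45 % identity against
   the first repeat, which trimming then removes. Steps 4–6 iterate to a
   fixed point (bounded at 10 rounds).
7. **Terminal gap correction.** A repeat missing bases at one end borrows
   them from the adjacent spacer when the boundary bases match the
   representative; extra terminal bases the representative lacks are
   recorded as insertions.
8. **Long-spacer recovery.** When a repeat degenerates past recognition it
   fuses its two spacers. Spacers longer than 1.2 × the median are scanned
   by fitting the whole representative (gaps allowed); a region passing
   the recovery identity threshold (default = the 67 % extension
   threshold; configurable down to a floor of 35 %) splits the spacer into
   spacer / degenerate repeat / spacer, with empty flanks recorded as lost
   spacers.
9. **Edit annotation.** Each repeat is aligned to the representative;
   substitutions become (column, base) records, missing runs become
   (column, length) deletions, and extra runs become insertions recorded
   as (1-based forward-genome position, bases) — so the representative
   itself stays gap-free and one repeat's insertion never forces gap
   columns on the others. In reports, insertions print as `C [3167138]`
   to the right of the unit.

Every step preserves the invariant that unit sequences tile the genomic
span exactly (`reconstruct_span`), which is asserted on every emitted
array.

## Orientation

Arrays are reported 5′→3′ on the transcribed strand, with the AT-rich
leader (which contains the promoter and receives new spacers) at the 5′
end. Four predictors vote: a reference-bank match on plus or minus strand;
the ATTGAAA motif at the repeat 3′ end on either strand; A/T richness of
the 200-nt flanks with a ≥ 5-percentage-point margin (the richer flank is
5′); and the repeat-degeneracy gradient over the terminal three repeats of
each end with a ≥ 5-point identity margin (the more-mutated end is 3′,
leader-distal). Majority vote decides; confidence is HIGH when at least
two predictors agree unopposed, MEDIUM on a one-vote margin, LOW (orientation
unknown) otherwise. Reverse calls trigger reverse complementation: unit
coordinates remap to the reverse-strand axis (start ↦ L − end), unit order
flips, and edit annotations are mirrored exactly. This is a deliberately
simplified orientation model restricted to these four sequence-level
signals; dedicated orientation tools add further predictors (including
RNA secondary structure) that are out of scope, so accuracy targets here
are set by fixture construction, not by any published benchmark.

## Typing

Two independent indications, listed side by side and never arbitrated: the
matched bank entry's type (e.g. `I-E (repeat match)`), and the types of
signature cas genes found in the annotation (`cas3 → I, cas9 → II,
cas10 → III, csf1 → IV, cas12/cpf1 → V`). The gene scan is
annotation-only — case-insensitive word matches with a small synonym table
(cpf1→cas12, csn1→cas9, …) over `gene` and `product` qualifiers of
gene/CDS features; no sequence-based gene search is attempted, and reports
for un-annotated input carry an explicit note that absent annotation does
not mean absent genes. The bundled repeat bank is a small, literature-derived
approximation (TSV: sequence, family, cas_type, source); users supply
their own via `--repeat-bank`.

## Quality score

Nine components, each bounded, summed into the final score; arrays ≥ 4.0
are *good*, in [0, 4) *questionable*, below 0 discarded and never
reported. The bounds are fixed by the method's published description; the
linear maps inside them are this package's calibration (the upstream
supplementary definitions are not public) and every knob sits in
`ScoringConfig`:

| component | range | definition here |
|---|---|---|
| cas gene bonus | 0/+1 | +1 iff annotated cas1 or cas2 present |
| known repeat bonus | 0/+3 | +3 iff bank match at ≥ 90 % |
| motif bonus | 0/+3 | +3 iff ATTGAAA(N) at representative 3′ end |
| repeat identity | 0…+3 | mean identity mapped [0.80, 1.00] → [0, 3], scaled by repeat count (0 at 2 repeats, full from 4) |
| repeat dissimilarity | −1.5/0 | −1.5 iff ≥ 2 repeat variants each occur ≥ 2× |
| repeat length | −3…+1 | +1 in [23, 47], linear to −3 at ≤ 17 / ≥ 55 |
| spacer length | −3…0 | 0 in [25, 50], linear to −3 at ≤ 15 / ≥ 70 |
| spacer identity | −3…+1 | +1 if all pairs < 50 %; graded on mean best-pair identity to −3 at full duplication; 0 for a single spacer |
| repeat mismatch | −1…+1 | +1 if every repeat ≥ 90 %; graded on mean identity to −1 at ≤ 70 % |

The attainable maximum is exactly 13, and the all-maxima fixture reaches
it. Near-identical (not just identical) spacers are penalised because the
graded component uses alignment identity, not exact duplication — this is
what keeps diverged tandem repeats below the good cutoff even when they
slip past the structural filter. The repeat-count scaling of the identity
component reflects that internal consistency of a two-repeat array is
trivially perfect and carries no evidence; minimal two-repeat arrays land
in the questionable band unless external evidence (bank, motif, cas genes)
lifts them.

## Output

The text report renders each unit as: 1-based position (forward-genome,
descending for reversed arrays), repeat length, identity to the
representative, spacer length, the repeat in dot notation ('.' match,
base = substitution, '-' = deletion), the spacer sequence, and insertion
notes. The GFF3 output nests `direct_repeat` children and spacer children
under a `repeat_region` parent in 1-based inclusive forward coordinates
with the array score and orientation note. The Sequence Ontology has no
universally validated "spacer" term, so spacers are emitted as
`sequence_feature` with `note=CRISPR_spacer` by default (configurable to a
literal `spacer` type). The pipeline is deterministic end to end:
identical inputs give byte-identical outputs.

## Synthetic fixtures: what they emulate, and what they do not

`simulate.PlantSpec`/`generate_genome` plant arrays with exact truth:
AT-rich leaders, per-repeat substitution loads with a leader-distal
gradient (`rate × gradient^rank`), explicit substitution/insertion/deletion
events, total spacer loss, a 3′ motif suffix, and minus-strand placement.
Background is i.i.d. at configurable GC; all sampling derives sub-seeds
from one integer seed, bit-reproducibly. `generate_tandem_decoy` produces
adjacent diverged copies of a single unit.

Two generator rules guarantee that the planted truth is *identifiable*,
i.e. the unique optimum of the detection objective, without which
"boundary-exact recovery" would be ill-posed:

* the two bases at each end of every spacer cycle through A/C/G/T across
  units, so the column just past a true boundary can never satisfy the
  extension rules (with unconstrained random spacers, the flanking column
  is unanimous with probability 4^(1−n) per column and the planted
  boundary stops being the maximum-likelihood one);
* mutations never touch the first 11 bases of a repeat copy (except where
  a scenario deliberately destroys the seed word), so recovery of planted
  units tests refinement rather than seeding luck; the fused-spacer
  scenario additionally re-samples until the degenerate copy shares no
  11-mer with the clean repeat and the recovery fit points exactly at it.

Consequences for interpretation: passing fixture suites demonstrates the
algorithmic contracts — boundary logic, tandem discrimination, orientation
voting, recovery and scoring — under the stated conditions (repeats
23–48 nt, spacers 25–45 nt, 3–30 repeats, i.i.d. background). They do not
demonstrate performance on real genomes, where spacer composition is not
i.i.d., repeats have family-specific structure, mobile elements create
CRISPR-like repeats the decoy model does not imitate, and annotation
quality varies. The strand-symmetry suite uses mutation-free arrays
because the one-weak-column extension rule looks two columns ahead and is
therefore inherently direction-dependent on heavily mutated ends.

## Numerical and degenerate-input choices

Internal coordinates are 0-based half-open on the reported strand; output
converts to 1-based inclusive. Lowercase input is uppercased; IUPAC codes
other than N are rejected with a clear error. Identity comparisons use a
1e-9 tolerance on the threshold side that keeps boundary fixtures exact
(trim removes at ≤ 66 %, extension accepts at ≥ 67 %). Co-optimal
alignment ties are always broken deterministically (shortest then leftmost
fitted region; longer then leftmost local hit; alphabetical consensus).
Candidates whose refined spans overlap are deduplicated, keeping the array
with more repeats, then the wider, then the leftmost. The refinement
fixed-point loop is bounded at 10 iterations; `refine` is idempotent on
all fixture classes. Fixture problem sizes in the test and acceptance
suites (200/100/60/50/30-genome populations of a few kilobases each) were
chosen as the smallest populations that make the measured rates stable to
the integer seed.

## Known limitations

* The orientation predictor is a four-signal simplification; on arrays
  without leader, motif, bank or gradient signal it abstains
  (forward-as-found, flagged).
* The bundled repeat bank is illustrative, not exhaustive; typing and the
  known-repeat score bonus are only as good as the bank and the input
  annotation.
* Score components 4–9 are this package's calibration inside the
  published ranges; scores are comparable within a run, and the
  good/questionable boundary behaviour is validated on fixtures, but
  absolute values need not match other implementations.
* Arrays crossing the origin of circular genomes are not detected.
* The word scanner holds a dictionary of all w-mers of a sequence in
  memory — appropriate for single microbial genomes, not for metagenome
  assemblies.
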