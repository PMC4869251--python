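# crisparray

Detection, refinement, orientation, typing and quality scoring of CRISPR
arrays in bacterial and archaeal genomes.

CRISPR arrays are loci of near-identical direct repeats (typically
21–48 nt) separated by unique spacers acquired from foreign DNA; they are
the memory of prokaryotic adaptive immunity. Finding them accurately is
harder than finding repeats: tandem repeats mimic them, repeats mutate and
degenerate toward the leader-distal (3′) end, individual repeats carry
insertions and deletions, whole spacers are lost, and roughly half of all
arrays sit on the minus strand — so tools that ignore orientation report
them backwards, corrupting every downstream spacer/protospacer/PAM
analysis. `crisparray` is for microbial genomicists and annotation
pipelines that need arrays with exact repeat/spacer boundaries, corrected
orientation, per-repeat mutation annotations and a defensible confidence
score.

## How it works

1. **Seed detection** — a repeated word (default 11-mer) with gaps in the
   spacer range `[max(0, 30 − w), 125 + w]` marks a putative array.
2. **Tandem elimination** — candidates whose "spacers" lack a
   repeat-dissimilar structure are discarded as tandem repeats.
3. **Refinement** — repeats widen while flanking column identity ≥ 75 %;
   the array extends into its flanks with a Smith–Waterman gap-penalty
   sweep (5.5→10, accepting degenerate terminal repeats at ≥ 67 %
   identity, gap ≤ 125 nt, down to 0 for total spacer loss); boundaries
   are corrected against a library of known repeats, the ATTGAAA(N) 3′
   motif, or end-column degeneracy (≥ 20 % mismatch); terminal repeats not
   strictly above 66 % identity are trimmed; unusually long spacers
   (> 1.2 × median) are re-scanned for degenerate repeats hiding in them.
   Identity is `max(0, matches − gaps)/|reference| × 100` under unit
   costs.
4. **Orientation** — four voters (known-repeat strand, 3′ ATTGAAA motif,
   AT-rich leader flank, 3′ degeneracy gradient) decide the transcribed
   strand; reverse arrays are reverse-complemented and labelled.
5. **Typing** — the matched repeat family and annotated signature cas
   genes (cas3→I, cas9→II, cas10→III, csf1→IV, cas12→V) are listed side by
   side.
6. **Scoring** — nine bounded components (cas genes, known repeat, motif,
   repeat identity/length/homogeneity, spacer length/uniqueness) sum to a
   score with maximum 13; arrays ≥ 4.0 are *good*, 0–4 *questionable*,
   negative never reported.

Substitutions, insertions and deletions are annotated per repeat against
the representative (modal) repeat, so one repeat's insertion never forces
gap columns on the others; insertions print as `C [3167138]` — base(s) and
1-based genome position. See `docs/methods.md` for the full model,
parameter table and limitations.

## Worked example

Plant a known *E. coli*-family repeat in a synthetic genome, then detect:

```sh
crisparray simulate --repeat GTGTTCCCCGCGCCAGCGGGGATAAACCG \
    --n-repeats 5 --seed 0 --out ecoli_like.fasta --truth truth.gff
crisparray detect ecoli_like.fasta --min-score 0 --gff arrays.gff
```

prints

```
Array 1  synthetic:1201-1461  strand +  score 9.00 (good)
  Position  Length  Identity  SpLen  Repeat                         Spacer
      1201      29    100.0%     29  .............................  ACACTGCATGTCCGAAGTTTTGGTTTCGT
      1259      29    100.0%     32  .............................  CGATCACGATGCGGAGTAGTTATACAATCCTA
      1320      29    100.0%     26  .............................  GTATAGAATGTCGACAAACTTCGCAC
      1375      29    100.0%     29  .............................  TATCGAGATCTGGCAGAGTGATGATAACG
      1433      29    100.0%      -  .............................  |
Representative repeat : GTGTTCCCCGCGCCAGCGGGGATAAACCG
Score components:
  cas_gene_bonus               +0.00
  known_repeat_bonus           +3.00
  motif_bonus                  +0.00
  repeat_identity_metric       +3.00
  ...
  total                        +9.00
Direction             : forward (confidence MEDIUM)
CRISPR-Cas type(s)    : I-E (repeat match)
```

Reading it: one array of five 29-nt repeats (all dots = identical to the
representative) with four unique spacers at positions 1201–1461. The
score of 9.00 combines +3 for the match to a known repeat family (which
also yields the `I-E` type hint), +3 for perfect repeat identity, +1 each
for in-range repeat length, unique spacers and homogeneous repeats. With
GenBank input (`crisparray detect genome.gbk`), annotated cas genes add
their bonus and type hints. `arrays.gff` holds the same array as a
`repeat_region` parent with `direct_repeat`/spacer children for genome
browsers; reverse-oriented arrays appear on strand `-` with descending
positions in the text report.

The same functionality is importable:

```python
from crisparray import load_repeat_bank, read_genome, run_pipeline
result = run_pipeline(read_genome("ecoli_like.fasta")[0],
                      repeat_bank=load_repeat_bank())
print(result.arrays[0].score.total)   # 9.0
```

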