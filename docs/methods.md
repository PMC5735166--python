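# Methods note

Models, parameter defaults, and numerical conventions of `vanscape`.
The package analyses TE anti-silencing data (bisulfite methylomes, ChIP
tracks, motif content, protein-family evolution) and ships a seeded
simulator whose planted ground truth exercises every stage.

## Simulator

### Genome (`simulate_genome`)

One chromosome (default 150 kb) carries `n_te_families × copies_per_family`
TEs (default 2 × 5) in random order with inter-TE gaps of 500–1500 bp.
Each TE is three segments:

```
[100-bp pad | motif array | 100-bp pad]  coding  [100-bp pad | motif array | 100-bp pad]
      non-coding                                        non-coding
```

- **Motif arrays.** Each family has one IUPAC consensus (defaults
  `YAGTATTAY` and `AGTTGTMC`). An array is a tandem run of 4–8 units of
  20 bp, each unit containing one concrete, same-orientation instance of
  the consensus — the arrangement VANC proteins bind. Arrays appear as
  parallel diagonals in dot plots and are detectable by the
  tandem-repeat finder.
- **Coding segments** are random DNA *scrubbed*: re-mutated until they
  contain no match to the family consensus on either strand, so motif
  density contrasts (non-coding ≫ coding) are guaranteed, not
  probabilistic.
- **Strand.** Each TE gets a random strand; minus-strand TEs are inserted
  as the reverse complement with coordinates flipped, so orientation-aware
  code paths (profiles, array strandness) are exercised.
- **Ground truth** records per-array coordinates, motif, strand and copy
  number, plus planted hypomethylation intervals: CG truth = array ±
  `hypo_local_radius` (500 bp) **clipped to the TE body** (the methylome
  model only lowers methylation inside TEs — truth and generating model
  must agree); CHG/CHH truth = the whole body of every targeted-family TE.

What the simulator deliberately does **not** emulate: read mapping and
bisulfite conversion errors, copy-number variation between TE copies,
nucleotide composition bias, chromatin context, or overlapping/nested TEs.
It produces the *statistical* structure the analyses consume, not
realistic sequence.

### Methylomes (`simulate_methylomes`)

Every cytosine on both strands is emitted as a CX-style record. Coverage
is Poisson(`mean_coverage` = 30); methylated counts are
Binomial(coverage, p) with p from the context level (TE default CG 0.8,
CHG 0.5, CHH 0.15; background 0.02). In the affected sample, p drops by
`hypo_cg_drop` = 0.6 inside CG truth intervals and by 0.3 / 0.1 (CHG /
CHH) across targeted TE bodies. Levels are clamped to [0, 1].

### ChIP (`simulate_chip`)

IP and input depths are Poisson draws per 50-bp bin; over targeted arrays
the IP mean is multiplied by `chip_enrichment_factor` = 8. One summit per
targeted array at the array midpoint (summits are an upstream product;
here they are consumed, not called).

### Protein family (`simulate_family_evolution`)

A root protein (two 60-aa conserved domains flanking a 5-aa × 6 tandem
repeat block, joined by linkers) evolves down a user newick tree; per
branch of length b each site substitutes with probability 1 − e^(−b·rate),
conserved domains at 0.1× the rate. Leaf-specific truncation of repeat
copies (gap-padded) yields an alignment whose repeat-number variation the
dot plots and tandem-repeat finder can recover.

### Randomness

All streams derive from one seed via `np.random.default_rng([seed, tag])`
with a fixed tag per operation (genome 1, methylome 2, ChIP 3, evolution
4, discovery background 97). Each stage is therefore byte-reproducible
independently of which other stages run — this is what makes the
end-to-end manifest checksums stable.

## Analyses

### Significance statistic

`(Mn/Cn − Mt/Ct) / (1/√Cn + 1/√Ct)` for pooled methylated counts M and
totals C in untreated (n) and treated (t). Hand values: 0 for equal
ratios; 4.0 for 90/100 vs 10/100; scaling all counts by k² scales the
value by exactly k. Zero totals give NaN, never a silent 0.

### DMR caller

Fixed 0-anchored 100-bp windows (0-anchoring makes calls independent of
where data happens to start). A seed window needs ≥ `min_covered_sites`
covered CGs in *both* conditions (default 4 — below that a pooled-ratio
difference of 0.5 is reachable by noise at 30× coverage) and pooled
wt − treated ≥ 0.5 (inclusive). Runs of seeds separated by ≤ 1 non-seed
window merge into one DMR; reported levels re-pool the seed windows only.

### Profiles

- **Fractional profile**: TE split into 100 equal fractions, values pool
  counts over 7 consecutive fractions (94 values), oriented 5′→3′ of the
  TE strand; flanks default to the TE's own length so the x-axis is in TE
  lengths. TEs shorter than the fraction count return `None` (explicit
  skip marker).
- **Running profile**: each cytosine pooled with its next 4 same-context
  successors; the trailing 4 get NaN.
- **Metaplot**: 500-bp bins at 50-bp steps over ±5 kb around summits;
  offsets are bin centres chosen so every bin lies inside the span, giving
  191 offsets. Counts are pooled over summits before the ratio
  (coverage-weighted, not a mean of ratios).

### Motif discovery

DREME-style discriminative discovery on DMR sequences vs background.
Exact words of width 6–9 (canonical form: min of word and reverse
complement) are scored by sequence presence with a one-sided Fisher test
(hypergeometric tail). Sequentially: take the best word (ties: wider,
then lexicographic), refine it by greedy single-position IUPAC widening
while p improves, test the *refined* motif's E-value
(p × words-tested-in-round-1, a Bonferroni bound), erase matching
sequences, repeat. The pipeline samples 5 length-matched background
sequences per DMR from outside all TEs: with equal set sizes n the
smallest attainable p is 1/C(2n, n), which the multiple-testing factor
swamps when few DMRs exist.

### ChIP enrichment

CPM normalisation (library size defaults to the track's own mass); 10-kb
tiles scored as (IP + 0.5)/(input + 0.5) on overlap-weighted mean signal;
masked tiles dropped; terminal partial tiles flagged. Summit annotation
uses half-open interval containment.

### Evolution

- DNA dot plots: exact-word matches (word 10); an n× vs m× tandem array
  gives n + m − 1 diagonals.
- Protein dot plots: dotmatcher convention — BLOSUM62 sum over a 10-aa
  ungapped window, point when score ≥ 23.
- Tandem repeats: period-u self-match arrays, greedy extension while
  running identity ≥ 0.9, majority-vote consensus, overlaps resolved by
  longest span.
- Distances: Poisson correction d = −ln(1 − p) over ungapped columns;
  saturated or all-gap pairs are NaN (callers must handle, NJ refuses
  NaN).
- Neighbour joining: canonical Q-matrix algorithm; equal-Q ties break to
  the lowest index pair (deterministic); the final edge is split half and
  half — leaf-to-leaf path lengths, the quantities NJ guarantees on
  additive matrices, are unaffected by that arbitrary rooting.
- Bootstrap: alignment columns resampled with replacement; support of an
  edge = fraction of replicate trees containing the same bipartition
  (canonical side: the one without the alphabetically first leaf).

## Limitations

- Desk-scale only: defaults run in seconds on one CPU; the simulator is
  not a read-level or genome-scale emulator.
- The DMR caller tests a fixed effect size (level difference), not a
  per-window statistical test; coverage enters only through the
  covered-site floor.
- Discovery enumerates exact cores up to width 9 with one IUPAC widening
  pass; longer or gapped motifs are out of scope.
- The tandem-repeat finder is a simplified periodicity scan, not a full
  alignment-scored model; near-period-multiple calls are resolved purely
  by span.
- NJ exactness holds on additive matrices; on noisy distances it is the
  usual heuristic, with bootstrap supports as the uncertainty measure.
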