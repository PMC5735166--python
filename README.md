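# vanscape

Analysis toolkit for sequence-specific anti-silencing of DNA transposons,
with a fully synthetic study generator carrying planted ground truth.

Some transposable-element (TE) families encode anti-silencing proteins
(VANC proteins of *Arabidopsis* VANDAL elements) that bind short degenerate
DNA motifs — e.g. the 9-nt consensus `YAGTATTAY`, with C-type
(`..TTAC`) and T-type (`..TTAT`) instances, or the VANC6 motifs
`AGTTGTCC` / `AGTTGTAC` — arrayed in the same orientation at high density
in non-coding TE regions. Binding induces loss of CG methylation locally
around the arrays and milder element-wide loss of CHG/CHH methylation,
re-activating the family while leaving unrelated TEs silenced. This
package implements the computational side of that biology:

- **`vanscape.simulate`** — seeded generator for a TE-bearing genome
  (motif arrays in non-coding segments, scrubbed coding segments, both
  strands), paired wild-type/affected bisulfite methylomes (Poisson
  coverage × binomial methylation), ChIP coverage tracks with summits over
  the arrays, and an evolved, aligned protein family. Every planted
  feature is recorded in a `GroundTruth` object.
- **`vanscape.methylome`** — CX-report handling, the hypomethylation
  significance statistic `(Mn/Cn − Mt/Ct)/(1/√Cn + 1/√Ct)`, per-TE
  methylation changes, fractional (metagene) profiles, running
  5-cytosine profiles, summit-centred metaplots, and a CG-DMR caller
  (100-bp windows, ≥ 0.5 pooled difference, one-gap merging).
- **`vanscape.motif`** — IUPAC scanning on both strands, C/T/CC/AC hit
  typing, per-TE counts, same-orientation array detection, DREME-style
  discriminative motif discovery (exact words → Fisher test → greedy
  IUPAC generalisation → sequential extraction), and minimum-mismatch
  distances between degenerate patterns.
- **`vanscape.chip`** — CPM normalisation, tiled IP/input enrichment
  ratios with masking, and summit annotation against TE segments.
- **`vanscape.evolution`** — DNA exact-word and protein (BLOSUM62,
  dotmatcher-style) dot plots, a periodicity-based tandem-repeat finder,
  Poisson-corrected distances, canonical neighbour joining, and bootstrap
  supports.
- **`vanscape.pipeline` / `vanscape` CLI** — one-command end-to-end run
  on simulated data with a sha256 manifest, plus validation of every
  result against the planted truth.

## Worked example

```python
from vanscape.pipeline import RunConfig, run_full, validate_against_truth

config = RunConfig()                      # defaults: 150-kb genome, 10 TEs, seed 0
manifest = run_full(config, "study_out")  # writes every intermediate + manifest.json
report = validate_against_truth("study_out")
for key, value in report.items():
    print(f"{key}: {value}")
```

prints

```
dmr_sensitivity: 0.8254166666666667
dmr_precision: 0.9905
n_dmrs: 11
motif_rank: 1
chh_significance_separation: 6.155345377260901
summit_annotation_accuracy: 1.0
```

The discovery stage recovers the planted family consensus from the called
DMRs alone — `study_out/motifs.tsv` reads

```
pattern   pos_with  pos_total  neg_with  neg_total  p                       e
TAATACTR  8         11         2         55         1.1757529351932979e-06  0.01902720975023314
```

(`TAATACTR` is the reverse complement of `YAGTATTA`, the core of the
planted `YAGTATTAY` consensus; discovery reports the canonical
orientation of each word.)

Smaller pieces work standalone:

```python
from vanscape.motif import scan, min_mismatch, VANC21_CONSENSUS, VANC6_CC, VANC6_AC
for h in scan("GGCAGTATTACTTATAATACTAGG", VANC21_CONSENSUS):
    print(h.start, h.end, h.strand, h.matched, h.motif_type)
# 2 11 + CAGTATTAC C
# 13 22 - TAGTATTAT T
print(min_mismatch(VANC6_CC, VANC21_CONSENSUS))   # 3
print(min_mismatch(VANC6_AC, VANC21_CONSENSUS))   # 2

from vanscape.methylome import significance_value
print(significance_value(90, 100, 10, 100))        # 4.0
```

The same stages are exposed as a CLI (`vanscape simulate`, `vanscape meth
dmr`, `vanscape motif discover`, `vanscape chip bins`, `vanscape evo nj`,
`vanscape run`, `vanscape validate`, …); every subcommand reads and writes
plain TSV/FASTA/BED/newick files, so real data can be substituted for the
simulator at any stage.

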