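# guideforge

Guide-RNA design for experiments that target **many genomic sites at
once** — blocking hundreds of transcription-factor binding sites,
CRISPRi/CRISPRa tiling of TSSs, exon excision screens — plus full
**PE2/PE3 prime-editing** reagent design for single point edits.

Designing gRNAs for large sets of near-identical targets turns the usual
off-target logic upside down: a spacer that matches *another declared
target* is not an off-target at all, it is a bonus.  guideforge makes this
first-class through **target-set-specific filtering (TSSF)**: for every
spacer and every mismatch level *m* ∈ {0..k} it counts genome-wide matches
*G<sub>m</sub>* (both strands) and in-target matches *T<sub>m</sub>*, and
scores

```
off_m = G_m − T_m          off = Σ_{m=0..k} off_m
```

so only matches *outside* the declared target set count against a spacer.

The toolkit is organised along the workflow
**define → transform → find → count → score**:

- `intervals` — stranded, 1-based closed genomic intervals with the
  genome-arithmetic vocabulary (`extend`, `up_flank`, `down_flank`,
  `double_flank`, `cutsite_to_spacer`) and the named application presets:
  cut-within `[−16,+5]`, block `[−22,+22]`, CRISPRi TSS `[−50,+300]`,
  CRISPRa `[−300,0]` up-flank, excise `[−16,+x]` down-flank, and a
  both-flanks vicinity mode.
- `spacers` — N20-NGG spacer/PAM discovery (IUPAC patterns, both strands,
  per-target attribution; Cas9 cut after protospacer base 17).
- `offtargets` — two k-mismatch counting engines: `exact` (full-sensitivity
  vectorised multi-pattern scan) and `seeded` (pigeonhole seed-and-verify;
  guaranteed complete at ≤ 1 mismatch and never over-counting), plus TSSF
  aggregation and the `parallel` / `unique` retention policies.
- `prime` — PE2/PE3 design: editing spacers admissible when the edit sits
  at protospacer positions 18..17+nrt, pegRNA 3′ extension (RT template +
  primer binding site), and opposite-strand nicking spacers 40–90 nt
  downstream of the editing nick.
- `scoring` — logistic position-weight on-target scorer (Rule Set 1 class,
  vendored 30-mer weight table) and a line-oriented adapter for external
  trained scorers.
- `synth` — seeded synthetic genomes with planted mismatch neighbourhoods
  and the brute-force all-windows oracle, so everything is testable without
  reference-genome downloads.
- `pipeline` / `cli` — orchestration with provenance logging and a
  `guideforge` command-line tool.

## Worked example

Plant the spacer `GTGAGAAGGTCGCCTTTATT` at two loci of a 50-kb synthetic
chromosome, declare both as targets, and run the parallel-targeting
workflow with the blocking preset:

```python
from guideforge import *

plan = PlantSpec("GTGAGAAGGTCGCCTTTATTAGG",
                 [Placement("chr1", 10_000, "+"),
                  Placement("chr1", 35_000, "-")],
                 {"chr1": 50_000}, max_mm=2)
genome = make_genome(plan, seed=1)
targets = [GenomeInterval("chr1", 10_000, 10_019, "+", "siteA"),
           GenomeInterval("chr1", 35_003, 35_022, "-", "siteB")]
table, log = run_parallel_targeting(
    targets, genome, RunConfig(preset="block", engine="exact"))
print(table[table.spacer_seq == "GTGAGAAGGTCGCCTTTATT"]
      [["target_name", "spacer_range", "T0", "G0", "off0", "off"]])
```

```
target_name       spacer_range  T0  G0  off0  off
      siteA chr1:10000-10019:+   2   2     0    0
      siteB chr1:35003-35022:-   2   2     0    0
```

The spacer has two perfect genome matches (`G0 = 2`) — normally a
disqualifying multi-locus hit — but both fall inside declared targets
(`T0 = 2`), so under TSSF it is off-target free (`off = 0`) and is retained
for both sites.  The run log records version, config hash, genome checksum
and per-stage counts; re-running with the same inputs reproduces the TSV
byte for byte.

The same session from the shell:

```sh
guideforge block --genome ref.fa --targets sites.bed \
    --engine exact --out results/block
guideforge prime-edit --genome ref.fa --chrom chr20 --pos 4699600 \
    --ref G --alt T --out results/prnp
```

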