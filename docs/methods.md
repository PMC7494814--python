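# Methods

## Coordinate model

All intervals are 1-based and closed on both ends (`chr20:4699568-4699587`
spans 20 bases); BED input/output (0-based half-open) is converted only at
the I/O boundary.  Strand-aware arithmetic applies offsets in an
interval's own 5′→3′ reading direction, so a `[−16, +5]` extension of a
minus-strand target grows its genomic *end* by 16 and shrinks toward its
*start* by 5.  Unstranded (`*`) intervals are treated as plus strand by
strand-aware operations, with a logged warning.  Out-of-bounds results are
an error by default; an explicit `clip` option truncates to
`[1, chromosome length]` and warns — silent truncation would quietly
change the search space, so it is never the default.  Overlapping
transformed ranges are deliberately *not* merged: each keeps its parent
target's identity, which target attribution (below) requires.

## Spacer/PAM discovery

A hit is a `spacer_len + |PAM|` word fully contained in a (transformed)
target range, on either strand, whose terminal bases match the IUPAC PAM
pattern.  Full containment is what gives the presets their guarantees:
under `[−22, +22]` a contained 23-mer word must still overlap the original
target by ≥ 1 base.  PAM matching is IUPAC-aware on the pattern side only;
a genome `N` matches nothing, and spacers containing any non-ACGT base are
dropped (they are not synthesisable as a defined guide).  Hits are
reported per target — a spacer inside two overlapping targets yields two
rows — with a deduplicated view available for library export.  Output
order is fixed (chrom, start, strand, target) so runs are byte-identical.

The cut position (`cut_after`, the 17th protospacer base; Cas9 cleaves
immediately 3′ of it) gives the cut-within guarantee a subtlety: a
plus-strand word spans `[cut − 16, cut + 6]` but a minus-strand word spans
`[cut − 6, cut + 16]`.  The `[−16, +5]` offsets are therefore
*spacer-strand*-specific.  The pipeline realises this by searching the
symmetric `[−16, +16]` union window and filtering hits on
`cut_after ∈ [target start, target end]`, which reproduces the per-strand
windows exactly rather than approximately.

## Off-target counting and TSSF

Both engines count, per spacer, genomic windows at Hamming distance
exactly *m* for *m = 0..max_mm* on both strands (minus-strand matching via
the reverse-complemented pattern on the forward text, which preserves
Hamming distance).  Defaults: `max_mm = 2` for counting and filtering
(counts up to 3 supported), PAM-agnostic 20-mer matching with an optional
`pam_mode="required"` that restricts to PAM-adjacent windows.

- **exact** — a vectorised all-windows scan (numpy sliding windows over a
  byte-encoded chromosome).  By construction it has full sensitivity at
  every mismatch level; it is the reference engine.
- **seeded** — seed-and-verify: each spacer is split into `max_mm + 1`
  contiguous chunks; by the pigeonhole principle any window within
  `max_mm` mismatches preserves at least one chunk exactly.  Exact chunk
  occurrences are located via integer window codes, and candidates are
  verified by a full Hamming check.  Verification means precision 1.0;
  contiguous-partition seeding means no misses either, so the engine meets
  (and exceeds) its sensitivity contract — complete at *m* ≤ 1, never
  exceeding the exact engine anywhere.  The contract, not any particular
  third-party aligner, is what the tests pin down.

A window matching on both strands (reverse-complement palindrome) counts
twice: the two orientations are two distinct Cas9 binding events.
Counting is partitionable by chromosome and invariant to partition order.

Target attribution: `T_m` counts matches overlapping any declared
(transformed) target range by ≥ 1 base, ignoring the match strand — a
minus-strand match inside a plus-strand target still counts.  `off_m =
G_m − T_m`; any `T_m > G_m` is raised as an internal consistency error
(exit code 3 in the CLI) since targets must be a subset of the scanned
genome.  Retention policies: `parallel` keeps spacers with `off = 0`
across all levels (cross-target matches permitted — the point of TSSF);
`unique` keeps genome-unique spacers (`G0 = 1`, optionally also off-free),
used for prime editing and classic single-locus designs.

## Prime editing

The prime editor nicks between protospacer positions 17 and 18 and
rewrites the sequence 3′ of the nick on the protospacer strand from an
RNA-carried template.  An editing spacer is admissible iff every edited
base lies at protospacer positions `18..17 + nrt`; for a plus-strand
spacer starting at `s` and a single-base edit at `p` this is
`s ∈ [p − (nrt + 16), p − 17]` (minus strand mirrored), a 16-wide window
per strand at the default `nrt = 16`.  The positional rule is normative;
the search window around the edit is derived from it.  Multi-base edits
must fit entirely inside the template, with insertions measured against
the post-edit template length (strictest reading).

Defaults: `nrt = 16` nt RT template, `pbs_len = 13` nt primer binding
site (both configurable; `pbs_len > 17` is rejected because the PBS
cannot cross the protospacer 5′ end), nicking window 40–90 nt.  The 3′
extension is `revcomp(edited template 18..17+nrt)` followed by
`revcomp(protospacer 5..17)`, written 5′→3′, length
`nrt + pbs_len + (|alt| − |ref|)`.

Nicking spacers sit on the strand opposite the editing spacer.  Distance
is measured nick-to-nick (cut boundary to cut boundary) in the downstream
(3′-on-edited-strand) direction, because the spacing that matters
mechanistically is between the two single-strand cuts; the window is
inclusive.  Editing spacers are filtered to genome-unique exact matches
(`G0 = 1`, so e.g. a reverse-complement-palindromic protospacer with its
inherent two-orientation self-match is rejected); nicking spacers are
*reported* with full mismatch counts rather than auto-filtered — choosing
a performant pair is an experimental decision.  For TSSF bookkeeping of
editing spacers the declared target is the whole admissible design window
around the edit, so self-matches are in-target and an off-target-free
design reads `off = 0`.

## On-target scoring

Scores annotate spacers and never remove them (an optional `--min-score`
filter exists in the CLI).  The internal scorer is a Rule Set 1–class
logistic regression over a 30-nt context (4 nt upstream + protospacer +
PAM + 3 nt downstream, read 5′→3′ on the spacer strand; minus-strand
windows are reverse-complemented): intercept + position-specific mono- and
dinucleotide weights + a GC-count penalty, through a logistic, giving a
deterministic score strictly in (0, 1).  The weight table is vendored as a
TSV whose sha256 is verified at load; a frozen fixture of
context→score pairs guards both the file and the scoring loop at 1e-9.
Spacers whose context window leaves the chromosome or contains ambiguous
bases are flagged unscorable (score missing), not dropped.

Trained gradient-boosted scorers are not re-implemented — their value is
their fitted weights.  Instead a line-oriented external adapter (one
30-mer per stdin line, one score per stdout line) lets any such model be
plugged in; adapter absence, failure, or malformed output degrade to
missing scores with a warning and never abort a design run.

## Synthetic genomes and the oracle

`make_genome` draws an i.i.d. background at a configurable GC fraction
(default 0.41, a typical mammalian genome-wide value) and plants copies of
a base word (spacer+PAM) with an exact requested number of substitutions,
sparing the PAM bases unless asked.  The background is rejection-sampled
(bounded retries) until the planted core 20-mer has no additional
background occurrence within `max_mm` on either strand, verified by
`brute_force_matches` — a deliberately naive per-window Hamming scan with
no indexing, which is also the independent oracle for every
engine-equivalence test.  Synthetic genomes emulate match/mismatch
structure only; they have no repeats, isochores or realistic base
correlations, so passing tests demonstrate counting and design logic, not
performance or specificity on real genomes.  Full-genome checks against
published per-locus counts exist as optional integration tests that run
when a local reference FASTA path is provided.

## Problem sizes and numerical choices

The test suite and the acceptance script run on synthetic chromosomes of
5–150 kb with a handful of spacers — ample to exercise every code path
and to cross-validate engines against the quadratic oracle while keeping
the suite fast.  Determinism: every random draw flows through an explicit
`numpy` generator seed; result TSVs use fixed column order and `%.10g`
float formatting, so identical config + inputs give byte-identical
output.  Ties in spacer ordering are broken by (chrom, start, strand,
target name).  Empty inputs are results, not errors: an empty target set
yields an empty table and exit code 0.

## Known limitations

Only 3′ PAMs (Cas9-style) are supported, with a single spacer length per
search; no bulge/indel off-targets and no CFD/MIT-weighted off-target
scores — counting is by plain Hamming distance; the excise preset's
downstream extent `x` is application-specific and therefore a required
parameter; prime-editing efficiency is not predicted, and on-target scores
for editing spacers should be interpreted cautiously.
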