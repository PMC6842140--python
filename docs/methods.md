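# Methods

## The sampling model

`rnascout` treats read selection from a sequence archive as an online
resource-allocation problem.  The state is a per-tile count vector `c` over
`T` genome tiles (half-open windows of `tile_size` bp; the last tile of a
sequence may be shorter), counting uniquely aligned *spots* — one read for
single-end libraries, one read pair for paired ones; an aligned pair
increments exactly one tile once.  The objective `S(c) = Σ_j ln(1 + c_j)`
encodes the assumption that annotation accuracy gains from extra coverage
are diminishing: the first read in a tile is worth `ln 2`, the hundredth
almost nothing.  Tiles are a deliberately coarse proxy for transcripts; the
model only needs run profiles to be *distinguishable* at tile resolution,
not for tiles to coincide with genes.

One greedy step evaluates, for every eligible run, the score of the
expected count vector after one batch, `S(c + b·q̂_r·p̂_r)`, and samples the
argmax.  This is one-step lookahead only — no bandit-style confidence
bounds, no multi-batch planning.  The expectation is real-valued and
`ln(1+x)` is applied to reals; nothing is rounded.

The run profile `p̂_r[j] ∝ c_j^r + λ·T·p̄[j] + a` shrinks the run's own
(initially empty) tile counts towards the pooled profile `p̄` of everything
sampled so far.  Because `λ·T·p̄[j]` scales with `T`, the smoothing mass is
independent of tile granularity; with `λ ≫ a` an unsampled run is assumed
to look like the archive average, which is exactly what makes its expected
gain *small* once the average regions are well covered — the mechanism that
pushes the sampler towards complementary runs.

The quality weight `q̂_r = w_u·f_unique + w_s·f_spliced` uses fractions
pooled over all of the run's batches (not averages of per-batch fractions).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `b` | 50 000 | spots/batch | large enough to estimate a profile, small relative to a run |
| `tile_size` | 5000 | bp | transcript-scale windows |
| `λ` | 10 | – | pooled-profile pseudocount weight; dominates `a` |
| `a` | 1 | counts | keeps every tile reachable (`p̂ > 0` everywhere) |
| `max_batches` | 1000 | batches | session budget |
| `q_weights` | (0.9, 0.1) | – | unique alignability dominates usefulness; the spliced fraction is a weak, genome-dependent signal (intron density varies), so it gets a small weight. Configurable. |
| `blacklist_threshold` | 0.05 | fraction | a run whose first batch aligns uniquely below 5 % is junk for this purpose; *exactly* 5 % is kept (inclusive rule) |
| `initial_q_hat` | 1.0 | – | optimism for never-sampled runs drives exploration |
| `tie_rel_tol` | 1e-12 | relative | see numerical choices |

Open choices resolved here (the underlying quantities are not pinned down
by any published description):

* **Tie-break form.**  Among score-tied runs one is drawn with probability
  proportional to average read length (longer reads align and splice more
  informatively).  Missing lengths are imputed as the median of the known
  ones.  Any increasing weighting would do; proportionality is the simplest.
* **Unique-only coverage.**  Multi-mapped spots do not increment tiles:
  their placement is unreliable, and `q̂` already down-weights
  low-uniqueness runs.  The paired representative is the leftmost-mapping
  uniquely aligned mate; a spot spanning a tile boundary counts only for
  the tile of its leftmost aligned base (single-count conservation).
  Uniqueness is `NH == 1` where the tag exists, else `MAPQ ≥ 30`.
* **Blacklisted first batch is discarded.**  A run failing the quality
  filter is ignored *including* its first batch's alignments, so junk runs
  contribute nothing to coverage or intron sets (only their quality
  statistics are logged).
* **Failure policy.**  Three consecutive fetch/align failures blacklist a
  run; real archives contain dead accessions and the loop must not stall.
* **Range consumption.**  Within a run, the lowest not-yet-downloaded spot
  interval is taken next; the only hard requirement is that intervals stay
  pairwise disjoint so every spot is requested at most (with unlimited
  budget: exactly) once.

## Numerical choices

* Score ties are compared with relative tolerance `1e-12` (scaled by
  `max(|S_max|, 1)`); floating-point equality on sums of logs is
  meaningless.  All score-tied runs enter the tie-break draw.
* `p̄` with no counts anywhere is uniform `1/T` — the only symmetric
  choice — making the first profile estimates uniform as well.
* Degenerate `λ = a = 0` with an unsampled run would give a zero weight
  vector; the estimate falls back to uniform.
* All never-sampled runs share one `(p̂, q̂)` pair, so their expected score
  is computed once per selection step, not once per run.
* Empty downloads blacklist a run (nothing retrievable); a shorter-than-
  requested download truncates the run's catalogued size.
* An intron is emitted per CIGAR `N` operation as
  `(sequence, p+o, p+o+n−1)` with `o` the reference-consuming bases
  (`M/D/N/=/X`) preceding it — 1-based first/last intronic base.  Records
  with malformed CIGARs or positions running past the sequence end are
  logged and counted as unmapped.
* Intron identity is strand-agnostic `(sequence, start, end)`: inferring a
  spliced alignment's strand needs splice-site sequence inspection, which
  is out of scope; reference and predicted sets use the same convention, so
  the comparison is consistent.  A minimum-support filter on predicted
  introns is available but defaults to 1 (raw induced introns).

## The simulator

The synthetic archive emulates what matters to the algorithm: runs with
*distinct, skewed* expression profiles (Dirichlet with concentration 0.1 —
tissue-like sparsity), a configurable fraction of defective runs
(default 20 %, matching the order of magnitude of junk observed in public
archives), single-transcript gene models whose exon/intron structure yields
spliced reads, and exact determinism from one seed (every
`(run, spot-interval)` request is independently seeded, so re-requests and
request order cannot change results).

Defaults: 30 runs × 100 000 spots, 200 genes (2–4 exons of 100–300 bp,
introns 60–400 bp, intergenic gaps 200–4000 bp so genes spread over the
genome) on a 1 Mb genome in 2 sequences, 100 bp reads.  Low-alignability
runs emit exactly 3 % unique alignments (deterministic count, so the 5 %
filter's behaviour does not depend on binomial luck); the rest are split
between unmapped and `NH=2` multi-mapped.  Mislabeled-genomic runs place
unspliced reads uniformly on the genome.

Reads are emitted as already-aligned records, not FASTQ: alignment outcome
is the only thing the algorithm observes, so modelling bases and errors
would add cost without information.  Consequences for interpreting test
results on real data:

* there are **no alignment errors**, so observed introns are always a
  subset of the truth and specificity is 1 by construction — the simulator
  validates the pipeline arithmetic, not an aligner;
* no isoforms, no overlapping genes, no repeats, no adapter contamination;
* per-run profiles are stationary (no within-run batch effects).

## Problem sizes

The test suite and `scripts/acceptance.py` use desk-scale sessions chosen
to exercise every code path while keeping the whole suite under a minute
apart from the policy-comparison experiment: archives of 5–30 runs,
genomes of 0.12–1 Mb, batches of 300–2000 spots, and a 20-seed
greedy-vs-random comparison at 100 batches × 1000 spots.  Full-scale
parameters (`b = 50 000`, `maxBatches = 1000`) remain the defaults of the
public API and CLI.

## Known limitations

* The greedy policy is evaluated against a uniform-random baseline, not
  against an oracle with known profiles; on archives whose runs are all
  alike, greedy and random are statistically indistinguishable (as the
  objective predicts).
* At generous budgets the binary "tile covered" measure saturates under any
  policy; the score `S(c)` remains the discriminating metric there.
* The external fastq-dump/HISAT2/STAR adapter implements the fetch contract
  but is exercised manually; tests cover only its failure signalling.
* GFF3 handling assumes CDS features carry `Parent` (or
  `transcript_id`/`gene_id`) attributes; transcripts with overlapping CDS
  parts are skipped with a warning.
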