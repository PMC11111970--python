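# Methods

This note documents the models, thresholds, and design choices behind
`svkaryo`, and what the synthetic-data tests do and do not establish
about behavior on real sequencing data.

## Record model and coordinates

All SV callers' output is normalized to one record per event: two
breakpoints `(chrom1, pos1)` / `(chrom2, pos2)` in 1-based VCF
coordinates, an SV type (DEL, DUP, INV, INS, BND), strand orientation,
read support, a caller quality flag, and optional position coverage and
allele fraction. Intrachromosomal size is defined as `pos2 − pos1`
(not `+1`); this is the convention under which the published REH
coordinates reproduce their printed sizes exactly (e.g.
61,437,807 − 35,660,443 = 25,777,364 for the chr3 deletion). An
insertion's `pos2` is normalized to `pos1 + inserted length` so the same
identity holds for all intrachromosomal types.

Breakend (BND) mate pairs are deduplicated on parse: the junction is
stored once with the lexicographically smaller `(chrom, pos)` end as
breakpoint 1, and the strand pair reversed accordingly. Truth matching
canonicalizes end order on both sides, so tables written in narrative
(derivative-chromosome) order compare correctly. Strand orientation is
taken from bracket notation (`t[p[` → `+-`, `t]p]` → `++`, `]p]t` →
`-+`, `[p[t` → `--`); symmetric types carry `NA`, which is compatible
with any strand during merging. A strand-less breakend cannot be
expressed in bracket notation, so the writer emits `+-` for it — the one
field the VCF round trip does not preserve.

Read support means split reads for long-read callsets and discordant
mate pairs for short-read callsets. Support lookup tries a configurable
key list in order (INFO `SUPPORT`, `RE`, `PE`, `SR`, then FORMAT `DV`,
`PE`, `SR`, `RV`), covering the Sniffles- and TIDDIT-style dialects;
a record with no support field is kept with support 0 and a warning.
Records with neither `END` nor `SVLEN` are rejected rather than guessed.

## Consensus merging

Merging is greedy single linkage in a deterministic order (records
sorted by chrom1, pos1, chrom2, pos2, id). A record joins the existing
group whose representative — the first member's breakpoints — matches
its type (optional), is strand-compatible (`NA` matches anything), and
lies within `max_distance` (default 1000 bp) on **both** ends; among
multiple matching groups the smallest breakpoint-distance sum wins.
Using a fixed representative rather than a centroid keeps merging
idempotent: re-merging the representatives creates no new groups.
Records below `min_size` (default 100 bp) are excluded before
clustering, except breakends, which have no length and would otherwise
be lost wholesale; records with either breakpoint in a blacklist
interval (BED, 0-based half-open) are likewise excluded and counted, so
`excluded + grouped = input` always holds.

Consensus subsets are defined post hoc: a group belongs to the subset of
callsets `S` iff its supporting set contains `S`. This makes the minimum
supporting-caller count at merge time 1, with three-way and pairwise
consensus nested by construction.

## The large-SV filter cascade

The evaluation cascade for large-scale rearrangements:

1. **Pre-filter** — keep candidates with size > 100,000 bp (strict) or
   interchromosomal breakends.
2. **Three-criterion filter** — retain iff (a) the caller's own quality
   filters pass, (b) support ≥ 5 reads *and* strictly > 0.2 × mean depth
   of coverage of the dataset, and (c) position coverage ≤ 1.5 × mean
   depth (inclusive). The strict/inclusive reading follows the
   threshold wording literally; each rejection is labeled with the first
   failed criterion so the partition is auditable.
3. **Sampling and confirmation** — `sample_by_support` selects records
   at one exact support value (default 15), a deterministic
   pseudorandom slice through a noisy short-read callset;
   `cross_callset_confirm` accepts a candidate iff a same-type event
   within 1 kb on both ends exists in at least one other callset
   (presence in ≥ 2 callsets total). This is a deterministic proxy for
   manual inspection of split reads and discordant mates in a genome
   browser, and is documented as such: it cannot reproduce judgments
   that depended on raw read evidence.

Size strata use contiguous right-closed bins — Small [100, 1000],
Medium (1000, 10000], Large (10000, ∞) — because the conventional prose
form ("100 bp–1 kb", "1–10 kb", "> 10 kb") is boundary-ambiguous; the
bins are configurable. Heatmap binning counts each record once per
breakpoint chromosome (twice only for interchromosomal events), so
window counts conserve the total breakpoint count.

The SNV impact filter retains variants with population allele frequency
missing or ≤ 1e-4, a loss-of-function or NMD consequence, and ≥ 25%
(inclusive) of the gene's transcripts affected; annotations are read
from SnpEff-style `LOF=(gene|id|n|fraction)` / `NMD=` INFO tags.

## Karyotype profiling

**Copy states.** Per-chromosome mean depth is divided by a diploid
baseline to give a ratio; ratio < 0.75 is a loss, > 1.25 a gain. The
baseline self-bootstraps: the median over autosomes, refined once by
dropping chromosomes whose first-pass ratio is already outside
[0.75, 1.25]. With one trisomy and one monosomy among ten chromosomes
the contaminated first median is still close enough to classify the
aberrant chromosomes out of the refinement pool; a karyotype where most
chromosomes are aneuploid would defeat this bootstrap, which is a known
limitation.

**LOH.** SNVs are binned into fixed windows (default 1 Mb); a site is
heterozygous iff its VAF lies in the symmetric band [0.2, 0.8], making
the heterozygous fraction invariant under ref/alt relabeling. Maximal
runs of ≥ `min_run` (default 5) genomically adjacent windows with
heterozygous fraction ≤ 0.05 become segments; a segment whose mean depth
ratio lies in [0.8, 1.2] is copy-neutral LOH, otherwise deletion-driven
LOH. The defaults resolve a multi-ten-Mb chromosome-arm event; for the
test genome's 4-Mb segment the window is narrowed to 500 kb (8 windows)
— at 1 Mb the segment spans only 4 windows and is correctly not called
at the default `min_run`. Trisomic chromosomes show heterozygous VAF
clusters near 1/3 and 2/3; this signature is visible in the windowed
summaries but depth, not VAF, is the copy-state caller.

## Fusion screening

Candidates are keyed by the ordered (5′, 3′) gene pair; duplicate rows
within one caller collapse by summing reads, and per-caller tables merge
by pooling caller flags and read counts. Panel-of-normals subtraction
matches **unordered** pairs (an artifact is an artifact whichever way a
caller orients it), while truth matching in evaluation is **ordered**
(fusions are biologically directional). A candidate with identical
partner genes is dropped; the rest must satisfy at least one tier:

* **T1** — involves a gene from the disease-gene list and has ≥ 5
  supporting reads, summed across platforms (the platform split is
  deliberately not required; configurable);
* **T2** — called by ≥ 1 short-read and ≥ 1 long-read tool;
* **T3** — called by ≥ 3 short-read tools;
* **T4** — ≥ 10 supporting long reads.

All satisfied tiers are reported, and adding reads or callers can only
add tiers (monotonicity is property-tested). A default B-ALL gene list
ships with the package and is user-replaceable.

## Evaluation metrics

Truth matching is greedy one-to-one on (SV type, canonical chromosome
pair) with both ends within a tolerance (default 1 kb, the consensus
distance); ties resolve by smallest distance sum, then input order, so a
second candidate near one truth event is a false positive and TP never
exceeds the truth count. Sensitivity is TP/(TP+FN). The reported
"FPR" is FP/(FP+TP) — operationally a false-discovery proportion; this
definition reproduces the published (FP; FPR) pairs (128, 22) → 85.33%,
(606, 21) → 96.65%, (1469, 21) → 98.59% arithmetically, and the same
value is exposed under the conventional name FDR to avoid confusion.
Percentages are rounded half-up to 2 decimals, mean read support to 1
decimal, matching how such values are printed.

In the end-to-end pipeline the truth set is passed through the same
large-SV pre-filter as the candidates before matching; otherwise every
small truth variant would count as a miss against a candidate pool that
was restricted to large events by construction.

## Synthetic cell-line generator

The generator emulates the sequencing regime of a three-technology
cell-line study; its defaults are the test bench's study conditions:

| parameter | short-read | ONT-like | PacBio-like |
|---|---|---|---|
| mean depth (reads) | 34 | 18 | 15 |
| sensitivity | 0.91 | 0.96 | 0.91 |
| false positives / Mb | 15 | 1.3 | 6 |
| breakpoint jitter SD (bp) | 100 | 30 | 30 |
| support mean (× depth) | 0.47 | 0.62 | 0.64 |

Depths are the study's; sensitivities mirror the published large-SV
detection rates; FP loads per Mb are set so absolute counts on the
100-Mb toy genome echo the published 128/606/1469 ordering; support
fractions reproduce the published mean read supports (≈16/11/10 reads);
jitter reflects short reads' poorer breakpoint precision. The toy
genome is ten 10-Mb chromosomes with one trisomy (chr8), one monosomy
(chr10), and one 4-Mb cnLOH segment (chr9) — echoing a +16 / −X /
9p-cnLOH karyotype at desk scale — carrying ~500 non-overlapping truth
SVs (200 DEL / 100 DUP / 100 INV / 60 INS, log-uniform sizes 150 bp–500
kb; insertions 150 bp–5 kb) and 40 translocations. Two thirds of truth
SVs are heterozygous.

Observation model: each truth SV is emitted with probability
`sensitivity`; breakpoints get rounded Gaussian jitter truncated to
chromosome bounds; support ~ Poisson(support_fraction × depth), floor 1;
quality flags fail at 2%; position coverage ~ Normal(copy-scaled depth,
10%); allele fractions are binomial around 0.5 (het) or 0.98 (hom).
False positives arrive as Poisson(fp_rate × genome Mb) events
rejection-sampled ≥ 2 kb from any truth breakpoint so TP/FP labels are
unambiguous — a deliberate simplification that makes recovery tests
exact but removes the hard near-miss cases a real benchmark contains.
SNVs (200/Mb) have Poisson depth scaled by copy state (halved inside
deletion LOH), heterozygous alt depths Binomial(depth, ½) under disomy
and Binomial(depth, ⅓ or ⅔) under trisomy, and homozygosity inside LOH
segments. Fusion callers (five short-read, two long-read) detect truth
fusions per their sensitivity, add Poisson false pairs over a synthetic
gene pool, and inject panel pairs at a contamination rate.

All randomness flows from one `numpy` Generator seeded per run; a seed
reproduces every output exactly. Bit-identity across library versions
is not promised — the statistical contracts are.

**What the synthetic tests show, and do not.** Recovery tests establish
that the pipeline's estimators are unbiased under their own generative
assumptions (independent detection, Gaussian jitter, Poisson loads,
clean truth separation). They do not establish performance under real
data's failure modes: alignment artifacts clustered in repeats,
systematically shared false positives between technologies, breakpoint
ambiguity in segmental duplications, or subclonal structure. The
bundled REH tables cover the arithmetic of the published evaluation but
not the raw-data stages that produced its candidate pools.

## Test and acceptance problem sizes

The acceptance suite measures sensitivity recovery over 200 seeded
replicates of the full ~500-SV configuration (binomial 99% bounds on
the pooled detection count), false-discovery recovery over 50
replicates, copy-state concordance over 200 depth-table draws at 3%
depth noise, and cnLOH segment recovery (boundaries within one 500-kb
window) over 10 full SNV simulations — sizes chosen to give sub-percent
standard errors while keeping the suite fast on one CPU. The
acceptance script defaults to 60 replicates per estimate for the same
reason (`--replicates` raises it).

## Known limitations

* BND orientation is trusted as written; no re-derivation from reads.
* The confirmation step is a coordinate proxy for manual read review.
* The diploid-baseline bootstrap assumes a mostly diploid autosome set.
* LOH detection is run-length based, not an HMM/CBS segmentation; very
  short or SNV-poor events below `min_run` windows are invisible.
* Fusion screening operates on caller tables only; no realignment,
  frame annotation, or paralog disambiguation (e.g. highly similar
  paralog pairs can masquerade as one another in short-read calls).
* Pipeline evaluation assumes the truth VCF uses coordinates on the
  same reference as the callsets; no liftover is provided.
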