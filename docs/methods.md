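# Methods

## Coordinate and orientation conventions

All internal coordinates are 0-based half-open; GTF is read/written 1-based
inclusive and BED/BEDPE 0-based half-open, each format in its native
dialect. Chromosome names pass through verbatim — a `chr1`-vs-`1`
vocabulary mismatch raises an error listing both sides rather than being
silently normalized. One canonical transcript represents each gene:
longest CDS, then longest transcript, then lexicographically smallest
transcript id. *Upstream* and *downstream* are always relative to a gene's
own transcriptional strand, so "upstream of a minus-strand gene" means a
higher genomic coordinate; the distance from a breakend to a gene is the
gap in base pairs to the nearer transcript boundary (1 for an immediately
adjacent base).

A breakend's `side` encodes which flank survives into the derived
junction: `LEFT` means the retained segment lies at lower coordinates
(BEDPE strand `+`), `RIGHT` at higher (`-`). Orientation logic reduces to
two rules. A junction *walks into* a target gene when the direction of
travel from the junction into the retained target-side segment equals the
target's strand (`RIGHT` ⇔ `+`); a junction *leaves a 5′ gene in sense*
when travel from inside the retained 5′ segment toward the junction runs
with that gene's strand (`LEFT` ⇔ `+`). A fusion is
transcription-concordant when both hold — the two genes are juxtaposed on
one transcriptional strand. For DIB candidates (enhancer repositioning
downstream of the target), concordance means only that the intact target
is retained on the junction side; no read-through is implied.

## Classification and the uniform-breakpoint null

Each junction is classified by how many breakends fall inside gene bodies
(exon or intron alike — a breakend inside any overlapping gene counts as
genic). Under breakpoints falling uniformly over the genome, both ends are
genic with probability f², where f is the fraction of the genome covered
by the union of gene bodies; the observed gene–gene count out of N
junctions is tested against f² with a two-sided proportion test (exact
binomial, or the normal-approximation z-test; both are provided because
the flavor is a free choice and they agree to many orders of magnitude at
cohort scale).

## The splicing model

A chimeric transcript is predicted when (i) the 5′ gene's breakend lies in
one of its introns (an exonic breakpoint returns no prediction — the model
is defined for intronic breaks, which dominate because first introns are
large), and (ii) the 3′ gene is either broken in an intron (gene–gene
mode) or intact with the partner breakend in its upstream intergenic
region (UIB mode), transcription-concordant in both cases. The donor is
the 3′ boundary of the 5′ gene's last retained exon. In UIB mode the
acceptor is always the 3′ gene's exon 2: exon 1, stripped of its upstream
intron, presents no splice-acceptor signal, so the entire segment from the
donor through exon 1 is removed as a single intron. In gene–gene mode the
acceptor is the first exon after the 3′ breakend. Junction coordinates are
the genomic positions of the terminal exonic bases.

Frame is decided on annotation arithmetic, checked in the tests by
translating constructed toy sequences: `NON_CODING` when either gene lacks
a CDS; `FIVE_UTR_ONLY` when the retained 5′ exons carry zero coding bases
(the fusion borrows only promoter + UTR; the protein is the 3′ gene's,
intact); `THREE_EXON1_UTR_ORF_INTACT` when the 3′ gene's skipped prefix is
entirely untranslated (again a non-chimeric protein, translated from exon
≥ 2); otherwise `IN_FRAME` iff the retained 5′ coding length and the 3′
skipped coding prefix agree mod 3, else `OUT_OF_FRAME`. When a prediction
is both 5′-UTR-only and 3′-exon-1-UTR, `FIVE_UTR_ONLY` is reported — both
imply an intact non-chimeric protein, and the 5′ condition is checked
first. A prediction is *verified* when RNA junction records matching the
donor/acceptor (exact positions by default, `tol` configurable) sum to at
least 3 reads.

The chimera window — the maximal UIB distance at which a spliced fusion is
predicted — defaults to 100 kb, the scale of the largest introns; more
distant candidates are still emitted by the screen, flagged non-CP. The
cutoff is deliberately soft and configurable: distance alone does not
fully determine chimera formation.

## SV ingest filters

Read-support filtering keeps high-coverage calls with discordant + split
support ≥ 6 (the "and/or" of the combined evidence is read as a sum) and
low-coverage calls with ≥ 2 discordant pairs *and* ≥ 1 split read;
thresholds are parameters. Germline subtraction drops a call when a
panel-of-normals call matches both breakends within 100 bp on the same
chromosomes (either-end matching is a switch; both-ends is the default
because single-end coincidence is common at repeat edges). Repeat
filtering drops a call only when *both* breakends fall in repeat
intervals. Filters are idempotent and commute; removal counts per reason
are kept in the call set's provenance and written to the filtered BEDPE.

## The recurrence screen

For each target gene, tumor type and mode (UIB/DIB), samples carrying a
concordant intergenic breakend within the 4 Mb window enter the search, a
sample contributing its closest breakpoint (distance ties broken by sample
id). With distances ordered S₁ ≤ … ≤ Sₙ, every prefix {S₁..Sᵢ} is compared
with a two-sided Wilcoxon rank-sum test on the target's TPM and the
minimal-p prefix selected. The comparison group is, by default, all
remaining samples of the tumor type — the reading under which the test
measures upregulation against background; the verbatim alternative
(prefix vs the remaining breakpoint samples S₍ᵢ₊₁₎..Sₙ only) is available
as `--literal-split`. Fully tied data are assigned p = 1.

Filtering then removes every sample whose copy-number score for the target
is 2 (high-level amplification) — from the positive group and the control
background alike, so an amplified outlier can neither fake a positive nor
inflate the control; computes per-case fold as TPM over the control median
(pseudocount 0.1 on both sides of every fold ratio, to handle zeros);
flags out cases ≤ 4-fold; and requires the surviving group mean to exceed
5× the control mean. Events need ≥ 4 surviving samples (the recurrence
floor is applied *after* amplification exclusion — the stricter reading).
An event is `CP` when at least one positive sample's fusion yields a
verified chimera prediction for the target, `N_CP` otherwise; partner
recurrence is called when ≥ 2 positive samples share the partner breakend
cytoband. Reported per event: per-sample distances/folds/partners,
group-mean fold, the nominal minimal p together with the number of splits
tested, and distance summaries (mean, max, fractions beyond 1 and 2 Mb).

The minimal p over n splits is selection-biased; a seeded label-permutation
null (`permutations` > 0, default 1000 when enabled) reports an
`empirical_p` alongside it. Because the fold filters, not the p-value,
gate events by default, the bias does not create false events — the null
calibration below measures this directly.

Two simpler screens accompany the 4-Mb search. Gene–gene recurrence
collects pairs fused in ≥ 2 distinct samples, keyed (5′ gene, 3′ gene)
when breakend orientations determine the promoter donor and as an
unordered pair otherwise. The nearest-upstream-gene screen restricts
candidate breakends to the interval between a target's transcription start
and its nearest upstream neighbour, requires ≥ 2 samples whose target
expression lies consistently on one side of the control median (up- or
downregulation), and reports groups passing a two-sided rank-sum test at
p < 0.05 (the threshold is a parameter; no published value exists for this
step).

## Synthetic cohorts

The generator is the package's study-condition stand-in for a real
multi-tumor WGS + RNA cohort. Defaults: 4 chromosomes × 40 Mb, 160
non-overlapping genes with 3–10 exons, log-normal intron lengths (median 3
kb, σ = 1) with the first intron scaled 4× (first introns are markedly
larger in real annotations, which is what makes intron-1 breakpoints and
long splices plausible), 40% of coding genes given an untranslated first
exon so every frame outcome is reachable, and 10% non-coding genes. One
tumor type of 60 samples. Expression is TPM = baseline(gene) ×
fold(if positive) × lognormal(σ = 0.25), baseline log-normal around 20
TPM. Planted events (defaults: a 25-fold chimera-producing UIB at ≤ 30 kb,
a 110-fold UIB at megabase range, a 9-fold DIB, and a 3-sample gene–gene
fusion — spanning the moderate-to-extreme effect sizes reported for real
recurrent fusions) are realized as orientation-concordant SV calls;
chimera-producing events also emit ≥ 3 junction reads at the
model-predicted junction, computed by the predictor itself so that files
and model agree exactly. Per planted event, 2 amplified confounders
(copy-number score 2, 8× expression, no SV) exercise the GISTIC exclusion
path; germline events appear jittered (≤ 40 bp) in carrier tumor call sets
and in the panel of normals; background SVs arrive at 1.5 per sample
(plus low-support and repeat-trapped calls at lower rates) — enough to
interleave unrelated breakpoints into real 4-Mb windows without swamping
the toy genome. All randomness flows from one seed; outputs are
byte-reproducible.

What the generator does not emulate: read-level data, realistic chromosome
lengths or gene density, copy-number segmentation (scores are per-gene
integers), correlated expression programs, tumor purity/heterogeneity, and
breakpoint microhomology. Passing tests therefore demonstrate the
*logic* of the pipeline — orientation handling, splice-model arithmetic,
filter composition, split-search selection — at realistic effect sizes and
noise, not performance on real sequencing artifacts.

## Numerical and design choices

- Rank-sum tests use the exact distribution where SciPy provides it (small
  untied samples) and the tie-corrected normal approximation otherwise;
  all-tied inputs short-circuit to p = 1.
- Benjamini–Hochberg is the q-value procedure for the correlation screen;
  Pearson p-values come from the t-transform with n − 2 df.
- Mutual exclusivity is a pairwise two-sided-by-tails Fisher exact test,
  a stated simplification of dedicated combinatorial exclusivity tools;
  output columns are labelled accordingly.
- Ties: split-search p ties resolve to the smallest prefix; distance ties
  to the lexicographically smallest sample id; candidate lists sort by
  (distance, gene, mode).
- Degenerate inputs: a fully genic (or gene-free) toy genome makes the
  classification null a point mass — the proportion test reports NaN
  rather than failing; empty prefix-complements in the literal split mode
  are skipped; an empty control group is an error, not a silent pass.
- The per-sample problem sizes used by the test suite and
  `scripts/acceptance.py` (60-sample cohorts, 160-gene genomes, 200 null
  cohorts, 500 oracle instances) were chosen as the smallest scales at
  which every screen pathway — interleaved background breakpoints,
  amplified confounders, megabase UIB distances — is actually exercised.

## Known limitations

- The split search can only select distance-contiguous prefix groups, as
  the method defines it. When an unrelated sample's breakpoint interleaves
  closer to the target than true positives, those positives can be
  stranded outside the minimal-p prefix; with exactly 4 positives this can
  drop an event below the recurrence floor. This is a property of the
  method, visible in the synthetic cohorts at the weakest planted effects
  (6-fold, 4 samples), not an implementation artifact.
- Inversion calls contribute candidates only through their explicit
  per-record breakend sides; no second adjacency is inferred.
- The 4-Mb screen tests upregulation only; downregulation is covered only
  by the nearest-upstream-gene screen.
- Multi-isoform transcript structure, liftover and alignment-level
  processing are out of scope; the canonical-transcript choice can shift
  exon indices relative to other annotation sets.
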