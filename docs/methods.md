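# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of plastidkit.

## Scope and data model

All coordinates are 0-based half-open internally; the VCF-like writer emits
1-based positions.  Sample genomes are represented in the reference
coordinate frame (a substituted base array, per-position deletion flags, and
insertions anchored to a reference position).  This mirrors what short-read
mapping against a single chloroplast reference produces and makes
multi-sample pileups consistent by construction, at the cost of not modeling
alignment ambiguity itself.

## Synthetic-data generator

The generator emulates a chloroplast resequencing panel:

- **Reference** (default 160,129 bp): random sequence under the stationary
  GTR base frequencies; the second inverted repeat is the reverse complement
  of the first over the shorter span; genes are single in-frame exons
  (ATG…stop, no internal stops) placed on alternating strands in the large
  single-copy region; the analysis mask is the union of the inverted repeats
  and any planted nuclear-homologous tracts.
- **Evolution**: substitutions per branch are Poisson(rate × active sites ×
  duration) with GTR jump probabilities; indel events are Poisson at an
  independent rate, 59% insertions, with lengths on 1–36 bp calibrated so
  single-base events dominate, 2–5 bp events are ~14%, and ~90% of events
  are < 13 bp.  Substitutions and indels are placed uniformly over non-IR
  sequence only, so masking removes no planted variants; the paper-scale
  density of indel hotspots is not modeled (no generative model for them is
  available).
- **Large deletions** are planted between two copies of a short flank motif
  (e.g. TCCT) written into the reference; the deletion joins the copies,
  leaving one — the crossover-between-homologous-tracks mechanism.  A
  residual fraction of reference-carrying plastomes makes the deletion
  heteroplasmic in the carrier's pileup.
- **Hybridization** events give a recipient a fraction (leakage ∈ (0, 0.5))
  of a donor's plastomes: at every position where the two genomes differ,
  the donor base becomes a minor allele with expected fraction = leakage.
- **Pileups**: depth is Poisson(coverage) per position (default 2,000×);
  each read reports the sample allele, or the minor allele with probability
  equal to the SHP fraction, and is mutated to a uniform different base with
  probability `error_rate` (default 0.1%).  Inside a carried large deletion
  the depth collapses to Poisson(coverage × residual).
- **Determinism**: one master seed; each stage draws from a named stream
  derived via CRC-32 of the stage name, so identical configurations produce
  byte-identical outputs.

What the generator does *not* emulate: read-level artifacts (mapping bias,
indel realignment errors, strand bias, duplicate reads), alignment
ambiguity, sequence-context mutation hotspots, and events spanning the
circular origin (coordinates are linear on [0, L)).  Passing tests therefore
demonstrate correctness of the statistical machinery under idealized deep
coverage, not robustness to mapping artifacts.

Two fixtures are bundled: `toy8` (20 kb, 8 taxa, one hybridization and one
planted motif-flanked deletion) and `citrus34` (160,129 bp, 34 taxa in 11
clades, root age 13 My).  Tests and the acceptance script run end-to-end on
toy8, whose problem size keeps a full pass near one second; citrus34 is
exercised at the configuration/reference level and can be generated on
demand with `plastidkit simulate --fixture citrus34`.

## Variant calling

Haploid calls use the ≥ 90% read-support rule (boundary inclusive); support
in [0.90, 0.95) additionally carries a machine-readable `review` flag — a
deterministic stand-in for manual inspection of borderline calls.  Zero
depth is MISSING with a distinct no-coverage flag.  A position enters the
matrix iff it is unmasked and at least one call differs from the reference;
positions where every sample carries the same non-reference allele are also
reported as reference discrepancies (candidate reference errors).  Insertion
alleles are keyed `I:<seq>` at their anchor position.  Indels are
left-aligned; the leftmost equivalent representation is the canonical one.

Nuclear homology is detected by an in-package seed-and-extend search: exact
12-mer seeds, ungapped X-drop extension (+1/−2, X = 20), with thresholds
length > 100 bp, identity > 90% and Karlin–Altschul e-value
`K·m·n·exp(−λS) < 10⁻⁴` using the ungapped +1/−2 constants λ = 1.33,
K = 0.621.  Masking depends only on the threshold triple, so the simple
ungapped search is sufficient; it is not a general-purpose aligner.

`mapq_min = 29` is stored as provenance metadata only: the package never
sees reads, and the upstream filtering convention is recorded rather than
re-applied.

## Heteroplasmy and the paternity test

SHPs require minor count ≥ 5 and depth ≥ 1,000 (both boundaries inclusive),
restricted to the nonredundant SNV positions — this restriction is the main
sequencing-error control, since error-driven minor alleles rarely coincide
with segregating sites.  Tied minor alleles (both ≥ 5 reads) are emitted
once per allele and flagged ambiguous; the paternity test accepts either.

Cluster sharing uses the mean per-sample SHP count as the denominator for
clusters of ≥ 4 members and the minimum otherwise; percentages are rounded
to integers.  The paternity test excludes the hybrid itself and all known
hybrids from the candidate pool; MISSING candidate calls drop the position
from both counts; results are ranked by ratio and flagged `reported` when
more than 70 compatible positions support them.  Ancestral origins use
Dollo-like single-origin assignment at the MRCA of the carriers — justified
because heteroplasmy transmitted from one hybridization event has a single
origin by construction.

## Phylogeny and the clock test

The alignment concatenates variable SNV columns (biallelic and triallelic;
the 4-state model handles triallelic sites natively), propagating MISSING.
Neighbor joining runs on p-distances with pairwise deletion; the NJ
implementation breaks Q-criterion ties lexicographically so results are
bit-identical across runs, and finishes at a trifurcation so every
nontrivial bipartition is represented.  Supports are percentages of
site-resampled bootstrap replicates containing each bipartition.

Likelihoods use the pruning recursion over unique site patterns under GTR
(empirical base frequencies; exchangeabilities optionally optimized, off by
default — no Γ rate heterogeneity, matching a plain GTR configuration; a
switch exists in `GtrParams`).  MISSING states are marginalized (partial
likelihood of ones), not pairwise-deleted.  The clock fit parameterizes node
heights (root height log-transformed, interior nodes as sigmoid proportions
of their parent's height), guaranteeing ultrametricity; the unconstrained
fit optimizes log branch lengths.  Both use L-BFGS-B to an lnL tolerance of
10⁻⁶.  The LRT is `χ² = 2(−lnL_clock − (−lnL_free))` on `N − 2` df.  The
clock constraint is only meaningful on a sensibly rooted tree; the examples
midpoint-root the NJ tree first, and an externally supplied newick can be
used to reproduce a published topology exactly.

## Divergence dating

Branch counts are fitted branch lengths × alignment length, rounded to
integers (the convention of passing estimated substitution counts into the
dating step).  Ages are parameterized per node as
`age = lo + sigmoid(p)·(hi − lo)` where `hi` is the parent's age capped by
any maximum constraint and `lo` is the node's effective minimum (its own
minimum constraint propagated up from descendants), so parent > child and
all constraints hold at every iterate.  Langley–Fitch profiles the single
rate out in closed form.

Penalized likelihood alternates two well-conditioned subproblems until the
objective changes by < 10⁻⁹ (relative): (1) rates given ages — the penalty
is the exact quadratic form `r᾿Lr` (squared differences along parent–child
branch pairs plus the variance of root-adjacent rates, the standard
autocorrelated-rates convention), so this step is solved by damped Newton
with an exact linear solve, stable for arbitrarily large λ; (2) ages given
rates by L-BFGS-B on the reparameterized ages.  λ → ∞ provably reduces to
Langley–Fitch and the implementation reproduces that to < 0.1%; λ = 0
leaves ages unidentifiable (per-branch rates absorb any age change), which
is the expected degeneracy.  Cross-validation removes one terminal branch's
count at a time, refits, and predicts it as (parent-branch rate) × duration
(mean of the other root-adjacent rates when the parent is the root), scoring
`Σ (x − x̂)²/x̂`; the default grid is 10⁻²…10³ in half-log steps; ties go to
the first entry.  Zero-length terminal branches are excluded from folds.
The root-age scan loops the PL fit over 8–20 My in 1-My steps and reports
normalized age stability.  All-zero counts return constraint-midpoint ages
with rate 0 and a warning.  CI summaries match nodes across tree samples by
descendant leaf-set identity and report mean ± 2 SD.  K-means (k-means++,
50 restarts, fixed seed) labels branch-rate classes in ascending mean
order, falling back to k = number of distinct rates when k exceeds it.

The local-clock variant of Langley–Fitch (separate rates on user-defined
branch groups) is deliberately not implemented.

## Selection scan

Codon alignments concatenate exons (reverse-complemented for minus-strand
genes); any codon column touched by an indel in any sample is removed across
all rows, keeping frame; rows with internal stops are dropped with a
warning, and genes overlapping the inverted repeats are excluded.  Fitch
parsimony reconstructs ancestral codons per column over the observed codon
states; ambiguous assignments resolve toward fewer nonsynonymous changes,
then lexicographically.  Branch changes are decomposed by NG86 pathway
averaging (orderings through stop codons excluded unless all are); site
totals N and S are NG86 counts averaged over leaf sequences, with mutations
to stops counted as nonsynonymous so N + S = 3 × codons exactly.

The branch-ω model is a binomial surrogate for the full codon likelihood:
on a branch set with n nonsynonymous and s synonymous changes, n ~
Binomial(n + s, ωN/(ωN + S)).  The MLEs are closed-form
(ω̂ = (n/N)/(s/S), capped at 10⁻⁶ and 999 for zero counts).  The clade test
compares the two-ratio model against a foreground-neutral null (ω_fg = 1,
background free) with 1 df — the df is configurable because conventions
differ.  Genes with fewer than `min_subs = 5` total substitutions are
verdict `filtered` ("few mutations" made concrete).  The scan iterates all
internal clades × genes and reports Benjamini–Hochberg q-values alongside
raw p-values; empirical type-I error at nominal 5% is ~5–6% on neutral
simulations with ~100 substitutions per gene.  This surrogate preserves the
decision rule (ω above/below 1 plus an LRT against neutrality) but is not a
substitute for codon-model branch tests when branch lengths or codon
frequencies matter.

## Deletion calling

The caller thresholds depth at `drop_ratio` (default 0.2) times the profile
median, keeps runs of ≥ `min_sv_len` (default 50 bp) that do not touch the
profile boundary, and computes the residual reference fraction as interior
median / flanking median (300 bp flanks).  A residual ≥ 0.005 flags the
deletion heteroplasmic.  Breakpoints under flanking homology are ambiguous
by up to the homology length; calls are left-aligned, and recovery is exact
up to that inherent bound.  Microhomology is the longest shared context at
the two breakpoints (probed up to 25 bp, both junction orientations);
breakpoints bordering runs (≥ 4) of one base additionally report the
homopolymer unit and both run lengths.  Deletions are reconciled across
samples by exact breakpoint identity: identical deletions map to their
carriers' MRCA as one event; overlapping-but-distinct deletions remain
independent events.  A consensus hook intersects calls with an external call
set at reciprocal overlap ≥ 0.9.

## Numerical and testing notes

Problem sizes in the default test run were chosen to keep a full pass fast
while leaving the statistics informative: the end-to-end fixture is toy8
(20 kb × 8 taxa at 2,000×), donor-recovery uses 100 seeded replicates,
selection type-I uses 500 model-level neutral replicates, and the
pruning-likelihood oracle enumerates internal states on ≤ 4-taxon,
≤ 20-site instances.  Likelihood partials are rescaled per node to avoid
underflow; transition matrices come from the eigensystem of the symmetrized
GTR generator.  All stochastic tests are seeded.
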