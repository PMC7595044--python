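# Methods

## Statistical model of a covariation call

Covariation between genes a and b is assessed per replicate by Spearman's
ρ, computed exactly as the Pearson correlation of midranks (ties receive
average ranks). Under independence, the Fisher z-score
z = atanh(ρ)·√(n−3) is approximately N(0, 1), so each replicate yields a
two-sided p-value; pairs involving a constant gene are untestable in that
replicate. The consensus rule — significant at α = 0.01 in ≥ 2 of 3
replicates with the same ρ sign in *all* testable replicates — trades
single-replicate power for reproducibility: on exchangeable data the
consensus false-call rate is bounded by roughly 3·(α/2)²·(1/2)·2 ≈ 7.5×10⁻⁵
per pair, which the suite verifies empirically together with the
per-replicate type-I rate. The sign-consistency check is strict by
default; a lenient mode (signs compared among significant replicates only)
sits behind `strict_sign=False`. Riboprotein pairs (`^Rp[ls]` names) are
called but flagged, and excluded from networks and enrichment by default —
their dense mutual covariation would otherwise dominate every headline
count. p-values from every test in the package are floored at 2.3×10⁻¹⁶
(just above double machine epsilon).

The permutation null shuffles each gene's values across cells *within*
each replicate, independently per gene, preserving marginal distributions
and replicate structure while destroying all dependence; the complete
calling procedure is re-run per permutation. Two FDR summaries are
reported: max permuted count / observed (conservative, the default
headline) and mean-based. Ranks are computed once per replicate and
permuted directly, which makes a 50–100-permutation run on 2,000 genes a
matter of seconds.

## Enrichment background model

The expected covariation count of a pair set is the sum of
P(a,b) = degree(a)·degree(b)/total_degree, where total_degree is the
ordered double sum of the 0/1 covariation indicator (= 2 × edge count).
This convention is frozen by a hand example (edges {A–B, A–C} over four
genes: P(A,B) = 2·1/4 = 0.5, CES({A,B}) = 2) and checked exactly against a
literal double-sum implementation on random graphs. P is deliberately not
capped at 1; on tiny toy networks a single pair's expectation can exceed
1, which is acceptable because CES is a ratio of sums. For gene sets the
expected sum has the closed form ((Σd)² − Σd²)/2/total_degree, which is
algebraically identical to the pair sum and used as a fast path. Queries
with expected = 0 are reported as unreportable, never as ∞. Control sets
are size-matched uniform draws from the network's gene universe
(degree-matched draws available behind a flag); target-vs-control
comparisons use Welch's t-test. Per-regulator CES values (median across a
regulator's tables) are the default unit of comparison; per-bin values are
available via the randomized pair binning, whose trailing remainder is
dropped when it holds half a bin or less.

## Synthetic data generator

The generator emulates the study design the analysis assumes: three
well-plate replicates (110 cells each by default), ~2,000 genes,
negative-binomial counts, ERCC-like spike-ins, and latent per-cell
regulator activities a_k ~ N(0,1). Exon-layer means are
s_c·exp(β_g + Σ_k L_gk·a_k(c)) with log-normal size factor s_c
(sd 0.2) and gene baselines β_g ~ N(3, 1.2²) (about three orders of
magnitude of expression); counts are gamma-Poisson with shared dispersion
0.3, a typical Smart-Seq2 overdispersion. The intron layer uses the same
activities and baselines but omits miRNA-kind loadings — nascent
transcripts are spliced before cytoplasmic repression can act. Spike-ins
carry no factor loadings (purely technical noise). One RNG stream is
spawned per replicate from the master seed, so extending the design never
perturbs existing replicates. Mapping statistics in the cell metadata are
drawn to pass default QC; QC-rejection logic is exercised by a dedicated
fixture table instead.

Factor kinds: `tf` modules receive exactly sign-balanced ±loading (a
regulator with both activated and repressed targets, and no net effect on
a cell's total mRNA), `mirna` modules all-negative loadings (coordinated
repression, exon only, zeroed in knockout mode, with an optional
derepression offset on target baselines), `proximity_block` modules
all-positive loadings plus co-location on a synthetic chromosome at 40 kb
spacing with a matching contact table. The default regulator mix is
two-thirds TFs — shared transcriptional regulators far outnumber highly
expressed miRNA families in the emulated system — which also keeps the
coherent (same-sign) modules' common-mode effect on per-cell totals small.
That common-mode matters: with depth normalization, a large coherent
expression module couples *all* genes compositionally, and early versions
of the generator with a 1:1:1 kind mix produced exactly that artifact.

Two named configurations define the study conditions used throughout the
tests and the acceptance script:

- `modular_config` — 24 disjoint 20-gene modules at unit loading among
  2,000 genes; the benchmark for recovery (precision/recall against
  planted pairs) and network differencing.
- `transcriptome_config` — 8 TF + 4 miRNA regulators, each with 300
  graded-strength targets drawn across the whole transcriptome
  (overlapping sets, miRNA loadings at 0.55× the TF scale, reflecting the
  weaker per-target effect of miRNA repression). This yields a dense
  network in which most genes participate, the regime in which the CES
  background model is well calibrated; used for calibration, the
  knockout contrast and guilt-by-association.

What the generator does **not** emulate: transcriptional bursting
kinetics, read-level artifacts, doublets, batch effects beyond the scalar
size factor, or any dependence structure other than log-linear latent
factors. Passing tests therefore demonstrate correctness of the
statistical machinery under a monotone latent-factor world, not
performance guarantees on arbitrary real data.

## Preprocessing choices

QC thresholds use strict inequalities (> 200,000 reads, > 80% mapped,
> 40% of 19,127 annotated genes detected, < 1% spike-in, < 5%
mitochondrial, < 30% duplicates); all are overridable. Gene detection
means raw count ≥ 1, and a gene must be detected in at least half the
cells of *every* condition × replicate subset. RPM normalization divides
by the per-cell sum of endogenous (non-spike-in, non-mitochondrial)
counts — the cell's mRNA reads — ×10⁶, with no length normalization (rank
statistics only need relative abundance per gene). The 16-RPM
reliable-detection level is an advisory flag, never a filter. The
normalization diagnostic re-correlates applied size factors with
normalized genes and calls "overfitting" above 3× the nominal 1%
significant fraction. Variable genes are selected Brennecke-style: the
technical relation CV² = a₁/μ + a₀ is fitted by least squares on
log-mean-binned medians of spike-in CV² (spike-ins rescaled by their own
per-cell totals, since their fixed input concentration would otherwise
absorb cell-to-cell mRNA-content variance into the technical estimate),
and a gene is kept when (n−1)·CV²obs/CV²tech exceeds the χ²(n−1) quantile
at confidence 0.9. The criterion is monotone in confidence; a failed fit
(a₁ ≤ 0) falls back to keeping all genes with a warning. The external
cell-cycle classifier used in comparable workflows is out of scope; a
marker-score filter hook exists but is off by default.

## Network and annotation choices

Power-law fitting uses the discrete MLE with x_min = 1 (the observed
degree distributions are considered from degree 1; degree-0 genes are
excluded from fits but retained for isolated-gene accounting), maximizing
−n·log ζ(γ, x_min) − γ·Σ log k. No suitable installed library provides
this, so the likelihood, a log-log least-squares alternative, and a
zero-truncated-Poisson likelihood comparison (to flag random-graph-like
inputs) are implemented here; the two estimators are reported side by side
because exponent estimates are method-dependent.

Genomic coordinates are 0-based half-open throughout; interval distance is
gap length (0 when overlapping) and the ≤ 20 kb (intra) / ≤ 500 kb (inter)
gene-to-bin rules are boundary-inclusive. Gene bodies extend 2 kb upstream
strand-aware (unstranded records are treated as plus strand with a
warning). Intrachromosomal pairs require contact support strictly greater
than one normalized read; one contact supports a pair at most once even
when both genes match both bins. Linear gene distance is
|midpoint difference|. Distance strata (TAD, <5 MB, <25 MB, <50 MB,
>50 MB, same-chromosome-without-contact, interchromosomal) are mutually
exclusive, with TAD membership (both bodies inside one interval; first
containing TAD wins under overlap) taking precedence. miRNA targets rank
by 8mer count, then m8-7mer count, then cumulative weighted context score
(ascending — more negative is stronger); families below 4,000 RPM are
dropped (≥ kept). TF targets rank by score with lexicographic gene-id tie
break. Functional sets keep annotated sizes in [10, 100] inclusive,
filtering before universe intersection by default. Protein-interaction
tables: only experimentally evidenced pairs in score mode; complex and
reaction sets are not exclusive. Analyses at the relaxed α = 0.05 call
level (for sparse interchromosomal contact data) reuse the identical CES
machinery on an alternative call set.

## Predictions

Guilt-by-association scores every gene outside experiment 1's top 1000
(configurable) by its covariation count with experiment 1's top 100, and
validates per count group against experiment 2's top 1000. "Strongest
partners" for function inference are the top k = 10 by median-across-
replicates ρ, positive covariations only by default (a sign-aware mode
exists); enrichment per functional set is a one-sided Fisher exact test
against the gene universe, reported raw (no cross-gene multiple-testing
correction; a hierarchy-aware ontology correction is deliberately out of
scope, plain per-term tests are used instead).

## Problem sizes and determinism

The packaged study conditions (2,000 genes, 3 × 110 cells) run the full
pipeline in seconds and the complete acceptance recomputation in about two
minutes on one CPU; permutation runs default to 50–100 permutations at
these sizes (1,000 remains the recommended production setting). Every
stochastic step takes an explicit seed; identical configuration and seed
reproduce outputs bit-for-bit, including across replicate-count changes
(per-replicate RNG streams).
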