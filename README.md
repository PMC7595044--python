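# covarnet

Gene expression covariation networks from single-cell RNA-seq counts.

Two genes *covary* when their expression rises and falls together across
individual cells of a homogeneous population. Such intrinsic covariations —
measured after removing cell-cycle and differentiation confounders — carry
regulatory information: targets of the same transcription factor or miRNA
covary, as do genes in nuclear proximity or genes encoding physically
interacting proteins. `covarnet` implements the full analysis for
replicated single-cell experiments, plus a synthetic count generator with
planted covariation structure so every stage can be validated against
ground truth. It is aimed at computational biologists analysing
Smart-Seq2-style (counts-with-spike-ins, few hundred cells, biological
replicates) experiments.

## Method

**Consensus covariation calling.** Per biological replicate, all gene
pairs are scored with Spearman's rank correlation ρ (robust to outliers,
sensitive to any monotone dependence). Significance comes from the Fisher
z-transformation: z = atanh(ρ)·√(n−3) is approximately standard normal
under independence, giving a two-sided p per replicate. A pair is called
covarying iff p < 0.01 in ≥ 2 of 3 replicates *and* the sign of ρ agrees
across all testable replicates. All p-values below double machine epsilon
are conservatively floored at 2.3 × 10⁻¹⁶. The false-discovery level of
the whole procedure is bounded by permuting every gene's values within
replicates and re-running the caller (max permuted count / observed count).

**Covariation enrichment score (CES).** For a gene set, the expected
number of internal covariations under a degree-respecting random
background is Σ_pairs P(a,b) with

    P(sigCov(g_a, g_b)) = Σ_i sigCov(g_a, g_i) · Σ_j sigCov(g_b, g_j) / Σ_i Σ_j sigCov(g_i, g_j)

i.e. degree(a)·degree(b)/total_degree. CES = observed/expected is a
directly interpretable fold-enrichment (1 = chance level). Reverse
enrichment asks the converse: are called pairs more likely than
partner-permuted pairs to share a feature (e.g. a common miRNA)?

**Network analysis.** Calls form an undirected graph over the filtered
gene universe; the degree distribution is fitted with a discrete
power law P(k) ∝ k^(−γ) by maximum likelihood (alternative least-squares
fit and a Poisson-likelihood comparison reported alongside); wild-type and
perturbed networks are differenced into lost/gained covariations.

**Predictions.** Guilt-by-association: genes are ranked by their number of
covariations with a regulator's top 100 known targets and validated
against an independent experiment. Function inference: one-sided Fisher
exact enrichment of functional sets among a gene's strongest covariation
partners.

## Worked example

`examples/01_simulate_and_call.py` simulates 3 × 110 cells and 2,000 genes
with 24 planted 20-gene regulator modules, then runs the full calling
pipeline:

```
simulated 330 cells x 2040 genes (4560 planted covarying pairs)
after QC and filtering: 330 cells x 2031 genes
called 4756 covariations (3114 positive, 1642 negative)
precision 0.951, recall 0.992 against planted truth
```

95% of called pairs were genuinely planted and 99% of planted pairs were
recovered. The other examples demonstrate the permutation FDR bound
(`02`), enrichment scores with random-set controls (`03`), the
miRNA-knockout contrast at exon vs intron level (`04`), degree-distribution
fits and network differencing (`05`) and the prediction tools (`06`); each
prints a line explaining what its numbers mean. A thin CLI wraps the same
functions (`covarnet simulate|qc|normalize|covary|permute|network|diff|ces|run`).

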