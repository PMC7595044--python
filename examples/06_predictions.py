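"""Guilt-by-association target prediction and function inference.

If a gene covaries with many known targets of a regulator, it is likely a
target itself: genes are scored by their covariation count with the top 100
targets from one (noisy) experiment and validated against an independent
second experiment. Gene function is inferred from the functional
annotations of a gene's strongest covariation partners (one-sided Fisher
exact tests against the gene universe).
"""

import numpy as np

import covarnet as cn
import covarnet.preprocess as pp
from covarnet import network, predict, sim

adata, truth = cn.simulate_counts(sim.transcriptome_config(seed=1))
adata = pp.rpm_normalize(pp.filter_genes(pp.apply_cell_qc(adata)))
calls = cn.call_covariations(cn.replicate_correlations(adata))
net = network.build_network(calls)

# two noisy target rankings standing in for two ChIP experiments
f = truth.factors_of_kind("tf")[0]
true_rank = list(truth.loadings[f].abs().sort_values(ascending=False).index)
rng = np.random.default_rng(3)


def noisy_experiment(sd=150):
    scores = -np.arange(len(true_rank)) + rng.normal(0, sd, len(true_rank))
    return [true_rank[i] for i in np.argsort(-scores)]


curve = predict.guilt_by_association(
    net, noisy_experiment(), noisy_experiment(),
    seed_n=100, exclusion_n=300, validation_n=300,
)
print(f"validation base rate: {curve.attrs['base_rate']:.3f}")
lo = curve[curve["n_covariations"] <= 2]
hi = curve[curve["n_covariations"] >= 20]
print(f"genes with <=2 seed covariations validate at "
      f"{lo['n_validated'].sum() / lo['n_genes'].sum():.3f}")
print(f"genes with >=20 seed covariations validate at "
      f"{hi['n_validated'].sum() / hi['n_genes'].sum():.3f}")
print(f"monotone trend: Spearman rho {curve.attrs['trend_rho']:.2f} "
      f"(p {curve.attrs['trend_p']:.1e})")

# function inference for one module gene against its planted set
gene = truth.module_genes(f)[0]
sets = {"planted_module": truth.module_genes(f)}
for i in range(9):
    sets[f"random_{i}"] = list(rng.choice(net.genes, 30, replace=False))
out = predict.infer_function(gene, calls, sets, universe=list(net.genes),
                             bona_fide_term="planted_module")
top = out["enrichments"].iloc[0]
print(f"top inferred term for {gene}: {top['term']} (p {top['p']:.1e}); "
      f"bona fide term in top 10: {out['bona_fide_in_top10']}")
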