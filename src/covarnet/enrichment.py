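"""Covariation enrichment score (CES) and reverse enrichment.

Whether a gene set covaries more than chance predicts is judged against a
configuration-model-style background: the probability that a specific pair
(g_a, g_b) carries a significant covariation, were covariations distributed
randomly while respecting each gene's total, is

    P(sigCov(g_a, g_b)) = degree(g_a) * degree(g_b) / total_degree

with ``total_degree`` the ordered double sum of the 0/1 covariation
indicator over the whole universe (= 2 x edge count). Summing P over the
pairs of a query set gives the *expected covariations*; the CES is
observed / expected, so 1 means "as expected by chance" and the score is
directly interpretable as a fold-enrichment. P is deliberately not capped
at 1 — on pathological toy networks a single pair's expectation can exceed
1, which is acceptable because the CES is a ratio of sums.

Reverse enrichment asks the converse question: among the called covarying
pairs, is a pairwise feature (say, sharing a miRNA) more frequent than in a
partner-permuted version of the same pair list?
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import CovariationNetwork

P_FLOOR = 2.3e-16

__all__ = [
    "pair_probability",
    "ces",
    "CESResult",
    "bin_pairs",
    "compare_to_controls",
    "random_control_sets",
    "reverse_enrichment",
    "ces_profile",
]


def pair_probability(net: CovariationNetwork, a: str, b: str) -> float:
    """Background probability of a significant covariation between a and b."""
    if a == b:
        raise ValueError("self-pairs have no covariation probability")
    if a not in net or b not in net:
        raise ValueError(f"gene outside universe: {a if a not in net else b}")
    if net.total_degree == 0:
        return 0.0
    return net.degree_of(a) * net.degree_of(b) / net.total_degree


@dataclass
class CESResult:
    observed: int
    expected: float
    ces: float | None  # None when unreportable (expected == 0)
    n_pairs: int
    unreportable: bool = False
    bins: list["CESResult"] = field(default_factory=list)

    @property
    def log2_ces(self) -> float:
        if self.unreportable or not self.ces:
            return float("nan")
        return float(np.log2(self.ces))


def _pairs_of_set(genes: list[str]) -> list[tuple[str, str]]:
    gs = sorted(set(genes))
    return [(gs[i], gs[j]) for i in range(len(gs)) for j in range(i + 1, len(gs))]


def ces(
    net: CovariationNetwork,
    query: list[str] | set[str] | list[tuple[str, str]],
) -> CESResult:
    """CES of a gene set (all within-set pairs) or an explicit pair list.

    Genes outside the network universe are dropped from the query. A query
    whose expected count is zero is unreportable rather than infinite.
    """
    if len(query) and isinstance(next(iter(query)), (tuple, list)):
        pairs = [(a, b) for a, b in query if a in net and b in net and a != b]
    else:
        genes = [g for g in query if g in net]
        pairs = _pairs_of_set(genes)
    if not pairs:
        return CESResult(0, 0.0, None, 0, unreportable=True)
    observed = sum(1 for a, b in pairs if net.has_edge(a, b))
    expected = float(sum(pair_probability(net, a, b) for a, b in pairs))
    if expected == 0:
        return CESResult(observed, 0.0, None, len(pairs), unreportable=True)
    return CESResult(observed, expected, observed / expected, len(pairs))


def ces_gene_set_fast(net: CovariationNetwork, genes: list[str]) -> CESResult:
    """Closed-form CES for a gene set.

    expected = ((sum d)^2 - sum d^2) / 2 / total_degree, identical to the
    pair-probability sum (asserted against the literal double-sum oracle in
    the test suite); observed via the induced adjacency submatrix.
    """
    idx = [net.index_of(g) for g in sorted(set(genes)) if g in net]
    if len(idx) < 2 or net.total_degree == 0:
        return CESResult(0, 0.0, None, max(0, len(idx) * (len(idx) - 1) // 2),
                         unreportable=True)
    d = net.degree[idx]
    expected = float((d.sum() ** 2 - (d**2).sum()) / 2 / net.total_degree)
    sub = [net.genes[i] for i in idx]
    observed = int(net.graph.subgraph(sub).number_of_edges())
    n_pairs = len(idx) * (len(idx) - 1) // 2
    if expected == 0:
        return CESResult(observed, 0.0, None, n_pairs, unreportable=True)
    return CESResult(observed, expected, observed / expected, n_pairs)


def bin_pairs(
    pairs: list[tuple[str, str]], bin_size: int, seed: int = 0
) -> list[list[tuple[str, str]]]:
    """Randomized partition of a pair list into bins of ``bin_size``.

    The trailing remainder is dropped when it holds half a bin or less.
    Fewer pairs than one bin yields a single bin with a warning.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    shuffled = [pairs[i] for i in order]
    if len(shuffled) < bin_size:
        import warnings

        warnings.warn("fewer pairs than one bin; returning a single bin")
        return [shuffled]
    bins = [shuffled[i : i + bin_size] for i in range(0, len(shuffled), bin_size)]
    if 2 * len(bins[-1]) <= bin_size:
        bins = bins[:-1]
    return bins


def random_control_sets(
    net: CovariationNetwork, set_size: int, n_draws: int = 100, seed: int = 0
) -> list[list[str]]:
    """Size-matched random gene sets drawn uniformly from the universe."""
    rng = np.random.default_rng(seed)
    return [
        list(rng.choice(net.genes, size=set_size, replace=False))
        for _ in range(n_draws)
    ]


def compare_to_controls(target_ces: list[float], control_ces: list[float]) -> dict:
    """Welch two-sample t-test of target CES values against controls."""
    t_vals = [v for v in target_ces if np.isfinite(v)]
    c_vals = [v for v in control_ces if np.isfinite(v)]
    if len(t_vals) < 2 or len(c_vals) < 2:
        raise ValueError("need >= 2 finite CES values per group")
    if np.var(t_vals) == 0 and np.var(c_vals) == 0:
        return {"t": 0.0 if np.mean(t_vals) == np.mean(c_vals) else np.inf,
                "p": np.nan, "flag": "zero variance in both groups"}
    t, p = stats.ttest_ind(t_vals, c_vals, equal_var=False)
    return {"t": float(t), "p": float(max(p, P_FLOOR)), "flag": None}


def reverse_enrichment(
    net: CovariationNetwork,
    feature_pairs: set[tuple[str, str]],
    n_perm: int = 100,
    seed: int = 0,
) -> dict:
    """log2 ratio of feature sharing among called pairs vs permuted pairs.

    f_obs = fraction of the network's edges present in ``feature_pairs``;
    each permutation shuffles the partner column of the edge list over the
    network's genes (self and duplicate pairs redrawn), and the statistic is
    log2(f_obs / mean f_perm). Unreportable when the permuted mean is zero
    or f_obs is zero (log ratio -inf).
    """
    if net.n_edges == 0:
        raise ValueError("network has no edges")
    feats = {(a, b) if a < b else (b, a) for a, b in feature_pairs}
    edges = [((a, b) if a < b else (b, a)) for a, b in net.graph.edges]
    f_obs = np.mean([e in feats for e in edges])
    rng = np.random.default_rng(seed)
    genes = net.genes
    f_perm = np.zeros(n_perm)
    first = np.array([e[0] for e in edges])
    for b in range(n_perm):
        partners = rng.choice(genes, size=len(edges))
        seen: set[tuple[str, str]] = set()
        hits = 0
        total = 0
        for a, p in zip(first, partners):
            if a == p:
                continue
            key = (a, p) if a < p else (p, a)
            if key in seen:
                continue
            seen.add(key)
            total += 1
            if key in feats:
                hits += 1
        f_perm[b] = hits / total if total else 0.0
    mean_perm = float(f_perm.mean())
    out = {"f_obs": float(f_obs), "f_perm_mean": mean_perm, "n_perm": n_perm}
    if mean_perm == 0:
        out.update(log2_ratio=np.nan, unreportable=True, reason="permuted mean is 0")
    elif f_obs == 0:
        out.update(log2_ratio=-np.inf, unreportable=True, reason="f_obs is 0")
    else:
        out.update(log2_ratio=float(np.log2(f_obs / mean_perm)), unreportable=False)
    return out


def ces_profile(
    net: CovariationNetwork,
    ranked_targets: dict[str, list[str]],
    top_ns: tuple[int, ...] = (200, 300, 500),
) -> pd.DataFrame:
    """CES of the top-N targets of each regulator, for each N.

    Returns a tidy frame (regulator, top_n, observed, expected, ces) plus
    ``regulator == "__median__"`` rows carrying the median CES across
    regulators per N — the representative value when a regulator
    contributes several target tables. Regulators with fewer than N targets
    skip that N.
    """
    rows = []
    for reg, targets in ranked_targets.items():
        for n in top_ns:
            if len(targets) < n:
                continue
            r = ces_gene_set_fast(net, targets[:n])
            rows.append(
                {
                    "regulator": reg,
                    "top_n": n,
                    "observed": r.observed,
                    "expected": r.expected,
                    "ces": r.ces if not r.unreportable else np.nan,
                }
            )
    df = pd.DataFrame(rows, columns=["regulator", "top_n", "observed", "expected", "ces"])
    med = [
        {
            "regulator": "__median__",
            "top_n": n,
            "observed": np.nan,
            "expected": np.nan,
            "ces": float(sub["ces"].median()),
        }
        for n, sub in df.groupby("top_n")
        if len(sub)
    ]
    return pd.concat([df, pd.DataFrame(med)], ignore_index=True)
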