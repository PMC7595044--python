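"""Replicate-wise rank correlation and consensus covariation calling.

Two genes covary when their expression rises and falls together across
single cells. Per replicate, dependence is measured by Spearman's rank
correlation (Pearson correlation of midranks — robust to outliers, detects
any monotone relation) and tested via the Fisher z-transformation:
``z = atanh(rho) * sqrt(n - 3)`` is approximately standard normal under
independence, giving a two-sided p-value per pair and replicate.

A pair is *called* covarying when it is significant (p < alpha, default
0.01) in at least ``min_replicates`` of the replicates (default 2 of 3) and
the sign of rho agrees across all testable replicates; the call carries that
common sign. The false-discovery level of the whole procedure is estimated
by permuting every gene's values across cells (within replicate, preserving
marginals while destroying dependence) and re-running the full calling
procedure; the maximum permuted call count over the observed count is the
reported FDR bound.

All p-values are floored at 2.3e-16 (values below double machine epsilon
are conservatively rounded up).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 2.3e-16
MIN_CELLS = 20

__all__ = [
    "spearman_rho",
    "spearman_matrix",
    "fisher_z_p",
    "rho_threshold",
    "replicate_correlations",
    "call_covariations",
    "permutation_fdr",
    "alt_dependence",
    "hoeffding_d",
    "CovariationResult",
    "CallSet",
]


# ---------------------------------------------------------------------------
# elementary statistics


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation = Pearson correlation of midranks.

    Returns NaN when either vector is constant (rank correlation is then
    undefined and the pair is untestable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_matrix(X: np.ndarray) -> np.ndarray:
    """All-pairs Spearman over the rows of ``X`` (features x observations).

    Constant rows yield NaN against every partner. Memory is O(features^2),
    fine for a few thousand post-filter genes.
    """
    X = np.asarray(X, dtype=float)
    R = stats.rankdata(X, axis=1)
    sd = R.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        Rc = R - R.mean(axis=1, keepdims=True)
        denom = np.sqrt((Rc**2).sum(axis=1))
        denom[constant] = 1.0
        Rn = Rc / denom[:, None]
        rho = Rn @ Rn.T
    rho = np.clip(rho, -1.0, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    return rho


def fisher_z_p(rho, n: int):
    """Two-sided Fisher-z p-value for a correlation at sample size ``n``.

    ``z = atanh(rho) * sqrt(n - 3)``; ``p = 2 * (1 - Phi(|z|))`` floored at
    2.3e-16. ``|rho| = 1`` maps to the floor. Vectorized over ``rho``.
    """
    if n <= 3:
        raise ValueError("Fisher z-test requires n > 3")
    rho_arr = np.asarray(rho, dtype=float)
    out = np.full(rho_arr.shape, np.nan)
    finite = np.isfinite(rho_arr)
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(rho_arr[finite], -1, 1)) * np.sqrt(n - 3)
    p = 2.0 * stats.norm.sf(np.abs(z))
    out[finite] = np.maximum(p, P_FLOOR)
    return out if out.ndim else float(out)


def rho_threshold(alpha: float, n: int) -> float:
    """Smallest |rho| significant at ``alpha`` for sample size ``n``."""
    if n <= 3:
        raise ValueError("requires n > 3")
    z = stats.norm.ppf(1 - alpha / 2)
    return float(np.tanh(z / np.sqrt(n - 3)))


# ---------------------------------------------------------------------------
# replicate-wise correlation and consensus calling


@dataclass
class CovariationResult:
    """Per-replicate all-pairs statistics on one layer of one condition."""

    genes: np.ndarray  # gene names, order fixes matrix indices
    rho: np.ndarray  # (n_replicates, G, G)
    p: np.ndarray  # (n_replicates, G, G)
    n_cells: list[int]
    replicates: list[str]
    layer: str
    condition: str | None
    is_ribo: np.ndarray | None = None  # per-gene flag

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def replicate_correlations(
    adata: ad.AnnData,
    layer: str = "rpm",
    condition: str | None = None,
    min_cells: int = MIN_CELLS,
) -> CovariationResult:
    """All-pairs Spearman rho and Fisher-z p per replicate.

    Spike-in rows are excluded from the pair universe. ``condition``
    subsets ``obs["condition"]`` first when given.
    """
    if condition is not None:
        adata = adata[adata.obs["condition"] == condition]
    gene_mask = (
        ~adata.var["is_spikein"].to_numpy()
        if "is_spikein" in adata.var
        else np.ones(adata.n_vars, bool)
    )
    genes = adata.var_names.to_numpy()[gene_mask]
    is_ribo = (
        adata.var["is_ribo"].to_numpy()[gene_mask]
        if "is_ribo" in adata.var
        else np.zeros(len(genes), bool)
    )
    X = adata.layers[layer] if layer in adata.layers else adata.X
    X = np.asarray(X)[:, gene_mask]

    reps = list(dict.fromkeys(adata.obs["replicate"]))
    rho_stack, p_stack, n_cells = [], [], []
    for r in reps:
        idx = np.nonzero((adata.obs["replicate"] == r).to_numpy())[0]
        n = len(idx)
        if n < min_cells:
            raise ValueError(f"replicate {r} has {n} cells; >= {min_cells} required")
        rho = spearman_matrix(X[idx].T)
        p = fisher_z_p(rho, n)
        rho_stack.append(rho)
        p_stack.append(p)
        n_cells.append(n)
    return CovariationResult(
        genes=genes,
        rho=np.stack(rho_stack),
        p=np.stack(p_stack),
        n_cells=n_cells,
        replicates=[str(r) for r in reps],
        layer=layer,
        condition=condition,
        is_ribo=is_ribo,
    )


@dataclass
class CallSet:
    """Consensus covariation calls (undirected, signed gene pairs)."""

    calls: pd.DataFrame  # gene_a, gene_b, sign, rho_*, p_*, is_ribo_pair
    alpha: float
    min_replicates: int
    layer: str
    condition: str | None
    genes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    n_untestable: int = 0

    def pair_set(self, include_ribo: bool = False) -> set[tuple[str, str]]:
        df = self.calls if include_ribo else self.calls[~self.calls["is_ribo_pair"]]
        return set(map(tuple, df[["gene_a", "gene_b"]].to_numpy()))

    def __len__(self) -> int:
        return len(self.calls)


def _consensus_mask(
    rho: np.ndarray,
    p: np.ndarray,
    alpha: float,
    min_replicates: int,
    strict_sign: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean called matrix + sign matrix + untestable-pair matrix."""
    testable = ~np.isnan(rho)
    sig = testable & (p < alpha)
    n_sig = sig.sum(axis=0)
    n_testable = testable.sum(axis=0)
    pos = rho > 0
    neg = rho < 0
    if strict_sign:
        # sign must agree across every testable replicate; rho == 0 in any
        # testable replicate breaks consistency
        consistent_pos = ((pos & testable) | ~testable).all(axis=0)
        consistent_neg = ((neg & testable) | ~testable).all(axis=0)
    else:
        consistent_pos = ((pos & sig) | ~sig).all(axis=0)
        consistent_neg = ((neg & sig) | ~sig).all(axis=0)
    called = (
        (n_sig >= min_replicates)
        & (n_testable >= min_replicates)
        & (consistent_pos | consistent_neg)
    )
    sign = np.where(consistent_pos, 1, -1)
    untestable = n_testable < min_replicates
    return called, sign, untestable


def call_covariations(
    result: CovariationResult,
    alpha: float = 0.01,
    min_replicates: int = 2,
    strict_sign: bool = True,
) -> CallSet:
    """Consensus calls from per-replicate statistics.

    A pair is called iff significant (p < ``alpha``) in at least
    ``min_replicates`` replicates and sign-consistent — strictly across all
    testable replicates by default; ``strict_sign=False`` relaxes the check
    to the significant replicates only. Riboprotein pairs (both genes
    flagged) are called but marked ``is_ribo_pair`` for downstream
    exclusion from headline counts and enrichment.
    """
    called, sign, untestable = _consensus_mask(
        result.rho, result.p, alpha, min_replicates, strict_sign
    )
    iu = np.triu_indices(result.n_genes, k=1)
    sel = called[iu]
    ia, ib = iu[0][sel], iu[1][sel]
    data = {
        "gene_a": result.genes[ia],
        "gene_b": result.genes[ib],
        "sign": sign[iu][sel],
    }
    for r in range(len(result.replicates)):
        data[f"rho_{result.replicates[r]}"] = result.rho[r][ia, ib]
        data[f"p_{result.replicates[r]}"] = result.p[r][ia, ib]
    ribo = result.is_ribo
    if ribo is None:
        ribo = np.zeros(result.n_genes, bool)
    data["is_ribo_pair"] = ribo[ia] & ribo[ib]
    calls = pd.DataFrame(data)
    return CallSet(
        calls=calls,
        alpha=alpha,
        min_replicates=min_replicates,
        layer=result.layer,
        condition=result.condition,
        genes=result.genes,
        n_untestable=int(untestable[iu].sum()),
    )


def _count_calls(
    rho: np.ndarray, p: np.ndarray, alpha: float, min_replicates: int, strict_sign: bool
) -> int:
    called, _, _ = _consensus_mask(rho, p, alpha, min_replicates, strict_sign)
    iu = np.triu_indices(called.shape[0], k=1)
    return int(called[iu].sum())


def permutation_fdr(
    adata: ad.AnnData,
    n_perm: int = 1000,
    seed: int = 0,
    layer: str = "rpm",
    condition: str | None = None,
    alpha: float = 0.01,
    min_replicates: int = 2,
    strict_sign: bool = True,
) -> dict:
    """Permutation null for the full consensus-calling procedure.

    Each permutation independently shuffles every gene's values across the
    cells of each replicate (marginals preserved, dependence destroyed) and
    re-runs calling. Since ranks of permuted values are permuted ranks, the
    per-replicate rank matrices are computed once and their rows permuted.
    Returns per-permutation call counts, their max and mean, and FDR
    estimates ``max_count / observed`` and ``mean_count / observed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    res = replicate_correlations(adata, layer=layer, condition=condition)
    observed = _count_calls(res.rho, res.p, alpha, min_replicates, strict_sign)

    if condition is not None:
        adata = adata[adata.obs["condition"] == condition]
    gene_mask = (
        ~adata.var["is_spikein"].to_numpy()
        if "is_spikein" in adata.var
        else np.ones(adata.n_vars, bool)
    )
    X = np.asarray(adata.layers[layer] if layer in adata.layers else adata.X)
    X = X[:, gene_mask]
    rep_ranks = []
    for r in res.replicates:
        idx = np.nonzero((adata.obs["replicate"] == r).to_numpy())[0]
        rep_ranks.append(stats.rankdata(X[idx].T, axis=1))

    rng = np.random.default_rng(seed)
    counts = np.zeros(n_perm, dtype=int)
    G = res.n_genes
    for b in range(n_perm):
        rho_stack, p_stack = [], []
        for R, n in zip(rep_ranks, res.n_cells):
            perm = rng.permuted(R, axis=1)
            rho = _corr_of_ranks(perm)
            rho_stack.append(rho)
            p_stack.append(fisher_z_p(rho, n))
        counts[b] = _count_calls(
            np.stack(rho_stack), np.stack(p_stack), alpha, min_replicates, strict_sign
        )
    return {
        "observed": observed,
        "counts": counts,
        "max_count": int(counts.max()),
        "mean_count": float(counts.mean()),
        "fdr_estimate": counts.max() / observed if observed else np.inf,
        "fdr_estimate_mean": counts.mean() / observed if observed else np.inf,
        "empirical_p": float((counts >= observed).mean()),
    }


def _corr_of_ranks(R: np.ndarray) -> np.ndarray:
    sd = R.std(axis=1)
    constant = sd == 0
    Rc = R - R.mean(axis=1, keepdims=True)
    denom = np.sqrt((Rc**2).sum(axis=1))
    denom[constant] = 1.0
    Rn = Rc / denom[:, None]
    rho = np.clip(Rn @ Rn.T, -1.0, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    return rho


# ---------------------------------------------------------------------------
# alternative dependence measures (robustness reports)


def hoeffding_d(x: np.ndarray, y: np.ndarray) -> float:
    """Hoeffding's D, the classical U-statistic scaled to [-0.5, 1].

    O(n^2); requires n >= 5 (undefined below five points).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("Hoeffding's D requires n >= 5")
    R = stats.rankdata(x)
    S = stats.rankdata(y)
    # Q_i = 1 + #{j : x_j < x_i and y_j < y_i}, with 1/2 and 1/4 tie credits
    lt_x = (x[None, :] < x[:, None]).astype(float)
    lt_y = (y[None, :] < y[:, None]).astype(float)
    eq_x = (x[None, :] == x[:, None]).astype(float)
    eq_y = (y[None, :] == y[:, None]).astype(float)
    np.fill_diagonal(eq_x, 0.0)
    np.fill_diagonal(eq_y, 0.0)
    Q = (
        1.0
        + (lt_x * lt_y).sum(axis=1)
        + 0.5 * (eq_x * lt_y + lt_x * eq_y).sum(axis=1)
        + 0.25 * (eq_x * eq_y).sum(axis=1)
    )
    D1 = np.sum((Q - 1) * (Q - 2))
    D2 = np.sum((R - 1) * (R - 2) * (S - 1) * (S - 2))
    D3 = np.sum((R - 2) * (S - 2) * (Q - 1))
    D = (
        30.0
        * ((n - 2) * (n - 3) * D1 + D2 - 2 * (n - 2) * D3)
        / (n * (n - 1) * (n - 2) * (n - 3) * (n - 4))
    )
    return float(D)


def alt_dependence(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> float:
    """Pearson r or Hoeffding's D for overlap-robustness reports."""
    if method == "pearson":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])
    if method == "hoeffding_d":
        return hoeffding_d(x, y)
    raise ValueError(f"unknown method: {method!r}")
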