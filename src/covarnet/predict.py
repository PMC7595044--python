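"""Guilt-by-association target prediction and neighbourhood function inference.

If a gene covaries with many known targets of a regulator, it is plausibly a
target itself. The prediction screen counts, for every candidate gene, its
significant covariations with the top-ranked targets from one experiment
(the seed set), excludes genes already called targets in that experiment,
and scores each covariation-count group by how often its genes reappear
among the top targets of an independent second experiment.

Function inference works the other way: the functional annotations of a
gene's strongest covariation partners (top-k by rank correlation) are
tested for enrichment with one-sided Fisher's exact tests against the gene
universe, ranking candidate functions for the gene itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .covariation import CallSet
from .network import CovariationNetwork

__all__ = ["guilt_by_association", "infer_function"]


def guilt_by_association(
    net: CovariationNetwork,
    exp1_ranked: list[str],
    exp2_ranked: list[str],
    seed_n: int = 100,
    exclusion_n: int = 1000,
    validation_n: int = 1000,
) -> pd.DataFrame:
    """Validation-probability curve over covariation counts with seed targets.

    For every network gene outside the top ``exclusion_n`` of experiment 1,
    count its covariations with experiment 1's top ``seed_n`` targets;
    group genes by that count; per group report the fraction found in the
    top ``validation_n`` of experiment 2. Returns one row per count with
    columns n_covariations, n_genes, n_validated, validation_probability,
    plus the base validation rate among all scored genes in ``attrs``.
    """
    exp1 = [g for g in exp1_ranked if g in net]
    exp2 = [g for g in exp2_ranked if g in net]
    seeds = set(exp1[:seed_n])
    if len(seeds) < 10:
        raise ValueError(f"only {len(seeds)} seed targets in universe; >= 10 required")
    excluded = set(exp1[:exclusion_n])
    validation = set(exp2[:validation_n])

    records = []
    for g in net.genes:
        if g in excluded:
            continue
        count = sum(1 for s in seeds if net.has_edge(g, s))
        records.append((g, count, g in validation))
    df = pd.DataFrame(records, columns=["gene", "n_covariations", "validated"])
    curve = (
        df.groupby("n_covariations")
        .agg(n_genes=("gene", "size"), n_validated=("validated", "sum"))
        .reset_index()
    )
    curve["validation_probability"] = curve["n_validated"] / curve["n_genes"]
    curve.attrs["base_rate"] = float(df["validated"].mean())
    curve.attrs["n_scored"] = len(df)
    if len(curve) > 2:
        trend = stats.spearmanr(
            curve["n_covariations"], curve["validation_probability"]
        )
        curve.attrs["trend_rho"] = float(trend.statistic)
        curve.attrs["trend_p"] = float(trend.pvalue)
    return curve


def _median_rho(calls: pd.DataFrame) -> pd.Series:
    rho_cols = [c for c in calls.columns if c.startswith("rho_")]
    return calls[rho_cols].median(axis=1)


def top_partners(
    calls: CallSet, gene: str, k: int = 10, positive_only: bool = True
) -> tuple[list[str], bool]:
    """Top-k covariation partners of ``gene`` by median replicate rho.

    Returns (partners, flagged) where flagged is True when the gene has
    fewer than k partners (all are used).
    """
    df = calls.calls
    mask = (df["gene_a"] == gene) | (df["gene_b"] == gene)
    sub = df[mask].copy()
    if positive_only:
        sub = sub[sub["sign"] > 0]
    sub["partner"] = np.where(sub["gene_a"] == gene, sub["gene_b"], sub["gene_a"])
    sub["rho_med"] = _median_rho(sub)
    sub = sub.sort_values("rho_med", ascending=False)
    partners = list(sub["partner"].head(k))
    return partners, len(sub) < k


def infer_function(
    gene: str,
    calls: CallSet,
    functional_sets: dict[str, list[str]],
    universe: list[str] | np.ndarray,
    k: int = 10,
    positive_only: bool = True,
    bona_fide_term: str | None = None,
) -> dict:
    """Enriched functional terms among a gene's top covariation partners.

    The gene's top-``k`` partners by (positive, by default) median rho are
    tested per functional set with a one-sided Fisher's exact test of
    partner membership against the universe (the gene itself excluded).
    Terms are returned ranked by p; when ``bona_fide_term`` is given, the
    result reports whether it lands among the top ten enrichments.
    """
    partners, flagged = top_partners(calls, gene, k=k, positive_only=positive_only)
    if not partners:
        raise ValueError(f"{gene} has no covariation partners to test")
    uni = [g for g in universe if g != gene]
    pset = set(partners)
    rows = []
    for term, members in functional_sets.items():
        mem = set(members) & set(uni)
        in_both = len(pset & mem)
        in_partners_only = len(pset) - in_both
        in_set_only = len(mem) - in_both
        rest = len(uni) - in_both - in_partners_only - in_set_only
        _, p = stats.fisher_exact(
            [[in_both, in_partners_only], [in_set_only, rest]], alternative="greater"
        )
        rows.append({"term": term, "overlap": in_both, "set_size": len(mem),
                     "p": float(p)})
    table = (
        pd.DataFrame(rows).sort_values(["p", "term"], ignore_index=True)
        if rows
        else pd.DataFrame(columns=["term", "overlap", "set_size", "p"])
    )
    out = {
        "gene": gene,
        "partners": partners,
        "fewer_than_k": flagged,
        "enrichments": table,
    }
    if bona_fide_term is not None:
        out["bona_fide_in_top10"] = bona_fide_term in list(table["term"].head(10))
    return out
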