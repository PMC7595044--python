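"""Cell QC, gene filtering, RPM normalization and variable-gene selection.

Quality control keeps a cell only if all six mapping-statistic criteria hold
with strict inequalities: >200,000 sequenced reads, >80% mapped, >40% of the
annotation's genes detected (default annotation size 19,127), <1% spike-in
reads, <5% mitochondrial reads and <30% PCR duplicates. Gene filtering keeps
a gene only if it is detected (count >= 1) in at least half of the cells of
every condition x replicate subset; Gm-numbered predicted gene models are
dropped by regex. Normalization is plain reads-per-million over endogenous
(non-spike-in, non-mitochondrial by default) counts, with a diagnostic that
flags normalizations whose size factors still correlate with the normalized
genes (overfitting). Variable genes are selected against a technical noise
model CV^2 = a1/mu + a0 fitted on spike-ins.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .covariation import fisher_z_p, spearman_rho

P_FLOOR = 2.3e-16

__all__ = [
    "QCThresholds",
    "cell_qc",
    "filter_genes",
    "rpm_normalize",
    "normalization_diagnostic",
    "select_variable_genes",
]

QC_FIELDS = [
    "total_reads",
    "frac_mapped",
    "frac_genes_detected",
    "frac_spikein",
    "frac_mito",
    "frac_pcr_dup",
]


@dataclass(frozen=True)
class QCThresholds:
    min_reads: float = 200_000
    min_frac_mapped: float = 0.80
    min_frac_genes: float = 0.40
    max_frac_spikein: float = 0.01
    max_frac_mito: float = 0.05
    max_frac_dup: float = 0.30
    annotation_size: int = 19_127


def cell_qc(
    stats_df: pd.DataFrame, thresholds: QCThresholds | None = None
) -> pd.DataFrame:
    """Per-cell pass/fail with failure reasons.

    ``stats_df`` needs the six columns in :data:`QC_FIELDS` (one row per
    cell). A cell passes iff every criterion holds strictly; cells with
    missing values fail with reason ``"incomplete stats"``. Returns a frame
    indexed like the input with columns ``pass`` (bool) and ``reasons``
    (list of violated criteria).
    """
    thr = thresholds or QCThresholds()
    missing_cols = [c for c in QC_FIELDS if c not in stats_df.columns]
    records = []
    for _, row in stats_df.iterrows():
        if missing_cols or row[QC_FIELDS].isna().any():
            records.append((False, ["incomplete stats"]))
            continue
        reasons = []
        if not row["total_reads"] > thr.min_reads:
            reasons.append("min_reads")
        if not row["frac_mapped"] > thr.min_frac_mapped:
            reasons.append("min_frac_mapped")
        if not row["frac_genes_detected"] > thr.min_frac_genes:
            reasons.append("min_frac_genes")
        if not row["frac_spikein"] < thr.max_frac_spikein:
            reasons.append("max_frac_spikein")
        if not row["frac_mito"] < thr.max_frac_mito:
            reasons.append("max_frac_mito")
        if not row["frac_pcr_dup"] < thr.max_frac_dup:
            reasons.append("max_frac_dup")
        records.append((len(reasons) == 0, reasons))
    return pd.DataFrame(
        records, index=stats_df.index, columns=["pass", "reasons"]
    )


def apply_cell_qc(
    adata: ad.AnnData, thresholds: QCThresholds | None = None
) -> ad.AnnData:
    """Subset an AnnData to QC-passing cells (stats taken from ``obs``)."""
    report = cell_qc(adata.obs, thresholds)
    adata.obs["qc_pass"] = report["pass"].to_numpy()
    return adata[report["pass"].to_numpy()].copy()


DEFAULT_EXCLUDE_REGEXES = (r"^Gm\d+$",)
RIBO_REGEX = r"^Rp[ls]"


def filter_genes(
    adata: ad.AnnData,
    min_cell_fraction: float = 0.5,
    exclude_regexes: tuple[str, ...] = DEFAULT_EXCLUDE_REGEXES,
    exclude_ribo: bool = False,
    layer: str = "exon",
    rpm_advisory: float = 16.0,
) -> ad.AnnData:
    """Keep genes detected in >= ``min_cell_fraction`` of cells of every
    condition x replicate subset.

    Detection means raw count >= 1. Gene names matching any exclusion regex
    (default: Gm-numbered predicted models) are removed; riboprotein genes
    (``^Rp[ls]``) only when ``exclude_ribo`` is set — by default they are
    retained here and merely flagged, since their exclusion happens at the
    call/enrichment stage. Spike-in rows pass through untouched. Adds a
    boolean ``low_rpm_advisory`` var column marking genes whose mean RPM
    falls below the reliable-detection advisory level (default 16 RPM);
    advisory only, never a filter.
    """
    if not 0 < min_cell_fraction <= 1:
        raise ValueError("min_cell_fraction must be in (0, 1]")
    counts = _get_layer(adata, layer)
    spike = adata.var["is_spikein"].to_numpy() if "is_spikein" in adata.var else np.zeros(adata.n_vars, bool)
    detected = counts >= 1

    groups = adata.obs.groupby(
        ["condition", "replicate"], observed=True
    ).indices
    if not groups:
        raise ValueError("no condition x replicate subsets present")
    keep = np.ones(adata.n_vars, dtype=bool)
    for idx in groups.values():
        if len(idx) == 0:
            raise ValueError("empty condition x replicate subset")
        frac = detected[idx].mean(axis=0)
        keep &= frac >= min_cell_fraction

    names = adata.var_names.to_numpy().astype(str)
    patterns = list(exclude_regexes)
    if exclude_ribo:
        patterns.append(RIBO_REGEX)
    excluded = np.zeros(adata.n_vars, dtype=bool)
    for pat in patterns:
        rx = re.compile(pat)
        excluded |= np.array([bool(rx.search(n)) for n in names])
    keep &= ~excluded
    keep |= spike  # spike-ins are kept for the technical-noise fit

    out = adata[:, keep].copy()
    try:
        rpm = _rpm_matrix(out, layer=layer)
        out.var["low_rpm_advisory"] = rpm.mean(axis=0) < rpm_advisory
    except ValueError:
        # zero-depth cells (pre-QC input): the advisory is informational
        # only, never a reason to fail filtering
        out.var["low_rpm_advisory"] = False
    return out


def _get_layer(adata: ad.AnnData, layer: str | None) -> np.ndarray:
    X = adata.layers[layer] if layer and layer in adata.layers else adata.X
    return np.asarray(X)


def _rpm_matrix(
    adata: ad.AnnData,
    layer: str = "exon",
    exclude_spikeins: bool = True,
    exclude_mito: bool = True,
) -> np.ndarray:
    counts = _get_layer(adata, layer)
    endo = np.ones(adata.n_vars, dtype=bool)
    if exclude_spikeins and "is_spikein" in adata.var:
        endo &= ~adata.var["is_spikein"].to_numpy()
    if exclude_mito and "is_mito" in adata.var:
        endo &= ~adata.var["is_mito"].to_numpy()
    depth = counts[:, endo].sum(axis=1)
    if np.any(depth == 0):
        raise ValueError(
            "cell(s) with zero endogenous counts cannot be normalized "
            "(should have failed QC)"
        )
    return counts / depth[:, None] * 1e6


def rpm_normalize(
    adata: ad.AnnData,
    layer: str = "exon",
    out_layer: str = "rpm",
    exclude_spikeins: bool = True,
    exclude_mito: bool = True,
) -> ad.AnnData:
    """Add an RPM layer: counts / per-cell endogenous depth * 1e6.

    The denominator sums endogenous gene counts only — spike-ins (and, by
    default, mitochondrial genes) are excluded, i.e. the library size is the
    cell's mRNA read total. No length normalization: a ranked correlation
    downstream only needs each gene's relative abundance across cells.
    """
    adata.layers[out_layer] = _rpm_matrix(
        adata, layer=layer, exclude_spikeins=exclude_spikeins, exclude_mito=exclude_mito
    )
    return adata


def normalization_diagnostic(
    adata: ad.AnnData,
    size_factors: np.ndarray | pd.Series,
    layer: str = "rpm",
    alpha: float = 0.01,
    overfit_rate_multiplier: float = 3.0,
) -> dict:
    """Do the applied size factors still correlate with the normalized genes?

    For every gene, the Spearman correlation between the per-cell size
    factor and the gene's normalized values is computed with its Fisher-z
    p-value. Verdict is ``"overfitting"`` when the fraction of genes
    significant at ``alpha`` exceeds ``overfit_rate_multiplier`` times the
    nominal rate, ``"degenerate"`` for constant size factors, ``"ok"``
    otherwise.
    """
    sf = np.asarray(size_factors, dtype=float)
    if sf.shape[0] != adata.n_obs:
        raise ValueError("one size factor per cell required")
    X = _get_layer(adata, layer)
    if np.all(sf == sf[0]):
        return {
            "rho": pd.Series(np.nan, index=adata.var_names),
            "significant_fraction": np.nan,
            "verdict": "degenerate",
        }
    n = len(sf)
    rhos = np.array([spearman_rho(sf, X[:, j]) for j in range(adata.n_vars)])
    testable = ~np.isnan(rhos)
    pvals = np.full(adata.n_vars, np.nan)
    pvals[testable] = fisher_z_p(rhos[testable], n)
    frac = float(np.mean(pvals[testable] < alpha)) if testable.any() else np.nan
    verdict = "ok"
    if testable.any() and frac > overfit_rate_multiplier * alpha:
        verdict = "overfitting"
    return {
        "rho": pd.Series(rhos, index=adata.var_names),
        "p": pd.Series(pvals, index=adata.var_names),
        "significant_fraction": frac,
        "verdict": verdict,
    }


def select_variable_genes(
    adata: ad.AnnData,
    layer: str = "rpm",
    confidence: float = 0.9,
    min_spikeins: int = 20,
    n_bins: int = 10,
) -> np.ndarray:
    """Genes whose variance exceeds the spike-in technical noise model.

    Fits ``CV^2 = a1/mu + a0`` on spike-ins (least squares on per-bin median
    CV^2 over log-mean bins, which makes the fit robust to individual
    outlier species), then keeps a gene when its observed CV^2 exceeds the
    fitted technical CV^2 at its mean by a chi-square margin:
    ``(n-1) * cv2_obs / cv2_tech > chi2_{n-1}(confidence)``. Lowering the
    confidence never removes previously kept genes (the chi-square quantile
    is monotone). If the fitted ``a1`` is not positive the technical model is
    meaningless and all genes are kept with a warning.

    Returns a boolean mask over ``var_names`` (spike-ins always False).
    """
    X = _get_layer(adata, layer)
    spike = adata.var["is_spikein"].to_numpy()
    n_detected = int(((X[:, spike] > 0).any(axis=0)).sum())
    if n_detected < min_spikeins:
        raise ValueError(
            f"only {n_detected} spike-in species detected; >= {min_spikeins} required"
        )
    mu = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mu > 0, var / mu**2, np.nan)

    # spike-ins are added at fixed concentration per well, so their
    # technical CV^2 is estimated on counts rescaled by the per-cell
    # spike-in total (not the endogenous library size, whose cell-to-cell
    # variation would inflate the technical estimate)
    raw = _get_layer(adata, "exon")
    spike_depth = raw[:, spike].sum(axis=1)
    if np.any(spike_depth == 0):
        raise ValueError("cell(s) with zero spike-in counts")
    S = raw[:, spike] / spike_depth[:, None] * 1e6
    smu = S.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scv2 = np.where(smu > 0, S.var(axis=0, ddof=1) / smu**2, np.nan)
    # place spike means on the gene-RPM scale for the 1/mu fit
    scale = np.median(mu[spike][smu > 0] / smu[smu > 0]) if (smu > 0).any() else 1.0
    smu = smu * scale
    ok = (smu > 0) & np.isfinite(scv2)
    smu, scv2 = smu[ok], scv2[ok]
    log_mu = np.log(smu)
    edges = np.linspace(log_mu.min(), log_mu.max() + 1e-9, n_bins + 1)
    which = np.digitize(log_mu, edges) - 1
    bx, by = [], []
    for b in range(n_bins):
        m = which == b
        if m.sum() >= 1:
            bx.append(np.median(1.0 / smu[m]))
            by.append(np.median(scv2[m]))
    A = np.column_stack([bx, np.ones(len(bx))])
    (a1, a0), *_ = np.linalg.lstsq(A, np.array(by), rcond=None)
    if a1 <= 0:
        warnings.warn(
            "spike-in technical fit failed (a1 <= 0); keeping all genes",
            RuntimeWarning,
        )
        return ~spike
    n = adata.n_obs
    tech_cv2 = a1 / np.where(mu > 0, mu, np.nan) + a0
    with np.errstate(invalid="ignore"):
        stat = (n - 1) * cv2 / tech_cv2
    cut = stats.chi2.ppf(confidence, df=n - 1)
    keep = np.where(np.isfinite(stat), stat > cut, False)
    keep &= ~spike
    return keep
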