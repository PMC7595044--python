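"""Synthetic single-cell count generator with planted covariation structure.

Emulates a Smart-Seq2-style experiment on a homogeneous cell population:
three well-plate replicates of ~110 cells each, negative-binomial counts for
a few thousand genes, ERCC-like spike-ins carrying purely technical noise,
and latent per-cell regulator activities that induce known positive and
negative gene-pair covariations.

Three kinds of latent factors are planted:

``tf``
    A shared transcriptional regulator. Its activity modulates both exonic
    and intronic abundance of its module genes (signs random per gene, so
    both positive and negative pairs arise).
``mirna``
    A post-transcriptional repressor. Loadings are negative (repression) and
    apply to the exon layer only — intronic (nascent) abundance is unaffected
    because intron levels are set in the nucleus, before cytoplasmic
    repression can act. A ``knockout`` switch zeroes these loadings,
    emulating loss of the miRNA pathway.
``proximity_block``
    A block of genes co-located on one synthetic chromosome, sharing an
    activity as genes in one nuclear neighbourhood would. Affects both
    layers; loadings all positive.

Cell ``c`` in replicate ``r`` draws factor activities ``a_k(c) ~ N(0, 1)``;
the exon-layer mean for gene ``g`` is ``s_c * exp(beta_g + sum_k L_gk a_k(c))``
with log-normal size factor ``s_c``, and counts are negative binomial with a
shared dispersion. The intron layer uses the same activities but omits
mirna-kind terms. Ground truth (loadings and the implied covarying pairs) is
returned alongside the counts so every downstream stage can be scored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

FACTOR_KINDS = ("tf", "mirna", "proximity_block")

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_counts",
    "simulate_annotations",
    "default_factor_kinds",
]


_KIND_CYCLE = ("tf", "tf", "mirna", "tf", "proximity_block", "tf")


def default_factor_kinds(n_factors: int) -> list[str]:
    """Default regulator mix: two thirds transcription factors, the rest
    split between miRNA-like repressors and proximity blocks — shared
    transcriptional regulators far outnumber highly expressed miRNA
    families in a stem-cell transcriptome."""
    return [_KIND_CYCLE[i % len(_KIND_CYCLE)] for i in range(n_factors)]


@dataclass
class SimConfig:
    """Configuration of one synthetic experiment (one condition).

    Defaults mirror the study design the generator emulates: three
    replicates of 110 cells, 2,000 genes, disjoint 20-gene regulator
    modules, unit effect size on the log-mean, NB dispersion 0.1 and a
    0.2-sd log-normal library-size factor.
    """

    n_genes: int = 2000
    n_cells_per_replicate: list[int] = field(default_factory=lambda: [110, 110, 110])
    n_factors: int = 24
    factor_kinds: list[str] | None = None
    loading_scale: float = 1.0
    module_size: int = 20
    baseline_logmean_mean: float = 3.0
    baseline_logmean_sd: float = 1.2
    nb_dispersion: float = 0.3
    size_factor_sd: float = 0.2
    n_spikeins: int = 40
    knockout: bool = False
    derepression_offset: float = 0.0
    modules: list[list[int]] | None = None  # explicit gene indices per factor
    graded_loadings: bool = False
    factor_loading_scales: list[float] | None = None  # per-factor multiplier
    seed: int = 0

    def __post_init__(self) -> None:
        if self.factor_kinds is None:
            self.factor_kinds = default_factor_kinds(self.n_factors)
        if len(self.factor_kinds) != self.n_factors:
            raise ValueError(
                f"factor_kinds has length {len(self.factor_kinds)}, "
                f"expected n_factors={self.n_factors}"
            )
        unknown = set(self.factor_kinds) - set(FACTOR_KINDS)
        if unknown:
            raise ValueError(f"unknown factor kinds: {sorted(unknown)}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_genes < 1 or self.n_spikeins < 0 or self.module_size < 1:
            raise ValueError("n_genes, n_spikeins and module_size must be positive")
        if len(self.n_cells_per_replicate) == 0 or any(
            n < 1 for n in self.n_cells_per_replicate
        ):
            raise ValueError("each replicate must contain at least one cell")
        if self.factor_loading_scales is not None and len(
            self.factor_loading_scales
        ) != self.n_factors:
            raise ValueError("one loading-scale multiplier per factor required")
        if self.modules is not None:
            if len(self.modules) != self.n_factors:
                raise ValueError("one explicit module per factor required")
            for m in self.modules:
                if len(m) and (min(m) < 0 or max(m) >= self.n_genes):
                    raise ValueError("module gene index out of range")
        elif self.n_factors * self.module_size > self.n_genes:
            raise ValueError("disjoint modules do not fit into n_genes")

    def replace(self, **kwargs) -> "SimConfig":
        if "n_factors" in kwargs and "factor_kinds" not in kwargs:
            kwargs["factor_kinds"] = None
        return dataclasses.replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated condition.

    ``true_pairs`` maps unordered gene-name pairs to the expected sign of
    their covariation (+1/-1): every pair of genes sharing at least one
    factor with nonzero loadings, signed by the loading product. In knockout
    mode mirna loadings are zero, so pairs attributable only to mirna
    factors are absent.
    """

    loadings: pd.DataFrame  # genes x factors, effective (post-knockout)
    factor_kinds: list[str]
    true_pairs: dict[tuple[str, str], int]
    gene_positions: pd.DataFrame  # chrom/start/end/strand per gene
    config: SimConfig

    def pairs_of_factor(self, factor: str) -> dict[tuple[str, str], int]:
        """True pairs among genes loaded by one factor."""
        col = self.loadings[factor].to_numpy()
        genes = self.loadings.index.to_numpy()[col != 0]
        load = self.loadings.loc[genes, factor].to_numpy()
        out: dict[tuple[str, str], int] = {}
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                key = _pair_key(genes[i], genes[j])
                out[key] = 1 if load[i] * load[j] > 0 else -1
        return out

    def module_genes(self, factor: str) -> list[str]:
        col = self.loadings[factor]
        return list(col.index[col.to_numpy() != 0])

    def factors_of_kind(self, kind: str) -> list[str]:
        return [
            f
            for f, k in zip(self.loadings.columns, self.factor_kinds)
            if k == kind
        ]


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def _draw_loadings(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Gene x factor loading matrix.

    Modules are consecutive disjoint blocks of ``module_size`` genes unless
    ``config.modules`` lists explicit (possibly overlapping) gene indices
    per factor. With ``graded_loadings`` magnitudes decay linearly from
    ``loading_scale`` to a quarter of it along the module order, so the
    order doubles as the planted target-strength rank.
    """
    L = np.zeros((config.n_genes, config.n_factors))
    for k, kind in enumerate(config.factor_kinds):
        if config.modules is not None:
            genes = np.asarray(config.modules[k], dtype=int)
        else:
            genes = np.arange(k * config.module_size, (k + 1) * config.module_size)
        m = len(genes)
        if m == 0:
            continue
        scale = config.loading_scale
        if config.factor_loading_scales is not None:
            scale *= config.factor_loading_scales[k]
        if config.graded_loadings and m > 1:
            mag = np.linspace(1.0, 0.25, m) * scale
        else:
            mag = np.full(m, scale)
        if kind == "mirna":
            # repression: coordinated down-regulation of all targets
            L[genes, k] = -mag
        elif kind == "proximity_block":
            L[genes, k] = mag
        else:
            # tf: mixed activated/repressed targets, balanced so the module
            # has no net effect on the cell's total mRNA
            half = m // 2
            signs = np.array([1.0] * (m - half) + [-1.0] * half)
            rng.shuffle(signs)
            L[genes, k] = signs * mag
    return L


def _true_pairs_from_loadings(
    loadings: np.ndarray, gene_names: np.ndarray
) -> dict[tuple[str, str], int]:
    out: dict[tuple[str, str], int] = {}
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        idx = np.nonzero(col)[0]
        for ii in range(len(idx)):
            for jj in range(ii + 1, len(idx)):
                i, j = idx[ii], idx[jj]
                key = _pair_key(gene_names[i], gene_names[j])
                sign = 1 if col[i] * col[j] > 0 else -1
                # a pair driven by several factors keeps the first sign;
                # disjoint default modules never hit this branch
                out.setdefault(key, sign)
    return out


def _gene_positions(config: SimConfig) -> pd.DataFrame:
    """Synthetic coordinates: each proximity block co-located on its own
    chromosome at 40 kb spacing; all other genes spread 10 Mb apart over
    background chromosomes."""
    n = config.n_genes
    chrom = np.empty(n, dtype=object)
    start = np.zeros(n, dtype=np.int64)
    gene_len = 20_000
    in_block = np.zeros(n, dtype=bool)
    block_no = 0
    for k, kind in enumerate(config.factor_kinds):
        if kind != "proximity_block":
            continue
        block_no += 1
        if config.modules is not None:
            genes = np.asarray(config.modules[k], dtype=int)
        else:
            genes = np.arange(k * config.module_size, (k + 1) * config.module_size)
        in_block[genes] = True
        chrom[genes] = f"chr_block{block_no}"
        start[genes] = np.arange(len(genes)) * 40_000
    bg = np.nonzero(~in_block)[0]
    per_chrom = 50
    for pos, g in enumerate(bg):
        chrom[g] = f"chr_bg{pos // per_chrom + 1}"
        start[g] = (pos % per_chrom) * 10_000_000
    strand = np.where(np.arange(n) % 2 == 0, "+", "-")
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": start + gene_len,
            "strand": strand,
        },
        index=[f"g{i:04d}" for i in range(n)],
    )


def _nb_counts(
    mean: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """NB draw with Var = mu + dispersion * mu^2 (gamma-Poisson mixture)."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_counts(config: SimConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Simulate one condition and return (AnnData, SyntheticTruth).

    The AnnData is cells x genes with layers ``exon`` (also ``X``),
    ``intron``, per-cell metadata (replicate, condition, synthetic mapping
    statistics that all pass default QC) and per-gene metadata (coordinates,
    ``is_spikein`` flag). One RNG stream is spawned per replicate from the
    master seed, so adding a replicate never perturbs earlier ones.
    """
    cfg = config
    master = np.random.SeedSequence(cfg.seed)
    n_rep = len(cfg.n_cells_per_replicate)
    global_seq, *rep_seqs = master.spawn(n_rep + 1)
    g_rng = np.random.default_rng(global_seq)

    gene_names = np.array([f"g{i:04d}" for i in range(cfg.n_genes)])
    beta = g_rng.normal(
        cfg.baseline_logmean_mean, cfg.baseline_logmean_sd, size=cfg.n_genes
    )
    L_full = _draw_loadings(cfg, g_rng)
    L_exon = L_full.copy()
    L_intron = L_full.copy()
    mirna_cols = [k for k, kind in enumerate(cfg.factor_kinds) if kind == "mirna"]
    # nascent transcripts never see cytoplasmic repression
    L_intron[:, mirna_cols] = 0.0
    beta_exon = beta.copy()
    if cfg.knockout:
        target_mask = (L_exon[:, mirna_cols] != 0).any(axis=1) if mirna_cols else None
        L_exon[:, mirna_cols] = 0.0
        if target_mask is not None:
            beta_exon[target_mask] += cfg.derepression_offset
    # intron layer drawn at the exon scale so the two layers are directly
    # comparable for genes without post-transcriptional regulation
    beta_intron = beta

    spike_names = np.array([f"ERCC-{i:04d}" for i in range(cfg.n_spikeins)])
    spike_logmean = (
        np.linspace(-1.0, 6.0, cfg.n_spikeins) if cfg.n_spikeins else np.empty(0)
    )

    exon_blocks, intron_blocks, obs_blocks = [], [], []
    for r, (n_cells, seq) in enumerate(zip(cfg.n_cells_per_replicate, rep_seqs)):
        rng = np.random.default_rng(seq)
        a = rng.standard_normal((n_cells, cfg.n_factors))
        log_s = rng.normal(0.0, cfg.size_factor_sd, size=n_cells)
        s = np.exp(log_s)[:, None]
        mu_exon = s * np.exp(beta_exon[None, :] + a @ L_exon.T)
        mu_intron = s * np.exp(beta_intron[None, :] + a @ L_intron.T)
        exon = _nb_counts(mu_exon, cfg.nb_dispersion, rng)
        intron = _nb_counts(mu_intron, cfg.nb_dispersion, rng)
        if cfg.n_spikeins:
            mu_spike = np.broadcast_to(
                np.exp(spike_logmean)[None, :], (n_cells, cfg.n_spikeins)
            )
            spike = _nb_counts(np.array(mu_spike), cfg.nb_dispersion, rng)
        else:
            spike = np.zeros((n_cells, 0), dtype=np.int64)
        exon_blocks.append(np.hstack([exon, spike]))
        intron_blocks.append(np.hstack([intron, np.zeros_like(spike)]))

        # synthetic mapping statistics, drawn so that every cell passes the
        # default QC thresholds (QC-rejection paths are exercised by a
        # dedicated fixture, not the generator)
        tot = exon.sum(axis=1) + spike.sum(axis=1)
        obs_blocks.append(
            pd.DataFrame(
                {
                    "replicate": f"r{r + 1}",
                    "condition": "ko" if cfg.knockout else "wt",
                    "size_factor": s.ravel(),
                    "total_reads": np.maximum(tot * 3, 250_000),
                    "frac_mapped": 0.85 + 0.05 * rng.random(n_cells),
                    "frac_genes_detected": np.clip(
                        (exon > 0).sum(axis=1) / 19_127 + 0.41, 0.41, 0.99
                    ),
                    "frac_spikein": 0.003 + 0.005 * rng.random(n_cells),
                    "frac_mito": 0.01 + 0.01 * rng.random(n_cells),
                    "frac_pcr_dup": 0.10 + 0.05 * rng.random(n_cells),
                },
                index=[f"r{r + 1}_c{c:03d}" for c in range(n_cells)],
            )
        )

    X = np.vstack(exon_blocks)
    obs = pd.concat(obs_blocks)
    var = pd.DataFrame(index=np.concatenate([gene_names, spike_names]))
    var["is_spikein"] = np.concatenate(
        [np.zeros(cfg.n_genes, bool), np.ones(cfg.n_spikeins, bool)]
    )
    var["is_mito"] = False
    var["is_ribo"] = False
    positions = _gene_positions(cfg)
    for col in ("chrom", "start", "end", "strand"):
        var[col] = None
        var.loc[positions.index, col] = positions[col]
    adata = ad.AnnData(X=X.astype(np.float64), obs=obs, var=var)
    adata.layers["exon"] = X.astype(np.float64)
    adata.layers["intron"] = np.vstack(intron_blocks).astype(np.float64)
    adata.uns["condition"] = "ko" if cfg.knockout else "wt"

    truth = SyntheticTruth(
        loadings=pd.DataFrame(
            L_exon,
            index=gene_names,
            columns=[f"factor_{k + 1}" for k in range(cfg.n_factors)],
        ),
        factor_kinds=list(cfg.factor_kinds),
        true_pairs=_true_pairs_from_loadings(L_exon, gene_names),
        gene_positions=positions,
        config=cfg,
    )
    return adata, truth


# ---------------------------------------------------------------------------
# named study configurations


def modular_config(seed: int = 1, **overrides) -> SimConfig:
    """Sparse disjoint-module conditions for recovery benchmarking: the
    default 2,000 genes, 3 x 110 cells, 24 disjoint 20-gene modules at unit
    loading."""
    return SimConfig(seed=seed, **overrides)


def transcriptome_config(
    seed: int = 1,
    knockout: bool = False,
    n_tf: int = 8,
    n_mirna: int = 4,
    targets_per_factor: int = 300,
    **overrides,
) -> SimConfig:
    """Transcriptome-wide covariation conditions.

    Emulates a network in which most genes participate: regulators (TFs and
    miRNA families) each target a few hundred genes drawn across the whole
    transcriptome with graded strength, so target sets overlap, degrees
    spread broadly and the called network reaches a mean degree of order
    ten, as in a dense co-expression study. Used for enrichment-score
    calibration and the miRNA-knockout comparison.
    """
    n_genes = overrides.pop("n_genes", 2000)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 915_001)))
    kinds = ["tf"] * n_tf + ["mirna"] * n_mirna
    modules = [
        list(map(int, rng.choice(n_genes, size=targets_per_factor, replace=False)))
        for _ in kinds
    ]
    # miRNA-mediated repression is a weaker covariation source than shared
    # transcription factors in this system
    scales = [1.0] * n_tf + [overrides.pop("mirna_relative_scale", 0.55)] * n_mirna
    return SimConfig(
        n_genes=n_genes,
        n_factors=len(kinds),
        factor_kinds=kinds,
        modules=modules,
        graded_loadings=True,
        loading_scale=overrides.pop("loading_scale", 0.8),
        factor_loading_scales=scales,
        knockout=knockout,
        seed=seed,
        **overrides,
    )


# ---------------------------------------------------------------------------
# annotation bundle


def simulate_annotations(truth: SyntheticTruth) -> dict[str, pd.DataFrame | dict]:
    """Derive annotation tables from planted truth.

    Returns a dict with keys ``gmt`` (set name -> gene list), ``tf_targets``
    and ``mirna_targets`` (ranked score tables; re-ranking them with the
    genesets readers reproduces the planted |loading| order exactly),
    ``genes_bed`` (BED-like frame), ``contacts`` (bin-pair contact table in
    which proximity-block genes mutually contact) and ``interactions``
    (pairwise table for the designated complex factor: the first tf factor,
    else the first factor).
    """
    cfg = truth.config
    factors = list(truth.loadings.columns)
    if list(truth.loadings.index) != [f"g{i:04d}" for i in range(cfg.n_genes)]:
        raise ValueError("truth loadings do not match the simulated gene universe")

    gmt = {f: truth.module_genes(f) for f in factors}

    def _ranked_table(factor: str) -> pd.DataFrame:
        genes = truth.module_genes(factor)
        load = truth.loadings.loc[genes, factor].abs()
        order = sorted(genes, key=lambda g: (-load[g], g))
        k = len(order)
        return pd.DataFrame(
            {
                "family": factor,
                "gene": order,
                "n_8mer": [(k - i + 3) // 4 for i in range(k)],
                "n_m8_7mer": [(k - i + 1) // 2 for i in range(k)],
                "context_score": [-(k - i) / 10.0 for i in range(k)],
                "score": [float(k - i) for i in range(k)],
            }
        )

    tf_tables, mirna_tables = [], []
    for f, kind in zip(factors, truth.factor_kinds):
        if kind == "tf":
            tf_tables.append(_ranked_table(f))
        elif kind == "mirna":
            mirna_tables.append(_ranked_table(f))

    bed = truth.gene_positions.reset_index(names="gene")[
        ["chrom", "start", "end", "gene", "strand"]
    ]

    contact_rows = []
    bin_size = 40_000
    for f, kind in zip(factors, truth.factor_kinds):
        if kind != "proximity_block":
            continue
        genes = truth.module_genes(f)
        pos = truth.gene_positions.loc[genes]
        chrom = pos["chrom"].iloc[0]
        bins = sorted({int(s) // bin_size for s in pos["start"]})
        for i in range(len(bins)):
            for j in range(i, len(bins)):
                contact_rows.append(
                    {
                        "chromA": chrom,
                        "startA": bins[i] * bin_size,
                        "endA": (bins[i] + 1) * bin_size,
                        "chromB": chrom,
                        "startB": bins[j] * bin_size,
                        "endB": (bins[j] + 1) * bin_size,
                        "support": 2.0,
                    }
                )
    contacts = pd.DataFrame(
        contact_rows,
        columns=["chromA", "startA", "endA", "chromB", "startB", "endB", "support"],
    )

    complex_factor = next(
        (f for f, k in zip(factors, truth.factor_kinds) if k == "tf"),
        factors[0] if factors else None,
    )
    inter_rows = []
    if complex_factor is not None:
        for (a, b), sign in truth.pairs_of_factor(complex_factor).items():
            inter_rows.append(
                {"gene_a": a, "gene_b": b, "experimental": 500, "kind": "complex"}
            )
    interactions = pd.DataFrame(
        inter_rows, columns=["gene_a", "gene_b", "experimental", "kind"]
    )

    return {
        "gmt": gmt,
        "tf_targets": (
            pd.concat(tf_tables, ignore_index=True)
            if tf_tables
            else pd.DataFrame(columns=["family", "gene", "score"])
        ),
        "mirna_targets": (
            pd.concat(mirna_tables, ignore_index=True)
            if mirna_tables
            else pd.DataFrame(
                columns=["family", "gene", "n_8mer", "n_m8_7mer", "context_score"]
            )
        ),
        "genes_bed": bed,
        "contacts": contacts,
        "interactions": interactions,
    }
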