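"""Gene sets and gene-pair feature sets from annotation exports.

Readers and builders for the feature collections whose covariation
enrichment is of interest: ranked miRNA target lists (TargetScan-style
columns: number of 8mer sites, number of m8-7mer sites, cumulative weighted
context score), ranked ChIP-seq transcription-factor target tables,
Hi-C-derived nuclear-proximity gene pairs with mutually exclusive distance
strata, GO/KEGG-style GMT gene sets with size filtering, and protein
interaction tables (STRING-like experimental-evidence scores, Reactome-like
complex/reaction labels).

Coordinates are 0-based half-open (BED convention) throughout; interval
distance is the gap length, 0 when intervals overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RankedTargetList",
    "rank_mirna_targets",
    "load_tf_targets",
    "hic_gene_pairs",
    "stratify_pairs",
    "load_functional_sets",
    "read_gmt",
    "write_gmt",
    "stratify_interactions",
    "split_by_interaction",
]


@dataclass
class RankedTargetList:
    regulator: str
    targets: list[str]  # strongest first
    table: pd.DataFrame  # rank keys, one row per target in rank order

    def top(self, n: int) -> list[str]:
        return self.targets[:n]

    def __len__(self) -> int:
        return len(self.targets)


MIRNA_COLUMNS = ["n_8mer", "n_m8_7mer", "context_score"]


def rank_mirna_targets(
    table: pd.DataFrame,
    min_expression_rpm: float = 4000.0,
    expressed_mirnas: dict[str, float] | None = None,
    family_col: str = "family",
    gene_col: str = "gene",
) -> dict[str, RankedTargetList]:
    """Ranked target lists per miRNA family.

    Targets are sorted stably by number of 8mer sites (descending), then
    m8-7mer sites (descending), then cumulative weighted context score
    (ascending — more negative means stronger repression). Families whose
    expression (from ``expressed_mirnas``, family -> RPM) falls below
    ``min_expression_rpm`` are dropped (>= 4000 RPM kept). Duplicate target
    rows keep the best-ranked occurrence.
    """
    missing = [c for c in MIRNA_COLUMNS + [family_col, gene_col] if c not in table]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    out: dict[str, RankedTargetList] = {}
    for fam, sub in table.groupby(family_col, sort=False):
        if expressed_mirnas is not None:
            rpm = expressed_mirnas.get(fam, 0.0)
            if not rpm >= min_expression_rpm:
                continue
        ranked = sub.sort_values(
            MIRNA_COLUMNS, ascending=[False, False, True], kind="stable"
        ).drop_duplicates(subset=gene_col, keep="first")
        out[str(fam)] = RankedTargetList(
            regulator=str(fam),
            targets=list(ranked[gene_col]),
            table=ranked.reset_index(drop=True),
        )
    return out


def load_tf_targets(
    score_table: pd.DataFrame,
    top_n: int | None = None,
    factor: str = "tf",
    gene_col: str = "gene",
    score_col: str = "score",
) -> RankedTargetList:
    """Ranked TF target list: score descending, ties broken by gene id."""
    if gene_col not in score_table or score_col not in score_table:
        raise ValueError(f"need columns {gene_col!r} and {score_col!r}")
    ranked = score_table.sort_values(
        [score_col, gene_col], ascending=[False, True], kind="stable"
    ).drop_duplicates(subset=gene_col, keep="first")
    targets = list(ranked[gene_col])
    if top_n is not None:
        if top_n > len(targets):
            warnings.warn(
                f"top_n={top_n} exceeds table length {len(targets)}; using full list"
            )
        targets = targets[:top_n]
    return RankedTargetList(
        regulator=factor, targets=targets, table=ranked.reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# nuclear proximity from binned contact tables

CONTACT_COLUMNS = ["chromA", "startA", "endA", "chromB", "startB", "endB", "support"]


def _gene_bodies(annotation: pd.DataFrame, upstream: int = 2000) -> pd.DataFrame:
    """Gene body = annotated interval extended ``upstream`` bp upstream,
    strand-aware (minus-strand genes extend to the right). Unstranded
    records are treated as plus strand with a warning."""
    need = ["chrom", "start", "end"]
    if any(c not in annotation for c in need):
        raise ValueError("annotation needs chrom/start/end columns")
    ann = annotation.copy()
    if "strand" not in ann or ann["strand"].isna().any():
        warnings.warn("unstranded gene records treated as plus strand")
        ann["strand"] = ann.get("strand", pd.Series("+", index=ann.index)).fillna("+")
    minus = ann["strand"] == "-"
    ann["body_start"] = np.where(minus, ann["start"], ann["start"] - upstream)
    ann["body_end"] = np.where(minus, ann["end"] + upstream, ann["end"])
    ann["body_start"] = ann["body_start"].clip(lower=0)
    return ann


def _interval_gap(gs, ge, s, e) -> np.ndarray:
    """Gap between half-open intervals [gs, ge) and [s, e); 0 if overlapping."""
    return np.maximum(0, np.maximum(gs - e, s - ge))


def hic_gene_pairs(
    contacts: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    mode: str = "intra",
    max_gene_bin_distance: int | None = None,
    min_support: float = 1.0,
    upstream: int = 2000,
) -> pd.DataFrame:
    """Gene pairs supported by binned chromatin contacts.

    A gene matches a contact bin when the gap between its body (annotation
    plus 2 kb upstream, strand-aware) and the bin is at most
    ``max_gene_bin_distance`` (inclusive; default 20 kb intrachromosomal /
    500 kb interchromosomal, matching 40 kb and 500 kb binning). A pair is
    emitted when its two genes match the two bins of one contact; in intra
    mode only contacts with support strictly greater than 1 normalized read
    count (``min_support``); in inter mode all pairs are kept and ranked by
    total support. Duplicate pairs are merged, support summed.

    ``gene_annotation`` is indexed by gene with chrom/start/end/strand.
    Returns gene_a, gene_b, same_chromosome, linear_distance (midpoint to
    midpoint; NaN interchromosomal), contact_support.
    """
    if mode not in ("intra", "inter"):
        raise ValueError(f"unknown mode {mode!r}")
    missing = [c for c in CONTACT_COLUMNS if c not in contacts]
    if missing:
        raise ValueError(f"contact table missing columns: {missing}")
    if max_gene_bin_distance is None:
        max_gene_bin_distance = 20_000 if mode == "intra" else 500_000
    ann = _gene_bodies(gene_annotation, upstream=upstream)
    ann_chroms = set(ann["chrom"])
    c_chroms = set(contacts["chromA"]) | set(contacts["chromB"])
    if not c_chroms & ann_chroms:
        raise ValueError(
            f"no shared chromosome names between contacts ({sorted(c_chroms)[:5]}) "
            f"and annotation ({sorted(ann_chroms)[:5]})"
        )
    by_chrom = {c: sub for c, sub in ann.groupby("chrom")}

    def _matches(chrom, s, e) -> list[str]:
        sub = by_chrom.get(chrom)
        if sub is None:
            return []
        gap = _interval_gap(
            sub["body_start"].to_numpy(), sub["body_end"].to_numpy(), s, e
        )
        return list(sub.index[gap <= max_gene_bin_distance])

    support: dict[tuple[str, str], float] = {}
    for row in contacts.itertuples(index=False):
        intra_contact = row.chromA == row.chromB
        if mode == "intra":
            if not intra_contact or not row.support > min_support:
                continue
        elif intra_contact:
            continue
        ga = _matches(row.chromA, row.startA, row.endA)
        gb = _matches(row.chromB, row.startB, row.endB)
        # one contact supports each gene pair once, even when both genes
        # match both of its bins
        row_pairs = {
            (a, b) if a < b else (b, a)
            for a in ga
            for b in gb
            if a != b
        }
        for key in row_pairs:
            support[key] = support.get(key, 0.0) + float(row.support)

    mid = (ann["start"] + ann["end"]) / 2.0
    rows = []
    for (a, b), sup in support.items():
        same = ann.loc[a, "chrom"] == ann.loc[b, "chrom"]
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "same_chromosome": bool(same),
                "linear_distance": abs(mid[a] - mid[b]) if same else np.nan,
                "contact_support": sup,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_a",
            "gene_b",
            "same_chromosome",
            "linear_distance",
            "contact_support",
        ],
    ).sort_values(["gene_a", "gene_b"], ignore_index=True)
    if mode == "inter":
        out = out.sort_values("contact_support", ascending=False, ignore_index=True)
    return out


STRATA = ("TAD", "<5MB", "<25MB", "<50MB", ">50MB", "same_chr_no_contact",
          "interchromosomal")


def stratify_pairs(
    pairs: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    tads: pd.DataFrame | None = None,
    thresholds_mb: tuple[float, ...] = (5.0, 25.0, 50.0),
    upstream: int = 2000,
) -> pd.DataFrame:
    """Assign every gene pair to exactly one mutually exclusive stratum.

    Contact-supported same-chromosome pairs go to ``TAD`` when both gene
    bodies lie inside one TAD interval, otherwise to the smallest linear
    distance category containing them (<5MB, <25MB, <50MB, >50MB —
    exclusive: a <5MB pair is not also <25MB). Same-chromosome pairs
    without contact support go to ``same_chr_no_contact``, different
    chromosomes to ``interchromosomal``. ``pairs`` needs gene_a/gene_b and,
    for the contact distinction, a ``contact_support`` column (missing
    column means all pairs count as supported). Overlapping TADs: the first
    containing interval wins (warned).
    """
    ann = _gene_bodies(gene_annotation, upstream=upstream)
    mid = (ann["start"] + ann["end"]) / 2.0
    tad_by_chrom: dict[str, pd.DataFrame] = {}
    if tads is not None:
        tad_by_chrom = {c: sub for c, sub in tads.groupby("chrom")}
        for c, sub in tad_by_chrom.items():
            s = sub.sort_values("start")
            if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
                warnings.warn(f"overlapping TAD intervals on {c}; first wins")

    def _in_one_tad(a: str, b: str, chrom: str) -> bool:
        sub = tad_by_chrom.get(chrom)
        if sub is None:
            return False
        for t in sub.itertuples(index=False):
            if (
                ann.loc[a, "body_start"] >= t.start
                and ann.loc[a, "body_end"] <= t.end
                and ann.loc[b, "body_start"] >= t.start
                and ann.loc[b, "body_end"] <= t.end
            ):
                return True
        return False

    strata = []
    distances = []
    supported = (
        pairs["contact_support"] > 0
        if "contact_support" in pairs
        else pd.Series(True, index=pairs.index)
    )
    for i, row in pairs.iterrows():
        a, b = row["gene_a"], row["gene_b"]
        ca, cb = ann.loc[a, "chrom"], ann.loc[b, "chrom"]
        if ca != cb:
            strata.append("interchromosomal")
            distances.append(np.nan)
            continue
        dist = abs(mid[a] - mid[b])
        distances.append(dist)
        if not supported[i]:
            strata.append("same_chr_no_contact")
            continue
        if _in_one_tad(a, b, ca):
            strata.append("TAD")
            continue
        for thr in sorted(thresholds_mb):
            if dist < thr * 1e6:
                strata.append(f"<{int(thr)}MB")
                break
        else:
            strata.append(f">{int(max(thresholds_mb))}MB")
    out = pairs.copy()
    out["linear_distance"] = distances
    out["stratum"] = strata
    return out


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file (name <TAB> description <TAB> genes...).

    Malformed lines are skipped with a warning carrying the line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                warnings.warn(f"malformed GMT line {lineno}; skipped")
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def load_functional_sets(
    gmt: dict[str, list[str]] | str,
    min_size: int = 10,
    max_size: int = 100,
    universe: set[str] | None = None,
    filter_on_annotated_size: bool = True,
) -> dict[str, list[str]]:
    """Size-filtered functional gene sets.

    Sets with annotated size in [min_size, max_size] (inclusive) are
    retained — fewer than ``min_size`` or more than ``max_size`` genes are
    discarded. By default the size filter applies to the annotated set and
    the universe intersection happens afterwards; set
    ``filter_on_annotated_size=False`` to intersect first.
    """
    sets = read_gmt(gmt) if isinstance(gmt, str) else gmt
    out: dict[str, list[str]] = {}
    for name, genes in sets.items():
        genes = list(dict.fromkeys(genes))
        measured = (
            genes
            if filter_on_annotated_size or universe is None
            else [g for g in genes if g in universe]
        )
        if not min_size <= len(measured) <= max_size:
            continue
        if universe is not None:
            genes = [g for g in genes if g in universe]
        out[name] = genes
    return out


# ---------------------------------------------------------------------------
# protein interaction strata


def stratify_interactions(
    pair_table: pd.DataFrame,
    mode: str,
    score_bins: tuple[float, ...] = (0, 300, 600, 900, 1001),
    experimental_col: str = "experimental",
    kind_col: str = "kind",
) -> dict[str, set[tuple[str, str]]]:
    """Labeled pair sets from an interaction table.

    ``string_score`` mode keeps pairs with experimental evidence (score
    > 0) and partitions them into score bins (labels ``score_[lo,hi)``);
    ``reactome`` mode returns ``complex`` and ``reaction`` pair sets (a
    pair labeled with both appears in both — the sets are not exclusive).
    """
    def _key(a, b):
        return (a, b) if a < b else (b, a)

    if mode == "string_score":
        if experimental_col not in pair_table:
            raise ValueError(f"need column {experimental_col!r}")
        exp = pair_table[pair_table[experimental_col] > 0]
        out: dict[str, set[tuple[str, str]]] = {}
        edges = list(score_bins)
        for lo, hi in zip(edges[:-1], edges[1:]):
            sub = exp[(exp[experimental_col] >= lo) & (exp[experimental_col] < hi)]
            pairs = {_key(a, b) for a, b in sub[["gene_a", "gene_b"]].to_numpy()}
            if pairs:
                out[f"score_[{lo:g},{hi:g})"] = pairs
        return out
    if mode == "reactome":
        if kind_col not in pair_table:
            raise ValueError(f"need column {kind_col!r}")
        out = {"complex": set(), "reaction": set()}
        for row in pair_table.itertuples(index=False):
            kinds = str(getattr(row, kind_col)).split("|")
            for k in kinds:
                if k in out:
                    out[k].add(_key(row.gene_a, row.gene_b))
        return out
    raise ValueError(f"unknown mode {mode!r}")


def split_by_interaction(
    pairs: set[tuple[str, str]], interacting: set[tuple[str, str]]
) -> dict[str, set[tuple[str, str]]]:
    """Partition annotation-sharing pairs by protein-interaction presence
    (+PI / -PI); the two parts cover all and only the input pairs."""
    def _key(p):
        a, b = p
        return (a, b) if a < b else (b, a)

    inter = {_key(p) for p in interacting}
    norm = {_key(p) for p in pairs}
    plus = {p for p in norm if p in inter}
    return {"+PI": plus, "-PI": norm - plus}
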