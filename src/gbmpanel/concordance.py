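"""Cross-model concordance of panel genes across PDX lines.

A PDX line profiled as dissociated cells, microtumors and spheroids gives
three expression profiles of the same tumor.  For each gene, z-scores are
computed across all samples pooled; within a line, the sign of the product
of two models' z-scores says whether the gene moves in the same direction in
both models (concordant) or not.  Aggregating the three model pairs over
lines classifies every gene into Venn regions: *core* genes concordant in
all three pairs, pair-specific genes, and *none*.

Also here: per-line Pearson correlations between model profiles (optionally
restricted to a gene subset), Kruskal-Wallis screening for model-specific
genes, variance filtering, and bi-clustering support.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .types import ExprMatrix, ModelType, ScaleTag

__all__ = [
    "MODEL_PAIRS",
    "ConcordanceConfig",
    "ConcordanceTable",
    "zscore_by_gene",
    "model_profiles",
    "pairwise_directionality",
    "classify_overlap",
    "per_line_model_correlation",
    "model_specific_genes",
    "variance_filter",
    "hier_cluster",
]

#: The three model pairs compared per line, in canonical order.
MODEL_PAIRS: list[tuple[ModelType, ModelType]] = [
    (ModelType.CELLS, ModelType.MICROTUMOR),
    (ModelType.CELLS, ModelType.SPHEROID),
    (ModelType.MICROTUMOR, ModelType.SPHEROID),
]

_PAIR_LABEL = {
    (ModelType.CELLS, ModelType.MICROTUMOR): "cells-mt",
    (ModelType.CELLS, ModelType.SPHEROID): "cells-sph",
    (ModelType.MICROTUMOR, ModelType.SPHEROID): "mt-sph",
}


@dataclass
class ConcordanceConfig:
    """Aggregation and screening thresholds for the concordance analysis.

    ``line_fraction`` is the fraction of informative PDX lines in which a
    model pair must be concordant before the pair counts as agreeing for a
    gene.  A bare majority (0.5) lets roughly one null gene in five through
    to the core set — a sign-product on uncorrelated models is a coin flip
    per line — so the default demands a two-thirds supermajority, which
    keeps the null core rate well under 5% while strong cross-model genes
    still pass every pair.
    """

    line_fraction: float = 2.0 / 3.0
    zero_policy: str = "discordant"  # or "ignore"
    kw_alpha: float = 0.01
    variance_top_k: int = 17

    def __post_init__(self) -> None:
        if not 0 < self.line_fraction <= 1:
            raise ValueError("line_fraction must lie in (0, 1]")
        if not 0 < self.kw_alpha < 1:
            raise ValueError("kw_alpha must lie in (0, 1)")
        if self.zero_policy not in {"discordant", "ignore"}:
            raise ValueError("zero_policy must be 'discordant' or 'ignore'")


class ConcordanceTable:
    """Per gene x (line, model-pair) concordance signs (+1, -1, NaN).

    NaN marks pairs for which a line lacks one of the two models.
    """

    def __init__(self, signs: pd.DataFrame):
        if not isinstance(signs.columns, pd.MultiIndex):
            raise ValueError("signs must have (line, pair) MultiIndex columns")
        self.signs = signs

    @property
    def genes(self) -> list[str]:
        return list(self.signs.index)

    @property
    def lines(self) -> list[str]:
        return sorted(set(self.signs.columns.get_level_values(0)))

    def pair_agreement(self, line_fraction: float) -> pd.DataFrame:
        """Per gene x pair: does the pair agree in >= line_fraction of lines with data?"""
        out = {}
        for pair in _PAIR_LABEL.values():
            cols = self.signs.xs(pair, axis=1, level=1)
            informative = cols.notna().sum(axis=1)
            concordant = (cols > 0).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = concordant / informative
            out[pair] = (informative > 0) & (frac >= line_fraction)
        return pd.DataFrame(out, index=self.signs.index)


def zscore_by_gene(expr: ExprMatrix) -> ExprMatrix:
    """Z-score each gene across all samples pooled (n-1 SD).

    Constant genes are flagged with a warning and set to all zeros.
    """
    values = expr.values
    if values.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s) z-scored to 0: "
            f"{list(values.index[constant])[:5]}..."
        )
    safe_sd = sd.where(~constant, 1.0)
    z = values.sub(mean, axis=0).div(safe_sd, axis=0)
    return expr.with_values(z, ScaleTag.ZSCORE)


def model_profiles(expr: ExprMatrix) -> dict[tuple[str, ModelType], pd.Series]:
    """One profile per (PDX line, model); replicates are averaged."""
    groups: dict[tuple[str, ModelType], list[str]] = {}
    for s in expr.samples:
        if not s.pdx_id or s.model is None:
            raise ValueError(f"sample {s.sample_id!r} lacks pdx_id or model annotation")
        groups.setdefault((s.pdx_id, s.model), []).append(s.sample_id)
    return {
        key: expr.values[ids].mean(axis=1) for key, ids in sorted(groups.items())
    }


def pairwise_directionality(
    z: ExprMatrix, config: ConcordanceConfig | None = None
) -> ConcordanceTable:
    """Sign of the z-score product for each gene, line, and model pair.

    A zero product is discordant (-1) under the default policy, or NaN
    (ignored) under ``zero_policy='ignore'``.  Pairs with a missing model
    are NaN.
    """
    config = config or ConcordanceConfig()
    if z.scale_tag is not ScaleTag.ZSCORE:
        z = zscore_by_gene(z)
    profiles = model_profiles(z)
    lines = sorted({line for line, _ in profiles})
    cols: dict[tuple[str, str], pd.Series] = {}
    for line in lines:
        for a, b in MODEL_PAIRS:
            label = _PAIR_LABEL[(a, b)]
            if (line, a) in profiles and (line, b) in profiles:
                product = profiles[(line, a)] * profiles[(line, b)]
                sign = pd.Series(np.sign(product), index=product.index)
                if config.zero_policy == "discordant":
                    sign = sign.replace(0.0, -1.0)
                else:
                    sign = sign.replace(0.0, np.nan)
                cols[(line, label)] = sign
            else:
                cols[(line, label)] = pd.Series(np.nan, index=z.values.index)
    signs = pd.DataFrame(cols)
    signs.columns = pd.MultiIndex.from_tuples(signs.columns, names=["line", "pair"])
    return ConcordanceTable(signs)


def classify_overlap(
    table: ConcordanceTable, config: ConcordanceConfig | None = None
) -> pd.Series:
    """Assign each gene to a Venn region of model agreement.

    ``core`` = all three pairs agree (in >= line_fraction of lines with
    data), ``none`` = no pair agrees; otherwise the label joins the
    agreeing pairs, e.g. ``cells-mt`` or ``cells-mt+mt-sph``.
    """
    config = config or ConcordanceConfig()
    agree = table.pair_agreement(config.line_fraction)
    labels = []
    for _, row in agree.iterrows():
        pairs = [p for p in agree.columns if row[p]]
        if len(pairs) == len(agree.columns):
            labels.append("core")
        elif not pairs:
            labels.append("none")
        else:
            labels.append("+".join(pairs))
    return pd.Series(labels, index=agree.index, name="overlap_class")


def per_line_model_correlation(
    expr: ExprMatrix, genes: list[str] | None = None
) -> pd.DataFrame:
    """Pearson r between model profiles for each line (NaN where missing).

    Rows are PDX lines, columns the three model pairs; restricted to the
    given gene subset when provided.
    """
    if genes is not None:
        if len(genes) < 3:
            raise ValueError("gene subset must have at least 3 genes")
        expr = expr.subset_genes(genes)
    profiles = model_profiles(expr)
    lines = sorted({line for line, _ in profiles})
    out = pd.DataFrame(index=lines, columns=list(_PAIR_LABEL.values()), dtype=float)
    for line in lines:
        for a, b in MODEL_PAIRS:
            if (line, a) in profiles and (line, b) in profiles:
                r = stats.pearsonr(profiles[(line, a)], profiles[(line, b)])[0]
                out.loc[line, _PAIR_LABEL[(a, b)]] = r
    return out


def kruskal_by_gene(expr: ExprMatrix, groups: dict[str, list[str]]) -> pd.DataFrame:
    """Kruskal-Wallis H and p per gene across the given sample groups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, ids in groups.items():
        if len(ids) == 0:
            raise ValueError(f"group {name!r} has no samples")
    blocks = {name: expr.values[ids] for name, ids in groups.items()}
    rows = []
    for gene in expr.genes:
        samples = [blocks[name].loc[gene].to_numpy() for name in groups]
        if np.ptp(np.concatenate(samples)) == 0:
            # all observations tied: no evidence of a group effect
            rows.append({"gene": gene, "H": 0.0, "p": 1.0})
            continue
        H, p = stats.kruskal(*samples)
        rows.append({"gene": gene, "H": float(H), "p": float(p)})
    return pd.DataFrame(rows).set_index("gene")


def model_specific_genes(
    expr: ExprMatrix, config: ConcordanceConfig | None = None
) -> pd.DataFrame:
    """Genes whose expression differs by derivative model (KW p <= kw_alpha)."""
    config = config or ConcordanceConfig()
    groups: dict[str, list[str]] = {}
    for s in expr.samples:
        if s.model is None:
            raise ValueError(f"sample {s.sample_id!r} has no model annotation")
        groups.setdefault(s.model.value, []).append(s.sample_id)
    if len(groups) < 2:
        raise ValueError("need samples from at least 2 models")
    for name, ids in groups.items():
        if len(ids) < 3:
            raise ValueError(f"model group {name!r} has {len(ids)} samples; need >= 3")
    table = kruskal_by_gene(expr, groups)
    return table[table["p"] <= config.kw_alpha].sort_values("p")


def variance_filter(expr: ExprMatrix, genes: list[str], top_k: int) -> list[str]:
    """Top-k genes by across-sample variance (ties broken by symbol)."""
    if top_k > len(genes):
        raise ValueError(f"top_k={top_k} exceeds {len(genes)} genes")
    variances = expr.values.loc[genes].var(axis=1, ddof=1)
    order = sorted(genes, key=lambda g: (-variances[g], g))
    return order[:top_k]


def hier_cluster(
    expr: ExprMatrix, genes: list[str] | None = None
) -> dict[str, object]:
    """Average-linkage bi-clustering with correlation distance.

    Returns linkage matrices plus leaf orders for genes and samples.  If any
    row/column is constant (correlation undefined) the distance falls back
    to Euclidean with a warning.
    """
    values = expr.values if genes is None else expr.values.loc[genes]
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("clustering needs at least 2 genes and 2 samples")

    def _linkage(mat: np.ndarray):
        if np.any(mat.std(axis=1) == 0):
            warnings.warn("constant rows; falling back to Euclidean distance")
            d = pdist(mat, metric="euclidean")
        else:
            d = pdist(mat, metric="correlation")
        return hierarchy.linkage(d, method="average")

    gene_link = _linkage(values.to_numpy())
    sample_link = _linkage(values.to_numpy().T)
    return {
        "gene_linkage": gene_link,
        "sample_linkage": sample_link,
        "gene_order": [values.index[i] for i in hierarchy.leaves_list(gene_link)],
        "sample_order": [values.columns[i] for i in hierarchy.leaves_list(sample_link)],
    }


def cut_clusters(linkage: np.ndarray, n_clusters: int) -> np.ndarray:
    """Flat cluster labels from a linkage cut into n_clusters groups."""
    return hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
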