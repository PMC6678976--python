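"""Responder vs non-responder differential expression.

Counts are converted to counts-per-million, log2(CPM + pseudocount) is
compared between groups with a Welch t-test (Mann-Whitney optionally), and a
gene is called significant when both p <= alpha and |log2FC| >= the
fold-change cutoff (default |log2FC| >= 2).  No multiple-testing correction
is applied by default — the screening rule is a raw-p, large-effect filter —
but Benjamini-Hochberg can be switched on.

Also here: Kruskal-Wallis screening of genes associated with a drug-response
label, and the set intersection used to derive response-concordance
signatures.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import kruskal_by_gene
from .types import ExprMatrix, Response, ScaleTag

__all__ = [
    "DEConfig",
    "cpm",
    "differential_expression",
    "response_associated_genes",
    "intersect_signature",
]


@dataclass
class DEConfig:
    alpha: float = 0.05
    lfc_threshold: float = 2.0
    test: str = "welch_t"  # or "wilcoxon"
    pseudocount: float = 1.0
    fdr: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")
        if self.test not in {"welch_t", "wilcoxon"}:
            raise ValueError("test must be 'welch_t' or 'wilcoxon'")


def cpm(expr: ExprMatrix) -> ExprMatrix:
    """Scale every sample's counts to sum to one million."""
    totals = expr.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero total count in lane(s): {list(zero.index)}")
    scaled = expr.values * (1e6 / totals)
    return expr.with_values(scaled, ScaleTag.CPM)


def differential_expression(
    expr: ExprMatrix,
    group_a: list[str],
    group_b: list[str],
    config: DEConfig | None = None,
) -> pd.DataFrame:
    """Per-gene log2 fold change (A minus B) and p-value on log2(CPM+pc).

    Input must be on a count scale (raw or normalized); it is converted to
    CPM internally.  Returns a table with columns ``log2fc``, ``p``,
    ``mean_log10cpm``, ``neg_log10_p`` (volcano y-axis) and ``significant``
    (p <= alpha AND |log2fc| >= lfc_threshold; on adjusted p if fdr=True,
    in which case a ``p_adj`` column is added).
    """
    config = config or DEConfig()
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if expr.scale_tag not in (ScaleTag.RAW_COUNT, ScaleTag.NORMALIZED_COUNT, ScaleTag.CPM):
        raise ValueError(f"expected counts or CPM, got scale {expr.scale_tag.value}")
    mat = expr if expr.scale_tag is ScaleTag.CPM else cpm(expr)
    log2cpm = np.log2(mat.values + config.pseudocount)
    a = log2cpm[group_a]
    b = log2cpm[group_b]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    if config.test == "welch_t":
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(
                a.to_numpy(), b.to_numpy(), axis=1, equal_var=False
            )
        p = pd.Series(p, index=log2cpm.index).fillna(1.0)  # constant genes
    else:
        pvals = []
        for gene in log2cpm.index:
            x, y = a.loc[gene].to_numpy(), b.loc[gene].to_numpy()
            if np.ptp(np.concatenate([x, y])) == 0:
                pvals.append(1.0)
            else:
                pvals.append(stats.mannwhitneyu(x, y, alternative="two-sided")[1])
        p = pd.Series(pvals, index=log2cpm.index)
    mean_log10cpm = np.log10(mat.values[group_a + group_b] + config.pseudocount).mean(axis=1)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "mean_log10cpm": mean_log10cpm,
        }
    )
    p_for_call = p
    if config.fdr:
        table["p_adj"] = _benjamini_hochberg(p)
        p_for_call = table["p_adj"]
    table["neg_log10_p"] = -np.log10(np.maximum(p_for_call, np.finfo(float).tiny))
    table["significant"] = (p_for_call <= config.alpha) & (
        table["log2fc"].abs() >= config.lfc_threshold
    )
    return table.sort_values("p")


def _benjamini_hochberg(p: pd.Series) -> pd.Series:
    order = np.argsort(p.to_numpy())
    n = len(p)
    ranked = p.to_numpy()[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return pd.Series(out, index=p.index)


def response_associated_genes(
    expr: ExprMatrix, drug: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Genes whose expression tracks a drug's response label (KW p <= alpha).

    Untested samples are excluded; responder and non-responder groups must
    both be present.
    """
    groups: dict[str, list[str]] = {}
    for s in expr.samples:
        resp = s.response(drug)
        if resp is Response.UNTESTED:
            continue
        groups.setdefault(resp.value, []).append(s.sample_id)
    if len(groups) < 2:
        raise ValueError(
            f"all tested samples share one {drug} response; nothing to compare"
        )
    table = kruskal_by_gene(expr, groups)
    return table[table["p"] <= alpha].sort_values("p")


def intersect_signature(set_a: list[str], set_b: list[str]) -> list[str]:
    """Sorted intersection of two gene lists."""
    return sorted(set(set_a) & set(set_b))
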