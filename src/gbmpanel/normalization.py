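"""Three-stage nCounter count normalization plus reference-gene selection.

The pipeline mirrors the nSolver convention: (1) background subtraction using
the geometric mean of the negative control probes, flooring at 1; (2) lane
(positive-control) normalization using the geometric mean of the positive
control probes; (3) codeset-content normalization using the geometric mean of
a small set of stable reference genes.  Each multiplicative factor is the
arithmetic mean of the per-lane geometric means divided by the lane's own
geometric mean, so after each stage the relevant control geomeans are equal
across lanes.

Reference genes can be supplied (the panel default is CC2D1B, GPATCH3, MRPS5,
PIK3R4 and SF3A3) or chosen from the data by :func:`select_reference_genes`,
which looks for genes with a low percent coefficient of variation that are
highly mutually Spearman-correlated.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    CountMatrix,
    ExprMatrix,
    NON_CONTROL_CLASSES,
    ProbeClass,
    SampleAnnotation,
    ScaleTag,
)

__all__ = [
    "DEFAULT_REFERENCE_GENES",
    "NormalizationReport",
    "RefGeneCriteria",
    "geometric_mean",
    "subtract_background",
    "positive_normalize",
    "content_normalize",
    "select_reference_genes",
    "normalize_pipeline",
]

#: Panel reference probes used for content normalization by default.
DEFAULT_REFERENCE_GENES = ["CC2D1B", "GPATCH3", "MRPS5", "PIK3R4", "SF3A3"]


@dataclass
class NormalizationReport:
    """Per-lane factors and bookkeeping produced by the pipeline."""

    background: dict[str, float] = field(default_factory=dict)
    positive_factor: dict[str, float] = field(default_factory=dict)
    content_factor: dict[str, float] = field(default_factory=dict)
    reference_genes: list[str] = field(default_factory=list)
    floored_count: int = 0

    def combined_factor(self) -> dict[str, float]:
        """Product of positive and content factors per lane."""
        return {
            lane: self.positive_factor.get(lane, 1.0) * self.content_factor.get(lane, 1.0)
            for lane in set(self.positive_factor) | set(self.content_factor)
        }

    def to_dict(self) -> dict:
        return {
            "background": self.background,
            "positive_factor": self.positive_factor,
            "content_factor": self.content_factor,
            "reference_genes": self.reference_genes,
            "floored_count": self.floored_count,
        }


@dataclass
class RefGeneCriteria:
    """Thresholds for data-driven reference-gene selection."""

    max_pct_cv: float = 15.0
    min_mutual_spearman: float = 0.75
    n_select: int = 5

    def __post_init__(self) -> None:
        if self.max_pct_cv <= 0:
            raise ValueError("max_pct_cv must be positive")
        if not -1.0 <= self.min_mutual_spearman <= 1.0:
            raise ValueError("min_mutual_spearman must lie in [-1, 1]")
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")


def geometric_mean(values) -> float:
    """exp(mean(log x)) over strictly positive values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of empty input")
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


def _control_geomeans(counts: CountMatrix, names: list[str], label: str) -> pd.Series:
    """Per-lane geomean of the named probes; +1 offset if any zero present."""
    block = counts.counts.loc[names]
    if (block.to_numpy() == 0).any():
        warnings.warn(
            f"zero counts among {label} probes; applying +1 offset before geometric mean"
        )
        block = block + 1.0
    return block.apply(geometric_mean, axis=0)


def subtract_background(counts: CountMatrix) -> tuple[CountMatrix, pd.Series]:
    """Subtract the per-lane negative-probe geomean from non-control counts.

    Counts falling below 1 after subtraction are floored at 1 (a count of
    zero signal).  Control probe rows are left untouched for audit.  Returns
    the adjusted matrix and the per-lane background estimates; the number of
    floored cells is stashed on the matrix as ``_floored_count``.
    """
    negatives = counts.names_of_class(ProbeClass.NEGATIVE)
    if not negatives:
        raise ValueError("no Negative control probes; cannot estimate background")
    background = _control_geomeans(counts, negatives, "negative control")
    out = counts.copy()
    mask = counts.probe_classes.isin(NON_CONTROL_CLASSES).to_numpy()
    block = out.counts.loc[mask] - background
    floored = int((block.to_numpy() < 1).sum())
    out.counts.loc[mask] = block.clip(lower=1.0)
    out._floored_count = floored  # type: ignore[attr-defined]
    return out, background


def _factor_normalize(
    counts: CountMatrix, anchor_names: list[str], target_mask: np.ndarray, label: str
) -> tuple[CountMatrix, pd.Series]:
    geomeans = _control_geomeans(counts, anchor_names, label)
    zero = geomeans[geomeans == 0]
    if len(zero):
        raise ValueError(f"zero {label} geomean in lane(s): {list(zero.index)}")
    factors = geomeans.mean() / geomeans
    out = counts.copy()
    out.counts.loc[target_mask] = out.counts.loc[target_mask] * factors
    return out, factors


def positive_normalize(counts: CountMatrix) -> tuple[CountMatrix, pd.Series]:
    """Scale each lane so positive-control geomeans match their grand mean.

    factor_lane = mean_over_lanes(positive geomean) / lane's positive geomean,
    applied to every probe (controls included, so the invariant is auditable).
    """
    positives = counts.names_of_class(ProbeClass.POSITIVE)
    if not positives:
        raise ValueError("no Positive control probes")
    mask = np.ones(len(counts.probes), dtype=bool)
    return _factor_normalize(counts, positives, mask, "positive control")


def content_normalize(
    counts: CountMatrix, reference_genes: list[str] | None = None
) -> tuple[CountMatrix, pd.Series]:
    """Scale each lane so reference-gene geomeans match their grand mean.

    Factors are computed over the reference genes and applied to all
    non-control probes (the reference genes themselves included, so their
    geomeans equalize across lanes).
    """
    reference_genes = list(reference_genes or DEFAULT_REFERENCE_GENES)
    missing = [g for g in reference_genes if g not in counts.counts.index]
    if missing:
        raise ValueError(f"reference genes absent from panel: {missing}")
    if (counts.counts.loc[reference_genes].to_numpy() <= 0).any():
        raise ValueError("reference genes must have positive counts in every lane")
    mask = counts.probe_classes.isin(NON_CONTROL_CLASSES).to_numpy()
    return _factor_normalize(counts, reference_genes, mask, "reference gene")


def select_reference_genes(expr: ExprMatrix, criteria: RefGeneCriteria | None = None) -> list[str]:
    """Pick stable reference genes: low %CV, high mutual Spearman correlation.

    Candidates are genes whose percent coefficient of variation
    (100 * sd / mean, n-1 sd) is at most ``max_pct_cv``.  A set is grown
    greedily: seed with the most-correlated admissible pair, then repeatedly
    add the candidate with the highest mean correlation to the current set,
    requiring every admitted pair to reach ``min_mutual_spearman``.  Ties are
    broken by lower %CV then by symbol.
    """
    criteria = criteria or RefGeneCriteria()
    values = expr.values
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples to assess reference-gene stability")
    if len(values) < criteria.n_select:
        raise ValueError(
            f"panel has {len(values)} genes; cannot select {criteria.n_select}"
        )
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_cv = (100.0 * sds / means).replace([np.inf, -np.inf], np.nan)
    candidates = pct_cv[(pct_cv <= criteria.max_pct_cv) & pct_cv.notna() & (means > 0)]
    # Perfectly constant genes have %CV exactly 0 but undefined correlation;
    # they stay candidates and rank first on the CV tie-break.
    if len(candidates) < criteria.n_select:
        raise ValueError(
            f"only {len(candidates)} genes pass the %CV filter; need {criteria.n_select}"
        )
    cand = sorted(candidates.index, key=lambda g: (candidates[g], g))
    sub = values.loc[cand].T  # samples x candidates
    rho = sub.corr(method="spearman").fillna(0.0)  # constant genes -> rho 0
    np.fill_diagonal(rho.values, 1.0)

    def _order_key(g: str) -> tuple[float, str]:
        return (float(candidates[g]), g)

    # Seed: the admissible pair with the highest rho.
    best_pair, best_val = None, -np.inf
    for i, a in enumerate(cand):
        for b in cand[i + 1 :]:
            v = rho.loc[a, b]
            if v >= criteria.min_mutual_spearman and v > best_val:
                best_pair, best_val = (a, b), v
    if criteria.n_select == 1:
        return [cand[0]]
    if best_pair is None:
        raise ValueError(
            "no candidate pair reaches the mutual Spearman threshold; "
            f"0 admissible sets of size {criteria.n_select}"
        )
    selected = list(best_pair)
    remaining = [g for g in cand if g not in selected]
    while len(selected) < criteria.n_select:
        scored = []
        for g in remaining:
            pair_vals = rho.loc[g, selected]
            if (pair_vals >= criteria.min_mutual_spearman).all():
                scored.append((-float(pair_vals.mean()), *_order_key(g), g))
        if not scored:
            raise ValueError(
                f"only {len(selected)} mutually correlated reference genes found; "
                f"need {criteria.n_select}"
            )
        scored.sort()
        pick = scored[0][-1]
        selected.append(pick)
        remaining.remove(pick)
    return selected


def normalize_pipeline(
    counts: CountMatrix,
    reference_genes: list[str] | None = None,
    samples: list[SampleAnnotation] | None = None,
) -> tuple[ExprMatrix, NormalizationReport]:
    """Run background -> positive -> content normalization.

    Returns a normalized-count :class:`ExprMatrix` holding only the
    non-control (Endogenous + Housekeeping) probes, plus the report of
    per-lane backgrounds and factors.
    """
    report = NormalizationReport()
    stage1, background = subtract_background(counts)
    report.background = {k: float(v) for k, v in background.items()}
    report.floored_count = getattr(stage1, "_floored_count", 0)
    stage2, pos_factors = positive_normalize(stage1)
    report.positive_factor = {k: float(v) for k, v in pos_factors.items()}
    stage3, content_factors = content_normalize(stage2, reference_genes)
    report.content_factor = {k: float(v) for k, v in content_factors.items()}
    report.reference_genes = list(reference_genes or DEFAULT_REFERENCE_GENES)

    keep = stage3.probe_classes.isin(NON_CONTROL_CLASSES).to_numpy()
    frame = stage3.counts.loc[keep]
    ann = samples or [SampleAnnotation(sample_id=l) for l in stage3.lanes]
    expr = ExprMatrix(frame, samples=ann, scale_tag=ScaleTag.NORMALIZED_COUNT)
    return expr, report
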