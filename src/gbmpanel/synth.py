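"""Synthetic fixtures with known ground truth for every pipeline stage.

Four generators emulate the data the pipeline expects:

* :func:`make_nanostring_counts` — nCounter-like lanes: endogenous genes with
  log-normal counts, 8 negative control probes (low Poisson background),
  6 positive control probes on a geometric ladder, housekeeping genes with
  near-zero biological variance, and known per-lane scale factors.
* :func:`make_labeled_dataset` — z-scored multiclass expression with planted
  class-discriminative marker genes for feature selection.
* :func:`make_signature_panel` — a signature-reduction panel with planted
  unimodal (uninformative) genes, bimodal (informative) genes, and
  correlated redundant blocks built on shared latent variables.
* :func:`make_multimodel_panel` — a PDX-line x derivative-model panel with
  planted core genes (line-specific level shared across models),
  model-specific shifts, and drug-response-associated genes.

Counts are log-normal-then-rounded rather than negative binomial: nCounter
per-probe noise is near log-normal at moderate counts and nothing downstream
models dispersion.  Every generator is a pure function of its spec's seed.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fastemc import LabeledDataset
from .normalization import DEFAULT_REFERENCE_GENES
from .types import (
    CountMatrix,
    ExprMatrix,
    ModelType,
    ProbeClass,
    ProbeInfo,
    Response,
    SampleAnnotation,
    ScaleTag,
    Signature,
)

__all__ = [
    "GroundTruth",
    "NanoStringSpec",
    "LabeledSpec",
    "SignatureSpec",
    "MultiModelSpec",
    "DECountsSpec",
    "make_nanostring_counts",
    "make_labeled_dataset",
    "make_signature_panel",
    "make_multimodel_panel",
    "make_de_counts",
]

#: Counts of synthetic control probes on a standard codeset.
N_NEGATIVE_PROBES = 8
N_POSITIVE_PROBES = 6


@dataclass
class GroundTruth:
    """What was planted: per-gene roles and the hidden generative factors."""

    roles: dict[str, str] = field(default_factory=dict)
    lane_scales: dict[str, float] = field(default_factory=dict)
    class_labels: dict[str, str] = field(default_factory=dict)
    response_labels: dict[str, str] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g, r in self.roles.items() if r == role]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls.from_json(Path(path).read_text())


def _check(condition: bool, message: str, problems: list[str]) -> None:
    if not condition:
        problems.append(message)


def _validate(problems: list[str]) -> None:
    if problems:
        raise ValueError("invalid spec: " + "; ".join(problems))


# ---------------------------------------------------------------------------
# nCounter-like counts
# ---------------------------------------------------------------------------

@dataclass
class NanoStringSpec:
    """Study conditions for simulated nCounter lanes.

    Defaults mirror a 350-gene panel run across a dozen lanes with modest
    lane-efficiency spread (+-20%), background around 6 counts, and positive
    probes on the standard 4x geometric ladder.
    """

    n_genes: int = 350
    n_lanes: int = 12
    lane_scales: list[float] | None = None  # default: log-uniform in [0.8, 1.25]
    noise_sd: float = 0.5  # per-gene biological noise, log2 units
    hk_noise_sd: float = 0.02  # housekeeping biological noise, log2 units (near-zero)
    negative_mean: float = 6.0  # Poisson mean of negative control probes
    positive_levels: tuple = (32.0, 128.0, 512.0, 2048.0, 8192.0, 32768.0)
    base_log2_range: tuple = (5.0, 10.0)
    housekeeping_names: tuple = tuple(DEFAULT_REFERENCE_GENES)
    seed: int = 0


def make_nanostring_counts(spec: NanoStringSpec) -> tuple[CountMatrix, GroundTruth]:
    problems: list[str] = []
    _check(spec.n_genes >= 1, "n_genes must be >= 1", problems)
    _check(spec.n_lanes >= 1, "n_lanes must be >= 1", problems)
    _check(spec.noise_sd >= 0, "noise_sd must be >= 0", problems)
    _check(len(spec.positive_levels) == N_POSITIVE_PROBES,
           f"need {N_POSITIVE_PROBES} positive levels", problems)
    if spec.lane_scales is not None:
        _check(len(spec.lane_scales) == spec.n_lanes,
               "lane_scales length must equal n_lanes", problems)
        _check(all(s > 0 for s in spec.lane_scales),
               "lane_scales must be positive", problems)
    _validate(problems)

    rng = np.random.default_rng(spec.seed)
    lanes = [f"L{j + 1:02d}" for j in range(spec.n_lanes)]
    if spec.lane_scales is None:
        scales = np.exp(rng.uniform(np.log(0.8), np.log(1.25), spec.n_lanes))
    else:
        scales = np.asarray(spec.lane_scales, dtype=float)

    probes: list[ProbeInfo] = []
    blocks: list[np.ndarray] = []
    roles: dict[str, str] = {}

    gene_names = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    mu = rng.uniform(*spec.base_log2_range, size=spec.n_genes)
    endo = scales[None, :] * 2 ** (
        mu[:, None] + rng.normal(0.0, spec.noise_sd, (spec.n_genes, spec.n_lanes))
    )
    for g in gene_names:
        probes.append(ProbeInfo(g, ProbeClass.ENDOGENOUS))
        roles[g] = "endogenous"
    blocks.append(endo)

    hk_mu = rng.uniform(8.0, 10.0, size=len(spec.housekeeping_names))
    hk = scales[None, :] * 2 ** (
        hk_mu[:, None]
        + rng.normal(0.0, spec.hk_noise_sd, (len(spec.housekeeping_names), spec.n_lanes))
    )
    for g in spec.housekeeping_names:
        probes.append(ProbeInfo(g, ProbeClass.HOUSEKEEPING))
        roles[g] = "housekeeping"
    blocks.append(hk)

    neg = rng.poisson(spec.negative_mean, (N_NEGATIVE_PROBES, spec.n_lanes)).astype(float)
    for i in range(N_NEGATIVE_PROBES):
        name = f"NEG_{chr(65 + i)}"
        probes.append(ProbeInfo(name, ProbeClass.NEGATIVE))
        roles[name] = "negative_control"
    blocks.append(neg)

    # positive probes are spike-ins: only a small counting-noise wobble
    pos = np.asarray(spec.positive_levels, dtype=float)[:, None] * scales[None, :]
    pos = pos * 2 ** rng.normal(0.0, 0.01, pos.shape)
    for i in range(N_POSITIVE_PROBES):
        name = f"POS_{chr(65 + i)}"
        probes.append(ProbeInfo(name, ProbeClass.POSITIVE))
        roles[name] = "positive_control"
    blocks.append(pos)

    counts = np.round(np.vstack(blocks))
    truth = GroundTruth(
        roles=roles,
        lane_scales={lane: float(s) for lane, s in zip(lanes, scales)},
    )
    return CountMatrix(probes, counts, lanes), truth


# ---------------------------------------------------------------------------
# Labeled multiclass expression
# ---------------------------------------------------------------------------

@dataclass
class LabeledSpec:
    """Study conditions for planted-marker subtype classification data.

    ``marker_mode='contrast'`` gives each marker gene a random +-effect
    offset per class (every marker separates the classes); ``'per_class'``
    assigns markers to one class each and shifts only that class.
    """

    n_genes: int = 200
    n_samples: int = 120
    n_classes: int = 4
    n_markers: int = 10
    effect: float = 1.5  # class-mean offset in units of the noise SD
    marker_mode: str = "contrast"
    class_names: tuple | None = None
    seed: int = 0


def make_labeled_dataset(spec: LabeledSpec) -> tuple[LabeledDataset, GroundTruth]:
    problems: list[str] = []
    _check(spec.n_classes >= 2, "n_classes must be >= 2", problems)
    _check(0 <= spec.n_markers <= spec.n_genes,
           "n_markers must lie in [0, n_genes]", problems)
    _check(spec.n_samples >= 2 * spec.n_classes,
           "need at least 2 samples per class", problems)
    _check(spec.marker_mode in {"contrast", "per_class"},
           "marker_mode must be 'contrast' or 'per_class'", problems)
    _validate(problems)

    rng = np.random.default_rng(spec.seed)
    classes = list(
        spec.class_names
        or ["classical", "mesenchymal", "neural", "proneural", "gcimp"][: spec.n_classes]
    )
    if len(classes) != spec.n_classes:
        raise ValueError("class_names length must equal n_classes")
    # balanced classes, remainder to the first classes
    per = spec.n_samples // spec.n_classes
    labels = [classes[k] for k in range(spec.n_classes) for _ in range(per)]
    labels += [classes[k] for k in range(spec.n_samples - len(labels))]
    genes = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    sample_ids = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    y = np.array([classes.index(l) for l in labels])

    X = rng.normal(0.0, 1.0, (spec.n_genes, spec.n_samples))
    roles = {g: "noise" for g in genes}
    marker_idx = rng.choice(spec.n_genes, size=spec.n_markers, replace=False)
    for j, gi in enumerate(marker_idx):
        if spec.marker_mode == "contrast":
            signs = rng.choice([-1.0, 1.0], size=spec.n_classes)
            while np.all(signs == signs[0]):  # a flat offset separates nothing
                signs = rng.choice([-1.0, 1.0], size=spec.n_classes)
            X[gi] += spec.effect * signs[y]
            roles[genes[gi]] = "class_marker"
        else:
            k = j % spec.n_classes
            X[gi] += spec.effect * (y == k)
            roles[genes[gi]] = f"class_marker:{classes[k]}"

    # z-score genes so the dataset arrives on the scale the selector expects
    X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
    samples = [SampleAnnotation(sample_id=s) for s in sample_ids]
    expr = ExprMatrix(X, genes=genes, samples=samples, scale_tag=ScaleTag.ZSCORE)
    data = LabeledDataset(expr=expr, labels=dict(zip(sample_ids, labels)))
    truth = GroundTruth(roles=roles, class_labels=dict(zip(sample_ids, labels)))
    return data, truth


# ---------------------------------------------------------------------------
# Signature-reduction panels
# ---------------------------------------------------------------------------

@dataclass
class SignatureSpec:
    """Study conditions for reduction panels.

    ``redundant_blocks`` is a list of ``(size, rho)`` pairs; each block is a
    bimodal latent variable plus independent noise calibrated so pairwise
    Pearson correlation is ``rho``.  ``bimodal_sep`` is the component-mean
    separation in units of the within-component SD.
    """

    n_unimodal: int = 150
    n_bimodal: int = 50
    n_samples: int = 120
    bimodal_sep: float = 3.0
    redundant_blocks: list = field(default_factory=list)
    signature_name: str = "synthetic"
    seed: int = 0


def _bimodal(rng: np.random.Generator, n: int, sep: float) -> np.ndarray:
    assign = rng.random(n) < 0.5
    return assign * sep + rng.normal(0.0, 1.0, n)


def make_signature_panel(spec: SignatureSpec) -> tuple[ExprMatrix, Signature, GroundTruth]:
    problems: list[str] = []
    _check(spec.n_samples >= 3, "need >= 3 samples", problems)
    for blk in spec.redundant_blocks:
        size, rho = blk
        _check(size >= 2, "redundant blocks need size >= 2", problems)
        _check(0 < rho < 1 or rho == 1.0, "block rho must lie in (0, 1]", problems)
    _validate(problems)

    rng = np.random.default_rng(spec.seed)
    rows: list[np.ndarray] = []
    genes: list[str] = []
    roles: dict[str, str] = {}

    for i in range(spec.n_unimodal):
        rows.append(rng.normal(0.0, 1.0, spec.n_samples))
        g = f"U{i + 1:04d}"
        genes.append(g)
        roles[g] = "unimodal"
    for i in range(spec.n_bimodal):
        rows.append(_bimodal(rng, spec.n_samples, spec.bimodal_sep))
        g = f"B{i + 1:04d}"
        genes.append(g)
        roles[g] = "bimodal"
    for b, (size, rho) in enumerate(spec.redundant_blocks, start=1):
        latent = _bimodal(rng, spec.n_samples, spec.bimodal_sep)
        var_latent = 0.25 * spec.bimodal_sep**2 + 1.0  # Bernoulli(1/2) mixture variance
        tau = 0.0 if rho == 1.0 else float(np.sqrt(var_latent * (1 - rho) / rho))
        for j in range(size):
            rows.append(latent + rng.normal(0.0, tau, spec.n_samples))
            g = f"R{b}_{j + 1:02d}"
            genes.append(g)
            roles[g] = f"redundant_block:{b}"

    expr = ExprMatrix(
        np.vstack(rows),
        genes=genes,
        samples=[f"S{i + 1:03d}" for i in range(spec.n_samples)],
        scale_tag=ScaleTag.LOG2,
    )
    signature = Signature(name=spec.signature_name, genes=genes, source="synthetic")
    return expr, signature, GroundTruth(roles=roles)


def make_reduction_fixture(seed: int = 0) -> tuple[ExprMatrix, Signature, GroundTruth]:
    """A 40-gene signature engineered to reduce to 19 survivors.

    15 unimodal genes fall to the informativeness filter; three redundant
    blocks of sizes 4, 3 and 2 lose all but one member each (6 removals);
    the 16 singleton bimodal genes and 3 block survivors leave 19 genes.

    The construction is paired with BIC component selection (recorded in
    ``truth.extra``): at this separation (5 sigma, n=250) BIC detects every
    bimodal gene while its conservatism guarantees no unimodal gene is
    falsely split, making the 19-gene outcome seed-robust.
    """
    spec = SignatureSpec(
        n_unimodal=15,
        n_bimodal=16,
        n_samples=250,
        bimodal_sep=5.0,
        redundant_blocks=[(4, 0.97), (3, 0.97), (2, 0.97)],
        signature_name="engineered-40",
        seed=seed,
    )
    expr, signature, truth = make_signature_panel(spec)
    truth.extra["component_selection"] = "BIC"
    truth.extra["expected_kept"] = 19
    return expr, signature, truth


# ---------------------------------------------------------------------------
# Multi-line x multi-model panels
# ---------------------------------------------------------------------------

@dataclass
class MultiModelSpec:
    """Study conditions for the PDX line x derivative model panel.

    Defaults mirror the study layout: 11 PDX lines profiled as cells,
    microtumors and spheroids on a 350-gene panel, with some lines missing
    spheroids, core genes carrying a line-specific level shared across
    models, a block of spheroid-shifted model-specific genes, and a block of
    genes shifted in drug-responding lines.
    """

    n_lines: int = 11
    n_genes: int = 350
    n_core: int = 100
    n_model_specific: int = 30
    n_response: int = 20
    effect_core: float = 2.0  # SD of the line-specific latent, in noise-SD units
    effect_model: float = 2.0
    effect_response: float = 2.0
    noise_sd: float = 1.0
    specific_model: str = "spheroid"
    missing_spheroid_lines: int = 3
    responder_fraction: float = 0.5
    drug: str = "TMZ"
    seed: int = 0


def make_multimodel_panel(spec: MultiModelSpec) -> tuple[ExprMatrix, GroundTruth]:
    problems: list[str] = []
    _check(spec.n_lines >= 2, "need >= 2 lines", problems)
    _check(spec.n_core + spec.n_model_specific + spec.n_response <= spec.n_genes,
           "planted gene blocks exceed n_genes", problems)
    _check(0 <= spec.missing_spheroid_lines < spec.n_lines,
           "missing_spheroid_lines must be < n_lines", problems)
    _check(spec.specific_model in [m.value for m in ModelType],
           "specific_model must be a valid model", problems)
    _validate(problems)

    rng = np.random.default_rng(spec.seed)
    lines = [f"X{1000 + 7 * i}" for i in range(spec.n_lines)]
    models = list(ModelType)
    missing = set(rng.choice(spec.n_lines, size=spec.missing_spheroid_lines, replace=False))
    n_resp = int(round(spec.responder_fraction * spec.n_lines))
    responders = set(rng.choice(spec.n_lines, size=n_resp, replace=False))

    samples: list[SampleAnnotation] = []
    for li, line in enumerate(lines):
        for model in models:
            if model is ModelType.SPHEROID and li in missing:
                continue
            resp = Response.RESPONDER if li in responders else Response.NONRESPONDER
            samples.append(
                SampleAnnotation(
                    sample_id=f"{line}_{model.value}",
                    pdx_id=line,
                    model=model,
                    responses={spec.drug: resp},
                )
            )
    n_samples = len(samples)
    genes = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    roles = {g: "noise" for g in genes}
    X = rng.normal(0.0, spec.noise_sd, (spec.n_genes, n_samples))

    line_of = np.array([lines.index(s.pdx_id) for s in samples])
    model_of = np.array([s.model.value for s in samples])
    is_responder = np.array(
        [s.responses[spec.drug] is Response.RESPONDER for s in samples]
    )

    cursor = 0
    for i in range(cursor, cursor + spec.n_core):
        # line-specific +-effect level shared by all of a line's models, so
        # within-line z-products are positive ~95% of the time at 2 sigma;
        # signs are balanced across lines to keep the pooled mean near zero
        signs = np.ones(spec.n_lines)
        signs[: spec.n_lines // 2] = -1.0
        latent = spec.effect_core * spec.noise_sd * rng.permutation(signs)
        X[i] += latent[line_of]
        roles[genes[i]] = "core"
    cursor += spec.n_core
    for i in range(cursor, cursor + spec.n_model_specific):
        X[i] += spec.effect_model * spec.noise_sd * (model_of == spec.specific_model)
        roles[genes[i]] = "model_specific"
    cursor += spec.n_model_specific
    for i in range(cursor, cursor + spec.n_response):
        X[i] += spec.effect_response * spec.noise_sd * is_responder
        roles[genes[i]] = "response_assoc"

    expr = ExprMatrix(X, genes=genes, samples=samples, scale_tag=ScaleTag.LOG2)
    truth = GroundTruth(
        roles=roles,
        response_labels={
            s.sample_id: s.responses[spec.drug].value for s in samples
        },
        extra={
            "missing_spheroid_lines": sorted(lines[i] for i in missing),
            "responder_lines": sorted(lines[i] for i in responders),
            "drug": spec.drug,
        },
    )
    return expr, truth


# ---------------------------------------------------------------------------
# Two-group count data for differential expression
# ---------------------------------------------------------------------------

@dataclass
class DECountsSpec:
    """Two-group count data with planted fold changes on the log2 scale."""

    n_genes: int = 200
    n_per_group: int = 6
    n_de: int = 5
    log2fc: float = 3.0
    sigma: float = 0.5  # per-gene log2 noise SD
    base_log2_range: tuple = (5.0, 10.0)
    seed: int = 0


def make_de_counts(spec: DECountsSpec) -> tuple[ExprMatrix, list[str], list[str], GroundTruth]:
    """Counts for group A vs B plus the two sample-ID lists.

    Planted genes are shifted by ``log2fc`` in group A (responders).
    """
    problems: list[str] = []
    _check(spec.n_per_group >= 2, "need >= 2 samples per group", problems)
    _check(0 <= spec.n_de <= spec.n_genes, "n_de must lie in [0, n_genes]", problems)
    _validate(problems)
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    a_ids = [f"A{i + 1:02d}" for i in range(spec.n_per_group)]
    b_ids = [f"B{i + 1:02d}" for i in range(spec.n_per_group)]
    mu = rng.uniform(*spec.base_log2_range, size=spec.n_genes)
    log2 = mu[:, None] + rng.normal(
        0.0, spec.sigma, (spec.n_genes, 2 * spec.n_per_group)
    )
    de_idx = rng.choice(spec.n_genes, size=spec.n_de, replace=False)
    log2[de_idx, : spec.n_per_group] += spec.log2fc
    counts = np.round(2**log2)
    roles = {g: "null" for g in genes}
    for i in de_idx:
        roles[genes[i]] = "de"
    samples = [
        SampleAnnotation(sample_id=s, responses={"drug": Response.RESPONDER})
        for s in a_ids
    ] + [
        SampleAnnotation(sample_id=s, responses={"drug": Response.NONRESPONDER})
        for s in b_ids
    ]
    expr = ExprMatrix(counts, genes=genes, samples=samples, scale_tag=ScaleTag.RAW_COUNT)
    return expr, a_ids, b_ids, GroundTruth(roles=roles)
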