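"""Core data containers shared by every stage of the panel pipeline.

All containers are thin, validated wrappers around pandas objects so that
downstream modules can rely on a handful of invariants (unique gene symbols,
consistent dimensions, an accurate scale tag) instead of re-checking raw
DataFrames everywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeClass",
    "ProbeInfo",
    "CountMatrix",
    "ModelType",
    "Response",
    "SampleAnnotation",
    "ExprMatrix",
    "ScaleTag",
    "Signature",
]


class ProbeClass(str, Enum):
    """nCounter probe role.

    ``Negative`` and ``Positive`` are synthetic control probes (background
    estimation and lane-efficiency ladder); ``Housekeeping`` probes are
    candidate reference genes for content normalization; everything else on
    the panel is ``Endogenous``.
    """

    ENDOGENOUS = "Endogenous"
    NEGATIVE = "Negative"
    POSITIVE = "Positive"
    HOUSEKEEPING = "Housekeeping"


#: Probe classes that are *not* synthetic controls.
NON_CONTROL_CLASSES = (ProbeClass.ENDOGENOUS, ProbeClass.HOUSEKEEPING)


@dataclass(frozen=True)
class ProbeInfo:
    """A single probe on the codeset: gene symbol, role, optional accession."""

    name: str
    probe_class: ProbeClass
    accession: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("probe name must be non-empty")
        if not isinstance(self.probe_class, ProbeClass):
            object.__setattr__(self, "probe_class", ProbeClass(self.probe_class))


class CountMatrix:
    """Raw (or partially normalized) probe x lane nCounter counts.

    Parameters
    ----------
    probes
        Ordered probe descriptions; names must be unique.
    counts
        ``len(probes) x n_lanes`` nonnegative values.
    lanes
        Unique lane/sample identifiers, one per column.
    """

    def __init__(self, probes: Sequence[ProbeInfo], counts, lanes: Sequence[str]):
        self.probes = list(probes)
        names = [p.name for p in self.probes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate probe names: {dupes}")
        lanes = [str(l) for l in lanes]
        if len(set(lanes)) != len(lanes):
            raise ValueError("lane IDs must be unique")
        arr = np.asarray(counts, dtype=float)
        if arr.ndim != 2 or arr.shape != (len(self.probes), len(lanes)):
            raise ValueError(
                f"counts shape {arr.shape} inconsistent with "
                f"{len(self.probes)} probes x {len(lanes)} lanes"
            )
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("counts must be finite and nonnegative")
        self.counts = pd.DataFrame(arr, index=names, columns=lanes)

    # -- convenience accessors -------------------------------------------
    @property
    def probe_names(self) -> list[str]:
        return list(self.counts.index)

    @property
    def lanes(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def probe_classes(self) -> pd.Series:
        return pd.Series(
            [p.probe_class for p in self.probes], index=self.counts.index
        )

    def names_of_class(self, cls: ProbeClass) -> list[str]:
        return [p.name for p in self.probes if p.probe_class is cls]

    def probe_table(self) -> pd.DataFrame:
        """Probe annotation as a DataFrame (name, probe_class, accession)."""
        return pd.DataFrame(
            {
                "name": [p.name for p in self.probes],
                "probe_class": [p.probe_class.value for p in self.probes],
                "accession": [p.accession for p in self.probes],
            }
        )

    def copy(self) -> "CountMatrix":
        out = CountMatrix.__new__(CountMatrix)
        out.probes = list(self.probes)
        out.counts = self.counts.copy()
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"CountMatrix({len(self.probes)} probes x {len(self.lanes)} lanes)"


class ModelType(str, Enum):
    """Derivative model a sample was profiled from."""

    CELLS = "cells"
    MICROTUMOR = "microtumor"
    SPHEROID = "spheroid"


class Response(str, Enum):
    RESPONDER = "responder"
    NONRESPONDER = "nonresponder"
    UNTESTED = "untested"


@dataclass
class SampleAnnotation:
    """Per-sample metadata: PDX line of origin, derivative model, drug calls."""

    sample_id: str
    pdx_id: str = ""
    model: ModelType | None = None
    responses: dict[str, Response] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.model is not None and not isinstance(self.model, ModelType):
            self.model = ModelType(self.model)
        self.responses = {
            d: (r if isinstance(r, Response) else Response(r))
            for d, r in self.responses.items()
        }

    def response(self, drug: str) -> Response:
        return self.responses.get(drug, Response.UNTESTED)


class ScaleTag(str, Enum):
    RAW_COUNT = "raw_count"
    NORMALIZED_COUNT = "normalized_count"
    LOG2 = "log2"
    ZSCORE = "zscore"
    CPM = "cpm"
    LOG10CPM = "log10cpm"


class ExprMatrix:
    """Gene x sample expression values with sample annotations.

    ``scale_tag`` records what the values are (raw counts, normalized counts,
    log2, z-scores, CPM, log10 CPM) so downstream stages can refuse inputs on
    the wrong scale.
    """

    def __init__(
        self,
        values,
        genes: Sequence[str] | None = None,
        samples: Sequence[SampleAnnotation] | Sequence[str] | None = None,
        scale_tag: ScaleTag = ScaleTag.LOG2,
    ):
        if isinstance(values, pd.DataFrame):
            frame = values.astype(float)
            if genes is not None:
                frame.index = list(genes)
            if samples is None:
                samples = [str(c) for c in frame.columns]
        else:
            arr = np.asarray(values, dtype=float)
            if genes is None or samples is None:
                raise ValueError("genes and samples required for array input")
            ids = [s.sample_id if isinstance(s, SampleAnnotation) else str(s) for s in samples]
            frame = pd.DataFrame(arr, index=list(genes), columns=ids)
        self.samples = [
            s if isinstance(s, SampleAnnotation) else SampleAnnotation(sample_id=str(s))
            for s in samples
        ]
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample IDs must be unique")
        if list(frame.columns) != ids:
            frame.columns = ids
        if frame.index.has_duplicates:
            dupes = sorted(frame.index[frame.index.duplicated()].unique())
            raise ValueError(f"duplicate gene symbols: {dupes}")
        if frame.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.values = frame
        self.scale_tag = ScaleTag(scale_tag)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def annotation_frame(self) -> pd.DataFrame:
        """Sample annotations in long form (one row per sample x drug)."""
        rows = []
        for s in self.samples:
            base = {
                "sample_id": s.sample_id,
                "pdx_id": s.pdx_id,
                "model": s.model.value if s.model else "",
            }
            if s.responses:
                for drug, resp in s.responses.items():
                    rows.append({**base, "drug": drug, "response": resp.value})
            else:
                rows.append({**base, "drug": "", "response": ""})
        return pd.DataFrame(rows)

    def subset_genes(self, genes: Iterable[str]) -> "ExprMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExprMatrix(self.values.loc[genes], samples=self.samples, scale_tag=self.scale_tag)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExprMatrix":
        keep = list(sample_ids)
        by_id = {s.sample_id: s for s in self.samples}
        return ExprMatrix(
            self.values[keep],
            samples=[by_id[i] for i in keep],
            scale_tag=self.scale_tag,
        )

    def with_values(self, frame: pd.DataFrame, scale_tag: ScaleTag) -> "ExprMatrix":
        return ExprMatrix(frame, samples=self.samples, scale_tag=scale_tag)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExprMatrix({len(self.genes)} genes x {len(self.sample_ids)} samples, "
            f"scale={self.scale_tag.value})"
        )


@dataclass
class Signature:
    """A named gene list with free-text provenance."""

    name: str
    genes: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)
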