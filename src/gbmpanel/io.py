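"""Readers and writers for the panel's file formats.

Supported formats: NanoString RCC lane files (text, tagged sections), TSV/CSV
gene x sample matrices, GMT-style signature lists, and a long-form sample
annotation table (``sample_id, pdx_id, model, drug, response``).

The RCC dialect implemented is the publicly documented one: sections wrapped
in ``<Section_Name>`` / ``</Section_Name>`` tags, comma-separated rows, and a
``Code_Summary`` section with ``CodeClass,Name,Accession,Count`` columns.
Trailing blank lines and Windows line endings are tolerated.  Binary RLF
codeset files are not parsed; probe classes must arrive via RCC CodeClass or
a sidecar probe table.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

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
    "FormatError",
    "read_rcc",
    "write_rcc",
    "merge_lanes",
    "read_matrix",
    "write_matrix",
    "read_counts",
    "write_counts",
    "read_annotations",
    "write_annotations",
    "read_signatures",
    "write_signatures",
]


class FormatError(ValueError):
    """A file does not conform to its expected format."""


# ---------------------------------------------------------------------------
# RCC lane files
# ---------------------------------------------------------------------------

def _parse_rcc_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for raw in text.splitlines():
        line = raw.rstrip("\r")
        stripped = line.strip()
        if stripped.startswith("<") and stripped.endswith(">"):
            tag = stripped[1:-1]
            if tag.startswith("/"):
                current = None
            else:
                current = tag
                sections[current] = []
            continue
        if current is not None:
            sections[current].append(line)
    return sections


def read_rcc(path: str | Path) -> tuple[CountMatrix, dict[str, str]]:
    """Read one RCC lane file into a single-lane :class:`CountMatrix`.

    Returns the counts plus a flat metadata dict merged from the Header,
    Sample_Attributes and Lane_Attributes sections.  Unknown CodeClass values
    are mapped to Endogenous with a warning.
    """
    path = Path(path)
    sections = _parse_rcc_sections(path.read_text())
    if "Code_Summary" not in sections:
        raise FormatError(f"{path}: missing Code_Summary section")

    meta: dict[str, str] = {}
    for sec in ("Header", "Sample_Attributes", "Lane_Attributes"):
        for line in sections.get(sec, []):
            if "," in line:
                key, _, value = line.partition(",")
                if key:
                    meta[f"{sec}.{key}"] = value

    probes: list[ProbeInfo] = []
    counts: list[float] = []
    rows = [l for l in sections["Code_Summary"] if l.strip()]
    if rows and rows[0].replace(" ", "").lower().startswith("codeclass,"):
        rows = rows[1:]
    for line in rows:
        parts = line.split(",")
        if len(parts) < 4:
            raise FormatError(f"{path}: malformed Code_Summary row: {line!r}")
        code_class, name, accession = parts[0], parts[1], parts[2]
        count_str = ",".join(parts[3:])
        try:
            cls = ProbeClass(code_class)
        except ValueError:
            warnings.warn(
                f"{path}: unknown CodeClass {code_class!r} for probe {name!r}; "
                "treating as Endogenous"
            )
            cls = ProbeClass.ENDOGENOUS
        try:
            count = float(count_str)
        except ValueError:
            raise FormatError(
                f"{path}: non-numeric Count {count_str!r} in row for probe {name!r}"
            ) from None
        probes.append(ProbeInfo(name=name, probe_class=cls, accession=accession))
        counts.append(count)

    lane_id = (
        meta.get("Sample_Attributes.ID")
        or meta.get("Lane_Attributes.ID")
        or path.stem
    )
    cm = CountMatrix(probes, np.asarray(counts)[:, None], [lane_id])
    return cm, meta


def _format_count(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_rcc(path: str | Path, counts: CountMatrix, meta: dict[str, str] | None = None) -> None:
    """Write a single-lane CountMatrix as an RCC file.

    Integer counts are written without a decimal point, so a read/write cycle
    reproduces the Code_Summary rows of an integer-count fixture exactly.
    """
    if len(counts.lanes) != 1:
        raise ValueError("write_rcc expects a single-lane CountMatrix")
    meta = meta or {}
    lines: list[str] = []
    for sec in ("Header", "Sample_Attributes", "Lane_Attributes"):
        entries = {
            k.split(".", 1)[1]: v for k, v in meta.items() if k.startswith(sec + ".")
        }
        if sec == "Sample_Attributes" and "ID" not in entries:
            entries["ID"] = counts.lanes[0]
        lines.append(f"<{sec}>")
        lines.extend(f"{k},{v}" for k, v in entries.items())
        lines.append(f"</{sec}>")
        lines.append("")
    lines.append("<Code_Summary>")
    lines.append("CodeClass,Name,Accession,Count")
    col = counts.counts.iloc[:, 0]
    for probe in counts.probes:
        lines.append(
            f"{probe.probe_class.value},{probe.name},{probe.accession},"
            f"{_format_count(col[probe.name])}"
        )
    lines.append("</Code_Summary>")
    Path(path).write_text("\n".join(lines) + "\n")


def merge_lanes(lanes: Sequence[CountMatrix]) -> CountMatrix:
    """Column-bind single-lane CountMatrices sharing one probe list.

    Lane IDs are kept in input order; duplicates are deduplicated by
    suffixing ``_2``, ``_3``, ...
    """
    if not lanes:
        raise ValueError("no lanes to merge")
    ref = [(p.name, p.probe_class) for p in lanes[0].probes]
    for i, lane in enumerate(lanes[1:], start=2):
        probes = [(p.name, p.probe_class) for p in lane.probes]
        if probes != ref:
            mism = next(
                (j for j, (a, b) in enumerate(zip(ref, probes)) if a != b),
                min(len(ref), len(probes)),
            )
            raise ValueError(
                f"lane {i} probe list differs from lane 1 at position {mism}"
            )
    seen: dict[str, int] = {}
    ids: list[str] = []
    for lane in lanes:
        lid = lane.lanes[0]
        if lid in seen:
            seen[lid] += 1
            lid = f"{lid}_{seen[lid]}"
        else:
            seen[lid] = 1
        ids.append(lid)
    mat = np.column_stack([lane.counts.iloc[:, 0].to_numpy() for lane in lanes])
    return CountMatrix(lanes[0].probes, mat, ids)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    # round_trip parsing so write/read cycles are lossless at full precision
    return pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")


def read_matrix(
    path: str | Path,
    annotations_path: str | Path | None = None,
    scale_tag: ScaleTag = ScaleTag.LOG2,
) -> ExprMatrix:
    """Read a gene x sample TSV/CSV matrix, optionally joining annotations.

    The annotation join is a left join on ``sample_id``: samples without an
    annotation row get empty line/model and untested drug responses;
    annotation rows for unknown samples are dropped with a warning.
    """
    frame = _read_table(path)
    if frame.index.has_duplicates:
        dupes = sorted(frame.index[frame.index.duplicated()].unique())
        raise FormatError(f"{path}: duplicate gene symbols: {dupes}")
    samples: list[SampleAnnotation]
    if annotations_path is not None:
        ann = read_annotations(annotations_path)
        known = {a.sample_id: a for a in ann}
        extra = sorted(set(known) - set(map(str, frame.columns)))
        if extra:
            warnings.warn(f"annotation rows for samples absent from matrix dropped: {extra}")
        samples = [
            known.get(str(c), SampleAnnotation(sample_id=str(c))) for c in frame.columns
        ]
    else:
        samples = [SampleAnnotation(sample_id=str(c)) for c in frame.columns]
    return ExprMatrix(frame, samples=samples, scale_tag=scale_tag)


def write_matrix(path: str | Path, expr: ExprMatrix) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    # %.17g round-trips IEEE doubles exactly
    expr.values.to_csv(path, sep=sep, index_label="gene", float_format="%.17g")


def read_counts(path: str | Path, probes_path: str | Path) -> CountMatrix:
    """Read a probe x lane count matrix with a sidecar probe-class table.

    The probe table needs columns ``name`` and ``probe_class`` (``accession``
    optional); every matrix row must be described.
    """
    frame = _read_table(path)
    if frame.index.has_duplicates:
        dupes = sorted(frame.index[frame.index.duplicated()].unique())
        raise FormatError(f"{path}: duplicate probe names: {dupes}")
    sep = "," if str(probes_path).endswith(".csv") else "\t"
    table = pd.read_csv(probes_path, sep=sep, dtype=str).fillna("")
    info = {
        row["name"]: ProbeInfo(
            name=row["name"],
            probe_class=ProbeClass(row["probe_class"]),
            accession=row.get("accession", ""),
        )
        for _, row in table.iterrows()
    }
    missing = [n for n in frame.index if n not in info]
    if missing:
        raise FormatError(f"{probes_path}: no probe class for: {missing}")
    probes = [info[n] for n in frame.index]
    return CountMatrix(probes, frame.to_numpy(), [str(c) for c in frame.columns])


def write_counts(path: str | Path, counts: CountMatrix, probes_path: str | Path | None = None) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    counts.counts.to_csv(path, sep=sep, index_label="probe", float_format="%.17g")
    if probes_path is not None:
        counts.probe_table().to_csv(probes_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read the long-form annotation table into SampleAnnotation records."""
    sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    required = {"sample_id"}
    if not required <= set(table.columns):
        raise FormatError(f"{path}: annotation table needs columns {sorted(required)}")
    out: dict[str, SampleAnnotation] = {}
    for _, row in table.iterrows():
        sid = row["sample_id"]
        if sid not in out:
            model = row.get("model", "")
            out[sid] = SampleAnnotation(
                sample_id=sid,
                pdx_id=row.get("pdx_id", ""),
                model=ModelType(model) if model else None,
            )
        drug = row.get("drug", "")
        resp = row.get("response", "")
        if drug and resp:
            out[sid].responses[drug] = Response(resp)
    return list(out.values())


def write_annotations(path: str | Path, samples: Sequence[SampleAnnotation]) -> None:
    rows = []
    for s in samples:
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
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Signatures (GMT-style)
# ---------------------------------------------------------------------------

def read_signatures(path: str | Path) -> list[Signature]:
    """Read GMT-style signature lines: ``name TAB source TAB gene1 TAB ...``."""
    out: list[Signature] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        name, source = fields[0], fields[1]
        genes: list[str] = []
        for g in fields[2:]:
            g = g.strip()
            if not g:
                continue
            if g in genes:
                warnings.warn(f"{path}:{lineno}: duplicate gene {g!r} in {name!r} dropped")
                continue
            genes.append(g)
        out.append(Signature(name=name, genes=genes, source=source))
    return out


def write_signatures(path: str | Path, signatures: Sequence[Signature]) -> None:
    lines = [
        "\t".join([s.name, s.source, *s.genes]) for s in signatures
    ]
    Path(path).write_text("\n".join(lines) + "\n")
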