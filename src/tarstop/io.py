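"""Readers and writers for datasets and screening traces.

Datasets travel as JSON-lines or CSV with columns ``id, title,
abstract, label``; traces as a single JSON document per run.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Literal

from .types import Dataset, Record, ScoreSnapshot, ScreeningTrace, ValidationError

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_trace",
    "write_trace",
]

_REQUIRED_FIELDS = ("id", "title", "abstract", "label")


class FormatError(ValueError):
    """Raised when an input file does not match the expected schema."""


def _coerce_label(raw, where: str) -> int:
    # strict {0,1}: accepts ints, bools and the strings "0"/"1" only
    if isinstance(raw, bool):
        return int(raw)
    if isinstance(raw, int) and raw in (0, 1):
        return raw
    if isinstance(raw, str) and raw.strip() in ("0", "1"):
        return int(raw.strip())
    raise ValidationError(f"{where}: label must be 0 or 1, got {raw!r}")


def _record_from_mapping(obj: dict, where: str) -> Record:
    for f in _REQUIRED_FIELDS:
        if f not in obj or obj[f] is None:
            raise FormatError(f"{where}: missing required field {f!r}")
    return Record(
        id=str(obj["id"]),
        title=str(obj["title"]),
        abstract=str(obj["abstract"]),
        label=_coerce_label(obj["label"], where),
    )


def read_dataset(
    path: str | Path, format: Literal["jsonl", "csv"] | None = None, name: str | None = None
) -> Dataset:
    """Read a labeled screening dataset from JSONL or CSV.

    The format is inferred from the file suffix when not given. Input
    order is preserved; labels are coerced strictly to {0, 1}.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    records: list[Record] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise FormatError(f"{path}:{lineno}: invalid JSON ({exc})") from exc
                records.append(_record_from_mapping(obj, f"{path}:{lineno}"))
    elif format == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise FormatError(f"{path}: empty CSV (header required)")
            missing = set(_REQUIRED_FIELDS) - set(reader.fieldnames)
            if missing:
                raise FormatError(f"{path}: header missing column(s) {sorted(missing)}")
            for lineno, row in enumerate(reader, 2):
                records.append(_record_from_mapping(row, f"{path}:{lineno}"))
    else:
        raise ValueError(f"unknown format {format!r}")
    return Dataset(records=records, name=name or path.stem)


def write_dataset(dataset: Dataset, path: str | Path, format: Literal["jsonl", "csv"] | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in dataset.records:
                fh.write(
                    json.dumps(
                        {"id": r.id, "title": r.title, "abstract": r.abstract, "label": r.label},
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_REQUIRED_FIELDS)
            for r in dataset.records:
                writer.writerow([r.id, r.title, r.abstract, r.label])
    else:
        raise ValueError(f"unknown format {format!r}")


def write_trace(trace: ScreeningTrace, path: str | Path) -> None:
    """Serialize a trace as one JSON document."""
    doc = {
        "dataset_name": trace.dataset_name,
        "seed": trace.seed,
        "init_size": trace.init_size,
        "order": list(trace.order),
        "labels_in_order": [int(x) for x in trace.labels_in_order],
        "iteration_boundaries": list(trace.iteration_boundaries),
        "snapshots": [
            {
                "iteration": s.iteration,
                "taken_after": s.taken_after,
                "scores": {k: float(v) for k, v in s.scores.items()},
            }
            for s in trace.snapshots
        ],
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def read_trace(path: str | Path) -> ScreeningTrace:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    try:
        return ScreeningTrace(
            dataset_name=doc["dataset_name"],
            order=list(doc["order"]),
            labels_in_order=doc["labels_in_order"],
            init_size=int(doc["init_size"]),
            seed=int(doc.get("seed", 0)),
            iteration_boundaries=[int(x) for x in doc.get("iteration_boundaries", [])],
            snapshots=[
                ScoreSnapshot(
                    iteration=int(s["iteration"]),
                    taken_after=int(s["taken_after"]),
                    scores={k: float(v) for k, v in s["scores"].items()},
                )
                for s in doc.get("snapshots", [])
            ],
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing trace field {exc}") from exc
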