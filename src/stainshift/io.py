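"""Readers/writers for annotations, label sets and manifests, plus the
reproducible Monte-Carlo dataset splitter.

Annotations are stored as JSON lines (one object per line, sorted keys) with
a CSV export using the header ``image_id,rater_id,study_phase,x,y,cls``.
All JSON output is byte-stable: sorted keys, fixed float formatting via
``repr`` of Python floats.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .datamodel import LabelSet, PointAnnotation, Split

_FIELDS = ("image_id", "rater_id", "study_phase", "x", "y", "cls")


class AnnotationFormatError(ValueError):
    """Malformed annotation row; message names the line and field."""


def write_annotations(annotations: list[PointAnnotation], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(json.dumps(
                {"image_id": a.image_id, "rater_id": a.rater_id,
                 "study_phase": a.study_phase, "x": float(a.x), "y": float(a.y),
                 "cls": a.cls}, sort_keys=True) + "\n")


def read_annotations(path: str | Path) -> list[PointAnnotation]:
    path = Path(path)
    out: list[PointAnnotation] = []
    if path.suffix == ".csv":
        return _read_annotations_csv(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                row = json.loads(line)
            except json.JSONDecodeError as exc:
                raise AnnotationFormatError(f"line {lineno}: invalid JSON") from exc
            out.append(_row_to_annotation(row, lineno))
    return out


def _row_to_annotation(row: dict, lineno: int) -> PointAnnotation:
    for f in _FIELDS:
        if f not in row or row[f] == "":
            raise AnnotationFormatError(f"line {lineno}: missing field {f!r}")
    try:
        x = float(row["x"])
        y = float(row["y"])
    except (TypeError, ValueError):
        raise AnnotationFormatError(f"line {lineno}: field 'x'/'y' not numeric")
    try:
        return PointAnnotation(image_id=str(row["image_id"]),
                               rater_id=str(row["rater_id"]),
                               study_phase=str(row["study_phase"]),
                               x=x, y=y, cls=str(row["cls"]))
    except ValueError as exc:
        raise AnnotationFormatError(f"line {lineno}: {exc}") from exc


def write_annotations_csv(annotations: list[PointAnnotation], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FIELDS)
        for a in annotations:
            writer.writerow([a.image_id, a.rater_id, a.study_phase,
                             float(a.x), float(a.y), a.cls])


def _read_annotations_csv(path: Path) -> list[PointAnnotation]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            out.append(_row_to_annotation(row, lineno))
    return out


# ---------------------------------------------------------------------------
# label sets


def write_label_set(label_set: LabelSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"name": label_set.name,
               "points": {img: [[float(x), float(y), int(s)] for x, y, s in pts]
                          for img, pts in sorted(label_set.points.items())}}
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)


def read_label_set(path: str | Path) -> LabelSet:
    with open(path) as fh:
        payload = json.load(fh)
    points = {img: [(float(x), float(y), int(s)) for x, y, s in pts]
              for img, pts in payload["points"].items()}
    return LabelSet(name=payload["name"], points=points)


# ---------------------------------------------------------------------------
# manifest


def write_manifest(path: str | Path, image_entries: list[dict], mpp: float,
                   ground_truth_path: str | None = None) -> None:
    """Dataset manifest: image files, shared mpp, optional ground-truth file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"mpp": mpp, "images": sorted(image_entries, key=lambda e: e["image_id"]),
               "ground_truth": ground_truth_path}
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Monte-Carlo splits


def monte_carlo_splits(image_ids: list[str], n_splits: int = 5,
                       fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                       seed: int = 0) -> list[Split]:
    """Independent random 70/15/15 partitions of the image ids.

    Validation and test sizes are rounded down, the remainder goes to the
    training set; every model configuration is evaluated on the same splits,
    so the function is deterministic in (image_ids order, seed).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids = list(image_ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 images to split")
    rng = np.random.default_rng(seed)
    n = len(ids)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_val, n_test = max(n_val, 1), max(n_test, 1)
    splits = []
    for k in range(n_splits):
        perm = rng.permutation(n)
        shuffled = [ids[i] for i in perm]
        test = tuple(sorted(shuffled[:n_test]))
        val = tuple(sorted(shuffled[n_test:n_test + n_val]))
        train = tuple(sorted(shuffled[n_test + n_val:]))
        splits.append(Split(split_index=k, train=train, val=val, test=test))
    return splits


def write_splits(splits: list[Split], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [{"split_index": s.split_index, "train": list(s.train),
                "val": list(s.val), "test": list(s.test)} for s in splits]
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)


def read_splits(path: str | Path) -> list[Split]:
    with open(path) as fh:
        payload = json.load(fh)
    return [Split(split_index=d["split_index"], train=tuple(d["train"]),
                  val=tuple(d["val"]), test=tuple(d["test"])) for d in payload]
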