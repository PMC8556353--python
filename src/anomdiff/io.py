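"""Delimited-text serialization of datasets, references and predictions.

File dialect (version 1, recorded in every manifest):

* data file — one trajectory per line, semicolon-delimited:
  ``dim;x_0;...;x_{L-1}[;y_0;...][;z_0;...]`` (axis-major coordinates);
* reference file — one line per trajectory: T1 ``alpha``; T2 the model
  index in the fixed order ATTM=0, CTRW=1, FBM=2, LW=3, SBM=4; T3
  ``t_GT;model_1;alpha_1;model_2;alpha_2``;
* prediction file — T1 ``dim;alpha``; T2 ``dim;p0;p1;p2;p3;p4``;
  T3 ``dim;t;alpha_1;model_1;alpha_2;model_2``.

Floats are written with the shortest representation that parses back to the
same IEEE double, so write -> read round-trips bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .models import (
    ChangepointLabel,
    LabeledDataset,
    Model,
    RegularTrajectory,
    Task,
)

__all__ = [
    "FORMAT_VERSION",
    "Task3Prediction",
    "TaskPrediction",
    "write_dataset",
    "read_dataset",
    "write_predictions_t1",
    "read_predictions",
    "write_manifest",
]

FORMAT_VERSION = 1


class FileFormatError(ValueError):
    """Malformed data/reference/prediction file."""


@dataclass(frozen=True)
class Task3Prediction:
    """One parsed T3 prediction record (field names mirror the ground truth)."""

    changepoint: float
    alpha_1: float
    model_1: int
    alpha_2: float
    model_2: int


@dataclass
class TaskPrediction:
    """Parsed submission for one task."""

    task: Task
    # T1: ndarray of alpha; T2: (n, 5) probability matrix; T3: list of Task3Prediction
    values: object

    def __len__(self) -> int:
        return len(self.values)


def _fmt(x: float) -> str:
    # shortest repr that round-trips bit-exactly
    return repr(float(x))


def _data_line(traj: RegularTrajectory) -> str:
    coords = ";".join(_fmt(v) for v in traj.positions.ravel())
    return f"{traj.dim};{coords}"


def _label_line(task: Task, label) -> str:
    if task is Task.T1:
        return _fmt(label)
    if task is Task.T2:
        return str(label.value if isinstance(label, Model) else int(label))
    cp: ChangepointLabel = label
    return ";".join(
        [
            str(cp.changepoint),
            str(cp.model_1.value),
            _fmt(cp.alpha_1),
            str(cp.model_2.value),
            _fmt(cp.alpha_2),
        ]
    )


def write_dataset(
    dataset: LabeledDataset, data_path: str | Path, ref_path: str | Path | None = None
) -> None:
    """Write the trajectory file and (optionally) the reference label file."""
    data_path = Path(data_path)
    with data_path.open("w") as fh:
        for traj in dataset.trajectories:
            fh.write(_data_line(traj) + "\n")
    if ref_path is not None:
        with Path(ref_path).open("w") as fh:
            for label in dataset.labels:
                fh.write(_label_line(dataset.task, label) + "\n")


def _parse_floats(parts: list[str], lineno: int) -> list[float]:
    try:
        return [float(p) for p in parts]
    except ValueError as exc:
        raise FileFormatError(f"line {lineno}: unparseable number ({exc})") from exc


def _read_lines(path: str | Path) -> list[str]:
    with Path(path).open() as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_dataset(
    data_path: str | Path,
    ref_path: str | Path | None = None,
    task: Task | int = Task.T1,
) -> LabeledDataset:
    """Parse a data file (and optional reference file) back into a dataset."""
    task = Task(task) if not isinstance(task, Task) else task
    ds = LabeledDataset(task=task)
    for lineno, line in enumerate(_read_lines(data_path), start=1):
        parts = line.split(";")
        if len(parts) < 3:
            raise FileFormatError(f"line {lineno}: too few fields")
        dim = int(float(parts[0]))
        if dim not in (1, 2, 3):
            raise FileFormatError(f"line {lineno}: dimension must be 1, 2 or 3")
        coords = _parse_floats(parts[1:], lineno)
        if len(coords) % dim != 0:
            raise FileFormatError(
                f"line {lineno}: {len(coords)} coordinates not divisible by dim={dim}"
            )
        length = len(coords) // dim
        ds.trajectories.append(
            RegularTrajectory(np.array(coords).reshape(dim, length))
        )
    if ref_path is not None:
        ds.labels = _read_reference(ref_path, task)
        if len(ds.labels) != len(ds.trajectories):
            raise FileFormatError("data and reference files disagree in length")
    return ds


def _read_reference(path: str | Path, task: Task) -> list:
    labels: list = []
    for lineno, line in enumerate(_read_lines(path), start=1):
        parts = line.split(";")
        if task is Task.T1:
            if len(parts) != 1:
                raise FileFormatError(f"line {lineno}: T1 reference needs 1 field")
            labels.append(_parse_floats(parts, lineno)[0])
        elif task is Task.T2:
            if len(parts) != 1:
                raise FileFormatError(f"line {lineno}: T2 reference needs 1 field")
            labels.append(Model(int(float(parts[0]))))
        else:
            if len(parts) != 5:
                raise FileFormatError(f"line {lineno}: T3 reference needs 5 fields")
            vals = _parse_floats(parts, lineno)
            labels.append(
                ChangepointLabel(
                    changepoint=int(vals[0]),
                    model_1=Model(int(vals[1])),
                    alpha_1=vals[2],
                    model_2=Model(int(vals[3])),
                    alpha_2=vals[4],
                )
            )
    return labels


def reference_as_predictions(labels: list, task: Task) -> TaskPrediction:
    """Turn ground-truth labels into a perfect prediction set (self-scoring)."""
    if task is Task.T1:
        return TaskPrediction(task, np.asarray(labels, dtype=float))
    if task is Task.T2:
        probs = np.zeros((len(labels), 5))
        for i, lab in enumerate(labels):
            probs[i, lab.value if isinstance(lab, Model) else int(lab)] = 1.0
        return TaskPrediction(task, probs)
    preds = [
        Task3Prediction(
            float(l.changepoint), l.alpha_1, l.model_1.value, l.alpha_2, l.model_2.value
        )
        for l in labels
    ]
    return TaskPrediction(task, preds)


def read_predictions(
    path: str | Path, task: Task | int, length: int = 200
) -> TaskPrediction:
    """Parse and validate a prediction file for the given task."""
    task = Task(task) if not isinstance(task, Task) else task
    lines = _read_lines(path)
    if task is Task.T1:
        out = []
        for lineno, line in enumerate(lines, start=1):
            parts = line.split(";")
            if len(parts) != 2:
                raise FileFormatError(f"line {lineno}: T1 prediction needs dim;alpha")
            out.append(_parse_floats(parts, lineno)[1])
        return TaskPrediction(task, np.array(out))
    if task is Task.T2:
        rows = []
        for lineno, line in enumerate(lines, start=1):
            parts = line.split(";")
            if len(parts) != 6:
                raise FileFormatError(
                    f"line {lineno}: T2 prediction needs dim + 5 probabilities"
                )
            probs = np.array(_parse_floats(parts[1:], lineno))
            if np.any(probs < 0):
                raise FileFormatError(f"line {lineno}: negative probability")
            total = probs.sum()
            if total == 0:
                raise FileFormatError(f"line {lineno}: all-zero probability row")
            rows.append(probs / total)
        return TaskPrediction(task, np.array(rows))
    preds = []
    for lineno, line in enumerate(lines, start=1):
        parts = line.split(";")
        if len(parts) != 6:
            raise FileFormatError(
                f"line {lineno}: T3 prediction needs dim;t;alpha1;model1;alpha2;model2"
            )
        vals = _parse_floats(parts, lineno)
        t_hat = vals[1]
        if not (0 <= t_hat <= length):
            raise FileFormatError(
                f"line {lineno}: changepoint {t_hat} outside [0, {length}]"
            )
        for m in (vals[3], vals[5]):
            if int(m) not in range(5):
                raise FileFormatError(f"line {lineno}: model index {m} outside 0..4")
        preds.append(
            Task3Prediction(t_hat, vals[2], int(vals[3]), vals[4], int(vals[5]))
        )
    return TaskPrediction(task, preds)


def write_predictions_t1(alphas, dim: int, path: str | Path) -> None:
    """Write a T1 prediction file (used by the baseline estimator CLI path)."""
    with Path(path).open("w") as fh:
        for a in alphas:
            fh.write(f"{dim};{_fmt(a)}\n")


def write_manifest(path: str | Path, **entries) -> None:
    """JSON manifest sufficient to regenerate a dataset exactly."""
    payload = {"format_version": FORMAT_VERSION, **entries}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
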