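"""Core domain types and I/O for structural connectomes and cognitive scores.

A structural connectivity (SC) matrix is a square, symmetric, non-negative
weighted adjacency with zero diagonal; entry (i, j) quantifies white-matter
connection strength between brain regions i and j (e.g. volume-normalised
streamline counts).  Datasets pair each subject's matrix with a continuous
cognitive score.

On-disk format: one plain delimited square grid per subject (no header),
plus a scores CSV with columns ``subject_id,score`` (and an optional
``synthetic`` flag), plus a JSON manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMatrix",
    "EdgeVector",
    "ScoredSample",
    "ConnectomeDataset",
    "ValidationError",
    "vectorize_lower_triangle",
    "matricize",
    "load_dataset",
    "save_dataset",
    "reorder_nodes",
]

SYMMETRY_TOL = 1e-8
DIAGONAL_TOL = 1e-8


class ValidationError(ValueError):
    """Raised when a connectome or dataset violates its invariants."""


@dataclass(frozen=True)
class ConnectivityMatrix:
    """One subject's symmetric non-negative weighted adjacency."""

    weights: np.ndarray
    node_labels: tuple[str, ...] = ()

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"weights must be square, got shape {w.shape}")
        n = w.shape[0]
        if n < 3:
            raise ValidationError(f"need at least 3 nodes, got {n}")
        if not np.all(np.isfinite(w)):
            bad = np.argwhere(~np.isfinite(w))[0]
            raise ValidationError(f"non-finite weight at {tuple(bad)}")
        asym = np.abs(w - w.T)
        if asym.max() > SYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValidationError(
                f"asymmetry {asym[i, j]:.3g} at ({i}, {j}) exceeds {SYMMETRY_TOL}"
            )
        diag = np.abs(np.diag(w))
        if diag.max() > DIAGONAL_TOL:
            i = int(np.argmax(diag))
            raise ValidationError(f"nonzero diagonal at node {i}: {w[i, i]:.3g}")
        if w.min() < 0:
            i, j = np.unravel_index(np.argmin(w), w.shape)
            raise ValidationError(f"negative weight {w[i, j]:.3g} at ({i}, {j})")
        # absorb float I/O noise after the checks pass
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)
        labels = tuple(self.node_labels) or tuple(f"node{i}" for i in range(n))
        if len(labels) != n:
            raise ValidationError(
                f"{len(labels)} labels for {n} nodes"
            )
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    def strength(self) -> np.ndarray:
        """Node strength (weighted degree)."""
        return self.weights.sum(axis=1)


@dataclass(frozen=True)
class EdgeVector:
    """Strict-lower-triangle edge weights in fixed row-major order.

    Ordering: rows i = 1..n-1, columns j = 0..i-1 (0-based), i.e.
    (1,0), (2,0), (2,1), (3,0), ...
    """

    values: np.ndarray
    n_nodes: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64).ravel()
        expected = self.n_nodes * (self.n_nodes - 1) // 2
        if v.size != expected:
            raise ValidationError(
                f"edge vector length {v.size} != {expected} for n={self.n_nodes}"
            )
        v.flags.writeable = False
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ScoredSample:
    matrix: ConnectivityMatrix
    score: float
    subject_id: str
    synthetic: bool = False

    def __post_init__(self):
        if not np.isfinite(self.score):
            raise ValidationError(f"non-finite score for {self.subject_id}")


@dataclass(frozen=True)
class ConnectomeDataset:
    samples: tuple[ScoredSample, ...]
    atlas_name: str = "generic"

    def __post_init__(self):
        samples = tuple(self.samples)
        if not samples:
            raise ValidationError("dataset must contain at least one sample")
        n = samples[0].matrix.n_nodes
        labels = samples[0].matrix.node_labels
        ids = set()
        for s in samples:
            if s.matrix.n_nodes != n:
                raise ValidationError(
                    f"node count mismatch for {s.subject_id}: {s.matrix.n_nodes} != {n}"
                )
            if s.matrix.node_labels != labels:
                raise ValidationError(f"node labels differ for {s.subject_id}")
            if s.subject_id in ids:
                raise ValidationError(f"duplicate subject_id {s.subject_id!r}")
            ids.add(s.subject_id)
        object.__setattr__(self, "samples", samples)

    def __len__(self):
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, idx):
        return self.samples[idx]

    @property
    def n_nodes(self) -> int:
        return self.samples[0].matrix.n_nodes

    @property
    def scores(self) -> np.ndarray:
        return np.array([s.score for s in self.samples])

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(s.subject_id for s in self.samples)

    def matrices(self) -> np.ndarray:
        """Stacked weights, shape (n_subjects, n_nodes, n_nodes)."""
        return np.stack([s.matrix.weights for s in self.samples])

    def edge_matrix(self) -> np.ndarray:
        """Vectorized edges, shape (n_subjects, n_edges)."""
        return np.stack(
            [vectorize_lower_triangle(s.matrix).values for s in self.samples]
        )

    def subset(self, indices) -> "ConnectomeDataset":
        return ConnectomeDataset(
            tuple(self.samples[i] for i in indices), atlas_name=self.atlas_name
        )

    def originals(self) -> "ConnectomeDataset":
        return ConnectomeDataset(
            tuple(s for s in self.samples if not s.synthetic),
            atlas_name=self.atlas_name,
        )


def _tri_indices(n: int):
    # row-major over the strict lower triangle: i from 1..n-1, j < i
    return np.tril_indices(n, k=-1)


def vectorize_lower_triangle(m: ConnectivityMatrix) -> EdgeVector:
    """Extract the strict lower triangle in the fixed row-major ordering."""
    rows, cols = _tri_indices(m.n_nodes)
    return EdgeVector(values=m.weights[rows, cols], n_nodes=m.n_nodes)


def edge_count_to_n_nodes(n_edges: int) -> int:
    n = int((1 + np.sqrt(1 + 8 * n_edges)) / 2)
    if n * (n - 1) // 2 != n_edges:
        raise ValidationError(f"{n_edges} is not a triangular number")
    return n


def matricize(v: EdgeVector | np.ndarray, node_labels=()) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize_lower_triangle`; symmetric, zero diagonal."""
    if isinstance(v, EdgeVector):
        values, n = v.values, v.n_nodes
    else:
        values = np.asarray(v, dtype=np.float64).ravel()
        n = edge_count_to_n_nodes(values.size)
    w = np.zeros((n, n))
    rows, cols = _tri_indices(n)
    w[rows, cols] = values
    w = w + w.T
    return ConnectivityMatrix(weights=w, node_labels=node_labels)


def reorder_nodes(m: ConnectivityMatrix, permutation: Sequence[int]) -> ConnectivityMatrix:
    """Apply a node permutation: w'(i, j) = w(p(i), p(j))."""
    p = np.asarray(permutation, dtype=int)
    n = m.n_nodes
    if p.shape != (n,) or sorted(p.tolist()) != list(range(n)):
        raise ValidationError("permutation must be a bijection on 0..n-1")
    w = m.weights[np.ix_(p, p)]
    labels = tuple(m.node_labels[i] for i in p)
    return ConnectivityMatrix(weights=w, node_labels=labels)


def _read_matrix_file(path: Path) -> np.ndarray:
    text = Path(path).read_text().strip()
    delimiter = "," if "," in text.splitlines()[0] else None
    try:
        w = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    return w


def load_dataset(
    matrix_paths: Sequence[str | Path] | dict[str, str | Path],
    scores_table: str | Path,
    atlas_name: str = "generic",
) -> ConnectomeDataset:
    """Load matrices plus a scores CSV into a dataset.

    ``matrix_paths`` may be a mapping subject_id -> path, or a sequence whose
    file stems are the subject ids.  Sample order follows the scores table.
    """
    table = pd.read_csv(scores_table, float_precision="round_trip")
    if not {"subject_id", "score"} <= set(table.columns):
        raise ValidationError("scores table needs columns subject_id,score")
    if isinstance(matrix_paths, dict):
        path_by_id = {str(k): Path(v) for k, v in matrix_paths.items()}
    else:
        path_by_id = {Path(p).stem: Path(p) for p in matrix_paths}
    samples = []
    shape = None
    for _, row in table.iterrows():
        sid = str(row["subject_id"])
        if sid not in path_by_id:
            raise ValidationError(f"no matrix file for subject {sid!r}")
        w = _read_matrix_file(path_by_id[sid])
        if shape is None:
            shape = w.shape
        elif w.shape != shape:
            raise ValidationError(
                f"shape mismatch for {sid!r}: {w.shape} != {shape}"
            )
        samples.append(
            ScoredSample(
                matrix=ConnectivityMatrix(weights=w),
                score=float(row["score"]),
                subject_id=sid,
                synthetic=bool(row.get("synthetic", False)),
            )
        )
    return ConnectomeDataset(tuple(samples), atlas_name=atlas_name)


def save_dataset(d: ConnectomeDataset, out_dir: str | Path) -> Path:
    """Write one matrix file per subject, a scores CSV and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in d.samples:
        fname = f"{s.subject_id}.csv"
        np.savetxt(out / fname, s.matrix.weights, delimiter=",", fmt="%.17g")
        rows.append(
            {"subject_id": s.subject_id, "score": s.score, "synthetic": s.synthetic}
        )
    pd.DataFrame(rows).to_csv(out / "scores.csv", index=False)
    manifest = {
        "atlas_name": d.atlas_name,
        "n_subjects": len(d),
        "n_nodes": d.n_nodes,
        "node_labels": list(d.samples[0].matrix.node_labels),
        "scores": "scores.csv",
        "matrices": [f"{s.subject_id}.csv" for s in d.samples],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_dataset_dir(directory: str | Path) -> ConnectomeDataset:
    """Load a dataset previously written by :func:`save_dataset`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    table = directory / manifest["scores"]
    ids = [Path(p).stem for p in manifest["matrices"]]
    paths = {sid: directory / p for sid, p in zip(ids, manifest["matrices"])}
    ds = load_dataset(paths, table, atlas_name=manifest.get("atlas_name", "generic"))
    labels = manifest.get("node_labels")
    if labels:
        samples = tuple(
            replace(
                s,
                matrix=ConnectivityMatrix(
                    weights=s.matrix.weights, node_labels=tuple(labels)
                ),
            )
            for s in ds.samples
        )
        ds = ConnectomeDataset(samples, atlas_name=ds.atlas_name)
    return ds
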