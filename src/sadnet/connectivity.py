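"""Signed functional-connectivity matrices from ROI signals."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .timeseries import RoiTimeSeriesSet


@dataclass
class ConnectivityMatrix:
    """Symmetric signed Pearson matrix over ROIs with metadata."""

    values: np.ndarray
    roi_order: list[str]
    subject_id: str
    paradigm: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.roi_order = list(self.roi_order)
        n = len(self.roi_order)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match roi_order")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-8):
            raise ValueError("connectivity matrix must have unit diagonal")
        if np.abs(self.values).max() > 1.0 + 1e-8:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_rois(self) -> int:
        return len(self.roi_order)

    def off_diagonal(self) -> np.ndarray:
        """Copy with the self-correlations zeroed (graph-analysis input)."""
        out = self.values.copy()
        np.fill_diagonal(out, 0.0)
        return out

    def to_tsv(self, path) -> None:
        frame = pd.DataFrame(self.values, index=self.roi_order, columns=self.roi_order)
        frame.to_csv(path, sep="\t", float_format="%.10g")
        sidecar = Path(path).with_suffix(".json")
        with open(sidecar, "w") as fh:
            json.dump(
                {"subject_id": self.subject_id, "paradigm": self.paradigm},
                fh,
                sort_keys=True,
            )

    @classmethod
    def from_tsv(cls, path) -> "ConnectivityMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        sidecar = Path(path).with_suffix(".json")
        meta = {"subject_id": "unknown", "paradigm": "unknown"}
        if sidecar.exists():
            with open(sidecar) as fh:
                meta.update(json.load(fh))
        return cls(
            values=frame.to_numpy(dtype=float),
            roi_order=list(frame.columns),
            subject_id=meta["subject_id"],
            paradigm=meta["paradigm"],
        )


def correlation_matrix(ts: RoiTimeSeriesSet) -> ConnectivityMatrix:
    """Pearson correlation between every pair of ROI signals.

    All time points of the paradigm enter a single correlation per pair.
    A zero-variance column is an error naming the offending ROI.
    """
    variances = ts.data.var(axis=0)
    dead = np.flatnonzero(variances <= 1e-300)
    if len(dead):
        names = [ts.roi_order[i] for i in dead]
        raise ValueError(f"zero-variance ROI signal(s): {names}")
    values = np.corrcoef(ts.data, rowvar=False)
    values = np.clip(0.5 * (values + values.T), -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return ConnectivityMatrix(
        values=values,
        roi_order=ts.roi_order,
        subject_id=ts.subject_id,
        paradigm=ts.paradigm,
    )


def group_mean_matrix(
    matrices: list[ConnectivityMatrix], fisher: bool = False
) -> ConnectivityMatrix:
    """Entrywise mean of subject matrices.

    Plain averaging of r by default.  ``fisher=True`` averages
    arctanh(r) and transforms back (diagonal handled separately).
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    roi_order = matrices[0].roi_order
    paradigms = {m.paradigm for m in matrices}
    for m in matrices:
        if m.roi_order != roi_order:
            raise ValueError(
                f"mixed ROI orders: {m.subject_id} differs from {matrices[0].subject_id}"
            )
    stack = np.stack([m.values for m in matrices])
    if fisher:
        clipped = np.clip(stack, -1 + 1e-12, 1 - 1e-12)
        mean = np.tanh(np.arctanh(clipped).mean(axis=0))
    else:
        mean = stack.mean(axis=0)
    np.fill_diagonal(mean, 1.0)
    return ConnectivityMatrix(
        values=mean,
        roi_order=roi_order,
        subject_id="group-mean",
        paradigm=paradigms.pop() if len(paradigms) == 1 else "mixed",
    )


def edge_groups(matrix: ConnectivityMatrix, partition: np.ndarray) -> dict:
    """Split the undirected edges into intra- and inter-community groups.

    Returns one entry per community ("intra-<label>") plus "inter",
    each with the edge index pairs, their r values, count, mean and SEM.
    The groups are disjoint and exhaust all n(n-1)/2 edges.
    """
    partition = np.asarray(partition)
    n = matrix.n_rois
    if partition.shape != (n,):
        raise ValueError("partition must label every node")
    values = matrix.values
    groups: dict[str, dict] = {}

    def _put(key: str, i: int, j: int) -> None:
        entry = groups.setdefault(key, {"edges": [], "values": []})
        entry["edges"].append((i, j))
        entry["values"].append(float(values[i, j]))

    for i in range(n):
        for j in range(i + 1, n):
            if partition[i] == partition[j]:
                _put(f"intra-{partition[i]}", i, j)
            else:
                _put("inter", i, j)
    for entry in groups.values():
        vals = np.asarray(entry["values"])
        entry["count"] = len(vals)
        entry["mean"] = float(vals.mean())
        entry["sem"] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
    return groups
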