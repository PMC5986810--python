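"""Container and TSV round-trip for ROI time-series matrices."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class RoiTimeSeriesSet:
    """One subject x paradigm matrix of ROI signals.

    ``data`` is (n_volumes, n_rois) in arbitrary BOLD units, sampled
    every ``tr`` seconds; column ``j`` is the ROI named
    ``roi_order[j]``.  ``processing`` records which conditioning steps
    have already been applied, in order.
    """

    subject_id: str
    paradigm: str
    data: np.ndarray
    tr: float
    roi_order: list[str]
    processing: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.roi_order = list(self.roi_order)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_volumes, n_rois)")
        n_vol, n_roi = self.data.shape
        if n_vol < 8:
            raise ValueError(f"need at least 8 volumes, got {n_vol}")
        if n_roi != len(self.roi_order):
            raise ValueError(
                f"{n_roi} columns but {len(self.roi_order)} ROI names"
            )
        if len(set(self.roi_order)) != len(self.roi_order):
            raise ValueError("duplicate ROI names in roi_order")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contains NaN or infinite values")
        if self.tr <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray, extra_steps: list[str]) -> "RoiTimeSeriesSet":
        return RoiTimeSeriesSet(
            subject_id=self.subject_id,
            paradigm=self.paradigm,
            data=np.asarray(data, dtype=float),
            tr=self.tr,
            roi_order=list(self.roi_order),
            processing=self.processing + list(extra_steps),
        )

    def to_tsv(self, path) -> None:
        """Write header = ROI abbreviations, one row per volume."""
        frame = pd.DataFrame(self.data, columns=self.roi_order)
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, subject_id: str, paradigm: str, tr: float) -> "RoiTimeSeriesSet":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t")
        return cls(
            subject_id=subject_id,
            paradigm=paradigm,
            data=frame.to_numpy(dtype=float),
            tr=tr,
            roi_order=list(frame.columns),
        )
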