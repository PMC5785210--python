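"""Fluorescence trace container shared by the imaging, detection and
synthetic layers."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

VALID_KINDS = ("raw", "dff", "normalized")

#: Longest tolerated run of dropped (NaN) frames, in seconds.
MAX_DROPPED_RUN_S = 1.0


class TraceError(ValueError):
    """Invalid trace data or metadata."""


@dataclass
class FluorescenceTrace:
    """One region's fluorescence time series.

    Parameters
    ----------
    values
        Samples, arbitrary fluorescence units for ``kind="raw"`` or
        dimensionless for ``kind="dff"`` / ``"normalized"``.  NaN marks a
        dropped frame.
    frame_rate
        Acquisition rate in Hz (10 Hz for the slice-imaging protocol this
        package targets).
    t0
        Time of the first sample in seconds from recording start.
    kind
        One of ``raw``, ``dff``, ``normalized``.
    region, condition
        Region-of-interest label (e.g. ``DGH``, ``CA3``) and
        genotype/condition label, carried through the pipeline.
    drug_onset
        Time of convulsant application in seconds, if known.
    """

    values: np.ndarray
    frame_rate: float
    t0: float = 0.0
    kind: str = "raw"
    region: Optional[str] = None
    condition: Optional[str] = None
    drug_onset: Optional[float] = None
    trace_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise TraceError("trace values must be one-dimensional")
        if not self.frame_rate > 0:
            raise TraceError(f"frame_rate must be positive, got {self.frame_rate}")
        if self.kind not in VALID_KINDS:
            raise TraceError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Recording length in seconds (n_frames / frame_rate)."""
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return self.t0 + np.arange(self.n_frames) / self.frame_rate

    def with_values(self, values: np.ndarray, kind: Optional[str] = None) -> "FluorescenceTrace":
        """Copy of this trace with new samples (metadata preserved)."""
        return replace(self, values=np.asarray(values, dtype=np.float64),
                       kind=self.kind if kind is None else kind)

    def max_dropped_run_s(self) -> float:
        """Length in seconds of the longest run of NaN samples."""
        isnan = np.isnan(self.values)
        if not isnan.any():
            return 0.0
        # run-length encode the NaN mask
        edges = np.flatnonzero(np.diff(isnan.astype(np.int8)))
        starts = np.r_[0, edges + 1]
        ends = np.r_[edges + 1, isnan.size]
        runs = (ends - starts)[isnan[starts]]
        return float(runs.max()) / self.frame_rate

    def check_dropped_frames(self) -> None:
        """Raise if dropped-frame runs exceed the tolerated length."""
        worst = self.max_dropped_run_s()
        if worst > MAX_DROPPED_RUN_S:
            raise TraceError(
                f"run of {worst:.2f} s of dropped frames exceeds the "
                f"{MAX_DROPPED_RUN_S:.0f} s tolerance"
            )
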