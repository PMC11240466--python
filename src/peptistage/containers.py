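"""Core in-memory containers shared across the pipeline.

An :class:`MSMap` is a per-sample sparse MS1 centroid cloud — the (retention
time, m/z, intensity) triples left after instrument-side centroiding.  A
:class:`MarkerTable` is the samples x markers matrix of normalized intensities
that the differential screen and panel selection operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MSMap", "MarkerTable", "SCAN_RANGE"]

# Default positive-ion survey scan range, Da.
SCAN_RANGE = (500.0, 2500.0)


@dataclass
class MSMap:
    """Sparse MS1 centroid cloud for one sample.

    rt is in seconds, mz in Da, intensity a non-negative ion count.
    """

    sample_id: str
    rt: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray
    scan_range: tuple[float, float] = SCAN_RANGE

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (self.rt.shape == self.mz.shape == self.intensity.shape):
            raise ValueError("rt, mz, intensity must have the same length")
        if self.rt.size and self.rt.min() < 0:
            raise ValueError("retention times must be non-negative")
        if self.intensity.size and self.intensity.min() < 0:
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.rt.size

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def sorted_by_rt(self) -> "MSMap":
        order = np.argsort(self.rt, kind="stable")
        return MSMap(
            self.sample_id,
            self.rt[order],
            self.mz[order],
            self.intensity[order],
            self.scan_range,
        )


@dataclass
class MarkerTable:
    """Samples x markers matrix of (normalized) marker intensities.

    ``markers`` carries one row per marker: serial, mz, z and the consensus
    rt of the extraction window.  ``matrix`` is indexed by sample_id with one
    column per marker serial.  ``missing`` flags cells where no peak was found
    (raw intensity 0); downstream tests may drop flagged cells.
    """

    markers: pd.DataFrame  # columns: serial, mz, z, rt
    matrix: pd.DataFrame  # index: sample_id; columns: marker serial
    labels: pd.Series  # sample_id -> "early" | "late"
    batches: pd.Series  # sample_id -> batch id
    missing: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.matrix.columns) != list(self.markers["serial"]):
            raise ValueError("matrix columns must match marker serials in order")
        if self.markers["serial"].duplicated().any():
            raise ValueError("marker serials must be unique")
        if not np.isfinite(self.matrix.to_numpy()).all():
            raise ValueError("marker matrix must be finite")
        self.labels = self.labels.reindex(self.matrix.index)
        self.batches = self.batches.reindex(self.matrix.index)
        if self.labels.isna().any():
            raise ValueError("every sample needs a stage label")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_markers(self) -> int:
        return self.matrix.shape[1]

    def values_by_class(self, serial) -> tuple[np.ndarray, np.ndarray]:
        """(early values, late values) for one marker, missing cells dropped."""
        col = self.matrix[serial]
        keep = pd.Series(True, index=col.index)
        if self.missing is not None:
            keep = ~self.missing[serial].astype(bool)
        early = col[(self.labels == "early") & keep].to_numpy(dtype=float)
        late = col[(self.labels == "late") & keep].to_numpy(dtype=float)
        return early, late

    def subset(self, serials) -> "MarkerTable":
        serials = list(serials)
        mk = self.markers.set_index("serial").loc[serials].reset_index()
        miss = self.missing[serials] if self.missing is not None else None
        return MarkerTable(mk, self.matrix[serials].copy(), self.labels, self.batches, miss)

    def to_csv(self, path) -> None:
        out = self.matrix.copy()
        out.insert(0, "stage", self.labels)
        out.insert(1, "batch", self.batches)
        out.index.name = "sample_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path, markers: pd.DataFrame | None = None) -> "MarkerTable":
        df = pd.read_csv(path, index_col="sample_id")
        labels = df.pop("stage")
        batches = df.pop("batch")
        df.columns = [_maybe_int(c) for c in df.columns]
        if markers is None:
            markers = pd.DataFrame(
                {"serial": list(df.columns), "mz": np.nan, "z": 1, "rt": np.nan}
            )
        return cls(markers, df, labels, batches)


def _maybe_int(c):
    try:
        return int(c)
    except (TypeError, ValueError):
        return c
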