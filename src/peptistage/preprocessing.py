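"""Retention-time alignment, reference-peak normalization and batch adjustment.

Elution profiles are aligned by matching landmark time-marker peaks and
warping each run onto the consensus time axis with a monotone piecewise-
linear map.  Candidate biomarker intensities are then extracted, divided by
the intensity of a qualified co-eluting reference peak (per-sample), and
scaled to unit mean across samples per marker.  A location/scale batch
standardization removes multiplicative batch effects; it relies on the
study design placing both comparison groups in every batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MSMap, MarkerTable

__all__ = [
    "AlignmentMap",
    "AlignmentError",
    "ReferencePeak",
    "align_sample",
    "build_peak_table",
    "qualify_reference",
    "extract_intensity",
    "extract_and_normalize",
    "batch_adjust",
]

DEFAULT_RT_TOL = 20.0  # s, extraction window half-width
DEFAULT_MZ_TOL = 0.02  # Da
DEFAULT_RATIO_BAND = (0.8, 1.25)
DEFAULT_P_FLOOR = 0.3


class AlignmentError(ValueError):
    pass


@dataclass
class AlignmentMap:
    """Monotone piecewise-linear map from observed to consensus RT.

    Beyond the outermost nodes the map extends with the boundary node's
    constant offset, which keeps it continuous and monotone everywhere.
    """

    sample_id: str
    nodes: np.ndarray  # (k, 2): observed RT, consensus RT; strictly increasing

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 2 or self.nodes.shape[0] < 2:
            raise AlignmentError("need >= 2 (observed, consensus) node pairs")
        if not (np.all(np.diff(self.nodes[:, 0]) > 0) and np.all(np.diff(self.nodes[:, 1]) > 0)):
            raise AlignmentError("alignment nodes must be strictly increasing in both axes")

    def apply(self, rt: np.ndarray) -> np.ndarray:
        rt = np.asarray(rt, dtype=float)
        obs, cons = self.nodes[:, 0], self.nodes[:, 1]
        out = np.interp(rt, obs, cons)
        below = rt < obs[0]
        above = rt > obs[-1]
        out[below] = rt[below] + (cons[0] - obs[0])
        out[above] = rt[above] + (cons[-1] - obs[-1])
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.nodes, columns=["observed_rt", "consensus_rt"])


def align_sample(
    msmap: MSMap,
    landmarks,
    mz_tol: float = DEFAULT_MZ_TOL,
    rt_search: float = 30.0,
) -> tuple[MSMap, AlignmentMap]:
    """Warp one sample onto the consensus time axis via landmark peaks.

    ``landmarks`` is an iterable of (mz, consensus_rt) pairs or a DataFrame
    with ``mz``/``rt`` columns.  Each landmark must match exactly one centroid
    within ``mz_tol`` and ``rt_search``; landmark RTs map exactly onto their
    consensus values.
    """
    if isinstance(landmarks, pd.DataFrame):
        landmarks = list(zip(landmarks["mz"], landmarks["rt"]))
    landmarks = list(landmarks)
    if len(landmarks) < 2:
        raise AlignmentError("need at least 2 landmarks")

    pairs = []
    for mz, cons_rt in landmarks:
        hit = (np.abs(msmap.mz - mz) <= mz_tol) & (np.abs(msmap.rt - cons_rt) <= rt_search)
        n = int(hit.sum())
        if n == 0:
            raise AlignmentError(f"landmark (mz={mz:.4f}, rt={cons_rt:.1f}) unmatched")
        if n > 1:
            raise AlignmentError(f"landmark (mz={mz:.4f}, rt={cons_rt:.1f}) matched {n} centroids")
        pairs.append((float(msmap.rt[hit][0]), float(cons_rt)))

    pairs.sort()
    nodes = np.array(pairs)
    amap = AlignmentMap(msmap.sample_id, nodes)  # validates monotonicity
    aligned = MSMap(msmap.sample_id, amap.apply(msmap.rt), msmap.mz.copy(),
                    msmap.intensity.copy(), msmap.scan_range)
    return aligned, amap


def extract_intensity(
    msmap: MSMap, mz: float, rt: float,
    rt_tol: float = DEFAULT_RT_TOL, mz_tol: float = DEFAULT_MZ_TOL,
) -> float:
    """Summed centroid intensity in the closed (rt, mz) extraction window."""
    hit = (np.abs(msmap.mz - mz) <= mz_tol) & (np.abs(msmap.rt - rt) <= rt_tol)
    return float(msmap.intensity[hit].sum())


def build_peak_table(
    maps: list[MSMap],
    rt_tol: float = DEFAULT_RT_TOL,
    mz_tol: float = DEFAULT_MZ_TOL,
    template_index: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract a peaks x samples intensity table using one aligned map as the
    coordinate template.

    Returns (peaks, intensities): ``peaks`` has one row per template centroid
    (mz, rt); ``intensities`` is indexed like ``peaks`` with one column per
    sample (summed intensity in the extraction window).
    """
    template = maps[template_index]
    peaks = pd.DataFrame({"mz": template.mz, "rt": template.rt})
    data = {}
    for m in maps:
        col = np.empty(len(peaks))
        for i, (mz, rt) in enumerate(zip(peaks["mz"], peaks["rt"])):
            col[i] = extract_intensity(m, mz, rt, rt_tol, mz_tol)
        data[m.sample_id] = col
    return peaks, pd.DataFrame(data)


@dataclass
class ReferencePeak:
    """A normalization denominator: present in every sample, class-comparable."""

    mz: float
    rt: float
    intensity: pd.Series  # per-sample

    def __post_init__(self) -> None:
        if (self.intensity <= 0).any():
            raise ValueError("reference peak must have positive intensity in every sample")


def qualify_reference(
    candidate_mz: float,
    candidate_rt: float,
    peaks: pd.DataFrame,
    intensities: pd.DataFrame,
    labels: pd.Series,
    rt_window: float = 30.0,
    mz_window: float = 2.0,
    ratio_band: tuple[float, float] = DEFAULT_RATIO_BAND,
    p_floor: float = DEFAULT_P_FLOOR,
    exclude_tol: tuple[float, float] = (DEFAULT_MZ_TOL, DEFAULT_RT_TOL),
) -> tuple[ReferencePeak | None, list[dict]]:
    """Find a reference peak for one candidate marker, or explain why none.

    A peak qualifies if it (1) elutes within ``rt_window`` of the candidate,
    (2) is present (intensity > 0) in every sample, (3) lies within
    ``mz_window`` of the candidate m/z, and (4) is quantitatively comparable
    between classes: early/late mean ratio inside ``ratio_band`` and a
    two-sample t-test p-value >= ``p_floor``.  Among qualifiers the one with
    the smallest |Delta mz| wins (ties broken by |Delta rt|).  The candidate
    peak itself (within ``exclude_tol``) is never its own reference.

    Returns (reference or None, rejection records with a ``reason`` field —
    one of "window", "presence", "comparability", "self").
    """
    labels = labels.reindex(intensities.columns)
    early_cols = labels.index[labels == "early"]
    late_cols = labels.index[labels == "late"]
    rejections: list[dict] = []
    qualifiers: list[tuple[float, float, ReferencePeak]] = []

    d_mz = np.abs(peaks["mz"].to_numpy() - candidate_mz)
    d_rt = np.abs(peaks["rt"].to_numpy() - candidate_rt)
    for i in range(len(peaks)):
        rec = {"mz": float(peaks["mz"].iloc[i]), "rt": float(peaks["rt"].iloc[i])}
        if d_mz[i] <= exclude_tol[0] and d_rt[i] <= exclude_tol[1]:
            rejections.append({**rec, "reason": "self"})
            continue
        if d_mz[i] > mz_window or d_rt[i] > rt_window:
            rejections.append({**rec, "reason": "window"})
            continue
        inten = intensities.iloc[i]
        if (inten <= 0).any():
            rejections.append({**rec, "reason": "presence"})
            continue
        early = inten[early_cols].to_numpy(dtype=float)
        late = inten[late_cols].to_numpy(dtype=float)
        ratio = late.mean() / early.mean()
        p = stats.ttest_ind(early, late).pvalue if min(early.size, late.size) >= 2 else 1.0
        if not (ratio_band[0] <= ratio <= ratio_band[1]) or not (p >= p_floor or np.isnan(p)):
            rejections.append({**rec, "reason": "comparability"})
            continue
        qualifiers.append((d_mz[i], d_rt[i], ReferencePeak(rec["mz"], rec["rt"], inten)))

    if not qualifiers:
        return None, rejections
    qualifiers.sort(key=lambda q: (q[0], q[1]))
    return qualifiers[0][2], rejections


def extract_and_normalize(
    maps: list[MSMap],
    markers: pd.DataFrame,
    references: dict,
    labels: pd.Series,
    batches: pd.Series,
    rt_tol: float = DEFAULT_RT_TOL,
    mz_tol: float = DEFAULT_MZ_TOL,
    mode: str = "ratio",
) -> MarkerTable:
    """Extract marker intensities and normalize them for comparison.

    Per sample s and marker j: raw_sj is the summed intensity inside the
    extraction window; r_sj = raw_sj / (reference intensity of s for j);
    the final value is r_sj / mean_s(r_sj) (unit mean per marker) in the
    default ``ratio`` mode, or r_sj - mean_s(r_sj) in ``centered`` mode.
    A missing peak gives raw 0 and is flagged; flagged cells are excluded
    from the mean.

    ``markers`` needs columns serial/mz/z/rt; ``references`` maps serial ->
    :class:`ReferencePeak` (every marker must have one).
    """
    if mode not in ("ratio", "centered"):
        raise ValueError("mode must be 'ratio' or 'centered'")
    sample_ids = [m.sample_id for m in maps]
    serials = list(markers["serial"])
    missing_serials = [s for s in serials if s not in references]
    if missing_serials:
        raise ValueError(f"markers without a qualified reference: {missing_serials}")

    values = np.empty((len(maps), len(serials)))
    missing = np.zeros_like(values, dtype=bool)
    for j, (_, mk) in enumerate(markers.iterrows()):
        ref = references[mk["serial"]]
        for i, m in enumerate(maps):
            raw = extract_intensity(m, mk["mz"], mk["rt"], rt_tol, mz_tol)
            ref_int = float(ref.intensity[m.sample_id])
            if ref_int <= 0:
                raise ValueError(f"reference intensity <= 0 for sample {m.sample_id}")
            values[i, j] = raw / ref_int
            missing[i, j] = raw == 0.0
        ok = ~missing[:, j]
        mean = values[ok, j].mean() if ok.any() else 1.0
        if mode == "ratio":
            if mean > 0:
                values[:, j] /= mean
        else:
            values[:, j] -= mean

    return MarkerTable(
        markers.reset_index(drop=True),
        pd.DataFrame(values, index=sample_ids, columns=serials),
        labels.reindex(sample_ids),
        batches.reindex(sample_ids),
        missing=pd.DataFrame(missing, index=sample_ids, columns=serials),
    )


def batch_adjust(table: MarkerTable) -> MarkerTable:
    """Location/scale batch standardization of a marker table.

    Per marker, each batch's values are rescaled to the pooled cross-batch
    mean and standard deviation; the grand mean of every marker is preserved.
    This removes additive/multiplicative batch offsets without empirical-
    Bayes shrinkage, and is appropriate because both comparison groups are
    present in every batch by design.
    """
    counts = table.batches.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"batches with < 2 samples: {list(small.index)}")
    mat = table.matrix.to_numpy(dtype=float).copy()
    batches = table.batches.to_numpy()
    if len(set(batches)) == 1:
        return table

    for j in range(mat.shape[1]):
        col = mat[:, j]
        pooled_mean = col.mean()
        pooled_sd = col.std(ddof=1)
        adj = col.copy()
        for b in np.unique(batches):
            sel = batches == b
            mu, sd = col[sel].mean(), col[sel].std(ddof=1)
            if sd > 0 and pooled_sd > 0:
                adj[sel] = (col[sel] - mu) / sd * pooled_sd + pooled_mean
            else:
                adj[sel] = col[sel] - mu + pooled_mean
        adj += pooled_mean - adj.mean()  # preserve grand mean exactly
        mat[:, j] = adj

    return MarkerTable(
        table.markers,
        pd.DataFrame(mat, index=table.matrix.index, columns=table.matrix.columns),
        table.labels,
        table.batches,
        table.missing,
    )
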