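"""Differential screen: fold-change filter, per-marker t-tests, significance bands.

The discovery analysis screens normalized marker intensities for candidates
whose class means differ by at least 50% in either direction, evaluates each
with a two-sided two-sample Student's t-test, and partitions the results into
significant (p < 0.05) and near-significant (0.05 <= p < 0.10) bands.  No
multiple-testing correction is applied by default — a small discovery study
deliberately over-calls candidates and relies on independent confirmation —
but a Benjamini-Hochberg adjustment is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MarkerTable

__all__ = [
    "CandidateMarker",
    "screen_candidates",
    "test_markers",
    "filter_significant",
    "candidates_frame",
]


@dataclass(frozen=True)
class CandidateMarker:
    serial: int
    mz: float
    z: int
    p_value: float
    status: str  # "U" higher mean in late stage, "D" lower

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")
        if self.status not in ("U", "D"):
            raise ValueError("status must be 'U' or 'D'")


def screen_candidates(table: MarkerTable, min_fold: float = 1.5) -> list:
    """Return serials whose class-mean ratio is >= min_fold or <= 1/min_fold.

    ``min_fold`` = 1.5 encodes a "50% greater or less" screen; the interval is
    closed, so a ratio of exactly 1.5 is retained.  Markers with an all-missing
    class are skipped with a warning.
    """
    if table.n_markers == 0:
        raise ValueError("empty marker table")
    kept = []
    for serial in table.matrix.columns:
        early, late = table.values_by_class(serial)
        if early.size == 0 or late.size == 0:
            warnings.warn(f"marker {serial}: a class has no non-missing values; skipped")
            continue
        me, ml = early.mean(), late.mean()
        if me == 0 and ml == 0:
            continue
        ratio = np.inf if me == 0 else ml / me
        if ratio >= min_fold or ratio <= 1.0 / min_fold:
            kept.append(serial)
    return kept


def _t_test(early: np.ndarray, late: np.ndarray, welch: bool) -> float:
    if early.std(ddof=0) == 0 and late.std(ddof=0) == 0:
        # degenerate convention: identical constants are indistinguishable,
        # distinct constants are maximally distinguishable
        return 1.0 if early.mean() == late.mean() else 0.0
    res = stats.ttest_ind(early, late, equal_var=not welch)
    return float(res.pvalue)


def test_markers(
    table: MarkerTable, serials=None, welch: bool = False, renumber: bool = True
) -> list[CandidateMarker]:
    """Two-sided two-sample t-test per marker on normalized intensities.

    Status is U if the late-stage mean exceeds the early-stage mean, else D
    (exact ties go to D for determinism).  With ``renumber`` (default) output
    serials are reassigned in ascending m/z order, as in a discovery-report
    table; otherwise the table's serials are kept.
    """
    serials = list(table.matrix.columns) if serials is None else list(serials)
    info = table.markers.set_index("serial")
    rows = []
    for serial in serials:
        early, late = table.values_by_class(serial)
        if early.size < 2 or late.size < 2:
            raise ValueError(f"marker {serial}: need >= 2 values per class")
        p = _t_test(early, late, welch)
        status = "U" if late.mean() > early.mean() else "D"
        rows.append((serial, float(info.loc[serial, "mz"]), int(info.loc[serial, "z"]), p, status))
    if not renumber:
        return [
            CandidateMarker(serial=s, mz=mz, z=z, p_value=p, status=status)
            for s, mz, z, p, status in rows
        ]
    rows.sort(key=lambda r: r[1])
    return [
        CandidateMarker(serial=i + 1, mz=mz, z=z, p_value=p, status=status)
        for i, (_, mz, z, p, status) in enumerate(rows)
    ]


test_markers.__test__ = False  # "test" refers to Student's t, not pytest


def filter_significant(
    candidates: list[CandidateMarker],
    alpha: float = 0.05,
    near_band: float = 0.10,
    bh_correct: bool = False,
) -> tuple[list[CandidateMarker], list[CandidateMarker]]:
    """Partition candidates into significant (p < alpha) and near-significant
    (alpha <= p < near_band) sets.  Boundaries are strict: p == alpha falls in
    the near band.  ``bh_correct`` applies Benjamini-Hochberg to the p-values
    before partitioning (off by default)."""
    if not candidates:
        raise ValueError("no candidates to filter")
    pvals = np.array([c.p_value for c in candidates])
    if bh_correct:
        pvals = stats.false_discovery_control(pvals, method="bh")
    significant = [c for c, p in zip(candidates, pvals) if p < alpha]
    near = [c for c, p in zip(candidates, pvals) if alpha <= p < near_band]
    return significant, near


def candidates_frame(candidates: list[CandidateMarker]) -> pd.DataFrame:
    """Discovery-report layout: Serial, m/z, z, p-Value, Status."""
    return pd.DataFrame(
        [
            {"serial": c.serial, "mz": c.mz, "z": c.z, "p_value": c.p_value, "status": c.status}
            for c in candidates
        ]
    )
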