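"""MS1 grid parsing, decision-value ranking and the DV-weighted vote classifier.

The machine-learning workflow treats each sample's MS1 map as an image:
the (retention time, m/z) plane is tiled into fixed-size half-open cells
("datapoints"), each holding one aggregated intensity per subject.  Cells
with no signal in any subject are discarded.  A decision value (DV)
measures between-class separation within each datapoint: DV >= 1 exactly
when the two classes' value ranges are disjoint (or touch at one point),
DV < 1 when they overlap.  Datapoints ranked by DV drive a weighted-vote
classifier: each selected datapoint votes for the class whose training mean
is nearer to the test subject's value, with weight equal to its training DV.
Selection and weighting are recomputed inside every holdout iteration from
training subjects only, so no test information leaks into the classifier.

A mock assembly — the same manifest with deliberately switched stage labels
— is run through the identical pipeline to measure how much apparent signal
overfitting of natural variation can produce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .containers import MSMap, SCAN_RANGE

__all__ = [
    "GridSpec",
    "DatapointGrid",
    "parse_grid",
    "decision_value",
    "dv_scores",
    "rank_datapoints",
    "make_mock_assembly",
    "train_vote_classifier",
    "learning_curve",
    "reparse_top",
    "feature_overlap",
    "cluster_order",
]

DV_CAP = 10.0


@dataclass(frozen=True)
class GridSpec:
    """Datapoint tiling: half-open cells [lo, hi) of rt_bin x mz_bin anchored
    at (rt0, mz0).  The survey parse uses 40 s x 0.2/0.1/0.05 Da; the
    follow-up re-parse uses 10 s x 0.01 Da."""

    rt_bin: float = 40.0
    mz_bin: float = 0.2
    rt0: float = 0.0
    mz0: float = SCAN_RANGE[0]
    mz_max: float = SCAN_RANGE[1]

    def __post_init__(self) -> None:
        if self.rt_bin <= 0 or self.mz_bin <= 0:
            raise ValueError("bin sizes must be positive")

    def cell_of(self, rt: np.ndarray, mz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        i = np.floor((np.asarray(rt) - self.rt0) / self.rt_bin).astype(np.int64)
        j = np.floor((np.asarray(mz) - self.mz0) / self.mz_bin).astype(np.int64)
        return i, j

    def cell_bounds(self, i: int, j: int) -> tuple[float, float, float, float]:
        """(rt_lo, rt_hi, mz_lo, mz_hi) of cell (i, j)."""
        return (
            self.rt0 + i * self.rt_bin,
            self.rt0 + (i + 1) * self.rt_bin,
            self.mz0 + j * self.mz_bin,
            self.mz0 + (j + 1) * self.mz_bin,
        )


@dataclass
class DatapointGrid:
    """Retained (non-empty) grid cells with one aggregated value per subject.

    ``cells`` is (n, 2) of (rt index, mz index) in lexicographic order;
    ``values`` is (n, n_subjects) of summed centroid intensities.
    """

    spec: GridSpec
    cells: np.ndarray
    values: np.ndarray
    subject_ids: list[str]

    @property
    def n_datapoints(self) -> int:
        return self.cells.shape[0]

    def bounds_frame(self) -> pd.DataFrame:
        rows = [self.spec.cell_bounds(int(i), int(j)) for i, j in self.cells]
        return pd.DataFrame(rows, columns=["rt_lo", "rt_hi", "mz_lo", "mz_hi"])


def parse_grid(maps: list[MSMap], spec: GridSpec) -> DatapointGrid:
    """Tile MS1 maps into datapoints, discarding cells empty in every subject.

    Aggregation within a cell is the intensity sum, so the per-subject total
    over all datapoints equals that subject's total in-range centroid
    intensity (exact conservation).  Centroids outside the m/z scan range
    are excluded with a warning.
    """
    per_subject: list[dict] = []
    for m in maps:
        in_range = (m.mz >= spec.mz0) & (m.mz < spec.mz_max) & (m.rt >= spec.rt0)
        n_out = int((~in_range).sum())
        if n_out:
            warnings.warn(f"{m.sample_id}: {n_out} centroids outside scan range excluded")
        i, j = spec.cell_of(m.rt[in_range], m.mz[in_range])
        acc: dict[tuple[int, int], float] = {}
        for ii, jj, inten in zip(i, j, m.intensity[in_range]):
            key = (int(ii), int(jj))
            acc[key] = acc.get(key, 0.0) + float(inten)
        per_subject.append(acc)

    all_cells = sorted(set().union(*per_subject)) if per_subject else []
    values = np.zeros((len(all_cells), len(maps)))
    for s, acc in enumerate(per_subject):
        for r, cell in enumerate(all_cells):
            if cell in acc:
                values[r, s] = acc[cell]
    keep = values.any(axis=1)
    cells = np.array(all_cells, dtype=np.int64).reshape(-1, 2)[keep]
    return DatapointGrid(spec, cells, values[keep], [m.sample_id for m in maps])


# --- decision value ---------------------------------------------------------


def decision_value(values_a, values_b) -> tuple[float, str]:
    """Between-class separation statistic for one datapoint.

    dv = |midrange(A) - midrange(B)| / (halfrange(A) + halfrange(B)), where
    halfrange(X) = (max - min)/2.  dv >= 1 if and only if the closed value
    ranges of the two classes are disjoint or touch at a single point (two
    identical constant classes coincide rather than touch and give dv 0;
    distinct constants give DV_CAP).  Direction is the class with the larger
    mean ("A" or "B").
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both class vectors must be nonempty")
    ha = (a.max() - a.min()) / 2.0
    hb = (b.max() - b.min()) / 2.0
    num = abs((a.max() + a.min()) / 2.0 - (b.max() + b.min()) / 2.0)
    if ha + hb == 0:
        dv = 0.0 if num == 0 else DV_CAP
    else:
        dv = num / (ha + hb)
    direction = "B" if b.mean() > a.mean() else "A"
    return float(dv), direction


def dv_scores(values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized decision values for a (datapoints x subjects) matrix.

    ``y`` is 0 (early) / 1 (late).  Returns (dv, direction) with direction
    +1 where the late class has the larger mean, -1 otherwise.
    """
    a = values[:, y == 0]
    b = values[:, y == 1]
    amax, amin = a.max(axis=1), a.min(axis=1)
    bmax, bmin = b.max(axis=1), b.min(axis=1)
    denom = (amax - amin) / 2.0 + (bmax - bmin) / 2.0
    num = np.abs((amax + amin) / 2.0 - (bmax + bmin) / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dv = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0),
                      np.where(num > 0, DV_CAP, 0.0))
    direction = np.where(b.mean(axis=1) > a.mean(axis=1), 1, -1)
    return dv, direction


def rank_datapoints(
    grid: DatapointGrid,
    labels: pd.Series,
    k_permutations: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank datapoints by DV (descending; ties broken by cell id) and attach a
    randomized reference: the mean DV of each datapoint over ``k_permutations``
    random relinkings of its values to the class labels."""
    y = _labels_to_y(labels, grid.subject_ids)
    dv, direction = dv_scores(grid.values, y)
    rng = np.random.default_rng(seed)
    rand_ref = np.zeros_like(dv)
    for _ in range(k_permutations):
        perm = rng.permutation(y.size)
        rand_dv, _ = dv_scores(grid.values, y[perm])
        rand_ref += rand_dv
    rand_ref /= max(k_permutations, 1)

    out = grid.bounds_frame()
    out.insert(0, "cell_rt_idx", grid.cells[:, 0])
    out.insert(1, "cell_mz_idx", grid.cells[:, 1])
    out["dv"] = dv
    out["direction"] = np.where(direction > 0, "late", "early")
    out["randomized_dv"] = rand_ref
    out["row"] = np.arange(len(out))
    out = out.sort_values(
        ["dv", "cell_rt_idx", "cell_mz_idx"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return out


def _labels_to_y(labels: pd.Series, subject_ids: list[str]) -> np.ndarray:
    lab = labels.reindex(subject_ids)
    if lab.isna().any():
        raise ValueError("labels must cover every subject")
    return (lab == "late").to_numpy().astype(int)


# --- mock assembly ----------------------------------------------------------


def make_mock_assembly(
    manifest: pd.DataFrame, n_switch_early: int, n_switch_late: int, seed: int = 0
) -> pd.DataFrame:
    """Switch stage labels for randomly chosen subjects to build a mock
    assembly; everything else in the manifest is unchanged."""
    early_idx = manifest.index[manifest["stage"] == "early"].to_numpy()
    late_idx = manifest.index[manifest["stage"] == "late"].to_numpy()
    if n_switch_early > early_idx.size or n_switch_late > late_idx.size:
        raise ValueError("switch count exceeds class size")
    rng = np.random.default_rng(seed)
    mock = manifest.copy()
    mock.loc[rng.choice(early_idx, n_switch_early, replace=False), "stage"] = "late"
    mock.loc[rng.choice(late_idx, n_switch_late, replace=False), "stage"] = "early"
    return mock


# --- weighted-vote classifier ----------------------------------------------


def _stratified_splits(y: np.ndarray, holdout: float, iterations: int, seed: int):
    """Per-iteration stratified holdout splits (train_idx, test_idx)."""
    rng = np.random.default_rng(seed)
    splits = []
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    n0 = max(1, round(holdout * idx0.size))
    n1 = max(1, round(holdout * idx1.size))
    if n0 >= idx0.size or n1 >= idx1.size:
        raise ValueError("holdout leaves a class without training subjects")
    for _ in range(iterations):
        t0 = rng.choice(idx0, n0, replace=False)
        t1 = rng.choice(idx1, n1, replace=False)
        test = np.sort(np.concatenate([t0, t1]))
        train = np.setdiff1d(np.arange(y.size), test)
        splits.append((train, test))
    return splits


def _vote_predict(values, train_idx, test_idx, y, n_top):
    """One holdout iteration: select top-N datapoints by training DV and
    classify held-out subjects by DV-weighted nearest-class-mean votes."""
    y_tr = y[train_idx]
    V_tr = values[:, train_idx]
    dv, _ = dv_scores(V_tr, y_tr)
    n_top = min(n_top, values.shape[0])
    # ties broken by row order (= cell id order) for determinism
    order = np.lexsort((np.arange(dv.size), -dv))
    top = order[:n_top]

    mean_early = V_tr[top][:, y_tr == 0].mean(axis=1)
    mean_late = V_tr[top][:, y_tr == 1].mean(axis=1)
    w = dv[top]

    preds = np.empty(test_idx.size, dtype=int)
    for t, s in enumerate(test_idx):
        v = values[top, s]
        d_early = np.abs(v - mean_early)
        d_late = np.abs(v - mean_late)
        late_w = w[d_late < d_early].sum()
        early_w = w[d_early < d_late].sum()  # equidistant datapoints abstain
        preds[t] = 1 if late_w > early_w else 0  # vote tie -> early
    return preds, top


def train_vote_classifier(
    grid_or_values,
    labels,
    n_top: int,
    holdout: float = 0.2,
    iterations: int = 50,
    seed: int = 0,
    splits=None,
) -> dict:
    """Estimate holdout error of the DV-weighted vote classifier at one N.

    Each iteration draws a stratified random holdout, recomputes DV and class
    means on the training subjects only, selects the top-N datapoints by
    training DV, and classifies each held-out subject by weighted vote.
    Returns the mean/sd error rate over iterations and per-iteration records.
    ``splits`` overrides the random holdouts with explicit
    (train_idx, test_idx) pairs — used for paired real/mock comparisons.
    """
    values, y = _coerce_values(grid_or_values, labels)
    if n_top < 1:
        raise ValueError("need n_top >= 1")
    if n_top > values.shape[0]:
        warnings.warn(f"n_top={n_top} exceeds {values.shape[0]} datapoints; clamped")
    if splits is None:
        if not 0 < holdout < 1:
            raise ValueError("holdout must be in (0, 1)")
        splits = _stratified_splits(y, holdout, iterations, seed)
    errors = []
    records = []
    for train_idx, test_idx in splits:
        if len(set(y[train_idx])) < 2:
            raise ValueError("a class is absent from a training split")
        preds, top = _vote_predict(values, train_idx, test_idx, y, n_top)
        err = float((preds != y[test_idx]).mean())
        errors.append(err)
        records.append({"test_idx": test_idx, "error": err, "selected": top})
    return {
        "n_top": n_top,
        "mean_error": float(np.mean(errors)),
        "sd_error": float(np.std(errors)),
        "iterations": records,
    }


def learning_curve(
    grid_or_values,
    labels,
    n_grid,
    holdout: float = 0.2,
    iterations: int = 50,
    seed: int = 0,
    mock_labels=None,
) -> pd.DataFrame:
    """Mean holdout error as a function of the number of datapoints used.

    If ``mock_labels`` is given, the mock curve is computed with the *same*
    holdout splits (paired seeds) so real-vs-mock differences reflect the
    labels, not the resampling.
    """
    n_grid = list(n_grid)
    if any(b < a for a, b in zip(n_grid, n_grid[1:])):
        raise ValueError("n_grid must be ascending")
    values, y = _coerce_values(grid_or_values, labels)
    splits = _stratified_splits(y, holdout, iterations, seed)
    rows = []
    for n in n_grid:
        res = train_vote_classifier(grid_or_values, labels, n, splits=splits)
        rows.append({"n_datapoints": n, "mean_error": res["mean_error"],
                     "sd_error": res["sd_error"], "assembly": "real"})
    if mock_labels is not None:
        for n in n_grid:
            res = train_vote_classifier(grid_or_values, mock_labels, n, splits=splits)
            rows.append({"n_datapoints": n, "mean_error": res["mean_error"],
                         "sd_error": res["sd_error"], "assembly": "mock"})
    return pd.DataFrame(rows)


def _coerce_values(grid_or_values, labels) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(grid_or_values, DatapointGrid):
        return grid_or_values.values, _labels_to_y(labels, grid_or_values.subject_ids)
    values = np.asarray(grid_or_values, dtype=float)
    if isinstance(labels, pd.Series):
        y = (labels == "late").to_numpy().astype(int)
    else:
        y = np.asarray(labels).astype(int)
    return values, y


# --- re-parse and cluster display ------------------------------------------


def reparse_top(
    ranked: pd.DataFrame,
    maps: list[MSMap],
    top_k: int,
    fine_spec: GridSpec | None = None,
) -> pd.DataFrame:
    """Re-bin the top-k ranked coarse cells at high resolution.

    Within each coarse cell, fine bins are anchored at the cell's lower
    bounds so they tile it exactly (intensity is conserved); the fine cell
    with the largest pooled intensity gives the feature coordinate
    (its rt/mz lower bounds).
    """
    if top_k > len(ranked):
        raise ValueError("top_k exceeds ranked datapoint count")
    fine_spec = fine_spec or GridSpec(rt_bin=10.0, mz_bin=0.01)
    rt = np.concatenate([m.rt for m in maps])
    mz = np.concatenate([m.mz for m in maps])
    inten = np.concatenate([m.intensity for m in maps])

    rows = []
    for _, cell in ranked.head(top_k).iterrows():
        sel = (
            (rt >= cell["rt_lo"]) & (rt < cell["rt_hi"])
            & (mz >= cell["mz_lo"]) & (mz < cell["mz_hi"])
        )
        if not sel.any():
            continue
        fi = np.floor((rt[sel] - cell["rt_lo"]) / fine_spec.rt_bin).astype(int)
        fj = np.floor((mz[sel] - cell["mz_lo"]) / fine_spec.mz_bin).astype(int)
        acc: dict[tuple[int, int], float] = {}
        for a, b, v in zip(fi, fj, inten[sel]):
            acc[(int(a), int(b))] = acc.get((int(a), int(b)), 0.0) + float(v)
        best = max(sorted(acc), key=lambda k: (acc[k], -k[0], -k[1]))
        rows.append({
            "coarse_rt_lo": cell["rt_lo"], "coarse_mz_lo": cell["mz_lo"],
            "feature_rt": cell["rt_lo"] + best[0] * fine_spec.rt_bin,
            "feature_mz": cell["mz_lo"] + best[1] * fine_spec.mz_bin,
            "feature_intensity": acc[best],
            "cell_total_intensity": float(inten[sel].sum()),
            "dv": cell.get("dv", np.nan),
        })
    return pd.DataFrame(rows)


def feature_overlap(
    feature_lists: dict[str, pd.DataFrame],
    rt_tol: float = 10.0,
    mz_tol: float = 0.01,
) -> pd.DataFrame:
    """Fraction of each resolution's re-parsed features unique to it,
    by coordinate matching within one fine cell."""
    rows = []
    for name, feats in feature_lists.items():
        others = [f for n, f in feature_lists.items() if n != name]
        unique = 0
        for _, f in feats.iterrows():
            found = any(
                ((np.abs(o["feature_rt"] - f["feature_rt"]) <= rt_tol)
                 & (np.abs(o["feature_mz"] - f["feature_mz"]) <= mz_tol)).any()
                for o in others if len(o)
            )
            unique += not found
        rows.append({"resolution": name, "n_features": len(feats),
                     "n_unique": unique,
                     "frac_unique": unique / len(feats) if len(feats) else np.nan})
    return pd.DataFrame(rows)


def cluster_order(
    grid_or_values, labels=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hierarchical leaf orders for a subjects-vs-datapoints heatmap.

    Average-linkage clustering with correlation distance on both axes of the
    value matrix; distances that are undefined for constant vectors are set
    to zero.  Returns (subject order, datapoint order, matrix).
    """
    if isinstance(grid_or_values, DatapointGrid):
        values = grid_or_values.values
    else:
        values = np.asarray(grid_or_values, dtype=float)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 datapoints")

    def order_of(mat: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = pdist(mat, metric="correlation")
        d = np.nan_to_num(d, nan=0.0)
        d = np.clip(d, 0.0, None)
        return leaves_list(linkage(d, method="average"))

    datapoint_order = order_of(values)
    subject_order = order_of(values.T)
    return subject_order, datapoint_order, values
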