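"""Synthetic two-cohort LC-MS datasets with planted differential markers.

The generator emulates the statistical structure of a serum-peptidomics
staging study: per-sample MS1 centroid clouds with ~10,000 background peaks,
a small set of planted differential markers (mostly down-regulated in the
late-stage class), landmark time-marker peaks present in every run,
per-sample retention-time drift, multiplicative batch effects and log-normal
intensity noise.  Every downstream stage of the pipeline — alignment,
normalization, the differential screen, panel selection and the grid
classifier — is testable against the generator's ground truth.

Intensity model: each analyte has a per-cohort base intensity; a sample's
observed intensity is

    base * class_factor * batch_shift**batch_index * exp(eps),
    eps ~ Normal(0, sigma),  sigma = sqrt(log(1 + noise_cv**2))

so the per-peak coefficient of variation equals ``noise_cv`` and intensities
stay positive.  Planted markers have class-mean fold-change ``effect`` in
their assigned direction (U: higher in late stage, D: lower).  Retention
times are warped per sample by a monotone piecewise-linear drift with node
jitter at five evenly spaced anchor times, which landmark-based alignment
can invert.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MSMap, MarkerTable, SCAN_RANGE

__all__ = ["CohortConfig", "GroundTruth", "generate_cohort", "simulate_marker_table", "assign_splits"]

RT_RANGE = (0.0, 3600.0)
N_WARP_ANCHORS = 5


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for a synthetic two-cohort experiment.

    Defaults mirror the confirmation-cohort design: 20 early-stage and 19
    late-stage subjects, ~10,000 distinct peaks per sample, 65 planted
    differential markers of which 56/65 are down-regulated late, two-fold
    differential effect and ~15% multiplicative intensity noise.
    """

    n_early: int = 20
    n_late: int = 19
    n_peaks: int = 10_000
    n_diff: int = 65
    frac_down: float = 56 / 65
    effect: float = 2.0
    n_landmarks: int = 8
    n_ref_companions: int = 3
    n_batches: int = 2
    batch_shift: float = 1.1
    rt_drift_sd: float = 5.0
    noise_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_early <= 0 or self.n_late <= 0:
            raise ValueError("cohort sizes must be positive")
        for name in ("n_peaks", "n_diff", "n_landmarks"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.frac_down <= 1:
            raise ValueError("frac_down must be in [0, 1]")
        if self.effect <= 0:
            raise ValueError("effect must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_batches < 1:
            raise ValueError("need at least one batch")

    @property
    def noise_sigma(self) -> float:
        return float(np.sqrt(np.log1p(self.noise_cv**2)))


@dataclass
class GroundTruth:
    """What was planted: marker coordinates/directions, landmarks, warps."""

    marker_coords: pd.DataFrame  # columns: serial, mz, z, rt, direction (U|D)
    landmark_coords: pd.DataFrame  # columns: mz, rt
    sample_warps: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    # per-analyte base intensities, for oracle use in tests
    base_intensity: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_down(self) -> int:
        return int((self.marker_coords["direction"] == "D").sum())

    @property
    def n_up(self) -> int:
        return int((self.marker_coords["direction"] == "U").sum())


def _unique_coords(rng, n, mz_range, rt_range, existing=None, mz_cell=0.01, rt_cell=10.0):
    """Sample coordinates unique at the finest parse resolution."""
    taken = set(existing or [])
    mzs, rts = [], []
    while len(mzs) < n:
        mz = rng.uniform(*mz_range)
        rt = rng.uniform(*rt_range)
        key = (int(mz / mz_cell), int(rt / rt_cell))
        if key in taken:
            continue
        taken.add(key)
        mzs.append(mz)
        rts.append(rt)
    return np.array(mzs), np.array(rts), taken


def _make_warp(rng, rt_drift_sd: float) -> tuple[np.ndarray, np.ndarray]:
    """True->observed RT warp: monotone piecewise-linear with jittered nodes."""
    anchors = np.linspace(RT_RANGE[0], RT_RANGE[1], N_WARP_ANCHORS)
    observed = anchors + rng.normal(0.0, rt_drift_sd, size=N_WARP_ANCHORS)
    observed = np.maximum(observed, 0.0)
    # enforce strict monotonicity (jitter << anchor spacing, so this is rare)
    for i in range(1, N_WARP_ANCHORS):
        if observed[i] <= observed[i - 1]:
            observed[i] = observed[i - 1] + 1e-6
    return anchors, observed


def generate_cohort(config: CohortConfig) -> tuple[list[MSMap], pd.DataFrame, GroundTruth]:
    """Generate per-sample MS1 maps, an assembly manifest and the ground truth.

    Landmarks and background peaks appear in every sample; planted markers
    have class-mean fold-change ``config.effect`` in their assigned direction.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    mz_lo, mz_hi = SCAN_RANGE
    rt_lo, rt_hi = RT_RANGE[0] + 120, RT_RANGE[1] - 120

    lm_mz, lm_rt, taken = _unique_coords(rng, config.n_landmarks, (mz_lo, mz_hi), (rt_lo, rt_hi))
    order = np.argsort(lm_rt)
    lm_mz, lm_rt = lm_mz[order], lm_rt[order]
    taken = set(taken)
    bg_mz, bg_rt, taken = _unique_coords(rng, config.n_peaks, (mz_lo, mz_hi), (rt_lo, rt_hi), taken)
    mk_mz, mk_rt, taken = _unique_coords(rng, config.n_diff, (mz_lo, mz_hi), (rt_lo, rt_hi), taken)
    mk_z = rng.integers(1, 3, size=config.n_diff)

    # Reference companions: real serum spectra are dense enough that a
    # co-eluting, near-m/z, class-comparable peak exists beside essentially
    # every marker; at desk-scale peak counts we plant that structure
    # explicitly (non-differential peaks straddling each marker).
    comp_mz, comp_rt = [], []
    for mz, rt in zip(mk_mz, mk_rt):
        for _ in range(config.n_ref_companions):
            comp_mz.append(np.clip(mz + rng.uniform(0.3, 1.5) * rng.choice([-1, 1]),
                                   mz_lo, mz_hi))
            comp_rt.append(np.clip(rt + rng.uniform(-10, 10), rt_lo, rt_hi))
    comp_mz, comp_rt = np.array(comp_mz), np.array(comp_rt)

    n_down = round(config.frac_down * config.n_diff)
    directions = np.array(["D"] * n_down + ["U"] * (config.n_diff - n_down))

    base_lm = np.full(config.n_landmarks, 5e4)
    base_bg = rng.lognormal(np.log(5e3), 1.0, size=config.n_peaks)
    base_mk = rng.lognormal(np.log(8e3), 0.5, size=config.n_diff)
    base_comp = rng.lognormal(np.log(8e3), 0.5, size=comp_mz.size)

    n_total = config.n_early + config.n_late
    stages = ["early"] * config.n_early + ["late"] * config.n_late
    sample_ids = [f"S{i + 1:03d}" for i in range(n_total)]
    # round-robin within stage keeps both comparison groups in every batch
    batches = {}
    for stage in ("early", "late"):
        ids = [s for s, st in zip(sample_ids, stages) if st == stage]
        for k, sid in enumerate(ids):
            batches[sid] = f"B{k % config.n_batches + 1}"

    true_mz = np.concatenate([lm_mz, bg_mz, mk_mz, comp_mz])
    true_rt = np.concatenate([lm_rt, bg_rt, mk_rt, comp_rt])
    base = np.concatenate([base_lm, base_bg, base_mk, base_comp])
    sigma = config.noise_sigma

    maps: list[MSMap] = []
    warps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    rows = []
    for sid, stage in zip(sample_ids, stages):
        class_factor = np.ones_like(base)
        if stage == "late" and config.n_diff:
            off = config.n_landmarks + config.n_peaks
            fold = np.where(directions == "U", config.effect, 1.0 / config.effect)
            class_factor[off:off + config.n_diff] = fold
        batch_idx = int(batches[sid][1:]) - 1
        noise = np.exp(rng.normal(0.0, sigma, size=base.size)) if sigma > 0 else 1.0
        intensity = base * class_factor * (config.batch_shift**batch_idx) * noise

        anchors, observed = _make_warp(rng, config.rt_drift_sd)
        warps[sid] = (anchors, observed)
        rt_obs = np.interp(true_rt, anchors, observed)
        maps.append(MSMap(sid, rt_obs, true_mz.copy(), intensity))
        rows.append({"sample_id": sid, "stage": stage, "batch_id": batches[sid],
                     "split": "discovery", "path": ""})

    manifest = pd.DataFrame(rows)
    truth = GroundTruth(
        marker_coords=pd.DataFrame({
            "serial": np.arange(1, config.n_diff + 1),
            "mz": mk_mz, "z": mk_z, "rt": mk_rt, "direction": directions,
        }),
        landmark_coords=pd.DataFrame({"mz": lm_mz, "rt": lm_rt}),
        sample_warps=warps,
        base_intensity={"landmark": base_lm, "background": base_bg,
                        "marker": base_mk, "companion": base_comp},
    )
    return maps, manifest, truth


def simulate_marker_table(config: CohortConfig) -> tuple[MarkerTable, pd.DataFrame]:
    """Draw a samples x markers intensity table directly from the cohort model.

    Skips the retention-time layer: columns are ``config.n_peaks`` null
    background markers followed by ``config.n_diff`` planted differential
    markers, with the same intensity model as :func:`generate_cohort`.
    Useful for calibration studies and for exercising the screen/panel
    stages at large marker counts.

    Returns the table and a frame describing the planted markers
    (serial, direction).
    """
    rng = np.random.default_rng(config.seed)
    n_markers = config.n_peaks + config.n_diff
    n_total = config.n_early + config.n_late
    stages = np.array(["early"] * config.n_early + ["late"] * config.n_late)
    sample_ids = [f"S{i + 1:03d}" for i in range(n_total)]

    base = rng.lognormal(np.log(5e3), 1.0, size=n_markers)
    n_down = round(config.frac_down * config.n_diff)
    directions = np.array(["D"] * n_down + ["U"] * (config.n_diff - n_down))
    fold = np.ones(n_markers)
    if config.n_diff:
        fold[config.n_peaks:] = np.where(directions == "U", config.effect, 1.0 / config.effect)

    batch_idx = np.zeros(n_total, dtype=int)
    for stage in ("early", "late"):
        idx = np.flatnonzero(stages == stage)
        batch_idx[idx] = np.arange(idx.size) % config.n_batches

    sigma = config.noise_sigma
    noise = np.exp(rng.normal(0.0, sigma, size=(n_total, n_markers))) if sigma > 0 else 1.0
    values = base[None, :] * noise
    values[stages == "late"] *= fold[None, :]
    values *= (config.batch_shift ** batch_idx)[:, None]

    serials = np.arange(1, n_markers + 1)
    markers = pd.DataFrame({
        "serial": serials,
        "mz": rng.uniform(*SCAN_RANGE, size=n_markers),
        "z": rng.integers(1, 3, size=n_markers),
        "rt": rng.uniform(*RT_RANGE, size=n_markers),
    })
    table = MarkerTable(
        markers,
        pd.DataFrame(values, index=sample_ids, columns=serials),
        pd.Series(stages, index=sample_ids),
        pd.Series([f"B{b + 1}" for b in batch_idx], index=sample_ids),
    )
    planted = pd.DataFrame({
        "serial": serials[config.n_peaks:],
        "direction": directions,
    })
    return table, planted


def assign_splits(manifest: pd.DataFrame, test_fraction: float, seed: int) -> pd.DataFrame:
    """Stratified train/test assignment written into the manifest's split column."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    out["split"] = "train"
    for stage in ("early", "late"):
        idx = out.index[out["stage"] == stage].to_numpy()
        n_test = max(1, round(test_fraction * idx.size))
        test_idx = rng.choice(idx, size=n_test, replace=False)
        out.loc[test_idx, "split"] = "test"
    return out
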