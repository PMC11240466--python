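#!/usr/bin/env python
"""Generate the synthetic two-cohort study and record its design.

Emulates the confirmation/validation design: 20 early-stage and 19
late-stage serum samples, ~2000 background peaks per MS1 map at desk scale,
65 planted differential markers (56 down / 9 up in the late class), landmark
time markers in every run, two balanced batches, per-sample retention-time
drift and 15% multiplicative noise.  Downstream drivers regenerate the same
cohort deterministically from STUDY_CONFIG; raw per-sample files, when
needed, go under scratch/.
"""

from pathlib import Path

from peptistage import CohortConfig, assign_splits, generate_cohort
from peptistage.msio import write_manifest

STUDY_CONFIG = CohortConfig(
    n_early=20, n_late=19, n_peaks=2000, n_diff=65, frac_down=56 / 65,
    effect=2.0, noise_cv=0.15, n_landmarks=8, n_batches=2, seed=2024,
)
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    maps, manifest, truth = generate_cohort(STUDY_CONFIG)
    manifest = assign_splits(manifest, test_fraction=15 / 39, seed=STUDY_CONFIG.seed)
    write_manifest(manifest, RESULTS / "manifest.csv")
    truth.marker_coords.to_csv(RESULTS / "ground_truth_markers.csv", index=False)
    truth.landmark_coords.to_csv(RESULTS / "landmarks.csv", index=False)
    n_peaks = [len(m) for m in maps]
    print(f"{len(maps)} samples; {min(n_peaks)}-{max(n_peaks)} centroids per map")
    print(f"planted markers: {truth.n_down} down, {truth.n_up} up in late stage")
    print(manifest.groupby(["batch_id", "stage"]).size().to_string())
    print(f"split: {dict(manifest['split'].value_counts())}")


if __name__ == "__main__":
    main()
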