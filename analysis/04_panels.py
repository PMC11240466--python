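#!/usr/bin/env python
"""Forward-selected multi-marker panels with masked validation.

Splits the cohort per the manifest (24 train / 15 test), compares the five
classifier families on the top single markers, grows panels through the AUC
threshold ladder (0.65 singles, 0.70 pairs, then 0.75/0.85/0.90/0.95) with
repeated stratified 2-fold CV, and scores the best panels on the masked
test split, including the fixed 0.7 / 0.9 score thresholds.
"""

import importlib
import sys
from pathlib import Path

import pandas as pd
from scipy import stats

sys.path.insert(0, str(Path(__file__).resolve().parent))
sim = importlib.import_module("01_simulate")

from peptistage import LadderConfig, MarkerTable, forward_select, validate_panel
from peptistage.panels import compare_classifiers, performance_frame

MAX_CANDIDATES = 8


def subset_samples(table: MarkerTable, ids) -> MarkerTable:
    return MarkerTable(table.markers, table.matrix.loc[ids], table.labels, table.batches)


def main() -> None:
    table = MarkerTable.from_csv(sim.RESULTS / "marker_table.csv")
    manifest = pd.read_csv(sim.RESULTS / "manifest.csv")
    train_ids = manifest.loc[manifest["split"] == "train", "sample_id"]
    test_ids = manifest.loc[manifest["split"] == "test", "sample_id"]
    train = subset_samples(table, train_ids)
    test = subset_samples(table, test_ids)
    print(f"train {train.n_samples} / test {test.n_samples} samples")

    X = train.matrix.to_numpy()
    y = (train.labels == "late").to_numpy()
    pvals = pd.Series(stats.ttest_ind(X[~y], X[y], axis=0).pvalue,
                      index=train.matrix.columns)
    candidates = list(pvals.sort_values().index[:MAX_CANDIDATES])
    print(f"candidates (train-set p-value order): {candidates}")

    config = LadderConfig(repeats=3, seed=sim.STUDY_CONFIG.seed, classifier="rf")
    ranking = compare_classifiers(train, candidates[:3], config)
    print("classifier comparison on the top-3 panel (identical folds):")
    for r in ranking:
        print(f"  {r['classifier']:>6}: AUC {r['auc']:.3f}")

    panels = forward_select(train, candidates, config)
    print(f"{len(panels)} panels cleared the ladder")
    for pm in panels[:5]:
        validate_panel(pm, train, test, thresholds=(0.7, 0.9), seed=config.seed)
        v = pm.validation
        t7, t9 = v["by_threshold"][0.7], v["by_threshold"][0.9]
        print(f"  {pm.marker_ids}: cv AUC {pm.cv_auc:.3f} | test AUC {v['auc']:.3f} "
              f"sens {v['sensitivity']:.2f} spec {v['specificity']:.2f} | "
              f"@0.7 sens {t7['sensitivity']:.2f}/spec {t7['specificity']:.2f} "
              f"@0.9 sens {t9['sensitivity']:.2f}/spec {t9['specificity']:.2f}")

    performance_frame(panels).to_csv(sim.RESULTS / "panels.csv", index=False)
    print("wrote results/panels.csv")


if __name__ == "__main__":
    main()
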