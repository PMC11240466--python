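"""Grid parsing, decision values, weighted voting and the mock control."""

import itertools

import numpy as np
import pandas as pd
import pytest

from peptistage import (
    CohortConfig,
    GridSpec,
    MSMap,
    cluster_order,
    decision_value,
    generate_cohort,
    learning_curve,
    make_mock_assembly,
    parse_grid,
    rank_datapoints,
    reparse_top,
    train_vote_classifier,
)
from peptistage.grid import DV_CAP, dv_scores, feature_overlap


def ranges_disjoint_or_touching(a, b):
    """Brute-force oracle: the closed class ranges are separated — they
    overlap in at most one point and are not the same degenerate point
    (two identical constant classes coincide rather than touch)."""
    if max(a) <= min(b) or max(b) <= min(a):
        return not (min(a) == max(a) == min(b) == max(b))
    return False


class TestParseGrid:
    def test_hand_binning(self):
        m = MSMap("s", [100.0], [600.05], [3.0])
        grid = parse_grid([m], GridSpec(rt_bin=40, mz_bin=0.2, mz0=500.0))
        assert grid.n_datapoints == 1
        assert tuple(grid.cells[0]) == (2, 500)
        assert grid.bounds_frame().iloc[0].tolist() == [80.0, 120.0, 600.0, 600.2]

    def test_empty_maps_give_zero_datapoints(self):
        m = MSMap("s", [], [], [])
        assert parse_grid([m], GridSpec()).n_datapoints == 0

    def test_finer_mz_bins_never_lose_cells(self, small_cohort):
        _, maps, _, _ = small_cohort
        coarse = parse_grid(maps[:4], GridSpec(mz_bin=0.2))
        fine = parse_grid(maps[:4], GridSpec(mz_bin=0.1))
        assert fine.n_datapoints >= coarse.n_datapoints

    def test_per_subject_intensity_conserved(self, small_cohort):
        _, maps, _, _ = small_cohort
        grid = parse_grid(maps, GridSpec())
        for s, m in enumerate(maps):
            in_range = (m.mz >= 500) & (m.mz < 2500)
            assert grid.values[:, s].sum() == pytest.approx(
                m.intensity[in_range].sum(), rel=0, abs=1e-6
            )

    def test_out_of_range_centroids_warn_and_drop(self):
        m = MSMap("s", [10.0, 20.0], [400.0, 600.0], [1.0, 2.0])
        with pytest.warns(UserWarning, match="outside scan range"):
            grid = parse_grid([m], GridSpec())
        assert grid.values.sum() == 2.0


class TestDecisionValue:
    @pytest.mark.parametrize(
        "a,b,expected,direction",
        [
            ((1, 2, 3), (5, 6, 7), 2.0, "B"),
            ((4, 4, 4), (4, 4, 4), 0.0, "A"),
            ((0, 2), (1, 3), 0.5, "B"),
            ((0, 0), (1, 1), DV_CAP, "B"),
        ],
    )
    def test_hand_examples(self, a, b, expected, direction):
        dv, d = decision_value(a, b)
        assert dv == pytest.approx(expected)
        assert d == direction

    def test_empty_class_is_an_error(self):
        with pytest.raises(ValueError):
            decision_value([], [1.0])

    def test_unity_threshold_characterizes_range_overlap(self):
        """dv >= 1 exactly when the class ranges are disjoint or touch at a
        single point (exhaustive over small integer vectors)."""
        vals = range(3)
        for la, lb in itertools.product(range(1, 4), repeat=2):
            for a in itertools.product(vals, repeat=la):
                for b in itertools.product(vals, repeat=lb):
                    dv, _ = decision_value(a, b)
                    assert (dv >= 1) == ranges_disjoint_or_touching(a, b), (a, b)

    def test_vectorized_scores_match_scalar(self):
        rng = np.random.default_rng(0)
        V = rng.uniform(size=(50, 12))
        y = np.array([0] * 6 + [1] * 6)
        dv, direction = dv_scores(V, y)
        for r in range(V.shape[0]):
            dv_r, d_r = decision_value(V[r, y == 0], V[r, y == 1])
            assert dv[r] == pytest.approx(dv_r)
            assert (direction[r] > 0) == (d_r == "B")


class TestRankDatapoints:
    def test_constant_datapoints_rank_by_cell_id(self, small_cohort):
        _, maps, manifest, _ = small_cohort
        m = MSMap("x", [10.0, 50.0, 90.0], [600.0, 700.0, 800.0], [1.0, 1.0, 1.0])
        maps = [MSMap(s.sample_id, m.rt, m.mz, m.intensity) for s in maps]
        grid = parse_grid(maps, GridSpec())
        ranked = rank_datapoints(grid, manifest.set_index("sample_id")["stage"])
        assert (ranked["dv"] == 0).all()
        assert ranked["cell_rt_idx"].is_monotonic_increasing

    def test_planted_signal_beats_its_randomized_reference(self):
        from peptistage import align_sample
        config = CohortConfig(n_early=10, n_late=10, n_peaks=100, n_diff=20,
                              noise_cv=0.1, seed=4)
        maps, manifest, truth = generate_cohort(config)
        aligned = [align_sample(m, truth.landmark_coords)[0] for m in maps]
        spec = GridSpec()
        grid = parse_grid(aligned, spec)
        ranked = rank_datapoints(grid, manifest.set_index("sample_id")["stage"], seed=1)
        planted_cells = {
            tuple(c) for c in np.column_stack(
                spec.cell_of(truth.marker_coords["rt"], truth.marker_coords["mz"])
            )
        }
        sel = ranked[[(i, j) in planted_cells
                      for i, j in zip(ranked["cell_rt_idx"], ranked["cell_mz_idx"])]]
        assert len(sel) >= 15
        assert (sel["dv"] > sel["randomized_dv"]).mean() >= 0.95


class TestMockAssembly:
    def test_switch_counts(self, small_cohort):
        _, _, manifest, _ = small_cohort
        mock = make_mock_assembly(manifest, 4, 3, seed=0)
        assert (mock["stage"] == "early").sum() == 6 - 4 + 3
        assert (mock["stage"] != manifest["stage"]).sum() == 7

    def test_study_design_switch_flips_class_balance(self):
        config = CohortConfig(n_peaks=5, n_diff=0, seed=0)
        _, manifest, _ = generate_cohort(config)
        mock = make_mock_assembly(manifest, 10, 9, seed=1)
        assert (mock["stage"] == "early").sum() == 19
        assert (mock["stage"] == "late").sum() == 20

    def test_zero_switches_is_identity_and_seed_reproducible(self, small_cohort):
        _, _, manifest, _ = small_cohort
        assert make_mock_assembly(manifest, 0, 0, seed=5).equals(manifest)
        a = make_mock_assembly(manifest, 3, 2, seed=9)
        b = make_mock_assembly(manifest, 3, 2, seed=9)
        assert a.equals(b)

    def test_excessive_switches_rejected(self, small_cohort):
        _, _, manifest, _ = small_cohort
        with pytest.raises(ValueError):
            make_mock_assembly(manifest, 100, 0)


class TestVoteClassifier:
    def labels(self, y):
        return pd.Series(np.where(np.asarray(y) == 1, "late", "early"))

    def test_perfectly_separating_datapoint_gives_zero_error(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        V = np.vstack([y.astype(float) * 10, np.random.default_rng(0).uniform(size=8)])
        res = train_vote_classifier(V, self.labels(y), n_top=1, holdout=0.25,
                                    iterations=20, seed=0)
        assert res["mean_error"] == 0.0

    def test_constant_datapoints_force_early_votes(self):
        """Every vote abstains on constants, so the tie rule predicts early
        and the error equals the late fraction of the holdout."""
        y = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        V = np.ones((5, 8))
        res = train_vote_classifier(V, self.labels(y), n_top=3, holdout=0.25,
                                    iterations=10, seed=1)
        # stratified holdout: 1 early + 1 late per iteration -> error 0.5
        assert res["mean_error"] == pytest.approx(0.5)

    def test_randomized_labels_near_chance(self):
        rng = np.random.default_rng(2)
        V = rng.uniform(size=(200, 20))
        y = np.array([0] * 10 + [1] * 10)
        res = train_vote_classifier(V, self.labels(y), n_top=50, holdout=0.2,
                                    iterations=30, seed=3)
        assert res["mean_error"] == pytest.approx(0.5, abs=0.15)

    def test_excess_n_top_clamps_with_warning(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        V = np.random.default_rng(1).uniform(size=(4, 6))
        with pytest.warns(UserWarning, match="clamped"):
            train_vote_classifier(V, self.labels(y), n_top=100, iterations=2, seed=0)

    def test_selection_uses_training_subjects_only(self):
        """Leakage canary: datapoint 0 separates the training subjects
        perfectly but overlaps once the held-out subject is included; the
        leakage-free implementation must still select datapoint 0."""
        y = np.array([0, 0, 0, 1, 1, 1, 1])
        V = np.array([
            [0, 0, 0, 10, 10, 10, 0],  # dv=DV_CAP on train; 1.0 with test subj
            [0, 1, 2, 6, 7, 8, 7],     # dv=3.0 either way
        ], dtype=float)
        splits = [(np.arange(6), np.array([6]))]
        res = train_vote_classifier(V, self.labels(y), n_top=1, splits=splits)
        assert list(res["iterations"][0]["selected"]) == [0]


class TestLearningCurve:
    def test_single_split_smoke(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        V = np.random.default_rng(0).uniform(size=(30, 6))
        out = learning_curve(V, pd.Series(np.where(y == 1, "late", "early")),
                             [1, 5], holdout=0.34, iterations=1, seed=0)
        assert set(out["n_datapoints"]) == {1, 5}

    def test_more_evidence_helps_on_planted_signal(self):
        config = CohortConfig(n_early=10, n_late=10, n_peaks=80, n_diff=20,
                              noise_cv=0.1, seed=6)
        maps, manifest, _ = generate_cohort(config)
        grid = parse_grid(maps, GridSpec())
        labels = manifest.set_index("sample_id")["stage"]
        out = learning_curve(grid, labels, [1, 40], iterations=25, seed=2)
        err = out.set_index("n_datapoints")["mean_error"]
        assert err[40] <= err[1]

    def test_mock_curve_paired_with_real(self):
        config = CohortConfig(n_early=10, n_late=10, n_peaks=80, n_diff=25,
                              noise_cv=0.1, seed=8)
        maps, manifest, _ = generate_cohort(config)
        grid = parse_grid(maps, GridSpec())
        labels = manifest.set_index("sample_id")["stage"]
        mock = make_mock_assembly(manifest, 5, 5, seed=3)
        out = learning_curve(grid, labels, [5, 40], iterations=25, seed=4,
                             mock_labels=mock.set_index("sample_id")["stage"])
        real = out[out["assembly"] == "real"]["mean_error"].min()
        mock_err = out[out["assembly"] == "mock"]["mean_error"].min()
        assert real < mock_err


class TestReparseTop:
    def test_single_centroid_cell_maps_to_its_fine_cell(self):
        m = MSMap("s", [95.0], [600.13], [5.0])
        grid = parse_grid([m], GridSpec())
        ranked = grid.bounds_frame()  # reparse needs only the cell bounds
        feats = reparse_top(ranked, [m], top_k=1)
        assert feats["feature_rt"].iloc[0] == pytest.approx(90.0)  # [90, 100) at 10 s
        assert feats["feature_mz"].iloc[0] == pytest.approx(600.13, abs=0.01)

    def test_fine_bins_conserve_cell_intensity(self, small_cohort):
        _, maps, manifest, _ = small_cohort
        grid = parse_grid(maps, GridSpec())
        ranked = rank_datapoints(grid, manifest.set_index("sample_id")["stage"])
        feats = reparse_top(ranked, maps, top_k=30)
        total_cells = grid.values.sum(axis=1)
        lookup = {(r["rt_lo"], r["mz_lo"]): total_cells[i]
                  for i, r in grid.bounds_frame().iterrows()}
        for _, f in feats.iterrows():
            assert f["cell_total_intensity"] == pytest.approx(
                lookup[(f["coarse_rt_lo"], f["coarse_mz_lo"])]
            )

    def test_shared_feature_counted_in_overlap(self):
        f1 = pd.DataFrame({"feature_rt": [100.0, 200.0], "feature_mz": [600.0, 700.0]})
        f2 = pd.DataFrame({"feature_rt": [100.0], "feature_mz": [600.0]})
        out = feature_overlap({"a": f1, "b": f2}).set_index("resolution")
        assert out.loc["a", "n_unique"] == 1
        assert out.loc["b", "n_unique"] == 0


class TestClusterOrder:
    def test_identical_subjects_are_adjacent(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(size=10)
        V = np.column_stack([base, base, rng.uniform(size=10), -base + 1])
        subj, dp, _ = cluster_order(V)
        pos = {s: i for i, s in enumerate(subj)}
        assert abs(pos[0] - pos[1]) == 1

    def test_planted_subgroups_separate(self):
        rng = np.random.default_rng(1)
        g1 = rng.normal(0, 0.1, size=(20, 4)) + np.linspace(0, 1, 20)[:, None]
        g2 = rng.normal(0, 0.1, size=(20, 4)) - np.linspace(0, 1, 20)[:, None]
        V = np.hstack([g1, g2])
        subj, _, _ = cluster_order(V)
        first_half = set(subj[:4])
        assert first_half in ({0, 1, 2, 3}, {4, 5, 6, 7})

    def test_orders_are_permutations(self, small_cohort):
        _, maps, _, _ = small_cohort
        grid = parse_grid(maps[:6], GridSpec())
        subj, dp, V = cluster_order(grid)
        assert sorted(subj) == list(range(6))
        assert sorted(dp) == list(range(V.shape[0]))
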