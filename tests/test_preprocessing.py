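"""Alignment, reference qualification, normalization and batch adjustment."""

import numpy as np
import pandas as pd
import pytest

from peptistage import (
    MSMap,
    align_sample,
    batch_adjust,
    build_peak_table,
    extract_and_normalize,
    qualify_reference,
)
from peptistage.preprocessing import AlignmentError, ReferencePeak


def landmarks_df(pairs):
    return pd.DataFrame(pairs, columns=["mz", "rt"])


class TestAlignSample:
    def test_landmarks_at_consensus_give_identity(self):
        m = MSMap("s", [100.0, 200.0, 300.0], [600.0, 700.0, 800.0], [1.0, 1.0, 1.0])
        lm = landmarks_df([(600.0, 100.0), (800.0, 300.0)])
        aligned, amap = align_sample(m, lm)
        assert np.allclose(aligned.rt, m.rt)
        assert np.allclose(amap.nodes[:, 0], amap.nodes[:, 1])

    def test_uniform_shift_inverted_exactly(self):
        true_rt = np.array([100.0, 150.0, 200.0, 300.0])
        m = MSMap("s", true_rt + 10.0, [600.0, 650.0, 700.0, 800.0], np.ones(4))
        lm = landmarks_df([(600.0, 100.0), (800.0, 300.0)])
        aligned, _ = align_sample(m, lm)
        assert np.allclose(aligned.rt, true_rt, atol=1e-9)

    def test_generator_warp_inverted_at_landmarks(self, small_cohort):
        """After alignment every landmark sits exactly at its consensus RT and
        other peaks are within the warp's node-jitter bound."""
        config, maps, _, truth = small_cohort
        lm = truth.landmark_coords
        for m in maps[:4]:
            aligned, _ = align_sample(m, lm)
            for mz, rt in zip(lm["mz"], lm["rt"]):
                hit = np.abs(aligned.mz - mz) <= 0.01
                hit &= np.abs(aligned.rt - rt) <= 4 * config.rt_drift_sd
                assert np.min(np.abs(aligned.rt[hit] - rt)) < 1e-9
            anchors, observed = truth.sample_warps[m.sample_id]
            bound = np.max(np.abs(observed - anchors)) * 2 + 1e-9
            true_rt = np.interp(m.rt, observed, anchors)
            assert np.max(np.abs(aligned.rt - true_rt)) <= bound

    def test_alignment_is_idempotent(self, small_cohort):
        _, maps, _, truth = small_cohort
        aligned, _ = align_sample(maps[0], truth.landmark_coords)
        again, amap = align_sample(aligned, truth.landmark_coords)
        assert np.allclose(again.rt, aligned.rt, atol=1e-9)
        assert np.allclose(amap.nodes[:, 0], amap.nodes[:, 1], atol=1e-9)

    def test_unmatched_landmark_is_an_error(self):
        m = MSMap("s", [100.0, 300.0], [600.0, 800.0], [1.0, 1.0])
        lm = landmarks_df([(600.0, 100.0), (900.0, 300.0)])
        with pytest.raises(AlignmentError, match="unmatched"):
            align_sample(m, lm)

    def test_multiply_matched_landmark_is_an_error(self):
        m = MSMap("s", [100.0, 101.0, 300.0], [600.0, 600.005, 800.0], np.ones(3))
        lm = landmarks_df([(600.0, 100.0), (800.0, 300.0)])
        with pytest.raises(AlignmentError, match="matched 2"):
            align_sample(m, lm)

    def test_non_monotone_matches_rejected(self):
        # observed order 100 < 200 but consensus order 190 > 110
        m = MSMap("s", [100.0, 200.0], [600.0, 700.0], [1.0, 1.0])
        lm = landmarks_df([(600.0, 190.0), (700.0, 110.0)])
        with pytest.raises(AlignmentError):
            align_sample(m, lm, rt_search=150)


class TestQualifyReference:
    def setup_tables(self, ref_intensities):
        peaks = pd.DataFrame({"mz": [500.0, 500.5], "rt": [100.0, 105.0]})
        samples = [f"s{i}" for i in range(6)]
        intens = pd.DataFrame(
            [np.array([50, 55, 45, 52, 48, 51]), np.asarray(ref_intensities, dtype=float)],
            columns=samples,
        )
        labels = pd.Series(["early"] * 3 + ["late"] * 3, index=samples)
        return peaks, intens, labels

    def test_absent_peak_rejected_for_presence(self):
        peaks, intens, labels = self.setup_tables([10, 10, 0, 10, 10, 10])
        ref, rej = qualify_reference(500.0, 100.0, peaks, intens, labels,
                                     exclude_tol=(0.0, 0.0))
        reasons = {(r["mz"], r["reason"]) for r in rej}
        assert (500.5, "presence") in reasons

    def test_class_imbalanced_peak_rejected_for_comparability(self):
        """Class means 100 vs 300 (ratio 3) fall outside the 0.8-1.25 band."""
        peaks, intens, labels = self.setup_tables([100, 100, 100, 300, 300, 300])
        ref, rej = qualify_reference(500.0, 100.0, peaks, intens, labels,
                                     exclude_tol=(0.0, 0.0))
        reasons = {(r["mz"], r["reason"]) for r in rej}
        assert (500.5, "comparability") in reasons

    def test_nearest_mz_wins_among_qualifiers(self):
        peaks = pd.DataFrame({"mz": [500.01, 500.05], "rt": [100.0, 100.0]})
        samples = [f"s{i}" for i in range(6)]
        vals = np.array([10, 11, 9, 10, 10.5, 9.5])
        intens = pd.DataFrame([vals, vals * 2], columns=samples)
        labels = pd.Series(["early"] * 3 + ["late"] * 3, index=samples)
        ref, _ = qualify_reference(500.0, 100.0, peaks, intens, labels,
                                   exclude_tol=(0.0, 0.0))
        assert ref.mz == pytest.approx(500.01)

    def test_no_qualifier_returns_none_not_unity(self):
        peaks, intens, labels = self.setup_tables([100, 100, 100, 300, 300, 300])
        intens.iloc[0] = [0, 1, 1, 1, 1, 1]  # first peak now absent somewhere
        ref, rej = qualify_reference(500.0, 100.0, peaks, intens, labels,
                                     exclude_tol=(0.0, 0.0))
        assert ref is None
        assert len(rej) == 2

    def test_never_selects_a_planted_marker(self, small_cohort):
        """Differential markers (two-fold effect) always fail the
        comparability band, so they cannot become their own references."""
        _, maps, manifest, truth = small_cohort
        labels = manifest.set_index("sample_id")["stage"]
        aligned = [align_sample(m, truth.landmark_coords)[0] for m in maps]
        peaks, intens = build_peak_table(aligned)
        marker_keys = {
            (round(mz, 3), round(rt, 1))
            for mz, rt in zip(truth.marker_coords["mz"], truth.marker_coords["rt"])
        }
        for _, mk in truth.marker_coords.iterrows():
            ref, _ = qualify_reference(mk["mz"], mk["rt"], peaks, intens, labels)
            if ref is not None:
                assert (round(ref.mz, 3), round(ref.rt, 1)) not in marker_keys


class TestExtractAndNormalize:
    def make_maps(self, raws):
        return [
            MSMap(f"s{i}", [100.0], [600.0], [raw]) for i, raw in enumerate(raws)
        ]

    def run(self, raws, refs, mode="ratio"):
        maps = self.make_maps(raws)
        ids = [m.sample_id for m in maps]
        markers = pd.DataFrame({"serial": [1], "mz": [600.0], "z": [1], "rt": [100.0]})
        references = {1: ReferencePeak(601.0, 100.0, pd.Series(refs, index=ids))}
        labels = pd.Series(["early", "late", "late"], index=ids)
        batches = pd.Series(["B1"] * 3, index=ids)
        return extract_and_normalize(maps, markers, references, labels, batches, mode=mode)

    def test_equal_raws_and_refs_give_unit_values(self):
        table = self.run([5.0, 5.0, 5.0], [2.0, 2.0, 2.0])
        assert np.allclose(table.matrix[1], 1.0)

    def test_hand_arithmetic(self):
        table = self.run([2.0, 4.0, 6.0], [1.0, 1.0, 1.0])
        assert np.allclose(table.matrix[1], [0.5, 1.0, 1.5])

    def test_global_sample_scaling_cancels(self):
        base = self.run([2.0, 4.0, 6.0], [1.0, 1.0, 1.0])
        scaled = self.run([4.0, 4.0, 6.0], [2.0, 1.0, 1.0])  # sample 0 doubled
        assert np.allclose(base.matrix[1], scaled.matrix[1])

    def test_unit_column_means_by_construction(self, small_cohort):
        _, maps, manifest, truth = small_cohort
        labels = manifest.set_index("sample_id")["stage"]
        batches = manifest.set_index("sample_id")["batch_id"]
        aligned = [align_sample(m, truth.landmark_coords)[0] for m in maps]
        peaks, intens = build_peak_table(aligned)
        refs = {}
        for _, mk in truth.marker_coords.iterrows():
            ref, _ = qualify_reference(mk["mz"], mk["rt"], peaks, intens, labels)
            if ref is not None:
                refs[mk["serial"]] = ref
        markers = truth.marker_coords[truth.marker_coords["serial"].isin(refs)]
        table = extract_and_normalize(aligned, markers, refs, labels, batches)
        assert len(refs) >= 5
        assert np.allclose(table.matrix.mean(axis=0), 1.0)

    def test_zero_reference_intensity_is_an_error(self):
        with pytest.raises(ValueError):
            self.run([2.0, 4.0, 6.0], [1.0, 0.0, 1.0])

    def test_missing_marker_without_reference_is_an_error(self):
        maps = self.make_maps([1.0, 1.0, 1.0])
        markers = pd.DataFrame({"serial": [1], "mz": [600.0], "z": [1], "rt": [100.0]})
        ids = [m.sample_id for m in maps]
        with pytest.raises(ValueError, match="without a qualified reference"):
            extract_and_normalize(
                maps, markers, {}, pd.Series(["early", "late", "late"], index=ids),
                pd.Series(["B1"] * 3, index=ids),
            )


class TestBatchAdjust:
    def test_single_batch_unchanged(self, make_toy_table):
        table = make_toy_table(np.random.default_rng(0).uniform(1, 2, (6, 3)),
                               ["early"] * 3 + ["late"] * 3)
        out = batch_adjust(table)
        assert np.allclose(out.matrix.to_numpy(), table.matrix.to_numpy())

    def test_pure_batch_factor_removed(self, make_toy_table):
        rng = np.random.default_rng(1)
        block = rng.uniform(1, 2, (4, 3))
        table = make_toy_table(np.vstack([block, block * 2.0]),
                               ["early", "early", "late", "late"] * 2)
        table.batches[:] = ["B1"] * 4 + ["B2"] * 4
        out = batch_adjust(table)
        mat = out.matrix
        b1 = mat.iloc[:4].mean(axis=0)
        b2 = mat.iloc[4:].mean(axis=0)
        assert np.allclose(b1, b2, atol=1e-9)
        assert np.allclose(mat.mean(axis=0), table.matrix.mean(axis=0), atol=1e-9)

    def test_class_effect_survives_orthogonal_batches(self):
        from peptistage import CohortConfig, simulate_marker_table
        config = CohortConfig(n_early=20, n_late=20, n_peaks=0, n_diff=6,
                              frac_down=0.5, effect=2.0, noise_cv=0.1,
                              n_batches=2, batch_shift=1.1, seed=9)
        table, planted = simulate_marker_table(config)
        out = batch_adjust(table)
        for _, row in planted.iterrows():
            early, late = out.values_by_class(row["serial"])
            ratio = late.mean() / early.mean()
            expected = 2.0 if row["direction"] == "U" else 0.5
            assert ratio == pytest.approx(expected, rel=0.10)

    def test_small_batch_is_an_error(self, make_toy_table):
        table = make_toy_table(np.ones((3, 2)), ["early", "late", "late"])
        table.batches[:] = ["B1", "B1", "B2"]
        with pytest.raises(ValueError, match="< 2"):
            batch_adjust(table)
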