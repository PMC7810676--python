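"""Split design, accuracy metrics, bootstrap summaries and the
experiment/results objects."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import wingbeat as wb
from wingbeat.evaluate import (
    ExperimentResults,
    FoldResult,
    OneVsAllExperiment,
    SplitSpec,
    accuracy,
    bootstrap_interval,
    build_split,
    derive_fold_seed,
    pairwise_accuracy,
    session_counts,
)

from conftest import make_flyer


class TestBuildSplit:
    def test_reference_design_counts(self, default_dataset):
        split = build_split(
            default_dataset, SplitSpec(target="sawfly", seed=1)
        )
        assert len(split.train_idx) == 669
        assert split.train_is_target.sum() == 333
        assert len(split.test_idx) == 450
        counts = pd.Series(split.test_species).value_counts()
        assert (counts == 50).all() and len(counts) == 9

    def test_strict_mode_disjoint(self, default_dataset):
        split = build_split(
            default_dataset, SplitSpec(target="sawfly", seed=2)
        )
        assert not set(split.train_idx) & set(split.test_idx)

    def test_same_seed_identical_indices(self, default_dataset):
        a = build_split(default_dataset, SplitSpec(target="pod_midge", seed=3))
        b = build_split(default_dataset, SplitSpec(target="pod_midge", seed=3))
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        np.testing.assert_array_equal(a.test_idx, b.test_idx)

    def test_small_pool_strict_raises_lenient_passes(self, library, sensor):
        ds = wb.simulate_labeled_dataset(library, 371, sensor=sensor, seed=4,
                                         peak_snr=30.0)
        with pytest.raises(ValueError):
            build_split(ds, SplitSpec(target="sawfly", seed=1, strict=True))
        split = build_split(
            ds, SplitSpec(target="sawfly", seed=1, strict=False)
        )
        assert len(split.train_idx) == 669 and len(split.test_idx) == 450

    def test_unknown_target_raises(self, default_dataset):
        with pytest.raises(ValueError):
            build_split(default_dataset, SplitSpec(target="dragonfly"))


class TestAccuracy:
    def test_confusion_matrix_formula(self):
        # TP=40, TN=35, FP=15, FN=10 -> (40+35)/100
        truth = np.array([True] * 50 + [False] * 50)
        predicted = np.concatenate(
            [
                np.repeat(True, 40), np.repeat(False, 10),   # targets
                np.repeat(False, 35), np.repeat(True, 15),   # others
            ]
        )
        assert accuracy(predicted, truth) == pytest.approx(0.75)

    def test_extremes(self):
        t = np.array([True, False, True])
        assert accuracy(t, t) == 1.0
        assert accuracy(~t, t) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            accuracy([True], [True, False])


class TestPairwiseAccuracy:
    def setup_method(self):
        self.species = np.array(
            ["t"] * 50 + ["o1"] * 50 + ["o2"] * 50, dtype=object
        )

    def test_all_target_prediction_gives_half(self):
        predicted = np.ones(150, dtype=bool)
        assert pairwise_accuracy(predicted, self.species, "t", "o1") == 0.5

    def test_equals_restricted_accuracy(self):
        rng = np.random.default_rng(5)
        predicted = rng.random(150) < 0.5
        sub = np.r_[np.arange(50), np.arange(50, 100)]
        expected = accuracy(predicted[sub], self.species[sub] == "t")
        assert pairwise_accuracy(predicted, self.species, "t", "o1") == expected

    def test_insufficient_events_raise(self):
        with pytest.raises(ValueError):
            pairwise_accuracy(np.ones(150, dtype=bool), self.species,
                              "t", "o3")


class TestBootstrapInterval:
    def test_constant_values_zero_width(self):
        assert bootstrap_interval([0.8] * 10) == (0.8, 0.8)

    def test_linear_interpolation_convention(self):
        lo, hi = bootstrap_interval(np.arange(1.0, 101.0))
        assert lo == pytest.approx(5.95)
        assert hi == pytest.approx(95.05)

    def test_contains_median(self):
        rng = np.random.default_rng(6)
        vals = rng.random(31)
        lo, hi = bootstrap_interval(vals)
        assert lo <= np.median(vals) <= hi

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError):
            bootstrap_interval([0.5])


class TestSessionAccounting:
    def test_reference_grid(self):
        assert session_counts(9, 3, 100) == (2700, 21_600)

    def test_reduced_grids(self):
        assert session_counts(9, 3, 2) == (54, 432)
        assert session_counts(9, 1, 5) == (45, 360)

    def test_fold_seed_stream(self):
        seeds = {
            derive_fold_seed(1, "sawfly", m, f)
            for m in ("wbf", "nn")
            for f in range(50)
        }
        assert len(seeds) == 100  # distinct across method x fold
        assert all(0 <= s < 2**31 for s in seeds)
        assert derive_fold_seed(1, "sawfly", "wbf", 0) == derive_fold_seed(
            1, "sawfly", "wbf", 0
        )


def synthetic_results(matrix, methods=("m1",), n_folds=1):
    """Build ExperimentResults from a {target: {other: acc}} per-method
    nested dict."""
    species = sorted(matrix[methods[0]])
    folds = []
    for method in methods:
        for target in species:
            for fold in range(n_folds):
                pairwise = dict(matrix[method][target])
                overall = float(np.mean(list(pairwise.values())))
                folds.append(
                    FoldResult(target, method, fold, overall, pairwise)
                )
    n_train = len(folds)
    return ExperimentResults(
        folds=folds, species=species, methods=list(methods),
        n_folds=n_folds, master_seed=0, n_training_sessions=n_train,
        n_pairwise_test_sessions=sum(len(f.pairwise) for f in folds),
    )


def grid(species, value_fn):
    return {
        t: {o: value_fn(t, o) for o in species if o != t} for t in species
    }


class TestHardestOther:
    species = [f"s{i}" for i in range(9)]

    def test_unique_minimum(self):
        res = synthetic_results(
            {"m1": grid(self.species,
                        lambda t, o: 0.6 if o == "s3" and t != "s3" else 0.9)}
        )
        assert res.hardest_other("s0", "m1") == "s3"

    def test_tie_broken_lexicographically(self):
        res = synthetic_results(
            {"m1": grid(self.species, lambda t, o: 0.7)}
        )
        assert res.hardest_other("s0", "m1") == "s1"

    def test_second_lowest_after_removal(self):
        def acc(t, o):
            return {"s3": 0.6, "s5": 0.65}.get(o, 0.9)

        full = synthetic_results({"m1": grid(self.species, acc)})
        assert full.hardest_other("s0", "m1") == "s3"
        reduced_species = [s for s in self.species if s != "s3"]
        reduced = synthetic_results({"m1": grid(reduced_species, acc)})
        assert reduced.hardest_other("s0", "m1") == "s5"


class TestCompareMethods:
    species = [f"s{i}" for i in range(9)]

    def test_self_comparison_all_ties(self):
        res = synthetic_results(
            {"m1": grid(self.species, lambda t, o: 0.8)}, methods=("m1",)
        )
        out = res.compare_methods("m1", "m1")
        assert out == {"a_wins": 0, "b_wins": 0, "ties": 72, "total": 72}

    def test_dominant_method_wins_everywhere(self):
        res = synthetic_results(
            {
                "m1": grid(self.species, lambda t, o: 0.9),
                "m2": grid(self.species, lambda t, o: 0.7),
            },
            methods=("m1", "m2"),
        )
        out = res.compare_methods("m1", "m2")
        assert out["a_wins"] == 72 and out["total"] == 72

    def test_unevaluated_method_raises(self):
        res = synthetic_results(
            {"m1": grid(self.species, lambda t, o: 0.8)}
        )
        with pytest.raises(ValueError):
            res.compare_methods("m1", "nn")


@pytest.fixture(scope="module")
def small_results(default_dataset, default_reps):
    exp = OneVsAllExperiment(
        default_dataset, methods=("wbf",), n_folds=2,
        representations=default_reps,
    )
    assert exp.planned_sessions() == (18, 144)
    return exp.fit(seed=7)


class TestExperimentEndToEnd:
    def test_session_bookkeeping(self, small_results):
        assert small_results.n_training_sessions == 18
        assert small_results.n_pairwise_test_sessions == 144

    def test_folds_frame_shape(self, small_results):
        df = small_results.folds_frame()
        assert len(df) == 18
        assert df["overall_accuracy"].between(0, 1).all()

    def test_summary_stats_match_raw_folds(self, small_results):
        """Means/medians in the summaries must be exactly recomputable
        from the raw per-fold values."""
        stats = small_results.pairwise_stats()
        for _, row in stats.sample(10, random_state=0).iterrows():
            vals = small_results.pairwise_values(
                row["target"], row["method"], row["other"]
            )
            assert row["mean"] == pytest.approx(vals.mean())
            assert row["median"] == pytest.approx(np.median(vals))
            assert row["q5"] <= row["median"] <= row["q95"]

    def test_overall_matches_brute_force_confusion(self, small_results,
                                                   default_dataset,
                                                   default_reps):
        """Re-run one fold by hand and recompute accuracy event by
        event."""
        from wingbeat import classify
        from wingbeat.evaluate import derive_fold_seed

        target = small_results.species[0]
        fold_seed = derive_fold_seed(7, target, "wbf", 0)
        split = build_split(default_dataset,
                            SplitSpec(target=target, seed=fold_seed))
        clf = classify.fit("wbf", default_reps.wbf[split.train_idx],
                           split.train_is_target, seed=fold_seed,
                           target_species=target)
        predicted = clf.predict(default_reps.wbf[split.test_idx])
        tp = int(np.sum(predicted & split.test_is_target))
        tn = int(np.sum(~predicted & ~split.test_is_target))
        expected = (tp + tn) / 450
        got = small_results.overall_values(target, "wbf")[0]
        assert got == pytest.approx(expected)

    def test_save_and_roundtrip(self, small_results, tmp_path):
        small_results.save(tmp_path)
        assert (tmp_path / "folds.csv").exists()
        assert (tmp_path / "summary.json").exists()
        assert (tmp_path / "matrix_wbf.csv").exists()
        restored = ExperimentResults.from_folds_frame(
            pd.read_csv(tmp_path / "folds.csv")
        )
        pd.testing.assert_frame_equal(
            restored.pairwise_stats(), small_results.pairwise_stats()
        )

    def test_matrix_shape_and_diagonal(self, small_results):
        mat = small_results.pairwise_matrix("wbf")
        assert mat.shape == (9, 9)
        assert mat.values[np.diag_indices(9)].tolist() == [
            pytest.approx(np.nan, nan_ok=True)
        ] * 9
        off_diag = mat.values[~np.eye(9, dtype=bool)]
        assert np.isfinite(off_diag).all()

    def test_summary_renders(self, small_results):
        text = small_results.summary()
        assert "training sessions: 18" in text
        assert "wbf" in text

    def test_invalid_construction(self, default_dataset):
        with pytest.raises(ValueError):
            OneVsAllExperiment(default_dataset, methods=("svm",))
        with pytest.raises(ValueError):
            OneVsAllExperiment(default_dataset, n_folds=0)
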