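"""One-vs-all evaluation: split design, accuracy metrics and the
bootstrapped repetition loop.

The design mirrors a fixed per-target fold: 333 training events from the
target species plus 42 from each of the other eight (336 "other", 669 in
total), tested on 50 held-out events per species (450).  The loop is
repeated over randomized folds (100 in the reference design) for every
target x method cell; accuracy is (TP + TN) / N, reported both on the
full 450-event test set and pairwise on the 100-event target-vs-one-other
subsets.  Spread across folds is summarised by the 90% bootstrapping
interval (5th-95th percentile).

The public surface is the model/results pair
:class:`OneVsAllExperiment` -> :class:`ExperimentResults`, with thin
functional wrappers (:func:`run_experiment`, :func:`accuracy`, ...)
around the same machinery.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import classify
from .classify import METHODS, ForestConfig, NNConfig
from .features import full_feature_set
from .simulate import LabeledEventSet
from .spectral import power_spectrum, spectral_vector

__all__ = [
    "SplitSpec",
    "Split",
    "FoldResult",
    "EventRepresentations",
    "OneVsAllExperiment",
    "ExperimentResults",
    "build_split",
    "accuracy",
    "pairwise_accuracy",
    "run_experiment",
    "bootstrap_interval",
    "hardest_other",
    "compare_methods",
    "session_counts",
    "derive_fold_seed",
]

logger = logging.getLogger("wingbeat")


@dataclass(frozen=True)
class SplitSpec:
    """Per-fold sampling design for one target species."""

    target: str
    n_target_train: int = 333
    n_other_train_each: int = 42
    n_test_each: int = 50
    seed: int = 0
    strict: bool = True

    def __post_init__(self) -> None:
        if min(self.n_target_train, self.n_other_train_each, self.n_test_each) <= 0:
            raise ValueError("all split counts must be positive")


@dataclass
class Split:
    """Index sets of one fold; indices refer to the parent dataset."""

    train_idx: np.ndarray
    train_is_target: np.ndarray
    test_idx: np.ndarray
    test_species: np.ndarray
    target: str

    @property
    def test_is_target(self) -> np.ndarray:
        return self.test_species == self.target


def build_split(dataset: LabeledEventSet, spec: SplitSpec) -> Split:
    """Draw one train/test fold according to ``spec``.

    Sampling is without replacement within each pool.  In strict mode
    train and test are disjoint, which requires a pool of at least
    ``n_target_train + n_test_each`` target events (383 in the reference
    design) and ``n_other_train_each + n_test_each`` (92) per other
    species.  In lenient mode the test draw comes from the full pool and
    may overlap the training set (logged as a warning), accommodating
    pools as small as the design counts themselves.
    """
    species = dataset.species()
    if len(species) < 2:
        raise ValueError("dataset must contain at least two species")
    if spec.target not in species:
        raise ValueError(f"target {spec.target!r} not in dataset")
    rng = np.random.default_rng(spec.seed)

    train_parts: List[np.ndarray] = []
    test_parts: List[np.ndarray] = []
    for sp in species:
        pool = dataset.indices_of(sp)
        n_train = spec.n_target_train if sp == spec.target else spec.n_other_train_each
        need = n_train + spec.n_test_each if spec.strict else max(
            n_train, spec.n_test_each
        )
        if len(pool) < need:
            raise ValueError(
                f"species {sp!r} pool has {len(pool)} events; "
                f"{need} required"
            )
        perm = rng.permutation(pool)
        train_parts.append(perm[:n_train])
        if spec.strict:
            test_parts.append(perm[n_train : n_train + spec.n_test_each])
        else:
            logger.warning(
                "lenient split: test draw for %s may overlap training set", sp
            )
            test_parts.append(rng.permutation(pool)[: spec.n_test_each])

    train_idx = np.concatenate(train_parts)
    test_idx = np.concatenate(test_parts)
    labels = np.asarray(dataset.labels, dtype=object)
    return Split(
        train_idx=train_idx,
        train_is_target=labels[train_idx] == spec.target,
        test_idx=test_idx,
        test_species=labels[test_idx],
        target=spec.target,
    )


def accuracy(predicted, truth) -> float:
    """(TP + TN) / N on boolean label arrays."""
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    if predicted.size == 0:
        raise ValueError("empty label arrays")
    return float(np.mean(predicted == truth))


def pairwise_accuracy(
    predicted, test_species, target: str, other: str, n_each: int = 50
) -> float:
    """Accuracy restricted to ``n_each`` target plus ``n_each``
    specific-other test events."""
    predicted = np.asarray(predicted, dtype=bool)
    test_species = np.asarray(test_species, dtype=object)
    t_idx = np.flatnonzero(test_species == target)[:n_each]
    o_idx = np.flatnonzero(test_species == other)[:n_each]
    if len(t_idx) < n_each or len(o_idx) < n_each:
        raise ValueError("insufficient test events for pairwise accuracy")
    idx = np.concatenate([t_idx, o_idx])
    return accuracy(predicted[idx], test_species[idx] == target)


def bootstrap_interval(values, level: float = 0.90) -> Tuple[float, float]:
    """(5th, 95th) percentile bootstrapping interval at the default 90%
    level, by the linear-interpolation percentile convention."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("bootstrap_interval requires at least 2 values")
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(values, [alpha, 100.0 - alpha], method="linear")
    return float(lo), float(hi)


def derive_fold_seed(master_seed: int, target: str, method: str, fold: int) -> int:
    """Deterministic per-fold seed stream, stable across platforms."""
    key = f"{master_seed}:{target}:{method}:{fold}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def session_counts(
    n_targets: int, n_methods: int, n_folds: int, n_others: Optional[int] = None
) -> Tuple[int, int]:
    """(training sessions, pairwise test sessions) of a full grid.

    Each target x method x fold is one training session; each is tested
    pairwise against every other species.
    """
    if n_others is None:
        n_others = n_targets - 1
    train = n_targets * n_methods * n_folds
    return train, train * n_others


@dataclass
class FoldResult:
    target: str
    method: str
    fold_index: int
    overall_accuracy: float
    pairwise: Dict[str, float]


@dataclass
class EventRepresentations:
    """The three classifier inputs, precomputed once per dataset."""

    wbf: np.ndarray       # (n, 1)
    features: np.ndarray  # (n, 12)
    vectors: np.ndarray   # (n, 2048)
    labels: np.ndarray    # (n,) species strings

    @classmethod
    def from_dataset(cls, dataset: LabeledEventSet) -> "EventRepresentations":
        feats = []
        vecs = []
        for ev in dataset.events:
            spec = power_spectrum(ev)
            feats.append(full_feature_set(ev, spectrum=spec).as_array())
            vecs.append(spectral_vector(spec).values.astype(np.float32))
        features = np.asarray(feats)
        return cls(
            wbf=features[:, :1].copy(),
            features=features,
            vectors=np.asarray(vecs, dtype=np.float32),
            labels=np.asarray(dataset.labels, dtype=object),
        )

    def inputs_for(self, method: str) -> np.ndarray:
        return {"wbf": self.wbf, "features": self.features, "nn": self.vectors}[method]


class OneVsAllExperiment:
    """Model object for the full one-vs-all evaluation grid.

    Built from a labeled event set (or precomputed
    :class:`EventRepresentations`); ``fit(seed)`` runs every
    target x method x fold cell and returns an
    :class:`ExperimentResults`.

    Parameters
    ----------
    dataset : LabeledEventSet
        Labeled events, at least two species.
    methods : sequence of {"wbf", "features", "nn"}
        Classification methods to evaluate.
    n_folds : int
        Randomized repetitions per target x method cell (reference
        design: 100).
    split : SplitSpec template (target/seed fields are overridden per cell).
    nn_config, forest_config : optional method configurations.
    """

    def __init__(
        self,
        dataset: LabeledEventSet,
        methods: Sequence[str] = METHODS,
        n_folds: int = 100,
        split: Optional[SplitSpec] = None,
        nn_config: Optional[NNConfig] = None,
        forest_config: Optional[ForestConfig] = None,
        representations: Optional[EventRepresentations] = None,
    ) -> None:
        unknown = set(methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if n_folds < 1:
            raise ValueError("n_folds must be >= 1")
        self.dataset = dataset
        self.methods = tuple(methods)
        self.n_folds = int(n_folds)
        self.split_template = split or SplitSpec(target="")
        self.nn_config = nn_config
        self.forest_config = forest_config
        self._reps = representations
        self.species = dataset.species()

    @property
    def representations(self) -> EventRepresentations:
        if self._reps is None:
            logger.info("computing event representations for %d events",
                        len(self.dataset))
            self._reps = EventRepresentations.from_dataset(self.dataset)
        return self._reps

    def planned_sessions(self, n_folds: Optional[int] = None) -> Tuple[int, int]:
        """(training, pairwise test) session counts of the grid."""
        return session_counts(
            len(self.species), len(self.methods), n_folds or self.n_folds
        )

    def fit(self, seed: int = 0) -> "ExperimentResults":
        """Run the full grid; deterministic given ``seed``."""
        reps = self.representations
        tmpl = self.split_template
        folds: List[FoldResult] = []
        n_train_sessions = 0
        n_pairwise_sessions = 0
        for target in self.species:
            others = [sp for sp in self.species if sp != target]
            for method in self.methods:
                X_all = reps.inputs_for(method)
                config = (
                    self.nn_config if method == "nn" else self.forest_config
                )
                for fold in range(self.n_folds):
                    fold_seed = derive_fold_seed(seed, target, method, fold)
                    split = build_split(
                        self.dataset,
                        SplitSpec(
                            target=target,
                            n_target_train=tmpl.n_target_train,
                            n_other_train_each=tmpl.n_other_train_each,
                            n_test_each=tmpl.n_test_each,
                            seed=fold_seed,
                            strict=tmpl.strict,
                        ),
                    )
                    clf = classify.fit(
                        method,
                        X_all[split.train_idx],
                        split.train_is_target,
                        config=config,
                        seed=fold_seed,
                        target_species=target,
                    )
                    n_train_sessions += 1
                    predicted = clf.predict(X_all[split.test_idx])
                    overall = accuracy(predicted, split.test_is_target)
                    pairwise = {}
                    for other in others:
                        pairwise[other] = pairwise_accuracy(
                            predicted,
                            split.test_species,
                            target,
                            other,
                            n_each=tmpl.n_test_each,
                        )
                        n_pairwise_sessions += 1
                    folds.append(
                        FoldResult(target, method, fold, overall, pairwise)
                    )
                logger.info(
                    "target=%s method=%s: %d folds done", target, method,
                    self.n_folds,
                )
        logger.info(
            "experiment complete: %d training sessions, %d pairwise test sessions",
            n_train_sessions, n_pairwise_sessions,
        )
        return ExperimentResults(
            folds=folds,
            species=list(self.species),
            methods=list(self.methods),
            n_folds=self.n_folds,
            master_seed=seed,
            n_training_sessions=n_train_sessions,
            n_pairwise_test_sessions=n_pairwise_sessions,
        )


@dataclass
class ExperimentResults:
    """Results of a fitted :class:`OneVsAllExperiment`.

    Carries the raw per-fold accuracies plus derived summaries: means,
    medians, 90% bootstrapping intervals, hardest-other species and the
    pairwise accuracy matrices.
    """

    folds: List[FoldResult]
    species: List[str]
    methods: List[str]
    n_folds: int
    master_seed: int
    n_training_sessions: int
    n_pairwise_test_sessions: int
    _frame: Optional[pd.DataFrame] = field(default=None, repr=False)

    @classmethod
    def from_folds_frame(cls, df: pd.DataFrame) -> "ExperimentResults":
        """Reconstruct results from a folds.csv table written by
        :meth:`save`."""
        acc_cols = [c for c in df.columns if c.startswith("acc_vs_")]
        species = sorted(
            set(df["target"]) | {c[len("acc_vs_"):] for c in acc_cols}
        )
        methods = list(dict.fromkeys(df["method"]))
        folds = []
        for _, row in df.iterrows():
            pairwise = {
                c[len("acc_vs_"):]: row[c]
                for c in acc_cols
                if pd.notna(row[c])
            }
            folds.append(
                FoldResult(
                    target=row["target"],
                    method=row["method"],
                    fold_index=int(row["fold"]),
                    overall_accuracy=float(row["overall_accuracy"]),
                    pairwise=pairwise,
                )
            )
        n_folds = int(df["fold"].max()) + 1 if len(df) else 0
        n_train = len(folds)
        n_pairwise = sum(len(fr.pairwise) for fr in folds)
        return cls(
            folds=folds,
            species=species,
            methods=methods,
            n_folds=n_folds,
            master_seed=-1,
            n_training_sessions=n_train,
            n_pairwise_test_sessions=n_pairwise,
        )

    def folds_frame(self) -> pd.DataFrame:
        """Long-form table: one row per fold x target x method, with the
        overall accuracy and one ``acc_vs_<other>`` column per species."""
        if self._frame is None:
            rows = []
            for fr in self.folds:
                row = {
                    "target": fr.target,
                    "method": fr.method,
                    "fold": fr.fold_index,
                    "overall_accuracy": fr.overall_accuracy,
                }
                for other, acc in fr.pairwise.items():
                    row[f"acc_vs_{other}"] = acc
                rows.append(row)
            self._frame = pd.DataFrame(rows)
        return self._frame

    def pairwise_values(self, target: str, method: str, other: str) -> np.ndarray:
        return np.array(
            [
                fr.pairwise[other]
                for fr in self.folds
                if fr.target == target and fr.method == method
            ]
        )

    def overall_values(self, target: str, method: str) -> np.ndarray:
        return np.array(
            [
                fr.overall_accuracy
                for fr in self.folds
                if fr.target == target and fr.method == method
            ]
        )

    def pairwise_stats(self) -> pd.DataFrame:
        """Mean / median / 90% interval per (target, method, other)."""
        rows = []
        for target in self.species:
            for method in self.methods:
                for other in self.species:
                    if other == target:
                        continue
                    vals = self.pairwise_values(target, method, other)
                    lo, hi = (
                        bootstrap_interval(vals)
                        if vals.size >= 2
                        else (float(vals[0]), float(vals[0]))
                    )
                    rows.append(
                        {
                            "target": target,
                            "method": method,
                            "other": other,
                            "mean": float(vals.mean()),
                            "median": float(np.median(vals)),
                            "q5": lo,
                            "q95": hi,
                        }
                    )
        return pd.DataFrame(rows)

    def overall_stats(self) -> pd.DataFrame:
        rows = []
        for target in self.species:
            for method in self.methods:
                vals = self.overall_values(target, method)
                lo, hi = (
                    bootstrap_interval(vals)
                    if vals.size >= 2
                    else (float(vals[0]), float(vals[0]))
                )
                rows.append(
                    {
                        "target": target,
                        "method": method,
                        "mean": float(vals.mean()),
                        "median": float(np.median(vals)),
                        "q5": lo,
                        "q95": hi,
                    }
                )
        return pd.DataFrame(rows)

    def hardest_other(self, target: str, method: str) -> str:
        """The other species with the lowest mean pairwise accuracy
        against ``target``; ties broken lexicographically."""
        means = {
            other: self.pairwise_values(target, method, other).mean()
            for other in self.species
            if other != target
        }
        if not means:
            raise ValueError("no pairwise distributions for this target")
        return min(sorted(means), key=lambda sp: means[sp])

    def pairwise_matrix(self, method: str) -> pd.DataFrame:
        """Mean pairwise accuracy, targets as rows, others as columns;
        the diagonal is undefined (NaN)."""
        mat = pd.DataFrame(
            np.nan, index=self.species, columns=self.species, dtype=float
        )
        for target in self.species:
            for other in self.species:
                if other == target:
                    continue
                mat.loc[target, other] = self.pairwise_values(
                    target, method, other
                ).mean()
        mat.index.name = "target"
        return mat

    def compare_methods(self, method_a: str, method_b: str) -> Dict[str, int]:
        """Per-(target, other) pair win counts on mean pairwise accuracy."""
        for m in (method_a, method_b):
            if m not in self.methods:
                raise ValueError(f"method {m!r} was not evaluated")
        a_wins = b_wins = ties = 0
        for target in self.species:
            for other in self.species:
                if other == target:
                    continue
                ma = self.pairwise_values(target, method_a, other).mean()
                mb = self.pairwise_values(target, method_b, other).mean()
                if ma > mb:
                    a_wins += 1
                elif mb > ma:
                    b_wins += 1
                else:
                    ties += 1
        return {"a_wins": a_wins, "b_wins": b_wins, "ties": ties,
                "total": a_wins + b_wins + ties}

    def method_means(self) -> pd.DataFrame:
        """Grand-mean overall accuracy per method across all targets."""
        df = self.folds_frame()
        return (
            df.groupby("method")["overall_accuracy"]
            .agg(["mean", "median", "std"])
            .reindex(self.methods)
        )

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = [
            "One-vs-all classification experiment",
            "=" * 64,
            f"species: {len(self.species)}   methods: {', '.join(self.methods)}"
            f"   folds: {self.n_folds}   seed: {self.master_seed}",
            f"training sessions: {self.n_training_sessions}   "
            f"pairwise test sessions: {self.n_pairwise_test_sessions}",
            "",
            "Overall accuracy on the full test set (mean over folds):",
        ]
        piv = (
            self.overall_stats()
            .pivot(index="target", columns="method", values="mean")
            .reindex(index=self.species, columns=list(self.methods))
        )
        lines.append(piv.to_string(float_format=lambda v: f"{v:.3f}"))
        lines.append("")
        lines.append("Hardest other species per target (median pairwise "
                     "accuracy, 90% interval):")
        for target in self.species:
            for method in self.methods:
                other = self.hardest_other(target, method)
                vals = self.pairwise_values(target, method, other)
                lo, hi = bootstrap_interval(vals) if vals.size >= 2 else (
                    vals[0], vals[0])
                lines.append(
                    f"  {target:<28s} {method:<9s} vs {other:<28s} "
                    f"{np.median(vals):.3f} [{lo:.3f}, {hi:.3f}]"
                )
        return "\n".join(lines)

    def to_summary_dict(self) -> dict:
        out = {
            "n_folds": self.n_folds,
            "master_seed": self.master_seed,
            "species": self.species,
            "methods": self.methods,
            "n_training_sessions": self.n_training_sessions,
            "n_pairwise_test_sessions": self.n_pairwise_test_sessions,
            "overall": self.overall_stats().to_dict(orient="records"),
            "pairwise": self.pairwise_stats().to_dict(orient="records"),
            "hardest_other": {
                method: {
                    target: self.hardest_other(target, method)
                    for target in self.species
                }
                for method in self.methods
            },
        }
        return out

    def save(self, outdir) -> None:
        """Write folds.csv, summary.json and one matrix_<method>.csv per
        method."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.folds_frame().to_csv(outdir / "folds.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.to_summary_dict(), fh, indent=2)
        for method in self.methods:
            self.pairwise_matrix(method).to_csv(
                outdir / f"matrix_{method}.csv"
            )


def run_experiment(
    dataset: LabeledEventSet,
    methods: Sequence[str] = METHODS,
    n_folds: int = 100,
    seed: int = 0,
    **kwargs,
) -> ExperimentResults:
    """Functional wrapper: build and fit a :class:`OneVsAllExperiment`."""
    return OneVsAllExperiment(
        dataset, methods=methods, n_folds=n_folds, **kwargs
    ).fit(seed=seed)


def hardest_other(results: ExperimentResults, target: str, method: str) -> str:
    return results.hardest_other(target, method)


def compare_methods(
    results: ExperimentResults, method_a: str, method_b: str
) -> Dict[str, int]:
    return results.compare_methods(method_a, method_b)
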