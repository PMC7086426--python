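"""Subject-level cross-validation, accuracy, and the bootstrap protocol.

Evaluation follows the small-cohort protocol: segments are the classifier's
samples, but fold splits assign whole *subjects* to train or test, so no
subject's segments ever straddle the split.  Accuracy is

    100 * (TP + TN) / (TP + TN + FP + FN)

with TBI as the positive class.  The cohort-level uncertainty estimate
resamples subjects with replacement (a bootstrap sample the size of the
original cohort), runs a balanced threefold cross-validation on each
resample, and summarizes the per-iteration mean accuracies by their mean,
sample SD, and 2.5th/97.5th percentile interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone

from .data import Recording, apply_montage, discard_initial, reject_artifacts, \
    segment_recording
from .errors import PlanError, UndefinedMetricError
from .montage import Montage

POSITIVE_CLASS = "tbi"
NEGATIVE_CLASS = "healthy"


@dataclass(frozen=True)
class ConfusionCounts:
    """Two-class confusion counts with TBI as the positive class."""

    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)


def accuracy(c: ConfusionCounts) -> float:
    """Percent of segments classified correctly."""
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined on zero evaluated segments")
    return 100.0 * (c.TP + c.TN) / c.total


@dataclass(frozen=True)
class FoldPlan:
    """Per-fold (train subject ids, test subject ids); test sets partition
    the subject set."""

    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    k: int

    def __post_init__(self):
        if len(self.folds) != self.k:
            raise PlanError(f"expected {self.k} folds, got {len(self.folds)}")
        tested: list[str] = []
        for train, test in self.folds:
            overlap = set(train) & set(test)
            if overlap:
                raise PlanError(f"subjects in both train and test: {sorted(overlap)}")
            tested.extend(test)
        if len(tested) != len(set(tested)):
            raise PlanError("a subject appears in more than one test fold")

    @property
    def subjects(self) -> frozenset[str]:
        return frozenset(s for _, test in self.folds for s in test)


def _subject_table(subjects) -> list[tuple[str, str]]:
    """Normalize to [(subject_id, class_label)] preserving input order."""
    table = []
    for s in subjects:
        if isinstance(s, Recording):
            table.append((s.subject_id, s.class_label))
        else:
            sid, label = s
            table.append((str(sid), str(label)))
    if len({sid for sid, _ in table}) != len(table):
        raise PlanError("duplicate subject ids in cohort")
    return table


def make_fold_plan(subjects, k: int = 3, scheme: str = "literal_threefold",
                   seed: int = 0) -> FoldPlan:
    """Build a subject-level fold plan.

    ``scheme="literal_threefold"`` reproduces the reference 15+15 assignment:
    fold 1 tests patients 11-15 and healthy 11-15, fold 2 tests 1-5, fold 3
    tests 6-10 (subjects numbered by input order within each class; k must
    be 3).  ``scheme="balanced_random"`` deals each class's subjects into k
    test groups under the seed, keeping test folds class-balanced to within
    one subject.
    """
    if k < 2:
        raise PlanError("k must be >= 2")
    table = _subject_table(subjects)
    by_class: dict[str, list[str]] = {}
    for sid, label in table:
        by_class.setdefault(label, []).append(sid)

    if scheme == "literal_threefold":
        if k != 3:
            raise PlanError("literal_threefold is defined for k=3")
        pos = by_class.get(POSITIVE_CLASS, [])
        neg = by_class.get(NEGATIVE_CLASS, [])
        if len(pos) != 15 or len(neg) != 15:
            raise PlanError(
                f"literal_threefold requires 15 {POSITIVE_CLASS} + 15 "
                f"{NEGATIVE_CLASS} subjects, got {len(pos)}+{len(neg)}"
            )
        # test blocks by within-class ordinal: fold1 -> 11..15, fold2 -> 1..5,
        # fold3 -> 6..10
        blocks = [(10, 15), (0, 5), (5, 10)]
        test_groups = [tuple(pos[a:b] + neg[a:b]) for a, b in blocks]
    elif scheme == "balanced_random":
        rng = np.random.default_rng(seed)
        groups: list[list[str]] = [[] for _ in range(k)]
        for label in sorted(by_class):
            ids = list(by_class[label])
            rng.shuffle(ids)
            for i, sid in enumerate(ids):
                groups[i % k].append(sid)
        test_groups = [tuple(g) for g in groups]
    else:
        raise PlanError(f"unknown scheme {scheme!r}")

    all_ids = [sid for sid, _ in table]
    folds = tuple(
        (tuple(s for s in all_ids if s not in set(test)), test)
        for test in test_groups
    )
    return FoldPlan(folds=folds, k=k)


# ---------------------------------------------------------------------------
# cohort preparation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrepConfig:
    """How recordings become segment stacks before classification."""

    montage: Montage | None = None
    discard_seconds: float = 0.0
    artifact_threshold: float | None = None
    window_seconds: float = 1.0
    max_segments: int | None = 60


def prepare_cohort(cohort: list[Recording], prep: PrepConfig | None = None
                   ) -> dict[str, tuple[np.ndarray, str]]:
    """Map subject id -> (segment stack of shape (n, channels, samples), class)."""
    prep = prep or PrepConfig()
    out: dict[str, tuple[np.ndarray, str]] = {}
    for rec in cohort:
        if rec.subject_id in out:
            raise PlanError(f"duplicate subject id {rec.subject_id!r} in cohort")
        if prep.montage is not None:
            rec = apply_montage(rec, prep.montage)
        if prep.discard_seconds:
            rec = discard_initial(rec, prep.discard_seconds)
        if prep.artifact_threshold is not None:
            rec, _ = reject_artifacts(rec, prep.artifact_threshold,
                                      prep.window_seconds)
        segments = segment_recording(rec, prep.window_seconds, prep.max_segments)
        out[rec.subject_id] = (np.stack([s.matrix for s in segments]),
                               rec.class_label)
    return out


def _counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    pos, neg = POSITIVE_CLASS, NEGATIVE_CLASS
    return ConfusionCounts(
        TP=int(np.sum((y_true == pos) & (y_pred == pos))),
        TN=int(np.sum((y_true == neg) & (y_pred == neg))),
        FP=int(np.sum((y_true == neg) & (y_pred == pos))),
        FN=int(np.sum((y_true == pos) & (y_pred == neg))),
    )


def _run_folds(
    prepared: dict[str, tuple[np.ndarray, str]],
    plan: FoldPlan,
    estimator,
    multiplicity: dict[str, int] | None = None,
) -> tuple[list[ConfusionCounts], float]:
    """Train/evaluate per fold on prepared segment stacks.

    ``multiplicity`` (bootstrap resamples) repeats a subject's segments on
    whichever side of the split the subject lands; identities are never
    split across sides.
    """
    missing = plan.subjects - set(prepared)
    if missing:
        raise PlanError(f"plan references absent subjects: {sorted(missing)}")
    mult = multiplicity or {}
    per_fold: list[ConfusionCounts] = []
    for train_ids, test_ids in plan.folds:
        def stack(ids):
            xs, ys = [], []
            for sid in ids:
                X, label = prepared[sid]
                for _ in range(mult.get(sid, 1)):
                    xs.append(X)
                    ys.append(np.full(X.shape[0], label, dtype=object))
            return np.concatenate(xs), np.concatenate(ys)

        X_train, y_train = stack(train_ids)
        X_test, y_test = stack(test_ids)
        model = clone(estimator).fit(X_train, y_train)
        y_pred = np.asarray(model.predict(X_test), dtype=object)
        per_fold.append(_counts(y_test, y_pred))
    mean_acc = float(np.mean([accuracy(c) for c in per_fold]))
    return per_fold, mean_acc


def cross_validate(cohort: list[Recording], plan: FoldPlan, estimator,
                   prep: PrepConfig | None = None
                   ) -> tuple[list[ConfusionCounts], float]:
    """Subject-level k-fold cross-validation of one classifier.

    Returns per-fold confusion counts and the mean fold accuracy (%).
    """
    prepared = prepare_cohort(cohort, prep)
    return _run_folds(prepared, plan, estimator)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_resample(subjects: list, rng_seed) -> list:
    """Sample-with-replacement of the original size, deterministic in the seed.

    ``rng_seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if len(subjects) == 0:
        raise PlanError("cannot resample an empty subject list")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    idx = rng.integers(0, len(subjects), size=len(subjects))
    return [subjects[i] for i in idx]


@dataclass
class BootstrapResult:
    """Summary of repeated cross-validation over bootstrap resamples."""

    per_iteration_acc: list[float]
    mean_acc: float
    sd: float
    ci95: tuple[float, float]
    n_iterations: int
    n_redrawn: int = 0

    def to_tsv(self) -> str:
        lines = ["iteration\taccuracy_pct"]
        lines += [f"{i + 1}\t{a:.4f}" for i, a in enumerate(self.per_iteration_acc)]
        return "\n".join(lines) + "\n"


def summarize_bootstrap(accs: list[float], n_redrawn: int = 0) -> BootstrapResult:
    arr = np.asarray(accs, dtype=float)
    return BootstrapResult(
        per_iteration_acc=list(map(float, arr)),
        mean_acc=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        ci95=(float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5))),
        n_iterations=len(arr),
        n_redrawn=n_redrawn,
    )


def run_bootstrap_cv(
    cohort: list[Recording],
    estimator,
    n_iterations: int = 100,
    base_seed: int = 0,
    k: int = 3,
    prep: PrepConfig | None = None,
) -> BootstrapResult:
    """Bootstrap-the-cohort evaluation of one classifier.

    Each iteration resamples subjects with replacement, builds a seeded
    class-balanced k-fold plan over the distinct resampled identities
    (a subject drawn m times contributes its segments m times on whichever
    side it lands), cross-validates, and records the mean fold accuracy.
    Degenerate resamples missing a class are redrawn and counted in
    ``n_redrawn``.
    """
    if n_iterations < 2:
        raise PlanError("n_iterations must be >= 2")
    prepared = prepare_cohort(cohort, prep)
    ids = list(prepared)
    labels = {sid: label for sid, (_, label) in prepared.items()}
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(base_seed), spawn_key=(1,)))
    accs: list[float] = []
    n_redrawn = 0
    for _ in range(n_iterations):
        while True:
            sample = bootstrap_resample(ids, rng)
            if len({labels[s] for s in sample}) >= 2:
                break
            n_redrawn += 1
        mult: dict[str, int] = {}
        for sid in sample:
            mult[sid] = mult.get(sid, 0) + 1
        unique = [(sid, labels[sid]) for sid in ids if sid in mult]
        plan = make_fold_plan(unique, k=k, scheme="balanced_random",
                              seed=int(rng.integers(0, 2**31)))
        _, mean_acc = _run_folds(prepared, plan, estimator, multiplicity=mult)
        accs.append(mean_acc)
    return summarize_bootstrap(accs, n_redrawn)
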