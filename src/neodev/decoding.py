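"""Population decoding of animal condition and stimulus type with
permutation-calibrated significance.

Condition decoding: post-stimulus population responses are reduced to
per-time-bin feature vectors (bin-mean dF/F of a fixed random cell subset),
one L2-penalised logistic classifier is trained per time bin on a
subject-wise 60/40 animal split, and the maximum test accuracy over bins is
the decoding score.  Its significance threshold is the 95th percentile of
the same max-over-bins score recomputed on many animal-level label
permutations, so the threshold respects within-animal trial correlations.

Stimulus-type decoding is per animal: each trial's full post-stimulus window
(cells x frames, flattened) feeds one classifier evaluated with
leave-one-recording-out cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .io import ValidationError

logger = logging.getLogger("neodev")

DEFAULT_C = 0.001  # sklearn inverse-strength convention (strong L2)


@dataclass
class TrialTensor:
    """Trials x cells x frames dF/F snippets with per-trial labels."""

    data: np.ndarray
    frame_rate: float
    animal_ids: np.ndarray
    condition: np.ndarray
    stimulus_type: np.ndarray | None = None
    recording_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("trial tensor must be trials x cells x frames")
        n = self.data.shape[0]
        for name in ("animal_ids", "condition", "stimulus_type", "recording_ids"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape != (n,):
                    raise ValidationError(f"{name} must have one entry per trial")
                setattr(self, name, v)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_cells(self) -> int:
        return self.data.shape[1]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]


@dataclass
class DecodingResult:
    """Observed accuracy, permutation null and the derived threshold."""

    accuracy_per_bin: np.ndarray
    max_accuracy: float
    best_bin: int
    null_max_accuracies: np.ndarray | None = None
    threshold: float | None = None
    train_animals: list = field(default_factory=list)
    test_animals: list = field(default_factory=list)

    @property
    def margin(self) -> float | None:
        if self.threshold is None:
            return None
        return self.max_accuracy - self.threshold

    @property
    def significant(self) -> bool | None:
        if self.threshold is None:
            return None
        return self.max_accuracy > self.threshold


def build_condition_features(
    tensor: TrialTensor,
    n_cells: int = 500,
    bin_ms: float = 500.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-time-bin feature vectors: bin-mean dF/F of a random cell subset.

    The cell subset is drawn once from ``seed`` and reused for every bin and
    trial.  A 20 s snippet at 30 Hz with 500 ms bins yields 40 bins of
    ``n_cells`` features.  Returns (n_bins, n_trials, n_cells_used).
    """
    bin_frames = int(round(bin_ms / 1000.0 * tensor.frame_rate))
    if bin_frames < 1 or bin_frames > tensor.n_frames:
        raise ValidationError(
            f"bin of {bin_frames} frames invalid for {tensor.n_frames}-frame snippets"
        )
    rng = np.random.default_rng(seed)
    if tensor.n_cells >= n_cells:
        cells = np.sort(rng.choice(tensor.n_cells, size=n_cells, replace=False))
    else:
        logger.info(
            "only %d cells available (< %d requested); using all",
            tensor.n_cells, n_cells,
        )
        cells = np.arange(tensor.n_cells)
    n_bins = tensor.n_frames // bin_frames
    x = tensor.data[:, cells, : n_bins * bin_frames]
    x = x.reshape(tensor.n_trials, cells.size, n_bins, bin_frames).mean(axis=3)
    return np.transpose(x, (2, 0, 1))  # bins x trials x cells


def _make_classifier(C: float, n_classes: int = 2):
    # L2 penalty (the solver default), strength via C; lbfgs leaves the
    # intercept unpenalised, which matters at strong regularisation
    clf = LogisticRegression(C=C, solver="lbfgs", tol=1e-6, max_iter=5000)
    if n_classes > 2:
        from sklearn.multiclass import OneVsRestClassifier

        return OneVsRestClassifier(clf)
    return clf


def subject_wise_split(
    animal_ids: np.ndarray,
    labels: np.ndarray,
    train_fraction: float,
    rng: np.random.Generator,
    max_retries: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign whole animals to train/test, stratified by class.

    Every class must appear on both sides; with fewer than 2 animals in some
    class this is impossible and an error is raised.
    """
    animals = np.unique(animal_ids)
    animal_label = {a: labels[animal_ids == a][0] for a in animals}
    classes = np.unique(labels)
    for a in animals:
        lbls = np.unique(labels[animal_ids == a])
        if lbls.size > 1:
            raise ValidationError(f"animal {a!r} carries multiple condition labels")
    for cls in classes:
        if sum(1 for a in animals if animal_label[a] == cls) < 2:
            raise ValidationError(
                f"subject-wise split impossible: class {cls!r} has < 2 animals"
            )
    for _ in range(max_retries):
        train_animals: list = []
        test_animals: list = []
        for cls in classes:
            members = np.array([a for a in animals if animal_label[a] == cls])
            members = members[rng.permutation(members.size)]
            n_train = int(round(train_fraction * members.size))
            n_train = min(max(n_train, 1), members.size - 1)
            train_animals.extend(members[:n_train])
            test_animals.extend(members[n_train:])
        train_mask = np.isin(animal_ids, train_animals)
        test_mask = ~train_mask
        ok = all(
            (labels[train_mask] == c).any() and (labels[test_mask] == c).any()
            for c in classes
        )
        if ok:
            assert not set(np.asarray(train_animals)) & set(np.asarray(test_animals))
            return np.asarray(train_animals), np.asarray(test_animals)
    raise ValidationError("could not draw a class-complete subject-wise split")


def train_condition_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    animal_ids: np.ndarray,
    train_fraction: float = 0.6,
    C: float = DEFAULT_C,
    seed: int = 0,
) -> DecodingResult:
    """Fit one logistic classifier per time bin on a subject-wise split.

    ``features`` is (n_bins, n_trials, n_features).  Returns per-bin test
    accuracies and their maximum (the decoding score).
    """
    labels = np.asarray(labels)
    animal_ids = np.asarray(animal_ids)
    rng = np.random.default_rng(seed)
    train_animals, test_animals = subject_wise_split(
        animal_ids, labels, train_fraction, rng
    )
    train_mask = np.isin(animal_ids, train_animals)
    test_mask = ~train_mask
    accs = np.empty(features.shape[0])
    for b in range(features.shape[0]):
        clf = _make_classifier(C, np.unique(labels).size)
        clf.fit(features[b][train_mask], labels[train_mask])
        accs[b] = clf.score(features[b][test_mask], labels[test_mask])
    best = int(np.argmax(accs))
    return DecodingResult(
        accuracy_per_bin=accs,
        max_accuracy=float(accs[best]),
        best_bin=best,
        train_animals=list(train_animals),
        test_animals=list(test_animals),
    )


def permutation_significance(
    features: np.ndarray,
    labels: np.ndarray,
    animal_ids: np.ndarray,
    n_perm: int = 7000,
    alpha: float = 0.05,
    train_fraction: float = 0.6,
    C: float = DEFAULT_C,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Significance threshold from animal-level label permutations.

    Condition labels are shuffled across animals (all trials of an animal
    move together), the whole train/split/fit procedure is re-run, and the
    (1 - alpha) quantile of the null max-over-bins accuracies is the
    threshold.  Returns ``(threshold, null_accuracies)``.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d < 100: threshold quantile will be unstable", n_perm)
    labels = np.asarray(labels)
    animal_ids = np.asarray(animal_ids)
    animals = np.unique(animal_ids)
    animal_label = np.array([labels[animal_ids == a][0] for a in animals])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(animals.size)
        lut = dict(zip(animals, animal_label[perm]))
        perm_labels = np.array([lut[a] for a in animal_ids])
        res = train_condition_classifier(
            features,
            perm_labels,
            animal_ids,
            train_fraction=train_fraction,
            C=C,
            seed=int(rng.integers(2**31 - 1)),
        )
        null[p] = res.max_accuracy
    threshold = float(np.quantile(null, 1.0 - alpha)) if alpha < 1.0 else float(null.min())
    return threshold, null


def decode_condition(
    tensor: TrialTensor,
    n_cells: int = 500,
    bin_ms: float = 500.0,
    n_perm: int = 7000,
    alpha: float = 0.05,
    train_fraction: float = 0.6,
    C: float = DEFAULT_C,
    seed: int = 0,
) -> DecodingResult:
    """End-to-end condition decoding with a permutation threshold."""
    features = build_condition_features(tensor, n_cells, bin_ms, seed)
    res = train_condition_classifier(
        features, tensor.condition, tensor.animal_ids, train_fraction, C, seed
    )
    threshold, null = permutation_significance(
        features,
        tensor.condition,
        tensor.animal_ids,
        n_perm=n_perm,
        alpha=alpha,
        train_fraction=train_fraction,
        C=C,
        seed=seed + 1,
    )
    res.null_max_accuracies = null
    res.threshold = threshold
    return res


def stimulus_type_decoder(
    tensor: TrialTensor,
    n_cells: int = 500,
    C: float = DEFAULT_C,
    seed: int = 0,
) -> float:
    """Per-animal stimulus-type decoding accuracy.

    Each trial's post-stimulus window is flattened to a cells x frames
    feature vector (500 cells x 600 frames = 300,000 features at the
    defaults) and a single classifier is cross-validated recording-wise
    (leave one recording out).  ``tensor`` must carry trials of one animal
    with ``stimulus_type`` and ``recording_ids`` set.
    """
    if tensor.stimulus_type is None or tensor.recording_ids is None:
        raise ValidationError("stimulus-type decoding needs stimulus_type and recording_ids")
    if np.unique(tensor.animal_ids).size != 1:
        raise ValidationError("stimulus-type decoder is fit per animal")
    recs = np.unique(tensor.recording_ids)
    if recs.size < 2:
        raise ValidationError("need >= 2 recordings for recording-wise cross-validation")
    for stim in np.unique(tensor.stimulus_type):
        if np.unique(tensor.recording_ids[tensor.stimulus_type == stim]).size < 2:
            raise ValidationError(
                f"stimulus type {stim!r} present in < 2 recordings"
            )
    rng = np.random.default_rng(seed)
    if tensor.n_cells >= n_cells:
        cells = np.sort(rng.choice(tensor.n_cells, size=n_cells, replace=False))
    else:
        cells = np.arange(tensor.n_cells)
    x = tensor.data[:, cells, :].reshape(tensor.n_trials, -1)
    y = tensor.stimulus_type
    correct = 0
    n_classes = np.unique(y).size
    for rec in recs:
        test = tensor.recording_ids == rec
        clf = _make_classifier(C, n_classes)
        clf.fit(x[~test], y[~test])
        correct += int((clf.predict(x[test]) == y[test]).sum())
    return correct / tensor.n_trials
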