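"""Nearest-class-subspace classification of ROI time-series matrices.

Each class of subjects is stacked into an order-3 tensor with modes
(time, region, sample).  A single HOSVD per class yields orthonormal bases
for the leading time and region subspaces and a set of core slices spanning
the class's sample subspace.  A test matrix is projected into each class's
time x region subspace and approximated as a linear combination of the first
``k3`` (restricted) core slices; the class with the smallest reconstruction
error wins.

The *enhanced* variant appends the unlabeled test matrix to every class
tensor before decomposition.  An in-class test sample reinforces the leading
mode-3 singular values and slices, lowering its own reconstruction error;
an out-of-class sample behaves like noise and is pushed into the trailing
slices that the truncation discards.  No label information leaks: the test
sample is appended to *all* classes symmetrically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tensor import (
    HOSVDResult,
    TruncationRanks,
    hosvd,
    mode_singular_values,
    unfold,
)

__all__ = [
    "ClassTensor",
    "ClassModel",
    "ClassificationResult",
    "ConfusionCounts",
    "augment_class_tensor",
    "fit_class_model",
    "project_test",
    "reconstruction_error",
    "classify",
    "evaluate_loocv",
    "singular_value_perturbation",
    "energy_ranks",
    "noise_floor_rank",
    "default_ranks",
]

#: Relative tolerance below which two class errors are declared tied.
TIE_RTOL = 1e-12


@dataclass
class ClassTensor:
    """All subjects of one class stacked along mode 3: shape (T, R, S)."""

    data: np.ndarray
    class_label: str
    subject_ids: list[str] | None = None
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("class tensor must be order-3 (time, region, sample)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"class {self.class_label!r} tensor has non-finite entries")
        if self.subject_ids is not None and len(self.subject_ids) != self.n_samples:
            raise ValueError("subject_ids length does not match the sample mode")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def drop_sample(self, index: int) -> "ClassTensor":
        """Return a copy with one subject removed (for leave-one-out loops)."""
        data = np.delete(self.data, index, axis=2)
        ids = None
        if self.subject_ids is not None:
            ids = [s for i, s in enumerate(self.subject_ids) if i != index]
        return ClassTensor(data, self.class_label, ids, self.region_labels)


@dataclass
class ClassModel:
    """Truncated class bases: time basis, region basis and restricted core slices."""

    time_basis: np.ndarray  # T x k1, orthonormal columns
    region_basis: np.ndarray  # R x k2, orthonormal columns
    core_slices: np.ndarray  # k1 x k2 x S, core restricted to (1:k1, 1:k2, :)
    ranks: TruncationRanks
    class_label: str
    augmented: bool = False


@dataclass
class ClassificationResult:
    predicted_label: str
    errors: dict[str, float]
    coefficients: dict[str, np.ndarray]
    tie: bool = False

    def __post_init__(self) -> None:
        for label, r in self.errors.items():
            if r < 0:
                raise ValueError(f"negative reconstruction error for class {label!r}")


@dataclass
class ConfusionCounts:
    """Binary confusion bookkeeping with an explicit positive class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    positive_class: str = ""

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def update(self, true_label: str, predicted_label: str) -> None:
        if true_label == self.positive_class:
            if predicted_label == true_label:
                self.tp += 1
            else:
                self.fn += 1
        else:
            if predicted_label == true_label:
                self.tn += 1
            else:
                self.fp += 1


def _check_test_matrix(test, shape: tuple[int, int]) -> np.ndarray:
    X = np.asarray(test, dtype=float)
    if X.shape != shape:
        raise ValueError(
            f"test matrix shape {X.shape} does not match expected (T, R) = {shape}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("test matrix has non-finite entries")
    return X


def augment_class_tensor(X: ClassTensor, test) -> ClassTensor:
    """Append the test matrix as an extra sample slice; the input is not modified."""
    M = _check_test_matrix(test, (X.n_timepoints, X.n_regions))
    data = np.concatenate([X.data, M[:, :, None]], axis=2)
    ids = None if X.subject_ids is None else [*X.subject_ids, "<test>"]
    return ClassTensor(data, X.class_label, ids, X.region_labels)


def energy_ranks(
    X: ClassTensor, energy: float = 0.95, max_k3: int | None = None
) -> TruncationRanks:
    """Smallest per-mode ranks retaining ``energy`` of each mode's squared singular values."""
    if not 0 < energy <= 1:
        raise ValueError(f"energy fraction must be in (0, 1], got {energy}")
    ks = []
    for mode in (1, 2, 3):
        s2 = mode_singular_values(X.data, mode) ** 2
        total = s2.sum()
        if total == 0:
            ks.append(1)
            continue
        k = int(np.searchsorted(np.cumsum(s2) / total, energy) + 1)
        ks.append(min(k, len(s2)))
    if max_k3 is not None:
        ks[2] = min(ks[2], max_k3)
    return TruncationRanks(*ks)


def noise_floor_rank(X: ClassTensor, spread_factor: float = 1.5) -> int:
    """Number of sample-mode singular values above the estimated noise floor.

    Subject noise produces a bulk of comparable singular values at the bottom
    of the mode-3 spectrum; coherent class structure stands above it.  The
    bulk level and half-width are estimated robustly from the lower half of
    the spectrum (median and 90th-percentile order statistics, so the
    estimate tolerates colored noise whose bulk is wider than the white-noise
    prediction), and singular values above
    ``median + spread_factor * (median - q90)`` are counted as structure.
    This count is the natural choice for the number of core slices ``k3``
    used in the reconstruction-error solve; an energy criterion over-selects
    badly there, because the bulk of a noise-dominated spectrum holds most of
    the energy but no class signal.
    """
    s = mode_singular_values(X.data, 3)
    S = len(s)
    med = s[S // 2]
    low = s[min(int(0.9 * S), S - 1)]
    edge = med + spread_factor * (med - low)
    return max(1, min(int(np.sum(s > edge)), S - 1))


def default_ranks(
    classes: list[ClassTensor], energy: float = 0.95
) -> dict[str, TruncationRanks]:
    """Shared default ranks: energy criterion for (k1, k2), noise floor for k3.

    All three ranks are harmonized to the elementwise minimum over classes,
    because the residuals being compared are not dimension-normalized:
    a class projecting into a smaller k1 x k2 space collects less noise
    energy in its residual (and more slices always shrink the least-squares
    residual), so unequal ranks would bias the decision for structural
    rather than fit-quality reasons.
    """
    per_class = [energy_ranks(X, energy) for X in classes]
    k1 = min(r.k1 for r in per_class)
    k2 = min(r.k2 for r in per_class)
    k3 = min(noise_floor_rank(X) for X in classes)
    shared = TruncationRanks(k1, k2, k3)
    return {X.class_label: shared for X in classes}


def fit_class_model(
    X: ClassTensor, ranks: TruncationRanks, *, augmented: bool = False
) -> ClassModel:
    """One HOSVD of the class tensor, truncated to the leading time/region bases.

    Returns the first ``k1`` time singular vectors, the first ``k2`` region
    singular vectors and the core restricted to ``(1:k1, 1:k2, :)`` — *all*
    sample-mode slices are kept; ``ranks.k3`` only controls how many slices
    the reconstruction-error solve uses.
    """
    ranks.validate(X.data.shape)
    h: HOSVDResult = hosvd(X.data)
    return ClassModel(
        time_basis=h.factors[0][:, : ranks.k1],
        region_basis=h.factors[1][:, : ranks.k2],
        core_slices=h.core[: ranks.k1, : ranks.k2, :],
        ranks=ranks,
        class_label=X.class_label,
        augmented=augmented,
    )


def project_test(test, model: ClassModel) -> np.ndarray:
    """Project a T x R test matrix into the class's leading time x region subspace."""
    X = _check_test_matrix(
        test, (model.time_basis.shape[0], model.region_basis.shape[0])
    )
    return model.time_basis.T @ X @ model.region_basis


def reconstruction_error(
    Z: np.ndarray, model: ClassModel, k3: int | None = None
) -> tuple[float, np.ndarray]:
    """Best approximation of ``Z`` by the first ``k3`` restricted core slices.

    The restricted slices lose mutual orthogonality once modes 1-2 are
    truncated, so the coefficients are found by general linear least squares
    on the flattened slices (minimum-norm solution on rank deficiency), not
    by inner-product projection.  Returns the attained Frobenius-norm
    residual and the coefficient vector.
    """
    if k3 is None:
        k3 = model.ranks.k3
    if k3 < 1:
        raise ValueError(f"k3 must be at least 1, got {k3}")
    n_slices = model.core_slices.shape[2]
    if k3 > n_slices:
        raise ValueError(f"k3={k3} exceeds the {n_slices} available core slices")
    Z = np.asarray(Z, dtype=float)
    if Z.shape != model.core_slices.shape[:2]:
        raise ValueError(
            f"projected matrix shape {Z.shape} does not match the core slice "
            f"shape {model.core_slices.shape[:2]}"
        )
    design = model.core_slices[:, :, :k3].reshape(-1, k3)
    lam, _, rank, _ = np.linalg.lstsq(design, Z.reshape(-1), rcond=None)
    if rank < k3:
        warnings.warn(
            f"rank-deficient slice set for class {model.class_label!r} "
            f"(rank {rank} < k3={k3}); using the minimum-norm solution",
            stacklevel=2,
        )
    r = float(np.linalg.norm(Z.reshape(-1) - design @ lam))
    return r, lam


def _resolve_ranks(
    classes: list[ClassTensor],
    ranks: TruncationRanks | dict[str, TruncationRanks] | None,
    energy: float,
) -> dict[str, TruncationRanks]:
    if ranks is None:
        return default_ranks(classes, energy)
    if isinstance(ranks, TruncationRanks):
        return {X.class_label: ranks for X in classes}
    return {X.class_label: ranks[X.class_label] for X in classes}


def classify(
    test,
    classes: list[ClassTensor],
    ranks: TruncationRanks | dict[str, TruncationRanks] | None = None,
    *,
    energy: float = 0.95,
    enhance: bool = True,
) -> ClassificationResult:
    """Assign a test matrix to the class with the smallest reconstruction error.

    ``ranks`` may be a single :class:`TruncationRanks` shared by all classes,
    a mapping from class label to ranks, or ``None`` for the default policy
    (:func:`default_ranks`: energy criterion for k1/k2, noise-floor count for
    k3, computed on the training tensors only, never on the augmented ones).

    With ``enhance=True`` the test matrix is appended to *every* class tensor
    before its HOSVD, symmetrically and without any label information.
    Ties (relative error gap below ``TIE_RTOL``) go to the class listed first.
    """
    if len(classes) < 2:
        raise ValueError("classification requires at least two classes")
    shape = (classes[0].n_timepoints, classes[0].n_regions)
    for X in classes:
        if (X.n_timepoints, X.n_regions) != shape:
            raise ValueError(
                f"class {X.class_label!r} has shape {(X.n_timepoints, X.n_regions)}, "
                f"expected {shape}"
            )
    M = _check_test_matrix(test, shape)
    rank_map = _resolve_ranks(classes, ranks, energy)

    errors: dict[str, float] = {}
    coefficients: dict[str, np.ndarray] = {}
    order: list[str] = []
    for X in classes:
        r_cls = rank_map[X.class_label]
        n_train = X.n_samples + (1 if enhance else 0)
        if r_cls.k3 > n_train:
            raise ValueError(
                f"k3={r_cls.k3} exceeds the {n_train} samples available for "
                f"class {X.class_label!r}"
            )
        fit_on = augment_class_tensor(X, M) if enhance else X
        model = fit_class_model(fit_on, r_cls, augmented=enhance)
        Z = project_test(M, model)
        r, lam = reconstruction_error(Z, model, r_cls.k3)
        errors[X.class_label] = r
        coefficients[X.class_label] = lam
        order.append(X.class_label)

    r_min = min(errors.values())
    scale = max(max(errors.values()), 1.0)
    near = [lbl for lbl in order if errors[lbl] - r_min <= TIE_RTOL * scale]
    return ClassificationResult(
        predicted_label=near[0],
        errors=errors,
        coefficients=coefficients,
        tie=len(near) > 1,
    )


def evaluate_loocv(
    classes: list[ClassTensor],
    ranks: TruncationRanks | dict[str, TruncationRanks] | None = None,
    *,
    energy: float = 0.95,
    enhance: bool = True,
    positive_class: str | None = None,
    match_sizes: bool = False,
) -> tuple[ConfusionCounts, list[dict]]:
    """Leave-one-out cross-validation over every subject of every class.

    Each held-out subject is removed from its own class tensor and classified
    against all classes; with enhancement, *all* class tensors (including the
    reduced home class) are augmented with the held-out sample.  When ranks
    are chosen automatically they are recomputed per fold on training data
    only.  Returns aggregate confusion counts (the designated positive class
    defaults to the last class in the list, conventionally the patient group)
    plus one record per subject.

    ``match_sizes=True`` additionally drops one subject from every *other*
    class per fold (cyclically, so each subject is dropped equally often),
    making all training tensors the same size as the reduced home class when
    class sizes are equal.  The plain protocol leaves the home class one
    subject smaller, which under enhancement slightly favors it — the test
    sample carries more weight in a smaller augmented tensor.  Matched folds
    remove that structural asymmetry; permutation null controls should use
    them so chance-level behavior is actually centered on chance.
    """
    for X in classes:
        if X.n_samples < 3:
            raise ValueError(
                f"class {X.class_label!r} needs at least 3 subjects for LOOCV"
            )
    if positive_class is None:
        positive_class = classes[-1].class_label
    labels = {X.class_label for X in classes}
    if positive_class not in labels:
        raise ValueError(f"positive class {positive_class!r} not among {sorted(labels)}")

    counts = ConfusionCounts(positive_class=positive_class)
    records: list[dict] = []
    for ci, X in enumerate(classes):
        for si in range(X.n_samples):
            test = X.data[:, :, si]
            fold_classes = [
                cls.drop_sample(si if i == ci else si % cls.n_samples)
                if (i == ci or match_sizes)
                else cls
                for i, cls in enumerate(classes)
            ]
            res = classify(test, fold_classes, ranks, energy=energy, enhance=enhance)
            counts.update(X.class_label, res.predicted_label)
            subject = (
                X.subject_ids[si] if X.subject_ids is not None else f"{X.class_label}:{si}"
            )
            records.append(
                {
                    "subject_id": subject,
                    "true_label": X.class_label,
                    "predicted_label": res.predicted_label,
                    "tie": res.tie,
                    **{f"error_{lbl}": r for lbl, r in res.errors.items()},
                }
            )
    return counts, records


def singular_value_perturbation(X: ClassTensor, test) -> np.ndarray:
    """Absolute change of the mode-3 singular values when the test sample is appended.

    The original spectrum (length S) is padded with a zero to align with the
    augmented spectrum (length S+1).  Appending an in-class sample perturbs
    the leading singular values; an out-of-class sample mostly perturbs the
    trailing ones — the diagnostic behind the enhanced classifier.
    """
    M = _check_test_matrix(test, (X.n_timepoints, X.n_regions))
    s_orig = np.linalg.svd(unfold(X.data, 3), compute_uv=False)
    s_aug = np.linalg.svd(unfold(augment_class_tensor(X, M).data, 3), compute_uv=False)
    n = X.n_samples + 1
    pad = lambda s: np.pad(s, (0, n - s.size))  # noqa: E731
    return np.abs(pad(s_aug) - pad(s_orig))
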