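"""Synthetic two-class ROI time-series cohorts with known ground truth.

The generator emulates the statistical structure the tensor pipeline
exploits, not the physiology of BOLD acquisition.  Each subject of class
``i`` is

    X_s = B + A_i (G_i + sigma_c Z_s) B_i^T + E_s,

with three layers:

* a strong rank-(qb1, qb2) *background* pattern ``B`` shared by every
  subject of every class (the common resting-state structure that dominates
  any cohort);
* a class signal living in a low-dimensional time x region subspace
  ``A_i (x) B_i``: a fixed mean coefficient ``G_i`` plus per-subject random
  loadings ``Z_s`` (subjects express their class's components with
  individual strength).  The subspaces are class-specific by default; with
  ``share_components=True`` both classes use the same subspace and differ
  through per-class ``expression_scales`` — the disease-attenuated
  ("hypoactivation") regime;
* noise ``E_s`` whose columns follow a stationary AR(1) process over time
  with cross-region covariance equal to the inverse of a known sparse
  precision matrix (chain, hub or random support) on the correlation scale.

The class subspaces/means carry the discriminative signal; the precision
supports are the ground truth for connectivity recovery.  Everything is
reproducible from the seed.

The default configuration mirrors the shape of a two-group rs-fMRI study
(130 time points, 116 AAL regions, 38 control and 44 patient subjects);
``SyntheticConfig.small()`` gives a reduced shape for fast tests and
``SyntheticConfig.small_shared()`` the shared-components regime.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassTensor

__all__ = [
    "PrecisionSpec",
    "SyntheticConfig",
    "GroundTruth",
    "make_precision",
    "generate_cohort",
    "write_cohort",
    "cohort_digest",
]


@dataclass(frozen=True)
class PrecisionSpec:
    """Ground-truth sparse precision over regions.

    kind: 'chain' (tridiagonal), 'hub' (node 1 connected to all others) or
    'random' (Erdos-Renyi support at the given density).  Off-diagonal edge
    weights have magnitude ``weight``; the diagonal is set for strict
    diagonal dominance, guaranteeing positive definiteness.
    """

    kind: str = "chain"
    weight: float = 0.4
    density: float = 0.1  # used by kind='random'

    def __post_init__(self) -> None:
        if self.kind not in ("chain", "hub", "random"):
            raise ValueError(f"unknown precision kind {self.kind!r}")
        if not 0 < abs(self.weight) < 1:
            raise ValueError("edge weight magnitude must lie in (0, 1)")


def make_precision(spec: PrecisionSpec, R: int, rng: np.random.Generator) -> np.ndarray:
    """Build the SPD ground-truth precision matrix for ``R`` regions."""
    P = np.zeros((R, R))
    if spec.kind == "chain":
        for i in range(R - 1):
            P[i, i + 1] = P[i + 1, i] = -spec.weight
    elif spec.kind == "hub":
        for i in range(1, R):
            P[0, i] = P[i, 0] = -spec.weight
    else:  # random support
        iu = np.triu_indices(R, k=1)
        mask = rng.random(len(iu[0])) < spec.density
        P[iu[0][mask], iu[1][mask]] = -spec.weight
        P = P + P.T
    row_sums = np.abs(P).sum(axis=1)
    np.fill_diagonal(P, row_sums + 1.0)  # strictly diagonally dominant -> SPD
    if np.linalg.eigvalsh(P).min() <= 0:
        raise ValueError("constructed precision matrix is not positive definite")
    return P


@dataclass
class SyntheticConfig:
    """Study conditions for a two-class synthetic cohort.

    Strength parameters are Frobenius-norm ratios against the expected noise
    norm of one subject (noise entries have unit stationary variance):
    ``background_strength`` for the shared pattern, ``snr`` for the class
    mean coefficient, ``subject_variability`` for the per-subject component
    loadings.
    """

    T: int = 130
    R: int = 116
    n_per_class: tuple[int, ...] = (38, 44)
    class_labels: tuple[str, ...] = ("NC", "eMCI")
    background_rank: tuple[int, int] = (5, 5)
    background_strength: float = 3.0
    signal_ranks: tuple[tuple[int, int], ...] = ((2, 2), (2, 2))
    share_components: bool = False
    expression_scales: tuple[float, ...] = (1.0, 1.0)
    snr: float = 0.5
    subject_variability: float = 3.0
    precision_specs: tuple[PrecisionSpec, ...] = (
        PrecisionSpec("chain"),
        PrecisionSpec("hub"),
    )
    temporal_smoothing: float = 0.3  # AR(1) coefficient, in [0, 1)
    zscore: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.T, self.R) < 2 or min(self.n_per_class) < 2:
            raise ValueError("dimensions and class sizes must be at least 2")
        n_cls = len(self.n_per_class)
        per_class = (
            self.class_labels, self.signal_ranks, self.precision_specs,
            self.expression_scales,
        )
        if any(len(item) != n_cls for item in per_class):
            raise ValueError("per-class configuration lists have inconsistent lengths")
        if self.share_components and len(set(self.signal_ranks)) != 1:
            raise ValueError("shared components require equal signal ranks per class")
        if not 0 <= self.temporal_smoothing < 1:
            raise ValueError("temporal smoothing (AR(1) coefficient) must be in [0, 1)")
        if self.snr < 0 or self.subject_variability < 0 or self.background_strength < 0:
            raise ValueError("strength parameters must be non-negative")

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """Reduced shape (T=60, R=20, 20 subjects per class) for fast tests."""
        defaults = dict(T=60, R=20, n_per_class=(20, 20), seed=seed)
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def small_shared(
        cls, seed: int = 0, scales: tuple[float, float] = (1.0, 0.6), **overrides
    ) -> "SyntheticConfig":
        """Small cohort in the shared-components regime.

        Both classes express the same component subspace; the patient class
        expresses it at a reduced scale (default 0.6), emulating attenuated
        expression of common networks in disease.
        """
        defaults = dict(share_components=True, expression_scales=scales)
        defaults.update(overrides)
        return cls.small(seed=seed, **defaults)

    @classmethod
    def connectivity(
        cls, seed: int = 0, n: int = 50, **overrides
    ) -> "SyntheticConfig":
        """Small cohort tuned for connectivity-recovery experiments.

        The low-rank signal layers are switched off (weak mean only) so the
        region dependence structure — the inverse of the ground-truth
        precision — is the dominant source of cross-region covariance.
        """
        defaults = dict(
            n_per_class=(n, n), background_strength=0.0, snr=0.3,
            subject_variability=0.0,
        )
        defaults.update(overrides)
        return cls.small(seed=seed, **defaults)


@dataclass
class GroundTruth:
    """What the generator knows: per-class precisions, covariances and patterns."""

    precisions: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]
    patterns: dict[str, np.ndarray]  # background + class mean pattern
    config: SyntheticConfig | None = field(repr=False, default=None)


def _orthonormal(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    Q, Rm = np.linalg.qr(rng.standard_normal((n, k)))
    return Q * np.sign(np.where(np.diag(Rm) == 0, 1.0, np.diag(Rm)))


def _ar1_noise(
    rng: np.random.Generator, T: int, chol: np.ndarray, phi: float
) -> np.ndarray:
    """T x R noise: stationary AR(1) over time, cross-region covariance chol @ chol.T."""
    innov = rng.standard_normal((T, chol.shape[0])) @ chol.T
    if phi == 0:
        return innov
    E = np.empty_like(innov)
    E[0] = innov[0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, T):
        E[t] = phi * E[t - 1] + scale * innov[t]
    return E


def _zscore_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def generate_cohort(cfg: SyntheticConfig) -> tuple[list[ClassTensor], GroundTruth]:
    """Generate one ClassTensor per class plus the generating ground truth."""
    rng = np.random.default_rng(cfg.seed)
    region_labels = [f"ROI_{i:03d}" for i in range(1, cfg.R + 1)]
    noise_norm = np.sqrt(cfg.T * cfg.R)

    qb1, qb2 = cfg.background_rank
    Ab, Bb = _orthonormal(rng, cfg.T, qb1), _orthonormal(rng, cfg.R, qb2)
    background = Ab @ rng.standard_normal((qb1, qb2)) @ Bb.T
    nb = np.linalg.norm(background)
    if nb > 0 and cfg.background_strength > 0:
        background *= cfg.background_strength * noise_norm / nb
    else:
        background = np.zeros((cfg.T, cfg.R))

    shared_basis = None
    if cfg.share_components:
        q1, q2 = cfg.signal_ranks[0]
        shared_basis = (_orthonormal(rng, cfg.T, q1), _orthonormal(rng, cfg.R, q2))

    classes: list[ClassTensor] = []
    precisions: dict[str, np.ndarray] = {}
    covariances: dict[str, np.ndarray] = {}
    patterns: dict[str, np.ndarray] = {}
    for label, n_subj, (q1, q2), pspec, scale in zip(
        cfg.class_labels, cfg.n_per_class, cfg.signal_ranks,
        cfg.precision_specs, cfg.expression_scales,
    ):
        P = make_precision(pspec, cfg.R, rng)
        Sigma = np.linalg.inv(P)
        d = np.sqrt(np.diag(Sigma))  # rescale to unit stationary variance
        Sigma = Sigma / np.outer(d, d)
        chol = np.linalg.cholesky(Sigma)

        if shared_basis is not None:
            A, B = shared_basis
        else:
            A, B = _orthonormal(rng, cfg.T, q1), _orthonormal(rng, cfg.R, q2)
        G = rng.standard_normal((q1, q2))
        if cfg.snr > 0:
            G *= cfg.snr * noise_norm / np.linalg.norm(G)
        else:
            G = np.zeros((q1, q2))
        sigma_c = cfg.subject_variability * noise_norm / np.sqrt(q1 * q2)

        data = np.empty((cfg.T, cfg.R, n_subj))
        for s in range(n_subj):
            C = scale * (G + sigma_c * rng.standard_normal((q1, q2)))
            X = background + A @ C @ B.T + _ar1_noise(rng, cfg.T, chol, cfg.temporal_smoothing)
            data[:, :, s] = _zscore_columns(X) if cfg.zscore else X
        ids = [f"{label}_{s + 1:03d}" for s in range(n_subj)]
        classes.append(ClassTensor(data, label, ids, region_labels))
        precisions[label] = np.linalg.inv(Sigma)
        covariances[label] = Sigma
        patterns[label] = background + scale * (A @ G @ B.T)
    return classes, GroundTruth(precisions, covariances, patterns, cfg)


# %.17g round-trips IEEE doubles exactly: written cohorts reload bit-for-bit
_FLOAT_FMT = "%.17g"


def write_cohort(
    classes: list[ClassTensor],
    out_dir: str | Path,
    ground_truth: GroundTruth | None = None,
) -> Path:
    """Write a cohort in the on-disk format the loaders and CLI consume.

    Creates ``manifest.tsv`` (subject_id, class, path) plus one TSV per
    subject (header row of region labels, T rows x R columns) and, when
    ground truth is given, a ``ground_truth/`` directory with the per-class
    precision matrices and mean patterns.  Output bytes are deterministic
    for a fixed cohort.  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for X in classes:
        labels = X.region_labels or [f"ROI_{i:03d}" for i in range(1, X.n_regions + 1)]
        header = "\t".join(labels)
        ids = X.subject_ids or [f"{X.class_label}_{s + 1:03d}" for s in range(X.n_samples)]
        for s, sid in enumerate(ids):
            fname = f"{sid}.tsv"
            np.savetxt(
                out / fname,
                X.data[:, :, s],
                fmt=_FLOAT_FMT,
                delimiter="\t",
                header=header,
                comments="",
            )
            rows.append((sid, X.class_label, fname))
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows, columns=["subject_id", "class", "path"]).to_csv(
        manifest, sep="\t", index=False
    )
    if ground_truth is not None:
        gt_dir = out / "ground_truth"
        gt_dir.mkdir(exist_ok=True)
        for label, P in ground_truth.precisions.items():
            np.savetxt(gt_dir / f"precision_{label}.tsv", P, fmt=_FLOAT_FMT, delimiter="\t")
        for label, pat in ground_truth.patterns.items():
            np.savetxt(gt_dir / f"pattern_{label}.tsv", pat, fmt=_FLOAT_FMT, delimiter="\t")
    return manifest


def cohort_digest(out_dir: str | Path) -> str:
    """SHA-256 over every file in a cohort directory (sorted paths) — determinism checks."""
    out = Path(out_dir)
    h = hashlib.sha256()
    for path in sorted(p for p in out.rglob("*") if p.is_file()):
        h.update(str(path.relative_to(out)).encode())
        h.update(path.read_bytes())
    return h.hexdigest()
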