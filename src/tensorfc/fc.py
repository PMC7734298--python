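"""Class-level ("general") functional connectivity from HOSVD region features.

Instead of estimating one connectivity matrix per subject and averaging, each
brain region of a class is compressed to a short feature vector: row ``l`` of
the region-mode singular matrix, restricted to its first ``k3`` columns.
These coefficients express the reduced region slice as a linear combination
of the leading mode-2 core slices, so regions that co-vary across time and
subjects receive similar coefficients.  Treating the ``k3`` coefficients as
observations of ``R`` region variables gives a (rank-deficient) covariance
matrix, from which a sparse precision matrix is estimated by L1-penalized
maximum likelihood (graphical lasso) and converted to partial correlations.

A signed difference graph between two class networks highlights connections
strengthened or weakened in the positive (patient) class; node importance is
summarized by the Onnela weighted clustering coefficient of the absolute
difference graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .classify import ClassTensor, energy_ranks
from .tensor import TruncationRanks, hosvd

__all__ = [
    "RegionFeatureMatrix",
    "FCNetwork",
    "DifferenceGraph",
    "region_features",
    "covariance_from_features",
    "sice",
    "partial_correlation",
    "build_class_fc",
    "difference_graph",
    "difference_to_networkx",
]


@dataclass
class RegionFeatureMatrix:
    """R x k3 matrix of HOSVD-domain region features for one class.

    ``weights`` holds the first k3 region-mode singular values: the natural
    scale of each coefficient direction, used by the weighted covariance
    construction downstream.
    """

    F: np.ndarray
    region_labels: list[str]
    class_label: str
    k3: int
    weights: np.ndarray | None = None


@dataclass
class FCNetwork:
    """Partial-correlation connectivity network with its SPD precision estimate."""

    W: np.ndarray  # R x R symmetric, zero diagonal, entries in [-1, 1]
    precision: np.ndarray  # R x R symmetric positive definite
    lam: float
    region_labels: list[str]
    class_label: str = ""
    ranks: TruncationRanks | None = None


@dataclass
class DifferenceGraph:
    """Signed difference of two class networks (positive = stronger in class 2)."""

    D: np.ndarray
    node_weights: np.ndarray  # Onnela weighted clustering coefficients of |D|
    region_labels: list[str]
    edge_threshold: float = 0.0


def _default_labels(R: int) -> list[str]:
    return [f"ROI_{i:03d}" for i in range(1, R + 1)]  # 1-based ROI indices


def region_features(
    X: ClassTensor, ranks: TruncationRanks | int
) -> RegionFeatureMatrix:
    """Region feature vectors: rows of the truncated region-mode singular matrix.

    ``F[l, :]`` holds the coefficients that express the reduced region slice
    ``Y(:, l, :)`` in the leading ``k3`` mode-2 slices of the partially
    truncated core, which are exactly the first ``k3`` entries of row ``l``
    of the mode-2 singular matrix.
    """
    k3 = ranks.k3 if isinstance(ranks, TruncationRanks) else int(ranks)
    if k3 < 1:
        raise ValueError(f"k3 must be at least 1, got {k3}")
    if k3 > X.n_samples:
        raise ValueError(
            f"k3={k3} exceeds the {X.n_samples} samples of class {X.class_label!r}"
        )
    h = hosvd(X.data)
    V = h.factors[1]
    labels = X.region_labels or _default_labels(X.n_regions)
    return RegionFeatureMatrix(
        F=V[:, :k3].copy(),
        region_labels=list(labels),
        class_label=X.class_label,
        k3=k3,
        weights=h.mode_singular_values[1][:k3].copy(),
    )


def covariance_from_features(
    F: RegionFeatureMatrix | np.ndarray,
    *,
    correlation: bool = True,
    weighted: bool = True,
) -> np.ndarray:
    """Sample covariance over regions, treating the k3 coefficients as observations.

    Each region contributes ``k3`` observations (its feature vector); columns
    are centered and the usual 1/(k3-1) covariance over regions is formed.
    With ``weighted=True`` (default) each observation is scaled by its
    region-mode singular value, making the result a rank-k3 truncation of the
    empirical region covariance: without the weighting the rows of the
    singular matrix carry no scale and their Gram matrix tends to a
    structureless projector as k3 grows.  With ``correlation=True`` (default)
    the result is scaled to a correlation matrix so the graphical-lasso
    penalty is comparable across runs; regions with vanishing feature
    variance keep unit diagonal and zero off-diagonals.  The rank is at most
    ``k3`` (usually far below R), which is precisely why a penalized inverse
    is used downstream rather than direct inversion.
    """
    mat = F.F if isinstance(F, RegionFeatureMatrix) else np.asarray(F, dtype=float)
    k3 = mat.shape[1]
    if k3 < 2:
        raise ValueError(f"need at least 2 feature coefficients per region, got {k3}")
    if weighted and isinstance(F, RegionFeatureMatrix) and F.weights is not None:
        mat = mat * F.weights
    obs = mat.T  # k3 observations x R region variables
    centered = obs - obs.mean(axis=0, keepdims=True)
    C = centered.T @ centered / (k3 - 1)
    if correlation:
        d = np.sqrt(np.diag(C).copy())
        zero = d <= 0
        d[zero] = 1.0
        C = C / np.outer(d, d)
        C[zero, :] = 0.0
        C[:, zero] = 0.0
        np.fill_diagonal(C, 1.0)
    return (C + C.T) / 2


def sice(
    C: np.ndarray,
    lam: float,
    *,
    max_iter: int = 5000,
    tol: float = 1e-10,
    rho: float = 1.0,
) -> np.ndarray:
    """Sparse inverse covariance estimation (graphical lasso).

    Maximizes ``log det(S) - tr(C S) - lam * sum_{i != j} |S_ij|`` over SPD
    matrices ``S`` (the diagonal is not penalized, the convention of standard
    graphical-lasso solvers).  Solved by ADMM with an eigendecomposition-based
    proximal step for the log-det term and elementwise soft-thresholding for
    the penalty; this converges to far tighter optima than the usual
    coordinate-descent stopping rules at the dimensions of ROI networks
    (~10^2 regions).  ``lam = 0`` requires a well-conditioned ``C`` and
    returns its plain inverse.

    Raises ``RuntimeError`` with the iteration count and residuals if the
    ADMM residuals fail to drop below tolerance.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"covariance must be square, got shape {C.shape}")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("covariance matrix must be symmetric")
    if lam < 0:
        raise ValueError(f"sparsity parameter must be non-negative, got {lam}")
    if lam == 0:
        cond = np.linalg.cond(C)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"unpenalized estimation needs a well-conditioned covariance "
                f"(condition number {cond:.3g}); use lam > 0"
            )
        S = np.linalg.inv(C)
        return (S + S.T) / 2

    p = C.shape[0]
    Z = np.eye(p)
    U = np.zeros((p, p))
    r_prim = s_dual = np.inf
    for _ in range(max_iter):
        # proximal step of -log det + tr(CS): spectral solve
        eigval, Q = np.linalg.eigh(rho * (Z - U) - C)
        theta_eig = (eigval + np.sqrt(eigval**2 + 4 * rho)) / (2 * rho)
        Theta = (Q * theta_eig) @ Q.T
        Z_old = Z
        M = Theta + U
        Z = np.sign(M) * np.maximum(np.abs(M) - lam / rho, 0.0)
        np.fill_diagonal(Z, np.diag(M))  # diagonal unpenalized
        U = U + Theta - Z
        r_prim = np.linalg.norm(Theta - Z)
        s_dual = rho * np.linalg.norm(Z - Z_old)
        if r_prim < tol * max(1.0, np.linalg.norm(Theta)) and s_dual < tol * max(
            1.0, np.linalg.norm(U)
        ):
            break
    else:
        raise RuntimeError(
            f"graphical lasso (ADMM) did not converge in {max_iter} iterations: "
            f"primal residual {r_prim:.3g}, dual residual {s_dual:.3g}"
        )
    precision = (Z + Z.T) / 2
    if np.linalg.eigvalsh(precision).min() <= 0:  # pragma: no cover - safeguarded
        raise RuntimeError("graphical lasso returned a non-positive-definite precision")
    return precision


def partial_correlation(precision: np.ndarray) -> np.ndarray:
    """Partial correlations from an SPD precision: ``-S_ij / sqrt(S_ii S_jj)``."""
    P = np.asarray(precision, dtype=float)
    if not np.allclose(P, P.T, atol=1e-8):
        raise ValueError("precision matrix must be symmetric")
    try:
        np.linalg.cholesky(P)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision matrix must be positive definite") from exc
    d = np.sqrt(np.diag(P))
    W = -P / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2


def build_class_fc(
    X: ClassTensor,
    ranks: TruncationRanks | int | None = None,
    lam: float = 0.1,
    *,
    energy: float = 0.95,
    correlation: bool = True,
    weighted: bool = True,
    shrinkage: float = 0.05,
) -> FCNetwork:
    """Full pipeline: region features -> covariance -> sparse precision -> partial correlations.

    ``ranks`` may be explicit, an integer ``k3``, or ``None`` to keep the
    smallest ``k3`` retaining ``energy`` of the sample-mode spectrum.
    ``shrinkage`` blends the (rank-deficient, k3 < R) feature covariance
    toward the identity before estimation, which keeps the graphical-lasso
    solver stable without visibly moving the recovered edge ranking.
    """
    if ranks is None:
        ranks = energy_ranks(X, energy)
    feats = region_features(X, ranks)
    C = covariance_from_features(feats, correlation=correlation, weighted=weighted)
    if not 0 <= shrinkage < 1:
        raise ValueError("shrinkage must lie in [0, 1)")
    if shrinkage > 0:
        C = (1 - shrinkage) * C + shrinkage * np.eye(C.shape[0])
    precision = sice(C, lam)
    W = partial_correlation(precision)
    return FCNetwork(
        W=W,
        precision=precision,
        lam=lam,
        region_labels=feats.region_labels,
        class_label=X.class_label,
        ranks=ranks if isinstance(ranks, TruncationRanks) else None,
    )


def difference_graph(
    fc_pos: FCNetwork, fc_neg: FCNetwork, edge_threshold: float = 0.0
) -> DifferenceGraph:
    """Signed difference ``fc_pos - fc_neg`` with clustering-coefficient node weights.

    Positive entries mark connections stronger in the positive (patient)
    class, negative entries connections weaker there.  Edges below the
    threshold in magnitude are dropped.  Node weights are Onnela-type
    weighted clustering coefficients of ``|D|`` (edge weights max-normalized
    to [0, 1]), computed on the thresholded graph.
    """
    if edge_threshold < 0:
        raise ValueError("edge threshold must be non-negative")
    if fc_pos.region_labels != fc_neg.region_labels:
        raise ValueError("the two networks have different region labels")
    D = fc_pos.W - fc_neg.W
    D = np.where(np.abs(D) >= edge_threshold, D, 0.0) if edge_threshold > 0 else D.copy()
    np.fill_diagonal(D, 0.0)
    G = nx.from_numpy_array(np.abs(D))
    # networkx's weighted clustering is the Onnela geometric-mean formula with
    # weights normalized by the maximum edge weight, giving values in [0, 1].
    cc = nx.clustering(G, weight="weight")
    node_weights = np.array([cc[i] for i in range(D.shape[0])])
    return DifferenceGraph(
        D=D,
        node_weights=node_weights,
        region_labels=list(fc_pos.region_labels),
        edge_threshold=edge_threshold,
    )


def difference_to_networkx(dg: DifferenceGraph) -> nx.Graph:
    """Graph view of a difference network: weight = signed difference, sign attribute."""
    G = nx.Graph()
    for i, label in enumerate(dg.region_labels):
        G.add_node(label, clustering_coefficient=float(dg.node_weights[i]), roi_index=i + 1)
    R = len(dg.region_labels)
    for i in range(R):
        for j in range(i + 1, R):
            w = float(dg.D[i, j])
            if w != 0.0:
                G.add_edge(
                    dg.region_labels[i],
                    dg.region_labels[j],
                    weight=w,
                    sign=1 if w > 0 else -1,
                )
    return G
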