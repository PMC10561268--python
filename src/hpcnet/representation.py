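"""Representational similarity and decoding analyses.

Quantifies what the trained network represents: converged rate vectors per
(sequence, frame) are compared pairwise by cosine dissimilarity (RDMs), and
object identity is read out with a linear decoder under stratified k-fold
cross-validation, against k-means, raw-input linear decoding and linear
slow-feature-analysis baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .config import NetworkConfig
from .core import WeightSet, reset_state, run_to_convergence
from .stimuli import Dataset

__all__ = [
    "RepresentationMatrix",
    "RDMResult",
    "DecodingResult",
    "infer_representations",
    "cosine_dissimilarity",
    "compute_rdm",
    "block_structure_score",
    "decode_linear",
    "kmeans_baseline",
    "sfa_baseline",
    "LinearSFA",
]


@dataclass
class RepresentationMatrix:
    """Converged rate vectors, one row per (sequence, frame), sequence-major."""

    data: np.ndarray  # (n_seq * n_frames, n_units)
    labels: np.ndarray  # (n_rows,) object label per row
    area: int
    n_frames: int
    converged: np.ndarray | None = None  # per-row convergence flags

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.shape[0] != self.labels.shape[0]:
            raise ValueError("one label per representation row required")
        if not np.isfinite(self.data).all():
            raise ValueError("representations contain non-finite entries")


@dataclass
class RDMResult:
    """Square matrix of pairwise cosine dissimilarities, RepresentationMatrix order."""

    matrix: np.ndarray
    labels: np.ndarray
    n_frames: int


@dataclass
class DecodingResult:
    """Held-out accuracies of one read-out method."""

    accuracies: np.ndarray  # per fold (possibly across repeated seeds)
    method: str
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if ((self.accuracies < 0) | (self.accuracies > 1)).any():
            raise ValueError("accuracies must lie in [0, 1]")
        self.mean = float(self.accuracies.mean())
        self.sd = float(self.accuracies.std(ddof=1)) if self.accuracies.size > 1 else 0.0


def infer_representations(
    weights: WeightSet,
    dataset: Dataset,
    config: NetworkConfig,
    area: int,
) -> RepresentationMatrix:
    """Converged rates of one area for every still frame of the dataset.

    For each frame (all frames run as an independent batch sharing the
    frozen weights): reset activity, clamp the frame, run inference to
    convergence, record the area's rate vector.  Rows are sequence-major,
    matching the RDM ordering.
    """
    if not (1 <= area < len(config.area_sizes)):
        raise ValueError(f"area must be in 1..{len(config.area_sizes) - 1}")
    frames = dataset.frames_matrix()  # (R, n_pixels)
    n_frames = dataset.sequences[0].n_frames
    state = reset_state(config, batch_size=frames.shape[0])
    state, converged, _ = run_to_convergence(state, weights, frames, config)
    reps = state.y[area].T.copy()  # (R, n_units)
    return RepresentationMatrix(
        data=reps,
        labels=dataset.frame_labels(),
        area=area,
        n_frames=n_frames,
        converged=np.atleast_1d(converged),
    )


def cosine_dissimilarity(r1: np.ndarray, r2: np.ndarray) -> float:
    """``1 - r1.r2 / (|r1||r2|)``; raises on a zero vector."""
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    n1, n2 = np.linalg.norm(r1), np.linalg.norm(r2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("cosine dissimilarity is undefined for a zero vector")
    return float(1.0 - float(r1 @ r2) / (n1 * n2))


def compute_rdm(reps: RepresentationMatrix) -> RDMResult:
    """Full pairwise cosine-dissimilarity matrix over all representation rows."""
    X = reps.data
    if X.shape[0] < 2:
        raise ValueError("need at least two representations")
    norms = np.linalg.norm(X, axis=1)
    bad = np.where(norms == 0.0)[0]
    if bad.size:
        raise ValueError(f"zero-vector representation at row(s) {bad.tolist()}")
    d = squareform(pdist(X, metric="cosine"))
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)  # guard tiny negative rounding
    return RDMResult(matrix=d, labels=reps.labels.copy(), n_frames=reps.n_frames)


def block_structure_score(rdm: RDMResult, n_frames: int | None = None):
    """Mean dissimilarity within sequence blocks vs across blocks.

    Within-block pairs exclude the diagonal.  Low within / high across is
    the block-diagonal signature of transformation-invariant coding.
    """
    n_frames = rdm.n_frames if n_frames is None else n_frames
    m = rdm.matrix
    R = m.shape[0]
    if R % n_frames != 0:
        raise ValueError("row count must be divisible by n_frames")
    block = np.repeat(np.arange(R // n_frames), n_frames)
    same = block[:, None] == block[None, :]
    off_diag = ~np.eye(R, dtype=bool)
    within = float(m[same & off_diag].mean())
    across = float(m[~same].mean())
    return within, across


def _stratified_folds(labels: np.ndarray, k: int, seed: int):
    counts = np.bincount(labels)
    if (counts[counts > 0] < k).any():
        raise ValueError(f"every class needs at least k={k} samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def decode_linear(
    reps,
    labels: np.ndarray | None = None,
    k: int = 3,
    seed: int = 0,
    C: float = 1.0,
    method: str = "pc_area",
) -> DecodingResult:
    """Linear read-out of object identity, stratified k-fold.

    A multinomial logistic regression (one output unit per class, linear
    map + softmax fit) is trained on k-1 folds and scored on the held-out
    fold; folds are stratified by class.
    """
    if isinstance(reps, RepresentationMatrix):
        X, y = reps.data, reps.labels
    else:
        X, y = np.asarray(reps, dtype=float), np.asarray(labels, dtype=int)
    accs = []
    for train_idx, test_idx in _stratified_folds(y, k, seed):
        clf = LogisticRegression(C=C, max_iter=5000)
        clf.fit(X[train_idx], y[train_idx])
        accs.append(clf.score(X[test_idx], y[test_idx]))
    return DecodingResult(accuracies=np.array(accs), method=method)


def kmeans_baseline(
    inputs: np.ndarray,
    labels: np.ndarray,
    n_classes: int,
    seed: int = 0,
    k: int = 3,
) -> DecodingResult:
    """k-means on raw inputs, clusters mapped to labels by majority vote.

    Clustering is fit on the training folds only; each cluster takes the
    majority label of its training members (empty clusters fall back to the
    overall majority label), and accuracy is scored on the held-out fold
    using the same stratified folds as the linear decoder.
    """
    X = np.asarray(inputs, dtype=float)
    y = np.asarray(labels, dtype=int)
    accs = []
    for train_idx, test_idx in _stratified_folds(y, k, seed):
        km = KMeans(n_clusters=n_classes, random_state=seed, n_init=10)
        train_clusters = km.fit_predict(X[train_idx])
        overall = np.bincount(y[train_idx]).argmax()
        mapping = np.full(n_classes, overall, dtype=int)
        for c in range(n_classes):
            members = y[train_idx][train_clusters == c]
            if members.size:
                mapping[c] = np.bincount(members).argmax()
        pred = mapping[km.predict(X[test_idx])]
        accs.append(float(np.mean(pred == y[test_idx])))
    return DecodingResult(accuracies=np.array(accs), method="kmeans")


class LinearSFA:
    """Linear slow feature analysis on whitened inputs.

    Finds the linear projections of the (whitened) input whose outputs vary
    most slowly across consecutive frames within each sequence: the
    generalized eigenproblem of the temporal-difference covariance under
    unit-variance, decorrelated outputs.  Output features are ordered from
    slowest up; ``delta_values_`` holds the mean squared temporal
    derivative of each feature (0 = constant within sequences, ≈2 for
    whitened white noise).

    scikit-learn style: ``fit(sequences)`` then ``transform(X)``.
    """

    def __init__(self, n_components: int = 10, ridge: float = 1e-9):
        self.n_components = n_components
        self.ridge = ridge

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components, "ridge": self.ridge}

    def set_params(self, **params) -> "LinearSFA":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, sequences, y=None) -> "LinearSFA":
        """`sequences`: iterable of (n_frames, n_features) arrays (or a Dataset)."""
        if isinstance(sequences, Dataset):
            seqs = [s.flat() for s in sequences]
        else:
            seqs = [np.asarray(s, dtype=float) for s in sequences]
        X = np.concatenate(seqs, axis=0)
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        # whitening via eigendecomposition of the input covariance
        cov = Xc.T @ Xc / max(Xc.shape[0] - 1, 1)
        evals, evecs = np.linalg.eigh(cov)
        keep = evals > max(self.ridge, evals.max() * 1e-10)
        if not keep.all():
            import warnings

            warnings.warn(
                "degenerate input covariance: "
                f"dropping {int((~keep).sum())} directions, ridge-regularized",
                RuntimeWarning,
            )
        evals, evecs = evals[keep], evecs[:, keep]
        self.whitener_ = evecs / np.sqrt(evals + self.ridge)
        # covariance of temporal differences in whitened space
        offset = 0
        diffs = []
        for s in seqs:
            Z = (s - self.mean_) @ self.whitener_
            if Z.shape[0] > 1:
                diffs.append(np.diff(Z, axis=0))
            offset += s.shape[0]
        D = np.concatenate(diffs, axis=0)
        dcov = D.T @ D / max(D.shape[0], 1)
        dvals, dvecs = np.linalg.eigh(dcov)  # ascending: slowest first
        n = min(self.n_components, dvecs.shape[1])
        self.components_ = self.whitener_ @ dvecs[:, :n]
        self.delta_values_ = dvals[:n]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_

    def fit_transform(self, sequences, y=None) -> np.ndarray:
        self.fit(sequences)
        if isinstance(sequences, Dataset):
            X = sequences.frames_matrix()
        else:
            X = np.concatenate([np.asarray(s, dtype=float) for s in sequences], axis=0)
        return self.transform(X)


def sfa_baseline(
    dataset: Dataset,
    labels: np.ndarray | None = None,
    n_components: int = 10,
    seed: int = 0,
    k: int = 3,
) -> DecodingResult:
    """Linear SFA of the raw pixels, slowest features fed to the linear decoder."""
    sfa = LinearSFA(n_components=n_components)
    feats = sfa.fit_transform(dataset)
    y = dataset.frame_labels() if labels is None else np.asarray(labels, dtype=int)
    result = decode_linear(feats, y, k=k, seed=seed, method="sfa")
    return result
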