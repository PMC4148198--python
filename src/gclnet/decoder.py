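"""Decoding the GC population code and quantifying its information content.

The spiking network is cascaded with a nearest-centroid classifier: k-means
(k = number of stimulus patterns N) is fitted to spike-count vectors from a
separate set of trial realizations, and each test vector is assigned to its
nearest centroid. Network plus decoder form a discrete channel from N input
patterns to N output classes; mutual information is computed from the
confusion matrix under a flat prior over inputs (maximum log2 N bits).

With few trials per pattern the plug-in MI is biased upward; the default
correction subtracts the mean MI of label-shuffled surrogates, and a
Panzeri-Treves style analytic correction is available as an alternative.

Population sparseness uses the Treves-Rolls measure
S = (C - (sum r)^2 / sum r^2) / (C - 1): 0 for uniform activity across the C
cells, 1 when a single cell is active.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "DecoderModel",
    "MIEstimate",
    "SparsenessResult",
    "fit_decoder",
    "assign",
    "confusion_matrix",
    "mutual_information",
    "population_sparseness",
]


@dataclass
class DecoderModel:
    n_classes: int
    centroids: np.ndarray  # (N, n_gc)
    seed: int = 0


@dataclass
class MIEstimate:
    raw_bits: float
    corrected_bits: float
    n_samples_per_pattern: int
    correction_method: str


@dataclass
class SparsenessResult:
    S: float
    n_cells: int


def fit_decoder(
    training_vectors: np.ndarray, n_classes: int, seed: int = 0
) -> DecoderModel:
    """k-means tessellation of the spike-count output space."""
    x = np.asarray(training_vectors, dtype=float)
    if n_classes < 2:
        raise ValueError("need at least two classes")
    if n_classes > len(x):
        raise ValueError("more classes than training vectors")
    km = KMeans(n_clusters=n_classes, n_init=10, random_state=seed)
    with warnings.catch_warnings():
        # duplicate vectors (e.g. silent populations) legitimately yield
        # fewer distinct clusters than requested
        warnings.simplefilter("ignore", ConvergenceWarning)
        km.fit(x)
    return DecoderModel(
        n_classes=n_classes, centroids=km.cluster_centers_, seed=seed
    )


def assign(model: DecoderModel, vectors: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels (Euclidean); ties go to the lowest index."""
    x = np.atleast_2d(np.asarray(vectors, dtype=float))
    if x.shape[1] != model.centroids.shape[1]:
        raise ValueError("vector dimensionality does not match the decoder")
    # squared distances; argmin picks the lowest index on exact ties
    d2 = (
        (x**2).sum(axis=1, keepdims=True)
        - 2.0 * x @ model.centroids.T
        + (model.centroids**2).sum(axis=1)
    )
    return np.argmin(d2, axis=1)


def confusion_matrix(
    true_labels: np.ndarray, assigned_labels: np.ndarray, n_classes: int
) -> np.ndarray:
    true_labels = np.asarray(true_labels, dtype=int)
    assigned_labels = np.asarray(assigned_labels, dtype=int)
    if true_labels.size == 0:
        raise ValueError("empty labels")
    if true_labels.shape != assigned_labels.shape:
        raise ValueError("label arrays must have equal length")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (true_labels, assigned_labels), 1)
    return cm


def _plugin_mi_bits(cm: np.ndarray) -> float:
    n = cm.sum()
    pj = cm.sum(axis=1, keepdims=True) / n  # flat prior: equal row mass
    pk = cm.sum(axis=0, keepdims=True) / n
    p = cm / n
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / (pj @ pk)[mask])))


def _panzeri_treves_bias(cm: np.ndarray) -> float:
    """First-order undersampling bias of plug-in MI in bits."""
    n = cm.sum()
    r_per_row = np.count_nonzero(cm, axis=1)
    r_joint = int(np.sum(r_per_row))
    r_marg = np.count_nonzero(cm.sum(axis=0))
    n_rows = np.count_nonzero(cm.sum(axis=1))
    return (r_joint - r_marg - n_rows + 1) / (2.0 * n * np.log(2.0))


def mutual_information(
    true_labels: np.ndarray,
    assigned_labels: np.ndarray,
    n_classes: int,
    correction: str = "shuffle",
    n_shuffles: int = 20,
    seed: int = 0,
) -> MIEstimate:
    """Plug-in MI (bits) between pattern labels and decoded classes.

    A flat prior over inputs is assumed (equal trials per pattern). The
    ``shuffle`` correction subtracts the mean MI over label-shuffled
    surrogates; ``panzeri-treves`` subtracts the analytic first-order bias;
    ``none`` reports the raw value.
    """
    cm = confusion_matrix(true_labels, assigned_labels, n_classes)
    raw = _plugin_mi_bits(cm)
    if correction == "none":
        corrected = raw
    elif correction == "panzeri-treves":
        corrected = raw - _panzeri_treves_bias(cm)
    elif correction == "shuffle":
        rng = np.random.default_rng(seed)
        assigned = np.asarray(assigned_labels, dtype=int)
        bias = np.mean(
            [
                _plugin_mi_bits(
                    confusion_matrix(
                        true_labels, rng.permutation(assigned), n_classes
                    )
                )
                for _ in range(n_shuffles)
            ]
        )
        corrected = raw - bias
    else:
        raise ValueError(f"unknown correction {correction!r}")
    n_per = len(np.asarray(true_labels)) // max(n_classes, 1)
    return MIEstimate(
        raw_bits=raw,
        corrected_bits=float(corrected),
        n_samples_per_pattern=int(n_per),
        correction_method=correction,
    )


def population_sparseness(counts: np.ndarray) -> SparsenessResult:
    """Treves-Rolls population sparseness of one spike-count vector.

    An all-zero vector is defined as maximally sparse (S = 1), the limit of a
    single vanishing active cell.
    """
    r = np.asarray(counts, dtype=float).ravel()
    c = r.size
    if c < 2:
        raise ValueError("need at least two cells")
    ssq = float((r**2).sum())
    if ssq == 0.0:
        return SparsenessResult(S=1.0, n_cells=c)
    s = (c - r.sum() ** 2 / ssq) / (c - 1)
    return SparsenessResult(S=float(s), n_cells=c)
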