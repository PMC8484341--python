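"""Per-channel k-means vector quantization and combined clustering.

Each event's wavelet-coefficient vector (80-dimensional at instrument
defaults) is quantized to one of k=8 clusters per scatter channel using
k-means with the squared Euclidean metric. Centroids are re-ordered into a
canonical order (descending L2 norm) so cluster numbering is reproducible
across seeds and machines. Two channels (FSCL and FSCU by convention) are
combined in conjunction into an 8x8 = 64-cell contingency table of
*combined clusters*, which is what the cell-cycle enrichment analysis
operates on.

Frozen centroids support *transfer assignment*: later acquisitions (sorted
aliquots, arrest time points) are assigned to the reference sample's
centroids without refitting, so cluster sizes stay directly comparable.
A fingerprint over the centroid bytes guards against silently mixing
assignments from different models.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .errors import ContractError


def _canonical_order(centroids: np.ndarray) -> np.ndarray:
    """Permutation sorting centroids by descending L2 norm, ties by coordinates."""
    norms = np.linalg.norm(centroids, axis=1)
    # lexsort: last key is primary; negative norm => descending; coordinate
    # columns (reversed so the first coordinate is the strongest tiebreak)
    keys = [-centroids[:, i] for i in range(centroids.shape[1] - 1, -1, -1)]
    keys.append(-norms)
    return np.lexsort(keys)


class PulseKMeans(ClusterMixin, BaseEstimator):
    """k-means vector quantizer for wavelet feature vectors.

    Lloyd's algorithm with k-means++ initialization and ``n_init`` restarts
    (best inertia kept), then canonical reordering of the centroids. No
    feature standardization is applied: coefficient magnitude carries pulse
    amplitude information that distinguishes the cell classes.

    Parameters
    ----------
    n_clusters : int
        Number of clusters k (default 8).
    seed : int
        Random seed; fits are bit-reproducible given the seed.
    n_init : int
        Number of k-means++ restarts.
    channel, level : optional metadata recorded in the model fingerprint.

    Attributes
    ----------
    cluster_centers_ : (k, d) array, canonically ordered.
    labels_ : training-set labels under the canonical numbering.
    inertia_ : sum of squared distances at the kept restart.
    fingerprint_ : hex digest identifying the fitted model.
    """

    def __init__(self, n_clusters: int = 8, seed: int = 0, n_init: int = 10,
                 channel: str | None = None, level: int | None = None):
        self.n_clusters = n_clusters
        self.seed = seed
        self.n_init = n_init
        self.channel = channel
        self.level = level

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ContractError("features must be a 2-D (n_events, dim) array")
        if X.shape[0] < self.n_clusters:
            raise ContractError(
                f"need at least k={self.n_clusters} events, got {X.shape[0]}"
            )
        km = KMeans(
            n_clusters=self.n_clusters,
            init="k-means++",
            n_init=self.n_init,
            random_state=self.seed,
            algorithm="lloyd",
        ).fit(X)
        order = _canonical_order(km.cluster_centers_)
        self.cluster_centers_ = np.ascontiguousarray(km.cluster_centers_[order])
        relabel = np.empty(self.n_clusters, dtype=np.int64)
        relabel[order] = np.arange(self.n_clusters)
        self.labels_ = relabel[km.labels_]
        self.inertia_ = float(km.inertia_)
        self.n_features_in_ = X.shape[1]
        self.fingerprint_ = self._fingerprint()
        return self

    def _fingerprint(self) -> str:
        hsh = hashlib.sha256()
        hsh.update(np.round(self.cluster_centers_, 10).tobytes())
        hsh.update(json.dumps(
            {"k": self.n_clusters, "channel": self.channel, "level": self.level}
        ).encode())
        return hsh.hexdigest()[:16]

    def predict(self, X) -> np.ndarray:
        """Nearest-centroid labels; ties break toward the lower canonical index."""
        if not hasattr(self, "cluster_centers_"):
            raise ContractError("model is not fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.cluster_centers_.shape[1]:
            raise ContractError(
                f"feature dimension {X.shape} does not match centroids "
                f"{self.cluster_centers_.shape}"
            )
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)  # argmin picks the first (lowest) index on ties

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    # -- portable serialization (JSON; text, versioned) ---------------------

    def save(self, path) -> None:
        if not hasattr(self, "cluster_centers_"):
            raise ContractError("model is not fitted")
        payload = {
            "format": "mapsfc-cluster-model", "version": 1,
            "k": self.n_clusters, "seed": self.seed, "n_init": self.n_init,
            "channel": self.channel, "level": self.level,
            "inertia": self.inertia_, "fingerprint": self.fingerprint_,
            "centroids": self.cluster_centers_.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "PulseKMeans":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "mapsfc-cluster-model" or payload.get("version") != 1:
            raise ContractError(f"{path} is not a version-1 cluster model file")
        model = cls(n_clusters=payload["k"], seed=payload["seed"],
                    n_init=payload["n_init"], channel=payload["channel"],
                    level=payload["level"])
        model.cluster_centers_ = np.asarray(payload["centroids"], dtype=np.float64)
        model.inertia_ = payload["inertia"]
        model.n_features_in_ = model.cluster_centers_.shape[1]
        model.fingerprint_ = payload["fingerprint"]
        return model


@dataclass
class CombinedClustering:
    """Conjunction of two per-channel cluster labelings.

    The combined id of an event with labels (a, b) is ``a * k_b + b``; the
    contingency table counts events per (a, b) cell.
    """

    labels_a: np.ndarray
    labels_b: np.ndarray
    k_a: int
    k_b: int
    fingerprint_a: str | None = None
    fingerprint_b: str | None = None
    combined_ids: np.ndarray = field(init=False)
    contingency: np.ndarray = field(init=False)

    def __post_init__(self):
        a = np.asarray(self.labels_a, dtype=np.int64)
        b = np.asarray(self.labels_b, dtype=np.int64)
        if a.shape != b.shape:
            raise ContractError("channel label vectors differ in length")
        if a.size and (a.min() < 0 or a.max() >= self.k_a or b.min() < 0 or b.max() >= self.k_b):
            raise ContractError("labels out of range for the declared k")
        self.labels_a, self.labels_b = a, b
        self.combined_ids = a * self.k_b + b
        self.contingency = np.bincount(
            self.combined_ids, minlength=self.k_a * self.k_b
        ).reshape(self.k_a, self.k_b)

    @property
    def n_events(self) -> int:
        return self.labels_a.size

    def sizes(self) -> np.ndarray:
        """Flat per-combined-cluster event counts (length k_a * k_b)."""
        return self.contingency.reshape(-1)


def fit_channel_clusters(features: np.ndarray, k: int = 8, seed: int = 0,
                         n_init: int = 10, channel: str | None = None,
                         level: int | None = None) -> PulseKMeans:
    """Fit one channel's cluster model (thin wrapper over :class:`PulseKMeans`)."""
    return PulseKMeans(n_clusters=k, seed=seed, n_init=n_init,
                       channel=channel, level=level).fit(features)


def assign(features: np.ndarray, model: PulseKMeans) -> np.ndarray:
    """Assign events to a frozen model's nearest centroids."""
    return model.predict(features)


def combine(labels_a, labels_b, k_a: int = 8, k_b: int = 8,
            fingerprint_a: str | None = None,
            fingerprint_b: str | None = None) -> CombinedClustering:
    """Combine two per-channel labelings into combined clusters."""
    return CombinedClustering(labels_a, labels_b, k_a, k_b,
                              fingerprint_a=fingerprint_a, fingerprint_b=fingerprint_b)
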