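"""Treatment-selection policy estimators (scikit-learn style).

Each estimator learns, from one observed (treatment, outcome) pair per
patient, a full patient-by-treatment remission-probability surface:

* :class:`DPNNPolicy` — the differential-prototype network: a symmetric
  autoencoder whose latent codes are summarized by distances to trainable
  prototypes, fed with a treatment one-hot into a classifier, trained
  jointly against accuracy + reconstruction + (negated) prototype-outcome
  variance.
* :class:`KMNNPolicy` — two-phase baseline: K-means on features alone,
  then a separately trained classifier on centroid distances + treatment.
* :class:`CBRPolicy` — case-based reasoning: per-arm cosine-similarity
  nearest neighbours with similarity-weighted outcome averaging.
* :class:`RandomPolicy` — uniform recommendations, the no-model reference.

All follow the sklearn estimator contract (``get_params``/``set_params``,
``fit(X, y, treatment=...)``, fitted attributes with trailing underscores)
and share the policy surface ``predict_all(X)`` (N x k probabilities),
``predict_proba(X, treatment)`` and ``recommend(X)`` (row-wise argmax,
ties to the lowest treatment index).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics.pairwise import cosine_similarity
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .nn import MLP, Adam, DPNNetwork, bce_grad, bce_loss

__all__ = ["DPNNPolicy", "KMNNPolicy", "CBRPolicy", "RandomPolicy"]


def _one_hot(t: np.ndarray, k: int) -> np.ndarray:
    t = np.asarray(t, dtype=int)
    if t.min() < 0 or t.max() >= k:
        raise ValueError(f"treatment indices must lie in 0..{k - 1}")
    return np.eye(k)[t]


class _PolicyMixin:
    """Shared prediction surface for all policy estimators."""

    def predict_proba(self, X, treatment) -> np.ndarray:
        """Remission probability of each patient under ``treatment``.

        ``treatment`` is a scalar arm index or a length-N vector.
        """
        M = self.predict_all(X)
        t = np.broadcast_to(np.asarray(treatment, dtype=int), (M.shape[0],))
        return M[np.arange(M.shape[0]), t]

    def recommend(self, X) -> np.ndarray:
        """Recommended arm per patient: row-wise argmax of predict_all."""
        return self.predict_all(X).argmax(axis=1)

    def predict(self, X) -> np.ndarray:
        return self.recommend(X)


def _validate_fit_inputs(est, X, y, treatment, n_treatments):
    X, y = check_X_y(X, y)
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    t = np.asarray(treatment, dtype=int)
    if t.shape[0] != X.shape[0]:
        raise ValueError("treatment vector length does not match X")
    k = int(n_treatments) if n_treatments is not None else int(t.max()) + 1
    return X, y, t, k


class DPNNPolicy(_PolicyMixin, BaseEstimator):
    """Differential-prototype network for treatment selection.

    Parameters
    ----------
    n_prototypes : int, default 5
        Number of trainable latent prototypes (the assumed subgroup count).
    latent_dim : int, default 10
        Width of the autoencoder bottleneck.
    encoder_hidden, classifier_hidden : tuple of int
        Hidden-layer widths of the encoder (mirrored in the decoder) and
        of the classification head.
    lambda1, lambda2 : float
        Weights of the reconstruction loss and of the (negated)
        prototype-variance loss in the combined objective.
    alpha : float in (0, 1)
        Balance between intra-prototype (across-treatment) and
        inter-prototype (across-subgroup) variance inside the variance loss.
    distance : {"sqeuclidean", "euclidean"}
        Metric of the prototype layer; squared Euclidean is the default
        (differentiable everywhere).
    variance_normalization : {"l", "lk"}
        Divisor convention of the variance terms (number of prototypes, or
        prototypes times treatments).
    standardize : bool, default True
        Z-score features on the training data before the network.
    epochs, batch_size, learning_rate
        Adam training schedule; mini-batches are reshuffled every epoch.
    n_treatments : int or None
        Number of arms; inferred from the treatment vector when None.
    random_state : int or None
        Seeds initialization and batch shuffling.
    """

    def __init__(
        self,
        n_prototypes: int = 5,
        latent_dim: int = 10,
        encoder_hidden: tuple = (14,),
        classifier_hidden: tuple = (16,),
        lambda1: float = 0.01,
        lambda2: float = 0.05,
        alpha: float = 0.85,
        distance: str = "sqeuclidean",
        variance_normalization: str = "l",
        standardize: bool = True,
        epochs: int = 100,
        batch_size: int = 10,
        learning_rate: float = 1e-4,
        n_treatments: int | None = None,
        random_state: int | None = None,
    ):
        self.n_prototypes = n_prototypes
        self.latent_dim = latent_dim
        self.encoder_hidden = encoder_hidden
        self.classifier_hidden = classifier_hidden
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.alpha = alpha
        self.distance = distance
        self.variance_normalization = variance_normalization
        self.standardize = standardize
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.n_treatments = n_treatments
        self.random_state = random_state

    def fit(self, X, y, treatment):
        """Joint training of autoencoder, prototypes and classifier.

        Every mini-batch step runs one feed-forward, evaluates the combined
        loss (recomputing the prototype-outcome matrix), and backpropagates
        through all components including the prototype matrix.
        """
        X, y, t, k = _validate_fit_inputs(self, X, y, treatment, self.n_treatments)
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1/lambda2 must be non-negative")
        rng = np.random.default_rng(self.random_state)
        self.scaler_ = StandardScaler() if self.standardize else None
        Xs = self.scaler_.fit_transform(X) if self.scaler_ is not None else X
        self.n_features_in_ = X.shape[1]
        self.n_treatments_ = k
        T = _one_hot(t, k)
        net = DPNNetwork(
            input_dim=X.shape[1],
            latent_dim=self.latent_dim,
            n_prototypes=self.n_prototypes,
            n_treatments=k,
            encoder_hidden=self.encoder_hidden,
            classifier_hidden=self.classifier_hidden,
            distance=self.distance,
            rng=rng,
        )
        opt = Adam(net.params, lr=self.learning_rate)
        n = Xs.shape[0]
        if n < self.batch_size and self.epochs > 0:
            raise ValueError("fewer samples than batch_size")
        history = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                loss, _, grads = net.loss_and_grads(
                    Xs[idx], T[idx], y[idx],
                    self.lambda1, self.lambda2, self.alpha,
                    self.variance_normalization,
                )
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite combined loss ({loss}) at step {opt.t}"
                    )
                opt.step(grads)
                epoch_loss += loss
                n_batches += 1
            history.append(epoch_loss / max(n_batches, 1))
        self.network_ = net
        self.prototypes_ = net.prototypes
        self.loss_history_ = np.asarray(history)
        return self

    def _transform_X(self, X):
        check_is_fitted(self, "network_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        return self.scaler_.transform(X) if self.scaler_ is not None else X

    def predict_all(self, X) -> np.ndarray:
        """Predicted remission probability for every patient-arm pair, (N, k)."""
        return self.network_.predict_proba_matrix(self._transform_X(X))

    def encode(self, X) -> np.ndarray:
        """Latent codes of patients under the trained encoder."""
        return self.network_.encode(self._transform_X(X))

    def prototype_outcome_matrix(self) -> np.ndarray:
        """Predicted remission of each prototype under each arm, (l, k)."""
        check_is_fitted(self, "network_")
        return self.network_.prototype_outcome_matrix()

    # ------------------------------------------------------------ checkpoint
    def save(self, path) -> None:
        """Serialize weights, prototypes and config to one .npz archive."""
        check_is_fitted(self, "network_")
        net = self.network_
        arrays = {"prototypes": net.prototypes}
        for tag, mlp in (("enc", net.encoder), ("dec", net.decoder), ("clf", net.classifier)):
            for i, (W, b) in enumerate(zip(mlp.W, mlp.b)):
                arrays[f"{tag}_W{i}"] = W
                arrays[f"{tag}_b{i}"] = b
        if self.scaler_ is not None:
            arrays["scaler_mean"] = self.scaler_.mean_
            arrays["scaler_scale"] = self.scaler_.scale_
        import json as _json

        params = dict(self.get_params())
        params["encoder_hidden"] = list(params["encoder_hidden"])
        params["classifier_hidden"] = list(params["classifier_hidden"])
        meta = {"params": params, "n_features_in": int(self.n_features_in_),
                "n_treatments": int(self.n_treatments_)}
        arrays["meta_json"] = np.frombuffer(_json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "DPNNPolicy":
        import json as _json

        with np.load(path) as data:
            meta = _json.loads(bytes(data["meta_json"].tobytes()).decode())
            params = meta["params"]
            params["encoder_hidden"] = tuple(params["encoder_hidden"])
            params["classifier_hidden"] = tuple(params["classifier_hidden"])
            est = cls(**params)
            est.n_features_in_ = meta["n_features_in"]
            est.n_treatments_ = meta["n_treatments"]
            net = DPNNetwork(
                input_dim=est.n_features_in_,
                latent_dim=est.latent_dim,
                n_prototypes=est.n_prototypes,
                n_treatments=est.n_treatments_,
                encoder_hidden=est.encoder_hidden,
                classifier_hidden=est.classifier_hidden,
                distance=est.distance,
                rng=np.random.default_rng(0),
            )
            net.prototypes[...] = data["prototypes"]
            for tag, mlp in (("enc", net.encoder), ("dec", net.decoder), ("clf", net.classifier)):
                for i in range(len(mlp.W)):
                    mlp.W[i][...] = data[f"{tag}_W{i}"]
                    mlp.b[i][...] = data[f"{tag}_b{i}"]
            est.network_ = net
            est.prototypes_ = net.prototypes
            if "scaler_mean" in data:
                scaler = StandardScaler()
                scaler.mean_ = data["scaler_mean"]
                scaler.scale_ = data["scaler_scale"]
                scaler.var_ = scaler.scale_**2
                scaler.n_features_in_ = est.n_features_in_
                est.scaler_ = scaler
            else:
                est.scaler_ = None
        return est


class KMNNPolicy(_PolicyMixin, BaseEstimator):
    """K-means + neural-network baseline.

    Phase 1 clusters the training features alone (outcomes and treatments
    hidden from the clustering).  Phase 2 trains a fully connected
    classifier on each patient's vector of Euclidean distances to the
    centroids, concatenated with the treatment one-hot.  The two phases
    are separate: the centroids are frozen before the classifier sees any
    outcome.  The classifier head mirrors the DPN head so the comparison
    isolates the prototype training, not capacity.
    """

    def __init__(
        self,
        n_clusters: int = 5,
        classifier_hidden: tuple = (16,),
        standardize: bool = True,
        epochs: int = 100,
        batch_size: int = 10,
        learning_rate: float = 1e-4,
        n_treatments: int | None = None,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.classifier_hidden = classifier_hidden
        self.standardize = standardize
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.n_treatments = n_treatments
        self.random_state = random_state

    def fit(self, X, y, treatment):
        X, y, t, k = _validate_fit_inputs(self, X, y, treatment, self.n_treatments)
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        rng = np.random.default_rng(self.random_state)
        seed = int(rng.integers(0, 2**31 - 1))
        self.scaler_ = StandardScaler() if self.standardize else None
        Xs = self.scaler_.fit_transform(X) if self.scaler_ is not None else X
        self.n_features_in_ = X.shape[1]
        self.n_treatments_ = k
        km = KMeans(n_clusters=self.n_clusters, n_init=10, random_state=seed)
        km.fit(Xs)
        self.kmeans_ = km
        self.centroids_ = km.cluster_centers_
        # phase 2: classifier on (centroid distances, treatment one-hot)
        D = km.transform(Xs)  # Euclidean distances to centroids
        T = _one_hot(t, k)
        clf = MLP([self.n_clusters + k, *self.classifier_hidden, 1], "sigmoid", rng)
        opt = Adam(clf.params, lr=self.learning_rate)
        n = Xs.shape[0]
        if n < self.batch_size and self.epochs > 0:
            raise ValueError("fewer samples than batch_size")
        Cin = np.hstack([D, T])
        history = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                probs_col, cache = clf.forward(Cin[idx])
                loss = bce_loss(probs_col[:, 0], y[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite classifier loss ({loss})")
                _, grads = clf.backward(cache, bce_grad(probs_col[:, 0], y[idx])[:, None])
                opt.step(grads)
                epoch_loss += loss
                n_batches += 1
            history.append(epoch_loss / max(n_batches, 1))
        self.classifier_ = clf
        self.loss_history_ = np.asarray(history)
        return self

    def transform(self, X) -> np.ndarray:
        """Centroid-distance representation of patients, (N, n_clusters)."""
        check_is_fitted(self, "kmeans_")
        X = check_array(X)
        Xs = self.scaler_.transform(X) if self.scaler_ is not None else X
        return self.kmeans_.transform(Xs)

    def predict_all(self, X) -> np.ndarray:
        D = self.transform(X)
        k = self.n_treatments_
        out = np.empty((D.shape[0], k))
        for j in range(k):
            T = np.zeros((D.shape[0], k))
            T[:, j] = 1.0
            out[:, j] = self.classifier_.forward(np.hstack([D, T]))[0][:, 0]
        return out


class CBRPolicy(_PolicyMixin, BaseEstimator):
    """Case-based reasoning baseline.

    The predicted remission probability of a query patient under arm ``t``
    is the cosine-similarity-weighted mean outcome of the ``n_neighbors``
    most similar training patients who actually received ``t``.  Negative
    similarities are clamped to zero (a dissimilar case should not vote);
    if every retained weight is zero the arm's training base rate is used.
    """

    def __init__(
        self,
        n_neighbors: int = 10,
        standardize: bool = True,
        n_treatments: int | None = None,
        random_state: int | None = None,
    ):
        self.n_neighbors = n_neighbors
        self.standardize = standardize
        self.n_treatments = n_treatments
        self.random_state = random_state

    def fit(self, X, y, treatment):
        X, y, t, k = _validate_fit_inputs(self, X, y, treatment, self.n_treatments)
        self.scaler_ = StandardScaler() if self.standardize else None
        Xs = self.scaler_.fit_transform(X) if self.scaler_ is not None else X
        self.n_features_in_ = X.shape[1]
        self.n_treatments_ = k
        self.arm_X_, self.arm_y_, self.arm_rate_ = [], [], []
        for j in range(k):
            mask = t == j
            if not mask.any():
                raise ValueError(f"treatment arm {j} has no training patients")
            if mask.sum() < self.n_neighbors:
                raise ValueError(
                    f"treatment arm {j} has {mask.sum()} patients, fewer than "
                    f"n_neighbors={self.n_neighbors}"
                )
            self.arm_X_.append(Xs[mask])
            self.arm_y_.append(y[mask])
            self.arm_rate_.append(float(y[mask].mean()))
        return self

    def predict_all(self, X) -> np.ndarray:
        check_is_fitted(self, "arm_X_")
        X = check_array(X)
        Xs = self.scaler_.transform(X) if self.scaler_ is not None else X
        n, k = Xs.shape[0], self.n_treatments_
        out = np.empty((n, k))
        for j in range(k):
            sim = cosine_similarity(Xs, self.arm_X_[j])
            # top-n neighbours per query, weights clamped at zero
            top = np.argpartition(-sim, self.n_neighbors - 1, axis=1)[:, : self.n_neighbors]
            rows = np.arange(n)[:, None]
            w = np.maximum(sim[rows, top], 0.0)
            yj = self.arm_y_[j][top]
            wsum = w.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                pred = (w * yj).sum(axis=1) / wsum
            out[:, j] = np.where(wsum > 0, pred, self.arm_rate_[j])
        return out


class RandomPolicy(_PolicyMixin, BaseEstimator):
    """Uniform-random treatment recommendation (no-model reference)."""

    def __init__(self, n_treatments: int | None = None, random_state: int | None = None):
        self.n_treatments = n_treatments
        self.random_state = random_state

    def fit(self, X, y, treatment):
        X, y, t, k = _validate_fit_inputs(self, X, y, treatment, self.n_treatments)
        self.n_features_in_ = X.shape[1]
        self.n_treatments_ = k
        self.rate_ = float(np.mean(y))
        self._rng = np.random.default_rng(self.random_state)
        return self

    def predict_all(self, X) -> np.ndarray:
        """Uniform random scores, so the row-wise argmax is a uniform pick."""
        check_is_fitted(self, "n_treatments_")
        X = check_array(X)
        return self._rng.random((X.shape[0], self.n_treatments_))

    def recommend(self, X) -> np.ndarray:
        check_is_fitted(self, "n_treatments_")
        X = check_array(X)
        return self._rng.integers(0, self.n_treatments_, size=X.shape[0])
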