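"""Numpy building blocks for the differential-prototype network (DPN).

The network is small (two or three dense layers per component) and is
trained with explicit, hand-derived backpropagation; every gradient path in
this module is covered by central finite-difference tests.  Components:

* :class:`MLP` — dense feed-forward block with ReLU hidden layers and a
  linear or sigmoid output, returning caches for the backward pass.
* prototype distance layer — (squared) Euclidean distances from encoded
  samples to the trainable prototype matrix, with gradients to both.
* the three loss components and their composition:

  - ``bce_loss``: binary cross-entropy of the predicted remission
    probability against the observed outcome (lower is better);
  - ``reconstruction_loss``: per-sample unsquared Euclidean distance
    between input and autoencoder reconstruction, averaged over the batch;
  - ``prototype_variance_loss``: the negated weighted sum of the
    intra-prototype variance (spread of a prototype's predicted outcomes
    across treatments) and the inter-prototype variance (spread across
    prototypes for a fixed treatment) of the prototype-outcome matrix
    ``Y_P``; negated because the training objective *rewards* spread.

  The combined objective is ``L = L1 + lambda1 * L2 + lambda2 * L3``.

Batch averaging: the printed definitions of the accuracy and reconstruction
terms are sums over the training set; here both are divided by the batch
size so the ``lambda`` weights do not depend on batch size.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

EPS = 1e-7  # probability clamp inside logarithms


# ----------------------------------------------------------------- layers
class MLP:
    """Dense feed-forward block with ReLU hidden layers.

    Parameters
    ----------
    sizes : sequence of int
        Layer widths, ``[n_in, *hidden, n_out]``.
    out_activation : {"linear", "sigmoid"}
        Activation applied to the final layer.
    rng : numpy Generator
        Source for the uniform fan-in weight initialization.
    """

    def __init__(self, sizes, out_activation: str = "linear", rng: np.random.Generator | None = None):
        if out_activation not in ("linear", "sigmoid"):
            raise ValueError(f"unknown out_activation {out_activation!r}")
        if rng is None:
            rng = np.random.default_rng()
        self.sizes = list(sizes)
        self.out_activation = out_activation
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for n_in, n_out in zip(self.sizes[:-1], self.sizes[1:]):
            bound = 1.0 / np.sqrt(n_in)
            self.W.append(rng.uniform(-bound, bound, size=(n_in, n_out)))
            self.b.append(rng.uniform(-bound, bound, size=n_out))

    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def forward(self, X: np.ndarray):
        """Returns (output, cache); cache feeds :meth:`backward`."""
        acts = [X]
        a = X
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            if i < last:
                a = np.maximum(z, 0.0)
            elif self.out_activation == "sigmoid":
                a = expit(z)
            else:
                a = z
            acts.append(a)
        return a, acts

    def backward(self, cache, d_out: np.ndarray):
        """Backprop ``d_out = dL/d(output)`` through the block.

        Returns ``(d_input, grads)`` with ``grads`` aligned to :attr:`params`.
        """
        acts = cache
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        last = len(self.W) - 1
        delta = d_out
        for i in range(last, -1, -1):
            a_out = acts[i + 1]
            if i == last:
                if self.out_activation == "sigmoid":
                    delta = delta * a_out * (1.0 - a_out)
                # linear: delta unchanged
            else:
                delta = delta * (a_out > 0)
            a_in = acts[i]
            gW[i] = a_in.T @ delta
            gb[i] = delta.sum(axis=0)
            delta = delta @ self.W[i].T
        return delta, gW + gb


def mirror_sizes(encoder_sizes) -> list[int]:
    """Decoder layer widths for a symmetrical autoencoder."""
    return list(reversed(encoder_sizes))


# -------------------------------------------------- prototype distance layer
def prototype_distances(Z: np.ndarray, P: np.ndarray, squared: bool = True) -> np.ndarray:
    """Distances from each encoded sample to each prototype, shape (N, l)."""
    diff = Z[:, None, :] - P[None, :, :]
    d2 = np.einsum("ilq,ilq->il", diff, diff)
    return d2 if squared else np.sqrt(d2)


def prototype_distances_backward(
    Z: np.ndarray, P: np.ndarray, dD: np.ndarray, squared: bool = True
):
    """Gradients of a scalar loss through the distance layer.

    ``dD`` is dL/dD; returns ``(dZ, dP)``.
    """
    if not squared:
        d2 = prototype_distances(Z, P, squared=True)
        root = np.sqrt(d2)
        with np.errstate(divide="ignore", invalid="ignore"):
            dD = np.where(root > 0, dD / (2.0 * root), 0.0)
    dZ = 2.0 * (dD.sum(axis=1, keepdims=True) * Z - dD @ P)
    dP = -2.0 * (dD.T @ Z - dD.sum(axis=0)[:, None] * P)
    return dZ, dP


# ----------------------------------------------------------------- losses
def bce_loss(probs: np.ndarray, y: np.ndarray, eps: float = EPS) -> float:
    """Mean binary cross-entropy, probabilities clamped to [eps, 1-eps]."""
    p = np.clip(probs, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def bce_grad(probs: np.ndarray, y: np.ndarray, eps: float = EPS) -> np.ndarray:
    p = np.clip(probs, eps, 1.0 - eps)
    g = (p - y) / (p * (1.0 - p)) / y.shape[0]
    # clamped region has zero local derivative
    g[(probs < eps) | (probs > 1.0 - eps)] = 0.0
    return g


def reconstruction_loss(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Mean per-sample Euclidean distance between input and reconstruction."""
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch {X.shape} vs {X_hat.shape}")
    return float(np.mean(np.linalg.norm(X - X_hat, axis=1)))


def reconstruction_grad(X: np.ndarray, X_hat: np.ndarray) -> np.ndarray:
    diff = X_hat - X
    norms = np.linalg.norm(diff, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(norms > 0, diff / norms, 0.0)
    return g / X.shape[0]


def _divisor(Y: np.ndarray, normalization: str) -> float:
    l, k = Y.shape
    if normalization == "l":
        return float(l)
    if normalization == "lk":
        return float(l * k)
    raise ValueError(f"unknown normalization {normalization!r}")


def intra_variance(Y: np.ndarray, normalization: str = "l") -> float:
    """Spread of predicted outcomes across treatments within each prototype.

    Sum over prototypes of the within-row squared deviations of the
    prototype-outcome matrix, divided by the number of prototypes
    (``normalization="lk"`` divides by l*k instead).
    """
    centered = Y - Y.mean(axis=1, keepdims=True)
    return float((centered**2).sum() / _divisor(Y, normalization))


def inter_variance(Y: np.ndarray, normalization: str = "l") -> float:
    """Spread of predicted outcomes across prototypes for each treatment."""
    centered = Y - Y.mean(axis=0, keepdims=True)
    return float((centered**2).sum() / _divisor(Y, normalization))


def prototype_variance_loss(Y: np.ndarray, alpha: float, normalization: str = "l") -> float:
    """Negated weighted variance mix; always <= 0 since both terms are >= 0."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return -(alpha * intra_variance(Y, normalization) + (1.0 - alpha) * inter_variance(Y, normalization))


def prototype_variance_grad(Y: np.ndarray, alpha: float, normalization: str = "l") -> np.ndarray:
    div = _divisor(Y, normalization)
    row_c = Y - Y.mean(axis=1, keepdims=True)
    col_c = Y - Y.mean(axis=0, keepdims=True)
    return -(alpha * 2.0 * row_c + (1.0 - alpha) * 2.0 * col_c) / div


def combined_loss(L1: float, L2: float, L3: float, lambda1: float, lambda2: float) -> float:
    """Linear combination ``L1 + lambda1 * L2 + lambda2 * L3``."""
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("loss weights must be non-negative")
    return L1 + lambda1 * L2 + lambda2 * L3


# -------------------------------------------------------------- optimizer
class Adam:
    """Adam over a flat list of parameter arrays (updates in place)."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# ------------------------------------------------------------- the network
class DPNNetwork:
    """Encoder + decoder + trainable prototypes + treatment-aware classifier.

    The encoder maps the m observed features to a q-dimensional code; the
    prototype layer replaces the code by its vector of (squared) distances
    to ``n_prototypes`` trainable latent points; the classifier consumes
    the distance vector concatenated with a one-hot treatment and outputs a
    remission probability.  Everything, prototypes included, is trained
    jointly against the combined loss.
    """

    def __init__(
        self,
        input_dim: int,
        latent_dim: int,
        n_prototypes: int,
        n_treatments: int,
        encoder_hidden=(14,),
        classifier_hidden=(16,),
        distance: str = "sqeuclidean",
        rng: np.random.Generator | None = None,
    ):
        if n_prototypes < 2:
            raise ValueError("need at least 2 prototypes")
        if distance not in ("sqeuclidean", "euclidean"):
            raise ValueError(f"unknown distance {distance!r}")
        if rng is None:
            rng = np.random.default_rng()
        self.input_dim = input_dim
        self.latent_dim = latent_dim
        self.n_prototypes = n_prototypes
        self.n_treatments = n_treatments
        self.distance = distance
        enc_sizes = [input_dim, *encoder_hidden, latent_dim]
        self.encoder = MLP(enc_sizes, "linear", rng)
        self.decoder = MLP(mirror_sizes(enc_sizes), "linear", rng)
        # "randomly initiated" prototypes, standard normal in latent space
        self.prototypes = rng.standard_normal((n_prototypes, latent_dim))
        self.classifier = MLP(
            [n_prototypes + n_treatments, *classifier_hidden, 1], "sigmoid", rng
        )

    # ---------------------------------------------------------- forward ops
    @property
    def params(self) -> list[np.ndarray]:
        return self.encoder.params + self.decoder.params + [self.prototypes] + self.classifier.params

    def encode(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.input_dim:
            raise ValueError(f"expected {self.input_dim} features, got {X.shape[1]}")
        return self.encoder.forward(X)[0]

    def reconstruct(self, codes: np.ndarray) -> np.ndarray:
        if codes.shape[1] != self.latent_dim:
            raise ValueError(f"expected {self.latent_dim}-d codes, got {codes.shape[1]}")
        return self.decoder.forward(codes)[0]

    def distances(self, codes: np.ndarray) -> np.ndarray:
        return prototype_distances(codes, self.prototypes, self.distance == "sqeuclidean")

    def classify(self, D: np.ndarray, T_onehot: np.ndarray) -> np.ndarray:
        if D.shape[0] != T_onehot.shape[0]:
            raise ValueError("distance and treatment rows misaligned")
        return self.classifier.forward(np.hstack([D, T_onehot]))[0][:, 0]

    def prototype_outcome_matrix(self) -> np.ndarray:
        """Predicted remission probability of every prototype under every
        treatment, shape (n_prototypes, n_treatments).

        Each prototype is represented exactly as a patient encoded at that
        point would be: by its distance vector to all prototypes (zero
        self-distance), paired with each treatment one-hot.
        """
        l, k = self.n_prototypes, self.n_treatments
        Dp = prototype_distances(self.prototypes, self.prototypes, self.distance == "sqeuclidean")
        D_rep = np.repeat(Dp, k, axis=0)  # (l*k, l), prototype-major
        T_rep = np.tile(np.eye(k), (l, 1))
        return self.classify(D_rep, T_rep).reshape(l, k)

    def predict_proba_matrix(self, X: np.ndarray) -> np.ndarray:
        """All-treatment prediction surface, shape (N, k)."""
        D = self.distances(self.encode(X))
        out = np.empty((X.shape[0], self.n_treatments))
        for j in range(self.n_treatments):
            T = np.zeros((X.shape[0], self.n_treatments))
            T[:, j] = 1.0
            out[:, j] = self.classify(D, T)
        return out

    # ------------------------------------------------------- loss & gradient
    def loss_and_grads(self, X, T_onehot, y, lambda1, lambda2, alpha, variance_normalization="l"):
        """Forward pass and full hand-derived gradient of the combined loss.

        Returns ``(loss, parts, grads)`` with ``parts = (L1, L2, L3)`` and
        ``grads`` aligned with :attr:`params`.
        """
        sq = self.distance == "sqeuclidean"
        l, k = self.n_prototypes, self.n_treatments
        n = X.shape[0]
        # forward
        Z, enc_cache = self.encoder.forward(X)
        X_hat, dec_cache = self.decoder.forward(Z)
        D = prototype_distances(Z, self.prototypes, sq)
        Dp = prototype_distances(self.prototypes, self.prototypes, sq)
        # one classifier pass over the batch rows and the l*k prototype rows
        Cin = np.empty((n + l * k, l + k))
        Cin[:n, :l] = D
        Cin[:n, l:] = T_onehot
        Cin[n:, :l] = np.repeat(Dp, k, axis=0)
        Cin[n:, l:] = np.tile(np.eye(k), (l, 1))
        out_col, clf_cache = self.classifier.forward(Cin)
        probs = out_col[:n, 0]
        Y_P = out_col[n:, 0].reshape(l, k)

        L1 = bce_loss(probs, y)
        L2 = reconstruction_loss(X, X_hat)
        L3 = prototype_variance_loss(Y_P, alpha, variance_normalization)
        loss = combined_loss(L1, L2, L3, lambda1, lambda2)

        # backward — accuracy and prototype-variance paths share the classifier
        d_out = np.empty((n + l * k, 1))
        d_out[:n, 0] = bce_grad(probs, y)
        d_out[n:, 0] = (
            lambda2 * prototype_variance_grad(Y_P, alpha, variance_normalization)
        ).ravel()
        dCin, clf_grads = self.classifier.backward(clf_cache, d_out)
        dD = dCin[:n, :l]
        dZ_dist, dP_dist = prototype_distances_backward(Z, self.prototypes, dD, sq)
        dDp = dCin[n:, :l].reshape(l, k, l).sum(axis=1)  # (l, l) in Dp layout
        dP_a, dP_b = prototype_distances_backward(self.prototypes, self.prototypes, dDp, sq)
        dP = dP_dist + dP_a + dP_b

        # reconstruction path
        dXhat = lambda1 * reconstruction_grad(X, X_hat)
        dZ_dec, dec_grads = self.decoder.backward(dec_cache, dXhat)
        _, enc_grads = self.encoder.backward(enc_cache, dZ_dist + dZ_dec)

        grads = enc_grads + dec_grads + [dP] + clf_grads
        return loss, (L1, L2, L3), grads
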