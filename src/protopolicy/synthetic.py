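"""Synthetic cohort simulator with full counterfactual remission surfaces.

Real treatment-selection data only ever reveals the outcome of the one
treatment a patient actually received.  To benchmark a selection policy we
need the whole counterfactual surface — the remission probability of every
patient under every treatment — so this module builds cohorts by "reverse
engineering": latent subgroup prototypes are drawn first, patients are
scattered around them in latent space, per-treatment outcome functions are
applied to the *latent* coordinates, and only then is each patient decoded
into the observed feature space the models are allowed to see.

The generative process (all randomness from one seeded generator):

1. ``n_prototypes_true`` prototypes in a ``latent_dim``-dimensional latent
   space, coordinates i.i.d. Normal(0, ``prototype_sd``).
2. ``patients_per_prototype`` patients per prototype, each coordinate
   Normal(prototype coordinate, ``patient_sd``).
3. One two-layer ReLU network per treatment arm (weights standard normal)
   maps latent coordinates to a 2-vector of logits; a softmax turns the
   logits into a remission probability.  Treatments are assigned uniformly
   at random (independent of features), and the observed binary outcome is
   a Bernoulli draw from the assigned arm's probability.
4. Latent coordinates are decoded through a fixed random linear map into
   ``observed_dim`` observable features, and ``n_irrelevant`` pure-noise
   standard-normal features are appended.

Models consume only ``(X, t, y)``; the latent coordinates, subgroup labels
and the true probability matrix ``P_true`` are retained for evaluation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import softmax

__all__ = [
    "SyntheticConfig",
    "RemissionFunctionSet",
    "Cohort",
    "generate_prototypes",
    "generate_latent_patients",
    "sample_remission_functions",
    "true_remission_probability",
    "remission_probability_matrix",
    "assign_treatments_and_outcomes",
    "decode_to_observed",
    "generate_cohort",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the cohort generator.

    Defaults are the benchmark study conditions: 5 latent subgroups in a
    10-d latent space (prototype and patient spread both 10), 2,000
    patients per subgroup (N = 10,000), 4 treatment arms, and decoding to
    16 observed + 4 irrelevant features (d = 20).
    """

    n_prototypes_true: int = 5
    latent_dim: int = 10
    patients_per_prototype: int = 2000
    n_treatments: int = 4
    prototype_sd: float = 10.0
    patient_sd: float = 10.0
    remission_hidden_dim: int = 5
    observed_dim: int = 16
    n_irrelevant: int = 4
    seed: int = 0

    @property
    def n_patients(self) -> int:
        return self.n_prototypes_true * self.patients_per_prototype

    @property
    def n_features(self) -> int:
        return self.observed_dim + self.n_irrelevant

    def validate(self) -> None:
        for name in (
            "n_prototypes_true",
            "latent_dim",
            "patients_per_prototype",
            "n_treatments",
            "remission_hidden_dim",
            "observed_dim",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_irrelevant < 0:
            raise ValueError("n_irrelevant must be >= 0")
        if self.prototype_sd < 0 or self.patient_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class RemissionFunctionSet:
    """One random two-layer ReLU outcome function per treatment arm.

    Arm ``j`` maps a latent vector ``z`` to logits ``relu(z @ W1[j]) @ W2[j]``
    (a 2-vector: remission / non-remission); the remission probability is
    the softmax of the logits, component 0.
    """

    W1: tuple[np.ndarray, ...]  # each latent_dim x hidden
    W2: tuple[np.ndarray, ...]  # each hidden x 2

    @property
    def n_treatments(self) -> int:
        return len(self.W1)


@dataclass
class Cohort:
    """A tabular cohort: features, received treatment, observed outcome.

    ``P_true`` (N x k true remission probabilities), ``latent_Z`` and
    ``prototype_label`` are generator-side ground truth, present only for
    simulated cohorts and never shown to models.
    """

    X: np.ndarray
    t: np.ndarray
    y: np.ndarray
    P_true: np.ndarray | None = None
    latent_Z: np.ndarray | None = None
    prototype_label: np.ndarray | None = None
    config: SyntheticConfig | None = None

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        for name in ("t", "y", "P_true", "latent_Z", "prototype_label"):
            arr = getattr(self, name)
            if arr is not None and arr.shape[0] != n:
                raise ValueError(f"{name} has {arr.shape[0]} rows, X has {n}")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("outcomes must be binary")

    @property
    def n_patients(self) -> int:
        return self.X.shape[0]

    @property
    def n_treatments(self) -> int:
        if self.P_true is not None:
            return self.P_true.shape[1]
        return int(self.t.max()) + 1

    def subset(self, idx: np.ndarray) -> "Cohort":
        """Row-subset view (copies), keeping whatever side information exists."""
        opt = lambda a: None if a is None else a[idx]
        return Cohort(
            X=self.X[idx],
            t=self.t[idx],
            y=self.y[idx],
            P_true=opt(self.P_true),
            latent_Z=opt(self.latent_Z),
            prototype_label=opt(self.prototype_label),
            config=self.config,
        )

    # ------------------------------------------------------------------ I/O
    def to_csv(self, out_dir: str | Path) -> None:
        """Write cohort.csv (f0..f{d-1}, treatment, outcome), ptrue.csv
        (p0..p{k-1}) when available, and a JSON sidecar with the config."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        d = self.X.shape[1]
        df = pd.DataFrame(self.X, columns=[f"f{i}" for i in range(d)])
        df["treatment"] = self.t
        df["outcome"] = self.y
        df.to_csv(out / "cohort.csv", index=False)
        if self.P_true is not None:
            pd.DataFrame(
                self.P_true, columns=[f"p{j}" for j in range(self.P_true.shape[1])]
            ).to_csv(out / "ptrue.csv", index=False)
        meta = {}
        if self.config is not None:
            meta["config"] = dataclasses.asdict(self.config)
            meta["seed"] = self.config.seed
        (out / "cohort.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, in_dir: str | Path) -> "Cohort":
        src = Path(in_dir)
        df = pd.read_csv(src / "cohort.csv")
        feat_cols = [c for c in df.columns if c.startswith("f")]
        P_true = None
        if (src / "ptrue.csv").exists():
            P_true = pd.read_csv(src / "ptrue.csv").to_numpy(dtype=float)
        config = None
        meta_path = src / "cohort.json"
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            if "config" in meta:
                config = SyntheticConfig(**meta["config"])
        return cls(
            X=df[feat_cols].to_numpy(dtype=float),
            t=df["treatment"].to_numpy(dtype=int),
            y=df["outcome"].to_numpy(dtype=int),
            P_true=P_true,
            config=config,
        )


# --------------------------------------------------------------- generation
def generate_prototypes(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the true subgroup prototypes, shape (n_prototypes_true, latent_dim)."""
    config.validate()
    return rng.normal(
        0.0, config.prototype_sd, size=(config.n_prototypes_true, config.latent_dim)
    )


def generate_latent_patients(
    prototypes: np.ndarray, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Scatter patients_per_prototype patients around each prototype.

    Returns (latent_Z of shape (N, latent_dim), prototype_label of shape (N,)).
    """
    if prototypes.shape != (config.n_prototypes_true, config.latent_dim):
        raise ValueError(
            f"prototypes shape {prototypes.shape} does not match config "
            f"({config.n_prototypes_true}, {config.latent_dim})"
        )
    labels = np.repeat(np.arange(config.n_prototypes_true), config.patients_per_prototype)
    Z = prototypes[labels] + rng.normal(
        0.0, config.patient_sd, size=(config.n_patients, config.latent_dim)
    )
    return Z, labels


def sample_remission_functions(
    config: SyntheticConfig, rng: np.random.Generator
) -> RemissionFunctionSet:
    """Draw one random two-layer ReLU outcome function per treatment arm."""
    W1, W2 = [], []
    for _ in range(config.n_treatments):
        W1.append(rng.standard_normal((config.latent_dim, config.remission_hidden_dim)))
        W2.append(rng.standard_normal((config.remission_hidden_dim, 2)))
    return RemissionFunctionSet(W1=tuple(W1), W2=tuple(W2))


def true_remission_probability(
    fns: RemissionFunctionSet, z: np.ndarray, treatment: int
) -> float:
    """True remission probability of latent vector ``z`` under one arm."""
    if not 0 <= treatment < fns.n_treatments:
        raise ValueError(f"treatment index {treatment} out of range 0..{fns.n_treatments - 1}")
    logits = np.maximum(np.asarray(z) @ fns.W1[treatment], 0.0) @ fns.W2[treatment]
    # clamp: softmax is in (0,1) exactly, but float64 saturates for large logits
    return float(np.clip(softmax(logits)[0], 1e-12, 1.0 - 1e-12))


def remission_probability_matrix(fns: RemissionFunctionSet, Z: np.ndarray) -> np.ndarray:
    """Full counterfactual surface: (N, k) remission probabilities."""
    cols = []
    for j in range(fns.n_treatments):
        logits = np.maximum(Z @ fns.W1[j], 0.0) @ fns.W2[j]
        cols.append(softmax(logits, axis=1)[:, 0])
    return np.clip(np.column_stack(cols), 1e-12, 1.0 - 1e-12)


def assign_treatments_and_outcomes(
    latent_Z: np.ndarray,
    fns: RemissionFunctionSet,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uniform random treatment per patient; Bernoulli outcome from the
    assigned arm's true probability.  Assignment ignores features, so the
    cohort is unconfounded by construction."""
    if fns.n_treatments != config.n_treatments:
        raise ValueError("remission function count does not match n_treatments")
    n = latent_Z.shape[0]
    P_true = remission_probability_matrix(fns, latent_Z)
    t = rng.integers(0, config.n_treatments, size=n)
    y = (rng.random(n) < P_true[np.arange(n), t]).astype(int)
    return t, y, P_true


def decode_to_observed(
    latent_Z: np.ndarray, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Decode latent coordinates to the observed feature space.

    A single random linear map (latent_dim x observed_dim, standard-normal
    entries, drawn once per cohort) produces the informative block; the
    n_irrelevant extra columns are pure standard-normal noise.
    """
    D = rng.standard_normal((config.latent_dim, config.observed_dim))
    observed = latent_Z @ D
    noise = rng.standard_normal((latent_Z.shape[0], config.n_irrelevant))
    return np.hstack([observed, noise])


def generate_cohort(config: SyntheticConfig | None = None, **kwargs) -> Cohort:
    """Run the full generative process under ``config`` (seeded, reproducible)."""
    if config is None:
        config = SyntheticConfig(**kwargs)
    config.validate()
    rng = np.random.default_rng(config.seed)
    prototypes = generate_prototypes(config, rng)
    Z, labels = generate_latent_patients(prototypes, config, rng)
    fns = sample_remission_functions(config, rng)
    t, y, P_true = assign_treatments_and_outcomes(Z, fns, config, rng)
    X = decode_to_observed(Z, config, rng)
    return Cohort(
        X=X, t=t, y=y, P_true=P_true, latent_Z=Z, prototype_label=labels, config=config
    )
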