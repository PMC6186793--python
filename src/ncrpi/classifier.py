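"""Feature fusion and interchangeable classifier backends.

Protein and RNA descriptors are concatenated (protein block first) into
one fused vector per pair and fed to a binary classifier. Three backends
sit behind one interface so classifier comparisons are a config change:

``goss_gbdt``
    LightGBM with gradient-based one-side sampling (GOSS) and exclusive
    feature bundling enabled — the default.
``plain_gbdt``
    LightGBM as a conventional gradient-boosted decision tree, with GOSS
    and feature bundling switched off.
``svm``
    RBF-kernel support vector machine with Platt-calibrated probability
    outputs (scikit-learn SVC).

GOSS keeps every training instance whose gradient magnitude is in the top
p fraction (set A), samples a fraction q of the remainder at random
(set B), and amplifies B's gradient sums by (1-p)/q when estimating the
variance gain of a candidate split:

    V(b) = 1/n * [ (sum_{A_l} g + (1-p)/q * sum_{B_l} g)^2 / n_l
                 + (sum_{A_r} g + (1-p)/q * sum_{B_r} g)^2 / n_r ]

where l/r split A and B at feature value b and n_l, n_r count instances
of A∪B on each side. The gradient-boosting internals are delegated to
LightGBM; :func:`goss_sample` and :func:`goss_variance_gain` reimplement
the sampling and gain estimate standalone so the statistic itself is
auditable and testable (with p=1 and B empty it reduces exactly to the
exhaustive variance gain).
"""

from __future__ import annotations

import math
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.svm import SVC

from .data_io import Dataset, PairSample
from .pssm_features import Pssm, PzmBasisCache, pzm_feature_vector
from .rna_features import rna_feature

BACKENDS = ("goss_gbdt", "plain_gbdt", "svm")

DEFAULT_GBDT_PARAMS = {
    "n_estimators": 100,
    "num_leaves": 31,
    "learning_rate": 0.1,
    "min_child_samples": 10,
}
DEFAULT_GOSS_PARAMS = {"top_rate": 0.2, "other_rate": 0.1}
DEFAULT_SVM_PARAMS = {"C": 1.0, "gamma": "scale"}


@dataclass(frozen=True)
class FusedSample:
    """One supervised instance: fused feature vector + label + pair identity."""

    features: np.ndarray
    label: int
    pair: PairSample | None = None


@dataclass
class FeatureConfig:
    """Feature-extraction settings shared by training, CV and the CLI.

    alpha_max: pseudo-Zernike order bound (65 protein features at 10).
    k: RNA word size (256 columns at 4).
    rna_mode: "svd", "frequency" or "concat".
    pssm_noise_sd: Gaussian scale for synthetic profile noise.
    """

    alpha_max: int = 10
    k: int = 4
    rna_mode: str = "svd"
    pssm_noise_sd: float = 0.3


@dataclass
class ClassifierConfig:
    backend: str = "goss_gbdt"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValueError(
                f"unknown backend {self.backend!r}, expected one of {BACKENDS}"
            )


@dataclass
class ModelHandle:
    backend: str
    hyperparameters: dict
    model: object
    feature_dim: int
    training_seed: int


@dataclass(frozen=True)
class GossContext:
    """Inputs of one GOSS split-gain evaluation (one feature, one split point)."""

    gradients: np.ndarray
    feature_values: np.ndarray
    split_point: float
    top_fraction: float
    remainder_fraction: float
    set_a: np.ndarray
    set_b: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.gradients, dtype=float)
        x = np.asarray(self.feature_values, dtype=float)
        if g.size == 0 or g.shape != x.shape:
            raise ValueError("gradients and feature_values must be equal-length, nonempty")
        a = np.asarray(self.set_a, dtype=int)
        b = np.asarray(self.set_b, dtype=int)
        if np.intersect1d(a, b).size:
            raise ValueError("A and B must be disjoint")
        object.__setattr__(self, "gradients", g)
        object.__setattr__(self, "feature_values", x)
        object.__setattr__(self, "set_a", a)
        object.__setattr__(self, "set_b", b)


def fuse_features(protein_fv, rna_fv) -> np.ndarray:
    """Concatenate protein and RNA descriptors, protein block first."""
    prot = np.asarray(getattr(protein_fv, "magnitudes", protein_fv), dtype=float)
    rna = np.asarray(getattr(rna_fv, "values", rna_fv), dtype=float)
    if np.any(np.isnan(prot)) or np.any(np.isnan(rna)):
        raise ValueError("NaN in feature vectors")
    return np.concatenate([prot.ravel(), rna.ravel()])


def featurize_dataset(
    dataset: Dataset,
    pssms: dict[str, Pssm],
    config: FeatureConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, list[PairSample]]:
    """Extract per-pair fused features for a whole dataset.

    Feature extraction is fit-free (no statistics learned from the data),
    so computing it once for all pairs introduces no train/test leakage.
    Returns (X, y, pairs) with X of shape (n_pairs, d).
    """
    config = config or FeatureConfig()
    cache = PzmBasisCache()
    prot_feats: dict[str, np.ndarray] = {}
    for prot in dataset.proteins:
        if prot.id not in pssms:
            raise KeyError(f"no PSSM provided for protein {prot.id!r}")
        prot_feats[prot.id] = pzm_feature_vector(
            pssms[prot.id], config.alpha_max, cache
        ).magnitudes
    rna_feats = {
        rna.id: rna_feature(rna, config.k, config.rna_mode).values
        for rna in dataset.rnas
    }
    rows = [
        fuse_features(prot_feats[p.protein_id], rna_feats[p.rna_id])
        for p in dataset.pairs
    ]
    return np.stack(rows), dataset.labels, list(dataset.pairs)


def goss_sample(gradients, p: float, q: float, seed: int = 0):
    """Split instances into GOSS sets A (top-|gradient|) and B (random rest).

    A holds the ceil(p*n) indices of largest |gradient| (ties broken toward
    the lower index); B is a uniform sample without replacement of size
    ceil(q*n) drawn from the complement — p and q are both fractions of the
    full training set, which is what makes the (1-p)/q amplification in
    :func:`goss_variance_gain` an unbiased reweighting of the small-gradient
    gradient sums. Requires q <= 1-p (B cannot exceed the remainder);
    deterministic given seed.
    """
    g = np.asarray(gradients, dtype=float)
    if g.size == 0:
        raise ValueError("empty gradient vector")
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    if not 0 <= q < 1:
        raise ValueError("q must be in [0, 1)")
    n = g.size
    n_top = math.ceil(p * n)
    order = np.lexsort((np.arange(n), -np.abs(g)))
    set_a = np.sort(order[:n_top])
    rest = np.sort(order[n_top:])
    n_b = math.ceil(q * n) if rest.size else 0
    if n_b > rest.size:
        raise ValueError(
            f"infeasible q={q}: B would need {n_b} instances but only "
            f"{rest.size} remain outside A"
        )
    rng = np.random.default_rng(seed)
    set_b = (
        np.sort(rng.choice(rest, size=n_b, replace=False))
        if n_b > 0
        else np.array([], dtype=int)
    )
    return set_a, set_b


def goss_variance_gain(ctx: GossContext) -> float:
    """Estimated variance gain of splitting at ctx.split_point over A∪B."""
    g, x, b = ctx.gradients, ctx.feature_values, ctx.split_point
    a_idx, b_idx = ctx.set_a, ctx.set_b
    n = g.size
    a_left = a_idx[x[a_idx] <= b]
    a_right = a_idx[x[a_idx] > b]
    b_left = b_idx[x[b_idx] <= b]
    b_right = b_idx[x[b_idx] > b]
    n_left = a_left.size + b_left.size
    n_right = a_right.size + b_right.size
    if n_left == 0 or n_right == 0:
        raise ValueError("split leaves one side empty over A∪B")
    if b_idx.size > 0:
        if ctx.remainder_fraction <= 0:
            raise ValueError("q must be positive when B is nonempty")
        amp = (1.0 - ctx.top_fraction) / ctx.remainder_fraction
    else:
        amp = 0.0
    left = g[a_left].sum() + amp * g[b_left].sum()
    right = g[a_right].sum() + amp * g[b_right].sum()
    return (left**2 / n_left + right**2 / n_right) / n


def _stack_samples(samples):
    X = np.stack([s.features for s in samples])
    y = np.array([s.label for s in samples], dtype=int)
    return X, y


def train(
    samples,
    y=None,
    backend: str = "goss_gbdt",
    hyperparameters: dict | None = None,
    seed: int = 0,
) -> ModelHandle:
    """Fit a backend on fused samples (list of FusedSample, or X with y).

    Single-threaded and deterministic for a given seed.
    """
    if y is None:
        X, y = _stack_samples(samples)
    else:
        X = np.asarray(samples, dtype=float)
        y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per label")
    if np.any(np.isnan(X)):
        raise ValueError("NaN in training features")
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    if backend not in BACKENDS:
        raise ValueError(f"unknown backend {backend!r}")

    params = dict(hyperparameters or {})
    if backend == "svm":
        merged = {**DEFAULT_SVM_PARAMS, **params}
        model = SVC(
            kernel="rbf", probability=True, random_state=seed, **merged
        )
    else:
        merged = {**DEFAULT_GBDT_PARAMS, **params}
        if backend == "goss_gbdt":
            merged = {**DEFAULT_GOSS_PARAMS, **merged}
            merged.update(data_sample_strategy="goss", enable_bundle=True)
        else:
            merged.update(data_sample_strategy="bagging", enable_bundle=False)
        model = LGBMClassifier(
            random_state=seed,
            n_jobs=1,
            deterministic=True,
            force_row_wise=True,
            verbose=-1,
            **merged,
        )
    model.fit(X, y)
    return ModelHandle(
        backend=backend,
        hyperparameters=merged,
        model=model,
        feature_dim=X.shape[1],
        training_seed=seed,
    )


def predict_scores(handle: ModelHandle, samples) -> np.ndarray:
    """Interaction scores in [0, 1], one per sample (higher = interacting)."""
    if handle.model is None:
        raise ValueError("model is not fitted")
    if isinstance(samples, (list, tuple)) and samples and isinstance(samples[0], FusedSample):
        X, _ = _stack_samples(samples)
    else:
        X = np.asarray(samples, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != handle.feature_dim:
        raise ValueError(
            f"feature dimension mismatch: model expects {handle.feature_dim}, "
            f"got {X.shape[1]}"
        )
    with warnings.catch_warnings():
        # fitted-on-ndarray wrappers emit a spurious feature-name warning
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names"
        )
        return handle.model.predict_proba(X)[:, 1]


def save_model(handle: ModelHandle, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(handle, fh)


def load_model(path) -> ModelHandle:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with open(path, "rb") as fh:
        handle = pickle.load(fh)
    if not isinstance(handle, ModelHandle):
        raise ValueError(f"{path} does not contain a saved model")
    return handle
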