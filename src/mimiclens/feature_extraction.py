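"""Image -> feature-vector extraction with two pluggable backends.

* ``MorphometricExtractor`` — a deterministic backend built from per-channel
  colour histograms, hindwing white-spot statistics, red-mark coverage and
  silhouette shape moments.  It is the reference backend for pipeline tests
  because its output is an exact function of the rendered pattern.
* ``SwavMiniExtractor`` — a desk-scale self-supervised trainer in the style
  of SwAV: two global and two local crops per image, online prototype
  assignment balanced by Sinkhorn-Knopp, and a swapped-prediction
  cross-entropy between views.  The encoder is a fixed random-feature layer
  followed by a trainable linear projection; gradients for the projection
  and the prototypes are computed analytically (stop-gradient on the
  Sinkhorn targets, as in the original algorithm).

Either backend can be lifted to an arbitrary output dimension D (default
2048) by a fixed seeded Gaussian random projection, which approximately
preserves the cosine geometry that all downstream similarity analysis uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.measure import label, moments_hu, moments_normalized, moments_central
from skimage.transform import resize

from .synthetic_wings import SpecimenImage, SPOT_THRESHOLD, MIN_SPOT_AREA_FRAC

__all__ = [
    "FeatureVector",
    "DatasetSplit",
    "TrainerConfig",
    "split_dataset",
    "sinkhorn_normalize",
    "swav_swapped_loss",
    "train_extractor",
    "extract_features",
    "morphometric_features",
    "MorphometricExtractor",
    "SwavMiniExtractor",
    "evaluate_robustness",
]

DEFAULT_DIM = 2048
_PROJECTION_SEED = 900_001  # fixed: projections must be a pure function of D


@dataclass
class FeatureVector:
    specimen_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite feature values for {self.specimen_id}")


@dataclass
class DatasetSplit:
    train: list[str]
    val: list[str]
    test: list[str]
    ratios: tuple[float, float, float] = (8.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        sets = [set(self.train), set(self.val), set(self.test)]
        if (sets[0] & sets[1]) or (sets[0] & sets[2]) or (sets[1] & sets[2]):
            raise ValueError("splits are not pairwise disjoint")


def split_dataset(manifest: pd.DataFrame,
                  ratios: tuple[float, float, float] = (8.0, 1.0, 1.0),
                  seed: int = 0) -> DatasetSplit:
    """Stratified train/val/test split of the manifest's specimens.

    Within each taxon, val and test receive ``floor(n * share)`` items and
    the remainder goes to train; the 8:1:1 default therefore sends 201/25/25
    of a 251-item single-stratum set to train/val/test.
    """
    total = float(sum(ratios))
    if total <= 0 or min(ratios) < 0:
        raise ValueError(f"invalid split ratios {ratios}")
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for _taxon, grp in manifest.groupby("taxon_id", sort=True):
        ids = list(grp["specimen_id"])
        rng.shuffle(ids)
        n = len(ids)
        n_val = int(np.floor(n * ratios[1] / total))
        n_test = int(np.floor(n * ratios[2] / total))
        val.extend(ids[:n_val])
        test.extend(ids[n_val:n_val + n_test])
        train.extend(ids[n_val + n_test:])
    return DatasetSplit(train=train, val=val, test=test,
                        ratios=tuple(ratios), seed=seed)


# ---------------------------------------------------------------------------
# Sinkhorn-Knopp balanced assignment and the swapped-prediction loss
# ---------------------------------------------------------------------------

def sinkhorn_normalize(scores: np.ndarray, epsilon: float = 1.0,
                       n_iters: int = 50) -> np.ndarray:
    """Balanced soft assignment of B samples to K prototypes.

    Exponentiates ``scores / epsilon`` and alternately rescales rows and
    columns so that rows sum to 1/B and columns to 1/K.  Entries stay
    strictly positive.
    """
    scores = np.asarray(scores, float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    B, K = scores.shape
    # subtract the max for numerical stability; cancelled by normalization
    Q = np.exp((scores - scores.max()) / epsilon)
    Q /= Q.sum()
    for _ in range(n_iters):
        Q /= Q.sum(axis=1, keepdims=True) * B      # rows -> 1/B
        Q /= Q.sum(axis=0, keepdims=True) * K      # cols -> 1/K
    return Q


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def swav_swapped_loss(proj_view1: np.ndarray, proj_view2: np.ndarray,
                      prototypes: np.ndarray, temperature: float = 0.1,
                      sinkhorn_epsilon: float = 0.05,
                      sinkhorn_iters: int = 3) -> float:
    """Swapped-prediction loss between two views of the same batch.

    Each view's softmax prototype prediction is scored against the *other*
    view's Sinkhorn-balanced assignment: L = -(1/2B) * sum q2 log p1 +
    q1 log p2, with rows of q summing to one.
    """
    z1, z2 = (np.asarray(v, float) for v in (proj_view1, proj_view2))
    if z1.shape != z2.shape:
        raise ValueError(f"view shapes differ: {z1.shape} vs {z2.shape}")
    if z1.shape[1] != prototypes.shape[1]:
        raise ValueError("projection and prototype dimensions differ")
    B = z1.shape[0]
    s1, s2 = z1 @ prototypes.T, z2 @ prototypes.T
    q1 = sinkhorn_normalize(s1, sinkhorn_epsilon, sinkhorn_iters) * B
    q2 = sinkhorn_normalize(s2, sinkhorn_epsilon, sinkhorn_iters) * B
    logp1 = np.log(_softmax(s1 / temperature))
    logp2 = np.log(_softmax(s2 / temperature))
    return float(-(np.sum(q2 * logp1) + np.sum(q1 * logp2)) / (2 * B))


# ---------------------------------------------------------------------------
# Morphometric backend
# ---------------------------------------------------------------------------

_HIST_BINS = 16


def _soft_histogram(values: np.ndarray, n_bins: int = _HIST_BINS,
                    vmax: float = 256.0) -> np.ndarray:
    """Linearly interpolated histogram: each value splits its unit weight
    between the two nearest bin centers, so counts vary smoothly when a
    colour sits near a bin edge.  Bin weights sum to len(values)."""
    t = np.clip(values / (vmax / n_bins) - 0.5, 0.0, n_bins - 1.0)
    lo = np.floor(t).astype(int)
    frac = t - lo
    hi = np.minimum(lo + 1, n_bins - 1)
    return (np.bincount(lo, weights=1.0 - frac, minlength=n_bins)
            + np.bincount(hi, weights=frac, minlength=n_bins))


def morphometric_features(image: SpecimenImage) -> FeatureVector:
    """Deterministic hand-crafted features for one specimen.

    Layout (58 dims): 3 x 16 per-channel soft histograms of the specimen
    silhouette, hindwing white-spot count, white-spot area fraction of the
    hindwing, red-mark area fraction of the image, and the 7 Hu moments of
    the silhouette.

    Scale: histograms are area *fractions* of the silhouette (each channel
    block sums to 1).  The white photographic background is excluded — it
    carries no morphological signal — and normalizing to fractions keeps
    every block at O(1) magnitude, so colour composition, the spot-count
    trait (0-4) and the red/white coverage fractions all contribute to
    cosine similarity instead of raw pixel counts drowning everything else.
    """
    px = image.pixels
    silhouette = ~np.all(px >= 245, axis=-1)
    body = px[silhouette].astype(float)
    feats = [_soft_histogram(body[:, c]) / max(1, len(body)) for c in range(3)]
    mask = image.hindwing_mask
    if mask is None:
        warnings.warn(f"{image.specimen_id}: no hindwing mask; "
                      "spot features fall back to zeros")
        n_spots, spot_frac = 0.0, 0.0
    else:
        white = np.all(px >= SPOT_THRESHOLD, axis=-1) & mask
        labels = label(white, connectivity=2)
        min_area = max(1, int(MIN_SPOT_AREA_FRAC * mask.sum()))
        areas = np.bincount(labels.ravel())[1:]
        n_spots = float(np.sum(areas >= min_area))
        spot_frac = float(white.sum() / mask.sum())
    r, g, b = px[..., 0].astype(int), px[..., 1].astype(int), px[..., 2].astype(int)
    red_frac = float(np.mean((r > 120) & (r - g > 60) & (r - b > 60)))
    hu = moments_hu(moments_normalized(moments_central(silhouette.astype(float))))
    vec = np.concatenate([np.concatenate(feats).astype(float),
                          [n_spots, spot_frac, red_frac], hu])
    return FeatureVector(specimen_id=image.specimen_id, values=vec)


class MorphometricExtractor:
    """Deterministic backend; no training required."""

    name = "morphometric"
    native_dim = 3 * _HIST_BINS + 3 + 7

    def transform_one(self, image: SpecimenImage) -> np.ndarray:
        return morphometric_features(image).values


# ---------------------------------------------------------------------------
# SwAV-mini backend
# ---------------------------------------------------------------------------

@dataclass
class TrainerConfig:
    """Hyperparameters of the desk-scale self-supervised trainer."""

    n_prototypes: int = 8
    temperature: float = 0.1
    sinkhorn_epsilon: float = 0.05
    sinkhorn_iters: int = 3
    n_global_crops: int = 2
    n_local_crops: int = 2
    epochs: int = 5
    batch_size: int = 16
    learning_rate: float = 0.1
    seed: int = 0
    input_size: int = 32
    hidden_dim: int = 256
    proj_dim: int = 128

    def __post_init__(self):
        if self.n_prototypes < 2:
            raise ValueError("n_prototypes must be >= 2")
        for name in ("temperature", "sinkhorn_epsilon", "learning_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sinkhorn_iters", "epochs", "batch_size",
                     "n_global_crops"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _resize_flat(px: np.ndarray, size: int) -> np.ndarray:
    small = resize(px.astype(float) / 255.0, (size, size, 3),
                   order=1, anti_aliasing=False, preserve_range=True)
    return small.reshape(-1) - 0.5


def _random_crop(px: np.ndarray, rng: np.random.Generator,
                 scale_lo: float, scale_hi: float) -> np.ndarray:
    h, w = px.shape[:2]
    s = rng.uniform(scale_lo, scale_hi)
    ch, cw = max(8, int(h * s)), max(8, int(w * s))
    y0 = rng.integers(0, h - ch + 1)
    x0 = rng.integers(0, w - cw + 1)
    crop = px[y0:y0 + ch, x0:x0 + cw]
    if rng.random() < 0.5:
        crop = crop[:, ::-1]
    jit = rng.uniform(0.8, 1.2, size=3)
    return np.clip(crop * jit, 0, 255)


class SwavMiniExtractor:
    """Tiny self-supervised encoder trained with the swapped-prediction
    objective.

    Encoder: flatten(resize 32x32) -> fixed random ReLU layer -> trainable
    linear projection -> L2 normalization.  Prototypes are unit rows updated
    jointly with the projection by SGD.
    """

    name = "swav-mini"

    def __init__(self, config: TrainerConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d_in = 3 * config.input_size ** 2
        self.W1 = rng.normal(0, np.sqrt(2.0 / d_in),
                             (config.hidden_dim, d_in))  # frozen random features
        self.W2 = rng.normal(0, np.sqrt(1.0 / config.hidden_dim),
                             (config.proj_dim, config.hidden_dim))
        C = rng.normal(0, 1, (config.n_prototypes, config.proj_dim))
        self.prototypes = C / np.linalg.norm(C, axis=1, keepdims=True)
        self.loss_trace: list[float] = []
        self.native_dim = config.proj_dim

    # -- forward pieces ----------------------------------------------------
    def _encode(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        H = np.maximum(X @ self.W1.T, 0.0)
        Z = H @ self.W2.T
        norms = np.linalg.norm(Z, axis=1, keepdims=True)
        norms = np.maximum(norms, 1e-12)
        return H, Z, Z / norms

    def transform_one(self, image: SpecimenImage) -> np.ndarray:
        x = _resize_flat(image.pixels, self.config.input_size)[None, :]
        return self._encode(x)[2][0]

    # -- training ----------------------------------------------------------
    def _train_step(self, views: list[np.ndarray], is_global: list[bool]) -> float:
        cfg = self.config
        B = views[0].shape[0]
        enc = [self._encode(v) for v in views]
        scores = [zn @ self.prototypes.T for _, _, zn in enc]
        targets = [sinkhorn_normalize(s, cfg.sinkhorn_epsilon,
                                      cfg.sinkhorn_iters) * B
                   for s, g in zip(scores, is_global) if g]
        n_global = len(targets)
        # each view predicts every *other* global view's assignment
        preds = [_softmax(s / cfg.temperature) for s in scores]
        loss = 0.0
        grads_s = [np.zeros_like(s) for s in scores]
        n_terms = 0
        g_idx = [i for i, g in enumerate(is_global) if g]
        for ti, t_view in enumerate(g_idx):
            q = targets[ti]
            for v in range(len(views)):
                if v == t_view:
                    continue
                p = preds[v]
                loss += -np.sum(q * np.log(np.maximum(p, 1e-30))) / B
                grads_s[v] += (p - q / q.sum(axis=1, keepdims=True)) \
                    / (B * cfg.temperature)
                n_terms += 1
        loss /= n_terms
        dW2 = np.zeros_like(self.W2)
        dC = np.zeros_like(self.prototypes)
        for v, (H, Z, Zn) in enumerate(enc):
            gs = grads_s[v] / n_terms
            if not np.any(gs):
                continue
            dC += gs.T @ Zn
            dZn = gs @ self.prototypes
            norms = np.maximum(np.linalg.norm(Z, axis=1, keepdims=True), 1e-12)
            dZ = (dZn - Zn * np.sum(dZn * Zn, axis=1, keepdims=True)) / norms
            dW2 += dZ.T @ H
        self.W2 -= cfg.learning_rate * dW2
        self.prototypes -= cfg.learning_rate * dC
        self.prototypes /= np.linalg.norm(self.prototypes, axis=1, keepdims=True)
        return float(loss)

    def fit(self, images: Sequence[SpecimenImage]) -> "SwavMiniExtractor":
        cfg = self.config
        if len(images) < 2:
            raise ValueError("need at least 2 images to train")
        if cfg.batch_size > len(images):
            raise ValueError(f"batch_size {cfg.batch_size} exceeds "
                             f"dataset size {len(images)}")
        rng = np.random.default_rng(cfg.seed + 1)
        idx = np.arange(len(images))
        for _epoch in range(cfg.epochs):
            rng.shuffle(idx)
            epoch_losses = []
            for start in range(0, len(idx) - cfg.batch_size + 1, cfg.batch_size):
                batch = [images[i] for i in idx[start:start + cfg.batch_size]]
                views, is_global = [], []
                for n, (lo, hi) in (
                    (cfg.n_global_crops, (0.6, 1.0)),
                    (cfg.n_local_crops, (0.25, 0.5)),
                ):
                    for _ in range(n):
                        X = np.stack([
                            _resize_flat(
                                _random_crop(im.pixels.astype(float), rng, lo, hi),
                                cfg.input_size)
                            for im in batch])
                        views.append(X)
                        is_global.append(lo >= 0.6)
                epoch_losses.append(self._train_step(views, is_global))
            self.loss_trace.append(float(np.mean(epoch_losses)))
        return self


def train_extractor(images: Sequence[SpecimenImage],
                    config: TrainerConfig | None = None) -> SwavMiniExtractor:
    """Train the SwAV-mini extractor; deterministic for a fixed config."""
    return SwavMiniExtractor(config or TrainerConfig()).fit(images)


# ---------------------------------------------------------------------------
# Extraction and evaluation
# ---------------------------------------------------------------------------

def _projection(d_in: int, d_out: int) -> np.ndarray:
    rng = np.random.default_rng(_PROJECTION_SEED)
    return rng.normal(0, 1.0 / np.sqrt(d_out), (d_out, d_in))


def extract_features(images: Sequence[SpecimenImage], extractor,
                     D: int | None = None) -> pd.DataFrame:
    """Extract one feature vector per image.

    Returns a DataFrame indexed by specimen_id with columns ``f0..f{D-1}``.
    When ``D`` differs from the backend's native dimension the vectors are
    mapped through a fixed Gaussian random projection, so a 58- or 128-dim
    backend can serve the conventional 2048-dim downstream interface while
    approximately preserving cosine geometry.
    """
    raw = np.stack([extractor.transform_one(im) for im in images])
    if D is not None and D != raw.shape[1]:
        raw = raw @ _projection(raw.shape[1], D).T
    return pd.DataFrame(raw,
                        index=pd.Index([im.specimen_id for im in images],
                                       name="specimen_id"),
                        columns=[f"f{i}" for i in range(raw.shape[1])])


def evaluate_robustness(features: pd.DataFrame, labels: pd.Series,
                        split: DatasetSplit) -> float:
    """Nearest-centroid test accuracy.

    Each test specimen is assigned to the taxon whose train-set mean feature
    vector is closest in cosine distance; returns the fraction of correct
    assignments in [0, 1].
    """
    labels = labels.reindex(features.index)
    if labels.isna().any():
        raise ValueError("every specimen with features needs a label")
    train_lab = labels.loc[split.train]
    test_lab = labels.loc[split.test]
    missing = set(test_lab) - set(train_lab)
    if missing:
        raise ValueError(f"taxa in test but not train: {sorted(missing)}")
    centroids = features.loc[split.train].groupby(train_lab).mean()
    C = centroids.to_numpy()
    C = C / np.maximum(np.linalg.norm(C, axis=1, keepdims=True), 1e-12)
    X = features.loc[split.test].to_numpy()
    X = X / np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-12)
    pred = centroids.index.to_numpy()[np.argmax(X @ C.T, axis=1)]
    return float(np.mean(pred == test_lab.to_numpy()))
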