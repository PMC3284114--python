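"""Synthetic imbalanced two-class data.

Emulates the study setting — a pool of image-patch feature vectors with a
rare target class (roughly 4% prevalence, ~25:1 class ratio) — so that
every training strategy and the cost model can be exercised with known
ground truth and without any external dataset.

Two generators are provided:

* :func:`make_feature_pool` — feature-space pools: both classes are
  multivariate Gaussians with shared identity covariance whose means are
  separated by ``class_separation`` along a random unit direction.  The
  separation is therefore measured in pooled-noise units and directly
  controls the Bayes error of the pool.
* :func:`make_texture_dataset` — image patches whose classes differ in
  second-order statistics: the minority class is an oriented sinusoidal
  grating embedded in Gaussian noise, the majority class pure Gaussian
  noise.  Haralick and Gabor features separate them by construction.

Minority counts are deterministic (``round(n_total * minority_fraction)``),
not binomial, so class-balance invariants are exactly testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import child_rng
from .exceptions import ValidationError
from .pool import MAJORITY, MINORITY, Pool

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PoolSpec:
    """Recipe for a synthetic feature pool.

    Attributes
    ----------
    n_total : int
        Pool size (>= 2).
    minority_fraction : float
        Prevalence of the minority class, in (0, 1).  The pool contains
        exactly ``round(n_total * minority_fraction)`` minority samples.
    class_separation : float
        Distance between the two class means, in units of the shared
        (identity) noise covariance.  0 makes the classes identical.
    dim : int
        Feature dimension.
    seed : int
        Root seed; identical specs produce bitwise-identical pools.
    """

    n_total: int = 12588
    minority_fraction: float = 0.04
    class_separation: float = 2.0
    dim: int = 14
    seed: int = 0

    def __post_init__(self):
        if self.n_total < 2:
            raise ValidationError("n_total must be >= 2")
        if not 0.0 < self.minority_fraction < 1.0:
            raise ValidationError("minority_fraction must be in (0, 1)")
        if self.class_separation < 0:
            raise ValidationError("class_separation must be >= 0")
        if self.dim < 1:
            raise ValidationError("dim must be >= 1")

    @property
    def n_minority(self) -> int:
        return int(round(self.n_total * self.minority_fraction))


def make_feature_pool(spec: PoolSpec) -> Pool:
    """Generate a two-Gaussian pool with an exact minority count.

    The minority mean sits at ``class_separation * u`` for a random unit
    vector ``u``; the majority mean at the origin.  Both classes share an
    identity covariance, so ``class_separation`` is the Mahalanobis
    distance between the class centroids.
    """
    rng = child_rng(spec.seed, 0)
    n1 = spec.n_minority
    n2 = spec.n_total - n1
    direction = rng.normal(size=spec.dim)
    direction /= np.linalg.norm(direction)
    mu1 = spec.class_separation * direction

    X = np.empty((spec.n_total, spec.dim))
    y = np.empty(spec.n_total, dtype=np.int8)
    X[:n1] = mu1 + rng.normal(size=(n1, spec.dim))
    y[:n1] = MINORITY
    X[n1:] = rng.normal(size=(n2, spec.dim))
    y[n1:] = MAJORITY

    # shuffle so class blocks are not positional
    order = rng.permutation(spec.n_total)
    ids = np.array([f"s{i:06d}" for i in range(spec.n_total)], dtype=object)
    return Pool(ids=ids, X=X[order], y=y[order], role="train")


def split_pool(pool: Pool, test_fraction: float, seed: int) -> tuple[Pool, Pool]:
    """Uniform random partition into disjoint train/test pools.

    At least one sample always lands in the test pool.  Returns
    ``(train, test)``; their union is the input and their intersection is
    empty.
    """
    if len(pool) == 0:
        raise ValidationError("cannot split an empty pool")
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError("test_fraction must be in (0, 1)")
    rng = child_rng(seed, 1)
    n = len(pool)
    n_test = max(1, int(round(n * test_fraction)))
    if n_test >= n:
        n_test = n - 1
    perm = rng.permutation(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    return pool.subset(np.sort(train_idx), role="train"), pool.subset(np.sort(test_idx), role="test")


@dataclass(frozen=True)
class TextureParams:
    """Class-conditional texture parameters for image-patch generation.

    The minority class is a sinusoidal grating (frequency in cycles/pixel,
    orientation in radians, amplitude in gray levels) plus Gaussian noise;
    the majority class is Gaussian noise alone on the same background.
    """

    frequency: float = 0.2
    orientation: float = np.pi / 4
    amplitude: float = 40.0
    noise_sigma: float = 20.0
    background: float = 128.0


def make_texture_dataset(
    n_regions: int,
    patch_size: int = 30,
    minority_fraction: float = 0.04,
    texture_params: TextureParams | None = None,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], pd.DataFrame, np.ndarray]:
    """Generate labeled grayscale patches tiled onto a single image.

    Returns ``(images, regions, labels)`` where ``images`` maps image id
    to an 8-bit grayscale array, ``regions`` is a table with columns
    ``image_id,x,y,size,label`` (0-based top-left origin, half-open
    extents), and ``labels`` is the per-region label vector (1 = textured
    minority class).
    """
    if patch_size < 8:
        raise ValidationError("patch_size must be >= 8")
    if n_regions < 1:
        raise ValidationError("n_regions must be >= 1")
    if not 0.0 < minority_fraction < 1.0:
        raise ValidationError("minority_fraction must be in (0, 1)")
    tp = texture_params or TextureParams()
    if tp.amplitude == 0 and tp.noise_sigma == 0:
        logger.warning("degenerate texture_params: zero contrast for both classes")

    rng = child_rng(seed, 2)
    n1 = int(round(n_regions * minority_fraction))
    labels = np.zeros(n_regions, dtype=np.int8)
    labels[:n1] = MINORITY
    rng.shuffle(labels)

    yy, xx = np.mgrid[0:patch_size, 0:patch_size]
    carrier = 2 * np.pi * tp.frequency * (xx * np.cos(tp.orientation) + yy * np.sin(tp.orientation))

    n_cols = int(np.ceil(np.sqrt(n_regions)))
    n_rows = int(np.ceil(n_regions / n_cols))
    canvas = np.full((n_rows * patch_size, n_cols * patch_size), tp.background, dtype=float)

    rows = []
    image_id = "synthetic_000"
    for i in range(n_regions):
        r, c = divmod(i, n_cols)
        patch = tp.background + rng.normal(scale=tp.noise_sigma, size=(patch_size, patch_size))
        if labels[i] == MINORITY:
            phase = rng.uniform(0, 2 * np.pi)
            patch += tp.amplitude * np.sin(carrier + phase)
        y0, x0 = r * patch_size, c * patch_size
        canvas[y0 : y0 + patch_size, x0 : x0 + patch_size] = patch
        rows.append({"image_id": image_id, "x": x0, "y": y0, "size": patch_size, "label": int(labels[i])})

    images = {image_id: np.clip(canvas, 0, 255).astype(np.uint8)}
    regions = pd.DataFrame(rows, columns=["image_id", "x", "y", "size", "label"])
    return images, regions, labels
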