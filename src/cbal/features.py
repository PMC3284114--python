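"""Patch-level texture features for region classification.

Each image region (by default a 30x30-pixel square) is summarized by the
average of pixel-wise feature responses over the region, yielding one
value per feature:

* first-order statistics of the gray levels (mean, median, standard
  deviation, range, Sobel gradient magnitude, directional gradients);
* the 13 classical Haralick statistics of a symmetric, direction-averaged
  gray-level co-occurrence matrix (GLCM);
* mean magnitudes of a bank of zero-DC complex Gabor filters
  parameterized by frequency and orientation (default 5 frequencies x 8
  orientations = 40 filters).

A named default selection of 14 features (2 first-order + 5 Haralick + 7
Gabor) is shipped as the standard configuration for the minority-class
training experiments; any subset of the registry can be selected by name.

GLCM construction uses :func:`skimage.feature.graycomatrix`; the Haralick
statistics themselves are computed here (natural logarithms; the sum
variance is centered on the sum average).  Degenerate inputs are handled
explicitly: a constant patch has energy 1, entropy 0 and, by convention,
correlation 1 (its co-occurrence mass is a single diagonal cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from skimage.feature import graycomatrix
from skimage.filters import gabor_kernel, sobel

from .exceptions import ValidationError

# ---------------------------------------------------------------------------
# registry

FIRST_ORDER_NAMES = ["mean", "median", "std", "range", "sobel_mean", "grad_x_mean", "grad_y_mean"]

HARALICK_NAMES = [
    "energy",
    "contrast",
    "correlation",
    "variance",
    "homogeneity",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "info_corr_1",
    "info_corr_2",
]


@dataclass(frozen=True)
class GaborBankSpec:
    """A Gabor filter bank: one filter per (frequency, orientation) pair.

    Frequencies are in cycles/pixel and must lie in (0, 0.5]; orientations
    in radians.
    """

    frequencies: tuple = (0.05, 0.1, 0.2, 0.3, 0.4)
    orientations: tuple = tuple(np.pi * k / 8 for k in range(8))

    def __post_init__(self):
        for f in self.frequencies:
            if not 0.0 < f <= 0.5:
                raise ValidationError(f"Gabor frequency {f} outside (0, 0.5]")

    def names(self) -> list[str]:
        return [
            _gabor_name(f, t) for f in self.frequencies for t in self.orientations
        ]

    def kernels(self) -> dict[str, np.ndarray]:
        out = {}
        for f in self.frequencies:
            for t in self.orientations:
                k = gabor_kernel(frequency=f, theta=t)
                out[_gabor_name(f, t)] = k - k.mean()  # zero the DC response
        return out


def _gabor_name(frequency: float, theta: float) -> str:
    return f"gabor_f{frequency:g}_t{int(round(np.degrees(theta)))}"


DEFAULT_BANK = GaborBankSpec()

#: full feature registry: 7 first-order + 13 Haralick + 40 Gabor = 60 names
ALL_FEATURE_NAMES = FIRST_ORDER_NAMES + HARALICK_NAMES + DEFAULT_BANK.names()

#: the shipped 14-feature selection: 2 first-order + 5 Haralick + 7 Gabor
DEFAULT_SELECTION_14 = (
    ["std", "range"]
    + ["info_corr_1", "correlation", "energy", "contrast", "entropy"]
    + [_gabor_name(0.2, np.pi * k / 8) for k in range(7)]
)


@dataclass(frozen=True)
class FeatureVector:
    """Named feature values for one region."""

    values: dict = field(default_factory=dict)
    region_id: str = ""

    def as_array(self, order: list[str] | None = None) -> np.ndarray:
        names = order or list(self.values)
        return np.array([self.values[n] for n in names], dtype=float)


# ---------------------------------------------------------------------------
# first-order statistics


def _as_gray_2d(patch) -> np.ndarray:
    a = np.asarray(patch, dtype=float)
    if a.ndim == 3 and a.shape[2] in (3, 4):
        # ITU-R 601 luminance
        a = 0.299 * a[..., 0] + 0.587 * a[..., 1] + 0.114 * a[..., 2]
    if a.ndim != 2 or a.size == 0:
        raise ValidationError("patch must be a non-empty 2-D (or RGB) array")
    return a


def first_order_features(patch) -> dict[str, float]:
    """Gray-level statistics of a patch.

    Returns mean, median, population standard deviation, intensity range,
    mean Sobel gradient magnitude, and mean horizontal/vertical gradients.
    """
    a = _as_gray_2d(patch)
    gy, gx = np.gradient(a) if min(a.shape) > 1 else (np.zeros_like(a), np.zeros_like(a))
    return {
        "mean": float(a.mean()),
        "median": float(np.median(a)),
        "std": float(a.std()),
        "range": float(a.max() - a.min()),
        "sobel_mean": float(sobel(a).mean()) if min(a.shape) > 2 else 0.0,
        "grad_x_mean": float(np.abs(gx).mean()),
        "grad_y_mean": float(np.abs(gy).mean()),
    }


# ---------------------------------------------------------------------------
# Haralick statistics


def quantize(patch, levels: int) -> np.ndarray:
    """Quantize a patch to ``levels`` equal-width gray bins (0..levels-1)."""
    a = _as_gray_2d(patch)
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.zeros(a.shape, dtype=np.uint8)
    q = np.floor((a - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def cooccurrence_matrix(patch, levels: int = 64, distance: int = 1) -> np.ndarray:
    """Symmetric GLCM averaged over the 4 standard directions, normalized.

    The patch is quantized to ``levels`` bins; pixel pairs at the given
    distance are counted along 0, 45, 90 and 135 degrees; each direction's
    symmetric count matrix is normalized to sum to 1 and the four are
    averaged.
    """
    if levels < 2:
        raise ValidationError("levels must be >= 2")
    a = quantize(patch, levels)
    if min(a.shape) <= distance:
        raise ValidationError("patch must be larger than the co-occurrence distance")
    glcm = graycomatrix(
        a, distances=[distance], angles=list(_GLCM_ANGLES), levels=levels, symmetric=True
    ).astype(float)[:, :, 0, :]
    sums = glcm.sum(axis=(0, 1))
    sums[sums == 0] = 1.0
    return (glcm / sums).mean(axis=2)


def haralick_from_glcm(P: np.ndarray) -> dict[str, float]:
    """The 13 classical Haralick statistics of a normalized GLCM."""
    L = P.shape[0]
    i = np.arange(L)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())

    ii, jj = np.meshgrid(i, i, indexing="ij")
    # p_{x+y}(k), k = 0..2L-2 and p_{|x-y|}(k), k = 0..L-1
    p_sum = np.bincount((ii + jj).ravel(), weights=P.ravel(), minlength=2 * L - 1)
    p_diff = np.bincount(np.abs(ii - jj).ravel(), weights=P.ravel(), minlength=L)
    k_sum = np.arange(2 * L - 1)
    k_diff = np.arange(L)

    def _ent(p):
        nz = p[p > 0]
        return float(-(nz * np.log(nz)).sum())

    energy = float((P**2).sum())
    contrast = float((k_diff**2 * p_diff).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(((ii * jj * P).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y))
    else:
        correlation = 1.0  # point-mass GLCM: degenerate, perfectly correlated
    variance = float((((ii - mu_x) ** 2) * P).sum())
    homogeneity = float((P / (1.0 + (ii - jj) ** 2)).sum())
    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = _ent(p_sum)
    entropy = _ent(P.ravel())
    diff_mean = float((k_diff * p_diff).sum())
    difference_variance = float(((k_diff - diff_mean) ** 2 * p_diff).sum())
    difference_entropy = _ent(p_diff)

    # information measures of correlation
    pxy = np.outer(px, py)
    mask = (P > 0) & (pxy > 0)
    hxy1 = float(-(P[mask] * np.log(pxy[mask])).sum())
    hxy2 = _ent(pxy.ravel())
    hx, hy = _ent(px), _ent(py)
    denom = max(hx, hy)
    info_corr_1 = float((entropy - hxy1) / denom) if denom > 0 else 0.0
    info_corr_2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return {
        "energy": energy,
        "contrast": contrast,
        "correlation": correlation,
        "variance": variance,
        "homogeneity": homogeneity,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "info_corr_1": info_corr_1,
        "info_corr_2": info_corr_2,
    }


def haralick_features(patch, levels: int = 64, distance: int = 1) -> dict[str, float]:
    """13 Haralick statistics of a patch (64 gray levels, distance 1 by default)."""
    return haralick_from_glcm(cooccurrence_matrix(patch, levels=levels, distance=distance))


# ---------------------------------------------------------------------------
# Gabor filter bank


def _convolve_same(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """FFT convolution returning the image's shape.

    The image is reflect-padded by the kernel half-width first so border
    responses come from mirrored content rather than implicit zeros (a
    zero-DC kernel then responds ~0 everywhere on a constant image).
    Reflect padding tiles the image when the kernel support exceeds it.
    """
    pad = []
    for s, ks in zip(img.shape, kernel.shape):
        half = ks // 2 + 1
        pad.append((half, half))
    padded = img
    for axis, (p, _) in enumerate(pad):
        # np.pad reflect cannot exceed the axis length; apply repeatedly
        remaining = p
        while remaining > 0:
            step = min(remaining, padded.shape[axis] - 1)
            width = [(0, 0)] * padded.ndim
            if step == 0:  # degenerate 1-pixel axis
                width[axis] = (remaining, remaining)
                padded = np.pad(padded, width, mode="edge")
                break
            width[axis] = (step, step)
            padded = np.pad(padded, width, mode="reflect")
            remaining -= step
    out = signal.fftconvolve(padded, kernel, mode="same")
    slices = tuple(slice(p, p + s) for (p, _), s in zip(pad, img.shape))
    return out[slices]


def gabor_response_images(image, bank: GaborBankSpec = DEFAULT_BANK, names=None) -> dict[str, np.ndarray]:
    """Pixel-wise Gabor magnitude images for (a subset of) the bank."""
    a = _as_gray_2d(image)
    kernels = bank.kernels()
    if names is not None:
        kernels = {n: kernels[n] for n in names}
    return {name: np.abs(_convolve_same(a, k)) for name, k in kernels.items()}


def gabor_features(patch, bank: GaborBankSpec = DEFAULT_BANK) -> dict[str, float]:
    """Mean zero-DC Gabor magnitude per (frequency, orientation) filter.

    On a constant patch every magnitude is ~0 because each kernel's DC
    component is removed.
    """
    responses = gabor_response_images(patch, bank)
    return {name: float(r.mean()) for name, r in responses.items()}


# ---------------------------------------------------------------------------
# region featurization


def compute_features(patch, selection, bank: GaborBankSpec = DEFAULT_BANK, levels: int = 64, distance: int = 1) -> dict[str, float]:
    """Compute the named features of one patch (patch-local Gabor)."""
    unknown = [n for n in selection if n not in ALL_FEATURE_NAMES and n not in bank.names()]
    if unknown:
        raise ValidationError(f"unknown feature names: {unknown}")
    out: dict[str, float] = {}
    if any(n in FIRST_ORDER_NAMES for n in selection):
        out.update(first_order_features(patch))
    if any(n in HARALICK_NAMES for n in selection):
        out.update(haralick_features(patch, levels=levels, distance=distance))
    gabor_names = [n for n in selection if n.startswith("gabor_")]
    if gabor_names:
        resp = gabor_response_images(patch, bank, names=gabor_names)
        out.update({n: float(r.mean()) for n, r in resp.items()})
    return {n: out[n] for n in selection}


def patch_feature_vector(
    image,
    region,
    selection=None,
    bank: GaborBankSpec = DEFAULT_BANK,
    levels: int = 64,
    distance: int = 1,
    region_id: str = "",
    _gabor_cache: dict | None = None,
) -> FeatureVector:
    """Feature vector of one square region of an image.

    ``region`` is ``(x, y, size)`` with a 0-based top-left origin and
    half-open extents.  First-order and Haralick features are computed on
    the region itself; Gabor responses are computed by full-image
    convolution and averaged over the region (pass ``_gabor_cache`` to
    reuse response images across regions of the same image).
    """
    selection = list(selection) if selection is not None else list(DEFAULT_SELECTION_14)
    a = _as_gray_2d(image)
    x, y, size = (int(region[k]) for k in ("x", "y", "size")) if hasattr(region, "keys") else map(int, region)
    if x < 0 or y < 0 or x + size > a.shape[1] or y + size > a.shape[0]:
        raise ValidationError(f"region (x={x}, y={y}, size={size}) out of image bounds {a.shape}")
    patch = a[y : y + size, x : x + size]

    gabor_names = [n for n in selection if n.startswith("gabor_")]
    values: dict[str, float] = {}
    non_gabor = [n for n in selection if not n.startswith("gabor_")]
    if non_gabor:
        values.update(compute_features(patch, non_gabor, bank=bank, levels=levels, distance=distance))
    if gabor_names:
        if _gabor_cache is None:
            _gabor_cache = {}
        for n in gabor_names:
            if n not in _gabor_cache:
                _gabor_cache.update(gabor_response_images(a, bank, names=[n]))
            values[n] = float(_gabor_cache[n][y : y + size, x : x + size].mean())
    values = {n: values[n] for n in selection}
    if not all(np.isfinite(v) for v in values.values()):
        raise ValidationError("non-finite feature value computed")
    return FeatureVector(values=values, region_id=region_id)


def featurize_regions(images: dict, regions, selection=None, bank: GaborBankSpec = DEFAULT_BANK, levels: int = 64, distance: int = 1):
    """Feature table for a region table (columns image_id,x,y,size[,label]).

    Returns a pandas DataFrame with columns ``id``, one per selected
    feature, and ``label`` if the region table carries labels — the same
    schema the synthetic feature pools use.
    """
    import pandas as pd

    selection = list(selection) if selection is not None else list(DEFAULT_SELECTION_14)
    rows = []
    caches: dict[str, dict] = {}
    for idx, region in regions.iterrows():
        img = images[region["image_id"]]
        cache = caches.setdefault(region["image_id"], {})
        fv = patch_feature_vector(
            img, region, selection, bank=bank, levels=levels, distance=distance,
            region_id=f"{region['image_id']}_r{idx:05d}", _gabor_cache=cache,
        )
        row = {"id": fv.region_id, **fv.values}
        if "label" in regions.columns:
            row["label"] = int(region["label"])
        rows.append(row)
    return pd.DataFrame(rows)
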