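"""Per-spot image patches, feature embedding and PCA reduction.

Each retained spot yields a square crop (default 50 px) centered on its
pixel coordinate, zero-padded at image borders and resized to a common side
(default 224 px).  Patches are standardized with the ImageNet channel
statistics and embedded by a pluggable feature extractor; the embedded
features are PCA-reduced to the latent morphological matrix M (default 50
dimensions) that drives the morphological adjacency graph.

The default extractor is a deterministic hand-crafted descriptor (channel
histograms, a downsampled intensity grid and channel moments); any callable
mapping a patch batch to fixed-length vectors — e.g. a pretrained CNN — can
be plugged in instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import resize as _resize
from sklearn.decomposition import PCA

__all__ = [
    "PatchSet",
    "MorphFeatureMatrix",
    "extract_patches",
    "standardize_patches",
    "augment_patches",
    "HistogramStubExtractor",
    "embed_patches",
    "reduce_pca",
    "morphological_features",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])


@dataclass
class PatchSet:
    """Per-spot RGB patches plus padding bookkeeping."""

    patches: np.ndarray  # (n, side, side, 3) float
    centers: np.ndarray  # (n, 2) pixel coordinates (x, y)
    pad_mask: np.ndarray  # (n,) fraction of padded pixels in the raw crop
    crop: int
    standardized: bool = False


@dataclass
class MorphFeatureMatrix:
    """Latent morphological features M (spots x d) with provenance."""

    M: np.ndarray
    raw_dim: int
    extractor_id: str
    explained_variance_ratio: np.ndarray | None = None


def extract_patches(
    image: np.ndarray, coords: np.ndarray, crop: int = 50, out_size: int = 224
) -> PatchSet:
    """Crop a ``crop`` x ``crop`` window around each spot and resize.

    Windows extending past the image are filled with black (0); ``pad_mask``
    records the padded fraction of each raw crop.
    """
    if crop < 1:
        raise ValueError("crop must be >= 1")
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be an RGB (H, W, 3) array")
    coords = np.asarray(coords, dtype=np.float64)
    h, w = image.shape[:2]
    half = crop // 2
    n = coords.shape[0]
    patches = np.zeros((n, out_size, out_size, 3), dtype=np.float64)
    pad = np.zeros(n)
    n_outside = 0
    for i, (x, y) in enumerate(coords):
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = cx - half, cx - half + crop
        y0, y1 = cy - half, cy - half + crop
        raw = np.zeros((crop, crop, 3), dtype=np.float64)
        sx0, sx1 = max(x0, 0), min(x1, w)
        sy0, sy1 = max(y0, 0), min(y1, h)
        if sx0 < sx1 and sy0 < sy1:
            raw[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = image[sy0:sy1, sx0:sx1]
            pad[i] = 1.0 - ((sx1 - sx0) * (sy1 - sy0)) / (crop * crop)
        else:
            pad[i] = 1.0
            n_outside += 1
        if crop == out_size:
            patches[i] = raw
        else:
            patches[i] = _resize(
                raw, (out_size, out_size, 3), order=1, preserve_range=True,
                anti_aliasing=False,
            )
    if n_outside:
        warnings.warn(f"{n_outside} spot centers lie outside the image; all-padding")
    return PatchSet(patches=patches, centers=coords.copy(), pad_mask=pad, crop=crop)


def standardize_patches(ps: PatchSet) -> PatchSet:
    """Scale pixels to [0, 1] and standardize with ImageNet channel stats."""
    if ps.standardized:
        raise ValueError("patches are already standardized")
    if ps.patches.ndim != 4 or ps.patches.shape[3] != 3:
        raise ValueError("standardization requires RGB patches")
    scaled = ps.patches / 255.0
    out = (scaled - IMAGENET_MEAN) / IMAGENET_STD
    return replace(ps, patches=out, standardized=True)


def _augment_one(patch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply the seeded augmentation suite to one [0,255] RGB patch."""
    from skimage.filters import gaussian
    from skimage.transform import AffineTransform, rotate, warp

    out = patch.copy()
    # 1. autocontrast: stretch each channel to the full range
    if rng.random() < 0.5:
        lo = out.min(axis=(0, 1), keepdims=True)
        hi = out.max(axis=(0, 1), keepdims=True)
        span = np.where(hi > lo, hi - lo, 1.0)
        out = (out - lo) / span * 255.0
    # 2. Gaussian blur
    if rng.random() < 0.5:
        out = gaussian(out, sigma=rng.uniform(0.3, 1.5), channel_axis=2,
                       preserve_range=True)
    # 3. random affine (small shear + translation)
    if rng.random() < 0.5:
        tf = AffineTransform(
            shear=rng.uniform(-0.1, 0.1),
            translation=rng.uniform(-3, 3, size=2),
        )
        out = warp(out, tf.inverse, preserve_range=True)
    # 4-5. horizontal / vertical flips
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1]
    # 6. rotation
    if rng.random() < 0.5:
        out = rotate(out, angle=rng.uniform(-15, 15), preserve_range=True)
    # 7. color jitter: per-channel gain
    if rng.random() < 0.5:
        out = out * rng.uniform(0.85, 1.15, size=3)
    return np.clip(out, 0, 255)


def augment_patches(ps: PatchSet, seed: int, enabled: bool = True) -> PatchSet:
    """Seeded random augmentation of raw (non-standardized) patches.

    The suite covers autocontrast, Gaussian blur, random affine, horizontal
    and vertical flips, rotation and color jitter; disabled -> identity.
    """
    if not enabled:
        return ps
    if ps.standardized:
        raise ValueError("augment before standardization")
    rng = np.random.default_rng(seed)
    out = np.stack([_augment_one(p, rng) for p in ps.patches])
    return replace(ps, patches=out)


class HistogramStubExtractor:
    """Deterministic hand-crafted patch descriptor.

    Concatenates per-channel 16-bin histograms, an 8x8 mean-pooled intensity
    grid and per-channel mean/std — 118 dimensions.  Works on standardized
    or raw patches, needs no learned weights, and is batch-size invariant.
    """

    id = "histogram-stub-v1"
    n_bins = 16
    grid = 8

    @property
    def dim(self) -> int:
        return 3 * self.n_bins + self.grid**2 + 6

    def __call__(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float64)
        n, side = batch.shape[0], batch.shape[1]
        feats = np.empty((n, self.dim))
        # common value range so histograms are comparable across patches
        lo, hi = -3.0, 3.0
        scaled = np.clip((batch - lo) / (hi - lo), 0.0, 1.0)
        for i in range(n):
            p = scaled[i]
            hists = [
                np.histogram(p[..., c], bins=self.n_bins, range=(0, 1))[0] / p[..., c].size
                for c in range(3)
            ]
            gray = p.mean(axis=2)
            cells = gray[: side - side % self.grid, : side - side % self.grid]
            cs = cells.shape[0] // self.grid
            pooled = cells.reshape(self.grid, cs, self.grid, cs).mean(axis=(1, 3))
            moments = np.concatenate([p.mean(axis=(0, 1)), p.std(axis=(0, 1))])
            feats[i] = np.concatenate([*hists, pooled.ravel(), moments])
        return feats


def embed_patches(ps: PatchSet, extractor=None, batch_size: int = 64) -> np.ndarray:
    """Map patches to fixed-length feature vectors, one row per spot."""
    if extractor is None:
        extractor = HistogramStubExtractor()
    n = ps.patches.shape[0]
    chunks = []
    dim = None
    for start in range(0, n, batch_size):
        out = np.asarray(extractor(ps.patches[start:start + batch_size]))
        if dim is None:
            dim = out.shape[1]
        elif out.shape[1] != dim:
            raise ValueError(
                f"extractor output dim changed across batches: {out.shape[1]} != {dim}"
            )
        chunks.append(out)
    return np.concatenate(chunks, axis=0)


def reduce_pca(raw: np.ndarray, d: int = 50, extractor_id: str = "unknown") -> MorphFeatureMatrix:
    """Top-d principal components of the centered raw features.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making the output deterministic.
    """
    raw = np.asarray(raw, dtype=np.float64)
    n, p = raw.shape
    max_d = min(n, p)
    if d > max_d:
        warnings.warn(f"d={d} exceeds min(n, dim)={max_d}; clamping")
        d = max_d
    pca = PCA(n_components=d, svd_solver="full")
    M = pca.fit_transform(raw)
    flips = np.sign(
        pca.components_[np.arange(d), np.abs(pca.components_).argmax(axis=1)]
    )
    flips[flips == 0] = 1.0
    M = M * flips
    return MorphFeatureMatrix(
        M=M,
        raw_dim=p,
        extractor_id=extractor_id,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def morphological_features(
    image: np.ndarray,
    coords: np.ndarray,
    *,
    crop: int = 50,
    out_size: int = 224,
    d: int = 50,
    extractor=None,
    augment_seed: int | None = None,
) -> MorphFeatureMatrix:
    """Full histology path: patches -> standardize -> embed -> PCA."""
    ps = extract_patches(image, coords, crop=crop, out_size=out_size)
    if augment_seed is not None:
        ps = augment_patches(ps, seed=augment_seed, enabled=True)
    ps = standardize_patches(ps)
    if extractor is None:
        extractor = HistogramStubExtractor()
    raw = embed_patches(ps, extractor)
    return reduce_pca(raw, d=d, extractor_id=getattr(extractor, "id", "custom"))
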