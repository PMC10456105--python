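"""Gray-level co-occurrence matrices and the two texture statistics built on them.

A GLCM for a grayscale raster counts ordered pixel pairs ``(reference,
neighbor)`` separated by a fixed displacement — a distance ``d`` along one of
the four canonical directions (0°, 45°, 90°, 135°).  Entry ``(i, j)`` of the
G×G matrix holds the number (or, after normalization, the probability) of
pairs whose reference pixel has gray level ``i`` and whose neighbor has level
``j``.  Two scalar features summarize the matrix:

* contrast  ``Σ (i−j)² p(i,j)`` — second moment of the gray-level difference;
  zero for a constant image, at most ``(G−1)²``.
* homogeneity ``Σ p(i,j) / (1 + |i−j|)`` — mass concentration near the
  diagonal; one for a constant image, always in ``(0, 1]``.

The homogeneity denominator is linear in the gray-level difference by
default.  The quadratic variant ``1 + (i−j)²`` (the inverse difference moment
used by several texture libraries) is available through
:func:`glcm_homogeneity` for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrayImage",
    "GLCMConfig",
    "GLCMatrix",
    "TextureFeatures",
    "displacement_vector",
    "compute_glcm",
    "glcm_contrast",
    "glcm_homogeneity",
    "texture_features",
]

#: Canonical angle → (Δrow, Δcol) unit displacement.  Row axis points down
#: the image, so 90° (up) is a negative row offset and 0° is the immediate
#: right neighbor.
_ANGLE_UNIT = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class GrayImage:
    """Integer-valued 2D raster with gray levels ``0 .. levels-1``."""

    pixels: np.ndarray
    levels: int = 256

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("GrayImage requires a non-empty 2D raster")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("GrayImage pixels must be integers")
        if self.levels < 2:
            raise ValueError("levels must be at least 2")
        if px.min() < 0 or px.max() >= self.levels:
            raise ValueError(
                f"pixel values must lie in 0..{self.levels - 1}; "
                f"found range {px.min()}..{px.max()}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GLCMConfig:
    """Displacement and quantization settings for a co-occurrence matrix.

    Parameters
    ----------
    distance : int
        Offset ``d`` between reference and neighbor pixel, in pixels.
    angle : int
        One of 0, 45, 90, 135 degrees.
    levels : int
        Matrix dimension ``G``; pixel values must be below it.
    symmetric : bool
        Count each pair in both orders.  Off by default: "directly to the
        right" is an ordered relation.
    normalized : bool
        Divide counts by the number of pairs so entries form a probability
        distribution.
    """

    distance: int = 1
    angle: int = 0
    levels: int = 256
    symmetric: bool = False
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("distance must be a positive integer")
        if self.angle not in _ANGLE_UNIT:
            raise ValueError(
                f"unsupported angle {self.angle}; admissible angles are 0, 45, 90, 135"
            )
        if self.levels < 2:
            raise ValueError("levels must be at least 2")


@dataclass(frozen=True)
class GLCMatrix:
    """A computed co-occurrence matrix together with its configuration."""

    entries: np.ndarray
    config: GLCMConfig
    total_pairs: int

    def normalized(self) -> "GLCMatrix":
        """Return a probability-normalized copy (no-op if already normalized)."""
        if self.config.normalized:
            return self
        if self.total_pairs == 0:
            raise ValueError("cannot normalize: empty co-occurrence domain")
        cfg = GLCMConfig(
            self.config.distance,
            self.config.angle,
            self.config.levels,
            self.config.symmetric,
            normalized=True,
        )
        return GLCMatrix(self.entries / self.total_pairs, cfg, self.total_pairs)


@dataclass(frozen=True)
class TextureFeatures:
    """Contrast and homogeneity of one image/channel/ROI."""

    contrast: float
    homogeneity: float


def displacement_vector(config: GLCMConfig) -> tuple[int, int]:
    """(Δrow, Δcol) offset from reference pixel to neighbor for *config*."""
    ur, uc = _ANGLE_UNIT[config.angle]
    return ur * config.distance, uc * config.distance


def compute_glcm(image: GrayImage, config: GLCMConfig) -> GLCMatrix:
    """Count gray-level co-occurrences of *image* for the configured offset.

    Pairs are counted only where both endpoints lie inside the raster; there
    is no padding or wrap-around, so an ROI crop never co-occurs with pixels
    outside it.
    """
    px = image.pixels
    G = config.levels
    if image.levels > G or px.max() >= G:
        raise ValueError(
            f"quantization contract violation: pixel values up to {px.max()} "
            f"do not fit a {G}-level matrix; requantize first"
        )
    dr, dc = displacement_vector(config)
    H, W = px.shape
    r0, r1 = max(0, -dr), H - max(0, dr)
    c0, c1 = max(0, -dc), W - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        raise ValueError(
            f"empty co-occurrence domain: no pixel pair fits offset ({dr}, {dc}) "
            f"in a {H}x{W} image"
        )
    ref = px[r0:r1, c0:c1].ravel().astype(np.int64)
    nbr = px[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel().astype(np.int64)

    counts = np.bincount(ref * G + nbr, minlength=G * G).reshape(G, G)
    total = int(ref.size)
    if config.symmetric:
        counts = counts + counts.T
        total *= 2
    if config.normalized:
        entries = counts / total
    else:
        entries = counts
    return GLCMatrix(entries, config, total)


def _probabilities(matrix: GLCMatrix) -> np.ndarray:
    if matrix.total_pairs == 0:
        raise ValueError("texture feature undefined: empty co-occurrence domain")
    if matrix.config.normalized:
        return matrix.entries
    return matrix.entries / matrix.total_pairs


def glcm_contrast(matrix: GLCMatrix) -> float:
    """``Σ (i−j)² p(i,j)``; zero iff all mass lies on the diagonal."""
    p = _probabilities(matrix)
    G = p.shape[0]
    i, j = np.ogrid[0:G, 0:G]
    return float(np.sum((i - j) ** 2 * p))


def glcm_homogeneity(matrix: GLCMatrix, kind: str = "linear") -> float:
    """Diagonal-concentration statistic of a normalized GLCM.

    ``kind="linear"`` (default) weights entry ``(i, j)`` by ``1/(1+|i−j|)``.
    ``kind="squared"`` uses ``1/(1+(i−j)²)``, the inverse difference moment
    convention of common texture libraries, kept for cross-validation.
    """
    p = _probabilities(matrix)
    G = p.shape[0]
    i, j = np.ogrid[0:G, 0:G]
    if kind == "linear":
        w = 1.0 / (1.0 + np.abs(i - j))
    elif kind == "squared":
        w = 1.0 / (1.0 + (i - j) ** 2)
    else:
        raise ValueError(f"unknown homogeneity kind {kind!r}; use 'linear' or 'squared'")
    return float(np.sum(w * p))


def texture_features(image: GrayImage, config: GLCMConfig | None = None) -> TextureFeatures:
    """Compute contrast and homogeneity of *image* in one call.

    With no *config*, uses the immediate right neighbor (d=1, θ=0°) over the
    full 8-bit range — the conventional setting for cross-polarized skin ROIs.
    """
    if config is None:
        config = GLCMConfig(levels=image.levels)
    m = compute_glcm(image, config).normalized()
    return TextureFeatures(glcm_contrast(m), glcm_homogeneity(m))
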