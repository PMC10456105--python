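"""Synthetic cross-polarized forearm-skin image pairs.

No photographs accompany the clinical tables this package reproduces, so the
pipeline is exercised on simulated before/after image pairs that carry the
statistical structure the analysis assumes:

* a smooth base reflectance field — heavily blurred white noise riding on a
  per-channel skin tone, brightest in red and darkest in blue, as
  cross-polarized imaging of lightly pigmented skin produces;
* hyperpigmented macules modelled as isotropic Gaussian decrements whose
  depth scales per channel with melanin absorption weights w_R < w_G < w_B,
  so lesions darken the blue channel most;
* additive Gaussian sensor noise, applied last and clamped to 0-255;
* a treatment factor λ ∈ [0, 1] that multiplies every lesion amplitude by
  (1 − λ) in the "after" image while base field and lesion layout stay
  fixed — raising brightness, lowering GLCM contrast and raising homogeneity.

Everything is deterministic given the seed; the same seed reproduces the
pair bit for bit.  The defaults are artifact choices documented in the
methods note; nothing here claims to match any particular camera.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .images import RGBImage, save_rgb

__all__ = [
    "SyntheticSkinParams",
    "SyntheticPair",
    "generate_pair",
    "generate_cohort",
    "write_pair",
    "write_cohort",
]


@dataclass(frozen=True)
class SyntheticSkinParams:
    """Full parameterization of one simulated before/after pair.

    Sizes default to the 800x727 acquisition raster of the clinical rig being
    emulated; tests use smaller rasters for speed.  ``scale_mm_per_px``
    corresponds to a 7 cm field of view across the image width.
    """

    height: int = 727
    width: int = 800
    base_tone: tuple[float, float, float] = (190.0, 150.0, 120.0)
    #: correlation length of the smooth base field, pixels
    base_smoothness: float = 50.0
    #: standard deviation of the smooth base field, 8-bit levels
    base_variation: float = 6.0
    n_blobs: int = 35
    #: 8-bit decrement at blob centre, sampled uniformly per blob
    blob_amplitude: tuple[float, float] = (15.0, 40.0)
    #: Gaussian sigma of a blob, pixels, sampled uniformly per blob
    blob_sigma: tuple[float, float] = (8.0, 24.0)
    #: melanin absorption weights (w_R, w_G, w_B); blue darkens most
    channel_weights: tuple[float, float, float] = (0.5, 0.75, 1.0)
    noise_sd: float = 2.0
    #: treatment factor lambda: lesion amplitudes shrink by (1 - lambda) after
    treatment: float = 0.6
    scale_mm_per_px: float = 0.0875
    seed: int = 0

    @classmethod
    def scaled(cls, height: int, width: int, **overrides) -> "SyntheticSkinParams":
        """Parameters for a raster that images the same 7 cm skin field at a
        reduced resolution: every length (blob sigmas, base-field correlation
        length) shrinks by width/800 and the mm-per-pixel scale grows to
        match, so the scene statistics per unit skin area are preserved."""
        f = width / cls.width
        defaults = dict(
            height=height,
            width=width,
            base_smoothness=cls.base_smoothness * f,
            blob_sigma=(cls.blob_sigma[0] * f, cls.blob_sigma[1] * f),
            scale_mm_per_px=cls.scale_mm_per_px / f,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("image size must be positive")
        if not 0.0 <= self.treatment <= 1.0:
            raise ValueError("treatment factor must lie in [0, 1]")
        wr, wg, wb = self.channel_weights
        if not (wb >= wg >= wr > 0):
            raise ValueError("channel weights must satisfy w_B >= w_G >= w_R > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for lo, hi in (self.blob_amplitude, self.blob_sigma):
            if not (0 < lo <= hi):
                raise ValueError("blob amplitude/sigma ranges must be positive, lo <= hi")
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be non-negative")
        if self.base_variation < 0 or self.base_smoothness <= 0:
            raise ValueError("base field parameters must be positive")


@dataclass(frozen=True)
class SyntheticPair:
    before: RGBImage
    after: RGBImage
    blob_centers: np.ndarray  # (n, 2) row, col
    blob_sigmas: np.ndarray
    blob_amplitudes: np.ndarray
    params: SyntheticSkinParams


def _base_field(rng: np.random.Generator, p: SyntheticSkinParams) -> np.ndarray:
    """Zero-mean unit-SD smooth field with correlation length ~base_smoothness."""
    white = rng.standard_normal((p.height, p.width))
    smooth = gaussian_filter(white, sigma=p.base_smoothness, mode="reflect")
    sd = smooth.std()
    if sd == 0:  # degenerate 1x1 raster
        return np.zeros_like(smooth)
    return smooth / sd


def _lesion_field(
    centers: np.ndarray, sigmas: np.ndarray, amps: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Sum of isotropic Gaussian decrements, evaluated on local windows."""
    H, W = shape
    L = np.zeros(shape)
    for (r0, c0), s, a in zip(centers, sigmas, amps):
        half = int(np.ceil(4 * s))
        r_lo, r_hi = max(0, int(r0) - half), min(H, int(r0) + half + 1)
        c_lo, c_hi = max(0, int(c0) - half), min(W, int(c0) + half + 1)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr = np.arange(r_lo, r_hi)[:, None] - r0
        cc = np.arange(c_lo, c_hi)[None, :] - c0
        L[r_lo:r_hi, c_lo:c_hi] += a * np.exp(-(rr**2 + cc**2) / (2 * s**2))
    return L


def generate_pair(params: SyntheticSkinParams) -> SyntheticPair:
    """Simulate one before/after cross-polarized skin image pair.

    Pixel model, channel k with weight w_k, stage factor λ_stage (0 before,
    λ after)::

        clamp(round(tone_k + variation * f(r,c)
                    - w_k * (1 - λ_stage) * Σ_b a_b exp(-d²/2σ_b²)
                    + ε), 0, 255)

    with ε ~ N(0, noise_sd²) drawn independently per stage and per channel.
    Base field f and the lesion layout are shared between the two stages.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    f = _base_field(rng, p)
    centers = np.column_stack(
        [rng.uniform(0, p.height, p.n_blobs), rng.uniform(0, p.width, p.n_blobs)]
    )
    sigmas = rng.uniform(*p.blob_sigma, p.n_blobs)
    amps = rng.uniform(*p.blob_amplitude, p.n_blobs)
    lesions = _lesion_field(centers, sigmas, amps, (p.height, p.width))

    images = []
    for lam_stage in (0.0, p.treatment):
        noise = rng.standard_normal((p.height, p.width, 3)) * p.noise_sd
        chans = []
        for k, (tone, w) in enumerate(zip(p.base_tone, p.channel_weights)):
            clean = tone + p.base_variation * f - w * (1.0 - lam_stage) * lesions
            chans.append(clean + noise[:, :, k])
        stacked = np.stack(chans, axis=-1)
        pixels = np.clip(np.floor(stacked + 0.5), 0, 255).astype(np.uint8)
        images.append(RGBImage(pixels, scale=p.scale_mm_per_px))

    return SyntheticPair(
        before=images[0],
        after=images[1],
        blob_centers=centers,
        blob_sigmas=sigmas,
        blob_amplitudes=amps,
        params=p,
    )


def generate_cohort(
    n_patients: int = 12,
    params: SyntheticSkinParams | None = None,
    master_seed: int = 0,
    blob_count_jitter: float = 0.3,
    amplitude_jitter: float = 0.2,
) -> list[SyntheticPair]:
    """Simulate a cohort of before/after pairs from one parameter template.

    Per-patient seeds derive deterministically from *master_seed*; each
    subject's lesion count and amplitude range are jittered within the stated
    relative bounds to emulate between-subject variability.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be at least 1")
    if params is None:
        params = SyntheticSkinParams()
    ss = np.random.SeedSequence(master_seed)
    patient_seeds = ss.generate_state(n_patients).astype(np.int64)
    jitter_rng = np.random.default_rng(ss.spawn(1)[0])

    pairs = []
    for seed in patient_seeds:
        lo = max(1, int(round(params.n_blobs * (1 - blob_count_jitter))))
        hi = int(round(params.n_blobs * (1 + blob_count_jitter)))
        n_blobs = int(jitter_rng.integers(lo, hi + 1)) if params.n_blobs > 0 else 0
        a_scale = float(jitter_rng.uniform(1 - amplitude_jitter, 1 + amplitude_jitter))
        amp = (params.blob_amplitude[0] * a_scale, params.blob_amplitude[1] * a_scale)
        p = replace(params, n_blobs=n_blobs, blob_amplitude=amp, seed=int(seed))
        pairs.append(generate_pair(p))
    return pairs


def write_pair(pair: SyntheticPair, out_dir: str | Path, stem: str) -> dict[str, str]:
    """Write before/after PNGs plus a ground-truth JSON; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "before": str(out / f"{stem}_before.png"),
        "after": str(out / f"{stem}_after.png"),
        "truth": str(out / f"{stem}_truth.json"),
    }
    save_rgb(pair.before, paths["before"])
    save_rgb(pair.after, paths["after"])
    truth = {
        "params": asdict(pair.params),
        "blob_centers": pair.blob_centers.tolist(),
        "blob_sigmas": pair.blob_sigmas.tolist(),
        "blob_amplitudes": pair.blob_amplitudes.tolist(),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return paths


def write_cohort(pairs: list[SyntheticPair], out_dir: str | Path) -> Path:
    """Write every pair plus a manifest CSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "seed", "treatment", "before_path", "after_path",
                    "truth_path"])
        for i, pair in enumerate(pairs, start=1):
            paths = write_pair(pair, out, f"patient{i:02d}")
            # names only, so reruns into different directories stay byte-identical
            w.writerow([i, pair.params.seed, pair.params.treatment,
                        Path(paths["before"]).name, Path(paths["after"]).name,
                        Path(paths["truth"]).name])
    return manifest
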