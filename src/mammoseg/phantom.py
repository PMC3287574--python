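"""Synthetic mammogram-ROI phantoms with known ground truth.

Real screening-mammogram ROIs show a bright mass with a soft, ill-defined
boundary sitting on fibro-glandular clutter plus film/detector noise, and
reference contours come from radiologists. The phantom emulates exactly the
features the segmentation pipeline is sensitive to — a radially symmetric
soft-edged disk (sigmoid falloff), a low-frequency textured background
(smoothed seeded white noise) and per-pixel Gaussian noise — while the
ground-truth mask is known by construction, so every overlap metric is
exact. It deliberately does not model spiculation, compression physics or
overlapping vasculature; results on phantoms bound algorithmic behavior,
not clinical accuracy.

Generation is fully deterministic per seed: the same spec yields
bit-identical pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .raster_io import round_half_away

__all__ = ["PhantomSpec", "generate_phantom", "standard_suite", "STANDARD_SUITE_SIZE"]

STANDARD_SUITE_SIZE = 20
_TEXTURE_SMOOTH_SIGMA = 16.0  # px; sets the spatial scale of the clutter


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic ROI (intensities on the 0-255 scale).

    ``contrast`` is the mass-over-background intensity lift; ``softness``
    the sigmoid boundary fall-off width in pixels (models ill-defined mass
    margins); ``texture_sigma`` the amplitude of the low-frequency
    background field; ``noise_sigma`` the per-pixel Gaussian noise level.
    ``center=None`` places the mass at the image center.
    """

    seed: int
    height: int = 256
    width: int = 256
    center: tuple[float, float] | None = None
    radius: float = 40.0
    contrast: float = 80.0
    softness: float = 6.0
    background_level: float = 100.0
    texture_sigma: float = 10.0
    noise_sigma: float = 15.0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom dimensions must be positive")
        if not self.radius > 0 or not self.softness > 0:
            raise ValueError("radius and softness must be > 0")
        if self.radius + self.softness >= min(self.height, self.width) / 2:
            raise ValueError("mass (radius + softness) does not fit the frame")
        if self.texture_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("texture_sigma and noise_sigma must be >= 0")

    @property
    def effective_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return ((self.height - 1) / 2.0, (self.width - 1) / 2.0)


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom: returns ``(image uint8, ground-truth mask uint8)``.

    The image is ``clip_[0,255](background + texture(seed) +
    contrast * sigmoid((radius - d)/softness) + noise(seed))`` where ``d``
    is the Euclidean distance to the mass center; the mask is ``d <= radius``
    and is independent of both noise fields.
    """
    rng = np.random.default_rng(spec.seed)
    rr, cc = np.mgrid[0:spec.height, 0:spec.width].astype(float)
    cy, cx = spec.effective_center
    d = np.hypot(rr - cy, cc - cx)

    image = np.full(d.shape, spec.background_level, dtype=float)

    if spec.texture_sigma > 0:
        raw = rng.standard_normal(d.shape)
        texture = ndimage.gaussian_filter(raw, sigma=_TEXTURE_SMOOTH_SIGMA, mode="reflect")
        std = texture.std()
        if std > 0:  # rescale the heavily-smoothed field back to unit std
            image += texture * (spec.texture_sigma / std)
    else:
        rng.standard_normal(d.shape)  # keep the noise stream position fixed

    image += spec.contrast / (1.0 + np.exp(-(spec.radius - d) / spec.softness))

    if spec.noise_sigma > 0:
        image += spec.noise_sigma * rng.standard_normal(d.shape)

    image = np.clip(round_half_away(image), 0, 255).astype(np.uint8)
    mask = (d <= spec.radius).astype(np.uint8)
    return image, mask


def standard_suite(n: int = STANDARD_SUITE_SIZE, seed_offset: int = 0) -> list[PhantomSpec]:
    """The fixture suite used throughout the tests: ``n`` 256x256 phantoms.

    Seeds ``seed_offset .. seed_offset+n-1``, radius 40, contrast 80,
    softness 6, background 100, texture 10, noise 15.
    """
    base = PhantomSpec(seed=0)
    return [replace(base, seed=seed_offset + i) for i in range(n)]
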