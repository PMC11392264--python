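"""Seeded synthetic generator of low-contrast lesion image/mask pairs.

The generator emulates the failure modes that make endoscopic lesion
segmentation hard: a small mean intensity offset between lesion and
background (low contrast), lesion boundaries smoothed into the background
(blur), large variation in lesion size, and per-pixel sensor noise.  Each
lesion is an ellipse whose radius is perturbed by a random low-order
trigonometric series, giving organic-looking blobs from a handful of seeded
draws.

Every sample is a pure function of ``(spec, spec.seed, index)``: the RNG
stream for sample *i* is derived by a counter-based split, so datasets are
reproducible regardless of generation order.
"""

from __future__ import annotations

import dataclasses
import math
import pathlib

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .exceptions import InvalidSpecError

# Axis-ratio range of the underlying ellipses (minor/major); fixed so the
# feasibility check below has a closed form.
_AXIS_RATIO_RANGE = (0.6, 1.0)
_MAX_HARMONICS = 5
_MAX_PERTURBATION = 0.20  # relative radial amplitude
# Fraction of the nominal area range kept as a margin so that rasterization
# never pushes a realized lesion fraction outside the declared range.
_AREA_MARGIN = 0.08


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic lesion image distribution.

    Attributes
    ----------
    image_size:
        Pixels per side (square); must be a multiple of 32 so that five
        stride-2 halvings are exact.
    n_lesions_range:
        Inclusive interval for the number of lesions per image.
    contrast_delta:
        Mean foreground-minus-background intensity offset, in [0, 1] image
        units.  The generator compensates for the background texture so the
        pre-noise offset is exact per sample.
    boundary_blur_sigma:
        Gaussian blur radius (pixels) applied to the lesion silhouette
        before compositing; the mask itself is never blurred.
    noise_sigma:
        Per-pixel additive Gaussian noise standard deviation.
    lesion_area_fraction_range:
        Allowed fraction of the image area per lesion.
    seed:
        Base RNG seed for the whole dataset.
    """

    image_size: int = 256
    n_lesions_range: tuple[int, int] = (1, 3)
    contrast_delta: float = 0.15
    boundary_blur_sigma: float = 2.0
    noise_sigma: float = 0.05
    lesion_area_fraction_range: tuple[float, float] = (0.02, 0.30)
    seed: int = 0

    def __post_init__(self):
        s = self.image_size
        if s < 32 or s % 32 != 0:
            raise InvalidSpecError(f"image_size must be ≥32 and a multiple of 32, got {s}")
        lo_n, hi_n = self.n_lesions_range
        if not (0 <= lo_n <= hi_n):
            raise InvalidSpecError(f"bad n_lesions_range {self.n_lesions_range}")
        if not (0 < self.contrast_delta <= 0.5):
            raise InvalidSpecError(f"contrast_delta must be in (0, 0.5], got {self.contrast_delta}")
        lo_a, hi_a = self.lesion_area_fraction_range
        if not (0 < lo_a <= hi_a < 0.6):
            raise InvalidSpecError(f"bad lesion_area_fraction_range {self.lesion_area_fraction_range}")
        if self.noise_sigma < 0:
            raise InvalidSpecError("noise_sigma must be nonnegative")
        if self.boundary_blur_sigma < 0:
            raise InvalidSpecError("boundary_blur_sigma must be nonnegative")
        # Feasibility: the largest perturbed semi-axis must fit when the
        # lesion is centred.  Major semi-axis a = size*sqrt(f/(pi*rho)),
        # stretched by at most (1 + max perturbation).
        rho_min = _AXIS_RATIO_RANGE[0]
        f_max_feasible = math.pi * rho_min * (0.5 / (1.0 + _MAX_PERTURBATION)) ** 2
        if hi_a > f_max_feasible:
            raise InvalidSpecError(
                f"lesion_area_fraction_range upper bound {hi_a:.3f} cannot fit in the "
                f"image (maximum feasible fraction {f_max_feasible:.3f})"
            )


@dataclasses.dataclass
class SamplePair:
    """One image/mask pair: image (3, H, W) in [0, 1]; mask (H, W) in {0, 1}."""

    image: np.ndarray
    mask: np.ndarray
    identifier: str

    def __post_init__(self):
        if self.image.shape[1:] != self.mask.shape:
            raise ValueError("image and mask spatial dimensions differ")


def _lesion_silhouette(rng: np.random.Generator, size: int,
                       area_range: tuple[float, float]) -> np.ndarray:
    """Rasterize one randomly deformed ellipse as a boolean (size, size) array."""
    lo, hi = area_range
    span = hi - lo
    f = rng.uniform(lo + _AREA_MARGIN * span, hi - _AREA_MARGIN * span) if span > 0 else lo
    rho = rng.uniform(*_AXIS_RATIO_RANGE)
    a = size * math.sqrt(f / (math.pi * rho))  # major semi-axis
    b = a * rho
    margin = a * (1.0 + _MAX_PERTURBATION)
    margin = min(margin, size / 2.0)
    cy = rng.uniform(margin, size - margin)
    cx = rng.uniform(margin, size - margin)
    theta = rng.uniform(0.0, math.pi)
    n_harm = int(rng.integers(2, _MAX_HARMONICS + 1))
    amps = rng.uniform(0.0, _MAX_PERTURBATION / n_harm, size=n_harm)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=n_harm)

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = (ct * dx + st * dy) / a
    v = (-st * dx + ct * dy) / b
    r = np.hypot(u, v)  # =1 on the unperturbed boundary
    ang = np.arctan2(v, u)
    boundary = np.ones_like(r)
    for k in range(n_harm):
        boundary += amps[k] * np.cos((k + 1) * ang + phases[k])
    return r <= boundary


def generate_sample(spec: SyntheticSpec, index: int) -> SamplePair:
    """Generate one image/mask pair; bit-identical for identical (spec, index)."""
    size = spec.image_size
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, int(index)]))

    # Background: smoothed random texture around mid-gray with mild channel tint.
    texture = gaussian_filter(rng.standard_normal((size, size)), sigma=size / 16.0)
    tstd = texture.std()
    if tstd > 0:
        texture = texture / tstd * 0.06
    tint = rng.uniform(-0.03, 0.03, size=3)
    background = 0.45 + texture[None, :, :] + tint[:, None, None]

    n_lesions = int(rng.integers(spec.n_lesions_range[0], spec.n_lesions_range[1] + 1))
    mask = np.zeros((size, size), dtype=bool)
    for _ in range(n_lesions):
        mask |= _lesion_silhouette(rng, size, spec.lesion_area_fraction_range)

    image = background
    if mask.any() and not mask.all():
        blurred = mask.astype(np.float64)
        if spec.boundary_blur_sigma > 0:
            blurred = gaussian_filter(blurred, sigma=spec.boundary_blur_sigma)
        # Absorb the background texture's in/out-of-mask imbalance into the
        # lesion amplitude so the pre-noise contrast equals contrast_delta
        # exactly for this sample.
        bg_gap = background[:, mask].mean() - background[:, ~mask].mean()
        bl_gap = blurred[mask].mean() - blurred[~mask].mean()
        amplitude = (spec.contrast_delta - bg_gap) / bl_gap
        image = background + amplitude * blurred[None, :, :]

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=(3, size, size))
    image = np.clip(image, 0.0, 1.0)
    # Quantize to 8-bit levels so PNG round-trips are exact.
    image = np.round(image * 255.0) / 255.0

    return SamplePair(image=image.astype(np.float32),
                      mask=mask.astype(np.uint8),
                      identifier=f"sample_{index:05d}")


def generate_dataset(spec: SyntheticSpec, n: int, out_dir) -> "DatasetManifest":
    """Write ``n`` image/mask PNG pairs under ``out_dir`` and return the manifest.

    Layout: ``out_dir/images/<id>.png`` (RGB) and ``out_dir/masks/<id>.png``
    (8-bit grayscale with values {0, 255}); a two-column ``manifest.tsv``
    lists the relative image and mask paths.
    """
    from .image_io import DatasetManifest, PairEntry  # local import: no cycle at module load

    out_dir = pathlib.Path(out_dir)
    images_dir = out_dir / "images"
    masks_dir = out_dir / "masks"
    try:
        images_dir.mkdir(parents=True, exist_ok=True)
        masks_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directories under {out_dir}: {exc}") from exc

    pairs = []
    lines = []
    for i in range(n):
        sample = generate_sample(spec, i)
        img8 = np.round(sample.image * 255.0).astype(np.uint8).transpose(1, 2, 0)
        msk8 = (sample.mask * 255).astype(np.uint8)
        img_path = images_dir / f"{sample.identifier}.png"
        msk_path = masks_dir / f"{sample.identifier}.png"
        try:
            Image.fromarray(img8, mode="RGB").save(img_path)
            Image.fromarray(msk8, mode="L").save(msk_path)
        except OSError as exc:
            raise OSError(f"failed writing {img_path} / {msk_path}: {exc}") from exc
        pairs.append(PairEntry(image_path=img_path, mask_path=msk_path,
                               identifier=sample.identifier))
        lines.append(f"images/{sample.identifier}.png\tmasks/{sample.identifier}.png")

    (out_dir / "manifest.tsv").write_text("\n".join(lines) + ("\n" if lines else ""))
    return DatasetManifest(pairs=pairs)
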