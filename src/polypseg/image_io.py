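"""Reading and writing image/mask pairs and predicted masks.

Images are decoded to RGB and scaled to [0, 1]; masks are single-channel and
strictly binary after loading — every I/O path thresholds, so masks can never
acquire intermediate values.  Coordinates are (row, column) with the origin
at the top-left; images and masks are co-registered.
"""

from __future__ import annotations

import dataclasses
import pathlib
import warnings

import numpy as np
from PIL import Image

from .exceptions import CorruptInputError, EmptyDatasetError
from .synthetic import SamplePair

_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


@dataclasses.dataclass(frozen=True)
class PairEntry:
    image_path: pathlib.Path
    mask_path: pathlib.Path
    identifier: str


@dataclasses.dataclass
class DatasetManifest:
    pairs: list[PairEntry]

    def __post_init__(self):
        ids = [p.identifier for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate identifiers in manifest")

    def __len__(self):
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def _stem_index(directory: pathlib.Path) -> dict[str, pathlib.Path]:
    files = {}
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() in _IMAGE_SUFFIXES:
            files[path.stem] = path
    return files


def list_pairs(images_dir, masks_dir) -> DatasetManifest:
    """Match images and masks by filename stem, sorted lexicographically.

    Orphans (an image without a mask, or vice versa) are reported with a
    warning and excluded.  An empty intersection raises
    :class:`EmptyDatasetError`.
    """
    images_dir = pathlib.Path(images_dir)
    masks_dir = pathlib.Path(masks_dir)
    if not images_dir.is_dir():
        raise FileNotFoundError(f"images directory not found: {images_dir}")
    if not masks_dir.is_dir():
        raise FileNotFoundError(f"masks directory not found: {masks_dir}")
    images = _stem_index(images_dir)
    masks = _stem_index(masks_dir)
    common = sorted(set(images) & set(masks))
    for stem in sorted(set(images) - set(masks)):
        warnings.warn(f"image without mask excluded: {images[stem]}", stacklevel=2)
    for stem in sorted(set(masks) - set(images)):
        warnings.warn(f"mask without image excluded: {masks[stem]}", stacklevel=2)
    if not common:
        raise EmptyDatasetError(
            f"no matched image/mask pairs between {images_dir} and {masks_dir}")
    return DatasetManifest(
        pairs=[PairEntry(images[s], masks[s], s) for s in common])


def load_pair(entry: PairEntry, target_size: int) -> SamplePair:
    """Load one pair resized to ``target_size``.

    The image is bilinearly resized and scaled to [0, 1]; the mask is
    resized nearest-neighbour and thresholded at 127/255 back to {0, 1}.
    """
    if target_size % 32 != 0:
        raise ValueError(f"target_size must be a multiple of 32, got {target_size}")
    try:
        with Image.open(entry.image_path) as im:
            image = im.convert("RGB")
            if image.size != (target_size, target_size):
                image = image.resize((target_size, target_size), Image.BILINEAR)
            image_arr = np.asarray(image, dtype=np.float32) / 255.0
    except (OSError, SyntaxError) as exc:
        raise CorruptInputError(f"cannot decode image {entry.image_path}: {exc}") from exc
    try:
        with Image.open(entry.mask_path) as im:
            mask = im.convert("L")
            if mask.size != (target_size, target_size):
                mask = mask.resize((target_size, target_size), Image.NEAREST)
            mask_arr = (np.asarray(mask) > 127).astype(np.uint8)
    except (OSError, SyntaxError) as exc:
        raise CorruptInputError(f"cannot decode mask {entry.mask_path}: {exc}") from exc
    return SamplePair(image=image_arr.transpose(2, 0, 1), mask=mask_arr,
                      identifier=entry.identifier)


def load_batch(manifest: DatasetManifest, target_size: int):
    """Stack a whole manifest into (N, 3, S, S) images and (N, S, S) masks."""
    images, masks = [], []
    for entry in manifest:
        pair = load_pair(entry, target_size)
        images.append(pair.image)
        masks.append(pair.mask)
    return np.stack(images), np.stack(masks)


def save_mask(p, threshold: float, path) -> None:
    """Write a probability map as an 8-bit PNG: 255 where p ≥ threshold, else 0."""
    arr = np.asarray(getattr(p, "data", p), dtype=np.float64)
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ValueError(f"expected a single-map probability array, got shape {arr.shape}")
    out = np.where(arr >= threshold, 255, 0).astype(np.uint8)
    path = pathlib.Path(path)
    try:
        Image.fromarray(out, mode="L").save(path)
    except OSError as exc:
        raise OSError(f"failed writing mask {path}: {exc}") from exc


def normalize_image(image: np.ndarray, mode: str = "unit",
                    mean=(0.485, 0.456, 0.406), std=(0.229, 0.224, 0.225)) -> np.ndarray:
    """Optional per-channel standardization for pretrained-weight compatibility.

    ``mode='unit'`` leaves the plain [0, 1] scaling; ``mode='imagenet'``
    standardizes each channel with the given statistics.
    """
    if mode == "unit":
        return image
    if mode == "imagenet":
        m = np.asarray(mean, dtype=image.dtype).reshape(3, 1, 1)
        s = np.asarray(std, dtype=image.dtype).reshape(3, 1, 1)
        return (image - m) / s
    raise ValueError(f"unknown normalization mode {mode!r}")
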