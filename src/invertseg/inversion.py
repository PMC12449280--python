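"""Intensity-inversion preprocessing for cross-modality segmentation transfer.

A CT-trained segmentation model expects dense tissue (bone) to be bright
and air to be very dark.  In T1-weighted MRI the ordering of soft tissue
and bone is roughly reversed, so a simple intensity negative within the
volume's own value range,

    x  ->  max(X) - x + min(X),

moves an MR volume much closer to the intensity structure such a model
was trained on.  Plain inversion, however, turns background air into the
brightest structure in the image; the ``inverted_black`` variant
therefore zeroes every voxel whose (clipped, pre-inversion) intensity
lies within the first percentile of the volume:

    INV(x) = 0                        if x <= percentile_p(X)
           = max(X) - x + min(X)      otherwise

with p = 1 by default.  Because background air in magnitude MR images
forms a large, near-constant plateau at the bottom of the histogram, the
first-percentile *value* threshold captures essentially all of it.

Three named variants are exposed, matching the experimental arms of the
pipeline: ``unprocessed`` (identity), ``inverted`` (clip then plain
negative) and ``inverted_black`` (clip, negative, background zeroed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import Volume

__all__ = [
    "PreprocessVariant",
    "VARIANT_NAMES",
    "clip_intensities",
    "invert_plain",
    "invert_black",
    "preprocess",
]

VARIANT_NAMES = ("unprocessed", "inverted", "inverted_black")

# Default clip window and background percentile for the inverted variants.
DEFAULT_CLIP_LO = 0.0
DEFAULT_CLIP_HI = 3000.0
DEFAULT_BACKGROUND_PERCENTILE = 1.0


@dataclass(frozen=True)
class PreprocessVariant:
    """A named preprocessing recipe.

    Parameters
    ----------
    name:
        One of ``unprocessed``, ``inverted``, ``inverted_black``.
    clip_lo, clip_hi:
        Intensity clip window applied before inversion (defaults 0/3000).
        Ignored by ``unprocessed``, which by definition receives no
        processing at all.
    background_percentile:
        Percentile (in (0, 100)) of the clipped, pre-inversion
        intensities at or below which voxels are forced to 0 by
        ``inverted_black``.
    """

    name: str
    clip_lo: float = DEFAULT_CLIP_LO
    clip_hi: float = DEFAULT_CLIP_HI
    background_percentile: float = DEFAULT_BACKGROUND_PERCENTILE

    def __post_init__(self):
        if self.name not in VARIANT_NAMES:
            raise ValueError(f"unknown variant {self.name!r}; expected one of {VARIANT_NAMES}")
        if not self.clip_lo < self.clip_hi:
            raise ValueError(f"clip_lo must be < clip_hi, got ({self.clip_lo}, {self.clip_hi})")
        if not 0 < self.background_percentile < 100:
            raise ValueError(
                f"background_percentile must lie in (0, 100), got {self.background_percentile}"
            )


def clip_intensities(v: Volume, lo: float = DEFAULT_CLIP_LO, hi: float = DEFAULT_CLIP_HI) -> Volume:
    """Clamp every intensity into [lo, hi]; geometry unchanged."""
    if not lo < hi:
        raise ValueError(f"lo must be < hi, got ({lo}, {hi})")
    return v.with_data(np.clip(np.asarray(v.data, dtype=np.float64), lo, hi))


def invert_plain(v: Volume) -> Volume:
    """Intensity negative within the volume's own value range.

    Each voxel x maps to ``max(X) - x + min(X)`` where X is the multiset
    of all voxel values.  The output has the same minimum and maximum as
    the input, the map reverses intensity order, and applying it twice
    is the identity.
    """
    data = np.asarray(v.data, dtype=np.float64)
    if data.size == 0:
        raise ValueError("cannot invert an empty volume")
    hi = data.max()
    lo = data.min()
    return v.with_data(hi - data + lo)


def invert_black(v: Volume, p: float = DEFAULT_BACKGROUND_PERCENTILE) -> Volume:
    """Inversion with first-percentile background zeroing.

    Let t be the p-th percentile (linear interpolation) of all voxel
    values.  Voxels with x <= t become exactly 0; every other voxel maps
    to ``max(X) - x + min(X)``.  The threshold is inclusive: on a
    constant volume every voxel is at the percentile value and the
    output is identically zero.
    """
    if not 0 < p < 100:
        raise ValueError(f"percentile must lie in (0, 100), got {p}")
    data = np.asarray(v.data, dtype=np.float64)
    if data.size == 0:
        raise ValueError("cannot invert an empty volume")
    t = np.percentile(data, p)
    hi = data.max()
    lo = data.min()
    out = np.where(data <= t, 0.0, hi - data + lo)
    return v.with_data(out)


def preprocess(v: Volume, variant: PreprocessVariant | str) -> Volume:
    """Apply a named preprocessing variant.

    ``unprocessed`` returns the input untouched; ``inverted`` clips then
    takes the plain negative; ``inverted_black`` clips, then inverts with
    the percentile threshold computed on the clipped pre-inversion
    intensities.
    """
    if isinstance(variant, str):
        variant = PreprocessVariant(name=variant)
    if variant.name == "unprocessed":
        return v
    clipped = clip_intensities(v, variant.clip_lo, variant.clip_hi)
    if variant.name == "inverted":
        return invert_plain(clipped)
    return invert_black(clipped, variant.background_percentile)
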