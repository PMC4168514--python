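"""Per-pixel color features across five color spaces, and the highlight map.

Every pixel of an 8-bit RGB image is described by 15 features drawn from
five color spaces commonly used in plant image analysis:

====================  =======================================================
space                 features and conventions
====================  =======================================================
normalized rgb        r, g, b = R/(R+G+B) etc.; sum to 1; 1/3 each at black
HSV                   H in degrees [0, 360), 0 for achromatic pixels;
                      S, V in [0, 1]
CIE L*a*b*            sRGB primaries, D65 white point; L* in [0, 100]
CIE L*u*v*            same primaries/white point
YCbCr                 BT.601 full-range: Y, Cb, Cr in [0, 255]
====================  =======================================================

All arithmetic is floating point; intermediate results are never
re-quantized to 8 bits.

The highlight map ``V·(1−S)`` is the cue used to separate individual fruits
inside a fruit cluster: flash-overexposed regions have high value and low
saturation, so they stand out as values near 1.
"""

from __future__ import annotations

import numpy as np
from skimage import color as _skcolor

#: Order of the 15 per-pixel color features.
FEATURE_NAMES: tuple[str, ...] = (
    "r", "g", "b",
    "H", "S", "V",
    "Lstar", "astar", "bstar",
    "Lstar_uv", "ustar", "vstar",
    "Y", "Cb", "Cr",
)

# BT.601 full-range RGB -> YCbCr (JFIF convention), inputs in [0, 255].
_YCBCR_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)
_YCBCR_OFFSET = np.array([0.0, 128.0, 128.0])


def _validate_rgb_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB image, got shape {image.shape}")
    if image.shape[0] == 0 or image.shape[1] == 0:
        raise ValueError("empty image")
    if image.dtype != np.uint8:
        arr = np.asarray(image, dtype=np.float64)
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("RGB channel values must lie in [0, 255]")
    return image


def feature_planes(image: np.ndarray) -> np.ndarray:
    """Compute the 15 color-feature planes of an 8-bit RGB image.

    Parameters
    ----------
    image
        H×W×3 array, channel order RGB, values in [0, 255].

    Returns
    -------
    ndarray
        Float array of shape (H, W, 15) ordered as :data:`FEATURE_NAMES`.
    """
    image = _validate_rgb_image(image)
    rgb = np.asarray(image, dtype=np.float64)
    rgb01 = rgb / 255.0

    total = rgb.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        chrom = rgb / total[..., None]
    chrom[total == 0] = 1.0 / 3.0  # black is achromatic

    hsv = _skcolor.rgb2hsv(rgb01)
    hsv[..., 0] *= 360.0  # hue in degrees
    hsv[..., 0][hsv[..., 1] == 0] = 0.0  # hue undefined when achromatic

    lab = _skcolor.rgb2lab(rgb01)  # sRGB, D65
    luv = _skcolor.rgb2luv(rgb01)

    # chroma extremes (pure blue/red) land at 255.5 before the [0,255]
    # clamp the full-range convention prescribes
    ycbcr = np.clip(rgb @ _YCBCR_MATRIX.T + _YCBCR_OFFSET, 0.0, 255.0)

    return np.concatenate([chrom, hsv, lab, luv, ycbcr], axis=2)


def pixel_features(pixel) -> np.ndarray:
    """15-component color-feature vector of one 8-bit RGB pixel.

    Equivalent to ``feature_planes`` on a 1×1 image.
    """
    arr = np.asarray(pixel, dtype=np.float64).reshape(1, 1, 3)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB channel values must lie in [0, 255]")
    return feature_planes(arr)[0, 0]


def highlight_map(image: np.ndarray) -> np.ndarray:
    """Specular-highlight map ``V·(1−S)`` of an RGB image.

    Overexposed flash reflections have value near 1 and saturation near 0,
    so they map to values near 1 while fruit body, foliage and background
    map much lower.  Returns an H×W float plane in [0, 1].
    """
    image = _validate_rgb_image(image)
    hsv = _skcolor.rgb2hsv(np.asarray(image, dtype=np.float64) / 255.0)
    return hsv[..., 2] * (1.0 - hsv[..., 1])
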