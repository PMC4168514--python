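"""Stage 2: blob extraction, 19 blob features, random-forest filtering.

Pixel segmentation over-detects: sensor speckles, highlights on background
objects and stem fragments all land in the fruit class.  Each 8-connected
component of fruit pixels becomes a "blob" — the minimal enclosing
rectangle of the component, its binary mask and the cropped RGB patch.
A random forest over 19 features (mask-mean of the 15 color features,
gray-histogram contrast, GLCM angular second moment, size = width×height,
aspect = width/height) sorts blobs into multi-fruit / single-fruit /
non-fruit; non-fruit blobs are discarded by downstream stages.

Texture dialect: grayscale is BT.601 luma rounded to 8 bits; the GLCM uses
256 gray levels, the single offset (0, 1) plus its symmetric pair,
normalized, computed over the full rectangular patch (the rectangle is what
the classifier sees, so texture context includes the background inside the
bbox).  Color means in contrast are taken over mask pixels only, which
avoids background bleed.  Patches too small to contain a single horizontal
pixel pair take the constant-texture limit ASM = 1, contrast = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from skimage.feature import graycomatrix
from skimage.measure import label as _cc_label, regionprops
from sklearn.ensemble import RandomForestClassifier

from tomatodetect.color_features import FEATURE_NAMES, feature_planes
from tomatodetect.pixel_segmentation import CLASS_CODES

BLOB_CLASSES: tuple[str, ...] = ("multi_fruit", "single_fruit", "non_fruit")
_BLOB_CODES = {name: i for i, name in enumerate(BLOB_CLASSES)}

BLOB_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"mean_{n}" for n in FEATURE_NAMES
) + ("hist_contrast", "glcm_asm", "size", "aspect")

_MODEL_FORMAT_VERSION = 1


@dataclass
class Blob:
    """A connected fruit-pixel region cropped by its minimal rectangle."""

    bbox: tuple[int, int, int, int]  # (row0, col0, height, width)
    mask: np.ndarray                 # bool, height×width, one 8-conn component
    patch: np.ndarray                # RGB crop of the bbox
    blob_class: str | None = None
    blob_id: int | None = None

    @property
    def size(self) -> int:
        return self.bbox[2] * self.bbox[3]

    @property
    def aspect(self) -> float:
        return self.bbox[3] / self.bbox[2]


@dataclass
class BlobClassifier:
    """Fitted random forest with mean-decrease-Gini feature importances."""

    forest: RandomForestClassifier
    hyperparams: dict
    seed: int
    class_counts: dict[str, int] = field(default_factory=dict)
    format_version: int = field(default=_MODEL_FORMAT_VERSION)

    @property
    def importances(self) -> dict[str, float]:
        return dict(zip(BLOB_FEATURE_NAMES, self.forest.feature_importances_))

    def importance_ranking(self) -> list[str]:
        """Feature names sorted by decreasing mean-decrease-Gini."""
        imp = self.forest.feature_importances_
        return [BLOB_FEATURE_NAMES[i] for i in np.argsort(imp)[::-1]]

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "BlobClassifier":
        obj = joblib.load(path)
        if not isinstance(obj, BlobClassifier):
            raise TypeError(f"{path} does not contain a blob model")
        if obj.format_version != _MODEL_FORMAT_VERSION:
            raise ValueError(
                f"blob model format {obj.format_version} unsupported "
                f"(expected {_MODEL_FORMAT_VERSION})"
            )
        return obj


def extract_blobs(classmap: np.ndarray, image: np.ndarray) -> list[Blob]:
    """One Blob per 8-connected component of fruit-class pixels.

    Blobs are ordered row-major by bbox origin; their masks are pairwise
    disjoint and their union is exactly the fruit-pixel set.
    """
    classmap = np.asarray(classmap)
    image = np.asarray(image)
    if classmap.shape != image.shape[:2]:
        raise ValueError(
            f"classmap shape {classmap.shape} does not match image "
            f"{image.shape[:2]}"
        )
    fruit = classmap == CLASS_CODES["fruit"]
    labeled = _cc_label(fruit, connectivity=2)  # 8-connectivity
    blobs: list[Blob] = []
    for prop in regionprops(labeled):
        r0, c0, r1, c1 = prop.bbox
        blobs.append(
            Blob(
                bbox=(r0, c0, r1 - r0, c1 - c0),
                mask=prop.image.astype(bool),
                patch=image[r0:r1, c0:c1].copy(),
            )
        )
    blobs.sort(key=lambda b: (b.bbox[0], b.bbox[1]))
    for i, b in enumerate(blobs):
        b.blob_id = i
    return blobs


def grayscale(patch: np.ndarray) -> np.ndarray:
    """BT.601 luma of an RGB patch, rounded to the nearest 8-bit level."""
    rgb = np.asarray(patch, dtype=np.float64)
    luma = rgb[..., 0] * 0.299 + rgb[..., 1] * 0.587 + rgb[..., 2] * 0.114
    return np.clip(np.rint(luma), 0, 255).astype(np.uint8)


def glcm_asm(gray: np.ndarray, levels: int = 256) -> float:
    """Angular second moment Σ p(i,j)² of the patch GLCM.

    Offset (0, 1) plus its symmetric pair, normalized, ``levels`` gray
    levels.  Raises ``ValueError`` when the patch supports no horizontal
    pixel pair; callers substitute the constant-texture limit 1.0.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2 or gray.shape[1] < 2:
        raise ValueError("patch supports no (0,1)-offset pixel pair")
    glcm = graycomatrix(
        gray.astype(np.uint8), distances=[1], angles=[0],
        levels=levels, symmetric=True, normed=True,
    )
    p = glcm[:, :, 0, 0]
    return float(np.sum(p * p))


def hist_contrast(gray: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Histogram contrast: variance of the (masked) gray-level distribution."""
    gray = np.asarray(gray, dtype=np.float64)
    if mask is not None:
        vals = gray[np.asarray(mask, dtype=bool)]
    else:
        vals = gray.ravel()
    if vals.size == 0:
        raise ValueError("empty mask: histogram contrast undefined")
    return float(np.var(vals))


def blob_features(blob: Blob) -> np.ndarray:
    """19-component feature vector of one blob.

    Color means over mask pixels; texture over the full rectangular patch;
    size and aspect from the bbox.
    """
    planes = feature_planes(blob.patch)
    mask = blob.mask
    color_means = planes[mask].mean(axis=0)
    gray = grayscale(blob.patch)
    try:
        asm = glcm_asm(gray)
    except ValueError:
        asm = 1.0  # constant-texture limit for degenerate patches
    if gray.size >= 2:
        contrast = hist_contrast(gray)
    else:
        contrast = 0.0
    return np.concatenate(
        [color_means, [contrast, asm, float(blob.size), float(blob.aspect)]]
    )


def train_blob_classifier(
    features: np.ndarray | list[np.ndarray],
    labels: list[str],
    hyperparams: dict | None = None,
    seed: int = 0,
) -> BlobClassifier:
    """Fit the 3-class random forest on blob feature vectors.

    Defaults: 500 trees, √19 features per split, bootstrap sampling,
    out-of-bag scoring enabled.  All three blob classes must be present.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.array([_BLOB_CODES[l] for l in labels])
    missing = set(BLOB_CLASSES) - {BLOB_CLASSES[c] for c in np.unique(y)}
    if missing:
        raise ValueError(f"missing blob classes in training set: {sorted(missing)}")
    params = {"n_estimators": 500, "max_features": "sqrt", "bootstrap": True}
    if hyperparams:
        params.update(hyperparams)
    forest = RandomForestClassifier(
        random_state=seed, oob_score=True, n_jobs=1, **params
    )
    forest.fit(X, y)
    counts = {BLOB_CLASSES[c]: int((y == c).sum()) for c in np.unique(y)}
    return BlobClassifier(forest=forest, hyperparams=params, seed=seed,
                          class_counts=counts)


def classify_blobs(classifier: BlobClassifier, blobs: list[Blob]) -> list[Blob]:
    """Assign each blob one of the three classes (in place; list returned)."""
    from sklearn.exceptions import NotFittedError
    from sklearn.utils.validation import check_is_fitted

    try:
        check_is_fitted(classifier.forest)
    except NotFittedError as exc:
        raise RuntimeError("blob classifier is not fitted") from exc
    if not blobs:
        return blobs
    X = np.stack([blob_features(b) for b in blobs])
    pred = classifier.forest.predict(X)
    for b, c in zip(blobs, pred):
        b.blob_class = BLOB_CLASSES[int(c)]
    return blobs
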