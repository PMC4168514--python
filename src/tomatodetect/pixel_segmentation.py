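"""Stage 1: CART pixel classification into fruit / leaf / stem / background.

Training pixels come either from seed clicks (each seed contributes itself
plus its in-bounds 8-neighbors, all with the seed's label) or from full
label masks.  A decision tree (CART, Gini impurity) over the 15 color
features is fit once and then applied to whole images, producing a per-pixel
4-class map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.tree import DecisionTreeClassifier

from tomatodetect.color_features import FEATURE_NAMES, feature_planes

#: Canonical class order; integer codes index into this tuple.
CLASS_NAMES: tuple[str, ...] = ("background", "fruit", "leaf", "stem")
CLASS_CODES: dict[str, int] = {name: i for i, name in enumerate(CLASS_NAMES)}

_MODEL_FORMAT_VERSION = 1


@dataclass
class PixelSample:
    """One labeled training pixel: 15 color features plus a class label."""

    features: np.ndarray
    label: str

    def __post_init__(self) -> None:
        if self.label not in CLASS_CODES:
            raise ValueError(f"unknown pixel class {self.label!r}")
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.shape != (len(FEATURE_NAMES),):
            raise ValueError("feature vector must have exactly 15 components")


@dataclass
class PixelClassifier:
    """Fitted CART pixel model plus its training metadata."""

    tree: DecisionTreeClassifier
    class_counts: dict[str, int]
    hyperparams: dict
    seed: int
    format_version: int = field(default=_MODEL_FORMAT_VERSION)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "PixelClassifier":
        obj = joblib.load(path)
        if not isinstance(obj, PixelClassifier):
            raise TypeError(f"{path} does not contain a pixel model")
        if obj.format_version != _MODEL_FORMAT_VERSION:
            raise ValueError(
                f"pixel model format {obj.format_version} unsupported "
                f"(expected {_MODEL_FORMAT_VERSION})"
            )
        return obj

    def top_split_features(self, n: int = 3) -> list[str]:
        """Names of the first split features encountered breadth-first.

        Useful for checking which color axes carry the segmentation; on
        canopy scenes these tend to be chroma/opponent axes (b*, Cr, S, r).
        """
        t = self.tree.tree_
        order: list[str] = []
        queue = [0]
        while queue and len(order) < n:
            node = queue.pop(0)
            if t.children_left[node] == -1:  # leaf
                continue
            name = FEATURE_NAMES[t.feature[node]]
            if name not in order:
                order.append(name)
            queue.extend([t.children_left[node], t.children_right[node]])
        return order


def collect_training_pixels(
    image: np.ndarray, seeds: list[tuple[int, int, str]]
) -> list[PixelSample]:
    """Expand seed clicks into labeled samples (seed + 8-neighbors).

    Each seed ``(row, col, label)`` contributes the seed pixel and every
    in-bounds 8-neighbor, all carrying the seed's label.  Duplicates from
    adjacent seeds are kept.
    """
    planes = feature_planes(image)
    h, w = planes.shape[:2]
    samples: list[PixelSample] = []
    for row, col, label in seeds:
        if not (0 <= row < h and 0 <= col < w):
            raise IndexError(f"seed ({row}, {col}) outside {h}×{w} image")
        for dr in (0, -1, 1):
            for dc in (0, -1, 1):
                rr, cc = row + dr, col + dc
                if 0 <= rr < h and 0 <= cc < w:
                    samples.append(PixelSample(planes[rr, cc], label))
    return samples


def samples_from_mask(
    image: np.ndarray, mask: np.ndarray, max_per_class: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[PixelSample]:
    """Turn a full label mask (integer codes per ``CLASS_NAMES``) into samples.

    With ``max_per_class`` set, pixels are subsampled per class without
    replacement using ``rng``.
    """
    mask = np.asarray(mask)
    if mask.shape != np.asarray(image).shape[:2]:
        raise ValueError("mask dimensions must match the image")
    planes = feature_planes(image)
    samples: list[PixelSample] = []
    for code, name in enumerate(CLASS_NAMES):
        rows, cols = np.nonzero(mask == code)
        if max_per_class is not None and len(rows) > max_per_class:
            if rng is None:
                rng = np.random.default_rng(0)
            idx = rng.choice(len(rows), size=max_per_class, replace=False)
            rows, cols = rows[idx], cols[idx]
        for r, c in zip(rows, cols):
            samples.append(PixelSample(planes[r, c], name))
    return samples


def train_pixel_classifier(
    samples: list[PixelSample],
    hyperparams: dict | None = None,
    seed: int = 0,
) -> PixelClassifier:
    """Fit the CART pixel model.

    Defaults: Gini impurity, unlimited depth, ``min_samples_leaf=50`` (a
    large leaf floor keeps the tree compact and noise-resistant at the
    ~10^5-pixel training scale), no class reweighting.  All defaults can be
    overridden through ``hyperparams``.
    """
    if not samples:
        raise ValueError("no training samples")
    X = np.stack([s.features for s in samples])
    y = np.array([CLASS_CODES[s.label] for s in samples])
    present = np.unique(y)
    if len(present) < 2:
        raise ValueError(
            "training requires at least two classes; got only "
            f"{CLASS_NAMES[present[0]]!r}"
        )
    params = {"criterion": "gini", "min_samples_leaf": 50, "max_depth": None}
    if hyperparams:
        params.update(hyperparams)
    tree = DecisionTreeClassifier(random_state=seed, **params)
    tree.fit(X, y)
    counts = {CLASS_NAMES[c]: int((y == c).sum()) for c in present}
    return PixelClassifier(tree=tree, class_counts=counts,
                           hyperparams=params, seed=seed)


def segment_pixels(classifier: PixelClassifier, image: np.ndarray) -> np.ndarray:
    """Label every pixel of ``image`` with the fitted tree.

    Returns an H×W integer map coded per :data:`CLASS_NAMES`.
    Deterministic: the same model on the same image always yields the same
    map.
    """
    from sklearn.exceptions import NotFittedError
    from sklearn.utils.validation import check_is_fitted

    tree = classifier.tree
    try:
        check_is_fitted(tree)
    except NotFittedError as exc:
        raise RuntimeError("pixel classifier is not fitted") from exc
    planes = feature_planes(image)
    h, w = planes.shape[:2]
    pred = tree.predict(planes.reshape(-1, len(FEATURE_NAMES)))
    return pred.reshape(h, w).astype(np.uint8)
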