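"""Seeded generator of flash-lit nighttime canopy scenes with exact truth.

Scenes emulate flash photography of tomato plants against a dark
background: disk-shaped fruits in three growth stages (small dark-green
young fruits near the stem color, pale whitish-green immature fruits,
red mature fruits), each carrying one small near-white specular highlight
from the flash; elliptical leaves; thick, slightly slanted brownish-green
stems; optional fruit clusters (trusses) of mutually tangent fruits whose
fruit-pixel regions form a single 8-connected component; optional leaf
occlusion of fruits; isolated fruit-colored "salt" speckles emulating
sensor noise and background glints (the raw material of non-fruit blobs);
and additive Gaussian sensor noise clipped to [0, 255].

Young fruits are deliberately colored close to the stem family so that the
hardest real failure mode — young fruit confused with stem — exists in the
benchmark.  All stage color families remain pairwise distinguishable at
zero noise.

Every scene carries exact ground truth (the full class map plus each
fruit's centroid, radius, stage and truss membership), so pipeline metrics
computed on synthetic scenes are genuine accuracy measurements.  All
randomness flows from a single root seed through ``numpy`` generator
spawning, making scenes bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as _draw_disk, ellipse as _draw_ellipse, polygon as _draw_polygon

from tomatodetect.blob_analysis import Blob, extract_blobs
from tomatodetect.color_features import feature_planes
from tomatodetect.evaluation import GroundTruthFruit
from tomatodetect.pixel_segmentation import CLASS_CODES, PixelSample

_FRUIT = CLASS_CODES["fruit"]
_LEAF = CLASS_CODES["leaf"]
_STEM = CLASS_CODES["stem"]
_BACKGROUND = CLASS_CODES["background"]


class PlacementError(RuntimeError):
    """Raised when fruits cannot be placed under the cluster spec."""


@dataclass
class SceneConfig:
    """Rendering parameters of one synthetic canopy scene.

    Defaults describe the standard study conditions: a 480×640 frame,
    eight isolated fruits across the three stages plus one three-fruit
    truss, flash highlights on every fruit, moderate sensor noise
    (σ = 2 gray levels), a 0.2% salt-speckle rate and no occlusion.
    """

    height: int = 480
    width: int = 640
    # isolated fruits per growth stage
    n_young: int = 3
    n_immature: int = 3
    n_mature: int = 2
    # fruit radius ranges (pixels) per stage; young are the smallest
    radius_young: tuple[int, int] = (6, 10)
    radius_immature: tuple[int, int] = (11, 16)
    radius_mature: tuple[int, int] = (15, 22)
    # trusses of touching fruits (multi-fruit blobs)
    n_trusses: int = 1
    fruits_per_truss: int = 3
    truss_stage: str = "mature"
    truss_overlap: int = 2  # pixels of mutual disk overlap, keeps 8-connectivity
    # stage / organ base colors (RGB); per-object jitter applied on top
    color_young: tuple[int, int, int] = (88, 124, 50)
    color_immature: tuple[int, int, int] = (180, 200, 160)
    color_mature: tuple[int, int, int] = (185, 40, 35)
    color_leaf: tuple[int, int, int] = (45, 105, 35)
    color_stem: tuple[int, int, int] = (100, 110, 62)
    color_background: tuple[int, int, int] = (15, 15, 20)
    color_highlight: tuple[int, int, int] = (250, 250, 246)
    color_jitter: int = 6
    # specular highlight geometry: radius/offset as fractions of fruit radius
    highlight_radius_frac: float = 0.22
    highlight_offset_frac: float = 0.4
    # radial flash falloff on fruit disks: rim brightness = 1 - shading_amp
    shading_amp: float = 0.3
    # intrinsic per-pixel surface texture (multiplicative Gaussian, relative);
    # distinct from sensor noise: real organ surfaces are never flat-colored
    texture_sigma: float = 0.02
    # foliage
    n_leaves: int = 14
    n_stems: int = 3
    leaf_axes: tuple[int, int] = (18, 9)
    stem_width: int = 4
    # degradations
    occlusion_fraction: float = 0.0
    noise_sigma: float = 2.0
    salt_rate: float = 2e-3
    max_placement_tries: int = 400

    def stage_params(self) -> dict[str, tuple[int, tuple[int, int], tuple[int, int, int]]]:
        return {
            "young": (self.n_young, self.radius_young, self.color_young),
            "immature": (self.n_immature, self.radius_immature, self.color_immature),
            "mature": (self.n_mature, self.radius_mature, self.color_mature),
        }


@dataclass
class SceneTruth:
    """Exact ground truth of a rendered scene."""

    classmap: np.ndarray                 # H×W uint8, codes per CLASS_NAMES
    fruits: list[GroundTruthFruit]
    trusses: dict[int, list[int]] = field(default_factory=dict)  # truss id -> fruit indices
    highlights: list[tuple[float, float]] = field(default_factory=list)  # per fruit


def _jitter(rng: np.random.Generator, color, amount: int) -> np.ndarray:
    c = np.asarray(color, dtype=np.float64)
    return np.clip(c + rng.integers(-amount, amount + 1, size=3), 0, 255)


def _stage_color(cfg: SceneConfig, stage: str) -> tuple[int, int, int]:
    return cfg.stage_params()[stage][2]


def _textured(rng, color, n, texture_sigma):
    base = np.broadcast_to(np.asarray(color, dtype=np.float64), (n, 3))
    if texture_sigma <= 0:
        return base.copy()
    return base * (1.0 + rng.normal(0.0, texture_sigma, size=(n, 1)))


def _paint_disk(image, classmap, center, radius, color, code, rng,
                texture_sigma, shading_amp=0.0):
    rr, cc = _draw_disk(center, radius, shape=classmap.shape)
    px = _textured(rng, color, rr.size, texture_sigma)
    if shading_amp > 0:
        # flash lighting: bright at the disk center, darker toward the rim
        d2 = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / radius**2
        px *= (1.0 - shading_amp * d2)[:, None]
    image[rr, cc] = px
    classmap[rr, cc] = code


def _place_circle(rng, cfg, placed, radius):
    """Rejection-sample a fruit center not colliding with placed circles."""
    margin = radius + 2
    for _ in range(cfg.max_placement_tries):
        cy = rng.uniform(margin, cfg.height - margin)
        cx = rng.uniform(margin, cfg.width - margin)
        if all(np.hypot(cy - py, cx - px) > radius + pr + 3 for py, px, pr in placed):
            return cy, cx
    raise PlacementError("could not place fruit without collision")


def _truss_centers(rng, cfg, placed, radii):
    """Chain of mutually tangent (slightly overlapping) disk centers."""
    for _ in range(cfg.max_placement_tries):
        centers = []
        margin = max(radii) * (len(radii) + 1)
        cy = rng.uniform(margin, cfg.height - margin)
        cx = rng.uniform(margin, cfg.width - margin)
        centers.append((cy, cx))
        ok = True
        for i in range(1, len(radii)):
            gap = radii[i - 1] + radii[i] - cfg.truss_overlap
            for _ in range(40):
                ang = rng.uniform(0, 2 * np.pi)
                ny = centers[-1][0] + gap * np.sin(ang)
                nx = centers[-1][1] + gap * np.cos(ang)
                inside = (radii[i] + 2 <= ny <= cfg.height - radii[i] - 2
                          and radii[i] + 2 <= nx <= cfg.width - radii[i] - 2)
                clear = all(
                    np.hypot(ny - y, nx - x) >= radii[i] + radii[j] - cfg.truss_overlap - 0.5
                    for j, (y, x) in enumerate(centers[:-1])
                )
                if inside and clear:
                    centers.append((ny, nx))
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        collision = any(
            np.hypot(cy2 - py, cx2 - px) <= r2 + pr + 3
            for (cy2, cx2), r2 in zip(centers, radii)
            for py, px, pr in placed
        )
        if not collision:
            return centers
    raise PlacementError("could not place truss without collision")


def _draw_highlight(image, rng, cfg, center, radius):
    hr = max(2, round(cfg.highlight_radius_frac * radius))
    off = min(cfg.highlight_offset_frac * radius, radius - hr - 1)
    ang = rng.uniform(0, 2 * np.pi)
    hy = center[0] + off * np.sin(ang)
    hx = center[1] + off * np.cos(ang)
    rr, cc = _draw_disk((hy, hx), hr, shape=image.shape[:2])
    image[rr, cc] = _textured(rng, cfg.color_highlight, rr.size, cfg.texture_sigma)
    return (hy, hx)


def generate_scene(config: SceneConfig, seed: int) -> tuple[np.ndarray, SceneTruth]:
    """Render one scene and its exact ground truth.

    Deterministic: the same config and seed always produce bit-identical
    images.  Raises :class:`PlacementError` when the requested fruits
    cannot be placed after bounded retries.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    image = np.empty((cfg.height, cfg.width, 3), dtype=np.float64)
    image[:] = cfg.color_background
    classmap = np.full((cfg.height, cfg.width), _BACKGROUND, dtype=np.uint8)

    # stems: slanted thick quads, full height
    for _ in range(cfg.n_stems):
        x0 = rng.uniform(0, cfg.width)
        slant = rng.uniform(-30, 30)
        w = cfg.stem_width + rng.integers(0, 3)
        rr, cc = _draw_polygon(
            [0, 0, cfg.height - 1, cfg.height - 1],
            [x0, x0 + w, x0 + slant + w, x0 + slant],
            shape=classmap.shape,
        )
        image[rr, cc] = _textured(rng, _jitter(rng, cfg.color_stem, cfg.color_jitter),
                                  rr.size, cfg.texture_sigma)
        classmap[rr, cc] = _STEM

    # leaves: random ellipses
    for _ in range(cfg.n_leaves):
        cy = rng.uniform(0, cfg.height)
        cx = rng.uniform(0, cfg.width)
        rot = rng.uniform(0, np.pi)
        rr, cc = _draw_ellipse(cy, cx, cfg.leaf_axes[0], cfg.leaf_axes[1],
                               shape=classmap.shape, rotation=rot)
        image[rr, cc] = _textured(rng, _jitter(rng, cfg.color_leaf, cfg.color_jitter),
                                  rr.size, cfg.texture_sigma)
        classmap[rr, cc] = _LEAF

    fruits: list[GroundTruthFruit] = []
    trusses: dict[int, list[int]] = {}
    placed: list[tuple[float, float, float]] = []  # (cy, cx, r)
    pending_highlights: list[tuple[tuple[float, float], float]] = []

    # trusses first (they need the most room)
    for t in range(cfg.n_trusses):
        lo, hi = cfg.stage_params()[cfg.truss_stage][1]
        radii = [int(rng.integers(lo, hi + 1)) for _ in range(cfg.fruits_per_truss)]
        centers = _truss_centers(rng, cfg, placed, radii)
        trusses[t] = []
        for (cy, cx), r in zip(centers, radii):
            color = _jitter(rng, _stage_color(cfg, cfg.truss_stage), cfg.color_jitter)
            _paint_disk(image, classmap, (cy, cx), r, color, _FRUIT,
                        rng, cfg.texture_sigma, shading_amp=cfg.shading_amp)
            trusses[t].append(len(fruits))
            fruits.append(GroundTruthFruit(centroid=(cy, cx), radius=float(r),
                                           stage=cfg.truss_stage, truss=t))
            placed.append((cy, cx, float(r)))
            pending_highlights.append(((cy, cx), float(r)))

    # isolated fruits
    for stage, (count, (lo, hi), color) in cfg.stage_params().items():
        for _ in range(count):
            r = int(rng.integers(lo, hi + 1))
            cy, cx = _place_circle(rng, cfg, placed, r)
            _paint_disk(image, classmap, (cy, cx), r,
                        _jitter(rng, color, cfg.color_jitter), _FRUIT,
                        rng, cfg.texture_sigma, shading_amp=cfg.shading_amp)
            fruits.append(GroundTruthFruit(centroid=(cy, cx), radius=float(r),
                                           stage=stage, truss=None))
            placed.append((cy, cx, float(r)))
            pending_highlights.append(((cy, cx), float(r)))

    # one specular highlight per fruit (flash reflection)
    highlight_centers = [
        _draw_highlight(image, rng, cfg, center, r)
        for center, r in pending_highlights
    ]

    # partial occlusion: a leaf ellipse clipped over the fruit edge
    for (cy, cx, r) in placed:
        if rng.uniform() < cfg.occlusion_fraction:
            rr, cc = _draw_ellipse(
                cy + r * 0.8, cx + rng.uniform(-r, r),
                cfg.leaf_axes[0], cfg.leaf_axes[1],
                shape=classmap.shape, rotation=rng.uniform(0, np.pi),
            )
            image[rr, cc] = _textured(rng, _jitter(rng, cfg.color_leaf, cfg.color_jitter),
                                      rr.size, cfg.texture_sigma)
            classmap[rr, cc] = _LEAF

    # salt speckles: isolated fruit/highlight-colored pixels off the fruits.
    # They keep their underlying truth label — they are sensor noise, and the
    # pixel stage is expected to misread them, feeding non-fruit blobs.
    n_salt = int(round(cfg.salt_rate * cfg.height * cfg.width))
    if n_salt:
        from scipy.ndimage import binary_dilation

        forbidden = binary_dilation(classmap == _FRUIT, iterations=2)
        free = np.flatnonzero(~forbidden.ravel())
        picks = rng.choice(free, size=min(n_salt, free.size), replace=False)
        salt_colors = np.array([cfg.color_mature, cfg.color_highlight])
        which = rng.integers(0, 2, size=picks.size)
        ys, xs = np.unravel_index(picks, classmap.shape)
        image[ys, xs] = salt_colors[which]

    if cfg.noise_sigma > 0:
        image = image + rng.normal(0.0, cfg.noise_sigma, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return image, SceneTruth(classmap=classmap, fruits=fruits, trusses=trusses,
                             highlights=highlight_centers)


def generate_pixel_training_set(
    config: SceneConfig, n_per_class: int, seed: int
) -> list[PixelSample]:
    """Uniformly sampled labeled pixels, exactly ``n_per_class`` per class.

    ``n_per_class`` may be a mapping from class name to count (the field
    practice weighs the fruit class more heavily than the others).  Quotas
    are spread over at least ``min_scenes`` freshly generated scenes so
    the training set covers many distinct organ color draws, mirroring
    training over a set of images rather than one frame.
    """
    min_scenes = 12
    if isinstance(n_per_class, dict):
        quotas = {name: int(n_per_class[name]) for name in CLASS_CODES}
    else:
        quotas = {name: int(n_per_class) for name in CLASS_CODES}
    per_scene = {name: max(1, -(-quotas[name] // min_scenes)) for name in quotas}
    root = np.random.default_rng(seed)
    samples: dict[str, list[PixelSample]] = {name: [] for name in quotas}
    for _ in range(64):  # scene budget
        if all(len(samples[n]) >= quotas[n] for n in quotas):
            break
        scene_seed = int(root.integers(0, 2**31 - 1))
        image, truth = generate_scene(config, scene_seed)
        planes = feature_planes(image)
        for name, code in CLASS_CODES.items():
            need = min(per_scene[name], quotas[name] - len(samples[name]))
            if need <= 0:
                continue
            rows, cols = np.nonzero(truth.classmap == code)
            if rows.size == 0:
                raise ValueError(f"scene contains no pixels of class {name!r}")
            take = min(need, rows.size)
            idx = root.choice(rows.size, size=take, replace=False)
            for r, c in zip(rows[idx], cols[idx]):
                samples[name].append(PixelSample(planes[r, c], name))
    missing = {n: quotas[n] - len(samples[n]) for n in quotas
               if len(samples[n]) < quotas[n]}
    if missing:
        raise ValueError(f"could not fill class quotas: {missing}")
    out: list[PixelSample] = []
    for name in CLASS_CODES:
        out.extend(samples[name][: quotas[name]])
    return out


def _speckle_blob(image: np.ndarray, cfg: SceneConfig, rng: np.random.Generator) -> Blob:
    """A 1–4 pixel salt speckle blob with its local background patch."""
    h, w = image.shape[:2]
    n_px = int(rng.integers(1, 5))
    cy = int(rng.integers(5, h - 6))
    cx = int(rng.integers(5, w - 6))
    pts = {(cy, cx)}
    while len(pts) < n_px:
        py, px = next(iter(pts))
        pts.add((py + int(rng.integers(-1, 2)), px + int(rng.integers(-1, 2))))
    rows = np.array([p[0] for p in pts])
    cols = np.array([p[1] for p in pts])
    r0, c0 = rows.min(), cols.min()
    hgt, wid = rows.max() - r0 + 1, cols.max() - c0 + 1
    patch = image[r0:r0 + hgt, c0:c0 + wid].astype(np.float64).copy()
    mask = np.zeros((hgt, wid), dtype=bool)
    salt = [cfg.color_mature, cfg.color_highlight][int(rng.integers(0, 2))]
    mask[rows - r0, cols - c0] = True
    patch[mask] = salt
    return Blob(bbox=(int(r0), int(c0), int(hgt), int(wid)), mask=mask,
                patch=np.clip(np.rint(patch), 0, 255).astype(np.uint8))


def _count_fruits_in_blob(blob: Blob, centroid_px: list[tuple[int, int]]) -> int:
    r0, c0, hgt, wid = blob.bbox
    return sum(
        1 for (fy, fx) in centroid_px
        if r0 <= fy < r0 + hgt and c0 <= fx < c0 + wid
        and blob.mask[fy - r0, fx - c0]
    )


def generate_blob_training_set(
    config: SceneConfig,
    counts: tuple[int, int, int],
    seed: int,
    pixel_classifier=None,
) -> tuple[list[Blob], list[str]]:
    """Labeled blobs: ``counts`` = (n_multi, n_single, n_non).

    With ``pixel_classifier`` given, blobs are collected exactly the way
    the pipeline produces them: training scenes are pixel-segmented with
    the model, and every fruit-class component is labeled by the number of
    ground-truth fruit centroids it contains (≥2 multi-fruit, 1
    single-fruit, 0 non-fruit).  The non-fruit class then carries the real
    misclassification palette — noise pixels that crossed into the fruit
    class — which is what the blob filter must learn to reject.

    Without a pixel model, fruit blobs come from the true class map
    (multi-fruit from trusses, single-fruit from isolated fruits) and
    non-fruit blobs are injected salt speckles with their surrounding
    patch.  Labels are exact by construction in both modes.

    Non-fruit blobs are subsampled at random per scene (rather than taken
    in scan order from one frame) so the set reflects the full variety of
    false-positive components, including the rare fruit-colored organ
    pixels, not just sensor salt.
    """
    n_multi, n_single, n_non = counts
    root = np.random.default_rng(seed)
    blobs: list[Blob] = []
    labels: list[str] = []
    got = {"multi_fruit": 0, "single_fruit": 0, "non_fruit": 0}
    want = {"multi_fruit": n_multi, "single_fruit": n_single,
            "non_fruit": n_non if pixel_classifier is not None else 0}
    non_per_scene = max(1, -(-want["non_fruit"] // 8))
    for _ in range(64):
        if all(got[k] >= want[k] for k in want):
            break
        scene_seed = int(root.integers(0, 2**31 - 1))
        image, truth = generate_scene(config, scene_seed)
        centroid_px = [(int(round(f.centroid[0])), int(round(f.centroid[1])))
                       for f in truth.fruits]
        if pixel_classifier is not None:
            from tomatodetect.pixel_segmentation import segment_pixels

            classmap = segment_pixels(pixel_classifier, image)
        else:
            classmap = truth.classmap
        scene_non: list[Blob] = []
        for blob in extract_blobs(classmap, image):
            inside = _count_fruits_in_blob(blob, centroid_px)
            if inside >= 2:
                label = "multi_fruit"
            elif inside == 1:
                label = "single_fruit"
            else:
                scene_non.append(blob)
                continue
            if got[label] < want[label]:
                blobs.append(blob)
                labels.append(label)
                got[label] += 1
        take = min(non_per_scene, want["non_fruit"] - got["non_fruit"],
                   len(scene_non))
        if take > 0:
            for idx in root.choice(len(scene_non), size=take, replace=False):
                blobs.append(scene_non[idx])
                labels.append("non_fruit")
                got["non_fruit"] += 1
    short = {k: want[k] - got[k] for k in want if got[k] < want[k]}
    if short:
        raise ValueError(f"could not collect requested blobs, short by {short}")
    if pixel_classifier is None:
        backdrop, _ = generate_scene(config, int(root.integers(0, 2**31 - 1)))
        for _ in range(n_non):
            blobs.append(_speckle_blob(backdrop, config, root))
            labels.append("non_fruit")
    return blobs, labels
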