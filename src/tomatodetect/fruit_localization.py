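"""Stage 3: individual fruit positions from classified blobs.

A single-fruit blob is located at the centroid (center of gravity) of its
mask.  A multi-fruit blob — a truss of touching fruits — is resolved
through the flash highlight each fruit carries: the highlight map V·(1−S)
of the blob's mask pixels is clustered with 1-D X-means, the cluster with
the highest mean map value is kept (the overexposed regions), and each
surviving 8-connected component of kept pixels, above a minimum area,
yields one detection at its centroid.

X-means grows the number of clusters from k = 1 by attempting a 2-means
split of every cluster and accepting the split when the Bayesian
information criterion of the two-cluster model of that cluster's points
exceeds the one-cluster model's.  The BIC uses an identical spherical
Gaussian per cluster (variance pooled across clusters via the maximum
likelihood estimate) with free-parameter count k·(d+1)+1; ties break toward
fewer clusters, which biases against over-counting fruits.  Splits are
initialized deterministically at the extreme points of the parent cluster,
so the whole stage is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _cc_label, regionprops

from tomatodetect.blob_analysis import Blob, classify_blobs, extract_blobs
from tomatodetect.color_features import highlight_map
from tomatodetect.pixel_segmentation import segment_pixels


@dataclass
class FruitDetection:
    """One detected fruit position in image coordinates."""

    position: tuple[float, float]  # (row, col)
    source: str                    # single_blob_centroid | multi_blob_highlight
    blob_id: int | None = None


@dataclass
class ClusterResult:
    """Outcome of 1-D X-means clustering."""

    k: int
    assignment: np.ndarray   # cluster index per sample
    centroids: np.ndarray    # one centroid per cluster
    means: np.ndarray        # per-cluster mean of the clustered value (== centroids in 1-D)


def _kmeans2_1d(values: np.ndarray, max_iter: int = 100):
    """Deterministic multi-start 2-means on 1-D data.

    Lloyd iterations in one dimension reduce to thresholding at the
    centroid midpoint; each start is a deterministic quantile threshold and
    the converged solution with the lowest SSE wins, which keeps the split
    boundary out of the interior of a dense mode whenever a deeper valley
    exists.  Returns (assignment, centroids, sse).
    """
    starts = np.quantile(values, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
    best = None
    for thr in np.unique(starts):
        assign = (values > thr).astype(np.intp)
        if assign.min() == assign.max():
            continue
        c = np.array([values[assign == 0].mean(), values[assign == 1].mean()])
        for _ in range(max_iter):
            new_assign = (values > (c[0] + c[1]) / 2.0).astype(np.intp)
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for j in (0, 1):
                sel = values[assign == j]
                if sel.size:
                    c[j] = sel.mean()
        sse = float(((values - c[assign]) ** 2).sum())
        if best is None or sse < best[2]:
            best = (assign, c, sse)
    if best is None:  # all values identical
        return (np.zeros(len(values), dtype=np.intp),
                np.array([values[0], values[0]]), 0.0)
    return best


def _bic(values: np.ndarray, assign: np.ndarray, centroids: np.ndarray,
         var_floor: float) -> float:
    """Gaussian-cluster BIC (larger is better) of a k-means solution.

    Each cluster is a Gaussian with its own MLE variance, weighted by the
    mixing proportion n_j/n; the penalty is (p/2)·log n with
    p = k·(d+1)+1, d = 1.  ``var_floor`` bounds per-cluster variances away
    from zero so that a perfectly separating split of multimodal data gets
    a very large but finite likelihood, while constant data (parent and
    children equally degenerate) never gains from splitting.
    """
    n = len(values)
    k = len(centroids)
    ll = 0.0
    for j in range(k):
        sel = values[assign == j]
        nj = sel.size
        if nj == 0:
            continue
        sigma2 = max(float(np.var(sel)), var_floor)
        ll += nj * np.log(nj / n) - 0.5 * nj * np.log(2.0 * np.pi * sigma2) - 0.5 * nj
    p = k * 2 + 1
    return ll - 0.5 * p * np.log(n)


def _lloyd_1d(values: np.ndarray, centroids: np.ndarray,
              max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Global 1-D k-means refinement from given centroids.

    In one dimension nearest-centroid assignment is thresholding at the
    midpoints of the sorted centroids.
    """
    c = np.sort(np.asarray(centroids, dtype=np.float64))
    assign = np.zeros(values.size, dtype=np.intp)
    for _ in range(max_iter):
        edges = (c[:-1] + c[1:]) / 2.0
        new_assign = np.searchsorted(edges, values)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(c.size):
            sel = values[assign == j]
            if sel.size:
                c[j] = sel.mean()
        c = np.sort(c)
    # drop empty clusters
    keep = np.array([np.any(assign == j) for j in range(c.size)])
    c = c[keep]
    remap = np.cumsum(keep) - 1
    return remap[assign], c


def xmeans_1d(values, kmax: int = 20, seed: int | None = None,
              min_cluster: int = 3) -> ClusterResult:
    """X-means clustering of scalar values with BIC-driven splitting.

    Starts with one cluster and alternates two phases until a local BIC
    optimum (or ``kmax``) is reached: every cluster attempts a 2-means
    split, accepted when the two-cluster BIC of that cluster's points
    exceeds the one-cluster BIC; then all centroids are refined by global
    k-means, which re-snaps cluster boundaries after splits.  Splits that
    would create a cluster smaller than ``min_cluster`` points are not
    considered.  Ties in BIC keep the smaller model, biasing toward fewer
    clusters.

    ``seed`` is accepted for interface stability; the deterministic
    extreme-point initialization makes the result seed-independent.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("cannot cluster an empty value set")
    if kmax < 1:
        raise ValueError("kmax must be >= 1")

    span = float(values.max() - values.min())
    var_floor = max(span, 1.0) ** 2 * 1e-18 + 1e-300

    centroids = np.array([values.mean()])
    assign = np.zeros(values.size, dtype=np.intp)
    best_model = (_bic(values, assign, centroids, var_floor), assign, centroids)
    while centroids.size < kmax:
        # one split per round — the BIC-best — so every k along the way is
        # visited and scored
        best_split: tuple[float, int, np.ndarray] | None = None
        for j in range(centroids.size):
            vals = values[assign == j]
            if vals.size < 2 * min_cluster:
                continue
            parent = _bic(vals, np.zeros(vals.size, dtype=np.intp),
                          np.array([vals.mean()]), var_floor)
            sub_assign, sub_c, _ = _kmeans2_1d(vals)
            sizes = np.bincount(sub_assign, minlength=2)
            if sizes.min() < min_cluster:
                continue
            child = _bic(vals, sub_assign, sub_c, var_floor)
            gain = child - parent
            if gain > 0 and (best_split is None or gain > best_split[0]):
                best_split = (gain, j, sub_c)
        if best_split is None:  # ties keep the parent
            break
        _, j, sub_c = best_split
        new_centroids = np.concatenate(
            [np.delete(centroids, j), sub_c]
        )
        assign, centroids = _lloyd_1d(values, new_centroids)
        score = _bic(values, assign, centroids, var_floor)
        if score > best_model[0]:  # keep the best-scoring model visited
            best_model = (score, assign.copy(), centroids.copy())

    _, assign, centroids = best_model
    return ClusterResult(k=centroids.size, assignment=assign,
                         centroids=centroids, means=centroids.copy())


def locate_single(blob: Blob) -> FruitDetection:
    """Center of gravity of a single-fruit blob, in image coordinates."""
    rows, cols = np.nonzero(blob.mask)
    if rows.size == 0:
        raise ValueError("empty blob mask")
    r0, c0 = blob.bbox[0], blob.bbox[1]
    return FruitDetection(
        position=(r0 + float(rows.mean()), c0 + float(cols.mean())),
        source="single_blob_centroid",
        blob_id=blob.blob_id,
    )


def locate_multi(
    blob: Blob,
    min_region: int = 5,
    kmax: int = 20,
    seed: int | None = None,
) -> list[FruitDetection]:
    """Individual fruit positions inside a multi-fruit blob.

    Pipeline: highlight map of the blob patch → X-means over the map values
    of mask pixels → keep the cluster with the highest mean → 8-connected
    components of kept pixels → drop components below ``min_region`` pixels
    → one detection at each remaining component centroid.
    """
    rows, cols = np.nonzero(blob.mask)
    if rows.size == 0:
        raise ValueError("empty blob mask")
    hmap = highlight_map(blob.patch)
    result = xmeans_1d(hmap[rows, cols], kmax=kmax, seed=seed)
    top = result.k - 1  # clusters sorted by centroid ascending
    keep = np.zeros(blob.mask.shape, dtype=bool)
    sel = result.assignment == top
    keep[rows[sel], cols[sel]] = True

    labeled = _cc_label(keep, connectivity=2)
    r0, c0 = blob.bbox[0], blob.bbox[1]
    detections: list[FruitDetection] = []
    for prop in regionprops(labeled):
        if prop.area < min_region:
            continue
        cy, cx = prop.centroid
        detections.append(
            FruitDetection(
                position=(r0 + float(cy), c0 + float(cx)),
                source="multi_blob_highlight",
                blob_id=blob.blob_id,
            )
        )
    return detections


def detect_fruits(
    image: np.ndarray,
    pixel_clf,
    blob_clf,
    min_region: int = 5,
    kmax: int = 20,
    seed: int | None = None,
    stats: dict | None = None,
) -> list[FruitDetection]:
    """Full detection cascade on one RGB image.

    Segment pixels → extract candidate blobs → classify and drop non-fruit
    blobs → locate fruits (centroid or highlight clustering).  Detections
    are returned sorted row-major.  Pass a dict as ``stats`` to receive
    per-stage counts (candidate blobs, surviving blobs by class).
    """
    classmap = segment_pixels(pixel_clf, image)
    blobs = extract_blobs(classmap, image)
    classify_blobs(blob_clf, blobs)

    detections: list[FruitDetection] = []
    n_single = n_multi = 0
    for blob in blobs:
        if blob.blob_class == "single_fruit":
            detections.append(locate_single(blob))
            n_single += 1
        elif blob.blob_class == "multi_fruit":
            detections.extend(
                locate_multi(blob, min_region=min_region, kmax=kmax, seed=seed)
            )
            n_multi += 1
    if stats is not None:
        stats.update(
            candidate_blobs=len(blobs),
            single_fruit_blobs=n_single,
            multi_fruit_blobs=n_multi,
            non_fruit_blobs=len(blobs) - n_single - n_multi,
            detections=len(detections),
        )
    detections.sort(key=lambda d: d.position)
    return detections
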