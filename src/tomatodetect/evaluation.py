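"""Detection evaluation: ground-truth matching, recall, precision, parts.

Recall = matched fruits / all fruits (completeness); precision = matched
detections / all detections (exactness).  A detection can match a fruit
when it falls inside the fruit's disk (distance from the ground-truth
centroid ≤ ground-truth radius); pairs are matched greedily in increasing
distance order, each fruit and each detection used at most once.  Recall is
also reported per growth stage (young / immature / mature — the three-way
taxonomy by color and size).  Metrics that are undefined (no fruits, no
detections) are reported as absent, never coerced to 0 or 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from tomatodetect.fruit_localization import FruitDetection

STAGES: tuple[str, ...] = ("young", "immature", "mature")


@dataclass
class GroundTruthFruit:
    """One annotated fruit: centroid, radius and growth stage."""

    centroid: tuple[float, float]  # (row, col)
    radius: float
    stage: str
    truss: int | None = None       # truss membership, None for isolated fruits

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("fruit radius must be positive")
        if self.stage not in STAGES:
            raise ValueError(f"unknown growth stage {self.stage!r}")


@dataclass
class Matching:
    """One-to-one detection↔fruit correspondence."""

    pairs: list[tuple[int, int]]          # (detection index, fruit index)
    n_detections: int
    n_fruits: int
    fruit_stages: list[str]

    @property
    def matched_fruits(self) -> set[int]:
        return {f for _, f in self.pairs}

    @property
    def matched_detections(self) -> set[int]:
        return {d for d, _ in self.pairs}


@dataclass
class DetectionReport:
    """Per-stage and overall recall, precision, and the match lists."""

    recall_by_stage: dict[str, float | None]
    n_by_stage: dict[str, int]
    overall_recall: float | None
    precision: float | None
    n_fruits: int
    n_detections: int
    n_matched: int
    false_positives: list[int] = field(default_factory=list)
    false_negatives: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "stages": {
                    s: {"recall": self.recall_by_stage[s], "n": self.n_by_stage[s]}
                    for s in STAGES
                },
                "overall": {
                    "recall": self.overall_recall,
                    "precision": self.precision,
                    "n_fruits": self.n_fruits,
                    "n_detections": self.n_detections,
                    "n_matched": self.n_matched,
                },
            },
            indent=2,
        )

    def to_text(self) -> str:
        def fmt(x):
            return "-" if x is None else f"{x:.2f}"

        lines = [f"{'stage':<10}{'recall':>8}{'n':>6}"]
        for s in STAGES:
            lines.append(f"{s:<10}{fmt(self.recall_by_stage[s]):>8}{self.n_by_stage[s]:>6}")
        lines.append(f"{'overall':<10}{fmt(self.overall_recall):>8}{self.n_fruits:>6}")
        lines.append(f"precision {fmt(self.precision)} "
                     f"({self.n_matched}/{self.n_detections} detections relevant)")
        return "\n".join(lines)


def match_detections(
    dets: list[FruitDetection], truth: list[GroundTruthFruit]
) -> Matching:
    """Greedy one-to-one matching of detections to fruit disks.

    All (detection, fruit) pairs with distance ≤ the fruit's radius are
    sorted by distance and accepted greedily, skipping pairs whose
    detection or fruit is already used.
    """
    candidates: list[tuple[float, int, int]] = []
    for di, det in enumerate(dets):
        for fi, fruit in enumerate(truth):
            d = float(np.hypot(det.position[0] - fruit.centroid[0],
                               det.position[1] - fruit.centroid[1]))
            if d <= fruit.radius:
                candidates.append((d, di, fi))
    candidates.sort()
    used_d: set[int] = set()
    used_f: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, di, fi in candidates:
        if di in used_d or fi in used_f:
            continue
        pairs.append((di, fi))
        used_d.add(di)
        used_f.add(fi)
    return Matching(pairs=pairs, n_detections=len(dets), n_fruits=len(truth),
                    fruit_stages=[f.stage for f in truth])


def recall(matching: Matching, stage_filter: str | None = None) -> float:
    """Matched fruits ÷ total fruits, optionally restricted to one stage."""
    if stage_filter is None:
        idx = range(matching.n_fruits)
    else:
        idx = [i for i, s in enumerate(matching.fruit_stages) if s == stage_filter]
    total = len(list(idx))
    if total == 0:
        raise ZeroDivisionError("recall undefined: no ground-truth fruits")
    matched = matching.matched_fruits
    if stage_filter is None:
        hit = len(matched)
    else:
        hit = sum(1 for i, s in enumerate(matching.fruit_stages)
                  if s == stage_filter and i in matched)
    return hit / total


def precision(matching: Matching) -> float:
    """Relevant (matched) detections ÷ all detections."""
    if matching.n_detections == 0:
        raise ZeroDivisionError("precision undefined: no detections")
    return len(matching.matched_detections) / matching.n_detections


def evaluate_detections(
    dets: list[FruitDetection], truth: list[GroundTruthFruit]
) -> DetectionReport:
    """Match and summarize into a report (absent metrics stay ``None``)."""
    m = match_detections(dets, truth)
    by_stage: dict[str, float | None] = {}
    n_stage: dict[str, int] = {}
    for s in STAGES:
        n = sum(1 for st in m.fruit_stages if st == s)
        n_stage[s] = n
        by_stage[s] = recall(m, s) if n else None
    return DetectionReport(
        recall_by_stage=by_stage,
        n_by_stage=n_stage,
        overall_recall=recall(m) if m.n_fruits else None,
        precision=precision(m) if m.n_detections else None,
        n_fruits=m.n_fruits,
        n_detections=m.n_detections,
        n_matched=len(m.pairs),
        false_positives=sorted(set(range(m.n_detections)) - m.matched_detections),
        false_negatives=sorted(set(range(m.n_fruits)) - m.matched_fruits),
    )


def partition_parts(
    image: np.ndarray,
    truth: list[GroundTruthFruit],
    cut_rows: tuple[int, int],
) -> list[tuple[np.ndarray, list[GroundTruthFruit]]]:
    """Split an image vertically into top / middle / bottom sub-scenes.

    Rows [0, r1), [r1, r2), [r2, H) — half-open intervals; each fruit is
    assigned to the part containing its centroid row, with coordinates
    shifted into the crop frame.
    """
    h = image.shape[0]
    r1, r2 = cut_rows
    if not (0 < r1 < r2 < h):
        raise ValueError(f"invalid cut rows {cut_rows} for height {h}")
    bounds = [(0, r1), (r1, r2), (r2, h)]
    parts: list[tuple[np.ndarray, list[GroundTruthFruit]]] = []
    for lo, hi in bounds:
        sub_truth = [
            GroundTruthFruit(
                centroid=(f.centroid[0] - lo, f.centroid[1]),
                radius=f.radius, stage=f.stage, truss=f.truss,
            )
            for f in truth
            if lo <= f.centroid[0] < hi
        ]
        parts.append((image[lo:hi].copy(), sub_truth))
    return parts
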