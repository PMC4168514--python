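"""File formats: RGB images, indexed-PNG class maps, CSV truth/detections."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from tomatodetect.evaluation import GroundTruthFruit
from tomatodetect.fruit_localization import FruitDetection
from tomatodetect.pixel_segmentation import CLASS_NAMES

# palette for indexed class-map PNGs: background, fruit, leaf, stem
_PALETTE = [0, 0, 0, 220, 40, 40, 40, 180, 60, 150, 120, 60]

DETECTION_COLUMNS = ["image_id", "row", "col", "source", "blob_id"]
TRUTH_COLUMNS = ["image_id", "row", "col", "radius", "stage"]


def load_rgb(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF as an 8-bit H×W×3 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_rgb(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def save_classmap(path: str | Path, classmap: np.ndarray) -> None:
    """Write a class map as an indexed PNG (codes 0–3)."""
    im = Image.fromarray(np.asarray(classmap, dtype=np.uint8), mode="P")
    im.putpalette(_PALETTE)
    im.save(path)

def load_classmap(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im if im.mode == "P" else im.convert("L"))
    if arr.max() >= len(CLASS_NAMES):
        raise ValueError(f"{path}: class codes exceed {len(CLASS_NAMES) - 1}")
    return arr.astype(np.uint8)


def save_detections(path: str | Path, dets: list[FruitDetection], image_id: str) -> None:
    pd.DataFrame(
        [
            {"image_id": image_id, "row": d.position[0], "col": d.position[1],
             "source": d.source, "blob_id": d.blob_id}
            for d in dets
        ],
        columns=DETECTION_COLUMNS,
    ).to_csv(path, index=False)


def load_detections(path: str | Path) -> dict[str, list[FruitDetection]]:
    df = pd.read_csv(path)
    out: dict[str, list[FruitDetection]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["image_id"]), []).append(
            FruitDetection(position=(float(row["row"]), float(row["col"])),
                           source=str(row["source"]),
                           blob_id=None if pd.isna(row["blob_id"]) else int(row["blob_id"]))
        )
    return out


def save_truth_csv(path: str | Path, fruits: list[GroundTruthFruit], image_id: str) -> None:
    pd.DataFrame(
        [
            {"image_id": image_id, "row": f.centroid[0], "col": f.centroid[1],
             "radius": f.radius, "stage": f.stage}
            for f in fruits
        ],
        columns=TRUTH_COLUMNS,
    ).to_csv(path, index=False)


def load_truth_csv(path: str | Path) -> dict[str, list[GroundTruthFruit]]:
    df = pd.read_csv(path)
    out: dict[str, list[GroundTruthFruit]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["image_id"]), []).append(
            GroundTruthFruit(centroid=(float(row["row"]), float(row["col"])),
                             radius=float(row["radius"]), stage=str(row["stage"]))
        )
    return out
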