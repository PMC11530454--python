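"""Round-trip loading of a generated study directory (manifest + rasters +
ground truth + annotations) back into a StudyDataset."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .datamodel import CellObject, ImagePair, StudyConfig, StudyDataset
from .io import read_annotations, read_manifest


def load_study(datadir: str | Path) -> StudyDataset:
    datadir = Path(datadir)
    manifest = read_manifest(datadir / "manifest.json")
    with open(datadir / manifest["ground_truth"]) as fh:
        gt = json.load(fh)
    from PIL import Image

    images = []
    for entry in manifest["images"]:
        image_id = entry["image_id"]
        cells = [CellObject(id=c["id"], x=c["x"], y=c["y"], phase=c["phase"],
                            he_visible=c["he_visible"],
                            phh3_positive=c["phh3_positive"],
                            phh3_intensity=c.get("phh3_intensity", 0.0))
                 for c in gt[image_id]]
        if "he" in entry:
            he = np.asarray(Image.open(datadir / entry["he"]))
            phh3 = np.asarray(Image.open(datadir / entry["phh3"]))
        else:
            he = np.zeros((1, 1, 3), dtype=np.uint8)
            phh3 = he.copy()
        images.append(ImagePair(image_id=image_id, he_image=he, phh3_image=phh3,
                                mpp=manifest["mpp"], cells=cells))
    annotations = read_annotations(datadir / "annotations.jsonl")
    raters = sorted({a.rater_id for a in annotations})
    config = StudyConfig(n_images=len(images),
                         image_size_px=max(images[0].he_image.shape[0], 1),
                         mpp=manifest["mpp"], n_raters=max(len(raters), 1))
    return StudyDataset(config=config, images=images, annotations=annotations,
                        profiles=[])
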