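"""File formats: multi-page TIFF cubes with JSON sidecars, PNG masks, CSVs.

An ``MsiCube`` is stored as a multi-page TIFF with one page per channel in
roster-major channel order, next to a JSON sidecar listing per-channel
metadata (channel id, illuminant, sensor) and the acquisition parameters.
Foreground masks are 8-bit PNGs (0 = background, 255 = foreground).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .radiometry import all_channel_ids
from .synthetic import ForegroundMask, MsiCube


def save_cube(cube: MsiCube, mask: ForegroundMask, path_base: str | Path) -> dict:
    """Write ``<base>.tiff``, ``<base>.json`` and ``<base>_mask.png``.

    Returns the mapping of artifact kinds to paths.
    """
    base = Path(path_base)
    base.parent.mkdir(parents=True, exist_ok=True)
    tiff_path = base.with_suffix(".tiff")
    # pages in channel order
    pages = np.moveaxis(np.asarray(cube.pixels), -1, 0)
    tifffile.imwrite(tiff_path, pages, photometric="minisblack")
    channels = [
        {"index": i, "channel_id": cid,
         "illuminant": cid.split(":")[0], "sensor": cid.split(":")[1]}
        for i, cid in enumerate(all_channel_ids())
    ]
    sidecar = {
        "specimen_id": cube.specimen_id,
        "class_label": cube.class_label,
        "scene_id": cube.scene_id,
        "channels": channels,
        **cube.meta,
    }
    json_path = base.with_suffix(".json")
    json_path.write_text(json.dumps(sidecar, indent=2))
    mask_path = base.parent / f"{base.name}_mask.png"
    Image.fromarray((mask.mask * 255).astype(np.uint8), mode="L").save(mask_path)
    return {"tiff": tiff_path, "sidecar": json_path, "mask": mask_path}


def load_cube(path_base: str | Path) -> tuple[MsiCube, ForegroundMask]:
    base = Path(path_base)
    pages = tifffile.imread(base.with_suffix(".tiff"))
    sidecar = json.loads(base.with_suffix(".json").read_text())
    pixels = np.moveaxis(pages, 0, -1)
    meta = {k: v for k, v in sidecar.items()
            if k not in ("specimen_id", "class_label", "scene_id", "channels")}
    cube = MsiCube(pixels=pixels, specimen_id=sidecar["specimen_id"],
                   class_label=sidecar["class_label"], scene_id=sidecar["scene_id"],
                   meta=meta)
    mask_img = Image.open(base.parent / f"{base.name}_mask.png")
    mask = ForegroundMask(mask=np.asarray(mask_img) > 127)
    return cube, mask


def write_manifest(records: Iterable[dict], path: str | Path) -> pd.DataFrame:
    """Dataset manifest CSV: scene_id, specimen_id, split, class_label, paths."""
    df = pd.DataFrame(list(records))
    df.to_csv(path, index=False)
    return df
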