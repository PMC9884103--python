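"""Foreground-only 32 x 32 patch extraction and leakage-free splits.

Scenes are tiled on a fixed grid anchored at pixel (0, 0) into contiguous,
non-overlapping 32 x 32 tiles (row-major; partial tiles at the right/bottom
edges are discarded).  A tile is kept only if every one of its 1024 mask
pixels is tissue foreground — patches touching any background are omitted.
Patches are routed into train/validation/test splits by specimen id so that
no specimen contributes to more than one split, and per-channel
normalization statistics are computed from training patches only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .radiometry import ILLUMINANT_ROSTER, SENSOR_ROSTER, all_channel_ids, channel_index
from .synthetic import ForegroundMask, MsiCube, SceneRecord

logger = logging.getLogger(__name__)

PATCH = 32
SPLITS = ("train", "validation", "test")

#: Named channel views.  ``rgb3`` is the broadband-white RGB triplet (the
#: non-multispectral baseline); ``msi18`` drops the UV triplet, whose light
#: the blocked sensor cannot detect; ``msi21`` is the full channel set.
CHANNEL_VIEWS: dict[str, list[int]] = {
    "rgb3": [channel_index("arri_white", s) for s in SENSOR_ROSTER],
    "msi18": [channel_index(il, s) for il in ILLUMINANT_ROSTER if il != "uv405"
              for s in SENSOR_ROSTER],
    "msi21": list(range(21)),
}


def view_channel_ids(view: str | Sequence[int]) -> list[str]:
    ids = all_channel_ids()
    return [ids[i] for i in resolve_view(view)]


def resolve_view(view: str | Sequence[int]) -> list[int]:
    """Channel indices for a named view or an explicit custom subset."""
    if isinstance(view, str):
        try:
            return list(CHANNEL_VIEWS[view])
        except KeyError:
            raise ValueError(f"unknown channel view {view!r}") from None
    idx = [int(i) for i in view]
    if len(idx) == 0:
        raise ValueError("channel subset must be non-empty")
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate channel indices in custom view")
    if any(i < 0 or i >= 21 for i in idx):
        raise ValueError("channel index out of range [0, 21)")
    return idx


def tile_foreground_patches(
    cube: MsiCube, mask: ForegroundMask
) -> tuple[np.ndarray, np.ndarray]:
    """Extract all-foreground 32 x 32 tiles from one scene.

    Returns ``(patches, coords)`` where ``patches`` is (N, 32, 32, 21) in the
    cube dtype and ``coords`` is (N, 2) tile-grid (row, col) origins in units
    of 32 pixels.  Tiles are scanned row-major from origin (0, 0); a tile is
    kept iff all of its mask pixels are foreground.
    """
    pix = cube.pixels
    m = mask.mask
    if pix.shape[:2] != m.shape:
        raise ValueError(f"cube {pix.shape[:2]} and mask {m.shape} shapes differ")
    H, W = m.shape
    nrow, ncol = H // PATCH, W // PATCH
    if nrow == 0 or ncol == 0 or not m.any():
        return (np.empty((0, PATCH, PATCH, pix.shape[2]), dtype=pix.dtype),
                np.empty((0, 2), dtype=int))
    # all-foreground test per tile via a block reduction of the mask
    blocks = m[:nrow * PATCH, :ncol * PATCH].reshape(nrow, PATCH, ncol, PATCH)
    keep = blocks.all(axis=(1, 3))
    rows, cols = np.nonzero(keep)
    if rows.size == 0:
        return (np.empty((0, PATCH, PATCH, pix.shape[2]), dtype=pix.dtype),
                np.empty((0, 2), dtype=int))
    patches = np.stack(
        [pix[r * PATCH:(r + 1) * PATCH, c * PATCH:(c + 1) * PATCH, :]
         for r, c in zip(rows, cols)], axis=0)
    return patches, np.column_stack([rows, cols])


@dataclass
class SplitAssignment:
    """Map specimen_id -> split; each specimen belongs to exactly one split."""

    assignment: Mapping[str, str]

    def __post_init__(self) -> None:
        for spec_id, split in self.assignment.items():
            if split not in SPLITS:
                raise ValueError(f"unknown split {split!r} for specimen {spec_id!r}")

    def split_of(self, specimen_id: str) -> str:
        try:
            return self.assignment[specimen_id]
        except KeyError:
            raise ValueError(f"specimen {specimen_id!r} has no split assignment") from None


@dataclass
class PatchSplit:
    """All patches of one split: raw counts plus provenance arrays."""

    patches: np.ndarray  # (N, 32, 32, C) raw counts
    labels: np.ndarray  # (N,) integer class labels
    specimen_ids: np.ndarray  # (N,) strings
    scene_ids: np.ndarray  # (N,) strings
    coords: np.ndarray  # (N, 2) tile-grid origins

    def __len__(self) -> int:
        return int(self.labels.size)


@dataclass
class PatchDataset:
    """Patch splits with train-only normalization statistics.

    ``channel_mean``/``channel_sd`` are per-channel scalars computed over all
    pixels of all *training* patches; validation and test patches never enter
    the statistics.  ``normalize`` maps raw counts to the z-scored input
    space the classifier consumes.
    """

    splits: dict[str, PatchSplit]
    class_names: tuple[str, ...]
    view: str | tuple[int, ...] = "msi21"
    channel_indices: tuple[int, ...] = tuple(range(21))
    channel_mean: np.ndarray | None = None
    channel_sd: np.ndarray | None = None
    normalized: bool | str = True

    @property
    def n_channels(self) -> int:
        return len(self.channel_indices)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def normalization_mode(self) -> str:
        """One of ``zscore`` (per-channel), ``global`` (one shared scale,
        preserving relative channel amplitudes) or ``none`` (raw counts)."""
        if self.normalized is True:
            return "zscore"
        if self.normalized is False:
            return "none"
        if self.normalized in ("zscore", "global", "none"):
            return self.normalized
        raise ValueError(f"unknown normalization mode {self.normalized!r}")

    def compute_normalization(self) -> None:
        train = self.splits["train"]
        if len(train) == 0:
            raise ValueError("cannot compute normalization from an empty train split")
        x = train.patches.astype(np.float64)
        if self.normalization_mode == "global":
            # one scale for all channels: conditioning without re-weighting
            # dim channels relative to bright ones
            sd = float(x.std())
            self.channel_mean = np.zeros(x.shape[-1])
            self.channel_sd = np.full(x.shape[-1], sd if sd > 0 else 1.0)
        else:
            self.channel_mean = x.mean(axis=(0, 1, 2))
            sd = x.std(axis=(0, 1, 2))
            self.channel_sd = np.where(sd > 0, sd, 1.0)

    def normalize(self, patches: np.ndarray) -> np.ndarray:
        """Raw counts -> model input space (train statistics only)."""
        x = patches.astype(np.float32)
        if self.normalization_mode == "none":
            return x
        if self.channel_mean is None:
            raise ValueError("normalization statistics not computed")
        return (x - self.channel_mean.astype(np.float32)) / self.channel_sd.astype(np.float32)

    def model_inputs(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        s = self.splits[split]
        return self.normalize(s.patches), s.labels

    def counts_table(self) -> pd.DataFrame:
        """Patches per class per split (one row per class, plus totals)."""
        rows = []
        for k, name in enumerate(self.class_names):
            row = {"class": name}
            for split in SPLITS:
                row[split] = int((self.splits[split].labels == k).sum())
            rows.append(row)
        df = pd.DataFrame(rows)
        total = {"class": "total", **{s: int(df[s].sum()) for s in SPLITS}}
        return pd.concat([df, pd.DataFrame([total])], ignore_index=True)

    def select_channels(self, view: str | Sequence[int]) -> "PatchDataset":
        """A view of this dataset restricted to a channel subset.

        Channel order is preserved.  Works on a dataset holding the full
        21-channel patches; normalization statistics are recomputed for the
        view (still train-only).
        """
        if self.n_channels != 21:
            raise ValueError("select_channels expects the full 21-channel dataset")
        idx = resolve_view(view)
        splits = {
            name: PatchSplit(
                patches=s.patches[..., idx],
                labels=s.labels,
                specimen_ids=s.specimen_ids,
                scene_ids=s.scene_ids,
                coords=s.coords,
            )
            for name, s in self.splits.items()
        }
        ds = PatchDataset(splits=splits, class_names=self.class_names,
                          view=view if isinstance(view, str) else tuple(idx),
                          channel_indices=tuple(idx), normalized=self.normalized)
        if len(ds.splits["train"]) > 0:
            ds.compute_normalization()
        return ds

    def describe(self) -> dict:
        return {
            "view": self.view if isinstance(self.view, str) else list(self.view),
            "channel_indices": list(self.channel_indices),
            "channel_ids": [all_channel_ids()[i] for i in self.channel_indices],
            "n_channels": self.n_channels,
            "normalized": self.normalized,
            "counts": {s: len(self.splits[s]) for s in SPLITS},
        }


def assemble_splits(
    scenes: Iterable[SceneRecord],
    class_names: Sequence[str],
    assignment: SplitAssignment | None = None,
    normalized: bool | str = True,
) -> PatchDataset:
    """Tile every scene and route its patches by specimen into splits.

    With ``assignment=None`` the split recorded on each scene is used (the
    generator already assigns specimens to splits disjointly); an explicit
    ``SplitAssignment`` overrides it.  A specimen appearing in two splits is
    an error.  Consumes the scene iterable lazily, so it pairs with the
    generator without holding all cubes in memory.
    """
    class_names = tuple(class_names)
    class_to_idx = {c: k for k, c in enumerate(class_names)}
    buf: dict[str, dict[str, list]] = {
        s: {"patches": [], "labels": [], "specimen_ids": [], "scene_ids": [], "coords": []}
        for s in SPLITS}
    seen_split_of: dict[str, str] = {}
    n_channels = None
    for rec in scenes:
        split = assignment.split_of(rec.specimen_id) if assignment else rec.split
        prev = seen_split_of.setdefault(rec.specimen_id, split)
        if prev != split:
            raise ValueError(
                f"specimen {rec.specimen_id!r} assigned to both {prev!r} and {split!r}")
        patches, coords = tile_foreground_patches(rec.cube, rec.mask)
        n_channels = patches.shape[-1]
        n = patches.shape[0]
        if n == 0:
            logger.warning("scene %s yielded no all-foreground patches", rec.scene_id)
            continue
        b = buf[split]
        b["patches"].append(patches)
        b["labels"].append(np.full(n, class_to_idx[rec.class_label], dtype=np.int64))
        b["specimen_ids"].append(np.full(n, rec.specimen_id, dtype=object))
        b["scene_ids"].append(np.full(n, rec.scene_id, dtype=object))
        b["coords"].append(coords)
    splits = {}
    for s, b in buf.items():
        if b["patches"]:
            splits[s] = PatchSplit(
                patches=np.concatenate(b["patches"], axis=0),
                labels=np.concatenate(b["labels"]),
                specimen_ids=np.concatenate(b["specimen_ids"]),
                scene_ids=np.concatenate(b["scene_ids"]),
                coords=np.concatenate(b["coords"], axis=0),
            )
        else:
            c = n_channels or 21
            splits[s] = PatchSplit(
                patches=np.empty((0, PATCH, PATCH, c)), labels=np.empty(0, np.int64),
                specimen_ids=np.empty(0, object), scene_ids=np.empty(0, object),
                coords=np.empty((0, 2), int))
    # leakage check: specimen sets pairwise disjoint
    sets = {s: set(splits[s].specimen_ids.tolist()) for s in SPLITS}
    for a in SPLITS:
        for b_ in SPLITS:
            if a < b_ and sets[a] & sets[b_]:
                raise ValueError(f"specimens {sets[a] & sets[b_]} appear in both "
                                 f"{a!r} and {b_!r}")
    ds = PatchDataset(splits=splits, class_names=class_names, normalized=normalized,
                      view="msi21" if (n_channels or 21) == 21 else tuple(range(n_channels)),
                      channel_indices=tuple(range(n_channels or 21)))
    if len(splits["train"]) > 0:
        ds.compute_normalization()
    return ds


def save_patch_dataset(ds: PatchDataset, out_dir: str | Path) -> None:
    """One binary container per split plus a JSON descriptor and counts CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in SPLITS:
        sp = ds.splits[s]
        np.savez_compressed(
            out / f"patches_{s}.npz", patches=sp.patches, labels=sp.labels,
            specimen_ids=sp.specimen_ids.astype(str), scene_ids=sp.scene_ids.astype(str),
            coords=sp.coords)
    desc = ds.describe()
    desc["class_names"] = list(ds.class_names)
    if ds.channel_mean is not None:
        desc["channel_mean"] = ds.channel_mean.tolist()
        desc["channel_sd"] = ds.channel_sd.tolist()
    (out / "descriptor.json").write_text(json.dumps(desc, indent=2))
    ds.counts_table().to_csv(out / "patch_counts.csv", index=False)


def load_patch_dataset(out_dir: str | Path) -> PatchDataset:
    out = Path(out_dir)
    desc = json.loads((out / "descriptor.json").read_text())
    splits = {}
    for s in SPLITS:
        z = np.load(out / f"patches_{s}.npz", allow_pickle=False)
        splits[s] = PatchSplit(
            patches=z["patches"], labels=z["labels"],
            specimen_ids=z["specimen_ids"].astype(object),
            scene_ids=z["scene_ids"].astype(object), coords=z["coords"])
    view = desc["view"]
    ds = PatchDataset(
        splits=splits, class_names=tuple(desc["class_names"]),
        view=view if isinstance(view, str) else tuple(view),
        channel_indices=tuple(desc["channel_indices"]),
        normalized=desc["normalized"])
    if "channel_mean" in desc:
        ds.channel_mean = np.asarray(desc["channel_mean"])
        ds.channel_sd = np.asarray(desc["channel_sd"])
    return ds
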