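"""Plate-manifest I/O, well-based partitioning and image batch loading.

A plate manifest is a CSV with columns ``path,well,frame,time_h,
temperature_c,hpf`` (one row per image; ``hpf`` is the training label).
Partitioning is done on a well-by-well basis so that all frames of one
embryo land on the same side of the train/test split — splitting frames of
the same embryo across sets would leak near-duplicate images.  Wells listed
in an exclusion file (dead or out-of-view embryos in the real experiment)
are removed before splitting.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["path", "well", "frame", "time_h", "temperature_c", "hpf"]

__all__ = [
    "SplitSpec",
    "load_manifest",
    "read_exclusion_list",
    "partition_by_well",
    "load_image",
    "load_batch",
    "MANIFEST_COLUMNS",
]


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.5
    excluded_wells: frozenset[str] = field(default_factory=frozenset)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )


def load_manifest(path: str | os.PathLike, check_files: bool = True) -> pd.DataFrame:
    """Load a plate manifest CSV; image paths are resolved relative to it.

    Rows whose image file is missing are dropped with a logged warning.
    Raises ``ValueError`` on a malformed header, an empty manifest,
    negative labels, empty well ids or duplicate (well, frame) pairs.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"well": str})
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest {path} missing columns: {missing_cols}")
    if len(df) == 0:
        raise ValueError(f"manifest {path} is empty")
    df = df[MANIFEST_COLUMNS].copy()
    df["path"] = [str((path.parent / p).resolve()) for p in df["path"]]
    if (df["hpf"] < 0).any():
        raise ValueError("negative hpf label in manifest")
    if (df["well"].str.len() == 0).any() or df["well"].isna().any():
        raise ValueError("empty well id in manifest")
    if df.duplicated(subset=["well", "frame"]).any():
        raise ValueError("duplicate (well, frame) pairs in manifest")
    if check_files:
        exists = df["path"].map(os.path.isfile)
        for p in df.loc[~exists, "path"]:
            logger.warning("dropping manifest row, image not found: %s", p)
        df = df[exists].reset_index(drop=True)
        if len(df) == 0:
            raise ValueError(f"manifest {path}: no image file could be found")
    return df


def read_exclusion_list(path: str | os.PathLike) -> frozenset[str]:
    """Read well ids to exclude, one per line; blank lines and # comments ignored."""
    wells = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            wells.add(line)
    return frozenset(wells)


def partition_by_well(
    manifest: pd.DataFrame, split: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a manifest into disjoint train/test manifests by whole wells.

    Excluded wells appear in neither output.  The number of training wells
    is ``round(train_fraction * n_wells)`` clamped so both sides keep at
    least one well.  Deterministic given ``split.seed``.
    """
    wells = sorted(set(manifest["well"]) - set(split.excluded_wells))
    if len(wells) < 2:
        raise ValueError(
            f"need at least 2 non-excluded wells to partition, have {len(wells)}"
        )
    rng = np.random.default_rng(split.seed)
    order = rng.permutation(len(wells))
    n_train = int(round(split.train_fraction * len(wells)))
    n_train = min(max(n_train, 1), len(wells) - 1)
    train_wells = {wells[i] for i in order[:n_train]}
    test_wells = {wells[i] for i in order[n_train:]}
    train = manifest[manifest["well"].isin(train_wells)].reset_index(drop=True)
    test = manifest[manifest["well"].isin(test_wells)].reset_index(drop=True)
    return train, test


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read one image as float32 (H, W, 3) on [0, 1].

    Integer images are divided by their dtype max, so an 8-bit and a 16-bit
    export of the same scene load identically.  Grayscale images are
    replicated to three channels so channel-wise operations (e.g. the
    saturation augmentation) are well defined.
    """
    try:
        img = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt file, unknown format
        raise IOError(f"could not read image {path}: {exc}") from exc
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(np.float32) / np.iinfo(img.dtype).max
    else:
        img = img.astype(np.float32)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    elif img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[:, :, :3]
    elif img.ndim == 3 and img.shape[2] == 1:
        img = np.repeat(img, 3, axis=2)
    return img


def load_batch(
    records: pd.DataFrame, target_height: int, target_width: int
) -> tuple[np.ndarray, np.ndarray]:
    """Load manifest rows into an (N, H, W, 3) float32 batch plus hpf labels.

    Images are resized to the target shape by direct bilinear interpolation
    (no padding), preserving row order.
    """
    from skimage.transform import resize

    images = np.empty((len(records), target_height, target_width, 3), dtype=np.float32)
    for i, p in enumerate(records["path"]):
        if not os.path.isfile(p):
            raise IOError(f"image file not found: {p}")
        img = load_image(p)
        if img.shape[:2] != (target_height, target_width):
            img = resize(
                img,
                (target_height, target_width),
                order=1,
                preserve_range=True,
                anti_aliasing=False,
            ).astype(np.float32)
        images[i] = img
    labels = records["hpf"].to_numpy(dtype=np.float32)
    return images, labels
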