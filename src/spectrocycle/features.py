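"""Per-cell quantitative features: spectra, histograms, texture.

Turns (stack, mask) pairs into the cells x features table the classifiers
consume.  For a C-channel stack the default inventory is C channel means,
C(C,2) unordered channel-intensity ratios, and per-channel standard
deviation, skewness, GLCM entropy and GLCM homogeneity -- 731 features for
the 34-channel layout -- plus ``line`` and ``phase`` metadata columns.

Conventions fixed here for reproducibility: biased (population) moments;
grey-level co-occurrence on per-cell min-max quantisation to 32 levels,
counting only pixel pairs with both members inside the cell mask,
symmetrised and averaged over the four unit offsets.  Consequently scaling
all pixel values by k > 0 scales means and standard deviations by k and
leaves ratios, skewness, entropy and homogeneity unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stack import MultispectralStack

__all__ = [
    "CellImage",
    "MIN_CELL_PIXELS",
    "DEFAULT_GLCM_LEVELS",
    "DEFAULT_GLCM_OFFSETS",
    "extract_cells",
    "mean_intensities",
    "intensity_ratios",
    "histogram_stats",
    "texture_stats",
    "build_feature_table",
    "feature_names",
]

MIN_CELL_PIXELS = 20
DEFAULT_GLCM_LEVELS = 32
DEFAULT_GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class CellImage:
    """One segmented cell: masked pixel vectors plus its bounding-box image."""

    cell_id: int
    pixels: np.ndarray  # (n_px, C)
    image: np.ndarray  # (h, w, C) bounding-box crop
    mask: np.ndarray  # (h, w) bool

    def __post_init__(self) -> None:
        if self.pixels.shape[0] < MIN_CELL_PIXELS:
            raise ValueError(
                f"cell {self.cell_id} has {self.pixels.shape[0]} pixels, "
                f"minimum is {MIN_CELL_PIXELS}")


def extract_cells(
    stack: MultispectralStack, labels: np.ndarray, min_pixels: int = MIN_CELL_PIXELS
) -> list[CellImage]:
    """Split a labelled stack into per-cell images (cells < min_pixels dropped)."""
    cells = []
    for cell_id in np.unique(labels):
        if cell_id == 0:
            continue
        mask = labels == cell_id
        if mask.sum() < min_pixels:
            continue
        rows, cols = np.nonzero(mask)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        crop_mask = mask[r0:r1, c0:c1]
        crop = stack.pixels[r0:r1, c0:c1, :].astype(float)
        cells.append(
            CellImage(
                cell_id=int(cell_id),
                pixels=stack.pixels[rows, cols, :].astype(float),
                image=crop,
                mask=crop_mask,
            )
        )
    return cells


def mean_intensities(cell: CellImage) -> np.ndarray:
    """Arithmetic mean of masked pixels per channel."""
    return cell.pixels.mean(axis=0)


def intensity_ratios(
    means: np.ndarray,
    pairs: list[tuple[int, int]] | None = None,
    floor: float = 1e-6,
) -> np.ndarray:
    """Channel-intensity ratios mean_i / max(mean_j, floor).

    Defaults to all unordered pairs (i < j), avoiding duplicated reciprocal
    information; the floor keeps ratios finite.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    means = np.asarray(means, dtype=float)
    if pairs is None:
        pairs = default_ratio_pairs(len(means))
    return np.array(
        [means[i] / max(means[j], floor) for i, j in pairs], dtype=float)


def default_ratio_pairs(n_channels: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n_channels) for j in range(i + 1, n_channels)]


def histogram_stats(cell: CellImage) -> tuple[np.ndarray, np.ndarray]:
    """Population standard deviation and Fisher-Pearson skewness per channel.

    Skewness is defined as 0 for (near-)constant channels.
    """
    x = cell.pixels
    mu = x.mean(axis=0)
    d = x - mu
    m2 = (d**2).mean(axis=0)
    m3 = (d**3).mean(axis=0)
    std = np.sqrt(m2)
    skew = np.zeros_like(m2)
    ok = m2 >= 1e-12
    skew[ok] = m3[ok] / m2[ok] ** 1.5
    return std, skew


def _cooccurrence(
    q: np.ndarray, mask: np.ndarray, offset: tuple[int, int], levels: int
) -> np.ndarray:
    """Symmetric pair-count matrix for one offset, masked pixels only."""
    dr, dc = offset
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    ma = mask[r0:r1, c0:c1]
    mb = mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    both = ma & mb
    counts = np.bincount(
        (a[both] * levels + b[both]).ravel(), minlength=levels * levels
    ).reshape(levels, levels).astype(float)
    return counts + counts.T


def _quantise(vals: np.ndarray, levels: int) -> np.ndarray:
    lo, hi = vals.min(), vals.max()
    if hi - lo < 1e-12:
        return np.zeros(vals.shape, dtype=np.int64)
    q = np.floor((vals - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def texture_stats(
    cell: CellImage,
    levels: int = DEFAULT_GLCM_LEVELS,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_GLCM_OFFSETS,
) -> tuple[np.ndarray, np.ndarray]:
    """GLCM entropy and homogeneity per channel.

    Per channel the masked pixels are quantised to ``levels`` equal-width
    bins over the cell's own min-max range; the co-occurrence matrix counts
    only pairs with both pixels in the mask, is symmetrised, normalised per
    offset and averaged over offsets.  Entropy is -sum p log2 p over nonzero
    entries; homogeneity is sum p / (1 + |i - j|).
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    n_chan = cell.image.shape[2]
    entropy = np.empty(n_chan)
    homogeneity = np.empty(n_chan)
    i_idx, j_idx = np.meshgrid(
        np.arange(levels), np.arange(levels), indexing="ij")
    inv_dist = 1.0 / (1.0 + np.abs(i_idx - j_idx))
    for c in range(n_chan):
        img = cell.image[:, :, c]
        q = np.zeros(img.shape, dtype=np.int64)
        q[cell.mask] = _quantise(img[cell.mask], levels)
        mats = []
        total_pairs = 0.0
        for off in offsets:
            m = _cooccurrence(q, cell.mask, off, levels)
            s = m.sum()
            total_pairs += s / 2.0
            if s > 0:
                mats.append(m / s)
        if total_pairs < 2:
            raise ValueError("cell too small for texture")
        p = np.mean(mats, axis=0)
        nz = p[p > 0]
        entropy[c] = float(-(nz * np.log2(nz)).sum())
        homogeneity[c] = float((p * inv_dist).sum())
    return entropy, homogeneity


def feature_names(n_channels: int) -> list[str]:
    """Deterministic column order of the feature table."""
    names = [f"mean_c{c:02d}" for c in range(n_channels)]
    names += [f"ratio_c{i:02d}_c{j:02d}"
              for i, j in default_ratio_pairs(n_channels)]
    for prefix in ("std", "skew", "entropy", "homog"):
        names += [f"{prefix}_c{c:02d}" for c in range(n_channels)]
    return names


def cell_features(cell: CellImage, floor: float = 1e-6) -> np.ndarray:
    means = mean_intensities(cell)
    ratios = intensity_ratios(means, floor=floor)
    std, skew = histogram_stats(cell)
    entropy, homog = texture_stats(cell)
    return np.concatenate([means, ratios, std, skew, entropy, homog])


def build_feature_table(
    stacks: list[MultispectralStack],
    masks: list[np.ndarray],
    truth: pd.DataFrame,
    min_pixels: int = MIN_CELL_PIXELS,
) -> pd.DataFrame:
    """One row per cell (>= ``min_pixels`` px), labels joined from truth.

    The truth table must contain ``cell_id``, ``line`` and ``phase`` for
    every mask label; unknown ids raise.  Output columns: features in
    deterministic order, then ``line`` and ``phase``; index is ``cell_id``.
    """
    labels_by_id = truth.set_index("cell_id")
    rows, ids = [], []
    for stack, mask in zip(stacks, masks):
        for cell in extract_cells(stack, mask, min_pixels):
            rows.append(cell_features(cell))
            ids.append(cell.cell_id)
    missing = [i for i in ids if i not in labels_by_id.index]
    if missing:
        raise KeyError(f"mask ids missing from truth table: {missing}")
    n_chan = stacks[0].n_channels
    table = pd.DataFrame(np.array(rows), columns=feature_names(n_chan))
    table.index = pd.Index(ids, name="cell_id")
    table["line"] = labels_by_id.loc[ids, "line"].to_numpy()
    table["phase"] = labels_by_id.loc[ids, "phase"].to_numpy()
    if table.isna().any().any():
        raise ValueError("feature table contains missing values")
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature (non-metadata) columns of a feature table."""
    return [c for c in table.columns if c not in ("line", "phase")]
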