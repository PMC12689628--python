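"""3D cleared-hemisphere plaque and microglia quantification.

Probability maps from a pixel classifier are binarized (strictly above 0.2),
segmented into 26-connected components, summarized (voxel count, centroid,
total/mean/population-std probability), filtered (2-10000 voxels, std/mean
ratio >= 0.1, bounds inclusive), and colocalized with the binarized
microglia mask. A precomputed region-label volume stands in for atlas
registration; the alignment preprocessing chain (2x average downsampling,
intensity capping, 3D Gaussian blur with sigma 2) is provided as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
import tifffile

#: 26-connectivity structuring element (all neighbours incl. corners)
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

DEFAULT_VOXEL_SIZE = (3.0, 3.26, 3.26)  # z, y, x in micrometres


@dataclass
class ProbabilityVolume:
    """Pixel-classifier probability map on a 3D voxel grid."""

    values: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3:
            raise ValueError("probability volume must be 3D")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.values.astype(np.float32))

    @classmethod
    def from_tiff(cls, path: str | Path,
                  voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
                  ) -> "ProbabilityVolume":
        return cls(values=np.asarray(tifffile.imread(str(path)), float),
                   voxel_size=voxel_size)


@dataclass
class PlaqueCandidate:
    """One 26-connected component with its probability statistics."""

    component_id: int
    voxel_count: int
    centroid: tuple[float, float, float]
    total_prob: float
    mean_prob: float
    std_prob: float                # population standard deviation
    engulfed: bool = False
    region: str | None = None

    @property
    def std_mean_ratio(self) -> float:
        return self.std_prob / self.mean_prob


def binarize(vol: ProbabilityVolume | np.ndarray,
             threshold: float = 0.2) -> np.ndarray:
    """Binary mask of voxels with probability strictly above ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    values = vol.values if isinstance(vol, ProbabilityVolume) else np.asarray(vol)
    return values > threshold


def components26(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Label maximal 26-connected components.

    Labels are assigned 1..K in raster-scan order of each component's first
    voxel (lexicographic by z, y, x), which makes the labeling deterministic.
    """
    mask = np.asarray(mask, bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    labels, n = ndimage.label(mask, structure=STRUCT_26)
    return labels, int(n)


def candidate_stats(labels: np.ndarray, prob: ProbabilityVolume | np.ndarray
                    ) -> list[PlaqueCandidate]:
    """Per-component voxel count, centroid, and probability statistics."""
    values = prob.values if isinstance(prob, ProbabilityVolume) else np.asarray(prob, float)
    if labels.shape != values.shape:
        raise ValueError("labels and probability volume must share a grid")
    n = int(labels.max())
    if n == 0:
        return []
    ids = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones_like(values), labels, ids)
    totals = ndimage.sum_labels(values, labels, ids)
    means = totals / counts
    stds = ndimage.standard_deviation(values, labels, ids)  # population std
    centroids = ndimage.center_of_mass(np.ones_like(values), labels, ids)
    return [PlaqueCandidate(component_id=int(i), voxel_count=int(c),
                            centroid=tuple(float(v) for v in ctr),
                            total_prob=float(t), mean_prob=float(m),
                            std_prob=float(s))
            for i, c, ctr, t, m, s in zip(ids, counts, centroids, totals,
                                          means, stds)]


def filter_candidates(candidates: list[PlaqueCandidate], min_vox: int = 2,
                      max_vox: int = 10000,
                      min_ratio: float = 0.1) -> list[PlaqueCandidate]:
    """Retain candidates with min_vox <= size <= max_vox and std/mean >=
    min_ratio (all bounds inclusive)."""
    return [c for c in candidates
            if min_vox <= c.voxel_count <= max_vox
            and c.std_mean_ratio >= min_ratio]


def colocalize(plaques: list[PlaqueCandidate], labels: np.ndarray,
               microglia_mask: np.ndarray
               ) -> tuple[list[PlaqueCandidate], float]:
    """Flag plaques engulfed by microglia and compute the global overlap.

    A plaque is engulfed iff at least one of its voxels lies in the microglia
    mask. The global metric is the microglia-overlapping plaque volume as a
    fraction of the total retained plaque volume (0 when there are no
    plaques). Flags are set in place; the list is returned for convenience.
    """
    microglia_mask = np.asarray(microglia_mask, bool)
    if labels.shape != microglia_mask.shape:
        raise ValueError("labels and microglia mask must share a grid")
    if not plaques:
        return plaques, 0.0
    ids = np.array([p.component_id for p in plaques])
    overlaps = ndimage.sum_labels(microglia_mask.astype(float), labels, ids)
    total_vox = 0
    overlap_vox = 0.0
    for p, ov in zip(plaques, overlaps):
        p.engulfed = bool(ov > 0)
        total_vox += p.voxel_count
        overlap_vox += float(ov)
    return plaques, overlap_vox / total_vox


def preprocess_for_alignment(volume: np.ndarray, cap: float,
                             sigma: float = 2.0, factor: int = 2) -> np.ndarray:
    """Registration preprocessing: 2x average downsampling, intensity cap,
    isotropic 3D Gaussian blur (sigma in downsampled voxels).

    Dimensions are cropped to a multiple of ``factor`` before averaging.
    Registration itself is out of scope.
    """
    v = np.asarray(volume, float)
    if v.ndim != 3:
        raise ValueError("volume must be 3D")
    crop = tuple(s - s % factor for s in v.shape)
    if any(c == 0 for c in crop):
        raise ValueError("volume too small for the downsampling factor")
    v = v[: crop[0], : crop[1], : crop[2]]
    v = v.reshape(crop[0] // factor, factor, crop[1] // factor, factor,
                  crop[2] // factor, factor).mean(axis=(1, 3, 5))
    v = np.minimum(v, cap)
    return ndimage.gaussian_filter(v, sigma=sigma)


def region_counts(plaques: list[PlaqueCandidate], label_volume: np.ndarray,
                  regions: dict[int, str] | None = None) -> pd.Series:
    """Assign each plaque to a region by centroid lookup and count.

    ``regions`` maps integer labels to region names (e.g. hippocampal
    formation, isocortex, thalamus, ...). Label 0 — and centroids outside the
    label volume — fall into the ``unassigned`` bucket.
    """
    label_volume = np.asarray(label_volume)
    if label_volume.ndim != 3:
        raise ValueError("label volume must be 3D")
    names: dict[int, str] = dict(regions or {})
    counts: dict[str, int] = {}
    for p in plaques:
        idx = tuple(int(round(c)) for c in p.centroid)
        inside = all(0 <= i < s for i, s in zip(idx, label_volume.shape))
        lab = int(label_volume[idx]) if inside else 0
        name = names.get(lab, f"label_{lab}") if lab != 0 else "unassigned"
        p.region = name
        counts[name] = counts.get(name, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def quantify_volume(plaque_prob: ProbabilityVolume,
                    microglia_prob: ProbabilityVolume,
                    threshold: float = 0.2, min_vox: int = 2,
                    max_vox: int = 10000, min_ratio: float = 0.1,
                    label_volume: np.ndarray | None = None,
                    regions: dict[int, str] | None = None
                    ) -> tuple[list[PlaqueCandidate], float, pd.DataFrame]:
    """Full pipeline: binarize, label, summarize, filter, colocalize.

    Returns the retained plaques, the microglia-overlap volume fraction, and
    a candidate table (one row per pre-filter candidate).
    """
    if plaque_prob.values.shape != microglia_prob.values.shape:
        raise ValueError("plaque and microglia volumes must share a grid")
    labels, _ = components26(binarize(plaque_prob, threshold))
    candidates = candidate_stats(labels, plaque_prob)
    plaques = filter_candidates(candidates, min_vox, max_vox, min_ratio)
    _, fraction = colocalize(plaques, labels, binarize(microglia_prob, threshold))
    if label_volume is not None:
        region_counts(plaques, label_volume, regions)
    retained = {p.component_id for p in plaques}
    table = pd.DataFrame([{
        "id": c.component_id, "voxels": c.voxel_count,
        "centroid_z": c.centroid[0], "centroid_y": c.centroid[1],
        "centroid_x": c.centroid[2], "mean_prob": c.mean_prob,
        "std_prob": c.std_prob, "ratio": c.std_mean_ratio,
        "retained": c.component_id in retained,
        "engulfed": c.engulfed if c.component_id in retained else False,
        "region": c.region,
    } for c in candidates])
    return plaques, fraction, table
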