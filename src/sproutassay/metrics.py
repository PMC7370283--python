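"""Per-chip sprouting readouts from a segmentation.

Three readouts characterise a chip: the migration distance (mean y of the
k furthest nuclei beyond the monolayer baseline, minus the baseline), the
total sprout area (vessel-mask area beyond the baseline, counted only in
connected components that contain at least one nucleus), and the number of
nuclei within the sprouts.  The skeleton length of the vessel mask is
carried as a fourth, auxiliary readout.

The baseline (default 400 µm) is the average image y-position where the
monolayer meets the gel on negative-control chips; it is an empirical
calibration of the imaging layout and is exposed for recalibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.measure import label

from sproutassay.segmentation import SegmentationResult, skeleton_length

__all__ = [
    "SproutMetrics",
    "migration_distance",
    "total_sprout_area",
    "nuclei_in_sprouts",
    "quantify_chip",
    "estimate_baseline",
]


@dataclass(frozen=True)
class SproutMetrics:
    """Quantification record for one chip."""

    chip_id: str
    total_area: float        # µm²
    migration_distance: float  # µm
    nuclei_in_sprouts: int
    total_length: float      # µm
    n_sites: int = 1

    def __post_init__(self) -> None:
        if min(self.total_area, self.migration_distance,
               self.nuclei_in_sprouts, self.total_length) < 0:
            raise ValueError("sprouting metrics must be non-negative")


def migration_distance(
    nuclei: np.ndarray,
    baseline_y: float,
    k: int = 10,
) -> float:
    """Mean y of the k furthest nuclei beyond the baseline, minus the baseline.

    Only nuclei with y > baseline_y (i.e. inside the gel) are eligible.
    If fewer than k are eligible, all of them are averaged — a fully
    inhibited chip must still map to a finite minimum signal, so zero
    eligible nuclei give distance 0.  Ties at the k-th value are broken
    by (y, then x) ordering so the result is deterministic.
    """
    if baseline_y < 0:
        raise ValueError("baseline_y must be >= 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    pts = np.asarray(nuclei, dtype=float).reshape(-1, 2)
    beyond = pts[pts[:, 1] > baseline_y]
    if beyond.shape[0] == 0:
        return 0.0
    order = np.lexsort((beyond[:, 0], beyond[:, 1]))  # y major, x minor
    top = beyond[order][-k:]
    return max(float(top[:, 1].mean() - baseline_y), 0.0)


def _gel_component_labels(seg: SegmentationResult) -> np.ndarray:
    """Connected-component labels of the vessel mask restricted to the gel."""
    baseline_px = int(round(seg.baseline_y / seg.pixel_size))
    gel_mask = seg.vessel_mask.copy()
    gel_mask[:baseline_px, :] = False
    return label(gel_mask, connectivity=2)


def _nuclei_px(seg: SegmentationResult) -> np.ndarray:
    """Nuclei as integer (row, col) indices, clipped to the image."""
    if seg.nuclei.size == 0:
        return np.empty((0, 2), dtype=int)
    rows = np.round(seg.nuclei[:, 1] / seg.pixel_size).astype(int)
    cols = np.round(seg.nuclei[:, 0] / seg.pixel_size).astype(int)
    ny, nx = seg.vessel_mask.shape
    return np.column_stack([rows.clip(0, ny - 1), cols.clip(0, nx - 1)])


def total_sprout_area(seg: SegmentationResult) -> float:
    """Vessel area (µm²) beyond the baseline, counted only where nuclei are.

    The vessel mask is restricted to y > baseline, split into connected
    components, and only components containing at least one nucleus
    centroid contribute — debris and anucleate protrusions are excluded.
    """
    lab = _gel_component_labels(seg)
    if lab.max() == 0:
        return 0.0
    px_idx = _nuclei_px(seg)
    if px_idx.size == 0:
        return 0.0
    hit = np.unique(lab[px_idx[:, 0], px_idx[:, 1]])
    hit = hit[hit > 0]
    if hit.size == 0:
        return 0.0
    n_px = int(np.isin(lab, hit).sum())
    return n_px * seg.pixel_size**2


def nuclei_in_sprouts(seg: SegmentationResult) -> int:
    """Number of nuclei beyond the baseline that fall inside the vessel mask."""
    px_idx = _nuclei_px(seg)
    if px_idx.size == 0:
        return 0
    beyond = seg.nuclei[:, 1] > seg.baseline_y
    inside = seg.vessel_mask[px_idx[:, 0], px_idx[:, 1]]
    return int(np.count_nonzero(beyond & inside))


def quantify_chip(
    sites: Sequence[SegmentationResult],
    chip_id: str,
    k: int = 10,
) -> SproutMetrics:
    """Aggregate per-site segmentations into one chip record.

    Intensive readouts (migration distance) are averaged across sites;
    extensive ones (area, nuclei count, skeleton length) are summed.
    A single site passes through unchanged.
    """
    if len(sites) == 0:
        raise ValueError("need at least one site")
    pixel_sizes = {s.pixel_size for s in sites}
    if len(pixel_sizes) > 1:
        raise ValueError(f"sites have mismatched pixel sizes: {pixel_sizes}")
    distances = [migration_distance(s.nuclei, s.baseline_y, k) for s in sites]
    return SproutMetrics(
        chip_id=chip_id,
        total_area=float(sum(total_sprout_area(s) for s in sites)),
        migration_distance=float(np.mean(distances)),
        nuclei_in_sprouts=int(sum(nuclei_in_sprouts(s) for s in sites)),
        total_length=float(
            sum(skeleton_length(s.vessel_mask, s.pixel_size) for s in sites)
        ),
        n_sites=len(sites),
    )


def estimate_baseline(nuclei: np.ndarray, bin_um: float = 20.0) -> float:
    """Estimate the monolayer/gel boundary from the nuclei density profile.

    Returns the upper edge (µm) of the y-bin with maximal nuclei density —
    the monolayer band.  Off by default in the pipeline, which uses the
    fixed calibrated baseline; this helper supports recalibration on new
    imaging layouts.
    """
    pts = np.asarray(nuclei, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("cannot estimate a baseline without nuclei")
    y = pts[:, 1]
    bins = np.arange(0.0, y.max() + bin_um, bin_um)
    counts, edges = np.histogram(y, bins=bins)
    return float(edges[np.argmax(counts) + 1])
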