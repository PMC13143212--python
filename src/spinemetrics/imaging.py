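"""Colocalization, cluster, synapse-particle and NFAT quantification.

Implements the intensity-threshold (mean + k·s.d.) masking, Manders
overlap coefficients M1/M2, rolling-ball background subtraction, cluster
size / integrated-density statistics, an area-and-circularity particle
filter for synapse masks, and the nuclear/cytosolic NFAT translocation
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, restoration

from .images import BinaryMask, GrayscaleImage, LabelMap
from .segmentation import label_clusters


def threshold_mean_plus_ksd(image: GrayscaleImage, k: float = 2.0
                            ) -> tuple[BinaryMask, float]:
    """Mask of pixels strictly above mean + k·s.d. of the whole image.

    With a constant image the s.d. is zero and the strict inequality gives
    an empty mask.
    """
    v = image.values
    threshold = float(v.mean() + k * v.std())
    return BinaryMask(v > threshold, image.pixel_size), threshold


def manders(channel_a: GrayscaleImage, channel_b: GrayscaleImage,
            mask_a: BinaryMask, mask_b: BinaryMask) -> tuple[float, float]:
    """Manders overlap coefficients.

    M1 = fraction of channel A's above-threshold intensity lying inside
    channel B's mask; M2 symmetric. Intensity-weighted (JACoP convention),
    not pixel-counting.
    """
    if channel_a.shape != channel_b.shape:
        raise ValueError("channels must be registered to the same shape")
    a, b = channel_a.values, channel_b.values
    ma, mb = mask_a.values, mask_b.values
    sum_a = a[ma].sum()
    sum_b = b[mb].sum()
    if sum_a <= 0 or sum_b <= 0:
        raise ValueError("empty or zero-intensity mask: Manders undefined")
    m1 = a[ma & mb].sum() / sum_a
    m2 = b[ma & mb].sum() / sum_b
    return float(m1), float(m2)


def rolling_ball_subtract(image: GrayscaleImage, radius_px: int) -> GrayscaleImage:
    """Rolling-ball background subtraction.

    The radius should be set to the approximate diameter of the largest
    cluster of interest, so real structures are not absorbed into the
    background. Output clamped at zero.
    """
    if radius_px < 1:
        raise ValueError("radius must be >= 1")
    if radius_px > max(image.shape):
        raise ValueError("radius exceeds image extent")
    background = restoration.rolling_ball(image.values, radius=radius_px)
    return GrayscaleImage(np.clip(image.values - background, 0.0, None),
                          image.pixel_size)


@dataclass(frozen=True)
class ClusterStats:
    n_clusters: int
    mean_cluster_area_um2: float
    integrated_density: float
    hist_edges_um2: np.ndarray
    hist_counts: np.ndarray


def cluster_stats(image: GrayscaleImage, mask: BinaryMask,
                  bin_width_um2: float = 0.1,
                  hist_max_um2: float = 3.0) -> ClusterStats:
    """Cluster count, mean area, integrated density and area histogram.

    Clusters are the connected components of the thresholded mask;
    integrated density is the summed intensity over all above-threshold
    pixels. Histogram bins default to 0.1 µm² width over 0-3 µm² (areas
    beyond the range land in the last bin).
    """
    labeled = label_clusters(mask, connectivity=8)
    px2 = mask.pixel_size**2
    areas = np.array([n * px2 for n in labeled.island_sizes.values()])
    edges = np.arange(0.0, hist_max_um2 + bin_width_um2 / 2, bin_width_um2)
    if areas.size:
        counts, _ = np.histogram(np.clip(areas, None, edges[-1] - 1e-12), edges)
    else:
        counts = np.zeros(len(edges) - 1, dtype=int)
    return ClusterStats(
        n_clusters=labeled.n_islands,
        mean_cluster_area_um2=float(areas.mean()) if areas.size else 0.0,
        integrated_density=float(image.values[mask.values].sum()),
        hist_edges_um2=edges,
        hist_counts=counts,
    )


@dataclass(frozen=True)
class ParticleFilterSpec:
    """Area (µm²) and circularity acceptance ranges, both inclusive."""

    min_area_um2: float = 0.01
    max_area_um2: float = 5.0
    min_circularity: float = 0.1
    max_circularity: float = 1.0

    def __post_init__(self):
        if not (0 <= self.min_circularity <= self.max_circularity):
            raise ValueError("invalid circularity bounds")
        if not (0 <= self.min_area_um2 <= self.max_area_um2):
            raise ValueError("invalid area bounds")


# clockwise Moore neighbourhood (image coordinates, row axis downward)
_MOORE_CW = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))


def boundary_chain_perimeter(mask: np.ndarray) -> float:
    """Perimeter as the length of the closed 8-connected boundary pixel
    chain (Moore neighbour tracing), diagonal steps counting √2.

    The trace follows the outer contour once around, so a 1-px-wide
    filament is measured along both of its sides — which is what makes the
    circularity of a line collapse toward zero. An isolated pixel gets its
    pixel-boundary length 4.
    """
    pts = np.argwhere(mask)
    if len(pts) == 0:
        return 0.0
    if len(pts) == 1:
        return 4.0
    pixset = set(map(tuple, pts))
    start = tuple(pts[np.lexsort((pts[:, 1], pts[:, 0]))[0]])  # topmost, leftmost
    bg0 = (start[0] - 1, start[1])          # above the topmost pixel: background
    cur, bg = start, bg0
    length = 0.0
    seen_states = set()
    while True:
        idx_bg = _MOORE_CW.index((bg[0] - cur[0], bg[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            idx = (idx_bg + k) % 8
            cand = (cur[0] + _MOORE_CW[idx][0], cur[1] + _MOORE_CW[idx][1])
            if cand in pixset:
                nxt = cand
                prev_idx = (idx_bg + k - 1) % 8
                new_bg = (cur[0] + _MOORE_CW[prev_idx][0],
                          cur[1] + _MOORE_CW[prev_idx][1])
                break
        if nxt is None:                      # no neighbour: isolated pixel
            return 4.0
        length += np.hypot(nxt[0] - cur[0], nxt[1] - cur[1])
        cur, bg = nxt, new_bg
        state = (cur, bg)
        if cur == start and (state in seen_states or bg == bg0):
            break
        if state in seen_states:             # safety against cycling
            break
        seen_states.add(state)
    return float(length)


def circularity(mask: np.ndarray, method: str = "chain") -> float:
    """4π·area / perimeter², capped at 1."""
    area = float(mask.sum())
    if method == "chain":
        perim = boundary_chain_perimeter(mask)
    elif method == "crofton":
        perim = float(measure.perimeter_crofton(mask, directions=4))
    else:
        raise ValueError(f"unknown perimeter method {method!r}")
    if perim <= 0:
        return 1.0
    return min(1.0, 4.0 * np.pi * area / perim**2)


def particle_filter(labelmap: LabelMap, spec: ParticleFilterSpec,
                    perimeter_method: str = "chain") -> dict[int, float]:
    """Keep particles whose area (µm²) and circularity fall inside the
    spec ranges; returns surviving label → area in µm²."""
    px2 = labelmap.pixel_size**2
    surviving = {}
    for lab, n in labelmap.island_sizes.items():
        area = n * px2
        if not spec.min_area_um2 <= area <= spec.max_area_um2:
            continue
        circ = circularity(labelmap.labels == lab, method=perimeter_method)
        if not spec.min_circularity <= circ <= spec.max_circularity:
            continue
        surviving[lab] = area
    return surviving


def nfat_ratio(gfp: GrayscaleImage, nucleus_mask: BinaryMask,
               cytoplasm_mask: BinaryMask) -> float:
    """Nuclear/cytosolic (N/C) mean-intensity ratio of the tagged NFAT
    signal — the translocation readout."""
    nuc, cyt = nucleus_mask.values, cytoplasm_mask.values
    if (nuc & cyt).any():
        raise ValueError("nucleus and cytoplasm masks overlap")
    if not nuc.any() or not cyt.any():
        raise ValueError("empty compartment mask")
    return float(gfp.values[nuc].mean() / gfp.values[cyt].mean())
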