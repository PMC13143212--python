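"""Dendritic spine isolation from binarized fluorescence images.

The primary route severs spine necks by iterative peeling (removal of
border pixels, i.e. erosion with the 4-connected cross element), discards
the isolated spine heads, geodesically reconstructs the surviving dendritic
channel inside the original mask, and takes the residual as the spines
(including their necks). An independent route reconstructs the channel by
dilating the dendritic centerline, found from the occupied-disk fraction
around each pixel. Agreement of the two routes cross-validates the
segmentation.

Connectivity convention: foreground components are 8-connected, the
border-pixel test uses 4-adjacency to background (the standard
digital-topology pairing).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

from .images import BinaryMask, GrayscaleImage, LabelMap

# structuring elements: cross = 4-neighbourhood, square = 8-neighbourhood
CROSS = ndi.generate_binary_structure(2, 1)
SQUARE = ndi.generate_binary_structure(2, 2)


# ---------------------------------------------------------------------------
# thresholding and labeling

def binarize(image: GrayscaleImage, threshold: float) -> BinaryMask:
    """Mask of pixels with intensity >= ``threshold``."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return BinaryMask(image.values >= threshold, image.pixel_size)


def label_clusters(mask: BinaryMask, connectivity: int = 8) -> LabelMap:
    """Hoshen–Kopelman connected-component labeling.

    Single raster-scan pass with union-find over provisional labels, the
    percolation-theory algorithm: each foreground pixel looks at its
    already-visited neighbours, adopts the root label of any occupied one
    and unions the rest. Labels are then relabeled consecutively 1..n.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    m = mask.values
    rows, cols = m.shape
    labels = np.zeros((rows, cols), dtype=np.int64)
    parent = [0]  # parent[i] = union-find parent of provisional label i

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    if connectivity == 4:
        neighbours = ((-1, 0), (0, -1))
    else:
        neighbours = ((-1, -1), (-1, 0), (-1, 1), (0, -1))

    next_label = 1
    for r in range(rows):
        for c in range(cols):
            if not m[r, c]:
                continue
            roots = []
            for dr, dc in neighbours:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and labels[rr, cc] > 0:
                    roots.append(find(labels[rr, cc]))
            if not roots:
                parent.append(next_label)
                labels[r, c] = next_label
                next_label += 1
            else:
                target = min(roots)
                labels[r, c] = target
                for other in roots:
                    parent[other] = target

    # resolve provisional labels and relabel consecutively
    remap: dict[int, int] = {}
    out = np.zeros_like(labels)
    for r in range(rows):
        for c in range(cols):
            if labels[r, c] > 0:
                root = find(labels[r, c])
                if root not in remap:
                    remap[root] = len(remap) + 1
                out[r, c] = remap[root]
    return LabelMap(out, pixel_size=mask.pixel_size)


def remove_small_islands(labelmap: LabelMap, min_area: int) -> BinaryMask:
    """Keep exactly the pixels of islands with size >= ``min_area``."""
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    keep = {lab for lab, n in labelmap.island_sizes.items() if n >= min_area}
    values = np.isin(labelmap.labels, sorted(keep)) & (labelmap.labels > 0)
    return BinaryMask(values, labelmap.pixel_size)


def resolve_threshold(image: GrayscaleImage, spec) -> float:
    """Resolve a threshold given either a number or a ``"mean+k*sd"`` string."""
    if isinstance(spec, str):
        s = spec.replace(" ", "").lower()
        try:
            return float(s)
        except ValueError:
            pass
        if not s.startswith("mean+") or not s.endswith("*sd"):
            raise ValueError(f"unrecognized threshold spec {spec!r}")
        k = float(s[len("mean+"):-len("*sd")])
        return float(image.values.mean() + k * image.values.std())
    return float(spec)


# ---------------------------------------------------------------------------
# peeling

@dataclass(frozen=True)
class PeelRecord:
    """Outcome of iterative border-pixel removal.

    ``depth_map[r, c]`` is the iteration (1-based) at which a foreground
    pixel was removed; 0 marks pixels never removed — the surviving core.
    """

    depth_map: np.ndarray
    n_iterations: int
    pixel_size: float

    def core_mask(self, original: BinaryMask) -> BinaryMask:
        """Pixels of the original mask never removed by peeling."""
        return BinaryMask(original.values & (self.depth_map == 0), self.pixel_size)


def peel(mask: BinaryMask, n_iterations: int) -> PeelRecord:
    """Iteratively remove every foreground pixel 4-adjacent to background.

    Each iteration is an erosion with the cross structuring element; the
    depth map records when each pixel fell. Stops early once the mask is
    empty.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    current = mask.values.copy()
    depth = np.zeros(mask.shape, dtype=np.int32)
    performed = 0
    for it in range(1, n_iterations + 1):
        if not current.any():
            break
        eroded = ndi.binary_erosion(current, structure=CROSS, border_value=0)
        removed = current & ~eroded
        depth[removed] = it
        current = eroded
        performed = it
    return PeelRecord(depth_map=depth, n_iterations=performed,
                      pixel_size=mask.pixel_size)


def auto_peel_depth(mask: BinaryMask, max_depth: int = 10) -> int:
    """Convenience mode for the severing depth: the earliest depth at
    which the peeled image has the most islands — every neck severed while
    the spine heads still survive. (A depth the user knows from the neck
    widths is preferable; this is a data-driven fallback.)"""
    counts = []
    current = mask.values.copy()
    for _ in range(max_depth):
        current = ndi.binary_erosion(current, structure=CROSS, border_value=0)
        if not current.any():
            break
        n, _ = _flood_count(current)
        counts.append(n)
    if not counts:
        return 1
    return 1 + int(np.argmax(counts))


def _flood_count(values: np.ndarray) -> tuple[int, np.ndarray]:
    lab, n = ndi.label(values, structure=SQUARE)
    return n, lab


def reconstruct(seed: np.ndarray, within: np.ndarray, n_iterations: int,
                structure: np.ndarray | None = CROSS) -> np.ndarray:
    """Geodesic dilation: ``n_iterations`` dilations of ``seed``, each
    intersected with the ``within`` mask. Always a subset of ``within``.
    ``structure=None`` alternates cross and square elements, growing an
    octagonal (nearly Euclidean) ball instead of a diamond or square."""
    out = seed & within
    for i in range(n_iterations):
        if structure is None:
            element = CROSS if i % 2 == 0 else SQUARE
        else:
            element = structure
        out = ndi.binary_dilation(out, structure=element) & within
    return out


# ---------------------------------------------------------------------------
# segmentation results

@dataclass(frozen=True)
class SegmentationResult:
    """Channel/spine partition of a cleaned binary mask."""

    channel_mask: BinaryMask
    spine_islands: LabelMap
    method_tag: str

    @property
    def n_spines(self) -> int:
        return self.spine_islands.n_islands

    def spine_mask(self, label: int) -> BinaryMask:
        return self.spine_islands.mask_of(label)


def _largest_label(labelmap: LabelMap) -> int:
    # largest pixel count, ties broken by lowest label index
    return min(labelmap.island_sizes,
               key=lambda lab: (-labelmap.island_sizes[lab], lab))


def extract_spines_by_peeling(mask: BinaryMask, neck_halfwidth_px: int = 3,
                              min_head_area: int = 4) -> SegmentationResult:
    """Sever spine necks by peeling, rebuild the channel, keep the rest.

    1. peel ``neck_halfwidth_px`` iterations so every neck thinner than
       twice the depth is severed;
    2. label the peeled image and keep only the largest island — the
       dendritic channel core — discarding isolated spine heads;
    3. reconstruct the channel with the same number of geodesic dilations
       inside the original mask;
    4. the residual (original minus channel), labeled and filtered by
       ``min_head_area``, is the spines including their necks.
    """
    if neck_halfwidth_px < 1:
        raise ValueError("neck_halfwidth_px must be >= 1")
    record = peel(mask, neck_halfwidth_px)
    core = mask.values & (record.depth_map == 0)
    if not core.any():
        raise ValueError("peel depth exceeds structure width")
    core_labels = label_clusters(BinaryMask(core, mask.pixel_size), connectivity=8)
    channel_core = core_labels.labels == _largest_label(core_labels)
    channel = reconstruct(channel_core, mask.values, neck_halfwidth_px, CROSS)
    residual = BinaryMask(mask.values & ~channel, mask.pixel_size)
    labeled = label_clusters(residual, connectivity=8)
    spine_fg = remove_small_islands(labeled, min_head_area)
    spines = label_clusters(spine_fg, connectivity=8)
    return SegmentationResult(
        channel_mask=BinaryMask(channel, mask.pixel_size),
        spine_islands=spines,
        method_tag="peel",
    )


# ---------------------------------------------------------------------------
# centerline route

@dataclass(frozen=True)
class Centerline:
    """Ordered 1-pixel path through the dendritic channel."""

    path: list  # list of (row, col)
    pixel_size: float
    closed: bool = False

    @property
    def length_um(self) -> float:
        return self.length_px * self.pixel_size

    @property
    def length_px(self) -> float:
        pts = self.path + ([self.path[0]] if self.closed else [])
        total = 0.0
        for (r0, c0), (r1, c1) in zip(pts, pts[1:]):
            total += np.hypot(r1 - r0, c1 - c0)
        return total

    def raster(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        rr, cc = zip(*self.path)
        out[list(rr), list(cc)] = True
        return out

    def arclengths(self) -> np.ndarray:
        """Cumulative arclength (µm) at each path pixel."""
        steps = [0.0]
        for (r0, c0), (r1, c1) in zip(self.path, self.path[1:]):
            steps.append(np.hypot(r1 - r0, c1 - c0) * self.pixel_size)
        return np.cumsum(steps)


def _disk_footprint(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    xx, yy = np.meshgrid(r, r)
    return (xx**2 + yy**2) <= radius**2


def occupancy_map(mask: BinaryMask, radius_px: int) -> np.ndarray:
    """Fraction of the disk of ``radius_px`` around each pixel occupied by
    the mask — high on the channel axis, low on thin protrusions."""
    disk = _disk_footprint(radius_px).astype(float)
    occ = ndi.convolve(mask.values.astype(float), disk, mode="constant", cval=0.0)
    return occ / disk.sum()


def _directional_ridge(occ: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pixels whose occupancy is a local maximum along at least one of the
    four principal directions — central pixels of a tubular cross-section."""
    ridge = np.zeros_like(mask)
    padded = np.pad(occ, 1, mode="constant", constant_values=-1.0)
    c = padded[1:-1, 1:-1]
    for dr, dc in ((1, 0), (0, 1), (1, 1), (1, -1)):
        fwd = padded[1 + dr:padded.shape[0] - 1 + dr,
                     1 + dc:padded.shape[1] - 1 + dc]
        bwd = padded[1 - dr:padded.shape[0] - 1 - dr,
                     1 - dc:padded.shape[1] - 1 - dc]
        ridge |= (c >= fwd) & (c >= bwd)
    return ridge & mask


def _path_neighbours(pixels: set) -> dict:
    adj = {p: [] for p in pixels}
    for (r, c) in pixels:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                q = (r + dr, c + dc)
                if q in adj:
                    adj[(r, c)].append(q)
    return adj


def _bfs_farthest(adj: dict, start) -> tuple:
    seen = {start: None}
    queue = deque([start])
    last = start
    while queue:
        p = queue.popleft()
        last = p
        for q in adj[p]:
            if q not in seen:
                seen[q] = p
                queue.append(q)
    return last, seen


def extract_centerline(mask: BinaryMask, occupancy_radius_px: int = 4,
                       allow_closed: bool = False) -> Centerline:
    """Dendritic centerline from the occupied-disk fraction.

    Candidate central pixels (directional occupancy maxima) are thinned to
    a 1-pixel skeleton; the longest end-to-end path through its dominant
    component is returned in order. A purely cyclic skeleton (annulus) is
    an error unless ``allow_closed``.
    """
    if occupancy_radius_px < 1:
        raise ValueError("occupancy_radius_px must be >= 1")
    if not mask.values.any():
        raise ValueError("empty mask has no centerline")
    occ = occupancy_map(mask, occupancy_radius_px)
    ridge = _directional_ridge(occ, mask.values)
    ridge = ndi.binary_closing(ridge, structure=SQUARE) & mask.values
    skel = skeletonize(ridge)
    if not skel.any():
        raise ValueError("no elongated structure found")
    lab, n = ndi.label(skel, structure=SQUARE)
    sizes = ndi.sum_labels(skel, lab, index=np.arange(1, n + 1))
    skel = lab == (1 + int(np.argmax(sizes)))
    pixels = set(map(tuple, np.argwhere(skel)))
    adj = _path_neighbours(pixels)
    degrees = {p: len(v) for p, v in adj.items()}
    endpoints = [p for p, d in degrees.items() if d <= 1]
    if not endpoints:
        if not allow_closed:
            raise ValueError("centerline is a closed loop; pass allow_closed=True")
        # walk the cycle once
        start = next(iter(pixels))
        path = [start]
        prev = None
        while True:
            nxt = [q for q in adj[path[-1]] if q != prev]
            if not nxt or nxt[0] == start:
                break
            prev = path[-1]
            path.append(nxt[0])
        return Centerline(path=path, pixel_size=mask.pixel_size, closed=True)
    # double BFS: farthest endpoint pair spans the main axis
    e1, _ = _bfs_farthest(adj, endpoints[0])
    e2, parents = _bfs_farthest(adj, e1)
    path = [e2]
    while parents[path[-1]] is not None:
        path.append(parents[path[-1]])
    path = _extend_endpoints(path, mask.values)
    return Centerline(path=path, pixel_size=mask.pixel_size, closed=False)


def _extend_endpoints(path: list, mask: np.ndarray, lookback: int = 10) -> list:
    """Prolong both path ends to the mask boundary — thinning retracts
    skeleton tips by roughly the tube radius, which would otherwise shorten
    every measured centerline. Each step moves to the deepest (most medial)
    neighbour in the forward direction, so the extension follows the tube
    axis instead of drifting toward a boundary."""
    depth = ndi.distance_transform_edt(mask)
    neighbours = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                  if (dr, dc) != (0, 0)]
    out = list(path)
    for flip in (False, True):
        if flip:
            out.reverse()
        k = min(lookback, len(out) - 1)
        if k == 0:
            break
        tail = np.asarray(out[0], float) - np.asarray(out[k], float)
        norm = np.hypot(*tail)
        if norm == 0:
            continue
        d = tail / norm
        seen = set(out)
        # most-aligned steps first, so depth ties keep the straight course
        ordered = sorted(neighbours,
                         key=lambda s: -(s[0] * d[0] + s[1] * d[1]) / np.hypot(*s))
        for _ in range(mask.shape[0] + mask.shape[1]):
            cur = out[0]
            best, best_depth = None, 0.0
            for dr, dc in ordered:
                if dr * d[0] + dc * d[1] < 0.5 * np.hypot(dr, dc):
                    continue
                nxt = (cur[0] + dr, cur[1] + dc)
                if not (0 <= nxt[0] < mask.shape[0]
                        and 0 <= nxt[1] < mask.shape[1]) \
                        or not mask[nxt] or nxt in seen:
                    continue
                if depth[nxt] > best_depth:
                    best, best_depth = nxt, depth[nxt]
            if best is None:
                break
            out.insert(0, best)
            seen.add(best)
    return out


def extract_spines_by_centerline(mask: BinaryMask, centerline: Centerline,
                                 n_layers: int,
                                 min_head_area: int = 4) -> SegmentationResult:
    """Rebuild the channel by dilating the centerline; spines are the rest.

    ``n_layers`` geodesic dilations (alternating cross/square, so the
    layers grow a near-Euclidean octagonal profile) of the centerline
    raster inside the mask restore the channel width; the labeled
    residual, filtered by ``min_head_area``, gives the spine islands.
    """
    if n_layers < 0:
        raise ValueError("n_layers must be >= 0")
    seed = centerline.raster(mask.shape)
    if (seed & ~mask.values).any():
        raise ValueError("centerline must lie inside the mask")
    channel = reconstruct(seed, mask.values, n_layers, None)
    residual = BinaryMask(mask.values & ~channel, mask.pixel_size)
    labeled = label_clusters(residual, connectivity=8)
    spine_fg = remove_small_islands(labeled, min_head_area) if min_head_area > 1 \
        else labeled.foreground()
    spines = label_clusters(spine_fg, connectivity=8)
    return SegmentationResult(
        channel_mask=BinaryMask(channel, mask.pixel_size),
        spine_islands=spines,
        method_tag="centerline",
    )


# ---------------------------------------------------------------------------
# cross-validation and head/neck split

@dataclass(frozen=True)
class MethodComparison:
    """Per-spine agreement between two segmentation routes."""

    matches: list  # (label_a, label_b, jaccard)
    unmatched_a: list
    unmatched_b: list

    @property
    def mean_jaccard(self) -> float:
        if not self.matches:
            return float("nan")
        return float(np.mean([j for _, _, j in self.matches]))


def compare_methods(a: SegmentationResult, b: SegmentationResult) -> MethodComparison:
    """Match spines across methods by maximal pixel overlap and report the
    Jaccard index of each matched pair plus any unmatched spines."""
    la, lb = a.spine_islands.labels, b.spine_islands.labels
    if la.shape != lb.shape:
        raise ValueError("results come from different masks")
    pairs = []
    for lab_a, size_a in a.spine_islands.island_sizes.items():
        sel = la == lab_a
        hit = lb[sel]
        hit = hit[hit > 0]
        if hit.size == 0:
            continue
        ids, counts = np.unique(hit, return_counts=True)
        for lab_b, ov in zip(ids, counts):
            pairs.append((int(ov), lab_a, int(lab_b)))
    pairs.sort(reverse=True)
    used_a, used_b, matches = set(), set(), []
    for ov, lab_a, lab_b in pairs:
        if lab_a in used_a or lab_b in used_b:
            continue
        used_a.add(lab_a)
        used_b.add(lab_b)
        union = np.sum((la == lab_a) | (lb == lab_b))
        matches.append((lab_a, lab_b, ov / union))
    return MethodComparison(
        matches=matches,
        unmatched_a=sorted(set(a.spine_islands.island_sizes) - used_a),
        unmatched_b=sorted(set(b.spine_islands.island_sizes) - used_b),
    )


def split_head_neck(spine_island: BinaryMask, max_neck_width_px: float = 3.0,
                    min_neck_area: int = 4) -> tuple[BinaryMask, BinaryMask]:
    """Split a spine island into head and neck by severing the thin neck
    and rebuilding the head — the same peel/sever/reconstruct idea used on
    the channel, here with metric-accurate (Euclidean-distance) peeling so
    small round heads are not clipped by the discrete cross element.

    A strip of width ``max_neck_width_px`` has interior depth (distance to
    background) at most (w+1)/2, so pixels deeper than that belong to a
    head; the largest such core, dilated back by the same radius inside
    the island, is the head; the rest is the neck. Conventions for the
    degenerate shapes: an island nowhere deeper than the sever radius is
    all neck (thin spine); residual neck components below ``min_neck_area``
    — opening slivers of a wide blob — are merged back into the head, so a
    stubby spine has an empty neck.
    """
    px = spine_island.pixel_size
    # work on a 2x-upsampled grid: half-pixel distances distinguish a head
    # whose inscribed square is only one pixel wider than the neck, which
    # full-pixel distances quantize onto the same value
    up = np.kron(spine_island.values, np.ones((2, 2), dtype=bool))
    # half-pixel units: a w-px strip has interior depth w on the 2x grid,
    # a head one pixel wider reaches w+1; sever midway between them
    sever_radius = max_neck_width_px + 0.5
    depth = ndi.distance_transform_edt(up)
    core = depth > sever_radius
    if not core.any():
        empty = BinaryMask(np.zeros(spine_island.shape, bool), px)
        return empty, spine_island
    lab, n = ndi.label(core, structure=SQUARE)
    sizes = ndi.sum_labels(core, lab, index=np.arange(1, n + 1))
    head_core = lab == (1 + int(np.argmax(sizes)))
    grow = ndi.distance_transform_edt(~head_core)
    head_up = (grow <= sever_radius) & up
    # a pixel is head when at least half of its subpixels are
    head = (head_up.reshape(spine_island.shape[0], 2,
                            spine_island.shape[1], 2).sum(axis=(1, 3)) >= 2)
    head &= spine_island.values
    neck = spine_island.values & ~head
    lab_n, k = ndi.label(neck, structure=SQUARE)
    for i in range(1, k + 1):
        comp = lab_n == i
        if comp.sum() < min_neck_area:
            head |= comp
            neck &= ~comp
    return BinaryMask(head, px), BinaryMask(neck, px)
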