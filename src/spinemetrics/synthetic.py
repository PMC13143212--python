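"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the data the quantification rules were built for:

* maximum-intensity-projection-like images of a tubular dendrite
  (default diameter 0.78 µm at 0.1 µm/px, the scale of the real material)
  decorated with mushroom / stubby / thin spines of known head area and
  neck width, blurred by a Gaussian PSF, with Gaussian noise and small
  disconnected noise islands;
* registered channel pairs with a known pixel-overlap structure, hence
  known Manders coefficients;
* store-operated Ca²⁺ entry (SOCE) ratio traces with known basal level,
  depletion transient, influx slope, peak and plateau.

Everything is deterministic per seed; each generated object returns the
exact ground truth alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .images import BinaryMask, GrayscaleImage
from .segmentation import SQUARE
from .traces import CalciumTrace, TraceFeatures

# ---------------------------------------------------------------------------
# dendrite images


@dataclass(frozen=True)
class SpineSpec:
    """One spine: anchored on the centerline, protruding along the local
    normal. Dimensions in µm; ``side`` chooses the normal direction."""

    anchor: tuple[float, float]            # (row, col), on the centerline
    side: int                              # +1 / -1
    neck_length_um: float
    neck_width_um: float
    head_diameter_um: float
    shape_class: str = "mushroom"          # mushroom | stubby | thin

    def __post_init__(self):
        if self.side not in (+1, -1):
            raise ValueError("side must be +1 or -1")
        if self.shape_class not in ("mushroom", "stubby", "thin"):
            raise ValueError(f"unknown shape_class {self.shape_class!r}")
        if self.shape_class == "mushroom" and self.head_diameter_um < self.neck_width_um:
            raise ValueError("mushroom head must be at least as wide as its neck")
        if self.shape_class == "stubby" and self.neck_length_um > 1e-9:
            raise ValueError("stubby spines have no neck")


@dataclass(frozen=True)
class DendriteSpec:
    """Geometry and imaging parameters of one synthetic dendrite image."""

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.1                       # µm/px
    centerline_control_points: tuple = ((128.0, 10.0), (128.0, 246.0))
    dendrite_diameter_um: float = 0.78
    spines: tuple = ()
    background_level: float = 100.0
    signal_level: float = 400.0
    psf_sigma_px: float = 0.8
    noise_sd: float = 0.0
    n_noise_islands: int = 0
    noise_island_max_area: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.dendrite_diameter_um <= 0:
            raise ValueError("dendrite diameter must be positive")
        if self.psf_sigma_px < 0 or self.noise_sd < 0:
            raise ValueError("psf_sigma and noise_sd must be >= 0")
        if len(self.centerline_control_points) < 2:
            raise ValueError("need at least two centerline control points")


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """True geometry behind a generated dendrite image."""

    spine_count: int
    head_areas_um2: list
    neck_base_points: list                 # (row, col) floats
    local_diameters_um: list
    centerline_length_um: float
    channel_mask: BinaryMask
    spine_masks: list                      # list of BinaryMask

    def to_json(self, path) -> None:
        payload = {
            "spine_count": self.spine_count,
            "head_areas_um2": list(map(float, self.head_areas_um2)),
            "neck_base_points": [list(map(float, p)) for p in self.neck_base_points],
            "local_diameters_um": list(map(float, self.local_diameters_um)),
            "centerline_length_um": float(self.centerline_length_um),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _densify(control_points, step: float = 0.25) -> np.ndarray:
    """Linear interpolation of the control polyline at sub-pixel steps."""
    pts = np.asarray(control_points, dtype=float)
    out = [pts[0]]
    for p0, p1 in zip(pts, pts[1:]):
        seg = np.hypot(*(p1 - p0))
        n = max(int(np.ceil(seg / step)), 1)
        for i in range(1, n + 1):
            out.append(p0 + (p1 - p0) * i / n)
    return np.asarray(out)


def _polyline_length(points: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(points, axis=0).T)))


def _distance_to_polyline(shape, control_points) -> np.ndarray:
    """Exact per-pixel Euclidean distance (px) to the control polyline,
    computed against each straight segment so sub-pixel centerline
    placement matters (it sets the rasterized tube width)."""
    pts = np.asarray(control_points, dtype=float)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    best = np.full(shape, np.inf)
    for a, b in zip(pts, pts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d = np.hypot(rr - a[0], cc - a[1])
        else:
            t = np.clip(((rr - a[0]) * ab[0] + (cc - a[1]) * ab[1]) / denom, 0, 1)
            d = np.hypot(rr - (a[0] + t * ab[0]), cc - (a[1] + t * ab[1]))
        best = np.minimum(best, d)
    return best


def _nearest_on_polyline(points: np.ndarray, anchor) -> tuple[int, np.ndarray]:
    d2 = (points[:, 0] - anchor[0]) ** 2 + (points[:, 1] - anchor[1]) ** 2
    return int(np.argmin(d2)), np.sqrt(d2.min())


def _local_normal(points: np.ndarray, idx: int) -> np.ndarray:
    lo, hi = max(idx - 2, 0), min(idx + 2, len(points) - 1)
    tangent = points[hi] - points[lo]
    tangent /= np.hypot(*tangent)
    return np.array([-tangent[1], tangent[0]])


def _draw_spine(spec: DendriteSpec, spine: SpineSpec, polyline: np.ndarray,
                grid_r: np.ndarray, grid_c: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize one spine; returns (full mask, head-disk mask, neck base)."""
    px = spec.pixel_size
    radius_px = spec.dendrite_diameter_um / 2 / px
    idx, gap = _nearest_on_polyline(polyline, spine.anchor)
    if gap > 1.0:
        raise ValueError(f"spine anchor {spine.anchor} not on the centerline")
    anchor = polyline[idx]
    normal = _local_normal(polyline, idx) * spine.side
    tangent = np.array([normal[1], -normal[0]])

    neck_len_px = spine.neck_length_um / px
    neck_w_px = spine.neck_width_um / px
    head_r_px = spine.head_diameter_um / 2 / px

    vr = grid_r - anchor[0]
    vc = grid_c - anchor[1]
    along = vr * normal[0] + vc * normal[1]
    perp = vr * tangent[0] + vc * tangent[1]

    mask = np.zeros(grid_r.shape, dtype=bool)
    if spine.shape_class == "stubby":
        centre_d = radius_px + head_r_px - 0.5      # slight overlap keeps contact
        head_centre = anchor + normal * centre_d
    else:
        mask |= (along >= 0) & (along <= radius_px + neck_len_px) \
            & (np.abs(perp) <= neck_w_px / 2)
        head_centre = anchor + normal * (radius_px + neck_len_px + head_r_px - 0.5)
    head = (grid_r - head_centre[0]) ** 2 + (grid_c - head_centre[1]) ** 2 \
        <= head_r_px**2
    mask |= head
    neck_base = anchor + normal * radius_px
    return mask, head, neck_base


def generate_dendrite_image(spec: DendriteSpec
                            ) -> tuple[GrayscaleImage, SyntheticGroundTruth]:
    """Render the dendrite image and its exact ground truth.

    The image is background + signal·(channel ∪ spines) blurred by the
    Gaussian PSF, plus pixel noise and, finally, small random islands kept
    at least 2 px away from the dendrite (so they are never 8-connected to
    it). Bit-identical for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    px = spec.pixel_size
    polyline = _densify(spec.centerline_control_points)
    if np.any(polyline < 0) or np.any(polyline[:, 0] > shape[0] - 1) \
            or np.any(polyline[:, 1] > shape[1] - 1):
        raise ValueError("centerline leaves the image bounds")
    dist = _distance_to_polyline(shape, spec.centerline_control_points)
    radius_px = spec.dendrite_diameter_um / 2 / px
    channel = dist <= radius_px

    grid_r, grid_c = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    spine_masks, head_areas, neck_bases = [], [], []
    all_spines = np.zeros(shape, dtype=bool)
    for spine in spec.spines:
        full, head, base = _draw_spine(spec, spine, polyline, grid_r, grid_c)
        island = full & ~channel
        if not island.any():
            raise ValueError("spine lies entirely inside the channel")
        touches_edge = island[0, :].any() or island[-1, :].any() \
            or island[:, 0].any() or island[:, -1].any()
        if touches_edge:
            raise ValueError(f"spine at {spine.anchor} leaves the image bounds")
        spine_masks.append(BinaryMask(island, px))
        head_areas.append(float((head & ~channel).sum()) * px**2)
        neck_bases.append(tuple(base))
        all_spines |= island

    foreground = channel | all_spines
    image = spec.background_level + spec.signal_level * foreground.astype(float)
    if spec.psf_sigma_px > 0:
        image = ndi.gaussian_filter(image, spec.psf_sigma_px)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, shape)

    # disconnected noise islands, >= 2 px clear of the dendrite structure
    forbidden = ndi.binary_dilation(foreground, structure=SQUARE, iterations=2)
    placed = 0
    attempts = 0
    while placed < spec.n_noise_islands and attempts < 200 * max(spec.n_noise_islands, 1):
        attempts += 1
        r = int(rng.integers(2, shape[0] - 2))
        c = int(rng.integers(2, shape[1] - 2))
        blob_r = float(rng.uniform(0.7, np.sqrt(spec.noise_island_max_area / np.pi)))
        blob = (grid_r - r) ** 2 + (grid_c - c) ** 2 <= blob_r**2
        if (blob & forbidden).any() or blob.sum() > spec.noise_island_max_area:
            continue
        image[blob] = spec.background_level + spec.signal_level
        forbidden |= ndi.binary_dilation(blob, structure=SQUARE, iterations=2)
        placed += 1

    truth = SyntheticGroundTruth(
        spine_count=len(spine_masks),
        head_areas_um2=head_areas,
        neck_base_points=neck_bases,
        local_diameters_um=[spec.dendrite_diameter_um] * len(spine_masks),
        centerline_length_um=_polyline_length(polyline) * px,
        channel_mask=BinaryMask(channel, px),
        spine_masks=spine_masks,
    )
    return GrayscaleImage(image, px), truth


def random_dendrite_spec(seed: int, n_spines: int = 6,
                         base: DendriteSpec = DendriteSpec(),
                         neck_width_um: float = 0.3,
                         neck_length_range_um: tuple = (0.4, 0.6),
                         head_diameter_range_um: tuple = (0.5, 0.7),
                         min_spacing_um: float = 2.0) -> DendriteSpec:
    """A study-scale dendrite with ``n_spines`` mushroom spines at random
    positions and sides, spaced at least ``min_spacing_um`` apart."""
    rng = np.random.default_rng(seed)
    # sub-pixel jitter of the centerline: the rasterized tube width then
    # averages to the nominal diameter across seeds instead of snapping to
    # an odd pixel count
    offset = rng.uniform(0.0, 1.0, size=2)
    cps = tuple((r + offset[0], c + offset[1])
                for r, c in base.centerline_control_points)
    base = replace(base, centerline_control_points=cps)
    polyline = _densify(base.centerline_control_points)
    arcs = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(polyline, axis=0).T))])
    usable = arcs[-1] * base.pixel_size - 2.0      # keep 1 µm clear of each end
    spacing_px = min_spacing_um / base.pixel_size
    positions = []
    tries = 0
    while len(positions) < n_spines and tries < 2000:
        tries += 1
        s = rng.uniform(1.0, 1.0 + usable) / base.pixel_size
        if all(abs(s - p) >= spacing_px for p in positions):
            positions.append(s)
    spines = []
    for s in sorted(positions):
        idx = int(np.argmin(np.abs(arcs - s)))
        spines.append(SpineSpec(
            anchor=tuple(polyline[idx]),
            side=int(rng.choice((-1, 1))),
            neck_length_um=float(rng.uniform(*neck_length_range_um)),
            neck_width_um=neck_width_um,
            head_diameter_um=float(rng.uniform(*head_diameter_range_um)),
            shape_class="mushroom",
        ))
    return replace(base, spines=tuple(spines), seed=seed)


# ---------------------------------------------------------------------------
# colocalization pairs


def generate_coloc_pair(n_pixels_on_a: int, n_pixels_on_b: int, n_overlap: int,
                        image_shape: tuple[int, int] = (64, 64),
                        intensities: tuple[float, float] = (1000.0, 1000.0),
                        pixel_size: float = 0.1, seed: int = 0
                        ) -> tuple[GrayscaleImage, GrayscaleImage, float, float]:
    """Two registered channels with an exact pixel-overlap structure.

    With uniform on-pixel intensities the expected Manders coefficients
    are M1 = overlap/n_on_A and M2 = overlap/n_on_B, returned alongside.
    """
    if n_overlap > min(n_pixels_on_a, n_pixels_on_b):
        raise ValueError("overlap exceeds a channel's pixel count")
    if n_pixels_on_a < 1 or n_pixels_on_b < 1:
        raise ValueError("each channel needs at least one on-pixel")
    total_needed = n_pixels_on_a + n_pixels_on_b - n_overlap
    n_px = image_shape[0] * image_shape[1]
    if total_needed > n_px // 4:
        raise ValueError("counts too dense for a clean mean+2sd threshold")
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_px, size=total_needed, replace=False)
    shared = flat[:n_overlap]
    only_a = flat[n_overlap:n_pixels_on_a]
    only_b = flat[n_pixels_on_a:]
    a = np.zeros(n_px)
    b = np.zeros(n_px)
    a[np.concatenate([shared, only_a]).astype(int)] = intensities[0]
    b[np.concatenate([shared, only_b]).astype(int)] = intensities[1]
    m1 = n_overlap / n_pixels_on_a
    m2 = n_overlap / n_pixels_on_b
    return (GrayscaleImage(a.reshape(image_shape), pixel_size),
            GrayscaleImage(b.reshape(image_shape), pixel_size), m1, m2)


# ---------------------------------------------------------------------------
# SOCE traces


@dataclass(frozen=True)
class TraceSpec:
    """Shape parameters of a synthetic SOCE protocol trace.

    Phases (frame indices): baseline | TG in 0 mM Ca²⁺ (store depletion)
    | Ca²⁺ re-addition with linear influx to the SOCE peak | decay to the
    plateau. The depletion transient settles back to basal well before
    re-addition, and the influx rise is anchored at the frame before
    re-addition, as in the recorded protocol.
    """

    frame_interval_s: float = 2.0
    n_frames: int = 150
    tg_frame: int = 20
    readdition_frame: int = 80
    plateau_start_frame: int = 120
    basal_ratio: float = 0.4
    depletion_peak_delta: float = 0.3
    influx_slope: float = 0.02             # ratio/s
    soce_peak_delta: float = 0.4
    plateau_delta: float = 0.25
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.tg_frame < self.readdition_frame < self.plateau_start_frame \
                < self.n_frames:
            raise ValueError("phases must be ordered and within the trace")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.influx_slope > 0:
            rise = self.soce_peak_delta / (self.influx_slope * self.frame_interval_s)
            if rise < 5:
                raise ValueError("influx rise shorter than the 5-frame fit window")
            if self.readdition_frame - 1 + rise >= self.plateau_start_frame:
                raise ValueError("SOCE peak would fall inside the plateau window")
        if self.readdition_frame - self.tg_frame < 12:
            raise ValueError("depletion phase too short to settle before re-addition")


def _clamped_decay(t: np.ndarray, t0: float, t1: float, tau: float) -> np.ndarray:
    """exp decay from 1 at t0 to exactly 0 at t1."""
    e_end = np.exp(-(t1 - t0) / tau)
    return (np.exp(-(t - t0) / tau) - e_end) / (1.0 - e_end)


def soce_curve(spec: TraceSpec) -> np.ndarray:
    """The noise-free ratio curve of the protocol."""
    t = np.arange(spec.n_frames) * spec.frame_interval_s
    r = np.full(spec.n_frames, spec.basal_ratio)
    # depletion transient: 3-frame rise, decay finished 6 frames before re-addition
    rise_end = spec.tg_frame + 3
    settle = spec.readdition_frame - 6
    seg = slice(spec.tg_frame, rise_end)
    r[seg] += spec.depletion_peak_delta * \
        (np.arange(1, rise_end - spec.tg_frame + 1) / (rise_end - spec.tg_frame))
    seg = slice(rise_end, settle)
    tau_dep = (t[settle] - t[rise_end]) / 6.0
    r[seg] += spec.depletion_peak_delta * _clamped_decay(t[seg], t[rise_end],
                                                         t[settle], tau_dep)
    if spec.influx_slope > 0:
        anchor = t[spec.readdition_frame - 1]
        peak_frame = spec.readdition_frame - 1 + int(round(
            spec.soce_peak_delta / (spec.influx_slope * spec.frame_interval_s)))
        seg = slice(spec.readdition_frame, peak_frame + 1)
        r[seg] = spec.basal_ratio + spec.influx_slope * (t[seg] - anchor)
        peak_value = r[peak_frame]
        plateau_value = spec.basal_ratio + spec.plateau_delta
        seg = slice(peak_frame + 1, spec.plateau_start_frame)
        tau = (t[spec.plateau_start_frame] - t[peak_frame]) / 4.0
        r[seg] = plateau_value + (peak_value - plateau_value) * _clamped_decay(
            t[seg], t[peak_frame], t[spec.plateau_start_frame], tau)
        r[spec.plateau_start_frame:] = plateau_value
    return r


def generate_soce_trace(spec: TraceSpec,
                        f380_amplitude: float = 1000.0,
                        background: float = 100.0
                        ) -> tuple[CalciumTrace, TraceFeatures]:
    """Synthesize a two-wavelength trace and return the true features.

    Noise of ``noise_sd`` is added on the ratio scale (the 380 nm channel
    is held constant, so the ratio carries all the variation). Truth is
    computed from the noise-free curve: the influx slope is exact because
    the five fit frames are collinear by construction.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_frames) * spec.frame_interval_s
    clean = soce_curve(spec)
    noisy = clean + (rng.normal(0.0, spec.noise_sd, spec.n_frames)
                     if spec.noise_sd > 0 else 0.0)
    f380 = np.full(spec.n_frames, background + f380_amplitude)
    f340 = background + noisy * f380_amplitude
    events = {
        "tg_addition": spec.tg_frame,
        "ca_readdition": spec.readdition_frame,
        "basal_window": (0, spec.tg_frame),
        "depletion_window": (spec.tg_frame, spec.readdition_frame),
        "plateau_window": (spec.plateau_start_frame, spec.n_frames),
    }
    trace = CalciumTrace(time=t, f340=f340, f380=f380,
                         bg340=np.full(spec.n_frames, background),
                         bg380=np.full(spec.n_frames, background),
                         events=events)
    dep = slice(spec.tg_frame, spec.readdition_frame)
    truth = TraceFeatures(
        basal_ratio=spec.basal_ratio,
        delta_peak=float(clean[spec.readdition_frame:spec.plateau_start_frame].max()
                         - spec.basal_ratio),
        delta_plateau=spec.plateau_delta,
        influx_rate=spec.influx_slope,
        auc=float(np.trapezoid(clean[dep] - spec.basal_ratio, t[dep])),
    )
    return trace, truth


# ---------------------------------------------------------------------------
# file output


def write_dendrite_fixture(spec: DendriteSpec, path_stem) -> tuple[Path, Path]:
    """Write the image as single-plane TIFF plus a ``.truth.json`` sidecar."""
    image, truth = generate_dendrite_image(spec)
    stem = Path(path_stem)
    tiff = stem.with_suffix(".tiff")
    image.to_tiff(tiff)
    sidecar = stem.with_suffix(".truth.json")
    truth.to_json(sidecar)
    return tiff, sidecar
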