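"""Calibrated morphometry of fungal asexual structures in micrographs.

Detects conidia (ellipsoidal asexual spores) and conidiophores (the stalks
bearing them) in grayscale micrographs, filters conidia to those lying flat
in the sagittal plane, and reports length, width, and projected area in
micrometers.  The workflow is: global automatic threshold on the
darker-object polarity, hole filling, 8-connected labelling, border and
area gating, a shape gate for sagittal presentation, and calibrated
measurement from the fitted ellipse (axes) and the pixel mask (area).

All public measurements are in µm / µm²; pixel quantities never leave this
module.  Calibration is a single isotropic scale in pixels per micron; the
default 15.8097 px/µm corresponds to the imaging setup the toolkit was
built around.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import filters, measure, morphology

from .errors import InputFormatError, ValidationError

DEFAULT_PIXELS_PER_MICRON = 15.8097


@dataclass(frozen=True)
class CalibrationScale:
    """Isotropic image calibration in pixels per micron."""

    pixels_per_micron: float = DEFAULT_PIXELS_PER_MICRON

    def __post_init__(self) -> None:
        if not np.isfinite(self.pixels_per_micron) or self.pixels_per_micron <= 0:
            raise ValidationError(
                f"pixels_per_micron must be a positive finite number, "
                f"got {self.pixels_per_micron!r}"
            )


@dataclass
class Micrograph:
    """A single grayscale micrograph with optional calibration."""

    intensities: np.ndarray
    scale: CalibrationScale | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValidationError("micrograph intensities must be a 2-D array")
        if min(self.intensities.shape) < 3:
            raise ValidationError("micrograph must be at least 3x3 pixels")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("micrograph intensities must be finite")

    @property
    def height(self) -> int:
        return self.intensities.shape[0]

    @property
    def width(self) -> int:
        return self.intensities.shape[1]


@dataclass
class LabeledRegion:
    """A connected foreground component with its basic shape descriptors.

    Axis lengths are full (not semi-) axes of the ellipse with the same
    normalized second central moments as the pixel set, as is conventional
    in image-analysis region properties.
    """

    label: int
    mask: np.ndarray  # boolean, full-image frame
    area_px: int
    centroid: tuple[float, float]
    major_axis_px: float
    minor_axis_px: float
    orientation: float
    solidity: float
    touches_border: bool
    bbox: tuple[int, int, int, int] = field(default=(0, 0, 0, 0))

    @property
    def aspect_ratio(self) -> float:
        if self.minor_axis_px <= 0:
            return float("inf")
        return self.major_axis_px / self.minor_axis_px


@dataclass(frozen=True)
class SagittalCriteria:
    """Shape gate deciding whether a region is a spore lying flat.

    A conidium photographed in the sagittal plane shows its full long-axis
    profile: a convex, ellipse-like outline with moderate elongation.
    Merged, overlapping, or obliquely-oriented spores fail on solidity,
    aspect ratio, or the residual between the region and its fitted
    ellipse.
    """

    min_solidity: float = 0.90
    aspect_range: tuple[float, float] = (1.2, 4.0)
    ellipse_residual_max: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.min_solidity <= 1:
            raise ValidationError("min_solidity must be in (0, 1]")
        if self.aspect_range[0] < 1:
            raise ValidationError("aspect_range minimum must be >= 1")
        if self.aspect_range[1] < self.aspect_range[0]:
            raise ValidationError("aspect_range must be (min, max) with min <= max")


@dataclass(frozen=True)
class ConidiumMeasure:
    """Calibrated measurements of one conidium."""

    length_um: float
    width_um: float
    area_um2: float
    sagittal: bool = True
    isolate_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if not (self.length_um >= self.width_um > 0):
            raise ValidationError("require length_um >= width_um > 0")
        if self.area_um2 <= 0:
            raise ValidationError("area_um2 must be positive")
        if self.area_um2 > self.length_um * self.width_um * (1 + 1e-9):
            raise ValidationError("area_um2 exceeds the length x width bounding box")


@dataclass(frozen=True)
class ConidiophoreMeasure:
    """Calibrated measurements of one conidiophore."""

    total_length_um: float
    base_width_um: float
    isolate_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.total_length_um <= 0:
            raise ValidationError("total_length_um must be positive")
        if self.base_width_um <= 0:
            raise ValidationError("base_width_um must be positive")


@dataclass(frozen=True)
class TraitSummary:
    """mean +/- SD [min-max] summary of one trait, sample SD (n-1)."""

    trait: str
    mean: float
    sd: float
    min: float
    max: float
    n: int

    def __str__(self) -> str:  # the field's standard reporting format
        return (
            f"{self.trait}: {self.mean:.1f} ± {self.sd:.1f} "
            f"[{self.min:.1f}–{self.max:.1f}] (n={self.n})"
        )


def load_micrograph(
    path: str | Path, scale: CalibrationScale | float | None = None
) -> Micrograph:
    """Load a TIFF/PNG micrograph, converting RGB to grayscale by channel mean.

    Intensities of 8/16-bit grayscale inputs are preserved losslessly.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:  # Pillow raises many concrete types
        raise InputFormatError(f"could not read image {path}: {exc}") from exc
    if arr.size == 0:
        raise ValidationError(f"image {path} has zero size")
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    if isinstance(scale, (int, float)):
        scale = CalibrationScale(float(scale))
    return Micrograph(intensities=arr.astype(float), scale=scale, source=str(path))


def _region_from_slice(mask: np.ndarray, label: int, shape: tuple[int, int]) -> LabeledRegion:
    props = measure.regionprops(mask.astype(np.uint8))[0]
    r0, c0, r1, c1 = props.bbox
    touches = r0 == 0 or c0 == 0 or r1 == shape[0] or c1 == shape[1]
    return LabeledRegion(
        label=label,
        mask=mask,
        area_px=int(props.area),
        centroid=tuple(props.centroid),
        major_axis_px=float(props.axis_major_length),
        minor_axis_px=float(props.axis_minor_length),
        orientation=float(props.orientation),
        solidity=float(props.solidity),
        touches_border=touches,
        bbox=props.bbox,
    )


def segment_objects(
    micrograph: Micrograph,
    min_area_um2: float = 1.0,
    max_area_um2: float = 50.0,
    dark_objects: bool = True,
) -> list[LabeledRegion]:
    """Segment candidate structures from a calibrated micrograph.

    Otsu global threshold (dark objects on a light background by default),
    hole filling, 8-connected labelling.  Regions touching the image border
    or outside the [min_area_um2, max_area_um2] gate are discarded.  Labels
    are renumbered 1..k in raster order of first pixel.
    """
    if micrograph.scale is None:
        raise ValidationError("micrograph has no calibration scale attached")
    if not 0 < min_area_um2 < max_area_um2:
        raise ValidationError("require 0 < min_area_um2 < max_area_um2")
    img = micrograph.intensities
    if np.ptp(img) == 0:
        return []
    thr = filters.threshold_otsu(img)
    fg = img < thr if dark_objects else img > thr
    if not fg.any():
        return []
    fg = ndi.binary_fill_holes(fg)
    labels, _ = ndi.label(fg, structure=np.ones((3, 3), dtype=int))
    s = micrograph.scale.pixels_per_micron
    lo_px, hi_px = min_area_um2 * s * s, max_area_um2 * s * s
    regions: list[LabeledRegion] = []
    for obj_label in range(1, labels.max() + 1):
        mask = labels == obj_label
        area = int(mask.sum())
        if not lo_px <= area <= hi_px:
            continue
        region = _region_from_slice(mask, label=len(regions) + 1, shape=img.shape)
        if region.touches_border:
            continue
        region.label = len(regions) + 1
        regions.append(region)
    return regions


def _ellipse_mask(region: LabeledRegion, shape: tuple[int, int]) -> np.ndarray:
    """Raster mask of the region's moment-equivalent fitted ellipse."""
    rr, cc = skdraw.ellipse(
        region.centroid[0],
        region.centroid[1],
        region.major_axis_px / 2.0,
        region.minor_axis_px / 2.0,
        shape=shape,
        # skimage.draw.ellipse rotation and regionprops orientation share
        # the same convention (angle from the row axis, same sign)
        rotation=region.orientation,
    )
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def classify_sagittal(
    region: LabeledRegion, criteria: SagittalCriteria | None = None
) -> bool:
    """True iff the region looks like a single spore lying flat.

    Requires solidity >= min_solidity, aspect ratio inside aspect_range,
    and a symmetric-difference area between the region and its fitted
    ellipse of at most ellipse_residual_max x area_px.
    """
    if region.area_px < 1:
        raise ValidationError("region is empty")
    criteria = criteria or SagittalCriteria()
    if region.minor_axis_px <= 0:  # degenerate (e.g. 1-px) region
        return False
    if region.solidity < criteria.min_solidity:
        return False
    aspect = region.aspect_ratio
    if not criteria.aspect_range[0] <= aspect <= criteria.aspect_range[1]:
        return False
    ell = _ellipse_mask(region, region.mask.shape)
    residual = np.logical_xor(region.mask, ell).sum() / region.area_px
    return bool(residual <= criteria.ellipse_residual_max)


def measure_conidium(
    region: LabeledRegion,
    scale: CalibrationScale,
    isolate_id: str = "",
    replicate_id: str = "",
) -> ConidiumMeasure:
    """Measure one sagittal conidium in micrometers.

    Length and width are the fitted-ellipse major/minor axes; area is the
    pixel count, so irregular spores are measured as imaged.
    """
    if region.minor_axis_px <= 0:
        raise ValidationError("region has zero minor axis; cannot measure")
    s = scale.pixels_per_micron
    length = region.major_axis_px / s
    width = region.minor_axis_px / s
    area = region.area_px / (s * s)
    # The moment-equivalent ellipse of a rasterized ellipse can have
    # area (pi/4 * L * W) slightly below the pixel count; the bounding-box
    # invariant still holds because pi/4 < 1.
    return ConidiumMeasure(
        length_um=length,
        width_um=width,
        area_um2=min(area, length * width),
        sagittal=True,
        isolate_id=isolate_id,
        replicate_id=replicate_id,
    )


def _skeleton_graph(skel: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Return skeleton pixel coordinates and 8-neighbour adjacency."""
    coords = np.argwhere(skel)
    return coords, [tuple(rc) for rc in coords]


def _longest_geodesic(skel: np.ndarray) -> tuple[float, list[tuple[int, int]]]:
    """Longest shortest-path through the skeleton (two-sweep BFS-style).

    Edge weights are 1 for 4-neighbours and sqrt(2) for diagonals.  Returns
    (length in px, path as list of pixel coordinates).
    """
    import heapq

    coords = np.argwhere(skel)
    pixel_ids = {tuple(rc): i for i, rc in enumerate(map(tuple, coords))}
    n = len(coords)
    if n == 0:
        raise ValidationError("empty skeleton")
    neighbours: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for (r, c), i in pixel_ids.items():
        for dr, dc in offsets:
            j = pixel_ids.get((r + dr, c + dc))
            if j is not None:
                neighbours[i].append((j, float(np.hypot(dr, dc))))

    def dijkstra(src: int) -> tuple[np.ndarray, np.ndarray]:
        dist = np.full(n, np.inf)
        prev = np.full(n, -1, dtype=int)
        dist[src] = 0.0
        heap = [(0.0, src)]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist[u]:
                continue
            for v, w in neighbours[u]:
                nd = d + w
                if nd < dist[v]:
                    dist[v] = nd
                    prev[v] = u
                    heapq.heappush(heap, (nd, v))
        return dist, prev

    dist0, _ = dijkstra(0)
    far = int(np.argmax(np.where(np.isfinite(dist0), dist0, -1)))
    dist1, prev = dijkstra(far)
    end = int(np.argmax(np.where(np.isfinite(dist1), dist1, -1)))
    path_ids = []
    u = end
    while u != -1:
        path_ids.append(u)
        u = int(prev[u]) if u != far else -1
    path = [tuple(coords[i]) for i in reversed(path_ids)]
    return float(dist1[end]), path


def measure_conidiophore(
    region: LabeledRegion,
    scale: CalibrationScale,
    isolate_id: str = "",
    replicate_id: str = "",
    n_base_pixels: int = 3,
) -> ConidiophoreMeasure:
    """Measure an elongated stalk: geodesic length and width at its base.

    Total length is the longest geodesic path along the morphological
    skeleton, extended at each end by the endpoint's distance to the region
    boundary (the skeleton stops about half a width short of each tip).
    Local width is twice the Euclidean distance transform at skeleton
    pixels; the basal end is the skeleton endpoint with the larger local
    width, and base width averages the ``n_base_pixels`` skeleton pixels
    nearest that endpoint.

    The elongation precondition (length more than twice the mean width,
    i.e. an aspect clearly above 2) rejects compact blobs; it is checked on
    the skeleton geometry so that curved or L-shaped stalks still qualify.
    """
    skel = morphology.skeletonize(region.mask)
    if not skel.any():
        raise ValidationError("region skeletonized to nothing")
    # endpoints = skeleton pixels with exactly one 8-neighbour
    neighbour_count = ndi.convolve(skel.astype(int), np.ones((3, 3), int),
                                   mode="constant") - 1
    if not np.any(skel & (neighbour_count == 1)):
        raise ValidationError("skeleton has no endpoints (ring-like region)")
    length_px, path = _longest_geodesic(skel)
    if length_px <= 0 or len(path) < 2:
        raise ValidationError("degenerate skeleton")
    edt = ndi.distance_transform_edt(region.mask)
    width_at = lambda rc: 2.0 * edt[rc]  # noqa: E731
    length_px += edt[path[0]] + edt[path[-1]]
    mean_width_px = float(np.mean([width_at(rc) for rc in path]))
    if mean_width_px > 0 and length_px / mean_width_px <= 2:
        raise ValidationError(
            f"region aspect ratio {length_px / mean_width_px:.2f} <= 2; "
            "not an elongated structure"
        )
    # basal endpoint = path end with larger local width
    if width_at(path[0]) >= width_at(path[-1]):
        base_path = path[:n_base_pixels]
    else:
        base_path = path[::-1][:n_base_pixels]
    base_width_px = float(np.mean([width_at(rc) for rc in base_path]))
    s = scale.pixels_per_micron
    return ConidiophoreMeasure(
        total_length_um=length_px / s,
        base_width_um=base_width_px / s,
        isolate_id=isolate_id,
        replicate_id=replicate_id,
    )


def summarize_traits(values: Sequence[float], trait: str = "") -> TraitSummary:
    """Sample mean, SD (n-1 denominator), min, max, and n of one trait."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot summarize an empty set of measures")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return TraitSummary(
        trait=trait,
        mean=float(arr.mean()),
        sd=sd,
        min=float(arr.min()),
        max=float(arr.max()),
        n=int(arr.size),
    )


def measure_micrograph(
    micrograph: Micrograph,
    min_area_um2: float = 1.0,
    max_area_um2: float = 50.0,
    criteria: SagittalCriteria | None = None,
    isolate_id: str = "",
    replicate_id: str = "",
) -> list[ConidiumMeasure]:
    """Full pipeline: segment, gate to sagittal spores, measure."""
    regions = segment_objects(micrograph, min_area_um2, max_area_um2)
    out = []
    for region in regions:
        if classify_sagittal(region, criteria):
            out.append(
                measure_conidium(
                    region, micrograph.scale, isolate_id=isolate_id,
                    replicate_id=replicate_id,
                )
            )
    return out
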