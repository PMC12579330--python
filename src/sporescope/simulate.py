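"""Seeded synthetic fixtures for every pipeline stage.

Three generators emulate the statistical structure of real study data so
the whole toolkit is testable without any download:

* micrograph fields of ellipsoidal spores with dimensions drawn from
  truncated normal distributions (defaults: length 4.4 +/- 0.4 µm on
  [3.4, 5.5], width 2.0 +/- 0.2 µm on [1.5, 2.6]), plus optional
  "oblique" objects (overlapping ellipse pairs) that the sagittal filter
  must reject;
* flow-cytometry channel histograms as Gaussian peaks with a stated CV
  plus an optional exponential debris background;
* tidy morphometric observation tables with the nested factor layout
  site x host ploidy / individual / replicate.

Every generator is a pure function of its spec (which includes the seed):
identical inputs give byte-identical outputs, and ground truth is always
returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .cytometry import EventHistogram, bin_events
from .errors import ValidationError
from .morphometry import CalibrationScale, Micrograph

# ---------------------------------------------------------------------------
# micrographs


@dataclass(frozen=True)
class SporeFieldSpec:
    """Layout and optics of one synthetic spore micrograph."""

    n_sagittal: int = 10
    n_oblique: int = 0
    length_mean_um: float = 4.4
    length_sd_um: float = 0.4
    length_range_um: tuple[float, float] = (3.4, 5.5)
    width_mean_um: float = 2.0
    width_sd_um: float = 0.2
    width_range_um: tuple[float, float] = (1.5, 2.6)
    pixels_per_micron: float = 15.8097
    shape: tuple[int, int] = (700, 700)
    background: float = 1.0
    foreground: float = 0.2
    noise_sd: float = 0.02
    blur_sigma: float = 0.8
    min_separation_px: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sagittal < 0 or self.n_oblique < 0:
            raise ValidationError("object counts must be non-negative")
        if self.length_range_um[0] <= 0 or self.width_range_um[0] <= 0:
            raise ValidationError("dimension ranges must have positive support")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    """Rejection sampling keeps the support exact and the code obvious."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def _render_ellipse(canvas: np.ndarray, cy: float, cx: float,
                    a_px: float, b_px: float, theta: float,
                    value: float, supersample: int = 4) -> None:
    """Draw an anti-aliased filled ellipse by subpixel coverage."""
    h, w = canvas.shape
    r = int(np.ceil(max(a_px, b_px))) + 2
    r0, r1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
    c0, c1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    yy, xx = np.mgrid[r0:r1, c0:c1]
    cover = np.zeros((r1 - r0, c1 - c0))
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    for oy in offs:
        for ox in offs:
            dy = yy + oy - cy
            dx = xx + ox - cx
            u = dy * cos_t + dx * sin_t      # along major axis
            v = -dy * sin_t + dx * cos_t     # along minor axis
            cover += (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    cover /= supersample ** 2
    patch = canvas[r0:r1, c0:c1]
    canvas[r0:r1, c0:c1] = patch * (1 - cover) + value * cover


def synth_micrograph(spec: SporeFieldSpec) -> tuple[Micrograph, pd.DataFrame]:
    """Render a spore field and return it with its ground-truth table.

    Truth rows carry the analytic length, width, and area (pi a b) of each
    sagittal spore in µm / µm²; oblique objects (overlapping ellipse pairs)
    appear with ``kind='oblique'`` and NaN dimensions.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.pixels_per_micron
    h, w = spec.shape
    canvas = np.full(spec.shape, spec.background, dtype=float)

    n = spec.n_sagittal
    lengths = _truncated_normal(rng, spec.length_mean_um, spec.length_sd_um,
                                *spec.length_range_um, size=n)
    widths = _truncated_normal(rng, spec.width_mean_um, spec.width_sd_um,
                               *spec.width_range_um, size=n)

    placed: list[tuple[float, float, float]] = []  # (cy, cx, clearance radius)

    def place(radius_px: float, max_tries: int = 2000) -> tuple[float, float]:
        margin = radius_px + 4
        if 2 * margin >= min(h, w):
            raise ValidationError("canvas too small for requested objects")
        for _ in range(max_tries):
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if all(np.hypot(cy - py, cx - px) >
                   radius_px + pr + spec.min_separation_px
                   for py, px, pr in placed):
                placed.append((cy, cx, radius_px))
                return cy, cx
        raise ValidationError(
            "could not place all objects without overlap; use a larger canvas"
        )

    rows = []
    for i in range(n):
        a = lengths[i] * s / 2.0
        b = widths[i] * s / 2.0
        theta = rng.uniform(0, np.pi)
        cy, cx = place(a)
        _render_ellipse(canvas, cy, cx, a, b, theta, spec.foreground)
        rows.append({
            "object_id": i + 1, "kind": "sagittal",
            "length_um": lengths[i], "width_um": widths[i],
            "area_um2": np.pi * lengths[i] * widths[i] / 4.0,
            "center_row": cy, "center_col": cx, "orientation": theta,
        })

    for j in range(spec.n_oblique):
        L = _truncated_normal(rng, spec.length_mean_um, spec.length_sd_um,
                              *spec.length_range_um, size=1)[0]
        W = _truncated_normal(rng, spec.width_mean_um, spec.width_sd_um,
                              *spec.width_range_um, size=1)[0]
        a, b = L * s / 2.0, W * s / 2.0
        theta = rng.uniform(0, np.pi)
        cy, cx = place(1.6 * a)
        # two partially overlapping ellipses at an angle: a concave
        # dumbbell the solidity gate must reject
        dtheta = rng.uniform(np.pi / 4, np.pi / 2)
        off = 0.8 * a
        _render_ellipse(canvas, cy, cx, a, b, theta, spec.foreground)
        _render_ellipse(canvas, cy + off * np.cos(theta + dtheta),
                        cx + off * np.sin(theta + dtheta),
                        a, b, theta + dtheta, spec.foreground)
        rows.append({
            "object_id": n + j + 1, "kind": "oblique",
            "length_um": np.nan, "width_um": np.nan, "area_um2": np.nan,
            "center_row": cy, "center_col": cx, "orientation": theta,
        })

    if spec.blur_sigma > 0:
        canvas = ndi.gaussian_filter(canvas, spec.blur_sigma)
    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0, spec.noise_sd, size=canvas.shape)

    truth = pd.DataFrame(rows)
    mg = Micrograph(intensities=canvas,
                    scale=CalibrationScale(spec.pixels_per_micron))
    return mg, truth


# ---------------------------------------------------------------------------
# flow cytometry


@dataclass(frozen=True)
class FcSimSpec:
    """Gaussian fluorescence peaks plus optional exponential debris."""

    peaks: tuple[tuple[float, float, int], ...] = ((200.0, 5.0, 10_000),)
    debris_fraction: float = 0.0
    debris_decay: float = 50.0       # exponential scale, channel units
    n_channels: int = 1024
    channel_max: float = 1024.0
    seed: int = 0

    def __post_init__(self) -> None:
        for mean, cv, events in self.peaks:
            if events <= 0:
                raise ValidationError("peak events must be positive")
            if cv <= 0:
                raise ValidationError("peak cv_percent must be positive")
            if not 0 < mean < self.channel_max:
                raise ValidationError("peak mean outside channel range")
        if not 0 <= self.debris_fraction < 1:
            raise ValidationError("debris_fraction must be in [0, 1)")


def synth_fc_histogram(spec: FcSimSpec) -> tuple[EventHistogram, pd.DataFrame]:
    """Simulate a channel histogram and return it with peak/debris truth."""
    rng = np.random.default_rng(spec.seed)
    chunks, rows = [], []
    total_peak_events = sum(ev for _, _, ev in spec.peaks)
    if total_peak_events == 0:
        raise ValidationError("no events requested")
    for mean, cv, events in spec.peaks:
        draw = rng.normal(mean, cv * mean / 100.0, size=events)
        draw = np.clip(draw, 1e-6, spec.channel_max - 1e-6)
        chunks.append(draw)
        rows.append({"kind": "peak", "mean_channel": mean,
                     "cv_percent": cv, "events": events})
    n_debris = int(round(spec.debris_fraction / (1 - spec.debris_fraction)
                         * total_peak_events))
    if n_debris > 0:
        deb = rng.exponential(spec.debris_decay, size=n_debris)
        deb = deb[deb < spec.channel_max]
        chunks.append(np.clip(deb, 1e-6, None))
        rows.append({"kind": "debris", "mean_channel": np.nan,
                     "cv_percent": np.nan, "events": len(deb)})
    events_all = np.concatenate(chunks)
    counts, edges = np.histogram(events_all, bins=spec.n_channels,
                                 range=(0.0, spec.channel_max))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EventHistogram(centers, counts), pd.DataFrame(rows)


def synth_fc_events(spec: FcSimSpec) -> np.ndarray:
    """Raw event intensities for the same model (for event-list CSV fixtures)."""
    rng = np.random.default_rng(spec.seed)
    chunks = []
    for mean, cv, events in spec.peaks:
        chunks.append(np.clip(rng.normal(mean, cv * mean / 100.0, size=events),
                              1e-6, spec.channel_max - 1e-6))
    return np.concatenate(chunks)


# ---------------------------------------------------------------------------
# morphometric tables


TRAITS_DEFAULT: dict[str, tuple[float, float, float]] = {
    # trait -> (grand mean, individual-level SD, replicate-level SD)
    "conidium_length_um": (4.4, 0.2, 0.35),
    "conidium_width_um": (2.0, 0.1, 0.18),
    "conidium_area_um2": (7.1, 0.5, 0.9),
    "conidiophore_length_um": (12.4, 1.2, 2.0),
    "conidiophore_width_um": (1.8, 0.15, 0.35),
}

CELLS_DEFAULT: tuple[tuple[str, str], ...] = (
    ("Mon", "4x"), ("Can", "4x"), ("Cab", "6x"), ("Can", "8x"),
)


@dataclass(frozen=True)
class MorphSimSpec:
    """Nested-design trait table: site x ploidy cells / individuals / reps.

    ``site_effects`` and ``ploidy_effects`` map trait -> level -> additive
    shift; unlisted combinations default to zero.
    """

    cells: tuple[tuple[str, str], ...] = CELLS_DEFAULT
    individuals_per_cell: int = 4
    replicates_per_individual: int = 10
    traits: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(TRAITS_DEFAULT))
    site_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    ploidy_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.individuals_per_cell < 1 or self.replicates_per_individual < 1:
            raise ValidationError("layout counts must be >= 1")
        for trait, (_, sd_i, sd_r) in self.traits.items():
            if sd_i < 0 or sd_r < 0:
                raise ValidationError(f"negative variance component for {trait!r}")


def synth_morphtable(spec: MorphSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a tidy trait table; truth records every individual effect.

    trait value = grand mean + site effect + ploidy effect
                  + individual random effect + replicate noise
    """
    rng = np.random.default_rng(spec.seed)
    rows, truth_rows = [], []
    for site, ploidy in spec.cells:
        for ind in range(1, spec.individuals_per_cell + 1):
            ind_id = f"{site}{ploidy}_i{ind}"
            ind_effects = {
                trait: rng.normal(0, sd_i)
                for trait, (_, sd_i, _) in spec.traits.items()
            }
            truth_rows.append({"site": site, "host_ploidy": ploidy,
                               "individual": ind_id, **ind_effects})
            for rep in range(1, spec.replicates_per_individual + 1):
                row = {"site": site, "host_ploidy": ploidy,
                       "individual": ind_id, "replicate": f"r{rep}"}
                for trait, (mu, _, sd_r) in spec.traits.items():
                    val = (mu
                           + spec.site_effects.get(trait, {}).get(site, 0.0)
                           + spec.ploidy_effects.get(trait, {}).get(ploidy, 0.0)
                           + ind_effects[trait]
                           + rng.normal(0, sd_r))
                    row[trait] = val
                rows.append(row)
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
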