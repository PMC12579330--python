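"""Flow-cytometry peak calling, QC, and genome-size / ploidy estimation.

Genome size is estimated by the standard-ratio method: a sample's G1 peak
position on the fluorescence axis is compared with that of an internal
reference standard of known DNA content run in the same tube, so

    pg_sample = pg_standard x (mean_sample / mean_standard).

Peaks are single Gaussians fitted to a smoothed channel histogram; the
coefficient of variation (CV, 100 x sd/mean) of each peak is the standard
quality metric.  QC gates follow common practice for propidium-iodide
measurements: at least 5,000 nuclei per peak, CV below 3% for plant nuclei
and below 10% for fungal nuclei.

DNA mass converts to base pairs with 1 pg = 978 Mbp (configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .errors import InputFormatError, ValidationError

MBP_PER_PG = 978.0

#: Default monoploid (1Cx) reference for host-plant ploidy calls, in pg.
#: Convention derived from the mean monoploid content implied by the three
#: host cytotypes the toolkit was built around; override per study system.
DEFAULT_MONOPLOID_PG = 1.95


@dataclass(frozen=True)
class EventHistogram:
    """Counts per fluorescence channel."""

    channels: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", np.asarray(self.channels, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        if self.channels.ndim != 1 or self.channels.shape != self.counts.shape:
            raise ValidationError("channels and counts must be matching 1-D arrays")
        if self.channels.size == 0:
            raise ValidationError("empty histogram")
        if np.any(np.diff(self.channels) <= 0):
            raise ValidationError("channels must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")

    @property
    def total_events(self) -> int:
        return int(round(self.counts.sum()))


@dataclass(frozen=True)
class PeakCall:
    """One fitted fluorescence peak."""

    mean_channel: float
    cv_percent: float
    events: int

    def __post_init__(self) -> None:
        if self.mean_channel <= 0:
            raise ValidationError("mean_channel must be positive")
        if self.cv_percent < 0:
            raise ValidationError("cv_percent must be non-negative")
        if self.events < 0:
            raise ValidationError("events must be non-negative")


@dataclass(frozen=True)
class ReferenceStandard:
    """An internal DNA-content standard."""

    name: str
    genome_pg: float
    basis: str  # "2C" or "1C"

    def __post_init__(self) -> None:
        if self.genome_pg <= 0:
            raise ValidationError("genome_pg must be positive")
        if self.basis not in ("1C", "2C"):
            raise ValidationError("basis must be '1C' or '2C'")


#: Registry of the primary standards used for sizing; keys are normalized,
#: display names kept verbatim.
STANDARDS: dict[str, ReferenceStandard] = {
    "solanum": ReferenceStandard(
        "Solanum lycopersicum 'Stupicképolnírané'", 1.96, "2C"
    ),
    "pisum": ReferenceStandard("Pisum sativum 'Ctirad'", 9.09, "2C"),
    "secale": ReferenceStandard("Secale cereale 'Daňkovské'", 16.19, "2C"),
    "colletotrichum": ReferenceStandard(
        "Colletotrichum acutatum PT812", 0.069, "1C"
    ),
}


@dataclass(frozen=True)
class QcPolicy:
    """Acceptance gates for a peak pair (sample + standard)."""

    min_events: int = 5000
    cv_max_percent: float = 3.0

    def __post_init__(self) -> None:
        if self.min_events <= 0:
            raise ValidationError("min_events must be positive")
        if self.cv_max_percent <= 0:
            raise ValidationError("cv_max_percent must be positive")

    @classmethod
    def for_kingdom(cls, kingdom: str, min_events: int = 5000) -> "QcPolicy":
        """Plant nuclei gate at CV < 3%, fungal nuclei at CV < 10%."""
        limits = {"plant": 3.0, "fungus": 10.0}
        if kingdom not in limits:
            raise ValidationError(f"unknown kingdom {kingdom!r}; use plant|fungus")
        return cls(min_events=min_events, cv_max_percent=limits[kingdom])


@dataclass(frozen=True)
class GenomeSizeEstimate:
    pg: float
    mbp: float
    qc_pass: bool
    cv_sample: float
    cv_standard: float
    notes: str = ""


@dataclass(frozen=True)
class PloidyCall:
    ploidy: int
    residual: float


def read_cytometry(path: str | Path, format: str = "event-list-csv",
                   n_bins: int = 1024) -> EventHistogram:
    """Read cytometry data as a channel histogram.

    ``histogram-csv`` expects two columns (channel, count) and passes
    through unchanged; ``event-list-csv`` expects one intensity per row and
    is binned into ``n_bins`` equal-width bins over the observed range.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"cytometry file not found: {path}")
    if format == "fcs":
        raise InputFormatError(
            "FCS input is not supported in this build; export a delimited "
            "histogram or event list instead"
        )
    if format not in ("histogram-csv", "event-list-csv"):
        raise ValidationError(f"unknown cytometry format {format!r}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise InputFormatError(f"could not parse {path}: {exc}") from exc
    if df.empty:
        raise ValidationError(f"no data rows in {path}")
    if format == "histogram-csv":
        if df.shape[1] < 2:
            raise InputFormatError(f"{path}: histogram CSV needs channel,count columns")
        return EventHistogram(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())
    events = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(events))[0]
    if bad.size:
        raise InputFormatError(
            f"{path}: non-numeric intensity at data line {bad[0] + 1}"
        )
    return bin_events(events, n_bins=n_bins)


def bin_events(events: np.ndarray, n_bins: int = 1024) -> EventHistogram:
    """Bin an event list into an equal-width channel histogram."""
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        raise ValidationError("empty event list")
    if np.any(events < 0):
        raise ValidationError("negative fluorescence intensity in event list")
    lo, hi = events.min(), events.max()
    if hi == lo:
        hi = lo + 1.0
    counts, edges = np.histogram(events, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EventHistogram(centers, counts)


def _gaussian(x: np.ndarray, amp: float, mu: float, sd: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def detect_peaks(
    hist: EventHistogram,
    n_expected: int = 1,
    smooth_window: int = 11,
    min_peak_fraction: float = 0.01,
) -> list[PeakCall]:
    """Locate up to ``n_expected`` fluorescence peaks, low channel first.

    Candidate maxima are found by prominence on a Savitzky-Golay-smoothed
    histogram, then each is refined by a Gaussian least-squares fit within
    +/- 2 FWHM of the candidate.  CV is 100 x fitted sd / fitted mean;
    events integrates the observed counts within +/- 3 fitted sd.
    """
    if hist.total_events <= 0:
        raise ValidationError("histogram has no events")
    if n_expected < 1:
        raise ValidationError("n_expected must be >= 1")
    counts = hist.counts.astype(float)
    window = min(smooth_window, len(counts) - (1 - len(counts) % 2))
    if window >= 5:
        smoothed = signal.savgol_filter(counts, window_length=window, polyorder=3)
        smoothed = np.clip(smoothed, 0, None)
    else:
        smoothed = counts
    min_prom = max(min_peak_fraction * hist.total_events / max(len(counts) // 64, 1),
                   1.0)
    idx, props = signal.find_peaks(smoothed, prominence=min_prom)
    if idx.size == 0:
        warnings.warn("no peak above the prominence floor", stacklevel=2)
        return []
    order = np.argsort(props["prominences"])[::-1][:n_expected]
    calls: list[PeakCall] = []
    for i in idx[np.sort(order)]:
        call = _refine_peak(hist, smoothed, int(i))
        if call is not None and call.events >= min_peak_fraction * hist.total_events:
            calls.append(call)
    calls.sort(key=lambda c: c.mean_channel)
    if not calls:
        warnings.warn("no peak holding >=1% of total events", stacklevel=2)
    return calls


def _refine_peak(hist: EventHistogram, smoothed: np.ndarray,
                 i: int) -> PeakCall | None:
    channels, counts = hist.channels, hist.counts
    half = smoothed[i] / 2.0
    # crude FWHM from the smoothed trace
    left = i
    while left > 0 and smoothed[left] > half:
        left -= 1
    right = i
    while right < len(smoothed) - 1 and smoothed[right] > half:
        right += 1
    fwhm = max(channels[right] - channels[left], 2 * np.median(np.diff(channels)))
    lo = channels[i] - 2 * fwhm
    hi = channels[i] + 2 * fwhm
    sel = (channels >= lo) & (channels <= hi)
    x, y = channels[sel], counts[sel]
    if x.size < 5:
        return None
    sd0 = fwhm / 2.355
    try:
        popt, _ = optimize.curve_fit(
            _gaussian, x, y,
            p0=[max(counts[i], 1.0), channels[i], sd0],
            bounds=([0, x.min(), 1e-9], [np.inf, x.max(), (hi - lo)]),
            maxfev=10000,
        )
    except RuntimeError:
        return None
    amp, mu, sd = popt
    if mu <= 0 or sd <= 0:
        return None
    win = (channels >= mu - 3 * sd) & (channels <= mu + 3 * sd)
    events = int(round(counts[win].sum()))
    return PeakCall(mean_channel=float(mu), cv_percent=float(100.0 * sd / mu),
                    events=events)


def estimate_genome_size(
    sample_peak: PeakCall,
    standard_peak: PeakCall,
    standard: ReferenceStandard,
    policy: QcPolicy | None = None,
    mbp_per_pg: float = MBP_PER_PG,
) -> GenomeSizeEstimate:
    """Standard-ratio genome size: pg = standard pg x channel ratio.

    The estimate is on the same C-value basis (1C or 2C) as the standard.
    QC passes only if both peaks hold at least ``min_events`` events and
    both CVs are at or below ``cv_max_percent``.
    """
    if standard_peak.mean_channel <= 0:
        raise ValidationError("standard peak mean must be positive")
    policy = policy or QcPolicy()
    pg = standard.genome_pg * sample_peak.mean_channel / standard_peak.mean_channel
    qc = (
        sample_peak.events >= policy.min_events
        and standard_peak.events >= policy.min_events
        and sample_peak.cv_percent <= policy.cv_max_percent
        and standard_peak.cv_percent <= policy.cv_max_percent
    )
    notes = "" if qc else "failed QC gate"
    return GenomeSizeEstimate(
        pg=float(pg),
        mbp=float(pg * mbp_per_pg),
        qc_pass=bool(qc),
        cv_sample=sample_peak.cv_percent,
        cv_standard=standard_peak.cv_percent,
        notes=notes,
    )


def infer_ploidy(
    pg_2C: float,
    monoploid_pg: float = DEFAULT_MONOPLOID_PG,
    candidates: tuple[int, ...] = (4, 6, 8),
) -> PloidyCall:
    """Assign the candidate ploidy whose implied 1Cx is nearest the reference.

    Minimizes |pg_2C / p - monoploid_pg| over the candidate set; ties break
    toward the smaller ploidy.
    """
    if pg_2C <= 0 or monoploid_pg <= 0:
        raise ValidationError("pg values must be positive")
    if not candidates:
        raise ValidationError("candidate set is empty")
    best_p, best_r = None, np.inf
    for p in sorted(candidates):
        r = abs(pg_2C / p - monoploid_pg)
        if r < best_r - 1e-15:
            best_p, best_r = p, r
    return PloidyCall(ploidy=int(best_p), residual=float(best_r))


def pg_mb_convert(value: float, direction: str = "pg_to_mb",
                  mbp_per_pg: float = MBP_PER_PG) -> float:
    """Convert between picograms of DNA and megabase pairs (1 pg = 978 Mbp)."""
    if value <= 0:
        raise ValidationError("value must be positive")
    if direction == "pg_to_mb":
        return value * mbp_per_pg
    if direction == "mb_to_pg":
        return value / mbp_per_pg
    raise ValidationError(f"unknown direction {direction!r}")
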