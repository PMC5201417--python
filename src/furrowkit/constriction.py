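"""Apical constriction rate analysis normalized to myosin accumulation.

During ventral furrow formation, cells accumulate apical myosin in pulses
and constrict their apical surface.  Because the rate of myosin
accumulation varies between cells and correlates with constriction, raw
constriction rates cannot be compared directly between genotypes.  The
procedure implemented here normalizes for this: apical-area and myosin
intensity traces are smoothed, instantaneous rates computed, and
"accumulation events" detected as time points where a cell's myosin
accumulation rate lies within a band of [mean + 1 sd, mean + 2 sd] of the
pooled rate distribution of control cells.  Constriction rates compared
across genotypes are then conditioned on these matched-accumulation
instants, so a residual difference reflects how much constriction a unit
of myosin recruitment buys — the motor output — rather than recruitment
itself.

Tissue-level dynamics are summarized by aligning embryos at constriction
onset (from the smoothed mean-area derivative) and measuring the time for
the mean apical area to fall to 50% of its pre-onset value A0.

Units are minutes and µm² throughout; myosin intensity is in arbitrary
units (a.u.), rates in a.u./min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

__all__ = [
    "CellTrace",
    "EmbryoDataset",
    "ControlRateStats",
    "EventSet",
    "MyosinStack",
    "HalfTimeResult",
    "preprocess_myosin_stack",
    "smooth_trace",
    "instantaneous_rates",
    "control_rate_stats",
    "detect_accumulation_events",
    "constriction_rates_at_events",
    "genotype_event_rates",
    "align_embryos",
    "time_to_half_area",
    "intensity_profile_pair",
]

#: default Gaussian smoothing width for area/myosin traces, in frames
DEFAULT_TRACE_SIGMA = 2.0


@dataclass
class CellTrace:
    """Per-cell apical area (µm²) and mean apical myosin intensity (a.u.)."""

    cell_id: str
    times: np.ndarray  # minutes
    apical_area: np.ndarray
    myosin_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.apical_area = np.asarray(self.apical_area, dtype=float)
        self.myosin_intensity = np.asarray(self.myosin_intensity, dtype=float)
        n = self.times.size
        if self.apical_area.size != n or self.myosin_intensity.size != n:
            raise ValueError("times, area and myosin must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.apical_area <= 0):
            raise ValueError("apical area must be positive")


@dataclass
class EmbryoDataset:
    """All cell traces of one embryo, with genotype label and calibration."""

    embryo_id: str
    genotype: str
    cells: list[CellTrace]
    frame_interval: float  # seconds
    alignment_offset: float | None = None  # minutes; set by align_embryos
    unalignable: bool = False

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError("embryo must contain at least one cell")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def mean_area(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean apical area over cells at each time point."""
        times = self.cells[0].times
        stack = np.vstack([c.apical_area for c in self.cells])
        return times, stack.mean(axis=0)


def smooth_trace(values: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with reflective boundaries; length preserved."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 points to smooth")
    if sigma <= 0:
        return values.copy()
    return gaussian_filter1d(values, sigma=sigma, mode="reflect")


def instantaneous_rates(tr: CellTrace,
                        sigma: float = DEFAULT_TRACE_SIGMA
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous constriction and myosin-accumulation rates.

    Both channels are smoothed first, then differentiated by central
    differences (one-sided at the ends).  The constriction rate is
    -d(area)/dt, so positive values mean the apex is shrinking.

    Returns
    -------
    (constriction_rate, myosin_rate)
        µm²/min and a.u./min series, same length as the trace.
    """
    area = smooth_trace(tr.apical_area, sigma)
    myo = smooth_trace(tr.myosin_intensity, sigma)
    area_rate = -np.gradient(area, tr.times)
    myo_rate = np.gradient(myo, tr.times)
    return area_rate, myo_rate


@dataclass
class ControlRateStats:
    """Pooled myosin-accumulation-rate statistics of the control genotype."""

    mean_rate: float
    sd_rate: float
    n_points: int
    source_genotype: str


def control_rate_stats(controls: Sequence[EmbryoDataset],
                       sigma: float = DEFAULT_TRACE_SIGMA) -> ControlRateStats:
    """Mean and sd of myosin accumulation rate pooled over all control cells.

    Every time point of every cell of every control embryo enters the pool
    with equal weight.
    """
    if not controls:
        raise ValueError("need at least one control embryo")
    pool = []
    for emb in controls:
        for cell in emb.cells:
            _, myo_rate = instantaneous_rates(cell, sigma)
            pool.append(myo_rate)
    rates = np.concatenate(pool)
    if rates.size == 0:
        raise ValueError("control pool is empty")
    sd = float(rates.std(ddof=1)) if rates.size > 1 else 0.0
    return ControlRateStats(mean_rate=float(rates.mean()), sd_rate=sd,
                            n_points=int(rates.size),
                            source_genotype=controls[0].genotype)


@dataclass
class EventSet:
    """Detected rapid-myosin-accumulation instances.

    Instances are individual (cell_id, time index) pairs, not merged runs,
    so n(events) counts constriction instances directly.
    """

    instances: list[tuple[str, int]]
    lo_sd: float
    hi_sd: float

    def __post_init__(self) -> None:
        if not self.lo_sd < self.hi_sd:
            raise ValueError("lo_sd must be < hi_sd")

    def __len__(self) -> int:
        return len(self.instances)


def detect_accumulation_events(rates_by_cell: Mapping[str, np.ndarray],
                               stats: ControlRateStats,
                               lo: float = 1.0,
                               hi: float = 2.0) -> EventSet:
    """Flag time points whose myosin accumulation rate falls in the band
    [mean + lo*sd, mean + hi*sd] of the control statistics (closed
    interval, boundary ties included)."""
    if stats.sd_rate <= 0:
        raise ValueError("control sd must be positive for event detection")
    lo_thr = stats.mean_rate + lo * stats.sd_rate
    hi_thr = stats.mean_rate + hi * stats.sd_rate
    instances: list[tuple[str, int]] = []
    for cell_id, rates in rates_by_cell.items():
        rates = np.asarray(rates, dtype=float)
        idx = np.flatnonzero((rates >= lo_thr) & (rates <= hi_thr))
        instances.extend((cell_id, int(i)) for i in idx)
    return EventSet(instances=instances, lo_sd=lo, hi_sd=hi)


def constriction_rates_at_events(area_rates_by_cell: Mapping[str, np.ndarray],
                                 ev: EventSet) -> np.ndarray:
    """Constriction rates (µm²/min) at each flagged accumulation instance."""
    if len(ev) == 0:
        warnings.warn("empty event set; no constriction rates to report",
                      stacklevel=2)
        return np.empty(0)
    out = np.empty(len(ev))
    for j, (cell_id, idx) in enumerate(ev.instances):
        if cell_id not in area_rates_by_cell:
            raise KeyError(f"event references unknown cell {cell_id!r}")
        rates = np.asarray(area_rates_by_cell[cell_id], dtype=float)
        if not 0 <= idx < rates.size:
            raise IndexError(
                f"event index {idx} out of range for cell {cell_id!r}")
        out[j] = rates[idx]
    return out


def genotype_event_rates(embryos: Sequence[EmbryoDataset],
                         stats: ControlRateStats,
                         lo: float = 1.0, hi: float = 2.0,
                         sigma: float = DEFAULT_TRACE_SIGMA
                         ) -> tuple[np.ndarray, EventSet]:
    """Full per-genotype pipeline: rates, event detection, event-conditioned
    constriction rates, for a list of same-genotype embryos.

    Cell ids are namespaced by embryo id so cells from different embryos
    cannot collide.
    """
    area_rates: dict[str, np.ndarray] = {}
    myo_rates: dict[str, np.ndarray] = {}
    for emb in embryos:
        for cell in emb.cells:
            key = f"{emb.embryo_id}/{cell.cell_id}"
            a, m = instantaneous_rates(cell, sigma)
            area_rates[key] = a
            myo_rates[key] = m
    events = detect_accumulation_events(myo_rates, stats, lo=lo, hi=hi)
    if len(events) == 0:
        return np.empty(0), events
    return constriction_rates_at_events(area_rates, events), events


def align_embryos(datasets: Sequence[EmbryoDataset],
                  onset_slope_threshold: float = 1.0,
                  sustain_frames: int = 3,
                  sigma: float = DEFAULT_TRACE_SIGMA) -> list[EmbryoDataset]:
    """Detect constriction onset per embryo and set alignment offsets.

    Onset is the first time the smoothed mean-area derivative is at or
    below ``-onset_slope_threshold`` (µm²/min) for ``sustain_frames``
    consecutive frames.  ``alignment_offset`` is set to the onset time, so
    aligned time = time - offset puts every onset at 0.  Embryos with no
    onset are flagged ``unalignable``.
    """
    if sustain_frames < 1:
        raise ValueError("sustain_frames must be >= 1")
    for emb in datasets:
        times, mean_area = emb.mean_area()
        slope = np.gradient(smooth_trace(mean_area, sigma), times)
        below = slope <= -onset_slope_threshold
        onset_idx = None
        run = 0
        for i, b in enumerate(below):
            run = run + 1 if b else 0
            if run >= sustain_frames:
                onset_idx = i - sustain_frames + 1
                break
        if onset_idx is None:
            emb.unalignable = True
            emb.alignment_offset = None
        else:
            emb.unalignable = False
            emb.alignment_offset = float(times[onset_idx])
    return list(datasets)


@dataclass
class HalfTimeResult:
    """Time for mean apical area to fall to 50% of A0.

    A0 is the mean area 2 min before constriction onset; ``half_time`` is
    measured from onset.  ``censored`` is True when the series ends before
    reaching 0.5*A0 (half_time is then NaN).
    """

    a0: float
    half_time: float
    censored: bool


def time_to_half_area(mean_area: np.ndarray, times: np.ndarray,
                      onset_time: float = 0.0,
                      baseline_lead: float = 2.0) -> HalfTimeResult:
    """Compute A0 and the time to reach 50% of A0, from onset.

    A0 is the mean area interpolated at (onset - baseline_lead) minutes,
    clipped to the start of the series.  The 0.5*A0 crossing is located by
    linear interpolation between the bracketing frames.  A series that
    never crosses is reported as censored, not an error.
    """
    times = np.asarray(times, dtype=float)
    mean_area = np.asarray(mean_area, dtype=float)
    if times.size != mean_area.size or times.size < 2:
        raise ValueError("need matching series of length >= 2")
    t_ref = max(onset_time - baseline_lead, float(times[0]))
    a0 = float(np.interp(t_ref, times, mean_area))
    target = 0.5 * a0
    after = times >= onset_time
    t_a, area_a = times[after], mean_area[after]
    below = area_a <= target
    if not below.any():
        return HalfTimeResult(a0=a0, half_time=float("nan"), censored=True)
    j = int(np.argmax(below))
    if j == 0:
        return HalfTimeResult(a0=a0, half_time=float(t_a[0] - onset_time),
                              censored=False)
    t0, t1 = t_a[j - 1], t_a[j]
    y0, y1 = area_a[j - 1], area_a[j]
    t_cross = t0 + (y0 - target) / (y0 - y1) * (t1 - t0)
    return HalfTimeResult(a0=a0, half_time=float(t_cross - onset_time),
                          censored=False)


@dataclass
class MyosinStack:
    """Confocal myosin z-stack for one time frame, with cytoplasmic stats.

    ``data`` has shape (z, y, x).  The cytoplasmic mean and sd define the
    threshold that separates apical myosin structures from cytoplasmic
    background.
    """

    data: np.ndarray
    cyto_mean: float | None = None
    cyto_sd: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 2:
            raise ValueError("stack must be 3D with >= 2 z-slices")


def preprocess_myosin_stack(s: MyosinStack,
                            background_region: tuple[slice, slice] | None = None,
                            n_sd: float = 2.5,
                            smoothing_sigma: float = 0.5) -> np.ndarray:
    """Project apical myosin, suppressing cytoplasmic signal.

    For every (y, x) pixel the two brightest z-values are considered; of
    those, only values exceeding cyto_mean + ``n_sd``*cyto_sd are kept and
    the projection is their maximum (0 where neither qualifies).  The
    projection is then Gaussian smoothed (σ = 0.5 px by default).

    Cytoplasmic statistics come from the stack's own fields or, failing
    that, are estimated over ``background_region`` (a (y, x) slice pair
    applied to every z-slice).
    """
    if s.cyto_mean is not None and s.cyto_sd is not None:
        mean, sd = s.cyto_mean, s.cyto_sd
    elif background_region is not None:
        ys, xs = background_region
        bg = s.data[:, ys, xs]
        mean, sd = float(bg.mean()), float(bg.std(ddof=0))
    else:
        raise ValueError(
            "cytoplasmic statistics missing: provide cyto_mean/cyto_sd on "
            "the stack or a background_region to estimate them")
    threshold = mean + n_sd * sd

    top2 = np.sort(s.data, axis=0)[-2:]  # two brightest z-values per pixel
    qualifying = np.where(top2 > threshold, top2, -np.inf)
    projection = qualifying.max(axis=0)
    projection[~np.isfinite(projection)] = 0.0
    if smoothing_sigma > 0:
        projection = gaussian_filter(projection, sigma=smoothing_sigma)
    return projection


def intensity_profile_pair(img_a: np.ndarray, img_b: np.ndarray,
                           pixel_size: float,
                           line_length: float = 33.0,
                           smoothing_sigma: float = 1.0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Myosin intensity profiles of two embryos imaged side by side.

    Each image is a z-stack (z, y, x) or a time series of z-stacks
    (t, z, y, x) sharing one calibration (``pixel_size``, µm/px).  Images
    are Gaussian smoothed (σ in px), maximum-projected over z, and — for
    time series — the frame of peak total intensity is selected per
    embryo.  The profile is the mean intensity over the image width (y)
    along a ``line_length`` µm window centred on the profile peak.

    Because the two embryos are acquired in the same field under identical
    illumination, the two profiles are directly comparable in absolute
    units.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")

    def profile(img: np.ndarray) -> np.ndarray:
        img = np.asarray(img, dtype=float)
        if img.ndim == 3:
            frames = img[None]
        elif img.ndim == 4:
            frames = img
        else:
            raise ValueError("image must be (z, y, x) or (t, z, y, x)")
        projections = []
        for frame in frames:
            smoothed = np.stack([
                gaussian_filter(zslice, sigma=smoothing_sigma)
                for zslice in frame])
            projections.append(smoothed.max(axis=0))
        peak = int(np.argmax([p.sum() for p in projections]))
        proj = projections[peak]
        full = proj.mean(axis=0)  # mean across the width (y)
        n_window = min(int(round(line_length / pixel_size)), full.size)
        centre = int(np.argmax(full))
        lo = int(np.clip(centre - n_window // 2, 0, full.size - n_window))
        return full[lo:lo + n_window]

    prof_a = profile(img_a)
    prof_b = profile(img_b)
    if prof_a.size != prof_b.size:
        raise ValueError("images do not share calibration / field size")
    return prof_a, prof_b
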