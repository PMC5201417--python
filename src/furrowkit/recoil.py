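"""Laser-ablation recoil analysis: wound-edge tracking and viscoelastic fits.

After a line incision in an epithelium under tension, the flanking tissue
recoils away from the cut.  The displacement of the wound edge x(t) is
modelled as a Kelvin-Voigt element (spring of stiffness ζ and dashpot of
viscosity η in parallel, loaded by tissue tension T):

    x(t) = (T/ζ) (1 - exp(-ζ t / η)) = A (1 - exp(-t/τ))

Only the lumped parameters A = T/ζ (recoil amplitude, µm) and τ = η/ζ
(relaxation time, s) are identifiable from displacement alone; the initial
recoil velocity v0 = A/τ = T/η (µm/s) is the tension read-out at constant
viscosity.  A power law x(t) = β t^α provides a model-free descriptor of
tissue viscoelasticity (α -> 1 fluid-like, α -> 0 solid-like).  Fits with
R² of 50% or less are flagged as not accepted and excluded from cohort
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes, remove_small_objects

__all__ = [
    "Kymograph",
    "DisplacementTrace",
    "KelvinVoigtFit",
    "PowerLawFit",
    "CohortSummary",
    "extract_edges",
    "fit_kelvin_voigt",
    "initial_recoil_velocity",
    "time_decay_constant",
    "fit_power_law",
    "recoil_cohort_summary",
]

#: analysis window along the incision, µm (centre of the cut)
DEFAULT_REGION_WIDTH = 4.25
#: minimal R² for a fit to enter downstream statistics
R2_MIN = 0.5


@dataclass
class Kymograph:
    """Space x time image of an ablation with physical calibration.

    ``image`` rows are time frames, columns are positions along the cut.
    ``cut_position`` is the incision centre in µm along the spatial axis;
    only the central ``region_width`` µm around it are analysed.
    """

    image: np.ndarray
    pixel_size: float
    frame_interval: float
    cut_position: float
    region_width: float = DEFAULT_REGION_WIDTH

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("kymograph image must be 2D (time x space)")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.image.shape[0]) * self.frame_interval

    @property
    def positions(self) -> np.ndarray:
        """Pixel-centre coordinates along the spatial axis, µm."""
        return (np.arange(self.image.shape[1]) + 0.5) * self.pixel_size


@dataclass
class DisplacementTrace:
    """Wound-edge displacement vs time for one ablation.

    t = 0 is the first post-cut frame.  Frames where no wound edge could
    be located carry NaN displacement (missing, not zero).
    """

    times: np.ndarray
    displacement: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.times.shape != self.displacement.shape:
            raise ValueError("times and displacement must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(self.displacement < 0):
                raise ValueError("displacement must be non-negative")

    @property
    def n_valid(self) -> int:
        return int(np.sum(np.isfinite(self.displacement)))

    def valid(self) -> tuple[np.ndarray, np.ndarray]:
        m = np.isfinite(self.displacement)
        return self.times[m], self.displacement[m]


def extract_edges(k: Kymograph, threshold_method: str = "otsu",
                  threshold: float | None = None,
                  min_object_px: int = 3) -> DisplacementTrace:
    """Extract wound-edge displacement from a kymograph.

    The image is binarized (Otsu by default, or a fixed ``threshold``),
    specks smaller than ``min_object_px`` are removed from foreground and
    background, and per time row the dark (wound) run nearest the cut
    position within the analysis region is measured.  Displacement is the
    edge-to-edge wound distance divided by two (each edge moves half the
    opening).  Rows without a detectable wound give NaN.
    """
    if threshold_method == "fixed":
        if threshold is None:
            raise ValueError("fixed threshold_method requires a threshold value")
        thr = threshold
    elif threshold_method == "otsu":
        thr = threshold_otsu(k.image)
    else:
        raise ValueError(f"unknown threshold_method: {threshold_method!r}")

    tissue = k.image > thr
    if min_object_px > 1:
        tissue = remove_small_objects(tissue, max_size=min_object_px - 1)
        tissue = remove_small_holes(tissue, max_size=min_object_px - 1)

    pos = k.positions
    half_w = k.region_width / 2.0
    region = np.abs(pos - k.cut_position) <= half_w
    if not region.any():
        raise ValueError("analysis region lies outside the kymograph")
    region_idx = np.flatnonzero(region)

    n_frames = k.image.shape[0]
    disp = np.full(n_frames, np.nan)
    for row in range(n_frames):
        wound = ~tissue[row, region_idx]
        if not wound.any():
            continue
        # connected runs of wound pixels within the region
        padded = np.concatenate(([False], wound, [False])).astype(int)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)  # exclusive
        # pick the run nearest (containing, ideally) the cut position
        centres = pos[region_idx[(starts + ends - 1) // 2]]
        best = int(np.argmin(np.abs(centres - k.cut_position)))
        width_px = int(ends[best] - starts[best])
        disp[row] = 0.5 * width_px * k.pixel_size

    if not np.any(np.isfinite(disp)):
        warnings.warn("no wound detected in any frame (uncut tissue?)",
                      stacklevel=2)
    return DisplacementTrace(times=k.times, displacement=disp,
                             metadata={"pixel_size": k.pixel_size})


def _kv_model(t: np.ndarray, amplitude: float, tau: float) -> np.ndarray:
    return amplitude * (1.0 - np.exp(-t / tau))


@dataclass
class KelvinVoigtFit:
    """Kelvin-Voigt fit x(t) = A (1 - exp(-t/τ)).

    v0 = A/τ is the initial recoil velocity (tension over viscosity);
    ``accepted`` is True iff R² > 0.5 and the optimizer converged.
    """

    amplitude: float
    tau: float
    r_squared: float
    accepted: bool
    converged: bool
    n_points: int
    standard_errors: dict[str, float] = field(default_factory=dict)

    @property
    def v0(self) -> float:
        return self.amplitude / self.tau

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return _kv_model(np.asarray(t, dtype=float), self.amplitude, self.tau)


@dataclass
class PowerLawFit:
    """Power-law fit x(t) = β t^α (t > 0)."""

    beta: float
    alpha: float
    r_squared: float
    accepted: bool
    converged: bool
    n_points: int

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.beta * np.asarray(t, dtype=float) ** self.alpha


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_kelvin_voigt(tr: DisplacementTrace, r2_min: float = R2_MIN) -> KelvinVoigtFit:
    """Least-squares Kelvin-Voigt fit of a displacement trace.

    Requires at least 5 non-missing points and a trace whose time axis
    starts at the first post-cut frame (t = 0).  Missing frames are
    dropped from the fit.  Initial guesses: A from the maximal observed
    displacement, τ from the time at which (1 - 1/e) of that maximum is
    first reached.
    """
    t, x = tr.valid()
    if tr.n_valid < 5:
        raise ValueError("need >= 5 non-missing displacement points")
    if tr.times[0] != 0:
        raise ValueError("trace must start at t = 0 (first post-cut frame)")

    a0 = max(float(x.max()), 1e-9)
    reach = t[x >= (1 - np.exp(-1)) * a0]
    tau0 = float(reach[0]) if reach.size and reach[0] > 0 else max(
        float(t[-1]) / 3.0, 1e-6)
    try:
        popt, pcov = curve_fit(_kv_model, t, x, p0=[a0, tau0],
                               bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                               maxfev=20000)
    except RuntimeError:
        return KelvinVoigtFit(np.nan, np.nan, np.nan, accepted=False,
                              converged=False, n_points=int(t.size))
    amplitude, tau = float(popt[0]), float(popt[1])
    r2 = _r2(x, _kv_model(t, amplitude, tau))
    se = np.sqrt(np.diag(pcov))
    return KelvinVoigtFit(
        amplitude=amplitude, tau=tau, r_squared=r2,
        accepted=r2 > r2_min, converged=True, n_points=int(t.size),
        standard_errors={"amplitude": float(se[0]), "tau": float(se[1])})


def initial_recoil_velocity(f: KelvinVoigtFit) -> float:
    """Initial recoil velocity v0 = A/τ (µm/s) of an accepted fit.

    v0 equals dx/dt at t = 0 and is proportional to the pre-cut tissue
    tension at constant viscosity.
    """
    if not f.accepted:
        raise ValueError(
            f"fit not accepted (R² = {f.r_squared:.3f} <= {R2_MIN}); "
            "v0 is not meaningful")
    return f.v0


def time_decay_constant(f: KelvinVoigtFit) -> float:
    """Relaxation time τ = η/ζ (s) of an accepted fit."""
    if not f.accepted:
        raise ValueError(
            f"fit not accepted (R² = {f.r_squared:.3f} <= {R2_MIN}); "
            "τ is not meaningful")
    return f.tau


def _power_model(t: np.ndarray, beta: float, alpha: float) -> np.ndarray:
    return beta * np.power(t, alpha)


def fit_power_law(tr: DisplacementTrace, r2_min: float = R2_MIN) -> PowerLawFit:
    """Least-squares power-law fit x = β t^α on the points with t > 0.

    t = 0 is excluded because the power law is singular in α there.  The
    fit is performed on displacement directly (not log-log), matching the
    least-squares treatment of the Kelvin-Voigt fit.
    """
    t, x = tr.valid()
    m = t > 0
    t, x = t[m], x[m]
    if t.size < 5:
        raise ValueError("need >= 5 non-missing points with t > 0")
    beta0 = max(float(x[-1]) / float(t[-1]) ** 0.5, 1e-9)
    try:
        popt, _ = curve_fit(_power_model, t, x, p0=[beta0, 0.5],
                            bounds=([1e-12, 1e-6], [np.inf, 10.0]),
                            maxfev=20000)
    except RuntimeError:
        return PowerLawFit(np.nan, np.nan, np.nan, accepted=False,
                           converged=False, n_points=int(t.size))
    beta, alpha = float(popt[0]), float(popt[1])
    r2 = _r2(x, _power_model(t, beta, alpha))
    return PowerLawFit(beta=beta, alpha=alpha, r_squared=r2,
                       accepted=r2 > r2_min, converged=True,
                       n_points=int(t.size))


@dataclass
class CohortSummary:
    """Per-genotype recoil statistics.

    ``table`` has one row per genotype with distribution summaries
    (median, quartiles, min, max) of v0, τ and α over accepted fits plus
    counts of excluded (R² <= 0.5 or failed) fits.  ``mean_displacement``
    maps genotype -> (times, mean, sd) over that genotype's traces.
    """

    table: pd.DataFrame
    mean_displacement: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]


def _dist_stats(values: Sequence[float], prefix: str) -> dict[str, float]:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return {f"{prefix}_{s}": float("nan")
                for s in ("median", "q25", "q75", "min", "max")}
    return {
        f"{prefix}_median": float(np.median(v)),
        f"{prefix}_q25": float(np.percentile(v, 25)),
        f"{prefix}_q75": float(np.percentile(v, 75)),
        f"{prefix}_min": float(v.min()),
        f"{prefix}_max": float(v.max()),
    }


def recoil_cohort_summary(
    kv_fits: Mapping[str, Sequence[KelvinVoigtFit]],
    power_fits: Mapping[str, Sequence[PowerLawFit]] | None = None,
    traces: Mapping[str, Sequence[DisplacementTrace]] | None = None,
) -> CohortSummary:
    """Summarize recoil mechanics per genotype.

    Only accepted fits (R² > 0.5, converged) enter the distribution
    statistics; excluded counts are reported alongside.
    """
    rows = []
    for genotype, fits in kv_fits.items():
        accepted = [f for f in fits if f.accepted]
        if not accepted:
            raise ValueError(f"no accepted Kelvin-Voigt fit for {genotype!r}")
        row: dict[str, object] = {
            "genotype": genotype,
            "n_fits": len(fits),
            "n_excluded_kv": len(fits) - len(accepted),
        }
        row.update(_dist_stats([f.v0 for f in accepted], "v0"))
        row.update(_dist_stats([f.tau for f in accepted], "tau"))
        if power_fits is not None and genotype in power_fits:
            pf = list(power_fits[genotype])
            pacc = [f for f in pf if f.accepted]
            row["n_excluded_power"] = len(pf) - len(pacc)
            row.update(_dist_stats([f.alpha for f in pacc], "alpha"))
        rows.append(row)

    curves: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    if traces is not None:
        for genotype, trs in traces.items():
            stack = np.vstack([tr.displacement for tr in trs])
            times = trs[0].times
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean = np.nanmean(stack, axis=0)
                sd = np.nanstd(stack, axis=0, ddof=1) if stack.shape[0] > 1 \
                    else np.zeros_like(mean)
            curves[genotype] = (times, mean, sd)

    return CohortSummary(table=pd.DataFrame(rows), mean_displacement=curves)
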