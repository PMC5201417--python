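"""Steady-state ATPase kinetics and in vitro motility analysis.

Characterizes an allelic series of myosin regulatory-light-chain (RLC)
variants by fitting actin-activated ATP-hydrolysis rates to the
Michaelis-Menten model

    rate([A]) = k_basal + k_cat * [A] / (K_app + [A])

where ``k_basal`` is the basal hydrolysis rate without actin (s^-1),
``k_cat`` the maximal actin-activated rate (s^-1), and ``K_app`` the
apparent actin affinity (µM).  When a variant's rate depends nearly
linearly on actin over the assayed range, ``k_cat`` and ``K_app`` are not
separately identifiable; the model-free statistic ``k_100`` (the measured
rate at 100 µM actin) is then used to compare variants, via fold-activation
(phosphorylated / unphosphorylated) and percent-of-reference ratios.

Also provides per-filament track speeds for the in vitro motility assay,
with optional stage-drift correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ATPaseDataset",
    "MMParams",
    "MMFit",
    "K100Summary",
    "TrackSet",
    "michaelis_menten",
    "fit_michaelis_menten",
    "k100_summary",
    "fold_activation",
    "percent_of_reference",
    "track_speeds",
]


@dataclass(frozen=True)
class MMParams:
    """Michaelis-Menten parameters for actin-activated ATPase activity.

    Attributes
    ----------
    k_basal : float
        Basal ATP hydrolysis rate without actin, s^-1.  Non-negative.
    k_cat : float
        Maximal actin-activated hydrolysis rate, s^-1.  Non-negative.
    K_app : float
        Apparent actin affinity (half-saturating actin concentration), µM.
        Strictly positive.
    """

    k_basal: float
    k_cat: float
    K_app: float

    def __post_init__(self) -> None:
        if self.k_basal < 0 or self.k_cat < 0:
            raise ValueError("k_basal and k_cat must be non-negative")
        if self.K_app <= 0:
            raise ValueError("K_app must be strictly positive")


def michaelis_menten(actin: np.ndarray | float, k_basal: float, k_cat: float,
                     K_app: float) -> np.ndarray | float:
    """Evaluate rate = k_basal + k_cat*[A]/(K_app + [A])."""
    actin = np.asarray(actin, dtype=float)
    return k_basal + k_cat * actin / (K_app + actin)


@dataclass
class ATPaseDataset:
    """Replicated (actin, rate) measurements for one myosin variant.

    ``observations`` is a tidy table with columns ``actin_uM``,
    ``rate_per_s`` and ``replicate``.
    """

    variant: str
    mlck_treated: bool
    observations: pd.DataFrame

    REQUIRED_COLUMNS = ("actin_uM", "rate_per_s", "replicate")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED_COLUMNS) - set(self.observations.columns)
        if missing:
            raise ValueError(f"observations missing columns: {sorted(missing)}")
        a = self.observations["actin_uM"].to_numpy(dtype=float)
        r = self.observations["rate_per_s"].to_numpy(dtype=float)
        if len(a) == 0:
            raise ValueError("dataset has no observations")
        if np.any(a < 0):
            raise ValueError("actin concentrations must be non-negative")
        if not np.all(np.isfinite(r)):
            raise ValueError("rates must be finite")

    @property
    def actin(self) -> np.ndarray:
        return self.observations["actin_uM"].to_numpy(dtype=float)

    @property
    def rates(self) -> np.ndarray:
        return self.observations["rate_per_s"].to_numpy(dtype=float)

    def n_distinct_concentrations(self) -> int:
        return int(np.unique(self.actin).size)


@dataclass
class MMFit:
    """Result of a Michaelis-Menten fit.

    ``identifiable`` is False when the fitted K_app exceeds the maximum
    assayed actin concentration: the curve is then nearly linear over the
    measured range and k_cat / K_app are not individually constrained by
    the data.  ``converged`` is False for failed optimizations; parameters
    are then NaN and the fit should not be interpreted.
    """

    params: MMParams | None
    standard_errors: dict[str, float]
    r_squared: float
    identifiable: bool
    n_points: int
    converged: bool
    fixed_k_basal: bool = False

    @property
    def k_basal(self) -> float:
        return self.params.k_basal if self.params is not None else float("nan")

    @property
    def k_cat(self) -> float:
        return self.params.k_cat if self.params is not None else float("nan")

    @property
    def K_app(self) -> float:
        return self.params.K_app if self.params is not None else float("nan")


def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_michaelis_menten(ds: ATPaseDataset) -> MMFit:
    """Fit the Michaelis-Menten model to a steady-state ATPase dataset.

    Unweighted nonlinear least squares over all individual observations.
    With at least three distinct actin concentrations all three parameters
    are free; with exactly two distinct concentrations (one of which must
    be 0 µM) ``k_basal`` is fixed to the 0 µM mean and the remaining two
    parameters are fit.

    Initial guesses: k_basal from the rate at the lowest actin
    concentration, k_cat from the span max(rate) - k_basal, K_app from the
    actin concentration nearest half-maximal activation.  All parameters
    are bounded below by zero.

    Returns
    -------
    MMFit
        Estimates with standard errors (from the covariance of the fit),
        R², and the identifiability flag.  Non-convergence is reported via
        ``converged=False`` rather than raised.
    """
    actin = ds.actin
    rates = ds.rates
    n_distinct = ds.n_distinct_concentrations()
    has_zero = np.any(actin == 0)

    if n_distinct < 2 or (n_distinct == 2 and not has_zero):
        raise ValueError(
            "need >= 3 distinct actin concentrations (or 2 including 0 µM "
            f"for a reduced fit); got {n_distinct}"
        )

    order = np.argsort(actin)
    a_sorted, r_sorted = actin[order], rates[order]
    kb0 = float(np.mean(r_sorted[a_sorted == a_sorted[0]]))
    kc0 = max(float(r_sorted.max()) - kb0, 1e-6)
    half = kb0 + 0.5 * kc0
    above = a_sorted[r_sorted >= half]
    ka0 = float(above[0]) if above.size and above[0] > 0 else max(
        float(np.median(a_sorted[a_sorted > 0])), 1.0)

    fixed_kb = n_distinct == 2
    try:
        if fixed_kb:
            kb_fixed = float(np.mean(rates[actin == 0]))

            def model2(a, kc, ka):
                return michaelis_menten(a, kb_fixed, kc, ka)

            popt, pcov = curve_fit(
                model2, actin, rates, p0=[kc0, ka0],
                bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=20000)
            kb, kc, ka = kb_fixed, float(popt[0]), float(popt[1])
            se = np.sqrt(np.diag(pcov))
            errors = {"k_basal": 0.0, "k_cat": float(se[0]),
                      "K_app": float(se[1])}
        else:
            popt, pcov = curve_fit(
                michaelis_menten, actin, rates, p0=[kb0, kc0, ka0],
                bounds=([0, 0, 1e-9], [np.inf, np.inf, np.inf]), maxfev=20000)
            kb, kc, ka = (float(v) for v in popt)
            se = np.sqrt(np.diag(pcov))
            errors = {"k_basal": float(se[0]), "k_cat": float(se[1]),
                      "K_app": float(se[2])}
    except RuntimeError:
        return MMFit(params=None, standard_errors={}, r_squared=float("nan"),
                     identifiable=False, n_points=len(rates), converged=False,
                     fixed_k_basal=fixed_kb)

    predicted = michaelis_menten(actin, kb, kc, ka)
    r2 = _r_squared(rates, predicted)
    identifiable = ka <= float(actin.max())
    return MMFit(params=MMParams(kb, kc, ka), standard_errors=errors,
                 r_squared=r2, identifiable=identifiable,
                 n_points=len(rates), converged=True, fixed_k_basal=fixed_kb)


@dataclass
class K100Summary:
    """Model-free activity summary: rates at 0 µM and 100 µM actin."""

    variant: str
    mlck_treated: bool
    k_basal: float
    k_basal_sd: float
    k_100: float
    k_100_sd: float
    n_replicates_0: int
    n_replicates_100: int


def k100_summary(ds: ATPaseDataset) -> K100Summary:
    """Mean +/- sd of observed rates at exactly 0 and 100 µM actin.

    These are raw-observation statistics, not fitted-curve predictions, so
    they remain meaningful for variants whose Michaelis-Menten parameters
    are not identifiable.  A single replicate yields sd = 0 with a warning.
    """
    actin = ds.actin
    rates = ds.rates
    out: dict[float, tuple[float, float, int]] = {}
    for conc in (0.0, 100.0):
        sel = rates[np.isclose(actin, conc)]
        if sel.size == 0:
            raise ValueError(f"dataset has no observations at {conc:g} µM actin")
        if sel.size == 1:
            warnings.warn(
                f"single replicate at {conc:g} µM actin for {ds.variant}; "
                "sd reported as 0", stacklevel=2)
            out[conc] = (float(sel[0]), 0.0, 1)
        else:
            out[conc] = (float(sel.mean()), float(sel.std(ddof=1)), int(sel.size))
    return K100Summary(
        variant=ds.variant, mlck_treated=ds.mlck_treated,
        k_basal=out[0.0][0], k_basal_sd=out[0.0][1],
        k_100=out[100.0][0], k_100_sd=out[100.0][1],
        n_replicates_0=out[0.0][2], n_replicates_100=out[100.0][2])


def fold_activation(k100_phos: float, k100_unphos: float) -> float:
    """Activation by RLC phosphorylation: k_100(phosphorylated) / k_100(unphosphorylated)."""
    if k100_unphos <= 0:
        raise ValueError("unphosphorylated k_100 must be positive")
    return k100_phos / k100_unphos


def percent_of_reference(k100_variant: float, k100_reference: float) -> float:
    """Variant activity as a percentage of a reference variant's k_100."""
    if k100_reference <= 0:
        raise ValueError("reference k_100 must be positive")
    return 100.0 * k100_variant / k100_reference


@dataclass
class TrackSet:
    """Filament trajectories from the in vitro motility assay.

    Each track is an (n, 3) array of (time s, x nm, y nm) with strictly
    increasing times; all tracks share one frame interval.
    """

    tracks: list[np.ndarray]
    frame_interval: float

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        coerced = []
        for i, t in enumerate(self.tracks):
            arr = np.asarray(t, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"track {i} is not an (n, 3) array")
            if np.any(np.diff(arr[:, 0]) <= 0):
                raise ValueError(f"track {i} times are not strictly increasing")
            coerced.append(arr)
        self.tracks = coerced


def track_speeds(ts: TrackSet, drift_correct: bool = True) -> np.ndarray:
    """Per-track mean speeds (nm/s), optionally stage-drift corrected.

    Drift correction subtracts the global mean frame-to-frame displacement
    vector, pooled over every step of every track, from each step before
    computing step lengths.  Speed is mean step length / frame interval.
    """
    if len(ts.tracks) == 0:
        raise ValueError("empty track set")
    steps_per_track = []
    for i, t in enumerate(ts.tracks):
        if t.shape[0] < 2:
            raise ValueError(f"track {i} has fewer than 2 points")
        steps_per_track.append(np.diff(t[:, 1:3], axis=0))
    if drift_correct:
        all_steps = np.vstack(steps_per_track)
        drift = all_steps.mean(axis=0)
        steps_per_track = [s - drift for s in steps_per_track]
    return np.array([
        float(np.linalg.norm(s, axis=1).mean()) / ts.frame_interval
        for s in steps_per_track
    ])
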