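"""Seeded synthetic datasets with known ground truth.

Every downstream analysis stage — Michaelis-Menten fitting, wound-recoil
edge extraction and viscoelastic fits, and the myosin-normalized
constriction-rate pipeline — consumes data in the same containers real
experiments would produce.  This module generates those containers from
explicit generative models so that parameter-recovery, calibration and
scaling behaviour of the pipeline can be tested end to end without any
microscopy or enzymology data.

Generative models
-----------------
* ATPase datasets: exact Michaelis-Menten curves plus additive Gaussian
  noise, truncated at zero (rates are physical).
* Recoil traces: Kelvin-Voigt displacement x(t) = A(1 - exp(-t/τ)) plus
  Gaussian noise, optionally rendered as a kymograph image with a dark
  widening wound in bright tissue.
* Embryos: per cell, myosin intensity is a baseline plus Poisson-timed
  piecewise-linear pulses (linear rise, linear decay); the apical
  area-loss rate is coupled to the instantaneous myosin accumulation rate
  through a genotype-specific ``motor_activity_factor``, so a weaker
  motor constricts less for the same myosin recruitment.
* Motility tracks: constant-speed random-heading walks plus a common
  linear stage drift plus positional noise.

All generators are deterministic given their seed; per-cell and per-track
substreams are derived with ``numpy.random.SeedSequence.spawn`` so partial
regeneration is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constriction import CellTrace, EmbryoDataset
from .enzymology import ATPaseDataset, MMParams, TrackSet, michaelis_menten
from .recoil import DisplacementTrace, Kymograph

__all__ = [
    "MMParams",
    "KVParams",
    "SynthEmbryoConfig",
    "gen_atpase_dataset",
    "gen_displacement_trace",
    "gen_kymograph",
    "gen_embryo",
    "gen_motility_tracks",
]


@dataclass(frozen=True)
class KVParams:
    """Kelvin-Voigt ground truth: tension T, spring stiffness ζ, dashpot η.

    Only the ratios are observable in displacement: amplitude A = T/ζ
    (µm), relaxation time τ = η/ζ (s), initial velocity v0 = T/η (µm/s).
    """

    T: float
    zeta: float
    eta: float

    def __post_init__(self) -> None:
        if self.T <= 0 or self.zeta <= 0 or self.eta <= 0:
            raise ValueError("T, zeta and eta must all be positive")

    @property
    def amplitude(self) -> float:
        return self.T / self.zeta

    @property
    def tau(self) -> float:
        return self.eta / self.zeta

    @property
    def v0(self) -> float:
        return self.T / self.eta


def gen_atpase_dataset(params: MMParams, actin_concs, noise_sd: float,
                       n_replicates: int, seed: int,
                       variant: str = "synthetic",
                       mlck_treated: bool = True) -> ATPaseDataset:
    """Replicated steady-state ATPase measurements from known kinetics.

    Rates are k_basal + k_cat*[A]/(K_app + [A]) + N(0, noise_sd²),
    truncated at zero.
    """
    actin = np.asarray(list(actin_concs), dtype=float)
    if actin.size == 0:
        raise ValueError("actin_concs must be non-empty")
    if np.any(actin < 0):
        raise ValueError("actin concentrations must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    truth = michaelis_menten(actin, params.k_basal, params.k_cat, params.K_app)
    rows = []
    for rep in range(n_replicates):
        noise = rng.normal(0.0, noise_sd, size=actin.size) if noise_sd > 0 \
            else np.zeros(actin.size)
        rates = np.maximum(truth + noise, 0.0)
        for a, r in zip(actin, rates):
            rows.append({"actin_uM": a, "rate_per_s": r, "replicate": rep})
    return ATPaseDataset(variant=variant, mlck_treated=mlck_treated,
                         observations=pd.DataFrame(rows))


def gen_displacement_trace(params: KVParams, dt: float, duration: float,
                           noise_sd: float, seed: int,
                           metadata: dict | None = None) -> DisplacementTrace:
    """Kelvin-Voigt recoil trace sampled every ``dt`` seconds.

    x(t) = A(1 - exp(-t/τ)) + N(0, noise_sd²), clipped at zero so the
    trace remains a physical displacement.  Noise-free traces are exactly
    the closed form (monotone, x(0) = 0).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be at least one sample interval")
    times = np.arange(0.0, duration + 0.5 * dt, dt)
    x = params.amplitude * (1.0 - np.exp(-times / params.tau))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=times.size)
        x = np.maximum(x, 0.0)
    return DisplacementTrace(times=times, displacement=x,
                             metadata=dict(metadata or {}))


def gen_kymograph(trace: DisplacementTrace, pixel_size: float,
                  image_width: float, gap_center: float,
                  intensity_fg: float, intensity_bg: float,
                  noise_sd: float, seed: int,
                  frame_interval: float | None = None) -> Kymograph:
    """Render a displacement trace as a tissue-ablation kymograph.

    Each time row shows bright tissue (``intensity_fg``) flanking a dark
    wound (``intensity_bg``) of width twice the displacement, centred at
    ``gap_center`` µm; a pixel belongs to the wound when its centre lies
    strictly inside the open interval.  Gaussian noise is added per pixel.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if intensity_fg <= intensity_bg:
        raise ValueError("intensity_fg must exceed intensity_bg")
    disp = np.nan_to_num(trace.displacement, nan=0.0)
    max_d = float(disp.max())
    if gap_center - max_d < 0 or gap_center + max_d > image_width:
        raise ValueError("wound would extend beyond the image extent")
    n_px = int(round(image_width / pixel_size))
    centres = (np.arange(n_px) + 0.5) * pixel_size
    image = np.full((trace.times.size, n_px), float(intensity_fg))
    for row, d in enumerate(disp):
        wound = np.abs(centres - gap_center) < d
        image[row, wound] = intensity_bg
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    if frame_interval is None:
        dts = np.diff(trace.times)
        frame_interval = float(dts[0]) if dts.size else 1.0
    return Kymograph(image=image, pixel_size=pixel_size,
                     frame_interval=frame_interval, cut_position=gap_center)


@dataclass(frozen=True)
class SynthEmbryoConfig:
    """Generative settings for one synthetic embryo.

    Defaults emulate a ventral-furrow time-lapse: ~60 cells followed for
    10 min at 5 s frame intervals, myosin pulsing roughly every 80 s per
    cell, apical areas starting near 40 µm².  ``motor_activity_factor``
    scales how much area loss a unit of myosin accumulation produces
    (1.0 = wild-type motor; smaller = weaker motor), implementing the
    coupling: area-loss rate = factor * gain * accumulation rate (only
    rising myosin contracts; constriction is ratcheted, so decaying
    pulses do not re-expand the apex).

    Noise levels (``area_noise_sd`` 0.3 µm², ``intensity_noise_sd``
    2 a.u. on a 100 a.u. baseline) are package defaults chosen to be small
    relative to signal dynamics, not derived from any measurement.
    """

    n_cells: int = 60
    frame_interval: float = 5.0        # s
    duration: float = 600.0            # s
    myosin_pulse_rate: float = 0.75    # events/min per cell
    myosin_pulse_amplitude_mean: float = 20.0  # a.u./s accumulation rate
    myosin_pulse_amplitude_sd: float = 5.0
    pulse_rise_s: float = 10.0
    pulse_decay_s: float = 20.0
    motor_activity_factor: float = 1.0
    area_gain: float = 0.015           # µm² lost per a.u. accumulated
    area_start_um2: float = 40.0
    area_start_sd: float = 3.0
    area_floor_um2: float = 2.0
    baseline_intensity: float = 100.0  # a.u.
    area_noise_sd: float = 0.3         # µm²
    intensity_noise_sd: float = 2.0    # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not 0.0 <= self.motor_activity_factor <= 1.0:
            raise ValueError("motor_activity_factor must be in [0, 1]")


def _cell_pulse_profile(times_s: np.ndarray, cfg: SynthEmbryoConfig,
                        rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Myosin signal above baseline and its rising-phase accumulation rate.

    Pulse onsets are a homogeneous Poisson process; each pulse rises
    linearly at its own amplitude (a.u./s) for ``pulse_rise_s`` then
    decays linearly to zero over ``pulse_decay_s``.  Returns (intensity
    above baseline, accumulation rate from rising phases only), both per
    frame.
    """
    expected = cfg.myosin_pulse_rate * (cfg.duration / 60.0)
    n_pulses = rng.poisson(expected)
    onsets = rng.uniform(0.0, cfg.duration, size=n_pulses)
    amps = np.maximum(
        rng.normal(cfg.myosin_pulse_amplitude_mean,
                   cfg.myosin_pulse_amplitude_sd, size=n_pulses), 0.0)
    signal = np.zeros_like(times_s)
    rise_rate = np.zeros_like(times_s)
    for t0, amp in zip(onsets, amps):
        dt = times_s - t0
        rising = (dt >= 0) & (dt < cfg.pulse_rise_s)
        peak = amp * cfg.pulse_rise_s
        decaying = (dt >= cfg.pulse_rise_s) & \
            (dt < cfg.pulse_rise_s + cfg.pulse_decay_s)
        signal[rising] += amp * dt[rising]
        signal[decaying] += peak * (
            1.0 - (dt[decaying] - cfg.pulse_rise_s) / cfg.pulse_decay_s)
        rise_rate[rising] += amp
    return signal, rise_rate


def gen_embryo(config: SynthEmbryoConfig, embryo_id: str = "synthetic",
               genotype: str = "synthetic") -> EmbryoDataset:
    """Generate one embryo of coupled myosin/area cell traces.

    Per cell: myosin intensity = baseline + pulses + noise (floored at 0);
    apical area integrates
    dA/dt = -motor_activity_factor * area_gain * accumulation_rate(t),
    floored at ``area_floor_um2``, plus measurement noise.  Cell
    substreams are spawned from the config seed, so traces are independent
    of ``motor_activity_factor`` (the same seed across genotypes yields
    identical pulse trains and noise, only differently scaled area loss).
    """
    cfg = config
    times_s = np.arange(0.0, cfg.duration + 0.5 * cfg.frame_interval,
                        cfg.frame_interval)
    times_min = times_s / 60.0
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_cells)
    cells = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pulses, rise_rate = _cell_pulse_profile(times_s, cfg, rng)
        a_start = max(rng.normal(cfg.area_start_um2, cfg.area_start_sd),
                      cfg.area_floor_um2 + 1.0)
        loss_rate = cfg.motor_activity_factor * cfg.area_gain * rise_rate
        area = a_start - np.concatenate(
            ([0.0], np.cumsum(0.5 * (loss_rate[1:] + loss_rate[:-1])
                              * np.diff(times_s))))
        area = np.maximum(area, cfg.area_floor_um2)
        myo_noise = rng.normal(0.0, cfg.intensity_noise_sd, times_s.size) \
            if cfg.intensity_noise_sd > 0 else 0.0
        area_noise = rng.normal(0.0, cfg.area_noise_sd, times_s.size) \
            if cfg.area_noise_sd > 0 else 0.0
        myosin = np.maximum(cfg.baseline_intensity + pulses + myo_noise, 0.0)
        area_obs = np.maximum(area + area_noise, 0.5 * cfg.area_floor_um2)
        cells.append(CellTrace(cell_id=f"cell{i:03d}", times=times_min,
                               apical_area=area_obs,
                               myosin_intensity=myosin))
    return EmbryoDataset(embryo_id=embryo_id, genotype=genotype, cells=cells,
                         frame_interval=cfg.frame_interval)


def gen_motility_tracks(true_speed: float, drift_velocity: tuple[float, float],
                        n_tracks: int, duration: float, noise_sd: float,
                        seed: int, frame_interval: float = 1.0) -> TrackSet:
    """Filament tracks: constant-speed random-heading walk + stage drift.

    Each frame-to-frame step has length ``true_speed * frame_interval``
    in an independent uniform direction, plus the common drift
    displacement, plus Gaussian positional noise.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    if duration < frame_interval:
        raise ValueError("duration must cover at least one step")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / frame_interval))
    times = np.arange(n_steps + 1) * frame_interval
    drift = np.asarray(drift_velocity, dtype=float) * frame_interval
    tracks = []
    for _ in range(n_tracks):
        headings = rng.uniform(0.0, 2.0 * np.pi, size=n_steps)
        steps = true_speed * frame_interval * np.column_stack(
            (np.cos(headings), np.sin(headings))) + drift
        pos = np.vstack((np.zeros(2), np.cumsum(steps, axis=0)))
        if noise_sd > 0:
            pos = pos + rng.normal(0.0, noise_sd, size=pos.shape)
        tracks.append(np.column_stack((times, pos)))
    return TrackSet(tracks=tracks, frame_interval=frame_interval)
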