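# Methods

## Michaelis–Menten enzymology

Steady-state ATPase datasets are tables of (actin µM, rate s⁻¹, replicate)
for one myosin variant and phosphorylation state. The fit minimizes
unweighted squared residuals of `rate = k_basal + k_cat·[A]/(K_app + [A])`
over all individual observations (for a balanced design this equals fitting
replicate means). Initial guesses are taken from the data — k_basal from the
lowest-concentration mean, k_cat from the rate span, K_app from the
concentration nearest half-maximal activation — with all parameters bounded
below by zero. With only two distinct concentrations (one of them 0 µM),
k_basal is fixed to the 0 µM mean and the remaining two parameters are fit.
Standard errors come from the covariance of the least-squares solution; R²
is computed about the mean. Non-convergence is reported as a flagged failed
fit rather than an exception so an allelic-series table is always complete.

**Identifiability.** When the fitted K_app exceeds the maximum assayed actin
concentration the response is nearly linear over the measured range and
k_cat and K_app trade off freely; the fit is flagged `identifiable = False`
and comparisons should use k₁₀₀, the mean measured rate at exactly 100 µM
actin. k₁₀₀ is deliberately computed from raw observations, not from the
fitted curve, so it remains meaningful for flagged fits. Fold-activation is
k₁₀₀(+kinase)/k₁₀₀(−kinase) for the same variant; percent-of-reference is
100·k₁₀₀(variant)/k₁₀₀(reference). Both conventions (a variant's own
unphosphorylated denominator vs a common wild-type denominator) are
available by passing the appropriate values; the package does not guess
which a given published ratio used.

**Track speeds.** Motility tracks are (t, x, y) sequences on a common frame
interval. Stage drift is estimated as the global mean frame-to-frame
displacement vector pooled over every step of every track and subtracted
from each step; speed is the mean corrected step length divided by the frame
interval. Pooling all steps equally weights long tracks more, which matches
how drift affects the data.

## Recoil mechanics

Kymographs are space × time images along the centre 4.25 µm of the incision
(configurable `region_width`). Extraction binarizes the image (Otsu by
default; a fixed threshold is supported), removes connected components
smaller than `min_object_px` (default 3 px) from both foreground and
background, and per time row measures the dark run nearest the cut
position; displacement is the edge-to-edge distance divided by two. Rows
with no detectable wound are recorded as missing (NaN), never zero.

The Kelvin–Voigt model is fit in the identifiable parameterization
(A, τ) = (T/ζ, η/ζ); T, ζ, η are not separately recoverable from
displacement alone and are never reported individually — only
v₀ = A/τ = T/η and τ. The power law x = β·tᵅ is fit in linear space
(consistent with least squares on displacement) on points with t > 0, since
the model's sensitivity to α vanishes at t = 0 where x = 0. Both fits use
R² about the mean; fits with R² ≤ 0.5 or failed optimizations are flagged
`accepted = False` and excluded from cohort statistics, with exclusion
counts reported. t = 0 is taken to be the first post-cut frame; if the cut
itself occupies time, the caller shifts the time origin before fitting.

## Constriction rate analysis

All times are minutes, areas µm², myosin intensities arbitrary units.
Traces are smoothed with a Gaussian kernel (σ = 2 frames by default,
reflective boundaries — note reflection flattens slopes within ~4σ of the
series ends) and differentiated with central differences; constriction rate
is −dA/dt so positive means constricting. Control statistics pool the
myosin accumulation rate over every time point of every control cell with
equal weight (per-embryo weighting is a possible alternative; pooling was
chosen as the simplest convention). Accumulation events are individual
(cell, time point) instances whose rate lies in the closed band
[mean + 1·sd, mean + 2·sd] of the control pool; instances are not merged
into runs, so event counts are constriction-instance counts.

Embryo alignment detects constriction onset as the first time the smoothed
mean-area derivative stays at or below −1 µm²/min (configurable) for 3
consecutive frames; these onset parameters are package choices — "when the
tissue begins to constrict" admits many operationalizations. A₀ is the mean
area interpolated 2 min before onset (clipped to the series start), and the
50%·A₀ crossing is located by linear interpolation, reported as censored if
the series ends first.

Myosin z-stacks are background-suppressed by keeping, per pixel, the larger
of the two brightest z-values that exceed the cytoplasmic mean + 2.5 sd
(zero if neither qualifies), then smoothing with σ = 0.5 px. An alternative
reading — summing or averaging the two qualifying slices instead of taking
their maximum — would scale the projection but not change which pixels are
nonzero; the max-of-qualifying rule is implemented. Cytoplasmic statistics
come from caller-supplied values or a designated background region.
Side-by-side intensity profiles smooth with σ = 1 px, max-project z, select
each embryo's peak-intensity frame, and average over the image width along
a 33 µm window centred on the profile peak.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, not
the underlying biology or optics:

- **ATPase**: exact Michaelis–Menten curves plus additive Gaussian noise
  (sd 0.02 s⁻¹ in the default assay emulation, 4 replicates over eight
  concentrations spanning 0–100 µM), truncated at zero. Truncation keeps
  rates physical but biases low-rate observations upward: at 0 µM with
  truth 0.01 s⁻¹ and noise 0.02 s⁻¹, E[max(rate, 0)] ≈ 0.014 s⁻¹, which
  propagates a bias of roughly +0.002 s⁻¹ into fitted k_basal values at
  these settings.
- **Recoil**: Kelvin–Voigt displacement plus Gaussian noise clipped at
  zero, optionally rendered as a kymograph (bright tissue, dark wound of
  width 2× displacement; a pixel is wound if its centre lies inside the
  opening). Rendering–extraction round trips are accurate to one pixel.
- **Embryos**: per cell, myosin is a 100 a.u. baseline plus Poisson-timed
  pulses (default 0.75 min⁻¹ per cell, ~every 80 s) shaped as a linear
  rise (10 s at ~20 a.u./s) and linear decay (20 s); apical area
  integrates `dA/dt = −factor · gain · accumulation_rate` with gain
  0.015 µm²/a.u., only rising myosin contracting (constriction is
  ratcheted), floored at 2 µm². Defaults: 60 cells, 5 s frames, 10 min,
  areas starting at 40 ± 3 µm², measurement noise 0.3 µm² and 2 a.u.
  Noise levels are package choices — small relative to signal dynamics —
  not derived from measurements. Cell substreams are spawned from the
  config seed independently of the motor factor, so two genotypes with
  the same seed share identical pulse trains and noise.
- **Motility**: constant-speed random-heading steps plus common linear
  drift plus positional noise.

What the generator does **not** emulate: segmentation error structure,
photobleaching, spatially correlated myosin dynamics between neighbouring
cells, mechanical coupling across the tissue, wound healing after recoil,
or heteroscedastic assay noise. Passing tests therefore demonstrate that
the pipeline recovers known parameters under its own model assumptions,
not that those assumptions hold for any particular microscope or assay.

### Problem sizes for the packaged analyses

The allelic-series demonstrations use one embryo of 120 cells per genotype
with motor factors {1.00, 0.74, 0.60, 0.47}: a 10-min window for
event-conditioned rate comparisons (sized so no genotype reaches the area
floor inside the window, which would bias the strongest genotype's mean
downward) and 23-min movies for half-times (so the weakest genotype still
crosses 50%·A₀). These sizes give ~1500 events per genotype and rate-ratio
recovery within a few percent.

## Statistics

Group comparisons use the two-sided Mann–Whitney U test: the exact null
distribution when both groups have ≤ 8 observations and no ties, otherwise
the tie-corrected normal approximation with continuity correction. No
multiple-testing correction is applied by default. Box-plot summaries
report median, quartiles, and whiskers at the most extreme values within
1.5·IQR of the box, listing outliers individually.

## Numerical choices and edge cases

- All optimizations use `scipy.optimize.curve_fit` with data-driven initial
  guesses and non-negativity bounds; convergence failures are flagged, not
  raised.
- R² of a zero-variance series is defined as 1 for a perfect fit, else 0.
- Single-replicate summary statistics report sd = 0 with a warning.
- Event-band membership uses closed interval boundaries.
- The acceptance band decision (R² > 0.5 strictly) is deterministic and
  idempotent for a given trace.
- Seeds: one seed per dataset; per-cell/per-track substreams derive from
  `numpy.random.SeedSequence.spawn`, so regenerating a subset of cells
  yields identical traces.

## Known limitations

- The Kelvin–Voigt and power-law fits assume a single relaxation process
  and no wound-healing phase; traces that include closure violate both.
- Event-conditioned rate comparisons assume the control band transfers
  across genotypes, i.e. myosin intensity calibration is comparable
  between imaging sessions.
- The onset detector requires a sustained mean-area slope; very gradual
  constriction onsets are detected late, shifting A₀ slightly downward.
- k_basal estimates inherit the zero-truncation bias described above when
  rates near zero are measured with comparatively large noise.
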