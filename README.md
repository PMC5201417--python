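# furrowkit

Quantitative analysis linking the motor activity of non-muscle myosin II to
epithelial tissue contraction, built around the regulatory-light-chain (RLC)
allelic series used in *Drosophila* ventral furrow studies. The package is
aimed at quantitative cell biologists who have (a) steady-state ATPase assay
tables, (b) laser-ablation kymographs or wound-displacement traces, and
(c) segmented per-cell apical-area / myosin-intensity time series — and who
want the three analyses done consistently, with seeded synthetic data
standing in for any of the three when testing.

## The analyses

**Enzymology.** Actin-activated ATP hydrolysis rates are fit to the
Michaelis–Menten model

```
rate([A]) = k_basal + k_cat·[A] / (K_app + [A])
```

by unweighted nonlinear least squares. When the fitted K_app exceeds the
assayed actin range the fit is flagged non-identifiable and the model-free
statistic k₁₀₀ (measured rate at 100 µM actin) is used instead, with
fold-activation (±kinase) and percent-of-reference ratios. Motility-assay
track speeds are computed with global stage-drift correction.

**Recoil mechanics.** Wound-edge displacement after a laser cut is extracted
from kymographs (binarization, speck removal, edge-to-edge distance / 2) and
fit to a Kelvin–Voigt element, `x(t) = A(1 − e^(−t/τ))` with `A = T/ζ`,
`τ = η/ζ`; the initial recoil velocity `v₀ = A/τ = T/η` is the tension
read-out. A power law `x = β·tᵅ` gives a model-free viscoelasticity
descriptor. Fits with R² ≤ 50% are excluded from cohort statistics.

**Constriction rates.** Per-cell area and myosin traces are smoothed and
differentiated; "accumulation events" are time points where the myosin
accumulation rate lies within [mean + 1·sd, mean + 2·sd] of the pooled
control-cell distribution. Comparing constriction rates only at these
matched instants normalizes out cell-to-cell differences in myosin
recruitment, isolating motor output. Embryos are aligned at constriction
onset and summarized by the time for mean apical area to fall to 50% of A₀
(the mean area 2 min before onset).

A seeded generator (`furrowkit.synth`) produces all three data classes with
known ground truth, so every stage is testable end to end.

## Worked example

```python
import furrowkit as fk

# fold-activation of the wild-type motor from its measured k100 values
print(round(fk.fold_activation(0.82, 0.12), 2))      # 6.83
print(round(fk.percent_of_reference(0.23, 0.82), 1)) # 28.0

# recover Michaelis-Menten kinetics from a simulated assay
ds = fk.gen_atpase_dataset(fk.MMParams(0.010, 1.23, 38.9),
                           [0, 2.5, 5, 10, 20, 40, 70, 100],
                           noise_sd=0.02, n_replicates=4, seed=1)
fit = fk.fit_michaelis_menten(ds)
print(round(fit.k_cat, 3), round(fit.K_app, 1))      # 1.257 40.0

# tension from a noiseless synthetic ablation, via the full image path
tr = fk.gen_displacement_trace(fk.KVParams(T=2, zeta=1, eta=5),
                               dt=0.5, duration=25, noise_sd=0, seed=0)
kymo = fk.gen_kymograph(tr, pixel_size=0.05, image_width=20, gap_center=10,
                        intensity_fg=100, intensity_bg=10, noise_sd=0, seed=0)
kv = fk.fit_kelvin_voigt(fk.extract_edges(kymo))
print(round(fk.initial_recoil_velocity(kv), 3))      # 0.399  (truth 0.4 µm/s)
```

The first two numbers are the activation ratio (6.83-fold, i.e. phosphorylation
turns the motor on) and the phosphomimetic's activity as a percentage of the
phosphorylated wild type (28% — phosphomimetics do not mimic phosphorylation).
The fitted k_cat/K_app sit within the assay noise of the generating truth,
and the recoil velocity recovered through rendering + edge extraction +
fitting is within half a percent of the generative T/η.

A full pipeline run (synthetic inputs, all stages, tidy outputs and
provenance) is driven by a YAML config:

```
furrowkit synth out/demo --seed 1
```

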