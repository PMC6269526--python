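# mpam — multi-parametric photoacoustic microscopy quantification

`mpam` is an analysis stack for studies of microvascular and wound-healing
responses to pro-angiogenic therapies in mouse models. It converts raw
multi-parametric photoacoustic microscopy (PAM) data into single-vessel
physiology, quantifies wound-bed oxygenation from ratiometric
fluorescence/phosphorescence nanoparticle images, and summarises wound
closure and skin pharmacokinetics — with every stage validated end to end on
synthetic phantoms carrying known ground truth.

## What it computes

**PAM stage.** The vascular structure image is the depth maximum of the
A-line envelope (analytic-signal magnitude). Oxygen saturation comes from
dual-wavelength (532/559 nm) spectral unmixing: per pixel, solve

    amp(λ) = F(λ) · [cHbO2·εHbO2(λ) + cHb·εHb(λ)],   sO2 = cHbO2 / (cHbO2 + cHb)

with non-negativity enforced on the concentrations. Blood flow speed comes
from decorrelation flowmetry: the Pearson correlation between repeated
A-lines at lag k follows C(k) = exp(−(v·k/(f·w))²) for A-line rate f and beam
waist w, and v is fitted from the measured decay.

**Vessel stage.** Vessels are segmented (tubeness-seeded hysteresis
threshold), skeletonised and split at junctions. Per vessel: mean diameter d,
mean sO2, mean speed v, and volumetric flow F = v·π·d²/4 (µL/min). From
arterial/venous classes (sO2 threshold):

    OEF  = (saO2 − svO2) / saO2          oxygen extraction fraction
    MRO2 = (Σ arterial F) · OEF          relative oxygen metabolism

with saO2, svO2 flow-weighted class means.

**Oxygen mapping.** Blue (fluorescence, oxygen-insensitive) over red
(phosphorescence, Stern–Volmer quenched: I0/I = 1 + Ksv·pO2) after background
subtraction gives a per-pixel ratio that increases with tissue oxygen; its
grayscale rendering (low oxygen → black) is averaged over the wound-bed ROI.

**Endpoints.** Open-wound area as % of day 0; noncompartmental PK (Cmax,
Tmax, linear trapezoidal AUC over the observed window); two-way
(group × time) ANOVA with Tukey-adjusted pairwise comparisons per timepoint,
reported with the conventional significance stars.

## Worked example

The numbered scripts under `analysis/` reproduce the full study on synthetic
phantoms and write their tables under `results/`:

```sh
python analysis/01_simulate_study.py
python analysis/02_pam_recovery.py
```

prints, among other lines:

```
sO2 recovery over 50 vessels at 20 dB SNR: RMSE = 0.0129
flow recovery 0.2-5 mm/s: median |rel err| = 3.4%, monotone = True
```

i.e. per-vessel oxygen saturation is recovered to ±0.013 (fraction of 1) at
realistic noise, and programmed flow speeds between 0.2 and 5 mm/s are
recovered with a 3.4% median error, in rank order. `analysis/05_closure_pk_stats.py`
runs the wound-closure study at the generators' default closure rates and the
default skin PK profile:

```
open wound at day 6 (% of original area): treated = 54%, vehicle = 76%
skin PK (noiseless default profile): Cmax = 36.0 pg/mg at Tmax = 6 h, AUC(0-144 h) = 1079 pg*h/mg
```

followed by the Tukey star table for the treated-vs-vehicle comparison.

The same stages are available as a CLI over TIFF/CSV bundles with JSON
provenance sidecars (config hash, seed, version):

```sh
mpam all --out results/run --seed 7      # simulate → pam → vessels → oxymap → wound → pk → stats
mpam simulate --config my_config.json    # any stage individually
```

## Layout

```
src/mpam/        library: synthetic, pam, vessels, oxymap, endpoints, cli/config/io
analysis/        numbered study drivers (simulate → quantify → endpoints)
tests/           pytest suite incl. end-to-end recovery properties
scripts/         acceptance.py (headline quantities, JSON output)
docs/methods.md  models, parameters, numerical choices, limitations
```
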