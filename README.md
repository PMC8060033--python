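# phasorca

Phasor-based FRET–FLIM quantification of **absolute cytosolic calcium
concentrations** from donor-fluorophore decay data of a genetically encoded
calcium indicator (the eCFP/citrine construct TN-XXL).

Calcium binding to the sensor's troponin C linker quenches the eCFP donor by
Förster resonance energy transfer, shortening its fluorescence lifetime.
Time-correlated single-photon counting (TCSPC) records a per-pixel photon
arrival-time histogram; inverting the lifetime–calcium relationship turns a
FLIM image into a calcium map in nM — an internal concentration standard
that, unlike intensity-ratio FRET, is insensitive to tissue scattering and
photobleaching.  The package is written for microscopists and image analysts
who need calibrated single-cell calcium from intravital or live-cell FLIM.

## The model

**Titration (time domain).**  The donor lifetime follows a Hill sigmoid of
free calcium:

    τ([Ca²⁺]) = τ_FRET + (τ_free − τ_FRET) / (1 + 10^(−(log₁₀[Ca²⁺] − log₁₀ K_d)·h)),

with `K_d = 475 nM`, Hill slope `h = −1.43`, `τ_free = 2312 ps` (unquenched,
0 nM) and `τ_FRET = 744 ps` (fully quenched, 39 µM) from a lysate titration.
The closed-form inverse gives [Ca²⁺] from a monoexponentially fitted
lifetime (the *time-domain pathway*).

**Phasor (phase domain).**  Each decay is condensed into its first-harmonic
Fourier coordinates g = ⟨cos ωt⟩, s = ⟨sin ωt⟩ at ω = 2π·80 MHz.
Monoexponential decays lie on the universal semicircle
(g − ½)² + s² = ¼; the two-state sensor places every measured phasor on the
chord between the calcium-free endpoint **p**_free and the calcium-saturated
endpoint **p**_FRET, at the FRET-species intensity fraction *w*.  Projecting
a phasor onto this calibration segment and inverting a Hill curve fitted to
*w* versus the titration concentrations yields [Ca²⁺] without any
multi-exponential fitting (the *phase-domain pathway*).  Detector noise has
an effectively infinite lifetime and collects near the origin; points inside
a radius of ¾·FWHM = 0.3 of the noise cloud are gated out.

On top of the two pathways the package provides per-pixel calcium maps and
per-object/track quantification from label masks, ratiometric ΔR/R trace
analysis with the 20% responder threshold, biexponential
colocalization-intensity thresholding for cell-contact classification, and a
synthetic TCSPC generator (periodic-steady-state decays, Poisson noise,
Gaussian IRF, image scenes with ground truth) that exercises everything end
to end.

## Worked example

Simulate a lysate titration (two-species mixture decays, 60 replicates per
level, 10⁶ photons each), build both calibrations from it, and quantify a
synthetic three-cell scene:

```sh
phasorca simulate-titration --out demo/titration --seed 11 --mode biexp --replicates 60
phasorca calibrate --titration demo/titration --out demo/cal.json
```

```
Hill titration fit
==================
  Kd               192.4 nM   (se 0.8)
  Hill slope      -1.582      (se 0.010)
  tau_free        2309.9 ps   (anchor, fixed)
  tau_FRET         744.5 ps   (anchor, fixed)
  n intermediate points  11
  residual sum of squares  1.843e-22
```

These are *apparent* parameters: a monoexponential fit applied to
two-component mixture decays yields a lifetime between the intensity- and
amplitude-weighted means, so the sigmoid fitted to apparent lifetimes has a
shifted K_d.  Inversion through the same fitted curve is self-consistent,
which is exactly how the cross-validation below uses it.  (Fitting a
titration simulated in `--mode monoexp`, where each level has a single
apparent lifetime, returns the generating constants: K_d = 473 ± 46 nM,
slope = −1.43 ± 0.17.)

```sh
phasorca simulate-scene --out demo/scene --seed 11      # cells at 200/475/1200 nM
phasorca quantify --scene demo/scene --calibration demo/cal.json --out demo/quant
cat demo/quant/objects.csv
```

```
frame_index,label_id,g,s,total_photons,ca_nM,status,flags,...
0,1,0.518,0.452,202409.0,189.7,ok,,
0,2,0.642,0.405,202460.0,455.8,ok,above_linear_range,
0,3,0.771,0.359,201873.0,1110.0,ok,above_linear_range,
```

The three cells (ground truth 200, 475 and 1200 nM, ~2·10⁵ photons each)
come back at 190, 456 and 1110 nM — within 8%, with the out-of-linear-range
flag raised where the titration curve is no longer locally linear.  Finally,
the two inversion pathways agree on fresh linear-range decays:

```sh
phasorca simulate-titration --out demo/linear --seed 12 --mode biexp \
    --levels "0,270,380,520,700,850,39000"
phasorca crossval --decays demo/linear --calibration demo/cal.json
# max cross-pathway deviation: 2.20%
```

The same operations are available as a library:

```python
import phasorca as pc

hill = pc.HillCalibration()                   # Kd 475 nM, slope -1.43
tau = pc.lifetime_from_calcium(475.0, hill)   # 1.528e-09 s
pc.calcium_from_lifetime(tau, hill).ca_nM     # 475.0
pc.linear_range(hill)                         # (262.6, 859.1) nM
```

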