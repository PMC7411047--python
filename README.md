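# flashgrab

Analysis pipeline for flash-grab orientation-adaptation studies: psychometric
tilt-aftereffect estimation, retinotopic and laminar fMRI representation
indices, and time-resolved lateralized EEG decoding with cluster-mass
permutation inference — plus a synthetic-data generator that emulates the
statistical structure each analysis assumes.

## The scientific problem

The flash-grab effect (FGE) is a visual illusion: a bar flashed at the moment
a moving background reverses direction is perceived displaced — or, for a bar
anchored at fixation, *tilted* — in the post-reversal motion direction.
Because the retinal image stays fixed while the percept changes, the FGE is a
handle for separating feedforward (retinal-input) from feedback (percept-
related) signals in visual cortex. Three measurement channels are involved:

* **Psychophysics.** Adapting to an FGE-tilted (but retinally vertical) bar
  produces a tilt aftereffect (TAE). The percentage of "upward" 2AFC
  responses as a function of test angle `x` is fitted with a four-parameter
  logistic

  `p(x) = γ + (1 − λ − γ) / (1 + exp(−β (x − α)))`

  by least squares on per-angle proportions. The point of subjective
  equality (PSE) is the inflection `α`; the TAE is half the distance between
  the PSEs measured after adaptation in the two opposite directions. A
  pointer-adjustment task measures the raw illusion size in degrees.

* **fMRI.** Voxels with known retinotopic polar-angle preferences are sorted
  into 360 one-degree bins; the binned response curve per illusion direction
  (clockwise / counter-clockwise) is summarized by the polar angle that
  splits the area under the curve into equal halves. The difference between
  the two conditions' equal-area angles measures the cortical displacement
  of the flashed bar's representation. With cortical-depth estimates, voxels
  are further split into superficial / middle / deep bins (depth fractions
  0–0.4 / 0.4–0.8 / 0.8–1.0) and per-layer indices contrast the two
  conditions inside fixed polar-angle windows (illusory index over ±[6°, 14°],
  input index over [−4°, 4°]).

* **EEG.** A bar flashed (or perceived) left vs. right of the vertical
  meridian drives opposite hemispheres; contralateral-minus-ipsilateral
  difference waves over homologous posterior electrode pairs isolate the
  lateralized response. Linear SVMs (C = 1.0) trained per time point on
  "mini-ERPs" (averages of k = 9 same-class trials, a 3-fold SNR gain)
  under stratified 10-fold cross-validation trace when side information
  becomes decodable; temporal cross-decoding (train at one time/condition,
  test at another) probes whether early and late representations share
  structure. Significance uses cluster-mass permutation tests: same-sign
  suprathreshold runs form clusters, cluster mass is the sum of t (or r)
  values, and the max/min cluster-mass permutation distributions supply
  two-tailed critical values at the 97.5th/2.5th percentiles.

No empirical recordings ship with the package; the `synth` module generates
2AFC trial tables, adjustment settings, voxel tables and multi-subject EEG
epoch sets with exactly the structure these analyses assume, under
bit-reproducible seeding.

## Worked example

```python
import numpy as np
from flashgrab import (ObserverParams, simulate_2afc_trials,
                       PsychometricModel, tae_magnitude)

angles = [-6.9, -2.3, -1.1, 0.0, 1.1, 2.3, 6.9]
fits = []
for sign in (+1, -1):                       # two adaptation directions
    obs = ObserverParams(alpha=sign * 3.7, beta=1.5, gamma=0.02, lapse=0.02)
    trials = simulate_2afc_trials(obs, angles, n_per_angle=20, seed=42)
    fits.append(PsychometricModel.from_trials(trials).fit())

print(fits[0].summary())
res = tae_magnitude(fits[0], fits[1])
print(f"TAE = {res.tae:.2f} deg")
```

prints

```
Psychometric fit  [s00 main]
----------------------------------
PSE alpha (deg)          4.0660
slope beta (1/deg)       1.8624
lower asymptote gamma    0.0184
lapse lambda             0.0000
residual SS              0.0028
angles / trials          7 / 140
converged                True
TAE = 3.27 deg
```

i.e. from 140 noisy binary responses per direction the fitted inflection
lands near the generating ±3.7°, and the TAE — half the PSE distance — is
recovered to within half a degree for this single simulated observer
(averaging across a group tightens this considerably; see the calibration
suite).

The end-to-end driver runs every stage on synthetic data and writes a JSON
report:

```bash
flashgrab run --seed 1 --out out/
flashgrab simulate voxels --seed 1 --out voxels.tsv
flashgrab fmri estimate --voxels voxels.tsv --out estimates.tsv
```

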