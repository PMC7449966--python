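# liverspec

Analysis pipeline for **optical needle biopsy of the liver**: during a
percutaneous biopsy, a fiber-optic probe inside the needle records
fluorescence spectra (365 and 450 nm excitation) and diffuse reflectance
spectra (DRS) at each target site, and the measurements classify the site
as intact liver or tumor before the tissue sample is taken.  `liverspec`
implements the computational side of such a study end to end:

* **Monte Carlo photon transport** for the probe geometry (100 µm source
  fiber, 200 µm collection fiber, 220 µm apart, NA 0.22, fused-silica
  face) in a homogeneous semi-infinite liver, with a pinned liver
  optical-property table (360–1000 nm).  It produces the detected
  fraction, the sampling-volume cross-section through the fiber centers,
  the **sensing depth** (deepest voxel above 10⁻³ of the maximum
  detected-photon visitation) and the **penetration depth** (depth where
  the normalized fluence falls to 10⁻³).
* **Oxygen-saturation inversion**: reflectance in the 675–825 nm fitting
  band is modelled as a function of the tissue composition
  `µa(λ) = B·[S·µa_HbO₂ + (1−S)·µa_Hb] + W·µa_water`,
  `µs′(λ) = a·(λ/500)^(−b)`; a Monte-Carlo-generated training set and a
  small feed-forward network map a mean-normalized measured spectrum to
  the saturation S (StO₂).
* **Fluorescence features**: dark correction, filter-aware band cropping,
  and the diagnostic emission peak wavelengths λ365 and λ450.
* **Statistics and classification**: exact/asymptotic Mann–Whitney U
  tests, and linear soft-margin SVMs on (λ365, λ450, StO₂) evaluated by
  leave-one-out cross-validation — the full 3-feature rule plus the three
  2-feature pairings, reported as sensitivity/specificity.
* **Synthetic cohort generator** reproducing the study design (20
  subjects × {liver, tumor} sites × 20 fluorescence spectra per
  excitation + 100 DRS spectra) with configurable effect sizes, so the
  whole pipeline is testable without any clinical data.
* A packaged clinical cohort table (subject, gender, age, tumor size,
  histopathology, diagnosis) with bookkeeping queries.

## Worked example

```python
import numpy as np
from liverspec import (ProbeGeometry, SimulationConfig, run_simulation,
                       sensing_depth, penetration_depth,
                       liver_reference_properties)

geo = ProbeGeometry()                       # the needle-probe defaults
props = liver_reference_properties(450.0)   # mu_a=30, mu_s'~14.8 1/cm
cfg = SimulationConfig(n_photons=10_000_000, seed=20,
                       slab_half=0.0025, roulette_threshold=1e-5)
res = run_simulation(geo, props, cfg)
print(f"detected fraction {res.detected_fraction:.2e}")
print(f"sensing depth     {sensing_depth(res.sampling_map, 1e-3)*1e4:.0f} um")
```

prints

```
detected fraction 1.79e-05
sensing depth     655 um
```

i.e. at the 450 nm excitation only ~18 of every million launched photon
packets reach the collection fiber inside its acceptance cone, and the
tissue volume those photons interrogate (at the 10⁻³ visitation contour)
ends ~0.65 mm below the probe face — the measurement is local to the
needle tip.  In the NIR window the same engine gives 10⁻³ penetration
depths of several millimetres, which is why the saturation fit uses the
675–825 nm band.

The classification stage consumes one feature row per measured site:

```python
from liverspec.sto2_inverse import build_training_set, train_saturation_regressor
from liverspec.synthetic_cohort import generate_cohort, extract_features
from liverspec.classify_stats import classifier_suite, suite_report

ts = build_training_set(n_samples=2000, seed=0, noise_frac=0.01, noise_replicas=6)
model = train_saturation_regressor(ts, seed=0)
features = extract_features(generate_cohort(seed=42), model)
print(suite_report(classifier_suite(features))["classifier_1"])
```

```
{'features': ['lambda365', 'lambda450', 'sto2'], 'sensitivity': 1.0,
 'specificity': 0.95, 'tp': 20, 'fp': 1, 'tn': 19, 'fn': 0}
```

A thin CLI mirrors these stages
(`liverspec simulate-depth|simulate-volume|gen-spectra|train-sto2|fit-sto2|synth-cohort|extract-features|classify|cohort-stats`).

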