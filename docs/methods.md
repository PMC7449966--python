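# Methods

## Optical model of liver tissue

Tissue is a homogeneous semi-infinite medium characterised at each
wavelength by absorption µa (1/cm), scattering µs (1/cm), the
Henyey–Greenstein anisotropy g and refractive index n.  Two sources of
these properties coexist in the package:

* a **compositional model** — µa is a linear mix of whole-blood
  hemoglobin at 150 g/L (oxygenated fraction S, blood volume fraction B)
  and water (fraction W); reduced scattering follows
  µs′ = a·(λ/500 nm)^(−b).  The bundled chromophore table
  (`data/blood_water_absorption.csv`, 10-nm nodes, 400–1000 nm) is
  assembled from the standard hemoglobin-extinction and water
  compilations; its oxy/deoxy curves cross once near 804 nm (isosbestic
  region), with deoxy dominant below and oxy above.
* a **pinned liver reference table**
  (`data/liver_optical_properties.csv`, 10-nm nodes, 360–1000 nm)
  representing an in-vivo, well-perfused liver: Soret/Q hemoglobin
  structure damped by vessel packaging (µa ≈ 46 at 365 nm, 30 at 450 nm,
  ~1.3 1/cm across the NIR plateau), µs′ = 13·(λ/500)^(−1.2), g rising
  0.88→0.95, n falling 1.40→1.37.  Exact in-vivo liver properties vary
  widely between published sources; this table is a fixed, documented
  choice so that every simulation result is reproducible.  It extends to
  360 nm so the 365 nm excitation can be simulated; the chromophore
  table keeps its conventional 400–1000 nm support.

Interpolation is linear with no extrapolation; out-of-range wavelengths
raise.

Units: lengths in cm internally, wavelengths in nm, coefficients in 1/cm.

## Photon transport

Weighted photon packets are launched uniformly over the source-fiber
face, into a cone uniform in solid angle with in-tissue half-angle
asin(NA/n) (Snell-consistent étendue; the same cone bounds detection).
The probe face occludes the surface, so the boundary at z = 0 is a
fused-silica interface (n = 1.46) everywhere; the specular entry loss is
deducted analytically from the initial weight.  Free paths are
exponential in µt = µa + µs; at each interaction a fraction µa/µt of the
weight is absorbed and the rest scatters through a Henyey–Greenstein
deflection; packets below weight 1e-4 undergo Russian roulette
(survival 0.1, unbiased).  Surface crossings are resolved with
unpolarized Fresnel reflectances.  The ledger
(specular/absorbed/detected/escaped/path-terminated/roulette-net) sums
to the launched weight exactly, which the tests check to 1e-6.

**Azimuthal-averaging detection.**  The trajectory ensemble is
rotationally symmetric about the vertical axis through each packet's
launch point.  A packet exiting inside the acceptance cone at radial
displacement r from its launch point would land on the detector face for
a computable arc of rotations; the kernel scores the packet's weight
times that arc fraction as detected (complement as escaped) and, for the
sampling map, rotates the entire path onto an azimuth drawn uniformly
from the valid arc.  This is an exact integral over a symmetry of the
problem — expectations and the ledger are unchanged — and reduces the
variance of detection-conditioned estimators by roughly the inverse arc
fraction (~100×), which is what makes desk-scale runs of 10⁶–10⁷ packets
sufficient where a naive estimator would need 10⁹.

**Sampling volume.**  The cross-section through the source and detector
centers is voxelized at 10 µm; detected packets deposit weight × dwell
length (track-length / photon-hitting-density estimator) in every voxel
their rotated path crosses inside a slab about the y = 0 plane.  The map
is normalized to its maximum; the **sensing depth** is the deepest voxel
at or above a threshold (default 1e-3, the dynamic range of the
spectrometer).  Depth runs use a ±25 µm slab and roulette threshold 1e-5
— precision settings that stabilise the 1e-3 contour tail at 10⁷
packets (the slab averages five voxel planes over which the map is
nearly constant).

**Penetration depth.**  Fluence versus depth is scored with the
absorption estimator (absorbed weight / µa) in 50-µm slabs inside a
0.5-mm-radius cylinder about the source axis — the probe footprint —
and normalized to its near-surface maximum; the penetration depth is
the deepest bin at or above 1e-3.  A laterally integrated convention
would give systematically larger depths; the footprint average reflects
what the probe itself illuminates.

Determinism: a run is bit-for-bit reproducible from its seed (single
threaded, self-contained kernel RNG).

## Forward reflectance models

`simulate_drs` runs one full transport simulation per 10-nm wavelength
node and interpolates — the reference forward route.

The accelerated **white Monte Carlo** forward
(`WhiteMonteCarloForward`) runs zero-absorption baselines once per
scattering node (default 8 nodes, geometric over 1.5–24 1/cm,
3×10⁶ packets each) and records (arc fraction, path length) for every
in-cone exit; the reflectance at any absorption follows from
Beer–Lambert reweighting Σ f·exp(−µa·L), interpolated log-log across the
scattering grid.  The model medium is isotropically scattering at the
reduced scattering coefficient (first-order similarity): this keeps the
zero-absorption transport tractable (anisotropic g = 0.9 packets at
albedo 1 random-walk ~20× longer) at the cost of quantitative amplitude
fidelity at this sub-mfp source–detector separation — the tests document
agreement with the direct anisotropic simulation to within a factor
~2–3 in amplitude and ~±30 % in band shape.  Because the inversion is
trained and applied within the same forward model, this bias does not
propagate into saturation estimates.  Path lengths are capped at 12 cm;
for the band's smallest absorptions this truncates a few-percent of the
Beer–Lambert tail, again consistently between training and application.

## Oxygen-saturation inversion

Training sets are Latin-hypercube samples over S ∈ [0,1], B ∈
[0.01,0.2], a ∈ [5,25] 1/cm, b ∈ [0.5,2] (W fixed at 0.7), with spectra
on the 16 nodes of 675–825 nm, divided by their band mean (removing the
unknown collection-efficiency scale and making estimates invariant to
positive rescaling of the input, up to floating-point rounding).  The
regressor is a feed-forward network (default 2×64 tanh units) on
z-scored features; the default training protocol replicates each sample
6× with independent 1 % multiplicative noise and fits with adam and
early stopping (20 % validation split), which teaches the network the
conditional mean under measurement noise.  Estimates are clipped to
[0,1]; degenerate inputs (constant or non-positive band) are evaluated
but flagged.

**Identifiability limit.**  In this band and parameterisation the
saturation direction in normalized-spectrum space is nearly collinear
with combinations of the nuisance directions (B, a, b): projecting the
S-derivative out of the nuisance subspace leaves ~7 % of its norm.  A
brute-force grid posterior (the Bayes-optimal estimator) recovers S from
single spectra at 1 % noise with RMSE ≈ 0.15 over these priors; the
network reaches the same value, i.e. the limit is informational, not a
training artifact.  Consequently single-spectrum saturation estimates
carry substantial uncertainty, and even noiseless spectra invert only to
~0.04 RMSE (approximate input collisions).  Site-level estimates in this
package are medians over 100 replicate spectra with site-fixed nuisances
(~0.05 per-site error), which is what the classification stage consumes;
a 0.20 liver–tumor saturation gap therefore remains a strong feature.
Richer spectral sampling, wider bands, or absolute-intensity calibration
would be required to do better per spectrum.

## Fluorescence features

Emission spectra are dark-subtracted, floored at zero and cropped to
410–700 nm (365 nm excitation) or 505–800 nm (450 nm excitation) — the
long-pass filter edges (400/495 nm) plus a 10-nm guard, inside the
400–900 nm detection range.  The diagnostic feature is the wavelength of
the maximum after a 5-nm moving average (peak jitter from detector noise
would otherwise alias into the feature); exact ties resolve to the
shortest wavelength, and a zero/low signal raises rather than returning
a spurious peak.  Per-site features are medians over replicates.

## Statistics and classification

The Mann–Whitney U test is exact by enumeration of all C(n, n₁) group
assignments for n ≤ 12 (two-sided p = probability of |U − n₁n₂/2| at
least as large as observed, which handles ties), and otherwise uses the
normal approximation with tie correction and 0.5 continuity correction.
Group differences are read at p < 0.01.

Classification is a soft-margin linear SVM (C = 1, no class weighting)
on z-scored features, evaluated by leave-one-site-out cross-validation
with tumor as the positive class; the suite reports the 3-feature rule
and the three 2-feature pairings in a fixed order.  A known property of
this design: on data with *no* class signal the SVM degenerates towards
a majority vote, and leave-one-out then under-represents the held-out
class in training, pushing null metrics *below* chance (sometimes to
zero).  Null-control tests therefore scatter widely around and below
0.5 — evidence of absent optimistic bias, not of a defect.

## Synthetic cohort

The generator reproduces the study design — 20 subjects, one liver and
one tumor site each, 20 fluorescence spectra per excitation and 100 DRS
spectra per site — with tumor saturation above liver (0.75 vs 0.55,
SD 0.08) and liver fluorescence peaks red-shifted relative to tumor
(15 nm at both excitations, SD 4 nm).  These effect sizes are synthetic
working values chosen to produce clearly separable yet noisy groups; the
clinical literature reports directions and significance, not
distributional parameters.  Fluorescence emission is a single Gaussian
band (width 25 nm) — adequate because only the peak wavelength is
consumed — and DRS replicates share a site composition and differ by a
log-normal collection-efficiency scale and 1 % noise.  What passing
tests on this cohort do **not** show: robustness to real fluorophore
mixtures (NADH/FAD/collagen/bilirubin superpositions), blood-absorption
dips carved into emission bands, instrument response drift,
heterogeneous or layered tissue, or needle-positioning error.

## Problem sizes and numerical choices

Depth runs use 10⁷ launched packets (sensing) and 10⁶ per node
(penetration sweep); training sets 2000 Latin-hypercube points with 6
noise replicas; cohorts 5 600 spectra.  Voxels 10 µm, fluence bins
50 µm, path cap 100 cm (12 cm in the white model), roulette 1e-4
(1e-5 in depth runs).  Exact similarity scaling — depths scale as 1/k
under (µa, µs) → (kµa, kµs) — holds when probe geometry and scoring
grids scale as 1/k together with the coefficients, and is tested that
way; with the geometry held fixed the relation is only approximate
because the 220-µm fiber separation does not scale.
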