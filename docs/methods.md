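# Methods

This note documents the models, parameters and numerical choices behind the
package, and what its synthetic studies can and cannot say about real
scanner data.

## Attenuation physics

Mass attenuation curves (μ/ρ, cm²/g) for water, gold, iodine, gadolinium,
calcium and aluminum are embedded as plain-text tables at NIST XCOM grade
accuracy (a few percent on the heavy elements, exact anchors for water,
e.g. 0.2059 cm²/g at 60 keV). Each K edge is stored as a doubled abscissa
holding the below- and above-edge limits; interpolation is log-log linear
within segments and never crosses an edge, and a query exactly at the edge
energy resolves to the above-edge value (right-continuous tie-break). The
gold table starts at 15 keV, above the Au L-shell edges, so every table is
monotone decreasing between its listed discontinuities; photons below
15 keV play no role in a 30 keV-thresholded acquisition.

The tube spectrum is Kramers-law bremsstrahlung, fluence ∝ (kVp − E),
hardened by 2.5 mm of aluminum (default 120 kVp; 80/100 kVp supported).
Characteristic tungsten lines, detector pile-up, charge sharing and scatter
are not modeled; the detector response is an ideal indicator per bin with
the default thresholds 30/53/78/83/98 keV and the last bin closed at the
tube voltage. A measured spectrum can be loaded from a two-column text
file to override the analytic one.

## Phantoms and geometry

Phantoms are 2-D axial slices on an isotropic 250 µm grid (the scanner's
reconstructed voxel), carrying per-material mg/mL maps plus a
water-equivalent density map. A slice is one voxel thick, so region areas
convert to volumes through the 1.5625×10⁻² µL voxel. Regions are
rasterized center-of-voxel; mass-bearing regions (pellets, cell cluster,
scaffold) are filled nearest-the-center-first with one fractional rim voxel
so the deposited mass is exact, not discretization-limited. Pellets use a
packing volume of 2.8 pL/cell (10⁶ cells occupy 2.8 µL) and a gold load of
128 pg/cell, making the pellet concentration 45.7 mg/mL. The brain slice
is an 11 × 9 mm ellipse of 1.04 g/mL tissue with a fluid-filled lesion
cavity, an optional two-voxel calcium annulus at 150 mg/mL standing in for
the skull (bone density is a free choice here; the value makes the
calcium cross-talk clearly visible), a gold cell cluster and an
overlapping iodine scaffold region of configurable mass and volume.

Acquisition is 2-D parallel-beam — views spread over 180°, detector pitch
equal to the voxel pitch — rather than the scanner's helical fan beam, so
that ramp-filtered back-projection is exact for the geometry and a full
study runs in minutes on one CPU. Projection is rotate-and-sum (the
discrete Radon transform of scikit-image). Desk-scale defaults are a
64-voxel grid with 96 views for tubes and pellets and a 128-voxel grid
with 192 views for the brain slice; these sizes were chosen once as the
package's working scale.

## Noise model and flux calibration

Counts are independent Poisson draws of the polychromatic Beer–Lambert
expectation per bin. Tube current and rotation time enter only through
their product, so they are absorbed into a single blank-fluence scalar
(expected counts per detector element per view, summed over the spectrum).
The default, 26,576 counts, was calibrated once with
`scripts/calibrate_flux.py` so that the reconstructed gold map of the
default water phantom has a background SD of 10 mg/mL — the noise level at
which the analytic detection limit lands at the few-thousand-cells-per-
voxel scale reported for this kind of system. Noise in the gold map scales
as flux^(−1/2), which the calibration exploits and the tests verify.

## Maximum-likelihood decomposition

Each ray's five bin counts are decomposed into line integrals A (g/cm²)
of the basis materials (default water/gold/iodine) by maximizing the exact
Poisson log-likelihood under the tabulated attenuation curves. The
maximizer uses Fisher scoring — Newton-type steps with the expected
information, which is positive definite where the observed Hessian need
not be — with backtracking line search, initialized from weighted least
squares on −ln(y/blank) with per-bin effective (spectrum-weighted)
coefficients. Convergence is declared when the Newton decrement gᵀF⁻¹g
falls below 10⁻⁹ (log-likelihood units), within at most 50 iterations;
rays with zero counts in every bin are flagged non-convergent and reported
as A = 0. No nonnegativity constraint is applied: clamping negative line
integrals would bias the sinogram-domain mean, so clamping is deferred to
display. The implementation is vectorized over all rays of a sinogram.

Calcium is deliberately absent from the default basis. Bone then projects
onto the remaining basis functions, and its smooth high-Z excess over
water is best matched by iodine: the skull appears in the iodine image
(positive iodine leakage on skull-crossing rays) while the gold channel
stays comparatively clean. With the embedded tables the mean absolute gold
leakage on skull-only rays is ≈ 0.3× the iodine leakage; the tests bound
it at 0.5×. A four-material basis is available when cross-talk-free bone
handling matters more than fidelity to the three-material behavior.

A calibrated mode mirrors scanner practice: per-bin effective coefficients
are fitted by least squares to tube scans of known concentration (the fit
needs at least two distinct concentrations, including zero, per basis
material). In the thin-object limit the fitted coefficients equal the
spectrum-weighted mean attenuation per bin to better than 2 %; at the full
printed concentration range beam hardening depresses the widest bin's
coefficient by ≈ 3 %, which is physics, not misfit.

## Reconstruction and Hounsfield convention

Material sinograms reconstruct by FBP with a ramp (Ram-Lak) filter and
linear-interpolation back-projection; Hann apodization is available when
noise matters more than resolution. Units propagate g/cm² → g/cm³ →
mg/mL through the voxel pitch. The conventional image pools all bins,
takes p = −ln(Σy/Σblank) (counts clamped at 0.5 so empty rays stay
finite), reconstructs to linear attenuation and converts to HU against a
water reference weighted over the *detected* band (E ≥ 30 keV). Weighting
over the full emitted spectrum would include photons the detector never
counts and would shift water to ≈ −100 HU; with the detected-band
convention water reconstructs at 0 ± 30 HU and air at −1000 HU at default
noise.

## Quantification and the two detection limits

ROIs on gold maps are algorithmic for reproducibility: voxels above 2σ of
a signal-free background region, largest connected component, hole-filled.
Mass is Σ concentration × voxel volume with negative voxels kept (zero
clamping inflates mass in noise); cells = mass / 128 pg. Thresholded ROIs
lose the blurred rim of a deposit, so image-derived mass runs a few
percent low — the pellet series fits with slope ≈ 0.96 at R² > 0.999.

The single-voxel detection limit is reported two ways:

* **analytic**: N = k·σ_bg·V_voxel / load with k = 4 (Rose criterion) —
  the cell number whose voxel concentration equals 4σ. At σ_bg = 10 mg/mL
  this is ≈ 4.9×10³ cells per 250 µm voxel.
* **empirical**: the smallest N whose reconstructed inclusion-voxel value
  exceeds 4σ_bg in ≥ 95 % of 20 seeded replicate acquisitions through the
  full chain (N scanned upward in steps of 250).

These answer different questions and differ by a computable factor: 95 %
power at a 4σ threshold needs a mean signal of (4 + z₀.₉₅)σ ≈ 5.65σ, and
the band-limited ramp-FBP system recovers only f ≈ 0.83 of a single-voxel
impulse (measured; independent of view count), so the empirical limit sits
at ≈ 5.65/(4f) ≈ 1.7× the analytic one — ≈ 8.5×10³ cells at default
settings. The analytic figure is the right analogue of a 4σ-contrast
detectability quote; the empirical figure is the stricter "reliably seen
every scan" guarantee. No unbiased linear reconstruction can close the
gap at fixed σ, since that would require f > 1.

## Synthetic cohorts

Cohorts emulate the longitudinal designs: arms of 0.5/0.25/0.125 million
injected cells, imaging windows in weeks one and two, per-animal delivery
efficiency drawn log-normal (median 0.75, σ_log = 0.3, clipped to (0, 1]),
one administration-failure animal (efficiency ≈ 0.1) per cohort, and a
terminal ICP-OES measurement with 5 % multiplicative noise. The delivered
gold of a 0.5-million-cell arm then averages ≈ 48 µg with an across-animal
CV above 20 %. Gold, not cells, is the conserved quantity — imaging cannot
distinguish label retention from cell persistence — and each animal's truth
is exactly constant across time points. Each animal draws from its own
seeded stream, so cohort composition does not perturb other animals.

## Statistics

Calibration regression is ordinary least squares with R² = 1 − SS_res/SS_tot
(defined as 0 for a flat response). Bland–Altman uses differences
estimate − reference, the n−1 sample SD, and 1.96·SD limits of agreement.
The agreement report flags pairs outside the limits as outliers and
re-fits the regression without them, always reporting both fits rather
than choosing.

## What the synthetic studies do not show

The generator reproduces the study *conditions*, not the animals: no
anatomy beyond a schematic slice, no motion, no scatter or spectral
detector distortions, no helical geometry, no label biology (transfer to
endogenous macrophages, cell death). Passing tests therefore validate the
computational chain — decomposition optimality, unit bookkeeping,
statistical behavior — and the orders of magnitude, not scanner-specific
image quality. In-vivo quantities that depend on real biology (absolute
bias against a chemical assay, in-vivo R²) are covered only as properties
of an unbiased pipeline: bias → 0 with cohort size, ≈ 95 % of differences
inside the limits of agreement, heterogeneity and longitudinal stability
as designed.
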