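# Methods

This note records the models behind `guvscan`, the choices made where the
design was open, and what the synthetic benchmarks do and do not establish.

## Equivalent circuit of the coupled split-ring resonator

The two-port is a matched microstrip through line with a single shunt branch
at the coupling point: a coupling capacitor C<sub>c</sub> in series with the
ring loop. The loop is two transmission-line arcs (characteristic impedance
Z<sub>r</sub>, lengths 0.45 ℓ and 0.55 ℓ of the circumference ℓ) running
from the coupling node to the two sides of the split gap, which are bridged
by the split-gap capacitance C<sub>g</sub>. The one-port admittance of the
closed loop follows from the ABCD cascade arc–C<sub>g</sub>–arc with its
output tied back to its input, Y = C + (D−1)(1−A)/B.

With near-symmetric arcs the even modes leave the gap at a voltage node and
are weakly loaded, while the odd modes put the gap at an antinode: these are
the measurement modes. The slight arc asymmetry (split fraction 0.45) is
required for the gap load to couple to the odd modes at all — at exactly 1/2
the two gap terminals sit at equal potential and ΔC<sub>g</sub> would be
invisible. A by-product of the series-capacitor coupling is an additional
deep composite resonance between the two odd modes (near 5.2 GHz in the
default calibration); it is not used for measurement.

An ideal dispersionless ring would place the second odd mode at three times
the first (8.1 GHz for a 2.7 GHz fundamental); the device's modes are at 2.7
and 7.9 GHz, so the ring line carries a two-coefficient effective-permittivity
law ε<sub>eff</sub>(f) = ε₀(1 + s·f/10 GHz) that lets both modes calibrate
independently. Calibration proceeds in stages:

1. coarse placement (rescale ℓ to put the lowest dip on the first target,
   solve the slope from the mode condition ε(f)·f² = const), then a
   least-squares polish of (ln ℓ, s) on the two dip locations (tolerance
   10⁻³ relative);
2. ring-line loss α set by root-finding so the dissipated-power fraction
   1 − |S11|² − |S21|² at the first dip equals 0.45 on the undercoupled
   branch — the device couples up to about half the probing power into the
   ring, and this shunt topology caps the fraction at 1/2 exactly;
3. a reference-plane delay/offset pair solved in closed form so the baseline
   transmission phase at the two modes equals the published θ₀ (103.9° and
   339.88°). Phases are compared modulo 360° in (−180°, 180°].

The feed lines are matched and lossless, so passivity is governed by the
branch alone and holds for any nonnegative loss; reciprocity is structural
(single shunt branch). The baseline dip depth is not independently known;
with the dissipation anchored at 0.45 the model gives |S21| ≈ 0.59 at the
first mode, consistent with the synthetic baseline level 0.5 used by the
trace generator.

The carrier liquid (0.1 M glucose–water) is modelled as pure water with a
single-Debye relaxation (ε_s = 78.4, ε_∞ = 5.2, τ = 8.27 ps, zero ionic
conductivity — glucose is non-ionic and its correction at 0.1 M is
negligible); ε(2.7 GHz) ≈ 77.0 − j10.1, ε(7.9 GHz) ≈ 67.8 − j25.6.

## Quasi-static field solver

The split gap (500 nm) is over two hundred times smaller than the guided
wavelength at 7.9 GHz, so the gap load is computed electrostatically on the
2-D cross-section at slot mid-length; the 100 µm slot length enters as a
multiplier. The solver is a finite-volume discretization of
∇·(ε∇φ) = 0 on a tensor grid: electrodes (including the slot side-walls
across the 0.54 µm metal thickness) are Dirichlet at ±V/2, outer boundaries
zero normal flux, interface cells flux-averaged. The grid is uniform at
`slot_width / resolution` near the gap (default resolution 24), refined 4×
in the first half slot-width above the electrode plane where the membrane
band sits, geometrically stretched outwards (ratio 1.12) to 10 slot-widths
in x and below the metal, and to just above the channel ceiling in y; every
layer interface (nanometre membrane slabs included) is forced onto a grid
line. The direct sparse solve leaves machine-precision flux residuals.

Capacitance and sensitivities use the discrete energy functional with the
non-conjugated bilinear form (so a lossy stack yields the complex C = Q/V):
each cell's exact contribution ∂C/∂ε<sub>cell</sub> is accumulated from its
four edge conductances, which makes Σ ε·w = C an identity to machine
precision and gives Hellmann–Feynman layer kernels that match full re-solves
to better than 1 % for the small contrasts of interest.

Choices not fixed by the device description: membrane slab thicknesses 5.0 nm
(SM) and 4.0 nm (POPC) — SM's longer chains give the thicker bilayer, and the
two defaults carry the SM/POPC signal difference; substrate ε = 4.6
(borosilicate glass); PDMS lid ε = 2.7; slot interior filled with the bulk
liquid; the elevation film is water of configurable thickness between
electrode plane and membrane.

Verification against closed forms uses the zero-thickness homogeneous limit:
the centreline intensity of an ideal coplanar slot, 1/(1 + (2y/s)²), matches
within 2 % (at resolution 96 — the sharp-edge field singularity slows
convergence, so the oracle runs finer than the default), and the
elliptic-integral capacitance of coplanar strips, C = ε K(k′)/K(k) with
k = s/(s + 2w) for both half-spaces, matches within 2 % at default
resolution.

### Field direction at the membrane

Inside the slot the field is parallel-plate-like (≥ 99 % in-plane). For the
probing-field column — the slot interior plus the membrane band spanning the
slot opening — the in-plane component carries ≈ 99.5 % of the electric
energy, which is the sense in which the measurement probes ε<sub>∥</sub> and
the basis of the > 90 % acceptance check. Restricted to the 5 nm membrane
band alone the in-plane share is ≈ 0.83 over the slot span and ≈ 0.51 over
the full electrode width: the sharp 90° metal corners of the 2-D
electrostatic model concentrate perpendicular fringing at the gap edges
(stable from resolution 16 to 48). A real device has rounded edges and the
membrane's gap-spanning response dominates the signal, but this is a genuine
limitation of the sharp-corner cross-section model worth knowing about.

### Elevation attenuation

`elevation_factor` reports the membrane-band-averaged |E|² at elevation h
relative to contact, by exact clipped-cell integration. On the default
geometry the 100 nm value is ≈ 0.49. The literature quotes a "factor of
0.107 reduction" for 100 nm from a 3-D full-wave simulation; the phrasing is
ambiguous (reduced *by* 10.7 % vs *to* 10.7 % of the contact value) and the
underlying computation is not reproducible here, so the package reports its
own ratio alongside that number without asserting agreement. The kernel
route is self-consistent: the membrane-layer weight with a 100 nm film over
the weight at contact matches `elevation_factor(100 nm)` within a few
percent.

## Permittivity extraction

The forward map composes the membrane-layer kernel weight w (evaluated once
on the unperturbed all-water stack, so it is independent of the trial
permittivity), the circuit's ΔS21 under a gap-load change, and a complex
instrument gain:

    ΔS21(ε) = G · δs21( w · (ε − ε_water(f)) , f )

G is anchored per (lipid, frequency) on one published (permittivity,
Δ|S21|) pair and makes that anchor's response real-positive and equal to the
published magnitude by construction; consistency at the anchor is therefore
exact and only the *other* points are informative. Inversion is damped least
squares on (ε′, ε″) with multi-start from the medium value and 1.5× it,
bounds ε′ ≥ 1, ε″ ≥ 0, ties broken by residual then by lower ε″. The map is
near-linear, so round trips recover printed values to ~10⁻¹⁰ relative and a
zero observation returns the Debye water value (ε′ ≈ 77.0 at 2.7 GHz, 67.8
at 7.9 GHz). When the observation demands ε″ < 0 (which happens for fixed
observations at large elevations), the optimum pins to the boundary and the
result carries a `boundary` flag instead of raising. Magnitude-only
observations are interpreted on the gain-anchored real axis; the complex
mode is the default.

## Trace analysis

Segmentation is binary segmentation on mean shifts of |S21| with penalty
6 σ̂² ln n, σ̂ the robust (median absolute first-difference) noise estimate,
minimum split spacing 20 ms. Adjacent levels closer than the sensitivity
threshold (4 σ̂, following the detection convention) are merged; levels
beyond the threshold from the entry baseline form event runs. A run shorter
than the minimum plateau duration (0.3 s, half the shortest scan time) is a
single transient; a longer run whose level sequence is non-monotone — the
signature of membrane layers stacking and unstacking — is folded; remaining
long levels are plateaus. A two-domain GUV (strong SM-rich section first,
weaker POPC-rich second) is monotone-decreasing and yields two plateaus;
a folded trace (level a₁, then a₁+a₂, then a₁) is not. On noiseless planted
steps the change points are exact to the sample.

Δ|S21| uses magnitude means (not magnitudes of complex means), making it
invariant to a global phase. Classification is nearest published cohort mean
in z-score units with an ambiguity band of 0.5 z. Cohort σ is the population
(divide-by-n) standard deviation, with the sample version also exposed;
error bars are max − µ and µ − min.

## Synthetic data

Generators are pure functions of (preset, seed); cohorts derive child seeds
via numpy's `SeedSequence`. A trace is 3 s at 500 Hz (the 1 kHz IFBW bounds
the point rate; the actual rate is not published), baseline |S21| = 0.5,
plateau amplitudes Normal(µ, σ) truncated at zero from the published cohort
presets, durations Uniform(0.6, 0.9) s, steps instantaneous, additive i.i.d.
complex Gaussian noise, GUV passage lowering |S21|. The per-sample noise sd
is 0.25 × 10⁻⁴: the published cohort σ's are GUV-to-GUV spread rather than
instrument noise, and the noise must leave the smallest published section
value (2.71 × 10⁻⁴) detectable at the 4 σ̂ threshold, as the measured
plateaus clearly were. Cohort statistics drop traces whose plateau stays
below the detection threshold — with the published POPC presets a small
fraction of generated GUVs is genuinely unmeasurable, as it would be at the
bench.

What passing the synthetic benchmarks shows: the segmentation, statistics
and inversion recover exactly the structure they were given, at the
published operating points, with correct uncertainty scaling. What they do
not show: robustness to drift, flow-rate variation, partial gap coverage,
non-flat membranes or any systematic the generator does not model (a linear
drift term exists but is off by default).

## GUV geometry estimators

Size regimes are classified against the 25 µm channel width: below it a GUV
stays spherical and uncontrolled in height; up to 1.2× it flattens and scans
well; beyond that folding/breaking dominates. The flattening estimator
conserves volume: it finds the truncated-sphere radius R with caps cut at
±h/2 (h = 18.8 µm) matching the free-sphere volume and reports the contact
disc 2√(R² − h²/4) for both directions; a 25 µm GUV gives ≈ 17.8 µm. The
literature's anisotropic 11 × 20.5 µm estimate is not derivable from
constant-volume (or constant-area) truncation alone and its method is
unstated, so it is stored as reference metadata and not asserted.

## Problem sizes and tolerances

Default field resolution is 24 cells per slot width (~27 k nodes, direct
sparse solve well under a second); the conformal-profile oracle runs at 96.
Cohort recovery uses 200 master seeds × 10 traces per preset; the large-n
pipeline check uses 1500 traces. Circuit calibration tolerances: 10⁻³
relative on mode frequencies, 0.5° on baseline phases; inversion residual
tolerance 10⁻⁶ relative to the observation.
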