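# Methods

This note documents the models, estimators and numerical choices behind
`actintwist`, and what its synthetic data do and do not emulate.

## Helical geometry

A filament is generated by a screw transform: rotate a protomer by the
per-protomer twist about the filament axis and translate it by the rise.
For actin the genetic helix is left-handed with twist magnitude near
166.6° (bare) or 162.5° (cofilin-supertwisted) and rise ≈ 2.75 nm.
Crossovers of the two long-pitch strands recur every
`180/(180 − |twist|)` protomers, so

- protomers per half helix = nearest odd integer to that ratio (odd
  because AFM counts peaks from both strands between crossovers; exact
  even ties round upward, though they do not occur for physical twists),
- HHP = protomers-per-crossover × rise,
- MAD = 2 × rise (geometric), or HHP / counted pairs (the AFM estimate).

The default rise of 2.75 nm is MAD/2 with the canonical 5.5 nm axial
spacing; structure-derived transforms carry their own rise. Published
transform tables are compared through the total axis–angle magnitude
only, never through a specific Euler convention, because the secondary
Euler components of filament generators are fractions of a degree and the
convention is not identifiable from them.

## Ensemble PCA

Chains are reduced to Cα traces in gene numbering (deposited id + offset;
default offset +2 because the first two gene-encoded residues of actin
are absent from the mature chain — configurable per entry). Common
residues across an ensemble are the set intersection of residue numbers;
since every member is the same protein, no sequence alignment is needed.
The subdomain table (SD1–SD4, with OD = SD1∪SD2 and ID = SD3∪SD4) ships
as a versioned YAML config; the boundaries follow the conventional
four-subdomain partition of the actin fold but are a configurable
assumption, since different authors shift them by a few residues.

Members are superposed on a reference (first chain by default) using
*only* the inner domain, which makes outer-domain hinge and twist motions
visible as variance instead of being averaged away. PCA is the
eigendecomposition (via SVD) of the unweighted covariance of flattened
3N coordinate deviations. Eigenvector signs are arbitrary; an optional
reference member can be forced to non-negative scores. Back-projection of
a mode is `mean + amplitude × eigenvector`.

## Pseudo-AFM rendering

The probe is a sphere of radius `R` (default 2.0 nm) smoothly capped on a
cone of half-angle `θ` (default 5°, interpreted as half-angle and
configurable). For an atom sphere (radius `r_a`, height `z_a`, lateral
distance `d` from the pixel) the apex contact height is closed-form:
sphere–sphere contact `z_a + sqrt((R+r_a)² − d²) − R` while
`d ≤ (R+r_a)cos θ`, else sphere–cone contact
`z_a + (R+r_a)/sin θ − R − d/tan θ`. The pixel height is the maximum over
atoms, floored at the mica plane (the model is translated so its lowest
sphere surface touches z = 0). Gaussian noise (default 0.1 nm RMS) is
added before quantization to the z-ADC step (default 0.064 nm),
mimicking detector noise followed by digitisation. Atom radii use a small
per-element van der Waals table with a 0.15 nm fallback.

## Profile analysis

Section profiles average heights over ±3 nm perpendicular to a polyline
(trapezoid weights, bilinear interpolation), are re-referenced to the
lowest point on the line, and are resampled to 0.5 nm before any spectral
or peak operation. Band-pass and low-pass filters are brick-wall in the
Fourier domain; the low-pass used for crossover detection
reflection-pads by one cutoff period to suppress edge ringing.

Peak detection is fully deterministic (no analyst corrections):

1. Candidate maxima by prominence (floor: 2% of the profile span).
2. A dynamic program keeps chains of peaks whose successive gaps lie in
   the admissible minor-pitch window (3–6.6 nm); chains are grown
   greedily by total prominence with leftmost tie-breaks, and candidates
   closer than the window's lower bound to a kept peak are rejected —
   this is what discards spurious bumps riding on a real peak's flank.
3. Crossover points are the maxima of the >25 nm low-pass envelope
   (sub-sample refined by a quadratic fit), subject to a minimum
   crossover spacing of 15 nm and an edge margin of one minimum major
   pitch. The stated admissible range for the minimum major pitch is
   15–25 nm; 15 nm is enforced as the hard minimum and 25 nm is used as
   the envelope cutoff period, which isolates the half-helix fundamental
   from its harmonics. Envelope maxima are used directly rather than
   snapped to the tallest nearby bump because the crossover phase of a
   helix is carried by the envelope, while the tallest discrete protomer
   bump near a crossover jitters by several nm.

Each half helix is the interval between consecutive crossovers;
protomer pairs = (number of major + minor peaks in the half-open
interval) − 0.5, which yields 6.5 for the canonical 13-protomer half
helix, and MAD = HHP / pairs. Because the protomer-peak lattice carries a
phase relative to the crossovers, counting boundaries are shifted to
`m + φ − g/2` (g = median minor gap, φ = circular-mean peak phase at the
crossovers), which parks the boundary maximally far from every peak and
makes the count immune to sub-pixel localisation jitter.

## Autocorrelation

Temporal ACF uses the standard biased estimator
`ACF(k) = Σ_{i≤n−k}(y_i−ȳ)(y_{i+k}−ȳ) / Σ_i(y_i−ȳ)²`, so ACF(0) = 1 and
|ACF| ≤ 1. Gaps (NaN) contribute pairwise-complete products rescaled by
the nominal/valid count ratio; series with >30% gaps warn. The
double-exponential fit `a1·e^(−t/t1) + a2·e^(−t/t2) + y0` is made
identifiable on noisy estimates by three guards: the fit window stops
where |ACF| has stayed under its sampling floor (~2/√n_eff) for several
lags; residuals are weighted by the Bartlett large-lag standard error;
and the offset is bounded to ±0.05 by default, since the ACF of a
stationary series decays to zero and a loose offset absorbs the slow
component. Multi-start (8 seeded log-uniform starts) guards against local
minima; constants are reported with t1 ≤ t2 and near-degenerate fits are
flagged. For movie-scale data the per-pair ACFs should be averaged
(`mean_acf`) before fitting — single-pair records at a few hundred frames
carry irreducible estimator spread comparable to the constants
themselves.

Spatial ACF: mean-subtract, brick-wall band filter to the protomer
periodicity (5–8 nm default), then inverse FFT of the power spectrum
(Wiener–Khinchin; circular, verified against direct summation at 1e-9).
The Hilbert envelope (analytic-signal magnitude) provides a non-negative
oscillation envelope used for initialisation and QC. The decaying
sinusoid `ρ(d) = exp(−d/D1)[D2 cos(d/D3+γ1) + D4 sin(d/D5+γ2) +
D6 cos(d/D7+γ3) + D8 sin(d/D9+γ4)]` is fitted to the ACF itself (the
envelope only initialises D1 via a log-linear fit) by a hand-rolled Nadam
optimizer with analytic gradients: step 1e-2 with per-parameter scale
factors, 5000 iterations, early stop on a 500-step plateau, 8 seeded
restarts, and box constraints (D1 in 1–500 nm; the reciprocal-period
parameters constrained so periods lie in 2–60 nm). A rigid rendered
filament is perfectly periodic, so its fitted D1 is essentially unbounded;
finite decay constants arise from twist disorder, which the simulator
plants explicitly.

## Distribution statistics

Histogram fits use fixed bin widths (0.2 nm for heights, 1.0 nm for
HHPs), Poisson weights (bin variance ≈ counts) and a component-sd floor
of one bin width; both choices exist to keep the extra-sum-of-squares
F-test between the single- and double-Gaussian fits calibrated (null
rejection ≈ 5% at α = 0.05 in simulation; unweighted fits reject at
>20%). Degrees of freedom are (3, bins − 6) on the binned residuals, and
a two-component fit that is worse than the single fit returns p = 1.
The supertwisted fraction is the fitted normal mass below 30 nm (or the
empirical proportion for raw values). Cluster growth rate divides the 11
cofilin sites of a supertwisted half helix by the observed lag time.

## Synthetic data: what it emulates, and what it does not

`make_helix_points` places one spherical blob per protomer on the genetic
helix (axial `j·rise`, azimuth `−j·twist`, blob radius 2.5 nm at 2.5 nm
helix radius), which reproduces the morphology that matters for the
pipeline: crossover maxima with ~2–3.5 nm helical height modulation,
minor bumps of ~1 nm at the protomer-pair spacing, and a 1.3 nm
within-image height offset for cofilin-decorated ranges (inside the
observed 1–1.6 nm band). Ground truth (crossover positions, HHP, pairs,
MAD) is computed analytically from the spec.

Two deliberate simplifications matter when interpreting green tests:

- A *rigid* filament at an incommensurate twist (e.g. 13.42 protomers
  per crossover) necessarily alternates 13- and 14-protomer half
  helices, so per-interval pair counts mix the x.5 classes even with a
  perfect detector; only the modal count equals the nearest-odd value.
  Exact per-interval recovery is therefore validated on
  odd-commensurate generators (11, 13, 15, 17 protomers per crossover,
  paired with the observed class pitches), where ≥90% of half helices
  report the exact class. Real filaments fluctuate between these classes
  thermally; the generator does not model that dynamics.
- A class at 9 protomers per crossover with a ~28.6 nm pitch renders
  with a 6.4–7.2 nm bump spacing, outside the 3–6.6 nm admissibility
  window, and is genuinely unmeasurable under these constraints (it was
  also the rarest class in real data); the sweep starts at 11.

The axial-distance simulator is a sum of two stationary AR(1) processes
with autocorrelation times (t1, t2), variance weights (a1, a2), a total
fluctuation SD of 0.25 nm around a 5.5 nm mean, and white measurement
noise (0.05 nm default) — the simplest stationary process whose exact ACF
is the fitted double exponential. It does not model drift, tracking
dropouts (though the ACF estimator handles NaNs), or coupling between
neighbouring pairs.

## Problem sizes

Default test and acceptance runs use 62–90-protomer filaments
(~170–250 nm), 4–6 noise seeds per condition, 258-frame × 27-pair
axial-distance movies, and 20 seeded curves for decay-constant recovery —
sizes at which every estimator's sampling error is comfortably inside the
asserted tolerances.

## Known limitations

- PDB/mmCIF reading takes the first model only; occupancy/B-factors and
  multi-conformer averaging are ignored.
- PE/BE side assignment of half helices is a labelling rule supplied by
  the caller (the shorter bare neighbour of a cofilin cluster is the
  pointed-end side), not inferred from images.
- Scanner artefacts (piezo nonlinearity, drift, scan-line noise) are out
  of scope; synthetic pixels are ideal.
- The F-test calibration holds for the shipped binning defaults; very
  sparse histograms (n ≲ 100 per component) remain anti-conservative.
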