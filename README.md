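# actintwist

Quantitative analysis of helical twist in actin filaments, for structural
biologists and AFM groups working on actin–cofilin mechanics.

Actin filaments are double-stranded helices whose two long-pitch strands
cross every half-helical pitch (HHP ≈ 36 nm for bare F-actin, 13 protomers
= 6.5 protomer pairs per half helix). Cofilin binding supertwists the
helix, shortening the HHP by ~25% (≈ 11 protomers per half helix), and
this variability in twist is measurable in high-speed AFM movies as the
spacing of crossover and protomer peaks along the filament. `actintwist`
implements the full analysis chain around these observables:

- **structure_ensemble** — Cα extraction from PDB/mmCIF, common-residue
  mapping, inner-domain (SD3+SD4) superposition, and PCA of the protomer
  conformational ensemble (the G-/F-/C-actin transition modes), with mode
  back-projection.
- **filament_builder** — Kabsch fitting of the rigid transform between
  adjacent protomers, axis–angle twist/rise, and helical parameters:
  protomers per crossover = 180/(180 − |twist|),
  HHP = that × rise, MAD = 2 × rise; long-filament construction by
  repeated application of the generator.
- **pseudo_afm** — tip-dilation rendering of atomic or coarse-grained
  models (sphere-capped cone probe, closed-form contact heights), with
  noise and z-quantization.
- **profile_analysis** — longitudinal section profiles (±3 nm band
  average), Laplacian-of-Gaussian filtering, band-pass filtering,
  constrained peak detection (minor pitches in 3–6.6 nm, minimum major
  pitch 15 nm), and per-half-helix measurement of HHP, protomer pairs
  (peak count − 0.5) and MAD (HHP/pairs).
- **correlation** — temporal autocorrelation of axial-distance series
  (biased estimator, gap-aware) with double-exponential fitting
  (t₁, t₂); spatial autocorrelation of protomer-height profiles via the
  Wiener–Khinchin theorem, Hilbert envelopes, and a
  Nadam-optimised exponentially decaying sinusoid
  ρ(d) = exp(−d/D1)[D2 cos(d/D3+γ1) + D4 sin(d/D5+γ2) + …].
- **twist_stats** — Gaussian/double-Gaussian histogram fits with an
  extra-sum-of-squares F-test, the supertwisted half-helix fraction
  (HHP < 30 nm), and cofilin-cluster growth rates (11 molecules per half
  helix / lag time).
- **synthetic_data** — seeded generators for every input the pipeline
  consumes: helical filament point clouds (bare, cofilin-decorated,
  hybrid), two-timescale axial-distance series, decaying-sinusoid curves
  and planted-mode structural ensembles, each with analytic ground truth.

## Worked example

Render a canonical synthetic filament, measure its half helices, and fit
the twist dynamics of a simulated axial-distance movie:

```bash
$ actintwist simulate filament --seed 1 --out fil.csv
wrote fil.csv (ground-truth HHP 36.91 nm)

$ actintwist profile --map fil.csv --out hhp.csv
3 half helices -> hhp.csv

$ cat hhp.csv
hhp_nm,protomer_pairs,mad_nm
36.22206430947935,6.5,5.572625278381438
36.690216018309016,6.5,5.644648618201387
38.11134801630418,6.5,5.863284310200642

$ actintwist simulate adseries --frames 258 --pairs 27 --dt 0.2 --seed 1 --out ad.csv
$ actintwist acf temporal --series ad.csv --dt 0.2 --out fit.json
t1 0.319 s, t2 1.814 s -> fit.json
```

The three measured half helices recover the generator's 6.5 protomer
pairs, with pitches scattered around the geometric 36.91 nm and MADs
around HHP/6.5 ≈ 5.7 nm. The temporal fit recovers the two planted
axial-distance correlation times (0.4 s and 2.0 s defaults) from the
averaged per-pair autocorrelation of a 258-frame series.

The same operations are available as library calls
(`render_filament`, `extract_profile`, `detect_peaks`,
`measure_half_helices`, `temporal_acf`, `fit_expdec2`, …).

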