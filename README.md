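# woodsans

Small-angle neutron scattering (SANS) analysis of wood cell-wall
nanostructure: reduction of 2D detector frames into aligned / amorphous /
isotropic 1D profiles, fitting of a composite empirical scattering model
(low-q power law + mid-q unified level + Gaussian diffraction peak +
background), and extraction of elementary-fibril (EF) spacing and mid-q
structure metrics. A synthetic-data module generates ground-truth-labelled
frames and profiles so the whole pipeline can be exercised and validated
without any external download.

## What it does

1. **Reduction** (`woodsans.reduction`) — per-pixel q via
   `q = 4π sin(θ)/λ`, monitor/sensitivity/dark/background corrections with
   Poisson error propagation, anisotropy detection from the second circular
   harmonic of the azimuthal profile, sector averaging (aligned sector and
   its 90°-rotated amorphous counterpart, both pooled with their 180°
   mirrors), and merging of the two instrument configurations
   (1.7 m / 14.5 m sample-to-detector, q = 0.003–0.27 Å⁻¹).
2. **Model** (`woodsans.model`) — the composite empirical intensity model
   with a Beaucage-style unified level
   `G·exp(−q²Rg²/3) + B·(q/erf(qRg/√6)³)^−P`, plus wavelength-spread
   resolution smearing (Δλ/λ = 13%).
3. **Fitting** (`woodsans.fitting`) — the staged protocol: subtract the
   amorphous from the aligned profile, two-level fit (power law + peak) for
   P₁ and the peak position q₀, three-level fit for the mid-q R_g and P₂,
   optional fixed parameters for weak-featured samples, and χ²-profile
   uncertainty intervals from the rule `χ²(θ) < 1.06·χ²_min`.
4. **Reporting** (`woodsans.report`) — EF spacing `d = 2π/q₀` (nm), q-region
   classification, treatment-to-treatment percent changes, and study report
   tables (CSV + text).
5. **Synthetic data** (`woodsans.synthetic`) — seeded, deterministic
   generators for 1D profiles and 2D Poisson-noise frames with two-fold
   azimuthal lobes, plus two scenario builders (`pulse-series`,
   `decay-series`) whose ground truths follow the published study tables.

## CLI

```sh
# generate a synthetic study (HDF5 frames + CSV manifest)
woodsans simulate --scenario pulse-series --seed 1 --out sim/

# reduce + fit every sample in the manifest
woodsans analyze --in sim/ --out fits/

# assemble the study report table
woodsans report --fits fits/ --metadata sim/manifest.csv --out report/study
```

## Layout

```
src/woodsans/
  model.py       # composite empirical model + smearing
  reduction.py   # frames -> 1D profiles; HDF5 + ASCII formats
  fitting.py     # staged fits, chi-square profiling, report files
  report.py      # EF spacing, q regions, study tables
  synthetic.py   # ground-truth generators and scenarios
  pipeline.py    # end-to-end glue used by the CLI and tests
  cli.py         # click entry point (`woodsans`)
```
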