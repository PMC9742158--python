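# t1aniso

Orientation-resolved T1 relaxometry versus diffusion-MRI microstructure,
with a synthetic brain-phantom generator that makes every stage of the
analysis verifiable by parameter recovery — no data download required.

The pipeline chains five stages:

1. **phantom** — multi-subject 3 T / 7 T synthetic studies: z-slab tissue
   classes holding fans of Watson-dispersed mini-bundles that sweep the
   fibre-to-field angle range, two-shell diffusion signals from
   Watson-averaged stick/zeppelin tensors, and six-TI inversion-recovery
   series whose ground-truth T1 follows a field-dependent angular law
   (Gaussian peak plus optional 0-90 degree gradient), all with Rician
   noise and per-subject biological variability.
2. **dti** — weighted-least-squares log-linear tensor fit (OLS
   initialisation, one WLS pass with squared predicted-signal weights),
   FA / MD / eigensystem maps.
3. **orientation** — fibre-to-field angle maps from V1 (sign-invariant,
   degrees in [0, 90]) and the analytic Watson kappa <-> ODI bijection.
4. **relaxometry** — vectorized magnitude IR fitting
   `y(TI) = |S0 (1 - 2 eta exp(-TI/T1))|` with grid-search initialisation,
   damped Gauss-Newton refinement, optional Rician noise-floor
   pre-correction, and an F-test guard that frees the inversion
   efficiency only when the data warrant it.
5. **anisotropy** — microstructure-conditioned angular statistics:
   voxel selection by index windows, 4.5-degree-bin 1D/2D profiles
   (per subject, then across subjects), the two-anchor straight-line
   baseline and its peak / parallel-minus-perpendicular deltas, S0
   normalisation, box-ROI statistics with Welch tests, mask SNR tables,
   and a cross-field summary table.

The bundled presets (`scenario_3T`, `scenario_7T`) are *calibrated*: each
class's angular T1 law is solved (a 3x3 linear inversion of the exact
measurement operators) so that the noise-free pipeline reproduces the
target selection-level statistics exactly; noisy runs recover them within
cohort scatter.

## CLI

```sh
t1aniso all --preset scenario_3T --out results/run3t --seed 42
t1aniso report --config runconfig.yaml
```

Verbs `simulate`, `fit-dti`, `fit-t1`, `profile`, `report`, `all` run the
corresponding stages.  Outputs follow a BIDS-like layout
(`sub-XX/{dwi,ir,truth,dti,relax}/`, FSL-style `bvals`/`bvecs` and map
naming) plus `group/` CSV profiles, a summary table, PNG figures and a
`provenance.json` with seeds, versions and output checksums.  Re-running
the same config reproduces identical CSVs bit for bit.

A run config YAML looks like:

```yaml
out_dir: results/run3t
preset: scenario_3T          # or scenario_yaml: my_scenario.yaml
preset_overrides: {n_subjects: 4, grid_shape: [20, 20, 10]}
make_plots: true
```

## Package layout

```
src/t1aniso/
  phantom.py      scenario/tissue-class types, layout, DWI + IR simulators
  watson.py       Watson axis sampler and exact axial moments
  presets.py      calibrated 3 T / 7 T scenario presets
  dti.py          WLS tensor fit, FA/MD
  orientation.py  fibre-to-field angles, ODI <-> kappa
  relaxometry.py  voxel-wise IR T1/S0/eta fitting
  anisotropy.py   profiles, baselines, deltas, ROI stats, SNR, group table
  pipeline.py     cohort orchestration and on-disk report bundle
  cli.py, io.py, datasets.py
```
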