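# depchain

Quantifying dielectrophoretic (DEP) response from micrographs of microparticle
pearl chains.

When polarizable microparticles (polystyrene beads, yeast cells) are suspended
in a low-conductivity buffer and driven by a non-uniform AC field, the
time-averaged DEP force on a small sphere is

    F_DEP = 2 π a³ ε_m Re(f_cm) ∇E²_rms ,      f_cm = (ε*_p − ε*_m) / (ε*_p + 2 ε*_m)

with complex permittivities ε* = ε − i σ/ω.  Positive Re(f_cm) drives the
particles toward high-field regions, where they assemble into *pearl chains*
aligned with the field; the chains grow longer as the drive voltage rises.
`depchain` turns that observation into a measurement: it detects particles in
a micrograph by normalized cross-correlation template matching, groups them
into chains with a geometric adjacency rule (centers within 2r + c, where r
is the pearl radius in pixels and c = r/4 a tolerance), counts chains by
length (the predictors C1..C18, C_L = number of chains with exactly L
particles), ranks predictor importance with RReliefF, and regresses the
applied voltage (1–10 V at 200 kHz) from the counts with a small neural
network trained from scratch (SGDM / RMSProp / ADAM update rules
implemented in-package).  A morphological segmentation pipeline
(threshold → dilation → opening → hole fill / border clear → closing) and the
Clausius–Mossotti physics (spectra, crossover frequency, dipole and surface
force forms) round out the toolkit.

Because the original image corpus is not redistributable, the package ships a
synthetic micrograph generator with exact ground truth whose voltage-to-
chain-length calibration reproduces the experimentally reported shares
(84% C2 / 15% C3 at 3 V; ~40% of chains longer than 4 particles beyond 5 V;
majority of chains with 8+ particles above 7 V).  Every downstream stage is
tested against that ground truth and against independent brute-force oracles.

Audience: microfluidics / lab-on-chip researchers who want a transparent,
scriptable baseline for image-based DEP force estimation, and anyone needing
a self-contained reference implementation of the chain-counting feature
pipeline.

## Worked example

Run the whole pipeline on a freshly generated dataset (10 voltages × 50
images, 512×512 px, radius-10 px particles, Gaussian noise sd 8):

```bash
depchain run --out demo_run --seed 42
```

which logs the stages and prints the held-out test report:

```json
{
  "mae": 0.2807897407971438,
  "mre": 0.049560022516641926,
  "mse": 0.1823599621483693,
  "rmse": 0.42703625390400907,
  "r_squared": 0.9794491568080183,
  "accuracy": 0.8,
  "n": 100
}
```

Reading: on the 20% held-out images the network recovers the applied voltage
with a root-mean-square error of 0.43 V, a mean absolute error of 0.28 V, an
R² of 0.979, and 80% of predictions fall strictly within the half-volt band
(`accuracy` counts |y − ŷ| < 0.5).  The run directory contains
`features.csv` (image_id, voltage, C2..C18, singletons, overflow),
`weights.csv` (RReliefF importances — in this run the long-chain counts
C8–C11 carry the largest weights, ~0.04–0.06, while the short-chain counts
are near zero), `model.json`, `report.json`, and a `manifest.json` with
SHA-256 checksums of every artifact; re-running with the same seed
reproduces the checksums bit for bit.

The physics tool works standalone; for 10–20 µm polystyrene beads
(ε_p = 2.55, σ_p ≈ 0) in the low-conductivity buffer (ε_m = 80,
σ_m = 1.8×10⁻⁴ S/m):

```bash
$ depchain physics
no crossover frequency (limits have the same sign)
spectrum -> cm_spectrum.csv
```

(PS beads are less polarizable than the buffer at every frequency, so
Re(f_cm) stays negative and there is no crossover.)

Stages are also available individually: `simulate`, `detect`, `extract`,
`segment`, `rank`, `train`, `evaluate` — see `depchain --help`.

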