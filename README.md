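# pasvd

Blockwise singular-value-decomposition (SVD) separation of interleaved
ultrasound (US) / photoacoustic (PA) multiframe data into stationary-tissue,
flow, and noise components — plus detection of *stationary* PA sources (such
as intraplaque hemorrhage) by masking flow-associated PA signal, a synthetic
mock-loop phantom simulator, and generalized contrast-to-noise ratio (gCNR)
evaluation.

## How it works

1. **preprocess** — envelope detection (analytic-signal magnitude per
   A-line), log compression, frame averaging, percentile contrast stretch.
2. **svd_core** — the image plane is tiled into rectangular blocks; each
   block's Casorati matrix (pixels × frames) gets a full SVD. Singular-value
   curves (dB) are smoothed over the block grid, then two thresholds are
   placed automatically on every curve: the *low-order* threshold at the
   first order where the ratio of consecutive singular values drops below a
   preset, and the *high-order* threshold at the global minimum of the
   twice-smoothed first difference of the curve. Threshold fields are
   median-filtered over the grid, and partial reconstructions from the
   three singular-order bands are scattered back into full-size stacks.
   The three components sum to the input exactly.
3. **masking** — a binary perfusion mask is distilled from the US flow
   component (Gaussian blur → temporal standard deviation → dynamic-range
   compression → edge detection → morphological closing → fill). Combined
   with thresholded PA data (perfusion=1, PA=2, overlap=3), the overlap is
   grown iteratively through 8-connected neighbors until it covers every PA
   structure touching perfusion; inverting the grown set yields the final
   mask that keeps only stationary PA sources.
4. **metrics** — gCNR = 1 − η, where η is the overlap of unit-mass
   histograms of signal vs background ROI pixels on shared bins.
5. **synthetic** — a seeded 2-D phantom: 3-mm pulsatile lumen (~9 % wall
   strain at 1 Hz), a 0.25–1.0 mm constant-flow arteriole, two 1-mm
   stationary blood channels, speckle texture, sensor noise, and interleaved
   PA frames with depth-dependent fluence and shadowing. Ground-truth masks
   are exact by construction.

## CLI

All subcommands are deterministic functions of (inputs, config, seed); every
resolved parameter is logged (`-v`) and stored as provenance in the output
container (HDF5; multi-frame TIFF is supported for single stacks).

```sh
pasvd simulate --config configs/arteriole_0p5mm.yaml --seed 0 --output sim.h5
pasvd filter   --input sim.h5 --group /us --output filt.h5
pasvd detect   --input sim.h5 --output det.h5 --overlay-png overlay.png
pasvd gcnr     --input sim.h5 --signal 50,70,50,70 --background 5,25,5,25
pasvd run      --seed 0 --output full.h5          # simulate + filter + detect
pasvd sweep-blocksize --seed 0 --out sweep.json   # 7 block sizes × 3 components
```

Config files are flat YAML key-value maps; every key has a default
(`FilterConfig`, `MaskParams`, `PhantomConfig`). Presets for the four
arteriole diameters and four orientations are in `configs/`.

## Layout

```
src/pasvd/
  preprocess.py   FrameStack type, envelope/log/averaging/stretch
  svd_core.py     block grid, spectra, thresholds, blockwise filter
  masking.py      perfusion mask, overlap growing, stationary-PA detection
  metrics.py      histogram overlap, gCNR, gCNR improvement
  synthetic.py    phantom configuration and simulator
  io.py           HDF5/TIFF stack I/O, YAML config, provenance
  cli.py          `pasvd` entry point
tests/            pytest suite (unit, property, acceptance); oracles.py
                  holds the independent brute-force oracles
scripts/acceptance.py
configs/          phantom presets
```
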