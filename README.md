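# hexspot

Shock-filter-driven registration and segmentation of images whose objects
sit on a **hexagonal grid** — primarily one-colour microarray scans, where
each bright spot is a DNA probe whose fluorescence encodes a gene's
expression level. Hexagonal (double-density) layouts pack more probes per
slide than rectangular grids, but most gridding software assumes
rectangular layouts; `hexspot` closes that gap while keeping the
computation on cheap 1D profiles.

## Method

The workhorse is the 1D shock filter

```
u_t = −sign(G_σ ∗ u_xx) · |u_x|
```

applied to the image's axis-mean luminance profiles
`V(i) = (1/N) Σ_j p_ij` and `H(j) = (1/M) Σ_i p_ij`. The upwind
(Osher–Rudin) discretisation erodes where the Gaussian-smoothed second
derivative is positive and dilates where it is negative, so a profile
evolves to a **piecewise-constant steady state whose jumps sit exactly at
the edges** of the original bumps — the borders between lines of spots
(vertical profile) or between spots (horizontal profile). The scheme
satisfies a max–min principle and does not increase total variation.

The full workflow:

1. **Preprocess** — point-wise `log(1+p)` stretched to the full 16-bit
   range (recovers weakly expressed spots), small median denoise, white
   top-hat with an elliptical structuring element (removes background
   trends), Radon-transform rotation detection and correction.
2. **Grid decomposition** — shock-filter the vertical profile; the
   inflexion pattern delimits each line of spots between the centres of
   its neighbouring lines. Each band is padded with background rows and
   morphologically opened with an ellipse of the spot radii, which deletes
   the half-spots of the interleaved neighbouring lines. The uneven-line
   and even-line families become two rectangular-grid sub-images
   `I_uev` / `I_ev` whose pixel-wise maximum reproduces the original.
3. **Spot localisation** — shock-filter each line's horizontal profile;
   plateau midpoints are the spot x-centres. An ideal lattice (pitch from
   profile autocorrelation, phase by least squares over both parity
   families jointly) fills in missing spots. Every site gets a pitch-sized
   area of interest `S` ("cookie cutter").
4. **Segmentation & features** — Otsu threshold inside `S`, keep the
   connected component at the spot centre; report background-subtracted
   intensity `I = mean(fg) − mean(bg)`, a model-fit `R²`, and the
   coefficient of variation `CV = σ/ν`. Evaluation against a reference
   annotation uses the mean Euclidean centre distance
   `mE = (1/N_s) Σ |m_i − m_i^ref|`, positioning accuracy (% of spots
   within half a spot diameter), Pearson agreement of feature vectors and
   replicate MAE.

A synthetic generator (`hexspot.synthetic`) renders 16-bit hexagonal
arrays with full ground truth — spot diameter 14 px, weak and missing
spots, noise, optional rotation — so the entire workflow is testable
without any proprietary scanner data.

## Worked example

```sh
python examples/01_simulate_and_quantify.py
```

```
simulated 280 x 600 image, 160 lattice sites (2 missing, 8 weak)
detected 8 lines (hexagonal layout), 160 spots
alignment accuracy : 100.0 %   (spots centred within half a spot diameter of truth)
mean centre error  : 0.100 px  (std 0.269 px)
intensity fidelity : Pearson r = 0.9986  (recovered background-subtracted intensity vs true amplitude)
```

Every lattice site of the simulated array is recovered: all 160 spots are
positioned within half a spot diameter (7 px) of the truth, the mean
centre error is a tenth of a pixel, and the recovered background-subtracted
intensities track the true spot amplitudes almost perfectly. The other
scripts in `examples/` demonstrate the shock filter on a single profile,
the dual-grid decomposition, replicate reproducibility metrics and the
workflow on hard-edged (non-microarray) dot arrays.

The same workflow is available from the shell:

```sh
hexspot simulate --seed 42 --out img.tif --truth truth.csv
hexspot run img.tif --out-dir out
hexspot evaluate --spots out/spots.csv --truth truth.csv
```

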