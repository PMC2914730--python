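# rotmorph

Rotational morphological processing (RMP) for automatic spot detection in
biological microscopy images — fluorescent labels, colloidal gold
particles, and any other small bright features on an uneven background.

## The problem and the method

Labeled proteins appear in micrographs as small bright spots that are
often closely packed, low-contrast and noisy. The classical extractor is
the top-hat transform, `TH_B(f) = f − γ_B(f)`, where `γ_B` is the
grayscale opening by a structuring element (SE) `B`: it removes the
background and keeps bright structures the SE cannot fit inside. With the
usual disk or square SE, however, adjacent spots merge — the wide SE
cannot slip through the gap between them.

A 1-pixel-wide straight line SE *can* slip through a 1-pixel gap, but a
single orientation is not isotropic, and a discrete line cannot be
rotated to arbitrary angles. RMP rotates the **image** instead of the SE:
for `i = 0 … N−1`, the image is rotated by `π·i/N` (clockwise, about the
frame center), opened with a fixed horizontal line SE `B_L` of odd length
`L`, and rotated back; the union (pixelwise maximum) of the `N` opened
images is the RMP opening

```
γ'_B(f)(x, y) = max_i  h_i(x, y),     h_i = R_{−i}( γ_B( R_i(f) ) )
```

and the RMP top-hat `TH'_B(f) = f − γ'_B(f)` is the spot extractor. `N =
36` (5° steps) is the point where restoration quality saturates.

The end-to-end pipeline is: (1) noise reduction — RMP opening with a line
shorter than the spot diameter; (2) extraction — RMP top-hat with a line
longer than the spot diameter; (3) binarization of the strictly positive
residual; (4) optional cleanup by a conventional binary disk opening;
(5) 8-connected labeling with per-spot measurements (centroid, area,
averaged Feret diameter, integrated intensity).

The package also ships the fully synthetic benchmark used to validate
all of this: 512×512 fields of 2-D Gaussian spots (17-px domain, peaks
255/127), Poisson noise over uniform or gradient backgrounds, PSNR
measurement, and recall/precision/F-measure scoring against conventional
top-hat and h-dome baselines. No external data is needed anywhere.

## Worked example

```python
import numpy as np
from rotmorph import PipelineConfig, run_pipeline
from rotmorph.benchmark import (TYPE_A, add_poisson_noise, generate_source_image,
                                match_detections, prf, psnr)

source, centers = generate_source_image(TYPE_A, 0)   # 15 planted spots
noisy = add_poisson_noise(source, TYPE_A, 1)
print(f"PSNR of the noisy image: {psnr(source, noisy):.2f} dB")

cfg = PipelineConfig(se_noise=13, se_spot=21, n_directions=36,
                     presmooth="gaussian3x3", cleanup_disk=13)
result = run_pipeline(noisy, cfg, resolution=0.09)    # 0.09 um/px
print(f"detected spots: {len(result.records)}")

tp, fp, fn = match_detections(centers, result.centroids, tol=4.0)
recall, precision, f = prf(tp, fp, fn)
print(f"TP={tp} FP={fp} FN={fn} -> recall={recall:.1f}% "
      f"precision={precision:.1f}% F={f:.1f}%")
```

prints

```
PSNR of the noisy image: 13.90 dB
detected spots: 15
TP=15 FP=0 FN=0 -> recall=100.0% precision=100.0% F=100.0%
```

The noisy field sits at 13.9 dB PSNR (heavy Poisson noise over a uniform
background of ~51 gray levels), yet the pipeline recovers every planted
spot with no false alarms. Each record carries the measurements, e.g. the
first spot here has area 268 px, averaged Feret diameter 19.37 px
(1.74 µm at the chosen resolution) and integrated intensity 36727.

## Command line

```sh
rotmorph extract cells.tif --se-noise 5 --se-spot 13 \
    --resolution 0.90 --unit nm --invert --out results/
rotmorph simulate --n-spots 15 --background gradient --out sim/
rotmorph benchmark --n-images 10 --ladder --out bench/
rotmorph measure mask.tif cells.tif --resolution 0.90 --unit nm
```

`extract` writes the binary mask (TIFF), a red-overlay PNG, per-spot and
histogram CSVs (0-based row/col coordinates) and a JSON run manifest with
every parameter, the seed and library versions. The `--se-noise 5
--se-spot 13 --resolution 0.90` setting above is the one used for
10-nm colloidal gold at 0.90 nm/px; `--invert` handles EM contrast.

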