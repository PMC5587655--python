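# rcrecon

Row-column ultrasound reconstruction toolkit: a forward model of sparse,
speckled, depth-varying-PSF acquisition, and MAP despeckling/inpainting with
an edge-guided, stochastically connected random field, plus the standard
image-quality metrics (PSNR, CoC, ENL, CNR, FWHM).

## What it does

Row-column addressed 2-D arrays acquire fan-beams of readings, leaving most
lattice voxels unobserved, corrupted by multiplicative speckle, and blurred
by a point spread function that widens with depth and carries edge-wave
ghost lobes. The package:

- **simulates** that acquisition: reflectivity phantoms (cyst ladder,
  L-shape, triple point targets), Gaussian scatterer fields, fan-beam
  sampling masks, a simplified spatial-impulse-response evaluator for
  rectangular line elements, a depth-indexed PSF kernel bank (parametric or
  SIR-derived, with optional ghost replicas), and log-domain speckle whose
  density is the Fisher–Tippett (Gumbel-minimum) law;
- **reconstructs** by minimizing a random-field energy: a Fisher–Tippett
  unary term gated by the uncertainty layer (missing voxels contribute
  exactly nothing), plus a pairwise term over stochastically realized
  long-range cliques weighted by spatial-proximity and first-order-variation
  penalties, optimized by monotone gradient descent with backtracking;
- **evaluates** reconstructions against the ground-truth phantom with
  PSNR/CoC/ENL/CNR on display-domain (log-compressed, dynamic-range
  windowed) images, and FWHM/peak counting for point-target resolution.

## Layout

| module | contents |
|---|---|
| `rcrecon.phantoms` | phantom specs, rasterization, scatterer fields |
| `rcrecon.acquisition` | SIR/PSF bank, speckle, fan-beam masks, forward model, lattice interpolation |
| `rcrecon.graph` | edge map, affinities, stochastic clique sampler |
| `rcrecon.crf_energy` | unary/pairwise potentials, total energy, analytic gradient |
| `rcrecon.inference` | gradient-descent MAP reconstruction, volume driver, baseline |
| `rcrecon.metrics` | PSNR, CoC, ENL, CNR, FWHM, region helpers |
| `rcrecon.interface` | YAML-driven scenarios, TIFF/JSON serialization, CLI |

## CLI

```sh
# end-to-end: phantom -> observation -> reconstruction -> metrics
rcrecon run --phantom cyst --seed 1 --out out/

# stage by stage
rcrecon simulate --phantom lshape --seed 2 --out sim/
rcrecon reconstruct --input sim/observation.tif --mask sim/mask.tif \
    --out recon.tif --trace trace.csv
rcrecon evaluate --ideal sim/phantom.tif --recon recon.tif --out report.json

# PSF kernel bank builder (parametric or SIR mode)
rcrecon psf --mode sir --depths 10,25 --pitch 0.1,0.1 --out bank.tif
```

All stages accept `--config cfg.yaml`; CLI flags override config keys. Every
artifact is written as float32 TIFF with a JSON sidecar carrying the pitch,
origin, seed and a config hash, so runs are reproducible byte for byte.

## Conventions

Slices are `[z, x]` arrays (axial, lateral), voxel-center coordinates in
mm, z increasing away from the transducer; volumes stack slices along the
elevation axis and are reconstructed slice-independently. The optimization
variable is the log-envelope image (speckle is additive there); estimates
are exponentiated for display at a configurable dynamic range (40 dB
default).
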