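# ptikit

Uniaxial permittivity-tensor imaging in Python: a vectorial partially
coherent forward model that encodes a specimen's permittivity tensor into
polarization-resolved intensity stacks under oblique illumination, and the
matching multi-channel inverse algorithm that decodes mean permittivity,
differential permittivity, 3D orientation and optic-sign probability at
diffraction-limited 3D resolution.

Everything runs on synthetic phantoms with exact ground truth — no external
data is required.

## What is inside

| module | role |
| --- | --- |
| `ptikit.tensor_core` | uniaxial tensor algebra: composition, the seven scattering-potential components, dual-sign closed-form extraction |
| `ptikit.optics_otf` | illumination patterns (brightfield disk + rotated sectors), dyadic Green's tensor spectrum, vectorial transfer functions `H[m, l, alpha](u)` |
| `ptikit.forward_sim` | nonlinear single-scattering (vector Born) simulator and the exactly-linear weak-object forward |
| `ptikit.stokes_pipeline` | polarization-camera instrument model, intensity/Stokes conversion, background correction, DC normalization |
| `ptikit.inverse_recon` | per-frequency Tikhonov solve of the seven components, dual-sign property extraction, optic-sign probability, end-to-end `reconstruct` |
| `ptikit.phantoms` | star / bead / tube phantoms with exact ground truth |
| `ptikit.analysis_metrics` | FWHM metrology, structure-tensor orientation, orientation histograms, multi-scale coarse-graining, continuity weight, projected retardance |
| `ptikit.cli_io` | YAML config, OME-TIFF / zarr IO, the `pti` command line |

## Quick start (library)

```python
import numpy as np
from ptikit.tensor_core import GridSpec
from ptikit.optics_otf import DetectionSpec, sector_patterns, compute_transfer_functions
from ptikit.forward_sim import simulate_stokes, simulate_background
from ptikit.inverse_recon import ReconstructionConfig, reconstruct
from ptikit.phantoms import star_target

grid = GridSpec((64, 64, 64), (0.15, 0.1, 0.1), wavelength_um=0.532, medium_index=1.515)
patterns = sector_patterns(grid, na_illu=1.4, source_stride=2)   # 9 patterns
detection = DetectionSpec(na_obj=1.47)                           # 4 analyzers
tfset = compute_transfer_functions(patterns, detection, grid)

phantom = star_target(grid, n_wedges=8, thickness_um=0.6,
                      line_spacing_um=0.5, line_width_um=0.15,
                      n_o=1.525, n_e=1.55, sign=+1)
stokes = simulate_stokes(phantom, patterns, detection, grid)     # vector Born
background = simulate_background(patterns, detection, grid)

cfg = ReconstructionConfig(reg_iso=1e-4, reg_aniso=1e-2, optic_sign_window=0.4)
result = reconstruct(stokes, background, tfset, cfg)
# result.mean_permittivity, .diff_permittivity, .omega, .theta, .p_plus
```

Keep the specimen inside the central half of the z window: the axial window
must be roomy enough that through-focus light does not fold back onto the
specimen.

## Command line

```bash
pti info --wavelength-um 0.532 --na 1.4     # theoretical resolution
pti phantom --spec phantom.yaml --out phantom.zarr
pti otf --config run.yaml --out otf.zarr
pti simulate --config run.yaml --phantom phantom.zarr --out stokes.zarr [--raw]
pti reconstruct --config run.yaml --data stokes.zarr --otf otf.zarr --out result.zarr
pti analyze {fwhm, histogram, project-retardance, coarse-grain} ...
```

`run.yaml` holds the instrument block (NAs, wavelength, medium index, voxel
size, grid shape, analyzer angles), the pattern block and the reconstruction
block; see `ptikit.cli_io.RunConfig`.

## Conventions

* volumes are `(z, y, x)` with physical coordinates in micrometres, origin
  at the grid center; spectra use the `numpy.fft` frequency order;
* forward Fourier transform `exp(-i 2 pi u . r)`;
* right circular polarization is `(x - i y)/sqrt(2)` (S3 = -1), transported
  along meridians at oblique incidence;
* the symmetry axis is parameterized by azimuth `omega` in `[0, 2 pi)` and
  inclination `theta` in `[0, pi/2]` (upper-hemisphere axis convention);
* each illumination source's axial frequency is snapped to the `u_z` grid so
  the transfer functions are the exact linearization of the FFT simulator.
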