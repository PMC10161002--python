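# droprheo

Quantitative image analysis of biomolecular-condensate material properties
from time-lapse microscopy, built for the question "is this condensate a
liquid?". The package measures, end to end from raw movie frames:

- **Fusion rheology** — when two droplets of a simple fluid coalesce, the
  aspect ratio of the fusing pair relaxes as
  `AR(t) = 1 + (AR_init − 1)·e^(−t/τ)` with a relaxation time that scales
  with droplet size, `τ ≈ (η/γ)·l`, where `l = d₁ + d₂` is the sum of the
  pre-fusion diameters. Regressing τ against l over many fusion events gives
  the **inverse capillary velocity η/γ** (s/μm), the viscosity-to-surface-
  tension ratio that characterises the fluid. A volume-conservation check
  (`d_post³ ≈ d₁³ + d₂³`) validates each event.
- **Droplet mobility** — single-particle tracking, ensemble mean-squared
  displacement over lag time (`MSD = 4·D·τ_lag` in 2D), the diffusion
  coefficient `D` from the linear fit, and the anomalous exponent α from the
  log-log slope, classifying motion as diffusive, subdiffusive or immobile.
- **FRAP** — fluorescence recovery after photobleaching for partial-, half-
  and whole-droplet bleach geometries: pre-bleach normalization, a
  single-exponential recovery fit yielding the rate `k`, half-time
  `t₁/₂ = ln2/k` and mobile fraction, with fold-change comparisons across
  conditions.
- **Phase diagrams and dissolution** — condensate-presence classification
  over salt-condition grids, and a dissolution score (condensate area
  remaining after a chelation treatment) that separates fluid condensates
  from photocrosslinked, solidified ones.

Because these readouts are usually validated against known ground truth, the
package ships a first-class **synthetic-scene generator**: physics-based
movies of fusing droplet pairs, Brownian/confined droplet ensembles,
intradroplet lattice diffusion under photobleaching with a mobile/immobile
split, dissolving or persisting droplet fields, and condition grids — all
rendered through a realistic optics model (Gaussian PSF blur, Poisson shot
noise, Gaussian read noise, uniform background) with the exact ground truth
returned alongside every stack.

## Worked example

Recover the inverse capillary velocity from a synthetic panel of ten fusion
movies (peak SNR 10, droplet diameters 2–6 μm, true η/γ = 0.5 s/μm):

```python
import droprheo as dr
from droprheo import fusion_rheology as fr

optics = dr.OpticsModel(pixel_size=0.1, blur_sigma=1.0, background_level=0.1,
                        photon_scale=dr.photon_scale_for_snr(10.0))
panel = dr.simulate_fusion_panel(n_events=10, icv_true=0.5, optics=optics,
                                 diameter_range=(2.0, 6.0),
                                 frame_interval=0.25, seed=42)
events = []
for stack, truth in panel:
    per_frame = dr.segment_stack(stack)
    tracks = dr.link_tracks(per_frame, max_displacement_um=0.8)
    events.extend(dr.detect_fusions(tracks, stack.frame_interval))

table, cap = fr.analyze_events(events, r2_min=0.8)
print(f"events detected: {len(events)}")
print(f"inverse capillary velocity: {cap.slope_icv:.3f} +/- "
      f"{cap.slope_se:.3f} s/um (true 0.500), r^2 = {cap.r_squared:.4f}")
print(f"mean volume ratio: {table['volume_ratio'].mean():.3f}")
```

prints

```
events detected: 10
inverse capillary velocity: 0.500 +/- 0.003 s/um (true 0.500), r^2 = 0.9998
mean volume ratio: 1.010
```

i.e. every simulated coalescence was detected, the τ-vs-l regression is
linear (r² > 0.999) with a slope matching the generator's η/γ to three
decimals, and droplet volume is conserved through fusion to ~1%.

## Command line

A thin CLI mirrors the library stages:

```bash
droprheo simulate fusion --d1 3 --d2 3 --icv 0.5 --out movie.tif --seed 5
droprheo fusions  --stack movie.tif --outdir events/
droprheo rheology --events events/events.csv --ar-series events/ar_series.csv --out icv.json
droprheo msd      --tracks tracks.csv --frame-interval 0.5 --dmin 4 --dmax 8 --out msd.json
droprheo frap     --stack frap.tif --roi partial_disk --radius 1.0 --out frap.json
droprheo dissolve --stack assay.tif --treatment-frame 30 --out dissolution.json
droprheo run      --config run.toml --mode fusion
```

Stacks are multi-page uint16 TIFFs with a flat `key=value` sidecar
(`<stack>.meta.txt`) carrying the calibration (μm/px, s/frame), the
quantization scale and the seed; tables are CSV with a header row; results
are JSON. Every output embeds the parameters and seed needed to regenerate
it, and re-running a pipeline with the same config is byte-identical.

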