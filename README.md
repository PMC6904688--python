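# penpet

Desk-scale simulation and analysis of **penalized-likelihood PET
reconstruction (BSREM with a relative-difference penalty) versus
post-filtered OSEM**, scored with NEMA NU-2 image-quality metrics and a
clinical-style lesion metric suite.

Modern PET scanners ship a convergent Bayesian reconstruction (BSREM, the
basis of vendor "penalized-likelihood" modes) as an alternative to the
clinical standard of early-stopped, post-smoothed OSEM. The practical
question for physicists and method developers is how much background noise
the penalty removes at matched lesion contrast — and therefore how far
acquisition time or injected dose could be cut. `penpet` provides a fully
self-contained, reproducible test bed for that question: a digital NEMA IEC
image-quality phantom and a lesion phantom, a 2D multi-slice Poisson
acquisition simulator with attenuation, resolution blur and a scatter
background, both reconstruction algorithms over a β sweep, and the standard
metric definitions.

## Model and metrics

Reconstructions share the forward model ȳ = f ⊙ (A P x) + b (matched sparse
projector pair A/Aᵀ, image-space Gaussian PSF P, known attenuation factors
and scatter mean). OSEM runs 3 iterations × 16 subsets with a 5.0 mm
Gaussian post-filter. BSREM maximizes the penalized Poisson log-likelihood

    Φ(x) = Σᵢ [ yᵢ log ȳᵢ(x) − ȳᵢ(x) ] − β Σ_{⟨j,k⟩} w_jk
           (x_j − x_k)² / (x_j + x_k + γ|x_j − x_k| + ε),   γ = 2,

by relaxed, preconditioned subset ascent with non-negativity projection.
Image quality follows the NEMA NU-2 conventions, for each hot sphere j:

    CR_j  = (C_H,j/C_B,j − 1) / (a_H/a_B − 1)
    COV_j = SD_j / C_B,j          (over 60 background ROI means)
    CNR_j = CR_j / COV_j

and the lesion suite uses 41%-of-maximum VOIs, SUV statistics against a
liver-like reference (SUV 2.2), noise = SD/SUV_mean, SNR =
(SUV_mean,lesion − SUV_mean,liver)/SD_liver, contrast, and
MATV = SUV_mean × volume. The penalty weight is not transferable between
systems, so the pipeline CR-matches β to OSEM on the 37 mm sphere
(`match_beta`) before any comparison. See `docs/methods.md` for the full
model description, parameter defaults and design rationale.

## Worked example

Simulate the 8:1 NEMA phantom at the 20-minute-analog count budget,
reconstruct with clinical OSEM, and score it:

```python
import penpet as pp
from penpet import nema

grid = pp.GridSpec()
vol  = pp.build_phantom(pp.PhantomSpec(sphere_ratio=8.0), grid)
geom = pp.ProjectionGeometry()
acq  = pp.AcquisitionSettings(duration=1200.0)          # 20-min analog
true = pp.forward_project(vol, geom, psf_fwhm=acq.psf_fwhm)
att  = pp.attenuation_factors(vol.mu, geom, grid)
y    = pp.sample_counts(pp.expected_counts(true, att, acq), seed=1)

res = pp.osem_reconstruct(y, att, None, pp.OSEMSettings())
img, factor = pp.calibrate_to_concentration(res, vol)
print(nema.sphere_metrics(img, vol).round(4).to_string(index=False))
```

Output:

```
 diameter_mm     CR    COV     CNR
        10.0 0.3471 0.2380  1.4582
        13.0 0.6241 0.2054  3.0381
        17.0 0.7839 0.1761  4.4525
        22.0 0.8208 0.1370  5.9927
        28.0 0.8674 0.1088  7.9764
        37.0 0.8922 0.0779 11.4550
```

Reading the table: the 37 mm sphere recovers 89% of its true 8:1 contrast,
the corresponding background ROI means vary by 7.8%, and contrast recovery
falls toward small spheres as partial-volume losses grow — the standard NEMA
picture. Swapping in `pp.bsrem_reconstruct(y, att, None,
pp.BSREMSettings(beta=0.1, max_iterations=15))` gives the penalized
counterpart; `penpet.analysis.noise_reduction_summary` runs the whole
CR-matched comparison (β sweep, ratios, count thinning, lesion phantom) and
`penpet.pipeline.run_experiment` the factorial study from a YAML config.

A command-line interface mirrors the library:

```bash
penpet print-config > study.yaml
penpet run-all --config study.yaml --seed 1
penpet headline --seed 1            # the CR-matched noise-reduction folds
```

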