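# pmctseq

Sequential post-mortem CT analysis of the lateral cerebral ventricles.

## The problem

In forensic imaging, the same cadaver can be CT-scanned repeatedly over the
first post-mortem day ("sequential scanning"). Two quiet but robust changes
unfold inside the skull: the lateral cerebral ventricles (LCV) — the paired
CSF-filled cavities of the cerebrum — shrink approximately linearly, and the
mean attenuation of the CSF inside them rises approximately linearly on the
Hounsfield scale. Both trends are candidates for estimating the post-mortem
interval (PMI), the elapsed time since death.

`pmctseq` is for researchers who want to study or reuse this measurement
chain. It provides:

* a **synthetic phantom** generator (`pmctseq.phantom`) producing head-CT-like
  series — a bilateral, horned ventricular CSF compartment inside brain,
  skull and air — with known ground truth, linear volume/HU trajectories,
  partial-volume blur and reconstruction noise;
* the **segmentation pipeline** of the sequential-scan method: a rough
  observer trace is turned into hard foreground/background seed regions by
  physical-radius morphology (`pmctseq.seeds`), optionally propagated across
  acquisitions with a cubic B-spline free-form deformation
  (`pmctseq.register`), per-acquisition Gaussian-mixture intensity models are
  fitted by EM (`pmctseq.appearance`), and the ventricles are extracted as
  the global minimizer of the seeded graph-cut energy

      E(L) = Σ_p D_p(L_p) + λ Σ_{(p,q)∈N} w_pq [L_p ≠ L_q],

  with data terms `D_p` the per-class negative log-likelihoods and
  contrast-sensitive neighbor weights
  `w_pq = exp(−(I_p−I_q)²/2σ²)/dist(p,q)`, solved exactly by max-flow/min-cut
  (`pmctseq.graphcut`);
* **quantification** per time point — volume by voxel counting, mean HU over
  the labeled voxels, with quality-control flags for collapsed ventricles
  (`pmctseq.measure`);
* **PMI models** — per-case ordinary least squares fits `y = a·t + b` of
  volume and attenuation against hours post-mortem, inverted (alone or
  inverse-variance combined) into PMI estimates with first-order confidence
  intervals (`pmctseq.pmi`).

## Worked example

Simulate a case whose ventricles shrink at 0.27 ml/h from 27.08 ml while the
CSF rises at 0.23 HU/h from 11.12 HU, scanned every 3 h from 2 to 20 h
post-mortem, then segment, measure and fit:

```python
from pmctseq import (PhantomSpec, make_phantom_series, make_rough_delineation,
                     seeds_from_rough, segment_series, fit_linear)

spec = PhantomSpec(grid_shape=(96, 96, 96), v0_ml=27.08, vol_rate_ml_per_h=-0.27,
                   hu0_csf=11.12, hu_rate_per_h=0.23,
                   schedule_h=tuple(float(t) for t in range(2, 21, 3)), rng_seed=42)
series = make_phantom_series(spec)
rough = make_rough_delineation(series[0][1], 1.0, 42, spec.spacing_mm)
seeds = seeds_from_rough(rough, 2.0, 4.0, 8.0, spec.spacing_mm)
results = segment_series([v for v, _ in series], seeds)
measurements = [r.measurement for r in results]
```

This prints (per time point, then the fitted trends):

```
t=  2.0 h  volume= 26.54 ml  mean HU=12.05  qc=ok
t=  5.0 h  volume= 25.73 ml  mean HU=12.73  qc=ok
t=  8.0 h  volume= 24.95 ml  mean HU=13.43  qc=ok
t= 11.0 h  volume= 24.16 ml  mean HU=14.14  qc=ok
t= 14.0 h  volume= 23.38 ml  mean HU=14.84  qc=ok
t= 17.0 h  volume= 22.64 ml  mean HU=15.60  qc=ok
t= 20.0 h  volume= 21.98 ml  mean HU=16.38  qc=ok
volume: y = -0.255 t + 27.00  (slope SE 0.003, R2 0.999)
hu:     y = +0.240 t + 11.53  (slope SE 0.003, R2 0.999)
PMI from HU 13.92: 10.0 h  [95% CI 9.8-10.2 h]
```

The measured volumes track the generated linear trend within a few percent
(the small slope differences come from partial-volume blur and noise); each
measurement is the voxel count times the physical voxel volume, and the mean
HU is averaged over the labeled voxels. Inverting the fitted HU trend at a
measured attenuation returns the estimated hours post-mortem.

The same workflow is available from the shell via the `pmctseq` command
(`make-phantom`, `make-seeds`, `propagate-seeds`, `fit-appearance`,
`segment`, `measure`, `fit`, `estimate-pmi`); volumes and masks are NIfTI,
measurement tables CSV, models JSON.

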