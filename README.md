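# epidose

**EPID transit dosimetry: quadratic thickness calibration and the effect of
respiratory motion on portal-dose images.**

During radiotherapy delivery, the electronic portal imaging device (EPID)
mounted behind the patient records the exiting beam. Calibrated well, that
image becomes an *in vivo* dosimeter: it reveals delivery errors, anatomy
changes and — the focus of this package — intra-fraction respiratory motion.
`epidose` implements the full analysis chain for the *quadratic thickness
calibration* method on a synthetic phantom/EPID/motion simulator, so every
stage is reproducible end-to-end without measured data:

1. **Calibration** — from flood images of uniform water-equivalent slabs
   (t = 0, 2, 4, 7, 11, 16, 21 cm), fit per pixel

   I(x, y) = I₀(x, y) · exp(−α(x, y)·t − β(x, y)·t²)

   by linear least squares in the log domain after dark-current subtraction
   I = I_raw − I_dark. The quadratic term absorbs beam hardening and
   spectral variation.
2. **Reconstruction** — invert the model for the equivalent Plastic-Water
   thickness t_PW(x, y) = [−α + √(α² − 4β·ln(I/I₀))]/(2β), inside an
   iterative loop correcting for the open-field output factor F and the
   scatter-to-primary ratio SPR = k₀·A·t (k₀ = 1.93×10⁻⁵ /cm³, A the field
   area), which converges within five iterations.
3. **Segmentation** — threshold field mask, Moore/Freeman chain-code field
   edge, polygon "breast" region of interest filled by an even-odd scanline.
4. **Analysis** — convert thickness maps back to intensity
   (α = 0.05 /cm, β = 10⁻⁴ /cm²), then compare moving deliveries against the
   static reference with per-pixel local dose differences (5/3/2/1%
   thresholds) and a **local-dose 2D gamma analysis** at 5%/5 mm … 1%/1 mm.
5. **Simulation** — an analytic breast-on-chest-wall phantom, sinusoidal
   (0.5/1.0/1.5 cm at 12–20 cycles/min) and irregular patient-like breathing
   traces, and a 60-frame (430 ms) frame-integrating acquisition model with
   per-frame noise.

The calibration/reconstruction core follows the scikit-learn estimator
protocol (`QuadraticCalibrator.fit`, `ThicknessReconstructor.transform`),
with plain functions (`fit_quadratic`, `reconstruct`, `gamma_2d`, …) as thin
wrappers.

## Worked example

```python
import numpy as np
from epidose import (QuadraticCalibrator, dark_correct, reconstruct,
                     thickness_to_intensity, gamma_2d, roi_from_outline_cm)
from epidose import simulate as sim

spec    = sim.AcquisitionSpec(seed=0)            # 256x256, 60 frames, 0.5% noise
forward = sim.ForwardModel()                     # alpha=0.05, beta=1e-4, k0=1.93e-5
series  = sim.make_calibration_series(calib=forward, spec=spec)
cal     = QuadraticCalibrator.from_series(series)

phantom = sim.make_breast_phantom(16.0)          # 16 cm peak separation
beam    = sim.treatment_beam()                   # 14 x 8 cm wedged field
static  = sim.make_static_trace(60.0)
moving  = sim.make_sinusoid_trace(1.0, 12.0, duration=60.0)

open_tx = dark_correct(sim.acquire(None, beam, static, forward, spec), series.dark)
img_s   = dark_correct(sim.acquire(phantom, beam, static, forward, spec), series.dark)
img_m   = dark_correct(sim.acquire(phantom, beam, moving, forward, spec), series.dark)

t_s = reconstruct(img_s, cal, open_treat=open_tx, area_treat=beam.field_area)
t_m = reconstruct(img_m, cal, open_treat=open_tx, area_treat=beam.field_area)
print(f"converged in {t_s.iterations_run} iterations")

roi = roi_from_outline_cm(phantom.breast_outline, spec.pixel_pitch, t_s.shape)
gm  = gamma_2d(thickness_to_intensity(t_m), thickness_to_intensity(t_s),
               roi.filled_mask & t_s.valid_mask, 2.0, 2.0)
print(f"2%/2mm pass rate: {gm.pass_rate:.1f}% over {gm.n_roi} ROI pixels")
```

Output:

```
converged in 5 iterations
2%/2mm pass rate: 99.1% over 5648 ROI pixels
```

A 1.0 cm sinusoid leaves ~99% of the breast ROI within 2%/2 mm; at 1.5 cm
this drops to ~74%, while changing only the breathing *frequency* moves the
pass rate by well under 1% — the method is amplitude-sensitive and
frequency-insensitive, as expected when many motion cycles fit in one
delivery and no interplay with a static aperture is possible.

The same study runs from the shell with the packaged demo configuration
(sinusoid grid + two patient-like traces):

```bash
epidose run-all --out demo_run          # ~20 s; prints the gamma pass-rate table
epidose simulate --out sim_out --seed 1 # or stage-by-stage:
epidose calibrate --series sim_out/calibration_series --out cal_out
epidose reconstruct --image sim_out/images/static.tiff \
    --dark sim_out/calibration_series/dark.tiff --calib cal_out \
    --open-treat sim_out/images/open_treat.tiff --field-area 112 --out rec_out
```

## Layout

- `src/epidose/simulate.py` — phantom, beams, motion traces, acquisition
- `src/epidose/calibration.py` — dark correction, per-pixel quadratic fit
- `src/epidose/reconstruction.py` — inversion + iterative scatter correction
- `src/epidose/segmentation.py` — field mask, chain code, polygon ROI
- `src/epidose/analysis.py` — dose differences, local 2D gamma, experiments
- `src/epidose/{io,config,cli}.py` — TIFF/CSV IO, validated configs, CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
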