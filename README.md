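# aquamap

Single-scan quantitative brain water-content mapping from long-TR (10 s)
multi-echo gradient-echo data, with a synthetic phantom generator that makes
every processing stage verifiable without scanner data.

The pipeline converts a 4D magnitude + phase echo series into a calibrated
percent-water map in four stages:

1. **Decay fit** (`aquamap.decay`) — voxel-wise extrapolation to TE = 0 with a
   log-domain mono-exponential fit; background field gradients are estimated
   from the multi-echo phase, echoes are selected per voxel by the 0.8·π
   through-slice dephasing rule and the through-slice sinc modulation is
   divided out.
2. **Bias removal** (`aquamap.bias`) — the combined transmit/receive
   inhomogeneity is modeled as the exponential of a low-order cosine (DCT)
   expansion and estimated jointly with an intensity-only Gaussian-mixture
   segmentation (EM + Gauss–Newton, gauge-fixed to unit geometric mean).
3. **Calibration** (`aquamap.calibration`) — the mode of the high-confidence
   CSF intensity distribution is the internal 100%-water standard; CSF's
   residual T1 saturation is handled by a steady-state factor (0.93 for TR
   10 s, T1 4.3 s, effective flip 72°).
4. **Statistics** (`aquamap.stats`) — per-tissue histograms with Gaussian-fit
   centers/FWHM, test-retest voxel variability, two-sample distribution tests
   and the `mean(WM) + 1.5·SD(WM)` oedema threshold rule.

Supporting modules: `aquamap.acquisition` (spoiled-GRE steady-state physics
and protocol optimisation), `aquamap.phantom` (brain-like and ten-tube
"revolver" phantoms with full ground truth, Rician noise, smooth bias fields,
B0 gradient hotspots), `aquamap.io` (NIfTI + JSON sidecar I/O) and
`aquamap.pipeline` (stage composition).

## Command line

```sh
# synthesize a brain phantom with noise, smooth receive field and jitter
aquamap simulate --kind brain --out data/ --seed 1 --snr 97 \
    --jitter-sd 1.2 --bias-amplitude 0.15

# full pipeline: decay fit -> bias removal -> CSF calibration -> statistics
aquamap map --mag data/echo_mag.nii --phase data/echo_phase.nii \
    --sidecar data/echo_acq.json --out out/

# individual stages
aquamap fit --mag ... --phase ... --sidecar ... --out out/
aquamap debias --s0 out/s0.nii --out out/
aquamap calibrate --s0-corrected out/s0_corrected.nii \
    --csf-prob out/csf_prob.nii --sidecar data/echo_acq.json --out out/
aquamap stats --water out/water.nii --water out2/water.nii --out retest/

# protocol optimisation report (saturation levels, max flip angles,
# SNR per unit time, CSF steady-state factor)
aquamap protocol --t1 2.0 --level 0.007
```

Exit codes: 0 success, 1 usage error, 2 stage failure. Each command writes a
resolved-config JSON snapshot next to its outputs.

## Notes

- Echo times are millimetre/millisecond/degree at every interface; physics
  internals convert to SI. The unnormalized sinc (sin x / x, radians) is used
  throughout.
- No image registration is performed anywhere: retest analysis requires
  pre-aligned grids.
- The phantom simulator is seeded everywhere; identical seeds give
  bit-identical volumes.
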