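# respsort

Retrospective **respiratory sorting and left-ventricular quantification for
free-breathing, non-ECG-gated real-time cine CMR**.

Real-time (RT) cine acquisitions run continuously at a fixed frame rate:
frames are not sorted by cardiac phase, and free breathing translates the
heart through the imaging plane. Quantifying LV volumes from such data
requires picking, per slice, the end-diastolic (ED) and end-systolic (ES)
frames that *coincide with a fixed respiratory state* (end expiration or end
inspiration). `respsort` automates that selection and the downstream
volumetry:

1. **Respiratory curve.** From a user-placed ROI over the diaphragm, each
   frame becomes a flattened sub-image `x_i` (a 40 × 40 ROI on 128 × 128
   frames gives 1600-dimensional vectors). A weighted neighbourhood graph is
   built over the frames with Gaussian-kernel weights
   `W(i,j) = exp(−‖x_i − x_j‖² / 2σ²)`, and the one-dimensional Laplacian
   Eigenmaps embedding `y` minimizes `φ(y) = Σ_ij (y_i − y_j)² W(i,j)`
   subject to `yᵀDy = 1`, `yᵀD1 = 0` — the generalized eigenvector of
   `L y = λ D y` (L = D − W) for the smallest nonzero eigenvalue. The curve
   is oriented so local maxima are end expiration (diaphragm most cranial).
2. **Sorting.** Extrema are detected on the smoothed curve; frame windows
   open around each extreme (rest: ±15 expiration / ±10 inspiration;
   exercise: ±8 / ±5). Within the windows, the frames of maximum (ED) and
   minimum (ES) lumen blood volume are selected from a bright-blood Otsu
   proxy, and respiratory-matched short-axis stacks are assembled with QC
   flags (duplicate slices by normalized cross-correlation, incomplete
   slices, LV-length mismatch against the 4-chamber view).
3. **Quantification.** Summation of discs over endo/epicardial masks:
   EDV, ESV, SV = EDV − ESV, EF = SV/EDV, LVM = myocardial volume ×
   1.05 g/cm³ (plus LVMI, per-slice heart rate, and phase-contrast stroke
   volume as the net flow between first and last diastole per beat).
4. **Agreement statistics.** Bland–Altman (bias ± 1.96 SD limits of
   agreement), single-measure two-way mixed ICC with 95% CI, and
   within-subject coefficient of variation.

A fully synthetic **cine phantom** (translating diaphragm with a prolonged
end-expiratory plateau, contracting LV disc in a myocardial ring,
respiratory through-plane content change, Gaussian noise) provides exact
per-frame ground truth, so every stage of the pipeline is validated against
closed-form answers.

## Worked example

```python
import respsort as rs

# 8-slice phantom stack, 500 frames/slice, respiratory period 90 frames,
# 20 dB SNR; truth holds analytic volumes
stack, truth = rs.generate_cine_stack(n_slices=8, n_frames=500,
                                      noise_sd=rs.noise_sd_from_snr(20.0), seed=1)

resp_roi = rs.RespROI(72, 112, 12, 52)   # diaphragm
lv_roi = rs.RespROI(14, 72, 36, 92)      # blood pool

sorted_stack, diags = rs.sort_stack(stack, resp_roi, lv_roi,
                                    mode="rest", states=(rs.EXPIRATION,))
selections = [s for d in diags for s in d.selections]
masks = rs.masks_from_truth(truth.slices, selections)  # stands in for contours
result = rs.quantify_states(sorted_stack, masks)[rs.EXPIRATION]

print(f"EDV {result.edv_ml:.1f} ml (truth {truth.edv_ml:.1f})")
print(f"ESV {result.esv_ml:.1f} ml (truth {truth.esv_ml:.1f})")
print(f"SV {result.sv_ml:.1f} ml, EF {100 * result.ef:.1f}%")
print(f"LVM {result.lvm_g:.1f} g (truth {truth.lvm_g:.1f})")
```

prints

```
EDV 116.3 ml (truth 116.7)
ESV 40.3 ml (truth 40.4)
SV 76.0 ml, EF 65.3%
LVM 65.0 g (truth 64.5)
```

i.e. the pipeline recovers the analytic phantom volumes to well within 1%,
with SV + ESV = EDV holding exactly. The same chain is available from the
shell:

```bash
respsort phantom --out stack/ --seed 1
respsort embed stack/ --roi 72:112,12:52 --out curve.csv
respsort sort stack/ --roi 72:112,12:52 --lv-roi 14:72,36:92 --out sorted/
respsort quantify --stack sorted/ --masks masks/ --bsa 1.9 --out results.json
respsort agree --a a.csv --b b.csv --out agree.json
```

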