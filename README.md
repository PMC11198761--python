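# slipscan

Quantifying tumor–brain adhesion from MR elastography (MRE) with
slip-interface imaging.

Whether a meningioma is adherent to the surrounding brain strongly
affects how hard it is to resect, yet adhesion is usually only known at
surgery. Under the gentle 60 Hz vibration of a brain MRE exam, a
non-adherent tumor slides relative to the parenchyma, concentrating
shear strain in a thin layer at the interface; an adherent tumor moves
with the brain and shows no such concentration. `slipscan` turns
multi-offset, multi-direction MRE phase data into maps of this effect
and into a single per-tumor adhesion percentage:

1. **Displacement** — each axis is encoded with paired gradient
   polarities, so `u_d(t) = (φ₊d(t) − φ₋d(t)) / 2s` for the 8 phase
   offsets `t` over one vibration period.
2. **OSS** — the octahedral shear strain
   `OSS = (2/3)·√[(ε_xx−ε_yy)² + (ε_yy−ε_zz)² + (ε_zz−ε_xx)² + 6(ε_xy²+ε_xz²+ε_yz²)]`
   is computed per offset and averaged over the 8 offsets.
3. **NOSS** — the mean OSS is divided by the combined first-harmonic
   motion amplitude `A = √(A_x²+A_y²+A_z²)` (DFT bin 1 of the 8-sample
   series per component), making the map independent of how strongly
   the head was shaken.
4. **SIR (slip interface recognition)** — per axial slice, a
   rectangular partial (RP) NOSS image around the tumor ROI is
   standardized to max 1, the ROI boundary is traced, and every
   boundary point is classified non-adherent if any of three conditions
   on the point intensity `I(a)` and its adaptive 3×3/5×5 neighborhood
   patch holds: a distinct bright/dark rim (I), a traceable intensity
   step `|I(a) − patch mean| > τ` with `τ = 0.20 × patch range` (II),
   or large local variation `patch range > 0.80 × I(a)` at a faint
   point (III). The tumor's **non-adhesion percentage** is the pooled
   fraction of non-adherent boundary points over all slices.

Because no patient data accompany the method, the package ships a
synthetic shear-wave phantom (`slipscan.phantom`) — a spherical
inclusion whose surface slips over a controllable spherical-cap
fraction, with full displacement and label ground truth — plus the
evaluation statistics used to benchmark adhesion metrics (Cohen's κ
with CI, Mann–Whitney AUC, DeLong's paired ROC test, ICC(2,1)) and a
reconstruction of the earlier boundary-entropy adhesion metric for
comparison.

## Worked example

```python
from slipscan import (PhantomSpec, generate_phantom, compute_noss,
                      run_sir, run_entropy)

spec = PhantomSpec(slip_fraction=0.5, seed=7)   # half the surface slips
ds = generate_phantom(spec)
print(f"realized slip fraction: {ds.true_slip_fraction:.3f}")

noss = compute_noss(ds.phase, brain_mask=ds.brain_mask)["noss"]
result, labels, overlay = run_sir(noss, ds.tumor_mask)
print(f"boundary points analyzed: {result.n_points}")
print(f"non-adhesion: {result.non_adhesion_pct:.2f}%   adhesion: {result.adhesion_pct:.2f}%")
print(f"condition counts: {result.condition_counts}")
print(f"boundary entropy: {run_entropy(noss, ds.tumor_mask):.3f} bits")
```

```
realized slip fraction: 0.500
boundary points analyzed: 216
non-adhesion: 87.96%   adhesion: 12.04%
condition counts: {'I': 42, 'II': 76, 'III': 72}
boundary entropy: 3.738 bits
```

The phantom's cap covers half the tumor surface; the measured
non-adhesion percentage sits between the fully adherent (~70%) and
fully slipping (~97%) operating points of the classifier — SIR is a
deliberately sensitive detector, so even an adherent interface in a
smoothly varying NOSS background yields a substantial baseline, and
the *relative* percentage carries the adhesion information. `overlay`
is a label volume (0 = non-boundary, 1 = adherent, 2 = non-adherent)
ready to write as NIfTI for visual inspection.

The same chain is available from the shell:

```sh
slipscan phantom spec.yaml out/phantom
slipscan noss out/phantom out/maps --brain-mask out/phantom/brain_mask.nii.gz
slipscan sir out/maps/noss.nii.gz out/phantom/tumor_mask.nii.gz out/sir
slipscan eval kappa table.csv
```

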