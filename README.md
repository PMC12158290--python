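# pearspec

Estimation of relative leaf chlorophyll content (the **SPAD** value, a
dimensionless index from a transmittance-based leaf meter such as the
SPAD-502) from field reflectance spectra of fruit-tree canopy leaves, for
researchers in hyperspectral plant phenotyping and chemometrics.

Field spectra of orchard leaves — especially in dusty, arid growing regions —
carry strong high-frequency noise. `pearspec` implements a full comparison
pipeline for this setting:

1. **Smoothing** — a running median over the 1 nm band grid (default window
   5 bands), which removes isolated dust spikes without flattening the red
   edge.
2. **Transforms** — twelve representations of each spectrum *R(λ)*: the raw
   spectrum *R*, 1/*R*, log₁₀*R*, their central-difference first derivatives
   *R*′, (1/*R*)′, (log *R*)′, and a three-level discrete wavelet transform
   with the orthonormal Haar basis giving low-frequency approximation series
   **L1–L3** and high-frequency detail series **H1–H3**
   (a_i = (x_{2i}+x_{2i+1})/√2, d_i = (x_{2i}−x_{2i+1})/√2; resolution halves
   per level; Parseval's identity holds exactly).
3. **Band selection** — Pearson correlation of every band of every
   representation against SPAD, then greedy selection of k = 2 "sensitive
   bands" maximising |r| under a 50 nm minimum-separation constraint.
4. **Modeling** — either the classical two-band affine model
   *y = b₀ + b₁·x_{λ₁} + b₂·x_{λ₂}* by ordinary least squares, or partial
   least squares (PLS1, NIPALS) with the component count chosen by
   leave-one-out RMSE on the modeling split.
5. **Evaluation** — samples are split 60/27 into modeling and validation
   groups; models are compared by
   *R*² = 1 − Σ(CHLᵢ − CHLPᵢ)² / Σ(CHLᵢ − C̄HL)² and
   RMSE = √(Σ(CHLᵢ − CHLPᵢ)²/n), with the winner taken by highest
   validation *R*².

Because no field campaign of this kind is publicly deposited, the package
ships a first-class synthetic-spectra generator (`pearspec.synthetic`) that
emulates the study conditions: 87 leaves in four canopy directions
(22/22/22/21), SPAD ~ N(45.8, 3.64²) truncated to [32.6, 67.1] with ±1 SPAD
meter error, chlorophyll absorption wells at 450 and 670 nm whose depth is
linear in SPAD, a logistic red edge near 715 nm, a smooth noise continuum,
and per-band independent dust noise. See `docs/methods.md` for the model
and its limits.

## Worked example

```bash
pearspec run --simulate --seed 1 --output-dir demo_run
```

generates the 87-sample synthetic dataset and prints the twelve-row
comparison (abridged):

```
transform  band_1_nm  band_2_nm  r2_train  rmse_train  r2_valid  rmse_valid
        R    468.000    667.000     0.890       1.107     0.689       1.688
     logR    468.000    667.000     0.887       1.119     0.688       1.690
       L1    468.500    676.500     0.890       1.105     0.713       1.622
       H1    920.500    700.500     0.245       2.898    -0.220       3.342
       ...
winner: L1 (validation R^2 = 0.713, RMSE = 1.622)
```

Reading the output: each row is one spectral representation; the two band
columns are the selected sensitive wavelengths (for wavelet series these are
support-midpoint wavelengths, hence the .5 values at level 1); the metrics
are *R*²/RMSE on the 60-sample modeling group and the 27-sample validation
group. On dusty synthetic data the selected bands sit at the flanks of the
planted 450/670 nm chlorophyll wells, the low-frequency representations
(R, logR, L1–L3) validate near *R*² ≈ 0.7, and the detail-scale models
(H1–H3) collapse — the dust noise is decomposed almost entirely into the
high-frequency coefficients.

The same stages are available individually (`pearspec simulate|smooth|
transform|dwt|correlate|select|fit|evaluate|report`), and everything is
importable as a library:

```python
import pearspec as ps

ds = ps.generate_dataset(ps.SyntheticConfig(seed=1))
result = ps.run_pipeline(ds, ps.PipelineConfig(seed=1))
print(result.winner, result.evaluations[result.winner].r2_valid)
```

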