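# gatedose

Dose–volume histogram (DVH) analytics, relative-seriality NTCP modelling
and paired cohort comparison for breathing-adapted breast radiotherapy
planning studies.

## The problem

In left-sided breast cancer radiotherapy, part of the heart — and in
particular the left anterior descending (LAD) coronary artery — sits close
to the tangential treatment fields. Breathing-adapted techniques such as
enhanced inspiration gating (EIG) irradiate only during deep inspiration,
when the heart moves away from the chest wall, reducing cardiac dose
without compromising target coverage. Planning studies quantify this by
creating, per patient, a free-breathing (FB) plan and a gated (EIG) plan
on two CT scans of the same anatomy, then comparing organ-at-risk dose
metrics and modelled complication probabilities across the paired cohort.

`gatedose` implements that analysis chain for physicists and dosimetrists:

- **DVH core** (`gatedose.dvh`): differential/cumulative DVH containers on
  a 0.05 Gy grid with conversions, `D_mean`, `D_2%`, `V_xGy`, `V_x%`
  metrics and a plain-text CSV dialect.
- **NTCP models** (`gatedose.ntcp`): the relative seriality model with a
  Poisson dose–response,

  ```
  NTCP = { 1 − ∏ᵢ [1 − P(Dᵢ)ˢ]^ΔVᵢ }^(1/s),
  P(D) = 2^(−exp(e·γ·(1 − D/D₅₀)))
  ```

  over the bins of a normalized differential DVH, with a registry of
  published parameter sets for excess cardiac mortality
  (s = 1, γ = 1.28, D₅₀ = 52.3 Gy) and radiation pneumonitis
  (s = 0.012; γ = 0.974, D₅₀ = 27.52 Gy tangential; γ = 0.966,
  D₅₀ = 29.23 Gy locoregional).
- **Beam geometry** (`gatedose.geometry`): the maximum heart distance
  (MHD) — the maximal beam's-eye-view penetration of the heart contour
  past the posterior field edge of a tangential beam.
- **Cohort analysis** (`gatedose.cohort`): per-patient metric extraction,
  two-sided paired/unpaired Wilcoxon tests (exact enumeration for small
  tie-free samples, corrected normal approximation otherwise) and
  median [range] comparison tables at α = 0.01.
- **Synthetic cohorts** (`gatedose.simulate`): a seeded generator of
  paired FB/EIG DVH cohorts and beam's-eye-view scenes whose medians
  emulate a 16-patient tangential or locoregional breast cohort, so the
  whole pipeline is testable without patient data.

## Worked example

Simulate a 16-patient tangential cohort and compare the techniques:

```sh
$ gatedose simulate --out demo --seed 1 --n 16
wrote 192 files + manifest to demo (seed=1, n=16, tangential)

$ gatedose compare --in demo
tangential treatment (n per test varies; alpha=0.01)
metric                                          FB                   EIG         p
...
D_mean,heart (Gy)                    2.5 [1.9-3.4]         1.6 [1.6-1.7]    <0.001*
V_25Gy,heart (%)                     2.3 [0.8-4.2]         0.2 [0.1-0.4]    <0.001*
MHD (cm)                             1.3 [0.7-2.6]         0.5 [0.0-1.7]    <0.001*
V_25Gy,LAD (%)                     46.6 [9.1-95.0]        3.7 [0.8-35.5]    <0.001*
V_20Gy,lung (%)                     7.7 [5.0-20.1]       10.7 [4.5-16.8]     0.706
NTCP cardiac mortality (%)        0.86 [0.32-1.58]      0.09 [0.04-0.16]    <0.001*
```

Each row is one metric's cohort median with the range in brackets, per
technique, and the two-sided paired Wilcoxon p-value (`*` marks
significance at α = 0.01). Gating cuts the heart volume receiving more
than 25 Gy roughly tenfold and the modelled excess cardiac mortality
probability with it, while lung dose under tangential fields is
unchanged — the qualitative pattern such planning studies report.

Single-structure queries work on DVH or scene files directly:

```sh
$ gatedose ntcp demo/P01_heart_FB.csv --endpoint cardiac_mortality
cardiac_mortality (any): s=1.0, gamma=1.28, D50=52.3 Gy
NTCP = 0.87%

$ gatedose mhd demo/P01_scene_FB.csv
MHD = 1.7 cm
```

The same operations are available as library functions
(`relative_seriality_ntcp`, `max_heart_distance`, `build_cohort_report`,
…); see the module docstrings.

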