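# Methods

## DVH conventions

A differential DVH is stored as volume fractions ΔVᵢ on a uniform dose
grid identified by bin centers; the default bin width is 0.05 Gy, the
resolution typical of treatment-planning-system exports, but any positive
width is accepted. Cumulative values sit on the left bin edges, which
makes the differential↔cumulative round trip exact on a shared grid
(tested to 1e−9 per bin). All metrics operate on normalized fractions
(ΣΔVᵢ = 1 to 1e−6 internally; files whose mass deviates by up to 1e−3 are
renormalized on read, with a warning above 1e−4 — smaller deviations are
expected 6-decimal serialization rounding); absolute structure volume in
cm³ is carried as metadata and reported as its own metric.

`V_xGy` and `D_x%` interpolate linearly between grid points. Planning
systems differ on this; `dose_at_volume` therefore also offers
`method="nearest"`. "Volume receiving more than x Gy" is evaluated as the
interpolated cumulative value at x; on continuous DVHs the distinction
between > and ≥ has measure zero. `cumulative_to_differential` reuses the
input grid when it already is a uniform grid of the requested width
(making the round trip exact) and otherwise resamples from a
bin-width-aligned origin; trailing empty bins are dropped.

## Relative seriality NTCP

The Poisson dose–response `P(D) = 2^(−exp(e·γ·(1 − D/D₅₀)))` uses Euler's
number for `e` — the standard convention of the γ-parameterized Poisson
model, stated explicitly because the symbol is occasionally misread as a
free parameter. The organ response combines bins as
`NTCP = (1 − ∏ᵢ[1 − P(Dᵢ)ˢ]^ΔVᵢ)^(1/s)` with seriality s ∈ (0, 1].

Numerics: for a parallel organ (s ≈ 0.01) each factor `1 − Pˢ` is tiny
once P is moderate, so the product is accumulated as
`Σ ΔVᵢ·log1p(−exp(s·log Pᵢ))` and exponentiated once, with P clamped to
[1e−300, 1 − 1e−15]. If any bin with nonzero volume reaches the upper
clamp, NTCP is returned as exactly 1 with a warning. Uniform irradiation
at D₅₀ yields 0.5 to better than 1e−9 for every s in (0, 1]; at s = 1 the
log-space path agrees with the naive product to 1e−12.

Registered endpoints: excess cardiac mortality for the whole heart
(s = 1, γ = 1.28, D₅₀ = 52.3 Gy, both plan types) and radiation
pneumonitis for the ipsilateral lung with technique-specific fits
(s = 0.012, γ = 0.974, D₅₀ = 27.52 Gy tangential; γ = 0.966,
D₅₀ = 29.23 Gy locoregional) re-derived for a type-b photon algorithm.
No LAD endpoint parameters exist in the published literature this
registry draws on, so the LAD receives dose metrics only. No
fractionation (LQ/EQD2) correction is applied: the parameters are used at
the 2 Gy/fraction reference of the 50 Gy / 25 fraction prescription. The
cardiac output is the model's raw probability, reported under the label
"excess cardiac mortality" as the source parameter fit defines it; no
baseline subtraction is performed. Reports round NTCP to two decimals of
percent; full precision is kept in machine-readable output.

## Maximum heart distance

The aperture is abstracted to a straight posterior edge (point + unit
in-field normal) with an optional axis-aligned lateral bounding rectangle;
jagged per-leaf MLC edges are out of scope. The heart polygon is clipped
to the in-field half-plane (shapely), and since the perpendicular depth is
linear in position, its maximum over the clipped region is attained at a
vertex of the clipped polygon — no sampling is needed. Vertices exactly on
the edge count as 0; a heart wholly out of field gives MHD = 0. The
statistic is invariant under rigid motions of the whole scene (tested to
1e−9) and reported to one decimal of cm. The operation takes one scene;
when a plan has several fields the caller maximizes over scenes.

## Cohort statistics

Paired FB/EIG comparisons use the two-sided Wilcoxon signed-rank test
with zero differences dropped. With m ≤ 20 tie-free nonzero differences
the exact null distribution (equivalent to enumerating all 2^m sign
patterns) is used; otherwise the normal approximation with continuity and
tie correction. The exact route is what makes the headline claim checkable:
16 concordant pairs give exactly p = 2/2¹⁶ ≈ 3.05e−5. At n = 16 the
corrected approximation tracks the exact p to within ~0.011 (worst case
near mid-range p); the discrete exact test's true level at nominal
α = 0.01 is 0.0092. Stratum-vs-stratum comparisons use the rank-sum test
with the same exact/approximate switch. Significance is α = 0.01 per
test with no multiple-testing correction; tangential and locoregional
cohorts are analyzed separately, and a report refuses mixed strata.
Patients missing a structure under one technique are dropped from that
metric's paired test (logged); fewer than 5 complete pairs yields a
median [range] row with p = NaN rather than an unstable test.

## Synthetic cohort generator

The generator emulates DVH *shapes*, not 3-D dose. Organ-at-risk
cumulative DVHs are a two-component mixture
`V(D) = (1 − f_hi)·exp(−D/λ) + f_hi·logistic((D_hi − D)/w)`: an
exponential low-dose scatter tail plus a shoulder of in-field volume near
the field-edge dose D_hi ≈ 43–45 Gy. The in-field fraction f_hi is
log-normal per patient; gating multiplies it by an effect multiplier
(0.10 for heart and LAD; 1.0 for lung under tangential fields, where
inspiration does not change the relative irradiated lung volume much, and
0.8 under locoregional fields). Targets get a Gaussian cumulative
fall-off around the prescription, shifted so the mean dose is exactly
50 Gy (emulating normalization to the target mean).

Calibration constants were set once by moment matching against the
medians a 16-patient clinical stratum reports: f_hi medians from V_25Gy
(heart 2.2% tangential / 3.3% locoregional; LAD 40% / 51%; lung V_20Gy
9.1% / 27%), λ from `D_mean ≈ (1 − f)·λ + f·D_hi`, structure volumes and
breathing amplitudes (median 7.0 mm, log-normal) from the corresponding
published ranges, MHD depths (FB median 1.3 / 1.7 cm; gating shift
bringing medians to ≈ 0.4 / 0.6 cm with a point mass at 0 when the heart
leaves the field). These are stochastic targets with generous (±50%)
tolerance at n = 16, not exact claims, and all are overridable via
`CohortConfig`.

Pairing: each patient draws shared anatomy latents (f_hi location,
shoulder position, volume factor), and each technique adds small
independent log-normal noise (`pair_sigma`, default 0.25; `pair_sigma`
→ 0 gives perfectly correlated plans). With effect multipliers at 1 the
two techniques are exchangeable, so the paired test is calibrated at its
nominal level — verified over 2000 simulated null cohorts. With a
multiplier < 1 the gated f_hi is additionally capped at the FB value, so
the gated cumulative DVH sits at or below the FB one at every dose
≥ 10 Gy by construction.

What the generator does *not* reproduce: spatial dose anatomy (it is a
DVH-shape model); the clinical dissociation between lung D_mean and
V_20Gy significance in locoregional cohorts; and the cardiac D_2% median
— because f_hi is unimodal around 2%, the hottest-2% dose is bimodal
(either in the tail or on the shoulder), giving a higher median D_2% and
median cardiac NTCP (~0.9% vs ~0.5% FB tangential) than a real cohort
whose partial-shoulder patients fill the middle. Passing calibration
tests therefore shows the pipeline reproduces the *ordering and
separation* of the techniques under realistic DVH shapes, not that the
generator is a dose engine.

Determinism: one `numpy` generator seeded from `CohortConfig.seed` is
threaded through all draws in a documented order (see
`simulate.draw_patient`); identical configs give bit-identical cohorts,
including the serialized CSVs.

## Problem sizes

Tests and the acceptance script use 16-patient cohorts on a 0.05 Gy grid
to 60 Gy (1200 bins), the scale of the clinical study the defaults
emulate; the null-calibration check simulates 2000 heart-only cohorts.
The whole suite runs in well under a minute on one core.

## Known limitations

- The MLC aperture is a straight edge + rectangle; per-leaf edges would
  need a polygonal aperture.
- No DICOM-RT interfaces; the CSV dialect is the only on-disk format.
- NTCP confidence intervals and parameter fitting are out of scope; the
  registry is a lookup of published fits plus user-registered entries.
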