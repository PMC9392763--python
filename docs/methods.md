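# Methods

This note records the models, parameter choices and numerical decisions
behind `actinospec`, in the spirit of a statistical methods appendix.

## Units and dosimetry

Time is in hours, band irradiance in W·m⁻², dose in J·m⁻²
(`dose = E × t_h × 3600`); conversions are centralised in
`actinospec.dosimetry`. Neutral-density attenuation is `T = 10^(−OD)`,
multiplicative for stacked filters; the exposure design uses OD 0, 0.2 and
0.4, so adjacent conditions differ by a factor 10^0.2 ≈ 1.585 ("1.6-fold").
Band irradiance integrates the 1-nm spectroradiometer grid trapezoidally
over the nominal 10-nm filter bandwidth. Irradiance is treated as constant
during exposure (a continuously running arc lamp); no lamp-drift model is
included.

## Control scaling

Viability is scaled affinely between the plate's own lysed (positive, → 0)
and dark (negative, → 100) control means; replicate control wells are
averaged arithmetically, the conventional plate-control estimator. Values
outside [0, 100] are retained — clipping would bias the downstream slope
fits. ECIS traces are scaled per time point between the mean no-cell and
mean dark control traces (nearest-sample alignment, maximum gap one 11-min
sampling interval), then divided by their time-zero value; that order is the
default and a `t0_first` switch reverses it for sensitivity analysis. The
scaled trace is invariant to any multiplicative drift shared by data and
controls.

## Viability response spectrum

Per wavelength, ordinary least squares of scaled viability on irradiance
pools all technical and biological replicate wells as points (no
pre-averaging). Slopes are squared — damage slopes are negative, and squared
efficiencies admit a logarithmic axis — and divided by the squared slope at
the 405-nm visible reference. Positive ("protective") slopes are excluded
from the normalised spectrum by default and reported in diagnostics: the
square of a positive slope would masquerade as toxicity on a log plot. The
default irradiance axis is absolute band irradiance; a relative axis
(fraction of full intensity) is available, and the normalised spectrum is
invariant to any global rescaling of the axis. Wavelengths observed at fewer
than two irradiance levels are excluded with a logged warning rather than
fitted.

## ECIS action spectrum

The common action is a 60% decrease of a scaled, t0-normalised electrical
parameter; the crossing time is linearly interpolated between the two
bracketing 11-min samples, and the *first* crossing counts even if the trace
later recovers (earliest-action is the conservative reading). Traces are
truncated at lamp-off (68 h) so the post-exposure re-adhesion rise cannot
create or hide crossings. Wells that never cross inside the window are
censored: they are excluded from the wavelength's mean efficiency and
counted in `n_censored`, rather than being assigned an efficiency bound.
Efficiency is the reciprocal dose per well, averaged over uncensored wells
per wavelength, then normalised — to 400 nm by default for ECIS spectra
(the action-spectrum figures' reference) while viability and imaging
spectra default to 405 nm (the methods' reference); both are configurable.
The analysis frequency defaults to 16 kHz, the conventional monolayer-
impedance band; any measured frequency is selectable. Capacitance is
handled on the scaled axis, where cell loss moves every parameter toward
the no-cell level, so the same 60%-decrease test applies.

With 11-min sampling, a crossing time is only resolvable when it spans at
least a few samples; first-crossing detection under noise is slightly
early-biased where the trace approaches the threshold shallowly (an
extreme-value effect of order noise ÷ local slope), which is visible as a
few-percent downward bias of normalised efficiencies at the slow reference
end. This is a property of the estimator, not of the implementation.

## HCI response spectra

Feature values are averaged per (wavelength, ND) condition (NaN-tolerant),
normalised to the dark-control mean per feature (zero-dark features are
dropped with a warning), and each feature regressed on irradiance with the
same OLS core as the viability stage. The HCI regressions use the relative
irradiance axis: the three ND conditions share it across wavelengths, so
coefficients are comparable between wavelengths regardless of the lamp's
spectral output. Group spectra average *squared* slopes over the selected
features — averaging before squaring would let opposite-signed feature
responses cancel — and the 'all' spectrum equals the feature-count-weighted
mean of the compartment spectra by construction. Z-scoring features before
aggregation is available but off by default.

## Consensus clustering with Monte-Carlo references

For each K in 2…8, 500 subsamples of 80% of the items are clustered with
k-means and the consensus matrix of co-clustering frequencies (among
co-sampled pairs) assembled; PAC is the fraction of upper-triangle entries
in (0.1, 0.9], the conventional window. The null reference is B = 100
simulated K = 1 datasets preserving the real data's principal-component
structure: each reference draws n iid items from a Gaussian with the data's
mean and eigen-decomposed covariance. The sampling is deliberately iid
rather than variance-constrained: genuine unstructured data shows chance
clumping, and a construction that pins each reference's sample variances
exactly suppresses it, making references systematically less clusterable
than true K = 1 data and the p-values anticonservative (we measured
exactly this failure mode with an exact-variance sampler: roughly half of
null-profile scans reported a spurious significant K, versus none with iid
sampling). References are simulated once per scan and shared across K,
which keeps the K-wise p-values positively correlated and controls the
family-wise rate of spurious significant K on truly unstructured data. The p-value is the add-one
permutation estimator `(1 + #{null PAC ≤ real PAC})/(B + 1)`; RCSI is
`mean(ln null PAC) − ln(real PAC)` with PACs floored at 1/n_pairs. The
selected K maximises RCSI among K with p < 0.05, falling back to K = 1.

The inner k-means runs *once* per subsample with k-means++ seeding, the
original consensus-clustering convention: algorithmic seeding randomness is
part of the stability being measured. With only a dozen items, a
best-of-many inner fit makes every subsample's partition deterministic, so
PAC saturates at exactly 0 for structured and unstructured data alike and
the empirical p-value loses its power; a single seeded run leaves truly
separated clusters at PAC 0 (k-means++ virtually always seeds one centre
per cluster) while smearing null partitions into the ambiguous window. The
reported final partition, a quality question rather than a stability one,
uses a best-of-10 fit on the full data. The k-means itself is a vectorised
Lloyd iteration batched over all subsamples (with exact PCA row-score
reduction when features outnumber items, which preserves all pairwise
distances); scikit-learn's KMeans serves as an independent cross-check in
the tests, never as the implementation.

Two caveats at very small item counts: a two-cluster geometry spans a
single direction, so its eigen-matched null is near-one-dimensional and
occasionally perfectly stable, making K = 2 detection noticeably harder at
n ≈ 12 than K = 3; and PAC's granularity (1/66 at 12 items) means p-values
cannot fall below 1/(B+1).

## Synthetic data: what it emulates, and what it does not

All truth is planted on the scaled/normalised scale and mapped back through
the inverse of the scaling operations, so recovery tests exercise the
scaling code path; every output is bit-reproducible from (preset, seed).

**Study conditions.** Thirteen 10-nm bands (290–400 nm plus the 405-nm
visible reference), three irradiance levels (full, ND 0.2, ND 0.4), three
biological replicates × four technical wells for viability, 4 wells per
wavelength for ECIS at 11-min sampling over 72 h with lamp-off at 68 h, and
2% Gaussian measurement noise (percentage points on the scaled viability
axis; relative, multiplicative on normalised ECIS traces and raw feature
values). The 39 viability conditions of one biological replicate exceed a
96-well plate, so each replicate spans two physical plates, each with its
own lysed and dark control wells.

**Planted profile.** The `paper-profile` preset encodes the study's
headline effect sizes: ECIS relative efficiencies of 10⁴ (290–310 nm), 10²
(320–350 nm), 10 (360 nm) and 1 (370–405 nm, reference 400 nm); viability
losses of 10% (350 nm) and 30% (380 nm) per ND step with the remaining UV-A
bands set so the mean full-irradiance UV-A loss is exactly 20% of control;
three latent imaging bands 290–320 / 330–360 / 370–400 nm; and an extra
'spot'-kernel response at 350 nm in the nucleus, mitochondria and ROS
compartments but not PI/CellMask. `null` plants no effects; `two-band`
plants a UV-B/UV-A split only.

**Synthetic lamp.** The lamp emits wavelength-dependent band irradiance
(0.05 W·m⁻² in UV-B rising to 10 W·m⁻² at the visible end), as a real
mercury-halide source does. This matters for recoverability: with the
reference crossing placed at 60 h, a wavelength-independent lamp would put
a 10⁴-fold-efficient band's crossing at ~22 s, far below the 11-min
sampling interval, where no interpolation could recover it. Spreading the
dose range across irradiance and time keeps every planted crossing
(~1.2 h to 60 h) on the measurable grid — exactly the role of per-band
output differences in a real exposure apparatus.

**ECIS templates.** UV-B-like wells decline monotonically; UV-A-like wells
are biphasic — a rapid early drop, a plateau ending near 45 h, then a late
linear decline — with the template constructed to cross 60% of t0 exactly
at the planted time (the early drop carries fast crossings, the late
decline slow ones). Slow-responding wells also get a first-day
media-change bump, and every trace a post-lamp-off recovery rise. The dark
control matures slowly upward and never crosses; exposed raw traces are
built against the same control trajectories used for scaling, so the
pipeline inverts the forward model exactly at zero noise.

**Imaging model.** 380 features split evenly over four probe compartments
with a documented kernel allocation (20 intensity, 15 each SER
spot/ridge/edge and STAR morphology, 10 other SER, 5 count per
compartment). Per-feature slopes on the dark-normalised scale are
`band effect + band signature + feature loading + noise`: each latent band
carries its own random feature *signature* (s.d. 0.25) on top of its scalar
mean effect (−0.6 / −0.3 / −0.05 per relative-irradiance unit), because
three scalar offsets alone would put all bands on a single line in feature
space — a degenerate geometry no clustering referee could calibrate
against, and at odds with the premise that the bands reflect distinct
damage mechanisms. The 350-nm spot response adds −0.4 to the affected
features' slopes (a steeper response, hence a squared-slope peak). Two
technical wells per condition keep the plate within 96 wells.

**Not emulated:** plate-position (edge/row) effects, lamp drift, pipetting
covariance between neighbouring wells, heavy-tailed or heteroscedastic
imaging noise, feature–feature correlation beyond the planted structure,
and any image-level realism. Passing recovery tests therefore demonstrates
that the pipeline inverts its stated forward model under design-level
noise — not that real plates are free of the artefacts above.

## Problem sizes

The test suite and acceptance script run the full documented design:
viability 6 plates × ≤96 wells; ECIS 56 traces × 394 samples; imaging
82 wells × 380 features; clustering scans K = 2…8 with 500 resamples and
100 null references, repeated over ten independent seeds for the selection-
frequency checks. These sizes match the study design rather than being
scaled down; the batched k-means makes the ~3.5 million tiny clustering
fits of a scan affordable.

## Known limitations

- The p-value floor 1/(B+1) and PAC's 1/66 granularity at 12 items bound
  how emphatic the clustering evidence can be.
- The ECIS efficiency estimator inherits the first-crossing early bias
  described above; at 2% noise it is a few percent and well inside the
  1.5-fold recovery band the tests assert.
- Rb/α/Cm (cell-model) decomposition of impedance spectra is out of scope;
  the package analyses the measured electrical parameters directly.
- Quantal (photon-count) dose conversion is not implemented; all doses are
  radiometric.
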