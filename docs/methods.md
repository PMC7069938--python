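# Methods

## The imaging model

Both photoacoustic (PA) and single-plane-wave ultrasound (US) acquisition
with a linear array are, to good approximation, linear maps from the object
to the recorded radio-frequency (RF) channel data.  Discretizing the object
on a grid of n points and stacking the RF samples of the K active elements
into one vector gives

    S = A T₀ ,      S ∈ ℝᵐ,  A ∈ ℝ^{m×n},  T₀ ∈ ℝⁿ,  m = K · n_t ,

where column i of A is the vectorized RF response of a unit point source at
grid point i.  In PA mode T₀ is proportional to the optical absorption
distribution; in plane-wave US mode to the backscattering contrast.

Rather than measuring or simulating every column, the whole matrix is
derived from a **single PSF record** — the RF response of one point source
at a known position (x_j, z_j).  Under the assumption that the response of
every element has the same shape for all source positions and differs only
in arrival time, column i is the PSF record with each element trace k
shifted by the delay law

    Δt(i, j, k) = δ_US · (z_i − z_j)/c
                + ( ‖r_i − r_k‖ − ‖r_j − r_k‖ ) / c ,

with δ_US = 1 in plane-wave US (the emitted plane wave reaches deeper
points later) and δ_US = 0 in PA.  Wave propagation is treated as
homogeneous water (c = 1500 m/s, default); element directivity, attenuation
and per-element impulse-response variation are deliberately omitted — the
synthetic-data generator makes exactly the same assumption, so simulation
and model agree by construction (on purpose: the study isolates the roles
of noise and channel count, not model mismatch).

### Sign convention of the delay law

Positive Δt means the grid point's response arrives *later* than the PSF
source's response on that element.  For the plane-wave term this is
δ_US · (z_i − z_j)/c: a scatterer deeper than the PSF source is reached by
the emitted plane wave later, exactly as the geometric return-path term is
larger for a more distant point.  The convention is pinned down by a test
that compares every assembled matrix column against an independently
synthesized point response.

## Fractional delays

At the default 62.5 MHz sampling rate one sample corresponds to 24 µm of
path — twice the 12.5 µm reconstruction step — so nearest-sample shifting
would alias the grid.  All delays (RF synthesis, matrix assembly) are
applied as phase ramps in the frequency domain on the *unpadded* window,
i.e. as circular shifts with the Nyquist bin zeroed.  Two properties
motivate this exact form:

- **Compositionality.**  shift(a)∘shift(b) = shift(a+b) to machine
  precision.  The forward-model column for grid point i is then *exactly*
  the synthesis of a unit source at i (both are the base pulse shifted by
  the total delay), which the oracle-equivalence tests verify to ~1e−15.
  Padding-and-cropping between composed shifts, or keeping a complex phase
  at Nyquist, breaks this at the 1e−4…1e−6 level.
- **Band-limit hygiene.**  The Gaussian pulse at 15 MHz with 0.93
  fractional bandwidth has ~1e−4 relative spectral content at the 31.25 MHz
  Nyquist edge; zeroing that single bin makes the shift operator unitary on
  the remaining band.

The price is circular wrap-around: windows must keep waveforms clear of
their edges.  Record windows are chosen with a 7σ pulse-envelope guard
(envelope tail ~2e−11); the short per-element model windows may truncate
far-corner tails at the ~1% level, which is logged.

## Windowing and the matrix dimensions

A single common time window cannot be short: across the 12.7 mm aperture
the arrival time of a 15 mm-deep source varies by ~860 ns.  The model
therefore windows each element *around its own arrival time* from the PSF
source: n_t samples per element, rows grouped element-major.  With the
replica configuration (128 elements × 36 samples) the data vector has
m = 4608 entries and the grid (61 × 13 at 12.5 µm, a 751 µm × 151 µm
field of view centred on the scene) has n = 793 unknowns.  The resulting
matrix is strongly rank-deficient (numerical rank ≈ 339 at the default
bandwidth): the inversion is underdetermined and the l1 prior carries the
burden — the regime the method is designed for.

## Pulse model

A Gaussian-modulated sinusoid with the −6 dB fractional bandwidth
convention.  Defaults: centre frequency 15 MHz, sampling 62.5 MHz (4×
oversampling, the convention of the acquisition platforms used with this
probe class), fractional bandwidth **0.93**.  The bandwidth deserves a
note: the modeled probe is of the 8–22 MHz class, whose nominal band edges
give (22−8)/15 ≈ 0.93, and the wide-band forward matrix reproduces the
rank regime of the measured system (≈340 vs 322 for a 0.6-bandwidth
pulse).  All three are configuration parameters.

## Inversion

The estimate solves

    T̂ = argmin_T ‖S − A T‖₂² + α² ‖T‖₁

by FISTA, implemented exactly in this parameterization: the gradient of the
data term is 2Aᵀ(AT − S) with Lipschitz constant L = 2‖A‖₂² (estimated by
power iteration with a 5% step-safety margin), and the proximal threshold
per step is α²·step.  Iterations run on the cached Gram matrix AᵀA, making
each step O(n²) regardless of m.  The variant used is monotone FISTA with
function-value adaptive restart: an accelerated point that increases the
objective is discarded and the momentum reset, so the objective trace is
non-increasing by construction and convergence on sparse problems is much
faster than plain FISTA.  Initialization is T = 0; the generic default
stopping rule is a relative objective change below 1e−8 or 2000 iterations.

The **study engine** overrides the stopping rule to 1e−10 / 12000: near the
l1 optimum the objective plateaus while support mass still reorganizes
between adjacent grid cells, and the correlation metric is sensitive to
precisely that reorganization (noiseless-recovery correlation rises from
≈0.93 to ≈0.99 between the two tolerances).

### Choosing α

The regularization weight is chosen per condition by a scan, formalizing a
"make the image qualitatively consistent with a known-sparse sample"
heuristic: candidates are six log-spaced fractions (0.5…0.05) of
α_max = √(2‖AᵀS‖_∞) (the smallest α with an all-zero solution), solved
warm-started in descending order, and the *smallest* α whose support forms
at most `support_budget` (default 8) 8-connected clusters on the grid is
selected.  Clusters — not raw nonzero cells — because neighbouring columns
are highly coherent (12.5 µm apart under a ~100 µm PSF) and the l1 solution
legitimately splits each source's mass across adjacent cells; a perfect
noiseless recovery occupies ~25–50 cells in 5 clusters.  If no candidate
meets the budget (deep-noise regime) the sparsest candidate is used and the
report flagged for manual review.

## Delay-and-sum baseline

Plain DAS: per grid point, sum each active element's RF sample at the
modality-appropriate time of flight (linear interpolation, zero outside the
window), no apodization, no f-number gating; envelope along depth by the
analytic signal, per lateral line.  With the full aperture the synthetic
PSF's lateral FWHM is ≈152 µm at 15 mm depth — the five 125 µm-spaced
sources merge into the familiar bar-like pattern, which is what the sparse
reconstruction is measured against.

## Post-processing and the quality metric

The raw estimate is point-like, so displays (and the metric) use: Gaussian
smoothing (σ = 12.5 µm = one coarse step; kernel truncated at 4σ, zero
padding), bicubic-spline interpolation to a 3.125 µm grid (factor 4), and
normalization to unit maximum.  The magnitude |T̂| is used (the solver is
unconstrained by default; negative entries are noise artifacts).  Quality
is the normalized, non-mean-subtracted inner product C ∈ [0, 1] between the
processed reconstruction and the identically processed ideal object (value
1 in the grid cell of each true source).  C is scale-invariant, 1 exactly
for proportional images, and 0 for disjoint support.

"Resolved" is made testable: the lateral profile through the global maximum
must contain the expected number of local maxima with prominence ≥ 5% of
the peak; the spacing report returns centre-to-centre distances.

## The Monte-Carlo study

The synthetic scene is five unit point sources 125 µm apart at 15 mm depth
(the elevational focus), imaged by a 128-element, 100 µm-pitch array.
Element subsets are regular with the first and last element always
included, so every subset spans the full aperture and shares the
diffraction limit.  Per cell (N, SNR): the five-source RF is scaled so that
its peak amplitude over the noise rms σ_n = 30 equals the target SNR
(the study's SNR definition), i.i.d. Gaussian noise is added, the scene is
reconstructed with the cached N-element model, and C is computed.  α is
re-scanned once per cell on its first noise realization and reused across
realizations.  Cell means average 100 noise realizations in the full study;
the test suite uses 25 (cell checks) and 8 (trend sweep) realizations,
whose standard errors (0.01–0.05) are small against the ±0.1 agreement
band used for the study values.

Seeds derive from `SeedSequence((base_seed, N index, SNR index,
realization))`; by default the SNR index is dropped so noise draws are
*paired* across SNR levels within an N row, making the SNR trend a paired
comparison with strongly reduced Monte-Carlo variance.

### What the generator does and does not emulate

It emulates: the array geometry, one-way vs two-way delay structure, pulse
shape, additive electronics noise at a fixed rms, amplitude-controlled SNR,
and sub-sample arrival-time structure.  It does not emulate: element
directivity and mutual coupling, frequency-dependent attenuation, the
acoustically mismatched polymer layer of real phantoms, speed-of-sound
heterogeneity, or model mismatch between the PSF and the scene (the PSF is
synthesized with the same pulse).  Passing tests therefore demonstrate the
*algorithmic* behaviour of single-PSF model-based sparse reconstruction
under noise and channel decimation — not robustness to experimental
model error, which is the known hard part of applying the method to
measured data.

### Observed behaviour of the quality landscape

With this pipeline the mean correlation reproduces the study's reported
cell values — C ≈ 0.90 at (N = 64, SNR = 16), ≈ 0.64 at (16, 10), ≈ 0.25 at
(128, 0.8), each over 100 noise realizations — and the smallest element
count reaching C = 0.8 at SNR = 150 is 3 (N = 2 plateaus near C ≈ 0.43 at
any SNR).  Mean C increases with SNR
at every N.  It is, however, **not** monotone in N at fixed mid-range SNR:
around SNR ≈ 10 the N = 16 subset performs worse than N = 4 (its regular
decimation pattern has grating lobes that alias the 125 µm source spacing),
and the C = 0.8 contour is correspondingly non-monotone in N rather than
following a clean SNR ∝ √N law.  The trend tests assert exactly what the
pipeline produces; the contour-shape test documents this limitation.

## Numerical choices and degenerate inputs

- Grid raster order is depth-major (z fastest); it is part of the matrix
  contract and tested by round-trip.
- Regular subsets use round-half-up of the even partition of the index
  range; interior gaps differ by at most one index.
- Exact midpoint sources snap to the lower-index grid cell (documented
  tie-break); two sources in one cell warn.
- An identically-zero image skips normalization and is flagged; its
  correlation is treated as 0 by the study driver (and is an error in the
  metric itself).
- Power iteration runs to 1e−6 relative tolerance by default with a 5%
  safety factor on the step; the solver raises (not warns) on NaNs and on
  dimension mismatches.
- SNR of a noiseless record returns +inf (documented sentinel).

## Known limitations

- The forward model and the generator share the pulse model; experimental
  PSF mismatch (the dominant error source on real data) is out of scope.
- The α heuristic needs a support budget — i.e. prior knowledge that the
  scene is sparse with roughly known multiplicity; it is a formalization
  of a visual-tuning procedure, not an oracle-free model-selection rule.
- Plane-wave US is modeled at normal incidence with single scattering;
  compounding over angles is not implemented.
- N = 2 reconstructions sit in a heavily prior-driven regime; their
  quality saturates near C ≈ 0.45 and should not be over-interpreted.
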