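# Methods

`specklemix` models and inverts a non-invasive fluorescence acquisition
through a strongly scattering medium.  A phase-only SLM with `n_slm`
segments shapes a coherent beam that excites `N` fluorescent emitters hidden
behind the medium; the incoherent fluorescence scatters back through the
same medium and is recorded in epi-detection.  This note documents the
forward model, the reconstruction algorithms, the numerical choices, and
what the synthetic studies do and do not demonstrate.

## Forward model

For input phase pattern `p` the camera frame is

    I_out(p) = W (|T E_in(p)|^2)^e ,

where `T` (complex, `N x n_slm`) is the ingoing **field transmission
matrix**, `W` (non-negative, `D x N`) is the outgoing **intensity
transmission matrix** whose columns are the per-emitter fluorescent
eigen-patterns, `E_in(p)` is the unit-amplitude phasor vector of the SLM
pattern, and `e` is 1 for linear fluorescence or 2 for two-photon
excitation.  Rows of `T` are circular complex Gaussian (fully developed
speckle: excitation intensities are exponential, contrast 1).  Optional
noise: the stack is scaled to a mean photon budget, Poisson sampled,
Gaussian read noise added, clipped at zero, and scaled back.

### Memory effect

Thin diffusers translate the output speckle when the input is tilted,
within a finite patch.  Two ingredients realise this:

* **Tilt term.**  Each row of `T` carries a deterministic linear phase ramp
  over the SLM proportional to the emitter position; a shift of one speckle
  grain corresponds to a 2π ramp across the aperture.  Foci more than a
  grain apart therefore use (nearly) orthogonal ramps, which is what makes
  phase-conjugation focusing selective.
* **Patch decorrelation.**  The stochastic part of each row (and each
  eigen-pattern) is drawn from a latent Gaussian random field over
  object-plane position: latent vectors sit on a node grid and each
  emitter mixes them with normalized Gaussian weights.  The registered
  (tilt-compensated) field correlation between emitters separated by `d`
  is `c(d) = exp(-d^2 / (2 sigma^2))` with `sigma = me_range`; excitation
  *intensity* series then correlate as `c(d)^2`.  The construction is
  pairwise stationary: *any* two nearby emitters share a patch, not only
  pairs involving a designated reference — a property the displacement
  stitching relies on.  A single-reference blend
  `t_n = c a + sqrt(1-c^2) g_n` reproduces the same statistics for
  reference pairs but decorrelates non-reference neighbours, so the
  latent-field form is used instead.

Eigen-patterns are intensities of smoothed complex Gaussian fields
(`|field|^2`, pixelwise exponential, spatial contrast ≈ 1, periodic
boundary), mixed through the same latent machinery (kernel width chosen so
the *intensity* pattern correlation is `c(d)`), then circularly shifted by
the emitter position.  Within a patch, two eigen-patterns are translated
copies up to correlation `c(d)`, with the planted shift exact in integer
pixels — this is the construction oracle used by the cross-correlation
tests.  Physical diffraction propagation, polarization calculus, spectral
width and photobleaching are deliberately out of scope.

### Contrast statistics

For `N` equal emitters under linear excitation the frame contrast follows
the `sqrt(2/N)` law.  Two estimators are provided.  The **ensemble (RMS)
estimator** `sqrt(E[spatial var]) / E[spatial mean]` has expectation exactly
`sqrt(2/N)` for every `N` and is what the quantitative tests use.  The
per-frame mean of `std/mean` is biased low by O(1/N) (the exponential
excitation weights make the per-frame ratio a Dirichlet-type statistic with
expectation ≈ `sqrt(2/(N+1))`), noticeable below N ≈ 8; it is kept for
single-image use.  Averaging `k` independent polarization/spectral channels
divides the contrast by `sqrt(k)`; a polarizer therefore buys back a factor
`sqrt(2)`.  Two-photon excitation (`e = 2`) raises the contrast
(`sqrt(6/N)` for the RMS estimator), which is why non-linear contrast
mechanisms are attractive at large `N`.

## Reconstruction

### High-pass filtering

Frames are filtered by subtracting a periodic Gaussian blur (`sigma` in
pixels, default 8, i.e. several speckle grains) and clipping negatives to
keep the NMF input non-negative.  On real acquisitions this removes the
smooth fluorescent background; the clip is a deliberate nonlinearity whose
effect on the factorization is monitored by the recovery tests.

### NMF demixing

`I_out` admits a rank-`N` factorization `W H` with `H = |T E_in|^2`.  The
factorization uses Lee–Seung multiplicative updates on the Frobenius
objective, chosen for the monotonicity guarantee (the objective trace is
asserted non-increasing on every run).  Details:

* random non-negative initialization, seeded; best of `n_restarts` runs by
  final residual (default 2–3);
* the residual is tracked per iteration from cached Gram products at no
  extra `D x P` cost; convergence at relative objective change `tol`;
* scale/permutation ambiguity resolved by normalizing `W` columns to unit
  maximum, absorbing scale into `H`.

**Rank selection.**  The residual `||I - WH||_F` is scanned over trial
ranks; the estimate is the point of maximum curvature of the *log* residual
curve with a rank-0 baseline `||I||_F` prepended (raw-curve curvature peaks
at r = 1 for any steeply decaying curve, the log transform isolates the
change of slope at the true rank).  Confidence is the log-curvature at the
elbow; below 0.5 (an e-fold slope change) the elbow is declared unreliable
— typical beyond ~10 targets — and the caller should overestimate the rank
and prune afterwards, which is also the default pipeline behaviour.

**Component selection.**  With an overestimated rank the NMF produces
duplicates and spurious components.  Duplicates are pairs whose
eigen-patterns (zero-lag Pearson) *or* excitation series (rows of `H`)
correlate above `theta_dup = 0.8`; the excitation criterion matters because
the factorization sometimes splits one emitter into complementary
half-patterns whose spatial correlation is modest while their time series
are necessarily identical.  The higher-variance member of a pair is kept.
Spurious components can be flagged two ways: a cheap proxy (eigen-pattern
variance more than `theta_var = 2` robust z-scores below the population
median) and the physical test (the epi-variance focus verdict below).  The
pipeline defers to the physical test by default (`theta_var = None`): the
variance proxy can clip genuinely weak components when many emitters crowd
the rank, whereas a component that truly cannot focus always fails the
epi-variance verdict.

### Phase retrieval

Each selected row of `H` is an intensity-only measurement of one row of
`T`: `h_p = |<t, E_in(p)>|^2` with known patterns.  Recovery (defined up to
a global phase; all quality metrics are phase invariant) is well posed when
`P` is a few times `n_slm` and proceeds in two stages:

1. **Refined spectral initialization**: leading eigenvector of
   `(1/P) Σ f(h_p) conj(E_p) E_p^T` with `f(y) = max(1 - 1/y, -1)` on
   mean-normalized intensities; the weighting suppresses the unit bulk of
   the spectrum and reaches a given alignment with fewer measurements than
   the plain truncated weighting (`f(y) = y` clipped at `trunc` times the
   mean, also available).  The init is scaled so predicted and measured
   mean intensities match.
2. **Amplitude flow**: gradient descent on
   `(1/P) Σ (sqrt(h_p) - |<t, E_p>|)^2`, fixed step `0.2/L` with `L` the
   per-measurement spectral norm of the pattern matrix (power iteration),
   or backtracking line search (guaranteed non-increasing loss).  The
   amplitude loss is better conditioned than the intensity (Wirtinger)
   loss at moderate `P/n_slm`.

NMF rows carry arbitrary scale; measurements are normalized to unit mean
internally and the scale is re-attached.  Rows are retrieved
independently; per-row failures are reported without stopping the rest.

### Focusing and non-invasive validation

Phase conjugation displays `-arg(t)` on the SLM; for a circular Gaussian
row the focus intensity is `(Σ|t_k|)^2` and the expected enhancement over
random illumination is `1 + (pi/4)(n_slm - 1)`.  Control-side metrics
(available in simulation, or with a camera behind the sample) evaluate the
excitation at every emitter plus background probe positions: SNR is peak
over mean off-target intensity (a peak-over-std variant is logged alongside
since conventions differ); selectivity asks the target to be the brightest
emitter.  The **non-invasive** verdict uses only epi frames: focusing on
one of `N` emitters concentrates the fluorescence into a single
eigen-pattern, raising the frame's normalized spatial variance
(contrast squared) toward `N/2` times the random-illumination baseline;
a candidate passes when its score exceeds `theta_focus = 2` times the
baseline median.  Normalizing the variance by the squared frame mean makes
the score insensitive to the larger total fluorescence a successful focus
generates.  Control-side and epi-side quantities are kept strictly
separate so the non-invasive claim stays testable.

### Memory-effect imaging

Eigen-patterns of emitters within one patch are translated copies, so the
displacement `u_ij` between emitters is the argmax of their mean-subtracted,
norm-normalized circular FFT cross-correlation (integer pixels; sub-pixel
refinement is a possible extension).  The edge score is the peak height
over the robust (MAD) standard deviation of the off-peak plane; edges
require score > `theta_edge = 5`.  Two defences remove false peaks: edges
whose triangles are predominantly cycle-inconsistent (median residual
> 2 px) are dropped, and the global solve trims any remaining edge whose
least-squares misfit exceeds 2 px.  Positions are then solved per connected
component from all constraints `x_j - x_i = u_ij` jointly (avoiding the
drift of sequential accumulation along chains), with the reference node at
the origin; isolated components and singleton nodes are reported as
unlocatable, never placed by guesswork.  Reconstruction extent is limited
by patch *overlap*, not patch size: a chain of emitters whose patches
overlap is recovered across several ME ranges.

A classical MDS alternative embeds emitters from the scalar distance matrix
`|u_ij|` (missing entries completed by graph shortest path, double
centering, top-2 eigenvectors, Procrustes utilities for comparison).  Under
Gaussian displacement noise on radius-limited graphs the vector-based
least-squares stitcher measurably outperforms both sequential accumulation
and MDS (the tests assert the measured ordering); MDS remains useful when
only distances are trusted.

The pipeline cross-correlates the epi frames recorded under the conjugate
patterns by default; the raw `W` columns can be selected instead
(`imaging_source="nmf"`).

## Pipeline, reproducibility, problem sizes

`run_pipeline` executes simulate → high-pass → (rank) → NMF → select → PR
→ focus/validate → image, persisting each stage's artifacts (HDF5 canonical,
TIFF for microscopy interoperability, CSV reports) and a manifest with the
config snapshot, master seed, stage timings and SHA-256 hashes of all
outputs.  One master seed feeds named substreams (patterns, field TM,
intensity TM, noise, baselines), so noiseless reruns are bit-identical and
components are individually reproducible.

The bundled reference studies run on one CPU in a few minutes each: the
bead-focusing study uses 20 emitters, `n_slm = 256`, `P = 5120`,
`D = 64 x 64`, ~100 photons/pixel and rank 30; the dense-object study uses
50 emitters, `n_slm = 128`, `P = 4096`, rank 60, low noise; the
beyond-patch imaging study uses a 20-bead serpentine spanning ~3 ME ranges.
These sizes keep the governing ratios (`P/n_slm`, rank overestimation,
grains per frame) representative of much larger acquisitions.

## What the synthetic studies do and do not show

The generator plants the very structure the algorithms exploit: exact
integer shifts between eigen-patterns, Gaussian patch decorrelation, fully
developed speckle, stationary backgrounds.  Passing tests therefore
demonstrate the *algorithmic* chain — demixing, retrieval, conjugation,
validation, stitching — under controlled statistics, including shot noise
and rank misspecification.  They do not demonstrate robustness to
structured fluorescent background, spectrally broad or unpolarized detection
beyond the contrast scalings, sample drift or photobleaching during the
acquisition, sub-pixel displacements, non-Gaussian patch decorrelation of
real diffusers, or axial (3-D) structure — the eigen-pattern model is a 2-D
projection by construction.

## Known limitations

* Eigen-pattern synthesis plants shifts explicitly rather than propagating
  a second physical transmission matrix; cross-correlation ground truth is
  exact by construction (a modelling simplification, not a physics claim).
* Integer-pixel displacements only.
* The elbow rank estimator assumes a noise floor exists within `r_max`.
* Classical MDS requires a connected distance graph; disconnected objects
  are embedded per component by the stitcher only.
* The multiplicative-update NMF is the plain Frobenius variant; sparse or
  regularized variants are out of scope.
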