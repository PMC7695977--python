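# Methods notes

This note records the models implemented in `streamspa`, the numerical
choices made where the underlying methods left the design open, what the
synthetic data emulates, and the known limitations.

## Motion correction

The movie model is a static scene displaced per frame by a whole-frame
(stage drift) shift plus a smooth beam-induced local deformation. Global
alignment maximizes the band-limited correlation of every frame to the
evolving weighted-average reference, with the frame's own contribution
subtracted from the reference to avoid self-bias. Two stages:

1. *Coarse*: integer-pixel correlation-peak search within ±`max_shift`
   (default 20 px), up to 3 outer iterations, stopping when no frame moves
   by a full pixel.
2. *Refine*: L-BFGS-B over all 2n continuous shifts with analytic
   gradients of the correlations (∂cc/∂s via the Fourier shift theorem,
   restricted to the frequencies inside the resolution band so each
   evaluation touches ~10% of the plane). The leave-one-out references are
   frozen within a round and rebuilt between rounds (3 rounds).

The alignment band ramps linearly in 1/resolution from `res_start` = 8 Å
to `res_final` = 5 Å across outer iterations, with B-factor damping
exp(−Bg²/4), B = 50 Å² by default: both suppress noise-driven jitter in
the trajectories. Shifts are mean-centered over frames after every update,
which fixes the translational gauge of the problem.

Frame weights are w_i ∝ max(corr_i, 0) of the aligned frame against its
leave-one-out reference in the final band, normalized to sum 1. This is
one reasonable monotone transform of the correlations; it reproduces the
qualitative behavior required of it (uniform for identical frames, minimal
for an outlier frame) and is cheap.

Patch alignment reuses the same coarse+refine machinery on patches of the
globally corrected frames, with two differences: the search window is
±6 px (local motion is small), and during coarse iterations each patch
trajectory is smoothed by an independent 3rd-order 1D polynomial in time
per axis, which suppresses discontinuous jumps driven by the weak
per-patch signal. The requested patch grid (default 5×5) is capped so
patches keep ≥ 256 px per side; near-zero-variance patches (dead detector
regions) are flagged and excluded from the deformation fit.

The deformation model is a complete trivariate 3rd-order monomial basis
(20 terms, exponents ordered by total degree then lexicographically) over
coordinates normalized to [−1, 1] in x, y and t; x- and y-shifts are fitted
independently by least squares, and rank deficiency (too few distinct
patch positions for the cubic spatial terms) is a hard error, with a
global-shifts-only fallback at the pipeline level. Frames are resampled
with bilinear interpolation (adequate for ≤ 5 px local displacements) and
summed with the per-frame weights; the optional dose filter is the
critical-exposure parameterization D_c(g) = 0.24499·g^(−1.6649) + 2.8141
e⁻/Å², applied as exp(−D/(2D_c)) per frame in Fourier space, with an
optional voltage scale (1.0 at 300 kV, 0.8 commonly used at 200 kV).

## CTF estimation

The phase function is the CTFFIND4 form
χ(g, θ) = πλg²Δf(θ) − (π/2)λ³g⁴C_s + Δφ + A with
Δf(θ) = ½[Δf_x + Δf_y + (Δf_x − Δf_y)cos 2(θ − α_a)] and A = asin(w); the
wavelength is relativistic. Underfocus is positive; defocus is carried in
μm and converted to Å only inside χ and in STAR writers. The parameter
triple (Δf_x, Δf_y, α_a) is degenerate under swap-plus-90°;
`canonical_astigmatism` resolves it (Δf_x ≥ Δf_y) before any comparison.

The spectrum is the average power spectrum of 512² tiles at 50% overlap;
the background is estimated by a Gaussian low-pass of the averaged
spectrum with kernel width 1/(40 Å) in frequency and subtracted, and a
3-px central cross is zeroed to remove detector/readout streaks. The
score is the normalized correlation (no mean subtraction) between the
background-subtracted spectrum and CTF², evaluated over the 30–5 Å
annulus; CTF² is used consistently in the score and in its analytic
gradients because the measured quantity is power, not amplitude.

Fitting is the three-step strategy described in the README. Numerical
details worth recording:

* The 1D search (step 0.01 μm) and the fit-resolution profile compare
  against shell-averaged model values (CTF² averaged over the same
  integer-radius shells as the data, including the angular dependence for
  the astigmatic case). Near Nyquist a CTF half-period spans ~3 shells, so
  evaluating the model at shell centers instead systematically decorrelates
  an otherwise perfect fit.
* The Differential Evolution astigmatism search is seeded (default 42)
  and therefore deterministic; defoci are bounded to the 1D estimate
  ±0.1 μm, which encodes the assumption of modest astigmatism — fits with
  planted |Δf_x − Δf_y| well beyond ~0.2 μm are outside the method's
  intended regime.
* Step 3 maximizes f = cc + f_pen with f_pen = −(1/2N)((Δf_x−Δf_y)/0.05 μm)²
  (N = number of scored frequency samples) under L-BFGS-B with analytic
  gradients; α_a and Δφ stay fixed.
* The fit resolution is the last shell before the rolling 11-shell Pearson
  correlation between the radial spectrum and the model drops below 0.75;
  if it never reaches 0.75 the 30 Å bound is returned flagged.

The anisotropic model lays a grid with 512-px spacing over the exposed
area (⌊dim/512⌋ points per axis, centered: 49 points at 4000²). Tile
weights use exp(−d²/2) with d in units of the grid spacing — the natural
scale that makes each point average over its neighborhood without washing
out the field — keeping up to 32 nearest tiles contributing > 1% (weights
renormalized after the cut). Because the correlation-versus-defocus
landscape oscillates, each grid-point refit is preceded by a coarse local
scan (±0.3 μm, both defoci jointly) that re-centers the L-BFGS-B start in
the correct basin; without it, grid points whose true defocus is far from
the global estimate converge to a secondary maximum. The per-point defoci
are then fitted by two bivariate 3rd-order polynomials (10 terms each)
over normalized (x, y); the astigmatism angle and phase shift are shared
from the global fit. More than 50% failed grid points aborts the model.

## Particle picking

The locally normalized correlation divides the masked template correlation
by the local standard deviation of the micrograph under the same circular
mask, all through FFT convolutions; values are in [−1, 1] and invariant to
affine intensity changes of the micrograph. References are rotationally
augmented at 10° steps by default (disabled where the reference matches
the planted orientation). The 2D Otsu threshold maximizes between-class
variance on a 64×64 joint histogram of (value, 3×3 mean) using the two
diagonal quadrants, computed with cumulative-sum tables; the peak class is
the jointly-above quadrant. Particle candidates are per-connected-
component maxima of the map inside the mask; the distance filter is greedy
by descending score with threshold 2.7× the particle radius. Outlier
rejection computes per-window standard deviation, mean power-spectral
value (zero frequency excluded) and dynamic range, and rejects a peak when
any robust z-score (median/MAD, scale floored at 2% of the median
magnitude so homogeneous populations produce no formal outliers) exceeds
3.0. Extraction normalizes by the mean and standard deviation of the
pixels outside the particle radius.

## Stream 2D

The chunk buffer emits fixed-size chunks in arrival order and conserves
particles (emitted + held = streamed). The bundled 2D aligner is
deliberately simple plumbing: initial references are picked greedily from
the particles (first at random under the seed, then repeatedly the
particle least correlated to any existing reference, which spreads the
seeds over distinct views); each iteration matches every particle over
in-plane rotations (15° steps) and shifts (±6 px) against the lightly
smoothed (σ = 1.5 px) class averages and rebuilds the averages from the
*aligned* members. Smoothing the references matters: maximizing a
correlation over many transformations is biased toward noisier references,
which otherwise swallow the population. All stream logic is engine-
agnostic behind `classify_chunk`.

Class resolution is the FRC = 0.143 crossing of the even/odd half-set
averages (split by member order within the class); g_i is the integer
shell index of the last accepted shell, so higher g means better
resolution. The rejection rule standardizes g_i and cc_i over the class
population and rejects class j iff [z(g_j) < −1.5 or res_j > 30 Å] and
z(cc_j) < −1.5. The absolute resolution bound substitutes only for the
g-criterion — the correlation criterion is always required, following the
principle that a class must show *both* low resolution and weak
correlation; a strict-absolute mode (reject on res alone) is available as
an option. A zero population standard deviation makes the corresponding
z-criterion false for every class, so degenerate (identical-metric)
populations reject nothing. The adaptive fraction is
δ = min(0.4, 500 000/count) with a seeded uniform subset of
round(δ·count) particles marked for refinement.

## Optics groups

Beam shifts are clustered with complete-linkage hierarchical clustering
(Euclidean); when k is not given, the tree is cut at the largest relative
gap between consecutive merge heights (requiring a ratio ≥ 3, otherwise a
single cluster). Within each cluster, movies are partitioned by the
location identifier (the Data-section numbers of the EPU filename, which
encode the shot position within the hole template); partitions above
`max_pop` are split round-robin over members ordered by movie id, making
the result independent of input order. Groups are renumbered contiguously
from 1 + offset in (cluster, location) order. Beam tilt is not part of the
clustering metric; tilt information, when present, rides along unused.

## Synthetic data: what it does and does not emulate

* Movies are a seeded mixture of Gaussian blobs (σ 2–6 px) displaced by
  the planted motion (cubic-spline resampling) plus white Gaussian noise;
  SNR is defined as signal variance over noise variance per frame. There
  is no Poisson counting statistics, no detector MTF/DQE, no gain or
  defect structure — sufficient for registration accuracy, silent about
  detector-specific behavior.
* The planted local motion uses only the monomials x·t, y·t, x·y·t per
  axis. This is deliberate: global alignment absorbs the spatial mean of
  any local motion, and per-patch trajectories are centered in time, so
  only this gauge-free subspace is identifiable from images. The full
  20-term basis is exercised directly by the generate-and-refit oracle on
  the fitting routine.
* CTF micrographs are white noise filtered by |CTF|; a spatially varying
  defocus field is synthesized in 512-px blocks with the local CTF at each
  block center. Tile spectra therefore carry exact Thon rings but realistic
  background slopes, ice gradients and drift-induced ring attenuation are
  absent; passing recovery tests demonstrates estimator correctness, not
  robustness to all experimental pathologies.
* CTF recovery fixtures draw a mean defocus in 0.8–3.0 μm with astigmatism
  up to 0.2 μm — the modest-astigmatism regime the restrained search is
  designed for.
* EPU sessions place cluster centers at unit separation with Gaussian
  spread 0.01 (a 100:1 separation, comparable to well-separated AFIS
  patterns); filenames follow the FoilHole/Data convention.
* Classification chunks use four geometrically distinct templates (disk,
  ring, bar, wedge) standing in for well-separated projection views.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen as the smallest
sizes at which every quantity is meaningfully measurable: 2048² CTF
micrographs (49 tiles), a 4000² micrograph for the 49-point grid and the
defocus-tilt recovery, 16-frame 1024² movies for motion, 1024² picking
micrographs with 30 particles, 200-particle classification chunks, and
80-movie EPU sessions.

## Known limitations

* No EER/TIFF input, gain correction, or super-resolution binning; MRC
  mode 0/1/2/12 only.
* The reference 2D aligner is not a faithful stochastic hill-climbing
  classifier; it exists so the stream logic (metrics, rejection, global
  expansion) is testable end to end.
* Fit resolution uses plain radial averaging; strong astigmatism smears
  high-frequency rings across shells and lowers the reported resolution
  (no equiphase averaging).
* Per-particle CTF refinement during 3D, tilt series, and cluster
  submission are out of scope; exports hand off to downstream packages.
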