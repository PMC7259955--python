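# Methods

## The generative model

The simulator produces what a fast widefield SPT experiment on a nuclear
protein yields after spot detection and tracking: gapless 2D tracks of
observed positions at a fixed frame interval.

Each molecule is assigned one diffusive state for its whole lifetime —
chromatin-bound with probability `f_bound`, free otherwise. The fitted
kinetic model has no bound↔free exchange term, and the generator matches
that assumption; on the sub-second timescale of these tracks state changes
are rare for stably incorporated histones, which is the regime the model
describes. True positions evolve as 2D Brownian motion (per-axis step SD
√(2·D·dt)); observed positions add independent Gaussian localization noise
with SD `sigma_loc` per axis. Bound molecules use a small but nonzero
`d_bound` (chromatin is not rigid; 0.03 µm²/s is typical of nucleosomal
motion), and are treated as staying in focus: their chromosomal locus keeps
them inside the imaging slab on these timescales.

Free molecules additionally diffuse in z with the same coefficient, and a
track ends at the first passage of z to either face of the detection slab
(thickness `dz`, initial z uniform inside). First passage is sampled in
continuous time — a Gaussian step per frame plus the exact image-series
Brownian-bridge absorption probability inside each interval — so the axial
loss process is exactly the absorbing-slab diffusion problem that the
z-correction factor of the kinetic fit solves. The single-crossing
approximation to the bridge probability is not sufficient here: at
D = 5 µm²/s and dt = 10 ms the step SD is half the slab width, and the
neglected image terms shift survival by almost a percentage point; the
implementation keeps images k = −3..3.

Tracks also end by photobleaching, with geometric lifetimes (per-frame
probability `bleach_prob`, default 0.1, i.e. a 10-frame mean lifetime —
photobleaching-limited tracks of the length this imaging regime produces).
A `max_frames` cap (default 1000) bounds lifetimes when `bleach_prob` is 0.
Tracks shorter than `min_track_len` are dropped. Lateral initial positions
are uniform in the ROI, which bounds initialization only; motion is
unbounded. One integer seed drives all randomness through a single
generator stream, so equal seeds give byte-identical output.

Default parameters (dt = 10 ms, pixel 107 nm, σ = 30 nm, dz = 0.65 µm for
the far-red dye and 0.60 µm for the yellow-green dye) reproduce the
imaging regime of fast single-molecule tracking in yeast nuclei. Condition
presets set (`f_bound`, `d_bound`, `d_free`, `dz`) to the published
two-state estimates of the corresponding strains; the free-state D of the
Swr1 presets (1.0 µm²/s) is the package's own choice of a realistic value
for a ~1 MDa complex, as no measured value is printed for it.

What the generator deliberately omits: no raw-image synthesis or PSF
rendering, no detection failures or blur-based rejection, no gap closing or
re-detection of molecules that re-enter the slab (an exited molecule is
lost), no bound↔free exchange within a track, no anomalous or confined
diffusion, no z-dependence of localization error. Passing closed-loop tests
therefore demonstrates the estimators' correctness for this observation
model, not robustness to every artifact of real movies (see Limitations).

## Linking

Localizations are linked frame-to-frame by optimal assignment
(`scipy.optimize.linear_sum_assignment`) on squared displacement, gated at
`max_jump_px · pixel_size` (default 5 px × 107 nm = 0.535 µm), using the
standard augmented matrix in which an unmatched detection costs the squared
gate radius — a link is always preferred to a birth/death pair when the
gate allows it, and the total squared displacement is minimized. There is
no gap closing: a missed frame splits a track. Determinism does not depend
on input order (detections are sorted by (frame, x, y) before assignment).
At single-molecule densities the assignment problem is almost always
trivial, and the tests require ≥ 99% link accuracy at low density plus
exact agreement with exhaustive enumeration on crossing micro-instances.

## MSD route

Per track (≥ 6 frames): time-averaged MSD over all overlapping pairs;
ordinary least squares of MSD against lag time over lags 2–5·dt with a free
intercept; D = slope/4. The free intercept absorbs the 4σ² localization
offset (and any constant blur term), so no explicit noise subtraction is
applied. Tracks are accepted when R² > 0.8 and the slope is positive (log D
is undefined otherwise); rejected counts are logged. Acceptance-filtering a
4-point line fit is aggressive for slow tracks whose MSD is nearly flat
relative to noise — typically only ~40–50% of bound tracks pass — and the
surviving slow tracks are noise-selected toward larger apparent D: the
fitted slow-component mean lands near 0.04–0.05 µm²/s for a generative
0.03. This is worth knowing when comparing "mean bound D" values between
studies that do and do not filter.

The accepted log₁₀ D values are fitted with a two-component Gaussian
mixture (maximum-likelihood EM via scikit-learn, 10 seeded initializations,
best likelihood kept; components labeled slow/fast by mean). The slow
weight is the MSD-based bound-fraction estimate — a mixture weight, not a
per-track hard classification. Standard errors come from bootstrap
resampling of the track-level log D values (resample, refit, SD across
replicates; label switching resolved by mean ordering). Histogram binning
is presentation-only; fitting uses the raw values.

## Jump-length route

Displacements are compiled per interval multiple k = 1..6: each track of
≥ 3 frames contributes its earliest ≤ 4 jumps per interval, jumps beyond
1.2 µm are discarded, and empirical CDFs are evaluated on a 0.01 µm grid.
The two-state model CDF (per-interval renormalized over the considered
range, since the raw mixture has mass F₁ + Z·F₂ < 1 while every empirical
CDF reaches 1) is fitted by bounded least squares jointly across intervals,
each interval weighted by √(its jump count). Box bounds: D₁ ∈ [0.001, 0.1],
D₂ ∈ [0.15, 5] µm²/s, F₁ ∈ [0, 1], σ ∈ [0.01, 0.1] µm; σ is fitted from
the data; dz is fixed per dye. Three random seeded initializations inside
the bounds; best final objective wins; refits are deterministic under the
same seed.

### The z correction and the composition weighting

`z_correction(Δτ, dz, D)` is the survival probability of 1D diffusion
between absorbing planes from a uniform start: the eigenfunction series
(8/π²)·Σ_{n odd} n⁻²·exp(−n²π²DΔτ/dz²), truncated below 1e−12, with the
short-time boundary-layer form 1 − (4/√π)·√(DΔτ)/dz below
π²DΔτ/dz² = 0.01 where the series converges slowly (the two agree to
~1e−12 at the crossover). It is verified against an independent
Monte-Carlo absorbing-slab oracle to within 0.005 across Δτ = 10–60 ms,
dz ∈ {0.6, 0.65} µm, D = 0.15–5 µm²/s.

Weighting the free term by Z(Δτ) alone is correct for an ensemble observed
instantaneously, but compiled jumps come from finite tracks: a lag-k jump
starting at frame i exists only if its track survived max(i+k+1, 3) frames.
For the generator's observation model the expected number of compiled
lag-k jumps per molecule is exactly

    E[#jumps] = Σ_{i=0..3} q^(m−1) · S((m−1)·dt),   m = max(i+k+1, 3),

with q the per-frame bleaching survival (common to both states; S ≡ 1 for
bound molecules), because lateral displacements, bleaching and axial
survival are mutually independent and expectation is linear. The default
fit (`composition="track"`) therefore weights the free component by the
ratio of these expected counts, with q estimated from the observed
track-length distribution and refined once against the provisional fit
(the bound/free length mixture is solved for q). The instantaneous
weighting remains available (`composition="instantaneous"`); on
track-limited data it overestimates the bound fraction by 3–10 percentage
points across the preset conditions, precisely because free molecules that
left the slab before frame 3 never contribute jumps at any lag. With the
track-composition weighting, closed-loop recovery of `f_bound` is unbiased
to ≤ 0.5 points at large n and has a seed-to-seed SD of ~1–1.7 points at
5000 molecules; D₂ is recovered within a few percent.

Two kinds of uncertainty are reported and labeled: residual-covariance
(Gauss–Newton) standard errors of the point fit, which treat the correlated
CDF residuals as independent and are optimistic, and bootstrap-over-
trajectories errors (`bootstrap_two_state`), which resample the true
sampling unit and should be the quoted values.

## The two bound-fraction estimators disagree by construction

The jump-length estimate targets the molecule-level bound fraction and
models the axial attrition of free molecules explicitly. The MSD-mixture
slow weight is a property of the ≥ 6-frame track population: free molecules
at D ≈ 1.2 µm²/s survive 50 ms inside a 0.65 µm slab only ~20% of the
time, so the analyzable-track population is strongly enriched for bound
molecules, and the slow weight sits well above the molecule-level fraction
(e.g. ~0.93 of tracks when 0.82 of molecules are bound; ~0.45 when 0.21
are). The mixture itself is exact — tests confirm its weight equals the
ground-truth composition of accepted tracks to three decimals — the gap is
pure survivorship selection. Under this observation model (no re-detection
after slab exit, no gap closing, one track per molecule) no mixture over
≥ 6-frame tracks can recover the molecule-level fraction; estimators that
need the molecule-level quantity should use the jump-length route, and the
MSD slow weight should be read as "slow fraction of analyzable tracks". In
real experiments re-entry/re-detection and nuclear z-confinement reduce
(but do not eliminate) this selection, which is how the two estimators can
appear concordant on real data.

## Numerical and design notes

- Log base 10 for the D histograms.
- MSD uses overlapping (time-averaged) pairs; n_pairs(lag) = L − lag.
- Tracks with non-positive fitted slope are excluded from the log-D pool
  and counted.
- EM: scikit-learn GaussianMixture, `n_init=10` (3 inside bootstrap
  replicates), seeded; degenerate input (all values equal) raises;
  non-convergence is flagged, not silent.
- Assignment ties in linking are broken by the (x, y) sort of detections;
  exact cost ties between different matchings are resolved by the LAP
  solver deterministically for a given matrix.
- The empirical CDF is evaluated at bin edges by `searchsorted`; the model
  CDF is evaluated at the same edges and renormalized over [0, max_jump].
- `fit_two_state` requires jumps at ≥ 2 interval multiples; all-bound data
  fit cleanly (F₁ → 1, D₂ unidentified inside its bounds).
- Problem sizes in the test and acceptance suites (5000 molecules per
  condition; 10⁵ Monte-Carlo walkers per oracle cell) are chosen so that
  sampling noise sits comfortably inside the stated tolerances while a
  full run stays in the seconds-to-a-minute range.

## Known limitations

- No state exchange within tracks; proteins with fast binding kinetics
  (sub-100 ms dwell times) violate the model on both the generator and the
  fit side.
- Two states only; a third intermediate population, if present, is
  absorbed into the two fitted ones.
- The composition weighting assumes the generator's observation model
  (geometric bleaching independent of axial survival, absorbing slab,
  uniform initial z). Real data with gap tracking or strong z-confinement
  have a different — milder — attrition structure; the instantaneous
  weighting brackets that case from the other side.
- The linking stage does no gap closing and no blur/intensity filtering;
  it starts from localizations, not images.
- Residual-based fit errors underestimate uncertainty; use the trajectory
  bootstrap.
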