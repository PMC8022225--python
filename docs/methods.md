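# Methods

## Scope and units

All lengths are in µm, times in s, diffusion coefficients in µm²/s,
masses in kDa, DNA footprints in bp.  Frames are 0-based.  Pixel centres
sit at (i + 0.5)·pixel_size.

## Cell geometry

A cell volume is an ordered stack of coaxial cylindrical segments
(`CellGeometry`): the representation that falls out of segmented
microscopy outlines, where the distance from the midline to the cell
edge gives the radius of a cylindrical volume per length segment
(`geometry_from_outline`).  `make_spherocylinder` builds the canonical
rod shape — cylindrical mid-body plus hemispherical caps — by evaluating
r(a) = √(R² − d²) at segment midpoints; with 100 segments the enclosed
volume agrees with the analytic spherocylinder volume to ≪ 2%.

Where measured outlines are not supplied, inference uses a canonical
population of 50 spherocylinders with radius 0.45 µm and lengths uniform
on 2–4 µm (`default_cell_population`), emulating exponentially growing
*E. coli*.  This stand-in introduces a systematic uncertainty of a few
percentage points in bound-fraction estimates relative to using the true
segmented volumes of the measured cells (see *Limitations*).

## Brownian motion simulator

`simulate_tracks` / `simulate_dstar_values` propagate molecules with
isotropic Gaussian displacements of variance 2·D·dt per axis per
sub-frame; each camera frame is split into `n_subframes` (default 100)
sub-frames.  The observed frame position is the mean of the frame's
sub-frame (x, y) positions — motion blur under continuous illumination —
plus independent Gaussian localization error σ_loc per axis (default
35 nm).  The z coordinate only participates in confinement; observation
is the 2D projection, as for a camera imaging the whole cell depth.

**Acquisition defaults.** Frame interval 15.48 ms (15 ms exposure +
0.48 ms readout; 5.48 ms for the fast mode), bleach lifetime 85 ms
(exponential), pixel 96 nm.  Exposure is treated as the full frame
interval; camera dead time is ignored.

**Confinement** is reflective (specular), applied per coordinate: the
axial position is folded into [0, L] (triangle reflection, handling
multiple bounces via the modulo construction) and the radial coordinate
is folded at the boundary radius of the segment containing the new axial
position.  Sub-frame steps (≈ 0.03 µm at D = 2.7) are small relative to
the 0.45 µm radius, so per-coordinate folding is an accurate hard-wall
rule; the mean apparent D of confined tracks is unchanged (within Monte
Carlo error) when cap segmentation is refined from 25 to 1000 segments.
One caveat: for *very wide* geometries (radius ≥ several µm) coarse cap
segments create large radius discontinuities whose folds inflate
transverse displacements; unconfined sanity checks therefore use a
single-segment wide cylinder rather than a giant spherocylinder.

**Two-state interconversion.** When enabled, molecules switch between a
bound state (D_bound, default 0.04 — the apparent coefficient of
proteins riding on slow, constrained chromosomal DNA) and a free state
(D_free) with exponential dwell times.  State updates use the exact
two-state Markov transition probabilities over one sub-frame; each
sub-frame's displacement uses the state occupied at its start (the
sub-frame, ≈ 0.15 ms, is short against the 1 ms mean bound dwell).
Initial states are drawn from the stationary distribution (Φ, 1 − Φ);
initial positions are uniform over the cell volume regardless of state.
Only the dwell-time *ratio* is identifiable from apparent diffusion
data; the mean bound dwell (default 1 ms) anchors the exchange
timescale, which must stay below the 75 ms observation window per track.

**Photoactivation and bleaching.** Each molecule activates at a uniform
random movie frame and remains visible for an exponential time of mean
85 ms, i.e. a geometric number of frames.  The fast path used by the
inference loops (`simulate_dstar_values`) exploits the independence of
displacement statistics and track duration: since only tracks with ≥ 5
localizations yield a D_i*, it simulates exactly 5 frames per track
instead of sampling durations and discarding short tracks.  This is an
exact conditioning argument, not an approximation.

**Seeding.** A single integer seed (or a `numpy.random.Generator`)
drives all draws; identical seeds give identical output.

## Apparent diffusion statistics

`track_dstar` implements D_i* from the one-step MSD over the first
n = 4 consecutive-frame steps, truncating longer tracks after their 5th
localization.  Tracks shorter than 5 points, or whose first 4 steps span
a linking memory gap, are rejected and counted: a gap step covers 2Δt
and would bias the one-step MSD.

The sampling density of D_i* for a species with apparent coefficient D*
is Gamma with shape n and mean D* (`dstar_pdf`).  The one-species MLE is
therefore the sample mean (`fit_single`).  The two-species model — a
long-lived immobile fraction A plus a mobile fraction 1 − A — is fitted
by multi-start EM (`fit_mixture`); with fixed shape the M-step is exact
(responsibility-weighted means), and one deliberately degenerate start
(both components at the sample mean) guarantees the two-species
log-likelihood always dominates the one-species fit.  Components are
bounded to [10⁻³, 20] µm²/s and ordered D1* ≤ D2*; convergence is
declared at 10⁻⁸ on the log-likelihood.  Note the textbook
identifiability caveat: when the data hold a single species the two
components collapse (D1* ≈ D2*) and A is arbitrary — significance should
be judged by the likelihood ratio, not by A alone.

Confidence intervals come from bootstrap resampling of segmented cells
with replacement (default 1000 replicates; tracks within resampled cells
are pooled and refitted), propagating cell-to-cell variability.

Localization error adds σ_loc²/Δt to any apparent coefficient
(≈ 0.079 µm²/s at σ = 35 nm, Δt = 15.48 ms).  `offset_correct` subtracts
either this theoretical offset or an empirically measured baseline (the
apparent D* ≈ 0.07 µm²/s of chemically fixed cells); the empirical
variant gives the default bound-state coefficient 0.11 − 0.07 =
0.04 µm²/s.  Tracks are classified immobile/mobile at 0.15 µm²/s; values
exactly at the threshold count as mobile.

## Simulation-matching inference

`match_unbiased_d` scans candidate ground-truth D values (default grid
0–10 µm²/s, step 0.05), simulates the same number of molecules (× an
oversampling factor, default 10) in the supplied cell volumes under the
identical acquisition model, and scores normalized D* histograms
(bins 0.05 µm²/s over 0–10) by summed squared difference.  The argmin is
refined by a parabolic fit through its two neighbours.  All candidates
reuse a common random-number stream (common random numbers), so the
score is a smooth function of the candidate parameter and the argmin is
not blurred by independent Monte Carlo noise per grid point; the same
variance reduction is applied to the Φ grid.  Raw-count vs
normalized histograms and the binning are not externally prescribed;
normalized counts on a fixed 0.05 grid were chosen once and are exposed
as parameters.

`estimate_phi` scans the bound-time fraction Φ (default grid 0–1, step
0.01) with interconverting molecules at (D_free, D_bound = 0.04, mean
bound dwell 1 ms), fits each simulated D* sample with the one-species
model exactly as the experimental mobile population is fitted, and
returns the Φ whose fitted D* crosses the experimental target, with
linear interpolation between the bracketing grid points.  The fitted D*
is monotone decreasing in Φ; targets outside the simulated range at
Φ = 0 / Φ = 1 raise an explicit out-of-range error.

`partition_states` converts the mixture fraction A and the matched Φ
into the three-state split (100·A, 100·Φ(1−A), 100·(1−Φ)(1−A)), which
sums to 100 exactly before rounding; `total_bound` gives
100·(A + Φ(1−A)).

## Mass scaling

`fit_power_law` fits log10(D_free) against log10(M) by unweighted
ordinary least squares — no weighting scheme is prescribed for the
5-point panel, and equal weights are the neutral choice.  The slope is
the exponent α; the intercept is kept at full precision and converted to
the c of D = (c·M)ᵅ for display (the two parameterizations are
redundant).  On the measured panel (MukB 1006 kDa/1.2, RNAP 478/2.7,
LacI 220/3.3, Pol1 128/6.6, LigA 102/6.9) the fit gives α = −0.744,
much steeper than the Stokes–Einstein −1/3: the crowded cytoplasm sieves
by size even without the chromosome.  `predict_dfree` evaluates the
fitted line (at a fitted mass it returns the line value, not the raw
datum).

## Chromosome occupancy

Occupied bp = Σ copies × (long-lived + transient bound fraction) ×
footprint, against a genome content of 6.9 Mb (1.5 chromosomes × 4.6 Mb
under slow growth; configurable).  Footprints: RNAP 70 bp, HU 36 bp,
H-NS 30 bp, gyrase 100 bp, 10 bp where no literature estimate exists.
Simple additivity — no steric-overlap correction.  The bundled panel
stores integer-rounded percentages, so its recomputed total (2.00 Mb,
29.0%) sits slightly above the value obtained from unrounded fractions
(≈ 1.96 Mb, 28%); the difference is pure rounding and both are inside
the tolerances used in the tests.

## Oscillation analysis

Kymographs stack per-frame 1D intensity profiles along the long cell
axis; per-frame normalization to total fluorescence removes
photobleaching (and any global intensity factor) exactly.  Half-cell
signals are trapezoidal integrals over [0, L/2] and [L/2, L] sharing the
midpoint, so they sum to the whole-cell integral.  The period comes from
fitting a·cos(ωt) + b·sin(ωt) to a mean-subtracted half-cell trace: a
coarse scan over periods 4–200 s (capped at half the record length so at
least two full periods are present), with (a, b) solved linearly at each
ω, followed by bounded local refinement.  If the best fit explains less
than 20% of the trace variance the result is "no oscillation detected"
(`NoOscillationError`) rather than a number.  The wavelength is the mean
spacing of consecutive minima of the lightly smoothed time-averaged
profile (Gaussian smoothing, default 0.2 µm, configurable); maxima are
used instead for non-filamentous cells.  Stripe handling follows the
most literal reading of splitting at profile minima.

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure that the estimators
rely on: sparse photoactivated tracks, confined Brownian motion with
motion blur, sub-frame two-state exchange, exponential bleaching,
Gaussian localization error, and (via `render_movie`) shot-noise-limited
spot images.  It does **not** model EM-gain/readout noise, fluorophore
blinking kinetics beyond the 1-frame linking memory, anomalous or
crowded diffusion, explicit 1D sliding along DNA polymers, hydrodynamics,
or cell-to-cell parameter variability.  Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to every artefact of real movies.

Test problem sizes were chosen to make the statistical assertions sharp
at desk scale: 10⁴ tracks for distributional checks, 2·10⁴ samples for
mixture recovery, 10⁴ tracks per grid point for bound-fraction matching.

## Known limitations

* The canonical spherocylinder population is a stand-in for measured
  cell outlines; with it, matching a mobile D* of 0.36 µm²/s at
  D_free = 2.7 returns Φ ≈ 0.83–0.84 — the geometry-substitution
  systematic of a few percentage points noted above.
* The mixture fit assumes exactly two gamma components with a common
  shape; confinement and blur distort the component shapes slightly, so
  A carries a small model bias quantified in the end-to-end tests.
* Memory-gap steps are excluded from D_i* rather than rescaled; tracks
  broken by more than one missed frame are split by construction.
* Absolute dwell times are not estimable from these data — only the
  bound-time fraction Φ.
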