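# Methods

This note records the models, estimators, parameter choices and known
limitations behind `actent`, in the spirit of a simulation package's model
documentation. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Bending-mode representation

Filament centerlines (ordered 2D points, μm) are resampled to uniform
arc-length spacing by linear interpolation and represented by the tangent
angle θ(s) of each segment. The mode basis is the free-free cosine series

θ(s) = Σₙ aₙ √(2/L) cos(nπs/L),  n ≥ 1,

the standard decomposition used in persistence-length analysis of
semi-flexible polymers. θ is measured relative to its per-frame mean, which
removes the n = 0 rigid-rotation mode and makes the amplitudes invariant
under rigid-body motion (verified to < 10⁻⁶ in the tests). Amplitudes are
computed by midpoint quadrature on the segment-midpoint angles; because
cos(nπ(j+½)/N) at the N segment midpoints is an exactly orthogonal family
(the DCT-II nodes), synthesis followed by decomposition round-trips to
machine precision on the retained subspace, not merely to a discretisation
tolerance. The basis convention is recorded as a tag on every
`ModeTrajectory`; amplitudes are only comparable within one convention.
Whether transverse-displacement modes would be preferable is left open — the
tag exists so either convention can be slotted in without ambiguity.

Bending energy deliberately does **not** reuse the mode representation:
κ(s) comes from Taubin algebraic circle fits to rolling windows of
`n_window = 5` points (non-iterative, nearly unbiased for shallow arcs;
collinear windows give κ = 0), points within n_window//2 of either end are
excluded, and E_bend = (EI/2)∫κ² ds is a trapezoidal integral over the
interior. The two routes agree within 5% at small amplitude, which is one
of the cross-checks in the suite. Default EI = 0.073 pN·μm² (literature
flexural rigidity of F-actin); it is a configuration value, not a constant
baked into results.

## Entropy production estimator

Mode trajectories are treated as realisations of an overdamped Langevin
process. The steady-state phase-space velocity is estimated by
coarse-graining: every consecutive frame pair contributes Δa/Δt to the bin
containing the pair midpoint (a(t)+a(t+Δt))/2; bins with fewer than
`min_count = 10` transitions carry no velocity. The grid spans ±4 sample
standard deviations per dimension with 12 bins per dimension by default.
The phase space is 2-dimensional (a₁, a₂) by default: binned velocity
estimation suffers the curse of dimensionality, and the first two modes
carry most of the bending variance; higher modes are available behind the
same configuration.

The entropy integral ΔS(t) = ∫ ȧᵀ D⁻¹ v^ss[a] dτ is discretised as a
Stratonovich sum — each step contributes (Δa)ᵀ D⁻¹ v^ss evaluated in the
midpoint bin. Itô evaluation would bias the estimator; the midpoint rule is
the discrete counterpart of the Stratonovich product in the continuous
definition. Steps landing in unoccupied or out-of-grid bins contribute zero
and are tracked in a coverage diagnostic (the induced bias is toward
underestimation); series with coverage below 50% are flagged low-confidence.

**Self-consistency debiasing.** When v^ss is estimated from the same data
it is integrated against, each step is statistically coupled to its own
contribution to the bin mean (a positive O(1/occupancy) bias per step) and
to temporally correlated same-bin steps (a negative O(tr A·dt) counterpart).
At equilibrium these couplings accumulate into a spurious entropy rate of
either sign. The estimator therefore evaluates v^ss
leave-one-trajectory-out by default: the integrated trajectory's own binned
displacement sums are subtracted from the field before evaluation, which is
exact and cheap (one `bincount` per trajectory). For fields built from a
single deterministic trajectory this exclusion would empty the bins, so it
is switchable (`exclude_self=False`), and the deterministic-orbit oracle
(ΔS rate = ω² for a circular orbit of angular frequency ω) uses that mode.

The diffusion matrix comes from slender-rod hydrodynamics: per-unit-length
transverse drag ζ⊥ = 4πη/(ln(L/d)+0.84) (the standard logarithmic slender-
body result with end correction), mode drag γ = ζ⊥L in the orthonormal
basis, D = (T/γ)·I. Defaults: η = 10⁻³ Pa·s (water), d = 7 nm, L from the
trajectory, natural units k_B = T = 1 (a physical k_BT can be supplied).
Mode-dependent drag corrections are not applied; for the intensive,
S1-normalized quantities reported downstream a scalar mis-scaling of D
cancels (ΔS is linear in D⁻¹ — the "scale contract" property test).

Per-filament entropies are divided by L, averaged at each time point over
the filaments present, and the cumulative sum of the means (times T) is the
ensemble dissipation curve. The detailed-fluctuation-theorem control
histograms entropy increments over fixed windows into bins symmetric about
zero and fits ln(N₊/N₋) against the bin center by weighted least squares
through the origin (weights from counting error); slope 1 within CI
indicates compliance. A Gaussian with variance twice its mean satisfies the
identity exactly and serves as the analytic anchor.

## Director fields, order parameter, defects

Images are divided into 3.5 μm windows with 50% overlap (the overlap
fraction is a convention choice; it halves the grid spacing). Each window
is mean-subtracted, tapered by a Gaussian of σ = window/6 px (suppresses
edge leakage), Fourier transformed, and the DC region (radius 2 px) masked.
The orientation of an oriented texture concentrates spectral power along
its wavevector, so the director is taken orthogonal to the axis of least
second moment of the power spectrum (from second-order central moments).
Angles are radians, counterclockwise from the image x-axis (x = column,
origin top-left), folded to [0, π). Windows with zero intensity variance
are undefined and excluded downstream.

The order parameter is q = 2⟨cos²Δθ − ½⟩ over the 8 neighbours of each
interior window in a 3×3 kernel, with Δθ the headless angle difference
folded to [0°, 90°]: q = 1 for perfect co-alignment, 0 at 45° differences
(the maximum expected in a quasi-2D network). Undefined neighbours are
excluded from the mean (the treatment of blanks is our choice); border
windows carry no q; ⟨q⟩ averages unweighted over defined windows (intensity
weighting is a possible alternative we do not apply).

Disclination defects are located by summing director-angle differences
(each wrapped to (−π/2, π/2]) around 2×2 plaquettes: winding ±π marks a
charge ±1/2 defect at the plaquette center; detections within one window
spacing merge to their centroid. The plaquette winding method and the merge
radius are this package's design — they are standard topology but not a
published detector.

Myosin thick filaments are counted as local intensity maxima
(non-maximum suppression at `min_distance_px`, absolute threshold) and the
count divided by the field area gives the areal density ρ.

## Spectra, flow, anisotropy

Fluctuation spectra are measured along 1D profiles oriented along the local
perpendicular axis ê⊥ at every window center (default length 10 μm, spacing
= the window grid spacing; both configurable). Density profiles sample the
image by linear interpolation; director profiles sample the angle grid
through its nematic tensor components, and the fluctuation is the signed
small-angle deviation from the profile's own mean director (δn of a unit
director is, to first order, the angle deviation along ê⊥). Each profile is
mean-subtracted and its one-sided periodogram S(k) = |FFT|²·Δx/N at
k = 2πf accumulated (Wiener–Khinchin: equivalent to transforming the
autocorrelation, better behaved at finite length); profiles shorter than 8
samples are dropped with counts logged; spectra are binned onto a common
k⊥ grid. With this normalization white noise of variance σ² sits at σ²Δx
and (1/π)ΣS·Δk recovers the variance (the Parseval check, within 5%). The
absolute normalization convention is recorded in the output metadata. No
active-gel model fitting is performed on the spectra.

PIV is a minimal single-pass estimator: each non-overlapping interrogation
window (default 32 px) is cross-correlated against the search-extended
region of the second frame (±8 px), the peak refined by three-point
parabolic interpolation (sub-pixel residuals ≲0.1 px; the accuracy contract
in the tests is 0.2 px). Flat-correlation windows are flagged invalid and
excluded from averages rather than interpolated. The strain rate
ψ(t) = ⟨∇·v⟩ uses central differences (one-sided at borders) over valid
vectors; classification: contractile if |ψ_max| > ψ_c = 2×10⁻³ s⁻¹ with
the signed value retained (contraction negative), stable otherwise, thermal
when flagged motor-free.

The anisotropic velocity autocorrelation
δC_vv(r) = ⟨C⊥(r,t)/C⊥(0,t) − C∥(r,t)/C∥(0,t)⟩ₜ projects each velocity
onto the local (ê∥, ê⊥) frame and correlates each component **along its own
axis** (⊥ along ê⊥, ∥ along ê∥). The defining formula does not fix the
separation direction; this choice matches the transverse-coherence
("plucking") interpretation and is recorded in output metadata. δC_vv(0) = 0
identically; bins with fewer than 10 valid pairs in a frame are omitted for
that frame.

## Synthetic data: what it emulates and what it does not

The generator produces every pipeline input with known ground truth:

- **Mode dynamics**: Euler–Maruyama integration of da = A a dt + √(2D) dW,
  initialised from the exact stationary distribution and preceded by a
  burn-in of 10 slowest relaxation times. A non-stable drift is refused;
  |λ_max|·dt > 0.1 warns of discretisation bias. Activity enters as an
  antisymmetric (nonreciprocal) drift coupling between mode pairs rather
  than an explicit motor model, because the linear process has closed-form
  oracles: stationary covariance from the Lyapunov equation
  AC + CAᵀ + 2D = 0, phase-space velocity v^ss(a) = (A + DC⁻¹)a, and
  entropy rate tr[(A+DC⁻¹)ᵀD⁻¹(A+DC⁻¹)C] (= 2α²/k for drift −kI + αJ and
  unit diffusion).
- **Shapes and images**: filament shapes from prescribed amplitudes (the
  exact inverse of the analysis basis), Gaussian-profile line renderings
  with additive noise, striped textures along prescribed director patterns,
  Gaussian spot stacks with prescribed per-frame counts (minimum mutual
  separation 4σ so counting is unambiguous at zero noise), and prescribed
  uniform/radial/shear velocity fields plus backward advection of tracer
  images for PIV ground truth. Uniform and checkerboard textures are sine
  gratings with the wavevector perpendicular to the director; around a
  half-integer defect no single-valued grating phase exists, so defect
  textures are built from short oriented line segments instead.
- **Three-state experiment** (`default_synthetic_config`): S0 is
  equilibrium (α = 0, T = 1, 2000 steps of dt = 0.01); S1 applies α = 1
  with the noise temperature ramping 1 → 3 while the myosin count ramps
  from zero to its peak (4000 steps); C reduces driving to α = 0.5 with
  temperature relaxing 3 → 2 while counts decay (3000 steps); 20 filaments
  of L = 10 μm. The temperature ramp makes the bending energy grow through
  S1 (variance tracks T/k); the α schedule fixes the dissipation ordering
  S1 > S0 = 0 and S1 > C by construction (rate 2α²T_eff/k under a scalar
  estimator D). These values were chosen once as a plausible emulation of
  motor accumulation; they are the study condition, not tuning knobs.

What the generator does **not** emulate: motor–filament binding kinetics,
filament turnover, severing, polarity sorting, steric interactions, defect
motion, photobleaching, or the spatial correlation between the image
channels and the tracked filaments (trace-based and image-based chains are
generated independently). Passing tests therefore demonstrate that the
estimators recover known ground truth under their own model assumptions —
linear mode dynamics, Gaussian noise, clean rendering — not that those
assumptions hold for any particular experimental system.

## Segmentation and slopes

The myosin density series is smoothed by a 5-frame moving average. S0 ends
at the first *sustained* exceedance (3 consecutive smoothed frames) of the
onset threshold, default 5% of the series maximum — the sustained rule
suppresses spurious onsets from baseline noise. C starts at the smoothed
density maximum (motor aggregation makes tracked counts fall, so the peak
marks contraction onset; its density is the ρ_c estimate). A series still
rising at its last frame has no C state (flagged); an all-zero series is
entirely S0. The boundaries are carried as absolute times so that one
segmentation per experiment serves both the dissipation and bending curves,
whatever their sampling grids. Slopes are unweighted OLS per state with ≥3
points, normalized to the S1 slope of the same experiment (undefined if the
S1 slope is 0, with raw slopes still reported). Dissipation/bending versus
density tables restrict to S1 frames, pair by interpolating the curve onto
the density time base, and optionally bin by ρ with mean ± sd.

## Numerical and reproducibility choices

- All stochastic components take integer seeds (numpy `default_rng`);
  identical configuration and seed reproduce results bit-for-bit, including
  the written artifact bundle (no timestamps in outputs; provenance records
  the configuration, package version and coverage diagnostics).
- Angle interpolation everywhere goes through the nematic tensor
  (cos 2θ, sin 2θ) to respect the headless π-periodicity; angle differences
  wrap to (−π/2, π/2].
- Degenerate inputs fail loudly and early: repeated trace points,
  non-monotonic frames, non-uniform spacing before decomposition, unstable
  drift matrices, under-occupied phase-space grids, one-sided DFT samples.
- Problem sizes in the default suite and acceptance script (20 trajectories
  × 10⁵ steps for the driven recovery, 8 independent 5-trajectory batches
  for the equilibrium control, 1500 thermal shapes for equipartition,
  ~200–300 profiles per spectrum, 90-frame density schedules) were chosen
  as the smallest ensembles at which the statistical tolerances (15% rate
  recovery, 10% equipartition, 20% half-power, CI-covers-zero) are
  comfortably resolved.
- The equilibrium control uses independent replicate batches, each with its
  own coarse-grained field, because trajectories sharing one field have
  correlated estimator errors and a naive per-trajectory CI undercovers.

## Known limitations

- The coarse-grained estimator is a lower bound in practice: unoccupied
  bins contribute zero, and coarse binning smooths v^ss; both push the
  recovered rate slightly below truth (the driven recovery sits a few
  percent under the closed form at the default resolution).
- Two phase-space dimensions capture only the entropy flowing through the
  first two bending modes.
- The single-pass PIV has no window deformation or multi-pass refinement;
  displacements approaching the search radius are censored, so frame
  intervals must keep displacements a few pixels at most.
- The FFT orientation estimator degrades for textures with features
  comparable to the window size; the defect detector reports any plaquette
  winding of ±π, so noisy director fields benefit from the kernel-q mask
  before interpretation.
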