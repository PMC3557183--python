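# Methods

## Physical setting and model

During external radiotherapy with photons above the photoneutron threshold
(~15–18 MeV), the (γ,n) reaction converts tissue ¹²C, ¹⁶O and ¹⁴N into the
positron emitters ¹¹C (T½ = 20.39 min), ¹⁵O (2.04 min) and ¹³N (9.97 min).
A dynamic PET acquisition begun a transport delay after beam-off measures,
in any volume of interest, the superposed physical decays.  With
perfusion-driven washout neglected (the tissues of interest — urine in the
bladder, subcutaneous fat — are effectively closed compartments on the
30-min scale, and no in-beam measurement is available to constrain washout
anyway) the count rate is

S(t) = Σₖ Sₖ·2^(−t/T½,ₖ) + K,  Sₖ ≥ 0, K ≥ 0,

with t in minutes from the end of irradiation.  The amplitudes are
*defined at beam-off*; the irradiation itself (several minutes of build-up
over sequential beams) is not modelled as a production ramp.  K absorbs
any stationary background; it is constrained non-negative because a
negative constant count rate has no physical meaning.

Time is minutes everywhere.  Elemental fractions are unit fractions (0..1)
internally; percent appears only at I/O boundaries.

## Frame averaging

A PET frame integrates coincidences over its interval, so the model is
fitted to *frame-averaged* rates, evaluated in closed form:

mean over [a,b] = Σₖ Sₖ·T½,ₖ/(ln2·(b−a))·(2^(−a/T½,ₖ) − 2^(−b/T½,ₖ)) + K.

With a 2.04-min half-life and 2-min frames the difference between the
frame average and the midpoint sample is material (~1% of the frame value
for the fast component), so generator and fitter share the averaging
convention; a property test checks the closed form against adaptive
quadrature to 1e−10 relative.

The default schedule is the study protocol: transport delay 7.0 min
(a configuration field, never hard-coded), then 15 frames of 2 min.  Frame
values are raw, decay-uncorrected rates; `decay_correct` maps a rate
measured Δt after the reference back to it via 2^(Δt/T½) when a
reference-time amplitude is needed.

## Estimation

The objective is the unweighted sum of squared residuals between observed
and predicted frame means.  Optional inverse-variance ("poisson")
weighting is available but not the default, since the baseline analysis
this package implements uses ordinary least squares.

**Fixed regime.**  With half-lives pinned, the frame-averaged exponentials
form a design matrix and the problem is non-negative linear least squares,
solved exactly by NNLS — a convex problem with a global optimum, no
multi-start, no starting values.  At least n_components + 2 frames are
required (5 for the default three components).

**Free regime.**  Estimating half-lives too is ill-conditioned (a classic
multi-exponential identifiability problem).  It is solved by bounded
nonlinear least squares (trust-region reflective) from a deterministic
multi-start grid: each component's starting half-life takes the physical
value scaled by {0.5, 1, 2} (27 starts for three components), and the
amplitudes and K are warm-started from the exact fixed solve at those
half-lives.  Lowest SSE wins; ties break toward fewer nonzero components.
Components are sorted by descending half-life so labelling is
deterministic across runs.  The half-life lower bound is 0.1 min: it
excludes the degenerate spike-at-zero solution, and nothing faster is
measurable on 2-min frames starting 7 min post-irradiation (e.g. the
0.86-s ³⁹Ca product of bone calcium is gone long before the scan).  A
component whose fitted amplitude is numerically zero is flagged
unidentified: its half-life carries no information.  At least
2·n_components + 1 frames are required (7 for three components).

An exhaustive `grid_search_oracle` (NNLS amplitude solve at every
combination of half-lives on a coarse grid) serves as an independent check
that the nonlinear optimizer is never beaten by brute force; it refuses
grids above a stated evaluation budget.

## Confidence intervals

95% intervals per free parameter, two methods (the choice is exposed
because the baseline analysis does not pin one down):

* **linearized** (default): covariance s²(JᵀJ)⁻¹ with s² the residual
  variance at n − p degrees of freedom and J the (analytic, for the fixed
  regime; numerical, for the free regime) Jacobian; t-based intervals.
  A Jacobian condition number above 1e12 flags the interval unreliable
  rather than raising.
* **bootstrap**: parametric, seeded, resampling from the fitted curve.
  The estimated noise is heteroscedastic counting noise — per-frame
  variance proportional to the fitted rate, the proportionality constant
  moment-matched to the residual sum of squares with a degrees-of-freedom
  correction — because PET frame rates are scaled Poisson counts and a
  homoscedastic resample badly misstates the information content of the
  early, high-rate frames.  The noise-scale estimate is itself redrawn
  per replicate from its chi-square sampling distribution, and intervals
  are studentized (bootstrap-t) and clipped to the feasible region.  Both
  choices matter at 15 frames: without them the intervals undercover by
  several points, with them simulated coverage at high counts sits within
  a few points of the nominal 95% (verified by a 500-replicate simulation
  in the test suite).

The fitters are scikit-learn estimators (`fit(X, y)` with X the
(n_frames, 2) frame bounds and y the mean rates, `predict`, `get_params`)
so they compose with sklearn model selection; `fit_fixed`/`fit_free` wrap
them for TAC objects.

## Composition comparison

Each identified component maps to its nuclide's parent element; free-mode
components are labelled by the nearest physical half-life within a 35%
relative tolerance, chosen so that realistically scattered estimates
(≈19–21 min for ¹¹C, ≈2 min for ¹⁵O) label correctly while a ³⁰P
contaminant (2.5 min, from bone phosphorus) deliberately falls in the ¹⁵O
window — the two are physically indistinguishable on this protocol.
Fractions outside every window are reported "unassigned".

The hydrogen adjustment drops ¹H and trace elements and renormalizes C, N
and O over their sum (¹H cannot become a positron emitter, so activation
measurements are blind to it).  The operation is idempotent and
scale-invariant; applied to the bundled raw mass fractions it reproduces
the standard adjusted values (adipose 67.7% C / 0.8% N / 31.5% O; bladder
contents 4.0% C / 1.7% N / 94.3% O).  Count-rate fractions are identified
with mass fractions directly, i.e. with unit per-element activation
yields: per-element yield weights (cross-section × spectrum effects) are
exposed as an option but no values are asserted.  The comparison report is
descriptive — per-element differences and CI-overlap flags, no hypothesis
test — because agreement here is a qualitative question.

## Synthetic data

The generator emulates the acquisition the analysis assumes and nothing
more.  A `SimulationSpec` names a tissue (bundled or explicit fractions),
optional yield weights and contaminant components, a background constant,
a schedule, and a noise mode.  Amplitudes are the hydrogen-adjusted
fractions (renormalized after yield weighting); noise, when enabled, is
Poisson on per-frame counts with expectation amplitude_scale × frame mean
× frame duration, returned as rates — Poisson rather than Gaussian because
the regime of interest is explicitly low-count (induced activity is a few
percent of a diagnostic FDG injection).  `amplitude_scale` defaults to
1e4 expected counts per unit-rate frame-minute, giving noise visibly
above machine precision yet mild enough for stable three-component fits;
the actual per-frame count level of a patient acquisition is not published,
so this is a package choice, not a measured value.  Washout is not
simulated.  The miniature phantom places a superficial slab (fat) and a
central block (bladder) in a ≤64³ grid with zero background, returning the
volume and both masks; it exists to exercise the image pipeline
(extraction, NIfTI round trip), not to model anatomy, scanner PSF or
scatter.

What passing tests on these data do show: the estimation chain is exact on
noiseless data, unbiased under Poisson noise at moderate counts, and its
interval estimates are calibrated under the generator's assumptions.  What
they do not show: robustness to washout, residual motion, reconstruction
artefacts, scatter/randoms residuals, or yield differences between
elements — none of which the generator emulates.

## Numerical choices and limitations

* Fixed-regime optimum is exact (NNLS); the free regime is only as global
  as its 27-point multi-start, which covers half-lives from ~1 to ~41 min
  around the physical values; components faster than 0.1 min are out of
  scope by design.
* An all-zero TAC short-circuits to the exact zero solution (fractions
  flagged undefined) instead of leaving 1e−12 optimizer residue.
* Amplitudes below 1e−9 of the data scale count as zero for
  identification; ties in the multi-start break toward sparser solutions.
* TAC CSV floats are written with `repr` precision so a write→read round
  trip is bit-exact; NIfTI-1 has no per-frame timing field, so frame
  bounds travel in a JSON sidecar next to the volume.
* Three-component free fits on noisy low-count data remain fragile —
  near-equal half-lives merge, and the merged component takes the label of
  the nearest physical nuclide.  This mirrors the physics (³⁰P vs ¹⁵O) but
  means free-mode compositions should be read with their CIs, not alone.
* The acceptance simulations use the study's own problem size (15 frames
  of 2 min, three components) and coverage runs of 500 replicates; these
  sizes are the package's standard regression conditions.
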