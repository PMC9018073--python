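# Methods

## Model and assumptions

The simulator is a one-dimensional kinetic Monte Carlo model of the
anaphase B spindle. All microtubules are straight and aligned with the
spindle axis; their transverse positions are bookkeeping indices on a
chequerboard lattice, not mechanical coordinates. Motors, crosslinker
molecules and force balance are not represented: pole sliding is an
imposed constant speed (2·v_s of total elongation), as is observed
experimentally, and microtubule growth and shrinkage speeds are
constants. There is no nucleation — anaphase B spindles only lose
microtubules.

Catastrophe is modelled as the completion of n independent exponential
sub-steps of rate θ, giving the growth-duration CDF
F(t) = (1 − e^(−θt))ⁿ with non-integer n allowed. Durations are drawn
by the closed-form inverse transform t = −ln(1 − u^(1/n))/θ, which is
exact, seedable and rejection-free; uniform draws of exactly 0 or 1 are
resampled to avoid infinities. The analytic mean at the wild-type
parameters (θ = 3.17 min⁻¹, n = 8.53) is 52.6 s with SD 23.4 s,
matching the measured 52 ± 23 s.

Rescue operates on a conserved budget R (µm/min) spread along the
antiparallel overlap in the midzone, a region of fixed length Lm
centred on the spindle, drawn once per run from a truncated normal
(µ = 1.23 µm, σ = 0.25 µm, resampled until > 0.2 µm). A shrinking
microtubule with n antiparallel 4-connected lattice neighbours is
rescued at rate r = n·R·P(x; α, β)/(Lm·N), with N the *current* total
antiparallel-pair count and P a Beta density of the reduced midzone
coordinate (0 at the edge nearest the microtubule's own pole). Summed
over microtubules and integrated over the midzone this is exactly 2R
for any α, β, N — the conservation law behind the model's central
behaviour: as microtubules are lost, the survivors share the same
budget and become more stable, and because the neighbours of a lost
microtubule are by construction of the opposite orientation, loss is
self-balancing between the poles. The uniform variant (emulating loss
of the midzone crosslinker) instead uses r = R/(2·L_t) anywhere on the
spindle, with L_t the total polymer; its budget integrates to R/2,
the factor 2 keeping the two variants consistent.

## Stepping rules and numerical choices

The timestep is h = 0.01 min. Within a step the order is fixed for
reproducibility: poles move; growing microtubules elongate and their
catastrophe clocks tick (catastrophe when the clock expires or the tip
reaches the opposite pole, where the length is clipped to the pole
separation); shrinking microtubules shorten, are removed at zero length
or tested for rescue with Bernoulli probability 1 − e^(−r·h); the
neighbour census is refreshed. Ordering effects between these
sub-updates are O(h) ≈ 0.036 µm of length per event and were not
considered worth a more elaborate scheme. Time and pole separation are
recomputed from the step index, so S(t) = S₀ + 2·v_s·t holds to machine
precision over the whole run. Collapse is declared when the longest
microtubules of the two poles no longer overlap, with a non-strict
comparison (zero overlap collapses: crosslinking needs finite overlap),
or when a pole holds no microtubules. Runs stop at collapse or at
t_max = 20 min.

After a loss the lattice reorganises greedily: any single microtubule
may move to any empty site (orientation unchanged) if the move strictly
increases the antiparallel-pair count; the best move is applied
(ties broken by lowest microtubule id, then row-major target site) and
the search repeats until no improving move remains. The acceptance rule
is the modelled biology; the greedy-until-convergence search order and
deterministic tie-breaks are implementation choices made for
reproducibility.

The Beta density is evaluated in closed form with a precomputed
normalisation; at x ∈ {0, 1} the limit value is used (0 for the α,β > 1
defaults). It is hand-coded rather than dispatched through
`scipy.stats` because it sits in the innermost loop (per shrinking
microtubule per step); scipy remains the oracle in the tests.

Ensembles derive per-run seeds as master seed + run index, so results
are independent of scheduling; parameter scans support both uniform
random sampling over the published ranges (R: 1–120 µm/min, v_p:
0.35–1.5 µm/min) and fixed grids for reproducible comparisons.

## Quantification

`bin_by_spindle_length` averages any paired quantity in 1-µm bins. The
intensity scaling factor minimising Σ(sᵢ − f·eᵢ)² has the closed form
f = Σsᵢeᵢ/Σeᵢ²; the printed form of the score admits a reciprocal
reading (sᵢ − eᵢ/f), which is the same fit under f → 1/f. The
Kolmogorov–Smirnov distance is computed directly from the two
empirical CDFs evaluated at every observed point.

`fit_piecewise_elongation` fits the three-phase elongation curve
G(t) (continuous, slopes s1/s2/s3, breakpoints t1 < t2; anaphase B
onset = t2). The model is linear in (L0, s1, s2, s3) given the
breakpoints, so those are profiled out by least squares and (t1, t2)
optimised by multi-start Nelder–Mead over a 7×7 grid of quantile
initialisations. Fits with collapsed or escaped breakpoints, or with
indistinguishable adjacent slopes (unidentifiable breakpoint), are
flagged unreliable rather than fixed by hand.

`fit_erf_transition` uses the four-parameter form
v(d) = v_fast − (v_fast − v_slow)·(1 + erf((d − d0)/w))/2 — two
plateaus, midpoint, width. The original analysis does not print its
functional form; this parameterisation is the natural one for a
two-state transition and the recovery tests use it end to end.
`fit_catastrophe_cdf` fits the empirical CDF to (1 − e^(−θt))ⁿ,
initialised by matching the first two moments (the mean²/variance
ratio depends on n only, solved by bisection) and refined with
`curve_fit`.

## Imaging

The spindle in a probability frame is the parabola y = a·x² in a frame
rotated by θ about (X0, Y0). The fit maximises
F = Σ Pᵢ²·exp(−|a·xᵢ² − yᵢ|/λ) over the pixels with P > 0.8, with
λ = 0.55 µm; the optimiser is multi-start Nelder–Mead initialised from
the probability-weighted centroid and principal axis (and from the
previous frame's trace when fitting a sequence). Curvature is held at
zero until a trace longer than 6 µm has been seen — short spindles are
straight — and the sequence is fitted strictly causally (earlier frames
are not re-fitted when curvature unlocks). An optional constraint
passes the curve through two supplied pole points, as used when a
strong pole marker is available.

Edges are the extreme arc-length projections of P > 0.6 pixels onto the
curve (nearest point on a dense polyline); length is the closed-form
arc length of the parabola between them. Intensity is sampled along
seven parallel curves (normal offsets −3..+3 px, total width 0.77 µm at
0.11 µm/px) at 1-px arc spacing with bilinear interpolation, and the
per-point median of two flanking 4-px bands (offsets ±4..±7 px) is
subtracted — making the measurement exactly invariant to additive
background and linear in signal amplitude. Kymographs take per-frame
maxima over the same ±3 px band and align rows on the centre of mass
of the temporal maximum projection. Coordinates are 0-based and
pixel-centred; arc length is signed from the trace midpoint. Traces
touching the frame border are clipped rather than rejected.

## Synthetic data

Generators produce the inputs the analysis consumes, each returning
its ground truth: three-phase elongation series; event tables with
two-state speeds (plateaus 1.60 / 0.67 µm/min, distances uniform over
0.5–5 µm, the plotted range of the measurements), catastrophe-sampled
durations and Beta-field rescue positions mapped onto [−Lm/2, +Lm/2];
probability movies rendered as a Gaussian ridge (σ = 0.7 px) along the
scheduled curve with pole spots at the tips, profile widths chosen so
the P > 0.6 boundary coincides with the scheduled spindle extent to
within a pixel; and intensity series equal to polymer/f plus noise.
Noise is Gaussian everywhere and configurable. The generators emulate
the statistical structure of the real data — not point-spread
functions, camera noise, photobleaching or out-of-focus light — so
passing round-trip tests demonstrates correctness of the fitters on
data satisfying the model's assumptions, not robustness to every
microscopy artefact.

## Problem sizes and defaults

The shipped defaults are the study conditions: wild-type ensembles of
500 runs at R = 55 µm/min, α = 4, β = 2, v_p = 1.6 µm/min; scan and
variant comparisons at 200 runs per condition; 10⁵ draws for sampler
statistics; 5,000 durations for catastrophe-fit recovery; 8-frame
72×72 px movies for the imaging round trips. A full 20-min wild-type
run is ~2,000 steps and takes ~20 ms, so the complete ensemble suite
runs on a laptop in about a minute.

## Known limitations

The model is 1-D with a fixed midzone length per run; midzone dynamics,
bending, motor force balance and nucleation are out of scope. The
uniform-rescue variant changes the rescue geometry and the catastrophe
parameters together (as its dedicated parameter set specifies); the
alternative reading of that parameter pair (θ = 6.8 min⁻¹, n = 2.5) is
reachable through explicit configuration. Whether N in the rescue rate
should be the initial or the current pair count is not observable
directly; the current count is used (it is what keeps the budget
conserved as microtubules are lost), and the initial-count alternative
can be emulated only by freezing the lattice. The trace fitter is a
local optimiser: on probability maps with several bright structures it
needs the warm start from the previous frame or pole-point constraints
to stay on the spindle.
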