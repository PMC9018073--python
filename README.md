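# spindlesim

Stochastic modelling and quantification of the anaphase B spindle in
fission yeast.

During anaphase B the mitotic spindle elongates as motor proteins slide
apart the antiparallel interpolar microtubules that overlap in the
spindle midzone. Each microtubule undergoes dynamic instability —
stochastic switching between growth and shrinkage — so the spindle
survives only if shrinking microtubules are rescued before the overlap
between the two half-spindles is lost. `spindlesim` implements a
one-dimensional kinetic Monte Carlo model of this process in which a
*conserved budget of rescue factor* (CLASP, recruited to the midzone by
the PRC1-family crosslinker Ase1) is distributed along the midzone
overlap and concentrated at the midzone edges, together with the
statistics used to compare such a model with kymograph measurements and
the image-analysis math used to produce those measurements from
microscopy movies.

## The model

Two poles at ±S/2 separate at constant speed, S(t) = S₀ + 2·v_s·t.
Nine microtubules start on a 3×3 transverse chequerboard (5 from one
pole, 4 from the other) so that every 4-connected lattice contact is
antiparallel. Each microtubule grows at v_p or shrinks at v_d; the time
spent growing has CDF

    F(t) = (1 − e^(−θt))ⁿ        (θ = 3.17 min⁻¹, n = 8.53 wild type)

the distribution of the maximum of n independent exponential clocks —
catastrophe behaves as a multi-step process. A shrinking microtubule
whose plus end lies inside the midzone (a region of fixed length Lm
centred on the spindle) is rescued at rate

    r = n·R·P(x; α, β) / (Lm·N)

where n is its current number of antiparallel lattice neighbours, N the
total antiparallel pair count, R the conserved rescue budget and
P(x; α, β) a Beta density of the reduced midzone coordinate x (0 at the
edge nearest the microtubule's own pole). Integrated over all
microtubules and the midzone the total rescue activity is exactly 2R,
whatever α, β or N — losing microtubules makes the survivors more
stable, which drives even microtubule loss from both poles and prevents
spindle collapse. A uniform-rescue variant (r = R/(2·L_t) anywhere on
the spindle) emulates deletion of the crosslinker; those spindles
mostly collapse.

The quantification half of the package provides the three-phase
piecewise-linear spindle-elongation fit (anaphase B onset = second
breakpoint), the error-function fit of growth speed versus
distance-to-pole (fast/slow plateaus 1.60 / 0.67 µm/min), the
catastrophe-CDF fit, 1-µm binning with a closed-form intensity scaling
factor, and the Kolmogorov–Smirnov distance. The imaging half fits a
rotated parabola to pixel-probability maps, measures spindle edges,
length and background-subtracted intensity, and builds kymographs.
Synthetic-data generators (with ground truth) stand in for the
microscopy data, so the full pipeline is testable offline.

## Worked example

```sh
python examples/ensemble_stability.py
```

prints

```
wild type:   0.00 collapse fraction (0/100 runs), mean microtubule count at 15 min: 5.8
uniform rescue: 1.00 collapse fraction (100/100 runs)
  spindle length at collapse: 6.7 +/- 1.2 um (collapse before reaching the typical ~14 um final length)
```

With the rescue budget concentrated at the midzone edges (R = 55
µm/min, α = 4, β = 2) no spindle collapses in 20 simulated minutes and
roughly five of the nine microtubules remain at 15 min; spreading the
same kind of budget uniformly along the microtubules (R = 34 µm/min)
makes every spindle lose its antiparallel overlap early, at spindle
lengths far below the typical final length. The other example scripts
cover a single run with its simulated kymograph
(`single_run_and_kymograph.py`), fitter round trips on synthetic event
tables (`fit_growth_statistics.py`) and trace fitting on a synthetic
probability movie (`trace_synthetic_movie.py`).

A thin CLI wraps the same functions:

```sh
spindle simulate --seed 1 --out out/       # event log + length series
spindle ensemble --n-runs 100 --seed 1 --out out/
spindle scan --name R --n-points 10 --n-runs 50 --seed 1 --out out/
spindle kymo --seed 1 --out out/           # kymograph TIFF
```

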