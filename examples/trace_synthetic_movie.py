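"""Fit spindle traces to a synthetic probability movie and build a
kymograph.

The movie shows an elongating, slightly curved spindle rendered as a
probability map (pixel-classifier output). The trace fitter maximises a
probability-weighted functional of a rotated parabola, edges come from
projecting P > 0.6 pixels onto the curve, and the kymograph samples
intensity within 3 px of the trace.
"""
import numpy as np

from spindlesim import (ProbabilityFrame, build_kymograph, fit_spindle_trace,
                        gen_probability_movie, measure_trace_edges_and_length)

movie, truth = gen_probability_movie(seed=5)
true_lengths = truth.latents["lengths_um"]

traces, prev = [], None
for frame in movie:
    pf = ProbabilityFrame(frame)
    tr = fit_spindle_trace(pf, previous=prev)
    tr = measure_trace_edges_and_length(pf, tr)
    traces.append(tr)
    prev = tr

measured = np.array([t.length for t in traces])
print("frame  true length (um)  measured (um)")
for i, (lt, lm) in enumerate(zip(true_lengths, measured)):
    print(f"{i:>5}  {lt:>16.2f}  {lm:>13.2f}")
print(f"max |error|: {np.abs(measured - true_lengths).max():.3f} um "
      "(within 2 px = 0.22 um)")
print("curvature is held at 0 until the spindle passes 6 um: "
      f"a_curv by frame = {[round(t.a_curv, 4) for t in traces]}")

kymo = build_kymograph(list(movie), traces)
print(f"kymograph: {kymo.data.shape[0]} frames x {kymo.data.shape[1]} "
      "columns, aligned on the centre of mass of the temporal maximum")
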