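"""Synthetic-data generators with ground truth.

Each generator emulates one class of input the analysis consumes —
three-phase spindle-elongation series, two-state growth-event tables,
probability-map movies of a curved spindle, and intensity-versus-polymer
series — and returns the data together with a :class:`GroundTruth`
record of every generating parameter and latent value, so fitters can
be validated by round trip. All generators are deterministic functions
of (parameters, seed); noise is Gaussian throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .imaging import DEFAULT_PIXEL_SIZE, SpindleTrace
from .quantify import erf_transition, piecewise_elongation
from .simulation import sample_growth_duration

__all__ = ["GroundTruth", "gen_elongation_series", "gen_event_table",
           "gen_probability_movie", "gen_intensity_series",
           "render_trace_frame"]


@dataclass
class GroundTruth:
    generator: str
    params: dict[str, Any]
    seed: int
    latents: dict[str, Any] = field(default_factory=dict)


def gen_elongation_series(L0: float = 2.0, s1: float = 0.25,
                          s2: float = 1.2, s3: float = 0.7,
                          t1: float = 8.0, t2: float = 14.0,
                          noise_sd: float = 0.05, dt: float = 0.25,
                          T: float = 35.0, seed: int = 0
                          ) -> tuple[np.ndarray, GroundTruth]:
    """Three-phase spindle length vs time: slow prophase elongation,
    faster metaphase/anaphase A, then anaphase B, with additive Gaussian
    noise. Returns an (n, 2) array of (t, length) and the truth."""
    if not 0 < t1 < t2 < T:
        raise ValueError("need 0 < t1 < t2 < T")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, T + dt / 2, dt)
    clean = piecewise_elongation(t, L0, t1, t2, s1, s2, s3)
    y = clean + rng.normal(0.0, noise_sd, size=t.size) if noise_sd > 0 else clean.copy()
    truth = GroundTruth("elongation_series",
                        dict(L0=L0, s1=s1, s2=s2, s3=s3, t1=t1, t2=t2,
                             noise_sd=noise_sd, dt=dt, T=T),
                        seed, latents={"clean": clean})
    return np.column_stack([t, y]), truth


def gen_event_table(v_fast: float = 1.60, v_slow: float = 0.67,
                    d0: float = 2.5, w: float = 0.6,
                    theta_cat: float = 3.17, n_cat: float = 8.53,
                    alpha: float = 4.0, beta: float = 2.0,
                    Lm: float = 1.23, n_events: int = 400,
                    noise_sd: float = 0.1,
                    d_range: tuple[float, float] = (0.5, 5.0),
                    seed: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """Table of microtubule growth events with the field's structure.

    Per event: distance of the rescue site to the closest pole (uniform
    over ``d_range``), growth speed from the two-state error-function
    curve (fast ~1.60, slow ~0.67 µm/min) plus Gaussian noise, growth
    duration from the multi-step catastrophe distribution, and a signed
    rescue position drawn from the Beta(alpha, beta) rescue field mapped
    onto [-Lm/2, +Lm/2] (positive side = distal midzone edge).
    """
    rng = np.random.default_rng(seed)
    d = rng.uniform(*d_range, size=n_events)
    speed_clean = erf_transition(d, v_fast, v_slow, d0, w)
    speed = speed_clean + (rng.normal(0.0, noise_sd, size=n_events)
                           if noise_sd > 0 else 0.0)
    durations = np.array([sample_growth_duration(theta_cat, n_cat, rng)
                          for _ in range(n_events)])
    x = rng.beta(alpha, beta, size=n_events)
    pos_signed = (x - 0.5) * Lm
    table = pd.DataFrame({
        "distance_to_pole_um": d,
        "growth_speed_um_min": speed,
        "duration_min": durations,
        "pos_signed_um": pos_signed,
    })
    truth = GroundTruth("event_table",
                        dict(v_fast=v_fast, v_slow=v_slow, d0=d0, w=w,
                             theta_cat=theta_cat, n_cat=n_cat, alpha=alpha,
                             beta=beta, Lm=Lm, n_events=n_events,
                             noise_sd=noise_sd, d_range=d_range),
                        seed,
                        latents={"speed_clean": speed_clean, "x_reduced": x})
    return table, truth


def render_trace_frame(shape: tuple[int, int], trace: SpindleTrace,
                       length_um: float, ridge_sigma: float = 0.7,
                       spot_sigma: float = 0.7, spot_gain: float = 0.5
                       ) -> np.ndarray:
    """Render a probability frame: a ridge of probability ~1 along the
    parabolic trace over the given arc length (µm), with a brighter
    spot at each end (the pole bodies). Values are clipped to [0, 1]."""
    half_px = 0.5 * length_um / trace.pixel_size
    xpar = trace.x_of_arc(np.linspace(-half_px, half_px, 600),
                          x_span=half_px + 4.0)
    cx, cy = trace.curve_points(xpar)
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    d2 = ((xs.ravel()[:, None] - cx[None, :]) ** 2
          + (ys.ravel()[:, None] - cy[None, :]) ** 2).min(axis=1)
    img = np.exp(-d2 / (2.0 * ridge_sigma ** 2)).reshape(shape)
    for tip in (cx[0], cy[0]), (cx[-1], cy[-1]):
        d2s = (xs - tip[0]) ** 2 + (ys - tip[1]) ** 2
        img += spot_gain * np.exp(-d2s / (2.0 * spot_sigma ** 2))
    return np.clip(img, 0.0, 1.0)


def gen_probability_movie(trace_schedule: list[SpindleTrace] | None = None,
                          length_schedule=None,
                          noise_sd: float = 0.0,
                          frame_shape: tuple[int, int] = (72, 72),
                          pixel_size: float = DEFAULT_PIXEL_SIZE,
                          seed: int = 0
                          ) -> tuple[np.ndarray, GroundTruth]:
    """Movie of probability maps of an elongating, gently curved spindle.

    By default the spindle elongates from 4 to 7 µm over 8 frames while
    rotated 20° in the image, straight below 6 µm and curving beyond.
    Supplying explicit ``trace_schedule`` (SpindleTrace per frame) and
    ``length_schedule`` (µm per frame) overrides the default. Additive
    Gaussian noise is clipped back into [0, 1].
    """
    if (trace_schedule is None) != (length_schedule is None):
        raise ValueError("supply both schedules or neither")
    if trace_schedule is None:
        length_schedule = np.linspace(4.0, 7.0, 8)
        cx, cy = (frame_shape[1] - 1) / 2, (frame_shape[0] - 1) / 2
        trace_schedule = [
            SpindleTrace(cx, cy, np.deg2rad(20.0),
                         0.004 if L > 6.0 else 0.0, pixel_size)
            for L in length_schedule
        ]
    if len(trace_schedule) != len(length_schedule):
        raise ValueError("schedules must have the same length")
    rng = np.random.default_rng(seed)
    frames = []
    for tr, L in zip(trace_schedule, length_schedule):
        img = render_trace_frame(frame_shape, tr, float(L))
        if noise_sd > 0:
            img = np.clip(img + rng.normal(0.0, noise_sd, size=img.shape),
                          0.0, 1.0)
        frames.append(img)
    truth = GroundTruth("probability_movie",
                        dict(noise_sd=noise_sd, frame_shape=frame_shape,
                             pixel_size=pixel_size),
                        seed,
                        latents={"traces": trace_schedule,
                                 "lengths_um": np.asarray(length_schedule,
                                                          dtype=float)})
    return np.stack(frames), truth


def gen_intensity_series(polymer, spindle_length, f_true: float = 3.0,
                         noise_sd: float = 0.0, seed: int = 0
                         ) -> tuple[np.ndarray, GroundTruth]:
    """Fluorescence-intensity series proportional to polymer mass.

    Intensity = polymer / f_true + Gaussian noise, paired with spindle
    length, emulating total-tubulin intensity measurements whose scale
    factor the comparison machinery must recover.
    """
    if f_true <= 0:
        raise ValueError("f_true must be > 0")
    polymer = np.asarray(polymer, dtype=float)
    spindle_length = np.asarray(spindle_length, dtype=float)
    rng = np.random.default_rng(seed)
    intensity = polymer / f_true
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.size)
    truth = GroundTruth("intensity_series",
                        dict(f_true=f_true, noise_sd=noise_sd), seed,
                        latents={"clean": polymer / f_true})
    return np.column_stack([spindle_length, intensity]), truth
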