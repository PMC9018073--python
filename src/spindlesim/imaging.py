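"""Image-analysis math for spindle movies.

Works on per-frame pixel probability maps (output of a pixel
classifier: values in [0, 1], high where a pixel likely belongs to the
spindle) and on fluorescence frames. The spindle in a frame is modelled
as a parabola ``g(x) = alpha * x**2`` in a rotated coordinate frame
centred at (X0, Y0): the fit maximises a probability-weighted functional
of the distance to the curve, edges are found by projecting
high-probability pixels onto the curve, intensity is integrated along
seven parallel offset curves with median-of-flanking-bands background
subtraction, and kymographs are built by taking maxima within 3 px of
the trace at 1-px arc spacing.

Pixel coordinates are 0-based and pixel-centred, with X along columns
and Y along rows; arc length is signed from the trace midpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize

__all__ = ["ProbabilityFrame", "SpindleTrace", "IntensityMeasurement",
           "Kymograph", "NoSpindleError", "fit_spindle_trace",
           "measure_trace_edges_and_length", "measure_spindle_intensity",
           "build_kymograph", "DEFAULT_PIXEL_SIZE", "LAMBDA_WIDTH_UM"]

DEFAULT_PIXEL_SIZE = 0.11   # µm per pixel
LAMBDA_WIDTH_UM = 0.55      # characteristic width of the fit functional
FIT_THRESHOLD = 0.8         # pixels used for trace fitting
EDGE_THRESHOLD = 0.6        # pixels used for edge determination
STRAIGHT_CUTOFF_UM = 6.0    # curvature stays frozen at 0 below this length


class NoSpindleError(ValueError):
    """Raised when a frame has no pixel above the fit threshold."""


@dataclass
class ProbabilityFrame:
    data: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.clip(np.asarray(self.data, dtype=float), 0.0, 1.0)
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be > 0")

    def thresholded(self, threshold: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X, Y, P) of pixels above threshold inside the mask."""
        sel = self.data > threshold
        if self.mask is not None:
            sel &= self.mask.astype(bool)
        ys, xs = np.nonzero(sel)
        return xs.astype(float), ys.astype(float), self.data[ys, xs]


@dataclass
class SpindleTrace:
    """Rotated-parabola spindle model, in pixel units.

    The lab point (X, Y) maps to curve coordinates (x, y) by
    translation to (X0, Y0) followed by rotation by ``theta_rot``; the
    spindle lies along ``y = a_curv * x**2``.
    """

    X0: float
    Y0: float
    theta_rot: float
    a_curv: float
    pixel_size: float = DEFAULT_PIXEL_SIZE
    lambda_w: float = LAMBDA_WIDTH_UM
    edge_s: tuple[float, float] | None = None   # arc-length coords, px
    length: float = 0.0                          # µm
    F_value: float = field(default=0.0, compare=False)

    def to_curve_frame(self, X, Y) -> tuple[np.ndarray, np.ndarray]:
        c, s = math.cos(self.theta_rot), math.sin(self.theta_rot)
        dX = np.asarray(X, dtype=float) - self.X0
        dY = np.asarray(Y, dtype=float) - self.Y0
        return c * dX - s * dY, s * dX + c * dY

    def to_lab_frame(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        c, s = math.cos(self.theta_rot), math.sin(self.theta_rot)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return self.X0 + c * x + s * y, self.Y0 - s * x + c * y

    def arc_length(self, x) -> np.ndarray:
        """Signed arc length s(x) along y = a*x^2 from x = 0 (closed
        form antiderivative of sqrt(1 + (2 a x)^2))."""
        x = np.asarray(x, dtype=float)
        a = self.a_curv
        if a == 0.0:
            return x.copy()
        u = 2.0 * a * x
        return 0.5 * x * np.sqrt(1.0 + u * u) + np.arcsinh(u) / (4.0 * a)

    def x_of_arc(self, s, x_span: float) -> np.ndarray:
        """Invert s(x) by interpolation on a dense grid."""
        grid = np.linspace(-x_span, x_span, 4001)
        return np.interp(np.asarray(s, dtype=float), self.arc_length(grid), grid)

    def curve_points(self, x) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        return self.to_lab_frame(x, self.a_curv * x * x)

    def normal(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Unit normal of the curve at parameter x, in lab coordinates."""
        x = np.asarray(x, dtype=float)
        tx = np.ones_like(x)
        ty = 2.0 * self.a_curv * x
        norm = np.hypot(tx, ty)
        nx, ny = -ty / norm, tx / norm
        c, s = math.cos(self.theta_rot), math.sin(self.theta_rot)
        return c * nx + s * ny, -s * nx + c * ny


@dataclass
class IntensityMeasurement:
    total: float
    n_points: int
    signal_width_um: float
    background_band_px: int
    central_window_um: float | None


@dataclass
class Kymograph:
    data: np.ndarray               # (n_frames, n_cols)
    offsets: np.ndarray            # per-frame integer column offset applied
    pixel_size: float
    frame_interval: float = 1.0    # min


def _functional(xs, ys, ps, X0, Y0, theta, alpha, lam_px) -> float:
    c, s = math.cos(theta), math.sin(theta)
    dX = xs - X0
    dY = ys - Y0
    x = c * dX - s * dY
    y = s * dX + c * dY
    return float(np.sum(ps * ps * np.exp(-np.abs(alpha * x * x - y) / lam_px)))


def fit_spindle_trace(frame: ProbabilityFrame,
                      previous: SpindleTrace | None = None,
                      pole_points: tuple[tuple[float, float], tuple[float, float]] | None = None,
                      allow_curvature: bool | None = None) -> SpindleTrace:
    """Fit the rotated-parabola trace to one probability frame.

    Maximises ``F = sum_i P_i^2 * exp(-|a*x_i^2 - y_i| / lambda)`` over
    (X0, Y0, theta, a) using the pixels with P > 0.8, where lambda is
    the characteristic width (0.55 µm) in pixels. The optimiser is a
    multi-start Nelder-Mead initialised from the probability-weighted
    centroid and principal axis of the thresholded pixels, and from the
    previous frame's trace when supplied. Curvature is held at zero
    until a trace longer than 6 µm has been seen in the sequence
    (short spindles are straight); passing ``allow_curvature`` overrides
    that rule. If two pole points are supplied, the curve is constrained
    to pass through both (X0, Y0 and theta then follow from them and
    only the curvature is optimised).
    """
    xs, ys, ps = frame.thresholded(FIT_THRESHOLD)
    if xs.size == 0:
        raise NoSpindleError("no pixel above probability 0.8")
    lam_px = LAMBDA_WIDTH_UM / frame.pixel_size

    if allow_curvature is None:
        allow_curvature = previous is not None and previous.length > STRAIGHT_CUTOFF_UM

    if pole_points is not None:
        (xa, ya), (xb, yb) = pole_points
        X0, Y0 = 0.5 * (xa + xb), 0.5 * (ya + yb)
        theta0 = -math.atan2(yb - ya, xb - xa)
        if not allow_curvature:
            tr = SpindleTrace(X0, Y0, theta0, 0.0, frame.pixel_size)
            tr.F_value = _functional(xs, ys, ps, X0, Y0, theta0, 0.0, lam_px)
            return tr
        # constrained through both poles: for the pole separation 2*xh in
        # the rotated frame, y(+-xh)=a*xh^2 must vanish -> only a free
        # after shifting Y0 by -a*xh^2 along the normal; optimise a alone
        xh = 0.5 * math.hypot(xb - xa, yb - ya)

        def neg_f_a(p):
            a = p[0]
            c, s = math.cos(theta0), math.sin(theta0)
            # shift centre so the parabola passes through the poles
            Xc = X0 + s * (-a * xh * xh)
            Yc = Y0 + c * (-a * xh * xh)
            return -_functional(xs, ys, ps, Xc, Yc, theta0, a, lam_px)

        res = optimize.minimize(neg_f_a, [0.0], method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-10})
        a = float(res.x[0])
        c, s = math.cos(theta0), math.sin(theta0)
        tr = SpindleTrace(X0 + s * (-a * xh * xh), Y0 + c * (-a * xh * xh),
                          theta0, a, frame.pixel_size)
        tr.F_value = -res.fun
        return tr

    # principal-axis initialisation from weighted moments
    w = ps * ps
    mx, my = np.average(xs, weights=w), np.average(ys, weights=w)
    cov = np.cov(np.vstack([xs, ys]), aweights=w)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    major = evecs[:, int(np.argmax(evals))]
    theta0 = -math.atan2(major[1], major[0])

    starts = [np.array([mx, my, theta0, 0.0])]
    if previous is not None:
        starts.append(np.array([previous.X0, previous.Y0,
                                previous.theta_rot, previous.a_curv]))

    def neg_f(p):
        X0, Y0, theta, a = p
        if not allow_curvature:
            a = 0.0
        return -_functional(xs, ys, ps, X0, Y0, theta, a, lam_px)

    best = None
    for p0 in starts:
        res = optimize.minimize(neg_f, p0, method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-9,
                                         "maxiter": 3000, "maxfev": 5000})
        if best is None or res.fun < best.fun:
            best = res
    X0, Y0, theta, a = best.x
    if not allow_curvature:
        a = 0.0
    tr = SpindleTrace(float(X0), float(Y0), float(theta), float(a),
                      frame.pixel_size)
    tr.F_value = -best.fun
    return tr


def measure_trace_edges_and_length(frame: ProbabilityFrame,
                                   trace: SpindleTrace) -> SpindleTrace:
    """Locate the spindle edges on the fitted curve and measure length.

    All pixels with P > 0.6 are projected onto the parabola (nearest
    point on a dense polyline); the edges are the extreme arc-length
    projections and the length is the arc length of the curve between
    them (closed-form quadrature of sqrt(1 + g'(x)^2)), converted to µm.
    Returns a copy of the trace with ``edge_s`` and ``length`` set;
    empty projections give zero length and ``edge_s = None``.
    """
    xs, ys, _ = frame.thresholded(EDGE_THRESHOLD)
    if xs.size == 0:
        return replace(trace, edge_s=None, length=0.0)
    x, y = trace.to_curve_frame(xs, ys)
    span = float(max(np.abs(x).max(), 1.0)) + 2.0
    grid = np.linspace(-span, span, 2001)
    gx, gy = grid, trace.a_curv * grid * grid
    # nearest polyline vertex for each projected pixel
    d2 = (x[:, None] - gx[None, :]) ** 2 + (y[:, None] - gy[None, :]) ** 2
    nearest = grid[np.argmin(d2, axis=1)]
    s = trace.arc_length(nearest)
    s_lo, s_hi = float(s.min()), float(s.max())
    length_um = (s_hi - s_lo) * frame.pixel_size
    return replace(trace, edge_s=(s_lo, s_hi), length=length_um)


def _sample(image: np.ndarray, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Bilinear interpolation at (X, Y) pixel-centre coordinates."""
    return ndimage.map_coordinates(np.asarray(image, dtype=float),
                                   np.vstack([Y.ravel(), X.ravel()]),
                                   order=1, mode="nearest").reshape(X.shape)


def _arc_points(trace: SpindleTrace, s_lo: float, s_hi: float,
                spacing: float = 1.0) -> np.ndarray:
    n = max(int(math.floor((s_hi - s_lo) / spacing)) + 1, 2)
    s = s_lo + spacing * np.arange(n)
    span = abs(s_lo) + abs(s_hi) + 2.0
    return trace.x_of_arc(s, x_span=span)


def measure_spindle_intensity(image: np.ndarray, trace: SpindleTrace,
                              central_window: float | None = None
                              ) -> IntensityMeasurement:
    """Background-subtracted total intensity along the spindle.

    Samples seven parallel curves (normal offsets -3..+3 px, total width
    0.77 µm at 0.11 µm/px) at 1-px arc spacing between the trace edges.
    The background at each arc position is the median of two flanking
    4-px-wide bands (offsets ±4..±7 px) and is subtracted per sample
    point; the total is the sum over the signal region. An optional
    central window (µm, centred on the trace midpoint between the
    edges) restricts the measurement, as used for midzone-protein
    density.
    """
    if trace.edge_s is None:
        raise ValueError("trace has no edges; run edge measurement first")
    s_lo, s_hi = trace.edge_s
    if central_window is not None:
        mid = 0.5 * (s_lo + s_hi)
        half = 0.5 * central_window / trace.pixel_size
        s_lo, s_hi = max(s_lo, mid - half), min(s_hi, mid + half)
    xpar = _arc_points(trace, s_lo, s_hi)
    cx, cy = trace.curve_points(xpar)
    nx, ny = trace.normal(xpar)

    def band(offsets: np.ndarray) -> np.ndarray:
        X = cx[None, :] + offsets[:, None] * nx[None, :]
        Y = cy[None, :] + offsets[:, None] * ny[None, :]
        return _sample(image, X, Y)

    signal = band(np.arange(-3.0, 4.0))                    # (7, n)
    bg_off = np.concatenate([np.arange(-7.0, -3.0), np.arange(4.0, 8.0)])
    background = np.median(band(bg_off), axis=0)           # per arc point
    total = float(np.sum(signal - background[None, :]))
    return IntensityMeasurement(total=total, n_points=cx.size,
                                signal_width_um=7 * trace.pixel_size,
                                background_band_px=4,
                                central_window_um=central_window)


def build_kymograph(frames: list[np.ndarray], traces: list[SpindleTrace],
                    pixel_size: float = DEFAULT_PIXEL_SIZE,
                    frame_interval: float = 1.0) -> Kymograph:
    """Assemble a kymograph from per-frame images and fitted traces.

    Each frame contributes one row: the maximum intensity over pixels
    within 3 px of the trace, sampled at 1-px arc spacing (maximum over
    normal offsets -3..+3 px). Rows are aligned so that the centre of
    mass of the temporal maximum projection sits at the centre column.
    """
    if len(frames) != len(traces):
        raise ValueError("one trace per frame required")
    rows = []
    for img, tr in zip(frames, traces):
        if tr.edge_s is None:
            raise ValueError("traces must carry edges")
        s_lo, s_hi = tr.edge_s
        xpar = _arc_points(tr, s_lo, s_hi)
        cx, cy = tr.curve_points(xpar)
        nx, ny = tr.normal(xpar)
        offs = np.arange(-3.0, 4.0)
        X = cx[None, :] + offs[:, None] * nx[None, :]
        Y = cy[None, :] + offs[:, None] * ny[None, :]
        prof = _sample(img, X, Y).max(axis=0)
        # arc coordinate of each sample relative to the trace midpoint
        s_mid = 0.5 * (s_lo + s_hi)
        cols = np.round(s_lo + np.arange(prof.size) - s_mid).astype(int)
        rows.append((cols, prof))

    half = max(max(abs(c.min()), abs(c.max())) for c, _ in rows) + 1
    width = 2 * half + 1
    canvas = np.zeros((len(rows), width))
    for i, (cols, prof) in enumerate(rows):
        canvas[i, cols + half] = prof

    # centre-of-mass alignment on the temporal max projection
    profile = canvas.max(axis=0)
    if profile.sum() > 0:
        com = float(np.sum(np.arange(width) * profile) / profile.sum())
        shift = int(round(width // 2 - com))
    else:
        shift = 0
    aligned = np.roll(canvas, shift, axis=1)
    offsets = np.full(len(rows), shift)
    return Kymograph(data=aligned, offsets=offsets,
                     pixel_size=pixel_size, frame_interval=frame_interval)
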