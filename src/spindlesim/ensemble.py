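"""Batch execution of spindle simulations: ensembles, parameter scans
and simulated kymographs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import SimParams
from .simulation import LEFT, Trajectory, run_simulation

__all__ = ["EnsembleSummary", "ScanResult", "run_ensemble",
           "scan_parameter", "render_sim_kymograph", "SCAN_RANGES"]

#: uniform sampling ranges used when a parameter is scanned
SCAN_RANGES: dict[str, tuple[float, float]] = {
    "R": (1.0, 120.0),
    "v_p": (0.35, 1.5),
}


@dataclass
class EnsembleSummary:
    """Aggregate outcome of ``n_runs`` independent seeded simulations."""

    params: SimParams
    n_runs: int
    seeds: list[int]
    collapse_fraction: float
    collapse_lengths: list[float]
    #: (time grid, mean surviving microtubule count among runs still alive)
    mt_count_times: np.ndarray
    mt_count_mean: np.ndarray
    #: pooled (spindle length, total polymer) samples across runs
    polymer_vs_length: tuple[np.ndarray, np.ndarray]
    trajectories: list[Trajectory] | None = None

    def mean_mt_count_at(self, t: float) -> float:
        i = int(np.argmin(np.abs(self.mt_count_times - t)))
        return float(self.mt_count_mean[i])


@dataclass
class ScanResult:
    parameter: str
    values: np.ndarray
    summaries: list[EnsembleSummary] = field(default_factory=list)

    @property
    def collapse_fractions(self) -> np.ndarray:
        return np.array([s.collapse_fraction for s in self.summaries])


def run_ensemble(params: SimParams, n_runs: int, seed: int,
                 keep_trajectories: bool = False,
                 record_interval: float = 0.1) -> EnsembleSummary:
    """Run ``n_runs`` independent simulations with per-run seeds
    ``seed + i`` and aggregate collapse statistics, mean microtubule
    count versus time (over surviving runs) and pooled polymer-mass
    versus spindle-length samples."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = [seed + i for i in range(n_runs)]
    trajs = [run_simulation(params, s, record_interval) for s in seeds]

    collapse_lengths = [t.collapse_length for t in trajs if t.collapsed]
    grid = np.arange(0.0, params.t_max + record_interval / 2, record_interval)
    counts = np.full((n_runs, grid.size), np.nan)
    for i, tr in enumerate(trajs):
        n_tot = tr.n_left + tr.n_right
        idx = np.searchsorted(grid, tr.times - 1e-9)
        counts[i, idx[idx < grid.size]] = n_tot[idx < grid.size]
    import warnings
    with warnings.catch_warnings():
        # all-collapsed time points legitimately have no surviving run
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_counts = np.nanmean(counts, axis=0)

    S_all = np.concatenate([t.spindle_length for t in trajs])
    P_all = np.concatenate([t.polymer for t in trajs])
    return EnsembleSummary(
        params=params, n_runs=n_runs, seeds=seeds,
        collapse_fraction=len(collapse_lengths) / n_runs,
        collapse_lengths=collapse_lengths,
        mt_count_times=grid, mt_count_mean=mean_counts,
        polymer_vs_length=(S_all, P_all),
        trajectories=trajs if keep_trajectories else None,
    )


def scan_parameter(name: str, n_points: int, n_runs_per_point: int,
                   seed: int, params: SimParams | None = None,
                   grid: np.ndarray | None = None) -> ScanResult:
    """Collapse-probability curve along one scanned parameter.

    Values are drawn uniformly from the parameter's scan range
    (R: 1–120 µm/min, v_p: 0.35–1.5 µm/min) unless an explicit ``grid``
    is supplied; each value gets an independent ensemble.
    """
    if name not in SCAN_RANGES:
        raise ValueError(f"unknown scan parameter {name!r}; "
                         f"scannable: {sorted(SCAN_RANGES)}")
    params = params or SimParams()
    rng = np.random.default_rng(seed)
    if grid is None:
        lo, hi = SCAN_RANGES[name]
        values = np.sort(rng.uniform(lo, hi, size=n_points))
    else:
        values = np.asarray(grid, dtype=float)
    result = ScanResult(parameter=name, values=values)
    for i, v in enumerate(values):
        p = params.with_(**{name: float(v)})
        result.summaries.append(
            run_ensemble(p, n_runs_per_point, seed=seed + 10_000 * (i + 1)))
    return result


def render_sim_kymograph(traj: Trajectory, space_resolution: float = 0.11,
                         time_resolution: float | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise a simulated spindle into a kymograph.

    Time runs down the vertical axis, space along the horizontal with
    the spindle centre at the middle column. Returns ``(intensity,
    labels)`` arrays of shape ``(n_times, n_cols)``: intensity is 1 on
    any trace, 0 elsewhere; labels distinguish pole traces (1) from
    plus-end traces of left- (2) and right- (3) pole microtubules, so
    tips can be colour coded by orientation.
    """
    times = traj.times
    if time_resolution is not None:
        grid = np.arange(times[0], times[-1] + time_resolution / 2,
                         time_resolution)
        sel = np.searchsorted(times, grid - 1e-9).clip(0, times.size - 1)
    else:
        sel = np.arange(times.size)
    S_final = float(traj.spindle_length.max())
    n_cols = int(np.ceil(S_final / space_resolution)) + 1
    centre = n_cols // 2
    intensity = np.zeros((sel.size, n_cols))
    labels = np.zeros((sel.size, n_cols), dtype=np.uint8)

    def col(x: float) -> int | None:
        c = centre + int(round(x / space_resolution))
        return c if 0 <= c < n_cols else None

    for row, i in enumerate(sel):
        S = traj.spindle_length[i]
        for x in (-S / 2.0, S / 2.0):
            c = col(x)
            if c is not None:
                intensity[row, c] = 1.0
                labels[row, c] = 1
        for _mt_id, pole, length, _state in traj.mt_snapshots[i]:
            tip = (-S / 2.0 + length) if pole == LEFT else (S / 2.0 - length)
            c = col(tip)
            if c is not None:
                intensity[row, c] = 1.0
                labels[row, c] = 2 if pole == LEFT else 3
    return intensity, labels
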