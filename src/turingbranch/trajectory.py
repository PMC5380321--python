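"""Differentiation trajectories in the (S, Y) plane.

During a branching run each cell traces a path in (S, Y) space as the
substrate around it is consumed and its differentiation state rises.  The
path of a cell differentiating at a growing tip crosses the Turing region,
and the crossing point supplies the frozen (S, Y) parameters for the
decoupled activator-inhibitor simulation.

The differentiation transition is fast compared to practical snapshot
cadences, so the SY-curve is treated as a curve: membership tests resample
it by linear interpolation between snapshots before evaluating the Turing
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import AIContext
from .simulate import SimResult
from .stability import TuringRegionMap, turing_conditions

__all__ = [
    "DifferentiationTrajectory",
    "TrajectoryError",
    "NoDifferentiationError",
    "TrajectoryMissesRegionError",
    "candidate_tip_cells",
    "extract_trajectory",
    "mark_crossings",
    "select_turing_state",
]


class TrajectoryError(RuntimeError):
    pass


class NoDifferentiationError(TrajectoryError):
    """No cell crossed the differentiation threshold."""


class TrajectoryMissesRegionError(TrajectoryError):
    """The trajectory never enters the Turing region."""


@dataclass
class DifferentiationTrajectory:
    """(S, Y) time series of one tracked cell.

    ``crossings`` lists (start_index, end_index) of maximal sub-intervals
    lying inside a Turing region (filled by :func:`mark_crossings`).
    """

    times: np.ndarray
    S_values: np.ndarray
    Y_values: np.ndarray
    cell_index: tuple[int, int]
    crossings: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.S_values) == len(self.Y_values)):
            raise ValueError("times, S_values, Y_values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def resample(self, factor: int) -> "DifferentiationTrajectory":
        """Linearly interpolated copy with ``factor`` times denser sampling."""
        if factor <= 1:
            return replace(self, crossings=[])
        tf = np.linspace(self.times[0], self.times[-1],
                         (len(self.times) - 1) * factor + 1)
        return DifferentiationTrajectory(
            tf, np.interp(tf, self.times, self.S_values),
            np.interp(tf, self.times, self.Y_values), self.cell_index)


def candidate_tip_cells(sim: SimResult, *, threshold_frac: float = 0.5,
                        wall_margin: int = 6) -> tuple[list[tuple[int, int]], int]:
    """Cells differentiating at an advancing front in the second half of a run.

    Returns (cells, snapshot_index): the first snapshot of the second half
    in which cells at least ``wall_margin`` pixels from the walls newly
    cross ``threshold_frac * max(final Y)``, and all such cells.  Wall-
    adjacent cells are excluded because the zero-flux boundary distorts
    their substrate history.
    """
    snaps = sim.snapshots
    if len(snaps) < 10:
        raise TrajectoryError(f"need >= 10 snapshots, got {len(snaps)}")
    y_final_max = snaps[-1].Y.max()
    if y_final_max <= 0:
        raise NoDifferentiationError("Y is identically zero")
    thr = threshold_frac * y_final_max
    ny, nx = snaps[0].Y.shape
    m = wall_margin
    half = len(snaps) // 2
    crossed = np.zeros((ny, nx), dtype=bool)
    for s in snaps[: half + 1]:
        crossed |= s.Y > thr
    for j in range(half + 1, len(snaps)):
        newly = (snaps[j].Y > thr) & (snaps[j - 1].Y <= thr) & ~crossed
        cells = [(int(r), int(c)) for r, c in np.argwhere(newly)
                 if m <= r < ny - m and m <= c < nx - m]
        if cells:
            return cells, j
        crossed |= snaps[j].Y > thr
    raise NoDifferentiationError(
        "no interior cell crossed the differentiation threshold in the second half"
    )


def _transition_length(Y_series: np.ndarray, lo: float = 0.05, hi: float = 0.6) -> int:
    return int(((Y_series > lo) & (Y_series < hi)).sum())


def _series_for(sim: SimResult, cell: tuple[int, int]):
    times = np.array([s.t for s in sim.snapshots])
    S = np.array([s.S[cell] for s in sim.snapshots])
    Y = np.array([s.Y[cell] for s in sim.snapshots])
    return times, S, Y


def extract_trajectory(sim: SimResult, selection: str | tuple[int, int] = "tip-cell",
                       *, threshold_frac: float = 0.5, wall_margin: int = 6,
                       region: TuringRegionMap | None = None
                       ) -> DifferentiationTrajectory:
    """Pick a differentiating cell from a branching run and read off (S, Y).

    The default ``"tip-cell"`` rule considers the first cohort of interior
    cells whose Y crosses ``threshold_frac * max(final Y)`` during the
    second half of the run (cells differentiating at a front that is still
    advancing once the pattern is established) and tracks the one with the
    slowest transition, whose SY-curve is best resolved by the snapshot
    cadence.  If ``region`` is given, cells whose (resampled) curve passes
    through more region nodes are preferred.  Explicit grid coordinates
    override the rule.

    Raises
    ------
    NoDifferentiationError
        If no cell crosses the threshold (e.g. an unseeded run).
    """
    if isinstance(selection, tuple):
        cell = selection
    else:
        if selection != "tip-cell":
            raise ValueError(f"unknown selection rule {selection!r}")
        cells, _ = candidate_tip_cells(sim, threshold_frac=threshold_frac,
                                       wall_margin=wall_margin)

        def mask_hits(c: tuple[int, int]) -> int:
            # advisory nearest-node mask lookup, cheap cohort ranking only
            t, S, Y = _series_for(sim, c)
            tf = np.linspace(t[0], t[-1], (len(t) - 1) * 20 + 1)
            Sf, Yf = np.interp(tf, t, S), np.interp(tf, t, Y)
            js = np.clip(np.searchsorted(region.S_axis, Sf), 0, len(region.S_axis) - 1)
            iy = np.clip(np.searchsorted(region.Y_axis, Yf), 0, len(region.Y_axis) - 1)
            return int(region.mask[iy, js].sum())

        if region is not None:
            cell = max(cells, key=lambda c: (mask_hits(c),
                                             _transition_length(_series_for(sim, c)[2])))
        else:
            cell = max(cells, key=lambda c: _transition_length(_series_for(sim, c)[2]))
    times, S_values, Y_values = _series_for(sim, cell)
    return DifferentiationTrajectory(times, S_values, Y_values, tuple(cell))


def mark_crossings(traj: DifferentiationTrajectory, region: TuringRegionMap,
                   *, resample_factor: int = 20) -> DifferentiationTrajectory:
    """Resample the SY-curve and mark its maximal in-region sub-intervals.

    Membership is decided by exact re-evaluation of the Turing conditions at
    each resampled (S, Y) point; the discrete mask is advisory only.
    Returns the resampled trajectory with ``crossings`` filled.
    """
    traj = traj.resample(resample_factor)
    inside = np.array([region.contains(float(s), float(y))
                       for s, y in zip(traj.S_values, traj.Y_values)])
    crossings: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(inside):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            crossings.append((start, i - 1))
            start = None
    if start is not None:
        crossings.append((start, len(inside) - 1))
    traj.crossings = crossings
    return traj


def select_turing_state(traj: DifferentiationTrajectory, region: TuringRegionMap,
                        rule: str | tuple[float, float] = "crossing-midpoint"
                        ) -> AIContext:
    """Choose an in-region (S, Y) point on the trajectory.

    The default rule takes the midpoint (by index) of the longest in-region
    crossing of the resampled curve.  An explicit ``(S, Y)`` pair overrides
    the rule — used to inject externally chosen states — but is still
    checked for membership.

    Raises
    ------
    TrajectoryMissesRegionError
        If the trajectory has no in-region point (or the explicit override
        is outside the region).
    """
    if isinstance(rule, tuple):
        S, Y = float(rule[0]), float(rule[1])
        ctx = AIContext(region.params, S, Y)
        if not turing_conditions(ctx).overall:
            raise TrajectoryMissesRegionError(f"override point ({S}, {Y}) is outside the region")
        return ctx
    if rule != "crossing-midpoint":
        raise ValueError(f"unknown selection rule {rule!r}")
    if not traj.crossings:
        traj = mark_crossings(traj, region)
    if not traj.crossings:
        raise TrajectoryMissesRegionError("trajectory never enters the Turing region")
    start, end = max(traj.crossings, key=lambda c: c[1] - c[0])
    mid = (start + end) // 2
    return AIContext(region.params, float(traj.S_values[mid]), float(traj.Y_values[mid]))
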