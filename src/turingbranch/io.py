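"""Disk formats: HDF5 snapshot stacks, CSV tables, PNG renders."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .params import ModelParams
from .simulate import FieldState, GridSpec, SimResult
from .stability import DispersionCurve, TuringRegionMap
from .trajectory import DifferentiationTrajectory

__all__ = [
    "save_simresult",
    "load_simresult",
    "save_region_csv",
    "load_region_csv",
    "save_dispersion_csv",
    "save_trajectory_csv",
    "render_field",
    "render_region_overlay",
]

_FIELDS = ("A", "H", "S", "Y")


def save_simresult(sim: SimResult, path: str | Path) -> None:
    """One HDF5 group per snapshot (datasets A/H/S/Y, attribute t)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["converged"] = sim.converged
        fh.attrs["steps_taken"] = sim.steps_taken
        if sim.grid is not None:
            fh.attrs["nx"], fh.attrs["ny"] = sim.grid.nx, sim.grid.ny
            fh.attrs["dx"] = sim.grid.dx
            fh.attrs["boundary"] = sim.grid.boundary
        if sim.params is not None:
            for key, val in sim.params.to_dict().items():
                fh.attrs[f"param_{key}"] = val
        grp = fh.create_group("final")
        grp.attrs["t"] = sim.final.t
        for name in _FIELDS:
            grp.create_dataset(name, data=getattr(sim.final, name))
        for i, snap in enumerate(sim.snapshots):
            grp = fh.create_group(f"snapshot_{i:05d}")
            grp.attrs["t"] = snap.t
            for name in _FIELDS:
                grp.create_dataset(name, data=getattr(snap, name))


def _read_state(grp: h5py.Group) -> FieldState:
    return FieldState(*(np.asarray(grp[name]) for name in _FIELDS), t=float(grp.attrs["t"]))


def load_simresult(path: str | Path) -> SimResult:
    with h5py.File(path, "r") as fh:
        grid = None
        if "nx" in fh.attrs:
            grid = GridSpec(int(fh.attrs["nx"]), int(fh.attrs["ny"]),
                            float(fh.attrs["dx"]), str(fh.attrs["boundary"]))
        params = None
        pkeys = {k[6:]: float(v) for k, v in fh.attrs.items() if k.startswith("param_")}
        if pkeys:
            params = ModelParams(**pkeys)
        snaps = [_read_state(fh[k]) for k in sorted(fh) if k.startswith("snapshot_")]
        return SimResult(final=_read_state(fh["final"]), snapshots=snaps,
                         converged=bool(fh.attrs["converged"]),
                         steps_taken=int(fh.attrs["steps_taken"]),
                         grid=grid, params=params)


def save_region_csv(region: TuringRegionMap, path: str | Path) -> None:
    """Mask as CSV: first row S axis, first column Y axis, body 0/1."""
    body = np.column_stack([region.Y_axis, region.mask.astype(int)])
    header = "Y\\S," + ",".join(f"{s:.6g}" for s in region.S_axis)
    np.savetxt(path, body, delimiter=",", header=header, comments="",
               fmt=["%.6g"] + ["%d"] * len(region.S_axis))


def load_region_csv(path: str | Path, params: ModelParams) -> TuringRegionMap:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    S_axis = np.array([float(x) for x in header[1:]])
    body = np.loadtxt(path, delimiter=",", skiprows=1)
    return TuringRegionMap(S_axis, body[:, 0], body[:, 1:].astype(bool), params)


def save_dispersion_csv(curve: DispersionCurve, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([curve.k_values, curve.re_lambda_max]),
               delimiter=",", header="k,re_lambda", comments="")


def save_trajectory_csv(traj: DifferentiationTrajectory, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([traj.times, traj.S_values, traj.Y_values]),
               delimiter=",", header="t,S,Y", comments="")


def render_field(fieldarr: np.ndarray, path: str | Path, *, title: str = "") -> None:
    """Grayscale render; black marks high concentration, gray low."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(fieldarr, origin="lower", cmap="gray_r", interpolation="nearest")
    ax.set_axis_off()
    if title:
        ax.set_title(title, fontsize=9)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def render_region_overlay(region: TuringRegionMap, path: str | Path,
                          traj: DifferentiationTrajectory | None = None,
                          points: list[tuple[float, float]] | None = None) -> None:
    """Turing-region heatmap with an optional (S, Y) trajectory overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.pcolormesh(region.S_axis, region.Y_axis, region.mask.astype(float),
                  cmap="Greys", shading="auto", vmin=0, vmax=1.6)
    if traj is not None:
        ax.plot(traj.S_values, traj.Y_values, color="green", lw=1.5, label="trajectory")
        ax.legend(loc="upper left", fontsize=8)
    if points:
        ax.plot([p[0] for p in points], [p[1] for p in points], "r.", ms=8)
    ax.set_xlabel("S")
    ax.set_ylabel("Y")
    ax.set_title(f"Turing region (rho_H = {region.rho_H:g})", fontsize=9)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
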