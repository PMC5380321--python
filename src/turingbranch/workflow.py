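"""End-to-end orchestration: recipes, sweeps and figure-style outputs.

A recipe bundles a parameter sweep (over epsilon or rho_H) with the run
controls and any externally injected (S, Y) states.  :func:`run_workflow`
executes the four-step scheme per sweep value — branching simulation,
trajectory extraction, Turing-region overlay, state selection, AI
simulation, pattern metrics — recording every artifact in a JSON manifest;
stage failures are recorded and the run continues.  Bundled recipes encode
the published sweep lists and (S, Y) pairs.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as tbio
from .kinetics import AIContext
from .metrics import classify_branch_events, summarize_pattern
from .params import ModelParams, default_params
from .simulate import GridSpec, RunControls, simulate_ai, simulate_branching
from .stability import dispersion, scan_turing_region, wavelength_series
from .trajectory import extract_trajectory, mark_crossings, select_turing_state

__all__ = ["ExperimentRecipe", "BUILTIN_RECIPES", "FIGURE_TAGS",
           "run_workflow", "reproduce_figure"]

# Printed (S, Y) anchors, in sweep order (epsilon descending).
_PAIRS_TIP = [(0.320, 0.185), (0.352, 0.248), (0.395, 0.313)]
_PAIRS_SIDE = [(0.614, 0.478), (0.679, 0.510), (0.716, 0.530)]
_FIVE_RHO_H = [0.00005, 0.00007, 0.0001, 0.00013, 0.00015]


@dataclass(frozen=True)
class ExperimentRecipe:
    """A named parameter sweep with optional injected (S, Y) states."""

    name: str
    sweep_variable: str = "epsilon"  # "epsilon" | "rho_H"
    sweep_values: tuple[float, ...] = ()
    overrides: dict = field(default_factory=dict)
    injected_states: tuple[tuple[float, float] | None, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sweep_variable not in ("epsilon", "rho_H"):
            raise ValueError(f"unknown sweep variable {self.sweep_variable!r}")
        for v in self.sweep_values:
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"sweep values must be finite and positive, got {v}")
        if self.injected_states and len(self.injected_states) != len(self.sweep_values):
            raise ValueError("injected_states must match sweep_values in length")

    def params_for(self, value: float) -> ModelParams:
        return default_params(**{**self.overrides, self.sweep_variable: value})


BUILTIN_RECIPES: dict[str, ExperimentRecipe] = {
    "fig2": ExperimentRecipe("fig2", "epsilon", (1.0, 0.06),
                             injected_states=((0.352, 0.248), (0.679, 0.510))),
    "fig4": ExperimentRecipe("fig4", "epsilon", (1.5, 1.0, 0.7),
                             injected_states=tuple(_PAIRS_TIP)),
    "fig5": ExperimentRecipe("fig5", "epsilon", (0.1, 0.06, 0.045),
                             injected_states=tuple(_PAIRS_SIDE)),
    "fig7": ExperimentRecipe("fig7", "rho_H", tuple(_FIVE_RHO_H)),
    "fig8": ExperimentRecipe("fig8", "epsilon", (3.0, 2.0, 1.0, 0.5, 0.1, 0.06, 0.045),
                             overrides={"rho_H": 0.00005}),
    "fig9": ExperimentRecipe("fig9", "epsilon", (1.5, 1.2, 0.9, 0.45, 0.1, 0.06, 0.045),
                             overrides={"rho_H": 0.00007}),
    "fig10": ExperimentRecipe("fig10", "epsilon", (1.1, 0.85, 0.7, 0.07, 0.06, 0.045),
                              overrides={"rho_H": 0.00013}),
    "fig11": ExperimentRecipe("fig11", "epsilon", (0.9, 0.8, 0.65, 0.07, 0.06, 0.045),
                              overrides={"rho_H": 0.00015}),
}

FIGURE_TAGS = ("fig2", "fig4", "fig5", "fig6", "fig7", "fig8", "fig9", "fig10", "fig11")


def _branch_run_length(eps: float, reduced: bool) -> float:
    # slower fronts at weak substrate consumption need longer runs
    base = 2400.0 if eps >= 0.3 else 6000.0
    return base if reduced else 2.5 * base


def _branch_grid(reduced: bool) -> GridSpec:
    n = 96 if reduced else 200
    return GridSpec(nx=n, ny=n, dx=0.5, boundary="zero-flux")


def _ai_grid(reduced: bool) -> GridSpec:
    n = 128 if reduced else 200
    return GridSpec(nx=n, ny=n, dx=1.0, boundary="periodic")


def _ai_controls(reduced: bool) -> RunControls:
    return RunControls(max_steps=80_000 if reduced else 500_000)


class _Manifest:
    def __init__(self, path: Path, name: str):
        self.path = path
        self.data = {"name": name, "entries": []}
        if path.exists():
            self.data = json.loads(path.read_text())

    def save(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=2))

    def done(self, stage: str, value: float) -> bool:
        for e in self.data["entries"]:
            if e["stage"] == stage and e["sweep_value"] == value and e["status"] == "ok":
                artifact = e.get("artifact")
                if artifact is None or Path(artifact).exists():
                    return True
        return False

    def record(self, stage: str, value: float, status: str, *,
               artifact: str | None = None, seed: int | None = None,
               params: dict | None = None, error: str | None = None,
               extra: dict | None = None) -> None:
        self.data["entries"].append({
            "stage": stage, "sweep_value": value, "status": status,
            "artifact": artifact, "seed": seed, "params": params,
            "error": error, **(extra or {}),
        })
        self.path.write_text(json.dumps(self.data, indent=2))


def run_workflow(recipe: ExperimentRecipe, out_dir: str | Path, *,
                 reduced: bool = True) -> dict:
    """Run the four-step scheme for every sweep value of a recipe.

    Stages per value: branching simulation -> branch-event classification ->
    trajectory -> Turing region -> (S, Y) selection (injected state if the
    recipe carries one) -> AI simulation -> pattern summary -> dispersion.
    Per-stage failures are recorded in the manifest and downstream stages of
    that sweep value are skipped; completed stages with surviving artifacts
    are not recomputed on resume.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json", recipe.name)
    manifest.save()

    if recipe.sweep_variable == "rho_H":
        # region-scan sweep: one Turing region per rho_H value
        for value in recipe.sweep_values:
            if manifest.done("region", value):
                continue
            params = recipe.params_for(value)
            try:
                region = scan_turing_region(params, resolution=120 if reduced else 200)
                path = out / f"region_rhoH_{value:g}.csv"
                tbio.save_region_csv(region, path)
                tbio.render_region_overlay(region, out / f"region_rhoH_{value:g}.png")
                manifest.record("region", value, "ok", artifact=str(path),
                                params=params.to_dict(),
                                extra={"area_fraction": region.area_fraction,
                                       "n_components": region.n_components()})
            except Exception as exc:
                manifest.record("region", value, "failed", error=_fmt_exc(exc))
        return manifest.data

    for idx, value in enumerate(recipe.sweep_values):
        params = recipe.params_for(value)
        injected = recipe.injected_states[idx] if recipe.injected_states else None
        tag = f"{recipe.sweep_variable}_{value:g}"
        sim = None
        try:
            if not manifest.done("branching", value):
                sim = simulate_branching(params, _branch_grid(reduced),
                                         run_length=_branch_run_length(value, reduced),
                                         rng_seed=recipe.rng_seed)
                path = out / f"branching_{tag}.h5"
                tbio.save_simresult(sim, path)
                tbio.render_field(sim.final.Y, out / f"branching_{tag}.png",
                                  title=f"Y, {tag}")
                report = classify_branch_events(sim)
                manifest.record("branching", value, "ok", artifact=str(path),
                                seed=recipe.rng_seed, params=params.to_dict(),
                                extra={"overall_mode": report.overall_mode,
                                       "n_events": len(report.events)})
            else:
                sim = tbio.load_simresult(out / f"branching_{tag}.h5")
        except Exception as exc:
            manifest.record("branching", value, "failed", error=_fmt_exc(exc))
            continue

        try:
            region = scan_turing_region(params, resolution=120 if reduced else 200)
            traj = mark_crossings(extract_trajectory(sim, region=region), region)
            traj_path = out / f"trajectory_{tag}.csv"
            tbio.save_trajectory_csv(traj, traj_path)
            tbio.render_region_overlay(region, out / f"overlay_{tag}.png", traj=traj,
                                       points=[injected] if injected else None)
            ctx = select_turing_state(traj, region, rule=injected or "crossing-midpoint")
            manifest.record("trajectory", value, "ok", artifact=str(traj_path),
                            extra={"selected_S": ctx.S, "selected_Y": ctx.Y})
        except Exception as exc:
            manifest.record("trajectory", value, "failed", error=_fmt_exc(exc))
            continue

        try:
            ai = simulate_ai(ctx, _ai_grid(reduced), run_controls=_ai_controls(reduced),
                             rng_seed=recipe.rng_seed)
            ai_path = out / f"turing_{tag}.h5"
            tbio.save_simresult(ai, ai_path)
            tbio.render_field(ai.final.A, out / f"turing_{tag}.png", title=f"A, {tag}")
            summary = summarize_pattern(ai.final.A, ai.grid)
            curve = dispersion(ctx)
            manifest.record("turing_pattern", value, "ok", artifact=str(ai_path),
                            seed=recipe.rng_seed,
                            extra={"pattern": summary.to_dict(),
                                   "converged": ai.converged,
                                   "k_critical": curve.k_critical,
                                   "wavelength": curve.wavelength})
        except Exception as exc:
            manifest.record("turing_pattern", value, "failed", error=_fmt_exc(exc))
    return manifest.data


def _fmt_exc(exc: Exception) -> str:
    return "".join(traceback.format_exception_only(type(exc), exc)).strip()


def reproduce_figure(tag: str, out_dir: str | Path, *, reduced: bool = True) -> dict:
    """Re-run the computation behind a published figure panel set.

    Emits the figure-style images plus a CSV of computed metrics
    (wavelengths, spot counts, mode labels); returns a summary dict.
    Unknown tags raise with the list of valid ones.
    """
    if tag not in FIGURE_TAGS:
        raise ValueError(f"unknown figure tag {tag!r}; valid tags: {', '.join(FIGURE_TAGS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if tag == "fig6":
        params = default_params()
        pairs = _PAIRS_TIP + _PAIRS_SIDE
        ctxs = [AIContext(params, S, Y) for S, Y in pairs]
        series = wavelength_series(ctxs)
        rows = ["S,Y,wavelength,k_critical"]
        for (S, Y), (wl, _) in zip(pairs, series):
            rows.append(f"{S},{Y},{wl:.6g},{2*np.pi/wl:.6g}")
        (out / "wavelengths.csv").write_text("\n".join(rows) + "\n")
        _plot_dispersions(ctxs, out / "dispersion.png")
        return {"tag": tag, "wavelengths": [wl for wl, _ in series]}

    manifest = run_workflow(BUILTIN_RECIPES[tag], out, reduced=reduced)
    rows = ["sweep_value,stage,overall_mode,n_spots,pattern_class,wavelength"]
    per_value: dict[float, dict] = {}
    for e in manifest["entries"]:
        d = per_value.setdefault(e["sweep_value"], {})
        if e["stage"] == "branching" and e["status"] == "ok":
            d["overall_mode"] = e.get("overall_mode")
        if e["stage"] == "turing_pattern" and e["status"] == "ok":
            d["n_spots"] = e["pattern"]["n_spots"]
            d["pattern_class"] = e["pattern"]["pattern_class"]
            d["wavelength"] = e.get("wavelength")
        if e["stage"] == "region" and e["status"] == "ok":
            d["area_fraction"] = e.get("area_fraction")
    for value, d in per_value.items():
        rows.append(f"{value},summary,{d.get('overall_mode','')},{d.get('n_spots','')},"
                    f"{d.get('pattern_class','')},{d.get('wavelength','')}")
    (out / "metrics.csv").write_text("\n".join(rows) + "\n")
    return {"tag": tag, "manifest": manifest, "summary": per_value}


def _plot_dispersions(ctxs: list[AIContext], path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for i, ctx in enumerate(ctxs):
        curve = dispersion(ctx)
        color = "green" if i < 3 else "orange"
        ax.plot(curve.k_values, curve.re_lambda_max, color=color,
                label=f"S={ctx.S}, Y={ctx.Y}")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlim(0, 1.6)
    ax.set_ylim(-0.02, 0.012)
    ax.set_xlabel("wavenumber k")
    ax.set_ylabel("Re lambda")
    ax.legend(fontsize=7)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
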