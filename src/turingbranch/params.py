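"""Model parameters for the four-variable branching model.

The model couples an activator ``A``, a fast-diffusing inhibitor ``H``, a
depletable substrate ``S`` and a bistable cell-differentiation state ``Y``.
All rates and diffusion coefficients are dimensionless; the default values
are the reference parameter set used throughout the package.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["ModelParams", "load_params", "save_params", "default_params"]

# Symbol names accepted in config files, in canonical order.
_FIELD_NAMES = (
    "c", "mu", "rho_A", "D_A", "v", "rho_H", "D_H",
    "c0", "gamma", "epsilon", "D_S", "d", "e", "f", "kappa",
)


@dataclass(frozen=True)
class ModelParams:
    """Kinetic and transport constants of the branching model.

    Parameters
    ----------
    c : autocatalysis rate of the activator (term ``c A^2 S / H``).
    mu : activator linear decay rate.
    rho_A : activator secretion rate by differentiated cells.
    D_A : activator diffusion coefficient.
    v : inhibitor linear decay rate.
    rho_H : inhibitor secretion rate by differentiated cells.
    D_H : inhibitor diffusion coefficient (must exceed ``D_A`` for a
        lateral-inhibition instability to be possible).
    c0 : substrate production rate.
    gamma : substrate linear decay rate.
    epsilon : substrate consumption rate by differentiated cells.
    D_S : substrate diffusion coefficient.
    d : differentiation induction rate (``d A`` drives ``Y`` upward).
    e : differentiation-state decay rate.
    f : saturation constant of the ``Y^2 / (1 + f Y^2)`` self-activation.
    kappa : optional saturation constant of activator production; with
        ``kappa > 0`` the autocatalytic ``A^2`` is replaced by
        ``A^2 / (1 + kappa A^2)``, which moves the pattern repertoire from
        spots toward stripes and holes. Defaults to 0 (no saturation).
    """

    c: float = 0.002
    mu: float = 0.16
    rho_A: float = 0.03
    D_A: float = 0.02
    v: float = 0.04
    rho_H: float = 0.0001
    D_H: float = 0.3
    c0: float = 0.02
    gamma: float = 0.02
    epsilon: float = 1.0
    D_S: float = 0.06
    d: float = 0.008
    e: float = 0.1
    f: float = 10.0
    kappa: float = 0.0

    def __post_init__(self) -> None:
        for name in _FIELD_NAMES:
            value = getattr(self, name)
            if not (value >= 0.0):
                raise ValueError(f"parameter {name!r} must be nonnegative, got {value!r}")
        if self.D_A <= 0 or self.D_H <= 0:
            raise ValueError("D_A and D_H must be strictly positive")

    def replace(self, **kwargs: float) -> "ModelParams":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in _FIELD_NAMES}


def default_params(**overrides: float) -> ModelParams:
    """The reference parameter set, with optional field overrides."""
    return ModelParams(**overrides)


def load_params(path: str | Path) -> ModelParams:
    """Read parameters from a YAML or JSON config, one key per symbol.

    Unknown keys raise; missing keys fall back to the defaults.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must map parameter names to numbers")
    unknown = set(data) - set(_FIELD_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter name(s) in {path}: {sorted(unknown)}")
    return ModelParams(**{k: float(v) for k, v in data.items()})


def save_params(params: ModelParams, path: str | Path) -> None:
    path = Path(path)
    data = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def bundled_default_config() -> str:
    """Path-like access to the bundled default parameter file."""
    return str(resources.files("turingbranch").joinpath("data/default_params.yaml"))
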